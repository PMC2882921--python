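"""Gene/probe-set catalog: loading, validation and counting.

The catalog records which myeloma growth factors (MGF) and MGF receptors are
interrogable on the HG-U133 Plus 2.0 array.  Three transcriptions ship with
the package:

* ``table1a`` -- the 32 growth factors reported as myeloma growth factors in
  the literature; five of them also belong to the systematically screened
  VEGF/FGF/Wnt families and carry an ``also_family`` mark.
* ``table1b`` -- the complete VEGF (4), FGF (22) and Wnt (19) ligand families.
* ``table2``  -- the 48 candidate MGF receptors, with the published per-gene
  median/range/presence summary over 131 purified tumor-cell samples.

An empty ``probe_sets`` cell reproduces the published "NA" convention, which
covers both "no probe set on the array" and "no informative probe set";
only interrogability matters downstream, so the two are not distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

FAMILIES = ("KNOWN_MGF", "VEGF", "FGF", "WNT", "EGF", "TNF", "IL6_FAMILY", "OTHER")
ROLES = ("LIGAND", "RECEPTOR")


def _data_path(name: str):
    return resources.files("mgfscreen").joinpath("data").joinpath(name)


@dataclass(frozen=True)
class GeneEntry:
    """One catalog row: a gene, its family/role and candidate probe sets."""

    gene_symbol: str
    family: str
    role: str
    probe_sets: tuple[str, ...] = ()
    receptor_of: Optional[str] = None
    also_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family token {self.family!r} for gene {self.gene_symbol}"
            )
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role token {self.role!r} for gene {self.gene_symbol}"
            )

    @property
    def interrogable(self) -> bool:
        """True iff at least one candidate probe set exists."""
        return len(self.probe_sets) > 0


@dataclass(frozen=True)
class GeneCatalog:
    """Validated, symbol-unique collection of :class:`GeneEntry` rows."""

    entries: tuple[GeneEntry, ...]
    _by_symbol: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_symbol: dict[str, GeneEntry] = {}
        for entry in self.entries:
            if entry.gene_symbol in by_symbol:
                raise ValueError(f"duplicate gene symbol: {entry.gene_symbol}")
            by_symbol[entry.gene_symbol] = entry
        for entry in self.entries:
            if entry.receptor_of is not None:
                target = by_symbol.get(entry.receptor_of)
                if target is None:
                    raise ValueError(
                        f"receptor_of target {entry.receptor_of!r} of "
                        f"{entry.gene_symbol} is not in the catalog"
                    )
                if target.role != "LIGAND":
                    raise ValueError(
                        f"receptor_of target {entry.receptor_of!r} of "
                        f"{entry.gene_symbol} is not a LIGAND"
                    )
        object.__setattr__(self, "_by_symbol", by_symbol)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GeneEntry]:
        return iter(self.entries)

    def get(self, gene_symbol: str) -> GeneEntry:
        try:
            return self._by_symbol[gene_symbol]
        except KeyError:
            raise KeyError(f"gene {gene_symbol!r} not in catalog") from None

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self._by_symbol

    def entries_for(
        self, family: Optional[str] = None, role: Optional[str] = None
    ) -> tuple[GeneEntry, ...]:
        if family is not None and family not in FAMILIES:
            raise ValueError(f"unknown family token {family!r}")
        if role is not None and role not in ROLES:
            raise ValueError(f"unknown role token {role!r}")
        return tuple(
            e
            for e in self.entries
            if (family is None or e.family == family)
            and (role is None or e.role == role)
        )

    def ligands(self) -> tuple[GeneEntry, ...]:
        return self.entries_for(role="LIGAND")

    def receptors(self) -> tuple[GeneEntry, ...]:
        return self.entries_for(role="RECEPTOR")


def count_interrogable(
    catalog: GeneCatalog,
    family: Optional[str] = None,
    role: Optional[str] = None,
) -> tuple[int, int]:
    """(number interrogable, number listed) for a family/role selection.

    Either filter may be ``None`` to match everything; an empty selection
    yields ``(0, 0)``.
    """
    selected = catalog.entries_for(family=family, role=role)
    return sum(e.interrogable for e in selected), len(selected)


# -- loading -----------------------------------------------------------


def _entries_from_frame(frame: pd.DataFrame, source: str) -> list[GeneEntry]:
    required = {"gene", "family", "role", "probe_sets"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{source}: missing column(s) {sorted(missing)}")
    entries = []
    for row in frame.itertuples(index=False):
        raw = getattr(row, "probe_sets")
        probes = tuple(
            p.strip() for p in str(raw).split(";") if p.strip()
        ) if pd.notna(raw) else ()
        receptor_of = getattr(row, "receptor_of", None)
        receptor_of = None if pd.isna(receptor_of) or receptor_of == "" else str(receptor_of)
        also = getattr(row, "also_family", None)
        also = None if pd.isna(also) or also == "" else str(also)
        entries.append(
            GeneEntry(
                gene_symbol=str(row.gene),
                family=str(row.family),
                role=str(row.role),
                probe_sets=probes,
                receptor_of=receptor_of,
                also_family=also,
            )
        )
    return entries


def load_catalog(path: str | Path) -> GeneCatalog:
    """Load and validate a CSV catalog.

    Expected columns: ``gene, family, role, probe_sets`` (semicolon-separated,
    empty allowed) and optional ``receptor_of`` / ``also_family``.
    """
    frame = pd.read_csv(path, dtype=str)
    return GeneCatalog(tuple(_entries_from_frame(frame, str(path))))


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    rows = [
        {
            "gene": e.gene_symbol,
            "family": e.family,
            "role": e.role,
            "probe_sets": ";".join(e.probe_sets),
            "receptor_of": e.receptor_of or "",
            "also_family": e.also_family or "",
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- packaged transcriptions -------------------------------------------


def known_mgf_catalog() -> GeneCatalog:
    """The 32 growth factors reported as MGF in the literature."""
    return load_catalog(_data_path("table1a_known_mgf.csv"))


def family_catalog() -> GeneCatalog:
    """The complete VEGF, FGF and Wnt ligand families."""
    return load_catalog(_data_path("table1b_families.csv"))


def mgf_catalog(include_receptors: bool = True) -> GeneCatalog:
    """The merged study catalog.

    Ligands: the known-MGF list with its five family-overlap genes reassigned
    to their VEGF/FGF/Wnt families (so each gene appears once), yielding the
    51 interrogable MGF of the study.  Receptors: the 48 candidate MGF
    receptors, of which 36 are interrogable.
    """
    table1a = pd.read_csv(_data_path("table1a_known_mgf.csv"), dtype=str)
    table1a = table1a[table1a["also_family"].isna()]
    entries = _entries_from_frame(table1a, "table1a")
    entries += _entries_from_frame(
        pd.read_csv(_data_path("table1b_families.csv"), dtype=str), "table1b"
    )
    if include_receptors:
        entries += _entries_from_frame(
            pd.read_csv(_data_path("table2_receptors.csv"), dtype=str), "table2"
        )
    return GeneCatalog(tuple(entries))


# -- receptor expression transcription ---------------------------------


@dataclass(frozen=True)
class ReceptorTableRow:
    """Per-receptor summary over tumor-cell samples.

    ``presence_pct`` is an integer percentage of samples with a present call,
    or ``None`` where the published rendering does not pin the value down.
    """

    gene_symbol: str
    probe_set: Optional[str]
    median_signal: Optional[float]
    signal_range: Optional[tuple[float, float]]
    presence_pct: Optional[int]

    def validate_computed(self) -> None:
        """Invariants for rows the pipeline computed (not for transcriptions)."""
        if self.median_signal is not None and self.signal_range is not None:
            lo, hi = self.signal_range
            if not lo <= self.median_signal <= hi:
                raise ValueError(
                    f"{self.gene_symbol}: median {self.median_signal} outside "
                    f"range ({lo}, {hi})"
                )
        if self.presence_pct is not None and not 0 <= self.presence_pct <= 100:
            raise ValueError(
                f"{self.gene_symbol}: presence_pct {self.presence_pct} not in [0, 100]"
            )


def load_receptor_expression(path: str | Path | None = None) -> list[ReceptorTableRow]:
    """Load the published receptor expression summary (verbatim transcription).

    One printed median (ErbB3) lies outside its printed range; the
    transcription keeps the printed values untouched.
    """
    if path is None:
        path = _data_path("table2_expression.csv")
    frame = pd.read_csv(path)
    rows = []
    for row in frame.itertuples(index=False):
        probe = None if pd.isna(row.probe_set) else str(row.probe_set)
        median = None if pd.isna(row.median) else float(row.median)
        if pd.isna(row.range_min) or pd.isna(row.range_max):
            rng = None
        else:
            rng = (float(row.range_min), float(row.range_max))
        presence = None if pd.isna(row.presence_pct) else int(row.presence_pct)
        rows.append(
            ReceptorTableRow(
                gene_symbol=str(row.gene),
                probe_set=probe,
                median_signal=median,
                signal_range=rng,
                presence_pct=presence,
            )
        )
    return rows
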