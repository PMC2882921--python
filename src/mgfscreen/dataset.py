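"""Expression dataset container and tab-delimited I/O.

A dataset couples a probe-set x sample signal matrix with a probe-set x
sample detection-call matrix (tokens P/M/A as emitted by the array software)
and a per-sample population label.  Matrices are reconciled by identifier,
never by position, so files whose columns are permuted load identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Bone-marrow populations known to the pipeline.
POPULATIONS = ("MB", "PPC", "BMPC", "MMC", "WBM", "CD3", "CD14", "PMN", "BMSC", "OC")

#: Valid detection-call tokens: Present / Marginal / Absent.
CALL_TOKENS = frozenset({"P", "M", "A"})

_SIGNAL_INDEX_LABEL = "probe_set"


def _axis_mismatch(kind: str, left: pd.Index, right: pd.Index) -> str:
    missing = sorted(set(left) - set(right))
    extra = sorted(set(right) - set(left))
    parts = [f"{kind} axes differ between signal and call matrices"]
    if missing:
        parts.append(f"missing from calls: {', '.join(map(str, missing[:10]))}")
    if extra:
        parts.append(f"unexpected in calls: {', '.join(map(str, extra[:10]))}")
    return "; ".join(parts)


@dataclass
class ExpressionDataset:
    """Signal matrix, detection-call matrix and sample population labels.

    Attributes
    ----------
    signal : pandas.DataFrame
        Non-negative intensities, probe sets as index, samples as columns.
    call : pandas.DataFrame
        Detection calls over {P, M, A}, same axes as ``signal``.
    populations : pandas.Series
        One population label per sample, indexed by sample identifier.
    """

    signal: pd.DataFrame
    call: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        sig = self.signal
        if sig.index.has_duplicates:
            dup = sig.index[sig.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe identifiers: {dup[:10]}")
        if sig.columns.has_duplicates:
            dup = sig.columns[sig.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:10]}")
        if set(sig.index) != set(self.call.index):
            raise ValueError(_axis_mismatch("probe", sig.index, self.call.index))
        if set(sig.columns) != set(self.call.columns):
            raise ValueError(_axis_mismatch("sample", sig.columns, self.call.columns))
        # identifier-keyed reconciliation: call order follows signal order
        self.call = self.call.reindex(index=sig.index, columns=sig.columns)

        values = sig.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            raise ValueError("signal matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("signal matrix contains negative values")

        calls = self.call.to_numpy(dtype=object)
        bad = ~np.isin(calls, sorted(CALL_TOKENS))
        if bad.any():
            coords = [
                f"{sig.index[i]},{sig.columns[j]}"
                for i, j in zip(*np.nonzero(bad))
            ]
            raise ValueError(
                "invalid detection-call token(s) at " + "; ".join(coords[:10])
            )

        if set(self.populations.index) != set(sig.columns):
            raise ValueError(
                _axis_mismatch("sample", sig.columns, self.populations.index)
            )
        self.populations = self.populations.reindex(sig.columns)
        unknown = sorted(set(self.populations) - set(POPULATIONS))
        if unknown:
            raise ValueError(f"unknown population label(s): {', '.join(unknown)}")

    # -- basic views ---------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signal.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def n_probes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def samples_in(self, population: str) -> list[str]:
        """Sample identifiers carrying the given population label, in column order."""
        if population not in POPULATIONS:
            raise ValueError(f"unknown population label: {population}")
        mask = self.populations == population
        return list(self.populations.index[mask])

    def has_population(self, population: str, minimum: int = 1) -> bool:
        return len(self.samples_in(population)) >= minimum

    def population_sizes(self) -> dict[str, int]:
        counts = self.populations.value_counts()
        return {pop: int(counts.get(pop, 0)) for pop in POPULATIONS if counts.get(pop, 0)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(
            signal=self.signal[ids].copy(),
            call=self.call[ids].copy(),
            populations=self.populations.loc[ids].copy(),
        )


# -- file I/O ----------------------------------------------------------


def load_dataset(
    signal_path: str | Path,
    call_path: str | Path,
    samples_path: str | Path,
) -> ExpressionDataset:
    """Read the tab-delimited signal/call/sample-sheet trio.

    The signal and call files carry probe identifiers in the first column and
    a header row of sample identifiers; the sample sheet has two columns,
    ``sample_id`` and ``population``.  Axes are matched by identifier.
    """
    signal = pd.read_csv(
        signal_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    signal.index = signal.index.astype(str)
    signal.columns = signal.columns.astype(str)
    call = pd.read_csv(call_path, sep="\t", index_col=0, dtype=str)
    call.index = call.index.astype(str)
    call.columns = call.columns.astype(str)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    expected = ["sample_id", "population"]
    if list(sheet.columns[:2]) != expected:
        raise ValueError(
            f"sample sheet must have columns {expected}, got {list(sheet.columns)}"
        )
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in sample sheet: {dup[:10]}")
    populations = sheet.set_index("sample_id")["population"]
    return ExpressionDataset(signal=signal, call=call, populations=populations)


def write_dataset(
    ds: ExpressionDataset,
    signal_path: str | Path,
    call_path: str | Path,
    samples_path: str | Path,
) -> None:
    """Write the trio back to disk; signals round-trip at full precision."""
    ds.signal.to_csv(signal_path, sep="\t", index_label=_SIGNAL_INDEX_LABEL)
    ds.call.to_csv(call_path, sep="\t", index_label=_SIGNAL_INDEX_LABEL)
    sheet = pd.DataFrame(
        {"sample_id": ds.sample_ids, "population": ds.populations.to_numpy()}
    )
    sheet.to_csv(samples_path, sep="\t", index=False)
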