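"""Study-shaped synthetic expression datasets with planted compartment truth.

The generator emulates the study design: 131 purified tumor-cell samples,
75 whole-bone-marrow samples (optional; excluded from supervised analysis),
five each of T cells, monocytes, neutrophils and stromal cells, seven
osteoclasts, and the differentiation stages (6 memory B cells, 7
plasmablasts, 7 normal plasma cells).  Signals are log-normal around a
baseline of 100 arbitrary units (log2 s.d. 0.5 within a population);
populations expressing a gene sit at the baseline, the planted winner
population is elevated by a configurable fold (default 8), and silent
populations sit five log2 units below baseline.  Detection calls are
Bernoulli with presence probability 0.95 for expressing and 0.02 for silent
populations (a signal-linked option exists for realism).  A block of
ubiquitously expressed background probe sets stands in for the rest of the
array, so per-sample scaling is anchored the way it is on a real chip.
Every draw is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, GeneEntry
from .classify import CATEGORIES, CategoryAssignment, ENVIRONMENT_POPULATIONS
from .dataset import POPULATIONS, ExpressionDataset

#: Populations in generation order (also the sample-column order).
POPULATION_ORDER = ("MB", "PPC", "BMPC", "MMC", "WBM", "CD3", "CD14", "PMN", "BMSC", "OC")

#: Study sample sizes; whole bone marrow is generated only on request.
STUDY_POPULATION_SIZES: dict[str, int] = {
    "MMC": 131,
    "CD3": 5,
    "CD14": 5,
    "PMN": 5,
    "BMSC": 5,
    "OC": 7,
    "MB": 6,
    "PPC": 7,
    "BMPC": 7,
    "WBM": 0,
}

_COMPARTMENT_POPS = ("MMC", "CD3", "CD14", "PMN", "BMSC", "OC")
_ALL_EXPRESSED = ("MB", "PPC", "BMPC") + _COMPARTMENT_POPS

#: Categories whose recovery is driven by planted significance or planted
#: silence; the call-level rescue and residual classes are noisier by design.
CORE_RECOVERY_CATEGORIES = (
    "MYELOMA",
    "NICHE_BMSC",
    "NICHE_OC",
    "ENVIRONMENT",
    "NOT_EXPRESSED",
)


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one generated gene.

    ``expressing_populations`` sit at the baseline signal and emit present
    calls; ``elevated_populations`` (derived from the category when omitted)
    additionally carry the fold elevation.  ``present_prob`` overrides the
    per-population present-call probability (used e.g. to plant partial
    tumor presence for the rescue class).  ``n_probesets`` > 1 adds decoy
    probe sets with degraded presence to exercise probe selection.
    """

    gene_symbol: str
    planted_category: str
    expressing_populations: tuple[str, ...] = ()
    fold_elevation: float = 8.0
    n_probesets: int = 1
    elevated_populations: Optional[tuple[str, ...]] = None
    present_prob: Optional[Mapping[str, float]] = None

    def elevated(self) -> tuple[str, ...]:
        if self.elevated_populations is not None:
            return self.elevated_populations
        return {
            "MYELOMA": ("MMC",),
            "NICHE_BMSC": ("BMSC",),
            "NICHE_OC": ("OC",),
        }.get(self.planted_category, ())

    def validate(self) -> None:
        if self.planted_category not in CATEGORIES:
            raise ValueError(
                f"{self.gene_symbol}: unknown category {self.planted_category!r}"
            )
        if self.fold_elevation < 1.0:
            raise ValueError(f"{self.gene_symbol}: fold_elevation must be >= 1")
        if self.n_probesets < 1:
            raise ValueError(f"{self.gene_symbol}: n_probesets must be >= 1")
        for pop in self.expressing_populations + self.elevated():
            if pop not in POPULATIONS or pop == "WBM":
                raise ValueError(f"{self.gene_symbol}: invalid population {pop!r}")
        elevated = set(self.elevated()) & set(_COMPARTMENT_POPS)
        category = self.planted_category
        if category == "MYELOMA" and "MMC" not in elevated:
            raise ValueError(f"{self.gene_symbol}: MYELOMA requires an elevated MMC")
        if category == "NICHE_BMSC" and "BMSC" not in elevated:
            raise ValueError(f"{self.gene_symbol}: NICHE_BMSC requires elevated BMSC")
        if category == "NICHE_OC" and "OC" not in elevated:
            raise ValueError(f"{self.gene_symbol}: NICHE_OC requires elevated OC")
        if category == "ENVIRONMENT" and not (
            elevated & set(ENVIRONMENT_POPULATIONS)
        ):
            raise ValueError(
                f"{self.gene_symbol}: ENVIRONMENT requires an elevated marrow "
                "subpopulation (CD3/CD14/PMN)"
            )
        if category in ("SHARED", "MYELOMA_RESCUED", "NOT_EXPRESSED") and elevated:
            raise ValueError(
                f"{self.gene_symbol}: {category} must not elevate a compartment "
                "population"
            )
        expressing = set(self.expressing_populations) & set(_COMPARTMENT_POPS)
        if category == "NOT_EXPRESSED" and expressing:
            raise ValueError(
                f"{self.gene_symbol}: NOT_EXPRESSED must not express a compartment "
                "population"
            )
        if category == "MYELOMA_RESCUED":
            if expressing:
                raise ValueError(
                    f"{self.gene_symbol}: MYELOMA_RESCUED plants calls, not signal"
                )
            if not self.present_prob or self.present_prob.get("MMC", 0.0) <= 0:
                raise ValueError(
                    f"{self.gene_symbol}: MYELOMA_RESCUED needs a positive MMC "
                    "present_prob override"
                )
        if category == "SHARED":
            if "MMC" not in expressing or not (
                expressing & set(("CD3", "CD14", "PMN", "BMSC", "OC"))
            ):
                raise ValueError(
                    f"{self.gene_symbol}: SHARED requires expression in MMC and at "
                    "least one environment population"
                )


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study conditions."""

    population_sizes: Dict[str, int] = field(
        default_factory=lambda: dict(STUDY_POPULATION_SIZES)
    )
    genes: tuple[PlantedGene, ...] = ()
    baseline_log2_mean: float = float(np.log2(100.0))
    within_pop_log2_sd: float = 0.5
    present_prob_expressing: float = 0.95
    present_prob_silent: float = 0.02
    silent_log2_offset: float = 5.0
    decoy_presence_factor: float = 0.5
    n_background_probes: int = 2000
    wbm_tumor_weight: float = 0.3
    signal_linked_calls: bool = False
    call_signal_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = default_planted_panel()
        self.genes = tuple(self.genes)
        for gene in self.genes:
            gene.validate()
        symbols = [g.gene_symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate planted gene symbol(s): {dup[:10]}")
        for pop, n in self.population_sizes.items():
            if pop not in POPULATIONS:
                raise ValueError(f"unknown population {pop!r}")
            if n < 0:
                raise ValueError(f"negative sample count for {pop}")
        for name in ("present_prob_expressing", "present_prob_silent", "wbm_tumor_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.within_pop_log2_sd <= 0:
            raise ValueError("within_pop_log2_sd must be positive")
        if self.n_background_probes < 0:
            raise ValueError("n_background_probes must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted truth emitted alongside a generated dataset."""

    genes: tuple[PlantedGene, ...]
    probe_map: Dict[str, tuple[str, ...]]
    catalog: GeneCatalog
    realized_log2_fold: Dict[str, Optional[float]]

    def category_of(self, gene_symbol: str) -> str:
        for gene in self.genes:
            if gene.gene_symbol == gene_symbol:
                return gene.planted_category
        raise KeyError(gene_symbol)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_symbol": g.gene_symbol,
                    "planted_category": g.planted_category,
                    "expressing_populations": ";".join(g.expressing_populations),
                    "elevated_populations": ";".join(g.elevated()),
                    "fold_elevation": g.fold_elevation,
                    "probe_sets": ";".join(self.probe_map[g.gene_symbol]),
                    "realized_log2_fold": self.realized_log2_fold[g.gene_symbol],
                }
            )
        return pd.DataFrame(rows)


# -- default planted panel ---------------------------------------------


def default_planted_panel() -> tuple[PlantedGene, ...]:
    """51 genes mirroring the study's headline compartment accounting.

    3 tumor-compartment genes, 11 stromal-niche, 3 osteoclast-niche, 8
    environment (with the published winner populations), 9 silent, 5
    rescue-class and 12 shared genes.  Two genes carry a decoy probe set.
    """

    def planted(symbol, category, expressing=(), **kw):
        return PlantedGene(symbol, category, tuple(expressing), **kw)

    panel: list[PlantedGene] = []
    panel += [
        planted("FGF7", "MYELOMA", _ALL_EXPRESSED, n_probesets=2),
        planted("NRG3", "MYELOMA", _ALL_EXPRESSED),
        planted("WNT10A", "MYELOMA", _ALL_EXPRESSED),
    ]
    for symbol in (
        "BDNF", "FGF1", "FGF2", "FGF5", "GDF15", "IL6",
        "JAG1", "LIF", "VEGFC", "WNT3", "WNT5B",
    ):
        panel.append(
            planted(
                symbol, "NICHE_BMSC", _ALL_EXPRESSED,
                n_probesets=2 if symbol == "IL6" else 1,
            )
        )
    for symbol in ("IGF1", "IL10", "TNFSF13"):
        panel.append(planted(symbol, "NICHE_OC", _ALL_EXPRESSED))
    environment_winners = {
        "TNFSF13B": "CD14",
        "TNF": "CD14",
        "OSM": "CD14",
        "IL1B": "CD14",
        "IL15": "CD14",
        "HBEGF": "CD14",
        "FGF13": "PMN",
        "FGF9": "CD3",
    }
    for symbol, winner in environment_winners.items():
        panel.append(
            planted(
                symbol, "ENVIRONMENT", _ALL_EXPRESSED,
                elevated_populations=(winner,),
            )
        )
    for symbol in (
        "FGF3", "FGF4", "FGF6", "FGF11", "FGF14",
        "WNT2", "WNT7A", "WNT8A", "NRG4",
    ):
        panel.append(planted(symbol, "NOT_EXPRESSED"))
    for symbol in ("NRG2", "WNT4", "WNT11", "WNT16", "FGF18"):
        panel.append(
            planted(symbol, "MYELOMA_RESCUED", present_prob={"MMC": 0.10})
        )
    shared_expression = {
        "AREG": ("MB", "PPC", "BMPC", "MMC", "CD3", "CD14", "PMN"),
        "WNT5A": ("PPC", "BMPC", "MMC", "BMSC", "OC"),
        "CCL3": ("MB", "PPC", "BMPC", "MMC", "CD14"),
        "CLCF1": ("MMC", "CD14"),
        "VEGFA": ("MMC", "BMSC"),
        "FGF12": ("MMC", "PMN"),
        "HGF": ("MMC", "BMSC", "CD14", "PMN"),
        "PTN": ("MMC", "BMSC"),
        "NRG1": ("MMC", "CD3"),
        "JAG2": ("MMC", "BMSC"),
        "VEGFB": ("MMC", "CD14"),
        "WNT6": ("MB", "MMC", "CD3"),
    }
    for symbol, expressing in shared_expression.items():
        panel.append(planted(symbol, "SHARED", expressing))
    return tuple(panel)


def null_config(
    n_genes: int = 51,
    population_sizes: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> SyntheticConfig:
    """A no-effect configuration: every gene expressed identically everywhere.

    Used to check the false-positive behaviour of the contrast engine under
    the global null.
    """
    sizes = dict(population_sizes) if population_sizes else {"MMC": 131, "BMSC": 5}
    pops = tuple(p for p in POPULATION_ORDER if sizes.get(p, 0) > 0)
    genes = tuple(
        PlantedGene(f"NULL{i:03d}", "SHARED", pops, fold_elevation=1.0)
        for i in range(n_genes)
    )
    return SyntheticConfig(population_sizes=sizes, genes=genes, seed=seed)


# -- generation --------------------------------------------------------


def generate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw a dataset and its planted truth, fully reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    sizes = {p: int(cfg.population_sizes.get(p, 0)) for p in POPULATION_ORDER}
    sample_ids: list[str] = []
    populations: list[str] = []
    for pop in POPULATION_ORDER:
        for i in range(sizes[pop]):
            sample_ids.append(f"{pop}_{i + 1:03d}")
            populations.append(pop)
    if not sample_ids:
        raise ValueError("population_sizes yields no samples")

    env_pops = ("CD3", "CD14", "PMN", "BMSC", "OC")
    sd = cfg.within_pop_log2_sd
    base = cfg.baseline_log2_mean

    probe_ids: list[str] = []
    signal_rows: list[np.ndarray] = []
    call_rows: list[np.ndarray] = []
    probe_map: Dict[str, tuple[str, ...]] = {}
    realized: Dict[str, Optional[float]] = {}
    entries: list[GeneEntry] = []

    for gene in cfg.genes:
        elevated = set(gene.elevated())
        expressing = set(gene.expressing_populations) | elevated
        mu = {}
        prob = {}
        for pop in POPULATION_ORDER:
            if pop == "WBM":
                continue
            if pop in elevated:
                mu[pop] = base + np.log2(gene.fold_elevation)
            elif pop in expressing:
                mu[pop] = base
            else:
                mu[pop] = base - cfg.silent_log2_offset
            p = (
                cfg.present_prob_expressing
                if pop in expressing
                else cfg.present_prob_silent
            )
            if gene.present_prob and pop in gene.present_prob:
                p = float(gene.present_prob[pop])
            prob[pop] = p
        mu_env = float(np.mean([mu[p] for p in env_pops]))
        prob_env = float(np.mean([prob[p] for p in env_pops]))

        gene_probes = []
        primary_signal: Optional[np.ndarray] = None
        for k in range(gene.n_probesets):
            probe = f"{gene.gene_symbol}_{k + 1:02d}_at"
            degrade = cfg.decoy_presence_factor**k
            sig_parts: list[np.ndarray] = []
            call_parts: list[np.ndarray] = []
            for pop in POPULATION_ORDER:
                n = sizes[pop]
                if n == 0:
                    continue
                if pop == "WBM":
                    tumor = 2.0 ** rng.normal(mu["MMC"], sd, n)
                    envir = 2.0 ** rng.normal(mu_env, sd, n)
                    w = cfg.wbm_tumor_weight
                    sig = w * tumor + (1.0 - w) * envir
                    p = w * prob["MMC"] + (1.0 - w) * prob_env
                else:
                    sig = 2.0 ** rng.normal(mu[pop], sd, n)
                    p = prob[pop]
                if cfg.signal_linked_calls:
                    present = sig >= cfg.call_signal_threshold
                else:
                    present = rng.random(n) < min(p * degrade, 1.0)
                sig_parts.append(sig)
                call_parts.append(np.where(present, "P", "A"))
            row_signal = np.concatenate(sig_parts)
            probe_ids.append(probe)
            signal_rows.append(row_signal)
            call_rows.append(np.concatenate(call_parts))
            gene_probes.append(probe)
            if k == 0:
                primary_signal = row_signal
        probe_map[gene.gene_symbol] = tuple(gene_probes)
        entries.append(
            GeneEntry(
                gene_symbol=gene.gene_symbol,
                family="OTHER",
                role="LIGAND",
                probe_sets=tuple(gene_probes),
            )
        )

        reference = (expressing - elevated) - {"WBM"}
        reference = {p for p in reference if sizes[p] > 0}
        winners = {p for p in elevated if sizes[p] > 0}
        if winners and reference:
            pop_arr = np.asarray(populations)
            log2_sig = np.log2(primary_signal)
            in_win = np.isin(pop_arr, sorted(winners))
            in_ref = np.isin(pop_arr, sorted(reference))
            realized[gene.gene_symbol] = float(
                log2_sig[in_win].mean() - log2_sig[in_ref].mean()
            )
        else:
            realized[gene.gene_symbol] = None

    # Background block emulating the rest of the array: ubiquitously
    # expressed probe sets at the baseline level.  They anchor the
    # per-sample scaling the way the tens of thousands of other probe sets
    # do on a real chip; without them the planted genes themselves would
    # dominate the sample means and scaling would compress the planted folds.
    n_bg = cfg.n_background_probes
    if n_bg:
        n_samples = len(sample_ids)
        bg_signal = 2.0 ** rng.normal(base, sd, size=(n_bg, n_samples))
        bg_present = rng.random((n_bg, n_samples)) < cfg.present_prob_expressing
        if cfg.signal_linked_calls:
            bg_present = bg_signal >= cfg.call_signal_threshold
        probe_ids += [f"BG{i + 1:05d}_at" for i in range(n_bg)]
        signal_rows.append(bg_signal)
        call_rows.append(np.where(bg_present, "P", "A"))

    ds = ExpressionDataset(
        signal=pd.DataFrame(
            np.vstack(signal_rows), index=probe_ids, columns=sample_ids
        ),
        call=pd.DataFrame(np.vstack(call_rows), index=probe_ids, columns=sample_ids),
        populations=pd.Series(populations, index=sample_ids),
    )
    truth = SyntheticTruth(
        genes=cfg.genes,
        probe_map=probe_map,
        catalog=GeneCatalog(tuple(entries)),
        realized_log2_fold=realized,
    )
    return ds, truth


# -- recovery ----------------------------------------------------------


@dataclass
class RecoveryReport:
    """Planted-vs-assigned confusion counts and per-category recall."""

    confusion: pd.DataFrame
    recall: Dict[str, float]
    overall_accuracy: float

    def macro_recall(self, categories: Optional[Sequence[str]] = None) -> float:
        """Unweighted mean recall over the given (default: all planted) categories."""
        cats = list(categories) if categories is not None else sorted(self.recall)
        missing = [c for c in cats if c not in self.recall]
        if missing:
            raise KeyError(f"no planted genes in categor{'ies' if len(missing)>1 else 'y'}: {missing}")
        return float(np.mean([self.recall[c] for c in cats]))


def recovery_report(
    truth: SyntheticTruth,
    assignments: Sequence[CategoryAssignment],
) -> RecoveryReport:
    """Compare assigned categories against the planted truth."""
    assigned = {a.gene_symbol: a.category for a in assignments}
    planted = {g.gene_symbol: g.planted_category for g in truth.genes}
    if set(assigned) != set(planted):
        only_truth = sorted(set(planted) - set(assigned))
        only_assigned = sorted(set(assigned) - set(planted))
        raise ValueError(
            "gene universes differ; "
            f"only in truth: {only_truth[:10]}; only in assignments: {only_assigned[:10]}"
        )
    confusion = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for symbol, true_cat in planted.items():
        confusion.loc[true_cat, assigned[symbol]] += 1
    recall = {}
    for cat in CATEGORIES:
        total = int(confusion.loc[cat].sum())
        if total:
            recall[cat] = float(confusion.loc[cat, cat] / total)
    overall = float(np.trace(confusion.to_numpy()) / len(planted))
    return RecoveryReport(confusion=confusion, recall=recall, overall_accuracy=overall)
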