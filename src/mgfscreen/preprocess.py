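"""Scaling, flooring, informativeness filtering, probe selection, presence.

The array software reports one signal and one detection call per probe set
and sample.  Preprocessing mirrors the study conditions: each sample is
scaled to a mean intensity of 100, values under 1 are raised to 1, and a
probe set is "non-informative" when it is not-present in at least 95% of
samples.  When a gene is interrogated by several probe sets, the one with
the highest present-call percentage across all samples is used (highest
signal variance breaks ties, then the lexicographically smallest probe
identifier).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import GeneEntry
from .config import AnalysisConfig
from .dataset import ExpressionDataset


@dataclass
class GeneExpressionView:
    """A gene restricted to its selected probe set.

    ``signal`` and ``call`` are per-sample Series sharing the dataset's
    sample order.
    """

    gene_symbol: str
    chosen_probe: str
    signal: pd.Series
    call: pd.Series

    def presence(self, samples: Optional[Sequence[str]] = None) -> float:
        calls = self.call if samples is None else self.call.loc[list(samples)]
        return presence_fraction(calls)


# -- scaling -----------------------------------------------------------


def scaling_factors(ds: ExpressionDataset, cfg: AnalysisConfig) -> pd.Series:
    """Per-sample multiplicative factors bringing the mean signal to target.

    With ``trim_fraction`` > 0 a symmetrically trimmed mean is used instead
    of the arithmetic mean (for data conditioned like MAS5 trimmed means).
    """
    values = ds.signal.to_numpy(dtype=float)
    if cfg.trim_fraction > 0:
        means = sps.trim_mean(values, cfg.trim_fraction, axis=0)
    else:
        means = values.mean(axis=0)
    zero = np.asarray(means) <= 0
    if zero.any():
        bad = [ds.sample_ids[i] for i in np.nonzero(zero)[0]]
        raise ValueError(f"sample(s) with zero mean signal: {', '.join(bad[:10])}")
    return pd.Series(cfg.scale_target / means, index=ds.signal.columns)


def scale_dataset(ds: ExpressionDataset, cfg: AnalysisConfig) -> ExpressionDataset:
    """Scale each sample to the target mean, then floor low values.

    The order matters: flooring first would distort the mean.  Calls are
    unchanged.  Returns a new dataset.
    """
    factors = scaling_factors(ds, cfg)
    scaled = ds.signal.mul(factors, axis=1)
    floored = scaled.clip(lower=cfg.signal_floor)
    return ExpressionDataset(
        signal=floored, call=ds.call.copy(), populations=ds.populations.copy()
    )


# -- presence ----------------------------------------------------------


def presence_fraction(
    calls: Union[GeneExpressionView, pd.Series, Sequence[str]],
    samples: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of present calls; marginal and absent both count as not-present."""
    if isinstance(calls, GeneExpressionView):
        calls = calls.call
    if samples is not None:
        calls = pd.Series(calls).loc[list(samples)]
    arr = np.asarray(calls, dtype=object)
    if arr.size == 0:
        raise ValueError("presence_fraction needs a non-empty sample subset")
    return float(np.mean(arr == "P"))


# -- informativeness ---------------------------------------------------


def informative_probesets(ds: ExpressionDataset, cfg: AnalysisConfig) -> set[str]:
    """Probe sets that escape the non-informative rule.

    A probe set is excluded when its not-present fraction across ALL samples
    is at or above ``noninformative_absent_frac``.
    """
    not_present = (ds.call != "P").to_numpy().mean(axis=1)
    keep = not_present < cfg.noninformative_absent_frac
    return {p for p, k in zip(ds.probe_ids, keep) if k}


# -- probe selection ---------------------------------------------------


def select_probeset(
    gene: GeneEntry,
    ds: ExpressionDataset,
    candidates: Optional[Iterable[str]] = None,
) -> GeneExpressionView:
    """Pick the gene's representative probe set.

    Candidates are the gene's probe sets present in the dataset (optionally
    further restricted by ``candidates``).  Ranking: highest present-call
    fraction over all samples, then highest signal variance, then smallest
    probe identifier.
    """
    pool = set(gene.probe_sets if candidates is None else candidates)
    available = [p for p in gene.probe_sets if p in pool and p in ds.signal.index]
    if not available:
        raise ValueError(
            f"gene {gene.gene_symbol} has no candidate probe set in the dataset"
        )

    def score(probe: str):
        presence = presence_fraction(ds.call.loc[probe])
        variance = float(ds.signal.loc[probe].var(ddof=1)) if ds.n_samples > 1 else 0.0
        return (-presence, -variance, probe)

    chosen = min(available, key=score)
    return GeneExpressionView(
        gene_symbol=gene.gene_symbol,
        chosen_probe=chosen,
        signal=ds.signal.loc[chosen],
        call=ds.call.loc[chosen],
    )


def gene_views(
    ds: ExpressionDataset,
    genes: Iterable[GeneEntry],
    cfg: AnalysisConfig,
    apply_informative_filter: bool = False,
) -> tuple[list[GeneExpressionView], dict[str, str]]:
    """Representative views for every interrogable gene.

    Returns ``(views, dropped)`` where ``dropped`` maps gene symbols that
    could not be represented to a reason.  The non-informative screen is off
    by default: the shipped catalog already encodes it, and silencing weakly
    expressed genes here would make the not-expressed class undetectable.
    """
    informative = informative_probesets(ds, cfg) if apply_informative_filter else None
    views: list[GeneExpressionView] = []
    dropped: dict[str, str] = {}
    for gene in genes:
        if not gene.interrogable:
            dropped[gene.gene_symbol] = "no probe set"
            continue
        on_array = [p for p in gene.probe_sets if p in ds.signal.index]
        if not on_array:
            dropped[gene.gene_symbol] = "no probe set on the array"
            continue
        if informative is not None:
            on_array = [p for p in on_array if p in informative]
            if not on_array:
                dropped[gene.gene_symbol] = "all probe sets non-informative"
                continue
        views.append(select_probeset(gene, ds, candidates=on_array))
    return views, dropped
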