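"""Two-group contrast engine.

One contrast compares the expression of a set of genes between two disjoint
sample groups: a Student (pooled-variance) t-test on log2 signal, a
Benjamini-Hochberg adjustment across the genes of the contrast, the fold
change as the ratio of linear-scale group means, and the detection-call
exclusion flag (a gene overexpressed in a group where it is 100% absent is
not biologically relevant).  Whole-bone-marrow samples mix tumor and
environment cells and are rejected from any supervised group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .dataset import ExpressionDataset
from .preprocess import GeneExpressionView


@dataclass
class ContrastResult:
    """Per-gene record of one two-group comparison (group A vs group B)."""

    gene_symbol: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    fold_change: float
    t_statistic: float
    p_raw: float
    p_adj: float
    present_frac_a: float
    present_frac_b: float
    all_absent_in_winner: bool
    significant_over_b: bool

    def significant_under_b(self, cfg: AnalysisConfig) -> bool:
        """True when group B is significantly overexpressed relative to A."""
        if self.fold_change <= 0:
            return False
        return (
            self.p_adj <= cfg.alpha
            and 1.0 / self.fold_change >= cfg.min_fold_change
            and not self.all_absent_in_winner
        )


_COLUMNS = [
    "gene_symbol", "group_a", "group_b", "n_a", "n_b",
    "mean_a", "mean_b", "median_a", "median_b", "fold_change",
    "t_statistic", "p_raw", "p_adj", "present_frac_a", "present_frac_b",
    "all_absent_in_winner", "significant_over_b",
]


def contrasts_to_frame(results: Iterable[ContrastResult]) -> pd.DataFrame:
    """Stable-column-order table of contrast records (see README for columns)."""
    rows = [{c: getattr(r, c) for c in _COLUMNS} for r in results]
    return pd.DataFrame(rows, columns=_COLUMNS)


# -- t statistic -------------------------------------------------------


def _t_arrays(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample t over rows of ``a`` (g x n_a) and ``b`` (g x n_b).

    Degenerate rows (zero pooled variance) follow the convention: equal
    means give (t=0, p=1); unequal means give (t=+-inf, p=0).
    """
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = mean_a - mean_b
    if equal_var:
        df = np.full(a.shape[0], n_a + n_b - 2, dtype=float)
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    else:
        sa, sb = var_a / n_a, var_b / n_b
        se = np.sqrt(sa + sb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (sa + sb) ** 2 / (
                sa**2 / max(n_a - 1, 1) + sb**2 / max(n_b - 1, 1)
            )
        df = np.where(np.isfinite(df), df, n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    t = np.where(zero_se & (diff == 0), 0.0, t)
    t = np.where(zero_se & (diff > 0), np.inf, t)
    t = np.where(zero_se & (diff < 0), -np.inf, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, np.clip(p, 0.0, 1.0)


def student_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance by default.

    Each group needs at least two observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("student_t needs at least two observations per group")
    t, p = _t_arrays(a[None, :], b[None, :], equal_var=equal_var)
    return float(t[0]), float(p[0])


# -- multiple testing --------------------------------------------------


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment, returned in input order (ties share a value)."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# -- group comparison --------------------------------------------------


def compare_groups(
    ds: ExpressionDataset,
    genes: Sequence[GeneExpressionView],
    group_a: Sequence[str],
    group_b: Sequence[str],
    cfg: AnalysisConfig,
    label_a: Optional[str] = None,
    label_b: Optional[str] = None,
) -> list[ContrastResult]:
    """One :class:`ContrastResult` per gene for group A vs group B.

    The BH family is exactly the genes of this call.  Groups must be
    disjoint, have at least two samples each and contain no whole-bone-marrow
    sample.
    """
    ids_a, ids_b = list(group_a), list(group_b)
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap on sample(s): {sorted(overlap)[:10]}")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least two samples")
    for ids in (ids_a, ids_b):
        wbm = [s for s in ids if ds.populations.get(s) == "WBM"]
        if wbm:
            raise ValueError(
                f"whole-bone-marrow samples cannot enter a supervised group: {wbm[:10]}"
            )

    if label_a is None:
        label_a = "+".join(sorted(set(ds.populations.loc[ids_a]))) or "A"
    if label_b is None:
        label_b = "+".join(sorted(set(ds.populations.loc[ids_b]))) or "B"

    sample_index = pd.Index(ds.sample_ids)
    pos_a = sample_index.get_indexer(ids_a)
    pos_b = sample_index.get_indexer(ids_b)
    if (pos_a < 0).any() or (pos_b < 0).any():
        missing = [s for s, p in zip(ids_a + ids_b, list(pos_a) + list(pos_b)) if p < 0]
        raise ValueError(f"sample(s) not in dataset: {missing[:10]}")

    n_genes = len(genes)
    lin_a = np.empty((n_genes, len(ids_a)))
    lin_b = np.empty((n_genes, len(ids_b)))
    pres_a = np.empty(n_genes)
    pres_b = np.empty(n_genes)
    for i, view in enumerate(genes):
        sig = view.signal.to_numpy(dtype=float)
        calls = view.call.to_numpy(dtype=object)
        lin_a[i] = sig[pos_a]
        lin_b[i] = sig[pos_b]
        pres_a[i] = np.mean(calls[pos_a] == "P")
        pres_b[i] = np.mean(calls[pos_b] == "P")

    if cfg.test_scale == "log2":
        floor = max(cfg.signal_floor, np.finfo(float).tiny)
        test_a = np.log2(np.maximum(lin_a, floor))
        test_b = np.log2(np.maximum(lin_b, floor))
    else:
        test_a, test_b = lin_a, lin_b

    t, p_raw = _t_arrays(test_a, test_b, equal_var=cfg.equal_variance)
    p_adj = benjamini_hochberg(p_raw) if n_genes else np.array([])

    mean_a, mean_b = lin_a.mean(axis=1), lin_b.mean(axis=1)
    median_a = np.median(lin_a, axis=1)
    median_b = np.median(lin_b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_b > 0, mean_a / mean_b, np.inf)

    results = []
    for i, view in enumerate(genes):
        winner_absent = (
            pres_a[i] == 0.0 if fold[i] >= 1.0 else pres_b[i] == 0.0
        )
        significant = bool(
            p_adj[i] <= cfg.alpha
            and fold[i] >= cfg.min_fold_change
            and not winner_absent
        )
        results.append(
            ContrastResult(
                gene_symbol=view.gene_symbol,
                group_a=label_a,
                group_b=label_b,
                n_a=len(ids_a),
                n_b=len(ids_b),
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                median_a=float(median_a[i]),
                median_b=float(median_b[i]),
                fold_change=float(fold[i]),
                t_statistic=float(t[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                present_frac_a=float(pres_a[i]),
                present_frac_b=float(pres_b[i]),
                all_absent_in_winner=bool(winner_absent),
                significant_over_b=significant,
            )
        )
    return results
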