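"""Per-receptor expression summaries in tumor cells and presence buckets.

For each growth-factor receptor the summary reports, over the purified
tumor-cell (MMC) samples only: the median signal, the (min, max) range and
the percentage of samples with a present call (rounded half-up to an
integer, matching the published table).  Bucket counting over the presence
column reproduces the published headline statements (e.g. half of the
receptors present in at least 50% of patients).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneEntry, ReceptorTableRow, load_receptor_expression
from .config import AnalysisConfig
from .dataset import ExpressionDataset
from .preprocess import presence_fraction, select_probeset

#: (lower, upper, lower_inclusive, upper_inclusive)
Bucket = tuple[float, float, bool, bool]

#: Buckets behind the published presence statements: at least half the
#: patients; all patients; 99%; strictly between 90 and 99.
HEADLINE_BUCKETS: dict[str, Bucket] = {
    "ge_50": (50, 100, True, True),
    "eq_100": (100, 100, True, True),
    "eq_99": (99, 99, True, True),
    "gt_90_lt_99": (90, 99, False, False),
}


@dataclass
class ReceptorSummary:
    """Rows of per-receptor summaries, either computed or transcribed."""

    rows: list[ReceptorTableRow]
    source: str  # "computed" | "transcribed"

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            lo, hi = r.signal_range if r.signal_range is not None else (None, None)
            records.append(
                {
                    "gene_symbol": r.gene_symbol,
                    "probe_set": r.probe_set,
                    "median_signal": r.median_signal,
                    "range_min": lo,
                    "range_max": hi,
                    "presence_pct": r.presence_pct,
                }
            )
        return pd.DataFrame(records)


def _round_half_up_pct(fraction: float) -> int:
    return int(np.floor(100.0 * fraction + 0.5))


def summarize_receptors(
    ds: ExpressionDataset,
    receptor_genes: Iterable[GeneEntry],
    cfg: AnalysisConfig,
) -> ReceptorSummary:
    """Compute the per-receptor summary over the tumor-cell samples.

    Each receptor is represented by its selected probe set (probe selection
    uses all samples; the summary statistics use the MMC samples only).
    """
    mmc = ds.samples_in("MMC")
    if not mmc:
        raise ValueError("dataset has no MMC samples")
    rows: list[ReceptorTableRow] = []
    for gene in receptor_genes:
        view = select_probeset(gene, ds)
        values = view.signal.loc[mmc].to_numpy(dtype=float)
        row = ReceptorTableRow(
            gene_symbol=gene.gene_symbol,
            probe_set=view.chosen_probe,
            median_signal=float(np.median(values)),
            signal_range=(float(values.min()), float(values.max())),
            presence_pct=_round_half_up_pct(
                presence_fraction(view.call.loc[mmc])
            ),
        )
        row.validate_computed()
        rows.append(row)
    return ReceptorSummary(rows=rows, source="computed")


def transcribed_receptor_summary() -> ReceptorSummary:
    """The packaged verbatim transcription of the published receptor table."""
    return ReceptorSummary(rows=load_receptor_expression(), source="transcribed")


def bucket_counts(
    summary: ReceptorSummary,
    buckets: Sequence[Bucket],
) -> tuple[list[int], int]:
    """Count rows whose presence percentage falls in each bucket.

    Rows with unknown presence are excluded; their number is returned
    separately.  Buckets need not partition the axis.
    """
    for lower, upper, *_ in buckets:
        if lower > upper:
            raise ValueError(f"malformed bucket: lower {lower} > upper {upper}")
    known = [r.presence_pct for r in summary.rows if r.presence_pct is not None]
    n_unknown = len(summary.rows) - len(known)

    def inside(p: float, bucket: Bucket) -> bool:
        lower, upper, lo_inc, hi_inc = bucket
        above = p >= lower if lo_inc else p > lower
        below = p <= upper if hi_inc else p < upper
        return above and below

    counts = [sum(inside(p, b) for p in known) for b in buckets]
    return counts, n_unknown


def headline_bucket_counts(summary: ReceptorSummary) -> dict[str, int]:
    """The four published presence statements as named counts."""
    counts, _ = bucket_counts(summary, list(HEADLINE_BUCKETS.values()))
    return dict(zip(HEADLINE_BUCKETS.keys(), counts))
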