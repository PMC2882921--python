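"""Compartment classification and plasma-cell differentiation contrasts.

Every interrogable growth-factor gene receives exactly one compartment
label from a deterministic rule cascade (first match wins):

1. ``NOT_EXPRESSED`` -- below the presence floor in tumor cells and each
   marrow subpopulation, with zero present calls in stromal cells and
   osteoclasts.
2. ``MYELOMA`` -- tumor cells significantly overexpress the gene versus
   every other marrow population (T cells, monocytes, neutrophils, stromal
   cells, osteoclasts).
3. ``NICHE_BMSC`` / ``NICHE_OC`` -- stromal cells (resp. osteoclasts)
   significantly overexpress it versus tumor cells and the three marrow
   subpopulations; the two niche populations are not contrasted against
   each other by default.
4. ``ENVIRONMENT`` -- at least one marrow subpopulation significantly
   overexpresses it versus tumor cells, stromal cells and osteoclasts.
5. ``MYELOMA_RESCUED`` -- present in some tumor samples while absent in
   every other population, without reaching significance.
6. ``SHARED`` -- the residual: expressed in tumor cells and environment
   alike without a winner.

The differentiation analysis runs three stage contrasts per gene (memory B
cells vs pooled plasmablasts + normal plasma cells; plasmablasts vs normal
plasma cells; tumor cells vs normal plasma cells) and flags aberrant
expression: genes absent in every normal plasma-cell sample yet present in
more than 10% of tumor samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .config import AnalysisConfig
from .dataset import ExpressionDataset
from .preprocess import GeneExpressionView, presence_fraction
from .stats import ContrastResult, compare_groups

CATEGORIES = (
    "MYELOMA",
    "MYELOMA_RESCUED",
    "NICHE_BMSC",
    "NICHE_OC",
    "ENVIRONMENT",
    "SHARED",
    "NOT_EXPRESSED",
)

#: Marrow subpopulations purified from aspirates.
ENVIRONMENT_POPULATIONS = ("CD3", "CD14", "PMN")
#: In-vitro-generated candidate niche populations.
NICHE_POPULATIONS = ("BMSC", "OC")
#: Everything the tumor compartment is contrasted against.
NON_TUMOR_POPULATIONS = ENVIRONMENT_POPULATIONS + NICHE_POPULATIONS
#: Populations the compartment classification requires.
REQUIRED_POPULATIONS = ("MMC",) + NON_TUMOR_POPULATIONS

DIFFERENTIATION_CONTRASTS = ("B_vs_PPCBMPC", "PPC_vs_BMPC", "MMC_vs_BMPC")


@dataclass
class CategoryAssignment:
    """One gene's compartment label with the evidence that produced it."""

    gene_symbol: str
    category: str
    winning_population: Optional[str]
    supporting_contrasts: list[ContrastResult] = field(default_factory=list)
    rule_fired: str = ""


@dataclass
class DifferentiationResult:
    """One gene under one stage contrast."""

    gene_symbol: str
    contrast: str
    direction: str  # up_in_first | up_in_second | none
    contrast_result: ContrastResult
    aberrant_in_mmc: bool


ContrastTable = Dict[tuple[str, str], Dict[str, ContrastResult]]


def _require_populations(ds: ExpressionDataset, needed: Sequence[str]) -> None:
    missing = [p for p in needed if not ds.samples_in(p)]
    if missing:
        raise ValueError(f"dataset lacks required population(s): {', '.join(missing)}")


def compartment_contrasts(
    ds: ExpressionDataset,
    genes: Sequence[GeneExpressionView],
    cfg: AnalysisConfig,
) -> ContrastTable:
    """All pairwise contrasts the cascade consumes, keyed (winner, loser).

    Each (winner, loser) pair is one multiple-testing family across the
    genes of the call; whole-bone-marrow samples never enter a group.
    """
    _require_populations(ds, REQUIRED_POPULATIONS)
    niche_targets = {
        "BMSC": ("MMC",) + ENVIRONMENT_POPULATIONS,
        "OC": ("MMC",) + ENVIRONMENT_POPULATIONS,
    }
    if cfg.require_niche_cross_contrast:
        niche_targets["BMSC"] += ("OC",)
        niche_targets["OC"] += ("BMSC",)
    pairs: list[tuple[str, str]] = []
    pairs += [("MMC", p) for p in NON_TUMOR_POPULATIONS]
    for niche, targets in niche_targets.items():
        pairs += [(niche, t) for t in targets]
    for env in ENVIRONMENT_POPULATIONS:
        pairs += [(env, t) for t in ("MMC",) + NICHE_POPULATIONS]

    table: ContrastTable = {}
    for winner, loser in pairs:
        if (winner, loser) in table:
            continue
        results = compare_groups(
            ds,
            genes,
            ds.samples_in(winner),
            ds.samples_in(loser),
            cfg,
            label_a=winner,
            label_b=loser,
        )
        table[(winner, loser)] = {r.gene_symbol: r for r in results}
    return table


def classify_compartments(
    ds: ExpressionDataset,
    genes: Sequence[GeneExpressionView],
    cfg: AnalysisConfig,
    contrasts: Optional[ContrastTable] = None,
) -> list[CategoryAssignment]:
    """Assign each gene exactly one compartment category (rule cascade)."""
    _require_populations(ds, REQUIRED_POPULATIONS)
    if contrasts is None:
        contrasts = compartment_contrasts(ds, genes, cfg)

    samples = {pop: ds.samples_in(pop) for pop in REQUIRED_POPULATIONS}
    assignments: list[CategoryAssignment] = []
    for view in genes:
        gene = view.gene_symbol
        presence = {
            pop: presence_fraction(view.call.loc[ids])
            for pop, ids in samples.items()
        }

        # 1. below the presence floor everywhere
        if (
            presence["MMC"] < cfg.not_expressed_max_present_frac
            and all(
                presence[p] < cfg.not_expressed_max_present_frac
                for p in ENVIRONMENT_POPULATIONS
            )
            and all(presence[p] == 0.0 for p in NICHE_POPULATIONS)
        ):
            assignments.append(
                CategoryAssignment(gene, "NOT_EXPRESSED", None, [], "not_expressed")
            )
            continue

        # 2. tumor cells beat every other population
        tumor = [contrasts[("MMC", p)][gene] for p in NON_TUMOR_POPULATIONS]
        if all(c.significant_over_b for c in tumor):
            assignments.append(
                CategoryAssignment(gene, "MYELOMA", "MMC", tumor, "myeloma_overexpressed")
            )
            continue

        # 3. a niche population beats tumor cells and the subpopulations
        fired = False
        for niche in NICHE_POPULATIONS:
            targets = ("MMC",) + ENVIRONMENT_POPULATIONS
            if cfg.require_niche_cross_contrast:
                other = "OC" if niche == "BMSC" else "BMSC"
                targets += (other,)
            crs = [contrasts[(niche, t)][gene] for t in targets]
            if all(c.significant_over_b for c in crs):
                assignments.append(
                    CategoryAssignment(
                        gene, f"NICHE_{niche}", niche, crs, f"niche_{niche.lower()}"
                    )
                )
                fired = True
                break
        if fired:
            continue

        # 4. a marrow subpopulation beats tumor and both niche populations
        for env in ENVIRONMENT_POPULATIONS:
            crs = [
                contrasts[(env, t)][gene] for t in ("MMC",) + NICHE_POPULATIONS
            ]
            if all(c.significant_over_b for c in crs):
                assignments.append(
                    CategoryAssignment(gene, "ENVIRONMENT", env, crs, "environment")
                )
                fired = True
                break
        if fired:
            continue

        # 5. present in some tumor samples, absent everywhere else
        if presence["MMC"] > cfg.rescue_min_present_frac and all(
            presence[p] == 0.0 for p in NON_TUMOR_POPULATIONS
        ):
            assignments.append(
                CategoryAssignment(gene, "MYELOMA_RESCUED", "MMC", [], "myeloma_rescued")
            )
            continue

        # 6. residual
        assignments.append(CategoryAssignment(gene, "SHARED", None, [], "shared"))
    return assignments


def venn_counts(assignments: Sequence[CategoryAssignment]) -> dict[str, int]:
    """Gene count per category, all categories present (zero-filled)."""
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return counts


# -- plasma-cell differentiation ---------------------------------------


def aberrant_in_mmc(
    ds: ExpressionDataset, gene: GeneExpressionView, cfg: AnalysisConfig
) -> bool:
    """Absent in every normal plasma-cell sample yet present in more than
    ``aberrant_min_mmc_present_frac`` of tumor samples."""
    _require_populations(ds, ("BMPC", "MMC"))
    pres_bmpc = gene.presence(ds.samples_in("BMPC"))
    pres_mmc = gene.presence(ds.samples_in("MMC"))
    return pres_bmpc == 0.0 and pres_mmc > cfg.aberrant_min_mmc_present_frac


def differentiation_analysis(
    ds: ExpressionDataset,
    genes: Sequence[GeneExpressionView],
    cfg: AnalysisConfig,
) -> list[DifferentiationResult]:
    """Three stage contrasts per gene, with the aberrant-expression flag."""
    _require_populations(ds, ("MB", "PPC", "BMPC", "MMC"))
    groups = {
        "B_vs_PPCBMPC": (
            ds.samples_in("MB"),
            ds.samples_in("PPC") + ds.samples_in("BMPC"),
            "MB",
            "PPC+BMPC",
        ),
        "PPC_vs_BMPC": (ds.samples_in("PPC"), ds.samples_in("BMPC"), "PPC", "BMPC"),
        "MMC_vs_BMPC": (ds.samples_in("MMC"), ds.samples_in("BMPC"), "MMC", "BMPC"),
    }
    aberrant = {g.gene_symbol: aberrant_in_mmc(ds, g, cfg) for g in genes}
    results: list[DifferentiationResult] = []
    for name, (ids_a, ids_b, label_a, label_b) in groups.items():
        contrast = compare_groups(
            ds, genes, ids_a, ids_b, cfg, label_a=label_a, label_b=label_b
        )
        for cr in contrast:
            if cr.significant_over_b:
                direction = "up_in_first"
            elif cr.significant_under_b(cfg):
                direction = "up_in_second"
            else:
                direction = "none"
            results.append(
                DifferentiationResult(
                    gene_symbol=cr.gene_symbol,
                    contrast=name,
                    direction=direction,
                    contrast_result=cr,
                    aberrant_in_mmc=aberrant[cr.gene_symbol],
                )
            )
    return results
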