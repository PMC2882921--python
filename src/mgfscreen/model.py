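"""Model/Results interface over the screening pipeline.

:class:`CompartmentModel` fits the compartment classification of growth-
factor genes to an expression dataset; :class:`DifferentiationModel` fits
the plasma-cell differentiation contrasts.  Both follow the usual
model-object convention: construct from data, call :meth:`fit`, inspect the
returned results object (tables, counts, ``summary()``), or write it to
disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .catalog import GeneCatalog, mgf_catalog
from .classify import (
    CATEGORIES,
    CategoryAssignment,
    ContrastTable,
    DifferentiationResult,
    classify_compartments,
    compartment_contrasts,
    differentiation_analysis,
    venn_counts,
)
from .config import AnalysisConfig
from .dataset import ExpressionDataset, load_dataset
from .preprocess import GeneExpressionView, gene_views, scale_dataset
from .stats import contrasts_to_frame


class _BaseModel:
    def __init__(
        self,
        dataset: ExpressionDataset,
        catalog: Optional[GeneCatalog] = None,
        config: Optional[AnalysisConfig] = None,
        apply_informative_filter: bool = False,
    ) -> None:
        self.dataset = dataset
        self.catalog = catalog if catalog is not None else mgf_catalog()
        self.config = config if config is not None else AnalysisConfig()
        self.apply_informative_filter = apply_informative_filter

    @classmethod
    def from_files(
        cls,
        signal_path,
        call_path,
        samples_path,
        catalog: Optional[GeneCatalog] = None,
        config: Optional[AnalysisConfig] = None,
        **kwargs,
    ):
        ds = load_dataset(signal_path, call_path, samples_path)
        return cls(ds, catalog=catalog, config=config, **kwargs)

    def _prepare(self, genes) -> tuple[ExpressionDataset, list, dict]:
        scaled = scale_dataset(self.dataset, self.config)
        views, dropped = gene_views(
            scaled,
            genes,
            self.config,
            apply_informative_filter=self.apply_informative_filter,
        )
        return scaled, views, dropped


class CompartmentModel(_BaseModel):
    """Compartment classification of growth-factor genes.

    Parameters
    ----------
    dataset : ExpressionDataset
        Raw (unscaled) signals, calls and population labels.
    catalog : GeneCatalog, optional
        Gene catalog; ligand entries are classified.  Defaults to the
        packaged 51-gene MGF catalog.
    config : AnalysisConfig, optional
    apply_informative_filter : bool
        Re-apply the 95%-absent probe screen inside the fit (off by
        default; the packaged catalog already encodes it).
    """

    def fit(self) -> "CompartmentResults":
        scaled, views, dropped = self._prepare(self.catalog.ligands())
        contrasts = compartment_contrasts(scaled, views, self.config)
        assignments = classify_compartments(
            scaled, views, self.config, contrasts=contrasts
        )
        return CompartmentResults(
            model=self,
            dataset=scaled,
            views=views,
            dropped=dropped,
            contrasts=contrasts,
            assignments=assignments,
        )


@dataclass
class CompartmentResults:
    """Fitted compartment classification."""

    model: CompartmentModel
    dataset: ExpressionDataset
    views: list[GeneExpressionView]
    dropped: dict[str, str]
    contrasts: ContrastTable
    assignments: list[CategoryAssignment]

    @property
    def venn_counts(self) -> dict[str, int]:
        return venn_counts(self.assignments)

    @property
    def category_table(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            supporting = a.supporting_contrasts
            rows.append(
                {
                    "gene_symbol": a.gene_symbol,
                    "category": a.category,
                    "winning_population": a.winning_population or "",
                    "rule_fired": a.rule_fired,
                    "max_p_adj": max((c.p_adj for c in supporting), default=None),
                    "min_fold_change": min(
                        (c.fold_change for c in supporting), default=None
                    ),
                }
            )
        return pd.DataFrame(rows)

    def contrast_table(self) -> pd.DataFrame:
        frames = []
        for (winner, loser), per_gene in self.contrasts.items():
            frame = contrasts_to_frame(per_gene.values())
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        counts = self.venn_counts
        sizes = self.dataset.population_sizes()
        lines = [
            "Growth-factor compartment classification",
            "=" * 46,
            f"Genes classified: {len(self.assignments)}"
            + (f"   (dropped: {len(self.dropped)})" if self.dropped else ""),
            "Samples per population: "
            + ", ".join(f"{p}={n}" for p, n in sizes.items()),
            f"Thresholds: adj. p <= {self.model.config.alpha}, "
            f"fold change >= {self.model.config.min_fold_change}",
            "-" * 46,
        ]
        for category in CATEGORIES:
            lines.append(f"{category:<16} {counts[category]:>4}")
        lines.append("-" * 46)
        for a in self.assignments:
            winner = a.winning_population or "-"
            lines.append(f"{a.gene_symbol:<12} {a.category:<16} {winner}")
        return "\n".join(lines)

    def to_files(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "categories": out / "category_table.tsv",
            "venn": out / "venn_counts.json",
            "contrasts": out / "contrasts.tsv",
        }
        self.category_table.to_csv(paths["categories"], sep="\t", index=False)
        paths["venn"].write_text(json.dumps(self.venn_counts, indent=2) + "\n")
        self.contrast_table().to_csv(paths["contrasts"], sep="\t", index=False)
        return paths

    def plot_gene(self, gene_symbol: str, ax=None):
        """Bar plot of one gene's per-sample signal, grouped by population;
        absent calls are drawn as open bars (requires matplotlib)."""
        import matplotlib.pyplot as plt

        view = next(
            (v for v in self.views if v.gene_symbol == gene_symbol), None
        )
        if view is None:
            raise KeyError(f"gene {gene_symbol!r} not among fitted views")
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        pops = self.dataset.populations
        order = [s for s in self.dataset.sample_ids]
        values = view.signal.loc[order]
        present = (view.call.loc[order] == "P").to_numpy()
        colors = ["0.2" if p else "white" for p in present]
        ax.bar(range(len(order)), values.to_numpy(), color=colors,
               edgecolor="0.2", linewidth=0.4)
        boundaries = pops.loc[order].ne(pops.loc[order].shift()).to_numpy().nonzero()[0]
        for b in boundaries[1:]:
            ax.axvline(b - 0.5, color="0.7", linewidth=0.6)
        ax.set_ylabel("signal (a.u.)")
        ax.set_title(f"{gene_symbol} ({view.chosen_probe})")
        ax.set_xticks(boundaries)
        ax.set_xticklabels(pops.loc[order].iloc[boundaries], rotation=90, fontsize=7)
        return ax


class DifferentiationModel(_BaseModel):
    """Stage contrasts along normal plasma-cell differentiation and into tumor."""

    def fit(self) -> "DifferentiationResults":
        scaled, views, dropped = self._prepare(self.catalog.ligands() + self.catalog.receptors())
        results = differentiation_analysis(scaled, views, self.config)
        return DifferentiationResults(
            model=self, dataset=scaled, views=views, dropped=dropped, results=results
        )


@dataclass
class DifferentiationResults:
    """Fitted differentiation contrasts."""

    model: DifferentiationModel
    dataset: ExpressionDataset
    views: list[GeneExpressionView]
    dropped: dict[str, str]
    results: list[DifferentiationResult]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            cr = r.contrast_result
            rows.append(
                {
                    "gene_symbol": r.gene_symbol,
                    "contrast": r.contrast,
                    "direction": r.direction,
                    "fold_change": cr.fold_change,
                    "p_adj": cr.p_adj,
                    "n_first": cr.n_a,
                    "n_second": cr.n_b,
                    "aberrant_in_mmc": r.aberrant_in_mmc,
                }
            )
        return pd.DataFrame(rows)

    @property
    def aberrant_genes(self) -> list[str]:
        seen = []
        for r in self.results:
            if r.aberrant_in_mmc and r.gene_symbol not in seen:
                seen.append(r.gene_symbol)
        return seen

    def summary(self) -> str:
        table = self.table
        lines = [
            "Plasma-cell differentiation contrasts",
            "=" * 46,
            f"Genes analysed: {len(self.views)}"
            + (f"   (dropped: {len(self.dropped)})" if self.dropped else ""),
        ]
        for contrast, group in table.groupby("contrast", sort=False):
            up1 = int((group["direction"] == "up_in_first").sum())
            up2 = int((group["direction"] == "up_in_second").sum())
            lines.append(f"{contrast:<14} up in first: {up1:>3}   up in second: {up2:>3}")
        lines.append(f"Aberrantly expressed in tumor cells: {len(self.aberrant_genes)}")
        return "\n".join(lines)

    def to_files(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "differentiation.tsv"
        self.table.to_csv(path, sep="\t", index=False)
        return {"differentiation": path}
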