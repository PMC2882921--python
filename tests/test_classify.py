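"""Rule cascade for compartment labels and the differentiation contrasts."""

import numpy as np
import pytest

import mgfscreen as m
from conftest import SMALL_SIZES, make_dataset, small_synthetic

ALL_POPS = ("MB", "PPC", "BMPC", "MMC", "CD3", "CD14", "PMN", "BMSC", "OC")


def _classify(genes, seed=0, cfg=None, **kwargs):
    ds, truth = small_synthetic(genes, seed=seed, **kwargs)
    model = m.CompartmentModel(ds, catalog=truth.catalog, config=cfg)
    results = model.fit()
    return {a.gene_symbol: a for a in results.assignments}, results


class TestCascadeRules:
    def test_planted_tumor_gene_is_myeloma(self):
        genes = [m.PlantedGene("T1", "MYELOMA", ALL_POPS)]
        assigned, _ = _classify(genes)
        assert assigned["T1"].category == "MYELOMA"
        assert assigned["T1"].winning_population == "MMC"
        assert len(assigned["T1"].supporting_contrasts) == 5

    def test_bmsc_niche_does_not_need_to_beat_osteoclasts(self):
        # gene equally elevated in BMSC and OC: the niche rules skip the
        # cross-niche contrast, so BMSC fires first
        genes = [
            m.PlantedGene(
                "N1", "NICHE_BMSC", ALL_POPS, elevated_populations=("BMSC", "OC")
            )
        ]
        assigned, _ = _classify(genes)
        assert assigned["N1"].category == "NICHE_BMSC"

        cfg = m.AnalysisConfig(require_niche_cross_contrast=True)
        assigned, _ = _classify(genes, cfg=cfg)
        assert assigned["N1"].category == "SHARED"

    def test_planted_osteoclast_gene_is_niche_oc(self):
        genes = [m.PlantedGene("N2", "NICHE_OC", ALL_POPS)]
        assigned, _ = _classify(genes)
        assert assigned["N2"].category == "NICHE_OC"

    def test_environment_winner_recorded(self):
        genes = [
            m.PlantedGene(
                "E1", "ENVIRONMENT", ALL_POPS, elevated_populations=("CD14",)
            )
        ]
        assigned, _ = _classify(genes)
        assert assigned["E1"].category == "ENVIRONMENT"
        assert assigned["E1"].winning_population == "CD14"

    def test_partial_tumor_presence_with_silent_environment_is_rescued(self):
        genes = [
            m.PlantedGene("R1", "MYELOMA_RESCUED", present_prob={"MMC": 0.4})
        ]
        assigned, _ = _classify(genes, present_prob_silent=0.0)
        assert assigned["R1"].category == "MYELOMA_RESCUED"
        assert assigned["R1"].rule_fired == "myeloma_rescued"

    def test_silent_gene_is_not_expressed(self):
        genes = [m.PlantedGene("S1", "NOT_EXPRESSED")]
        assigned, _ = _classify(genes, present_prob_silent=0.0)
        assert assigned["S1"].category == "NOT_EXPRESSED"

    def test_rescue_fires_only_when_significance_rule_did_not(self):
        # expressed and elevated in tumor cells only, absent everywhere else:
        # the significance rule takes precedence over the rescue rule
        genes = [
            m.PlantedGene("P1", "MYELOMA", ("MMC",))
        ]
        assigned, _ = _classify(genes, present_prob_silent=0.0)
        assert assigned["P1"].category == "MYELOMA"
        assert assigned["P1"].rule_fired == "myeloma_overexpressed"

    def test_shared_is_the_residual(self):
        genes = [m.PlantedGene("X1", "SHARED", ("MMC", "CD14"))]
        assigned, _ = _classify(genes)
        assert assigned["X1"].category == "SHARED"

    def test_missing_population_is_reported(self, cfg):
        sizes = dict(SMALL_SIZES)
        sizes["OC"] = 0
        synth = m.SyntheticConfig(
            population_sizes=sizes,
            genes=(m.PlantedGene("G", "SHARED", ("MMC", "CD14")),),
            n_background_probes=50,
        )
        ds, truth = m.generate_dataset(synth)
        with pytest.raises(ValueError, match="OC"):
            m.CompartmentModel(ds, catalog=truth.catalog).fit()

    def test_categories_partition_the_gene_set(self):
        ds, truth = m.generate_dataset(
            m.SyntheticConfig(population_sizes=dict(SMALL_SIZES),
                              n_background_probes=300, seed=5)
        )
        results = m.CompartmentModel(ds, catalog=truth.catalog).fit()
        symbols = [a.gene_symbol for a in results.assignments]
        assert len(symbols) == len(set(symbols)) == len(truth.genes)
        assert all(a.category in m.CATEGORIES for a in results.assignments)
        assert sum(results.venn_counts.values()) == len(truth.genes)


class TestAberrantExpression:
    def _dataset(self, n_present_mmc, n_mmc=20, bmpc_calls=("A",) * 7):
        calls = list(bmpc_calls) + ["P"] * n_present_mmc + ["A"] * (
            n_mmc - n_present_mmc
        )
        signal = [[100.0] * (7 + n_mmc)]
        pops = ["BMPC"] * 7 + ["MMC"] * n_mmc
        return make_dataset(signal, [calls], pops)

    def _view(self, ds):
        return m.GeneExpressionView("G", "p1", ds.signal.loc["p1"], ds.call.loc["p1"])

    def test_fifteen_percent_tumor_presence_is_aberrant(self, cfg):
        ds = self._dataset(n_present_mmc=3)  # 15%
        assert m.aberrant_in_mmc(ds, self._view(ds), cfg)

    def test_exactly_ten_percent_is_not(self, cfg):
        ds = self._dataset(n_present_mmc=2)  # 10%, rule is strictly greater
        assert not m.aberrant_in_mmc(ds, self._view(ds), cfg)

    def test_any_normal_plasma_cell_presence_blocks(self, cfg):
        ds = self._dataset(n_present_mmc=18, bmpc_calls=("P",) + ("A",) * 6)
        assert not m.aberrant_in_mmc(ds, self._view(ds), cfg)


class TestDifferentiation:
    def test_pooled_group_sizes_match_study(self):
        ds, truth = m.generate_dataset(m.SyntheticConfig(seed=0))
        views, _ = m.gene_views(
            m.scale_dataset(ds, m.AnalysisConfig()),
            truth.catalog.ligands()[:3],
            m.AnalysisConfig(),
        )
        results = m.differentiation_analysis(ds, views, m.AnalysisConfig())
        pooled = [r for r in results if r.contrast == "B_vs_PPCBMPC"]
        assert pooled[0].contrast_result.n_a == 6
        assert pooled[0].contrast_result.n_b == 14

    def test_flat_gene_has_no_direction(self):
        genes = [m.PlantedGene("F1", "SHARED", ALL_POPS)]
        ds, truth = small_synthetic(genes)
        dr = m.DifferentiationModel(ds, catalog=truth.catalog).fit()
        assert set(dr.table["direction"]) == {"none"}

    def test_planted_late_stage_elevation_detected(self):
        genes = [
            m.PlantedGene(
                "L1", "SHARED", ALL_POPS, elevated_populations=("BMPC",),
                fold_elevation=4.0,
            )
        ]
        ds, truth = small_synthetic(genes)
        dr = m.DifferentiationModel(ds, catalog=truth.catalog).fit()
        row = dr.table.set_index("contrast").loc["PPC_vs_BMPC"]
        assert row["direction"] == "up_in_second"

    def test_missing_stage_population_reported(self):
        sizes = dict(SMALL_SIZES)
        sizes["PPC"] = 0
        synth = m.SyntheticConfig(
            population_sizes=sizes,
            genes=(m.PlantedGene("G", "SHARED", ("MMC", "CD14")),),
            n_background_probes=50,
        )
        ds, truth = m.generate_dataset(synth)
        with pytest.raises(ValueError, match="PPC"):
            m.DifferentiationModel(ds, catalog=truth.catalog).fit()
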