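"""Generator contracts: determinism, calibration, planted-truth recovery."""

import numpy as np
import pytest

import mgfscreen as m
from conftest import SMALL_SIZES


class TestGeneration:
    def test_same_seed_gives_bitwise_identical_data(self):
        a, _ = m.generate_dataset(m.SyntheticConfig(seed=7))
        b, _ = m.generate_dataset(m.SyntheticConfig(seed=7))
        assert a.signal.equals(b.signal)
        assert a.call.equals(b.call)
        c, _ = m.generate_dataset(m.SyntheticConfig(seed=8))
        assert not a.signal.equals(c.signal)

    def test_sample_counts_match_configuration(self):
        cfg = m.SyntheticConfig(seed=0)
        ds, _ = m.generate_dataset(cfg)
        assert ds.n_samples == sum(cfg.population_sizes.values())
        assert len(ds.samples_in("MMC")) == 131
        assert len(ds.samples_in("OC")) == 7
        assert len(ds.samples_in("WBM")) == 0

    def test_wbm_mixture_generated_on_request(self):
        sizes = dict(SMALL_SIZES, WBM=6)
        ds, _ = m.generate_dataset(
            m.SyntheticConfig(population_sizes=sizes, seed=1, n_background_probes=50)
        )
        assert len(ds.samples_in("WBM")) == 6

    def test_decoy_probes_present_and_primary_selected(self, cfg):
        ds, truth = m.generate_dataset(m.SyntheticConfig(seed=2))
        assert truth.probe_map["FGF7"] == ("FGF7_01_at", "FGF7_02_at")
        view = m.select_probeset(truth.catalog.get("FGF7"), ds)
        assert view.chosen_probe == "FGF7_01_at"

    def test_inconsistent_planted_gene_rejected(self):
        with pytest.raises(ValueError, match="MMC"):
            m.PlantedGene(
                "BAD", "MYELOMA", ("MMC",), elevated_populations=("BMSC",)
            ).validate()
        with pytest.raises(ValueError, match="environment"):
            m.PlantedGene("BAD", "SHARED", ("MMC",)).validate()

    def test_roundtrip_through_dataset_files(self, tmp_path):
        ds, _ = m.generate_dataset(
            m.SyntheticConfig(
                population_sizes=dict(SMALL_SIZES), seed=4, n_background_probes=20
            )
        )
        paths = (tmp_path / "s.tsv", tmp_path / "c.tsv", tmp_path / "m.tsv")
        m.write_dataset(ds, *paths)
        again = m.load_dataset(*paths)
        assert np.array_equal(again.signal.to_numpy(), ds.signal.to_numpy())
        assert again.call.equals(ds.call)


class TestCalibration:
    def test_present_call_rates_within_three_binomial_se(self):
        cfg = m.SyntheticConfig(seed=9)
        ds, truth = m.generate_dataset(cfg)
        mmc = ds.samples_in("MMC")
        n = len(mmc)
        for symbol, expected in (
            ("FGF7", cfg.present_prob_expressing),   # expressing in MMC
            ("FGF3", cfg.present_prob_silent),       # silent everywhere
            ("NRG2", 0.10),                          # planted partial presence
        ):
            probe = truth.probe_map[symbol][0]
            observed = float(np.mean(ds.call.loc[probe, mmc] == "P"))
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) <= 3 * se + 1e-12

    def test_realized_fold_within_three_se(self):
        cfg = m.SyntheticConfig(seed=10)
        ds, truth = m.generate_dataset(cfg)
        planted_log2 = np.log2(8.0)
        for symbol, n_win in (("FGF7", 131), ("BDNF", 5), ("IGF1", 7)):
            realized = truth.realized_log2_fold[symbol]
            n_ref = sum(cfg.population_sizes.values()) - n_win
            se = cfg.within_pop_log2_sd * np.sqrt(1 / n_win + 1 / n_ref)
            assert abs(realized - planted_log2) <= 3 * se

    def test_null_config_plants_no_effects(self):
        cfg = m.null_config(n_genes=5, seed=0)
        assert all(g.fold_elevation == 1.0 for g in cfg.genes)
        ds, truth = m.generate_dataset(cfg)
        assert ds.n_samples == 136


class TestRecovery:
    def test_identity_assignment_gives_identity_confusion(self):
        _, truth = m.generate_dataset(
            m.SyntheticConfig(population_sizes=dict(SMALL_SIZES),
                              n_background_probes=0, seed=0)
        )
        assignments = [
            m.CategoryAssignment(g.gene_symbol, g.planted_category, None)
            for g in truth.genes
        ]
        report = m.recovery_report(truth, assignments)
        assert report.overall_accuracy == 1.0
        assert all(v == 1.0 for v in report.recall.values())
        off_diag = report.confusion.to_numpy().sum() - np.trace(
            report.confusion.to_numpy()
        )
        assert off_diag == 0

    def test_single_miss_moves_one_off_diagonal(self):
        _, truth = m.generate_dataset(
            m.SyntheticConfig(population_sizes=dict(SMALL_SIZES),
                              n_background_probes=0, seed=0)
        )
        assignments = [
            m.CategoryAssignment(g.gene_symbol, g.planted_category, None)
            for g in truth.genes
        ]
        victim = next(
            i for i, g in enumerate(truth.genes) if g.planted_category == "MYELOMA"
        )
        assignments[victim] = m.CategoryAssignment(
            truth.genes[victim].gene_symbol, "SHARED", None
        )
        report = m.recovery_report(truth, assignments)
        assert report.confusion.loc["MYELOMA", "SHARED"] == 1
        assert report.recall["MYELOMA"] == pytest.approx(2 / 3)

    def test_gene_universe_mismatch_rejected(self):
        _, truth = m.generate_dataset(
            m.SyntheticConfig(population_sizes=dict(SMALL_SIZES),
                              n_background_probes=0, seed=0)
        )
        with pytest.raises(ValueError, match="universes"):
            m.recovery_report(truth, [m.CategoryAssignment("NOBODY", "SHARED", None)])

    def test_noise_free_limit_recovers_every_planted_gene(self):
        cfg = m.SyntheticConfig(
            seed=0,
            within_pop_log2_sd=1e-9,
            present_prob_expressing=1.0,
            present_prob_silent=0.0,
        )
        ds, truth = m.generate_dataset(cfg)
        results = m.CompartmentModel(ds, catalog=truth.catalog).fit()
        report = m.recovery_report(truth, results.assignments)
        assert report.overall_accuracy == 1.0
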