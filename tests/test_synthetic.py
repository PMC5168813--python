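"""Generator correctness: planted correlation structure, links, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedmet import (SynthConfig, generate_dataset, generate_germination,
                     generate_metabolite_latents, generate_morphology,
                     latents_to_peaks, normalize_peaks, welch_t_test)
from seedmet.normalize import PeakTable
from seedmet.synthetic import substream


def _null_config(**overrides):
    """All planted effects switched off."""
    base = dict(
        qtl_lines_frac=0.0, deteriorated_frac=0.0, treatment_effect=0.0,
        abortion_salinity_effect=0.0, germ_beta=0.0, t50_gamma=0.0,
        weight_qtl_lines={},
    )
    base.update(overrides)
    return SynthConfig(**base)


class TestLatents:
    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="set_sizes"):
            SynthConfig(n_metabolites=10, set_sizes=(4, 4))
        with pytest.raises(ValueError, match="rho_within"):
            SynthConfig(rho_within=-0.2)

    def test_degenerate_perfect_correlation(self):
        cfg = _null_config(n_ils=2, n_metabolites=4, set_sizes=(2, 2),
                           rho_within=1.0, rho_between=-1.0, rng_seed=3)
        _, latents, _ = generate_metabolite_latents(cfg)
        corr = latents.corr().to_numpy()
        expected = np.array([[1, 1, -1, -1], [1, 1, -1, -1],
                             [-1, -1, 1, 1], [-1, -1, 1, 1]], dtype=float)
        np.testing.assert_allclose(corr, expected, atol=1e-9)

    def test_infeasible_correlation_rejected(self):
        # large between-set |rho| with big blocks cannot be PSD
        cfg = _null_config(n_metabolites=20, set_sizes=(10, 10),
                           rho_within=0.1, rho_between=-0.9)
        with pytest.raises(ValueError, match="infeasible correlation"):
            generate_metabolite_latents(cfg)

    def test_empirical_correlations_near_targets(self):
        # 49 ILs + control, 5 plots, 2 treatments -> 500 rows
        cfg = _null_config(n_ils=49, n_plots=5, n_metabolites=12,
                           set_sizes=(8, 4), rng_seed=5)
        _, latents, truth = generate_metabolite_latents(cfg)
        corr = latents.corr()
        s1 = [m for m, s in truth.set_assignment.items() if s == "S1"]
        s2 = [m for m, s in truth.set_assignment.items() if s == "S2"]
        within = np.concatenate([
            corr.loc[s1, s1].to_numpy()[np.triu_indices(len(s1), 1)],
            corr.loc[s2, s2].to_numpy()[np.triu_indices(len(s2), 1)],
        ])
        between = corr.loc[s1, s2].to_numpy().ravel()
        assert abs(within.mean() - cfg.rho_within) < 0.1
        assert abs(between.mean() - cfg.rho_between) < 0.1

    def test_null_lines_reject_at_alpha(self):
        # with no planted effects, IL-vs-control t-tests are null: the
        # rejection rate over independent replicate experiments sits at alpha
        alpha, reps = 0.05, 400
        rejections = 0
        for seed in range(reps):
            cfg = _null_config(n_ils=1, n_plots=5, n_metabolites=4,
                               set_sizes=(2, 2), rng_seed=100_000 + seed)
            meta, latents, _ = generate_metabolite_latents(cfg)
            sdf = meta["treatment"] == "SDF"
            x = latents.loc[sdf & (meta["line"] == "IL01"), "met01"]
            y = latents.loc[sdf & (meta["line"] == "M82"), "met01"]
            _, _, p = welch_t_test(x, y)
            rejections += p < alpha
        rate = rejections / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se

    def test_balance_score_is_set_mean_difference(self, tiny_dataset):
        truth = tiny_dataset.truth
        s1 = [m for m, s in truth.set_assignment.items() if s == "S1"]
        s2 = [m for m, s in truth.set_assignment.items() if s == "S2"]
        cfg = tiny_dataset.config
        _, latents, _ = generate_metabolite_latents(cfg)
        expected = latents[s2].mean(axis=1) - latents[s1].mean(axis=1)
        pd.testing.assert_series_equal(truth.balance_score, expected)


class TestPeaks:
    def test_identity_when_factors_unity(self):
        cfg = _null_config(n_ils=3, n_metabolites=6, set_sizes=(4, 2),
                           block_sigma=0.0, load_sigma=0.0,
                           seed_mass_mean=1.0, seed_mass_sd=0.0,
                           missing_frac=0.0, rng_seed=2)
        meta, latents, _ = generate_metabolite_latents(cfg)
        peaks = latents_to_peaks(latents, meta, cfg)
        np.testing.assert_allclose(
            peaks[cfg.metabolites].to_numpy(), np.exp(latents.to_numpy()))

    def test_doubled_load_removed_by_sum_normalization(self):
        cfg = _null_config(n_ils=3, n_metabolites=6, set_sizes=(4, 2),
                           missing_frac=0.0, rng_seed=4)
        meta, latents, _ = generate_metabolite_latents(cfg)
        peaks = latents_to_peaks(latents, meta, cfg)
        doubled = peaks.copy()
        sample = doubled.index[0]
        doubled.loc[sample, cfg.metabolites] *= 2.0

        def rmc(df):
            pt = PeakTable(
                meta=df[["line", "treatment", "season", "plot", "run_block",
                         "seed_mass_extracted"]],
                peaks=df[cfg.metabolites])
            return normalize_peaks(pt).values

        pd.testing.assert_frame_equal(rmc(peaks), rmc(doubled))

    def test_missingness_fraction(self):
        cfg = _null_config(n_ils=20, n_metabolites=16, set_sizes=(10, 6),
                           missing_frac=0.05, rng_seed=6)
        meta, latents, _ = generate_metabolite_latents(cfg)
        peaks = latents_to_peaks(latents, meta, cfg)
        frac = peaks[cfg.metabolites].isna().to_numpy().mean()
        n_cells = peaks[cfg.metabolites].size
        tol = 4 * np.sqrt(0.05 * 0.95 / n_cells)
        assert abs(frac - 0.05) < tol


class TestGermination:
    def test_null_link_uncorrelated(self):
        cfg = _null_config(n_ils=30, n_plots=5, n_metabolites=8,
                           set_sizes=(5, 3), n_plates=1, rng_seed=8)
        meta, latents, truth = generate_metabolite_latents(cfg)
        germ = generate_germination(truth.balance_score, meta, cfg)
        percent = 100 * germ.groupby("plate_id")["cumulative"].max() \
            / cfg.seeds_per_plate
        key = germ.groupby("plate_id").first()
        sample = key["line"] + "_" + key["treatment"] + "_" + \
            key["plot"].astype(str)
        score = truth.balance_score.loc[sample].to_numpy()
        r, _ = stats.spearmanr(score, percent.to_numpy())
        assert abs(r) < 0.1

    def test_positive_link_significant(self, tiny_dataset):
        germ = tiny_dataset.germination
        percent = 100 * germ.groupby("plate_id")["cumulative"].max() \
            / tiny_dataset.config.seeds_per_plate
        key = germ.groupby("plate_id").first()
        sample = key["line"] + "_" + key["treatment"] + "_" + \
            key["plot"].astype(str)
        score = tiny_dataset.truth.balance_score.loc[sample].to_numpy()
        r, p = stats.spearmanr(score, percent.to_numpy())
        assert r > 0.3
        assert p < 1e-6

    def test_extreme_negative_score_gives_empty_plate(self):
        cfg = _null_config(n_ils=1, n_metabolites=4, set_sizes=(2, 2),
                           germ_beta=2.5)
        meta, _, _ = generate_metabolite_latents(cfg)
        score = pd.Series(-50.0, index=meta.index)
        germ = generate_germination(score, meta, cfg)
        assert (germ["cumulative"] == 0).all()


class TestMorphology:
    def test_salinity_increases_abortion_by_construction(self, tiny_dataset):
        morph = tiny_dataset.morphology
        mat = 100 * morph["mature"] / (morph["mature"] + morph["aborted"])
        assert mat[morph["treatment"] == "SDS"].mean() \
            < mat[morph["treatment"] == "SDF"].mean()

    def test_null_salinity_abortion_not_biased(self):
        reps, alpha, rejections = 200, 0.05, 0
        for seed in range(reps):
            cfg = _null_config(n_ils=2, n_metabolites=4, set_sizes=(2, 2),
                               rng_seed=200_000 + seed)
            meta, _, _ = generate_metabolite_latents(cfg)
            morph = generate_morphology(meta, cfg)
            mat = 100 * morph["mature"] / (morph["mature"] + morph["aborted"])
            _, _, p = welch_t_test(mat[morph["treatment"] == "SDS"],
                                   mat[morph["treatment"] == "SDF"])
            rejections += p < alpha
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_weight_unaffected_by_treatment(self, tiny_dataset):
        morph = tiny_dataset.morphology
        _, _, p = welch_t_test(
            morph.loc[morph["treatment"] == "SDS", "avg_seed_weight"],
            morph.loc[morph["treatment"] == "SDF", "avg_seed_weight"])
        assert p > 0.01


class TestReproducibility:
    def test_same_seed_bit_identical(self, tiny_config):
        a = generate_dataset(tiny_config)
        b = generate_dataset(tiny_config)
        pd.testing.assert_frame_equal(a.peaks, b.peaks)
        pd.testing.assert_frame_equal(a.germination, b.germination)
        pd.testing.assert_frame_equal(a.morphology, b.morphology)
        assert a.truth.set_assignment == b.truth.set_assignment
        assert a.truth.qtl_map == b.truth.qtl_map

    def test_substreams_are_independent_of_each_other(self):
        assert substream(1, "latents").random() != substream(1, "peaks").random()
        assert substream(1, "latents").random() == substream(1, "latents").random()

    def test_ground_truth_serialization_round_trip(self, tiny_dataset, tmp_path):
        paths = tiny_dataset.write(tmp_path)
        gt = pd.read_csv(paths["ground_truth"], sep="\t")
        sets = gt[gt["kind"] == "set"].set_index("key")["value"].to_dict()
        assert sets == tiny_dataset.truth.set_assignment
        qtls = gt[gt["kind"] == "qtl"]
        assert len(qtls) == len(tiny_dataset.truth.qtl_map)
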