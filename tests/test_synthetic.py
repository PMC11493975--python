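"""Ground-truth generators: determinism, calibration, and expectation checks."""

import numpy as np
import pytest

from isletage.birthdating import label_after_divisions
from isletage.maldi import auc_from_samples
from isletage.synthetic import (
    IonSpec,
    LabelingProtocol,
    MIMSSynthConfig,
    RegulonSpec,
    TurnoverParams,
    cohort_to_frame,
    expected_channel_means,
    random_grn_truth,
    simulate_cohort,
    simulate_nucleus_counts,
    synthesize_activity_matrix,
    synthesize_grn_runs,
    synthesize_ion_images,
    synthesize_mims_frames,
    synthesize_tolerance_curves,
)

PROTOCOL = LabelingProtocol()  # e0 = 0.98 - 0.0037, 12-month chase


class TestCohort:
    def test_all_quiescent_retain_full_label(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("CR", 1.0, 5.0), 50, seed=0)
        assert all(c.true_divisions == 0 for c in cells)
        assert all(c.true_excess == pytest.approx(PROTOCOL.e0) for c in cells)

    def test_zero_rate_means_no_divisions(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("AL", 0.0, 0.0), 50, seed=0)
        assert all(c.true_divisions == 0 for c in cells)

    def test_poisson_mean_of_divisions(self):
        lam_total = 2.0
        params = TurnoverParams("HFD", 0.0, lam_total / PROTOCOL.chase_months)
        cells = simulate_cohort(PROTOCOL, params, 10_000, seed=1)
        mean_k = np.mean([c.true_divisions for c in cells])
        assert abs(mean_k - lam_total) <= 3 * np.sqrt(lam_total / 10_000)

    def test_neurons_are_postmitotic(self):
        cells = simulate_cohort(
            PROTOCOL, TurnoverParams("AL", 0.0, 1.0), 30, seed=2, cell_type="neuron"
        )
        assert all(c.true_divisions == 0 for c in cells)

    def test_excess_satisfies_dilution_law_exactly(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("HFD", 0.3, 0.4), 500, seed=3)
        for c in cells:
            assert c.true_excess == label_after_divisions(PROTOCOL.e0, c.true_divisions)

    def test_deterministic_and_frame_export(self):
        params = TurnoverParams("AL", 0.5, 0.2)
        a = simulate_cohort(PROTOCOL, params, 20, seed=7)
        b = simulate_cohort(PROTOCOL, params, 20, seed=7)
        assert a == b
        df = cohort_to_frame(a)
        assert list(df.columns) == [
            "cell_id", "cell_type", "group", "true_divisions", "true_excess",
        ]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TurnoverParams("AL", 1.2, 0.1)
        with pytest.raises(ValueError):
            TurnoverParams("AL", 0.5, -0.1)
        with pytest.raises(ValueError):
            simulate_cohort(PROTOCOL, TurnoverParams("AL", 0.5, 0.1), 0, seed=0)
        with pytest.raises(ValueError):
            LabelingProtocol(natural_abundance=0.0)


class TestMimsSynthesis:
    def test_empty_cohort_background_only(self):
        config = MIMSSynthConfig(shape=(64, 64), n_fiducials=0)
        frames, mask, truth = synthesize_mims_frames([], config, seed=0)
        assert mask.max() == 0 and truth == {}
        assert frames[0].channels["15N"].mean() < 1.0  # background dose * f_nat

    def test_same_seed_identical_rasters(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("AL", 0.5, 0.2), 5, seed=1)
        config = MIMSSynthConfig(shape=(128, 128))
        f1, m1, _ = synthesize_mims_frames(cells, config, seed=9)
        f2, m2, _ = synthesize_mims_frames(cells, config, seed=9)
        np.testing.assert_array_equal(m1, m2)
        for ch in f1[0].channels:
            np.testing.assert_array_equal(f1[0].channels[ch], f2[0].channels[ch])

    def test_per_pixel_poisson_mean(self):
        # e=0.3, f_nat=0.0037 -> f=0.3037; D=1000 -> mean 15N count 303.7
        protocol = LabelingProtocol(initial_excess=0.3, chase_months=0.0)
        cells = simulate_cohort(protocol, TurnoverParams("AL", 1.0, 0.0), 1, seed=0)
        config = MIMSSynthConfig(
            shape=(256, 256), n_frames=1, dose_per_pixel=1000.0,
            nucleus_radius_range=(60.0, 60.0), hotspot_fraction=0.0, n_fiducials=0,
        )
        frames, mask, _ = synthesize_mims_frames(cells, config, seed=5)
        pix = frames[0].channels["15N"][mask == 1]
        assert pix.size >= 10_000
        se = np.sqrt(303.7 / pix.size)
        assert abs(pix.mean() - 303.7) <= 3 * se

    def test_expectation_conserved_before_sampling(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("CR", 0.8, 0.1), 6, seed=2)
        config = MIMSSynthConfig(shape=(128, 128))
        mean15, mean14 = expected_channel_means(cells, config, seed=3)
        # channel expectations partition the dose exactly
        _, mask, truth = synthesize_mims_frames(cells, config, seed=3)
        total = mean15 + mean14
        for lab, cell in truth.items():
            f = config.f_nat + cell.true_excess
            roi = mask == lab
            np.testing.assert_allclose(mean15[roi], total[roi] * f, atol=1e-9)
            np.testing.assert_allclose(mean14[roi], total[roi] * (1 - f), atol=1e-9)

    def test_hotspots_raise_dose_not_atom_fraction(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("CR", 1.0, 0.0), 1, seed=0)
        config = MIMSSynthConfig(
            shape=(128, 128), hotspot_fraction=0.5, hotspot_factor=3.0, n_fiducials=0
        )
        mean15, mean14 = expected_channel_means(cells, config, seed=1)
        _, mask, truth = synthesize_mims_frames(cells, config, seed=1)
        roi = mask == 1
        f = mean15[roi] / (mean15[roi] + mean14[roi])
        np.testing.assert_allclose(f, config.f_nat + truth[1].true_excess, atol=1e-12)
        assert np.unique((mean15 + mean14)[roi]).size == 2  # hot and cold doses

    def test_raster_too_small(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("AL", 0.5, 0.2), 40, seed=1)
        with pytest.raises(ValueError, match="too small"):
            synthesize_mims_frames(cells, MIMSSynthConfig(shape=(48, 48)), seed=0)

    def test_fast_count_measurements_match_binomial_se(self):
        cells = simulate_cohort(PROTOCOL, TurnoverParams("CR", 1.0, 0.0), 300, seed=4)
        ms = simulate_nucleus_counts(cells, total_dose=1e5, seed=5)
        f_true = 0.0037 + PROTOCOL.e0
        errs = np.array([m.atom_fraction - f_true for m in ms])
        se = np.sqrt(f_true * (1 - f_true) / 1e5)
        assert (np.abs(errs) <= 4 * se).mean() >= 0.99


class TestGrnRuns:
    def test_perfect_runs_equal_truth(self):
        truth = random_grn_truth(5, 20, 30, seed=0)
        rs = synthesize_grn_runs(truth, n_runs=5, p_true=1.0, p_false=0.0, seed=1)
        for run in rs.runs:
            assert {(tf, t) for tf, t, _ in run} == set(truth.true_edges)

    def test_degenerate_all_empty(self):
        truth = random_grn_truth(3, 10, 10, seed=0)
        rs = synthesize_grn_runs(truth, n_runs=4, p_true=0.0, p_false=0.0, seed=1)
        assert all(run == [] for run in rs.runs)

    def test_per_edge_support_calibrated(self):
        truth = random_grn_truth(10, 50, 50, seed=2)
        rs = synthesize_grn_runs(truth, 100, p_true=0.9, p_false=0.001, seed=3)
        counts = {e: 0 for e in truth.true_edges}
        for run in rs.runs:
            for tf, tgt, _ in run:
                if (tf, tgt) in counts:
                    counts[(tf, tgt)] += 1
        mean_support = np.mean([c / 100 for c in counts.values()])
        assert abs(mean_support - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / 100)

    def test_no_self_edges_in_truth(self):
        from isletage.synthetic import GRNTruth

        with pytest.raises(ValueError):
            GRNTruth({("A", "A"): 1.0}, 1, 1)

    def test_parameter_validation(self):
        truth = random_grn_truth(3, 10, 5, seed=0)
        with pytest.raises(ValueError):
            synthesize_grn_runs(truth, 5, p_true=0.5, p_false=0.9, seed=0)


class TestActivityMatrix:
    def test_degenerate_on_fractions(self):
        act, labels = synthesize_activity_matrix(
            100,
            [RegulonSpec("off", 0.0), RegulonSpec("on", 1.0)],
            seed=0,
        )
        assert not labels["off"].any() and labels["on"].all()
        assert act["off"].mean() < 0.3 < act["on"].mean()

    def test_on_count_binomial(self):
        spec = RegulonSpec("R", 0.5, on_mean=0.8, on_sd=0.02, off_mean=0.1, off_sd=0.02)
        _, labels = synthesize_activity_matrix(500, [spec], seed=1)
        assert abs(labels["R"].sum() - 250) <= 3 * np.sqrt(500 * 0.25)

    def test_bounded_and_deterministic(self):
        specs = [RegulonSpec("R", 0.4)]
        a1, l1 = synthesize_activity_matrix(200, specs, seed=2)
        a2, l2 = synthesize_activity_matrix(200, specs, seed=2)
        assert a1.equals(a2) and l1.equals(l2)
        assert (a1.to_numpy() >= 0).all() and (a1.to_numpy() <= 1).all()

    def test_mode_outside_unit_interval(self):
        with pytest.raises(ValueError):
            RegulonSpec("R", 0.5, on_mean=1.2)


class TestIonImages:
    def _masks(self, n=20):
        a = np.zeros((n, n), dtype=bool)
        b = np.zeros((n, n), dtype=bool)
        a[:, : n // 2] = True
        b[:, n // 2 :] = True
        return a, b

    def test_zero_effect_gives_null_auc(self):
        a, b = self._masks(20)  # 200 pixels per class
        aucs = []
        for seed in range(50):
            img = synthesize_ion_images(a, b, [IonSpec(300.0, 0.0)], seed=seed)[0]
            aucs.append(auc_from_samples(img.intensities[a], img.intensities[b]))
        na = nb = 200
        se_null = np.sqrt((na + nb + 1) / (12 * na * nb) / 50)
        assert abs(np.mean(aucs) - 0.5) <= 3 * se_null

    def test_huge_effect_saturates_auc(self):
        a, b = self._masks(10)
        img = synthesize_ion_images(a, b, [IonSpec(300.0, 20.0)], seed=1)[0]
        assert auc_from_samples(img.intensities[a], img.intensities[b]) == 1.0

    def test_deterministic_and_disjointness_enforced(self):
        a, b = self._masks(10)
        i1 = synthesize_ion_images(a, b, [IonSpec(300.0, 1.0)], seed=2)[0]
        i2 = synthesize_ion_images(a, b, [IonSpec(300.0, 1.0)], seed=2)[0]
        np.testing.assert_array_equal(i1.intensities, i2.intensities)
        with pytest.raises(ValueError):
            synthesize_ion_images(a, a, [IonSpec(300.0, 1.0)], seed=0)
        with pytest.raises(ValueError):
            synthesize_ion_images(a, np.zeros_like(b), [IonSpec(300.0, 1.0)], seed=0)


class TestToleranceCurves:
    def test_zero_decay_no_noise_is_flat(self):
        c, _ = synthesize_tolerance_curves(0.0, 150.0, [0, 10, 20], 0.0, seed=0)
        np.testing.assert_allclose(c.glucose, 150.0)

    def test_baseline_at_time_zero(self):
        c, _ = synthesize_tolerance_curves(0.02, 150.0, [0, 30, 60], 0.0, seed=0)
        assert c.glucose[0] == pytest.approx(150.0)

    def test_exponential_evaluation(self):
        c, _ = synthesize_tolerance_curves(0.02, 150.0, [0, 30, 60], 0.0, seed=0)
        assert c.glucose[-1] == pytest.approx(150 * np.exp(-1.2), abs=0.005)

    def test_validation(self):
        with pytest.raises(ValueError):
            synthesize_tolerance_curves(0.02, -5.0, [0, 10], 0.0, seed=0)
        with pytest.raises(ValueError):
            synthesize_tolerance_curves(0.02, 150.0, [10, 0], 0.0, seed=0)
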