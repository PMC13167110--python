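"""Synthetic ROI datasets, metrics, perturbation sweeps, and image fixtures."""

import math

import numpy as np
import pytest

from fluomux.simulate import (
    GroundTruth,
    Metrics,
    SimulationConfig,
    dual_label_config,
    equal_distribution_config,
    evaluate_assignments,
    noise_sd,
    prevalence_config,
    realistic_config,
    run_sweep,
    simulate_image_pair,
    simulate_roi_dataset,
    simulate_vessel_pair,
)
from fluomux.unmix import AssignmentResult, classify_subject


def _assign(roi, primary, secondaries=()):
    ids = ({primary} if primary else set()) | set(secondaries)
    return AssignmentResult(roi, ids, primary, tuple(secondaries), 1, {})


class TestDataset:
    def test_same_seed_is_bit_identical(self, library):
        cfg = realistic_config(seed=11, n_rois=50)
        sp1, t1 = simulate_roi_dataset(cfg, library)
        sp2, t2 = simulate_roi_dataset(cfg, library)
        assert t1.labels == t2.labels
        for a, b in zip(sp1, sp2):
            assert np.array_equal(a.values, b.values)

    def test_no_perturbation_gives_exact_scaled_references(self, library):
        cfg = equal_distribution_config(library.names, n_rois=30, snr=math.inf, seed=2)
        spectra, truth = simulate_roi_dataset(cfg, library)
        for s, lab, amps in zip(spectra, truth.labels, truth.amplitudes):
            assert np.allclose(s.values, amps[0] * library[lab[0]].values, atol=1e-12)

    def test_noise_sd_matches_definition(self, library, rng):
        cfg = equal_distribution_config(library.names, n_rois=10000, snr=5.0, seed=3)
        spectra, truth = simulate_roi_dataset(cfg, library, rng=rng)
        expected_sd = truth.perturbation["mean_amplitude"] / 5.0
        residuals = []
        for s, lab, amps in zip(spectra, truth.labels, truth.amplitudes):
            clean = amps[0] * library[lab[0]].values
            sel = clean > 4 * expected_sd  # channels safe from zero-clipping
            residuals.append((s.values - clean)[sel])
        sd = np.concatenate(residuals).std()
        assert sd == pytest.approx(expected_sd, rel=0.02)

    def test_dual_label_rois_list_two_distinct_fluorophores(self, library):
        cfg = dual_label_config(library.names, n_per_group=2, seed=4)
        spectra, truth = simulate_roi_dataset(cfg, library)
        n_pairs = sum(1 for lab in truth.labels if len(lab) == 2)
        assert n_pairs == 2 * 45
        for lab in truth.labels:
            if len(lab) == 2:
                assert lab[0] != lab[1]

    def test_gcamp_background_requires_gcamp_reference(self, library, injected):
        cfg = equal_distribution_config(injected, n_rois=5, gcamp_fraction=0.3, seed=0)
        with pytest.raises(ValueError, match="GCaMP"):
            simulate_roi_dataset(cfg, library.subset(injected))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig({"A": 0.4, "B": 0.4})
        with pytest.raises(ValueError):
            SimulationConfig({"A": 1.0}, snr=0.0)
        assert noise_sd(1.0, math.inf) == 0.0


class TestEvaluate:
    def test_all_correct(self):
        truth = GroundTruth(["a", "b"], [("X",), ("Y",)], [(1.0,), (1.0,)])
        m = evaluate_assignments([_assign("a", "X"), _assign("b", "Y")], truth)
        assert (m.accuracy, m.false_negative_rate, m.false_positive_rate) == (1, 0, 0)

    def test_crafted_set_matches_hand_tally(self):
        truth = GroundTruth(
            [f"r{i}" for i in range(10)],
            [("X",)] * 4 + [("Y",)] * 3 + [("X", "Y")] * 3,
            [(1.0,)] * 7 + [(1.0, 1.0)] * 3,
        )
        results = [
            _assign("r0", "X"),  # correct
            _assign("r1", "X"),  # correct
            _assign("r2", None),  # FN
            _assign("r3", "Y"),  # FP
            _assign("r4", "Y"),  # correct
            _assign("r5", None),  # FN
            _assign("r6", "Y"),  # correct
            _assign("r7", "X"),  # dual: one of pair
            _assign("r8", "X", ["Y"]),  # dual: both
            _assign("r9", "Z", ["X"]),  # dual: one of pair + outside FP
        ]
        m = evaluate_assignments(results, truth)
        assert m.n_single == 7 and m.n_dual == 3
        assert m.accuracy == pytest.approx(4 / 7)
        assert m.false_negative_rate == pytest.approx(2 / 7)
        assert m.false_positive_rate == pytest.approx(1 / 7)
        assert m.accuracy + m.false_negative_rate + m.false_positive_rate == pytest.approx(1.0)
        assert m.dual_at_least_one == pytest.approx(1.0)
        assert m.dual_both == pytest.approx(1 / 3)
        assert m.dual_secondary_fp == pytest.approx(1 / 3)
        assert m.per_fluorophore["X"]["accuracy"] == pytest.approx(2 / 4)

    def test_partial_dual_hit_is_not_a_false_positive(self):
        truth = GroundTruth(["d"], [("A", "B")], [(1.0, 1.0)])
        m = evaluate_assignments([_assign("d", "A")], truth)
        assert m.dual_at_least_one == 1.0
        assert m.dual_both == 0.0
        assert m.dual_secondary_fp == 0.0

    def test_id_mismatch_rejected(self):
        truth = GroundTruth(["a"], [("X",)], [(1.0,)])
        with pytest.raises(ValueError):
            evaluate_assignments([_assign("zzz", "X")], truth)

    def test_metrics_invariant_under_consistent_relabeling(self, library, injected):
        cfg = equal_distribution_config(library.names, n_rois=60, seed=8)
        spectra, truth = simulate_roi_dataset(cfg, library)
        res = classify_subject(spectra, library)
        m = evaluate_assignments(res.assignments, truth)
        mapping = {n: f"f{i}" for i, n in enumerate(library.names)}
        relabeled = [
            AssignmentResult(
                a.roi_id,
                {mapping[h] for h in a.hits},
                mapping[a.primary] if a.primary else None,
                tuple(mapping[s] for s in a.secondaries),
                a.pass_id,
                {},
            )
            for a in res.assignments
        ]
        truth2 = GroundTruth(
            truth.roi_ids,
            [tuple(mapping[n] for n in lab) for lab in truth.labels],
            truth.amplitudes,
        )
        m2 = evaluate_assignments(relabeled, truth2)
        assert m2.accuracy == m.accuracy
        assert m2.false_positive_rate == m.false_positive_rate


class TestSweep:
    def test_accuracy_nonincreasing_with_noise(self, library, injected):
        base = equal_distribution_config(injected, n_rois=200, seed=13)
        df = run_sweep(
            base, "snr", [20.0, 4.0], library,
            classifier_options={"assignable": injected}, replicates=3,
        )
        mean_acc = df.groupby("value")["accuracy"].mean()
        sd = df.groupby("value")["accuracy"].std().max()
        assert mean_acc[4.0] <= mean_acc[20.0] + max(2 * sd, 0.02)

    def test_dual_pass_beats_single_pass_at_high_prevalence(self, library):
        names = list(library.names)
        base = prevalence_config(names, "mOrange2", 0.8, n_rois=200, seed=14)
        kw = dict(replicates=3)
        df_dual = run_sweep(base, "prevalence", [0.8], library,
                            classifier_options={"dual_pass": True}, **kw)
        df_single = run_sweep(base, "prevalence", [0.8], library,
                              classifier_options={"dual_pass": False}, **kw)
        assert (df_dual["acc_mOrange2"].to_numpy()
                > df_single["acc_mOrange2"].to_numpy()).all()

    def test_unknown_axis_rejected(self, library):
        base = equal_distribution_config(library.names, n_rois=10)
        with pytest.raises(ValueError):
            run_sweep(base, "pinhole", [1.0], library, replicates=1)


class TestImageFixtures:
    def test_vessel_pair_deterministic(self):
        from fluomux.register import SimilarityTransform

        t = SimilarityTransform(3.0, -2.0, 4.0, 1.0)
        a1, b1 = simulate_vessel_pair(21, t)
        a2, b2 = simulate_vessel_pair(21, t)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_image_pair_scene_contents(self, library):
        from fluomux.register import SimilarityTransform

        t = SimilarityTransform(10.0, -15.0, 5.0, 1.9)
        stacks, mini, masks, truth, reference = simulate_image_pair(
            31, library, t, n_cells=10
        )
        assert set(stacks) == set(library.grid.laser_wavelengths)
        first = next(iter(stacks.values()))
        assert first.values.shape[1] == library.grid.n_bins
        assert len(masks) == len(truth.roi_ids)
        assert all(len(lab) == 1 for lab in truth.labels)
        assert mini.shape == reference.shape

    def test_zero_cells_still_renders_vessels(self, library):
        from fluomux.register import SimilarityTransform, correlation_score

        t = SimilarityTransform(6.0, -4.0, 3.0, 1.0)
        stacks, mini, masks, truth, reference = simulate_image_pair(
            33, library, t, n_cells=0, snr=1e9
        )
        assert masks == []
        # vessels alone still carry the registration signal
        assert correlation_score(reference, mini, t) > 0.8
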