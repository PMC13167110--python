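"""Beta fitting (NNLS), per-subject baselines, single- and dual-pass assignment."""

import numpy as np
import pytest

from fluomux.spectral import Fingerprint
from fluomux.unmix import (
    BaselineStats,
    BetaVector,
    ShareProfile,
    adjusted_cutoffs,
    classify_subject,
    compute_baseline,
    dual_pass_assign,
    fit_betas,
    fit_betas_many,
    single_pass_assign,
)


def _fp(library, values, label="roi"):
    grid = library.grid
    return Fingerprint(
        np.clip(np.asarray(values).reshape(grid.n_lasers, grid.n_bins), 0, None), label
    )


from oracles import fista_nnls  # noqa: E402 - independent NNLS cross-check


class TestFitBetas:
    def test_exact_library_member_recovered(self, library):
        fp = library["mVenus"]
        beta = fit_betas(fp, library)
        idx = library.names.index("mVenus")
        expect = np.zeros(len(library))
        expect[idx] = 1.0
        assert np.allclose(beta.beta_raw, expect, atol=1e-9)
        assert beta.residual == pytest.approx(0.0, abs=1e-9)

    def test_two_component_mixture_recovered(self, library):
        a = library["mTagBFP2"].values
        b = library["mNeptune2.5"].values
        beta = fit_betas(_fp(library, 0.7 * a + 0.3 * b), library)
        got = dict(zip(beta.fluorophores, beta.beta_raw))
        assert got["mTagBFP2"] == pytest.approx(0.7, abs=1e-6)
        assert got["mNeptune2.5"] == pytest.approx(0.3, abs=1e-6)
        assert sum(got.values()) == pytest.approx(1.0, abs=1e-5)

    def test_zero_spectrum_gives_zero_betas(self, library):
        beta = fit_betas(_fp(library, np.zeros(204)), library)
        assert np.all(beta.beta_raw == 0) and np.all(beta.beta_norm == 0)
        assert beta.residual == 0.0

    def test_grid_mismatch_rejected(self, library):
        bad = Fingerprint(np.ones((2, 4)))
        with pytest.raises(ValueError, match="grid"):
            fit_betas(bad, library)

    def test_agrees_with_projected_gradient_oracle(self, library, rng):
        design = library.matrix()
        for _ in range(50):
            truth = np.clip(rng.normal(0.3, 0.5, len(library)), 0, None)
            y = design @ truth + rng.normal(0, 0.02, design.shape[0])
            fp = _fp(library, y)
            beta = fit_betas(fp, library)
            oracle = fista_nnls(design, fp.flatten())
            assert np.allclose(beta.beta_raw, oracle, atol=1e-6)

    def test_many_matches_single(self, library, rng):
        fps = [
            _fp(library, library.matrix() @ np.clip(rng.normal(0.3, 0.4, 10), 0, None),
                f"r{i}")
            for i in range(5)
        ]
        singles = [fit_betas(f, library) for f in fps]
        many = fit_betas_many(fps, library)
        for s, m in zip(singles, many):
            assert np.allclose(s.beta_raw, m.beta_raw)
            assert np.allclose(s.beta_norm, m.beta_norm)


def _beta(roi, raw, norm=None, names=("A", "B")):
    raw = np.asarray(raw, float)
    return BetaVector(roi, raw, raw.copy() if norm is None else np.asarray(norm, float),
                      0.0, tuple(names))


class TestBaseline:
    def test_cutoff_is_mean_plus_k_sd(self):
        betas = [_beta(f"r{i}", [v, 0.0]) for i, v in enumerate([0.08, 0.10, 0.12])]
        base = compute_baseline(betas, k=1.5)
        sd = np.std([0.08, 0.10, 0.12])
        assert base.mean_raw[0] == pytest.approx(0.10)
        assert base.cutoff_raw[0] == pytest.approx(0.10 + 1.5 * sd)
        # the printed-rule arithmetic: mean 0.10, SD 0.02 -> cutoff 0.13
        assert 0.10 + 1.5 * 0.02 == pytest.approx(0.13)

    def test_identical_betas_give_zero_sd(self):
        base = compute_baseline([_beta(f"r{i}", [0.4, 0.1]) for i in range(5)])
        assert np.all(base.sd_raw == 0)
        assert np.allclose(base.cutoff_raw, base.mean_raw)

    def test_matches_direct_formula_oracle(self, rng):
        raws = rng.uniform(0, 1, (30, 2))
        betas = [_beta(f"r{i}", raws[i]) for i in range(30)]
        base = compute_baseline(betas)
        assert np.allclose(base.mean_raw, raws.mean(axis=0), atol=1e-12)
        assert np.allclose(base.sd_raw, raws.std(axis=0), atol=1e-12)

    def test_single_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_baseline([_beta("r0", [1.0, 2.0])])


def _baseline(names=("A", "B"), mean=0.10, sd=0.02, k=1.5):
    n = len(names)
    return BaselineStats(
        tuple(names),
        np.full(n, mean), np.full(n, sd),
        np.full(n, mean), np.full(n, sd),
        k=k,
    )


class TestSinglePass:
    def test_beta_above_cutoff_is_hit(self):
        base = _baseline()
        res = single_pass_assign(_beta("r", [0.15, 0.10]), base)
        assert res.hits == {"A"}
        assert res.primary == "A" and res.pass_id == 1

    def test_winner_take_all_by_zscore(self):
        base = _baseline(("A", "B", "C"))
        # z-scores: (0.184-0.1)/0.02 = 4.2 for A vs 2.1 for B
        res = single_pass_assign(_beta("r", [0.184, 0.142, 0.10], names=("A", "B", "C")), base)
        assert res.primary == "A"
        assert res.secondaries == ("B",)

    def test_betas_at_baseline_mean_give_no_hits(self):
        base = _baseline()
        res = single_pass_assign(_beta("r", [0.10, 0.10]), base)
        assert not res.hits and res.primary is None

    def test_hit_via_norm_channel_alone(self):
        base = _baseline()
        b = _beta("r", [0.10, 0.10], norm=[0.20, 0.10])
        res = single_pass_assign(b, base)
        assert res.hits == {"A"}

    def test_assignable_restriction(self):
        base = _baseline()
        res = single_pass_assign(_beta("r", [0.15, 0.15]), base, assignable=["B"])
        assert res.hits == {"B"}


class TestDualPass:
    def test_adjustment_formula(self):
        base = _baseline()
        theo = ShareProfile(("A", "B"), np.array([10.0, 90.0]), "theoretical_equal")
        exp = ShareProfile(("A", "B"), np.array([40.0, 60.0]))
        cut_raw, _ = adjusted_cutoffs(base, theo, exp)
        # r = 4 -> SD term divided by 4: 0.10 + 1.5*0.02/4 = 0.1075
        assert cut_raw[0] == pytest.approx(0.1075)
        # under-represented fluorophore keeps its cutoff (r <= 1)
        assert cut_raw[1] == pytest.approx(0.13)

    def test_zero_theoretical_share_rejected(self):
        base = _baseline()
        theo = ShareProfile(("A", "B"), np.array([0.0, 100.0]), "theoretical_equal")
        exp = ShareProfile(("A", "B"), np.array([50.0, 50.0]))
        with pytest.raises(ValueError):
            adjusted_cutoffs(base, theo, exp)

    def test_pass_two_only_touches_unassigned(self):
        base = _baseline()
        theo = ShareProfile.equal(("A", "B"))
        exp = ShareProfile(("A", "B"), np.array([80.0, 20.0]))
        out = dual_pass_assign([_beta("miss", [0.125, 0.10])], base, theo, exp)
        assert len(out) == 1
        assert out[0].pass_id == 2
        assert out[0].primary == "A"  # cutoff lowered to 0.1075 < 0.125

    def test_dominant_fluorophore_recovered_at_high_prevalence(self, library, injected):
        from fluomux.simulate import (
            evaluate_assignments,
            prevalence_config,
            simulate_roi_dataset,
        )

        cfg = prevalence_config(list(library.names), "mVenus", 0.8, n_rois=300, seed=9)
        spectra, truth = simulate_roi_dataset(cfg, library)
        dual = classify_subject(spectra, library, dual_pass=True)
        single = classify_subject(spectra, library, dual_pass=False)
        m_dual = evaluate_assignments(dual.assignments, truth)
        m_single = evaluate_assignments(single.assignments, truth)
        assert m_dual.per_fluorophore["mVenus"]["accuracy"] > 0.9
        assert (
            m_dual.per_fluorophore["mVenus"]["accuracy"]
            > m_single.per_fluorophore["mVenus"]["accuracy"]
        )


class TestClassifySubject:
    def test_pure_noiseless_equal_mix_fully_correct_in_pass_one(self, library, rng):
        spectra = []
        labels = []
        for i in range(40):
            name = library.names[i % len(library)]
            amp = float(np.exp(rng.normal(0, 0.5)))
            spectra.append(
                Fingerprint(amp * library[name].values, f"roi{i}")
            )
            labels.append(name)
        res = classify_subject(spectra, library)
        for a, truth in zip(res.assignments, labels):
            assert a.primary == truth
            assert a.pass_id == 1

    def test_permutation_equivariance(self, library, rng):
        from fluomux.simulate import equal_distribution_config, simulate_roi_dataset

        cfg = equal_distribution_config(library.names, n_rois=60, seed=4)
        spectra, _ = simulate_roi_dataset(cfg, library)
        perm = rng.permutation(len(spectra))
        res_a = classify_subject(spectra, library)
        res_b = classify_subject([spectra[i] for i in perm], library)
        by_id = {a.roi_id: a for a in res_b.assignments}
        assert np.allclose(res_a.baseline.cutoff_raw, res_b.baseline.cutoff_raw)
        for a in res_a.assignments:
            assert by_id[a.roi_id].primary == a.primary

    def test_constant_reference_offset_raises_baseline_not_hits(self, library, rng):
        from fluomux.simulate import equal_distribution_config, simulate_roi_dataset

        names = [n for n in library.names if n != "mScarlet"]
        cfg = equal_distribution_config(names, n_rois=200, seed=5)
        spectra, truth = simulate_roi_dataset(cfg, library.subset(names))
        shifted = [
            Fingerprint(s.values + 0.5 * library["mScarlet"].values, s.label)
            for s in spectra
        ]
        res0 = classify_subject(spectra, library, dual_pass=False)
        res1 = classify_subject(shifted, library, dual_pass=False)
        i = library.names.index("mScarlet")
        # the per-subject baseline absorbs the constant offset: its mean rises
        assert res1.baseline.mean_raw[i] > res0.baseline.mean_raw[i] + 0.4
        # hit rate for the offset fluorophore stays at the nominal per-channel
        # tail of the mean + 1.5 SD rule (~6.7% per beta channel, raw or norm)
        hits = sum("mScarlet" in a.hits for a in res1.assignments)
        assert hits <= 0.15 * len(shifted)
        # and it rarely wins the primary over the true label (dim ROIs only,
        # where the constant offset dominates the normalized spectrum)
        primaries = sum(a.primary == "mScarlet" for a in res1.assignments)
        assert primaries <= 0.05 * len(shifted)
        correct = sum(
            a.primary == lab[0] for a, lab in zip(res1.assignments, truth.labels)
        )
        assert correct / len(shifted) > 0.9

    def test_single_roi_rejected(self, library):
        with pytest.raises(ValueError):
            classify_subject([library["mVenus"]], library)

    def test_results_table_and_summary(self, library, rng):
        from fluomux.simulate import equal_distribution_config, simulate_roi_dataset

        cfg = equal_distribution_config(library.names, n_rois=30, seed=6)
        spectra, _ = simulate_roi_dataset(cfg, library)
        res = classify_subject(spectra, library)
        df = res.to_frame()
        assert len(df) == 30
        assert "beta_raw_mVenus" in df.columns
        text = res.summary()
        assert "mVenus" in text and "no match" in text


class TestNullCalibration:
    def test_null_hit_rate_matches_gaussian_tail_beyond_1p5_sd(self, rng):
        # under a Gaussian null each beta channel should fire at ~P(Z>1.5) = 6.68%
        n = 20000
        raw = rng.normal(1.0, 0.1, (n, 2))
        betas = [_beta(f"r{i}", raw[i]) for i in range(n)]
        base = compute_baseline(betas, k=1.5)
        hits = np.zeros(2)
        for b in betas:
            res = single_pass_assign(b, base)
            for j, name in enumerate(("A", "B")):
                hits[j] += name in res.hits
        rate = hits / n
        assert np.all(np.abs(rate - 0.0668) < 0.01)
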