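"""Weighted RSS objectives, meta-EP and the per-subject fit pipeline."""

import numpy as np
import pytest

from glucoclamp.errors import AlignmentError, DomainError
from glucoclamp.estimation import (ClampObjective, FitConfig, fit_subject,
                                   local_refine, meta_ep, rss_gi, rss_gig)
from glucoclamp.preprocess import k8_from_series
from glucoclamp.synthetic import SyntheticConfig, generate_cohort


from _oracles import bruteforce_rss_gi, bruteforce_rss_gig  # noqa: E402


class TestRSS:
    def test_zero_for_perfect_fit(self):
        g = np.linspace(0.2, 1.0, 10)
        i = np.linspace(0.1, 1.0, 5)
        assert rss_gi(g, g, i, i) == 0.0
        assert rss_gig(g, g, i, i, i, i, g, g) == 0.0

    def test_printed_gi_weighting(self):
        """nGc = nI = 2, both glucose residuals 1, insulin exact:
        RSS = (2/4) * 2 = 1."""
        assert rss_gi([1.0, 1.0], [2.0, 2.0], [0.3, 0.4], [0.3, 0.4]) \
            == pytest.approx(1.0)

    def test_printed_gig_weighting_equal_counts(self):
        """Equal counts give every variable weight 3/4."""
        o = np.array([1.0, 1.0])
        s = np.array([0.0, 0.0])
        z = np.zeros(2)
        # only glucose residuals: RSS = (3/4) * 2
        assert rss_gig(s, o, z, z, z, z, z, z) == pytest.approx(1.5)

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ng, ni = rng.integers(3, 30, size=2)
            og, sg = rng.normal(size=(2, ng))
            oi, si = rng.normal(size=(2, ni))
            got = rss_gi(sg, og, si, oi)
            assert got == pytest.approx(bruteforce_rss_gi(sg, og, si, oi),
                                        rel=1e-12)
            ngg, ncp = rng.integers(3, 15, size=2)
            ogg, sgg = rng.normal(size=(2, ngg))
            ocp, scp = rng.normal(size=(2, ncp))
            got = rss_gig(sg, og, si, oi, sgg, ogg, scp, ocp)
            want = bruteforce_rss_gig([(sg, og), (si, oi), (sgg, ogg),
                                       (scp, ocp)])
            assert got == pytest.approx(want, rel=1e-12)

    def test_misaligned_grids_raise(self):
        with pytest.raises(AlignmentError):
            rss_gi(np.ones(4), np.ones(5), np.ones(3), np.ones(3))


class TestMetaEP:
    def test_finds_sphere_minimum(self):
        target = np.array([1.2, -0.7])

        def sphere(X):
            return np.sum((X - target) ** 2, axis=1)

        res = meta_ep(sphere, [-4.0, -4.0], [4.0, 4.0], 40, 200, seed=7)
        np.testing.assert_allclose(res.x, target, atol=1e-2)

    def test_all_evaluations_respect_bounds(self):
        seen = []

        def objective(X):
            seen.append(X.copy())
            return np.sum(X ** 2, axis=1)

        lo, hi = np.array([-1.0, 0.5]), np.array([2.0, 3.0])
        meta_ep(objective, lo, hi, 10, 50, seed=1)
        allX = np.vstack(seen)
        assert np.all(allX >= lo - 1e-12) and np.all(allX <= hi + 1e-12)

    def test_seeded_determinism_is_bitwise(self):
        def noisy(X):
            return np.sum(X ** 2, axis=1) + 0.1 * np.sin(X[:, 0] * 50)

        a = meta_ep(noisy, [-2.0], [2.0], 12, 80, seed=42)
        b = meta_ep(noisy, [-2.0], [2.0], 12, 80, seed=42)
        assert a.fun == b.fun
        assert np.array_equal(a.x, b.x)

    def test_nan_objective_treated_as_infinite(self):
        def patchy(X):
            f = np.sum(X ** 2, axis=1)
            f[X[:, 0] > 0.5] = np.nan
            return f

        res = meta_ep(patchy, [-2.0, -2.0], [2.0, 2.0], 10, 60, seed=3)
        assert np.isfinite(res.fun)
        assert res.n_nan > 0

    def test_invalid_configuration_raises(self):
        with pytest.raises(DomainError):
            meta_ep(lambda X: np.zeros(len(X)), [0.0], [-1.0], 10, 5)
        with pytest.raises(DomainError):
            meta_ep(lambda X: np.zeros(len(X)), [0.0], [1.0], 1, 5)


class TestLocalRefine:
    @staticmethod
    def _residual(x):
        return np.asarray([x[0] - 0.3, 2.0 * (x[1] + 0.4)])

    def test_candidate_at_optimum_is_kept(self):
        x0 = np.array([0.3, -0.4])
        x, rss, _ = local_refine(x0, self._residual, [-1, -1], [1, 1])
        np.testing.assert_allclose(x, x0, atol=1e-8)
        assert rss == pytest.approx(0.0, abs=1e-15)

    def test_perturbed_candidate_improves(self):
        x0 = np.array([0.35, -0.35])
        rss0 = float(np.sum(self._residual(x0) ** 2))
        x, rss, conv = local_refine(x0, self._residual, [-1, -1], [1, 1])
        assert rss < rss0
        assert conv

    def test_bound_touching_candidate_stays_within_bounds(self):
        x, rss, _ = local_refine(np.array([1.0, 1.0]), self._residual,
                                 [-1, -1], [1, 1])
        assert np.all(x >= -1) and np.all(x <= 1)


@pytest.fixture(scope="module")
def noiseless_gi_cohort():
    cfg = SyntheticConfig(n_subjects=2, seed=11, group="control",
                          model_id="GI", integrator="rk4",
                          noise_cvs={"Gc": 0, "I": 0, "Gg": 0, "CP": 0})
    return generate_cohort(cfg)


class TestFitSubject:
    def test_selffit_reaches_machine_scale_rss(self, noiseless_gi_cohort):
        """Fitting the generating model to its own noiseless output."""
        coh = noiseless_gi_cohort
        rec = coh.records[0]
        ser = coh.series[rec.subject_id]
        rec.k8 = k8_from_series(rec, ser)
        fit = fit_subject(ser, rec, "GI",
                          config=FitConfig(seed=0, n_parents=16,
                                           n_generations=60))
        assert fit.rss < 1e-6
        assert fit.converged
        assert fit.K == 7
        # parameters respect the estimation bounds
        for name in fit.free_names:
            assert 1e-4 <= fit.params[name] <= 1e4

    def test_fit_is_reproducible_given_seed(self, noiseless_gi_cohort):
        coh = noiseless_gi_cohort
        rec = coh.records[1]
        ser = coh.series[rec.subject_id]
        rec.k8 = k8_from_series(rec, ser)
        cfgs = [FitConfig(seed=5, n_parents=12, n_generations=40)
                for _ in range(2)]
        fits = [fit_subject(ser, rec, "GI", config=c) for c in cfgs]
        assert fits[0].rss == fits[1].rss
        np.testing.assert_array_equal(fits[0].free_log10, fits[1].free_log10)

    def test_seed_to_seed_stability_on_noisy_subject(self):
        cfg = SyntheticConfig(n_subjects=1, seed=19, group="control",
                              model_id="GI")
        coh = generate_cohort(cfg)
        rec = coh.records[0]
        ser = coh.series[rec.subject_id]
        rec.k8 = k8_from_series(rec, ser)
        fc = FitConfig(seed=1, n_parents=16, n_generations=60)
        r1 = fit_subject(ser, rec, "GI", config=fc)
        fc2 = FitConfig(seed=2, n_parents=16, n_generations=60)
        r2 = fit_subject(ser, rec, "GI", config=fc2)
        assert abs(r1.rss - r2.rss) / max(r1.rss, r2.rss) \
            < fc.run_to_run_rtol

    def test_objective_pins_optimization_below_meta_ep(self,
                                                       noiseless_gi_cohort):
        """The full pipeline never returns a worse RSS than the global
        stage alone (monotone composition)."""
        coh = noiseless_gi_cohort
        rec = coh.records[0]
        ser = coh.series[rec.subject_id]
        rec.k8 = k8_from_series(rec, ser)
        obj = ClampObjective(ser, rec, "GI", config=FitConfig())
        ep = meta_ep(obj, obj.lower, obj.upper, 12, 40, seed=9)
        fit = fit_subject(ser, rec, "GI",
                          config=FitConfig(seed=9, n_parents=12,
                                           n_generations=40))
        assert fit.rss <= ep.fun + 1e-12
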