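"""Virtual-cohort generator: sampling, controller, OGTT, noise."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from glucoclamp.errors import ConfigError
from glucoclamp.metrics import di_cle
from glucoclamp.model_core import GIGParameters, fasting_state
from glucoclamp.synthetic import (SyntheticConfig, add_noise, generate_cohort,
                                  sample_parameters,
                                  simulate_clamp_with_controller,
                                  simulate_ogtt)

NOISELESS = {"Gc": 0, "I": 0, "Gg": 0, "CP": 0}


class TestSampling:
    def test_fixed_seed_reproduces_draws(self):
        cfg = SyntheticConfig(n_subjects=5, seed=123, group="sglt2i")
        a = sample_parameters(cfg)
        b = sample_parameters(cfg)
        for (pa, wa), (pb, wb) in zip(a, b):
            assert pa == pb and wa == wb

    def test_degenerate_ranges_are_deterministic(self):
        cfg = SyntheticConfig(n_subjects=3, seed=0, group="control")
        cfg.param_log_ranges = {k: (lo, lo) for k, (lo, hi)
                                in cfg.param_log_ranges.items()}
        draws = sample_parameters(cfg)
        assert draws[0][0] == draws[1][0] == draws[2][0]

    def test_draws_are_loguniform_within_ranges(self):
        cfg = SyntheticConfig(n_subjects=1, seed=7, group="sglt2i")
        lo, hi = cfg.param_log_ranges["kGgS"]
        vals = np.log10([p.kGgS for p, _ in sample_parameters(cfg, 2000)])
        assert vals.min() >= lo and vals.max() <= hi
        _, p = sps.kstest(vals, sps.uniform(loc=lo, scale=hi - lo).cdf)
        assert p > 0.01

    def test_ranges_outside_bounds_rejected(self):
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="control")
        bad = dict(cfg.param_log_ranges)
        bad["k4"] = (-5.0, -3.0)
        with pytest.raises(ConfigError):
            SyntheticConfig(n_subjects=1, seed=0, group="control",
                            param_log_ranges=bad)

    def test_group_structure_of_urinary_excretion(self):
        hi = max(p.k8 for p, _ in sample_parameters(
            SyntheticConfig(n_subjects=10, seed=1, group="control")))
        lo = min(p.k8 for p, _ in sample_parameters(
            SyntheticConfig(n_subjects=10, seed=1, group="sglt2i")))
        assert hi < lo  # drug arm excretes far more glucose


class TestController:
    def test_regulates_with_zero_insulin_action(self, gig_params):
        """Even without any insulin effect (k4 = k5 = 0) the infusion
        loop alone settles glucose at a target above the unforced
        steady state."""
        p = replace(gig_params, k4=0.0, k5=0.0, k1=0.05, kGN=0.0,
                    k2=0.03)
        base = p.k1 / (p.k2 + p.k8)
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="control",
                              target_glucose=base + 3.0,
                              noise_cvs=NOISELESS)
        res = simulate_clamp_with_controller(p, 65.0, cfg)
        win = res.t >= 90
        dev = np.abs(res.states["Gc"][win] - cfg.target_glucose)
        assert np.max(dev) / cfg.target_glucose < 0.05

    def test_no_infusion_needed_at_unforced_steady_state(self, gig_params):
        y0 = fasting_state(gig_params, "GIG")
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="control",
                              insulin_infusion=0.0, target_glucose=y0[0],
                              noise_cvs=NOISELESS)
        res = simulate_clamp_with_controller(gig_params, 65.0, cfg)
        assert res.fg == pytest.approx(0.0, abs=1e-3)

    def test_same_config_gives_identical_series(self, gig_params):
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="control")
        a = simulate_clamp_with_controller(gig_params, 65.0, cfg)
        b = simulate_clamp_with_controller(gig_params, 65.0, cfg)
        np.testing.assert_array_equal(a.states["Gc"], b.states["Gc"])
        np.testing.assert_array_equal(a.f1, b.f1)


class TestOGTT:
    def test_zero_dose_keeps_fasting_state(self, gig_params):
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="control",
                              ogtt_dose_g=0.0)
        res = simulate_ogtt(gig_params, 65.0, cfg)
        y0 = fasting_state(gig_params, "GIG")
        assert res.pg120 == pytest.approx(y0[0], rel=1e-6)

    def test_pg120_decreases_with_insulin_sensitivity(self, gig_params):
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="control")
        vals = [simulate_ogtt(replace(gig_params, k4=gig_params.k4 * f),
                              65.0, cfg).pg120
                for f in (0.5, 0.75, 1.0, 1.5, 2.25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_pg120_increases_with_glucagon_drive(self, gig_params):
        """A 5-point sweep of the glucagon axis kGN*kGgS/kGgC raises the
        2-h OGTT glucose monotonically."""
        cfg = SyntheticConfig(n_subjects=1, seed=0, group="sglt2i")
        vals = [simulate_ogtt(replace(gig_params, kGgS=gig_params.kGgS * f),
                              65.0, cfg).pg120
                for f in (0.5, 0.75, 1.0, 1.5, 2.25)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestNoise:
    def test_zero_cv_is_identity(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 5, 7)
        np.testing.assert_array_equal(add_noise(x, 0.0, rng), x)

    def test_empirical_cv_matches_nominal(self):
        rng = np.random.default_rng(1)
        x = np.full(10_000, 10.0)
        noisy = add_noise(x, 0.07, rng)
        cv = noisy.std() / noisy.mean()
        assert abs(cv - 0.07) / 0.07 < 0.10
        assert np.all(noisy > 0)

    def test_seeded_reproducibility(self):
        x = np.linspace(1, 5, 9)
        a = add_noise(x, 0.1, np.random.default_rng(5))
        b = add_noise(x, 0.1, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestGenerateCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(SyntheticConfig(n_subjects=4, seed=2,
                                               group="sglt2i"))

    def test_emits_requested_cohort_size(self, cohort):
        assert len(cohort.records) == 4
        assert set(cohort.series) == {r.subject_id for r in cohort.records}

    def test_ground_truth_metrics_recomputable_from_parameters(self, cohort):
        gt = cohort.ground_truth
        for _, row in gt.iterrows():
            assert row["true_DI_cle"] == di_cle(row["true_k4"],
                                                row["true_k5"],
                                                row["true_k7"])

    def test_emitted_files_round_trip_through_readers(self, cohort, tmp_path):
        from glucoclamp.io import read_cohort_dir, write_cohort
        write_cohort(cohort, tmp_path)
        records, series, gt = read_cohort_dir(tmp_path)
        assert len(records) == len(cohort.records)
        orig = cohort.records[0]
        back = next(r for r in records if r.subject_id == orig.subject_id)
        assert back.Gss == pytest.approx(orig.Gss, rel=1e-12)
        t0, v0 = cohort.series[orig.subject_id].samples["Gg"]
        t1, v1 = series[orig.subject_id].samples["Gg"]
        np.testing.assert_allclose(v1, v0, rtol=1e-12)

    def test_hormones_sparse_glucose_quasi_continuous(self, cohort):
        ts = cohort.series[cohort.records[0].subject_id]
        counts = ts.counts()
        assert counts["Gc"] == 121
        assert counts["I"] == counts["Gg"] == counts["CP"] == 12
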