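"""Composite endocrine indices: formulas, scaling laws, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucoclamp.errors import ConfigError, DomainError, InsufficientDataError
from glucoclamp.metrics import (di_cle, insulin_half_life, isi, ogtt_indices,
                                pi_cle_analytic, pi_cle_numeric, tgur)

positive = st.floats(1e-3, 1e3)


class TestDICle:
    @pytest.mark.parametrize("k4,k5,k7,want", [(1, 1, 1, 1.0),
                                               (2, 3, 2, 1.5)])
    def test_examples(self, k4, k5, k7, want):
        assert di_cle(k4, k5, k7) == pytest.approx(want)

    @given(k4=positive, k5=positive, k7=positive)
    @settings(max_examples=30, deadline=None)
    def test_homogeneity(self, k4, k5, k7):
        base = di_cle(k4, k5, k7)
        assert di_cle(2 * k4, k5, k7) == pytest.approx(2 * base, rel=1e-12)
        assert di_cle(k4, k5, 2 * k7) == pytest.approx(base / 4, rel=1e-12)

    def test_zero_clearance_rejected(self):
        with pytest.raises(DomainError):
            di_cle(1.0, 1.0, 0.0)


class TestPICleNumeric:
    @pytest.mark.parametrize("args,want", [((1, 1, 1, 1), 1.0),
                                           ((1, 1, 1, 3), 1.0),
                                           ((2, 2, 2, 2), 1.0)])
    def test_examples(self, args, want):
        assert pi_cle_numeric(*args) == pytest.approx(want)

    def test_decreasing_in_exponent_for_large_clearance(self):
        vals = [pi_cle_numeric(2.0, 3.0, 1.8, e) for e in (1, 2, 3)]
        assert vals[0] > vals[1] > vals[2]

    def test_invalid_exponent(self):
        with pytest.raises(ConfigError):
            pi_cle_numeric(1, 1, 1, 4)


class TestPICleAnalytic:
    def test_unit_inputs(self):
        pi, ggsen, ggsec = pi_cle_analytic(1, 1, 1, 1, 1)
        assert (pi, ggsen, ggsec) == (1.0, 1.0, 1.0)

    @given(gg0=positive, g0=positive, fg=positive, gss=positive,
           iss=positive)
    @settings(max_examples=30, deadline=None)
    def test_product_identity_and_homogeneity(self, gg0, g0, fg, gss, iss):
        pi, ggsen, ggsec = pi_cle_analytic(gg0, g0, fg, gss, iss)
        assert ggsen * ggsec == pytest.approx(pi, rel=1e-12)
        assert pi_cle_analytic(gg0, g0, 2 * fg, gss, iss)[0] == \
            pytest.approx(2 * pi, rel=1e-12)
        assert pi_cle_analytic(gg0, g0, fg, gss, 2 * iss)[0] == \
            pytest.approx(pi / 2, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            pi_cle_analytic(1, 0, 1, 1, 1)


class TestClampIndices:
    @pytest.mark.parametrize("u,g,i,want", [(1, 1, 1, 100.0),
                                            (1, 100, 50, 50.0)])
    def test_isi_examples(self, u, g, i, want):
        assert isi(u, g, i) == pytest.approx(want)

    def test_tgur_cohort_scale_consistency(self):
        """Mean-level infusion minus urinary loss from the clamp data."""
        assert tgur(4.17, 0.68) == pytest.approx(3.49)
        assert tgur(5.0, 0.0) == 5.0
        assert tgur(1.0, 1.0) == 0.0

    def test_tgur_warns_when_urinary_exceeds_infusion(self):
        with pytest.warns(RuntimeWarning):
            assert tgur(1.0, 2.0) == -1.0


class TestOGTTIndices:
    def test_flat_series_flags_insulinogenic_and_matsuda_form(self):
        t = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        res = ogtt_indices(t, np.full(5, 100.0), np.full(5, 10.0))
        assert not res.insulinogenic_defined
        assert math.isnan(res.insulinogenic)
        assert res.matsuda == pytest.approx(1e4 / (100.0 * 10.0))

    def test_matsuda_simple_value(self):
        t = np.array([0.0, 30.0, 120.0])
        res = ogtt_indices(t, np.array([100.0, 100.0 + 1e-9, 100.0]),
                           np.full(3, 10.0))
        assert res.matsuda == pytest.approx(10.0, rel=1e-6)

    def test_pg120_is_the_120min_sample(self):
        t = np.array([0.0, 30.0, 120.0])
        res = ogtt_indices(t, np.array([90.0, 140.0, 171.3]),
                           np.array([8.0, 30.0, 25.0]))
        assert res.pg120_mgdl == 171.3
        assert res.insulinogenic == pytest.approx((30.0 - 8.0) / 50.0)

    def test_missing_time_point_raises(self):
        with pytest.raises(InsufficientDataError):
            ogtt_indices(np.array([0.0, 60.0]), np.ones(2) * 100,
                         np.ones(2) * 10)


class TestHalfLife:
    def test_examples(self):
        assert insulin_half_life(math.log(2.0)) == pytest.approx(1.0)
        assert insulin_half_life(0.0693) == pytest.approx(10.0, rel=2e-3)

    def test_nonpositive_clearance_rejected(self):
        with pytest.raises(DomainError):
            insulin_half_life(0.0)


class TestAnalyticIndexRespondsToSecretionAxis:
    def test_increasing_in_glucagon_secretion_gain(self, gig_params):
        """The observable-based PI/cle rises monotonically along the
        glucagon secretion axis, which carries the cohort-level
        association with glycemia."""
        from dataclasses import replace

        from glucoclamp.synthetic import (SyntheticConfig,
                                          simulate_clamp_with_controller)

        cfg = SyntheticConfig(n_subjects=1, seed=0, group="sglt2i")
        vals = []
        for f in (0.5, 1.0, 2.0, 4.0):
            p = replace(gig_params, kGgS=gig_params.kGgS * f)
            r = simulate_clamp_with_controller(p, 65.0, cfg)
            pi, _, _ = pi_cle_analytic(r.y0[3], r.y0[0], r.fg, r.Gss, r.Iss)
            vals.append(pi)
        assert all(a < b for a, b in zip(vals, vals[1:]))
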