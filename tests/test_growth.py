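"""Gompertz curve algebra and least-squares fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from eidermoult.growth import (
    GompertzModel,
    GompertzParams,
    fit_gompertz,
    gompertz_inverse,
    gompertz_length,
    gompertz_slope,
)

P_REF = GompertzParams(A=230.0, mu=5.0, lam=10.0)

params_st = st.builds(
    GompertzParams,
    A=st.floats(20.0, 400.0),
    mu=st.floats(0.5, 12.0),
    lam=st.floats(-20.0, 60.0),
)


def transcription(t, A, mu, lam):
    # term-by-term transcription of the growth equation, independent of
    # the implementation's vectorised form
    inner = mu * math.exp(1.0) / A * (lam - t) + 1.0
    return A * math.exp(-math.exp(inner))


class TestCurve:
    def test_matches_direct_transcription_on_grid(self):
        for t in np.linspace(-10, 120, 27):
            assert gompertz_length(t, P_REF) == pytest.approx(
                transcription(t, 230.0, 5.0, 10.0), rel=1e-12)

    def test_asymptote(self):
        assert gompertz_length(1e6, P_REF) == pytest.approx(P_REF.A, rel=1e-12)

    def test_inflection_value_is_A_over_e(self):
        t_inf = P_REF.lam + P_REF.A / (P_REF.mu * math.e)
        assert gompertz_length(t_inf, P_REF) == pytest.approx(
            P_REF.A / math.e, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(p=params_st, t=st.floats(-50, 200), dt=st.floats(0.01, 50))
    def test_monotone_increasing(self, p, t, dt):
        y0, y1 = gompertz_length(t, p), gompertz_length(t + dt, p)
        assert y1 >= y0
        # strict except where float64 has saturated at either tail
        if y0 > 0.0 and y1 < p.A * (1 - 1e-12):
            assert y1 > y0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(A=-1.0, mu=5.0, lam=0.0)
        with pytest.raises(ValueError):
            GompertzParams(A=100.0, mu=0.0, lam=0.0)
        with pytest.raises(ValueError):
            GompertzParams(A=100.0, mu=5.0, lam=math.inf)


class TestInverse:
    def test_inflection_identity(self):
        t = gompertz_inverse(1.0 / math.e, P_REF)
        assert t == pytest.approx(P_REF.lam + P_REF.A / (P_REF.mu * math.e),
                                  rel=1e-12)

    @pytest.mark.parametrize("f", [0.015, 0.05, 0.88, 0.90])
    def test_round_trip(self, f):
        t = gompertz_inverse(f, P_REF)
        assert gompertz_length(t, P_REF) / P_REF.A == pytest.approx(
            f, rel=1e-9)

    def test_against_bracketing_root_oracle(self):
        # independent root-find of y(t)/A = 0.5 on the forward curve
        target = 0.5 * P_REF.A
        t_oracle = brentq(lambda t: gompertz_length(t, P_REF) - target,
                          -100.0, 500.0, xtol=1e-10)
        assert gompertz_inverse(0.5, P_REF) == pytest.approx(t_oracle,
                                                             abs=1e-6)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error(self, f):
        with pytest.raises(ValueError):
            gompertz_inverse(f, P_REF)


class TestSlope:
    def test_max_slope_equals_mu_on_fine_grid(self):
        t = np.linspace(-50, 200, 200001)
        assert gompertz_slope(t, P_REF).max() == pytest.approx(
            P_REF.mu, rel=1e-6)

    def test_slope_at_inflection_equals_mu(self):
        t_inf = P_REF.lam + P_REF.A / (P_REF.mu * math.e)
        assert gompertz_slope(t_inf, P_REF) == pytest.approx(P_REF.mu,
                                                             rel=1e-12)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        h = 1e-6
        for t in rng.uniform(-20, 120, 20):
            fd = (gompertz_length(t + h, P_REF)
                  - gompertz_length(t - h, P_REF)) / (2 * h)
            assert gompertz_slope(t, P_REF) == pytest.approx(fd, rel=1e-5)


class TestFit:
    def _noise_free(self, p=P_REF, t_end=80.0):
        t = np.repeat(np.arange(0.0, t_end, 3.5), 3)
        return t, gompertz_length(t, p)

    def test_noise_free_recovery(self):
        t, y = self._noise_free()
        res = GompertzModel(t, y).fit()
        assert res.converged
        assert res.params.A == pytest.approx(P_REF.A, rel=1e-6)
        assert res.params.mu == pytest.approx(P_REF.mu, rel=1e-6)
        assert res.params.lam == pytest.approx(P_REF.lam, rel=1e-6)
        assert res.rss == pytest.approx(0.0, abs=1e-8)

    def test_scale_equivariance(self):
        t, y = self._noise_free()
        c = 3.7
        r1 = GompertzModel(t, y).fit()
        r2 = GompertzModel(t, c * y).fit()
        assert r2.params.A == pytest.approx(c * r1.params.A, rel=1e-5)
        assert r2.params.mu == pytest.approx(c * r1.params.mu, rel=1e-5)
        assert r2.params.lam == pytest.approx(r1.params.lam, abs=1e-4)

    def test_objective_not_worse_than_truth(self):
        rng = np.random.default_rng(11)
        t = np.repeat(np.arange(0.0, 80.0, 3.5), 3)
        y = np.clip(gompertz_length(t, P_REF) + rng.normal(0, 1.0, t.size), 0, None)
        res = GompertzModel(t, y).fit()
        rss_truth = float(np.sum((gompertz_length(t, P_REF) - y) ** 2))
        assert res.rss <= rss_truth + 1e-6

    def test_quick_noisy_recovery(self):
        # twice-weekly triplicates, 1 mm caliper noise: mu recovered well
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(20):
            t = np.repeat(np.arange(0.0, 80.0, 3.5), 3)
            y = np.clip(gompertz_length(t, P_REF)
                        + rng.normal(0, 1.0, t.size), 0, None)
            res = GompertzModel(t, y).fit()
            errs.append(abs(res.params.mu - P_REF.mu))
        assert np.median(errs) < 0.15

    def test_too_few_time_points_rejected(self):
        t = np.array([0.0, 5.0, 10.0, 15.0])
        with pytest.raises(ValueError, match="distinct time"):
            GompertzModel(t, gompertz_length(t, P_REF))

    def test_degenerate_data_rejected(self):
        t = np.arange(0.0, 30.0, 3.5)
        with pytest.raises(ValueError, match="degenerate"):
            GompertzModel(t, np.full_like(t, 5.0))

    def test_negative_lengths_rejected(self):
        t = np.arange(0.0, 30.0, 3.5)
        y = gompertz_length(t, P_REF)
        y[0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            GompertzModel(t, y)

    def test_replicates_enter_individually(self, default_cohort):
        meas = default_cohort["feather_measurements"]
        grp = meas[(meas.bird_id == meas.bird_id.iloc[0])
                   & (meas.year == meas.year.iloc[0])
                   & (meas.feather == "P9")]
        res = fit_gompertz(grp)
        assert res.n_obs == len(grp)
        res_avg = fit_gompertz(grp, average_replicates=True)
        assert res_avg.n_obs == grp["t"].nunique()

    def test_summary_renders(self):
        t, y = self._noise_free()
        text = GompertzModel(t, y).fit().summary()
        assert "A (mm)" in text and "converged" in text

    def test_cohort_mu_within_printed_envelope(self, default_fits):
        """Group-mean P9 maximum growth rates from the default synthetic
        cohort land inside the 3.4-5.6 mm/day envelope spanned by the
        field study's reported means +- sd."""
        p9 = default_fits[default_fits.feather == "P9"]
        assert p9.converged.all()
        assert 3.4 < p9.mu.mean() < 5.6
        assert p9.mu.between(3.4, 5.6).mean() > 0.9
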