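"""Threshold-derived moult phenology and its closed-form identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eidermoult.growth import GompertzParams, GompertzModel, gompertz_length
from eidermoult.phenology import (
    RATE_5_90_FACTOR,
    MoultPhenology,
    PhenologyThresholds,
    derive_phenology,
    group_contrast,
    phenology_table,
)
from eidermoult.simulate import SimConfig, simulate_cohort

params_st = st.builds(
    GompertzParams,
    A=st.floats(20.0, 400.0),
    mu=st.floats(0.5, 12.0),
    lam=st.floats(-20.0, 60.0),
)


def _fit_of(p: GompertzParams):
    # sample the curve's active region so the fit is well conditioned for
    # any parameter draw
    from eidermoult.growth import gompertz_inverse
    t = np.linspace(gompertz_inverse(0.005, p), gompertz_inverse(0.995, p), 40)
    return GompertzModel(t, gompertz_length(t, p)).fit()


def test_rate_factor_matches_independent_evaluation():
    # closed form evaluated from scratch: 0.85*e / (ln(-ln .05) - ln(-ln .90))
    expected = 0.85 * math.e / (math.log(-math.log(0.05))
                                - math.log(-math.log(0.90)))
    assert RATE_5_90_FACTOR == pytest.approx(expected, rel=1e-12)
    assert RATE_5_90_FACTOR == pytest.approx(0.6902, abs=5e-5)


@settings(max_examples=60, deadline=None)
@given(p=params_st)
def test_rate_ratio_is_universal_constant(p):
    """rate_5_90 / mu is the same constant for any (A, mu, lam)."""
    ph = derive_phenology(_fit_of(p))
    assert ph.rate_5_90 / ph.max_rate == pytest.approx(RATE_5_90_FACTOR,
                                                       rel=1e-6)


def test_rate_agrees_with_secant_on_curve():
    p = GompertzParams(A=167.0, mu=5.0, lam=20.0)
    ph = derive_phenology(_fit_of(p))
    # independent secant between the 5% and 90% crossings, located by scan
    t = np.linspace(-50, 200, 2_000_001)
    y = gompertz_length(t, p)
    t05 = t[np.searchsorted(y, 0.05 * p.A)]
    t90 = t[np.searchsorted(y, 0.90 * p.A)]
    secant = (0.85 * p.A) / (t90 - t05)
    assert ph.rate_5_90 == pytest.approx(secant, rel=1e-3)


def test_duration_closed_form_and_homogeneity():
    th = PhenologyThresholds()
    span = math.log(-math.log(th.shed_fraction)) - math.log(
        -math.log(th.regain_fraction))
    p1 = GompertzParams(A=167.0, mu=5.0, lam=20.0)
    p2 = GompertzParams(A=167.0, mu=10.0, lam=20.0)
    d1 = derive_phenology(_fit_of(p1)).flightless_duration
    d2 = derive_phenology(_fit_of(p2)).flightless_duration
    assert d1 == pytest.approx(p1.A / (p1.mu * math.e) * span, rel=1e-6)
    assert d2 == pytest.approx(d1 / 2.0, rel=1e-6)


@settings(max_examples=30, deadline=None)
@given(p=params_st, shift=st.floats(-30, 30))
def test_duration_independent_of_lag(p, shift):
    shifted = GompertzParams(A=p.A, mu=p.mu, lam=p.lam + shift)
    d0 = derive_phenology(_fit_of(p))
    d1 = derive_phenology(_fit_of(shifted))
    assert d1.flightless_duration == pytest.approx(d0.flightless_duration,
                                                   rel=1e-6)
    assert d1.regain_t > d1.shed_t
    assert d1.rate_5_90 < d1.max_rate


def test_non_converged_fit_refused():
    fit = _fit_of(GompertzParams(167.0, 5.0, 20.0))
    fit.converged = False
    with pytest.raises(ValueError, match="non-converged"):
        derive_phenology(fit)


def test_threshold_validation():
    with pytest.raises(ValueError):
        PhenologyThresholds(shed_fraction=0.0)
    with pytest.raises(ValueError):
        PhenologyThresholds(rate_lo=0.9, rate_hi=0.05)


def test_default_cohort_durations_in_printed_band(default_fits):
    """Default synthetic cohorts yield mean P9 flightless durations in the
    40-45 day band bracketing the field study's group means."""
    phen = phenology_table(default_fits)
    p9 = phen[phen.feather == "P9"]
    assert 40.0 < p9.flightless_duration.mean() < 45.0


class TestGroupContrast:
    @staticmethod
    def _phen_frame(rows):
        return pd.DataFrame(rows)

    def test_zero_shift_contrast_near_zero(self):
        cfg = SimConfig(
            cohorts={2010: {"female": 30, "male": 30},
                     2011: {"female": 30, "male": 30}},
            study_years=(2012,), lam_warm_shift=0.0, seed=9)
        cohort = simulate_cohort(cfg)
        tp = cohort["true_params"]
        p9 = tp[tp.feather == "P9"].copy()
        p9["emergence_t"] = p9["shed_t"]  # any lam-anchored event works
        out = group_contrast(p9, cohort["birds"], "emergence_t")
        se = cfg.lam_sd * math.sqrt(2.0 / 60.0)
        assert abs(out["pooled_warm_minus_cold"]) < 3.0 * se

    def test_identical_birds_same_group(self):
        phen = self._phen_frame([
            {"bird_id": "a", "year": 2012, "emergence_t": 25.0},
            {"bird_id": "b", "year": 2012, "emergence_t": 25.0},
        ])
        roster = pd.DataFrame([
            {"bird_id": "a", "year": 2012, "sex": "female", "treatment": "cold"},
            {"bird_id": "b", "year": 2012, "sex": "female", "treatment": "cold"},
        ])
        out = group_contrast(phen, roster, "emergence_t")
        cell = out["cells"]
        assert float(cell["se"].iloc[0]) == 0.0
        assert math.isnan(out["pooled_warm_minus_cold"])  # no warm group

    def test_orphan_bird_listed(self):
        phen = self._phen_frame(
            [{"bird_id": "ghost", "year": 2012, "emergence_t": 1.0}])
        roster = pd.DataFrame(
            [{"bird_id": "a", "year": 2012, "sex": "male", "treatment": "cold"}])
        with pytest.raises(ValueError, match="ghost"):
            group_contrast(phen, roster, "emergence_t")


def test_moult_phenology_dataclass_roundtrip():
    ph = derive_phenology(_fit_of(GompertzParams(167.0, 5.0, 20.0)),
                          bird_id="b1", feather="P9")
    assert isinstance(ph, MoultPhenology)
    assert ph.flightless_duration == pytest.approx(ph.regain_t - ph.shed_t)
    assert ph.shed_t < ph.emergence_t < ph.regain_t
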