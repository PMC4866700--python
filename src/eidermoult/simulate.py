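"""Seeded synthetic-cohort generator emulating the crossover moult study.

Generates the four tables the analysis pipeline consumes, with the
statistical structure the downstream methods assume:

* a roster of birds in a water-temperature crossover (each bird's
  treatment alternates between consecutive moult years; defaults 13 birds,
  8 from the first cohort and 5 from the second);
* twice-weekly triplicate feather-length measurements following each
  bird-year's true Gompertz curve plus iid Gaussian noise (truncated at 0),
  emitted only once the true curve passes a field-detectability threshold
  (a new flight feather a few millimetres long);
* weekly body masses from a piecewise-linear moult-aligned trajectory
  (sex-specific baseline, treatment-specific anticipatory gain, a dip over
  the moult, treatment-separated recovery) plus Gaussian noise;
* 5-minute scan samples of birds in/out of the water, binomial per scan
  with treatment-specific in-water probability.

The warm-water treatment delays the lag phase (default +7 days) and leaves
the growth rate untouched; the delay is imposed, not emergent -- no
energetic mechanism is simulated.  Time is fractional days on a continuous
per-run axis; calendar rendering is a presentation concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GompertzParams, gompertz_length, gompertz_inverse

__all__ = ["Bird", "SimConfig", "simulate_cohort", "make_roster"]

FEATHERS = ("P9", "S1")


@dataclass(frozen=True)
class Bird:
    """One study bird and its treatment history."""

    bird_id: str
    sex: str
    cohort_year: int
    treatment_by_year: dict[int, str]

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        years = sorted(self.treatment_by_year)
        for a, b in zip(years, years[1:]):
            if b == a + 1 and self.treatment_by_year[a] == self.treatment_by_year[b]:
                raise ValueError(
                    f"bird {self.bird_id}: treatment must alternate between "
                    f"consecutive years ({a} and {b} both "
                    f"{self.treatment_by_year[a]!r})"
                )


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Feather true parameters are drawn per bird-year from normal
    distributions truncated at 0; ``feather_A`` and ``feather_mu`` map
    feather -> (mean, sd) in mm and mm/day.  The asymptote defaults are a
    calibration choice, not a measured value: with maximum growth rates
    near 5 mm/day, a 167 mm P9 asymptote yields ~42-day flightless
    periods, the magnitude typical of moulting eiders.
    """

    # cohort structure: cohort_year -> {sex: n}; 3 study years
    cohorts: dict[int, dict[str, int]] = field(
        default_factory=lambda: {2010: {"female": 4, "male": 4},
                                 2011: {"female": 2, "male": 3}})
    study_years: tuple[int, ...] = (2011, 2012, 2013)
    first_treatment: dict[int, str] = field(
        default_factory=lambda: {2010: "cold", 2011: "warm"})

    # feather growth truth
    feather_A: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"P9": (167.0, 8.0), "S1": (150.0, 8.0)})
    feather_mu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"P9": (5.05, 0.25), "S1": (4.60, 0.25)})
    lam_mean: float = 20.0           # cold-water lag phase, days
    lam_sd: float = 4.0
    lam_warm_shift: float = 7.0      # warm-water delay of the lag phase, days
    feather_lam_offset: dict[str, float] = field(
        default_factory=lambda: {"P9": 0.0, "S1": -1.0})

    # measurement protocol
    noise_sd: float = 1.0            # caliper noise, mm
    replicates: int = 3
    session_interval: float = 3.5    # twice weekly
    t_start: float = 0.0
    t_end: float = 90.0
    detection_threshold: float = 2.0  # mm; curve must exceed this to be measured

    # body mass model (grams)
    mass_base: dict[str, float] = field(
        default_factory=lambda: {"female": 1650.0, "male": 1760.0})
    mass_gain: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("cold", "female"): 307.0,
                                 ("warm", "female"): 158.0,
                                 ("cold", "male"): 167.0,
                                 ("warm", "male"): 110.0})
    mass_moult_dip: float = 50.0     # Start -> End drawdown, g
    mass_post_gain: dict[str, float] = field(
        default_factory=lambda: {"cold": 170.0, "warm": 50.0})
    mass_bird_sd: float = 80.0       # between-bird baseline spread, g
    mass_noise_sd: float = 25.0      # weighing noise, g
    weigh_interval: float = 7.0

    # scan sampling
    p_in_water: dict[str, float] = field(
        default_factory=lambda: {"cold": 0.275, "warm": 0.242})
    scans_per_session: dict[str, int] = field(
        default_factory=lambda: {"cold": 47, "warm": 52})
    sessions_per_treatment: dict[str, int] = field(
        default_factory=lambda: {"cold": 4, "warm": 5})
    n_birds_scanned: int = 13

    seed: int = 0

    def validate(self) -> None:
        for feather, (m, s) in {**self.feather_A}.items():
            if m <= 0:
                raise ValueError(f"asymptote mean for {feather} must be positive, got {m}")
            if s < 0:
                raise ValueError(f"asymptote sd for {feather} must be >= 0, got {s}")
        for feather, (m, s) in {**self.feather_mu}.items():
            if m <= 0:
                raise ValueError(f"growth-rate mean for {feather} must be positive, got {m}")
            if s < 0:
                raise ValueError(f"growth-rate sd for {feather} must be >= 0, got {s}")
        for name in ("lam_sd", "noise_sd", "mass_bird_sd", "mass_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for treatment, p in self.p_in_water.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"p_in_water[{treatment!r}] must be in [0, 1], got {p}")


def make_roster(config: SimConfig) -> list[Bird]:
    """Build the crossover roster: treatments alternate year over year,
    starting from each cohort's first-year assignment."""
    birds: list[Bird] = []
    other = {"cold": "warm", "warm": "cold"}
    for cohort_year, by_sex in sorted(config.cohorts.items()):
        first_study_year = max(cohort_year + 1, config.study_years[0])
        years = [y for y in config.study_years if y >= first_study_year]
        start = config.first_treatment.get(cohort_year, "cold")
        idx = 0
        for sex in ("female", "male"):
            for _ in range(by_sex.get(sex, 0)):
                idx += 1
                tby = {}
                treat = start
                for y in years:
                    tby[y] = treat
                    treat = other[treat]
                birds.append(Bird(
                    bird_id=f"E{cohort_year % 100:02d}-{idx:02d}",
                    sex=sex, cohort_year=cohort_year,
                    treatment_by_year=tby))
    return birds


def _truncnorm_pos(rng: np.random.Generator, mean: float, sd: float) -> float:
    # redraw until positive; all defaults are many sds above 0
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError("truncated-normal draw failed to land above 0")


def simulate_cohort(config: SimConfig | None = None) -> dict[str, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    dict of DataFrames
        ``birds`` (roster, one row per bird-year), ``true_params`` (the
        generating Gompertz parameters per bird-year-feather, with the
        true shed/regain dates), ``feather_measurements``,
        ``mass_series`` and ``scan_sessions``.  Identical config and seed
        give identical tables.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    roster = make_roster(config)
    bird_rows = []
    for b in roster:
        for year, treatment in sorted(b.treatment_by_year.items()):
            bird_rows.append({"bird_id": b.bird_id, "year": year,
                              "sex": b.sex, "cohort_year": b.cohort_year,
                              "treatment": treatment})
    birds = pd.DataFrame(bird_rows)

    session_times = np.arange(config.t_start, config.t_end + 1e-9,
                              config.session_interval)

    param_rows, meas_rows, mass_rows = [], [], []
    bird_offset = {b.bird_id: rng.normal(0.0, config.mass_bird_sd)
                   for b in roster}

    for b in roster:
        for year, treatment in sorted(b.treatment_by_year.items()):
            lam_bird = rng.normal(config.lam_mean, config.lam_sd)
            if treatment == "warm":
                lam_bird += config.lam_warm_shift
            for feather in FEATHERS:
                A = _truncnorm_pos(rng, *config.feather_A[feather])
                mu = _truncnorm_pos(rng, *config.feather_mu[feather])
                lam = lam_bird + config.feather_lam_offset[feather]
                p = GompertzParams(A=A, mu=mu, lam=lam)
                shed_t = gompertz_inverse(0.015, p)
                regain_t = gompertz_inverse(0.88, p)
                param_rows.append({
                    "bird_id": b.bird_id, "year": year, "feather": feather,
                    "A": A, "mu": mu, "lam": lam,
                    "shed_t": shed_t, "regain_t": regain_t})

                truth = gompertz_length(session_times, p)
                # measurable once past the field-detection length, and never
                # before the old feather's shed date
                visible = ((truth > config.detection_threshold)
                           & (session_times >= shed_t))
                for t, y_true in zip(session_times[visible], truth[visible]):
                    for rep in range(1, config.replicates + 1):
                        y = y_true + (rng.normal(0.0, config.noise_sd)
                                      if config.noise_sd > 0 else 0.0)
                        meas_rows.append({
                            "bird_id": b.bird_id, "year": year,
                            "feather": feather, "t": float(t),
                            "replicate": rep,
                            "length": float(max(y, 0.0))})

            # moult-aligned piecewise-linear mass trajectory, anchored on
            # the bird's P9 events
            p9 = param_rows[-2] if FEATHERS[0] == "P9" else param_rows[-1]
            shed, regain = p9["shed_t"], p9["regain_t"]
            base = config.mass_base[b.sex] + bird_offset[b.bird_id]
            gain = config.mass_gain[(treatment, b.sex)]
            nodes_t = np.array([shed - 30.0, shed, regain,
                                regain + 30.0])
            nodes_m = np.array([base,
                                base + gain,
                                base + gain - config.mass_moult_dip,
                                base + config.mass_post_gain[treatment]])
            weigh_times = np.arange(shed - 35.0, regain + 35.0 + 1e-9,
                                    config.weigh_interval)
            traj = np.interp(weigh_times, nodes_t, nodes_m)
            noise = (rng.normal(0.0, config.mass_noise_sd, traj.size)
                     if config.mass_noise_sd > 0 else np.zeros(traj.size))
            for t, m in zip(weigh_times, traj + noise):
                mass_rows.append({"bird_id": b.bird_id, "year": year,
                                  "t": float(t), "mass": float(m)})

    scan_rows = []
    for treatment in sorted(config.p_in_water):
        p = config.p_in_water[treatment]
        for s in range(config.sessions_per_treatment.get(treatment, 0)):
            sid = f"{treatment}-{s + 1:02d}"
            n_in = rng.binomial(config.n_birds_scanned, p,
                                size=config.scans_per_session[treatment])
            for k, ni in enumerate(n_in):
                scan_rows.append({
                    "session_id": sid, "treatment": treatment,
                    "scan_idx": k,
                    "n_in": int(ni),
                    "n_out": int(config.n_birds_scanned - ni)})

    return {
        "birds": birds,
        "true_params": pd.DataFrame(param_rows),
        "feather_measurements": pd.DataFrame(meas_rows),
        "mass_series": pd.DataFrame(mass_rows),
        "scan_sessions": pd.DataFrame(scan_rows),
    }
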