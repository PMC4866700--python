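"""Wet thermal conductance of a bird floating on water.

Conductance per unit plumage area is

    C_w = H * M / ((T_b - T_w) * A),   [W m^-2 degC^-1]

with H the mass-specific metabolic heat production (W/kg), M body mass
(kg), T_b deep-body temperature (degC), T_w water temperature, and A the
plumage surface area from the allometric relation A = 0.097 * M^(2/3) m^2.

Heat production is piecewise in water temperature for winter-acclimatized
eiders: minimal (3.83 W/kg) within the thermoneutral band 16-25 degC, and
rising linearly below the lower critical temperature, H = 5.48 - 0.09*T_w.
The two branches do not meet at 16 degC (gap 0.21 W/kg); the discontinuity
is inherent to the source calorimetry and is surfaced, not smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ThermoConstants",
    "plumage_area",
    "heat_production",
    "wet_conductance",
    "conductance_contrast",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Physiological and allometric constants for moulting eiders.

    Units: temperatures degC, heat production W/kg, area coefficient
    m^2 kg^(-2/3).
    """

    T_b: float = 40.2
    area_coeff: float = 0.097
    area_exp: float = 2.0 / 3.0
    H_thermoneutral: float = 3.83
    H_cold_intercept: float = 5.48
    H_cold_slope: float = 0.09
    LCT_water: float = 15.0
    thermoneutral_lo: float = 16.0
    thermoneutral_hi: float = 25.0

    def __post_init__(self) -> None:
        for name in ("T_b", "area_coeff", "H_thermoneutral",
                     "H_cold_intercept", "H_cold_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # cold-branch H must stay positive over the supported range
        if self.H_cold_intercept - self.H_cold_slope * self.thermoneutral_lo <= 0:
            raise ValueError("cold-branch heat production non-positive at band edge")


DEFAULT_CONSTANTS = ThermoConstants()


def plumage_area(M: float, c: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Plumage surface area (m^2) from body mass (kg): 0.097 * M^(2/3)."""
    if M <= 0:
        raise ValueError(f"body mass must be positive, got {M} kg")
    return c.area_coeff * M ** c.area_exp


def heat_production(T_w: float, c: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Minimal mass-specific heat production (W/kg) on water at ``T_w`` degC.

    Piecewise: the thermoneutral minimum within [16, 25] degC, the linear
    cold-water relation below 16 degC.  Temperatures outside [0, 25] degC
    are outside the supported calorimetry and are refused rather than
    extrapolated.
    """
    if not (0.0 <= T_w <= c.thermoneutral_hi):
        raise ValueError(
            f"water temperature {T_w} degC outside supported range "
            f"[0, {c.thermoneutral_hi}]; extrapolation refused"
        )
    if T_w >= c.thermoneutral_lo:
        return c.H_thermoneutral
    return c.H_cold_intercept - c.H_cold_slope * T_w


def wet_conductance(M: float, T_w: float,
                    c: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Wet thermal conductance (W m^-2 degC^-1) of a floating bird.

    Parameters
    ----------
    M : float
        Body mass, kg.
    T_w : float
        Water temperature, degC; must be below body temperature.
    """
    if T_w >= c.T_b:
        raise ValueError(
            f"water temperature {T_w} degC must be below body "
            f"temperature {c.T_b} degC"
        )
    H = heat_production(T_w, c)
    return H * M / ((c.T_b - T_w) * plumage_area(M, c))


def conductance_contrast(C_warm: float, C_cold: float) -> float:
    """Percent excess of warm-water over cold-water conductance,
    100 * (C_warm - C_cold) / C_cold (unrounded)."""
    if C_warm <= 0 or C_cold <= 0:
        raise ValueError("conductances must be positive")
    return 100.0 * (C_warm - C_cold) / C_cold
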