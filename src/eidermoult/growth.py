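"""Gompertz feather-growth model: analytic curve, inverse, slope, and
nonlinear least-squares fitting of repeated length measurements.

The parameterization is the one standard in growth-curve work (grofit
convention)::

    y(t) = A * exp(-exp(mu*e/A * (lam - t) + 1))

where ``A`` (mm) is the asymptotic feather length, ``mu`` (mm/day) the
maximum growth rate -- the slope at the inflection point, where the curve
passes ``A/e`` -- and ``lam`` (days) the lag phase, the t-intercept of the
tangent at the inflection.  This parameterization makes every parameter
directly interpretable, which is why moult studies report ``mu`` as "the
maximum feather growth rate" without further transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GompertzParams",
    "GompertzModel",
    "GompertzResults",
    "gompertz_length",
    "gompertz_inverse",
    "gompertz_slope",
    "fit_gompertz",
]

_E = math.e


@dataclass(frozen=True)
class GompertzParams:
    """The triple (A, mu, lam) defining one feather's regrowth curve.

    Parameters
    ----------
    A : float
        Asymptotic length, mm.  Must be positive.
    mu : float
        Maximum growth rate, mm/day.  Must be positive.
    lam : float
        Lag phase, days, on the same time axis as the measurements.
    """

    A: float
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and math.isfinite(self.A)):
            raise ValueError(f"A must be positive and finite, got {self.A}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not math.isfinite(self.lam):
            raise ValueError(f"lam must be finite, got {self.lam}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.A, self.mu, self.lam)


def _z(t, A, mu, lam):
    return mu * _E / A * (lam - np.asarray(t, dtype=float)) + 1.0


def gompertz_length(t, p: GompertzParams):
    """Feather length (mm) at time ``t`` (days).

    Strictly increasing in ``t`` and bounded in (0, A).  Accepts scalars or
    arrays.
    """
    z = _z(t, p.A, p.mu, p.lam)
    return p.A * np.exp(-np.exp(z))


def gompertz_inverse(fraction, p: GompertzParams):
    """Time (days) at which the curve reaches ``fraction`` of its asymptote.

    Analytic inversion:  y/A = f  <=>  t = lam + (A/(mu*e)) * (1 - ln(-ln f)).

    Raises
    ------
    ValueError
        If ``fraction`` is outside the open interval (0, 1), where the
        curve never arrives.
    """
    f = np.asarray(fraction, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    t = p.lam + (p.A / (p.mu * _E)) * (1.0 - np.log(-np.log(f)))
    return float(t) if np.isscalar(fraction) or np.ndim(fraction) == 0 else t


def gompertz_slope(t, p: GompertzParams):
    """Instantaneous growth rate dy/dt (mm/day) at time ``t``.

    Equals ``mu * e * exp(z - exp(z))`` with ``z = mu*e/A*(lam-t) + 1``;
    its maximum over t is exactly ``mu``, attained where y = A/e.
    """
    z = _z(t, p.A, p.mu, p.lam)
    return p.mu * _E * np.exp(z - np.exp(z))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GompertzResults:
    """Results of a Gompertz least-squares fit.

    Attributes
    ----------
    params : GompertzParams
        Point estimates (A, mu, lam).
    bse : dict
        Asymptotic standard errors from the Jacobian at the solution
        (NaN when the information matrix is singular).
    rss : float
        Residual sum of squares, mm^2.
    n_obs : int
        Number of observations used (replicates enter individually).
    converged : bool
        False whenever the optimizer stopped on the iteration limit or the
        solution sits on a parameter bound; downstream phenology refuses
        non-converged fits.
    resid_sd : float
        Residual standard deviation, mm (rss / (n - 3) dof).
    """

    params: GompertzParams
    bse: dict
    rss: float
    n_obs: int
    converged: bool
    resid_sd: float
    model: "GompertzModel" = field(repr=False, default=None)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def fittedvalues(self) -> np.ndarray:
        return gompertz_length(self.model.t, self.params)

    def predict(self, t):
        return gompertz_length(t, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Gompertz growth-curve fit",
            "=" * 42,
            f"{'n obs':<22}{self.n_obs:>20d}",
            f"{'converged':<22}{str(self.converged):>20}",
            f"{'RSS (mm^2)':<22}{self.rss:>20.4f}",
            f"{'resid sd (mm)':<22}{self.resid_sd:>20.4f}",
            "-" * 42,
            f"{'param':<10}{'estimate':>16}{'std err':>16}",
            f"{'A (mm)':<10}{p.A:>16.4f}{self.bse['A']:>16.4f}",
            f"{'mu (mm/d)':<10}{p.mu:>16.4f}{self.bse['mu']:>16.4f}",
            f"{'lam (d)':<10}{p.lam:>16.4f}{self.bse['lam']:>16.4f}",
            "=" * 42,
        ]
        return "\n".join(lines)


class GompertzModel:
    """Gompertz growth model for one feather's repeated length measurements.

    Replicate measurements at the same session enter the objective as
    independent observations (they are not pre-averaged); pass
    ``average_replicates=True`` to :meth:`from_dataframe` to collapse them.

    Parameters
    ----------
    t : array-like
        Measurement times, days.  At least 5 distinct values.
    y : array-like
        Feather lengths, mm, non-negative.

    Examples
    --------
    >>> p = GompertzParams(A=167.0, mu=5.0, lam=10.0)
    >>> t = np.arange(0, 60, 3.5)
    >>> res = GompertzModel(t, gompertz_length(t, p)).fit()
    >>> round(res.params.mu, 6)
    5.0
    """

    def __init__(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if np.any(y < 0):
            raise ValueError("feather lengths must be non-negative")
        if np.unique(t).size < 5:
            raise ValueError(
                f"need >= 5 distinct time points to fit 3 parameters, "
                f"got {np.unique(t).size}"
            )
        if np.ptp(y) == 0:
            raise ValueError("degenerate data: all lengths identical")
        order = np.argsort(t, kind="stable")
        self.t = t[order]
        self.y = y[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, t_col: str = "t",
                       y_col: str = "length",
                       average_replicates: bool = False) -> "GompertzModel":
        """Build a model from a long-format measurement table."""
        if average_replicates:
            g = df.groupby(t_col, as_index=False)[y_col].mean()
            return cls(g[t_col].to_numpy(), g[y_col].to_numpy())
        return cls(df[t_col].to_numpy(dtype=float), df[y_col].to_numpy(dtype=float))

    # -- initialization ----------------------------------------------------
    def _start_values(self) -> tuple[float, float, float]:
        # A0: 5% above the largest observation; mu0: steepest secant between
        # session means; lam0: tangent-intercept at the steepest secant.
        tu, inv = np.unique(self.t, return_inverse=True)
        ymeans = np.bincount(inv, weights=self.y) / np.bincount(inv)
        A0 = 1.05 * float(self.y.max())
        dy = np.diff(ymeans)
        dt = np.diff(tu)
        slopes = dy / dt
        k = int(np.argmax(slopes))
        mu0 = max(float(slopes[k]), 1e-6)
        t_mid = 0.5 * (tu[k] + tu[k + 1])
        y_mid = 0.5 * (ymeans[k] + ymeans[k + 1])
        lam0 = t_mid - y_mid / mu0
        return A0, mu0, lam0

    def fit(self, *, ftol: float = 1e-10) -> GompertzResults:
        """Fit (A, mu, lam) by least squares with an analytic Jacobian.

        Bounds: A in [0.8 x max length, 3 x max length], mu in (0, 10 x mu0],
        lam unbounded.  The asymptote's lower bound sits below the largest
        observation because measurement noise routinely pushes the sample
        maximum above the true plateau.  A solution on a bound or at the
        iteration limit is reported with ``converged=False`` rather than
        silently accepted.
        """
        A0, mu0, lam0 = self._start_values()
        ymax = float(self.y.max())
        lo = np.array([0.8 * ymax, 1e-9, -np.inf])
        hi = np.array([3.0 * ymax, 10.0 * mu0, np.inf])
        x0 = np.clip([A0, mu0, lam0], lo, hi)

        t, y = self.t, self.y

        def resid(x):
            A, mu, lam = x
            z = mu * _E / A * (lam - t) + 1.0
            return A * np.exp(-np.exp(z)) - y

        def jac(x):
            A, mu, lam = x
            z = mu * _E / A * (lam - t) + 1.0
            ez = np.exp(z)
            f = A * np.exp(-ez)
            # d f / dA, d f / dmu, d f / dlam
            dz_dA = -mu * _E / A**2 * (lam - t)
            dz_dmu = _E / A * (lam - t)
            dz_dlam = mu * _E / A
            df_dz = -f * ez
            return np.column_stack([
                f / A + df_dz * dz_dA,
                df_dz * dz_dmu,
                df_dz * dz_dlam,
            ])

        sol = least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                            ftol=ftol, xtol=1e-12, gtol=1e-12,
                            max_nfev=2000)

        on_bound = bool(
            np.any(np.isclose(sol.x, lo, rtol=1e-6, atol=0))
            or np.any(np.isclose(sol.x[:2], hi[:2], rtol=1e-6, atol=0))
        )
        converged = bool(sol.status > 0) and not on_bound

        A, mu, lam = sol.x
        params = GompertzParams(A=float(A), mu=float(mu), lam=float(lam))
        n = t.size
        rss = float(2.0 * sol.cost)
        dof = max(n - 3, 1)
        resid_sd = math.sqrt(rss / dof)

        # asymptotic SEs from (J'J)^-1 * s^2
        J = jac(sol.x)
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        bse = {"A": float(se[0]), "mu": float(se[1]), "lam": float(se[2])}

        return GompertzResults(params=params, bse=bse, rss=rss, n_obs=n,
                               converged=converged, resid_sd=resid_sd,
                               model=self)


def fit_gompertz(measurements: pd.DataFrame, *,
                 average_replicates: bool = False) -> GompertzResults:
    """Convenience wrapper: fit one feather's measurement table.

    ``measurements`` needs columns ``t`` (days) and ``length`` (mm);
    extra columns (bird_id, feather, replicate) are ignored.
    """
    return GompertzModel.from_dataframe(
        measurements, average_replicates=average_replicates
    ).fit()


def fit_cohort(measurements: pd.DataFrame, *,
               average_replicates: bool = False) -> pd.DataFrame:
    """Fit every (bird_id, year, feather) group in a long measurement table.

    Returns one row per group with the estimates, rss, residual sd and the
    convergence flag; groups that fail preconditions get ``converged=False``
    and NaN estimates rather than aborting the cohort.
    """
    keys = [k for k in ("bird_id", "year", "feather") if k in measurements.columns]
    rows = []
    for key, grp in measurements.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        try:
            res = fit_gompertz(grp, average_replicates=average_replicates)
            rec.update(A=res.params.A, mu=res.params.mu, lam=res.params.lam,
                       rss=res.rss, n_obs=res.n_obs, resid_sd=res.resid_sd,
                       converged=res.converged)
        except ValueError:
            rec.update(A=np.nan, mu=np.nan, lam=np.nan, rss=np.nan,
                       n_obs=len(grp), resid_sd=np.nan, converged=False)
        rows.append(rec)
    return pd.DataFrame(rows)
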