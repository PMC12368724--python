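"""Monomer-dimer equilibrium bookkeeping and dissociation-constant estimation.

A homodimer in a simple two-state equilibrium, M + M <=> D, obeys

    K_D = [M]^2 / [D]                       (concentration units)

with the mass balance C_total = [M] + 2 [D] expressed in monomer
equivalents.  Solving the two relations for [M] at a given total
concentration gives the closed form

    [M] = (-K_D + sqrt(K_D^2 + 8 K_D C_total)) / 4

Rearranged, the equilibrium reads [M]^2 = K_D [D]: a plot of [M]^2
against [D] over a dilution series is a straight line through the origin
whose slope is K_D.  `KdLinearEstimator` fits that slope;
`KdNonlinearEstimator` fits the same model directly to observed dimer
mass fractions as a function of C_total, which serves as a
cross-method diagnostic.  Both are scikit-learn compatible regressors.

All concentrations are in uM unless stated otherwise; dimer
concentrations are dimer-molar (moles of D, not of chains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SpeciesConcentrations",
    "DimerEquilibriumFit",
    "monomer_concentration",
    "dimer_fraction",
    "species_from_areas",
    "KdLinearEstimator",
    "KdNonlinearEstimator",
    "fit_kd_linear",
    "fit_kd_nonlinear",
    "bootstrap_kd",
]

#: dimer mass fractions outside this range carry almost no information on
#: K_D and dominate a through-origin fit; such points are flagged, not dropped.
LEVERAGE_FRACTION_LIMITS = (0.01, 0.99)


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Monomer/dimer speciation of one sample.

    Attributes
    ----------
    M : float
        Monomer concentration (uM).
    D : float
        Dimer concentration in dimer-molar units (uM of D particles).
    c_total : float
        Total protein in monomer equivalents (uM); C = [M] + 2[D].
    """

    M: float
    D: float
    c_total: float

    def __post_init__(self) -> None:
        if self.M < 0 or self.D < 0:
            raise ValueError("species concentrations must be non-negative")
        if not np.isclose(self.M + 2.0 * self.D, self.c_total, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"mass balance violated: [M] + 2[D] = {self.M + 2 * self.D!r} "
                f"!= c_total = {self.c_total!r}"
            )

    @property
    def dimer_mass_fraction(self) -> float:
        """Fraction of protein chains residing in dimers, 2[D]/C_total."""
        return 2.0 * self.D / self.c_total


@dataclass(frozen=True)
class DimerEquilibriumFit:
    """Result of a K_D fit over a dilution series."""

    kd: float                      # uM
    stderr: float                  # uM, asymptotic standard error
    n_points: int
    r_squared: float
    method: str                    # linear-origin | linear-free-intercept | nonlinear
    intercept: float = 0.0         # uM^2, zero for through-origin fits
    ci95: tuple[float, float] | None = None  # percentile bootstrap interval (uM)


def monomer_concentration(c_total, kd):
    """Equilibrium [M] at total chain concentration ``c_total`` and ``kd``.

    Vectorised over both arguments.  Units cancel, so any consistent
    concentration unit works.
    """
    c_total = np.asarray(c_total, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(c_total <= 0):
        raise ValueError("c_total must be positive")
    if np.any(kd <= 0):
        raise ValueError("Kd must be positive")
    # algebraically (-Kd + sqrt(Kd^2 + 8 Kd c))/4, written in conjugate
    # form to avoid cancellation when 8c << Kd
    m = 2.0 * c_total / (1.0 + np.sqrt(1.0 + 8.0 * c_total / kd))
    return m if m.ndim else float(m)


def dimer_fraction(c_total, kd):
    """Equilibrium dimer mass fraction 2[D]/C_total. Vectorised."""
    m = monomer_concentration(c_total, kd)
    return 1.0 - m / np.asarray(c_total, dtype=float)


def species_from_areas(area_M: float, area_D: float, c_total: float) -> SpeciesConcentrations:
    """Convert monomer/dimer peak areas into species concentrations.

    Assumes the detector responds identically per unit protein mass for
    both species, so the area fraction equals the mass fraction:
    f_M = A_M / (A_M + A_D), [M] = f_M * C_total, [D] = (1 - f_M) * C_total / 2.
    """
    if area_M < 0 or area_D < 0:
        raise ValueError("peak areas must be non-negative")
    if area_M == 0 and area_D == 0:
        raise ValueError("at least one peak area must be positive")
    if c_total <= 0:
        raise ValueError("c_total must be positive")
    f_m = area_M / (area_M + area_D)
    return SpeciesConcentrations(M=f_m * c_total, D=(1.0 - f_m) * c_total / 2.0,
                                 c_total=c_total)


def _flag_leverage(points: list[SpeciesConcentrations]) -> None:
    lo, hi = LEVERAGE_FRACTION_LIMITS
    bad = [p for p in points if not lo <= p.dimer_mass_fraction <= hi]
    if bad:
        warnings.warn(
            f"{len(bad)} sample(s) have dimer mass fraction outside "
            f"[{lo:.0%}, {hi:.0%}]; they carry high leverage in the K_D fit",
            stacklevel=3,
        )


class KdLinearEstimator(RegressorMixin, BaseEstimator):
    """Dissociation constant from the linearisation [M]^2 = K_D [D].

    Fit ``X`` = dimer concentrations [D] (uM, shape (n, 1)) against
    ``y`` = squared monomer concentrations [M]^2 (uM^2).  The slope is
    K_D in uM.

    Parameters
    ----------
    through_origin : bool, default True
        The equilibrium model has no intercept; the free-intercept mode
        is retained as a lack-of-fit diagnostic only.

    Attributes
    ----------
    kd_ : float
        Fitted slope, i.e. the dissociation constant (uM).
    intercept_ : float
        Fitted intercept (uM^2); exactly 0.0 when ``through_origin``.
    stderr_ : float
        Standard error of the slope (uM).
    r_squared_ : float
        Coefficient of determination against the fitted line
        (uncentred for through-origin fits).
    n_points_ : int
    """

    def __init__(self, through_origin: bool = True):
        self.through_origin = through_origin

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=1)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of dimer concentrations")
        d = X[:, 0]
        n_min = 1 if self.through_origin else 2
        if d.shape[0] < n_min:
            raise ValueError(f"need at least {n_min} point(s)")
        if np.allclose(d, 0.0):
            raise ValueError("degenerate design: all dimer concentrations are zero")

        if self.through_origin:
            sxx = float(np.dot(d, d))
            slope = float(np.dot(d, y)) / sxx
            intercept = 0.0
            resid = y - slope * d
            dof = max(d.shape[0] - 1, 1)
            ss_tot = float(np.dot(y, y))  # uncentred
        else:
            xm, ym = d.mean(), y.mean()
            sxx = float(np.sum((d - xm) ** 2))
            if sxx == 0:
                raise ValueError("degenerate design: all dimer concentrations equal")
            slope = float(np.sum((d - xm) * (y - ym)) / sxx)
            intercept = float(ym - slope * xm)
            resid = y - (slope * d + intercept)
            dof = max(d.shape[0] - 2, 1)
            ss_tot = float(np.sum((y - ym) ** 2))

        ss_res = float(np.dot(resid, resid))
        if slope <= 0:
            raise ValueError(f"fitted slope {slope!r} is not a valid K_D (must be > 0)")
        self.kd_ = slope
        self.intercept_ = intercept
        self.stderr_ = float(np.sqrt(ss_res / dof / sxx))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_points_ = int(d.shape[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        X = check_array(X)
        return self.kd_ * X[:, 0] + self.intercept_


class KdNonlinearEstimator(RegressorMixin, BaseEstimator):
    """Direct least-squares fit of the dimer mass fraction vs C_total.

    Fit ``X`` = total concentrations (uM, shape (n, 1)) against ``y`` =
    observed dimer mass fractions 2[D]/C_total.  The single parameter is
    K_D, optimised on a log scale to keep it positive.

    Attributes
    ----------
    kd_ : float
    stderr_ : float
        From the Gauss-Newton approximation to the covariance.
    r_squared_ : float
    n_points_ : int
    """

    def __init__(self, kd_init: float | None = None, xtol: float = 1e-12):
        self.kd_init = kd_init
        self.xtol = xtol

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        c = X[:, 0]
        if np.unique(c).size < 2:
            raise ValueError("need samples at >= 2 distinct total concentrations")
        kd0 = self.kd_init
        if kd0 is None:
            # moment start: invert the model at the median sample
            med_c, med_f = float(np.median(c)), float(np.clip(np.median(y), 1e-6, 1 - 1e-6))
            m = (1.0 - med_f) * med_c
            kd0 = m * m / (med_f * med_c / 2.0)

        def resid(log_kd):
            return dimer_fraction(c, np.exp(log_kd[0])) - y

        sol = least_squares(resid, x0=[np.log(kd0)], xtol=self.xtol, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise RuntimeError(f"K_D optimisation did not converge: {sol.message}")
        self.kd_ = float(np.exp(sol.x[0]))
        dof = max(c.shape[0] - 1, 1)
        ss_res = float(2.0 * sol.cost)
        jtj = float((sol.jac.T @ sol.jac).item())
        # delta method: var(kd) = var(log kd) * kd^2
        var_log = ss_res / dof / jtj if jtj > 0 else np.inf
        self.stderr_ = float(np.sqrt(var_log) * self.kd_)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_points_ = int(c.shape[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        X = check_array(X)
        return dimer_fraction(X[:, 0], self.kd_)


def _points_to_xy(points: list[SpeciesConcentrations]) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([p.D for p in points], dtype=float)
    m2 = np.array([p.M for p in points], dtype=float) ** 2
    return d.reshape(-1, 1), m2


def fit_kd_linear(points: list[SpeciesConcentrations],
                  through_origin: bool = True) -> DimerEquilibriumFit:
    """Estimate K_D from speciation points via the [M]^2-vs-[D] slope."""
    _flag_leverage(points)
    X, y = _points_to_xy(points)
    est = KdLinearEstimator(through_origin=through_origin).fit(X, y)
    return DimerEquilibriumFit(
        kd=est.kd_, stderr=est.stderr_, n_points=est.n_points_,
        r_squared=est.r_squared_, intercept=est.intercept_,
        method="linear-origin" if through_origin else "linear-free-intercept",
    )


def fit_kd_nonlinear(samples: list[tuple[float, float]]) -> DimerEquilibriumFit:
    """Estimate K_D from (C_total, dimer mass fraction) samples directly."""
    arr = np.asarray(samples, dtype=float)
    est = KdNonlinearEstimator().fit(arr[:, :1], arr[:, 1])
    return DimerEquilibriumFit(kd=est.kd_, stderr=est.stderr_, n_points=est.n_points_,
                               r_squared=est.r_squared_, method="nonlinear")


def _origin_slope_and_hc3(d: np.ndarray, m2: np.ndarray) -> tuple[float, float]:
    """Through-origin slope and its HC3 (leverage-corrected) sandwich SE."""
    sxx = float(np.dot(d, d))
    b = float(np.dot(d, m2)) / sxx
    e = m2 - b * d
    h = np.clip(d * d / sxx, None, 0.999)
    se = float(np.sqrt(np.sum(d * d * (e / (1.0 - h)) ** 2)) / sxx)
    return b, se


def bootstrap_kd(points: list[SpeciesConcentrations], n_boot: int = 1000,
                 seed: int | None = None, through_origin: bool = True,
                 interval: str = "studentized") -> tuple[tuple[float, float], float]:
    """Case-resampling bootstrap CI for the linear K_D estimator.

    Returns ``((lo95, hi95), stderr)``; ``stderr`` is the sd of the
    bootstrap slope distribution.  Reproducible for a fixed ``seed``.

    A log-spaced dilution series concentrates most of the design
    leverage in the one or two highest-concentration samples, which
    makes the plain percentile interval too narrow (the effective sample
    size for the variance is far below n).  The default ``studentized``
    interval (bootstrap-t, pivoted on an HC3 sandwich SE) is
    second-order accurate and restores near-nominal coverage;
    ``interval="percentile"`` is kept for comparison.
    """
    if len(points) < 3:
        raise ValueError("bootstrap needs at least 3 points")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if interval not in ("studentized", "percentile"):
        raise ValueError(f"unknown interval type {interval!r}")
    d = np.array([p.D for p in points], dtype=float)
    m2 = np.array([p.M for p in points], dtype=float) ** 2
    if not through_origin:
        # centre once; the slope of the centred fit is the free-intercept slope
        d, m2 = d - d.mean(), m2 - m2.mean()
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    db, m2b = d[idx], m2[idx]
    sxxb = np.einsum("ij,ij->i", db, db)
    ok = sxxb > 0
    db, m2b, sxxb = db[ok], m2b[ok], sxxb[ok]
    slopes = np.einsum("ij,ij->i", db, m2b) / sxxb
    stderr = float(np.std(slopes, ddof=1))

    if interval == "percentile":
        lo, hi = np.percentile(slopes, [2.5, 97.5])
        return (float(lo), float(hi)), stderr

    b, se = _origin_slope_and_hc3(d, m2)
    if se == 0.0:       # noise-free data: degenerate, zero-width interval
        return (b, b), stderr
    eb = m2b - slopes[:, None] * db
    hb = np.clip(db * db / sxxb[:, None], None, 0.999)
    seb = np.sqrt(np.einsum("ij,ij->i", db * db, (eb / (1.0 - hb)) ** 2)) / sxxb
    good = seb > 0
    t = (slopes[good] - b) / seb[good]
    t_lo, t_hi = np.percentile(t, [2.5, 97.5])
    return (float(b - t_hi * se), float(b - t_lo * se)), stderr
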