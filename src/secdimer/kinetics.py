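"""Initial-rate extraction and Michaelis-Menten parameter estimation.

Product time courses at each substrate concentration are reduced to
initial rates v0 (nmol/min) by an ordinary least-squares slope, then the
rates are fitted to

    v0 = Vmax [S] / (Km + [S])

by nonlinear least squares.  Vmax (nmol/min) divided by the amount of
enzyme in the assay (E0 x reaction volume, in nmol) gives the turnover
number k_cat (min^-1); k_cat / Km is the catalytic efficiency
(min^-1 mM^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "KineticsDataset",
    "MMFit",
    "initial_rates",
    "MichaelisMentenEstimator",
    "fit_michaelis_menten",
    "relative_efficiency",
]


@dataclass
class KineticsDataset:
    """Product accumulation (nmol) over time at several substrate levels.

    ``product[i, j]`` is the product formed at ``substrate_concs[i]`` after
    ``times[j]`` minutes.  ``e0_um`` and ``volume_ul`` describe the assay so
    rates can be converted to turnover numbers.
    """

    substrate_concs: np.ndarray   # mM
    times: np.ndarray             # min, strictly increasing
    product: np.ndarray           # nmol, shape (n_S, n_t)
    e0_um: float                  # enzyme concentration in the assay (uM)
    volume_ul: float = 100.0      # reaction volume (uL)

    def __post_init__(self) -> None:
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.product.shape != (self.substrate_concs.size, self.times.size):
            raise ValueError("product must have shape (n_substrates, n_times)")
        if np.any(self.product < 0):
            raise ValueError("product amounts must be non-negative")
        if self.e0_um <= 0 or self.volume_ul <= 0:
            raise ValueError("e0_um and volume_ul must be positive")

    @property
    def enzyme_nmol(self) -> float:
        """Amount of enzyme in the assay: E0 (uM) x volume (uL) / 1000."""
        return self.e0_um * self.volume_ul / 1000.0


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten parameters with asymptotic standard deviations."""

    kcat: float            # min^-1
    kcat_sd: float
    km: float              # mM
    km_sd: float
    efficiency: float      # kcat/Km, min^-1 mM^-1
    efficiency_sd: float
    n_points: int


def initial_rates(dataset: KineticsDataset) -> list[tuple[float, float]]:
    """Per-substrate initial rate from the slope of product vs time.

    Ordinary least squares with a free intercept (a small mixing
    dead-time offsets the intercept, not the slope).  Returns
    ``[(S_mM, v0_nmol_per_min), ...]`` in the dataset's substrate order.
    """
    if dataset.times.size < 2:
        raise ValueError("need at least 2 time points per substrate concentration")
    t = dataset.times
    tc = t - t.mean()
    slopes = (dataset.product - dataset.product.mean(axis=1, keepdims=True)) @ tc \
        / np.dot(tc, tc)
    return [(float(s), float(v)) for s, v in zip(dataset.substrate_concs, slopes)]


def _mm_rate(s, vmax, km):
    return vmax * s / (km + s)


class MichaelisMentenEstimator(RegressorMixin, BaseEstimator):
    """Nonlinear Michaelis-Menten regressor on initial rates.

    Fit ``X`` = substrate concentrations (mM, shape (n, 1)) against
    ``y`` = initial rates (nmol/min).  A direct hyperbolic fit is used —
    no Lineweaver-Burk linearisation, which distorts the error structure.

    Parameters
    ----------
    e0_um, volume_ul : float
        Assay composition used to convert Vmax to k_cat.

    Attributes
    ----------
    vmax_ : float           nmol/min
    kcat_ : float           min^-1
    km_ : float             mM
    kcat_sd_, km_sd_ : float
        From the fit covariance.
    efficiency_, efficiency_sd_ : float
        k_cat/Km with first-order (independent-error) propagation.
    """

    def __init__(self, e0_um: float = 0.09, volume_ul: float = 100.0):
        self.e0_um = e0_um
        self.volume_ul = volume_ul

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        s = X[:, 0]
        if np.unique(s).size < 3:
            raise ValueError("need rates at >= 3 distinct substrate concentrations")
        if np.any(y < 0):
            raise ValueError("initial rates must be non-negative")
        p0 = (float(y.max()) or 1.0, float(np.median(s)))
        try:
            popt, pcov = curve_fit(_mm_rate, s, y, p0=p0, maxfev=10000)
        except RuntimeError as exc:
            raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        vmax, km = map(float, popt)
        if vmax <= 0 or km <= 0:
            raise RuntimeError(f"non-physical fit: Vmax={vmax}, Km={km}")
        vmax_sd, km_sd = map(float, np.sqrt(np.diag(pcov)))
        enzyme_nmol = self.e0_um * self.volume_ul / 1000.0
        self.vmax_ = vmax
        self.km_ = km
        self.kcat_ = vmax / enzyme_nmol
        self.kcat_sd_ = vmax_sd / enzyme_nmol
        self.km_sd_ = km_sd
        self.efficiency_ = self.kcat_ / km
        self.efficiency_sd_ = self.efficiency_ * float(
            np.hypot(self.kcat_sd_ / self.kcat_, km_sd / km))
        self.n_points_ = int(s.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "vmax_")
        X = check_array(X)
        return _mm_rate(X[:, 0], self.vmax_, self.km_)


def fit_michaelis_menten(rates: list[tuple[float, float]], e0_um: float,
                         volume_ul: float = 100.0) -> MMFit:
    """Fit (S, v0) pairs; returns the parameter bundle in bench units."""
    arr = np.asarray(rates, dtype=float)
    est = MichaelisMentenEstimator(e0_um=e0_um, volume_ul=volume_ul).fit(
        arr[:, :1], arr[:, 1])
    return MMFit(kcat=est.kcat_, kcat_sd=est.kcat_sd_, km=est.km_, km_sd=est.km_sd_,
                 efficiency=est.efficiency_, efficiency_sd=est.efficiency_sd_,
                 n_points=est.n_points_)


def relative_efficiency(fit: MMFit, reference_fit: MMFit) -> tuple[float, float]:
    """Catalytic efficiency as a percentage of a reference enzyme's.

    Returns ``(percent, sd)`` with independent-error propagation of both
    efficiencies.
    """
    if reference_fit.efficiency <= 0:
        raise ValueError("reference efficiency must be positive")
    pct = 100.0 * fit.efficiency / reference_fit.efficiency
    sd = pct * float(np.hypot(fit.efficiency_sd / fit.efficiency,
                              reference_fit.efficiency_sd / reference_fit.efficiency))
    return pct, sd
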