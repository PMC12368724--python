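"""Synthetic SEC dilution series and enzyme time courses.

The generators produce data with exactly the statistical structure the
downstream analysis assumes, so every stage of the pipeline can be
exercised against known ground truth:

* A dilution series of two-Gaussian chromatograms whose noise-free peak
  areas follow the monomer-dimer equilibrium at a chosen true K_D, with
  multiplicative (lognormal) area noise and an optional linear baseline.
  The detector response is taken proportional to protein mass and equal
  per unit mass for monomer and dimer (A280-like), which is what lets
  the analysis map area fractions to mass fractions.  Peaks do not
  interconvert during elution — the chromatogram is a frozen snapshot of
  the loading equilibrium, appropriate for cold-column SEC where
  monomer-dimer exchange is slow.
* Michaelis-Menten product time courses, product(t) = v0 * t plus
  additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatography import Chromatogram
from .equilibrium import SpeciesConcentrations, monomer_concentration
from .kinetics import KineticsDataset

__all__ = [
    "SimulationConfig",
    "KineticsSimConfig",
    "simulate_equilibrium_species",
    "simulate_dilution_series",
    "simulate_timecourse",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic SEC dilution series.

    Defaults mirror a tandem Superdex-style separation of a ~120 kDa
    dimer (elutes ~25 mL) and its ~60 kDa monomer (~35 mL).

    Attributes
    ----------
    true_kd : float
        Dissociation constant used to speciate each sample (uM).
    c_totals : sequence of float
        Loaded total protein concentrations, monomer-equivalent (uM).
    monomer_center, dimer_center : float
        Peak retention volumes (mL); the dimer elutes earlier.
    monomer_width, dimer_width : float
        Gaussian sigma of each peak (mL).
    noise_cv : float
        Coefficient of variation of the lognormal multiplicative noise
        applied independently to each peak area.
    baseline_slope, baseline_intercept : float
        Linear detector drift (AU/mL and AU).
    response_factor : float
        Detector area per unit protein (AU*mL per uM of chains).
    vol_start, vol_stop, vol_step : float
        Recorded volume grid (mL).
    seed : int
        Seed of the generator's RNG; fixed seed -> bit-identical output.
    buffer_label : str
        Free-form label copied into each chromatogram's metadata.
    """

    true_kd: float
    c_totals: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    monomer_center: float = 35.0
    dimer_center: float = 25.0
    monomer_width: float = 0.8
    dimer_width: float = 0.8
    noise_cv: float = 0.0
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    response_factor: float = 1.0
    vol_start: float = 20.0
    vol_stop: float = 40.0
    vol_step: float = 0.02
    seed: int = 0
    buffer_label: str = "P100"

    def __post_init__(self) -> None:
        self.c_totals = tuple(float(c) for c in np.atleast_1d(self.c_totals))
        if self.true_kd <= 0:
            raise ValueError("true_kd must be positive")
        if any(c <= 0 for c in self.c_totals):
            raise ValueError("all c_totals must be positive")
        if self.monomer_center <= self.dimer_center:
            raise ValueError("monomer must elute after the dimer "
                             "(monomer_center > dimer_center)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.monomer_width <= 0 or self.dimer_width <= 0:
            raise ValueError("peak widths must be positive")
        if not self.vol_start < self.vol_stop or self.vol_step <= 0:
            raise ValueError("invalid volume grid")


@dataclass
class KineticsSimConfig:
    """Parameters of a synthetic Michaelis-Menten time-course experiment.

    ``noise_sd`` is an absolute Gaussian sd (nmol); ``noise_cv`` adds a
    component proportional to the expected product, sd = noise_sd +
    noise_cv * v0 * t.  Defaults follow a microplate stopped assay read
    at four times.
    """

    kcat: float                       # min^-1
    km: float                         # mM
    e0: float                         # uM enzyme in the assay
    substrate_concs: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)  # mM
    times: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)   # min
    noise_sd: float = 0.0             # nmol
    noise_cv: float = 0.0             # fraction of expected product
    volume_ul: float = 100.0          # reaction volume (uL)
    seed: int = 0

    def __post_init__(self) -> None:
        self.substrate_concs = tuple(float(s) for s in np.atleast_1d(self.substrate_concs))
        self.times = tuple(float(t) for t in np.atleast_1d(self.times))
        if min(self.kcat, self.km, self.e0) <= 0:
            raise ValueError("kcat, km and e0 must all be positive")
        if any(s <= 0 for s in self.substrate_concs):
            raise ValueError("substrate concentrations must be positive")
        if not all(b > a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")


def simulate_equilibrium_species(c_total: float, kd: float) -> SpeciesConcentrations:
    """Speciate one sample: [M] from the closed form, [D] by mass balance."""
    m = monomer_concentration(c_total, kd)
    return SpeciesConcentrations(M=m, D=(c_total - m) / 2.0, c_total=c_total)


def _gaussian(volume: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(
        -0.5 * ((volume - center) / sigma) ** 2)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    # mean-one lognormal so noise does not bias areas
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_dilution_series(config: SimulationConfig) -> list[Chromatogram]:
    """One chromatogram per total concentration in ``config.c_totals``.

    Noise-free peak areas are ``response_factor * c_total`` times the
    species mass fractions [M]/C and 2[D]/C; each area is then perturbed
    by an independent mean-one lognormal factor of CV ``noise_cv``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round((config.vol_stop - config.vol_start) / config.vol_step)) + 1
    volume = config.vol_start + config.vol_step * np.arange(n)
    out = []
    for i, c in enumerate(config.c_totals):
        sp = simulate_equilibrium_species(c, config.true_kd)
        f_mono = sp.M / c
        f_dim = 2.0 * sp.D / c
        area_m = config.response_factor * c * f_mono * _lognormal_factor(rng, config.noise_cv)
        area_d = config.response_factor * c * f_dim * _lognormal_factor(rng, config.noise_cv)
        signal = (_gaussian(volume, config.monomer_center, config.monomer_width, area_m)
                  + _gaussian(volume, config.dimer_center, config.dimer_width, area_d)
                  + config.baseline_intercept + config.baseline_slope * volume)
        meta = {
            "sample": f"sim-{i:02d}",
            "c_total_uM": float(c),
            "buffer": config.buffer_label,
            "temperature_C": 5.0,
            "seed": config.seed,
            "true_area_monomer": float(config.response_factor * c * f_mono),
            "true_area_dimer": float(config.response_factor * c * f_dim),
        }
        out.append(Chromatogram(volume=volume.copy(), signal=signal, meta=meta))
    return out


def simulate_timecourse(config: KineticsSimConfig) -> KineticsDataset:
    """Product time courses with rates v0 = kcat*E0*[S]/(Km+[S]).

    Product is in nmol for the configured assay volume; negative noisy
    readings clamp to zero (a plate reader cannot report negative
    product).
    """
    rng = np.random.default_rng(config.seed)
    s = np.asarray(config.substrate_concs)
    t = np.asarray(config.times)
    enzyme_nmol = config.e0 * config.volume_ul / 1000.0
    v0 = config.kcat * enzyme_nmol * s / (config.km + s)        # nmol/min
    expected = np.outer(v0, t)                                   # nmol
    sd = config.noise_sd + config.noise_cv * expected
    product = expected + rng.normal(0.0, 1.0, size=expected.shape) * sd
    return KineticsDataset(substrate_concs=s, times=t,
                           product=np.clip(product, 0.0, None),
                           e0_um=config.e0, volume_ul=config.volume_ul)
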