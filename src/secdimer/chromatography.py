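"""Chromatogram I/O, baseline correction and peak quantification.

A size-exclusion chromatogram is a detector trace (AU) over elution
volume (mL).  For a monomer-dimer system separated on a gel-filtration
column the dimer elutes first (smaller retention volume).  Peaks are
integrated by the trapezoidal rule over fixed, user-supplied windows;
with two known species this mirrors the visual peak assignment used in
bench practice and avoids fragile automatic segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Chromatogram",
    "Peak",
    "ChromatogramParseError",
    "NonMonotonicVolumeError",
    "TraceLengthError",
    "read_chromatogram",
    "write_chromatogram",
    "subtract_baseline",
    "quantify_species_peaks",
    "DEFAULT_DIMER_WINDOW",
    "DEFAULT_MONOMER_WINDOW",
]

# integration windows (mL) bracketing the ~25 mL dimer and ~35 mL monomer peaks
DEFAULT_DIMER_WINDOW = (22.0, 29.0)
DEFAULT_MONOMER_WINDOW = (31.0, 39.0)


class ChromatogramParseError(ValueError):
    """File could not be parsed into two numeric columns."""


class NonMonotonicVolumeError(ValueError):
    """Elution-volume axis is not strictly increasing."""


class TraceLengthError(ValueError):
    """Volume and signal arrays differ in length."""


@dataclass
class Chromatogram:
    """Elution trace with sample metadata.

    ``meta`` carries sample-level facts the trace itself cannot:
    at minimum ``c_total_uM`` (total loaded protein, monomer-equivalent)
    when the trace feeds a K_D fit, plus free-form labels (buffer,
    temperature, sample name).
    """

    volume: np.ndarray          # mL, strictly increasing
    signal: np.ndarray          # AU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volume.shape != self.signal.shape:
            raise TraceLengthError(
                f"volume ({self.volume.size}) and signal ({self.signal.size}) "
                "arrays differ in length"
            )
        if self.volume.size < 2:
            raise ValueError("a chromatogram needs at least 2 points")
        if not np.all(np.diff(self.volume) > 0):
            raise NonMonotonicVolumeError("volume axis must be strictly increasing")
        c = self.meta.get("c_total_uM")
        if c is not None and c <= 0:
            raise ValueError("meta['c_total_uM'] must be positive when present")

    @property
    def c_total(self) -> float | None:
        return self.meta.get("c_total_uM")


@dataclass(frozen=True)
class Peak:
    """Integrated peak over a fixed window."""

    lo: float       # mL
    hi: float       # mL
    apex: float     # mL, volume of the window maximum
    area: float     # AU*mL

    def __post_init__(self) -> None:
        if not self.lo <= self.apex <= self.hi:
            raise ValueError("apex must lie inside the integration window")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_chromatogram(path, dialect: str = "csv") -> Chromatogram:
    """Read a two-column (volume_mL, signal_AU) table.

    A YAML sidecar ``<path>.yaml``, if present, supplies ``meta``.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        if df.shape[1] < 2:
            raise ChromatogramParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
        vol = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
        sig = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    except (pd.errors.ParserError, ValueError, TypeError) as exc:
        if isinstance(exc, (NonMonotonicVolumeError, ChromatogramParseError)):
            raise
        raise ChromatogramParseError(f"{path}: {exc}") from exc
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    return Chromatogram(volume=vol, signal=sig, meta=meta)


def write_chromatogram(chrom: Chromatogram, path) -> Path:
    """Write the trace as CSV plus a YAML metadata sidecar; returns the CSV path."""
    path = Path(path)
    pd.DataFrame({"volume_mL": chrom.volume, "signal_AU": chrom.signal}).to_csv(
        path, index=False)
    if chrom.meta:
        _sidecar(path).write_text(yaml.safe_dump(chrom.meta, sort_keys=True))
    return path


def subtract_baseline(chrom: Chromatogram, method: str = "linear-endpoints",
                      k: int = 5) -> Chromatogram:
    """Subtract a linear baseline anchored at the trace endpoints.

    The line passes through the means of the first and last ``k`` points,
    which the SEC windows are chosen to keep peak-free.  The operation is
    idempotent: applying it twice equals applying it once.
    """
    if method != "linear-endpoints":
        raise ValueError(f"unknown baseline method {method!r}")
    v, s = chrom.volume, chrom.signal
    k = min(k, v.size // 2)
    if k < 1:
        raise ValueError("need at least 2 points for baseline estimation")
    x0, y0 = v[:k].mean(), s[:k].mean()
    x1, y1 = v[-k:].mean(), s[-k:].mean()
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0 + slope * (v - x0)
    return Chromatogram(volume=v.copy(), signal=s - baseline, meta=dict(chrom.meta))


def _integrate_window(chrom: Chromatogram, window: tuple[float, float]) -> Peak:
    lo, hi = window
    mask = (chrom.volume >= lo) & (chrom.volume <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window {window} covers fewer than 2 grid points")
    v, s = chrom.volume[mask], chrom.signal[mask]
    area = float(np.trapezoid(s, v))
    apex = float(v[np.argmax(s)])
    return Peak(lo=lo, hi=hi, apex=apex, area=max(area, 0.0))


def quantify_species_peaks(
    chrom: Chromatogram,
    monomer_window: tuple[float, float] = DEFAULT_MONOMER_WINDOW,
    dimer_window: tuple[float, float] = DEFAULT_DIMER_WINDOW,
) -> tuple[Peak, Peak]:
    """Integrate the dimer and monomer peaks; returns ``(dimer, monomer)``.

    Windows must be disjoint and lie within the recorded volume range.
    Areas are trapezoidal; tiny negative integrals (pure-noise windows)
    clamp to zero.
    """
    for name, (lo, hi) in (("monomer", monomer_window), ("dimer", dimer_window)):
        if lo >= hi:
            raise ValueError(f"{name} window is empty: {lo} >= {hi}")
        if lo < chrom.volume[0] or hi > chrom.volume[-1]:
            raise ValueError(f"{name} window {(lo, hi)} outside recorded volume range "
                             f"[{chrom.volume[0]}, {chrom.volume[-1]}]")
    if not (monomer_window[1] <= dimer_window[0] or dimer_window[1] <= monomer_window[0]):
        raise ValueError("monomer and dimer windows overlap")
    return _integrate_window(chrom, dimer_window), _integrate_window(chrom, monomer_window)
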