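"""Small-angle X-ray scattering of multilamellar lipid phases.

Works in the s = 2 sin(theta)/lambda convention (units 1/Angstrom), where a
lamellar repeat distance d produces equally spaced reflections at
s_n = n/d, i.e. relative positions 1 : 2 : 3.  Note d = 1/s_1 here — NOT
q = 2*pi/d; mixing the two conventions is a classic factor-2pi error.

Detector calibration uses a reference material of known d-spacing (silver
stearate, 48.8 A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

#: d-spacing of the silver stearate calibration standard, Angstrom.
SILVER_STEARATE_D = 48.8


@dataclass
class ScatteringCurve:
    """1-D intensity vs s (A^-1) with optional calibration provenance."""

    s: np.ndarray
    intensity: np.ndarray
    calibration: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must match in length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"s_invA": self.s, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ScatteringCurve":
        df = pd.read_csv(path)
        return cls(df["s_invA"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class LamellarIndexing:
    """Result of 1:2:3 indexing: assigned orders and the repeat distance d."""

    peak_positions: np.ndarray
    orders: np.ndarray
    d_spacing: float
    ratio_residual: float
    is_lamellar: bool

    def __post_init__(self) -> None:
        self.peak_positions = np.asarray(self.peak_positions, dtype=float)
        self.orders = np.asarray(self.orders, dtype=int)
        if self.d_spacing <= 0:
            raise ValueError("d_spacing must be positive")


def calibrate_axis(raw_channels, ref_peak_channel: float, d_ref: float = SILVER_STEARATE_D):
    """Linear channel -> s mapping anchored at s(0)=0, s(ref)=1/d_ref.

    ``raw_channels`` are detector channel indices; the reference peak
    channel is where the first-order reflection of the calibration
    standard falls.
    """
    if d_ref <= 0:
        raise ValueError("reference d-spacing must be positive")
    if ref_peak_channel <= 0:
        raise ValueError("reference peak channel must be positive")
    raw = np.asarray(raw_channels, dtype=float)
    return raw * (1.0 / d_ref) / ref_peak_channel


def find_reflections(curve: ScatteringCurve, min_prominence: float = 0.1,
                     smooth_bins: float = 3.0) -> np.ndarray:
    """Detect reflection positions (A^-1) in a scattering curve.

    Lightly smooths the intensity (Gaussian, ``smooth_bins`` bins), finds
    local maxima with prominence above ``min_prominence`` times the
    intensity span, then refines each position by a 3-point parabola for
    sub-bin accuracy.  Returns positions sorted ascending; empty with a
    warning when nothing qualifies.
    """
    y = gaussian_filter1d(curve.intensity, smooth_bins) if smooth_bins > 0 else curve.intensity
    span = float(y.max() - y.min())
    if span <= 0:
        warnings.warn("flat curve: no reflections found", stacklevel=2)
        return np.array([])
    idx, _ = find_peaks(y, prominence=min_prominence * span)
    if len(idx) == 0:
        warnings.warn("no reflections above the prominence threshold", stacklevel=2)
        return np.array([])
    positions = []
    for i in idx:
        if 0 < i < len(y) - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            frac = float(np.clip(frac, -0.5, 0.5))
            ds = curve.s[i + 1] - curve.s[i] if frac >= 0 else curve.s[i] - curve.s[i - 1]
            positions.append(curve.s[i] + frac * abs(ds))
        else:
            positions.append(curve.s[i])
    return np.sort(np.array(positions))


def index_lamellar(peaks, max_residual: float = 0.02) -> LamellarIndexing:
    """Index peaks as consecutive lamellar orders n = 1, 2, ... and get d.

    d is the mean of n/s_n over orders; ratio_residual is the worst
    relative deviation of s_n from n*s_1.  A residual above
    ``max_residual`` flags the pattern as non-lamellar (the d estimate is
    still returned, from the assumed order assignment).
    """
    peaks = np.sort(np.asarray(peaks, dtype=float))
    if len(peaks) == 0:
        raise ValueError("need at least one peak to index")
    if np.any(peaks <= 0):
        raise ValueError("peak positions must be positive")
    orders = np.arange(1, len(peaks) + 1)
    d = float(np.mean(orders / peaks))
    residual = float(np.max(np.abs(peaks / (orders * peaks[0]) - 1.0)))
    return LamellarIndexing(
        peak_positions=peaks,
        orders=orders,
        d_spacing=d,
        ratio_residual=residual,
        is_lamellar=residual <= max_residual,
    )
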