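"""Membrane partition of a hydrophobic solute: absorbance quantitation and
the saturating (hyperbolic) partition isotherm.

The incorporated solute-to-lipid molar ratio R_mem follows

    R_mem(x) = R_sat * x / (R_50 + x)

where x is the total solute-to-lipid molar ratio, R_sat the saturation
membrane molar ratio and R_50 the total ratio giving half-saturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


@dataclass
class AbsorbanceReading:
    """A single A450 reading of solubilised solute.

    epsilon450 is the molar extinction coefficient in mM^-1 cm^-1
    (default 2.86, cryptotanshinone at 450 nm in ethanol/buffer).
    """

    a450: float
    path_length: float = 1.0
    dilution_factor: float = 1.0
    epsilon450: float = 2.86

    def __post_init__(self) -> None:
        if self.a450 < 0:
            raise ValueError("absorbance must be >= 0")
        if self.path_length <= 0:
            raise ValueError("path length must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass
class PartitionDataset:
    """Measured (x, r_mem) points, optionally with replicate SDs."""

    x: np.ndarray
    r_mem: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.r_mem = np.asarray(self.r_mem, dtype=float)
        if self.x.shape != self.r_mem.shape:
            raise ValueError("x and r_mem must have matching lengths")
        if np.any(self.x < 0) or np.any(self.r_mem < 0):
            raise ValueError("ratios must be >= 0")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if self.replicate_sd.shape != self.x.shape:
                raise ValueError("replicate_sd length mismatch")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"x": self.x, "r_mem": self.r_mem})
        if self.replicate_sd is not None:
            df["sd"] = self.replicate_sd
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PartitionDataset":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["x"].to_numpy(), df["r_mem"].to_numpy(), sd)


@dataclass
class PartitionIsotherm:
    """Fitted saturating isotherm (R_sat, R_50) with standard errors."""

    r_sat: float
    r_50: float
    r_sat_se: float = float("nan")
    r_50_se: float = float("nan")
    residual_ss: float = float("nan")

    def __post_init__(self) -> None:
        if self.r_sat <= 0 or self.r_50 <= 0:
            raise ValueError("r_sat and r_50 must be positive")

    def to_dict(self) -> dict:
        return {
            "r_sat": self.r_sat,
            "r_50": self.r_50,
            "r_sat_se": self.r_sat_se,
            "r_50_se": self.r_50_se,
            "residual_ss": self.residual_ss,
        }

    def report(self) -> str:
        return (
            f"R_sat = {self.r_sat:.4f} +/- {self.r_sat_se:.4f}\n"
            f"R_50  = {self.r_50:.4f} +/- {self.r_50_se:.4f}\n"
            f"residual SS = {self.residual_ss:.3e}"
        )


def concentration_from_absorbance(reading: AbsorbanceReading) -> float:
    """Solute concentration in mM via Beer-Lambert with dilution correction.

    c = A450 / (epsilon * l) * dilution_factor
    """
    return reading.a450 / (reading.epsilon450 * reading.path_length) * reading.dilution_factor


def predict_isotherm(iso: PartitionIsotherm, x) -> np.ndarray | float:
    """Evaluate r_sat*x/(r_50+x); monotone in x and bounded by r_sat."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    out = iso.r_sat * x / (iso.r_50 + x)
    return float(out) if out.ndim == 0 else out


def _double_reciprocal_init(x: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Initial (r_sat, r_50) from the linearised 1/r = (r50/rsat)(1/x) + 1/rsat."""
    m = (x > 0) & (r > 0)
    if m.sum() < 2:
        return max(float(r.max()), 1e-6), max(float(np.median(x[x > 0])), 1e-6)
    slope, intercept = np.polyfit(1.0 / x[m], 1.0 / r[m], 1)
    if intercept <= 0 or slope <= 0:
        return max(float(r.max()), 1e-6), max(float(np.median(x[x > 0])), 1e-6)
    return 1.0 / intercept, slope / intercept


def fit_isotherm(data: PartitionDataset, weighted: bool = False) -> PartitionIsotherm:
    """Least-squares fit of (R_sat, R_50) to a partition dataset.

    Uses nonlinear least squares with the analytic Jacobian, started from a
    double-reciprocal linear fit.  With ``weighted=True`` and replicate SDs
    present, residuals are weighted by 1/sd.  Standard errors come from the
    Jacobian at the optimum.
    """
    x, r = data.x, data.r_mem
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values to fit the isotherm")
    if weighted and data.replicate_sd is not None:
        w = 1.0 / np.clip(data.replicate_sd, 1e-12, None)
    else:
        w = np.ones_like(x)

    def resid(p):
        rs, r50 = p
        return w * (rs * x / (r50 + x) - r)

    def jac(p):
        rs, r50 = p
        J = np.empty((len(x), 2))
        J[:, 0] = w * x / (r50 + x)
        J[:, 1] = -w * rs * x / (r50 + x) ** 2
        return J

    p0 = _double_reciprocal_init(x, r)
    sol = least_squares(resid, p0, jac=jac, bounds=([1e-12, 1e-12], [np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(
            f"isotherm fit did not converge: {sol.message}; last params {sol.x}"
        )
    res = sol.fun
    dof = max(len(x) - 2, 1)
    s2 = float(res @ res) / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return PartitionIsotherm(
        r_sat=float(sol.x[0]),
        r_50=float(sol.x[1]),
        r_sat_se=float(se[0]),
        r_50_se=float(se[1]),
        residual_ss=float(res @ res),
    )
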