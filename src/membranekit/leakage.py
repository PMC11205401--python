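"""Carboxyfluorescein (CF) dye-leakage quantification.

Self-quenched CF entrapped in vesicles dequenches on release, so vesicle
permeabilisation shows up as a fluorescence increase.  Leakage is expressed
relative to the initial fluorescence F_i and the post-detergent maximum F_d
(complete lysis = 100%):

    %leakage(t) = 100 * (F_t - F_i) / (F_d - F_i)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LeakageTrace:
    """A fluorescence time course with its F_i / F_d calibration."""

    t: np.ndarray
    f_t: np.ndarray
    f_i: float
    f_d: float
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_t = np.asarray(self.f_t, dtype=float)
        if self.t.shape != self.f_t.shape:
            raise ValueError("t and f_t must have matching lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.f_d <= self.f_i:
            raise ValueError("invalid calibration: f_d must exceed f_i")

    def percent(self) -> np.ndarray:
        return percent_leakage(self.f_t, self.f_i, self.f_d)

    def out_of_range(self) -> np.ndarray:
        """Flag samples outside [f_i, f_d] (noise / photobleaching)."""
        return (self.f_t < self.f_i) | (self.f_t > self.f_d)

    def to_csv(self, path) -> None:
        # calibration rides along as commented header lines
        with open(path, "w") as fh:
            fh.write(f"# f_i={self.f_i}\n# f_d={self.f_d}\n# label={self.label}\n")
            pd.DataFrame({"time": self.t, "fluorescence": self.f_t}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LeakageTrace":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, ln in enumerate(lines):
            if ln.startswith("#"):
                k, _, v = ln[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        return cls(
            t=df["time"].to_numpy(),
            f_t=df["fluorescence"].to_numpy(),
            f_i=float(meta["f_i"]),
            f_d=float(meta["f_d"]),
            label=meta.get("label", ""),
        )


def percent_leakage(f_t, f_i: float, f_d: float):
    """Percent CF leakage, 100*(F_t - F_i)/(F_d - F_i).

    Affine-invariant: rescaling all fluorescences by a > 0 and shifting by b
    leaves the result unchanged.  Values outside [0, 100] (when F_t falls
    outside the calibration span) are returned as-is, not clipped.
    """
    if f_d <= f_i:
        raise ValueError("invalid calibration: f_d must exceed f_i")
    f_t = np.asarray(f_t, dtype=float)
    out = 100.0 * (f_t - f_i) / (f_d - f_i)
    return float(out) if out.ndim == 0 else out


@dataclass
class LeakageSummary:
    """Extent at a report time, initial rate, and plateau estimate."""

    extent_percent: float
    t_report: float
    initial_rate_percent_per_s: float
    plateau_percent: float
    n_flagged: int
    label: str = ""


def summarize_trace(trace: LeakageTrace, t_report: float) -> LeakageSummary:
    """Summarise a leakage time course.

    extent: %leakage at the sample nearest ``t_report``;
    initial rate: linear-fit slope of % vs t over the first decile of
    samples (at least 5 points);
    plateau: mean % over the final decile.
    """
    n = len(trace.t)
    if n < 10:
        raise ValueError("need at least 10 samples to summarise a trace")
    if not (trace.t[0] <= t_report <= trace.t[-1]):
        raise ValueError("t_report outside the trace time range")
    pct = trace.percent()
    i_rep = int(np.argmin(np.abs(trace.t - t_report)))
    k = max(n // 10, 5)
    slope = np.polyfit(trace.t[:k], pct[:k], 1)[0]
    plateau = float(np.mean(pct[-max(n // 10, 1):]))
    return LeakageSummary(
        extent_percent=float(pct[i_rep]),
        t_report=float(trace.t[i_rep]),
        initial_rate_percent_per_s=float(slope),
        plateau_percent=plateau,
        n_flagged=int(trace.out_of_range().sum()),
        label=trace.label,
    )
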