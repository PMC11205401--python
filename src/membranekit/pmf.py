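"""Potential of mean force across a bilayer from umbrella sampling.

Harmonic umbrella windows restrain a tagged molecule at a ladder of
positions z_i along the bilayer normal; the weighted histogram analysis
method (WHAM) combines the biased window histograms into the unbiased
free-energy profile G(z) = -k_B T ln p(z).  The profile is zero-referenced
in the aqueous phase and, for a symmetric bilayer, may be symmetrized
about the bilayer center before the permeation barrier is read off as
max G - 0.

Internally energies are kJ/mol; profiles are stored and reported in
kcal/mol.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KCAL_PER_KJ, KJ_PER_KCAL, kT_kj


@dataclass
class UmbrellaWindows:
    """Biased reaction-coordinate samples from harmonic umbrella windows.

    centers are window positions z_i (nm); k_spring the restraint force
    constant (kJ mol^-1 nm^-2, default 1000); samples one array of z values
    per window.
    """

    centers: np.ndarray
    samples: list
    k_spring: float = 1000.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        if len(self.centers) != len(self.samples):
            raise ValueError("one sample array required per window center")
        if any(len(s) == 0 for s in self.samples):
            raise ValueError("every window must contain samples")
        if self.k_spring < 0:
            raise ValueError("k_spring must be >= 0")
        self._check_overlap()

    def _check_overlap(self) -> None:
        """Warn when adjacent windows share < 1% histogram mass."""
        order = np.argsort(self.centers)
        lo = min(s.min() for s in self.samples)
        hi = max(s.max() for s in self.samples)
        edges = np.linspace(lo, hi, 201)
        hists = []
        for i in order:
            h, _ = np.histogram(self.samples[i], bins=edges, density=False)
            tot = h.sum()
            hists.append(h / tot if tot else h)
        for a, b in zip(hists[:-1], hists[1:]):
            if np.minimum(a, b).sum() < 0.01:
                warnings.warn(
                    "adjacent umbrella windows share < 1% histogram mass; "
                    "WHAM stitching may be unreliable",
                    stacklevel=3,
                )
                break

    def write_dir(self, directory) -> None:
        """One tabular file per window (columns: time, z), pull-output style."""
        os.makedirs(directory, exist_ok=True)
        for i, (c, s) in enumerate(zip(self.centers, self.samples)):
            df = pd.DataFrame({"time": np.arange(len(s), dtype=float), "z": s})
            df.to_csv(
                os.path.join(directory, f"window_{i:03d}_z{c:+.3f}.tsv"),
                sep="\t",
                index=False,
            )

    @classmethod
    def read_dir(cls, directory, k_spring: float = 1000.0, temperature: float = 298.0):
        files = sorted(f for f in os.listdir(directory) if f.startswith("window_"))
        centers, samples = [], []
        for f in files:
            centers.append(float(f.rsplit("_z", 1)[1].removesuffix(".tsv")))
            samples.append(
                pd.read_csv(os.path.join(directory, f), sep="\t")["z"].to_numpy()
            )
        return cls(np.array(centers), samples, k_spring=k_spring, temperature=temperature)


@dataclass
class FreeEnergyProfile:
    """G(z) on a uniform grid, in kcal/mol.

    ``reference`` names the region where G was pinned to zero (e.g.
    ``"aqueous (upper 15%)"``); ``None`` means not yet referenced.
    """

    z: np.ndarray
    g: np.ndarray
    reference: str | None = None
    uncertainty: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.z.shape != self.g.shape:
            raise ValueError("z and g must match in length")
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-12):
            raise ValueError("z grid must be uniform")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0

    def interp(self, z) -> np.ndarray:
        valid = np.isfinite(self.g)
        return np.interp(z, self.z[valid], self.g[valid])

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"z_nm": self.z, "g_kcal_mol": self.g})
        if self.uncertainty is not None:
            df["sd_kcal_mol"] = self.uncertainty
        df.to_csv(path, index=False)


@dataclass
class BarrierResult:
    """Permeation barrier: max G minus the aqueous reference (kcal/mol)."""

    height: float
    z_at_max: float


class WhamConvergenceError(RuntimeError):
    def __init__(self, message: str, f_trace: np.ndarray):
        super().__init__(message)
        self.f_trace = f_trace


def _reference_shift(z: np.ndarray, g: np.ndarray, water_side: str, fraction: float):
    """Mean G over the outermost ``fraction`` of the grid on the water side."""
    span = z[-1] - z[0]
    if water_side == "upper":
        region = z >= z[-1] - fraction * span
    elif water_side == "lower":
        region = z <= z[0] + fraction * span
    elif water_side == "both":
        region = (z >= z[-1] - fraction * span / 2) | (z <= z[0] + fraction * span / 2)
    else:
        raise ValueError("water_side must be 'upper', 'lower' or 'both'")
    vals = g[region & np.isfinite(g)]
    if len(vals) == 0:
        raise ValueError("reference region contains no finite profile values")
    return float(np.mean(vals))


def wham(
    windows: UmbrellaWindows,
    bin_width: float = 0.05,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    water_side: str = "upper",
    reference_fraction: float = 0.15,
    f_init=None,
) -> FreeEnergyProfile:
    """Self-consistent WHAM estimate of G(z) from umbrella windows.

    Iterates the window free-energy constants f_i and unbiased bin
    probabilities p(z) until the largest relative change in the f_i (in
    k_B T units) drops below ``tol``.  The profile is zero-referenced on
    the aqueous plateau: the outermost ``reference_fraction`` of the grid
    on ``water_side``.

    Raises :class:`WhamConvergenceError` carrying the f_i trace if
    ``max_iter`` is reached.  Empty bins inside the sampled range are
    masked (NaN) with a warning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    kT = kT_kj(windows.temperature)
    lo = min(s.min() for s in windows.samples)
    hi = max(s.max() for s in windows.samples)
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    zc = 0.5 * (edges[:-1] + edges[1:])

    n_b = np.zeros(n_bins)
    for s in windows.samples:
        h, _ = np.histogram(s, bins=edges)
        n_b += h
    N_i = np.array([len(s) for s in windows.samples], dtype=float)

    # bias energies in kT units: U_ib = k/2 (z_b - z_i)^2
    u = 0.5 * windows.k_spring * (zc[None, :] - windows.centers[:, None]) ** 2 / kT
    log_c = -u  # (n_windows, n_bins)

    # iterate on g_i = f_i/kT, gauge-fixed to g_0 = 0; the result is
    # invariant to any constant added to the initial window free energies
    g_i = np.zeros(len(N_i)) if f_init is None else np.asarray(f_init, float) / kT
    f_trace = [g_i.copy()]
    occupied = n_b > 0
    log_nb = np.where(occupied, np.log(np.where(occupied, n_b, 1.0)), -np.inf)
    log_Ni = np.log(N_i)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator_b = logsumexp_i [ log N_i + g_i + log_c_ib ]
        a = log_Ni[:, None] + g_i[:, None] + log_c
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        log_p = log_nb - log_den  # unnormalised
        # g_i_new = -logsumexp_b [ log_p_b + log_c_ib ]
        b = log_p[None, :] + log_c
        bmax = np.max(np.where(np.isfinite(b), b, -np.inf), axis=1)
        g_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        g_new = g_new - g_new[0]
        delta = np.max(np.abs(g_new - g_i) / np.maximum(np.abs(g_new), 1.0))
        g_i = g_new
        if it % 100 == 0 or delta < tol:
            f_trace.append(g_i.copy())
        if delta < tol:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (delta={delta:.2e})",
            np.array(f_trace),
        )

    a = log_Ni[:, None] + g_i[:, None] + log_c
    amax = a.max(axis=0)
    log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
    with np.errstate(divide="ignore"):
        log_p = np.where(occupied, log_nb - log_den, -np.inf)
    g_kj = np.where(occupied, -kT * log_p, np.nan)

    # empty bins strictly inside the sampled range are holes worth flagging
    inside = (zc > lo) & (zc < hi)
    if np.any(~occupied & inside):
        warnings.warn(
            f"{int(np.sum(~occupied & inside))} empty bins inside the sampled "
            "range were masked",
            stacklevel=2,
        )

    g_kcal = g_kj * KCAL_PER_KJ
    shift = _reference_shift(zc, g_kcal, water_side, reference_fraction)
    g_kcal = g_kcal - shift
    return FreeEnergyProfile(
        z=zc,
        g=g_kcal,
        reference=f"aqueous ({water_side} {reference_fraction:.0%})",
        converged=True,
        n_iter=it,
    )


def symmetrize_profile(profile: FreeEnergyProfile, center: float = 0.0) -> FreeEnergyProfile:
    """Average G(z) with its mirror image about ``center``.

    G_sym(z) = (G(z) + G(2*center - z)) / 2 wherever both branches are
    defined; where only one branch is defined (half profiles) the available
    branch is used, which turns a half profile into a full mirrored one.
    """
    z, g = profile.z, profile.g
    dz = profile.dz or 1e-3
    zmin = min(z[0], 2 * center - z[-1])
    zmax = max(z[-1], 2 * center - z[0])
    n = int(round((zmax - zmin) / dz)) + 1
    # grid symmetric about center so mirror pairs land on grid points
    half = max(center - zmin, zmax - center)
    n_half = int(np.ceil(half / dz))
    zg = center + dz * np.arange(-n_half, n_half + 1)

    valid = np.isfinite(g)
    zv, gv = z[valid], g[valid]

    def branch(q):
        # clamp queries a rounding error outside the data range onto it
        eps = 1e-9 * max(1.0, abs(zv[0]), abs(zv[-1]))
        qc = np.clip(q, zv[0], zv[-1])
        out = np.interp(qc, zv, gv)
        out[(q < zv[0] - eps) | (q > zv[-1] + eps)] = np.nan
        return out

    g1 = branch(zg)
    g2 = branch(2 * center - zg)
    both = np.isfinite(g1) & np.isfinite(g2)
    either = np.isfinite(g1) | np.isfinite(g2)
    gs = np.full_like(zg, np.nan)
    gs[both] = 0.5 * (g1[both] + g2[both])
    only1 = np.isfinite(g1) & ~np.isfinite(g2)
    only2 = np.isfinite(g2) & ~np.isfinite(g1)
    gs[only1] = g1[only1]
    gs[only2] = g2[only2]
    keep = either
    # trim leading/trailing NaN but keep interior grid uniform
    idx = np.where(keep)[0]
    sl = slice(idx[0], idx[-1] + 1)
    unc = None
    if profile.uncertainty is not None:
        u = np.interp(zg, zv, profile.uncertainty[valid], left=np.nan, right=np.nan)
        u2 = np.interp(2 * center - zg, zv, profile.uncertainty[valid], left=np.nan, right=np.nan)
        unc = np.where(
            np.isfinite(u) & np.isfinite(u2), 0.5 * np.sqrt(u**2 + u2**2),
            np.where(np.isfinite(u), u, u2),
        )[sl]
    return FreeEnergyProfile(
        z=zg[sl],
        g=gs[sl],
        reference=profile.reference,
        uncertainty=unc,
        converged=profile.converged,
        n_iter=profile.n_iter,
    )


def barrier_height(profile: FreeEnergyProfile) -> BarrierResult:
    """Permeation barrier max(G) - 0 relative to the aqueous reference."""
    if profile.reference is None:
        raise ValueError("profile has no aqueous reference region defined")
    valid = np.isfinite(profile.g)
    if not np.any(valid):
        raise ValueError("profile has no finite values")
    i = int(np.nanargmax(profile.g))
    return BarrierResult(height=float(profile.g[i]), z_at_max=float(profile.z[i]))


def profile_uncertainty(
    windows: UmbrellaWindows,
    n_resamples: int = 50,
    seed: int | None = None,
    **wham_kwargs,
) -> tuple[FreeEnergyProfile, float]:
    """Block-bootstrap uncertainty for the WHAM profile and barrier.

    Samples within each window are resampled in contiguous blocks
    (length ~ sqrt(n)) to respect autocorrelation, WHAM is re-run per
    resample, and per-bin standard deviations plus the barrier SD are
    returned alongside the point-estimate profile.
    """
    rng = np.random.default_rng(seed)
    base = wham(windows, **wham_kwargs)
    profiles = []
    barriers = []
    for _ in range(n_resamples):
        resampled = []
        for s in windows.samples:
            n = len(s)
            blk = max(int(np.sqrt(n)), 1)
            n_blocks = int(np.ceil(n / blk))
            starts = rng.integers(0, max(n - blk, 1), size=n_blocks)
            idx = (starts[:, None] + np.arange(blk)[None, :]).ravel()[:n]
            resampled.append(s[idx % n])
        w = UmbrellaWindows(
            windows.centers, resampled, k_spring=windows.k_spring,
            temperature=windows.temperature,
        )
        p = wham(w, **wham_kwargs)
        profiles.append(np.interp(base.z, p.z, np.nan_to_num(p.g, nan=0.0)))
        barriers.append(barrier_height(p).height)
    base.uncertainty = np.std(np.stack(profiles), axis=0)
    return base, float(np.std(barriers))
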