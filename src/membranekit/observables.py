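"""Membrane observables computed from labeled bilayer trajectories.

Implements the standard bilayer validation metrics: area per lipid,
lateral diffusion via the Einstein relation, deuterium order parameters
S_CD, phosphate-to-phosphate thickness, mass density profiles along the
bilayer normal, and solute cluster statistics under a single-linkage
distance cutoff.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .constants import CM2_PER_S_PER_NM2_PER_PS, KG_PER_AMU
from .trajectory import LabeledTrajectory


@dataclass
class TimeSeriesStat:
    """A per-frame scalar observable with its mean and SD."""

    time: np.ndarray
    series: np.ndarray
    mean: float
    sd: float
    units: str = ""


@dataclass
class MSDCurve:
    """Lateral MSD vs lag time and the Einstein-relation diffusion fit.

    D = slope / (2 d) with d = 2 lateral dimensions; ``d_coeff`` is in
    cm^2/s (slope fitted in nm^2/ps, converted by 1 nm^2/ps = 1e-2 cm^2/s).
    """

    lag: np.ndarray
    msd: np.ndarray
    d_dims: int
    d_coeff: float
    fit_window: tuple


@dataclass
class OrderProfile:
    """Per-carbon deuterium order parameter S_CD = <(3 cos^2 theta - 1)/2>.

    theta is the angle between a C-D (here C-H) bond and the bilayer
    normal (z).  -0.5 corresponds to a perfectly ordered all-trans chain;
    Table-style summaries conventionally quote |S_CD|.
    """

    carbon_index: np.ndarray
    s_cd: np.ndarray

    @property
    def s_cd_abs(self) -> np.ndarray:
        return np.abs(self.s_cd)

    @property
    def chain_mean_abs(self) -> float:
        return float(np.mean(np.abs(self.s_cd)))


@dataclass
class DensityProfile:
    """Mass density (kg/m^3) along z about the bilayer center, per group."""

    z_centers: np.ndarray
    density: dict
    bin_width: float
    symmetrized: bool


@dataclass
class ClusterReport:
    """Solute cluster statistics under a single-linkage distance cutoff."""

    cutoff: float
    sizes_per_frame: list
    size_histogram: dict
    percent_monomers: float


# ----------------------------------------------------------------------
# area per lipid
# ----------------------------------------------------------------------
def area_per_lipid(traj: LabeledTrajectory, n_per_leaflet: int) -> TimeSeriesStat:
    """Per-frame lateral box area divided by lipids per leaflet (nm^2)."""
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    series = traj.box[:, 0] * traj.box[:, 1] / n_per_leaflet
    return TimeSeriesStat(
        time=traj.time, series=series,
        mean=float(series.mean()), sd=float(series.std(ddof=0)), units="nm^2",
    )


# ----------------------------------------------------------------------
# lateral diffusion
# ----------------------------------------------------------------------
def _unwrap_xy(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Rebuild continuous lateral positions from wrapped ones.

    Minimum-image step displacements are accumulated; assumes no particle
    moves more than half a box per frame (asserted).
    """
    steps = np.diff(pos, axis=0)
    b = box[1:, None, :2]
    steps -= b * np.round(steps / b)
    assert np.all(np.abs(steps) < 0.5 * b), "particle moved > box/2 in one frame"
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out


def _msd_time_origin_average(pos: np.ndarray) -> np.ndarray:
    """MSD(lag) averaged over all time origins and particles.

    pos: (F, N, k) continuous coordinates.  Returns (F,) with msd[0] = 0.
    """
    F = pos.shape[0]
    msd = np.zeros(F)
    for lag in range(1, F):
        d = pos[lag:] - pos[:-lag]
        msd[lag] = np.mean(np.sum(d * d, axis=-1))
    return msd


def lateral_diffusion(
    traj: LabeledTrajectory,
    role: str = "P",
    fit_window: tuple = (0.1, 0.5),
    remove_leaflet_com: bool = True,
    use_unwrapped: bool = False,
) -> MSDCurve:
    """Lateral diffusion coefficient from the Einstein relation.

    MSD(dt) is averaged over particles of the selected role and over all
    time origins; D = slope/(2*d), d = 2, fitted over lags between
    ``fit_window`` fractions of the trajectory length.  Per-leaflet lateral
    center-of-mass motion is removed before the MSD unless disabled.
    """
    if traj.n_frames < 100:
        raise ValueError("need >= 100 frames for a diffusion estimate")
    mask = traj.select(role=role)
    if not mask.any():
        raise ValueError(f"no particles with role {role!r}")
    if use_unwrapped:
        if traj.positions_unwrapped is None:
            raise ValueError("trajectory carries no unwrapped positions")
        xy = traj.positions_unwrapped[:, mask, :2].copy()
    else:
        xy = _unwrap_xy(traj.positions[:, mask, :2], traj.box)
    if remove_leaflet_com:
        leaf = traj.leaflet[mask]
        for lf in np.unique(leaf):
            sub = leaf == lf
            xy[:, sub, :] -= xy[:, sub, :].mean(axis=1, keepdims=True)

    msd = _msd_time_origin_average(xy)
    lag = traj.time - traj.time[0]
    max_lag = lag[-1]
    lo, hi = fit_window[0] * max_lag, fit_window[1] * max_lag
    sel = (lag >= lo) & (lag <= hi) & (lag > 0)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than 2 lags")
    slope = np.polyfit(lag[sel], msd[sel], 1)[0]  # nm^2 / ps
    d_dims = 2
    d_nm2_ps = slope / (2 * d_dims)
    return MSDCurve(
        lag=lag, msd=msd, d_dims=d_dims,
        d_coeff=float(d_nm2_ps * CM2_PER_S_PER_NM2_PER_PS),
        fit_window=(float(lo), float(hi)),
    )


# ----------------------------------------------------------------------
# order parameters
# ----------------------------------------------------------------------
_CD_RE = re.compile(r"^CD_([CH])_(\d+)$")


def order_parameters(traj: LabeledTrajectory) -> OrderProfile:
    """Deuterium order parameter per acyl carbon from CD_C_k / CD_H_k pairs."""
    carbons: dict[int, dict[str, np.ndarray]] = {}
    for kind in ("C", "H"):
        for i, r in enumerate(traj.role):
            m = _CD_RE.match(r)
            if m and m.group(1) == kind:
                k = int(m.group(2))
                carbons.setdefault(k, {}).setdefault(kind, []).append(i)
    if not carbons:
        raise ValueError("trajectory contains no CD bond particles")
    ks = sorted(carbons)
    s_cd = []
    for k in ks:
        entry = carbons[k]
        if "C" not in entry or "H" not in entry:
            raise ValueError(f"carbon {k}: missing CD partner atoms")
        ci = np.array(entry["C"])
        hi = np.array(entry["H"])
        mol_c = traj.molecule_id[ci]
        mol_h = traj.molecule_id[hi]
        order_c = np.argsort(mol_c, kind="stable")
        order_h = np.argsort(mol_h, kind="stable")
        if not np.array_equal(mol_c[order_c], mol_h[order_h]):
            missing = sorted(set(mol_c) ^ set(mol_h))
            raise ValueError(f"carbon {k}: unpaired CD atoms for molecules {missing}")
        ci, hi = ci[order_c], hi[order_h]
        v = traj.positions[:, hi, :] - traj.positions[:, ci, :]
        # bonds are short; re-image in case wrapping split a pair
        b = traj.box[:, None, :]
        v -= b * np.round(v / b)
        cos2 = (v[..., 2] / np.linalg.norm(v, axis=-1)) ** 2
        s_cd.append(float(np.mean(1.5 * cos2 - 0.5)))
    return OrderProfile(carbon_index=np.array(ks), s_cd=np.array(s_cd))


# ----------------------------------------------------------------------
# thickness
# ----------------------------------------------------------------------
def membrane_thickness(traj: LabeledTrajectory) -> TimeSeriesStat:
    """P-P bilayer thickness: |mean z(upper P) - mean z(lower P)| per frame."""
    up = traj.select(role="P", leaflet="upper")
    lo = traj.select(role="P", leaflet="lower")
    if not up.any() or not lo.any():
        raise ValueError("both leaflets must contain phosphate (P) particles")
    series = np.abs(
        traj.positions[:, up, 2].mean(axis=1) - traj.positions[:, lo, 2].mean(axis=1)
    )
    return TimeSeriesStat(
        time=traj.time, series=series,
        mean=float(series.mean()), sd=float(series.std(ddof=0)), units="nm",
    )


def _bilayer_center(traj: LabeledTrajectory) -> np.ndarray:
    """Per-frame bilayer center: midpoint of the leaflet P mean z positions."""
    up = traj.select(role="P", leaflet="upper")
    lo = traj.select(role="P", leaflet="lower")
    if not up.any() or not lo.any():
        raise ValueError("both leaflets must contain phosphate (P) particles")
    return 0.5 * (
        traj.positions[:, up, 2].mean(axis=1) + traj.positions[:, lo, 2].mean(axis=1)
    )


# ----------------------------------------------------------------------
# density profile
# ----------------------------------------------------------------------
def density_profile(
    traj: LabeledTrajectory,
    groups: dict,
    bin_width: float = 0.1,
    symmetrize: bool = False,
) -> DensityProfile:
    """Mass density profiles along z about the bilayer center.

    ``groups`` maps group names to role selectors (a selector string or a
    list of them; ``*`` suffix matches role prefixes).  Densities are mass
    histograms normalised by bin volume (kg/m^3), averaged over frames; the
    z origin is the per-frame bilayer center.  With ``symmetrize`` the
    profile is replaced by its average with its mirror image,
    rho(z) <- (rho(z) + rho(-z))/2.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    center = _bilayer_center(traj)
    masks = {}
    for name, sel in groups.items():
        sels = [sel] if isinstance(sel, str) else list(sel)
        m = np.zeros(traj.n_particles, dtype=bool)
        for s in sels:
            m |= traj.select(role=s)
        masks[name] = m

    any_mask = np.zeros(traj.n_particles, dtype=bool)
    for m in masks.values():
        any_mask |= m
    rel_all = traj.positions[:, any_mask, 2] - center[:, None]
    zmax = float(np.max(np.abs(rel_all))) + bin_width
    n_half = int(np.ceil(zmax / bin_width))
    edges = bin_width * np.arange(-n_half, n_half + 1)  # symmetric about 0
    zc = 0.5 * (edges[:-1] + edges[1:])

    area = traj.box[:, 0] * traj.box[:, 1]  # nm^2 per frame
    out = {}
    for name, m in masks.items():
        acc = np.zeros(len(zc))
        mass = traj.mass[m]
        for f in range(traj.n_frames):
            rel = traj.positions[f, m, 2] - center[f]
            h, _ = np.histogram(rel, bins=edges, weights=mass)
            acc += h / area[f]
        # amu / nm^3 -> kg / m^3  (1 amu/nm^3 = KG_PER_AMU / 1e-27 kg/m^3)
        rho = acc / (traj.n_frames * bin_width) * (KG_PER_AMU / 1e-27)
        if symmetrize:
            rho = 0.5 * (rho + rho[::-1])
        out[name] = rho
    return DensityProfile(z_centers=zc, density=out, bin_width=bin_width,
                          symmetrized=symmetrize)


# ----------------------------------------------------------------------
# solute clustering
# ----------------------------------------------------------------------
def _min_image_dists(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def cluster_stats(traj: LabeledTrajectory, cutoff: float = 0.30) -> ClusterReport:
    """Single-linkage solute clusters under a periodic-aware distance cutoff.

    Two solute molecules are linked when the minimum distance between any
    of their particles is below ``cutoff`` (nm); clusters are the connected
    components of that graph, evaluated per frame.  ``percent_monomers`` is
    the mean percentage of solute molecules sitting in size-1 components.
    """
    sol = traj.select(role="SOLUTE")
    if not sol.any():
        raise ValueError("trajectory contains no solute particles")
    mol_ids = np.unique(traj.molecule_id[sol])
    n_mol = len(mol_ids)
    part_idx = [np.where(sol & (traj.molecule_id == m))[0] for m in mol_ids]

    sizes_per_frame = []
    hist: dict[int, int] = {}
    monomer_frac = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        box = traj.box[f]
        adj = np.zeros((n_mol, n_mol), dtype=bool)
        for i in range(n_mol):
            for j in range(i + 1, n_mol):
                dmin = _min_image_dists(
                    traj.positions[f, part_idx[i]], traj.positions[f, part_idx[j]], box
                ).min()
                if dmin < cutoff:
                    adj[i, j] = adj[j, i] = True
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        sizes_per_frame.append(sizes)
        for s in sizes:
            hist[int(s)] = hist.get(int(s), 0) + 1
        monomer_frac[f] = np.sum(sizes == 1) / n_mol
    return ClusterReport(
        cutoff=cutoff,
        sizes_per_frame=sizes_per_frame,
        size_histogram=dict(sorted(hist.items())),
        percent_monomers=float(100.0 * monomer_frac.mean()),
    )
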