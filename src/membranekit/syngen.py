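"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure of one input class —
bilayer trajectories, partition datasets, leakage traces, umbrella-window
samples, lamellar scattering curves — with the generating parameters as
recoverable ground truth, so downstream analyses can be validated by
parameter recovery without external data.

None of this is molecular dynamics: the bilayer generator produces
role-labeled particles with the *target statistics* (Brownian lateral
motion, fixed-angle CD bonds, Gaussian leaflet planes, cluster assignments)
rather than physically interacting lipids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KJ_PER_KCAL, kT_kj
from .leakage import LeakageTrace
from .partition import PartitionDataset
from .pmf import FreeEnergyProfile, UmbrellaWindows
from .saxs import ScatteringCurve
from .trajectory import LabeledTrajectory

logger = logging.getLogger(__name__)

# nominal particle masses, amu
MASSES = {
    "P": 94.97,        # phosphate group
    "CARBONYL": 28.01,
    "CD_C": 13.02,     # CH of the acyl chain
    "CD_H": 1.008,
    "TERMINAL_CH3": 15.03,
    "SOLUTE": 296.36,  # cryptotanshinone
}

CD_BOND_LENGTH = 0.109  # nm
CARBONYL_DEPTH = 0.45   # nm below the phosphate plane
TERMINAL_Z = 0.15       # nm from the bilayer center


class PackingError(RuntimeError):
    """Raised when solute clusters cannot be placed at the required separations."""


@dataclass
class BilayerSpec:
    """Target statistics of a synthetic two-leaflet bilayer trajectory.

    Defaults emulate a 128-lipid POPC bilayer with 14 solute molecules at
    298 K: area per lipid 0.63 nm^2, P-P thickness 4.04 nm, lateral
    diffusion 5.45e-8 cm^2/s, |S_CD| 0.14 per carbon, 66.6% solute
    monomers.
    """

    n_lipids_per_leaflet: int = 64
    n_solutes: int = 14
    target_apl: float = 0.63            # nm^2
    target_thickness: float = 4.04      # nm
    target_D: float = 5.45e-8           # cm^2/s
    target_scd: tuple = tuple([0.14] * 14)   # per-carbon |S_CD|
    monomer_fraction: float = 66.6      # % of solutes expected as monomers
    n_frames: int = 600
    dt: float = 100.0                   # ps between frames
    temperature: float = 298.0          # K
    seed: int = 0
    z_noise_sd: float = 0.05            # nm

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet <= 0 or self.n_frames <= 0:
            raise ValueError("counts must be positive")
        if self.n_solutes < 0:
            raise ValueError("n_solutes must be >= 0")
        if self.target_apl <= 0 or self.target_thickness <= 0:
            raise ValueError("target_apl and target_thickness must be positive")
        if self.target_D < 0 or self.z_noise_sd < 0:
            raise ValueError("target_D and z_noise_sd must be >= 0")
        if not 0 <= self.monomer_fraction <= 100:
            raise ValueError("monomer_fraction must be within [0, 100]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(not 0 <= s <= 0.5 for s in self.target_scd):
            raise ValueError("per-carbon |S_CD| targets must be within [0, 0.5]")


@dataclass
class LeakageSimParams:
    """Mono-exponential leakage kinetics (synthetic-only model).

    %L(t) = plateau_percent * (1 - exp(-composition_modifier * rate_constant * t)).
    The composition modifier is a multiplicative factor on the rate emulating
    lipid-composition effects (> 1 for anionic-enhanced, < 1 for protected
    membranes).  f_i / f_d set the raw-fluorescence calibration used to emit
    the trace.
    """

    plateau_percent: float = 60.0
    rate_constant: float = 0.01        # 1/s
    lipid_conc: float = 20.0           # uM
    cpt_ratio: float = 0.1             # mol/mol
    composition_modifier: float = 1.0
    noise_sd: float = 0.0              # fluorescence units
    f_i: float = 50.0
    f_d: float = 550.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.plateau_percent <= 100:
            raise ValueError("plateau_percent must be within [0, 100]")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.f_d <= self.f_i:
            raise ValueError("f_d must exceed f_i")


# ----------------------------------------------------------------------
# bilayer trajectory
# ----------------------------------------------------------------------
def _theta_from_scd(s: float) -> float:
    """Polar angle whose fixed-angle order parameter is -s: cos^2 = (1-2s)/3."""
    return float(np.arccos(np.sqrt((1.0 - 2.0 * s) / 3.0)))


def _cluster_sizes(n: int, monomer_fraction: float, rng) -> list:
    """Cluster sizes for one frame with E[% monomers] = monomer_fraction.

    The monomer count is the integer randomisation of n*f; the remaining
    molecules are grouped into clusters of sizes 2 and 3.  A remainder of
    one molecule is resolved by moving the monomer count one step up or
    down with equal probability, preserving the expectation.
    """
    mu = n * monomer_fraction / 100.0
    m = int(np.floor(mu)) + int(rng.random() < (mu - np.floor(mu)))
    m = min(m, n)
    if n - m == 1:
        if m + 1 <= n and m - 1 >= 0:
            m += 1 if rng.random() < 0.5 else -1
        elif m + 1 <= n:
            m += 1
        else:
            m -= 1
    sizes = [1] * m
    r = n - m
    while r >= 5:
        s = 2 if rng.random() < 0.5 else 3
        sizes.append(s)
        r -= s
    if r == 4:
        sizes += [2, 2]
    elif r in (2, 3):
        sizes.append(r)
    return sizes


def _place_clusters(sizes, lx, ly, rng, min_seed_sep=0.9, max_attempts=400,
                    max_restarts=30):
    """Seed xy positions with pairwise min-image separation >= min_seed_sep.

    Cluster members sit within 0.10 nm of their seed, so a 0.9 nm seed
    separation keeps molecules of different clusters > 0.6 nm apart.
    Sequential rejection sampling is restarted from scratch on dead ends.
    """
    box = np.array([lx, ly])
    for _ in range(max_restarts):
        seeds = []
        for _ in sizes:
            for attempt in range(max_attempts):
                p = rng.random(2) * box
                ok = True
                for q in seeds:
                    d = p - q
                    d -= box * np.round(d / box)
                    if np.hypot(*d) < min_seed_sep:
                        ok = False
                        break
                if ok:
                    seeds.append(p)
                    break
            else:
                break  # dead end: restart the whole configuration
        if len(seeds) == len(sizes):
            return np.array(seeds)
    raise PackingError(
        f"cannot place {len(sizes)} solute clusters at >= {min_seed_sep} nm "
        f"separation in a {lx:.2f} x {ly:.2f} nm box"
    )


def gen_bilayer_trajectory(spec: BilayerSpec) -> LabeledTrajectory:
    """Synthetic labeled bilayer trajectory realising the spec's targets.

    Lateral lipid positions follow independent 2-D Brownian motion with
    per-step total variance 4*D*dt; leaflet phosphate planes sit at
    +/- thickness/2 with Gaussian z-noise; CD bonds point at the fixed
    polar angle solving (3 cos^2 theta - 1)/2 = -|S_CD| with uniform
    azimuth; solute molecules are re-assigned each frame to clusters of
    sizes 1-3 such that the expected monomer percentage equals the target
    (cluster members < 0.30 nm apart, monomers > 0.60 nm from everyone).
    The lateral box area is n_lipids_per_leaflet * target_apl.
    """
    rng = np.random.default_rng(spec.seed)
    n_leaf = spec.n_lipids_per_leaflet
    n_lip = 2 * n_leaf
    n_carbons = len(spec.target_scd)
    lx = ly = float(np.sqrt(n_leaf * spec.target_apl))
    lz = spec.target_thickness + 4.0
    half_t = spec.target_thickness / 2.0
    z_carb = half_t - CARBONYL_DEPTH

    # particle layout per lipid: P, CARBONYL, TERMINAL_CH3, (CD_C_k, CD_H_k)*
    roles, mols, leaflets, masses = [], [], [], []
    for i in range(n_lip):
        leaf = "upper" if i < n_leaf else "lower"
        for r in ("P", "CARBONYL", "TERMINAL_CH3"):
            roles.append(r)
            mols.append(i)
            leaflets.append(leaf)
            masses.append(MASSES[r])
        for k in range(n_carbons):
            for kind in ("C", "H"):
                roles.append(f"CD_{kind}_{k + 2}")
                mols.append(i)
                leaflets.append(leaf)
                masses.append(MASSES[f"CD_{kind}"])
    for j in range(spec.n_solutes):
        roles.append("SOLUTE")
        mols.append(n_lip + j)
        leaflets.append("none")
        masses.append(MASSES["SOLUTE"])

    n_part = len(roles)
    F = spec.n_frames
    pos_unwrapped = np.zeros((F, n_part, 3))

    # --- lipid lateral Brownian motion (shared by all particles of a lipid)
    d_nm2_ps = spec.target_D / 1e-2  # cm^2/s -> nm^2/ps
    step_sd = np.sqrt(2.0 * d_nm2_ps * spec.dt)  # per axis => 2D var 4 D dt
    xy0 = rng.random((n_lip, 2)) * [lx, ly]
    steps = (
        rng.normal(0.0, step_sd, size=(F - 1, n_lip, 2)) if step_sd > 0
        else np.zeros((F - 1, n_lip, 2))
    )
    lipid_xy = np.concatenate([xy0[None], xy0[None] + np.cumsum(steps, axis=0)])

    # --- z coordinates
    sign = np.where(np.arange(n_lip) < n_leaf, 1.0, -1.0)
    p_z = sign[None, :] * half_t + rng.normal(0, spec.z_noise_sd, size=(F, n_lip))
    carb_z = sign[None, :] * z_carb + rng.normal(0, spec.z_noise_sd, size=(F, n_lip))
    term_z = sign[None, :] * TERMINAL_Z + rng.normal(0, spec.z_noise_sd, size=(F, n_lip))

    per_lip = 3 + 2 * n_carbons
    lip_slice = np.arange(n_lip * per_lip).reshape(n_lip, per_lip)
    # xy of every lipid particle = the lipid's Brownian track
    for c in range(per_lip):
        pos_unwrapped[:, lip_slice[:, c], 0] = lipid_xy[:, :, 0]
        pos_unwrapped[:, lip_slice[:, c], 1] = lipid_xy[:, :, 1]
    pos_unwrapped[:, lip_slice[:, 0], 2] = p_z
    pos_unwrapped[:, lip_slice[:, 1], 2] = carb_z
    pos_unwrapped[:, lip_slice[:, 2], 2] = term_z

    # CD carbons along the chain between the carbonyl and terminal planes
    fracs = (np.arange(n_carbons) + 1) / (n_carbons + 1)
    for k in range(n_carbons):
        zk = sign[None, :] * (z_carb + fracs[k] * (TERMINAL_Z - z_carb))
        zk = zk + rng.normal(0, spec.z_noise_sd, size=(F, n_lip))
        c_idx = lip_slice[:, 3 + 2 * k]
        h_idx = lip_slice[:, 3 + 2 * k + 1]
        pos_unwrapped[:, c_idx, 2] = zk
        theta = _theta_from_scd(spec.target_scd[k])
        phi = rng.random((F, n_lip)) * 2 * np.pi
        bx = CD_BOND_LENGTH * np.sin(theta) * np.cos(phi)
        by = CD_BOND_LENGTH * np.sin(theta) * np.sin(phi)
        bz = CD_BOND_LENGTH * np.cos(theta)
        pos_unwrapped[:, h_idx, 0] += bx
        pos_unwrapped[:, h_idx, 1] += by
        pos_unwrapped[:, h_idx, 2] = zk + bz

    # --- solutes: per-frame cluster assignment and placement
    if spec.n_solutes > 0:
        sol_idx = np.arange(n_lip * per_lip, n_part)
        z_lo, z_hi = max(0.2, z_carb - 0.8), z_carb
        for f in range(F):
            sizes = _cluster_sizes(spec.n_solutes, spec.monomer_fraction, rng)
            seeds = _place_clusters(sizes, lx, ly, rng)
            j = 0
            for (sx, sy), size in zip(seeds, sizes):
                zc = rng.choice([-1.0, 1.0]) * rng.uniform(z_lo, z_hi)
                if size == 1:
                    offsets = np.zeros((1, 2))
                else:
                    ang = rng.random(size) * 2 * np.pi
                    rad = rng.uniform(0.02, 0.10, size=size)
                    offsets = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
                for o in offsets:
                    pos_unwrapped[f, sol_idx[j], 0] = sx + o[0]
                    pos_unwrapped[f, sol_idx[j], 1] = sy + o[1]
                    pos_unwrapped[f, sol_idx[j], 2] = zc
                    j += 1

    # wrap x, y into the box; z is bounded and kept about the bilayer center
    positions = pos_unwrapped.copy()
    positions[:, :, 0] %= lx
    positions[:, :, 1] %= ly

    return LabeledTrajectory(
        time=spec.dt * np.arange(F),
        box=np.tile([lx, ly, lz], (F, 1)),
        molecule_id=np.array(mols),
        role=np.array(roles, dtype=object),
        leaflet=np.array(leaflets, dtype=object),
        mass=np.array(masses),
        positions=positions,
        positions_unwrapped=pos_unwrapped,
    )


# ----------------------------------------------------------------------
# partition data
# ----------------------------------------------------------------------
def gen_partition_data(
    r_sat: float,
    r_50: float,
    x_values,
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> PartitionDataset:
    """Hyperbolic partition points r_sat*x/(r_50+x) + N(0, noise_sd), >= 0.

    With ``n_reps`` > 1 each x value is emitted that many times.  Negative
    noisy values are clipped to zero (count logged).
    """
    if r_sat <= 0 or r_50 <= 0:
        raise ValueError("r_sat and r_50 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(x_values, dtype=float), n_reps)
    r = r_sat * x / (r_50 + x)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=x.shape)
    n_clip = int(np.sum(r < 0))
    if n_clip:
        logger.info("clipped %d negative r_mem values to 0", n_clip)
        r = np.clip(r, 0.0, None)
    return PartitionDataset(x=x, r_mem=r)


# ----------------------------------------------------------------------
# leakage trace
# ----------------------------------------------------------------------
def gen_leakage_trace(params: LeakageSimParams, t_grid) -> LeakageTrace:
    """Raw-fluorescence trace for mono-exponential leakage kinetics.

    The underlying %L(t) is re-expressed as fluorescence via the stated
    F_i / F_d calibration so that ``percent_leakage`` inverts it exactly in
    the noiseless case.
    """
    t = np.asarray(t_grid, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")
    rng = np.random.default_rng(params.seed)
    rate = params.composition_modifier * params.rate_constant
    pct = params.plateau_percent * (1.0 - np.exp(-rate * t))
    f = params.f_i + (params.f_d - params.f_i) * pct / 100.0
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=t.shape)
    return LeakageTrace(t=t, f_t=f, f_i=params.f_i, f_d=params.f_d, label=params.label)


# ----------------------------------------------------------------------
# umbrella samples
# ----------------------------------------------------------------------
def gen_umbrella_samples(
    profile: FreeEnergyProfile,
    centers,
    k_spring: float = 1000.0,
    n_per_window: int = 5000,
    temperature: float = 298.0,
    seed: int = 0,
) -> UmbrellaWindows:
    """Boltzmann samples from harmonic umbrella windows over a known profile.

    Window i samples z from p_i(z) proportional to
    exp(-(G(z) + k/2 (z - z_i)^2) / k_B T) by inverse-CDF interpolation on
    a fine grid.  The profile (kcal/mol) must cover every window center
    +/- 3 sigma, sigma = sqrt(k_B T / k).
    """
    centers = np.asarray(centers, dtype=float)
    kT = kT_kj(temperature)
    if k_spring <= 0:
        raise ValueError("k_spring must be positive")
    sigma = float(np.sqrt(kT / k_spring))
    if centers.min() - 3 * sigma < profile.z[0] or centers.max() + 3 * sigma > profile.z[-1]:
        raise ValueError(
            "profile grid must cover [min(centers)-3 sigma, max(centers)+3 sigma]"
        )
    rng = np.random.default_rng(seed)
    samples = []
    for zi in centers:
        lo = max(profile.z[0], zi - 6 * sigma)
        hi = min(profile.z[-1], zi + 6 * sigma)
        zg = np.linspace(lo, hi, 600)
        energy = profile.interp(zg) * KJ_PER_KCAL + 0.5 * k_spring * (zg - zi) ** 2
        w = np.exp(-(energy - energy.min()) / kT)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(zg))])
        if cdf[-1] <= 0:
            raise ValueError(f"window at z={zi}: empty support")
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples.append(np.interp(u, cdf, zg))
    return UmbrellaWindows(
        centers=centers, samples=samples, k_spring=k_spring, temperature=temperature
    )


# ----------------------------------------------------------------------
# scattering curve
# ----------------------------------------------------------------------
def gen_scattering_curve(
    d: float,
    n_orders: int = 3,
    peak_width: float = 8e-4,
    background: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    s_range: tuple = (0.0075, 0.07),
    n_points: int = 800,
    amplitude: float = 100.0,
) -> ScatteringCurve:
    """Lamellar scattering curve with Gaussian reflections at s_n = n/d.

    Peak amplitudes fall off as 1/n; warns when any reflection lies outside
    the recorded s range.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    rng = np.random.default_rng(seed)
    s = np.linspace(s_range[0], s_range[1], n_points)
    y = np.full_like(s, float(background))
    for n in range(1, n_orders + 1):
        sn = n / d
        if not (s_range[0] <= sn <= s_range[1]):
            warnings.warn(
                f"order {n} reflection at s={sn:.5f} lies outside the recorded "
                f"s range {s_range}", stacklevel=2,
            )
        y += (amplitude / n) * np.exp(-0.5 * ((s - sn) / peak_width) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=s.shape)
    return ScatteringCurve(s=s, intensity=y, calibration=f"synthetic d={d} A")
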