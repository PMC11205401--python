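"""Labeled coordinate trajectories of bilayer systems.

A :class:`LabeledTrajectory` holds per-frame positions of role-labeled
particles (phosphate ``P``, ``CARBONYL``, CD-bond atom pairs ``CD_C_k`` /
``CD_H_k``, ``TERMINAL_CH3``, ``SOLUTE``) together with the simulation box,
which is the minimal information the membrane observables need.  Positions
are stored wrapped into the periodic box in x and y; generators may attach
the true unwrapped lateral positions for validation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("P", "CARBONYL", "TERMINAL_CH3", "SOLUTE")  # plus CD_C_k / CD_H_k
LEAFLETS = ("upper", "lower", "none")


@dataclass
class LabeledTrajectory:
    """Per-frame coordinates of role-labeled particles plus box dimensions.

    Parameters
    ----------
    time : (F,) array
        Frame times in ps.
    box : (F, 3) array
        Box dimensions (x, y, z) in nm per frame.
    molecule_id : (N,) int array
        Molecule each particle belongs to.
    role : (N,) str array
        Particle role: ``P``, ``CARBONYL``, ``CD_C_<k>``, ``CD_H_<k>``,
        ``TERMINAL_CH3`` or ``SOLUTE``.
    leaflet : (N,) str array
        ``upper``, ``lower`` or ``none`` (solutes / non-leaflet particles).
    mass : (N,) array
        Particle masses in amu.
    positions : (F, N, 3) array
        Wrapped coordinates in nm.  The z origin is at the bilayer center.
    positions_unwrapped : (F, N, 3) array, optional
        True continuous coordinates (no periodic wrapping); kept by
        generators so displacement estimators can be validated.
    """

    time: np.ndarray
    box: np.ndarray
    molecule_id: np.ndarray
    role: np.ndarray
    leaflet: np.ndarray
    mass: np.ndarray
    positions: np.ndarray
    positions_unwrapped: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id)
        self.role = np.asarray(self.role, dtype=object)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box dimensions must be positive")
        if self.positions.shape != (self.n_frames, self.n_particles, 3):
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        bad = set(self.leaflet) - set(LEAFLETS)
        if bad:
            raise ValueError(f"unknown leaflet labels: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def n_particles(self) -> int:
        return len(self.molecule_id)

    def select(self, role: str | None = None, leaflet: str | None = None) -> np.ndarray:
        """Boolean mask of particles matching a role and/or leaflet.

        ``role`` matches exactly, or as a prefix when it ends with ``*``
        (e.g. ``"CD_C_*"`` selects every CD carbon).
        """
        mask = np.ones(self.n_particles, dtype=bool)
        if role is not None:
            if role.endswith("*"):
                prefix = role[:-1]
                mask &= np.array([r.startswith(prefix) for r in self.role])
            else:
                mask &= self.role == role
        if leaflet is not None:
            mask &= self.leaflet == leaflet
        return mask

    # ------------------------------------------------------------------
    # tabular text round-trip
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per particle per frame."""
        F, N = self.n_frames, self.n_particles
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(F), N),
                "time_ps": np.repeat(self.time, N),
                "molecule_id": np.tile(self.molecule_id, F),
                "role": np.tile(self.role, F),
                "leaflet": np.tile(self.leaflet, F),
                "mass": np.tile(self.mass, F),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "z": self.positions[:, :, 2].ravel(),
                "box_x": np.repeat(self.box[:, 0], N),
                "box_y": np.repeat(self.box[:, 1], N),
                "box_z": np.repeat(self.box[:, 2], N),
            }
        )

    def write_table(self, path) -> None:
        """Write the trajectory as tab-separated text."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledTrajectory":
        frames = np.sort(df["frame"].unique())
        first = df[df["frame"] == frames[0]].sort_values("molecule_id", kind="stable")
        n = len(first)
        F = len(frames)
        pos = np.empty((F, n, 3))
        box = np.empty((F, 3))
        time = np.empty(F)
        df = df.sort_values(["frame"], kind="stable")
        for i, f in enumerate(frames):
            sub = df[df["frame"] == f]
            if len(sub) != n:
                raise ValueError(f"frame {f} has {len(sub)} particles, expected {n}")
            pos[i] = sub[["x", "y", "z"]].to_numpy()
            box[i] = sub[["box_x", "box_y", "box_z"]].iloc[0].to_numpy()
            time[i] = sub["time_ps"].iloc[0]
        return cls(
            time=time,
            box=box,
            molecule_id=first["molecule_id"].to_numpy(),
            role=first["role"].to_numpy(dtype=object),
            leaflet=first["leaflet"].to_numpy(dtype=object),
            mass=first["mass"].to_numpy(dtype=float),
            positions=pos,
        )

    @classmethod
    def read_table(cls, path) -> "LabeledTrajectory":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    # ------------------------------------------------------------------
    # multi-frame GRO
    # ------------------------------------------------------------------
    def write_gro(self, path, name_map: dict[str, str] | None = None) -> None:
        """Write a multi-frame GRO file (fixed width, nm).

        ``name_map`` maps roles to 5-character atom names; roles without an
        entry use a truncated role string.
        """
        name_map = name_map or {}

        def atom_name(role: str) -> str:
            return name_map.get(role, role.replace("CD_", "").replace("_", ""))[:5]

        buf = _io.StringIO()
        for f in range(self.n_frames):
            buf.write(f"membranekit frame t={self.time[f]:.3f} ps\n")
            buf.write(f"{self.n_particles:5d}\n")
            for i in range(self.n_particles):
                resid = int(self.molecule_id[i]) % 100000
                x, y, z = self.positions[f, i]
                buf.write(
                    f"{resid:5d}{'MOL':<5s}{atom_name(self.role[i]):>5s}"
                    f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = self.box[f]
            buf.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def read_gro(
    path,
    role_map: dict[str, str],
    leaflet_map: dict[int, str] | None = None,
    mass_map: dict[str, float] | None = None,
) -> LabeledTrajectory:
    """Read a multi-frame GRO file into a :class:`LabeledTrajectory`.

    GRO is a fixed-width format; multi-frame files are parsed natively
    (MDAnalysis's GRO reader handles a single frame only).  ``role_map``
    maps atom names to roles; atoms whose name has no entry are dropped.
    ``leaflet_map`` assigns leaflets by molecule id (default: sign of z in
    the first frame).  ``mass_map`` gives per-role masses in amu (default 1).
    """
    mass_map = mass_map or {}
    frames: list[np.ndarray] = []
    boxes: list = []
    times: list[float] = []
    names: list[str] | None = None
    resids: list[int] | None = None

    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i + 1])
        block = lines[i + 2 : i + 2 + n]
        if names is None:
            names = [ln[10:15].strip() for ln in block]
            resids = [int(ln[0:5]) for ln in block]
        xyz = np.array(
            [[float(ln[20:28]), float(ln[28:36]), float(ln[36:44])] for ln in block]
        )
        frames.append(xyz)
        boxes.append([float(v) for v in lines[i + 2 + n].split()[:3]])
        times.append(float(len(times)))
        i += 3 + n

    assert names is not None and resids is not None
    keep = [j for j, nm in enumerate(names) if nm in role_map]
    if not keep:
        raise ValueError("role_map matched no atoms")
    roles = np.array([role_map[names[j]] for j in keep], dtype=object)
    mol = np.array([resids[j] for j in keep])
    pos = np.stack(frames)[:, keep, :]
    box = np.asarray(boxes, dtype=float)
    z0 = pos[0, :, 2] - np.median(pos[0, :, 2])
    if leaflet_map is not None:
        leaf = np.array([leaflet_map.get(m, "none") for m in mol], dtype=object)
    else:
        leaf = np.where(z0 >= 0, "upper", "lower").astype(object)
        leaf[roles == "SOLUTE"] = "none"
    mass = np.array([mass_map.get(r, 1.0) for r in roles])
    return LabeledTrajectory(
        time=np.asarray(times, dtype=float),
        box=box,
        molecule_id=mol,
        role=roles,
        leaflet=leaf,
        mass=mass,
        positions=pos,
    )
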