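"""Reference study conditions for POPC / DMPC bilayers with cryptotanshinone.

These constants encode the reported reference values for the systems the
package is designed around — bilayer structural targets, the water
permeation barriers, partition parameters and lamellar spacings — and are
used as generator ground truths in validation runs.
"""

from __future__ import annotations

import numpy as np

from .syngen import BilayerSpec
from .pmf import FreeEnergyProfile

# --- partition isotherm (POPC, 25 C)
R_SAT_POPC = 0.30
R_50_POPC = 1.2
EPSILON_450_MM_CM = 2.86  # cryptotanshinone at 450 nm, mM^-1 cm^-1

# --- water permeation barriers, kcal/mol
BARRIER_POPC_KCAL = 6.8
BARRIER_POPC_CPT_KCAL = 4.84

# --- lamellar d-spacings, Angstrom
D_DMPC_7C = 59.6
D_DMPC_18C = 64.6
D_DMPC_34C = 60.0
D_SILVER_STEARATE = 48.8

# --- umbrella sampling defaults
UMBRELLA_K_SPRING = 1000.0  # kJ mol^-1 nm^-2


def popc_spec(**overrides) -> BilayerSpec:
    """Pure-POPC bilayer targets at 298 K (no solute)."""
    kw = dict(
        n_lipids_per_leaflet=64, n_solutes=0,
        target_apl=0.63, target_thickness=4.04, target_D=5.45e-8,
        target_scd=tuple([0.14] * 14), temperature=298.0,
    )
    kw.update(overrides)
    return BilayerSpec(**kw)


def popc_cpt_spec(**overrides) -> BilayerSpec:
    """POPC + 14 cryptotanshinone molecules at 298 K."""
    kw = dict(
        n_lipids_per_leaflet=64, n_solutes=14,
        target_apl=0.66, target_thickness=3.93, target_D=7.67e-8,
        target_scd=tuple([0.15] * 14), monomer_fraction=66.6, temperature=298.0,
    )
    kw.update(overrides)
    return BilayerSpec(**kw)


def dmpc_spec(**overrides) -> BilayerSpec:
    """Pure-DMPC bilayer targets at 312 K (no solute)."""
    kw = dict(
        n_lipids_per_leaflet=64, n_solutes=0,
        target_apl=0.61, target_thickness=3.81, target_D=7.3e-8,
        target_scd=tuple([0.20] * 12), temperature=312.0,
    )
    kw.update(overrides)
    return BilayerSpec(**kw)


def dmpc_cpt_spec(**overrides) -> BilayerSpec:
    """DMPC + 14 cryptotanshinone molecules at 312 K."""
    kw = dict(
        n_lipids_per_leaflet=64, n_solutes=14,
        target_apl=0.64, target_thickness=3.65, target_D=11.5e-8,
        target_scd=tuple([0.193] * 12), monomer_fraction=65.6, temperature=312.0,
    )
    kw.update(overrides)
    return BilayerSpec(**kw)


def gaussian_barrier_profile(
    barrier_kcal: float,
    width: float = 0.8,
    z_max: float = 4.5,
    dz: float = 0.01,
    center: float = 0.0,
) -> FreeEnergyProfile:
    """Smooth symmetric test profile: a Gaussian bump at the bilayer center.

    G(z) = B exp(-(z-center)^2 / (2 width^2)), in kcal/mol, on a grid from
    center - z_max to center + z_max.  Decays to ~0 in the aqueous region,
    so the barrier equals B after zero-referencing in water.
    """
    z = np.arange(center - z_max, center + z_max + dz / 2, dz)
    g = barrier_kcal * np.exp(-0.5 * ((z - center) / width) ** 2)
    return FreeEnergyProfile(z=z, g=g, reference="aqueous (construction)")
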