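# membranekit

Quantitative analyses for studies of small hydrophobic molecules in
phospholipid bilayers — built for the kind of combined experimental +
simulation workflow used to characterise how a membrane-active compound
(here modelled on cryptotanshinone, a diterpene quinone, partitioning into
POPC/DMPC membranes) changes bilayer structure and permeability.

It is aimed at membrane biophysicists who need the *analysis* layer of that
workflow as tested, reusable code:

- **Partition isotherms** — quantify membrane-incorporated solute from A450
  absorbance (Beer–Lambert, ε₄₅₀ = 2.86 mM⁻¹ cm⁻¹ default) and fit the
  saturating isotherm
  `R_mem = R_sat · x / (R_50 + x)`,
  where `x` is the total solute/lipid molar ratio, `R_sat` the saturation
  membrane molar ratio and `R_50` the half-saturation ratio.
- **Dye leakage** — carboxyfluorescein release,
  `%L = 100 (F_t − F_i)/(F_d − F_i)` with detergent lysis defining 100%,
  plus trace summaries (extent, initial rate, plateau).
- **Bilayer trajectory observables** — area per lipid, lateral diffusion by
  the Einstein relation `D = slope(MSD)/(2d)` with `d = 2`, deuterium order
  parameters `S_CD = ⟨(3cos²θ − 1)/2⟩`, phosphate–phosphate thickness, mass
  density profiles along the normal, and solute cluster statistics under a
  0.30 nm single-linkage cutoff.
- **Umbrella sampling / WHAM** — the weighted histogram analysis method
  combines harmonic-window histograms into `G(z) = −k_B T ln p(z)`,
  zero-referenced in the aqueous phase, optionally symmetrized about the
  bilayer center, with the permeation barrier read off as `max G`.
- **Lamellar SAXS indexing** — in the `s = 2 sinθ/λ` convention, lamellar
  reflections sit at `s_n = n/d`; the package calibrates the detector axis
  (silver stearate, d = 48.8 Å), detects reflections and indexes the
  repeat distance `d`.
- **Synthetic data generators** — every input class can be generated with
  known ground truth (Brownian lateral motion, fixed-angle CD bonds,
  Boltzmann umbrella samples, hyperbolic partition data, mono-exponential
  leakage, Gaussian lamellar peaks), so every stage is validated by
  parameter recovery.

## Worked example

Generate a synthetic POPC + solute bilayer trajectory at its reference
targets and recover them:

```python
import membranekit as mk
from membranekit.presets import popc_cpt_spec

traj = mk.gen_bilayer_trajectory(popc_cpt_spec(n_frames=400, seed=8))
apl  = mk.area_per_lipid(traj, 64)
th   = mk.membrane_thickness(traj)
d    = mk.lateral_diffusion(traj)
scd  = mk.order_parameters(traj)
clus = mk.cluster_stats(traj, cutoff=0.30)
print(f"area per lipid : {apl.mean:.3f} +/- {apl.sd:.3f} nm^2")
print(f"P-P thickness  : {th.mean:.3f} +/- {th.sd:.3f} nm")
print(f"lateral D      : {d.d_coeff:.2e} cm^2/s")
print(f"|S_CD| chain   : {scd.chain_mean_abs:.3f}")
print(f"monomers       : {clus.percent_monomers:.1f} %")
```

prints

```
area per lipid : 0.660 +/- 0.000 nm^2
P-P thickness  : 3.929 +/- 0.009 nm
lateral D      : 7.25e-08 cm^2/s
|S_CD| chain   : 0.150
monomers       : 66.4 %
```

i.e. the analysis recovers the generating targets (0.66 nm², 3.93 nm,
7.67×10⁻⁸ cm²/s, 0.15, 66.6%) within sampling error: the area per lipid is
exact by construction (constant box), the diffusion coefficient carries the
usual MSD-fit sampling uncertainty, and the monomer percentage fluctuates
frame to frame around its expectation.

There is also a CLI:

```bash
membranekit run-all --config config.yaml --seed 1 --out results/
membranekit partition data.csv          # isotherm fit
membranekit pmf windows_dir/ --symmetrize-center 0
membranekit saxs curve.csv
```

`run-all` executes the configured stages in dependency order and writes a
`manifest.json` recording every output checksum and every stage seed, so a
rerun with the same config is byte-identical.

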