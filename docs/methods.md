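# Methods

This note documents the models, estimators and numerical choices behind
membranekit, and what the synthetic-data validation does and does not
establish.

## Unit conventions

Internal lengths are nm, times ps, energies kJ/mol. Free energies are
reported in kcal/mol (1 kcal = 4.184 kJ). Lateral diffusion is reported in
cm²/s; since 1 nm² = 10⁻¹⁴ cm² and 1 ps = 10⁻¹² s, 1 nm²/ps = 10⁻² cm²/s
(asserted in the test suite). SAXS uses s = 2 sinθ/λ in Å⁻¹, so the
lamellar repeat is d = 1/s₁ — *not* the q = 2π/d convention; mixing the two
is a factor-2π error.

## Partition isotherm

Membrane-incorporated solute follows a saturating hyperbola
R_mem(x) = R_sat·x/(R_50 + x). Fitting uses nonlinear least squares
(scipy `least_squares`) with the analytic Jacobian, initialised from the
double-reciprocal linearisation 1/R_mem = (R_50/R_sat)(1/x) + 1/R_sat —
robust for hyperbolic models because the linearised estimate is already
consistent in the noiseless limit (this identity is itself a test oracle).
Standard errors come from s²(JᵀJ)⁻¹ at the optimum. When replicate SDs are
supplied, `weighted=True` switches to 1/sd weighting; since it is unknown
whether typical datasets of this kind are error-weighted, unweighted is the
default and both modes are provided. Negative noisy values from the
generator are clipped to zero with a logged count.

Solute quantitation is Beer–Lambert: c = A₄₅₀/(ε·l)·dilution, with
ε₄₅₀ = 2.86 mM⁻¹ cm⁻¹ as the default extinction coefficient (solute
dissolved in ethanol/buffer after membrane solubilisation).

## Leakage

%L = 100(F_t − F_i)/(F_d − F_i), with F_d from detergent lysis. The
percentage is affine-invariant in the fluorescence scale. Values outside
[0, 100] (noise, photobleaching) are *flagged*, never clipped, to preserve
raw-data fidelity. Trace summaries: extent at the sample nearest the report
time; initial rate as the linear-fit slope over the first decile of samples
(minimum 5 points) — an adequate estimator only while rate·t stays small
over that window, which is why kinetic runs should sample densely at early
times; plateau as the mean over the final decile.

The mono-exponential generator model
%L(t) = plateau·(1 − exp(−m·k·t)) is a synthetic-only construction: it is
the simplest monotone rise-to-plateau consistent with observed leakage time
courses, with a multiplicative composition modifier m (> 1 for
anionic-lipid-enhanced, < 1 for PE-protected membranes). It makes no claim
about leakage mechanism (graded vs all-or-none).

## Trajectory observables

The `LabeledTrajectory` container stores role-labeled particles (P,
CARBONYL, CD_C_k/CD_H_k, TERMINAL_CH3, SOLUTE) with per-frame boxes,
x/y-wrapped coordinates and z about the bilayer center.

- **Area per lipid**: per-frame box_x·box_y / lipids-per-leaflet.
- **Thickness**: |⟨z⟩_upper-P − ⟨z⟩_lower-P| per frame, averaged.
- **Lateral diffusion**: MSD(Δt) averaged over all time origins and
  particles of the selected role, D = slope/(2d), d = 2. Wrapped
  coordinates are unwrapped by accumulating minimum-image step
  displacements, which assumes no particle moves more than half a box per
  frame (asserted). The fit window defaults to lags between 10% and 50% of
  the trajectory length — the usual bias (short lags) vs variance (long
  lags, few origins) trade-off — and is a parameter. Per-leaflet lateral
  center-of-mass motion is removed by default and switchable
  (`remove_leaflet_com`); on N independent Brownian particles this removal
  biases D by the factor (1 − 1/N), ~1.6% at 64 lipids/leaflet, well inside
  the estimator's sampling error.
- **Order parameters**: S_CD = ⟨(3cos²θ − 1)/2⟩ per carbon over CD bond
  vectors (re-imaged in case wrapping split a pair), θ against the
  z axis. −0.5 is a perfectly ordered all-trans chain (bond ⊥ normal), 0
  the magic angle. Both the signed per-carbon profile and |S_CD| (the
  tabulation convention) are reported, plus the chain mean, since summary
  tables in this field often quote a single chain value.
- **Density profiles**: per-frame mass histograms of z about the bilayer
  center (midpoint of the leaflet P means, recomputed each frame),
  normalised by bin volume to kg/m³ on a bin grid symmetric about zero so
  that symmetrization ρ(z) ← (ρ(z)+ρ(−z))/2 is exact.
- **Clustering**: two solute molecules are linked when the minimum
  inter-particle distance between them (periodic minimum image) is below
  the cutoff, default 0.30 nm; clusters are single-linkage connected
  components per frame. The minimum-distance definition is chosen because a
  0.30 nm criterion is too small for center-of-mass separations of
  ~300 Da molecules; it corresponds to near-contact of any atoms.
  `percent_monomers` is the mean fraction of molecules in size-1
  components.

## Umbrella sampling and WHAM

Window i at center z_i with spring k biases by U_i(z) = k/2 (z − z_i)².
WHAM iterates

    p(z_b) ∝ n_b / Σ_i N_i exp[(f_i − U_i(z_b))/k_B T]
    exp(−f_i/k_B T) = Σ_b p(z_b) exp(−U_i(z_b)/k_B T)

in log-space (logsumexp) until the largest relative change in f_i (k_B T
units) is below `tol`. Defaults: bin width 0.05 nm, tol 10⁻⁷,
max_iter 10⁵ — standard practice at 0.1 nm window spacing; k defaults to
1000 kJ mol⁻¹ nm⁻², temperature 298 K. The gauge freedom (f_i defined up to
a constant) is fixed by f_0 = 0 each iteration; the converged profile is
invariant to constant shifts of the initial f_i (tested). Non-convergence
raises an error carrying the f_i trace; empty bins inside the sampled range
are masked with a warning, and adjacent windows sharing < 1% histogram mass
trigger an overlap warning.

G(z) = −k_B T ln p(z) is zero-referenced on the aqueous plateau, defined as
the outermost 15% of the grid on the water side (a parameter — "zero in the
aqueous phase" underdetermines the averaging region). For a symmetric
bilayer the profile may be symmetrized, G_sym(z) = (G(z) + G(2c − z))/2;
half-profiles are mirrored to full ones. The permeation barrier is
max G − 0 with its location. Because the barrier is a maximum over noisy
bins, it carries a small upward noise bias on flat-topped profiles, well
inside the sampling uncertainty at 5000 samples/window. Uncertainty, when
requested (`profile_uncertainty`), is a block bootstrap within windows
(block length ≈ √n to respect autocorrelation, 50 resamples by default).

The umbrella *generator* inverse-CDF samples p_i(z) ∝
exp(−[G(z) + U_i(z)]/k_B T) on a fine local grid (z_i ± 6σ, 600 points),
so for a flat profile window samples are exactly Gaussian with mean z_i and
variance k_B T/k — the analytic oracle used in tests.

## SAXS

Detector calibration is linear, anchored at s(0) = 0 and
s(ref channel) = 1/d_ref with silver stearate (48.8 Å) as the default
reference. Reflection detection lightly smooths the curve (Gaussian,
3 bins), takes local maxima with prominence ≥ 10% of the intensity span,
and refines positions with a 3-point parabola for sub-bin accuracy on
coarse detectors. Indexing assigns consecutive orders n = 1, 2, …;
d = mean(n/s_n); the worst relative deviation of s_n from n·s₁ is the ratio
residual, and a residual > 2% flags the pattern as non-lamellar.

## The synthetic bilayer generator

`gen_bilayer_trajectory` emulates a two-leaflet bilayer of 2×64 lipids
(± 14 solute molecules) as *statistics*, not physics:

- lateral lipid positions are independent 2-D Brownian walks with per-step
  total variance 4·D·dt (all particles of a lipid share its track);
- leaflet phosphate planes sit at ±thickness/2 with Gaussian z-noise
  (default 0.05 nm, a typical per-lipid plane fluctuation);
- CD bonds point at the fixed polar angle solving
  (3cos²θ − 1)/2 = −|S_CD| with uniform azimuth, so the generated order
  parameter is exact by construction;
- carbonyl planes sit 0.45 nm below the phosphate planes and terminal
  methyls 0.15 nm from the center, with CD carbons interpolated between —
  nominal glycerol/chain-end depths for a fluid PC bilayer;
- solutes are re-assigned each frame to clusters of sizes 1–3 (only small
  clusters are modelled, matching the observation that such solutes form
  clusters of a few molecules at most) with the monomer count randomised so
  its *expectation* equals the target percentage; cluster members are
  placed < 0.30 nm apart and cluster seeds ≥ 0.9 nm apart, guaranteeing
  monomers are > 0.6 nm from everyone (unsatisfiable packings raise an
  explicit error);
- solute depth is uniform between the carbonyl plane and ~0.8 nm above it,
  so solute density overlaps the carbonyl profile more than the terminal
  methyls.

Default problem sizes (600 frames at 100 ps spacing ≈ 60 ns of emulated
sampling; 500–1000 frames in the recovery runs) were chosen so each
recovery statistic's sampling error is several times smaller than the
tolerance it is checked against.

What this validates: that every estimator recovers known ground truth,
including unit conversions, periodic-boundary handling and calibration
inversions. What it does not validate: behaviour on real MD output —
correlated lipid motion, anomalous sub-diffusion at short lags, chain
conformational statistics, solvent, undulations, or force-field effects.
The generators share the trajectory *format* with real data, not its
dynamics.

## Known limitations

- WHAM assumes uncorrelated samples within windows; real umbrella time
  series need subsampling by their autocorrelation time first.
- The MSD fit window and leaflet-COM removal materially affect D on real
  (correlated) data; both are exposed as parameters.
- The leakage initial-rate estimator is biased low when the first decile of
  samples extends beyond the linear regime.
- Lamellar indexing assumes consecutive orders starting at 1; missing or
  spurious peaks must be culled before indexing.
- The GRO reader parses the fixed-width format natively (multi-frame GRO
  is read frame by frame); atom-name→role mapping is the user's
  responsibility via `role_map`.
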