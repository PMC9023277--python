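# Methods

This note documents the models behind each module, the defaults and their
units, the numerical choices, what the synthetic fixtures do and do not
emulate, and known limitations.

## Motif scanning (`seqscan`)

A putative quadruplex motif is `tract_count` ∈ {4, 8, 12} maximal runs of
at least `run_len` ∈ {2, 3} guanines separated by loops of `loop_min`–
`loop_max` nt (1–7 by default, up to 10 supported).  Tracts are *maximal*
G-runs: a G₅ run counts as one tract, never as overlapping G₃ registers —
register assignment is a modelling question downstream.  With that tract
definition, windows of consecutive runs are enumerated in ascending order;
the "leftmost, resume after the first tract" policy and the "all windows"
policy produce identical enumerations, so `mode` accepts both.  Complement
scanning applies the same rule to C runs and flags hits with strand `-` in
plus-strand coordinates.

Strand masses are average-mass free-acid values,
MW = nA·313.21 + nC·289.18 + nG·329.21 + nT·304.2 − 61.96 Da.  Extinction
coefficients are deliberately not computed: the tabulated ε values for the
tetramolecular references follow a convention (per strand? per tetramer?)
that cannot be reconstructed unambiguously, and a wrong ε silently corrupts
every downstream concentration.

## CD quantitation (`cdspec`)

Raw ellipticity is converted by Δε(λ) = θ_mdeg(λ)/(32980·c·l) with c the
molar concentration of the *particle* (tetramer concentration for
tetramolecular species — recorded in `norm_unit`) and l the pathlength in
cm.  The stacked-quartet calibration is the line Δε₂₆₄ = m·n + b fitted to
all-parallel reference quadruplexes with known quartet counts; the packaged
default is m = 95.1 ± 3.8 M⁻¹cm⁻¹/quartet, b = −85.5 ± 16.4 M⁻¹cm⁻¹,
r² = 0.998 (the underlying reference amplitudes are not tabulated anywhere
re-fittable, so the printed line is authoritative; `fit_calibration`
refits from user points via ordinary least squares).  Counts are reported
half-away-from-zero to one decimal.

The 264 nm amplitude is the maximum within ±3 nm of the target (band
maxima drift 1–2 nm between instruments).  Since the spectrum is stored as
samples, the interpolated maximum is taken over data knots and window
edges, which is exact for a piecewise-linear interpolant.  Digestion
difference spectra are `initial − final`, so the component digested away
(e.g. a B-form hairpin with its ~280 nm positive band) appears with
positive sign; mismatched grids are linearly resampled onto their overlap.

Limitation: the 264 nm heuristic assumes an all-parallel ensemble.  A
mixed-topology sample (a 295 nm shoulder is the tell-tale) yields an
amplitude contaminated by the other species; the count is still reported,
uncorrected.

## Hydrodynamics (`hydrocalc`)

Volumes: V_anh(Å³) = M(Da)·(v̄·10²⁴)/6.023×10²³ with v̄ = 0.55 cm³/g for
DNA.  The Avogadro constant is kept at 6.023×10²³ exactly as this formula
is conventionally printed, so tabulated arithmetic reproduces to the
digit; the ~0.03% difference from the CODATA value is far below every
tolerance used here.  Hydration: V_hyd = (δ/(ρ·v̄) + 1)·V_anh with
δ = 0.3 g/g.  Bead radii from volumes: AER = (3V_a/4π)^{1/3}.

Sedimentation coefficients come from the Kirkwood double-sum friction

    f = 6πη N ā / (1 + (ā/N) Σ_{i≠j} 1/R_ij)

followed by s = M(1 − v̄ρ)/(N_A f) and D_t = k_B T/f, with default buffer
conditions T = 20 °C, η = 0.0101 poise, ρ = 1.0092 g/cm³.  Two properties
of this approximation drive the implementation:

* over a closed shell of beads it converges to the Stokes friction of the
  enclosed sphere (the pair average of 1/R over a spherical surface is
  exactly 1/R_shell);
* over a *filled* body it underestimates friction — for a uniform ball the
  pair average is (6/5)/R, giving asymptotically 5/6 of Stokes — because
  the plain double sum lets screened interior beads contribute mobility.

`kirkwood_s20w` therefore applies the sum to the solvent-exposed bead
layer by default (`surface_only=True`).  Exposure is decided by ray
casting: a bead is buried when all 66 Fibonacci-distributed rays from its
centre pass within the blocking radius max(a_j, 0.8·nearest-neighbour
spacing) of some other bead.  On 1000-bead filled spheres this lands the
friction within ~3% of Stokes; `surface_only=False` gives the literal
all-bead sum for comparison.  Expected accuracy is a few percent for
compact particles — hence the integrative filter uses a tolerance band for
S agreement, never equality.

The frictional ratio uses an **anhydrous** reference sphere:
f₀ = 6πη·r₀ with r₀ from V_anh, hydration entering separately through δ.
This is the standard AUC bookkeeping and is flagged in the output, since
the alternative (hydrated reference) shifts f/f₀ down by ~15%.

Atomic models become beads at uniform AER = 2.53 Å, the atomic-level
setting used by shell-model hydrodynamics programs for nucleic acids.
Rotational diffusion, intrinsic viscosity and shell-size extrapolation are
out of scope.

## SAXS primary analysis (`saxscore`)

**Guinier.**  Weighted regression of ln I on q² (weights (I/σ)²), with the
fit window found self-consistently: q_max is moved to `limit`/R_g and the
fit repeated until R_g changes < 0.1%.  The default limit is 1.3 (common
practice for compact particles); note the sphere's systematic bias at a
window edge of q·R_g = 1.0 is ≈ +1%, so accuracy-critical checks fit at
0.8.  R_g = √(−3·slope), I₀ = exp(intercept), with the slope's weighted SE
propagated to R_g.

**P(r).**  The profile (truncated at q_cut = 0.3 Å⁻¹; the resolution
beyond which IFT inversions of this data class are unstable) is inverted
through I(q) = 4π ∫₀^Dmax p(r)·sinc(qr) dr on an `n_r`-node grid with
p(0) = p(D_max) = 0, minimising χ² + α‖p″‖².  α defaults to an L-curve
corner search (maximum curvature of log-residual vs log-seminorm over 30
log-spaced candidates, scaled by the operator norms), falling back to the
largest α keeping χ² within 10% of its minimum when the curvature
criterion degenerates.  Positivity is a soft penalty (iteratively
reweighted rows on negative nodes; 4 rounds) by default, exact NNLS with
`positivity="hard"`.  `estimate_dmax` scans a D_max grid and takes the
smallest value with p ≥ −2% of the peak and plateaued χ².
R_g² = ∫r²p dr/(2∫p dr) and I(0) = 4π∫p dr.  Note the second-moment
formula applies to pair-distance distributions of extended bodies; for a
literal two-point particle it returns d/√2, not the mass-based d/2,
because the histogram carries no self-pair terms.

**Dimensionless Kratky.**  (qR_g)²·I/I₀ against qR_g with the peak located
by quadratic interpolation through the three samples around the maximum.
The Gaussian-globular reference peak is (√3, 3/e) ≈ (1.73, 1.104); an
ideal hard sphere peaks slightly lower, at (1.612, 1.027) — the maximum of
u²[3(sin u − u cos u)/u³]² at u = 2.0816 mapped through x = u√(3/5).
Curves whose maximum sits on the data edge are flagged non-globular.

## Model scattering and fitting (`formfactor`)

Intensities are exact Debye double sums — no spherical-harmonic or
multipole acceleration, O(N²) and intended for ≤ ~5×10³ scatterers.
Per-atom amplitudes use the dummy-solvent form f_i = Z_i·g_i(q) −
ρ_s·V_i(r₀)·exp(−V_i^{2/3}q²/4π), with ρ_s = 0.3368 e⁻/Å³ (water adjusted
for buffer) and tabulated displaced volumes rescaled as
V_i(r₀) = V_i·(r₀/0.162 nm)³.  Atomic g(q) has two modes: constant-Z
(default; right for pseudo-atom fixtures) and 4-Gaussian Cromer–Mann
coefficients for real PDB input.  The hydration layer is a bead shell on
the solvent-accessible surface (probe 1.4 Å, ~3 Å spacing, 3 Å thickness;
one bead represents spacing²·thickness of shell volume) with contrast δρ.
Because amplitudes depend on atoms only through their (Z, V) type, the
pair sums are cached per type pair, making the (r₀, δρ) grid search
(7 × 15 nodes over 0.156–0.168 nm and 0–70 e⁻/nm³) cost little more than
one Debye evaluation; an optional parabolic refinement interpolates the
3×3 neighbourhood of the winning node and is kept only if it improves χ².
The scale c is solved analytically per node.  Model R_g is obtained the
same way an experimentalist gets it: a Guinier fit to the computed curve,
on a dense window reaching qR_g ≈ 0.65 so the truncation bias stays below
0.5%.

Absolute χ² values from this evaluator are not interchangeable with
CRYSOL's (different hydration representation); the filtering logic —
relative comparisons across models and frames, and R_g — is what is
preserved.

## Integrative filter (`isbfilter`)

Four criteria, each evaluated only when its observables were supplied:
|CD − model tetrads| ≤ 0.5 stacks (operationalising the ~7% scatter of
known three-stack references about the calibration line); observed S₂₀,w
inside the model's calculated range ± 0.1 S; |R_g,calc − R_g,obs|/R_g,obs
≤ 5%; and χ² ≤ library mean + k·SD with the 14-structure reference
library at 2.1 ± 0.7 and k = 2 (a z-score, not a hard universal cut,
because χ² scales with data S/N).  Verdict: consistent iff all evaluated
criteria pass; missing observables can never fail a model alone; nothing
evaluated → indeterminate.  All thresholds are configurable.

## Synthetic fixtures (`synthgen`)

Generators are pure functions of (parameters, seed).  Tetrad stacks are
pseudo-atom models: four guanosine-nucleotide-equivalent scatterers
(Z = 170, V = 300 Å³ — the whole dGMP residue, so excluded-volume effects
carry realistic weight) per quartet at 6.5 Å from the axis, 3.3 Å rise and
30° twist between planes, optional axial K⁺.  Scattering fixtures are
analytic (sphere, orientation-averaged cylinder, two-sphere dumbbell) or
Debye-computed (tetrad stack); noise is multiplicative Gaussian with
σ = noise_frac·I (plus a 10⁻⁹-scale floor guarding exact zeros), matching
detector statistics at moderate q.  Noise-free profiles carry a nominal
0.1%-scale σ so weighted fits remain defined.  Fixture profiles for
fit-recovery studies use 500 points over q = 0.005–0.35 Å⁻¹, the point
density and range of SEC-SAXS data.  CD fixtures are a positive Gaussian
band at 264 nm (apex pinned exactly to m·n + b after accounting for band
overlap) and a negative 240 nm band at −0.45 amplitude ratio.
Bead-sphere fixtures sample the closed ball on concentric shells (counts
∝ r², outermost centres exactly at R, volume-preserving radii).

What the fixtures do *not* emulate: real nucleotide chemistry and loops,
inter-particle interference, buffer-subtraction artefacts, instrumental
smearing, concentration-dependent aggregation, or mixed conformational
ensembles.  Passing the synthetic suite therefore demonstrates the
correctness of the estimators, not the absence of those experimental
effects in real data.

## Numerical conventions

Units: Å, Å⁻¹, Da, Svedberg, °C, poise, g/cm³, M⁻¹cm⁻¹ internally;
nm⁻¹ grids and mdeg signals are converted at the I/O boundary.  r₀ is
quoted in nm and δρ in e⁻/nm³ as is conventional for these parameters.
Display rounding of stack counts is half-away-from-zero.  Ties in
best-frame selection break to the lowest index.  All randomness flows
through explicit integer seeds.
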