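# Methods

## Physical model

### Free polymer in solution

A polymer is specified by its molar mass MW (Da) and dilute radius of
gyration R_g(0) (nm); where only a hydrodynamic radius is known,
`rg_from_rh` applies a coil Rh/Rg ratio (Kirkwood–Riseman value 0.665 by
default). The overlap concentration is taken as one chain mass per pervaded
spherical volume, c_p* = 3 MW/(4π N_A R_g(0)³). This convention reproduces
the printed overlap concentrations of all three reference PEGs from their
rounded radii (1.6 mg/mL exactly; 8.5 vs 8.6 and 54.5 vs 52.6, i.e. within
a few percent — the discrepancy is consistent with the inputs being quoted
to three significant figures).

Osmotic pressure uses the good-solvent crossover form
Π_P = (N_A kT/MW) c_p (1 + (c_p/c_p*)^1.3), which interpolates between the
van't Hoff law and the semi-dilute scaling Π ∝ c_p^2.3. The depletant size
is the concentration-dependent radius of gyration
R_P = R_g(0)·[(MW/N_A kT)·dΠ/dc_p]^(−1/2); the derivative is evaluated
analytically, (N_A kT/MW)(1 + 2.3(c_p/c_p*)^1.3), to avoid finite-difference
step artefacts near c_p = 0. R_P equals R_g(0) at dilution and tends to the
correlation (blob) length in the semi-dilute regime, which gives the
depletion potential its correct limits in both regimes. Theta- and
poor-solvent equations of state are out of scope: the systems modelled are
PEG and polysaccharide in aqueous saline, good solvents throughout.

### Inter-particle potential

Separation r is measured between bare particle surfaces (r = 0 at hard
contact). The depletion term is the Asakura–Oosawa potential for a ≫ R_P;
with a = 500 nm and R_P ≤ 63 nm this holds for every polymer considered
(the constructor warns when a/L < 10). The steric term for L < r < 2L is
the Flory–Huggins mixing free energy of two interpenetrating step-profile
brushes, (4πa/υ₁) φ̄² (1/2 − χ)(L − r/2)² in kT, with χ = 0.45 for PEG in
water and υ₁ = 2.99×10⁻²⁹ m³ (18 cm³/mol per molecule; the water molecular
volume is not stated with the model and must be assumed). For r ≤ L elastic
deformation dominates every other scale in the problem (~10⁴ kT at r = L),
so the region is modelled as a hard wall rather than with an explicit
elastic functional. Free-polymer/brush coupling (penetration of free chains
into the brush, or compression of the brush by them) is neglected, the same
simplification the original analysis makes.

The minimum of the total potential is located by a 10⁴-point log-spaced
scan of (L(1+10⁻⁶), max(4R_P, 4L)] followed by bounded scalar refinement
between the neighbouring grid points; an independent 10× brute-force scan
agrees to 0.1% in the tests. By convention u_min = min(0, min U), with
r_min = NaN when no well exists.

A consequence worth recording: at matched *reduced* concentration c_p/c_p*
the model gives a deeper well for the **smaller** polymer (|U| ∝ 1/R_g:
Π ∝ R_g⁻³ while the well width ∝ R_g), whereas at matched *mass*
concentration the larger polymer digs the deeper well, which is the
experimentally relevant comparison and the one asserted in the tests.

### Brush parameters

From an NMR loading (nmol chains per mg particles) the grafting density is
Γ = chains / (surface area per mg), assuming monodisperse spheres (default
polystyrene density 1.05 g/cm³ — required for the unit conversion but not
part of the published inputs; configurable). The Alexander–de Gennes step
profile gives N = (R_g/b)^(1/ν) Kuhn segments, brush length
L = N Γ^((1−ν)/2ν) b^(1/ν) and volume fraction φ = (Γb²)^((3ν−1)/2ν); with
b = 0.76 nm, ν = 0.588, R_g = 3.45 nm and Γ = 0.48 nm⁻² these evaluate to
N ≈ 13, L ≈ 6.4 nm, φ ≈ 0.43. N is kept real-valued internally and rounded
only for display. The overlap grafting density is Γ* = 1/(πR_g²) ≈ 0.027
chains/nm², giving Γ/Γ* ≈ 18 — the layer is well inside the brush regime.
(The original write-up quotes "Γ/Γ* ~ 5" alongside the same formula; direct
evaluation does not reproduce that ratio, and this package reports the
formula as written.)

### Transport

Solution viscosity follows the Huggins equation
η/η_s = 1 + [η]c + k_H([η]c)², and the particle diffusivity ratio is its
reciprocal (Stokes–Einstein–Sutherland at fixed radius and temperature).
Intrinsic viscosities and Huggins coefficients are user-supplied; the
examples use the PEO Mark–Houwink relation [η] = 0.0125 MW^0.78 mL/g and
k_H = 0.4, both literature-derived, clearly labelled as such. No
coagulation-kinetics model is included — the diffusivity ratio is the
endpoint. Wi = γ̇λ with λ(MW) ∝ MW^(2/3) available as a helper.

## Image analysis

The segmentation chain mirrors a FIJI macro workflow. Anchor slices are the
10th and 10th-from-last (1-based), i.e. 0-based indices 9 and n−10. Each
anchor is Otsu-thresholded; the foreground median defines the per-slice
"max" line and (mean background)/3 + 2(max background)/3 the "min" line,
both interpolated — and extrapolated — linearly across all slices, following
the approximately-linear depth attenuation assumption. One departure from a
verbatim macro port: if a nominal anchor slice happens to contain no
objects (possible in sparse samples, and fatal to a two-point line), the
nearest usable slice towards the stack centre is taken instead, and a stack
with no usable anchor anywhere is reported as background-only (empty table
plus a warning) rather than an error. A slice is "usable" when its Otsu
foreground median exceeds `min_anchor_contrast` (default 1.5×) times its
background statistic; an Otsu split of pure noise fails this test.

Rescaling clips each slice to its [min, max] band and stretches it to the
full 16-bit range; clipping is deliberate, since objects are measured by
volume and individual particles inside an aggregate need not be resolved.
Objects are labeled at 26-connectivity by default (configurable 6/18/26,
since the plugin behaviour being mirrored is not specified); the global
threshold on the rescaled stack is Otsu's, also configurable. Border
objects are kept by default. Volumes are voxel counts × voxel volume.

Singlet normalisation divides object volumes by the single-particle volume.
In "auto" mode the estimate automates the manual identify-ten-singlets
step: the leftmost well-populated mode of the log-binned volume histogram
is the singlet population, and the estimate is the median volume in that
mode (±1 bin). Objects below 0.25× the singlet volume are discarded as
debris (sub-singlet objects are optical noise by construction; the cut is
configurable). N_i = volume/singlet is rounded to the nearest integer with
a floor of 1 by default; a "none" mode keeps the fractional ratios.

## Statistics

The volume-weighted ECDF weights each aggregate by its particle count:
F̂(N) = Σ_{N_i≤N} N_i / ΣN_i, a right-continuous step function reaching
exactly 1 at the largest aggregate. The headline statistic is
⟨N⟩ = ΣN_i²/ΣN_i ≥ mean(N_i), with equality only for monodisperse samples.
Uncertainty is a percentile interval over bootstrap replicates: each
replicate resamples the n observed aggregates with replacement and
recomputes ⟨N⟩; 10,000 replicates and the (2.5, 25, 50, 75, 97.5)
percentiles by default, driven by a named seedable generator recorded in
the output. Percentile (not BCa) intervals are used, matching the
"empirical bootstrap CI" convention. The aggregation threshold of a
dilution series is operationalised as the smallest dilution factor whose
CI lower bound exceeds the control's CI upper bound — the verbal definition
("where aggregation begins to disappear") admits several formalisations,
so the criterion is a replaceable callable.

## Synthetic data

The generator emulates the study's imaging conditions: 200 × 200 × 40 µm
volumes of 113 slices, 1-µm particles, linear front-to-back intensity decay
(default 1.0 → 0.5, a two-fold drop), Gaussian background (mean 800, sd 120
counts) plus shot noise (sd = 5·√signal) on a 28,000-count signal, 16-bit
quantisation. Tables default to 300 aggregates, matching the at-least-300
convention of the measured ECDFs. Aggregates are compact clusters of
touching spheres grown by random contact addition and placed by rejection
so no two clusters overlap; a Gaussian blur of 0.7 µm axial / 0.25 µm
lateral FWHM stands in for the confocal PSF. XY sampling defaults to
768 × 768 (0.26 µm/pixel): Nyquist-adequate for the 0.25-µm lateral PSF,
which keeps the threshold-and-count volume measurement of a ~10-voxel-wide
particle from being dominated by discretisation scatter. All randomness
derives from the single fixture seed; fixture sets regenerate
byte-identically, with sha256 checksums in a manifest.

What the generator does *not* reproduce: a physically correct confocal PSF
(no axial asymmetry or depth-dependent aberration), scattering digesta,
co-aggregation with non-fluorescent material, aggregate shapes other than
compact touching-sphere clusters, and any real sample's size law (only ECDF
plots exist for those, so fixtures span several plausible laws —
point-mass, small mixtures, geometric, rounded lognormal). Passing the
recovery tests therefore demonstrates that the measurement chain is
faithful for well-separated compact aggregates under realistic noise and
attenuation, not that real digesta images segment equally well.

## Numerical choices and edge cases

- Units at interfaces: nm, mg/mL, Da, mM, µm, kT; SI conversions internal.
  mg/mL ≡ kg/m³ is relied on.
- Temperature defaults to 298.15 K (room-temperature assays), overridable.
- Energy continuity at the seams r = 2L and r = 2R_P holds to < 10⁻⁹ kT;
  the hard-core and hard-wall regions use +∞ sentinels.
- c_p = 0 short-circuits: Π = 0, R_P = R_g(0), u_min = 0 with NaN location.
- Bootstrap index matrices are chunked to bound memory at ~5×10⁶ draws.
- Empty aggregate tables are representable (background-only stacks) but all
  statistics on them raise; sub-singlet sizes are rejected at construction.
- Tie-break in the singlet histogram: the leftmost local maximum holding at
  least max(3, 3%) of the objects; if none qualifies, the global maximum.

## Known limitations

- The potential model is equilibrium thermodynamics; the assays it
  describes are 10-minute snapshots of a kinetically evolving suspension.
  Trends (onset, restabilisation, short-polymer stability) are the
  meaningful outputs, not absolute well depths.
- The AO form ignores polymer-polymer correlations beyond the crossover
  expressions and assumes non-adsorbing polymer.
- Segmentation accuracy degrades when aggregates touch each other or the
  imaging border (the generator avoids both; real crowded samples may not).
- The singlet auto-estimate needs a visible singlet population; samples
  with no free singlets require an explicit singlet volume.
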