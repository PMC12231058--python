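# Methods

`alpsim` studies how white-matter geometry — crossing fibers, axonal
undulation, anisotropic orientation dispersion, and heterogeneous vessel
orientation — biases the DTI-ALPS index and its underlying quantity, radial
asymmetry λ2/λ3. Everything runs on synthetic data with known ground truth;
this note records the models, the defaults and why, the numerical choices,
and what the synthetic experiments can and cannot say about real data.

## Coordinates, units, and conventions

All orientation logic uses RAS image coordinates: x = right–left (the RL
axis along which the ALPS construction assumes the perivascular space
runs), y = posterior–anterior, z = inferior–superior. Gradient tables are
FSL-dialect (bvec = 3×N, image frame); shells are assigned by rounding b to
the nearest 50 s/mm², with b ≤ 50 s/mm² treated as b0. Diffusivities are
mm²/s in the tensor/model layer and µm²/ms (= 10⁻³ mm²/s) inside the Monte
Carlo; b is s/mm² externally, ms/µm² internally. Eigenvectors are axial
(sign-ambiguous) everywhere: every statistic built from them — V2
coherence, angular differences, orientation-tensor downsampling — is
sign-flip invariant by construction, and serialization fixes signs (positive
x, then y, then z component) purely for byte reproducibility.

## Tensor fitting and ALPS statistics

Tensors are fit per shell (the selected shell plus **all** b0 volumes,
shared across shells) by log-linear least squares followed by 2 reweighted
passes with weights equal to the squared predicted signals — the standard
first-order optimal weighting for log-transformed data. Signals are clamped
at 10⁻¹⁰ before the log; negative eigenvalues are clamped at 10⁻¹² and
flagged. A design matrix of rank < 7 (coplanar gradients) is an error, not
a warning, because the resulting tensor would be silently rank-deficient.

* **Radial asymmetry** is λ2/λ3, undefined (NaN) where λ3 ≤ 0.
* **V2 coherence** is the fractional anisotropy of the orientation tensor
  T = mean(v₂v₂ᵀ) over an ROI; 1 for perfectly aligned secondary
  eigenvectors, ~0 for noise-driven random ones.
* **ALPS index** = mean(Dxx over projection ∪ association ROIs) /
  mean(Dyy over projection, Dzz over association), from the raw tensor in
  image coordinates; the bilateral value is the mean of the left and right
  indices. Because automated implementations disagree on the order of
  averaging, `alps_index(..., average="ratios")` also exposes the
  mean-of-ratios variant; both agree exactly on homogeneous ROIs.
* The **noise reference** for asymmetry simulates isotropic (λ2 = λ3)
  voxels at the dataset's SNR, fits them identically, and reports the 95th
  percentile of fitted λ2/λ3. Asymmetry below this level is explainable by
  the Rician noise floor alone. At SNR 25, b = 1000, the reference is ≈1.11.

## Crossing-fiber simulation

A voxel is a mixture of axially symmetric Gaussian compartments,
S(b,g) = S0 Σᵢ fᵢ exp(−b gᵀDᵢg). The sweep grids crossing angle θ (fiber 1
along z, fiber 2 rotated in the x–z plane) against secondary fraction f.
Study conditions: θ = 0…90° step 1°, f = 0…0.5 step 0.01, 1000 voxels per
cell, per-voxel eigenvalues drawn uniformly (λ1 ∈ [1,2]×10⁻³, λ2 = λ3 ∈
[0.1,0.6]×10⁻³ mm²/s — quoted ranges are read as ×10⁻³ mm²/s, i.e. µm²/ms,
since literal mm²/s is physically impossible for tissue), both compartments
of a voxel sharing one draw, Rician noise at SNR 25 (the midpoint of the
plausible 20–30 range). The analysis and acceptance runs use the reduced
grid (step 5°/0.05, 200 voxels per cell), which resolves the same surface
at desk scale. Monotonicity of the noise-free surface is checked with
eigenvalues held fixed; with per-voxel draws the surface is monotone only
in expectation.

Rician noise is |S + n₁ + i n₂| with n₁, n₂ ~ N(0, (S0/SNR)²). Noise-free
collinear crossings fit to λ2/λ3 = 1 at machine precision; with noise the
θ = 0 cell sits above 1 — the same noise floor the reference quantifies.

The **PVS sensitivity** experiment carves a 10% volume fraction out of the
tissue compartments for a fast anisotropic compartment along x
(λ∥ = 3.0×10⁻³, λ⊥ = 1.5×10⁻³ mm²/s, both configurable) and reports the
per-shell asymmetry delta with vs without it. Because the compartment's
apparent diffusivity is high, its signal is largely attenuated by b = 3000,
so the delta shrinks with b; at b = 1000 it is about an order of magnitude
smaller than the crossing-geometry effect at matched settings
(≈0.08 vs ≈1.8 asymmetry units in the default configuration).

## Undulation Monte Carlo

An axon is a tube of diameter d swept along x(z) = A sin(2πz/L) (circular
cross-section normal to the local tangent, infinite/periodic in z). The
swept-tube membership test — distance to the centerline ≤ d/2 — is exact
while d/2 stays below the centerline's minimum radius of curvature
1/(A(2π/L)²); construction fails loudly otherwise. Nearest-centerline
parameters are found by safeguarded Newton iteration from a warm start (the
public `distance_to_centerline` brackets the minimizer first, which is
exact because (z−t*)² ≤ f(t*) ≤ f(z)).

Walkers take Gaussian steps with per-axis σ = √(2 D0 dt); dt is chosen so
the RMS step √(6 D0 dt) ≤ d/4. D0 defaults to 2.0 µm²/ms, a typical
axoplasmic value. Steps crossing the wall are split at the crossing point
(secant estimate on the radial distance) and the remainder is mirrored
about the local surface normal, up to 10 times; a step still outside after
that is rejected (the walker stays), counted, and warned about above a
0.1% rate. Phase encoding uses finite rectangular PGSE pulses with the
trapezoid rule on the piecewise-linear path (this removes an O(dt) bias
visible in the free-diffusion check); δ = 10.6 ms and Δ = 43.1 ms by
default (public HCP-style timings), with Δ rounded onto the step grid and
the effective value used in q = √(b/(Δ−δ/3)). E(b,g) = |⟨e^{iφ}⟩| over
walkers.

Validation: free axial MSD matches 2·D0·T within 2% (10⁵ walkers);
transverse MSD plateaus at d²/8 per axis; the perpendicular signal in a
straight cylinder matches the van Gelderen Gaussian-phase expression within
5%; final positions are uniform in the tube (KS test).

Behavior of the two reference substrates (micro d=1, L=24, A=4 µm; macro
d=1, L=300, A=50 µm) under the default protocol: undulation adds apparent
diffusivity along x but not y, so λ2 (undulation plane) is 0.1–0.6 µm²/ms
while λ3 (through-plane, restricted in a 1 µm tube) is ~10⁻³ µm²/ms. The
resulting λ2/λ3 is therefore large — roughly 19–144 (micro) and 7–16
(macro) across b — an order of magnitude above typical in-vivo white-matter
values, because a voxel containing a single isolated undulating tube has
essentially no through-plane mobility. The **in-plane** ratio λ1/λ2 is the
better-behaved summary of undulation strength at this scale: ≈2.2–2.4
across b for the macro substrate (walkers ride locally tilted, nearly
straight segments, max tilt ≈46°) and ≈9–10 for the micro substrate (motion
averages over whole wavelengths, suppressing apparent x-diffusivity). Both
ratios are reported. Asymmetry rises monotonically with A at fixed d, L,
and the A = 0 tube is radially symmetric within Monte Carlo error.

Problem sizes: the acceptance script runs 5×10⁴ walkers per substrate
(≈10⁴ steps each, 2–3 minutes on one CPU; the Monte Carlo standard error of
the reported ratios is well under 1%); tests use 1–2×10⁴.

## FOD peaks and crossing metrics

FODs are real, even-order SH expansions (default lmax 8; canonical ordering
l ascending, m = −l…l, with m<0 ↔ √2·Im Y, m>0 ↔ √2·Re Y and no
Condon–Shortley factor). The second common convention (the two m-blocks
swapped) is handled by an explicit dialect tag and converter; evaluation
refuses mixed dialects rather than silently mis-ordering coefficients.
Synthetic FODs convolve planted orientations with a Watson-like kernel
exp(κ((u·d)²−1)) and project by least squares on a dense sphere sampling —
deconvolution itself is out of scope.

Peaks: 64 hemisphere seeds on a Fibonacci lattice, neighbor-wise local
maxima, batched projected gradient ascent (finite-difference tangent
gradients, adaptive step), antipodal/duplicate merging at 15° separation,
relative amplitude threshold 0.05 (the printed 0.05% variant would count
basis ripple as fibers; 0.0005 remains selectable via `rel_threshold`), at
most 3 peaks. Crossing metrics per ROI: single-fiber fraction, mean angle
between the two largest peaks folded to [0°, 90°], and crossing fraction as
the mean relative amplitude of non-dominant peaks (peak amplitudes, not
lobe integrals — documented choice). At lmax 8 the resolution limit sits
near 45°: sub-45° separations bias inward, so the sharp-crossing tests use
lmax 16 with a narrower kernel.

## Dispersion models

Watson- and Bingham-NODDI: S/S0 = ν_iso·e^{−b·3.0×10⁻³} + (1−ν_iso)·
[ν_ic·A_stick + (1−ν_ic)·A_zeppelin], both anisotropic compartments
spherically convolved with the orientation distribution; d∥ fixed at
1.7×10⁻³ mm²/s and the zeppelin uses tortuosity λ⊥ = d∥(1−ν_ic) — the
standard identifiability constraints for 2–3 shells. The Bingham density
∝ exp(−κ1(n·e₂)² − κ2(n·e₃)²) about mean axis μ1 reduces exactly to Watson
at κ1 = κ2; its normalising constant (a confluent hypergeometric function)
is evaluated numerically as part of the quadrature. Convolution uses a
fixed antipodally symmetric 724-point Fibonacci sphere set, with
quadrature points below 10⁻⁷ relative weight skipped (pure speed; the
nesting check bounds the induced error at 10⁻⁴ signal units).

Fitting is multi-start L-BFGS-B on a Gaussian (not Rician) likelihood —
adequate at SNR ≥ 30 but biased at low SNR, a documented caveat. κ is
log-parameterised with ceiling 128; κ2 = κ1·sigmoid(s) enforces ordering
smoothly. 8 starts are built from a coarse orientation grid ranked by
directional signal attenuation; the 2–3 most promising are polished fully.
lnL is the concentrated Gaussian value, BIC = k·ln n − 2·lnL with k = 5
(Watson) / 7 (Bingham), and ΔBIC = BIC_W − BIC_B (positive favours
Bingham). The dispersion-anisotropy index is

    DAB = (2/π)·arctan((κ1 − κ2)/κ2),

which is 0 iff κ1 = κ2, strictly increasing in κ1 − κ2 at fixed κ2, and →1
as κ2 → 0 with κ1 > 0. Among the candidate transforms of (κ1, κ2) this is
the one that satisfies all three contracts simultaneously; it can be
swapped behind the same interface without touching the fitting. At SNR 30,
planted (κ1, κ2) = (16, 4) is recovered with median DAB error < 0.05 and
median ΔBIC ≈ +110; Watson-generated voxels give median ΔBIC ≈ −10 (close
to the pure penalty −2·ln 288 ≈ −11.3) and DAB near 0.

## Vessel geometry

Multiscale Frangi vesselness from Gaussian-derivative Hessians (derivatives
converted to physical mm units, γ = 2 scale normalisation via σ²), with
α = β = 0.5 and c defaulting to half the maximum Hessian norm per scale;
dark polarity (veins dark on bright background) requires the two
large-|λ| Hessian eigenvalues positive. The vessel axis is the eigenvector
of the smallest-|λ| eigenvalue at the best-responding scale. Requested
scales below the voxel size are clamped with a warning. Orientation
comparisons are arccos|a·b| ∈ [0°, 90°]; downsampling to a coarser grid
averages outer products per block and takes the principal eigenvector —
the only sign-consistent way to average axial data. The ALPS-assumption
report tabulates per-ROI medians, IQRs, and aligned/orthogonal fractions of
vessel∠V1, vessel∠V2, and vessel∠RL; in the ideal construction these are
90°, 0°, 0°.

## Synthetic data

The phantom grid is 40×40×20 voxels at 1.5 mm — small enough for fast CI,
large enough to hold four 5 mm-diameter ALPS spheres (projection pair with
fibers along z, association pair along y, optional PVS compartment along
x). Signals come from the multi-tensor forward model (or the dispersion
forward model for Bingham regions); Rician noise at the spec SNR; every
phantom serializes its generating spec to a JSON sidecar and is bit
reproducible from (spec, seed). Ground truth per region includes the
mixture tensor, its eigensystem, and all planted parameters, so every
downstream metric has a hand-computable expectation in the noise-free,
single-compartment case (and the pipeline reproduces those to 10⁻⁶ or
better). Vessel volumes rasterize straight tubes with a flat-core smooth
profile (exp(−(r/R)⁴)); cohorts are metric = intercept + β·age + ε with
configurable per-ROI slopes, default n = 50 aged 35–90 with β ≈ −0.002/yr
asymmetry slopes — an aging-study-like design.

What the phantoms do **not** emulate: anatomy (gyri, ventricles, partial
volume at tissue borders), spatially varying SNR, motion/eddy artifacts,
exchange between compartments, or realistic vessel curvature. Passing
tests therefore demonstrate correctness of the estimators and the
direction/magnitude of geometric confounds under controlled conditions,
not performance on real acquisitions.

## Statistics

Per-(ROI, metric) ordinary least squares of metric on age with two-sided
slope tests; a whole-mask "global" test (subject-wise mean across ROIs) is
appended. FDR control is step-up Benjamini–Hochberg across the full
ROI×metric family by default (per-metric families selectable); adjusted
p-values are NaN-propagating, with NaNs excluded from the family size.
Effect sizes are unstandardised slopes (metric units per year). The
asymmetry–ALPS association is a Pearson correlation with two-sided p;
across graded crossing phantoms it is r ≈ 1.0 — at phantom scale the ALPS
index is numerically a re-expression of ROI-mean λ2/λ3.

## Known limitations

* The Gaussian likelihood overestimates tissue fractions at SNR < 20.
* Single-tube undulation voxels have no extra-axonal space, making λ3
  unrealistically small and λ2/λ3 correspondingly extreme; a packed
  substrate with extra-axonal water would temper both.
* Peak extraction below ~45° separation at lmax 8 merges lobes.
* The Frangi orientation is reliable only above the vesselness cut used to
  mask it (Otsu in the analyses); sub-voxel vessels are not modelled.
* The crossing sweep's eigenvalue draws are uniform and independent — a
  modelling convenience, not an empirical tissue distribution.
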