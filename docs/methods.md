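# Methods

This note documents the models implemented in `fretcal`, the parameter
defaults and why they hold those values, what the synthetic-data generator
does and does not emulate, and the numerical choices that an auditor of the
results would want stated explicitly.

## Cluster photometry

Images are `(z, y, x)` grids, 0-based, pixel centers at integer
coordinates, 160 nm pixels and 200 nm z-steps by default. Around a
user-supplied click, the in-focus plane is the 3-D intensity argmax within
a cylindrical x,y neighbourhood of the click (default radius 4 px; ties
break toward the lowest z, then row-major y, x, so results are
reproducible bit-for-bit). Quantification uses that single plane — no
z-summation — which under-reports total spot mass by the axial-Gaussian
plane fraction (~26% of the 3-D mass stays in the focal plane for a
300 nm axial sigma). Because all three channels share the same PSF model,
this factor cancels from every ratio the pipeline consumes.

Two ROI methods:

* **Metaphase box.** A 6×6 pixel box placed, within ±2 px of the detected
  peak, to maximize its central 4×4 sum; background is the per-pixel
  *median* of the 28 peripheral pixels of the concentric 8×8 box, scaled
  by the 36 signal pixels — the only scaling that cancels a flat field
  exactly. The median resists contamination from the sister cluster
  ~5 px away. Known, quantified biases: (i) the placement search picks
  noise maxima on signal-free input, a positive bias of a few counts
  (≈ 9 counts at 2-count read noise), under 1% of a realistic cluster;
  (ii) the median ring still clips a neighbouring cluster's near tail,
  costing a roughly constant couple of counts — negligible for bright
  channels but ~3–5% of a dim FRET-channel signal at metaphase
  separations. For this reason spectral control coefficients are best
  estimated on well-separated clusters (see below). (iii) mass recovery
  of a noiseless Gaussian spot is ≥ 90% for spot sigmas up to ~1.3 px and
  ~100% at the realistic 0.69 px (110 nm PSF / 160 nm pixel); at 1.5 px
  the ring median starts absorbing real tail signal and recovery drops to
  ~82%. Negative corrected intensities are reported as-is; clipping would
  bias dim-population averages upward.

* **Anaphase Gaussian.** For isolated clusters, a 2-D Gaussian with
  constant offset is least-squares fitted in a window (half-width 7 px by
  default); the mask is the elliptical contour at 2.5 fitted sigmas
  (configurable) and the corrected intensity is the in-mask sum minus the
  fitted offset. The 2.5-sigma contour carries 95.6% of the analytic
  Gaussian mass; the hard-edged pixel mask reproduces the closed form to
  <0.5% once the spot is adequately sampled (sigma ≳ 2 px) and to ~1–3%
  for very small spots, where the in/out status of boundary pixels
  dominates. Flat input raises a fit-failure error rather than returning
  a number.

Per cell, the focus plane and ROI geometry are determined once on a
reference channel (donor by default — brightest and least variable) and
applied unchanged to all channels. For the anaphase method the per-channel
background differs, so the amplitude and offset are re-estimated per
channel by linear least squares with the geometry (center, widths, mask)
frozen — the recorded `RoiSpec` is identical across channels.

## Spectral model and calibration

Donor bleed-through α (FRET-channel counts per donor-channel count) and
acceptor cross-excitation β (per acceptor-channel count) are means of
per-cluster ratios over single-label control cells, with standard errors
of those means; a regression-through-origin estimator is available. Donor
emission under acceptor excitation is taken as zero (a third coefficient
is not modelled). Sensitized emission and the proximity ratio follow the
definitions in the README; both may be negative for no-FRET clusters and
are never clipped.

Donor-quenching efficiency uses the ratio of two sample means with
first-order error propagation, `sd(r) = r·√((sem_A/m_A)² + (sem_B/m_B)²)`.
The calibration line is unweighted ordinary least squares of strain-level
efficiency on strain-level mean proximity ratio (a 1/sd² weighted option
exists); confidence intervals use the t-distribution with n−2 degrees of
freedom and are reported unbounded for two points. The published
GFP(S65T)/mCherry profile (`gfp_mcherry_defaults`) carries
α = 0.058 ± 0.0001, β = 0.061 ± 0.0002, slope = 0.1355, y₀ = 0.002,
R₀ = 5 nm and an acceptor maturation fraction of 0.30; the orientation
factor κ² = 0.66 is a documented assumption (isotropic rotation), not a
computation. Maturation correction divides the apparent efficiency by the
maturation fraction, which is exact when dark acceptors are the only
heterogeneity, and errors loudly if the corrected value reaches 1.

The calibration slope is only *approximately* insensitive to acceptor
maturation: sensitized emission and apparent efficiency scale together,
but the acceptor term of the proximity-ratio denominator shrinks too. At
the default brightnesses a 3.3-fold maturation change moves the implied
slope by ~14%. The slope is exactly invariant in the limit where the
donor bleed-through term dominates the denominator.

## Ring-labeling Monte Carlo

Positions sit equally spaced on a circle; chord distances are
`D·sin(πk/n)` and a spacing mode derives `D` so that the adjacent chord
matches a lattice-derived spacing (6.15 nm) exactly. With the default
13-position, 25 nm ring and 10 nm FRET radius, only adjacent positions
can pair (second neighbours are 11.6 nm apart), so the within-reach graph
is the 13-cycle. Labeling is i.i.d. Bernoulli (unbiased case) or a
uniformly random arrangement of a fixed donor count (abundance scans);
maturation independently darkens each fluorophore with the complementary
probability.

Three counting rules are implemented because they answer different
questions: `pair_count` (all bright donor–acceptor pairs in range,
multiple acceptors per donor allowed), `donor_count` (bright donors with
at least one bright acceptor in range), and `matching` (maximum bipartite
matching by augmenting paths — the strictest one-to-one pairing).
Analytic anchors: unbiased Bernoulli labeling at full maturation gives a
pair-count mean of exactly 13/2; fixed counts give `g(13−g)/6`, tied at
g = 6 and 7, which is what the abundance scan's plateau rule reports as
midpoint 6.5. The plateau rule collects every abundance whose mean lies
within one Monte Carlo standard error of the maximum, so statistically
tied optima are representable; with 10,000 replicates the reported
midpoint is 6.5 or one of the tied members (6 or 7).

A deliberate modelling distinction: under 25% acceptor maturation the
one-to-one pairing optimum shifts to 3–4 donors per ring *only when
pairing is limited by bright-fluorophore counts alone*, i.e. matching on
the complete donor–acceptor graph (`fret_radius_nm` ≥ ring diameter),
where the matching equals `min(#bright donors, #bright acceptors)`. With
the geometric 10 nm cut-off the cycle adjacency caps pairing and every
counting rule keeps its optimum near 6. Both configurations are exposed
and both facts are asserted in the acceptance tests. An exhaustive
enumerator (all `C(13, g)` arrangements or all 2¹³ labelings) provides
the exact distribution at full maturation and serves as the simulator's
oracle. One seeded generator drives each simulation; scans spawn child
seeds per abundance from the configured seed.

## TCSPC decay fitting

The decay model is a one- or two-component exponential mixture discretely
convolved with the measured, normalized IRF on the histogram binning and
truncated to the window. Fitting uses the *bin-integrated* one-sided
exponential kernel: point-sampling the decay at bin centers
misrepresents the kink at t = 0 (the rising edge) at TCSPC channel
widths, which inflated the reduced χ² to ~1.9 and biased the short
lifetime before this choice; with the integrated kernel χ² sits near 1.
The default objective is weighted least squares with Neyman weights
`max(counts, 1)`; a Poisson maximum-likelihood option (deviance
residuals) is available and preferable at very fine binnings where
Neyman weighting is biased. Initialization: log-linear tail fit seeds the
long lifetime, the short lifetime starts at a third of it, amplitudes
come from non-negative linear least squares at the seeded lifetimes.
Components are reported in decreasing-lifetime order; lifetimes ending on
optimizer bounds are flagged. Model order (1 vs 2) is the caller's
choice; an F-test helper compares nested fits but is never auto-applied.
The IRF is a fixed measured curve — no shift or jitter parameters.

Derived quantities: donor-with-acceptor fraction `A₂/(A₁+A₂)` and
lifetime efficiency `1 − τ₂/τ₁`, both computed at full precision (printed
literature values round their inputs first, so reproductions agree to
one or two tenths of a percentage point).

Estimation limits worth knowing: at 10⁵ photons in a 12.5 ns / 256
channel window, the Cramér–Rao bound for the short lifetime is ~3.7%
relative for an equal-amplitude mixture but ~7.2% when the short
component holds only ~11% of the photons (the amplitude ratio of the
dimmest published strain); recovery studies therefore use the
equal-amplitude configuration, and the imbalanced one is checked at the
looser tolerance appropriate to its information content.

## Synthetic-data generator

`CellTruth` describes a two-cluster cell: 128 donor/acceptor pairs per
cluster (16 kinetochores × 8 complexes), cluster separation 800 nm in
metaphase and 4.5 µm in anaphase, per-cell brightness multipliers drawn
from truncated normals with the measured channel variabilities
(σ_donor = 0.114, σ_acceptor = 0.166 — the acceptor is wider because its
maturation varies), binomial acceptor maturation, complete donor
maturation (what the narrow donor histogram implies), spectral mixing
with the default α/β, and a sensitized-detection factor γ = 1 (donor and
acceptor detection efficiencies are not separated; the proximity-ratio
normalization absorbs γ, and it is exposed for sensitivity tests).
Expected intensities follow the closure algebra:

```
I_D = g_D·B_D·N·(1 − E·f)      SE = g_D·B_D·N·E·f·γ
I_A = g_A·B_A·N_bright          I_F = SE + α·I_D + β·I_A
```

with `f` the realized bright-acceptor fraction. Rendering samples 3-D
Gaussian spots (σ_xy = 110 nm, σ_z = 300 nm — plausible for a 1.4 NA
objective and green emission; fixtures, not claims about any particular
instrument) on the camera grid, adds per-voxel Poisson shot noise, a
constant 100-count camera offset and 2-count Gaussian read noise.
Brightness defaults (40 counts per donor, 20 per acceptor) put cluster
signals in the few-thousand-count range typical of EMCCD imaging of
kinetochore clusters. Default calibration datasets use three FRET strains
with true per-pair efficiencies 0.02 / 0.10 / 0.25 — spanning the
published strain ladder — at up to 170 cells per strain and phase, the
published dataset size.

What the generator does **not** emulate: chromatic PSF differences
between channels (their absence is exactly why plane-fraction and
mask-truncation factors cancel in ratios here; on a real instrument they
partially cancel), axial mis-sampling of the focal plane, photobleaching,
cell-to-cell background structure, and optical aberrations. Passing
closure tests therefore demonstrates the correctness of the estimators
under the stated noise model, not robustness to instrument-specific
systematics.

TCSPC decays are sampled photon-by-photon: component chosen with
probability ∝ A·τ (its area), arrival = Gaussian IRF draw (center 0.5 ns,
width 0.1 ns, the scale of an SHG-measured response) + exponential draw;
photons outside the window are discarded, which truncates but does not
distort the within-window shape. Default window 12.5 ns / 256 channels
(a ~79.5 MHz repetition period).

## Problem sizes used in checks

Ring simulations use 10,000 replicates per condition (matching the
published simulation count); enumeration covers all 2¹³ labelings.
Calibration closure runs 3 strains × 170 cells × two phases plus 170
donor-only and 100 acceptor-only controls per phase; spectral
coefficients are estimated from the well-separated anaphase controls for
the reason given above. Decay recovery uses 100 replicate decays of 10⁵
photons. These sizes make the full suite complete in a few minutes on a
single core.

## Known limitations

* Single-plane photometry and the shared-PSF assumption are calibrated
  away only for ratio quantities; absolute molecule counting is out of
  scope.
* The proximity ratio depends on the labeling stoichiometry; the
  bias-correction factor from the ring scan assumes the ring model
  applies and full maturation unless configured otherwise.
* κ² = 0.66 is assumed, not measured; anisotropy analysis is not
  implemented.
* The calibration line is estimated from strain-level means; per-cluster
  efficiency estimates are not available from intensity data alone.
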