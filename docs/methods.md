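# Methods

`isletquant` quantifies β-cell functional development from volumetric
calcium-imaging recordings of the embryonic zebrafish islet, and from
GSIS/ensemble-calcium assays of cultured mouse islets.  Because the in
vivo measurements it targets are not redistributable, the package pairs
the analysis pipeline with a forward model — a synthetic-islet generator
whose presets are parameterised by published summary statistics — so that
every stage of the pipeline can be validated by round-trip recovery:
simulate with known ground truth, analyse blind, compare.

## The forward model

**Geometry.**  An islet is a sphere containing `n` β-cells of radius
`r = 3.5 μm` (β-cell diameter ≈ 7 μm); `n` is drawn from
N(`n_cells_mean`, `n_cells_sd`), rounded, floored at 1.  The islet radius
is set so that β-cells occupy `beta_fill_frac = 0.12` of the islet volume
(embryonic islets also contain α/δ cells, vasculature and interstitium;
this fraction makes the mantle and the core hold comparable cell numbers,
which the published per-compartment responsive counts at 72 hpf require).
Cell centroids are rejection-sampled uniformly with ≤10% sphere overlap.
Ground-truth compartments follow the outer-layer rule: a cell whose
centroid lies within one mean cell diameter of the islet surface is
*mantle*, otherwise *core*; a single-cell islet is mantle.

**Calcium transients.**  Glucose-responsive cells are drawn per
compartment.  Where the publication prints per-compartment responsive
*counts*, presets store those targets and each islet converts them to a
Bernoulli fraction `min(1, target/n_compartment)`, so the expected
recovered count equals the printed value independent of packing details.
A responsive cell's trace is `F(t) = F0·(1 + A·s(t))` with
`s(t) = (1 − e^(−u/τ_rise))·e^(−u/τ_decay)` (u = time since onset,
τ_rise = 8 s, τ_decay = 30 s, assumed — the publication shows transients
but no functional form), normalised so its sampled maximum is exactly 1;
the drawn amplitude `A` is therefore the exact Max ΔF/F0 of the
noise-free trace.  Onset is stimulus time plus a N(30 s, 10 s) delay,
truncated to the recording; neighbouring responsive cells share one
onset delay with probability `sync_group_prob` (0.3 by default).

**Amplitude distributions.**  `A` is drawn from a normal truncated at
the responsiveness floor (ΔF/F0 = 0.20), with the underlying mean
moment-matched so the *truncated* mean equals the printed stage mean.  A
"responsive" cell is by definition one with a supra-threshold transient;
truncating at zero instead would label sub-threshold cells responsive,
making the ground truth unrecoverable in principle and left-censoring
the recovered means.  Standard deviations are printed SEMs scaled by
√n_mid, with n_mid the midpoint of the published replicate ranges; the
registry flags these as approximations.

**Imaging.**  Recordings are T×Z×Y×X volumes at voxel size
(3.5, 0.8, 0.8) μm (z, y, x), one frame per second, mirroring optical
sectioning into ~12 planes.  Each frame: cells are rasterised at their
trace intensity over a background of 2 intensity units, convolved with
an anisotropic Gaussian PSF (σ = 1.8 μm axial, 0.6 μm lateral), then
acquired as the average of 5 exposures of Poisson shot noise
(`photon_scale` = 2 photons/unit) plus Gaussian read noise (σ = 2 units
per exposure).  The average of E i.i.d. Poisson draws is sampled exactly
as Poisson(E·λ)/E.  Bleaching is an optional exponential decay, off by
default (whether the original analysis bleach-corrected is unstated).
No noise statistics are published; these defaults give per-voxel SNR ≈ 40
on the basal image, consistent with an indicator described as having
very bright basal fluorescence.

**Vessels and glucose penetration.**  Vessels are polylines growing
inward from outside the islet; the deepest reaches exactly
`penetration × islet_radius` below the surface (0 at 48 hpf rising to
0.9 at 72 hpf; 0 in the avascular mutant).  Glucose entry is an explicit
finite-difference diffusion solve on a 2 μm grid with the islet surface
(and, optionally, vessels) clamped at the bath dose, plus a
Michaelis–Menten uptake sink; the sink makes *relative* penetration
dose-dependent, reproducing the qualitative supra-physiological (20 mM)
vs physiological (8 mM) contrast.  The default effective diffusivity
(1 μm²/s) is far below free glucose diffusion, standing in for tortuosity
and uptake; only qualitative/monotone conclusions are drawn from it.

**Secretion and ensemble calcium.**  Per-batch high-glucose secretion
and, for presets specified via the stimulation index, a per-batch GSI
are drawn from truncated normals with the published means/SDs; low
secretion is high/GSI, so both printed statistics are reproduced in
expectation (drawing low independently would Jensen-inflate the mean
recovered GSI).  Ensemble recordings simulate the sequential
0.5→2.8→16.7 mM protocol as whole-islet traces whose phase maxima are
drawn from the published percent-of-baseline distributions.

## The analysis pipeline

**Detection** runs on the average of all pre-stimulus frames (the basal
image), normalised to its mean (scale invariance).  Multi-scale
Laplacian-of-Gaussian filtering with per-axis sigmas handles the
anisotropic z sampling; peaks become watershed markers (minimum
separation 0.7× the expected diameter, ties broken by response then
linear index), and centroids are refined by intensity weighting over the
watershed regions.

**Traces and calls.**  F(t) is the mean over ROI voxels (extraction uses
spheres at 0.8× the expected radius to limit rim dilution and
neighbour bleed-through).  ΔF/F0 uses the first-frame F0 by default,
matching the study's definition; a pre-stimulus-mean mode is provided
because single-frame baselines are noise-sensitive.  A cell is
responsive when its post-stimulus maximum (180 s window — the response
is expected within 3 min) reaches `max(0.20, 5×baseline SD)`; the
threshold is inclusive and both knobs are exposed.  The original study
states no numeric criterion; 0.20 sits well below the smallest reported
responsive stage mean (53.4%).

**Stratification** re-derives mantle/core from detected centroids alone.
The islet centre is estimated by a least-squares sphere through the
convex-hull vertices, refined on the putative mantle shell and averaged
with the minimum-enclosing-ball centre; the surface radius is the mean
of the top-3 corrected order statistics of centroid distance (each
`d_(n−j)·((n+1)/(n−j))^(1/3)` is unbiased for a uniform-ball sample)
plus one known cell radius.  A plain inflated convex hull is *not* used:
with ~22 cells its facets cut ≈5 μm inside a spherical surface and
misclassify most of the core.  Detected equivalent radii are PSF-inflated
by ~20%, so stratification takes the expected cell radius as an argument,
like detection does.

Known limitation: the centre of the latent islet sphere can only be
located to ~1 μm from ~22 centroids (the minimum-enclosing ball is the
maximum-likelihood estimate under the uniform-ball model; sphere-fit and
jackknife ensembles plateau at the same error), and about half the cells
lie within ~1 μm of the mantle/core boundary under these conditions.
Label agreement with ground truth therefore tops out near 94%, not the
95% sometimes used as a rule of thumb; per-compartment *counts* remain
unbiased to within a fraction of a cell because misclassification is
nearly symmetric across the boundary.

**Statistics.**  Comparisons use the classical equal-variance Student
t-test (Welch optional) and one-way ANOVA followed by Dunnett's
many-to-one test; Dunnett-adjusted p-values are computed by seeded
Monte-Carlo integration (≥10⁵ draws) of the joint multivariate-t with
the design's exact correlation structure, which remains valid for
unbalanced groups, and are validated against quadrature and published
table values (k = 3, df = 20 → 2.54) in the tests.  Summaries treat the
islet (embryo) as the statistical unit: per-islet responsive count and
mean amplitude over responsive cells first, then mean ± SEM (sample
SD/√n) across islets; cell-pooled aggregation is available as a flag.
Significance stars follow p < 0.05/0.01/0.001 with strict inequalities.
The GSI is high/max(low, detection limit); the default ELISA floor is
0.1 ng/ml, chosen because adult low-glucose secretion (~0.27 ng/ml,
implied by the printed high value and GSI) was evidently measurable in
the original assay.

## What the generator does and does not emulate

It emulates: stage- and perturbation-dependent responsive counts and
amplitudes, the mantle-to-core progression, vessel ingrowth, frame-
averaged shot/read noise on PSF-blurred anisotropic volumes, mosaic
second-channel co-expression, and the secretion/ensemble-calcium arms.
It does not emulate: heartbeat/motion artifacts, tissue scattering or
depth-dependent aberrations, indicator kinetics beyond a fixed
double-exponential, cell movement or division during recording, or
non-β islet cells in the imaging channel.  Passing recovery tests
therefore demonstrates the pipeline is correct and unbiased under this
noise model — not that it is robust to motion or segmentation ambiguity
in real light-sheet data.

## Problem sizes

Recovery experiments use 12–16 islets per condition (matching the
published per-stage embryo numbers) of ~22 cells each, rendered at
~64×64×12 voxels × 220 one-second frames; detection-only checks use
50 islets of 60 frames; secretion checks use 1000 batches; ensemble
calcium uses 7 recordings of 1500 frames.  Deterministic seeding uses
`numpy.random.SeedSequence([base_seed, replicate])` throughout, so every
figure in the test suite and acceptance run is bit-reproducible.
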