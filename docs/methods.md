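# Methods

This note documents the models implemented in `memphys`, the choices made
where the methodology is genuinely open, and what the synthetic-data
validation does and does not establish.

## FRAP normalization and recovery fitting

Double normalization
R(t) = [(I−bg)/(I₀−bg₀)]·[(T₀−bg₀)/(T−bg)] uses pre-bleach means for all
"0" quantities.  Its purpose is twofold: R is unity before the bleach by
construction, and any multiplicative per-frame loss common to the bleached
ROI and the whole membrane (acquisition bleaching) cancels exactly.  Both
properties are enforced as tests.

The post-bleach curve is fitted with the empirical single-exponential
model R(t) = R(0) − a + a(1−b)(1−e^(−t/τ)) by bounded trust-region least
squares (a, b ∈ [0,1], τ ∈ (0, 10·t_max]; start a = R(0) − R(first post),
b = 0.2, τ from the half-recovery time).  Choices worth recording:

* **R(0) is fixed** to the pre-bleach mean rather than fitted.  The model
  has three parameters; a free offset trades against a and b and degrades
  identifiability.  Because the pre-bleach mean is itself an estimate, its
  variance (pre-bleach scatter / n_pre) is propagated into the parameter
  covariance via δθ = (JᵀJ)⁻¹Jᵀ1·δR₀.  Without this term the 95% CI for
  the immobile fraction covers the truth in fewer than half of simulated
  repeats; with it, empirical coverage is 93–94% (asserted at 90–99% over
  200 simulations).
* **Confidence bounds are covariance-based** (t-quantile × standard
  error), labeled as such in the JSON report; profile likelihood was not
  used.  Two conditions are compared by CI overlap.
* Fits are performed on the averaged curve; per-record fitting is
  available by simply fitting unaveraged curves.
* Degenerate immobile limits (b pinned at a bound, mobile amplitude
  a(1−b) below five noise SDs) are flagged rather than silently reported;
  τ is meaningless in that regime.
* τ is an empirical time constant, not a diffusion coefficient; no
  physical diffusion model is implied.

## Anisotropy and generalized polarization

r = (Ivv − G·Ivh)/(Ivv + 2G·Ivh) and GP = (I_blue − I_red)/(I_blue +
I_red) are pure intensity ratios.  The instrument factor G is always
supplied by configuration — it characterizes the detection path and cannot
be estimated from a single sample.  Array GP marks zero-sum pixels invalid
instead of raising, so isolated empty pixels do not abort an image.

## GP maps and domain segmentation

GP maps are computed after scalar background subtraction of both channels
(negatives clipped; pixels whose corrected sum is ≤ 0 are invalid).  The
high/low-GP segmentation applies one threshold to every image of a
comparison set.  A threshold "chosen by visual inspection" is not
reproducible, so the default rule is Otsu's threshold on the pooled GP
histogram of the whole set, which is deterministic and honors the
shared-threshold contract (segmenting the sets jointly or separately with
the pooled value is bit-identical; asserted).  A numeric override is
accepted and recorded.  Display look-up tables are presentation only.

## AFM force curves

Units: separation nm, force pN, modulus Pa (1 Pa = 10⁻⁶ pN/nm²).

**Contact point.**  The extension segment is modeled as a flat baseline
followed by a quadratic contact region; the breakpoint minimizing total
SSE is found by a coarse scan (≤ 256 candidates) refined locally.  The
baseline absorbs any constant force offset.  A curve whose maximum
deflection is under five robust noise SDs raises "no contact".

**Hertz fit.**  Four-sided pyramidal indenter,
F = [E/(1−ν²)]·(tan α/√2)·δ², with defaults ν = 0.5 (incompressible) and
face half-angle α = 35°, both configurable.  The fit range runs from
contact to the 1 nN load cap, mirroring the acquisition protocol.  With
the contact point fixed the model is linear in E, so the modulus is the
exact least-squares solution; a negative solution is clamped to zero and
flagged.

**Step detection.**  Two detectors run on every retraction segment:
(A) iterative step-function fitting — greedily insert the breakpoint with
the largest variance reduction while the inserted step height exceeds
k·σ, minimum segment length 5 samples, final heights re-estimated from the
piecewise-constant fit; (B) smoothed-derivative thresholding — boxcar
width 5, two-sided difference, |d| > k·σ with minimum event separation.
σ is estimated robustly as MAD(ΔF)·1.4826/√2; k = 3.  The default report
is the consensus (events found by both within 10 samples), which replaces
the non-deterministic "visual correction" step of interactive analysis.
On noiseless curves detector A provably coincides with exhaustive
breakpoint enumeration (asserted against a brute-force oracle); on flat
2 pN noise the false-positive rate is ≤ 0.05 steps/curve, and recall for
30 pN steps in 2 pN noise exceeds 95%.  Tether force is the step
magnitude (the "abrupt change in force"), not a plateau-to-baseline
difference; adhesive forces are negative on retraction and heights are
reported as magnitudes.

**Modulus-height profiles** use 25 equal-width bins over the observed
height range by default; binning is relative, so the zero reference of
the height axis is immaterial.

## Cell segmentation and per-cell fractions

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu foreground → h-maxima seeds
(h defaults to 10% of the smoothed dynamic range) → marker-controlled
watershed on inverted intensity → fragments under `min_area` merged into
their dominant neighbor → cluster splitting by distance-transform
watershed.  Two details depart from the simplest recipe, both because the
simple version demonstrably fails:

* a **foreground contrast guard** (foreground–background mean difference
  must exceed 4× the background SD) returns an empty labeling on images
  that contain only noise, where Otsu would otherwise hallucinate dozens
  of objects;
* the **cluster-splitting trigger** is not solidity alone: two equal
  disks overlapping by 20% of their area still have solidity ≈ 0.98, so a
  region is also split when its distance transform has two or more maxima
  deeper than 2 px (a single disk or a smooth ellipse has one).  Splits
  producing sub-`min_area` pieces are rejected.

Cells: seeded watershed on the smoothed membrane channel, seeded with
nucleus centroids (single pixels, so cell labels equal nucleus labels)
plus a background marker grown from the low-intensity region connected to
the image border; the cell/background boundary then settles on the crest
of the membrane staining.  Each cell's ring is thickened inward by
`thicken_px` (default 5 px at the simulator's scale — no physical width is
prescribed) to give the membrane mask; the remainder is the intracellular
mask.  The two masks partition the cell by construction, so membrane +
intracellular intensity equals whole-cell intensity exactly.  Cells
touching the image border are excluded from statistics (truncated masks
bias fractions).

Fractions are computed after scalar background subtraction (explicit
value, or the 5th intensity percentile when none is given) with negative
pixels clipped to zero; they are invariant to global multiplicative
scaling.  Endocytosed fraction = intracellular / (membrane +
intracellular); nuclear fraction = nuclear / whole cell (membrane
included).  Cells with zero total signal, or whose nucleus falls outside
any cell, are flagged and excluded.

## Synthetic data: what it emulates, and what it does not

Each generator inverts its analysis stage exactly in the noiseless limit
(asserted at ≤ 1e-10), and all randomness flows through explicit integer
seeds (bit-identical replay; no global state).

* **FRAP**: constant background, whole-membrane trace with multiplicative
  per-frame acquisition bleaching (0.2%/frame), bleached-ROI trace built
  so the double normalization returns the target recovery exactly;
  relative Gaussian noise (2%) applied last.  Defaults: 10 pre-bleach and
  150 post-bleach frames at 1 s.  Condition values: b = 0.15/0.45 —
  absolute levels are a design choice preserving the reported three-fold
  ratio (the source figures are graphical); a = 0.6 and τ = 15/30 s are
  typical magnitudes, likewise unprinted.
* **AFM**: per-curve modulus lognormal with median 614/459 Pa and σ fixed
  by σ² = 2 ln(mean/median) from the printed median/mean pairs
  (σ ≈ 1.018/1.048); contact point uniform in 1500–2500 nm and placed
  exactly on the sample grid; tether counts are rounded zero-truncated
  normals whose location is solved (Brent) so the truncated mean equals
  the printed mean with the printed SD as scale — naive truncation of the
  control distribution would inflate the mean by ~3%; step heights
  lognormal (σ_log = 0.3, a design choice with positive support that
  preserves the printed median); rupture separations uniform over
  300–3800 nm; 3000 samples per segment so that 11-tether curves rarely
  place two ruptures within the detector's resolution.  Gaussian force
  noise (2 pN) last.
* **GP images**: Gaussian-smoothed random field (length scale 8 px)
  thresholded at the quantile matching the preset area fraction; channel
  pair chosen so GP returns −0.55 in domains and −0.85 outside
  (microscopy-scale values; only their separation matters); 5%
  multiplicative photon noise, additive background 50 recorded in
  metadata.
* **Cell fields**: jittered-grid layout (no overlap by construction;
  an explicit shape that cannot hold the requested cells raises), radius
  24 ± 8% px, nucleus radius 10 px, membrane shell 5 px.  The membrane
  marker is a radial ridge peaking at the cell outline, so the watershed
  boundary lands on the true outline.  Ligand pools keep one pixel clear
  of the mask boundaries on either side, which makes the readout
  noise-limited rather than partial-volume-limited; per-cell true
  fractions are drawn with SD 0.05 about the preset and recorded.

Not emulated: physical diffusion during FRAP (image stacks are not
simulated — the record is constructed at the ROI-trace level), cantilever
dynamics and hydrodynamic drag, optical PSFs and shot-noise statistics,
irregular cell shapes, touching/overlapping cells, intracellular
structure.  Passing recovery tests therefore demonstrates correctness of
the estimators under their stated models, not robustness to every
real-microscope artifact; the segmentation margins in particular mean the
cell-field recovery exercises mask bookkeeping and watershed placement,
not sub-pixel boundary accuracy.

## Problem sizes

Validation uses the documented condition sizes: 500 retraction curves per
condition for tether statistics, 256 extension curves per condition for
moduli, nine 512×512 GP images per condition under one pooled threshold,
one 100-cell field per endocytosis condition, ten FRAP records per
condition.  One caveat: with σ_log ≈ 1.02, the sampling SD of a 256-draw
sample median is ≈ 8% of the median, so the recovered modulus medians
fluctuate by several percent between replicate seed blocks; this is a
property of the prescribed sample size, not of the estimator (per-curve
fit error is < 0.3%).

## Known limitations

* Consensus step detection merges ruptures closer than the detector
  resolution (~10 samples), slightly undercounting very tether-rich
  curves.
* Pooled-Otsu thresholding assumes the pooled GP histogram is bimodal; a
  set containing only near-uniform images would threshold noise.
* The watershed cell partition assumes one nucleus per cell and a closed
  membrane ridge; binucleate or ruptured cells are split or misassigned.
* Covariance CIs are symmetric and can cross parameter bounds for
  near-degenerate fits; bound-pinned parameters are flagged instead.
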