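# Methods

This document records the model behind each module, the default parameters
with their units and rationale, the numerical conventions, and the known
limitations. Nothing here is needed to *use* the package (see the README and
`examples/`); it is the reference for anyone auditing or extending it.

## 1. Cellular-automaton segmentation (`rvseg.automaton`)

### Model

Each pixel `p` carries a label (unlabeled / foreground / background), a
strength θ_p ∈ [0, 1], and a feature value: the slice intensity min–max
normalized to [0, 1]. At every synchronous step, each labeled neighbour `q`
(8-connectivity) attacks `p` with

    attack(q → p) = λ · g(|I_p − I_q|) · θ_q,     g(d) = max(1 − d, 0)

`p` is conquered by the strongest attacker whose attack *strictly* exceeds
θ_p, taking that label and the attacking strength. Updates are Jacobi-style
(all cells read the previous state), so the result is independent of pixel
visiting order; among equal-strength attackers the first in the fixed scan
order N, NE, E, SE, S, SW, W, NW wins, which makes ties deterministic.
Iteration stops when no pixel changes; because strengths are bounded by the
seed strength 1 and a pixel's strength never decreases, a fixpoint is always
reached, and in practice within tens of iterations (the hard cap is
rows × cols).

Seeded pixels start at θ = 1, the attainable maximum, so seeds are never
reconquered. This is the method's main robustness property *and* its main
failure mode: a seed pixel placed outside the target region is a permanent
error source. Hence the seeding policy below.

### Seeding policy (`init_labels`)

- **Foreground**: the rasterized seed polygon eroded by a disk of radius 2 px
  (`seed_erode_px`), insulating the automaton from small seed-drawing errors
  at the boundary. If erosion removes everything the seed is rejected with a
  request to draw a larger one.
- **Background**: the 1-px image border, plus every pixel farther than 10 px
  (`background_dilate_px`) from the seed whose temporal standard deviation
  across the cine phases is at or below the image median
  (`motion_percentile` = 50). The motion gate keeps background seeds off the
  beating heart even when the user's seed is drawn slightly off-centre.

`optimize_seed` runs the automaton and extracts the largest 8-connected
foreground component, fills its holes, traces the 0.5-level boundary,
resamples it to 120 vertices and lightly smooths it (one pass of a 3-point
circular moving average). If the refined area exceeds 4× the seed area the
result is flagged (`area_change_gt_300_percent`) — the typical signature of
a seed placed in homogeneous non-target tissue.

### Parameters

| name | default | units | rationale |
|---|---|---|---|
| `lam` | 1.0 | – | neutral attack gain; g already spans [0, 1] |
| `seed_erode_px` | 2 | px | tolerates ~2.5 mm of seed sloppiness at 1.25 mm pixels |
| `background_dilate_px` | 10 | px | keeps bg seeds ≥ 12.5 mm from the drawn contour |
| `motion_percentile` | 50 | % | static-tissue gate for bg seeding |
| `max_iterations` | rows × cols | – | theoretical worst case; never reached in practice |

## 2. Inter-slice propagation (`rvseg.propagation`)

### Alignment model

Adjacent short-axis slices are acquired in separate breath-holds and may be
translated relative to each other by several millimetres; toward the apex
the ventricle additionally shrinks and its cross-section drifts in-plane.
`align_adjacent` therefore searches jointly over integer pixel shifts within
a 10 mm radius (`search_radius_mm`) and isotropic scale factors 0.70–1.15 in
steps of 0.05 (`scale_search`), scoring normalized cross-correlation (NCC)
inside a window around the current contour (bounding box + 8 px margin).
The scale is applied about the window centre with linear interpolation;
among equal NCC scores the smallest shift wins (then scan order), so a
perfectly aligned stack yields shift (0, 0). A constant window (no intensity
structure) makes NCC undefined; the result is then (0, 0) with a
`degenerate` flag and the seed is transferred geometrically.

A pure-translation NCC search is *not* sufficient: when the anatomy shrinks
slice-to-slice, the best pure translation is biased by several pixels even
on a perfectly aligned stack, and a seed transferred at full size overshoots
the smaller blood pool — fatal, because automaton seeds are permanent. The
joint shift × scale search removes this bias, and the winning scale is also
applied to the transferred seed (about the window centre, then shifted),
i.e. the seed is moved by exactly the transform the matcher scored.

### Marching and fallbacks

From the user-seeded slice the pipeline marches basally and apically; each
refined contour becomes the next slice's seed. When alignment is disabled
or degenerate, the seed is transferred unchanged toward the base and shrunk
by √`apical_area_decay` (default 0.55, i.e. −45 % area per slice) toward the
apex — a deliberately conservative geometric prior: an undersized seed still
inside the blood pool is recovered by the automaton, an oversized one is
not. Slices whose refined area falls below `min_area_px` (10 px) are omitted
with a warning and the march stops in that direction, mirroring the clinical
convention of excluding sub-resolution apical cross-sections.

### LV attachment

`attach_to_lv` subtracts the left-ventricular epicardial polygon from the RV
polygon (exact polygon difference), implementing the convention that the RV
endocardial border runs along the septum rather than through it. Disjoint
inputs return the RV contour unchanged (`no_attachment` flag); a difference
that splinters into several pieces keeps the largest (`multi_junction`).

## 3. Volumetry (`rvseg.volumetrics`)

Simpson's rule in its clinical form: V = Σ_i A_i · (t + g), with A_i the
contour area from the shoelace formula scaled by the pixel spacing, t the
slice thickness and g the inter-slice gap (the gap volume is attributed to
the slice, the standard planimetric convention). EF = (EDV − ESV)/EDV × 100.
Slices omitted by propagation simply drop out of the sum; the per-phase
omission count is reported alongside.

## 4. Contour metrics (`rvseg.contour_metrics`)

- **Rasterization**: a pixel belongs to a polygon's mask when its *centre*
  lies strictly inside. This is deterministic, orientation-independent and
  exactly reproducible by an independent crossing-number (ray-casting)
  implementation, which the test suite exploits as an oracle.
- **Dice**: 2|A∩B| / (|A|+|B|) on masks; two empty masks score 1 by
  convention (perfect agreement about absence), empty vs non-empty scores 0.
- **Hausdorff distance**: contours are resampled to a uniform arc-length
  step of 0.25 mm (`DEFAULT_RESAMPLE_STEP_MM`) in physical coordinates, and
  the symmetric Hausdorff distance is computed between the vertex sets with
  KD-trees. The resampling bounds the discretization error of the
  polyline-vs-polyline distance by about one step.

## 5. Agreement statistics (`rvseg.agreement`)

Paired differences d = x − y are summarized as median (IQR, linear
interpolation percentiles), mean ± SD (ddof = 1), and Bland–Altman 95 %
limits of agreement mean ± 1.96·SD. Percentage differences use the pair mean
(x+y)/2 as denominator by default — symmetric in the two methods — or the
reference measurement y on request (natural for validity analyses against a
ground truth or manual standard); zero-denominator pairs are excluded and
counted.

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, and is
**exact** for n ≤ 12 remaining pairs: the two-sided p-value counts, over all
2ⁿ sign assignments of the observed ranks, those whose statistic
min(W⁺, W⁻) is at most the observed one. For larger n a normal approximation
with tie correction (Σ(t³−t)/48 variance reduction) and 0.5 continuity
correction is used. `run_protocol` applies the full battery to the
six-measurement observer design (M1, M2a, M2b, A1, A2a, A2b) yielding
inter-/intra-observer comparisons per method plus validity (A1 vs M1) for
EDV, ESV and EF.

## 6. Synthetic cine phantom (`rvseg.phantom`)

### Geometry

In-plane, the left ventricle is two concentric discs (endocardium radius
19 mm, wall 9 mm → epicardium 28 mm) and the RV blood pool is a **circular
lune**: a disc of radius 40 mm centred 24 mm from the LV centre, minus the
LV epicardial disc. The lune reproduces the RV's crescent cross-section with
a sharp septal attachment, has an exact closed-form area (disc area minus a
two-disc intersection term), and its boundary is constructed analytically
from the two circular arcs — so ground-truth contours are exact polygons,
not raster traces. A thin RV free wall (4 mm) surrounds the lune.

### Dynamics and calibration

Contraction scales the whole geometry by σ(p) = √(1 − c·w(p)), where w(p) is
a piecewise-cosine systolic weight (0 at ED, 1 at ES) and c the contraction
fraction; because areas scale as σ², the EF equals the RV contraction
fraction *exactly* (default 0.55 → EF 55.0 %). A quadratic apical taper
t_i = 1 − 0.57·(i/7)² scales each of the 8 ventricular slices. With 1.25 mm
pixels, 8 mm slices + 2 mm gap, the defaults give EDV ≈ 166.6 mL,
ESV ≈ 75.0 mL — volumes, EF and image geometry representative of a healthy
adult RV, which keeps the benchmark numbers interpretable on a clinical
scale.

Realism terms: three tissue intensity levels (blood 1.0, myocardium 0.35,
background 0.12, roughly SSFP-like contrast), additive Gaussian noise
(SD 0.04), and per-slice in-plane shifts drawn uniformly from a disc of
radius 2 mm, constant across phases — the breath-hold misalignment pattern.
Ground truth contours ride the shifted anatomy.

### What the phantom does not emulate

Partial-volume edges, intensity inhomogeneity and surface coils, papillary
muscles and trabeculation inside the blood pool, through-plane motion,
valve-plane descent, irregular RV shapes, arrhythmic phase sampling, and
Rician noise statistics. Results on the phantom are an upper bound on
clinical performance; the phantom's role is end-to-end verification against
exact ground truth, not realism.

### Seed perturbation

`perturb_seed` emulates a sloppy user contour: a smooth radial deformation
from 4 random Fourier modes, normalized so the maximum boundary displacement
equals the requested magnitude in mm, with a floor at 10 % of the original
radius and a retry loop (20 draws) guaranteeing a simple polygon.

## 7. Reproducibility and seeding

A single master seed is fanned out to every stochastic choice (per-subject
phantoms, per-run seed perturbations) through a splitmix64-style hash of
(master, path…) truncated to 31 bits, so cohorts are bit-reproducible,
subjects are independent, and adding a subject or run never changes earlier
ones. File formats are NIfTI (cine stacks; slice pixdim stores
thickness + gap, with the split recorded in a JSON sidecar), JSON (contours,
annotations) and CSV (volumes, metrics).

## 8. Known limitations

- The automaton assumes the seed lies inside the target blood pool; a seed
  across the boundary contaminates the result permanently (flagged, not
  repaired).
- Alignment searches integer shifts and a discrete scale ladder only;
  sub-pixel misalignment and rotation are uncorrected (both are below the
  automaton's tolerance on the phantom).
- The fixed apexward decay fallback (alignment off) handles shrinkage but
  not the in-plane drift of the apical cross-section; with alignment enabled
  this is handled by the shift search.
- Volumes use the slab-sum rule; no basal partial-slice interpolation.
- The exact Wilcoxon branch is O(2ⁿ) and capped at n = 12 by design.
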