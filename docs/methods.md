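# Methods

## The measurement

Cells suspended in buffer are driven by constant pressure through a linear
microchannel whose test section (width W = 18 µm, height H = 19.8 µm,
length L = 230 µm) is slightly narrower than the cells themselves.  Shear
and pressure forces deform the initially spherical cell into a bullet-like
shape as it transits.  High-speed brightfield imaging (15 000 frames/s,
0.97 µm/pixel, 1 µs exposure) records each transit across a region of
interest that extends five channel-widths upstream and downstream of the
test section.

Per frame, each detected cell contour is reduced to its projected area *A*
and perimeter *p*, and the deformation index

  DI = 1 − 2√(πA) / p

measures the departure from circularity: 0 for a circle, increasing with
elongation, and equal to 1 − √(4πA/p²), one minus the square root of the
usual circularity.  Per cell, the pipeline reports

* **D_c**, the undeformed diameter 2√(A/π) from the mean projected area over
  frames *before* the cell enters the test section (x < 0);
* **confinement** D_c/D_h, with D_h = 2WH/(W+H) ≈ 18.86 µm the hydraulic
  diameter of the rectangular duct;
* **DI_max**, the maximum DI over frames inside the test section
  (0 ≤ x ≤ L); deformation peaks before the exit plane, and this maximum is
  the cell's deformability readout;
* mean transit velocity from a least-squares fit of centroid x against time.

Population analysis gates cells to 0.85 < D_c/D_h < 0.95 (below the gate
cells barely deform; above it the cell surface risks wall contact), and
compares gated DI_max distributions with one-tailed Mann-Whitney U tests at
α = 0.01.  DI_max across a population is log-normal, which is why the
comparisons are nonparametric.

## Coordinate frame

x runs along the flow in micrometres with x = 0 at the test-section
entrance plane and x = L at the exit; the ROI spans [−mW, L + mW] with
m = 5 channel-widths by default.  Pixel (row, col) maps affinely to
physical (y, x) with pixel centres at half-integer offsets, so column 0's
centre sits at x = −mW + 0.485 µm at the default pixel size.  Subpixel
centroids are used throughout; "inside the test section" is evaluated on
the centroid (the natural choice given first-moment centroids; the
alternative, leading-edge position, differs by half a cell length and would
only shift profiles, not reorder them).

## Segmentation

1. Background: per-pixel temporal median over ≤101 evenly strided frames
   (requires ≥25 frames; a static background image can be supplied
   otherwise).  The median is robust to transiting cells, which occupy any
   given pixel in a small minority of frames.
2. Absolute difference |frame − background|, then a blank-frame guard:
   frames with fewer than 10 pixels above 10 % of dynamic range are
   returned empty without further work.
3. Gaussian smoothing (σ = 1 px) and a global Otsu threshold (a fixed
   threshold can be forced) give the detection mask; closing with a
   radius-1 disk (on an edge-padded copy, so objects truncated by the field
   of view keep their border pixels) and hole filling clean it up.
4. Connected components below an equivalent diameter of 7 µm are dropped as
   debris — far below the ≈16 µm gate floor, so the filter cannot bias
   gated populations.  Components touching the image border are measured
   but flagged and excluded from all per-cell summaries.
5. Measurement uses a *subpixel* closed contour per component, traced on a
   lightly smoothed difference image (σ = 0.5 px) at half the component's
   interior plateau contrast (half-maximum edge localisation).  Area comes
   from the shoelace formula on the contour, perimeter from polygonal arc
   length, centroid from polygon first moments.

Two measurement choices matter and are deliberate:

* **Subpixel contours, not pixel counting.**  A pixel-edge perimeter
  overestimates a disk's perimeter by up to ~27 %, which alone would push a
  rigid bead's DI far past the 0.024 calibration ceiling.  The half-maximum
  contour keeps the bead DI floor near 0.005.
* **Separate smoothing for detection (σ = 1) and measurement (σ = 0.5).**
  Heavy smoothing before contouring erodes high-curvature boundary
  segments (the bullet's rear shoulders) and biases the perimeter — hence
  DI — low by ~0.01 at DI ≈ 0.1.  At σ = 0.5 the static-shape DI error is
  within ±0.003 over DI 0.05–0.25, while detection keeps the stronger
  denoising.  The contour level is half the component's *own* plateau
  rather than the global threshold because Otsu's threshold drifts low when
  the foreground fraction is small, which would dilate contours and bias
  areas high.

## Tracking

Greedy nearest-neighbour linking with a velocity gate: a candidate in the
next frame must lie downstream of the track head by between v_min·Δt and
v_max·Δt (defaults 0 and 2× the nominal 0.3 m/s) with a bounded lateral
jump; ties within 1 px are resolved by smallest area difference, then
smallest ID.  New IDs are minted only in the upstream quarter of the ROI —
a cell is tagged when it first appears — so segmentation flicker cannot
create phantom mid-channel cells; mid-channel orphans are appended to the
nearest velocity-compatible track or dropped with a log entry.  Tracks
survive gaps up to 2 frames.  At the analysed occupancy (of order one cell
in the test section at a time) greedy matching is equivalent to global
assignment and easier to audit.

Frames where two or more tracks occupy the test section simultaneously are
flagged **coincident** on every involved track and excluded from all DI
readouts (neighbouring cells interact hydrodynamically); the raw rows are
kept.  A cell whose transit is only partially recorded is kept but marked
invalid and reported with a rejection reason; rejected cells are
first-class outputs because accept/reject accounting is the pipeline's QC
surface.

## Population statistics

* **Mann-Whitney U**: exact p by full enumeration when n₁·n₂ ≤ 400 and the
  pooled sample is tie-free, otherwise the normal approximation with tie
  and continuity corrections (scipy).  Tier ladder: ns (p > 0.01),
  \* (p < 0.01), ** (p < 0.001), *** (p < 0.0001), **** (p < 0.00001); the
  \* rung is an extension to make the ladder total, since published
  captions skip it.
* **Dose response / C_min**: a change "in either direction" must be
  detectable, so each dose arm is tested against control with both
  one-tailed alternatives and the pair is Bonferroni-corrected: significant
  iff 2·min(p) < 0.01.  C_min is the smallest significant dose; its
  direction labels softening (DI increases) or stiffening (DI decreases).
  The trend over doses ≥ C_min is classified by the same detection applied
  to successive dose pairs: no significant step → "No change"; all
  significant steps in the C_min direction → monotonic; anything else →
  "Non-monotonic".  Under a global null with four doses the family-wise
  false-positive rate is 1 − 0.99⁴ ≈ 0.039, verified by simulation.  No
  correction is applied *across* cell-line pairs in panel-style comparisons
  (raw pairwise tiers are reported); the within-pair Bonferroni is the only
  correction.
* **Pressure response**: ordinary least squares of mean gated DI on driving
  pressure; slope, intercept and R² are reported.  Means (not medians) are
  fitted; boxplot summaries report medians, quartiles and 10/90 whiskers
  with linear-interpolation quantiles, warning below n = 100.
* **Density contours**: 2-D Gaussian KDE (Scott bandwidth) on
  (confinement, DI), iso-contour at a fraction (default 50 %) of the peak
  density; contours enclosing less than four grid cells are discarded as
  aliasing artifacts of razor-thin ridges.
* **Manifold QC**: per-channel rigid-bead mean velocities must deviate from
  the grand mean by ≤3 %; channels with <20 beads warn, channels with zero
  beads fail coverage.

## Synthetic data generator

The generator renders ground-truthed transit videos so every stage is
testable without experimental data.  It emulates the study conditions:
rigid beads of diameter 15.13 µm with 6 % CV; deformable cells with
diameter 17 µm ± 8 % (placing a healthy fraction inside the confinement
gate) and log-normal DI_max (default median 0.10, log-σ 0.30, matching the
scale of gated epithelial-cell readouts at the 15 kPa working pressure);
transit velocity 0.3 m/s; Poisson arrivals at 100 cells/s.

Deformation is *planted*, not derived from fluid mechanics: each cell's
DI(x) is zero upstream, jumps at the entrance plane to 40 % of its DI_max,
rises linearly to DI_max at 0.85 L, holds to the exit, and relaxes
exponentially (length 60 µm) downstream.  This reproduces the qualitative
transit trajectory (entrance jump, monotone rise to a pre-exit maximum,
post-exit relaxation); the jump fraction, peak position and relaxation
length are fixture parameters, not physical claims — relaxation kinetics in
particular are not quantified by deformability measurements of this kind.
The DI–pressure mapping for multi-pressure fixtures is likewise a
user-supplied linear function, not a stress model.

Shapes form a one-parameter "bullet" family: a circular front cap, straight
sides of length e·r, and a rear half-ellipse flattened to semi-axis
r/(1 + e/2).  The family is convex, C¹, degenerates to a circle at e = 0,
and its polygon DI is strictly increasing in e, so a 1-D root-find realises
any feasible target DI; the family bound is DI ≈ 0.38 at e = 12, and
infeasible targets raise an explicit error.  The rear flattening is kept
gentle so boundary curvature radii stay on the order of a pixel — sharper
sub-pixel features would be unresolvable at the instrument's optics and
would make the planted DI unmeasurable in principle.  DI_max draws are
clipped at 0.32 to stay inside the family.

Rendering: cells are composited darker (level 0.32 of dynamic range) than
the background (0.72, with a low-order illumination gradient), emulating
dye-enhanced contrast; channel walls are drawn as static dark bands
flanking the test section only (the feeder sections are much wider than the
ROI) and cancel exactly in background subtraction.  Coverage is exact along
x (analytic scanline–pixel overlap) and 4× supersampled along y, so
renderer aliasing is negligible against measurement error.  Additive
Gaussian sensor noise (σ = 2 % of dynamic range) is applied per frame; no
motion blur is modelled (the emulated 1 µs exposure freezes 0.3 m/s motion
to 0.3 µm).  All randomness flows from one seed; per-frame noise uses a
generator keyed by (seed, frame index) so streamed and block rendering are
bit-identical.

**Arrival model.**  Poisson arrivals are hard-core thinned: consecutive
cells keep a minimum headway of the sum of their radii plus 5 µm, because
suspended cells exclude volume and cannot interpenetrate.  Co-transits of
the test section still arise naturally (the headway is ~20 µm against a
230 µm section).  Without the hard core, same-frame arrivals would render
as a single permanently merged peanut-shaped blob — an artifact no
per-track coincidence rule could remove, and one with no physical
counterpart.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: lateral migration and off-centre trajectories
beyond a small jitter; cell-to-cell hydrodynamic interaction (co-transits
overlap optically but do not perturb each other's shape); focus variation,
debris, and dead cells; shape response that actually depends on pressure or
cell stiffness; wall-induced deformation of over-sized cells (cells wider
than the channel are rendered with their free shape).  Recovery results on
synthetic data validate the *measurement chain*, not the biology.

## Numerical choices and degenerate inputs

* DI values that are negative by < 1e-9 (roundoff on near-perfect disks)
  are clamped to 0; larger isoperimetric violations raise, since no closed
  contour can produce them — they signal a perimeter-estimator bug.
* make_shape hits the target polygon DI by Brent root-finding (xtol 1e-10)
  and rescales to the exact target area; the renderer uses a cached
  257-point monotone lookup instead (realised-DI error < 2e-4, far below
  segmentation noise).
* Blank and saturated frames return empty observation lists, not errors.
* x-binning for pooled DI(x) profiles defaults to 10 µm bins with a
  centred 3-point moving average over occupied-bin means (shrunken windows
  at the ends); the alternative reading — smoothing along each cell's frame
  sequence — is noted but not used, since pooled bin means are what
  population profiles report.
* Quantiles are linear-interpolation (type-7); no convention is claimed
  beyond being stated here.
* Tracking tie-breaks (distance quantised by 1 px, then area difference,
  then ID) make linking deterministic.

## Problem sizes in the validation suite

The packaged validation runs use a 64-row sensor strip (the channel plus
walls occupy ~25 µm of image height, so the strip loses nothing) and scale
the recordings to: ~560 beads for the calibration ceiling; ten seeds of
~200 cells (2.0 s at 100 cells/s) for end-to-end parameter recovery; ten
seeds of ~60 cells for tracking fidelity; 100 replicates of a 150-cell,
control-plus-four-dose design for C_min power and 1000 replicates for the
null.  These sizes give comfortable Monte-Carlo margins for every asserted
bound while keeping a full run on one CPU in minutes.

## Known limitations

* The segmentation chain is a reconstruction of an off-line
  regionprops-style analysis; the exact published filter chains of any
  given instrument differ, and parameters here were chosen against the
  bead calibration contract, not against any real recording.
* Greedy tracking assumes dilute, unidirectional flow; it is not a
  multi-hypothesis tracker and has no appearance model.
* Per-cell DI_max is a maximum over noisy per-frame estimates and carries a
  small positive order-statistic bias (≲0.005 at default noise), partially
  offsetting the small negative contour-smoothing bias.
* No stiffness or Young's-modulus inversion is attempted; DI is reported
  as-is.  Ellipse-fit deformability metrics used by other cytometers are
  intentionally out of scope.
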