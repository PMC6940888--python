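# Methods

## The measurement problem

Very young broiler chicks (3–4 days old) handle feed with rapid beak
open–close cycles — *mandibulations* — whose kinematics depend on the feed's
particle size.  A feeding sequence runs: fixation, approach (head moves down
to the trough), grasping, withdrawal (head rises with the particle), then a
run of mandibulations through the stationing, transporting and swallowing
phases.  Because chicks cannot carry physical markers, the measurement has
to be marker-free: a lateral high-speed recording (250 fps here) is reduced
to per-frame head geometry by detecting natural landmarks — the eye (a dark,
highly circular blob) as the head reference point, and the two beak tips,
whose distance is the gape.

Per mandibulation the pipeline reports four variables:

* **maximum beak gape** (mm) — the largest upper-to-lower tip distance in
  the cycle;
* **head displacement** (mm) — the eye's cumulative 2-D path length over the
  cycle (the net start-to-end distance is also emitted as an auxiliary
  column, since "total displacement" is ambiguous and head jerks during
  swallowing vanish under a net measure);
* **time** (ms) — the cycle's frame count times 1000/fps; durations are
  deliberately frame-count-based, so detector failures are interpolated
  rather than dropped;
* **average head speed** (mm/s) — displacement divided by time.

Mandibulations are numbered 1, 2, 3 within each feeding sequence, with 4
standing for the fourth and every later cycle, starting right after the
withdrawal.  *Catch-and-throw* repositioning movements (augmented head
motion and beak aperture) are flagged per cycle.

## Vision chain

Per frame, four steps:

1. **Eye detection.**  Two-pass Otsu thresholding (the second pass restricted
   to the below-global-threshold pixels) isolates the darkest intensity
   class; connected components are filtered by area (0.4–2.5 of the expected
   eye-disc area) and circularity 4πA/P² ≥ 0.7, and ranked by circularity,
   then area, then smallest y, so the result is deterministic.  The centroid
   is the head reference point.  A Hough transform is deliberately avoided:
   the eye is the darkest compact blob in a lateral chick view, and the
   threshold+shape route is simpler and directly testable.
2. **Head ROI.**  A rectangle anchored at the eye: 14 eye radii toward the
   beak, 6 behind/above/below (the ROI must contain the whole beak),
   clipped at frame borders; the offset maps ROI coordinates back.
3. **Feed-particle removal.**  Otsu foreground in the ROI, components not
   4-connected to the eye's component dropped, then pixels inside the
   configured particle intensity band (default 60–120) excised.  A
   morphological opening is available (`particle_kernel ≥ 2`) but off by
   default — an opening blunts the thin beak-tip taper by about its kernel
   radius, which costs more accuracy than residual speckle.
4. **Beak-tip detection.**  Among cleaned foreground pixels at least 3 eye
   radii beyond the eye on the beak side, those within 3 px of the maximal
   extent are split into lobes by row gaps; each lobe's most distal pixel is
   its tip (upper tie-break: smallest y; lower: largest y).  A closed beak
   yields one lobe whose single distal point is returned for both tips,
   giving a near-zero gape.

Failed frames are flagged and filled by linear interpolation between
neighbouring detections; a sequence with more than 20 % failures is
rejected.  Calibration comes from a ruler image: median spacing of dark
intensity peaks along the tick axis (chosen automatically as the axis with
more peaks), needing at least three resolvable ticks.

## Cycle segmentation

The gape series is smoothed with a 3-frame moving average; peaks are local
maxima with prominence ≥ 0.3 mm, separation ≥ 4 frames, and height ≥ 1.0 mm.
The height floor is not redundant with prominence: between feeding
sequences the beak sits nearly closed at a sub-millimetre rest gape, and
those rest plateaus can carry ≥ 0.3 mm of prominence while no real beak
opening is anywhere near that small.  Cycle boundaries sit at gape minima,
never at zero — the beak never shuts fully at either end of a cycle.  Each cycle's end is the **earliest** frame within
0.15 mm of the inter-peak raw-gape minimum and the next cycle's start the
**latest** such frame: on a sharp V-shaped valley both rules give the same
frame (contiguous cycles), while a flat valley attaches to neither cycle and
ties resolve deterministically.  The reported peak frame is the argmax of
the raw (unsmoothed) gape inside the interval.

Feeding-sequence boundaries come from the eye track: an upward excursion of
≥ 2 mm completed within ≤ 50 frames, preceded by a downward approach
excursion (≥ 1 mm), detected with a 1 mm-hysteresis zig-zag over the
vertical eye position; the boundary opens where the steep rise flattens.
Boundaries closer than 30 frames are collapsed (two feeding sequences cannot
start that close).  An annotation file, when supplied, overrides the
heuristic entirely.  A cycle belongs to the sequence containing its peak
frame.

Catch-and-throw flags are annotation-first.  The built-in heuristic — flag
cycles whose max gape **and** displacement both strictly exceed their
episode medians — is an explicitly labelled convenience, not a claim to
reproduce visual identification; a single-cycle episode is never flagged.

## Statistics

Kinematic variables from feeding recordings are far from normal, so the
battery is nonparametric and implemented explicitly:

* **Spearman's rank correlation** — average ranks for ties, rho as the
  Pearson correlation of rank vectors, two-sided p from the t
  approximation with n−2 df (dataset sizes here are in the hundreds; an
  exact permutation p-value is available for n ≤ 10).
* **Mood's median test** — grand median of the pooled sample, 2×k table of
  counts above vs at-or-below it, Pearson chi-square with k−1 df.  Values
  equal to the grand median count in the at-or-below row by default (ties
  = "below"); "above" and "ignore" are offered because the convention is
  software-dependent.  Results carry a low-expected-count warning when any
  expected cell is below 5 and a degenerate flag when all values coincide.
* **Chi-square independence** on r×k count tables (expected counts from
  margins, no continuity correction) for catch-and-throw frequencies.
* **Descriptives** — mean, SE (sample sd/√n, missing for n = 1), and median
  (average-of-middle-two) per variable × order × feed; empty cells are
  absent, not zero.

No multiple-testing correction is applied by default (a Bonferroni helper
exists).  In tests, scipy's `median_test`, `chi2_contingency` and
`spearmanr` serve as independent oracles; the implementation never calls
them.

## Granulometry

Feed particle size is summarised by the geometric mean diameter and
geometric standard deviation of sieve-retained mass, base-10 logs
throughout: GMD = 10^(Σ Wᵢ log₁₀ d̄ᵢ / Σ Wᵢ), GSD = 10^√(Σ Wᵢ (log₁₀ d̄ᵢ −
log₁₀ GMD)² / Σ Wᵢ).  Class mean diameters are geometric means of adjacent
apertures; the pan pairs the finest aperture with a 38 µm floor
(configurable; an occupied pan with a zero floor is an error), and the top
sieve pairs its aperture with √2× itself, the usual sieve-ratio convention.
GMD is base-invariant; GSD is defined as 10^(log-sd) so a single occupied
class gives exactly 1.  Starter feeds of interest span roughly 0.4–1.3 mm
GMD (fine mash to crumble).

## Synthetic scenes and what they do (not) show

No feeding video ships with the package, so accuracy claims rest on
parameter recovery against a generator with exact ground truth.  A scene is
a bright background, a mid-gray head ellipse, two beak wedges hinged at a
vertex (symmetric rotation solved so the tip separation equals the scripted
gape exactly), a dark eye disc, feed particles at their own gray level —
one "grasped" particle tracking the tip region, the rest scattered — and
additive Gaussian noise applied **after** ground truth is recorded.  The
default frame is 384×256 px at 0.1 mm/px (a quarter-scale stand-in for a
1536×1024 recording), 250 fps, noise sd 3.  Gray levels are pairwise
separated by ≥ 20 units.  Scripts are built from episodes (approach down,
withdrawal up, then cycles); cycle gape profiles are unimodal with a fast
first opening step (≥ ~0.5 mm) so cycle starts are sharp minima even under
pixel quantisation, boundary gapes stay positive, and inter-sequence rest
gapes sit near 0.8 mm.  Head jitter is stationary around the trough
position (it wanders but does not drift), larger in first mandibulations
and in catch-and-throw cycles.

The default batch is the package's reference recording design: 19 birds ×
3 feeds = 57 sequences; scripted per-feed mandibulation totals 576 (F1, fine mash),
602 (F2, coarse mash), 551 (F3, crumble); catch-and-throw probabilities
0.26/0.20/0.33 per feed; per-feed, per-order central peak gapes (2.5–4.3 mm)
and cycle lengths (14–26 frames, i.e. 56–104 ms) at the scale reported for
chicks of this age.  These defaults are the study conditions, not tuning
knobs.

What passing recovery tests show: the vision chain localises the landmarks
it was built for, the segmentation boundary rule is exact on cycles whose
openings are fast relative to the frame period, and the bookkeeping
(orders, durations, identities) is correct.  What they do not show:
robustness to plumage texture, motion blur, shadows, out-of-plane head
rotation, tongue visibility ("slide-and-glue" is invisible to silhouette
analysis anyway), or particles whose gray level overlaps the head's —
the generator's distinct particle band is a stand-in, since visual criteria
separating feed from beak in real footage are not modelled.

## Numerical choices and degenerate inputs

* Pixel coordinates are 0-based, x rightward, y downward; frame intervals
  are half-open [start, end).  Displacement sums eye motion over all
  n_frames frame periods of the interval (the final step crosses into the
  frame that starts the next cycle, clamped at the series end), which makes
  speed × duration ≡ displacement hold exactly and keeps a 20-frame cycle
  at 0.5 px/frame equal to 1.0 mm and 12.5 mm/s.
* Eye candidate ties: circularity, then area, then smallest y.  Tip ties at
  equal extent: extreme y toward the lobe's outer edge.
* Segmentation boundary tolerance 0.15 mm (≈1.5 px at default scale):
  larger than quantisation error, far smaller than any real gape change.
* Constant stats input → flagged NaN result rather than an exception;
  all-identical Mood input → degenerate flag; zero contingency margins →
  hard error.
* The per-sequence failure budget (20 %) and the particle band (60–120) are
  scene-scale defaults; every parameter is a dataclass field.

## Problem sizes

The acceptance run and the test suite regenerate everything: the
study-scale batch (57 sequences, ≈43 000 frames) once, a 12-sequence
noise-free batch for segmentation counts, a 50-scene particle-removal
batch, 1000 null simulations for the type-I error of Mood's test, and 100
random datasets per oracle comparison.  These sizes keep a full run in the
minutes range on one core while leaving every per-record criterion at the
full n = 1729.

## Known limitations

* The generator's head is rigid; cranial kinesis (coupled upper-jaw motion)
  is only mimicked by symmetric wedge rotation, so beak-angle analyses are
  out of reach — tip distance is the gape measure, as in the target
  workflow.
* Withdrawal detection assumes feeding sequences separated by a clear
  down–up head excursion; grazing-style continuous feeding would need
  annotations.
* The catch-and-throw heuristic is intentionally crude; per-feed percentage
  recovery in the validation batch uses the scripted flags, not the
  heuristic.
* Speed is displacement/time by definition; no attempt is made to
  reconcile externally reported speed tables whose units are internally
  inconsistent.
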