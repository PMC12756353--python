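# Methods

## Input model and coordinate convention

The unit of analysis is an ordered, labelled sequence of 3D centroids of
vertebral bodies and intervertebral discs from L5 (caudal) to C7 (cranial)
— 18 vertebrae and the 17 intervening discs, 35 landmarks in all — in
millimetres. Coordinates are right-handed and patient-anatomical: +x the
patient's right, +y cranial, +z posterior. Under this convention a
right-convex curve has positive lateral displacement, thoracic kyphosis a
positive sagittal mean and lumbar lordosis a negative one. Per-centroid
rotation angles may be present in input files; they are carried as
metadata and consumed by no computation.

The disc at the lumbar→thoracic transition (the LT disc) splits the spine
into its two analysis regions. It is identified by label, `T12/L1` by
default, overridable per file (`--lt-label`) because the transition is an
anatomical judgement, not a property of the coordinates.

## Normalisation

Before any measurement the spine is mapped to a canonical frame: translate
L5 to the origin, rotate the L5→C7 chord onto +y by the minimal rotation
(axis = chord × ŷ), and scale uniformly so the chord measures 500 mm. The
transform is rigid plus isotropic scaling, so deformity shape is
preserved; "vertical height" is read as the straight chord, not the arc
(the difference is second order for near-vertical spines). The minimal
rotation leaves no residual axial freedom unless the chord is already
vertical, in which case the identity is applied; no further axial
re-orientation is performed, so inputs are assumed expressed in a
patient-anatomical frame. The applied rotation and scale are recorded for
audit. Degenerate input (L5 coincident with C7) is rejected.

## Interpolation and projections

The centroid polyline is interpolated with a cubic spline (natural end
conditions — the conventional default where nothing constrains the end
curvature) parameterised by cumulative chord length through all nodes,
the closest practical surrogate for arc length at this node density.
Resampling to 1 mm arc steps is approximate: the spline is evaluated on a
0.1 mm parameter grid, cumulative arc length is accumulated along that
fine polyline, and samples are taken at 1 mm arc targets by linear
interpolation in the parameter. This keeps spacing errors well below 1%
without root solving. Samples at or below the LT node's arc position are
lumbar, the rest thoracic — a curve-based split that remains correct for
decompensated spines that fold back in height.

Projections drop one coordinate: frontal = (x, y), sagittal = (z, y)
(the view from the patient's left), axial = (x, z). Planar curvature is
κ = |d′h″ − h′d″| / (d′² + h′²)^{3/2} with derivatives by central finite
differences on the 1 mm sampling (one-sided at the ends). No smoothing is
applied by default; an odd-length moving-average window is available.
Curvature is computed per projection because the colour-coded report is
planar; interior accuracy on analytic benchmarks (circular arc, sinusoid)
is a few tenths of a percent, but the natural end conditions ring for
roughly 100 mm from each endpoint, so endpoint-adjacent curvature should
not be over-interpreted.

## Dispersions and indices

The four quadrant dispersions of the frontal projection are RMS lateral
displacement **about zero** (the vertical reference line), not about the
quadrant mean. This is a deliberate reading: the quantity is motivated as
displacement from the expected vertical projection, and a mean-centred
standard deviation would score a uniformly offset curve as no deformity.
The conventional mean-centred alternative is available via
`ThresholdConfig.std_about_mean`. Samples exactly on the line belong to
neither side (any assignment would be arbitrary), and an empty quadrant
scores 0 by definition. Indices are computed on the 1 mm interpolated
samples, not on raw centroids, so each region's sample count is
proportional to its arc length.

s, v and kl follow the formulas in the README. s and v are undefined
(reported as null) when all four dispersions vanish; kl when the two
regional means coincide. kl can leave [−1, 1] when both regional sagittal
means share a sign (a uniformly kyphotic or lordotic spine); such values
fall into the outermost interpretation band.

## Classification bands and text

The default bands are in the README table; all are configurable and the
configuration digest is embedded in every report. Boundary conventions:
severity bands are lower-inclusive; |s| ≤ 0.5 reads both-sided; the
transitional vertical band [−0.25, +0.25] is closed (so the neighbouring
bands are open at that edge); the sagittal bands partition [−1, 1] with
the extreme-kyphosis band (0.65, 1.00]. The printed source of these bands
lists extreme kyphosis as beginning at +0.30, overlapping two other bands;
the only reading under which the seven categories are disjoint and ordered
starts it at +0.65, and that is what is implemented.

The description is templated: `<Severity> <side> <vertical> scoliosis with
<sagittal>.`, the sagittal clause omitted in the normal band. Below the
first severity bound there is no scoliosis: the side/vertical words are
suppressed (labelled n/a) and the text collapses to "Normal spine." or to
the sagittal label alone — though the numeric s and v are still reported,
since hiding computed values would hide auditable data. The transitional
spelling is canonically "thoraco-lumbar"; a message catalog lets clinics
re-word any label (including "thoracolumbar") without touching the index
values.

## Lenke concordance

Lenke curve types map to compatible vertical categories (1, 2 → thoracic /
mainly thoracic; 3, 4 → mainly thoracic / thoraco-lumbar; 5 → lumbar /
mainly lumbar / thoraco-lumbar; 6 → thoraco-lumbar / mainly lumbar;
Normal → a no-scoliosis output), and sagittal modifiers to compatible kl
categories (+ → significant/extreme kyphosis; N → normal spine / slight
kyphosis / slight lordosis; − → none, so a hypo-kyphotic modifier is never
concordant). Lordotic outputs (extreme or significant lordosis) have no
Lenke counterpart and are pooled into a "/" group regardless of the
modifier; a Lenke Normal patient, who carries no modifier, is scored
against the N band — the only partition consistent with every patient
occupying exactly one row of the sagittal table. Lumbar modifiers A/B/C
are parsed but unused: they reference the central sacral vertical line,
which centroid sequences ending at L5 cannot locate.

The chi-square statistic is the classic Σ(O−E)²/E with expected counts
from the margins, df = (r−1)(c−1), and an upper-tail p-value; the overall
percentage agreement is 100 × validated / total. Tables with a zero row or
column margin are rejected rather than silently patched. The observed
tables of the 94-patient reference validation cohort ship with the package
so the agreement statistics are reproducible without the restricted
clinical data.

## Synthetic spines

The generator emulates the geometry the pipeline consumes, not vertebral
anatomy: a 500 mm template with uniform level spacing (anatomical spacing
tables would add realism but no test power), a lordotic lumbar / kyphotic
thoracic pair of half-sine sagittal arcs (defaults 25 mm and 30 mm deep —
a normally balanced profile, kl ≈ 0.1), and a lateral arch peaking exactly
at the chosen apex vertebra with quarter-sine rise and fall over a 90 mm
half-width (a structural curve spanning about six levels). The arch form
keeps the analytic RMS over its support at amplitude/√2 while pinning the
displacement maximum to the apex label. Independent Gaussian noise (mm) is
added per coordinate, reproducibly from the seed. The default amplitude,
15 mm, lands in the very-significant severity band, the modal class of the
reference cohort; cohort mixes draw amplitudes 0–60 mm, spanning the whole
ladder.

What the generator does **not** emulate: vertebral geometry and axial
rotation (no rib-hump), anatomically graded level spacing, double curves
beyond a simple half-amplitude counter-bump, and measurement error that is
spatially correlated along the spine. Tests passing on these spines
therefore establish the internal consistency and statistical behaviour of
the pipeline, not clinical accuracy on scanner-derived centroids.

Two identifiability limits shaped the test design. First, recovery cohorts
draw apex levels clearly inside one region (L3–L2, T9–T5): for an apex at
the transition itself the region containing the apex can legitimately have
the smaller RMS once each region's zero-displacement samples dilute it, so
a v-sign "ground truth" would be ill-posed. Second, apex recovery counts
the reported lateral apex at the true apex vertebra *or an adjacent disc*:
with 15 mm landmark spacing, the no-noise displacement gap between the
apex vertebra and its neighbouring discs is a fraction of a millimetre at
clinical amplitudes, so under millimetre-scale independent noise the
argmax between those neighbours is not identifiable — the adjacency
criterion is the strongest claim the data support.

## Numerical choices and limitations

* Ties in apex selection break to the more caudal centroid.
* Dispersion/index values are deterministic functions of (input, config);
  reflection of the input negates s exactly and leaves v, kl and the
  dispersion maximum unchanged to ~1e−12 (floating-point rounding, not
  model error).
* Halving the 1 mm sampling moves large quantities by well under 0.5% and
  near-zero index values by < 0.005 absolute; near-zero quantities are
  compared absolutely because relative error is ill-conditioned there.
* Quadrant RMS values are diluted by near-zero spline samples inside a
  quadrant (e.g. spline ringing adjacent to a curve), so the effective
  RMS-to-amplitude ratio of a single arch on a full spine is ~0.56 rather
  than the 0.707 of the isolated arch; severity bands apply to the
  dispersion values as computed.
* The report renderer is deterministic given the Agg backend; κ saturates
  the colour map at 0.02/mm (50 mm radius) by default, configurable
  because strain normalisation is a presentation choice.
* No Cobb angles are computed anywhere; the severity bands are descriptive
  and deliberately not aligned with Cobb-based clinical thresholds, and
  the tool's output is not a medical diagnosis.
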