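# Methods

## Model and assumptions

`mousetrack` is a tracking-by-detection pipeline for a fixed overhead camera
over a square open-field arena. It assumes: (i) the camera is distortion-free
and square to the arena, so a single isotropic scale `px_per_cm =
arena_px / arena_cm` calibrates both axes; (ii) animals are darker than the
background (dark-coated mice on a white arena); (iii) the number of animals
`n` is known and constant; (iv) detections are per-frame and independent —
no motion model is used, identity rests entirely on appearance.

The pipeline is detector-agnostic: any callable mapping a frame to a list of
mask regions can replace the bundled threshold segmenter (for example,
polygons exported by an external neural detector and replayed through the
VIA-annotation reader). Everything downstream — fingerprinting, matching,
correction, analytics — only consumes masks and centroids.

## Fingerprint

A detection's binary mask is *buffered*: dilated `dilation_iters` times with
a square `dilation_kernel`, convolved with a separable Gaussian of size
`blur_kernel` (σ = 0.3·((k−1)/2 − 1) + 0.8, the conventional σ for a given
kernel size), and thresholded strictly above zero. The buffered support
therefore grows by `iters·(kernel//2) + blur//2` pixels. The frame is
cropped to the buffered support's bounding box, pixels outside it are zeroed
and excluded, the crop is downscaled by integer-factor block averaging
(`downscale`, default 4) and converted to grayscale (luma weights
0.299/0.587/0.114 for RGB input).

For every unordered pair of included pixels the Euclidean distance `d` and
intensity sum `s = I(p) + I(q) ∈ [0, 510]` fall into bin
`(min(⌊d/max_dist_px·n_dist_bins⌋, n_dist_bins−1), ⌊s/511·n_sum_bins⌋)`.
Self-pairs are excluded (they would add an uninformative d = 0 spike
proportional to area). Counts are normalized to unit mass so patches of
different sizes are comparable — without normalization the mean absolute
difference would be dominated by patch size rather than appearance. The bin
structure (32×32 uniform bins, distance domain [0, 64 px] with an overflow
bin) is a design choice of this package and is exposed in the configuration;
so is an optional seeded `max_pairs` subsample for very large regions (off
by default: quarter-scale mouse crops hold ~1–3 k pixels and the exact
O(k²) enumeration stays tractable).

Only the mask is blurred during buffering; image intensities are sampled
unblurred. Contour expansion (+5 px disk dilation) and Ramer–Douglas–Peucker
simplification (ε = 1.5) are applied to detections for annotation-style
polygon output; the fingerprint and the centroid are computed from the raw
detected mask, which avoids biasing appearance with background pixels that
simplification would admit.

## Matching

All (ID, detection) dissimilarities are sorted ascending and accepted
greedily: a pair is taken iff neither its ID nor its detection is already
used, until min(n, #detections) pairs are accepted. This
first-and-second-lowest-wins rule is deliberately *not* optimal bipartite
assignment — on the matrix [[0.1, 0.2], [0.15, 0.9]] greedy picks
0.1 + 0.9 while Hungarian would pick 0.2 + 0.15 — and the test suite pins
that distinction. Exact ties are broken by (lower ID, lower detection
index), a convention chosen for determinism. Each matched ID's reference
fingerprint is replaced by the new detection's (adjacent-frame comparison);
a missed ID keeps its last real fingerprint until it reappears.
Initialization assigns IDs 0..n−1 to the n largest detections of the first
frame that has at least n, ordered by (centroid_y, centroid_x).

## Correction

*Miss filling* carries an ID's last record forward (coordinates and area
held constant, `filled = 1`) through gaps of at most `max_gap` frames
(default 60 = 1 s at 60 Hz); longer gaps are structural, reported and left
open. Carry-forward rather than interpolation keeps the operation causal and
conservative. *Warnings*: for each consecutive frame pair and each ID i, if
some other ID's frame-N+1 position is strictly closer to i's frame-N
position than i's own new position, frame N+1 is flagged for review. The
per-ID reading of "closest" is used (warn i when some j beats i for i's own
previous position); exact ties do not warn, since over-warning is the
costlier failure for a human-in-the-loop step. Warnings never trigger an
automatic swap — near passes outnumber real switches, and a wrong automatic
exchange would corrupt the remainder of the track. A human-confirmed
`SwapDirective(frame, a, b)` exchanges the two labels from that frame to the
end (irreversible-switch semantics); applying it twice is the identity.

## Analytics

Geometric center = arithmetic mean of mask pixel coordinates, computed at
full resolution. Cumulative travel distance is the raw sum of per-frame
steps in cm — no smoothing or minimum-step floor, so the output reflects the
tracks exactly; filled frames contribute zero-length steps by construction.
Proximity uses a strict `< 6 cm` threshold on center distance; a frame at
exactly 6.0 cm is not proximate. Filled frames are included in proximity
counts (they carry coordinates); `behavior_summary` operates only on
corrected tables so every frame has all n animals.

## Synthetic scenes

The generator emulates the target recording geometry: a 640-px (32 cm,
20 px/cm) bright arena (intensity 230, Gaussian noise σ = 3) with n
elliptical animals of 8 cm × 3 cm body size — about 160 px long,
comparable relative to the arena to a mouse in a 1080p top-view rig — at
60 Hz. Motion is a persistent random walk: per-frame heading jitter
(σ = 0.2 rad), speed an autoregressive walk clipped to [0.5, 6] px/frame
(≤ 18 cm/s), reflecting walls, and a deterministic pairwise push that keeps
center separations above twice the semi-major axis so rendered masks never
merge. Coat textures are per-animal seeded multiplicative noise fields
(±25 %, Gaussian-smoothed) fixed in the body frame and rotated with heading;
base intensities are spaced over 40–90. All randomness derives from the
scene seed through independent named substreams, so frames can be rendered
lazily in any order and are byte-reproducible.

Injected errors mirror the two failure modes of real detectors: a *miss*
omits an animal from the render for one frame; an *appearance swap*
permanently exchanges two animals' textures at a frame, which makes any
appearance-based tracker exchange their IDs while the true positional
identities continue — an irreversible ID switch by construction. Ground
truth logs virtual mask statistics for every animal on every frame (missed
animals still exist), a cumulative path-length ledger, and the event log.

What the generator does **not** emulate: partial occlusion and merged blobs
(contacting animals), limb/tail articulation and pose changes, lighting
drift, shadows, motion blur, and infrared night-recording noise. Synthetic
animals also never approach closer than ~8 cm center-to-center, so the
bundled scenes exercise the proximity statistic only through constructed
tables. Passing tests therefore demonstrate the correctness of the
fingerprint, matching, correction and analytics machinery — not detector
robustness on real video, where a trained instance-segmentation model and
human review of warnings carry that burden.

## Evaluation

`evaluate_tracks` maps predicted IDs to truth animals by the fixed
one-to-one assignment minimizing total centroid distance over all frames
(Hungarian on the summed distance matrix), then reports per-frame centroid
errors (cm) with the fractions below 0.5 cm and 1.5 cm, the miss percentage
(animal-slots without a predicted or filled record), and the switch count —
the number of frames where the per-frame optimal predicted-to-truth
assignment changes relative to the previous frame, so one persistent
exchange counts once.

## Problem sizes and numerical choices

Verification scenes use 3 animals × 600 frames (10 s at 60 Hz), which the
package processes in well under a minute per run; examples use 300 frames.
RDP on closed contours splits at the two mutually farthest vertices (first
pair in row-major order on ties) and simplifies each open chain with the
classic recursion; ε = 0 returns the input unchanged, and a fully collinear
polygon degenerates to its two extreme vertices. Connected components use
8-connectivity to avoid splitting thin diagonal limbs. Track CSVs serialize
floats with `%.17g` (round-trip exact) and booleans as 0/1; manifests
contain no timestamps, so identical runs are byte-identical.
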