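# Methods

`pelviseg` implements a sequence-aware, semi-automated segmentation of bone
in axial pelvic CT stacks. The driving observation is that adjacent CT
slices are highly similar, so an expert only needs to mark the few slices
where the bone topology — the number and arrangement of bone cross-sections
— visibly changes. Those *key frames* are found automatically; their
(corrected) segmentations are then propagated to every other slice by a
watershed transform seeded with skeleton markers.

## Pre-processing

Raw CT values (Hounsfield units after the DICOM rescale transform) are
compressed to 8 bits through a display window of width `w` and level `c`:

    f(x) = 0                        for x <= c - w/2
         = (x - (c - w/2)) * 255/w  inside the window (rounded half-up)
         = 255                      for x >= c + w/2

The default is the bone window `w = 600`, `c = 900` Hu. The windowed slice
is binarized (non-zero → 1), cleaned with a 3×3 morphological closing then
opening, and the largest 8-connected component is kept as the body mask;
everything outside it (CT table, cables) is zeroed. All slices are then
cropped to one sequence-global bounding box (default margin 2 px) so that
every later stage sees same-shaped images.

Choices worth noting: the structuring element (3×3 square, closing before
opening) is the smallest that removes cable-thin artifacts without bridging
the table into the body; the crop box is global rather than per-slice
because the inter-slice similarity measures require identical shapes. The
binarization step presumes that air windows to exactly 0, which holds for
calibrated CT under a bone window; on images whose background carries
additive noise the body mask over-grows (see Limitations).

## Key-frame extraction

Stage 0 — *interesting image*. Each slice is Gaussian-smoothed (σ = 1 px,
kernel truncated at 4σ), decomposed with a single-level 2-D Haar transform,
and reconstructed from the approximation band alone. The reconstruction is
thresholded at `T1`, the mean of its non-zero pixels, and the resulting
binary mask multiplies the smoothed slice. This isolates the bright,
bone-dense region and suppresses background detail, so the slice-to-slice
difference signal is driven by bone, not by tissue or noise.

Stage 1 — *candidates*. `Dif_i` is the sum of absolute differences between
consecutive interesting images. With `T2 = 0.7 · mean(Dif)`, slice `i+1`
becomes a candidate whenever `Dif_i > T2`. The deliberately low factor 0.7
over-selects: missing a key frame is costly, carrying a redundant candidate
is cheap. Slice 1 is always retained (the selection rules only ever admit
the second member of a pair, and the head of the sequence needs a key frame
to match against).

Stage 2 — *target set*. On the pre-processed slices (not the interesting
images), mutual information is computed between each pair of consecutive
candidates; with `T3` the mean of those values, the second frame of every
pair with `I ≤ T3` (dissimilar — low gray-level dependence) survives to the
intermediate set. The same mean-threshold rule is then applied with the
normalized correlation coefficient (`T4` = mean NCC over consecutive
intermediate frames) to drop frames that are spatially redundant. Both
thresholds are fixed from a single initial pass; ties (value exactly at the
threshold) pass. Mutual information is computed on a 256×256 joint
histogram in bits; the logarithm base only rescales `T3`, so the mean rule
is unaffected by it.

The cascade has no recall guarantee: the thresholds are means of the very
distributions the changes belong to, so when a sequence's changes dominate
the candidate set (very clean, noise-free data) the weakest change can fall
on the wrong side of the mean. This is inherent to the single-sweep design;
the target-set size, in exchange, self-adapts to sequence complexity and
lands near 10–15 % of slices on the synthetic sequences here.

## Interactive marking

Each target key frame receives a first-guess bone mask (the same
`T1`-threshold machinery applied to the slice's wavelet approximation),
converted to watershed markers, refined by the watershed, and — in clinical
use — corrected by an expert. The package exposes this as a programmatic
API: point edits `{add: [(row, col, label)], remove: [(row, col)]}` applied
to the marker image, after which labels are renumbered so foreground
components are `1..K` and the background marker is `K+1`. Ground-truth
masks can also be supplied directly, which is how the synthetic experiments
emulate a perfect expert.

## Skeleton extraction (thinning)

Markers are skeletons produced by two-subiteration thinning. With the
neighborhood indexed

    p9 p2 p3
    p8 p1 p4
    p7 p6 p5

a foreground pixel is deleted when `2 ≤ n(p1) ≤ 6`, `s(p1) = 1` (one 0→1
transition around the circle, so deletion cannot split a region), and the
direction products `p2·p4·p6 = p4·p6·p8 = 0` (first subiteration) or
`p2·p4·p8 = p2·p6·p8 = 0` (second). Deletions are applied simultaneously
per subiteration; the two subiterations alternate to a fixed point. Pixels
outside the image count as background. The scheme's classical quirk — an
isolated 2×2 block vanishes entirely — is kept; marker generation re-seeds
any foreground component that lost all skeleton pixels with its centroid
pixel, so every component is guaranteed a seed.

## Marker-based watershed

The flooding surface is the L2 magnitude of the Sobel gradient (3×3
templates, replicate padding). Markers are the skeleton of the reference
foreground (one label per 8-connected component) plus the skeleton of its
complement as a single background label. Minima imposition forces the
surface's regional minima to be exactly the marker set: marker pixels are
set strictly below the global minimum and every other minimum is removed by
grayscale reconstruction-by-erosion (8-connectivity).

Flooding conventions, fixed here because the transform itself does not
dictate them, and mirrored exactly by the brute-force oracle in the tests:
8-connected claims served in increasing (surface value, FIFO) order,
neighbors claimed in raster order of the 3×3 neighborhood; a pixel claimed
by two different labels before it is first served becomes a watershed ridge
(label 0); ridge pixels still propagate the earliest claiming label so
enclosed plateaus remain reachable; marker pixels keep their labels. The
bone mask is the union of foreground-labeled basins; ridge pixels are not
part of it. Contours are traced per foreground basin with Moore-neighbor
tracing, clockwise from the topmost-then-leftmost pixel, as whole-pixel
coordinates.

A consequence worth stating plainly: the one-pixel watershed line between a
bone basin and the background basin falls *on* the blurred intensity step,
and roughly half-to-60 % of it lands on truth-bone pixels. The overlap cost
of this line is ≈ perimeter/(2·area) per bone — about 6–8 % for a 20–25 px
cross-section, vanishing for larger ones. Segmentation accuracy at a given
image scale is therefore bounded by bone size in pixels, not by the
algorithm's parameters.

## Propagation

Every slice is matched to the key frame with maximal NCC (whole target set
searched; ties break to the anatomically nearest, then smallest index), and
segmented with markers derived from that key frame's mask. Key frames are
themselves re-segmented through the watershed so their contours are
gradient-aligned like everyone else's. The whole pipeline is deterministic:
identical inputs produce bit-identical outputs.

## Evaluation

Per slice: overlap `O = |pred ∩ truth| / |truth| × 100`; mean deviation
`Mad` = average distance from each predicted contour point to the nearest
truth contour point (directed, in pixels; KD-tree accelerated, exactly
equal to the brute-force double loop). Slices are graded `accurate`
(O > 90), `fair` (80 ≤ O ≤ 90 — both boundaries inclusive, since the
band's endpoints are otherwise ambiguous), `unacceptable` (O < 80).

## The synthetic phantom

No patient data ships with the package; every sequence-level claim is
exercised on a synthetic phantom that emulates the features the method
actually relies on, slice by slice:

* an elliptical body of heterogeneous soft tissue: a coarse muscle/fat
  pattern (amplitude 20 gray levels, spatial scale 0.08·frame, nearly
  static along z) plus a fine partial-volume mottle (amplitude 6, scale
  1.5 px, faster z-decorrelation). The mottle exists at `noise_sigma = 0`:
  tissue texture is anatomy, not acquisition noise, and perfectly flat
  plateaus make histogram measures (MI) behave degenerately in ways real
  CT never does;
* 1–6 convex bone cross-sections (rotated ellipses) on a placement ring,
  sized adaptively so that the scheduled maximum count fits with guaranteed
  separation — fewer components means larger cross-sections, as in real
  anatomy — and carrying an internal trabecular/marrow texture (one-sided
  darkening up to 15 gray levels below the cortical peak);
* continuous evolution: per-slice centre drift (≤ 0.5 px/slice, capped at
  ±3 px), slow semi-axis "breathing", ramped growth of appearing bones and
  shrinking of vanishing ones (75 % size at the change slice, full size 8
  slices away);
* an event-coupled rearrangement at every topology-change slice: each
  active bone takes a one-time reflected step in position and shape,
  because real anatomy changes fastest along z exactly where
  cross-sections appear or vanish. Steps reflect off their bounds rather
  than clip, so every event is guaranteed to move every bone; a clipped
  cumulative scheme saturates after a few events and silently strips late
  changes of their signature;
* a bright off-body table strip (omitted on frames too small to keep it
  disjoint from the body under the 3×3 closing), partial-volume edge blur
  (Gaussian, σ = 0.7 px), and finally additive i.i.d. Gaussian noise of
  standard deviation `noise_sigma`, clipped to [0, 255].

Ground truth is the exact pre-blur ellipse geometry; the set of change
slices is the schedule's start indices. Intensities default to background
0, body 80, bone 220; a linear map to Hounsfield units (`to_hounsfield`)
pairs the 8-bit phantom with the 600/900 bone window exactly, so the
windowing stage can be exercised losslessly. Everything is bit-reproducible
from the parameter set plus one integer seed.

The default frame (192×192) emulates the *cropped* input image: the body
fills most of it and bone occupies 10–25 % of pixels, as in a pelvis crop
of a 512×512 scan. Bone semi-axes then land at 17–26 px — the same
perimeter/area regime as real pelvic cross-sections — which matters because
of the watershed-line bound above.

What the phantom does **not** model: real pelvic geometry (ilium wings,
acetabular sockets, sacral foramina), fractures and fragment contact,
Hounsfield-accurate tissue values, beam hardening or metal artifacts, and
non-convex or touching bone cross-sections. Passing tests therefore show
that the pipeline's machinery is correct and that its selection logic works
in the intended similarity regime — not that clinical accuracy on patient
scans is guaranteed.

## Study conditions and problem sizes

Sequence-level checks run on 60-slice, 192×192 sequences with 3–5 scheduled
changes placed at least 8 slices apart and 8 slices from the volume edges
(scan protocols position the anatomy of interest away from the edges),
component counts random-walking in [2, 4] — the two-to-four distinct
topologies a pelvic slice typically shows — and noise σ ∈ {0, 5, 10}
rotating across sequences. End-to-end segmentation checks use 20-slice
sequences with two changes, ground-truth masks standing in for expert
marking at the automatically selected key frames. Low-level oracle checks
use 16×16 random masks/surfaces (200 thinning, 100 watershed, 100 minima
imposition cases) against naive independently coded references. These sizes
keep the full suite and the acceptance script each within a few minutes on
one core.

## Known limitations

* Key-frame recall is statistical, not guaranteed: across 480 validation
  sequences at the study conditions, one noiseless sequence had a change
  slice farther than ±1 from every target key frame (its NCC sat 0.002
  above the mean threshold). Noise σ ≥ 5 regularizes the similarity
  distributions and removes the failure mode entirely.
* The watershed line's overlap cost makes reported O scale-dependent
  (see above); comparisons across image scales should use the same bone
  pixel sizes.
* The body-mask step assumes a background that windows to exactly zero;
  phantoms with background noise defeat the nonzero binarization, so the
  pipeline is run directly on phantom stacks (which already emulate the
  cropped input image) and the pre-processing stage is validated on
  noiseless phantoms and synthetic DICOM instead.
* `mutual_information` mixes content entropy with similarity (it is not
  normalized); on low-entropy sequences its mean threshold can behave
  unexpectedly. This is faithful to the selection rule implemented, not a
  defect of the implementation.
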