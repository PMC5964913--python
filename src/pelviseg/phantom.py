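"""Synthetic pelvic-CT-like phantom sequences with known ground truth.

The phantom emulates the features of an axial pelvic CT stack that the
segmentation pipeline actually relies on:

* a large elliptical "body" of heterogeneous soft tissue (a smooth random
  texture around the body intensity, evolving slowly along z) surrounded by
  dark air,
* 1-6 bright convex "bone" cross-sections (rotated ellipses) inside the body,
  whose *count* changes at known slice indices (the topology schedule) and
  whose positions drift slowly (< 1 px/slice) between changes, mimicking the
  high similarity of adjacent CT slices; bone interiors carry a trabecular/
  marrow texture below the cortical peak intensity,
* continuous shape evolution: bone semi-axes breathe slowly along the
  sequence, a newly appearing bone emerges at reduced size and grows in over
  a few slices, and a bone about to disappear shrinks back down first, the
  way real cross-sections emerge and vanish along z — so adjacent-slice
  differences have a realistic non-zero baseline with clear spikes at
  topology changes,
* event-coupled rearrangement: on a topology-change slice every active bone
  takes a one-time extra step in position and shape, reflecting that the
  anatomy changes fastest along z exactly where cross-sections appear or
  vanish; a change slice is therefore an *obvious* structural change, not a
  surgically local edit,
* an off-body "table" strip artifact,
* partial-volume edge blur (a small Gaussian PSF applied to the clean scene),
* additive i.i.d. Gaussian noise, clipped to the 8-bit range.

Every slice comes with a ground-truth bone mask (the exact ellipse geometry,
before blur and noise) and the set of slices where the topology changes.
Output is bit-reproducible for a fixed spec + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import SliceStack

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "MAX_BONES",
    "generate_phantom",
    "max_feasible_bones",
    "random_schedule",
    "to_hounsfield",
    "write_phantom",
]

MAX_BONES = 6

# Geometry as fractions of the smaller image dimension. Bone sizes adapt to
# the scheduled maximum component count (fewer components -> larger cross
# sections, as in real anatomy), which keeps the phantom in the same
# perimeter/area regime as real pelvic bone cross-sections (effective radii
# of tens of pixels at 512x512): one-pixel boundary effects then cost a few
# percent of bone area, not tens of percent.
# The frame emulates the *cropped* input image: the body fills most of it and
# bone occupies a realistic 10-25% of the pixels, as in a pelvis crop.
_RING_FRAC = 0.26          # radius of the circle the bone centres sit on
_BODY_FRAC = (0.42, 0.44)  # body ellipse semi-axes (rows, cols fraction)
_DRIFT_CAP = 3.0           # max cumulative drift of a bone centre, px
_DRIFT_STEP = 0.5          # max per-slice drift step, px (below 1 px/slice)
_MIN_BONE_RADIUS = 4.0     # thinning needs non-degenerate blobs
_CLEARANCE = 3.0           # required gap between bone boundaries, px
_BREATHE_AMP_FRAC = 0.4    # semi-axis oscillation amplitude vs allowed range
_BREATHE_PERIOD = (15.0, 40.0)  # slices per oscillation
_GROWTH_START = 0.75        # size factor at appearance / just before vanishing
_GROWTH_SLICES = 8        # slices to grow to (or shrink from) full size
_TEXTURE_AMP = 20.0        # coarse soft-tissue texture amplitude
_TEXTURE_SIGMA_FRAC = 0.08  # spatial scale of the coarse texture vs min dim
_TEXTURE_Z_RHO = 0.995     # slice-to-slice autocorrelation, coarse texture
_FINE_AMP = 6.0            # fine tissue mottle amplitude (partial volume)
_FINE_SIGMA = 1.5          # spatial scale of the mottle, px
_FINE_Z_RHO = 0.9          # slice-to-slice autocorrelation of the mottle
_EVENT_C_SHIFT = (1.0, 2.5)    # centre jump of every bone at a change, px
_BONE_TEX_SIGMA = 2.5      # spatial scale of trabecular/marrow texture, px
_BONE_TEX_Z_RHO = 0.98     # slice-to-slice autocorrelation of bone texture


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic CT-like sequence.

    ``topology_schedule`` is an ordered list of ``(start_slice, n_bones)``
    pairs (1-based slice indices, strictly increasing, first entry at slice
    1): from ``start_slice`` on, the slice contains ``n_bones`` bone
    components, until the next schedule entry.
    """

    n_slices: int
    topology_schedule: tuple[tuple[int, int], ...] = ((1, 3),)
    image_shape: tuple[int, int] = (192, 192)
    bone_intensity: float = 220.0
    body_intensity: float = 80.0
    background_intensity: float = 0.0
    noise_sigma: float = 0.0
    include_table_artifact: bool = True
    edge_blur_sigma: float = 0.7
    bone_texture_amp: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "topology_schedule",
            tuple((int(s), int(n)) for s, n in self.topology_schedule),
        )
        object.__setattr__(self, "image_shape", tuple(int(d) for d in self.image_shape))
        if self.n_slices < 1:
            raise ValueError("n_slices must be positive")
        if min(self.image_shape) < 32:
            raise ValueError("image_shape too small for a phantom")
        sched = self.topology_schedule
        if not sched or sched[0][0] != 1:
            raise ValueError("topology_schedule must start at slice 1")
        starts = [s for s, _ in sched]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("topology_schedule slice indices must be strictly increasing")
        if starts[-1] > self.n_slices:
            raise ValueError("schedule entry beyond the last slice")
        feasible = max_feasible_bones(self.image_shape)
        for _, n in sched:
            if n < 1:
                raise ValueError("bone count must be at least 1")
            if n > feasible:
                raise ValueError(
                    f"{n} bone components cannot fit in image_shape "
                    f"{self.image_shape} (max {feasible})"
                )
        if not (self.bone_intensity > self.body_intensity > self.background_intensity):
            raise ValueError("need bone_intensity > body_intensity > background_intensity")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (
            0 <= self.bone_texture_amp
            <= 0.3 * (self.bone_intensity - self.body_intensity)
        ):
            raise ValueError("bone_texture_amp must keep bone brighter than tissue")


@dataclass
class PhantomOutput:
    stack: SliceStack           # 8-bit slices (uint8)
    truth_masks: np.ndarray     # (L, H, W) bool, exact bone geometry
    truth_keyslices: frozenset[int]  # 1-based slices where the topology changes
    spec: PhantomSpec


def _bone_radius_range(image_shape: tuple[int, int], n_max: int) -> tuple[float, float]:
    """Semi-axis range for bones when up to ``n_max`` share the placement ring:
    as large as the ring spacing, the body outline and the drift budget allow."""
    h, w = image_shape
    m = min(h, w)
    ring = _RING_FRAC * m
    body_limit = min(_BODY_FRAC[0] * h, _BODY_FRAC[1] * w) - ring - _DRIFT_CAP - 2.0
    r_hi = body_limit
    if n_max > 1:
        chord = 2.0 * ring * np.sin(np.pi / n_max)
        r_hi = min(r_hi, (chord - _CLEARANCE - 2.0 * _DRIFT_CAP) / 2.0)
    return 0.75 * r_hi, r_hi


def max_feasible_bones(image_shape: tuple[int, int]) -> int:
    """Largest bone count whose ring placement keeps components separated and
    non-degenerate (semi-axes of at least a few pixels)."""
    for count in range(MAX_BONES, 0, -1):
        if _bone_radius_range(image_shape, count)[1] >= _MIN_BONE_RADIUS:
            return count
    return 0


def random_schedule(
    rng: np.random.Generator,
    n_slices: int = 60,
    n_changes: int | None = None,
    counts: tuple[int, int] = (2, 4),
    min_spacing: int = 8,
    edge_margin: int = 8,
) -> tuple[tuple[int, int], ...]:
    """A random topology schedule of the kind pelvic sequences exhibit.

    Change slices fall in the interior of the volume (at least ``edge_margin``
    slices from either end — scan protocols position the anatomy of interest
    away from the volume edges) and are separated by ``min_spacing`` slices;
    component counts random-walk by +/-1 within ``counts``. The default range
    2-4 matches the two-to-four distinct bone cross-sections a pelvic slice
    typically shows (a slice always has at least two).
    """
    if n_changes is None:
        n_changes = int(rng.integers(3, 6))
    lo, hi = counts
    # clamp the margins to what the sequence length can actually host
    edge_margin = min(edge_margin, max(1, n_slices // 5))
    first, last = edge_margin, n_slices - edge_margin - 1
    if last - first + 1 < n_changes:
        raise ValueError(f"{n_changes} changes cannot fit in {n_slices} slices")
    min_spacing = min(min_spacing, max(1, (last - first) // max(n_changes, 1)))
    while True:
        starts = np.sort(
            rng.choice(np.arange(first, last + 1), size=n_changes, replace=False)
        )
        if all(b - a >= min_spacing for a, b in zip(starts, starts[1:])):
            break
    sched = [(1, int(rng.integers(lo, hi)))]
    for s in starts:
        step = int(rng.choice((-1, 1)))
        c = min(hi, max(lo, sched[-1][1] + step))
        if c == sched[-1][1]:
            c = sched[-1][1] + (1 if c < hi else -1)
        sched.append((int(s), c))
    return tuple(sched)


def _scheduled_counts(spec: PhantomSpec) -> np.ndarray:
    counts = np.empty(spec.n_slices, dtype=int)
    sched = list(spec.topology_schedule) + [(spec.n_slices + 1, 0)]
    for (start, n), (nxt, _) in zip(sched, sched[1:]):
        counts[start - 1 : nxt - 1] = n
    return counts


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate a phantom sequence; deterministic for a fixed spec + seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    m = min(h, w)
    n_max = max(n for _, n in spec.topology_schedule)

    # Per-slot geometry, fixed over the sequence: one ring slot per bone of
    # the largest scheduled count, so the radius budget and the spacing agree.
    ring = _RING_FRAC * m
    phase = rng.uniform(0.0, 2 * np.pi)
    angles = phase + 2 * np.pi * np.arange(n_max) / max(n_max, 1)
    center = (h / 2.0, w / 2.0)
    homes = np.stack(
        [center[0] + ring * np.sin(angles), center[1] + ring * np.cos(angles)], axis=1
    )
    r_lo, r_hi = _bone_radius_range(spec.image_shape, n_max)
    r_lo = max(r_lo, _MIN_BONE_RADIUS)
    r_hi = max(r_hi, r_lo + 0.5)
    semi_axes = rng.uniform(r_lo, r_hi, size=(n_max, 2))
    thetas = rng.uniform(0.0, np.pi, size=n_max)

    # Slow "breathing" of the semi-axes along z (sub-pixel per slice).
    breathe_amp = _BREATHE_AMP_FRAC * (r_hi - r_lo) * rng.uniform(
        0.5, 1.0, size=(n_max, 2)
    )
    breathe_period = rng.uniform(*_BREATHE_PERIOD, size=(n_max, 2))
    breathe_phase = rng.uniform(0.0, 2 * np.pi, size=(n_max, 2))

    # Slow random-walk drift of each bone centre, capped so components can
    # never touch; per-slice steps stay below one pixel.
    steps = rng.uniform(-_DRIFT_STEP, _DRIFT_STEP, size=(spec.n_slices, n_max, 2))
    steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)

    # One-time rearrangement of every active bone at each topology-change
    # slice: the anatomy changes fastest along z exactly where cross-sections
    # appear or vanish. Steps reflect off the allowed corridor instead of
    # clipping, so every event is guaranteed to actually move every bone —
    # a clipped cumulative shift would saturate after a few events and leave
    # late changes without their rearrangement signature.
    event_slices = {s for s, _ in spec.topology_schedule if s > 1}
    corridor = max(r_hi - r_lo, 0.5)

    def _reflected_step(value: float, lo: float, hi: float, delta: float) -> float:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        cand = value + sign * delta
        if not (lo <= cand <= hi):
            cand = value - sign * delta
        return float(np.clip(cand, lo, hi))

    ax_shift = np.zeros((spec.n_slices, n_max, 2))
    c_shift = np.zeros((spec.n_slices, n_max, 2))
    cur_ax = np.zeros((n_max, 2))
    cur_c = np.zeros((n_max, 2))
    for s in range(spec.n_slices):
        if (s + 1) in event_slices:
            for k in range(n_max):
                for d in (0, 1):
                    delta = rng.uniform(0.25, 0.5) * corridor
                    lo = r_lo - semi_axes[k, d]
                    hi = r_hi - semi_axes[k, d]
                    cur_ax[k, d] = _reflected_step(cur_ax[k, d], lo, hi, delta)
                    delta = rng.uniform(*_EVENT_C_SHIFT)
                    cur_c[k, d] = _reflected_step(
                        cur_c[k, d], -_DRIFT_CAP, _DRIFT_CAP, delta
                    )
        ax_shift[s] = cur_ax
        c_shift[s] = cur_c
    drift = np.clip(drift + c_shift, -_DRIFT_CAP, _DRIFT_CAP)

    counts = _scheduled_counts(spec)
    body = _ellipse_mask(
        (h, w), center, _BODY_FRAC[0] * h, _BODY_FRAC[1] * w, 0.0
    )
    table = np.zeros((h, w), dtype=bool)
    if spec.include_table_artifact:
        # sit well below the body's blur tail so the binarized strip stays
        # disconnected from the body under a 3x3 morphological closing; on
        # frames too small to fit a disjoint strip, the artifact is omitted
        t0 = int(h / 2.0 + _BODY_FRAC[0] * h + 10.0)
        if t0 + 3 <= h:
            table[t0 : t0 + 3, w // 8 : w - w // 8] = True
        table &= ~body  # guaranteed disjoint by geometry; belt and braces
    table_intensity = spec.background_intensity + 0.8 * (
        spec.bone_intensity - spec.background_intensity
    )

    # Size factor per (slice, slot): bones appearing after slice 1 grow in
    # from _GROWTH_START, bones disappearing before the last slice shrink
    # back down to it first, so topology changes are obvious but not abrupt
    # whole-bone jumps.
    active = np.array([[k < counts[s] for k in range(n_max)] for s in range(spec.n_slices)])
    factor = np.ones((spec.n_slices, n_max))
    span = 1.0 - _GROWTH_START
    for k in range(n_max):
        col = active[:, k]
        s = 0
        while s < spec.n_slices:
            if not col[s]:
                s += 1
                continue
            e = s
            while e + 1 < spec.n_slices and col[e + 1]:
                e += 1
            for t in range(s, e + 1):
                f = 1.0
                if s > 0:
                    f = min(f, _GROWTH_START + span * (t - s) / _GROWTH_SLICES)
                if e < spec.n_slices - 1:
                    f = min(f, _GROWTH_START + span * (e - t) / _GROWTH_SLICES)
                factor[t, k] = f
            s = e + 1

    # Soft tissue is heterogeneous at two scales: a coarse muscle/fat pattern
    # that is almost static along z, and a fine partial-volume mottle that
    # decorrelates faster. Both evolve as AR(1) blends between slices; the
    # mottle exists even at noise_sigma = 0, because tissue texture is part
    # of the anatomy, not of the acquisition noise.
    tex_sigma = _TEXTURE_SIGMA_FRAC * m
    amp = min(_TEXTURE_AMP, 0.45 * (spec.bone_intensity - spec.body_intensity),
              0.9 * (spec.body_intensity - spec.background_intensity))
    fine_amp = min(_FINE_AMP, 0.3 * amp)

    def _field(sigma: float) -> np.ndarray:
        field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        sd = field.std()
        return field / sd if sd > 0 else field

    tex = _field(tex_sigma)
    fine = _field(_FINE_SIGMA)
    btex = _field(_BONE_TEX_SIGMA)

    images = np.empty((spec.n_slices, h, w), dtype=np.uint8)
    truth = np.zeros((spec.n_slices, h, w), dtype=bool)
    for s in range(spec.n_slices):
        if s > 0:
            tex = _TEXTURE_Z_RHO * tex + np.sqrt(1 - _TEXTURE_Z_RHO**2) * _field(tex_sigma)
            fine = _FINE_Z_RHO * fine + np.sqrt(1 - _FINE_Z_RHO**2) * _field(_FINE_SIGMA)
            btex = _BONE_TEX_Z_RHO * btex + np.sqrt(1 - _BONE_TEX_Z_RHO**2) * _field(
                _BONE_TEX_SIGMA
            )
        scene = np.full((h, w), spec.background_intensity, dtype=np.float64)
        scene[body] = np.clip(
            spec.body_intensity + amp * tex[body] + fine_amp * fine[body],
            spec.background_intensity + 1.0,
            spec.body_intensity + 2.0 * amp,
        )
        scene[table] = table_intensity
        for k in range(n_max):
            if not active[s, k]:
                continue
            axes = np.clip(
                semi_axes[k]
                + breathe_amp[k] * np.sin(2 * np.pi * s / breathe_period[k] + breathe_phase[k])
                + ax_shift[s, k],
                r_lo,
                r_hi,
            )
            axes = np.maximum(axes * factor[s, k], 3.0)
            c = homes[k] + drift[s, k]
            bone = _ellipse_mask((h, w), (c[0], c[1]), axes[0], axes[1], thetas[k])
            # trabecular/marrow heterogeneity: one-sided darkening below the
            # cortical peak, so bone stays clearly brighter than soft tissue
            scene[bone] = spec.bone_intensity - spec.bone_texture_amp * (
                0.5 + 0.5 * np.tanh(btex[bone])
            )
            truth[s] |= bone
        if spec.edge_blur_sigma > 0:
            scene = ndimage.gaussian_filter(scene, spec.edge_blur_sigma)
        if spec.noise_sigma > 0:
            scene = scene + rng.normal(0.0, spec.noise_sigma, size=(h, w))
        images[s] = np.clip(np.rint(scene), 0, 255).astype(np.uint8)

    keyslices = frozenset(s for s, _ in spec.topology_schedule)
    stack = SliceStack(images=images, pixel_spacing=(1.0, 1.0), slice_thickness=3.0)
    return PhantomOutput(stack=stack, truth_masks=truth, truth_keyslices=keyslices, spec=spec)


#: Linear map pairing the 8-bit phantom with the bone window (600/900 Hu):
#: gray g -> 600 + g * 600/255 Hu, so windowing the "raw" stack recovers the
#: 8-bit phantom exactly.
def to_hounsfield(images8: np.ndarray) -> np.ndarray:
    """Lift 8-bit phantom slices to a synthetic Hounsfield-unit stack."""
    return 600.0 + np.asarray(images8, dtype=np.float64) * (600.0 / 255.0)


def write_phantom(out: PhantomOutput, directory: str | Path) -> None:
    """Write slices and truth masks as PNGs plus a JSON sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    (directory / "slices").mkdir(parents=True, exist_ok=True)
    (directory / "truth").mkdir(parents=True, exist_ok=True)
    for i, (img, msk) in enumerate(zip(out.stack.images, out.truth_masks), start=1):
        iio.imwrite(directory / "slices" / f"slice_{i:04d}.png", img)
        iio.imwrite(directory / "truth" / f"mask_{i:04d}.png", msk.astype(np.uint8) * 255)
    sidecar = asdict(out.spec)
    sidecar["truth_keyslices"] = sorted(out.truth_keyslices)
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))
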