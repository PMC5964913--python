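"""Independent reference implementations used as oracles in the tests.

Everything here is deliberately written as plain nested loops / list scans,
sharing no code with the package, so that agreement between the two is
evidence of correctness rather than of shared bugs. The flooding and
tie-break conventions mirror the package's *documented* rules, not its code.
"""

from __future__ import annotations

import numpy as np

# --- two-subiteration thinning ------------------------------------------------

# p2..p9 around p1, circular: N, NE, E, SE, S, SW, W, NW
_OFFS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _nbhd(img, r, c):
    h, w = img.shape
    out = []
    for dr, dc in _OFFS:
        rr, cc = r + dr, c + dc
        out.append(int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0)
    return out


def thin_reference(mask: np.ndarray) -> np.ndarray:
    """Naive two-subiteration thinning with simultaneous deletion."""
    img = np.asarray(mask, dtype=np.uint8).copy()
    h, w = img.shape
    while True:
        deleted_any = False
        for sub in (1, 2):
            deletions = []
            for r in range(h):
                for c in range(w):
                    if not img[r, c]:
                        continue
                    p = _nbhd(img, r, c)
                    n = sum(p)
                    if not (2 <= n <= 6):
                        continue
                    s = 0
                    for i in range(8):
                        if p[i] == 0 and p[(i + 1) % 8] == 1:
                            s += 1
                    if s != 1:
                        continue
                    p2, p3, p4, p5, p6, p7, p8, p9 = p
                    if sub == 1:
                        ok = p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0
                    else:
                        ok = p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0
                    if ok:
                        deletions.append((r, c))
            for r, c in deletions:
                img[r, c] = 0
            if deletions:
                deleted_any = True
        if not deleted_any:
            return img.astype(bool)


# --- watershed flooding -------------------------------------------------------


def watershed_reference(surface: np.ndarray, marker_labels: np.ndarray) -> np.ndarray:
    """Brute-force priority flood with the package's documented conventions:
    8-connectivity, claims served in increasing (surface value, push order),
    neighbors claimed in raster order of the 3x3 neighborhood, a pixel claimed
    by two labels before its first service becomes ridge (0 in the output,
    -1 internally), ridge pixels propagate the earliest claiming label.

    Returns the label image with 0 on ridge pixels.
    """
    surface = np.asarray(surface, dtype=np.float64)
    h, w = surface.shape
    assigned = np.asarray(marker_labels, dtype=np.int64).copy()
    pending: list[tuple[float, int, int, int, int]] = []  # (v, seq, r, c, label)
    claims: dict[tuple[int, int], list[int]] = {}
    seq = 0

    def claim(r, c, label):
        nonlocal seq
        seq += 1
        pending.append((surface[r, c], seq, r, c, label))
        claims.setdefault((r, c), []).append(label)

    for r in range(h):
        for c in range(w):
            if assigned[r, c] > 0:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and assigned[rr, cc] == 0:
                            claim(rr, cc, int(assigned[r, c]))

    while pending:
        best = min(range(len(pending)), key=lambda i: pending[i][:2])
        _, _, r, c, label = pending.pop(best)
        if assigned[r, c] != 0:
            continue
        seen = claims[(r, c)]
        first = seen[0]
        if any(x != first for x in seen):
            assigned[r, c] = -1
        else:
            assigned[r, c] = label
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and assigned[rr, cc] == 0:
                    claim(rr, cc, first)

    out = assigned.copy()
    out[out == -1] = 0
    return out


# --- regional minima ----------------------------------------------------------


def regional_minima_reference(surface: np.ndarray) -> np.ndarray:
    """8-connected plateau components with no strictly lower neighbor."""
    surface = np.asarray(surface, dtype=np.float64)
    h, w = surface.shape
    visited = np.zeros((h, w), dtype=bool)
    minima = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if visited[r0, c0]:
                continue
            level = surface[r0, c0]
            plateau = [(r0, c0)]
            visited[r0, c0] = True
            is_min = True
            i = 0
            while i < len(plateau):
                r, c = plateau[i]
                i += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        if surface[rr, cc] == level:
                            if not visited[rr, cc]:
                                visited[rr, cc] = True
                                plateau.append((rr, cc))
                        elif surface[rr, cc] < level:
                            is_min = False
            if is_min:
                for r, c in plateau:
                    minima[r, c] = True
    return minima


# --- assorted brute-force helpers --------------------------------------------


def sad_reference(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            total += abs(float(b[r, c]) - float(a[r, c]))
    return total


def sobel_reference(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double-loop Sobel with replicate padding; returns (gx, gy)."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape

    def at(r, c):
        return img[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]

    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            p9, p2, p3 = at(r - 1, c - 1), at(r - 1, c), at(r - 1, c + 1)
            p8, p4 = at(r, c - 1), at(r, c + 1)
            p7, p6, p5 = at(r + 1, c - 1), at(r + 1, c), at(r + 1, c + 1)
            gx[r, c] = p9 + 2 * p2 + p3 - (p7 + 2 * p6 + p5)
            gy[r, c] = p9 + 2 * p8 + p7 - (p3 + 2 * p4 + p5)
    return gx, gy


def mad_reference(l1: np.ndarray, l2: np.ndarray) -> float:
    total = 0.0
    for p in np.asarray(l1, dtype=np.float64):
        best = None
        for q in np.asarray(l2, dtype=np.float64):
            d = float(np.hypot(p[0] - q[0], p[1] - q[1]))
            if best is None or d < best:
                best = d
        total += best
    return total / len(l1)


def histogram_entropy_bits(img: np.ndarray) -> float:
    """Shannon entropy (bits) of an image's 256-bin gray histogram."""
    counts: dict[int, int] = {}
    for v in np.asarray(img).ravel():
        key = int(v)
        counts[key] = counts.get(key, 0) + 1
    n = sum(counts.values())
    ent = 0.0
    for c in counts.values():
        p = c / n
        ent -= p * np.log2(p)
    return ent


# --- random case generators ---------------------------------------------------


def random_mask(rng: np.random.Generator, shape=(16, 16), p: float = 0.5) -> np.ndarray:
    return rng.random(shape) < p


def random_surface_and_markers(
    rng: np.random.Generator,
    shape=(16, 16),
    n_labels: int | None = None,
    integer_surface: bool = True,
    min_separation: int = 2,
):
    """A random flooding surface plus 2-4 separated single-pixel markers.

    Integer-valued surfaces produce many ties, stressing the documented
    tie-break rules. Markers of different labels are kept at Chebyshev
    distance >= ``min_separation`` so marker components are unambiguous.
    """
    h, w = shape
    if integer_surface:
        surface = rng.integers(0, 8, size=shape).astype(np.float64)
    else:
        surface = rng.random(shape)
    if n_labels is None:
        n_labels = int(rng.integers(2, 5))
    labels = np.zeros(shape, dtype=np.int32)
    placed: list[tuple[int, int]] = []
    label = 1
    attempts = 0
    while label <= n_labels and attempts < 1000:
        attempts += 1
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        if all(max(abs(r - pr), abs(c - pc)) >= min_separation for pr, pc in placed):
            labels[r, c] = label
            placed.append((r, c))
            label += 1
    return surface, labels, label - 1
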