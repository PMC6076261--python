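"""Independent brute-force oracles for image-analysis tests.

Deliberately naive implementations (BFS flood fill, per-pixel neighbor
counting, explicit local-mean windows) used only to check the pipeline;
they share no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGH4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of a binary mask via BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    comp.add((rr, cc))
                    for dr, dc in NEIGH8:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
                comps.append(comp)
    return comps


def perimeter_by_edges(pixels: set[tuple[int, int]]) -> int:
    """Count 4-neighbor edges from a region pixel to a non-region pixel."""
    edges = 0
    for r, c in pixels:
        for dr, dc in NEIGH4:
            if (r + dr, c + dc) not in pixels:
                edges += 1
    return edges


def form_factor_bruteforce(pixels: set[tuple[int, int]]) -> float:
    p = perimeter_by_edges(pixels)
    return 4.0 * np.pi * len(pixels) / p ** 2


def local_mean_mask(img: np.ndarray, block: int, offset: float) -> np.ndarray:
    """mask = img > (windowed mean − offset), edge-repeating reflect boundary
    (numpy's ``symmetric``), no smoothing."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    half = block // 2
    padded = np.pad(img, half, mode="symmetric")
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            window = padded[r:r + block, c:c + block]
            out[r, c] = img[r, c] > (window.mean() - offset)
    return out


def nearest_centroid_regions(shape, centroids, radius):
    """Per-pixel nearest-centroid assignment limited to a disc."""
    h, w = shape
    out = np.full((h, w), -1, dtype=int)
    for r in range(h):
        for c in range(w):
            best, best_d = -1, np.inf
            for k, (r0, c0) in enumerate(centroids):
                d = (r - r0) ** 2 + (c - c0) ** 2
                if d < best_d:
                    best_d, best = d, k
            if best_d <= radius ** 2:
                out[r, c] = best
    return out
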