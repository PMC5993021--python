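"""Independent brute-force oracles used by the test suite.

Every function here recomputes an expected value from first principles
(exhaustive enumeration, flood fill, closed forms) without calling the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def disk_area(center: tuple[float, float], radius: float, shape: tuple[int, int]) -> int:
    """Pixel count of a discretized disk by exhaustive membership testing."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            if (i - center[0]) ** 2 + (j - center[1]) ** 2 <= radius * radius:
                count += 1
    return count


def ball_heights(radius: float) -> dict[tuple[int, int], float]:
    """Height profile of the ball structuring element over its footprint."""
    n = int(math.floor(radius))
    heights = {}
    for dy in range(-n, n + 1):
        for dx in range(-n, n + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                heights[(dy, dx)] = math.sqrt(radius * radius - d2)
    return heights


def rolling_ball_opening(image: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening by exhaustive placement of the ball element.

    For every placement of the ball (center anywhere on the grid,
    out-of-bounds samples ignored) the ball is pushed up until it touches
    the surface; the opening at a pixel is the highest ball surface over
    all placements covering it.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    heights = ball_heights(radius)
    out = np.full((h, w), -np.inf)
    for cy in range(h):
        for cx in range(w):
            # how far up can the ball centered at (cy, cx) be pushed?
            shift = np.inf
            for (dy, dx), hgt in heights.items():
                y, x = cy + dy, cx + dx
                if 0 <= y < h and 0 <= x < w:
                    shift = min(shift, img[y, x] - hgt)
            # ball surface at this placement
            for (dy, dx), hgt in heights.items():
                y, x = cy + dy, cx + dx
                if 0 <= y < h and 0 <= x < w:
                    out[y, x] = max(out[y, x], shift + hgt)
    return out


def flood_fill_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected foreground components by stack flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def border_flood_background(mask: np.ndarray) -> np.ndarray:
    """Background pixels 4-connected to the image border; the complement of
    ``mask | background`` is the set of interior holes."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    outside = np.zeros_like(mask)
    stack = []
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j] and not outside[i, j]:
                outside[i, j] = True
                stack.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j] and not outside[i, j]:
                outside[i, j] = True
                stack.append((i, j))
    while stack:
        y, x = stack.pop()
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                stack.append((ny, nx))
    return outside


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance to the nearest background pixel, by enumeration."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    bg = [(i, j) for i in range(h) for j in range(w) if not mask[i, j]]
    out = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                out[i, j] = math.sqrt(
                    min((i - y) ** 2 + (j - x) ** 2 for y, x in bg)
                ) if bg else math.inf
    return out


def count_distance_maxima(mask: np.ndarray, min_separation: float) -> int:
    """Count distance-transform local maxima (plateau clusters merged when
    closer than ``min_separation``) on a small instance."""
    edt = brute_force_edt(mask)
    h, w = mask.shape
    candidates = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            is_max = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    y, x = i + dy, j + dx
                    if 0 <= y < h and 0 <= x < w and edt[y, x] > edt[i, j]:
                        is_max = False
            if is_max:
                candidates.append((edt[i, j], i, j))
    candidates.sort(reverse=True)
    kept: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if all((i - y) ** 2 + (j - x) ** 2 >= min_separation**2 for y, x in kept):
            kept.append((i, j))
    return len(kept)


def geodesic_assignment(
    fg: np.ndarray,
    seeds: np.ndarray,
    image: np.ndarray | None = None,
    regularization: float = 0.0,
    max_iter: int = 10000,
) -> np.ndarray:
    """Nearest-seed assignment by exhaustive relaxation (Bellman–Ford style).

    Distances use 8-connected steps of euclidean length plus
    ``regularization * |dI|``; each pixel takes the label of its nearest
    seed, ties to the lower label.  Independent of any priority-queue
    search: distances per seed are relaxed to a fixpoint.
    """
    fg = np.asarray(fg, dtype=bool)
    seeds = np.asarray(seeds)
    img = np.zeros_like(fg, dtype=float) if image is None else np.asarray(image, float)
    h, w = fg.shape
    labels = sorted(int(v) for v in np.unique(seeds) if v > 0)
    steps = [
        (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
        (-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)),
        (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2)),
    ]
    best = np.full((h, w), np.inf)
    assign = np.zeros((h, w), dtype=int)
    for lbl in labels:
        dist = np.full((h, w), np.inf)
        dist[(seeds == lbl)] = 0.0
        for _ in range(max_iter):
            changed = False
            for i in range(h):
                for j in range(w):
                    if not (fg[i, j] or seeds[i, j] > 0):
                        continue
                    for dy, dx, s in steps:
                        y, x = i + dy, j + dx
                        if 0 <= y < h and 0 <= x < w and np.isfinite(dist[y, x]):
                            cand = dist[y, x] + s + regularization * abs(img[y, x] - img[i, j])
                            if cand < dist[i, j] - 1e-15:
                                dist[i, j] = cand
                                changed = True
            if not changed:
                break
        improved = dist < best - 1e-12
        best[improved] = dist[improved]
        assign[improved] = lbl
    assign[~(fg | (seeds > 0))] = 0
    return assign


def ols_closed_form(x, y) -> tuple[float, float, float]:
    """Slope, intercept, R^2 by the closed-form least-squares sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sxx = sum((v - xbar) ** 2 for v in x)
    sxy = sum((a - xbar) * (b - ybar) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    sse = sum((b - (intercept + slope * a)) ** 2 for a, b in zip(x, y))
    sst = sum((b - ybar) ** 2 for b in y)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return slope, intercept, r2
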