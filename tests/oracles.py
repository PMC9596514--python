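"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written in the most transparent way
possible (nested loops, heapq, full enumeration) and shares no code with
the package.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def flood_reference(grad: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Plain-Python priority flood with the same contract as the package.

    Claims ordered by (gradient at claimed voxel, insertion order); seeds
    expanded first, sorted by (label, raster position); neighbors visited
    in (-i, +i, -j, +j, -k, +k) order; 6-connectivity; label on pop.
    """
    out = markers.copy()
    heap: list = []
    age = 0
    shape = grad.shape
    nbrs = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]

    def push_neighbors(p, lab):
        nonlocal age
        i, j, k = p
        for di, dj, dk in nbrs:
            q = (i + di, j + dj, k + dk)
            if all(0 <= q[a] < shape[a] for a in range(3)) and out[q] == 0:
                heapq.heappush(heap, (grad[q], age, lab, q))
                age += 1

    seed_pos = sorted((tuple(p) for p in np.argwhere(markers > 0)), key=lambda p: (markers[p], p))
    for p in seed_pos:
        push_neighbors(p, int(out[p]))
    while heap:
        _, _, lab, p = heapq.heappop(heap)
        if out[p] != 0:
            continue
        out[p] = lab
        push_neighbors(p, lab)
    return out


def median_filter_reference(data: np.ndarray) -> np.ndarray:
    """One 3x3x3 median pass with edge replication, by nested loops."""
    n0, n1, n2 = data.shape
    out = np.empty_like(data)
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                block = data[
                    max(i - 1, 0) : min(i + 2, n0),
                    max(j - 1, 0) : min(j + 2, n1),
                    max(k - 1, 0) : min(k + 2, n2),
                ]
                # edge replication: repeat border voxels so the window
                # always holds 27 samples
                vals = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            ii = min(max(i + di, 0), n0 - 1)
                            jj = min(max(j + dj, 0), n1 - 1)
                            kk = min(max(k + dk, 0), n2 - 1)
                            vals.append(data[ii, jj, kk])
                out[i, j, k] = np.median(vals)
    return out


def sobel_magnitude_reference(data: np.ndarray) -> np.ndarray:
    """3D Sobel magnitude by explicit kernel convolution (edge replicated)."""
    deriv = np.array([-1.0, 0.0, 1.0])
    smooth = np.array([1.0, 2.0, 1.0])
    n0, n1, n2 = data.shape
    padded = np.pad(data.astype(float), 1, mode="edge")
    total = np.zeros_like(data, dtype=float)
    for axis in range(3):
        kern = np.ones((3, 3, 3))
        for a in range(3):
            shape = [1, 1, 1]
            shape[a] = 3
            kern = kern * (deriv if a == axis else smooth).reshape(shape)
        resp = np.zeros_like(data, dtype=float)
        for di in range(3):
            for dj in range(3):
                for dk in range(3):
                    resp += kern[di, dj, dk] * padded[di : di + n0, dj : dj + n1, dk : dk + n2]
        total += resp**2
    return np.sqrt(total)


def lattice_ball_count(radius_um: float, voxel_size_um: float) -> int:
    """Number of lattice points with center within radius of the origin."""
    m = int(np.floor(radius_um / voxel_size_um)) + 1
    count = 0
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                if (i * i + j * j + k * k) * voxel_size_um**2 <= radius_um**2 + 1e-9:
                    count += 1
    return count


def dilate_reference(mask: np.ndarray, radius_um: float, voxel_size_um: float) -> np.ndarray:
    """Brute-force dilation: all voxels within radius of any foreground voxel."""
    fg = np.argwhere(mask) * voxel_size_um
    coords = np.argwhere(np.ones(mask.shape, dtype=bool)) * voxel_size_um
    best = np.full(coords.shape[0], np.inf)
    for start in range(0, fg.shape[0], 64):  # chunked to bound memory
        chunk = fg[start : start + 64]
        d2 = ((coords[:, None, :] - chunk[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        best = np.minimum(best, d2)
    return (best <= radius_um**2 + 1e-9).reshape(mask.shape)


def fill_holes_reference(mask: np.ndarray) -> np.ndarray:
    """Flood-fill background from the border (6-connectivity); rest is filled."""
    mask = mask.astype(bool)
    reach = np.zeros(mask.shape, dtype=bool)
    stack = []
    n0, n1, n2 = mask.shape
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                if (i in (0, n0 - 1) or j in (0, n1 - 1) or k in (0, n2 - 1)) and not mask[i, j, k]:
                    stack.append((i, j, k))
                    reach[i, j, k] = True
    while stack:
        i, j, k = stack.pop()
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = (i + di, j + dj, k + dk)
            if 0 <= q[0] < n0 and 0 <= q[1] < n1 and 0 <= q[2] < n2:
                if not mask[q] and not reach[q]:
                    reach[q] = True
                    stack.append(q)
    return mask | ~reach


def plane_from_three_points(p0, p1, p2):
    """Cross-product plane through exactly three points."""
    n = np.cross(np.asarray(p1) - p0, np.asarray(p2) - p0)
    return n / np.linalg.norm(n)


def rodrigues_rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def wilcoxon_enumeration(diffs: np.ndarray, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    le = float((ws <= w_obs + 1e-12).mean())
    ge = float((ws >= w_obs - 1e-12).mean())
    if alternative == "greater":
        return w_obs, min(ge, 1.0)
    if alternative == "less":
        return w_obs, min(le, 1.0)
    return w_obs, min(2.0 * min(le, ge), 1.0)


def icc21_reference(x: np.ndarray) -> float:
    """ICC(2,1) from explicitly written two-way ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2 for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
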