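"""Threshold-free cluster enhancement kernels.

Two interchangeable backends: a numba-compiled flood-fill version used by
the permutation loops (hundreds of thousands of maps in the error-rate
simulations), and a scipy.ndimage reference version.  Tests assert their
equivalence; the scipy path is used automatically when numba is missing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def tfce_scipy(values: np.ndarray, e: float, h: float, dh: float, connectivity: int = 26) -> np.ndarray:
    """Reference TFCE: per threshold, label suprathreshold components.

    ``tfce(v) = sum over thresholds t = dh, 2dh, ... <= value(v) of
    extent(t, component of v) ** e * t ** h * dh``.
    """
    structure = _STRUCTURES[connectivity]
    out = np.zeros_like(values, dtype=float)
    vmax = float(values.max(initial=0.0))
    if vmax <= 0 or dh <= 0:
        return out
    n_steps = int(np.floor(vmax / dh + 1e-12))
    for k in range(1, n_steps + 1):
        t = k * dh
        supra = values >= t - 1e-12 * dh
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out[supra] += (sizes[labels[supra]].astype(float) ** e) * (t ** h) * dh
    return out


@njit(cache=True)
def _tfce_flood(vals, order, nx, ny, nz, e, h, dh, conn26, out):  # pragma: no cover
    nvox = nx * ny * nz
    vmax = 0.0
    for i in range(nvox):
        if vals[i] > vmax:
            vmax = vals[i]
    for i in range(nvox):
        out[i] = 0.0
    if vmax <= 0.0 or dh <= 0.0:
        return
    n_steps = int(np.floor(vmax / dh + 1e-12))
    visited = np.zeros(nvox, dtype=np.uint8)
    stack = np.empty(nvox, dtype=np.int64)
    comp = np.empty(nvox, dtype=np.int64)
    # walk thresholds from the top so the suprathreshold prefix of `order`
    # (voxels sorted by value, descending) only grows
    m = 0
    for k in range(n_steps, 0, -1):
        t = k * dh
        thr = t - 1e-12 * dh
        while m < nvox and vals[order[m]] >= thr:
            m += 1
        for idx in range(m):
            visited[order[idx]] = 0
        contrib_base = (t ** h) * dh
        for idx in range(m):
            seed = order[idx]
            if visited[seed]:
                continue
            # BFS over the suprathreshold component containing seed
            visited[seed] = 1
            stack[0] = seed
            top = 1
            size = 0
            while top > 0:
                top -= 1
                cur = stack[top]
                comp[size] = cur
                size += 1
                cz = cur % nz
                cy = (cur // nz) % ny
                cx = cur // (ny * nz)
                for dx in range(-1, 2):
                    x = cx + dx
                    if x < 0 or x >= nx:
                        continue
                    for dy in range(-1, 2):
                        y = cy + dy
                        if y < 0 or y >= ny:
                            continue
                        for dz in range(-1, 2):
                            if dx == 0 and dy == 0 and dz == 0:
                                continue
                            if not conn26 and (abs(dx) + abs(dy) + abs(dz)) > 1:
                                continue
                            z = cz + dz
                            if z < 0 or z >= nz:
                                continue
                            nb = (x * ny + y) * nz + z
                            if visited[nb] == 0 and vals[nb] >= thr:
                                visited[nb] = 1
                                stack[top] = nb
                                top += 1
            add = (float(size) ** e) * contrib_base
            for s in range(size):
                out[comp[s]] += add


def tfce_fast(values: np.ndarray, e: float, h: float, dh: float, connectivity: int = 26) -> np.ndarray:
    """TFCE via the numba kernel (scipy fallback when numba is unavailable)."""
    if connectivity == 18 or not HAVE_NUMBA:
        return tfce_scipy(values, e, h, dh, connectivity)
    vals = np.ascontiguousarray(values, dtype=np.float64).ravel()
    order = np.argsort(vals)[::-1].astype(np.int64)
    out = np.empty_like(vals)
    nx, ny, nz = values.shape
    _tfce_flood(vals, order, nx, ny, nz, float(e), float(h), float(dh), connectivity == 26, out)
    return out.reshape(values.shape)
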