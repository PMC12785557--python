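"""Hot inner loops of the convolution layers.

The im2col pack and the col2im scatter-add are pure memory-movement and
dominate the cost of a training step when written as NumPy slice
assignments; numba compiles them to tight single-threaded loops. A NumPy
fallback keeps the package importable without numba (results are
identical either way — the kernels only copy and add).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap


# For a fixed window row i, the (offset j, channel) pair runs over a
# contiguous span of k*c floats in both the padded image row and the
# column buffer, so the innermost operation is a straight slice copy.


@njit(cache=True)
def _pack_jit(xpf: np.ndarray, k: int, c: int, h: int, w: int, cols: np.ndarray) -> None:
    n = xpf.shape[0]
    kc = k * c
    for b in range(n):
        for y in range(h):
            for i in range(k):
                src = xpf[b, y + i]
                base = i * kc
                for x in range(w):
                    x0 = x * c
                    for t in range(kc):
                        cols[b, y, x, base + t] = src[x0 + t]


@njit(cache=True)
def _scatter_jit(dwin: np.ndarray, k: int, c: int, h: int, w: int, dxpf: np.ndarray) -> None:
    n = dwin.shape[0]
    kc = k * c
    for b in range(n):
        for y in range(h):
            for i in range(k):
                dst = dxpf[b, y + i]
                base = i * kc
                for x in range(w):
                    x0 = x * c
                    for t in range(kc):
                        dst[x0 + t] += dwin[b, y, x, base + t]


def im2col_pack(xp: np.ndarray, k: int, h: int, w: int) -> np.ndarray:
    """Gather k x k windows of the padded NHWC input into columns.

    Returns an array of shape (n*h*w, k*k*c) whose flat column index is
    (window offset, channel).
    """
    n, hp, wp, c = xp.shape
    cols = np.empty((n, h, w, k * k, c), xp.dtype)
    if HAVE_NUMBA:
        _pack_jit(
            xp.reshape(n, hp, wp * c), k, c, h, w, cols.reshape(n, h, w, k * k * c)
        )
    else:
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i * k + j, :] = xp[:, i : i + h, j : j + w, :]
    return cols.reshape(n * h * w, k * k * c)


def col2im_add(dcols: np.ndarray, k: int, n: int, h: int, w: int, c: int) -> np.ndarray:
    """Scatter-add column gradients back onto a zero padded-input buffer."""
    p = k // 2
    hp, wp = h + 2 * p, w + 2 * p
    dxp = np.zeros((n, hp, wp, c), dcols.dtype)
    dwin = dcols.reshape(n, h, w, k * k, c)
    if HAVE_NUMBA:
        _scatter_jit(
            np.ascontiguousarray(dwin).reshape(n, h, w, k * k * c),
            k,
            c,
            h,
            w,
            dxp.reshape(n, hp, wp * c),
        )
    else:
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dwin[:, :, :, i * k + j, :]
    return dxp
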