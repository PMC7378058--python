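"""Memory-bound array kernels for the CNN engine.

The GEMMs of the conv/FC layers go through BLAS; what remains (patch
extraction, gradient scatter, 2x2 max pooling) is bandwidth-bound and is
JIT-compiled with numba when available, with plain numpy fallbacks that
produce identical results.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]


@njit(cache=False, fastmath=True)
def _nb_im2col(xp, cols):
    """xp: (B, H+2, W+2, C) zero-padded; cols: (B*H*W, 9C) out."""
    B, Hp, Wp, C = xp.shape
    H, W = Hp - 2, Wp - 2
    r = 0
    for b in range(B):
        for y in range(H):
            for x in range(W):
                k = 0
                for dy in range(3):
                    for dx in range(3):
                        for c in range(C):
                            cols[r, k] = xp[b, y + dy, x + dx, c]
                            k += 1
                r += 1


@njit(cache=False, fastmath=True)
def _nb_col2im_add(dcols, dpad):
    """Adjoint of _nb_im2col: scatter-add (B*H*W, 9C) into padded grads."""
    B, Hp, Wp, C = dpad.shape
    H, W = Hp - 2, Wp - 2
    r = 0
    for b in range(B):
        for y in range(H):
            for x in range(W):
                k = 0
                for dy in range(3):
                    for dx in range(3):
                        for c in range(C):
                            dpad[b, y + dy, x + dx, c] += dcols[r, k]
                            k += 1
                r += 1


@njit(cache=False, fastmath=True)
def _nb_convdx_relu_unpool(dcols, r, q, dx):
    """Fused backward tail of a pool -> ReLU -> conv chain.

    ``dcols = dflat @ W.T`` holds per-position patch gradients of the conv
    whose input is the pooled+rectified map ``r`` (B, Hm, Wm, C). For every
    position this gathers the conv input gradient (adjoint of patch
    extraction), masks it by the ReLU derivative of ``r`` and scatters it
    through the max-pool winners ``q`` into the pre-zeroed gradient ``dx``
    of the pre-pool map (B, 2Hm, 2Wm, C). One pass instead of three
    full-size intermediates.
    """
    B, Hm, Wm, C = r.shape
    for b in range(B):
        for y in range(Hm):
            for x in range(Wm):
                for c in range(C):
                    if r[b, y, x, c] <= 0:
                        continue
                    s = np.float32(0.0)
                    for dy in range(3):
                        yo = y - dy + 1
                        if yo < 0 or yo >= Hm:
                            continue
                        for dxo in range(3):
                            xo = x - dxo + 1
                            if xo < 0 or xo >= Wm:
                                continue
                            row = (b * Hm + yo) * Wm + xo
                            s += dcols[row, (dy * 3 + dxo) * C + c]
                    k = q[b, y, x, c]
                    dx[b, 2 * y + (k >> 1), 2 * x + (k & 1), c] = s


def convdx_relu_unpool(dcols, r, q, prepool_shape, ws=None, key="fused_dx"):
    """Wrapper for :func:`_nb_convdx_relu_unpool` with numpy fallback."""
    if ws is None:
        dx = np.zeros(prepool_shape, dtype=dcols.dtype)
    else:
        dx = ws.get(key, prepool_shape, dcols.dtype)
        dx.fill(0)
    if _HAVE_NUMBA:
        _nb_convdx_relu_unpool(dcols, r, q, dx)
        return dx
    dr = col2im3(dcols, r.shape)
    dr = np.where(r > 0, dr, 0.0).astype(dcols.dtype)
    return unpool2(dr, q, prepool_shape) if ws is None else \
        _copy_into(unpool2(dr, q, prepool_shape), dx)


def _copy_into(src, dst):
    np.copyto(dst, src)
    return dst


@njit(cache=False, fastmath=True)
def _nb_pool2(x, m, q):
    """2x2/2 max pool with winning quadrant (ties -> earliest of 00,01,10,11)."""
    B, H, W, C = x.shape
    for b in range(B):
        for py in range(H // 2):
            for px in range(W // 2):
                for c in range(C):
                    v00 = x[b, 2 * py, 2 * px, c]
                    v01 = x[b, 2 * py, 2 * px + 1, c]
                    v10 = x[b, 2 * py + 1, 2 * px, c]
                    v11 = x[b, 2 * py + 1, 2 * px + 1, c]
                    best = v00
                    idx = 0
                    if v01 > best:
                        best = v01
                        idx = 1
                    if v10 > best:
                        best = v10
                        idx = 2
                    if v11 > best:
                        best = v11
                        idx = 3
                    m[b, py, px, c] = best
                    q[b, py, px, c] = idx


@njit(cache=False, fastmath=True)
def _nb_unpool2(dout, q, dx):
    """Scatter pooled gradients to the winning positions (dx pre-zeroed)."""
    B, Hp, Wp, C = dout.shape
    for b in range(B):
        for py in range(Hp):
            for px in range(Wp):
                for c in range(C):
                    k = q[b, py, px, c]
                    dx[b, 2 * py + (k >> 1), 2 * px + (k & 1), c] = \
                        dout[b, py, px, c]


# ---------------------------------------------------------------------------
# public wrappers (numpy fallbacks when numba is unavailable)
# ---------------------------------------------------------------------------

class Workspace:
    """Reusable buffer pool keyed by name; avoids re-allocating the large
    per-batch intermediates (and the page faults that come with them) on
    every SGD step."""

    def __init__(self):
        self._bufs: dict[tuple, np.ndarray] = {}

    def get(self, key, shape, dtype=np.float32):
        full = (key, shape, np.dtype(dtype).str)
        buf = self._bufs.get(full)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._bufs[full] = buf
        return buf


def im2col3(x, ws=None, key="cols"):
    """(B,H,W,C) -> (B*H*W, 9C) 'same'-padded 3x3 patches."""
    B, H, W, C = x.shape
    xp = None if ws is None else ws.get(key + "_pad",
                                        (B, H + 2, W + 2, C), x.dtype)
    if xp is None:
        xp = np.zeros((B, H + 2, W + 2, C), dtype=x.dtype)
    else:
        xp.fill(0)
    xp[:, 1:-1, 1:-1, :] = x
    cols = (np.empty((B * H * W, 9 * C), dtype=x.dtype) if ws is None
            else ws.get(key, (B * H * W, 9 * C), x.dtype))
    if _HAVE_NUMBA:
        _nb_im2col(xp, cols)
        return cols
    view = cols.reshape(B, H, W, 9 * C)
    k = 0
    for dy in range(3):
        for dx in range(3):
            view[..., k * C:(k + 1) * C] = xp[:, dy:dy + H, dx:dx + W, :]
            k += 1
    return cols


def col2im3(dcols, x_shape, ws=None, key="dpad"):
    B, H, W, C = x_shape
    dpad = (np.zeros((B, H + 2, W + 2, C), dtype=dcols.dtype) if ws is None
            else ws.get(key, (B, H + 2, W + 2, C), dcols.dtype))
    if ws is not None:
        dpad.fill(0)
    if _HAVE_NUMBA:
        _nb_col2im_add(dcols, dpad)
    else:
        view = dcols.reshape(B, H, W, 9 * C)
        k = 0
        for dy in range(3):
            for dx in range(3):
                dpad[:, dy:dy + H, dx:dx + W, :] += view[..., k * C:(k + 1) * C]
                k += 1
    out = (np.empty((B, H, W, C), dtype=dcols.dtype) if ws is None
           else ws.get(key + "_out", (B, H, W, C), dcols.dtype))
    np.copyto(out, dpad[:, 1:-1, 1:-1, :])
    return out


def pool2(x, ws=None, key="pool"):
    B, H, W, C = x.shape
    if ws is None:
        m = np.empty((B, H // 2, W // 2, C), dtype=x.dtype)
        q = np.empty((B, H // 2, W // 2, C), dtype=np.int8)
    else:
        m = ws.get(key + "_m", (B, H // 2, W // 2, C), x.dtype)
        q = ws.get(key + "_q", (B, H // 2, W // 2, C), np.int8)
    if _HAVE_NUMBA:
        _nb_pool2(x, m, q)
        return m, q
    x00, x01 = x[:, 0::2, 0::2], x[:, 0::2, 1::2]
    x10, x11 = x[:, 1::2, 0::2], x[:, 1::2, 1::2]
    np.maximum(np.maximum(x00, x01), np.maximum(x10, x11), out=m)
    q[:] = np.where(x00 == m, 0,
                    np.where(x01 == m, 1, np.where(x10 == m, 2, 3)))
    return m, q


def unpool2(dout, q, x_shape, ws=None, key="unpool"):
    if ws is None:
        dx = np.zeros(x_shape, dtype=dout.dtype)
    else:
        dx = ws.get(key, x_shape, dout.dtype)
        dx.fill(0)
    if _HAVE_NUMBA:
        _nb_unpool2(dout, q, dx)
        return dx
    B, H, W, C = x_shape
    for sy, sx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        hit = q == (sy * 2 + sx)
        sub = dx[:, sy::2, sx::2]
        sub[hit] = dout[hit]
    return dx
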