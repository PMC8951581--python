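"""Inner convolution kernels.

Numba-jitted loops when numba is importable (cached to disk after first
compilation), otherwise a pure-numpy per-offset einsum fallback with
identical semantics.  Both paths compute stride-1 cross-correlation on a
pre-padded input.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def _corr3d_np(xp: np.ndarray, w: np.ndarray, out: np.ndarray) -> None:
    k = w.shape[2]
    do, ho, wo = out.shape[2:]
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, :, i:i + do, j:j + ho, l:l + wo]
                out += np.einsum("oc,ncdhw->nodhw", w[:, :, i, j, l], xs,
                                 optimize=True)


def _corr3d_dw_np(xp: np.ndarray, go: np.ndarray, dw: np.ndarray) -> None:
    k = dw.shape[2]
    do, ho, wo = go.shape[2:]
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, :, i:i + do, j:j + ho, l:l + wo]
                dw[:, :, i, j, l] = np.einsum("nodhw,ncdhw->oc", go, xs,
                                              optimize=True)


if _HAVE_NUMBA:

    @numba.njit(fastmath=True, cache=True)
    def _corr3d_nb(xp, w, out):  # pragma: no cover - exercised via wrapper
        n_b, ci_n, _, _, _ = xp.shape
        co_n = w.shape[0]
        k = w.shape[2]
        do, ho, wo = out.shape[2], out.shape[3], out.shape[4]
        for n in range(n_b):
            for o in range(co_n):
                for ci in range(ci_n):
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                wv = w[o, ci, i, j, l]
                                for d in range(do):
                                    for h in range(ho):
                                        for x in range(wo):
                                            out[n, o, d, h, x] += (
                                                wv * xp[n, ci, d + i, h + j, x + l])

def corr3d(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """out[n,o] = sum_{ci,offset} w[o,ci,offset] * xp[n,ci,shifted] (valid)."""
    k = w.shape[2]
    shape = (xp.shape[0], w.shape[0]) + tuple(s - k + 1 for s in xp.shape[2:])
    out = np.zeros(shape, dtype=np.float32)
    if _HAVE_NUMBA:
        _corr3d_nb(xp, w, out)
    else:
        _corr3d_np(xp, w, out)
    return out


def corr3d_dw(xp: np.ndarray, go: np.ndarray, w_shape: tuple) -> np.ndarray:
    """Gradient of corr3d w.r.t. the kernel (einsum: pairwise-summed, fast)."""
    dw = np.empty(w_shape, dtype=np.float32)
    _corr3d_dw_np(xp, go, dw)
    return dw
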