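"""Optional numba inner loops for the two curve-length features.

Higuchi curve lengths and DFA fluctuations are the only windowed features
whose batch computation is loop-bound; when numba is importable they are
JIT-compiled, otherwise the vectorized numpy fallbacks in
:mod:`.features` are used.  Both paths produce the same numbers (the test
suite holds every batch value to the per-window reference operations).
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def higuchi_lengths(frames: np.ndarray, k_max: int) -> np.ndarray:
    """Average normalized curve length L(k) per frame, k = 1..k_max."""
    n_frames, n = frames.shape
    out = np.empty((n_frames, k_max))
    for f in range(n_frames):
        for k in range(1, k_max + 1):
            acc = 0.0
            cnt = 0
            for m in range(1, k + 1):
                n_i = (n - m) // k
                if n_i < 1:
                    continue
                s = 0.0
                prev = frames[f, m - 1]
                for i in range(1, n_i + 1):
                    cur = frames[f, m - 1 + i * k]
                    s += abs(cur - prev)
                    prev = cur
                acc += s * (n - 1) / (n_i * k * k)
                cnt += 1
            out[f, k - 1] = acc / cnt
    return out


@njit(cache=False)
def dfa_fluctuations(frames: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """RMS detrended fluctuation F(n) per frame for each scale."""
    n_frames, n = frames.shape
    n_scales = scales.size
    out = np.empty((n_frames, n_scales))
    z = np.empty(n)
    for f in range(n_frames):
        mean = 0.0
        for i in range(n):
            mean += frames[f, i]
        mean /= n
        acc = 0.0
        for i in range(n):
            acc += frames[f, i] - mean
            z[i] = acc
        for si in range(n_scales):
            ns = scales[si]
            m = n // ns
            c = (ns - 1) / 2.0
            stc2 = ns * (ns * ns - 1.0) / 12.0
            rss_total = 0.0
            for j in range(m):
                base = j * ns
                sy = 0.0
                for i in range(ns):
                    sy += z[base + i]
                a = sy / ns
                syy = 0.0
                sty = 0.0
                for i in range(ns):
                    y = z[base + i] - a
                    syy += y * y
                    sty += (i - c) * y
                b = sty / stc2
                rss = syy - b * b * stc2
                if rss > 0.0:
                    rss_total += rss
            out[f, si] = np.sqrt(rss_total / (m * ns))
    return out
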