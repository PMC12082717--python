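"""Independent brute-force reference implementations used by the tests.

Everything here is written directly from the defining formulas with plain
loops and full DFTs, deliberately sharing no code with the package: the
package's vectorized paths are checked against these.
"""
from __future__ import annotations

import numpy as np


def one_sided_power(x):
    """|DFT|^2 at bins 1..N//2 (DC excluded, Nyquist included)."""
    full = np.abs(np.fft.fft(np.asarray(x, float))) ** 2
    return full[1: len(x) // 2 + 1]


def spectral_entropy(x):
    s = one_sided_power(x)
    p = s / s.sum()
    h = 0.0
    for pi in p:
        if pi > 0:
            h -= pi * np.log2(pi)
    return h


def hjorth_mobility(x):
    x = np.asarray(x, float)
    d = x[1:] - x[:-1]
    return np.sqrt(np.mean((d - d.mean()) ** 2) / np.mean((x - x.mean()) ** 2))


def hjorth_complexity(x):
    d = np.asarray(x, float)
    d = d[1:] - d[:-1]
    return hjorth_mobility(d) / hjorth_mobility(x)


def higuchi_fd(x, k_max):
    x = np.asarray(x, float)
    n = len(x)
    log_inv_k, log_l = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                continue
            total = 0.0
            for i in range(1, n_i + 1):
                total += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            lengths.append(total * (n - 1) / (n_i * k * k))
        log_inv_k.append(np.log(1.0 / k))
        log_l.append(np.log(np.mean(lengths)))
    return np.polyfit(log_inv_k, log_l, 1)[0]


def band_power(x, fs, f1, f2, total_band):
    s = one_sided_power(x)
    freqs = np.arange(1, len(x) // 2 + 1) * fs / len(x)
    lo, hi = total_band
    denom = sum(si for si, f in zip(s, freqs) if lo <= f < hi)
    num = sum(si for si, f in zip(s, freqs)
              if f1 <= f < f2 and lo <= f < hi)
    return num / denom


def dfa(x, scales):
    x = np.asarray(x, float)
    z = np.cumsum(x - x.mean())
    log_n, log_f = [], []
    for n in sorted(set(int(s) for s in scales)):
        m = len(z) // n
        sq_errs = []
        for j in range(m):
            seg = z[j * n:(j + 1) * n]
            t = np.arange(n)
            coeff = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coeff, t)
            sq_errs.append(np.mean(resid ** 2))
        log_n.append(np.log(n))
        log_f.append(0.5 * np.log(np.mean(sq_errs)))
    return np.polyfit(log_n, log_f, 1)[0]


def lower_median(values):
    v = sorted(float(x) for x in values)
    return v[(len(v) - 1) // 2]


def exhaustive_interval_search(d, threshold, hop_s, window_s, min_duration_s):
    """Brute-force search over every pair of supra-threshold endpoints.

    Qualifying span: endpoints above threshold, duration (last window end
    minus first window start) >= min_duration_s, lower median of the
    distances strictly above the threshold.  Returns the (i, j) window
    indices maximizing (excess, length, start index), or None.
    """
    d = np.asarray(d, float)
    n = len(d)
    best = None
    best_key = None
    for i in range(n):
        if not d[i] > threshold:
            continue
        for j in range(i, n):
            if not d[j] > threshold:
                continue
            if (j - i) * hop_s + window_s < min_duration_s - 1e-9:
                continue
            seg = d[i:j + 1]
            if not lower_median(seg) > threshold:
                continue
            excess = int((seg > threshold).sum()) - int((seg <= threshold).sum())
            key = (excess, j - i, i)
            if best_key is None or key > best_key:
                best, best_key = (i, j), key
    return best
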