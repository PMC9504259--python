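"""Independent brute-force evaluators used as oracles in the tests.

Everything here is written as literal loops over the defining formulas,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def bf_mav(window) -> float:
    total = 0.0
    for v in window:
        total += abs(v)
    return total / len(window)


def bf_mavs(mavs) -> list:
    out = []
    for i in range(len(mavs) - 1):
        out.append(mavs[i + 1] - mavs[i])
    out.append(0.0)
    return out


def bf_zc(window, threshold=0.01) -> int:
    count = 0
    for k in range(len(window) - 1):
        a, b = window[k], window[k + 1]
        crossing = (a > 0 and b < 0) or (a < 0 and b > 0)
        if crossing and abs(a - b) >= threshold:
            count += 1
    return count


def bf_ssc(window, threshold=0.01) -> int:
    count = 0
    for k in range(1, len(window) - 1):
        p, c, n = window[k - 1], window[k], window[k + 1]
        extremum = (c > p and c > n) or (c < p and c < n)
        if extremum and abs(c - n) >= threshold:
            count += 1
    return count


def bf_wl(window) -> float:
    total = 0.0
    for k in range(1, len(window)):
        total += abs(window[k] - window[k - 1])
    return total


def bf_windows(signal, window_len, overlap) -> list:
    """Enumerate buffer-style windows: starts at multiples of the stride,
    zero-padding past the end."""
    stride = window_len - overlap
    windows = []
    start = 0
    while start < len(signal):
        w = []
        for i in range(start, start + window_len):
            w.append(signal[i] if i < len(signal) else 0.0)
        windows.append(w)
        start += stride
    return windows


def bf_cwt_row(signal, psi_hat_vals) -> np.ndarray:
    """Direct DFT evaluation of one filter-bank row: for each shift b,
    (1/N) * sum_k X_k * psi_hat(s*omega_k) * exp(i*omega_k*b), with X_k
    computed by a literal DFT double loop."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    X = np.empty(n, dtype=complex)
    for k in range(n):
        acc = 0.0 + 0.0j
        for t in range(n):
            acc += x[t] * np.exp(-2j * math.pi * k * t / n)
        X[k] = acc
    out = np.empty(n, dtype=complex)
    for b in range(n):
        acc = 0.0 + 0.0j
        for k in range(n):
            acc += X[k] * psi_hat_vals[k] * np.exp(2j * math.pi * k * b / n)
        out[b] = acc / n
    return np.abs(out)
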