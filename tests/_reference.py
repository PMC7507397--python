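"""Naive, loop-based reference implementations used as independent oracles.

These are deliberately written in the most literal way possible (explicit
DFT sums, explicit convolution loops, explicit normal equations) and must
stay independent of the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def reference_wtc(x, y, fs, omega0=6.0, voices=12, period_min=2.0, period_max=16.0):
    """Literal implementation of the squared wavelet coherence definition.

    Returns (r2[s, t], periods, coi[t]).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    dt = 1.0 / fs

    ff = 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 * omega0))
    s0 = period_min / ff
    n_octaves = np.log2(period_max / period_min)
    n_scales = int(np.floor(n_octaves * voices)) + 1
    scales = np.array([s0 * 2.0 ** (j / voices) for j in range(n_scales)])

    n_fft = 1
    while n_fft < n:
        n_fft *= 2

    # explicit DFT via matrix product (still literal, just not O(N^2) python loops)
    tgrid = np.arange(n_fft)
    Fmat = np.exp(-2j * np.pi * np.outer(tgrid, tgrid) / n_fft)

    def cwt(sig):
        sig = sig - sig.mean()
        padded = np.zeros(n_fft)
        padded[:n] = sig
        xhat = Fmat @ padded
        omega = np.zeros(n_fft)
        for k in range(n_fft):
            kk = k if k <= n_fft // 2 else k - n_fft
            omega[k] = 2.0 * np.pi * kk / (n_fft * dt)
        W = np.zeros((n_scales, n), dtype=complex)
        for j, s in enumerate(scales):
            psi = np.zeros(n_fft)
            for k in range(n_fft):
                if omega[k] > 0:
                    psi[k] = (
                        np.pi ** (-0.25)
                        * np.sqrt(2.0 * np.pi * s / dt)
                        * np.exp(-0.5 * (s * omega[k] - omega0) ** 2)
                    )
            prod = xhat * psi
            full = (np.conj(Fmat) @ prod) / n_fft
            W[j] = full[:n]
        return W

    Wx = cwt(x)
    Wy = cwt(y)

    # circular convolution sum  out[t] = sum_u arr[(t - u) mod n] * k[u],
    # written as one literal index table
    tt = np.arange(n)
    conv_idx = (tt[:, None] - tt[None, :]) % n

    def smooth(arr):
        # circular Gaussian in time, kernel sampled on the grid
        out_t = np.zeros_like(arr)
        for j, s in enumerate(scales):
            sigma = s / np.sqrt(2.0)
            k = np.zeros(n)
            for i in range(n):
                d = min(i, n - i) * dt
                k[i] = np.exp(-0.5 * (d / sigma) ** 2)
            k = k / k.sum()
            out_t[j] = arr[j][conv_idx] @ k
        # centered boxcar over scales, truncated and renormalized
        win = max(1, int(round(0.6 * voices)))
        half = win // 2
        out = np.zeros_like(arr)
        for j in range(n_scales):
            lo = max(0, j - half)
            hi = min(n_scales, j + half + 1)
            out[j] = out_t[lo:hi].sum(axis=0) / (hi - lo)
        return out

    inv_s = 1.0 / scales[:, None]
    sxx = smooth((np.abs(Wx) ** 2 * inv_s).astype(complex)).real
    syy = smooth((np.abs(Wy) ** 2 * inv_s).astype(complex)).real
    sxy = smooth(Wx * np.conj(Wy) * inv_s)
    r2 = np.abs(sxy) ** 2 / (sxx * syy)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-10)

    periods = scales * ff
    coi = np.zeros(n)
    for t in range(n):
        coi[t] = ff / np.sqrt(2.0) * min(t, n - 1 - t) * dt
    return r2, periods, coi


def reference_bh(p_values: dict, q: float = 0.05):
    """Literal BH step-up loop: sort, scan from the largest rank down."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    k_star = 0
    for k in range(1, m + 1):
        if items[k - 1][1] <= k / m * q:
            k_star = k
    return {items[i][0] for i in range(k_star)}


def reference_gc(x, y, p):
    """Granger causality x->y via explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    rows = []
    t_own, t_full, targ = [], [], []
    for t in range(p, n):
        own = [1.0] + [y[t - k] for k in range(1, p + 1)]
        full = own + [x[t - k] for k in range(1, p + 1)]
        t_own.append(own)
        t_full.append(full)
        targ.append(y[t])
    A_own = np.array(t_own)
    A_full = np.array(t_full)
    b = np.array(targ)

    def rss(A):
        beta = np.linalg.solve(A.T @ A, A.T @ b)
        r = b - A @ beta
        return float(r @ r)

    return np.log(rss(A_own) / rss(A_full))


def reference_one_sample_t(values, mu0=0.0):
    v = np.asarray(values, float)
    n = v.size
    m = v.mean()
    sd = np.sqrt(((v - m) ** 2).sum() / (n - 1))
    return (m - mu0) / (sd / np.sqrt(n))


def reference_paired_t(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    return reference_one_sample_t(d)
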