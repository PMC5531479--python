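"""Independent brute-force references used only by the test suite.

These implement the defining equations directly (triple loops, no shared
code with the package) so they can serve as oracles for the vectorised
implementations.
"""

import numpy as np
from scipy.signal.windows import hann


def zamd_direct(x, y, l_h, l_g, n_freq_bins, hermitian_fill=False):
    """Direct evaluation of the discrete two-window cone-kernel distribution:
    for each time t and lag m, the g-weighted average of
    x[u+m] * conj(y[u-m]) over the cone |u - t| <= |m|, tapered by h(m) and
    Fourier-transformed over the lag."""
    n = len(x)
    N = n_freq_bins
    lh = (l_h - 1) // 2
    lg = (l_g - 1) // 2
    m_max = min(lh, N // 2 - 1, n - 1)
    h = hann(l_h, sym=True)
    h = h / h[lh]
    g = hann(l_g, sym=True)
    g = g / g.sum()
    S = np.zeros((n, N), dtype=complex)
    for t in range(n):
        K = np.zeros(N, dtype=complex)
        for m in range(-m_max, m_max + 1):
            c = min(abs(m), lg)
            mass = g[lg] + 2 * g[lg + 1 : lg + 1 + c].sum()
            acc = 0.0
            for p in range(-c, c + 1):
                i1, i2 = t + p + m, t + p - m
                if 0 <= i1 < n and 0 <= i2 < n:
                    acc += g[lg + p] * x[i1] * np.conj(y[i2])
            K[m % N] = h[lh + m] * acc / mass
        S[t] = np.fft.fft(K)
    return S


def wigner_ville(x):
    """Plain discrete Wigner-Ville distribution of an analytic signal
    (rectangular full-length windows, no smoothing); used to demonstrate the
    cone kernel's interference suppression."""
    n = len(x)
    W = np.zeros((n, n))
    for t in range(n):
        m_max = min(t, n - 1 - t, n // 2 - 1)
        K = np.zeros(n, dtype=complex)
        for m in range(-m_max, m_max + 1):
            K[m % n] = x[t + m] * np.conj(x[t - m])
        W[t] = np.fft.fft(K).real
    return W


def wilcoxon_exact_p(diffs):
    """Exact two-sided signed-rank p-value by enumerating all sign
    assignments (feasible for small n)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # midranks for ties
    absd = np.abs(d)
    for v in np.unique(absd):
        sel = absd == v
        ranks[sel] = ranks[sel].mean()
    w_obs = ranks[d > 0].sum()
    w_all = []
    for mask in range(2**n):
        signs = [(mask >> k) & 1 for k in range(n)]
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    mean_w = ranks.sum() / 2
    p = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return float(p)
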