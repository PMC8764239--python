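"""Independent brute-force reference implementations used as test oracles.

Everything here is written as explicit per-sample loops over Python scalars,
deliberately sharing no code with the package's vectorized estimators.
"""

import cmath
import math
from collections import Counter


def plv_oracle(phase_i, phase_k):
    total = 0j
    t = len(phase_i)
    for a, b in zip(phase_i, phase_k):
        total += cmath.exp(1j * (a - b))
    return abs(total / t)


def pli_oracle(z_i, z_k):
    def sgn(x):
        if x > 0:
            return 1
        if x < 0:
            return -1
        return 0

    total = 0
    for a, b in zip(z_i, z_k):
        total += sgn((a * b.conjugate()).imag)
    return abs(total / len(z_i))


def pcc_oracle(x_i, x_k):
    t = len(x_i)
    mu_i = sum(x_i) / t
    mu_k = sum(x_k) / t
    sd_i = math.sqrt(sum((v - mu_i) ** 2 for v in x_i) / t)
    sd_k = math.sqrt(sum((v - mu_k) ** 2 for v in x_k) / t)
    cov = sum((a - mu_i) * (b - mu_k) for a, b in zip(x_i, x_k)) / t
    return cov / (sd_i * sd_k)


def _bin_indices(x, bins):
    lo, hi = min(x), max(x)
    if hi == lo:
        return [0] * len(x)
    width = (hi - lo) / bins
    out = []
    for v in x:
        b = int((v - lo) / width)
        if b >= bins:
            b = bins - 1
        out.append(b)
    return out


def te_oracle(x_i, x_k, bins=4, lag=1):
    """Plug-in transfer entropy in bits via dictionary counting."""
    bi = _bin_indices(list(x_i), bins)
    bk = _bin_indices(list(x_k), bins)
    n = len(bi) - lag
    triples = [(bi[t], bk[t], bk[t + lag]) for t in range(n)]
    c_abc = Counter(triples)
    c_ab = Counter((a, b) for a, b, _ in triples)
    c_bc = Counter((b, c) for _, b, c in triples)
    c_b = Counter(b for _, b, _ in triples)
    te = 0.0
    for (a, b, c), n_abc in c_abc.items():
        p_abc = n_abc / n
        p_c_given_ab = n_abc / c_ab[(a, b)]
        p_c_given_b = c_bc[(b, c)] / c_b[b]
        te += p_abc * math.log2(p_c_given_ab / p_c_given_b)
    return max(te, 0.0)
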