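"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written from the defining formulas
(enumeration, direct matrix algebra, grid search) and shares no code paths
with the package implementation it checks.
"""

import itertools
import math

import numpy as np
from scipy import optimize

# haplotype h (0..7) has alleles (bit2, bit1, bit0) = (SNP1, SNP2, SNP3)
HAPS = [( (h >> 2) & 1, (h >> 1) & 1, h & 1) for h in range(8)]


# ---------------------------------------------------------------------------
# popgen formulas
# ---------------------------------------------------------------------------

def hwe_g_oracle(naa, nab, nbb):
    """G and Williams-corrected G for the 3-class HWE goodness-of-fit."""
    n = naa + nab + nbb
    p = (2 * naa + nab) / (2 * n)
    exp = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)]
    g = 0.0
    for o, e in zip((naa, nab, nbb), exp):
        if o > 0:
            g += 2 * o * math.log(o / e)
    q = 1 + (9 - 1) / (6 * n * (3 - 1))
    return g, g / q


def gtest_cont_oracle(table):
    """Contingency G with the Williams correction for an r x c table."""
    t = [list(map(float, row)) for row in table]
    r, c = len(t), len(t[0])
    row = [sum(x) for x in t]
    col = [sum(t[i][j] for i in range(r)) for j in range(c)]
    n = sum(row)
    g = 0.0
    for i in range(r):
        for j in range(c):
            if t[i][j] > 0:
                g += 2 * t[i][j] * math.log(t[i][j] * n / (row[i] * col[j]))
    df = (r - 1) * (c - 1)
    q = 1 + ((n * sum(1 / x for x in row) - 1)
             * (n * sum(1 / x for x in col) - 1)) / (6 * n * df)
    return g / q, df


def ld_oracle(t):
    """D, D', r from a 2x2 haplotype count table (rows/cols: allele A, B)."""
    t = np.asarray(t, dtype=float)
    n = t.sum()
    p_a = t[0].sum() / n
    p_b = t[:, 0].sum() / n
    d = t[0, 0] / n - p_a * p_b
    if d > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    r = d / math.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    return d, (abs(d) / dmax if dmax > 0 else 0.0), r


def wc_theta_oracle(per_breed_counts):
    """Weir-Cockerham theta from allele counts, HWE heterozygosity."""
    r = len(per_breed_counts)
    n = [t / 2 for _, t in per_breed_counts]
    p = [b / t for b, t in per_breed_counts]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    h = [2 * pi * (1 - pi) for pi in p]
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


# ---------------------------------------------------------------------------
# haplotype likelihood by enumeration
# ---------------------------------------------------------------------------

def _compatible(genotype, i, j):
    for g, ai, aj in zip(genotype, HAPS[i], HAPS[j]):
        if g >= 0 and ai + aj != g:
            return False
    return True


def genotype_prob(genotype, freqs):
    """P(genotype) by summing over all ordered haplotype pairs."""
    return sum(freqs[i] * freqs[j]
               for i in range(8) for j in range(8)
               if _compatible(genotype, i, j))


def window_loglik(genotypes, freqs):
    return float(sum(math.log(genotype_prob(tuple(g), freqs))
                     for g in genotypes))


def diplotype_posterior_oracle(genotype, freqs):
    """Posterior over unordered diplotypes (i <= j) by direct enumeration."""
    weights = {}
    for i in range(8):
        for j in range(i, 8):
            if _compatible(genotype, i, j):
                weights[(i, j)] = freqs[i] * freqs[j] * (2 if i != j else 1)
    total = sum(weights.values())
    if total == 0:
        return {k: 1 / len(weights) for k in weights}
    return {k: v / total for k, v in weights.items()}


def _simplex_grid(k, steps):
    """All compositions of `steps` into k parts, as frequency vectors."""
    out = []
    for cuts in itertools.combinations(range(steps + k - 1), k - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(steps + k - 2 - prev)
        out.append([p / steps for p in parts])
    return np.array(out)


def em_oracle_freqs(genotypes, support, steps=50):
    """ML haplotype frequencies by simplex grid search plus a softmax
    polish of the observed-data likelihood (independent of EM)."""
    support = list(support)
    k = len(support)
    grid = _simplex_grid(k, steps)
    best_ll, best = -np.inf, None
    for row in grid:
        freqs = np.zeros(8)
        freqs[support] = row
        try:
            ll = window_loglik(genotypes, freqs)
        except ValueError:
            continue
        if ll > best_ll:
            best_ll, best = ll, row

    def neg_ll(theta):
        w = np.exp(theta - theta.max())
        f = np.zeros(8)
        f[support] = w / w.sum()
        probs = [genotype_prob(tuple(g), f) for g in genotypes]
        if min(probs) <= 0:
            return 1e12
        return -sum(math.log(p) for p in probs)

    theta0 = np.log(np.maximum(best, 1e-6))
    res = optimize.minimize(neg_ll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
    w = np.exp(res.x - res.x.max())
    freqs = np.zeros(8)
    freqs[support] = w / w.sum()
    return freqs, -res.fun


# ---------------------------------------------------------------------------
# restricted likelihood by direct matrix algebra
# ---------------------------------------------------------------------------

def reml_loglik_direct(lam, y, X, A):
    """Restricted log-likelihood at variance ratio lambda, with sigma2_e
    profiled out, computed with explicit inverses (no eigen shortcut)."""
    n, p = X.shape
    H = lam * A + np.eye(n)
    Hi = np.linalg.inv(H)
    G = X.T @ Hi @ X
    Gi = np.linalg.inv(G)
    beta = Gi @ X.T @ Hi @ y
    r = y - X @ beta
    q = float(r @ Hi @ r)
    s2e = q / (n - p)
    _, ldh = np.linalg.slogdet(H)
    _, ldg = np.linalg.slogdet(G)
    return -0.5 * ((n - p) * (1 + math.log(2 * math.pi) + math.log(s2e))
                   + ldh + ldg)
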