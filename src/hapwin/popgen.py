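"""Descriptive population-genetic statistics, computed per breed.

Implements the window-characterisation statistics used around the association
analysis: the Hardy-Weinberg G-test with the Williams correction, the
contingency G-test for count heterogeneity between breeds, pairwise linkage
disequilibrium (D, D', r, r-squared with the 1/n small-sample correction),
the Weir & Cockerham (1984) F_ST estimator, and a per-gene LD summary with
the polarity-consistency measure.

All statistics are meant to be computed within breed, never on pooled
mixed-breed samples: breed divergence would otherwise masquerade as
disequilibrium.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HweResult",
    "LdSummary",
    "FstResult",
    "hwe_gtest",
    "gtest_heterogeneity",
    "ld_pair",
    "fst_weir_cockerham",
    "fst_multilocus",
    "ld_summary_by_gene",
]


@dataclasses.dataclass(frozen=True)
class HweResult:
    G: float
    G_adj: float
    df: int
    p: float


@dataclasses.dataclass(frozen=True)
class LdSummary:
    D: float
    Dprime: float
    r: float
    r2: float
    r2_corrected: float  # r2 - 1/n, deliberately unfloored
    n: int  # number of haplotypes (2 x individuals)
    distance_bp: int = 0


@dataclasses.dataclass(frozen=True)
class FstResult:
    theta: float
    a: float  # among-population variance component
    b: float  # between-individuals-within-population component
    c: float  # within-individual component


def hwe_gtest(n_aa: int, n_ab: int, n_bb: int) -> HweResult:
    """Hardy-Weinberg goodness-of-fit G-test over the 3 genotype classes.

    Expected counts come from the maximum-likelihood allele frequency;
    df = 1 (3 classes, 1 estimated frequency); the Williams correction for
    k = 3 classes is q = 1 + (k^2 - 1) / (6 n (k - 1)); zero-count cells
    contribute 0 to G.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one individual")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        raise ValueError("monomorphic sample: HWE test has undefined df")
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    obs = counts[counts > 0]
    exp = expected[counts > 0]
    g = 2.0 * float(np.sum(obs * np.log(obs / exp)))
    g = max(g, 0.0)
    k = 3
    q = 1.0 + (k * k - 1) / (6.0 * n * (k - 1))
    g_adj = g / q
    return HweResult(G=g, G_adj=g_adj, df=1, p=float(stats.chi2.sf(g_adj, 1)))


def gtest_heterogeneity(counts) -> tuple[float, int, float]:
    """Contingency G-test (e.g. breeds x genotype/haplotype categories) with
    the Williams correction for contingency tables.

    All-zero rows and columns are dropped first; the table must remain at
    least 2x2.  Returns (G_adj, df, p).
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    r, c = t.shape
    if r < 2 or c < 2:
        raise ValueError("degenerate table after dropping empty rows/columns")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    expected = np.outer(row, col) / n
    mask = t > 0
    g = 2.0 * float(np.sum(t[mask] * np.log(t[mask] / expected[mask])))
    g = max(g, 0.0)
    df = (r - 1) * (c - 1)
    q = 1.0 + ((n * np.sum(1.0 / row) - 1) * (n * np.sum(1.0 / col) - 1)
               / (6.0 * n * df))
    g_adj = g / q
    return g_adj, df, float(stats.chi2.sf(g_adj, df))


def _tabulate_haplotypes(haplotypes: Sequence[tuple[int, int]]) -> np.ndarray:
    t = np.zeros((2, 2))
    for a, b in haplotypes:
        t[int(a), int(b)] += 1
    return t


def ld_pair(hap_counts=None, *, freqs: Optional[np.ndarray] = None,
            n: Optional[int] = None, distance_bp: int = 0) -> LdSummary:
    """Pairwise LD between two biallelic SNPs from phased haplotype data.

    Input is either a 2x2 table of haplotype counts (rows = allele at the
    first SNP in order A,B; columns = allele at the second SNP), a list of
    (allele1, allele2) haplotypes coded 0/1, or a 2x2 `freqs` table with the
    haplotype sample size `n`.

    D = p_AB - p_A p_B; D' = |D| / D_max with the sign-dependent bound;
    r = D / sqrt(p_A q_A p_B q_B); r2_corrected = r^2 - 1/n (not floored).
    """
    if hap_counts is not None:
        t = np.asarray(hap_counts, dtype=float)
        if t.shape != (2, 2):
            t = _tabulate_haplotypes(hap_counts)
        n = int(round(t.sum()))
        f = t / t.sum()
    else:
        if freqs is None or n is None:
            raise ValueError("provide hap_counts, or freqs with n")
        f = np.asarray(freqs, dtype=float)
        f = f / f.sum()
    p_a = f[0, :].sum()  # allele A at first SNP
    p_b = f[:, 0].sum()  # allele A at second SNP
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic SNP: LD undefined")
    d = f[0, 0] - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(d) / d_max if d_max > 0 else 0.0
    r = d / math.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    r2 = r * r
    return LdSummary(D=d, Dprime=dprime, r=r, r2=r2,
                     r2_corrected=r2 - 1.0 / n, n=n, distance_bp=distance_bp)


def fst_weir_cockerham(per_breed_allele_counts: Sequence[tuple[int, int]],
                       het_counts: Optional[Sequence[int]] = None) -> FstResult:
    """Weir & Cockerham (1984) theta for one biallelic locus.

    `per_breed_allele_counts` is a list of (count of B alleles, total allele
    count) per breed; total allele count = 2 x individuals sampled.  If
    observed heterozygote counts are not supplied, within-breed
    Hardy-Weinberg proportions are assumed for the heterozygosity term.
    """
    counts = [(int(b), int(t)) for b, t in per_breed_allele_counts]
    if len(counts) < 2:
        raise ValueError("F_ST needs at least two breeds")
    if any(t < 1 for _, t in counts):
        raise ValueError("every breed needs at least one sampled allele")
    r = len(counts)
    n_i = np.array([t / 2.0 for _, t in counts])  # individuals
    p_i = np.array([b / t for b, t in counts])
    if het_counts is not None:
        h_i = np.array([h / ni for h, ni in zip(het_counts, n_i)])
    else:
        h_i = 2.0 * p_i * (1.0 - p_i)
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = float((n_i * p_i).sum() / (r * n_bar))
    s2 = float((n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar))
    h_bar = float((n_i * h_i).sum() / (r * n_bar))
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                               - h_bar / 4.0) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else 0.0
    return FstResult(theta=float(theta), a=float(a), b=float(b), c=float(c))


def fst_multilocus(loci: Sequence[Sequence[tuple[int, int]]]) -> float:
    """Multi-locus Weir-Cockerham theta: ratio of summed numerators to
    summed denominators over loci (monomorphic loci are skipped)."""
    num = den = 0.0
    used = 0
    for locus in loci:
        total_b = sum(b for b, _ in locus)
        total = sum(t for _, t in locus)
        if total_b == 0 or total_b == total:
            continue
        res = fst_weir_cockerham(locus)
        num += res.a
        den += res.a + res.b + res.c
        used += 1
    if used == 0 or den == 0:
        raise ValueError("no polymorphic loci for multi-locus F_ST")
    return num / den


def ld_summary_by_gene(
    ld_by_gene: Mapping[str, Mapping[str, LdSummary]],
    window_lengths: Mapping[str, int],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene LD summary across breeds plus LD-vs-length regression.

    For each gene: breed-mean D' and r2, the polarity consistency
    max(#breeds r>0, #breeds r<0) / #breeds with defined r, and the number
    of informative breeds (genes with < 2 informative breeds are flagged in
    the `flagged` column, not dropped).  The slopes are ordinary
    least-squares slopes of the breed-mean D' and r2 on window length in bp
    across genes.
    """
    rows = []
    for gene, per_breed in ld_by_gene.items():
        vals = list(per_breed.values())
        n_inf = len(vals)
        pos = sum(1 for v in vals if v.r > 0)
        neg = sum(1 for v in vals if v.r < 0)
        defined = pos + neg
        rows.append({
            "gene": gene,
            "length_bp": int(window_lengths[gene]),
            "mean_Dprime": float(np.mean([v.Dprime for v in vals])) if vals else np.nan,
            "mean_r2": float(np.mean([v.r2 for v in vals])) if vals else np.nan,
            "polarity_consistency": (max(pos, neg) / defined) if defined else np.nan,
            "n_breeds": n_inf,
            "flagged": n_inf < 2,
        })
    df = pd.DataFrame(rows)
    slopes = {}
    for col in ("mean_Dprime", "mean_r2"):
        sub = df.dropna(subset=[col])
        if len(sub) >= 2 and sub["length_bp"].nunique() > 1:
            slope = float(np.polyfit(sub["length_bp"], sub[col], 1)[0])
        else:
            slope = float("nan")
        slopes[col] = slope
    return df, slopes
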