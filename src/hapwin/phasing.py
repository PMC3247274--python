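"""Haplotype inference for 3-SNP windows by exact EM, and dosage matrices.

A window of 3 biallelic SNPs has 8 possible haplotypes, labelled h111..h222
with 1 = A allele and 2 = B allele at each position (h111 = AAA, h222 = BBB).
For such tiny windows the latent space per individual is at most a handful of
diplotype configurations, so haplotype frequencies can be estimated per
stratum (breed) by exact EM over the 8-point frequency simplex, with missing
genotypes marginalised in the E-step.  Phase assignment, missing-genotype
imputation and the minor-haplotype-frequency (MHF) filtered dosage matrix
all reuse the same posterior.

Individuals are treated as unrelated within a stratum for the purpose of
phasing; relatedness is handled downstream by the animal model.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MISSING

N_SNPS = 3
N_HAPS = 8

#: haplotype bit patterns: row h = (allele at SNP1, SNP2, SNP3), 0 = A, 1 = B;
#: ordered so that index == binary code with SNP1 as the most significant bit,
#: i.e. lexicographic in the h111..h222 labels.
HAP_ALLELES = np.array(list(itertools.product((0, 1), repeat=N_SNPS)), dtype=np.int8)
HAP_LABELS = ["h" + "".join(str(a + 1) for a in row) for row in HAP_ALLELES]

#: unordered diplotypes (i, j) with i <= j, in lexicographic order
DIPLOTYPES = [(i, j) for i in range(N_HAPS) for j in range(i, N_HAPS)]
_DIP_SUMS = np.array([HAP_ALLELES[i] + HAP_ALLELES[j] for i, j in DIPLOTYPES],
                     dtype=np.int8)  # (36, 3) genotype implied by each diplotype

__all__ = [
    "HAP_LABELS",
    "DIPLOTYPES",
    "BreedHapFreqs",
    "DosageMatrix",
    "WindowPhaser",
    "em_window_freqs",
    "posterior_diplotypes",
    "assign_dosages",
    "build_dosage_matrix",
]


@dataclasses.dataclass
class BreedHapFreqs:
    """EM haplotype frequency estimate for one stratum."""

    stratum: str
    freqs: np.ndarray  # (8,) probabilities over HAP_LABELS
    n_individuals: int
    loglik: float
    n_iter: int = 0
    loglik_trace: Optional[np.ndarray] = None

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (N_HAPS,) or (f < -1e-12).any() or abs(f.sum() - 1) > 1e-10:
            raise ValueError("freqs must be an 8-vector summing to 1")
        self.freqs = np.clip(f, 0.0, None)


@dataclasses.dataclass
class DosageMatrix:
    """Copies of each retained haplotype per individual.

    Under ML assignment entries are integers in {0,1,2} and each row sums
    to 2 over all 8 haplotypes before MHF filtering; under expected mode
    entries are posterior-expected copies (reals).
    """

    ids: list[str]
    labels: list[str]
    entries: np.ndarray  # (n, len(labels))
    mhf: float
    freqs: Optional[np.ndarray] = None  # (8,) scope-sample frequencies
    dropped_mass: Optional[np.ndarray] = None  # (n,) copies lost to filtering

    @property
    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=self.ids, columns=self.labels)


def _compatible_diplotypes(genotype: Sequence[int]) -> np.ndarray:
    """Indices into DIPLOTYPES compatible with a genotype vector (entries
    0/1/2 B-allele counts or MISSING, which matches anything)."""
    g = np.asarray(genotype)
    observed = g != MISSING
    ok = (_DIP_SUMS[:, observed] == g[observed]).all(axis=1)
    return np.flatnonzero(ok)


def _pattern_groups(genotypes: np.ndarray):
    """Group rows of an (n, 3) genotype slice by identical pattern.

    Returns list of (compatible diplotype indices, count, row indices).
    """
    groups: dict[tuple, list[int]] = {}
    for idx, row in enumerate(np.asarray(genotypes)):
        groups.setdefault(tuple(int(v) for v in row), []).append(idx)
    out = []
    for pattern, rows in groups.items():
        compat = _compatible_diplotypes(pattern)
        if compat.size == 0:
            raise ValueError(f"genotype {pattern} matches no diplotype")
        out.append((compat, len(rows), rows))
    return out


def _diplotype_weights(freqs: np.ndarray) -> np.ndarray:
    """Prior weight of each of the 36 diplotypes: f_i f_j (2 - delta_ij)."""
    w = np.empty(len(DIPLOTYPES))
    for k, (i, j) in enumerate(DIPLOTYPES):
        w[k] = freqs[i] * freqs[j] * (2.0 if i != j else 1.0)
    return w


def _em_run(groups, start: np.ndarray, max_iter: int, tol: float):
    freqs = start.copy()
    n_ind = sum(cnt for _, cnt, _ in groups)
    trace = []
    prev = -np.inf
    for it in range(max_iter):
        w = _diplotype_weights(freqs)
        counts = np.zeros(N_HAPS)
        loglik = 0.0
        for compat, cnt, _ in groups:
            wk = w[compat]
            denom = wk.sum()
            if denom <= 0:
                loglik = -np.inf
                post = np.full(len(compat), 1.0 / len(compat))
            else:
                loglik += cnt * np.log(denom)
                post = wk / denom
            for p, k in zip(post, compat):
                i, j = DIPLOTYPES[k]
                counts[i] += cnt * p
                counts[j] += cnt * p
        freqs = counts / (2.0 * n_ind)
        trace.append(loglik)
        if np.isfinite(loglik) and abs(loglik - prev) < tol:
            break
        prev = loglik
    return freqs, trace[-1], len(trace), np.array(trace)


def em_window_freqs(genotypes: np.ndarray,
                    strata: Optional[Sequence[str]] = None,
                    max_iter: int = 500, tol: float = 1e-10,
                    n_starts: int = 4, seed: int = 0
                    ) -> dict[str, BreedHapFreqs]:
    """EM haplotype frequency estimation per stratum for one 3-SNP window.

    The E-step enumerates every diplotype compatible with each (possibly
    partially missing) genotype; the M-step divides expected haplotype counts
    by 2n.  The best of `n_starts` random restarts plus one uniform start is
    kept per stratum; the observed-data log-likelihood is non-decreasing
    across iterations of each run.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[1] != N_SNPS:
        raise ValueError("genotypes must be (n_individuals, 3)")
    n = genotypes.shape[0]
    if strata is None:
        strata = ["all"] * n
    strata = np.asarray([str(s) for s in strata])
    rng = np.random.default_rng(seed)
    out: dict[str, BreedHapFreqs] = {}
    for stratum in dict.fromkeys(strata):
        rows = genotypes[strata == stratum]
        if (rows == MISSING).all():
            raise ValueError(
                f"stratum {stratum}: all genotypes missing at all 3 SNPs")
        groups = _pattern_groups(rows)
        starts = [np.full(N_HAPS, 1.0 / N_HAPS)]
        starts += [rng.dirichlet(np.ones(N_HAPS)) for _ in range(n_starts)]
        best = None
        for start in starts:
            freqs, loglik, n_iter, trace = _em_run(groups, start, max_iter, tol)
            if best is None or loglik > best[1]:
                best = (freqs, loglik, n_iter, trace)
        out[stratum] = BreedHapFreqs(stratum=stratum, freqs=best[0],
                                     n_individuals=len(rows), loglik=best[1],
                                     n_iter=best[2], loglik_trace=best[3])
    return out


def posterior_diplotypes(genotypes: np.ndarray,
                         freqs: Mapping[str, BreedHapFreqs] | BreedHapFreqs,
                         strata: Optional[Sequence[str]] = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """P(diplotype | genotype) per individual under stratum frequencies.

    Returns (posteriors, flagged): posteriors is (n, 36) over DIPLOTYPES and
    sums to 1 per row; flagged marks individuals whose every compatible
    diplotype has prior probability 0 (posterior set uniform over the
    compatible set).
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    if isinstance(freqs, BreedHapFreqs):
        freqs = {freqs.stratum: freqs}
    if strata is None:
        if len(freqs) != 1:
            raise ValueError("strata required with multiple frequency sets")
        strata = [next(iter(freqs))] * n
    strata = [str(s) for s in strata]
    post = np.zeros((n, len(DIPLOTYPES)))
    flagged = np.zeros(n, dtype=bool)
    weights = {s: _diplotype_weights(bf.freqs) for s, bf in freqs.items()}
    for idx in range(n):
        compat = _compatible_diplotypes(genotypes[idx])
        w = weights[strata[idx]][compat]
        total = w.sum()
        if total <= 0:
            post[idx, compat] = 1.0 / len(compat)
            flagged[idx] = True
        else:
            post[idx, compat] = w / total
    return post, flagged


def assign_dosages(posteriors: np.ndarray, mode: str = "ml"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype copy counts per individual from diplotype posteriors.

    mode='ml': counts from the maximum-posterior diplotype, ties broken by
    lexicographic (h_i, h_j) label order (the DIPLOTYPES ordering).
    mode='expected': posterior-expected copies (reals, rows sum to 2).

    Returns (dosages (n, 8), imputed_genotypes (n, 3)); imputed genotypes
    follow from the ML diplotype in both modes.
    """
    post = np.asarray(posteriors)
    ml_idx = post.argmax(axis=1)  # argmax returns first max = lexicographic
    imputed = _DIP_SUMS[ml_idx].astype(np.int8)
    n = post.shape[0]
    if mode == "ml":
        dos = np.zeros((n, N_HAPS))
        for row, k in enumerate(ml_idx):
            i, j = DIPLOTYPES[k]
            dos[row, i] += 1
            dos[row, j] += 1
    elif mode == "expected":
        dos = np.zeros((n, N_HAPS))
        for k, (i, j) in enumerate(DIPLOTYPES):
            dos[:, i] += post[:, k]
            dos[:, j] += post[:, k]
    else:
        raise ValueError("mode must be 'ml' or 'expected'")
    return dos, imputed


def build_dosage_matrix(dosages: np.ndarray, ids: Sequence[str],
                        mhf: float = 0.05, scope: str = "overall",
                        strata: Optional[Sequence[str]] = None) -> DosageMatrix:
    """MHF-filter an unfiltered (n, 8) dosage matrix.

    Haplotype frequencies are computed over the scope sample (column copy
    sums over 2n); haplotypes with frequency < mhf are excluded, the
    boundary frequency == mhf is kept.  scope='per_stratum' retains a
    haplotype reaching the threshold in at least one stratum.
    """
    if not 0.0 <= mhf <= 0.5:
        raise ValueError("mhf must be in [0, 0.5]")
    dos = np.asarray(dosages, dtype=float)
    n = dos.shape[0]
    freqs = dos.sum(axis=0) / (2.0 * n)
    if scope == "overall":
        keep = freqs >= mhf
    elif scope == "per_stratum":
        if strata is None:
            raise ValueError("per_stratum scope requires strata")
        strata = np.asarray([str(s) for s in strata])
        keep = np.zeros(N_HAPS, dtype=bool)
        for s in dict.fromkeys(strata):
            rows = dos[strata == s]
            keep |= rows.sum(axis=0) / (2.0 * len(rows)) >= mhf
    else:
        raise ValueError("scope must be 'overall' or 'per_stratum'")
    if not keep.any():
        raise ValueError(f"MHF filter at {mhf} drops every haplotype")
    labels = [HAP_LABELS[k] for k in np.flatnonzero(keep)]
    entries = dos[:, keep]
    dropped = dos[:, ~keep].sum(axis=1)
    return DosageMatrix(ids=list(ids), labels=labels, entries=entries,
                        mhf=mhf, freqs=freqs, dropped_mass=dropped)


class WindowPhaser(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: 3-SNP genotypes -> MHF-filtered haplotype
    dosages.

    fit() estimates per-stratum haplotype frequencies by exact EM;
    transform() computes diplotype posteriors under the fitted frequencies,
    assigns dosages (`mode`='ml' integer counts or 'expected' reals) and
    applies the MHF filter learned on the fitted sample.
    """

    def __init__(self, mhf: float = 0.05, mode: str = "ml",
                 scope: str = "overall", n_starts: int = 4,
                 max_iter: int = 500, tol: float = 1e-10,
                 random_state: int = 0):
        self.mhf = mhf
        self.mode = mode
        self.scope = scope
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, strata=None, ids=None):
        X = np.asarray(X)
        self.freqs_ = em_window_freqs(X, strata, max_iter=self.max_iter,
                                      tol=self.tol, n_starts=self.n_starts,
                                      seed=self.random_state)
        self.loglik_ = sum(bf.loglik for bf in self.freqs_.values())
        post, flagged = posterior_diplotypes(X, self.freqs_, strata)
        dos, imputed = assign_dosages(post, mode=self.mode)
        if ids is None:
            ids = [str(i) for i in range(X.shape[0])]
        dm = build_dosage_matrix(dos, ids, mhf=self.mhf, scope=self.scope,
                                 strata=strata)
        self.labels_ = dm.labels
        self.dosage_ = dm
        self.posteriors_ = post
        self.flagged_ = flagged
        self.imputed_genotypes_ = imputed
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, strata=None, ids=None):
        X = np.asarray(X)
        post, _ = posterior_diplotypes(X, self.freqs_, strata)
        dos, _ = assign_dosages(post, mode=self.mode)
        keep = [HAP_LABELS.index(lab) for lab in self.labels_]
        return dos[:, keep]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.labels_, dtype=object)
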