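"""Reported variance summaries from the beef-cattle candidate-gene study
that the pipeline's table families mirror, plus the internal arithmetic
that relates them.

These printed R^2 (%) values are inputs: the study's raw data are not
public, but several of its headline numbers are pure arithmetic over the
printed per-gene values (sums of per-SNP R^2, and the percent excess of
haplotype R^2 over the best single SNP) and can be recomputed exactly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = [
    "IMF_GENES",
    "IMF_SINGLE_SNP_R2",
    "IMF_BEST_SINGLE_SNP_R2",
    "IMF_MODEL_R2",
    "summed_single_r2",
    "variance_gain_pct",
    "mean_shortfall_pct",
]

IMF_GENES = ["ADIPOQ", "CAPN1", "CXCR4", "CEBPA", "FASN"]

#: per-SNP single-point R^2 (%) for intramuscular fat, in map order
IMF_SINGLE_SNP_R2: dict[str, list[float]] = {
    "ADIPOQ": [0.0, 1.4, 1.4],
    "CXCR4": [0.0, 1.1, 0.9],
    "CEBPA": [0.0, 1.4, 0.1],
    "CAPN1": [0.1, 0.2, 0.0],
}

#: best single-SNP R^2 (%) per gene; the FASN value is the re-analysis with
#: the 17 missing genotypes imputed (no FASN SNP reached P<0.05 before that)
IMF_BEST_SINGLE_SNP_R2: dict[str, float] = {
    "ADIPOQ": 1.4, "CAPN1": 0.2, "CXCR4": 1.1, "CEBPA": 1.4, "FASN": 0.8,
}

#: phenotypic variance (%) explained per gene under the four model kinds
IMF_MODEL_R2: dict[str, dict[str, float]] = {
    "summed_single": {"ADIPOQ": 2.8, "CAPN1": 0.3, "CXCR4": 2.0,
                      "CEBPA": 1.5, "FASN": 1.2},
    "simultaneous": {"ADIPOQ": 2.2, "CAPN1": 0.7, "CXCR4": 1.7,
                     "CEBPA": 1.5, "FASN": 1.4},
    "interactions": {"ADIPOQ": 2.6, "CAPN1": 0.9, "CXCR4": 1.8,
                     "CEBPA": 1.6, "FASN": 1.6},
    "haplotypes": {"ADIPOQ": 2.4, "CAPN1": 1.0, "CXCR4": 1.7,
                   "CEBPA": 1.9, "FASN": 1.8},
}


def summed_single_r2(per_snp_r2: Sequence[float]) -> float:
    """The 'SNPs estimated individually then summed' model row."""
    return float(sum(per_snp_r2))


def variance_gain_pct(haplotype_r2: Mapping[str, float],
                      best_single_r2: Mapping[str, float]) -> float:
    """Percent excess of summed haplotype R^2 over summed best-single-SNP
    R^2 across genes: 100 * (sum_hap - sum_single) / sum_single."""
    genes = list(haplotype_r2)
    hap = sum(haplotype_r2[g] for g in genes)
    single = sum(best_single_r2[g] for g in genes)
    return 100.0 * (hap - single) / single


def mean_shortfall_pct(haplotype_r2: Mapping[str, float],
                       other_r2: Mapping[str, float]) -> float:
    """Mean per-gene percent by which another model kind falls short of the
    haplotype model: mean over genes of 100 * (hap - other) / other."""
    genes = list(haplotype_r2)
    return float(sum(100.0 * (haplotype_r2[g] - other_r2[g]) / other_r2[g]
                     for g in genes) / len(genes))
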