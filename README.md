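# hapwin

Haplotype-window association analysis for quantitative traits in
structured, pedigreed livestock populations.

Single-point GWAS regressions test one SNP at a time; when the causal
variant is untyped, a short haplotype of adjacent SNPs can tag it far
better than any single marker.  `hapwin` implements that analysis for
candidate-gene windows in multi-breed cattle designs:

* **Phasing** — per-breed haplotype frequencies for 3-SNP windows
  (haplotypes h111..h222, 1 = A allele, 2 = B allele) by exact EM over the
  8-haplotype simplex, with missing-genotype imputation and minor-haplotype
  frequency (MHF < 0.05) filtering of the resulting 0/1/2 copy-count
  ("dosage") matrix.
* **Animal model** — pedigree REML for
  y = Xb + Za + e, a ~ N(0, A·σ²ₐ), with the numerator relationship matrix
  A from the tabular recursion, fixed effects breed/herd/sex/day plus an
  age covariate, and marker covariates fitted through one shared
  eigen-decomposition of A.  Partial haplotype substitution effects are
  tested by t = b/se; with all n retained haplotypes fitted simultaneously
  only n−1 are estimable.
* **Variance explained** — R² = (RSSₙ − RSS_w)/RSSₙ from the fixed-part
  residual sums of squares of models with and without the markers, so the
  denominator estimates the total phenotypic variance; per gene the
  pipeline compares single SNPs summed, 3 SNPs simultaneous, 3 SNPs plus
  interactions, and the haplotype model.
* **Popgen characterisation** — per-breed Hardy–Weinberg G-tests with the
  Williams correction, D′/r² (with the −1/n small-sample correction),
  r-polarity consistency across breeds, and Weir–Cockerham F_ST.
* **Synthetic data** — a first-class generator for study-like populations
  (7 pure breeds + 2 F1 crossbred groups, 940 phenotyped offspring of 246
  sires, F_ST 0.13 breed divergence via the Balding–Nichols model on
  haplotype frequencies, h² 0.47) with QTLs on typed SNPs, whole
  haplotypes, or hidden causal alleles nested within a haplotype, plus full
  ground truth for parameter-recovery testing.

## Worked example

```python
import hapwin
from hapwin.mixed_model import build_numerator_matrix
from hapwin.phasing import DosageMatrix
from hapwin.pipeline import (base_model, haplotype_assoc, phase_window,
                             variance_comparison)

cfg = hapwin.default_study_config(seed=1)      # 6 gene windows, 940 animals
study = hapwin.simulate_study(cfg)

amat = build_numerator_matrix(study.pedigree)
phen = study.phenotypes
ids = phen["individual"].tolist()
eig = amat.eigen(ids)                        # shared across all models
base = base_model(phen, eig)                 # no-marker model -> RSS_n
print("h2 = %.2f (s.e. %.2f)" % (base.h2, base.h2_se))

breeds = study.pedigree.breeds()
strata = [breeds[i] for i in study.genotypes.ids]
pw = phase_window(study.genotypes, cfg.windows[0].snp_ids, strata,
                  gene="ADIPOQ", seed=1)
dm = DosageMatrix(ids=ids, labels=pw.dosage.labels,
                  entries=pw.dosage.frame.loc[ids].to_numpy(),
                  mhf=0.05, freqs=pw.dosage.freqs)
print(haplotype_assoc("ADIPOQ", dm, phen, eig, base)
      [["term", "r2_pct", "b", "se", "p"]].round(4).to_string(index=False))
comp = variance_comparison("ADIPOQ", pw.imputed.loc[ids], dm, phen, eig, base)
print({k: round(v, 2) for k, v in comp.items() if k != "gene"})
```

prints

```
h2 = 0.39 (s.e. 0.13)
term  r2_pct       b     se      p
h111  2.1116  0.0587 0.1996 0.7688
h112  2.1116 -0.1126 0.2073 0.5873
h121  2.1116 -0.2128 0.2130 0.3180
h122  2.1116 -0.2013 0.2114 0.3413
h211  2.1116 -0.1514 0.2258 0.5028
h212  2.1116 -0.2973 0.2281 0.1927
{'r2_summed_single': 1.3, 'r2_simultaneous': 1.63, 'r2_interactions': 2.02, 'r2_haplotypes': 2.11}
```

The REML heritability (0.39 ± 0.13) recovers the simulated 0.47 within one
standard error.  This window carries a *hidden* causal allele riding 80% of
h111's copies, untyped by the three SNPs: the six common haplotypes fitted
simultaneously explain 2.11% of phenotypic variance versus 1.30% for the
three SNPs' individual R² summed — the haplotype advantage the pipeline is
built to measure.  The `b` column holds partial haplotype substitution
effects (trait units per copy) against the h111 reference.

A `hapwin` command-line tool wraps the same pipeline
(`hapwin simulate | phase | popgen | assoc | compare | run-all`); `run-all`
writes every per-gene table family (dosages, single-point scan, haplotype
fits, variance comparison, flanking-window controls, popgen summaries) plus
a JSON run manifest, byte-identical for a given config and seed.

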