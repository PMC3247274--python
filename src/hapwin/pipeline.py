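"""Per-gene orchestration: phasing, scans, haplotype fits, variance tables.

For each gene window the pipeline produces the study's table families:

* a popgen characterisation (per-breed HWE G-tests, per-breed LD for the
  outer SNP pair, per-SNP Weir-Cockerham F_ST across the pure breeds);
* a single-point scan: one animal-model fit per SNP, R^2 from the
  RSS-based comparison against the common no-marker base model;
* simultaneous haplotype fits of all MHF-retained haplotypes, with subset
  (exclude/only one label) and by-breed variants;
* a variance comparison: per-SNP R^2 summed, the 3 SNPs simultaneous, the
  3 SNPs plus their pairwise and three-way interaction products, and the
  haplotype model;
* flanking-window controls re-running the haplotype fit on the adjacent
  non-overlapping 3-SNP window.

The no-marker base model is fitted once per trait and reused for every R^2,
guaranteeing a common RSS_n.  All SNP dosages entering models are the
phasing-imputed ones, so missing genotypes never reach the fitter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import popgen
from .io import GenotypeMatrix, write_table, write_vcf
from .mixed_model import (ModelFit, RelationshipEigen, build_numerator_matrix,
                          reml_fit, rss_r2, substitution_tests)
from .phasing import HAP_ALLELES, HAP_LABELS, DosageMatrix, WindowPhaser
from .sim import SimulationConfig, StudyData, WindowSpec, simulate_study

__all__ = [
    "PhasedWindow",
    "phase_window",
    "base_model",
    "single_point_scan",
    "haplotype_assoc",
    "variance_comparison",
    "flanking_control",
    "run_study",
]


@dataclasses.dataclass
class PhasedWindow:
    gene: str
    snp_ids: list[str]
    phaser: WindowPhaser
    dosage: DosageMatrix
    imputed: pd.DataFrame  # imputed SNP dosages, index = individual


def phase_window(genotypes: GenotypeMatrix, snp_ids: Sequence[str],
                 strata: Sequence[str], gene: str = "", mhf: float = 0.05,
                 mode: str = "ml", seed: int = 0) -> PhasedWindow:
    """Phase one 3-SNP window per stratum and build its dosage matrix."""
    sub = genotypes.window(snp_ids)
    phaser = WindowPhaser(mhf=mhf, mode=mode, random_state=seed)
    phaser.fit(sub.data, strata=strata, ids=sub.ids)
    imputed = pd.DataFrame(phaser.imputed_genotypes_, index=sub.ids,
                           columns=sub.snp_ids)
    return PhasedWindow(gene=gene or (sub.snps[0].gene or ""),
                        snp_ids=list(sub.snp_ids), phaser=phaser,
                        dosage=phaser.dosage_, imputed=imputed)


def base_model(phenotypes: pd.DataFrame, eig: RelationshipEigen,
               trait: str = "trait", **kwargs) -> ModelFit:
    """The no-marker animal model whose RSS is the common RSS_n."""
    return reml_fit(phenotypes, eig, trait=trait, **kwargs)


def _assoc_rows(gene: str, fit: ModelFit, base: ModelFit,
                terms: Sequence[str], model_kind: str) -> pd.DataFrame:
    r2 = max(100.0 * rss_r2(fit, base), 0.0)
    tests = substitution_tests(fit, terms)
    tests.insert(0, "gene", gene)
    tests.insert(1, "model", model_kind)
    tests.insert(2, "r2_pct", r2)
    tests["n"] = fit.n_used
    return tests


def single_point_scan(gene: str, snp_dosages: pd.DataFrame,
                      phenotypes: pd.DataFrame, eig: RelationshipEigen,
                      base: ModelFit, trait: str = "trait") -> pd.DataFrame:
    """One REML fit per SNP; monomorphic SNPs are flagged, not tested."""
    rows = []
    for snp in snp_dosages.columns:
        col = snp_dosages[[snp]]
        if col[snp].nunique() <= 1:
            rows.append(pd.DataFrame([{
                "gene": gene, "model": "single", "r2_pct": np.nan,
                "term": snp, "b": np.nan, "se": np.nan, "t": np.nan,
                "p": np.nan, "estimable": False, "n": base.n_used}]))
            continue
        fit = reml_fit(phenotypes, eig, trait=trait, markers=col,
                       compute_h2_se=False)
        rows.append(_assoc_rows(gene, fit, base, [snp], "single"))
    return pd.concat(rows, ignore_index=True)


def _ordered_labels(dm: DosageMatrix) -> list[str]:
    """Retained labels by decreasing scope frequency (drop preference)."""
    freq = {lab: dm.freqs[HAP_LABELS.index(lab)] for lab in dm.labels}
    return sorted(dm.labels, key=lambda l: (-freq[l], l))


def haplotype_assoc(gene: str, dm: DosageMatrix, phenotypes: pd.DataFrame,
                    eig: RelationshipEigen, base: ModelFit,
                    subset: str | tuple = "all_common",
                    by_breed: bool = False,
                    trait: str = "trait") -> pd.DataFrame:
    """Simultaneous fit of MHF-retained haplotype dosages.

    subset: 'all_common', ('exclude', label) or ('only', label).  With
    all n retained columns plus the intercept only n-1 partial substitution
    effects are estimable; the most frequent haplotype is the dropped
    reference.  by_breed nests the requested (or most common) haplotype
    within breed, one coefficient per breed.
    """
    frame = dm.frame
    labels = list(dm.labels)
    if subset == "all_common":
        cols = labels
    else:
        kind, label = subset
        if kind == "exclude":
            cols = [l for l in labels if l != label]
        elif kind == "only":
            cols = [label] if label in labels else []
        else:
            raise ValueError(f"unknown subset: {subset}")
    if not cols:
        raise ValueError(f"subset {subset} leaves no haplotype columns")
    pref = [l for l in _ordered_labels(dm) if l in cols]
    if by_breed:
        label = cols[0] if subset != "all_common" else pref[0]
        fit = reml_fit(phenotypes, eig, trait=trait, markers=frame[[label]],
                       by_breed=label, compute_h2_se=False)
        terms = [n for n in fit.names if n.startswith(f"{label}:")]
        kind = "haplotypes_by_breed"
    else:
        fit = reml_fit(phenotypes, eig, trait=trait, markers=frame[cols],
                       drop_preference=pref, compute_h2_se=False)
        terms = cols
        kind = "haplotypes" if subset == "all_common" else f"haplotypes_{subset[0]}"
    return _assoc_rows(gene, fit, base, terms, kind)


def variance_comparison(gene: str, snp_dosages: pd.DataFrame,
                        dm: DosageMatrix, phenotypes: pd.DataFrame,
                        eig: RelationshipEigen, base: ModelFit,
                        trait: str = "trait") -> dict[str, float]:
    """The four-model variance table for one gene (values in percent).

    r2_summed_single is exactly the column sum of the single-point scan;
    interaction products are the raw pairwise and three-way dosage
    products, rank-checked (product columns are dropped first on detected
    rank deficiency).
    """
    scan = single_point_scan(gene, snp_dosages, phenotypes, eig, base, trait)
    summed = float(scan["r2_pct"].fillna(0.0).sum())

    polymorphic = [c for c in snp_dosages.columns
                   if snp_dosages[c].nunique() > 1]
    fit_sim = reml_fit(phenotypes, eig, trait=trait,
                       markers=snp_dosages[polymorphic], compute_h2_se=False)
    r2_sim = max(100.0 * rss_r2(fit_sim, base), 0.0)

    inter = snp_dosages[polymorphic].copy()
    cols = list(snp_dosages.columns)
    prods = []
    for i in range(3):
        for j in range(i + 1, 3):
            name = f"{cols[i]}*{cols[j]}"
            inter[name] = snp_dosages[cols[i]] * snp_dosages[cols[j]]
            prods.append(name)
    name3 = "*".join(cols)
    inter[name3] = snp_dosages[cols[0]] * snp_dosages[cols[1]] * snp_dosages[cols[2]]
    prods.append(name3)
    inter = inter.loc[:, inter.nunique() > 1]
    fit_int = reml_fit(phenotypes, eig, trait=trait, markers=inter,
                       drop_preference=list(reversed(prods)),
                       compute_h2_se=False)
    r2_int = max(100.0 * rss_r2(fit_int, base), 0.0)

    hap = haplotype_assoc(gene, dm, phenotypes, eig, base, trait=trait)
    r2_hap = float(hap["r2_pct"].iloc[0])
    return {"gene": gene, "r2_summed_single": summed, "r2_simultaneous": r2_sim,
            "r2_interactions": r2_int, "r2_haplotypes": r2_hap}


def flanking_control(genotypes: GenotypeMatrix, window: WindowSpec | Sequence[str],
                     side: str, strata: Sequence[str],
                     phenotypes: pd.DataFrame, eig: RelationshipEigen,
                     base: ModelFit, mhf: float = 0.05, mode: str = "ml",
                     seed: int = 0, trait: str = "trait") -> pd.DataFrame:
    """Haplotype fit of the adjacent non-overlapping 3-SNP window.

    The flanking window never reuses SNPs from the focal window; if fewer
    than 3 SNPs exist on the requested side of the same chromosome the
    chromosome edge is an error.
    """
    focal_ids = window.snp_ids if isinstance(window, WindowSpec) else list(window)
    by_id = {s.snp_id: s for s in genotypes.snps}
    chrom = by_id[focal_ids[0]].chrom
    chrom_snps = [s for s in genotypes.snps if s.chrom == chrom]
    ids_sorted = [s.snp_id for s in chrom_snps]
    lo = min(ids_sorted.index(i) for i in focal_ids)
    hi = max(ids_sorted.index(i) for i in focal_ids)
    if side == "left":
        flank = ids_sorted[max(lo - 3, 0):lo]
    elif side == "right":
        flank = ids_sorted[hi + 1:hi + 4]
    else:
        raise ValueError("side must be 'left' or 'right'")
    if len(flank) < 3:
        raise ValueError(f"chromosome edge: no 3-SNP {side} flank for {focal_ids}")
    assert not set(flank) & set(focal_ids)
    gene = by_id[focal_ids[0]].gene or focal_ids[0]
    pw = phase_window(genotypes, flank, strata, gene=f"{gene}_{side}_flank",
                      mhf=mhf, mode=mode, seed=seed)
    dm = pw.dosage
    phen_ids = phenotypes["individual"].astype(str).tolist()
    sub = DosageMatrix(ids=phen_ids, labels=dm.labels,
                       entries=dm.frame.loc[phen_ids].to_numpy(),
                       mhf=dm.mhf, freqs=dm.freqs)
    return haplotype_assoc(pw.gene, sub, phenotypes, eig, base, trait=trait)


# ---------------------------------------------------------------------------
# full study run
# ---------------------------------------------------------------------------

def _popgen_tables(study: StudyData, phased: dict[str, PhasedWindow]):
    """Per-breed HWE, per-breed EM-based LD for the outer SNP pair, and
    per-SNP F_ST across the pure breeds."""
    gm = study.genotypes
    breeds = study.pedigree.breeds()
    strata = np.array([breeds[i] for i in gm.ids])
    pure = list(study.config.breeds)
    hwe_rows, ld_rows, fst_rows = [], [], []
    ld_by_gene: dict[str, dict[str, popgen.LdSummary]] = {}
    lengths = {}
    for w in study.config.windows:
        gene = w.gene
        lengths[gene] = int(w.positions[2] - w.positions[0])
        ld_by_gene[gene] = {}
        sub = gm.window(w.snp_ids)
        for j, snp in enumerate(sub.snps):
            per_breed_counts = []
            for breed in pure:
                g = sub.data[strata == breed, j]
                g = g[g >= 0]
                n_aa, n_ab, n_bb = int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
                if len(g) and 0 < (2 * n_bb + n_ab) < 2 * len(g):
                    res = popgen.hwe_gtest(n_aa, n_ab, n_bb)
                    hwe_rows.append({"gene": gene, "snp": snp.snp_id,
                                     "breed": breed, "n": len(g),
                                     "G": res.G, "G_adj": res.G_adj,
                                     "df": res.df, "p": res.p})
                per_breed_counts.append((2 * n_bb + n_ab, 2 * len(g)))
            counts = [(b, t) for b, t in per_breed_counts if t > 0]
            total_b = sum(b for b, _ in counts)
            if len(counts) >= 2 and 0 < total_b < sum(t for _, t in counts):
                fst = popgen.fst_weir_cockerham(counts)
                fst_rows.append({"gene": gene, "snp": snp.snp_id,
                                 "theta": fst.theta, "a": fst.a,
                                 "b": fst.b, "c": fst.c})
        # LD between the outer SNPs from the EM haplotype frequencies
        for breed, bf in phased[gene].phaser.freqs_.items():
            f = bf.freqs
            t = np.zeros((2, 2))
            for h in range(8):
                t[HAP_ALLELES[h, 0], HAP_ALLELES[h, 2]] += f[h]
            try:
                ld = popgen.ld_pair(freqs=t, n=2 * bf.n_individuals,
                                    distance_bp=lengths[gene])
            except ValueError:
                continue
            ld_rows.append({"gene": gene, "breed": breed, "D": ld.D,
                            "Dprime": ld.Dprime, "r": ld.r, "r2": ld.r2,
                            "r2_corrected": ld.r2_corrected,
                            "r2_corrected_floored": max(ld.r2_corrected, 0.0),
                            "n": ld.n, "distance_bp": ld.distance_bp,
                            "source": "em"})
            if breed in pure:
                ld_by_gene[gene][breed] = ld
    summary, slopes = popgen.ld_summary_by_gene(ld_by_gene, lengths)
    return (pd.DataFrame(hwe_rows), pd.DataFrame(ld_rows),
            pd.DataFrame(fst_rows), summary, slopes)


def run_study(config: Optional[SimulationConfig] = None, out: str = "results",
              seed: Optional[int] = None, mhf: float = 0.05,
              dosage_mode: str = "ml",
              study: Optional[StudyData] = None) -> Path:
    """End-to-end study run on simulated inputs; writes every table family
    per window plus a run manifest.  Deterministic given (config, seed)."""
    from . import __version__
    from .sim import default_study_config

    if study is None:
        config = config or default_study_config()
        study = simulate_study(config, seed=seed)
    else:
        config = study.config
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)

    write_vcf(study.genotypes, outdir / "genotypes.vcf")
    study.pedigree.write(outdir / "pedigree.csv")
    study.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    config.to_yaml(outdir / "config.yaml")

    breeds = study.pedigree.breeds()
    strata = [breeds[i] for i in study.genotypes.ids]
    phased = {}
    for w in config.windows:
        phased[w.gene] = phase_window(study.genotypes, w.snp_ids, strata,
                                      gene=w.gene, mhf=mhf, mode=dosage_mode,
                                      seed=config.seed)
        phase_tab = pd.DataFrame({
            "individual": study.genotypes.ids,
            **{lab: phased[w.gene].dosage.frame[lab].to_numpy()
               for lab in phased[w.gene].dosage.labels}})
        write_table(phase_tab, outdir / f"{w.gene}_dosages.tsv")
        from .phasing import DIPLOTYPES, HAP_LABELS as _LABELS

        post = phased[w.gene].phaser.posteriors_
        ml = post.argmax(axis=1)
        write_table(pd.DataFrame({
            "individual": study.genotypes.ids,
            "hap1": [_LABELS[DIPLOTYPES[k][0]] for k in ml],
            "hap2": [_LABELS[DIPLOTYPES[k][1]] for k in ml],
            "posterior": post[np.arange(len(ml)), ml],
        }), outdir / f"{w.gene}_phased.tsv")

    hwe, ld, fst, ld_summary, slopes = _popgen_tables(study, phased)
    write_table(hwe, outdir / "popgen_hwe.tsv")
    write_table(ld, outdir / "popgen_ld.tsv")
    write_table(fst, outdir / "popgen_fst.tsv")
    write_table(ld_summary, outdir / "popgen_ld_summary.tsv")

    amat = build_numerator_matrix(study.pedigree)
    phen = study.phenotypes
    eig = amat.eigen(phen["individual"].astype(str).tolist())
    base = base_model(phen, eig)
    phen_ids = phen["individual"].astype(str).tolist()

    comparisons, errors = [], {}
    for w in config.windows:
        try:
            pw = phased[w.gene]
            snp_df = pw.imputed.loc[phen_ids]
            dm_full = pw.dosage
            dm = DosageMatrix(ids=phen_ids, labels=dm_full.labels,
                              entries=dm_full.frame.loc[phen_ids].to_numpy(),
                              mhf=dm_full.mhf, freqs=dm_full.freqs)
            scan = single_point_scan(w.gene, snp_df, phen, eig, base)
            write_table(scan, outdir / f"{w.gene}_single_point.tsv")
            hap = haplotype_assoc(w.gene, dm, phen, eig, base)
            write_table(hap, outdir / f"{w.gene}_haplotypes.tsv")
            comp = variance_comparison(w.gene, snp_df, dm, phen, eig, base)
            comparisons.append(comp)
            for side, fl in (("left", w.flank_left), ("right", w.flank_right)):
                if fl is None:
                    continue
                ctrl = flanking_control(study.genotypes, w, side, strata,
                                        phen, eig, base, mhf=mhf,
                                        mode=dosage_mode, seed=config.seed)
                write_table(ctrl, outdir / f"{w.gene}_flank_{side}.tsv")
        except Exception as exc:  # a stage error aborts that window only
            errors[w.gene] = f"{type(exc).__name__}: {exc}"
    write_table(pd.DataFrame(comparisons), outdir / "variance_comparison.tsv")

    manifest = {
        "version": __version__,
        "seed": int(config.seed if seed is None else seed),
        "mhf": mhf,
        "dosage_mode": dosage_mode,
        "n_phenotyped": int(len(phen)),
        "base_model": {"h2": base.h2, "h2_se": base.h2_se,
                       "sigma2_a": base.sigma2_a, "sigma2_e": base.sigma2_e,
                       "rss_n": base.rss},
        "ld_slopes": slopes,
        "window_errors": errors,
        "tables": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
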