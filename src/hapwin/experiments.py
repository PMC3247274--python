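"""Seeded benchmark experiments on the synthetic study.

These are the parameter-recovery and mechanism experiments that establish
what the pipeline can demonstrate on data with known truth: heritability
recovery at study scale, recovery of an injected haplotype substitution
effect, the realized among-breed differentiation, and the haplotype-versus-
single-SNP variance gap under a hidden causal allele versus a typed causal
SNP.

The expensive pieces (pedigree, numerator matrix, its eigen-decomposition)
are built once per study design and shared across replicates; each
replicate redraws breed frequencies, founder haplotypes, transmission and
phenotypes from its own seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import popgen
from .mixed_model import RelationshipEigen, build_numerator_matrix, reml_fit, rss_r2
from .phasing import DosageMatrix, HAP_LABELS
from .pipeline import _ordered_labels, phase_window, single_point_scan
from .sim import (QtlSpec, SimulationConfig, WindowSpec, _spread_freqs,
                  gene_drop, default_study_config, simulate_breed_freqs,
                  simulate_pedigree, simulate_phenotypes,
                  simulate_window_breed_freqs)  # noqa: F401 (simulate_breed_freqs re-exported)

__all__ = [
    "StudyMachinery",
    "build_machinery",
    "estimate_h2",
    "recover_haplotype_effect",
    "haplotype_vs_snp_gap",
    "realized_fst",
]


@dataclasses.dataclass
class StudyMachinery:
    """Fixed study design shared across simulation replicates."""

    config: SimulationConfig
    pedigree: object
    eig: RelationshipEigen
    strata: list
    founder_breeds: list


def build_machinery(seed: int = 0,
                    config: Optional[SimulationConfig] = None) -> StudyMachinery:
    """Build the study pedigree and eigen-decomposed relationship matrix."""
    config = config or default_study_config(seed=seed)
    pedigree = simulate_pedigree(config, seed=seed)
    amat = build_numerator_matrix(pedigree)
    offspring = [i for i in pedigree.individuals
                 if pedigree.parents(i) != ("", "")]
    eig = amat.eigen(offspring)
    breeds = pedigree.breeds()
    strata = [breeds[i] for i in pedigree.individuals]
    founder_breeds = sorted({b for _, s, d, _ in config.groups
                             for b in (s, d)})
    return StudyMachinery(config=config, pedigree=pedigree, eig=eig,
                          strata=strata, founder_breeds=founder_breeds)


def _one_window(qtl_mode: str, effect: float,
                carrier_fraction: float = 0.5) -> tuple[WindowSpec, QtlSpec]:
    w = WindowSpec(gene="W", chrom="chr1",
                   positions=(1_000_000, 1_045_000, 1_090_000),
                   base_freqs=_spread_freqs((3, 0, 5, 1, 7, 2, 6, 4)))
    if qtl_mode == "snp":
        q = QtlSpec(gene="W", mode="snp", snp_index=1, effect=effect)
    else:
        target = HAP_LABELS[int(np.argmax(w.base_freqs))] \
            if qtl_mode == "hidden" else HAP_LABELS[int(np.argsort(w.base_freqs)[-2])]
        q = QtlSpec(gene="W", mode=qtl_mode, haplotype=target, effect=effect,
                    carrier_fraction=carrier_fraction)
    return w, q


def _simulate_replicate(mach: StudyMachinery, window: WindowSpec,
                        qtl: QtlSpec, seed: int):
    root = np.random.SeedSequence(seed)
    r_freq, r_drop, r_phen = [np.random.default_rng(s) for s in root.spawn(3)]
    freqs = simulate_window_breed_freqs(window, mach.founder_breeds,
                                        mach.config.fst_target, r_freq)
    cfg = dataclasses.replace(mach.config, windows=[window], qtls=[qtl])
    truth, gm = gene_drop(mach.pedigree, [window], {"W": freqs}, [qtl], r_drop)
    phen = simulate_phenotypes(mach.pedigree, truth, cfg, r_phen)
    return truth, gm, phen


def _phase_aligned(mach, gm, window, phen, seed=0, mode="ml"):
    pw = phase_window(gm, window.snp_ids, mach.strata, gene=window.gene,
                      mhf=0.05, mode=mode, seed=seed)
    ids = phen["individual"].astype(str).tolist()
    dm_full = pw.dosage
    dm = DosageMatrix(ids=ids, labels=dm_full.labels,
                      entries=dm_full.frame.loc[ids].to_numpy(),
                      mhf=dm_full.mhf, freqs=dm_full.freqs)
    return pw.imputed.loc[ids], dm


def estimate_h2(mach: StudyMachinery, seed: int = 0) -> tuple[float, float]:
    """REML heritability on a no-QTL replicate of the study design."""
    cfg = dataclasses.replace(mach.config, windows=[], qtls=[])
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    from .sim import TruthRecord

    truth = TruthRecord(ids=mach.pedigree.individuals, genes=[],
                        diplotypes=np.zeros((len(mach.pedigree.individuals), 0, 2), np.int8),
                        carriers=np.zeros((len(mach.pedigree.individuals), 0, 2), bool),
                        joint_states=np.zeros((len(mach.pedigree.individuals), 0, 2), np.int32),
                        qtls=[], breed_hap_freqs={})
    phen = simulate_phenotypes(mach.pedigree, truth, cfg, rng)
    fit = reml_fit(phen, mach.eig)
    return fit.h2, fit.h2_se


def recover_haplotype_effect(mach: StudyMachinery, seed: int,
                             effect: float = 0.35,
                             dosage_source: str = "truth") -> dict:
    """One replicate of injected-haplotype-effect recovery.

    The QTL rides the second most frequent haplotype; the simultaneous fit
    never drops that column (the most frequent retained haplotype is the
    reference, which carries no effect), so its partial substitution effect
    estimates the injected effect directly.

    dosage_source='truth' fits the simulated diplotype counts and so
    isolates the mixed model's estimation properties; 'ml' or 'expected'
    route the replicate through EM phasing first, which adds covariate
    measurement error (attenuation) on top.
    """
    import pandas as pd

    window, qtl = _one_window("haplotype", effect)
    truth, gm, phen = _simulate_replicate(mach, window, qtl, seed)
    ids = phen["individual"].astype(str).tolist()
    if dosage_source == "truth":
        pos = {ind: k for k, ind in enumerate(truth.ids)}
        rows = np.array([pos[i] for i in ids])
        dos = np.zeros((len(ids), 8))
        for c in range(2):
            np.add.at(dos, (np.arange(len(ids)),
                            truth.diplotypes[rows, 0, c]), 1.0)
        freqs = dos.sum(axis=0) / (2 * len(ids))
        keep = freqs >= 0.05
        labels = [HAP_LABELS[k] for k in np.flatnonzero(keep)]
        frame = pd.DataFrame(dos[:, keep], index=ids, columns=labels)
        order = sorted(labels, key=lambda l: -freqs[HAP_LABELS.index(l)])
    else:
        _, dm = _phase_aligned(mach, gm, window, phen, mode=dosage_source)
        frame = dm.frame
        order = _ordered_labels(dm)
    pref = [l for l in order if l != qtl.haplotype]
    fit = reml_fit(phen, mach.eig, markers=frame, drop_preference=pref,
                   compute_h2_se=False)
    if qtl.haplotype not in fit.names or qtl.haplotype in fit.dropped:
        return {"b": np.nan, "se": np.nan, "covered": False}
    b, se = fit.coef(qtl.haplotype)
    return {"b": b, "se": se, "covered": bool(abs(b - effect) <= 2 * se)}


def haplotype_vs_snp_gap(mach: StudyMachinery, seed: int, qtl_mode: str,
                         effect: float, carrier_fraction: float = 0.8) -> dict:
    """One replicate of the headline mechanism: R^2 (percent) of the
    simultaneous haplotype model versus the best single SNP of the window."""
    window, qtl = _one_window(qtl_mode, effect, carrier_fraction)
    truth, gm, phen = _simulate_replicate(mach, window, qtl, seed)
    snp_df, dm = _phase_aligned(mach, gm, window, phen)
    base = reml_fit(phen, mach.eig, compute_h2_se=False)
    scan = single_point_scan(window.gene, snp_df, phen, mach.eig, base)
    best_snp = float(scan["r2_pct"].fillna(0.0).max())
    pref = _ordered_labels(dm)
    fit = reml_fit(phen, mach.eig, markers=dm.frame, drop_preference=pref,
                   compute_h2_se=False)
    r2_hap = max(100.0 * rss_r2(fit, base), 0.0)
    return {"r2_haplotypes": r2_hap, "r2_best_snp": best_snp,
            "gap": r2_hap - best_snp}


def realized_fst(seed: int = 0, n_windows: int = 300, n_breeds: int = 7,
                 fst_target: float = 0.13, n_per_breed: int = 120) -> float:
    """Multi-locus Weir-Cockerham F_ST over freshly simulated windows,
    sampling one SNP's allele counts per window under each breed's
    haplotype frequencies."""
    from .phasing import HAP_ALLELES

    rng = np.random.default_rng(seed)
    base = _spread_freqs(range(8))
    loci = []
    for _ in range(n_windows):
        freqs = simulate_breed_freqs(base, n_breeds, fst_target, rng)
        p = freqs[:, HAP_ALLELES[:, 0] == 1].sum(axis=1)
        counts = [(int(rng.binomial(2 * n_per_breed, pb)), 2 * n_per_breed)
                  for pb in p]
        total_b = sum(b for b, _ in counts)
        if 0 < total_b < 2 * n_per_breed * n_breeds:
            loci.append(counts)
    return popgen.fst_multilocus(loci)
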