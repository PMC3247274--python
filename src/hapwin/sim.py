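"""Synthetic multi-breed pedigreed populations with haplotype-borne QTLs.

The generator emulates the study design the pipeline targets: several pure
cattle breeds plus first-generation crossbred groups, a paternal half-sib
pedigree, breed-divergent 3-SNP haplotype frequencies (Balding-Nichols
F-model on the haplotype simplex, so high-D'/low-r2 LD structure emerges
from shared haplotype pools), gene-dropped genotypes, and phenotypes with a
known polygenic (animal-model) and QTL architecture.

A window's QTL can sit on a typed SNP, on a whole haplotype, or on a hidden
causal allele nested within one haplotype (only a fraction of that
haplotype's founder copies carry it) - the scenario that makes haplotype
dosages out-perform any single typed SNP.

Every draw flows from a single integer seed through named numpy
SeedSequence spawns, so a (config, seed) pair reproduces bit for bit.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GenotypeMatrix, PedigreeTable, SnpRecord
from .phasing import HAP_ALLELES, HAP_LABELS, N_HAPS

__all__ = [
    "FlankSpec",
    "WindowSpec",
    "QtlSpec",
    "SimulationConfig",
    "TruthRecord",
    "StudyData",
    "simulate_breed_freqs",
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "degrade",
    "simulate_study",
    "default_study_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FlankSpec:
    """An adjacent non-overlapping 3-SNP window coupled to the focal window.

    `coupling` is the probability that a transmitted flank haplotype simply
    copies the focal haplotype's index (creating inter-window LD); with
    coupling 0 the flank is independent of the focal window.
    """

    positions: tuple[int, int, int]
    base_freqs: Sequence[float]
    coupling: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (N_HAPS,) or abs(f.sum() - 1.0) > 1e-12 or (f < 0).any():
            raise ValueError("flank base_freqs must be an 8-vector summing to 1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        self.base_freqs = f


@dataclasses.dataclass
class WindowSpec:
    """A gene window: 3 adjacent SNPs with optional coupled flanking windows."""

    gene: str
    chrom: str
    positions: tuple[int, int, int]
    base_freqs: Sequence[float]
    flank_left: Optional[FlankSpec] = None
    flank_right: Optional[FlankSpec] = None

    def __post_init__(self):
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (N_HAPS,) or abs(f.sum() - 1.0) > 1e-12 or (f < 0).any():
            raise ValueError(f"{self.gene}: base_freqs must be an 8-vector "
                             "summing to 1 (within 1e-12)")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError(f"{self.gene}: SNP positions must strictly increase")
        self.base_freqs = f
        for fl, side in ((self.flank_left, "left"), (self.flank_right, "right")):
            if fl is None:
                continue
            if side == "left" and not max(fl.positions) < min(self.positions):
                raise ValueError(f"{self.gene}: left flank must precede window")
            if side == "right" and not min(fl.positions) > max(self.positions):
                raise ValueError(f"{self.gene}: right flank must follow window")

    @property
    def subwindows(self) -> list[tuple[str, tuple[int, ...], Optional[FlankSpec]]]:
        """Ordered (tag, positions, flankspec-or-None) for left/focal/right."""
        out = []
        if self.flank_left is not None:
            out.append(("5p", self.flank_left.positions, self.flank_left))
        out.append(("focal", self.positions, None))
        if self.flank_right is not None:
            out.append(("3p", self.flank_right.positions, self.flank_right))
        return out

    @property
    def focal_index(self) -> int:
        return 1 if self.flank_left is not None else 0

    @property
    def snp_ids(self) -> list[str]:
        return [f"{self.gene}_{k}" for k in (1, 2, 3)]

    def snp_records(self) -> list[SnpRecord]:
        recs = []
        for tag, positions, _ in self.subwindows:
            prefix = self.gene if tag == "focal" else f"{self.gene}_{tag}"
            for k, pos in enumerate(positions, start=1):
                recs.append(SnpRecord(snp_id=f"{prefix}_{k}", chrom=self.chrom,
                                      position=int(pos), allele_a="A",
                                      allele_b="G", gene=self.gene))
        return recs

    def joint_base_freqs(self) -> np.ndarray:
        """Joint distribution over the region's product haplotype space:
        the focal haplotype is drawn from base_freqs, each flank copies the
        focal index with probability `coupling`, else draws independently."""
        subs = self.subwindows
        k = len(subs)
        joint = np.zeros(N_HAPS ** k)
        focal_pos = self.focal_index
        for state in range(joint.size):
            digits = _decode_state(state, k)
            m = digits[focal_pos]
            p = self.base_freqs[m]
            for pos_idx, (tag, _, fl) in enumerate(subs):
                if fl is None:
                    continue
                h = digits[pos_idx]
                p *= fl.coupling * (h == m) + (1 - fl.coupling) * fl.base_freqs[h]
            joint[state] = p
        return joint


def _decode_state(state: int, k: int) -> tuple[int, ...]:
    """Base-8 digits of a region state, leftmost subwindow first."""
    digits = []
    for _ in range(k):
        digits.append(state % N_HAPS)
        state //= N_HAPS
    return tuple(reversed(digits))


@dataclasses.dataclass
class QtlSpec:
    """A quantitative-trait effect attached to a gene window.

    mode='haplotype': `effect` per copy of `haplotype`.
    mode='hidden':   a causal allele carried by a fraction
                     `carrier_fraction` of `haplotype` founder copies,
                     `effect` per carrier copy (untyped by the 3 SNPs).
    mode='snp':      `effect` per B allele at focal SNP `snp_index` (0-2).
    """

    gene: str
    mode: str
    effect: float
    haplotype: Optional[str] = None
    snp_index: Optional[int] = None
    carrier_fraction: float = 0.5

    def __post_init__(self):
        if self.mode not in ("haplotype", "hidden", "snp"):
            raise ValueError("mode must be haplotype, hidden or snp")
        if self.mode in ("haplotype", "hidden") and self.haplotype not in HAP_LABELS:
            raise ValueError(f"unknown haplotype label: {self.haplotype}")
        if self.mode == "snp" and self.snp_index not in (0, 1, 2):
            raise ValueError("snp_index must be 0, 1 or 2")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0, 1]")


DEFAULT_BREEDS = {"ANG": 220, "HFD": 146, "MGY": 55, "SHN": 81, "BRM": 78,
                  "BEL": 165, "SGT": 126}
DEFAULT_CROSSES = [("TAUX", "ANG", "BRM", 25), ("COMPX", "SGT", "BRM", 44)]


@dataclasses.dataclass
class SimulationConfig:
    """Study-design constants for the synthetic population.

    Defaults reproduce the target study's structure: 7 pure breeds
    (220 ANG, 146 HFD, 55 MGY, 81 SHN, 78 BRM, 165 BEL, 126 SGT) plus two
    first-cross groups (25 + 44), 246 sires averaging 3.8 offspring each
    (range 1-15), 34 herds, 2 sexes, 50 measurement days, among-breed
    differentiation F_ST 0.13, within-breed h2 0.47 on a unit-variance
    trait.
    """

    seed: int = 0
    breeds: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_BREEDS))
    crossbreds: list = dataclasses.field(default_factory=lambda: list(DEFAULT_CROSSES))
    n_sires: int = 246
    offspring_mean: float = 3.8
    offspring_min: int = 1
    offspring_max: int = 15
    n_herds: int = 34
    n_measurement_days: int = 50
    fst_target: float = 0.13
    windows: list = dataclasses.field(default_factory=list)
    qtls: list = dataclasses.field(default_factory=list)
    h2: float = 0.47
    sigma_p: float = 1.0
    trait_mean: float = 4.5
    fixed_effect_sds: dict = dataclasses.field(default_factory=lambda: {
        "breed": 0.5, "herd": 0.25, "sex": 0.2, "day": 0.15})
    age_range: tuple = (600.0, 900.0)
    age_slope: float = 0.002
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.offspring_min <= self.offspring_mean <= self.offspring_max:
            raise ValueError("offspring mean must lie within [min, max]")
        if self.n_sires < 1:
            raise ValueError("need at least one sire")
        self.windows = [w if isinstance(w, WindowSpec) else WindowSpec(**w)
                        for w in self.windows]
        self.qtls = [q if isinstance(q, QtlSpec) else QtlSpec(**q)
                     for q in self.qtls]

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    @property
    def breed_sizes(self) -> list[int]:
        return list(self.breeds.values())

    @property
    def groups(self) -> list[tuple[str, str, str, int]]:
        """(group label, sire breed, dam breed, size) for all strata."""
        out = [(b, b, b, n) for b, n in self.breeds.items()]
        out += [(name, s, d, n) for name, s, d, n in self.crossbreds]
        return out

    @property
    def sigma2_a(self) -> float:
        return self.h2 * self.sigma_p ** 2

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2) * self.sigma_p ** 2

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["windows"] = [dataclasses.asdict(w) for w in self.windows]
        d["qtls"] = [dataclasses.asdict(q) for q in self.qtls]
        for w in d["windows"]:
            w["base_freqs"] = [float(v) for v in w["base_freqs"]]
            w["positions"] = [int(v) for v in w["positions"]]
            for side in ("flank_left", "flank_right"):
                if w[side] is not None:
                    w[side]["base_freqs"] = [float(v) for v in w[side]["base_freqs"]]
                    w[side]["positions"] = [int(v) for v in w[side]["positions"]]
        d["crossbreds"] = [list(c) for c in d["crossbreds"]]
        d["age_range"] = list(d["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for w in d.get("windows", []):
            w["positions"] = tuple(w["positions"])
            for side in ("flank_left", "flank_right"):
                if w.get(side) is not None:
                    w[side]["positions"] = tuple(w[side]["positions"])
                    w[side] = FlankSpec(**w[side])
        d["crossbreds"] = [tuple(c) for c in d.get("crossbreds", [])]
        d["age_range"] = tuple(d.get("age_range", (600.0, 900.0)))
        return cls(**d)


# ---------------------------------------------------------------------------
# breed frequencies
# ---------------------------------------------------------------------------

def simulate_breed_freqs(base_freqs, n_breeds: int, fst_target: float,
                         seed=0) -> np.ndarray:
    """Breed-divergent frequency vectors under the Balding-Nichols F-model.

    Each breed's vector is Dirichlet(base * (1 - F) / F), giving
    E[p] = base and Var(p_i) = F p_i (1 - p_i): the expected among-breed
    differentiation equals `fst_target`.  F = 0 returns the base vector for
    every breed; categories with base frequency 0 stay fixed at 0.
    """
    base = np.asarray(base_freqs, dtype=float)
    if abs(base.sum() - 1.0) > 1e-12 or (base < 0).any():
        raise ValueError("base_freqs must sum to 1 with non-negative entries")
    if fst_target < 0 or fst_target >= 1:
        raise ValueError("fst_target must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fst_target == 0.0:
        return np.tile(base, (n_breeds, 1))
    conc = (1.0 - fst_target) / fst_target
    # gamma draws allow zero shape (point mass at 0), unlike rng.dirichlet
    g = rng.gamma(shape=np.tile(base * conc, (n_breeds, 1)))
    return g / g.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def _allocate(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder allocation of `total` slots by weights, min 1 each."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    out = np.maximum(np.floor(raw).astype(int), 1)
    while out.sum() > total:
        out[int(np.argmax(out))] -= 1
    rem = raw - np.floor(raw)
    while out.sum() < total:
        k = int(np.argmax(np.where(out < total, rem, -1)))
        out[k] += 1
        rem[k] = -1
    return out.tolist()


def _partition(total: int, k: int, lo: int, hi: int,
               rng: np.random.Generator) -> np.ndarray:
    """Split `total` offspring among k sires with counts in [lo, hi]."""
    if not k * lo <= total <= k * hi:
        raise ValueError(f"cannot split {total} offspring among {k} sires "
                         f"with family sizes in [{lo}, {hi}]")
    counts = np.full(k, lo)
    for _ in range(total - k * lo):
        open_ = np.flatnonzero(counts < hi)
        counts[rng.choice(open_)] += 1
    return counts


def simulate_pedigree(config: SimulationConfig, seed=None) -> PedigreeTable:
    """Two-generation paternal half-sib pedigree with breed strata.

    Sires are allocated to breed groups in proportion to group size; every
    offspring has a unique dam.  Crossbred groups are F1s: purebred sires of
    one breed mated to purebred dams of another, the offspring carrying the
    group's own stratum label.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    groups = config.groups
    sires_per_group = _allocate(config.n_sires, [g[3] for g in groups])
    rows = []
    for (label, sire_breed, dam_breed, size), n_sires in zip(groups, sires_per_group):
        counts = _partition(size, n_sires, config.offspring_min,
                            config.offspring_max, rng)
        off = 0
        for s in range(n_sires):
            sire_id = f"{label}_S{s + 1:03d}"
            rows.append((sire_id, "", "", sire_breed))
            for _ in range(int(counts[s])):
                off += 1
                dam_id = f"{label}_D{off:04d}"
                ind_id = f"{label}_O{off:04d}"
                rows.append((dam_id, "", "", dam_breed))
                rows.append((ind_id, sire_id, dam_id, label))
    df = pd.DataFrame(rows, columns=["individual", "sire", "dam", "breed"])
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery tests."""

    ids: list[str]
    genes: list[str]
    diplotypes: np.ndarray      # (n, W, 2) focal haplotype indices 0..7
    carriers: np.ndarray        # (n, W, 2) hidden-causal carrier flags
    joint_states: np.ndarray    # (n, W, 2) region product-space states
    qtls: list[QtlSpec]
    breed_hap_freqs: dict       # gene -> breed -> realized founder 8-vector
    u: Optional[pd.Series] = None   # true breeding values
    qtl_effects: Optional[pd.Series] = None  # per-individual QTL sum

    def qtl_copies(self, qtl: QtlSpec, windows: Sequence[WindowSpec]) -> np.ndarray:
        """Copies of the causal unit per individual for one QTL."""
        w = self.genes.index(qtl.gene)
        dip = self.diplotypes[:, w, :]
        if qtl.mode == "haplotype":
            target = HAP_LABELS.index(qtl.haplotype)
            return (dip == target).sum(axis=1).astype(float)
        if qtl.mode == "hidden":
            return self.carriers[:, w, :].sum(axis=1).astype(float)
        target_alleles = HAP_ALLELES[:, qtl.snp_index]
        return target_alleles[dip].sum(axis=1).astype(float)


def simulate_window_breed_freqs(window: WindowSpec, breed_names: Sequence[str],
                                fst_target: float, rng) -> dict[str, np.ndarray]:
    """Per-breed joint region frequencies via Balding-Nichols divergence."""
    joint = window.joint_base_freqs()
    mats = simulate_breed_freqs(joint, len(breed_names), fst_target, rng)
    return {b: mats[k] for k, b in enumerate(breed_names)}


def gene_drop(pedigree: PedigreeTable, windows: Sequence[WindowSpec],
              breed_freqs: dict, qtls: Sequence[QtlSpec] = (),
              seed=0) -> tuple[TruthRecord, GenotypeMatrix]:
    """Drop founder haplotypes through the pedigree and emit genotypes.

    Founder haplotypes are drawn independently from their breed's window
    frequencies; each offspring inherits one haplotype per parent with
    probability 1/2; there is no recombination within a window region.
    Hidden-causal carrier status is assigned at the founder draw and
    inherited with the haplotype copy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = pedigree.topological_order
    ids = pedigree.individuals
    pos = {ind: k for k, ind in enumerate(ids)}
    breeds = pedigree.breeds()
    parents = dict(zip(pedigree.df["individual"],
                       zip(pedigree.df["sire"], pedigree.df["dam"])))
    n, nw = len(ids), len(windows)
    joint_states = np.zeros((n, nw, 2), dtype=np.int32)
    carriers = np.zeros((n, nw, 2), dtype=bool)
    hidden = {q.gene: q for q in qtls if q.mode == "hidden"}
    genes = [w.gene for w in windows]
    realized: dict[str, dict[str, np.ndarray]] = {g: {} for g in genes}
    founder_draws: dict[str, dict[str, list[int]]] = {g: {} for g in genes}

    for w_idx, window in enumerate(windows):
        freqs = breed_freqs[window.gene]
        k = len(window.subwindows)
        focal_pos = window.focal_index
        cum = {b: np.cumsum(f) for b, f in freqs.items()}
        q = hidden.get(window.gene)
        target = HAP_LABELS.index(q.haplotype) if q else -1
        for ind in order:
            i = pos[ind]
            sire, dam = parents[ind]
            for copy, parent in enumerate((sire, dam)):
                if parent:
                    j = pos[parent]
                    pick = int(rng.integers(2))
                    joint_states[i, w_idx, copy] = joint_states[j, w_idx, pick]
                    carriers[i, w_idx, copy] = carriers[j, w_idx, pick]
                else:
                    breed = breeds[ind]
                    if breed not in cum:
                        raise ValueError(
                            f"no frequencies for founder breed {breed!r} "
                            f"at window {window.gene}")
                    state = int(np.searchsorted(cum[breed], rng.random()))
                    joint_states[i, w_idx, copy] = state
                    focal_hap = _decode_state(state, k)[focal_pos]
                    founder_draws[window.gene].setdefault(breed, []).append(focal_hap)
                    if q is not None and focal_hap == target:
                        carriers[i, w_idx, copy] = rng.random() < q.carrier_fraction
        for breed, draws in founder_draws[window.gene].items():
            realized[window.gene][breed] = (
                np.bincount(draws, minlength=N_HAPS) / len(draws))

    # decode joint states to focal diplotypes and SNP genotypes
    diplotypes = np.zeros((n, nw, 2), dtype=np.int8)
    snps, cols = [], []
    for w_idx, window in enumerate(windows):
        k = len(window.subwindows)
        states = np.arange(N_HAPS ** k)
        digit_table = np.array([_decode_state(s, k) for s in states])
        diplotypes[:, w_idx, :] = digit_table[joint_states[:, w_idx, :],
                                              window.focal_index]
        # region alleles: (state, total SNPs in region)
        allele_table = np.concatenate(
            [HAP_ALLELES[digit_table[:, d]] for d in range(k)], axis=1)
        geno = (allele_table[joint_states[:, w_idx, 0]]
                + allele_table[joint_states[:, w_idx, 1]])
        snps.extend(window.snp_records())
        cols.append(geno)
    data = np.concatenate(cols, axis=1).astype(np.int8) if cols else \
        np.zeros((n, 0), np.int8)
    gm = GenotypeMatrix(ids, snps, data)
    truth = TruthRecord(ids=list(ids), genes=genes, diplotypes=diplotypes,
                        carriers=carriers, joint_states=joint_states,
                        qtls=list(qtls), breed_hap_freqs=realized)
    return truth, gm


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(pedigree: PedigreeTable, truth: TruthRecord,
                        config: SimulationConfig, seed=0) -> pd.DataFrame:
    """Phenotypes for the non-founder generation under the animal model.

    y = mu + breed + herd + sex + day + beta_age * age + QTL + u + e with
    breeding values u consistent with the pedigree (founders N(0, sigma2_a),
    offspring = parental mean + Mendelian deviation N(0, sigma2_a / 2)) and
    sigma2_a / (sigma2_a + sigma2_e) = h2 exclusive of QTL variance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = pedigree.individuals
    pos = {ind: k for k, ind in enumerate(ids)}
    breeds = pedigree.breeds()
    sds = config.fixed_effect_sds
    s_a = np.sqrt(config.sigma2_a)

    u = np.zeros(len(ids))
    for ind in pedigree.topological_order:
        sire, dam = pedigree.parents(ind)
        i = pos[ind]
        if not sire and not dam:
            u[i] = rng.normal(0.0, s_a)
        else:
            mid = 0.0
            known = 0
            for p in (sire, dam):
                if p:
                    mid += u[pos[p]]
                    known += 1
            # Mendelian-sampling variance sigma2_a/2 for two non-inbred parents
            ms_var = config.sigma2_a * (1.0 - known / 4.0)
            u[i] = mid / 2.0 + rng.normal(0.0, np.sqrt(ms_var))
    truth.u = pd.Series(u, index=ids)

    group_labels = [g[0] for g in config.groups]
    breed_eff = {b: rng.normal(0.0, sds.get("breed", 0.0)) for b in group_labels}
    herds_per_group = _allocate(config.n_herds, [g[3] for g in config.groups])
    herd_of_group: dict[str, list[str]] = {}
    h = 0
    for (label, *_), nh in zip(config.groups, herds_per_group):
        herd_of_group[label] = [f"H{h + k + 1:02d}" for k in range(nh)]
        h += nh
    herd_eff = {hid: rng.normal(0.0, sds.get("herd", 0.0))
                for hids in herd_of_group.values() for hid in hids}
    sex_eff = {"M": rng.normal(0.0, sds.get("sex", 0.0)),
               "F": rng.normal(0.0, sds.get("sex", 0.0))}
    day_eff = {f"D{k + 1:02d}": rng.normal(0.0, sds.get("day", 0.0))
               for k in range(config.n_measurement_days)}

    qtl_total = np.zeros(len(ids))
    for q in truth.qtls:
        qtl_total += q.effect * truth.qtl_copies(q, config.windows)
    truth.qtl_effects = pd.Series(qtl_total, index=ids)

    offspring = [ind for ind in ids
                 if pedigree.parents(ind) != ("", "")]
    rows = []
    s_e = np.sqrt(config.sigma2_e)
    for ind in offspring:
        i = pos[ind]
        breed = breeds[ind]
        herd = herd_of_group[breed][int(rng.integers(len(herd_of_group[breed])))]
        sex = "M" if rng.random() < 0.5 else "F"
        day = f"D{int(rng.integers(config.n_measurement_days)) + 1:02d}"
        age = float(rng.uniform(*config.age_range))
        y = (config.trait_mean + breed_eff[breed] + herd_eff[herd]
             + sex_eff[sex] + day_eff[day] + config.age_slope * age
             + qtl_total[i] + u[i] + rng.normal(0.0, s_e))
        rows.append((ind, y, breed, herd, sex, day, age))
    return pd.DataFrame(rows, columns=["individual", "trait", "breed", "herd",
                                       "sex", "day", "age"])


def degrade(genotypes: GenotypeMatrix, missing_rate: float,
            seed=0) -> GenotypeMatrix:
    """Set genotype entries missing independently at `missing_rate`."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return genotypes
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = genotypes.data.copy()
    mask = rng.random(data.shape) < missing_rate
    data[mask] = -1
    return GenotypeMatrix(genotypes.ids, genotypes.snps, data, sort=False)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StudyData:
    config: SimulationConfig
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix
    truth: TruthRecord
    phenotypes: pd.DataFrame
    breed_freqs: dict  # gene -> breed -> joint region frequency vector


def simulate_study(config: SimulationConfig,
                   seed: Optional[int] = None) -> StudyData:
    """Run the full generator: pedigree, breed frequencies, gene drop,
    phenotypes, optional missingness.  Reproducible from (config, seed)."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    pedigree = simulate_pedigree(config, rngs[0])
    founder_breeds = sorted({b for _, s, d, _ in config.groups for b in (s, d)})
    breed_freqs = {
        w.gene: simulate_window_breed_freqs(w, founder_breeds,
                                            config.fst_target, rngs[1])
        for w in config.windows}
    truth, gm = gene_drop(pedigree, config.windows, breed_freqs,
                          config.qtls, rngs[2])
    phen = simulate_phenotypes(pedigree, truth, config, rngs[3])
    if config.missing_rate > 0:
        gm = degrade(gm, config.missing_rate, rngs[4])
    return StudyData(config=config, pedigree=pedigree, genotypes=gm,
                     truth=truth, phenotypes=phen, breed_freqs=breed_freqs)


def _spread_freqs(order: Sequence[int]) -> np.ndarray:
    """A fixed 8-haplotype frequency profile, permuted.

    Mass is concentrated on about five haplotypes, the reduced haplotype
    diversity (high D', low r2) typical of cattle gene windows at ~50 kb
    SNP spacing; roughly five haplotypes clear the 0.05 MHF filter.
    """
    base = np.array([0.30, 0.25, 0.18, 0.12, 0.06, 0.04, 0.03, 0.02])
    out = np.zeros(8)
    out[list(order)] = base
    return out


def default_study_config(seed: int = 0, effect: float = 0.35,
                      typed_effect: float = 0.25,
                      carrier_fraction: float = 0.8) -> SimulationConfig:
    """The bundled study-like configuration: six gene windows, five with a
    hidden causal allele nested in a common haplotype and one with a typed
    causal SNP; two windows carry flanking control windows (one independent,
    one in LD with the focal window)."""
    genes = ["ADIPOQ", "CXCR4", "CEBPA", "FASN", "CAST", "CAPN1"]
    perms = [(0, 1, 2, 3, 4, 5, 6, 7), (3, 0, 5, 1, 7, 2, 6, 4),
             (5, 2, 7, 0, 4, 6, 1, 3), (1, 6, 0, 4, 2, 7, 3, 5),
             (7, 4, 2, 6, 0, 3, 5, 1), (2, 5, 4, 7, 6, 1, 0, 3)]
    windows, qtls = [], []
    for k, (gene, perm) in enumerate(zip(genes, perms)):
        start = 1_000_000
        positions = (start, start + 45_000, start + 90_000)
        flank_left = flank_right = None
        if gene == "ADIPOQ":  # independent flank: null control
            flank_left = FlankSpec(positions=(start - 150_000, start - 105_000,
                                              start - 60_000),
                                   base_freqs=_spread_freqs(perms[(k + 1) % 6]),
                                   coupling=0.0)
        if gene == "FASN":  # coupled flank: attenuated-signal control
            flank_right = FlankSpec(positions=(start + 150_000, start + 195_000,
                                               start + 240_000),
                                    base_freqs=_spread_freqs(perms[(k + 2) % 6]),
                                    coupling=0.6)
        windows.append(WindowSpec(gene=gene, chrom=f"chr{k + 1}",
                                  positions=positions,
                                  base_freqs=_spread_freqs(perm),
                                  flank_left=flank_left,
                                  flank_right=flank_right))
        if gene == "CAPN1":
            qtls.append(QtlSpec(gene=gene, mode="snp", snp_index=1,
                                effect=typed_effect))
        else:
            common = HAP_LABELS[int(np.argmax(windows[-1].base_freqs))]
            qtls.append(QtlSpec(gene=gene, mode="hidden", haplotype=common,
                                effect=effect,
                                carrier_fraction=carrier_fraction))
    return SimulationConfig(seed=seed, windows=windows, qtls=qtls)
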