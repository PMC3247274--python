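"""Readers, writers and validated containers for the standard input formats.

Genotypes are stored as counts of the B allele per individual per SNP
(0, 1, 2, or missing).  B is the VCF ALT allele, or the second allele column
of a six-column (bim-style) PLINK MAP file.  Coordinates are 1-based
throughout, VCF convention.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PedigreeTable",
    "read_genotypes",
    "read_pedigree",
    "read_phenotypes",
    "write_vcf",
    "write_plink",
    "write_table",
]


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identifier, location and its two alleles."""

    snp_id: str
    chrom: str
    position: int  # 1-based bp
    allele_a: str
    allele_b: str
    gene: Optional[str] = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")


class GenotypeMatrix:
    """Individuals x SNPs matrix of B-allele counts {0,1,2} with -1 = missing.

    SNPs are kept sorted by (chromosome, position); entries are validated on
    construction.
    """

    def __init__(self, ids: Sequence[str], snps: Sequence[SnpRecord],
                 data: np.ndarray, sort: bool = True):
        data = np.asarray(data, dtype=np.int8)
        if data.shape != (len(ids), len(snps)):
            raise ValueError(
                f"genotype data shape {data.shape} does not match "
                f"{len(ids)} individuals x {len(snps)} SNPs")
        bad = ~np.isin(data, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be in {0,1,2} or missing (-1)")
        seen = set()
        for s in snps:
            if s.snp_id in seen:
                raise ValueError(f"duplicated snp_id: {s.snp_id}")
            seen.add(s.snp_id)
        if sort:
            order = sorted(range(len(snps)),
                           key=lambda k: (snps[k].chrom, snps[k].position))
            snps = [snps[k] for k in order]
            data = data[:, order]
        self.ids = list(ids)
        self.snps = list(snps)
        self.data = data

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def window(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Sub-matrix restricted to the named SNPs (kept in map order)."""
        idx = {s.snp_id: k for k, s in enumerate(self.snps)}
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(f"SNPs not in matrix: {missing}")
        cols = sorted(idx[s] for s in snp_ids)
        return GenotypeMatrix(self.ids, [self.snps[c] for c in cols],
                              self.data[:, cols], sort=False)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.ids == other.ids
                and self.snps == other.snps
                and np.array_equal(self.data, other.data))


UNKNOWN_PARENT = {"", "0", "NA", "na", "nan", "None", "."}


class PedigreeTable:
    """individual / sire / dam / breed records, validated acyclic.

    Unknown parents (blank, 0, NA) are coded as founders.  Parents that are
    referenced but have no row of their own are added as implicit founders
    with unknown breed.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        required = {"individual", "sire", "dam", "breed"}
        if not required.issubset(df.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        for col in ("individual", "sire", "dam", "breed"):
            df[col] = df[col].astype(str)
        df.loc[df["sire"].isin(UNKNOWN_PARENT), "sire"] = ""
        df.loc[df["dam"].isin(UNKNOWN_PARENT), "dam"] = ""
        if df["individual"].duplicated().any():
            dups = df.loc[df["individual"].duplicated(), "individual"].tolist()
            raise ValueError(f"duplicated individuals in pedigree: {dups}")
        known = set(df["individual"])
        implicit = sorted(
            {p for p in pd.concat([df["sire"], df["dam"]]) if p and p not in known})
        if implicit:
            df = pd.concat(
                [pd.DataFrame({"individual": implicit, "sire": "", "dam": "",
                               "breed": ""}), df],
                ignore_index=True)
        g = nx.DiGraph()
        g.add_nodes_from(df["individual"])
        for _, row in df.iterrows():
            for p in (row["sire"], row["dam"]):
                if p:
                    g.add_edge(p, row["individual"])
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cyc}")
        self.df = df.reset_index(drop=True)
        self._graph = g
        order = list(nx.lexicographical_topological_sort(g))
        self.topological_order = order

    @property
    def individuals(self) -> list[str]:
        return self.df["individual"].tolist()

    @property
    def founders(self) -> list[str]:
        m = (self.df["sire"] == "") & (self.df["dam"] == "")
        return self.df.loc[m, "individual"].tolist()

    def parents(self, individual: str) -> tuple[str, str]:
        row = self.df.loc[self.df["individual"] == individual].iloc[0]
        return row["sire"] or "", row["dam"] or ""

    def breeds(self) -> dict[str, str]:
        return dict(zip(self.df["individual"], self.df["breed"]))

    def write(self, path) -> None:
        out = self.df.copy()
        out.loc[out["sire"] == "", "sire"] = "0"
        out.loc[out["dam"] == "", "dam"] = "0"
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotype formats
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a VCF or PLINK PED/MAP file set into a GenotypeMatrix.

    B allele = ALT for VCF, second allele column of a 6-column MAP for PLINK.
    Multiallelic sites and duplicated SNP ids raise errors.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format: {format}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps, rows = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic site not supported: {v.ID or v.POS}")
        gene = v.INFO.get("GENE")
        snps.append(SnpRecord(snp_id=v.ID or f"{v.CHROM}:{v.POS}",
                              chrom=str(v.CHROM), position=int(v.POS),
                              allele_a=v.REF, allele_b=v.ALT[0], gene=gene))
        gt = v.gt_types  # 0 hom_ref, 1 het, 2 unknown, 3 hom_alt
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(col.astype(np.int8))
    vcf.close()
    data = np.column_stack(rows) if rows else np.zeros((len(ids), 0), np.int8)
    return GenotypeMatrix(ids, snps, data)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write an uncompressed minimal VCF 4.2 with GT-only genotypes."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,'
                 'Description="Gene window label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.ids) + "\n")
        for j, s in enumerate(gm.snps):
            gts = "\t".join(code[int(g)] for g in gm.data[:, j])
            info = f"GENE={s.gene}" if s.gene else "."
            fh.write(f"{s.chrom}\t{s.position}\t{s.snp_id}\t{s.allele_a}\t"
                     f"{s.allele_b}\t.\t.\t{info}\tGT\t{gts}\n")


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write PED plus a 6-column (bim-style) MAP carrying the A/B alleles."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.position}\t"
                     f"{s.allele_a}\t{s.allele_b}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, ind in enumerate(gm.ids):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j, s in enumerate(gm.snps):
                g = int(gm.data[i, j])
                pair = {0: (s.allele_a, s.allele_a),
                        1: (s.allele_a, s.allele_b),
                        2: (s.allele_b, s.allele_b),
                        MISSING: ("0", "0")}[g]
                fields.extend(pair)
            fh.write("\t".join(fields) + "\n")


def _read_plink(path) -> GenotypeMatrix:
    prefix = str(path)
    for suffix in (".ped", ".map"):
        if prefix.endswith(suffix):
            prefix = prefix[: -len(suffix)]
    snps = []
    with open(prefix + ".map") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(
                    "PLINK MAP must have 6 columns (chrom, id, cM, pos, "
                    "alleleA, alleleB) so the B allele is defined")
            chrom, snp_id, _, pos, a, b = parts[:6]
            snps.append(SnpRecord(snp_id=snp_id, chrom=chrom, position=int(pos),
                                  allele_a=a, allele_b=b))
    ids, rows = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snps):
                raise ValueError("PED row length does not match MAP")
            ids.append(parts[1])
            geno = []
            for j, s in enumerate(snps):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    geno.append(MISSING)
                    continue
                for a in (a1, a2):
                    if a not in (s.allele_a, s.allele_b):
                        raise ValueError(
                            f"allele {a} at {s.snp_id} not in MAP alleles")
                geno.append((a1 == s.allele_b) + (a2 == s.allele_b))
            rows.append(geno)
    data = np.asarray(rows, dtype=np.int8) if rows else np.zeros((0, len(snps)), np.int8)
    return GenotypeMatrix(ids, snps, data)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_pedigree(path) -> PedigreeTable:
    """Read a headered CSV pedigree (individual,sire,dam,breed)."""
    return PedigreeTable(pd.read_csv(path, dtype=str, keep_default_na=False))


PHENOTYPE_COLUMNS = ["individual", "trait", "breed", "herd", "sex", "day", "age"]


def read_phenotypes(path, pedigree: Optional[PedigreeTable] = None) -> pd.DataFrame:
    """Read a headered CSV phenotype table and validate it.

    Fixed-effect levels are kept as strings; trait and age are numeric.
    If a pedigree is given, every phenotyped individual must appear in it.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    df["trait"] = pd.to_numeric(df["trait"].replace("", np.nan))
    df["age"] = pd.to_numeric(df["age"])
    if np.isinf(df["trait"].fillna(0.0)).any():
        raise ValueError("trait values must be finite or missing")
    for col in ("breed", "herd", "sex", "day"):
        if (df[col] == "").any():
            raise ValueError(f"empty fixed-effect level in column {col}")
    if pedigree is not None:
        absent = sorted(set(df["individual"]) - set(pedigree.individuals))
        if absent:
            raise ValueError(
                f"phenotyped individuals absent from pedigree: {absent[:5]}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, sig_digits: int = 4) -> None:
    """Write a report TSV: floats at `sig_digits` significant digits with a
    full-precision companion column `<name>_raw` appended for each."""
    out = df.copy()
    float_cols = [c for c in out.columns if out[c].dtype.kind == "f"]
    for c in float_cols:
        out[c + "_raw"] = out[c].map(lambda v: repr(float(v)))
        out[c] = out[c].map(lambda v: f"%.{sig_digits}g" % v)
    out.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a report TSV back, restoring full precision from `_raw` columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for c in [c for c in df.columns if c.endswith("_raw")]:
        base = c[: -len("_raw")]
        df[base] = pd.to_numeric(df[c])
        df = df.drop(columns=c)
    return df
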