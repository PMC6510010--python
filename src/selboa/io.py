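"""Readers and writers for the package's on-disk formats.

Phased genotypes travel as phased VCF (``GT`` with ``|`` separators) or
as a haplotype TSV; pedigree and phenotypes as CSV; origin assignments
as TSV. Everything is gzip-capable (by file extension).

Haplotype-parent convention: for simulator output the first VCF allele
is the paternal gamete. External phased VCFs do not guarantee parental
order, so readers expose the convention explicitly and downstream code
treats gamete order as (paternal, maternal).
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from selboa.containers import BREEDS, GAMETES, MISSING, OriginAssignment, PhasedGenotypes

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_haplotype_tsv",
    "read_haplotype_tsv",
    "write_origins_tsv",
    "read_origins_tsv",
    "write_pedigree_csv",
    "read_pedigree_csv",
]


def _open(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t") if "b" not in mode else gzip.open(path, mode)
    return open(path, mode)


def write_phased_vcf(geno: PhasedGenotypes, path) -> None:
    """Minimal VCF 4.2 with phased GT; REF=A, ALT=B placeholders."""
    with _open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.marker_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.animal_ids) + "\n")
        haps = geno.haplotypes
        for j, row in enumerate(geno.marker_map.itertuples()):
            gts = "\t".join(f"{haps[i, 0, j]}|{haps[i, 1, j]}"
                            for i in range(geno.n_animals))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tB\t.\t.\t.\tGT\t{gts}\n")


def read_phased_vcf(path) -> PhasedGenotypes:
    """Read a phased VCF (cyvcf2); any unphased genotype is an error."""
    from cyvcf2 import VCF

    with _open(path, "r") as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                names = line.rstrip("\n").split("\t")[9:]
                if len(set(names)) != len(names):
                    raise ValueError("duplicate sample id in VCF header")
                break
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    map_rows = []
    hap_cols = []
    for v in vcf:
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        col = np.empty((len(samples), 2), dtype=np.uint8)
        for i, (a, b, phased) in enumerate(v.genotypes):
            if not phased:
                raise ValueError(f"record {vid}: unphased genotype "
                                 f"for sample {samples[i]}")
            if a < 0 or b < 0:
                raise ValueError(f"record {vid}: missing GT for sample {samples[i]}")
            col[i, 0], col[i, 1] = a, b
        map_rows.append((v.CHROM, v.POS, vid))
        hap_cols.append(col)
    vcf.close()
    if not map_rows:
        raise ValueError("no variant records found")
    mmap = pd.DataFrame(map_rows, columns=["chrom", "pos", "snp_id"])
    haps = np.stack(hap_cols, axis=2)  # (n, 2, m)
    return PhasedGenotypes(animal_ids=samples, marker_map=mmap, haplotypes=haps)


def write_haplotype_tsv(geno: PhasedGenotypes, path) -> None:
    """One row per gamete: animal, gamete, then one column per SNP."""
    with _open(path, "w") as fh:
        fh.write("animal\tgamete\t" + "\t".join(geno.marker_map["snp_id"]) + "\n")
        for i, a in enumerate(geno.animal_ids):
            for g, gname in enumerate(GAMETES):
                alleles = "\t".join(map(str, geno.haplotypes[i, g]))
                fh.write(f"{a}\t{gname}\t{alleles}\n")


def read_haplotype_tsv(path, marker_map: pd.DataFrame | None = None) -> PhasedGenotypes:
    df = pd.read_csv(path, sep="\t")
    snp_ids = list(df.columns[2:])
    animals = list(dict.fromkeys(df["animal"]))
    n, m = len(animals), len(snp_ids)
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    pos = {a: i for i, a in enumerate(animals)}
    gidx = {g: i for i, g in enumerate(GAMETES)}
    vals = df[snp_ids].to_numpy(dtype=np.uint8)
    for r, (a, g) in enumerate(zip(df["animal"], df["gamete"])):
        haps[pos[a], gidx[g]] = vals[r]
    if marker_map is None:
        marker_map = pd.DataFrame({
            "chrom": 1, "pos": np.arange(1, m + 1), "snp_id": snp_ids,
        })
    return PhasedGenotypes(animal_ids=animals, marker_map=marker_map, haplotypes=haps)


def write_origins_tsv(origins: OriginAssignment, path) -> None:
    """Long format: animal, snp_id, gamete, origin (breed label or 'missing')."""
    lab = origins.labels
    with _open(path, "w") as fh:
        fh.write("animal\tsnp_id\tgamete\torigin\n")
        for i, a in enumerate(origins.animal_ids):
            for g, gname in enumerate(GAMETES):
                for j, s in enumerate(origins.snp_ids):
                    code = lab[i, g, j]
                    name = "missing" if code == MISSING else BREEDS[code]
                    fh.write(f"{a}\t{s}\t{gname}\t{name}\n")


def read_origins_tsv(path) -> OriginAssignment:
    df = pd.read_csv(path, sep="\t")
    animals = list(dict.fromkeys(df["animal"]))
    snps = list(dict.fromkeys(df["snp_id"]))
    apos = {a: i for i, a in enumerate(animals)}
    spos = {s: i for i, s in enumerate(snps)}
    gidx = {g: i for i, g in enumerate(GAMETES)}
    code = {b: i for i, b in enumerate(BREEDS)}
    code["missing"] = MISSING
    lab = np.full((len(animals), 2, len(snps)), MISSING, dtype=np.int8)
    lab[df["animal"].map(apos), df["gamete"].map(gidx), df["snp_id"].map(spos)] = (
        df["origin"].map(code).astype(np.int8)
    )
    return OriginAssignment(animal_ids=animals, snp_ids=np.array(snps), labels=lab)


def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"animal", "sire", "dam", "population"}
    if not required <= set(df.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
    return df
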