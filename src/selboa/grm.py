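"""Genomic relationship matrices: across-breed and breed-of-origin partial.

Two flavours are built here:

* the classic VanRaden (first-method) matrix
  ``G = (M - 2 1 p')(M - 2 1 p')' / F`` with allele frequencies pooled
  across the entire genotyped population and ``F = sum_j 2 p_j (1-p_j)``;
* breed-specific *partial* relationship matrices for a three-way cross:
  purebred rows of breed *b* are centered with ``2 p_b``, crossbred rows
  carry only the single gamete of origin *b* centered with ``p_b``
  (alleles of other or missing origin contribute zero), and all blocks
  are scaled by the breed-specific heterozygosity sum
  ``F_b = sum_j 2 p_jb (1 - p_jb)``. Diagonals then reflect breed
  proportion: ~1 for purebreds of breed b, ~0.5 for crossbreds on the
  sire line, ~0.25 on each maternal line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from selboa.containers import (
    BREED_CODE,
    BREEDS,
    MATERNAL,
    MISSING,
    PATERNAL,
    OriginAssignment,
    PhasedGenotypes,
)

__all__ = [
    "GenomicMatrix",
    "PartialGRM",
    "vanraden_g",
    "breed_frequencies",
    "partial_grm",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_binary",
    "read_grm_binary",
]


@dataclass
class GenomicMatrix:
    """A symmetric genomic relationship matrix with its scaling metadata."""

    animal_ids: list[str]
    values: np.ndarray
    scaling_factor: float
    freq: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.animal_ids):
            raise ValueError("matrix shape inconsistent with animal_ids")
        if not np.isfinite(v).all():
            raise ValueError("non-finite relationship entries")
        if self.scaling_factor <= 0:
            raise ValueError("scaling factor must be positive")
        self.values = v

    def submatrix(self, ids: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in ids])
        return self.values[np.ix_(idx, idx)]


@dataclass
class PartialGRM(GenomicMatrix):
    """Breed-specific partial relationship matrix over purebred-b + crossbred animals."""

    breed: str = ""
    n_purebred: int = 0  # leading rows are purebred-b animals

    @property
    def purebred_ids(self) -> list[str]:
        return self.animal_ids[: self.n_purebred]

    @property
    def crossbred_ids(self) -> list[str]:
        return self.animal_ids[self.n_purebred:]


def vanraden_g(genotypes: PhasedGenotypes, snp_subset: np.ndarray | None = None,
               ) -> GenomicMatrix:
    """Across-breed VanRaden relationship matrix on the pooled population.

    ``snp_subset`` is an index array into the genotype marker map; allele
    frequencies are always computed on the supplied (pooled) animals.
    """
    if genotypes.n_animals < 2:
        raise ValueError("need at least 2 animals")
    m = genotypes.dosage()
    snp_ids = genotypes.snp_ids
    if snp_subset is not None:
        snp_subset = np.asarray(snp_subset)
        if snp_subset.size == 0:
            raise ValueError("empty SNP subset")
        m = m[:, snp_subset]
        snp_ids = snp_ids[snp_subset]
    p = m.mean(axis=0) / 2.0
    f = float(np.sum(2.0 * p * (1.0 - p)))
    if f <= 0:
        raise ValueError("all SNP monomorphic in the pooled population (F = 0)")
    z = m - 2.0 * p
    return GenomicMatrix(
        animal_ids=list(genotypes.animal_ids),
        values=z @ z.T / f,
        scaling_factor=f,
        freq=p,
        snp_ids=snp_ids,
    )


def _origin_content(crossbreds: PhasedGenotypes, origins: OriginAssignment,
                    breed: str) -> tuple[np.ndarray, np.ndarray]:
    """Per crossbred x SNP: allele content of origin ``breed`` and a mask.

    For the sire line the relevant gamete is paternal, for maternal lines
    maternal; the mask is False where the allele's origin is missing or
    belongs to the other maternal line.
    """
    code = BREED_CODE[breed]
    gam = PATERNAL if breed == "S" else MATERNAL
    pos = {a: i for i, a in enumerate(origins.animal_ids)}
    rows = np.array([pos[a] for a in crossbreds.animal_ids])
    spos = {s: i for i, s in enumerate(origins.snp_ids)}
    cols = np.array([spos[s] for s in crossbreds.snp_ids])
    lab = origins.labels[rows][:, gam][:, cols]
    allele = crossbreds.haplotypes[:, gam, :].astype(np.float64)
    mask = lab == code
    return np.where(mask, allele, 0.0), mask


def breed_frequencies(purebred: PhasedGenotypes, crossbreds: PhasedGenotypes,
                      origins: OriginAssignment, breed: str) -> np.ndarray:
    """Breed-of-origin allele frequencies p_b.

    Counts allele-1 copies of origin *b* across purebred-b animals (both
    gametes) and crossbreds (the single gamete assigned to *b*), divided
    by the total number of origin-b copies at the locus. Missing-origin
    alleles are excluded from both numerator and denominator.
    """
    content, mask = _origin_content(crossbreds, origins, breed)
    ones = purebred.dosage().sum(axis=0) + content.sum(axis=0)
    total = 2.0 * purebred.n_animals + mask.sum(axis=0)
    if np.any(total == 0):
        bad = purebred.snp_ids[total == 0][:5]
        raise ValueError(
            f"no origin-{breed} allele copies at SNP {list(bad)}; "
            "filter these loci before building partial matrices"
        )
    return ones / total


def partial_grm(purebred: PhasedGenotypes, crossbreds: PhasedGenotypes,
                origins: OriginAssignment, breed: str,
                snp_subset: np.ndarray | None = None) -> PartialGRM:
    """Breed-specific partial relationship matrix over (purebred-b, crossbred) animals.

    Purebred rows are centered as ``M_b - 2 p_b``; crossbred rows carry
    the origin-b gamete centered as ``M_CB(b) - p_b`` with entries of
    other/missing origin set to zero after centering. All blocks share
    the scaling ``F_b = sum 2 p_jb (1 - p_jb)``.
    """
    if snp_subset is not None:
        snp_subset = np.asarray(snp_subset)
        if snp_subset.size == 0:
            raise ValueError("empty SNP subset")
        purebred = purebred.subset_snps(snp_subset)
        crossbreds = crossbreds.subset_snps(snp_subset)
    if breed not in BREEDS:
        raise ValueError(f"unknown breed {breed!r}")
    p_b = breed_frequencies(purebred, crossbreds, origins, breed)
    f_b = float(np.sum(2.0 * p_b * (1.0 - p_b)))
    if f_b <= 0:
        raise ValueError(f"origin-{breed} frequencies are all monomorphic (F_b = 0)")
    z_pure = purebred.dosage() - 2.0 * p_b
    content, mask = _origin_content(crossbreds, origins, breed)
    z_cb = np.where(mask, content - p_b, 0.0)
    z = np.vstack([z_pure, z_cb])
    return PartialGRM(
        animal_ids=list(purebred.animal_ids) + list(crossbreds.animal_ids),
        values=z @ z.T / f_b,
        scaling_factor=f_b,
        freq=p_b,
        snp_ids=purebred.snp_ids,
        breed=breed,
        n_purebred=purebred.n_animals,
    )


# ---------------------------------------------------------------------------
# readers / writers


def write_grm_tsv(g: GenomicMatrix, path) -> None:
    """Long-format TSV (id1, id2, value), lower triangle including diagonal."""
    ids = g.animal_ids
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{g.values[i, j]:.10g}\n")


def read_grm_tsv(path) -> GenomicMatrix:
    df = pd.read_csv(path, sep="\t")
    ids = list(pd.unique(pd.concat([df["id1"], df["id2"]])))
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    v = np.zeros((n, n))
    i = df["id1"].map(pos).to_numpy()
    j = df["id2"].map(pos).to_numpy()
    v[i, j] = df["value"].to_numpy()
    v[j, i] = df["value"].to_numpy()
    return GenomicMatrix(animal_ids=ids, values=v, scaling_factor=float(np.trace(v)),
                         freq=np.array([]), snp_ids=np.array([]))


def write_grm_binary(g: GenomicMatrix, path) -> None:
    """Row-major float64 matrix with an ``.ids`` sidecar."""
    np.asarray(g.values, dtype="<f8").tofile(path)
    with open(str(path) + ".ids", "w") as fh:
        fh.write("\n".join(g.animal_ids) + "\n")


def read_grm_binary(path) -> GenomicMatrix:
    with open(str(path) + ".ids") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    v = np.fromfile(path, dtype="<f8").reshape(len(ids), len(ids))
    return GenomicMatrix(animal_ids=ids, values=v, scaling_factor=float(np.trace(v)),
                         freq=np.array([]), snp_ids=np.array([]))
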