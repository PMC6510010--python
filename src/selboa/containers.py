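"""Core in-memory containers shared across the package.

Conventions
-----------
* Breeds of a three-way terminal cross are labelled ``S`` (sire line),
  ``LR`` and ``LW`` (maternal lines); the commercial crossbred
  population is labelled ``CB``.
* Haplotypes are stored per animal as two ordered gametes, index 0 =
  paternal, index 1 = maternal.
* Breed-of-origin labels are small integer codes (index into ``BREEDS``);
  ``MISSING = -1`` marks an unassigned allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BREEDS: tuple[str, ...] = ("S", "LR", "LW")
CROSSBRED = "CB"
MISSING: int = -1

BREED_CODE = {b: i for i, b in enumerate(BREEDS)}

PATERNAL, MATERNAL = 0, 1
GAMETES = ("paternal", "maternal")


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes with a marker map.

    Parameters
    ----------
    animal_ids
        Ordered animal identifiers, one per row of ``haplotypes``.
    marker_map
        DataFrame with columns ``chrom``, ``pos``, ``snp_id``; positions
        strictly increasing within chromosome.
    haplotypes
        uint8 array of shape ``(n_animals, 2, n_snp)`` with allele codes
        {0, 1}; axis 1 is (paternal, maternal).
    """

    animal_ids: list[str]
    marker_map: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n, g, m = self.haplotypes.shape
        if n != len(self.animal_ids):
            raise ValueError("animal_ids length does not match haplotypes")
        if g != 2:
            raise ValueError("haplotypes must have two gametes per animal")
        if m != len(self.marker_map):
            raise ValueError("marker_map length does not match haplotypes")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.marker_map["snp_id"].to_numpy()

    def dosage(self) -> np.ndarray:
        """Allele-1 dosage matrix (n_animals, n_snp), values {0, 1, 2}."""
        return self.haplotypes.sum(axis=1).astype(np.float64)

    def subset_snps(self, index: np.ndarray) -> "PhasedGenotypes":
        index = np.asarray(index)
        return PhasedGenotypes(
            animal_ids=list(self.animal_ids),
            marker_map=self.marker_map.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[:, :, index],
        )

    def subset_animals(self, index: np.ndarray) -> "PhasedGenotypes":
        index = np.asarray(index)
        return PhasedGenotypes(
            animal_ids=[self.animal_ids[i] for i in index],
            marker_map=self.marker_map,
            haplotypes=self.haplotypes[index],
        )

    @staticmethod
    def concat(parts: list["PhasedGenotypes"]) -> "PhasedGenotypes":
        """Pool populations sharing one marker map (row-wise stack)."""
        base = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.snp_ids, base.snp_ids):
                raise ValueError("cannot concatenate genotypes with different marker maps")
        return PhasedGenotypes(
            animal_ids=[a for p in parts for a in p.animal_ids],
            marker_map=base.marker_map,
            haplotypes=np.concatenate([p.haplotypes for p in parts], axis=0),
        )


@dataclass
class OriginAssignment:
    """Breed-of-origin labels for every crossbred allele.

    ``labels`` has shape ``(n_animals, 2, n_snp)`` with entries in
    {0=S, 1=LR, 2=LW, -1=missing}; axis 1 is (paternal, maternal).
    """

    animal_ids: list[str]
    snp_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids)
        n, g, m = self.labels.shape
        if n != len(self.animal_ids) or g != 2 or m != len(self.snp_ids):
            raise ValueError("labels shape inconsistent with ids")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snp(self) -> int:
        return self.labels.shape[2]

    def assigned_fraction(self) -> np.ndarray:
        """Per-animal fraction of alleles with an assigned origin."""
        return (self.labels != MISSING).mean(axis=(1, 2))

    def subset(self, animal_index=None, snp_index=None) -> "OriginAssignment":
        lab = self.labels
        ids = self.animal_ids
        snps = self.snp_ids
        if animal_index is not None:
            animal_index = np.asarray(animal_index)
            lab = lab[animal_index]
            ids = [self.animal_ids[i] for i in animal_index]
        if snp_index is not None:
            snp_index = np.asarray(snp_index)
            lab = lab[:, :, snp_index]
            snps = snps[snp_index]
        return OriginAssignment(animal_ids=ids, snp_ids=snps, labels=lab)

    def agreement(self, other: "OriginAssignment") -> float:
        """Fraction of non-missing labels of ``self`` that match ``other``.

        Used to compare an inferred assignment with simulator truth over
        the shared animals and SNP.
        """
        a_idx = {a: i for i, a in enumerate(other.animal_ids)}
        s_idx = {s: i for i, s in enumerate(other.snp_ids)}
        rows = np.array([a_idx[a] for a in self.animal_ids])
        cols = np.array([s_idx[s] for s in self.snp_ids])
        truth = other.labels[rows][:, :, cols]
        mask = self.labels != MISSING
        if not mask.any():
            return float("nan")
        return float((self.labels[mask] == truth[mask]).mean())
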