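"""SNP targeting: from GEBV to breed-specific selected-SNP sets.

Pipeline: back-solve purebred GEBV for crossbred performance into
per-SNP allele-substitution effects for each breed of origin, group SNP
into origin-specific LD blocks from crossbred gametes, express each
block's contribution as a percentage of the crossbred genetic variance
(adjusted for block size), and pick the top blocks per breed of origin
until they jointly explain at most a 5% or 10% threshold. The union of
the per-breed picks, deduplicated, is the selected-SNP set that gets
breed-specific effects in the SEL-BOA model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from selboa.containers import (
    BREED_CODE,
    BREEDS,
    MATERNAL,
    PATERNAL,
    OriginAssignment,
    PhasedGenotypes,
)
from selboa.grm import PartialGRM

__all__ = [
    "SnpEffects",
    "LDBlockSet",
    "SelectedSnpSet",
    "backsolve_effects",
    "origin_gametes",
    "build_ld_blocks",
    "block_variance_explained",
    "select_snps",
]


@dataclass
class SnpEffects:
    """Back-solved allele substitution effects for one breed of origin."""

    breed: str
    alpha: np.ndarray
    snp_ids: np.ndarray
    scaling_factor: float

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.snp_ids):
            raise ValueError("effect vector length != SNP count")


@dataclass
class LDBlockSet:
    """Disjoint, exhaustive LD blocks of one breed of origin.

    ``blocks`` holds SNP indices (into the panel); ``pct_var`` the percent
    of crossbred genetic variance explained, adjusted by x̄_n/n_i.
    """

    breed: str
    blocks: list
    pct_var: np.ndarray | None = None
    x_n: float | None = None
    sigma_a2: float | None = None

    def __post_init__(self) -> None:
        seen = set()
        for blk in self.blocks:
            s = set(int(i) for i in blk)
            if seen & s:
                raise ValueError("LD blocks must be disjoint")
            seen |= s
        if self.pct_var is not None and np.any(np.asarray(self.pct_var) < -1e-12):
            raise ValueError("negative percent variance")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class SelectedSnpSet:
    """Merged selected-SNP panel for a given variance threshold."""

    threshold: float
    per_breed_blocks: dict          # breed -> list of block index arrays
    per_breed_pct: dict             # breed -> cumulative percent selected
    snp_index: np.ndarray           # merged, deduplicated panel indices
    panel_size: int

    @property
    def panel_fraction(self) -> float:
        return len(self.snp_index) / self.panel_size


def backsolve_effects(gebv: pd.Series, purebred: PhasedGenotypes,
                      partial: PartialGRM, ridge: float = 1e-6) -> SnpEffects:
    """Convert purebred GEBV for crossbred performance to SNP effects.

    alpha = F_b^-1 V_b' G_bb^-1 a_hat, with V_b the 2p_b-centered
    purebred genotypes; V_b alpha reconstructs a_hat (up to the ridge).
    """
    ids = partial.purebred_ids
    if set(gebv.index) != set(ids):
        missing = set(ids) - set(gebv.index)
        raise ValueError(f"GEBV missing for purebred animals, e.g. {list(missing)[:5]}")
    a_hat = gebv.loc[ids].to_numpy(dtype=float)
    pos = {a: i for i, a in enumerate(purebred.animal_ids)}
    order = [pos[a] for a in ids]
    v = purebred.dosage()[order] - 2.0 * partial.freq
    gbb = partial.values[: partial.n_purebred, : partial.n_purebred]
    gbb = gbb + ridge * np.eye(len(ids))
    alpha = v.T @ np.linalg.solve(gbb, a_hat) / partial.scaling_factor
    return SnpEffects(breed=partial.breed, alpha=alpha, snp_ids=partial.snp_ids,
                      scaling_factor=partial.scaling_factor)


def origin_gametes(crossbreds: PhasedGenotypes, origins: OriginAssignment,
                   breed: str) -> np.ndarray:
    """Haploid dosage of origin-``breed`` gametes; NaN where origin differs."""
    gam = PATERNAL if breed == "S" else MATERNAL
    code = BREED_CODE[breed]
    pos = {a: i for i, a in enumerate(origins.animal_ids)}
    rows = np.array([pos[a] for a in crossbreds.animal_ids])
    spos = {s: i for i, s in enumerate(origins.snp_ids)}
    cols = np.array([spos[s] for s in crossbreds.snp_ids])
    lab = origins.labels[rows][:, gam][:, cols]
    hap = crossbreds.haplotypes[:, gam, :].astype(float)
    hap[lab != code] = np.nan
    return hap


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation over pairwise-complete observations."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r * r


def build_ld_blocks(gametes: np.ndarray, marker_map: pd.DataFrame, breed: str,
                    r2_threshold: float = 0.3, max_span: int = 50) -> LDBlockSet:
    """Greedy agglomeration of consecutive SNP into origin-specific LD blocks.

    Within each chromosome a candidate SNP joins the current block when
    its r² with any block member at most ``max_span`` positions back
    exceeds ``r2_threshold``; otherwise it starts a new block. Singleton
    blocks are allowed. r² is computed on haploid origin gametes with
    missing entries excluded pairwise.
    """
    blocks = []
    start = 0
    for _, grp in marker_map.groupby("chrom", sort=False):
        idx = np.arange(start, start + len(grp))
        start += len(grp)
        cur = [idx[0]]
        for j in idx[1:]:
            hit = False
            for k in reversed(cur):
                if j - k > max_span:
                    break
                if _pairwise_r2(gametes[:, j], gametes[:, k]) > r2_threshold:
                    hit = True
                    break
            if hit:
                cur.append(j)
            else:
                blocks.append(np.array(cur))
                cur = [j]
        blocks.append(np.array(cur))
    return LDBlockSet(breed=breed, blocks=blocks)


def block_variance_explained(blockset: LDBlockSet, effects: SnpEffects,
                             purebred: PhasedGenotypes, sigma_a2: float,
                             ) -> LDBlockSet:
    """Percent of crossbred genetic variance explained per LD block.

    100 * Var(sum_j z_j alpha_j) / sigma_a2 * (x̄_n / n_i), with the
    variance taken across purebred individuals of the breed and x̄_n the
    mean block size. The adjustment penalises large blocks so explained
    variance is comparable across block sizes.
    """
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    z = purebred.dosage()
    x_n = float(np.mean([len(b) for b in blockset.blocks]))
    pct = np.empty(blockset.n_blocks)
    for i, blk in enumerate(blockset.blocks):
        g = z[:, blk] @ effects.alpha[blk]
        pct[i] = 100.0 * float(np.var(g)) / sigma_a2 * (x_n / len(blk))
    return LDBlockSet(breed=blockset.breed, blocks=blockset.blocks, pct_var=pct,
                      x_n=x_n, sigma_a2=sigma_a2)


def select_snps(blocksets: dict, threshold: float, panel_size: int,
                ) -> SelectedSnpSet:
    """Pick top LD blocks per breed of origin up to the variance threshold.

    Blocks are sorted by percent explained (descending; ties broken by
    larger block then lower genomic coordinate) and accumulated while the
    running total stays at or below ``threshold`` (a fraction, e.g. 0.05
    means 5% of the crossbred genetic variance). The per-breed selections
    are merged and deduplicated.
    """
    chosen_blocks, chosen_pct = {}, {}
    merged: set[int] = set()
    for breed, bs in blocksets.items():
        if bs.pct_var is None:
            raise ValueError("run block_variance_explained first")
        order = sorted(
            range(bs.n_blocks),
            key=lambda i: (-bs.pct_var[i], -len(bs.blocks[i]), int(bs.blocks[i][0])),
        )
        total = 0.0
        sel = []
        for i in order:
            if total + bs.pct_var[i] > threshold * 100.0 + 1e-12:
                break
            total += bs.pct_var[i]
            sel.append(bs.blocks[i])
        chosen_blocks[breed] = sel
        chosen_pct[breed] = total
        for blk in sel:
            merged.update(int(j) for j in blk)
    return SelectedSnpSet(
        threshold=threshold,
        per_breed_blocks=chosen_blocks,
        per_breed_pct=chosen_pct,
        snp_index=np.array(sorted(merged), dtype=int),
        panel_size=panel_size,
    )
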