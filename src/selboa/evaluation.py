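"""Relationship-aware cross-validation with deregressed proofs.

Validation of genomic predictions of purebred animals for crossbred
performance proceeds in four steps:

1. split every population into k clusters by K-means on a dissimilarity
   transform of the genomic relationship matrix, rebalance the crossbred
   clusters to roughly equal size, and pair each crossbred cluster with
   the most-related purebred cluster of every breed — these pairs are
   the folds;
2. for each fold, estimate pedigree-based EBV of purebred animals for
   crossbred performance from that fold's crossbred phenotypes only;
3. deregress the EBV (remove within-fold parent-average information,
   scale by own reliability) into pseudo-phenotypes (DRP) with
   information weights w;
4. score each model by the w-weighted correlation between DRP and GEBV,
   with SE = (1 - r^2) / sqrt(N).

The fold construction guarantees that a purebred animal's GEBV is
trained without the crossbred phenotypes most related to it; those are
reserved to build its validation DRP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from selboa.containers import BREEDS, CROSSBRED
from selboa.grm import GenomicMatrix

__all__ = [
    "CVFolds",
    "DrpTable",
    "AccuracyReport",
    "make_folds",
    "pedigree_a_matrix",
    "pedigree_ebv",
    "deregress",
    "weighted_accuracy",
]


@dataclass
class CVFolds:
    """Fold assignment per animal plus crossbred-purebred cluster pairing."""

    k: int
    assignment: pd.DataFrame    # animal, population, fold
    pairing: dict               # breed -> {crossbred fold -> purebred cluster}

    def animals(self, population: str, fold: int) -> list:
        df = self.assignment
        return df.loc[(df["population"] == population) & (df["fold"] == fold),
                      "animal"].tolist()


@dataclass
class DrpTable:
    """Deregressed proofs of validation purebreds with information weights."""

    table: pd.DataFrame  # animal, drp, weight, reliability, fold

    def __post_init__(self) -> None:
        if (self.table["weight"] < 0).any():
            raise ValueError("negative DRP weights")


@dataclass
class AccuracyReport:
    """Weighted validation accuracy per breed and fold."""

    rows: pd.DataFrame  # breed, fold, model, r, se, n

    def mean_by_breed(self, model: str) -> pd.Series:
        df = self.rows[self.rows["model"] == model]
        return df.groupby("breed")["r"].mean()


def make_folds(g: GenomicMatrix, populations: dict, k: int = 4,
               seed: int = 0, n_init: int = 20) -> CVFolds:
    """K-means folds on the G matrix with crossbred rebalancing and pairing.

    Per population, K-means is run on the rows of the dissimilarity
    matrix d_ij = max(G) - G_ij restricted to that population. Crossbred
    clusters are rebalanced to ~n/k by moving, from the largest cluster,
    the animal with the highest average relationship to the smallest
    cluster. Each crossbred cluster is then paired with one purebred
    cluster per breed by maximising the average between-cluster
    relationship (an assignment problem, so the pairing is a bijection).
    """
    ids = np.array(g.animal_ids)
    pop_of = np.array([populations[a] for a in ids])
    labels = {}
    for pop in list(BREEDS) + [CROSSBRED]:
        rows = np.flatnonzero(pop_of == pop)
        if rows.size == 0:
            continue
        if rows.size < k:
            raise ValueError(f"population {pop} smaller than k={k}")
        sub = g.values[np.ix_(rows, rows)]
        d = sub.max() - sub
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels[pop] = (rows, km.fit_predict(d))
    # rebalance crossbred clusters to ~n/k
    rows_cb, lab_cb = labels[CROSSBRED]
    sub = g.values[np.ix_(rows_cb, rows_cb)]
    target = len(rows_cb) / k
    lab_cb = lab_cb.copy()
    for _ in range(len(rows_cb)):
        sizes = np.bincount(lab_cb, minlength=k)
        big, small = int(sizes.argmax()), int(sizes.argmin())
        if sizes[big] <= math.ceil(target) or sizes[small] >= math.floor(target):
            break
        members = np.flatnonzero(lab_cb == big)
        receivers = np.flatnonzero(lab_cb == small)
        avg_rel = sub[np.ix_(members, receivers)].mean(axis=1)
        lab_cb[members[int(avg_rel.argmax())]] = small
    labels[CROSSBRED] = (rows_cb, lab_cb)
    # pair each crossbred cluster with the closest purebred cluster per breed
    pairing = {}
    fold_of = {}
    for i, a in zip(rows_cb, lab_cb):
        fold_of[ids[i]] = int(a)
    for b in BREEDS:
        if b not in labels:
            continue
        rows_b, lab_b = labels[b]
        rel = np.zeros((k, k))  # crossbred cluster x purebred cluster
        for ci in range(k):
            mci = rows_cb[lab_cb == ci]
            for pi in range(k):
                mpi = rows_b[lab_b == pi]
                rel[ci, pi] = g.values[np.ix_(mci, mpi)].mean()
        ri, pi = linear_sum_assignment(-rel)
        pairing[b] = {int(c): int(p) for c, p in zip(ri, pi)}
        inv = {p: c for c, p in pairing[b].items()}
        for i, a in zip(rows_b, lab_b):
            fold_of[ids[i]] = inv[int(a)]
    assign = pd.DataFrame({
        "animal": ids,
        "population": pop_of,
        "fold": [fold_of[a] for a in ids],
    })
    return CVFolds(k=k, assignment=assign, pairing=pairing)


def pedigree_a_matrix(pedigree: pd.DataFrame, animals: list | None = None,
                      ) -> tuple[np.ndarray, list]:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` needs columns animal/sire/dam with '0' for unknown
    parents; parents must be listed before offspring. When ``animals``
    is given, the pedigree is pruned to them plus all their ancestors.
    """
    ped = pedigree[["animal", "sire", "dam"]].astype(str)
    parent = {r.animal: (r.sire, r.dam) for r in ped.itertuples()}
    if animals is not None:
        keep = set()
        stack = [str(a) for a in animals]
        while stack:
            a = stack.pop()
            if a in keep or a == "0":
                continue
            keep.add(a)
            if a in parent:
                stack.extend(parent[a])
        ped = ped[ped["animal"].isin(keep)]
    order = ped["animal"].tolist()
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    a_mat = np.zeros((n, n))
    for i, aid in enumerate(order):
        s, d = parent[aid]
        si = pos.get(s, -1)
        di = pos.get(d, -1)
        f = 0.5 * a_mat[si, di] if si >= 0 and di >= 0 else 0.0
        a_mat[i, i] = 1.0 + f
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * a_mat[si]
        if di >= 0:
            row += 0.5 * a_mat[di]
        a_mat[i, :i] = row[:i]
        a_mat[:i, i] = row[:i]
    return a_mat, order


def pedigree_ebv(cb_phenotypes: pd.DataFrame, pedigree: pd.DataFrame,
                 sigma_a: float, sigma_litter: float, sigma_e: float,
                 target_animals: list) -> pd.DataFrame:
    """Pedigree BLUP of breeding values for crossbred performance.

    Fits crossbred phenotypes only (fixed level + covariate, litter,
    additive animal effect with the A-matrix over the crossbreds, their
    ancestors and the target purebreds) and returns EBV and reliability
    for ``target_animals``. With only crossbred records in the system a
    purebred animal's EBV is its prediction for crossbred performance.
    """
    cb = cb_phenotypes.reset_index(drop=True)
    wanted = list(dict.fromkeys([str(a) for a in cb["animal_id"]] +
                                [str(a) for a in target_animals]))
    a_mat, order = pedigree_a_matrix(pedigree, animals=wanted)
    pos = {a: i for i, a in enumerate(order)}
    missing = [a for a in wanted if a not in pos]
    if missing:
        raise ValueError(f"animals absent from pedigree: {missing[:5]}")
    n_rec = len(cb)
    n_ani = len(order)
    # fixed design: intercept + levels + covariate
    levels = sorted(cb["fixed_level"].unique())
    x_cols = [np.ones(n_rec)]
    for lv in levels[1:]:
        x_cols.append((cb["fixed_level"] == lv).to_numpy(float))
    if np.ptp(cb["covariate"].to_numpy()) > 0:
        x_cols.append(cb["covariate"].to_numpy(float))
    x = np.column_stack(x_cols)
    lit_codes, _ = pd.factorize(cb["litter_id"])
    n_lit = lit_codes.max() + 1
    w = np.zeros((n_rec, n_lit))
    w[np.arange(n_rec), lit_codes] = 1.0
    z = np.zeros((n_rec, n_ani))
    z[np.arange(n_rec), [pos[str(a)] for a in cb["animal_id"]]] = 1.0
    lam_u = sigma_e / sigma_litter if sigma_litter > 0 else None
    lam_a = sigma_e / sigma_a
    a_inv = np.linalg.inv(a_mat + 1e-8 * np.eye(n_ani))
    blocks = [x, w, z] if lam_u is not None else [x, z]
    full = np.hstack(blocks)
    coeff = full.T @ full
    off = x.shape[1]
    if lam_u is not None:
        coeff[off:off + n_lit, off:off + n_lit] += lam_u * np.eye(n_lit)
        off += n_lit
    coeff[off:off + n_ani, off:off + n_ani] += lam_a * a_inv
    rhs = full.T @ cb["trait_value"].to_numpy(float)
    cinv = np.linalg.pinv(coeff)
    sol = cinv @ rhs
    ebv = sol[off:off + n_ani]
    pev = np.diag(cinv)[off:off + n_ani] * sigma_e
    rel = 1.0 - pev / (np.diag(a_mat) * sigma_a)
    rel = np.clip(rel, 0.0, 1.0 - 1e-9)
    out = pd.DataFrame({"animal": order, "ebv": ebv, "reliability": rel})
    out = out.set_index("animal").loc[[str(a) for a in target_animals]]
    return out.reset_index()


def deregress(ebv_table: pd.DataFrame, pedigree: pd.DataFrame, h2: float,
              fold: int = 0, c: float = 0.1, min_reliability: float = 1e-3,
              ) -> DrpTable:
    """Deregressed proofs with information weights.

    For each validation animal the parent-average information from
    parents *in the same validation set* is removed on the information
    scale (r²/(1-r²)); the remaining own reliability scales the EBV
    deviation into a pseudo-phenotype: DRP = PA + (EBV - PA) / r²_own.
    The weight w (effective record contributions) follows the standard
    deregression weighting w = (1 - h²) / ((c + (1 - r²_own)/r²_own) h²)
    with ``c`` the fraction of genetic variance not explained by markers.
    Animals with no usable own information are dropped.
    """
    ped = pedigree[["animal", "sire", "dam"]].astype(str)
    parent = {r.animal: (r.sire, r.dam) for r in ped.itertuples()}
    tab = ebv_table.set_index("animal")
    rows = []
    for aid, row in tab.iterrows():
        r2 = float(row["reliability"])
        if r2 <= min_reliability:
            continue
        s, d = parent.get(str(aid), ("0", "0"))
        pa, r2_pa = 0.0, 0.0
        in_set = [p for p in (s, d) if p in tab.index]
        if in_set:
            pa = float(np.mean([tab.loc[p, "ebv"] for p in in_set]))
            r2_pa = float(np.sum([tab.loc[p, "reliability"] for p in in_set])) / 4.0
        info_total = r2 / (1.0 - r2)
        info_pa = r2_pa / (1.0 - r2_pa) if r2_pa < 1 else 0.0
        info_own = info_total - info_pa
        if info_own <= 0:
            continue
        r2_own = info_own / (1.0 + info_own)
        drp = pa + (float(row["ebv"]) - pa) / r2_own
        w = (1.0 - h2) / ((c + (1.0 - r2_own) / r2_own) * h2)
        rows.append((aid, drp, w, r2_own, fold))
    return DrpTable(pd.DataFrame(
        rows, columns=["animal", "drp", "weight", "reliability", "fold"]
    ))


def weighted_accuracy(drp: DrpTable, gebv: pd.Series) -> tuple[float, float, int]:
    """Weighted Pearson correlation between DRP and GEBV, with its SE.

    Returns (r, se, n) with se = (1 - r^2) / sqrt(n).
    """
    t = drp.table.set_index("animal")
    common = t.index.intersection(gebv.index)
    if len(common) < 3:
        raise ValueError("need at least 3 animals with both DRP and GEBV")
    w = t.loc[common, "weight"].to_numpy(float)
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    x = t.loc[common, "drp"].to_numpy(float)
    y = gebv.loc[common].to_numpy(float)
    wm = w / w.sum()
    mx, my = wm @ x, wm @ y
    cov = wm @ ((x - mx) * (y - my))
    vx = wm @ ((x - mx) ** 2)
    vy = wm @ ((y - my) ** 2)
    r = cov / math.sqrt(vx * vy)
    se = (1.0 - r * r) / math.sqrt(len(common))
    return float(r), float(se), int(len(common))
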