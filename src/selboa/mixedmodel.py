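"""Multi-trait GBLUP mixed models (G, BOA, SEL-BOA) with REML.

Model structure
---------------
Phenotypes of four populations (three purebred lines and the commercial
crossbred) are analysed jointly. Each population has its own fixed
effects (a factor plus a covariate), an iid common-litter effect and an
independent residual. Genetic effects come in components, each defined
by a relationship matrix K and a small trait-covariance matrix C, with
effect covariance ``C (x) K`` (Kronecker):

* a *breed-specific* component uses a partial relationship matrix and
  two trait slots — purebred performance of that breed and crossbred
  performance. Purebred records load on the first slot, crossbred
  records on the second; the purebred animals' crossbred-trait effect
  (their genomic merit for crossbred performance) and the crossbreds'
  purebred-trait effect (an artificial vector with zero incidence that
  merely completes the Kronecker structure) are unobserved but
  predictable.
* an *across-breed* component uses one VanRaden matrix over everybody
  and four trait slots (S, LR, LW purebred performance and crossbred
  performance) with a full 4x4 covariance.

Because every record maps to exactly one trait slot of each component,
the phenotypic covariance matrix is linear in the variance parameters:
``V = sum_k theta_k B_k`` with fixed structure matrices ``B_k``. REML
uses average-information updates on this linear structure, with
expectation-maximisation steps as a monotone fallback, and bending of
non-positive-definite component covariances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from selboa.containers import BREEDS, CROSSBRED
from selboa.grm import GenomicMatrix, PartialGRM, partial_grm, vanraden_g

__all__ = [
    "GeneticComponent",
    "ModelSpec",
    "FitResult",
    "MixedModel",
    "build_model_spec",
    "reml_fit",
    "derive_summaries",
    "predict_gebv",
    "crossbred_variance",
    "crossbred_h2",
]

#: contribution of each breed of origin to a crossbred genotype
CROSSBRED_WEIGHTS = {"S": 0.5, "LR": 0.25, "LW": 0.25}


@dataclass
class GeneticComponent:
    """One genetic (co)variance component: effects ~ N(0, C (x) K)."""

    label: str
    K: np.ndarray
    k_ids: list[str]
    trait_of: dict            # population label -> trait slot index
    trait_names: list[str]
    breed: str | None = None  # set for breed-specific components
    n_purebred: int = 0       # leading K rows that are purebred animals
    free_cov: list | None = None  # list of (i, j) with free covariance params

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=np.float64)
        t = len(self.trait_names)
        if self.free_cov is None:
            self.free_cov = [(i, j) for i in range(t) for j in range(i, t)]

    @property
    def trait_dim(self) -> int:
        return len(self.trait_names)


@dataclass
class ModelSpec:
    """A model family instance: components plus bookkeeping."""

    model_kind: str                    # "G" | "BOA" | "SELBOA"
    components: list[GeneticComponent]
    selected_snps: np.ndarray | None = None
    litter: bool = True


def build_model_spec(model_kind: str, pooled, purebreds, crossbreds, origins,
                     selected_index: np.ndarray | None = None,
                     full_cross_breed_cov: bool = True,
                     ridge: float = 1e-6) -> ModelSpec:
    """Assemble the genetic components of a G, BOA or SEL-BOA model.

    ``selected_index`` indexes SNP (of the shared post-filter panel) that
    get breed-specific effects under SEL-BOA. A SEL-BOA spec with no
    selected SNP degenerates structurally to the G model; with all SNP
    selected it degenerates to the BOA model.
    """
    model_kind = model_kind.upper().replace("-", "")
    n_snp = pooled.n_snp
    all_idx = np.arange(n_snp)

    def across(label, idx):
        g = vanraden_g(pooled, snp_subset=idx)
        k = g.values + ridge * np.eye(len(g.animal_ids))
        trait_of = {b: i for i, b in enumerate(BREEDS)}
        trait_of[CROSSBRED] = len(BREEDS)
        names = [f"PB_{b}" for b in BREEDS] + ["CB"]
        free = None
        if not full_cross_breed_cov:
            t = len(names)
            free = [(i, i) for i in range(t)] + [(i, t - 1) for i in range(t - 1)]
        # pooled genotypes are ordered purebreds first, then crossbreds
        return GeneticComponent(label=label, K=k, k_ids=g.animal_ids,
                                trait_of=trait_of, trait_names=names, free_cov=free,
                                n_purebred=pooled.n_animals - crossbreds.n_animals)

    def breed_specific(suffix, idx):
        comps = []
        for b in BREEDS:
            pg = partial_grm(purebreds[b], crossbreds, origins, b, snp_subset=idx)
            k = pg.values + ridge * np.eye(len(pg.animal_ids))
            comps.append(GeneticComponent(
                label=f"{b}-{suffix}", K=k, k_ids=pg.animal_ids,
                trait_of={b: 0, CROSSBRED: 1},
                trait_names=[f"PB_{b}", "CB"], breed=b,
                n_purebred=pg.n_purebred,
            ))
        return comps

    if model_kind == "G":
        return ModelSpec("G", [across("across-all", None)])
    if model_kind == "BOA":
        return ModelSpec("BOA", breed_specific("all", None))
    if model_kind == "SELBOA":
        if selected_index is None:
            selected_index = np.array([], dtype=int)
        selected_index = np.asarray(selected_index, dtype=int)
        rest = np.setdiff1d(all_idx, selected_index)
        if selected_index.size == 0:
            return ModelSpec("SELBOA", [across("across-all", None)],
                             selected_snps=selected_index)
        if rest.size == 0:
            return ModelSpec("SELBOA", breed_specific("all", None),
                             selected_snps=selected_index)
        comps = breed_specific("sel", selected_index)
        comps.append(across("nonsel", rest))
        return ModelSpec("SELBOA", comps, selected_snps=selected_index)
    raise ValueError(f"unknown model kind {model_kind!r}")


# ---------------------------------------------------------------------------
# parameter bookkeeping


@dataclass
class _Param:
    kind: str        # "gcov" | "litter" | "resid"
    comp: int = -1
    i: int = -1
    j: int = -1
    pop: str = ""

    def name(self) -> str:
        if self.kind == "gcov":
            return f"g{self.comp}[{self.i},{self.j}]"
        return f"{self.kind}:{self.pop}"


@dataclass
class FitResult:
    """REML estimates, predictions and derived summaries."""

    model_kind: str
    varcomps: dict               # component label -> C (DataFrame)
    litter_var: dict             # population -> variance
    residual_var: dict           # population -> variance
    loglik: float
    converged: bool
    iterations: int
    gebv: dict = field(default_factory=dict)   # label -> DataFrame (animals x traits)
    h2_pb: dict = field(default_factory=dict)
    h2_cb: float | None = None
    rpc: dict = field(default_factory=dict)    # (label, breed) -> value (clamped)
    rpc_raw: dict = field(default_factory=dict)
    clamp_log: list = field(default_factory=list)
    fixed_effects: pd.Series | None = None
    h2_cb_sel: float | None = None             # SEL-BOA: selected-SNP share of h2
    h2_cb_nonsel: float | None = None
    selected_share: dict = field(default_factory=dict)  # breed -> sel fraction of CB var

    def component(self, label: str) -> pd.DataFrame:
        return self.varcomps[label]


class MixedModel:
    """Observation-level assembly of the multi-trait model.

    Handles fixed-effect design construction, the mapping of records to
    trait slots of every component, the linear covariance structure, and
    REML estimation.
    """

    def __init__(self, phenotypes: pd.DataFrame, spec: ModelSpec,
                 litter: bool | None = None):
        self.spec = spec
        self.use_litter = spec.litter if litter is None else litter
        ph = phenotypes.reset_index(drop=True)
        self.ph = ph
        self.n = len(ph)
        self.y = ph["trait_value"].to_numpy(dtype=np.float64)
        self.pops = list(pd.unique(ph["population"]))
        self.X, self.x_names = self._build_fixed(ph)
        # component row maps
        self.comp_rows = []   # per comp: dict trait -> obs row indices
        self.comp_kidx = []   # per comp: dict trait -> K row indices
        for comp in spec.components:
            pos = {a: i for i, a in enumerate(comp.k_ids)}
            rows, kidx = {}, {}
            for pop, t in comp.trait_of.items():
                r = np.flatnonzero((ph["population"] == pop).to_numpy())
                if r.size == 0:
                    continue
                missing = [a for a in ph.loc[r, "animal_id"] if a not in pos]
                if missing:
                    raise ValueError(
                        f"animals absent from component {comp.label!r} matrix: "
                        f"{missing[:5]}"
                    )
                rows[t] = r
                kidx[t] = np.array([pos[a] for a in ph.loc[r, "animal_id"]])
            self.comp_rows.append(rows)
            self.comp_kidx.append(kidx)
        # litter structure per population
        self.pop_rows = {p: np.flatnonzero((ph["population"] == p).to_numpy())
                         for p in self.pops}
        self.litter_same = {}
        self.n_litters = {}
        if self.use_litter:
            for p, r in self.pop_rows.items():
                codes = pd.factorize(ph.loc[r, "litter_id"])[0]
                self.litter_same[p] = (codes[:, None] == codes[None, :])
                self.n_litters[p] = int(codes.max()) + 1
        self.params = self._param_list()

    # -- design ------------------------------------------------------------
    @staticmethod
    def _build_fixed(ph: pd.DataFrame):
        cols, names = [], []
        for pop in pd.unique(ph["population"]):
            mask = (ph["population"] == pop).to_numpy(dtype=float)
            cols.append(mask)
            names.append(f"{pop}:intercept")
            levels = sorted(ph.loc[ph["population"] == pop, "fixed_level"].unique())
            for lv in levels[1:]:
                cols.append(mask * (ph["fixed_level"] == lv).to_numpy(dtype=float))
                names.append(f"{pop}:{lv}")
            cov = ph["covariate"].to_numpy(dtype=float) * mask
            if np.ptp(cov[mask.astype(bool)]) > 0:
                cols.append(cov)
                names.append(f"{pop}:covariate")
        x = np.column_stack(cols)
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the confounded columns via pivoted QR
            _, _, piv = sla.qr(x, mode="economic", pivoting=True)
            bad = [names[i] for i in piv[rank:]]
            raise ValueError(f"singular fixed-effect design; confounded: {bad}")
        return x, names

    # -- parameters ---------------------------------------------------------
    def _param_list(self) -> list[_Param]:
        params = []
        for ci, comp in enumerate(self.spec.components):
            for (i, j) in comp.free_cov:
                params.append(_Param("gcov", comp=ci, i=i, j=j))
        if self.use_litter:
            for p in self.pops:
                params.append(_Param("litter", pop=p))
        for p in self.pops:
            params.append(_Param("resid", pop=p))
        return params

    def start_values(self) -> np.ndarray:
        theta = np.zeros(len(self.params))
        vy = {p: float(np.var(self.y[self.pop_rows[p]])) for p in self.pops}
        # how many components feed each population's trait slot
        feeds = {p: 0 for p in self.pops}
        for comp in self.spec.components:
            for p in comp.trait_of:
                if p in feeds:
                    feeds[p] += 1
        for k, prm in enumerate(self.params):
            if prm.kind == "resid":
                theta[k] = 0.45 * vy[prm.pop]
            elif prm.kind == "litter":
                theta[k] = 0.15 * vy[prm.pop]
            else:
                comp = self.spec.components[prm.comp]
                share = {}
                for p, t in comp.trait_of.items():
                    if p in vy:
                        share[t] = 0.4 * vy[p] / max(feeds[p], 1)
                if prm.i == prm.j:
                    theta[k] = share.get(prm.i, np.mean(list(share.values()) or [1.0]))
                else:
                    vi = share.get(prm.i, np.mean(list(share.values()) or [1.0]))
                    vj = share.get(prm.j, np.mean(list(share.values()) or [1.0]))
                    theta[k] = 0.5 * math.sqrt(vi * vj)
        return theta

    # -- covariance assembly -------------------------------------------------
    def comp_cov(self, theta: np.ndarray, ci: int) -> np.ndarray:
        comp = self.spec.components[ci]
        c = np.zeros((comp.trait_dim, comp.trait_dim))
        for k, prm in enumerate(self.params):
            if prm.kind == "gcov" and prm.comp == ci:
                c[prm.i, prm.j] = theta[k]
                c[prm.j, prm.i] = theta[k]
        return c

    def build_v(self, theta: np.ndarray) -> np.ndarray:
        v = np.zeros((self.n, self.n))
        for k, prm in enumerate(self.params):
            t = theta[k]
            if t == 0.0:
                continue
            if prm.kind == "gcov":
                rows, kidx = self.comp_rows[prm.comp], self.comp_kidx[prm.comp]
                comp = self.spec.components[prm.comp]
                if prm.i in rows and prm.j in rows:
                    blk = comp.K[np.ix_(kidx[prm.i], kidx[prm.j])]
                    v[np.ix_(rows[prm.i], rows[prm.j])] += t * blk
                    if prm.i != prm.j:
                        v[np.ix_(rows[prm.j], rows[prm.i])] += t * blk.T
            elif prm.kind == "litter":
                r = self.pop_rows[prm.pop]
                v[np.ix_(r, r)] += t * self.litter_same[prm.pop]
            else:
                r = self.pop_rows[prm.pop]
                v[r, r] += t
        return v

    # -- REML pieces ----------------------------------------------------------
    def _projection(self, theta: np.ndarray):
        v = self.build_v(theta)
        try:
            cf = sla.cho_factor(v, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        vi = sla.cho_solve(cf, np.eye(self.n), check_finite=False)
        vix = vi @ self.X
        xtvix = self.X.T @ vix
        try:
            cfx = sla.cho_factor(xtvix, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet_x = 2.0 * np.log(np.diag(cfx[0])).sum()
        beta = sla.cho_solve(cfx, vix.T @ self.y, check_finite=False)
        p = vi - vix @ sla.cho_solve(cfx, vix.T, check_finite=False)
        py = p @ self.y
        ll = -0.5 * (logdet_v + logdet_x + float(self.y @ py))
        return {"P": p, "Py": py, "ll": ll, "beta": beta, "Vi": vi}

    def loglik(self, theta: np.ndarray) -> float:
        st = self._projection(theta)
        return -np.inf if st is None else st["ll"]

    def _param_stats(self, theta, st):
        """Per parameter: <P,B_k>, y'P B_k P y, and t_k = B_k (Py)."""
        p, v = st["P"], st["Py"]
        trs = np.zeros(len(self.params))
        quads = np.zeros(len(self.params))
        tmat = np.zeros((self.n, len(self.params)))
        for k, prm in enumerate(self.params):
            if prm.kind == "gcov":
                rows, kidx = self.comp_rows[prm.comp], self.comp_kidx[prm.comp]
                comp = self.spec.components[prm.comp]
                i, j = prm.i, prm.j
                if i not in rows or j not in rows:
                    continue
                kij = comp.K[np.ix_(kidx[i], kidx[j])]
                pij = p[np.ix_(rows[i], rows[j])]
                vi, vj = v[rows[i]], v[rows[j]]
                if i == j:
                    trs[k] = float(np.sum(pij * kij))
                    quads[k] = float(vi @ kij @ vi)
                    tmat[rows[i], k] += kij @ vi
                else:
                    trs[k] = 2.0 * float(np.sum(pij * kij))
                    quads[k] = 2.0 * float(vi @ kij @ vj)
                    tmat[rows[i], k] += kij @ vj
                    tmat[rows[j], k] += kij.T @ vi
            elif prm.kind == "litter":
                r = self.pop_rows[prm.pop]
                same = self.litter_same[prm.pop]
                pr = p[np.ix_(r, r)]
                trs[k] = float(np.sum(pr * same))
                sv = same @ v[r]
                quads[k] = float(v[r] @ sv)
                tmat[r, k] = sv
            else:
                r = self.pop_rows[prm.pop]
                trs[k] = float(np.trace(p[np.ix_(r, r)]))
                quads[k] = float(v[r] @ v[r])
                tmat[r, k] = v[r]
        return trs, quads, tmat

    def _em_step(self, theta, st, trs, quads):
        """Monotone EM-REML update of all parameters."""
        new = theta.copy()
        for ci, comp in enumerate(self.spec.components):
            c = self.comp_cov(theta, ci)
            t = comp.trait_dim
            f = np.zeros((t, t))
            rows, kidx = self.comp_rows[ci], self.comp_kidx[ci]
            p, v = st["P"], st["Py"]
            for a in rows:
                for b in rows:
                    kab = comp.K[np.ix_(kidx[a], kidx[b])]
                    f[a, b] = float(v[rows[a]] @ kab @ v[rows[b]]) - float(
                        np.sum(p[np.ix_(rows[a], rows[b])] * kab)
                    )
            nk = comp.K.shape[0]
            c_new = c + c @ f @ c / nk
            c_new = _bend(0.5 * (c_new + c_new.T))
            for k, prm in enumerate(self.params):
                if prm.kind == "gcov" and prm.comp == ci:
                    new[k] = c_new[prm.i, prm.j]
        for k, prm in enumerate(self.params):
            if prm.kind == "litter":
                q = self.n_litters[prm.pop]
                new[k] = theta[k] + theta[k] ** 2 / q * (quads[k] - trs[k])
            elif prm.kind == "resid":
                q = len(self.pop_rows[prm.pop])
                new[k] = theta[k] + theta[k] ** 2 / q * (quads[k] - trs[k])
        return self._project(new)

    def _project(self, theta: np.ndarray) -> np.ndarray:
        """Pull parameters back into the admissible region."""
        new = theta.copy()
        vy = {p: float(np.var(self.y[self.pop_rows[p]])) for p in self.pops}
        for ci, comp in enumerate(self.spec.components):
            c = np.zeros((comp.trait_dim, comp.trait_dim))
            for k, prm in enumerate(self.params):
                if prm.kind == "gcov" and prm.comp == ci:
                    c[prm.i, prm.j] = new[k]
                    c[prm.j, prm.i] = new[k]
            c = _bend(c)
            for k, prm in enumerate(self.params):
                if prm.kind == "gcov" and prm.comp == ci:
                    new[k] = c[prm.i, prm.j]
        for k, prm in enumerate(self.params):
            if prm.kind == "litter":
                new[k] = max(new[k], 1e-8 * vy[prm.pop])
            elif prm.kind == "resid":
                new[k] = max(new[k], 1e-6 * vy[prm.pop])
        return new

    # -- main REML loop --------------------------------------------------------
    def reml(self, init: np.ndarray | None = None, tol: float = 1e-8,
             max_iter: int = 100, n_em_start: int = 3, verbose: bool = False):
        theta = self._project(self.start_values() if init is None else np.asarray(init))
        st = self._projection(theta)
        if st is None:
            raise ValueError("initial covariance matrix not positive definite")
        ll = st["ll"]
        lam = 1e-4
        converged = False
        small_dll = 0
        it = 0
        self.trace_ = [ll]
        for it in range(1, max_iter + 1):
            trs, quads, tmat = self._param_stats(theta, st)
            improved = False
            theta_new = st_new = None
            if it > n_em_start:
                score = 0.5 * (quads - trs)
                ai = 0.5 * (tmat.T @ st["P"] @ tmat)
                for _ in range(8):
                    try:
                        a = ai + lam * np.diag(np.maximum(np.diag(ai), 1e-12))
                        delta = np.linalg.solve(a, score)
                    except np.linalg.LinAlgError:
                        lam *= 10.0
                        continue
                    cand = self._project(theta + delta)
                    st_c = self._projection(cand)
                    if st_c is not None and st_c["ll"] >= ll - 1e-10:
                        theta_new, st_new, improved = cand, st_c, True
                        lam = max(lam / 10.0, 1e-10)
                        break
                    lam *= 10.0
            if not improved:
                cand = self._em_step(theta, st, trs, quads)
                st_c = self._projection(cand)
                if st_c is not None and st_c["ll"] >= ll - 1e-10:
                    theta_new, st_new = cand, st_c
                else:
                    # shrink the EM step toward the current point
                    ok = False
                    for frac in (0.5, 0.25, 0.1):
                        cand2 = self._project(theta + frac * (cand - theta))
                        st_c2 = self._projection(cand2)
                        if st_c2 is not None and st_c2["ll"] >= ll - 1e-10:
                            theta_new, st_new, ok = cand2, st_c2, True
                            break
                    if not ok:
                        converged = True
                        break
            dll = st_new["ll"] - ll
            dpar = np.max(np.abs(theta_new - theta) / (1.0 + np.abs(theta)))
            theta, st, ll = theta_new, st_new, st_new["ll"]
            self.trace_.append(ll)
            if verbose:
                print(f"iter {it}: loglik {ll:.6f} dll {dll:.2e} dpar {dpar:.2e}")
            if it > n_em_start and abs(dll) < tol * (1.0 + abs(ll)):
                small_dll += 1
                if dpar < 1e-6 or small_dll >= 3:
                    converged = True
                    break
            else:
                small_dll = 0
        return theta, st, ll, converged, it

    # -- predictions ------------------------------------------------------------
    def effects(self, theta: np.ndarray, st=None) -> dict:
        """BLUP of genetic effects for all animals of every component.

        Returns label -> DataFrame (rows K animals, columns trait slots).
        """
        if st is None:
            st = self._projection(theta)
        v = st["Py"]
        out = {}
        for ci, comp in enumerate(self.spec.components):
            c = self.comp_cov(theta, ci)
            rows, kidx = self.comp_rows[ci], self.comp_kidx[ci]
            w = {}
            for s in rows:
                w[s] = comp.K[:, kidx[s]] @ v[rows[s]]
            u = np.zeros((comp.K.shape[0], comp.trait_dim))
            for t in range(comp.trait_dim):
                for s, ws in w.items():
                    u[:, t] += c[t, s] * ws
            out[comp.label] = pd.DataFrame(u, index=comp.k_ids,
                                           columns=comp.trait_names)
        return out

    def to_fit_result(self, theta, st, ll, converged, iterations) -> FitResult:
        varcomps = {}
        for ci, comp in enumerate(self.spec.components):
            c = self.comp_cov(theta, ci)
            varcomps[comp.label] = pd.DataFrame(c, index=comp.trait_names,
                                                columns=comp.trait_names)
        litter = {p: theta[k] for k, prm in enumerate(self.params)
                  if prm.kind == "litter" for p in [prm.pop]}
        resid = {p: theta[k] for k, prm in enumerate(self.params)
                 if prm.kind == "resid" for p in [prm.pop]}
        fit = FitResult(
            model_kind=self.spec.model_kind, varcomps=varcomps,
            litter_var=litter, residual_var=resid, loglik=ll,
            converged=converged, iterations=iterations,
            gebv=self.effects(theta, st),
            fixed_effects=pd.Series(st["beta"], index=self.x_names),
        )
        return fit


def _bend(c: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Bend a symmetric matrix to the nearest PSD-ish matrix (eigenvalue floor)."""
    if c.size == 1:
        return np.maximum(c, floor_frac)
    w, q = np.linalg.eigh(0.5 * (c + c.T))
    floor = floor_frac * max(float(np.max(np.abs(w))), 1.0)
    if w.min() >= floor:
        return c
    w = np.maximum(w, floor)
    return q @ np.diag(w) @ q.T


# ---------------------------------------------------------------------------
# public operations


def build_mme(model: MixedModel, theta: np.ndarray):
    """Henderson mixed-model equations at fixed variance components.

    The genetic effect vector of each component spans *all* trait slots
    for *all* animals of its relationship matrix; slots without records
    (e.g. the artificial purebred-performance effect of crossbreds) get
    zero incidence columns. Returns (coefficient matrix, right-hand
    side, block description).
    """
    n = model.n
    r_inv = np.zeros(n)
    for k, prm in enumerate(model.params):
        if prm.kind == "resid":
            r_inv[model.pop_rows[prm.pop]] = 1.0 / theta[k]
    design = [("fixed", model.X, None)]
    if model.use_litter:
        cols = []
        d_inv = []
        for k, prm in enumerate(model.params):
            if prm.kind != "litter":
                continue
            r = model.pop_rows[prm.pop]
            codes = pd.factorize(model.ph.loc[r, "litter_id"])[0]
            z = np.zeros((n, codes.max() + 1))
            z[r, codes] = 1.0
            cols.append(z)
            d_inv.extend([1.0 / theta[k]] * (codes.max() + 1))
        design.append(("litter", np.hstack(cols), np.diag(d_inv)))
    for ci, comp in enumerate(model.spec.components):
        nk = comp.K.shape[0]
        t = comp.trait_dim
        z = np.zeros((n, t * nk))
        for s, rows in model.comp_rows[ci].items():
            z[rows, s * nk + model.comp_kidx[ci][s]] = 1.0
        c = model.comp_cov(theta, ci)
        g_inv = np.kron(np.linalg.inv(c), np.linalg.inv(comp.K))
        design.append((comp.label, z, g_inv))
    blocks = [z for _, z, _ in design]
    zfull = np.hstack(blocks)
    coeff = zfull.T @ (r_inv[:, None] * zfull)
    off = 0
    spans = {}
    for name, z, ginv in design:
        w = z.shape[1]
        if ginv is not None:
            coeff[off:off + w, off:off + w] += ginv
        spans[name] = (off, off + w)
        off += w
    rhs = zfull.T @ (r_inv * model.y)
    return coeff, rhs, spans


def reml_fit(spec: ModelSpec, phenotypes: pd.DataFrame,
             init: np.ndarray | None = None, tol: float = 1e-8,
             max_iter: int = 100, verbose: bool = False) -> FitResult:
    """Estimate all variance components by REML and return the fit."""
    model = MixedModel(phenotypes, spec)
    n_par = sum(c.trait_dim for c in spec.components)
    if model.n < n_par:
        raise ValueError("fewer records than genetic trait slots; not identifiable")
    theta, st, ll, converged, it = model.reml(init=init, tol=tol, max_iter=max_iter,
                                              verbose=verbose)
    fit = model.to_fit_result(theta, st, ll, converged, it)
    fit = derive_summaries(fit, spec)
    fit._model = model
    fit._theta = theta
    return fit


def crossbred_variance(cb_vars: dict, nonsel: float = 0.0) -> float:
    """Weighted crossbred additive variance 0.5*S + 0.25*LR + 0.25*LW (+ across)."""
    total = nonsel
    for b, v in cb_vars.items():
        total += CROSSBRED_WEIGHTS[b] * v
    return total


def crossbred_h2(cb_vars: dict, litter_cb: float, resid_cb: float,
                 nonsel: float = 0.0) -> float:
    va = crossbred_variance(cb_vars, nonsel)
    return va / (va + litter_cb + resid_cb)


def derive_summaries(fit: FitResult, spec: ModelSpec) -> FitResult:
    """Fill heritabilities and purebred-crossbred correlations; clamp r_pc.

    r_pc estimates above 1 are fixed to 0.99 and below 0 to 0 for
    downstream use; raw values are kept alongside and every clamp is
    logged.
    """
    fit.rpc_raw.clear()
    fit.rpc.clear()
    fit.clamp_log.clear()
    pb_var = {b: 0.0 for b in BREEDS}
    cb_breed = {}
    cb_across = 0.0
    for comp in spec.components:
        c = fit.varcomps[comp.label]
        if comp.breed is not None:
            b = comp.breed
            v_pb = float(c.iloc[0, 0])
            v_cb = float(c.iloc[1, 1])
            cov = float(c.iloc[0, 1])
            pb_var[b] += v_pb
            cb_breed[b] = cb_breed.get(b, 0.0) + v_cb
            key = (comp.label, b)
            fit.rpc_raw[key] = cov / math.sqrt(v_pb * v_cb) if v_pb > 0 and v_cb > 0 else float("nan")
        else:
            if "CB" not in c.index:
                continue  # custom component outside the four-trait layout
            v_cb = float(c.loc["CB", "CB"])
            cb_across += v_cb
            for b in BREEDS:
                if f"PB_{b}" not in c.index:
                    continue
                v_pb = float(c.loc[f"PB_{b}", f"PB_{b}"])
                pb_var[b] += v_pb
                cov = float(c.loc[f"PB_{b}", "CB"])
                key = (comp.label, b)
                fit.rpc_raw[key] = cov / math.sqrt(v_pb * v_cb) if v_pb > 0 and v_cb > 0 else float("nan")
    for key, r in fit.rpc_raw.items():
        if math.isnan(r):
            fit.rpc[key] = float("nan")
        elif r > 1.0:
            fit.rpc[key] = 0.99
            fit.clamp_log.append(f"r_pc {key} = {r:.3f} > 1 fixed to 0.99")
        elif r < 0.0:
            fit.rpc[key] = 0.0
            fit.clamp_log.append(f"r_pc {key} = {r:.3f} < 0 fixed to 0")
        else:
            fit.rpc[key] = r
    for b in BREEDS:
        denom = pb_var[b] + fit.litter_var.get(b, 0.0) + fit.residual_var.get(b, 0.0)
        fit.h2_pb[b] = pb_var[b] / denom if denom > 0 else float("nan")
    if CROSSBRED in fit.residual_var:
        litter_cb = fit.litter_var.get(CROSSBRED, 0.0)
        resid_cb = fit.residual_var[CROSSBRED]
        fit.h2_cb = crossbred_h2(cb_breed, litter_cb, resid_cb, nonsel=cb_across)
        if cb_breed and cb_across > 0:
            # SEL-BOA split: how the crossbred genetic variance and h2
            # divide between selected (breed-specific) and non-selected
            # (across-breed) SNP
            v_sel = crossbred_variance(cb_breed)
            denom = v_sel + cb_across + litter_cb + resid_cb
            fit.h2_cb_sel = v_sel / denom
            fit.h2_cb_nonsel = cb_across / denom
            fit.selected_share = {
                b: v / (v + cb_across) for b, v in cb_breed.items()
            }
    return fit


def predict_gebv(fit: FitResult, spec: ModelSpec, use_clamped: bool = True,
                 ) -> pd.DataFrame:
    """Purebred animals' GEBV for crossbred performance.

    Under BOA / SEL-BOA a purebred's crossbred GEBV is its crossbred-trait
    effect from its own breed component plus, under SEL-BOA, the
    across-breed crossbred-trait effect; under G it is the crossbred-trait
    effect of the across-breed component. When r_pc clamps were logged the
    effects are re-predicted at the clamped covariances.
    """
    model: MixedModel = fit._model
    theta = np.asarray(fit._theta, dtype=float).copy()
    if use_clamped and fit.clamp_log:
        for ci, comp in enumerate(spec.components):
            c = fit.varcomps[comp.label].to_numpy().copy()
            if comp.breed is not None:
                pairs = [((comp.label, comp.breed), 0, 1)]
            else:
                pairs = [((comp.label, b), comp.trait_names.index(f"PB_{b}"),
                          comp.trait_names.index("CB")) for b in BREEDS]
            for key, i, j in pairs:
                r = fit.rpc.get(key)
                raw = fit.rpc_raw.get(key)
                if r is None or raw is None or math.isnan(r) or r == raw:
                    continue
                c[i, j] = c[j, i] = r * math.sqrt(c[i, i] * c[j, j])
            for k, prm in enumerate(model.params):
                if prm.kind == "gcov" and prm.comp == ci:
                    theta[k] = c[prm.i, prm.j]
    effects = model.effects(theta)
    total = pd.Series(dtype=float)
    for comp in spec.components:
        u = effects[comp.label]["CB"]
        part = u.iloc[: comp.n_purebred]
        total = total.add(part, fill_value=0.0)
    total.name = "gebv_cb"
    return total.sort_index().to_frame()
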