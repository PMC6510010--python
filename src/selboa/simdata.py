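"""Forward simulator of a three-way terminal crossbreeding system.

Generates three divergent purebred lines — a sire line ``S`` and two
maternal lines ``LR`` and ``LW`` — plus reciprocal F1 dams and a
commercial crossbred population S × (LR × LW), with truth-tracked
breed-of-origin of every crossbred allele, true breeding values for
purebred and crossbred performance, and phenotypes with farm/sex-like
fixed effects, common-litter effects and residuals.

Founder divergence uses the Balding–Nichols construction: a common
ancestral allele frequency per locus and per-breed frequencies drawn
from a beta distribution whose drift parameter is calibrated in closed
form to the requested pairwise Weir–Cockerham F_ST values. Recombination
is modelled with a uniform genetic map of 1 Morgan per chromosome and a
Poisson(1) crossover count per meiosis and chromosome.

True purebred–crossbred genetic correlations are controlled per breed:
QTL allele-substitution effects for purebred and crossbred performance
are drawn jointly with the requested correlation. A configurable
fraction of QTL carries a crossbred-performance effect common to all
breeds of origin; an optional class of major QTL concentrates a chosen
fraction of the crossbred genetic variance in few loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from selboa.containers import (
    BREEDS,
    CROSSBRED,
    MATERNAL,
    PATERNAL,
    ConfigError,
    OriginAssignment,
    PhasedGenotypes,
)

__all__ = [
    "SimConfig",
    "SimData",
    "TruthTables",
    "simulate",
    "simulate_founders",
    "simulate_cross",
    "simulate_phenotypes",
    "weir_cockerham_fst",
]


def _default_fst() -> dict[frozenset, float]:
    return {
        frozenset(("S", "LR")): 0.17,
        frozenset(("S", "LW")): 0.12,
        frozenset(("LW", "LR")): 0.14,
    }


def _default_rpc() -> dict[str, float]:
    return {"S": 0.7, "LR": 0.3, "LW": 1.0}


def _default_h2_pb() -> dict[str, float]:
    return {"S": 0.17, "LR": 0.23, "LW": 0.22}


@dataclass
class SimConfig:
    """Configuration of one simulated crossbreeding study.

    Defaults emulate the statistical structure of a commercial pig
    three-way cross genotyped on a medium-density panel: pairwise
    F_ST 0.12–0.17 between lines, purebred heritabilities 0.17–0.23,
    crossbred heritability 0.30, and a common-litter effect absorbing
    ~18% of the crossbred phenotypic variance.
    """

    n_snp: int = 2000
    n_qtl: int = 400
    n_chrom: int = 10
    founders_per_breed: int = 300
    generations_purebred: int = 4
    n_sires_S: int = 50
    n_dams_LR: int = 150
    n_dams_LW: int = 150
    n_f1_dams: int = 100
    n_crossbred: int = 1000
    fst_target: dict = field(default_factory=_default_fst)
    qtl_effect_corr_pb_cb: dict = field(default_factory=_default_rpc)
    shared_qtl_fraction: float = 0.3
    n_major_qtl: int = 20
    major_qtl_var_fraction: float = 0.4
    major_qtl_corr_pb_cb: dict | None = None
    h2_pb: dict = field(default_factory=_default_h2_pb)
    h2_cb: float = 0.30
    litter_var_fraction: float = 0.18
    pb_litter_size: int = 5
    cb_litter_size: int = 5
    cb_genetic_variance: float = 2300.0
    trait_mean: float = 800.0
    n_fixed_levels: int = 4
    maf_floor: float = 0.05
    reciprocal_f1: bool = True
    seed: int = 2019

    def validate(self) -> None:
        counts = [
            self.n_snp, self.n_qtl, self.n_chrom, self.founders_per_breed,
            self.generations_purebred, self.n_sires_S, self.n_dams_LR,
            self.n_dams_LW, self.n_f1_dams, self.n_crossbred,
            self.pb_litter_size, self.cb_litter_size,
        ]
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        if self.n_qtl > self.n_snp:
            raise ConfigError("n_qtl must not exceed n_snp")
        if self.n_major_qtl > self.n_qtl:
            raise ConfigError("n_major_qtl must not exceed n_qtl")
        for frac in (self.shared_qtl_fraction, self.major_qtl_var_fraction,
                     self.h2_cb, self.litter_var_fraction, self.maf_floor):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        for pair, f in self.fst_target.items():
            if not 0.0 <= f < 0.5:
                raise ConfigError(f"F_ST target {f} for {set(pair)} unreachable (need < 0.5)")
        for b in BREEDS:
            if not -1.0 <= self.qtl_effect_corr_pb_cb[b] <= 1.0:
                raise ConfigError("QTL effect correlations must lie in [-1, 1]")
            if not 0.0 < self.h2_pb[b] <= 1.0:
                raise ConfigError("purebred h2 must lie in (0, 1]")
            if self.h2_pb[b] + self.litter_var_fraction > 1.0:
                raise ConfigError("h2 + litter fraction must not exceed 1")
        if not 0.0 < self.h2_cb <= 1.0:
            raise ConfigError("crossbred h2 must lie in (0, 1]")
        if self.h2_cb + self.litter_var_fraction > 1.0:
            raise ConfigError("h2 + litter fraction must not exceed 1")

    def drift_coefficients(self) -> dict[str, float]:
        """Per-breed Balding–Nichols drift parameters from pairwise F_ST.

        With independent drift per breed, the expected pairwise F_ST is
        approximately the mean of the two drift coefficients, giving the
        closed-form solve c_A = f_AB + f_AC - f_BC.
        """
        f = {pair: self.fst_target[pair] for pair in self.fst_target}

        def pairf(a, b):
            return f[frozenset((a, b))]

        c = {}
        for i, b in enumerate(BREEDS):
            others = [x for x in BREEDS if x != b]
            c[b] = pairf(b, others[0]) + pairf(b, others[1]) - pairf(others[0], others[1])
        for b, cb in c.items():
            if cb < 0.0 or cb >= 1.0:
                raise ConfigError(f"F_ST targets imply invalid drift {cb:.3f} for breed {b}")
        return c


@dataclass
class TruthTables:
    """Ground truth carried alongside the simulated data."""

    true_origin: OriginAssignment
    true_bv_pb: dict            # breed -> pd.Series over phenotyped purebreds
    true_bv_cb_purebred: dict   # breed -> pd.Series: purebred animals' merit for the crossbred trait
    true_bv_cb_by_origin: pd.DataFrame  # crossbred x (S, LR, LW, total)
    qtl_index: np.ndarray
    qtl_is_major: np.ndarray
    beta_pb: np.ndarray         # (3 breeds, n_qtl)
    beta_cb: np.ndarray         # (3 breeds, n_qtl)


@dataclass
class SimData:
    config: SimConfig
    purebreds: dict             # breed -> PhasedGenotypes (phenotyped generation)
    f1: PhasedGenotypes
    crossbreds: PhasedGenotypes
    pedigree: pd.DataFrame      # animal, sire, dam, population, sex, generation
    founder_freqs: pd.DataFrame
    truth: TruthTables
    phenotypes: pd.DataFrame | None = None

    def pooled_genotypes(self) -> PhasedGenotypes:
        """Phenotyped purebreds of all breeds plus crossbreds, stacked."""
        return PhasedGenotypes.concat(
            [self.purebreds[b] for b in BREEDS] + [self.crossbreds]
        )

    def population_of(self) -> dict:
        out = {}
        for b in BREEDS:
            for a in self.purebreds[b].animal_ids:
                out[a] = b
        for a in self.crossbreds.animal_ids:
            out[a] = CROSSBRED
        return out


# ---------------------------------------------------------------------------
# genetic map and meiosis


def _marker_map(n_snp: int, n_chrom: int) -> pd.DataFrame:
    per = np.full(n_chrom, n_snp // n_chrom)
    per[: n_snp % n_chrom] += 1
    rows = []
    for c in range(n_chrom):
        for i in range(per[c]):
            rows.append((c + 1, (i + 1) * 1000, f"snp{c + 1}_{i + 1}"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "snp_id"])


def _chrom_slices(marker_map: pd.DataFrame) -> list[slice]:
    slices = []
    start = 0
    for _, grp in marker_map.groupby("chrom", sort=False):
        slices.append(slice(start, start + len(grp)))
        start += len(grp)
    return slices


def _genetic_positions(marker_map: pd.DataFrame) -> list[np.ndarray]:
    """Per-chromosome genetic positions in Morgan, uniform 1 M/chromosome."""
    out = []
    for _, grp in marker_map.groupby("chrom", sort=False):
        m = len(grp)
        out.append((np.arange(m) + 0.5) / m)
    return out


def _meiosis(haps: np.ndarray, gpos: list[np.ndarray], slices: list[slice],
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's two haplotypes.

    Returns (gamete alleles, source haplotype index per locus); the source
    track is what propagates breed of origin through the cross.
    """
    m = haps.shape[1]
    source = np.empty(m, dtype=np.int8)
    for sl, pos in zip(slices, gpos):
        k = rng.poisson(1.0)
        cur = int(rng.integers(2))
        if k == 0:
            source[sl] = cur
            continue
        cuts = np.sort(rng.uniform(0.0, 1.0, size=k))
        seg = cur + np.searchsorted(cuts, pos)
        source[sl] = seg % 2
    gamete = haps[source, np.arange(m)]
    return gamete, source


# ---------------------------------------------------------------------------
# founders and purebred drift


# Per-generation drift of the litter mating design, expressed as a multiple
# of the ideal-population rate 1/(2N). Fitted once against pure-drift runs
# (F_ST targets zero) of the default scheme: sires drawn per litter with
# replacement, dams without, litter size ~5. Scales ~1/N for nearby configs.
_LITTER_SCHEME_DRIFT_FACTOR = 2.18


def _expected_drift(cfg: SimConfig) -> float:
    """Differentiation added after the founder frequency draw.

    Founder sampling contributes 1/(2N); each pedigreed generation adds
    drift at the litter-scheme rate. The Balding–Nichols calibration is
    discounted by this amount so realized F_ST hits the target after
    drift.
    """
    n = cfg.founders_per_breed
    per_gen = _LITTER_SCHEME_DRIFT_FACTOR / (2.0 * n)
    return 1.0 - (1.0 - 1.0 / (2.0 * n)) * (1.0 - per_gen) ** cfg.generations_purebred


def _draw_breed_frequencies(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    drift = _expected_drift(cfg)
    adj = SimConfig.__new__(SimConfig)
    adj.__dict__.update(cfg.__dict__)
    adj.fst_target = {
        pair: max((f - drift) / (1.0 - drift), 0.0)
        for pair, f in cfg.fst_target.items()
    }
    c = adj.drift_coefficients()
    m = cfg.n_snp
    anc = rng.uniform(0.1, 0.9, size=m)
    freqs = {}
    for b in BREEDS:
        cb = c[b]
        if cb <= 0.0:
            freqs[b] = anc.copy()
        else:
            a = anc * (1.0 - cb) / cb
            bb = (1.0 - anc) * (1.0 - cb) / cb
            freqs[b] = rng.beta(a, bb)
    # ensure every SNP is informative (MAF floor) in at least one breed
    stacked = np.vstack([freqs[b] for b in BREEDS])
    for _ in range(50):
        maf = np.minimum(stacked, 1.0 - stacked)
        bad = maf.max(axis=0) < cfg.maf_floor
        if not bad.any():
            break
        for i, b in enumerate(BREEDS):
            cb = c[b]
            if cb <= 0.0:
                stacked[i, bad] = np.clip(anc[bad], cfg.maf_floor, 1 - cfg.maf_floor)
            else:
                a = anc[bad] * (1.0 - cb) / cb
                bb = (1.0 - anc[bad]) * (1.0 - cb) / cb
                stacked[i, bad] = rng.beta(a, bb)
    else:
        stacked = np.clip(stacked, cfg.maf_floor, 1.0 - cfg.maf_floor)
    out = pd.DataFrame({"ancestral": anc})
    for i, b in enumerate(BREEDS):
        out[f"p_{b}"] = stacked[i]
    return out


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate the three purebred populations.

    Founder haplotypes are sampled at linkage equilibrium from
    Balding–Nichols breed frequencies calibrated to the pairwise F_ST
    targets, then ``generations_purebred`` rounds of pedigreed random
    mating (with recombination) are applied at constant census size.

    Returns ``(populations, founder_freqs, pedigree)`` where
    ``populations`` maps breed -> PhasedGenotypes of the final
    generation (the phenotyped animals).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mmap = _marker_map(config.n_snp, config.n_chrom)
    slices = _chrom_slices(mmap)
    gpos = _genetic_positions(mmap)
    freq_df = _draw_breed_frequencies(config, rng)

    n = config.founders_per_breed
    ped_rows = []
    pops = {}
    for b in BREEDS:
        p = freq_df[f"p_{b}"].to_numpy()
        haps = (rng.uniform(size=(n, 2, config.n_snp)) < p).astype(np.uint8)
        ids = [f"{b}.g0.{i + 1}" for i in range(n)]
        sexes = np.array(["M", "F"])[np.arange(n) % 2]
        for a, s in zip(ids, sexes):
            ped_rows.append((a, "0", "0", b, s, 0))
        for gen in range(1, config.generations_purebred + 1):
            males = [i for i in range(n) if sexes[i] == "M"]
            females = [i for i in range(n) if sexes[i] == "F"]
            n_litters = math.ceil(n / config.pb_litter_size)
            litter_sires = rng.choice(males, size=n_litters, replace=True)
            litter_dams = rng.choice(females, size=n_litters,
                                     replace=n_litters > len(females))
            new_haps = np.empty_like(haps)
            new_ids = []
            new_sexes = np.array(["M", "F"])[rng.integers(2, size=n)]
            for i in range(n):
                lit = i % n_litters
                si, di = litter_sires[lit], litter_dams[lit]
                pat, _ = _meiosis(haps[si], gpos, slices, rng)
                mat, _ = _meiosis(haps[di], gpos, slices, rng)
                new_haps[i, PATERNAL] = pat
                new_haps[i, MATERNAL] = mat
                aid = f"{b}.g{gen}.{i + 1}"
                new_ids.append(aid)
                ped_rows.append((aid, ids[si], ids[di], b, new_sexes[i], gen))
            haps, ids, sexes = new_haps, new_ids, new_sexes
        pops[b] = PhasedGenotypes(animal_ids=list(ids), marker_map=mmap, haplotypes=haps)
    pedigree = pd.DataFrame(
        ped_rows, columns=["animal", "sire", "dam", "population", "sex", "generation"]
    )
    return pops, freq_df, pedigree


# ---------------------------------------------------------------------------
# the three-way cross


def simulate_cross(purebreds: dict, config: SimConfig,
                   rng: np.random.Generator | None = None,
                   pedigree: pd.DataFrame | None = None):
    """Mate S sires to (reciprocal) F1 LR×LW dams.

    Returns ``(f1, crossbreds, pedigree, true_origin, cb_litters)``.
    Every crossbred allele carries its true breed of origin, propagated
    through recombination: the paternal gamete is always of origin S,
    the maternal gamete is a recombinant mosaic of LR and LW segments.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    for b in BREEDS:
        if purebreds[b].n_animals == 0:
            raise ConfigError(f"purebred population {b} is empty")
    mmap = purebreds["S"].marker_map
    slices = _chrom_slices(mmap)
    gpos = _genetic_positions(mmap)
    m = len(mmap)
    ped_rows = [] if pedigree is None else []
    gen_cross = 1 + (0 if pedigree is None else int(pedigree["generation"].max()))

    def _sex_of(pop: PhasedGenotypes, ped: pd.DataFrame | None):
        if ped is None:
            return {a: ("M" if i % 2 == 0 else "F") for i, a in enumerate(pop.animal_ids)}
        sub = ped.set_index("animal")["sex"]
        return {a: sub.get(a, "M" if i % 2 == 0 else "F")
                for i, a in enumerate(pop.animal_ids)}

    # --- F1 dams -----------------------------------------------------------
    lr, lw = purebreds["LR"], purebreds["LW"]
    lr_sex = _sex_of(lr, pedigree)
    lw_sex = _sex_of(lw, pedigree)
    lr_m = [i for i, a in enumerate(lr.animal_ids) if lr_sex[a] == "M"]
    lr_f = [i for i, a in enumerate(lr.animal_ids) if lr_sex[a] == "F"][: config.n_dams_LR]
    lw_m = [i for i, a in enumerate(lw.animal_ids) if lw_sex[a] == "M"]
    lw_f = [i for i, a in enumerate(lw.animal_ids) if lw_sex[a] == "F"][: config.n_dams_LW]
    if not lr_m or not lw_f or (config.reciprocal_f1 and (not lw_m or not lr_f)):
        raise ConfigError("insufficient parents for F1 matings")

    nf1 = config.n_f1_dams
    f1_haps = np.empty((nf1, 2, m), dtype=np.uint8)
    f1_ids = []
    f1_hap_origin = np.empty((nf1, 2), dtype=np.int8)  # breed code of each whole haplotype
    code = {b: i for i, b in enumerate(BREEDS)}
    for i in range(nf1):
        recip = config.reciprocal_f1 and i % 2 == 1  # LW sire x LR dam
        if recip:
            si = lw.animal_ids[int(rng.choice(lw_m))]
            di = lr.animal_ids[int(rng.choice(lr_f))]
            sire_pop, dam_pop = lw, lr
            pat_o, mat_o = code["LW"], code["LR"]
        else:
            si = lr.animal_ids[int(rng.choice(lr_m))]
            di = lw.animal_ids[int(rng.choice(lw_f))]
            sire_pop, dam_pop = lr, lw
            pat_o, mat_o = code["LR"], code["LW"]
        pat, _ = _meiosis(sire_pop.haplotypes[sire_pop.animal_ids.index(si)], gpos, slices, rng)
        mat, _ = _meiosis(dam_pop.haplotypes[dam_pop.animal_ids.index(di)], gpos, slices, rng)
        f1_haps[i, PATERNAL], f1_haps[i, MATERNAL] = pat, mat
        f1_hap_origin[i] = (pat_o, mat_o)
        aid = f"F1.{i + 1}"
        f1_ids.append(aid)
        ped_rows.append((aid, si, di, "F1", "F", gen_cross))
    f1 = PhasedGenotypes(animal_ids=f1_ids, marker_map=mmap, haplotypes=f1_haps)

    # --- commercial crossbreds --------------------------------------------
    s_pop = purebreds["S"]
    s_sex = _sex_of(s_pop, pedigree)
    s_males = [i for i, a in enumerate(s_pop.animal_ids) if s_sex[a] == "M"]
    if not s_males:
        raise ConfigError("no S sires available")
    sires = rng.choice(s_males, size=min(config.n_sires_S, len(s_males)), replace=False)

    ncb = config.n_crossbred
    n_litters = math.ceil(ncb / config.cb_litter_size)
    litter_sires = rng.choice(sires, size=n_litters, replace=True)
    litter_dams = rng.choice(nf1, size=n_litters, replace=n_litters > nf1)
    cb_haps = np.empty((ncb, 2, m), dtype=np.uint8)
    cb_origin = np.empty((ncb, 2, m), dtype=np.int8)
    cb_ids = []
    cb_litters = np.empty(ncb, dtype=object)
    for i in range(ncb):
        lit = i % n_litters
        si, di = int(litter_sires[lit]), int(litter_dams[lit])
        pat, _ = _meiosis(s_pop.haplotypes[si], gpos, slices, rng)
        mat, src = _meiosis(f1_haps[di], gpos, slices, rng)
        cb_haps[i, PATERNAL], cb_haps[i, MATERNAL] = pat, mat
        cb_origin[i, PATERNAL] = code["S"]
        cb_origin[i, MATERNAL] = f1_hap_origin[di][src]
        aid = f"CB.{i + 1}"
        cb_ids.append(aid)
        cb_litters[i] = f"CBlit.{lit + 1}"
        ped_rows.append((aid, s_pop.animal_ids[si], f1_ids[di], CROSSBRED, "U", gen_cross + 1))
    crossbreds = PhasedGenotypes(animal_ids=cb_ids, marker_map=mmap, haplotypes=cb_haps)
    true_origin = OriginAssignment(
        animal_ids=cb_ids, snp_ids=mmap["snp_id"].to_numpy(), labels=cb_origin
    )
    cross_ped = pd.DataFrame(
        ped_rows, columns=["animal", "sire", "dam", "population", "sex", "generation"]
    )
    full_ped = cross_ped if pedigree is None else pd.concat(
        [pedigree, cross_ped], ignore_index=True
    )
    return f1, crossbreds, full_ped, true_origin, pd.Series(cb_litters, index=cb_ids)


# ---------------------------------------------------------------------------
# QTL effects, breeding values, phenotypes


def _draw_qtl_effects(cfg: SimConfig, rng: np.random.Generator):
    nq = cfg.n_qtl
    perm = rng.permutation(cfg.n_snp)[:nq]
    qtl_index = np.sort(perm)
    is_major = np.zeros(nq, dtype=bool)
    if cfg.n_major_qtl > 0:
        is_major[rng.choice(nq, size=cfg.n_major_qtl, replace=False)] = True
    # major QTL are always breed-specific: large-effect regions are exactly
    # where effects differ by parental breed; sharing applies to the
    # polygenic background only
    shared = (rng.uniform(size=nq) < cfg.shared_qtl_fraction) & ~is_major

    # variance concentration: major QTL carry major_qtl_var_fraction of the
    # crossbred genetic variance in expectation
    n_major = int(is_major.sum())
    scale = np.ones(nq)
    if 0 < n_major < nq and cfg.major_qtl_var_fraction > 0:
        frac = cfg.major_qtl_var_fraction
        s2 = frac / (1.0 - frac) * (nq - n_major) / n_major
        scale[is_major] = math.sqrt(s2)

    major_corr = cfg.major_qtl_corr_pb_cb or cfg.qtl_effect_corr_pb_cb
    beta_pb = np.empty((len(BREEDS), nq))
    beta_cb = np.empty((len(BREEDS), nq))
    cb_shared = rng.normal(size=nq)
    for bi, b in enumerate(BREEDS):
        rho = np.where(is_major, major_corr[b], cfg.qtl_effect_corr_pb_cb[b])
        cb_own = rng.normal(size=nq)
        cb = np.where(shared, cb_shared, cb_own)
        eps = rng.normal(size=nq)
        pb = rho * cb + np.sqrt(np.clip(1.0 - rho**2, 0.0, None)) * eps
        beta_cb[bi] = cb * scale
        beta_pb[bi] = pb * scale
    return qtl_index, is_major, beta_pb, beta_cb


def _breeding_values(purebreds, crossbreds, true_origin, qtl_index, beta_pb, beta_cb):
    bv_pb, bv_cb_pure = {}, {}
    for bi, b in enumerate(BREEDS):
        d = purebreds[b].dosage()[:, qtl_index]
        bv_pb[b] = pd.Series(d @ beta_pb[bi], index=purebreds[b].animal_ids)
        bv_cb_pure[b] = pd.Series(d @ beta_cb[bi], index=purebreds[b].animal_ids)
    hap = crossbreds.haplotypes[:, :, qtl_index].astype(np.float64)
    orig = true_origin.labels[:, :, qtl_index]
    parts = {}
    for bi, b in enumerate(BREEDS):
        contrib = np.where(orig == bi, hap, 0.0)  # allele content of origin b
        parts[b] = (contrib.sum(axis=1)) @ beta_cb[bi]
    df = pd.DataFrame(parts, index=crossbreds.animal_ids)
    df["total"] = df[list(BREEDS)].sum(axis=1)
    return bv_pb, bv_cb_pure, df


def simulate_phenotypes(data: "SimData", rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Phenotypes for purebreds and crossbreds.

    y = population mean + fixed factor + covariate slope + litter + true
    breeding value + residual; litter and residual variances are scaled
    from the realized genetic variance so the heritabilities and the
    litter-variance fraction hold in expectation.
    """
    cfg = data.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    truth = data.truth
    ped = data.pedigree.set_index("animal")
    rows = []
    pops = [(b, data.purebreds[b]) for b in BREEDS] + [(CROSSBRED, data.crossbreds)]
    for pop_label, pop in pops:
        ids = pop.animal_ids
        if pop_label == CROSSBRED:
            g = truth.true_bv_cb_by_origin["total"].loc[ids].to_numpy()
            h2 = cfg.h2_cb
            litter_ids = data._cb_litters.loc[ids].to_numpy()
        else:
            g = truth.true_bv_pb[pop_label].loc[ids].to_numpy()
            h2 = cfg.h2_pb[pop_label]
            dams = ped.loc[ids, "dam"].to_numpy()
            sires = ped.loc[ids, "sire"].to_numpy()
            litter_ids = np.array([f"{pop_label}.{s}x{d}" for s, d in zip(sires, dams)])
        g = g - g.mean()
        vg = float(np.var(g))
        vp = vg / h2 if h2 > 0 else vg
        vu = cfg.litter_var_fraction * vp
        ve = max(vp - vg - vu, 0.0)
        uniq = pd.unique(litter_ids)
        litter_eff = dict(zip(uniq, rng.normal(0.0, math.sqrt(vu), size=len(uniq))))
        levels = rng.permutation(np.arange(len(ids)) % cfg.n_fixed_levels)
        level_eff = rng.normal(0.0, math.sqrt(0.3 * vp), size=cfg.n_fixed_levels)
        x = rng.normal(size=len(ids))
        slope = math.sqrt(0.05 * vp)
        e = rng.normal(0.0, math.sqrt(ve), size=len(ids))
        y = (cfg.trait_mean + level_eff[levels] + slope * x
             + np.array([litter_eff[l] for l in litter_ids]) + g + e)
        for i, a in enumerate(ids):
            rows.append((a, pop_label, y[i], f"lvl{levels[i] + 1}", x[i], litter_ids[i]))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "population", "trait_value", "fixed_level",
                 "covariate", "litter_id"],
    )


def simulate(config: SimConfig) -> SimData:
    """Run the full simulator; identical config+seed gives identical output."""
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0])
    r_found, r_cross, r_qtl, r_phen = [np.random.default_rng(s) for s in ss.spawn(4)]
    pops, freqs, ped = simulate_founders(config, rng=r_found)
    f1, cb, ped, true_origin, cb_litters = simulate_cross(pops, config, rng=r_cross,
                                                          pedigree=ped)
    qtl_index, is_major, beta_pb, beta_cb = _draw_qtl_effects(config, r_qtl)
    bv_pb, bv_cb_pure, bv_cb = _breeding_values(pops, cb, true_origin,
                                                qtl_index, beta_pb, beta_cb)
    # rescale effects so the crossbred genetic variance sits on the target scale
    v_raw = float(np.var(bv_cb["total"].to_numpy()))
    k = math.sqrt(config.cb_genetic_variance / v_raw) if v_raw > 0 else 1.0
    beta_pb, beta_cb = beta_pb * k, beta_cb * k
    for b in BREEDS:
        bv_pb[b] *= k
        bv_cb_pure[b] *= k
    bv_cb *= k
    truth = TruthTables(
        true_origin=true_origin,
        true_bv_pb=bv_pb,
        true_bv_cb_purebred=bv_cb_pure,
        true_bv_cb_by_origin=bv_cb,
        qtl_index=qtl_index,
        qtl_is_major=is_major,
        beta_pb=beta_pb,
        beta_cb=beta_cb,
    )
    data = SimData(
        config=config, purebreds=pops, f1=f1, crossbreds=cb, pedigree=ped,
        founder_freqs=freqs, truth=truth,
    )
    data._cb_litters = cb_litters
    data.phenotypes = simulate_phenotypes(data, rng=r_phen)
    return data


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST


def weir_cockerham_fst(pops: list[PhasedGenotypes]) -> float:
    """Multi-population Weir–Cockerham theta, ratio of averages over loci.

    Uses per-population allele frequencies and observed heterozygosity
    from the phased genotypes.
    """
    r = len(pops)
    n_i = np.array([p.n_animals for p in pops], dtype=float)
    p_i = np.vstack([p.dosage().mean(axis=0) / 2.0 for p in pops])
    h_i = np.vstack([(p.haplotypes[:, 0, :] != p.haplotypes[:, 1, :]).mean(axis=0)
                     for p in pops])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)
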