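"""End-to-end pipeline driver with content-hash caching.

Stage order: simulate -> assign-origin -> build-grm -> fit (G, BOA) ->
backsolve/select-snps -> fit (SEL-BOA per threshold) -> crossval. Each
stage writes its artifacts plus a manifest holding the configuration
hash and the content hashes of its outputs; a stage is skipped when the
manifest matches, and any corrupted or missing artifact triggers a
recompute. Every output directory carries the exact configuration and
seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from selboa import io as sio
from selboa.boa_assign import apply_filters, assign_origins, build_library
from selboa.containers import BREEDS, CROSSBRED, ConfigError
from selboa.evaluation import deregress, make_folds, pedigree_ebv, weighted_accuracy
from selboa.grm import partial_grm, read_grm_binary, vanraden_g, write_grm_binary
from selboa.mixedmodel import (
    build_model_spec,
    crossbred_variance,
    predict_gebv,
    reml_fit,
)
from selboa.simdata import SimConfig, simulate
from selboa.snp_targeting import (
    backsolve_effects,
    block_variance_explained,
    build_ld_blocks,
    origin_gametes,
    select_snps,
)

__all__ = ["RunConfig", "run_pipeline", "run_pipeline_until", "load_config"]

log = logging.getLogger("selboa")

_KNOWN_KEYS = {
    "sim", "models", "thresholds", "seed", "k_folds", "r2_threshold",
    "max_span", "reml_tol", "reml_max_iter", "core_lengths", "use_offset",
    "snp_rate", "animal_fraction", "min_allele_count",
}


@dataclasses.dataclass
class RunConfig:
    """Validated knobs of one pipeline run; serialized into every output dir."""

    sim: dict = dataclasses.field(default_factory=dict)
    models: list = dataclasses.field(default_factory=lambda: ["g", "boa", "selboa10"])
    thresholds: list = dataclasses.field(default_factory=lambda: [0.05, 0.10])
    seed: int = 2019
    k_folds: int = 4
    r2_threshold: float = 0.3
    max_span: int = 50
    reml_tol: float = 1e-8
    reml_max_iter: int = 100
    core_lengths: list | None = None
    use_offset: bool = True
    snp_rate: float = 0.9
    animal_fraction: float = 0.9
    min_allele_count: int = 5

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not 0 < cfg.k_folds <= 20:
            raise ConfigError("k_folds must be in 1..20")
        for t in cfg.thresholds:
            if not 0 <= t <= 1:
                raise ConfigError("thresholds must be fractions in [0, 1]")
        if not 0 <= cfg.r2_threshold <= 1:
            raise ConfigError("r2_threshold must be in [0, 1]")
        cfg.sim_config()  # validates the simulator block
        return cfg

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        if "fst_target" in sim:
            sim["fst_target"] = {frozenset(k.split("-")): v
                                 for k, v in sim["fst_target"].items()}
        cfg = SimConfig(**sim, seed=self.seed) if "seed" not in sim else SimConfig(**sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if "fst_target" in (d.get("sim") or {}):
            d["sim"]["fst_target"] = {"-".join(sorted(k)): v
                                      for k, v in d["sim"]["fst_target"].items()}
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Stage:
    """Manifest-based cache around one pipeline stage."""

    def __init__(self, outdir: Path, name: str, config_hash: str):
        self.dir = outdir / name
        self.name = name
        self.config_hash = config_hash
        self.manifest = self.dir / "MANIFEST.json"

    def is_hit(self) -> bool:
        if not self.manifest.exists():
            return False
        try:
            man = json.loads(self.manifest.read_text())
        except json.JSONDecodeError:
            return False
        if man.get("config_hash") != self.config_hash:
            return False
        for rel, digest in man.get("files", {}).items():
            f = self.dir / rel
            if not f.exists() or _hash_file(f) != digest:
                return False
        return True

    def seal(self) -> None:
        files = {
            f.name: _hash_file(f)
            for f in sorted(self.dir.iterdir())
            if f.is_file() and f.name != "MANIFEST.json"
        }
        self.manifest.write_text(json.dumps(
            {"config_hash": self.config_hash, "files": files}, indent=1))


class _PipelineDone(Exception):
    """Raised internally to stop after a requested stage."""


def run_pipeline_until(config: "RunConfig", outdir, stage: str) -> dict:
    """Run the pipeline only up to (and including) ``stage``."""
    try:
        return run_pipeline(config, outdir, until=stage)
    except _PipelineDone as done:
        return done.args[0]


def run_pipeline(config: RunConfig, outdir, until: str | None = None) -> dict:
    """Execute the stages in order; returns a summary dict.

    ``until`` names a stage after which execution stops (e.g.
    ``"targeting"``); earlier stages are cache-checked as usual. Raises
    on stage failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    summary: dict = {"stages": {}}
    ctx: dict = {}

    def stage(name, cfg_piece, compute, write, read):
        st = _Stage(outdir, name, _hash_obj([cfg_piece, config.seed]))
        if st.is_hit():
            log.info("stage %s: cache hit", name)
            read(st.dir)
            summary["stages"][name] = "cached"
            return
        log.info("stage %s: computing", name)
        st.dir.mkdir(parents=True, exist_ok=True)
        try:
            compute()
            write(st.dir)
        except Exception:
            log.error("stage %s failed", name)
            raise
        st.seal()
        summary["stages"][name] = "computed"

    def stage_and_check(name, cfg_piece, compute, write, read):
        stage(name, cfg_piece, compute, write, read)
        if until == name:
            raise _PipelineDone(summary)

    # ---- simulate ---------------------------------------------------------
    simcfg = config.sim_config()

    def sim_compute():
        ctx["data"] = simulate(simcfg)

    def sim_write(d: Path):
        data = ctx["data"]
        for b in BREEDS:
            sio.write_haplotype_tsv(data.purebreds[b], d / f"haps_{b}.tsv.gz")
        sio.write_haplotype_tsv(data.crossbreds, d / "haps_CB.tsv.gz")
        data.pedigree.to_csv(d / "pedigree.csv", index=False)
        data.phenotypes.to_csv(d / "phenotypes.csv", index=False)
        sio.write_origins_tsv(data.truth.true_origin, d / "true_origins.tsv.gz")
        data.crossbreds.marker_map.to_csv(d / "marker_map.csv", index=False)

    def sim_read(d: Path):
        ctx["data"] = simulate(simcfg)  # deterministic; cheaper than re-parsing

    simcfg_dict = dataclasses.asdict(simcfg)
    simcfg_dict["fst_target"] = {"-".join(sorted(k)): v
                                 for k, v in simcfg.fst_target.items()}
    stage_and_check("simulate", simcfg_dict, sim_compute, sim_write, sim_read)
    data = ctx["data"]

    # ---- assign origin ----------------------------------------------------
    boa_cfg = [config.core_lengths, config.use_offset, config.snp_rate,
               config.animal_fraction, config.min_allele_count]

    def boa_compute():
        specs = None
        if config.core_lengths:
            offs = (False, True) if config.use_offset else (False,)
            specs = [(c, o) for c in config.core_lengths for o in offs]
        lib = build_library(data.purebreds, window_specs=specs)
        asg = assign_origins(data.crossbreds, lib)
        filt, report = apply_filters(
            asg, data.purebreds, data.crossbreds,
            snp_rate=config.snp_rate, animal_fraction=config.animal_fraction,
            min_allele_count=config.min_allele_count)
        ctx["origins"], ctx["report"] = filt, report

    def boa_write(d: Path):
        sio.write_origins_tsv(ctx["origins"], d / "origins.tsv.gz")
        (d / "report.json").write_text(json.dumps(ctx["report"].to_dict(), indent=1))

    def boa_read(d: Path):
        ctx["origins"] = sio.read_origins_tsv(d / "origins.tsv.gz")

    stage_and_check("assign_origin", boa_cfg, boa_compute, boa_write, boa_read)
    origins = ctx["origins"]

    # restrict every population to the retained SNP / animals
    from selboa.boa_assign import restrict_to_assignment
    from selboa.containers import PhasedGenotypes
    pure, cross, phenos = restrict_to_assignment(
        origins, data.purebreds, data.crossbreds, data.phenotypes)
    pooled = PhasedGenotypes.concat([pure[b] for b in BREEDS] + [cross])

    # ---- GRMs -------------------------------------------------------------
    def grm_compute():
        ctx["G"] = vanraden_g(pooled)
        ctx["partials"] = {b: partial_grm(pure[b], cross, origins, b) for b in BREEDS}

    def grm_write(d: Path):
        write_grm_binary(ctx["G"], d / "G.bin")
        for b in BREEDS:
            write_grm_binary(ctx["partials"][b], d / f"partial_{b}.bin")

    def grm_read(d: Path):
        grm_compute()  # matrices are derived data; recompute in memory

    stage_and_check("build_grm", ["grm"], grm_compute, grm_write, grm_read)

    # ---- model fits -------------------------------------------------------
    fits: dict = {}

    def fit_model(tag, kind, selected=None):
        def compute():
            spec = build_model_spec(kind, pooled, pure, cross, origins,
                                    selected_index=selected)
            fit = reml_fit(spec, phenos, tol=config.reml_tol,
                           max_iter=config.reml_max_iter)
            gebv = predict_gebv(fit, spec)
            fits[tag] = (spec, fit, gebv)

        def write(d: Path):
            spec, fit, gebv = fits[tag]
            out = {
                "model": fit.model_kind, "loglik": fit.loglik,
                "converged": fit.converged, "iterations": fit.iterations,
                "h2_pb": fit.h2_pb, "h2_cb": fit.h2_cb,
                "rpc": {f"{k[0]}|{k[1]}": v for k, v in fit.rpc.items()},
                "rpc_raw": {f"{k[0]}|{k[1]}": v for k, v in fit.rpc_raw.items()},
                "clamp_log": fit.clamp_log,
                "litter_var": fit.litter_var, "residual_var": fit.residual_var,
                "varcomps": {k: v.to_dict() for k, v in fit.varcomps.items()},
            }
            (d / "fit.json").write_text(json.dumps(out, indent=1, default=float))
            gebv.to_csv(d / "gebv.csv")

        def read(d: Path):
            compute()

        stage_and_check(f"fit_{tag}", [tag, kind, None if selected is None else
                                       [int(i) for i in selected]],
                        compute, write, read)

    fit_model("g", "G")
    fit_model("boa", "BOA")

    # ---- targeting --------------------------------------------------------
    sel_cfg = [config.r2_threshold, config.max_span, config.thresholds]

    def target_compute():
        _, boa_fit, _ = fits["boa"]
        blocksets = {}
        effects = {}
        for b in BREEDS:
            pgm = ctx["partials"][b]
            u = boa_fit.gebv[f"{b}-all"]["CB"].iloc[: pgm.n_purebred]
            eff = backsolve_effects(u, pure[b], pgm)
            gam = origin_gametes(cross, origins, b)
            bs = build_ld_blocks(gam, pure[b].marker_map, b,
                                 r2_threshold=config.r2_threshold,
                                 max_span=config.max_span)
            sigma = float(boa_fit.varcomps[f"{b}-all"].loc["CB", "CB"])
            blocksets[b] = block_variance_explained(bs, eff, pure[b], sigma)
            effects[b] = eff
        ctx["blocksets"], ctx["effects"] = blocksets, effects
        ctx["selected"] = {t: select_snps(blocksets, t, pooled.n_snp)
                           for t in config.thresholds}

    def target_write(d: Path):
        rows = []
        for b, eff in ctx["effects"].items():
            for s, a in zip(eff.snp_ids, eff.alpha):
                rows.append((s, b, a))
        pd.DataFrame(rows, columns=["snp_id", "breed", "alpha"]).to_csv(
            d / "effects.tsv", sep="\t", index=False)
        mmap = pooled.marker_map
        brows = []
        for b, bs in ctx["blocksets"].items():
            for blk, pct in zip(bs.blocks, bs.pct_var):
                brows.append((mmap["chrom"].iloc[blk[0]],
                              mmap["snp_id"].iloc[blk[0]],
                              mmap["snp_id"].iloc[blk[-1]], b, pct))
        pd.DataFrame(brows, columns=["chrom", "start_snp", "end_snp", "breed",
                                     "pct_var"]).to_csv(
            d / "ld_blocks.tsv", sep="\t", index=False)
        for t, sel in ctx["selected"].items():
            ids = pooled.snp_ids[sel.snp_index]
            (d / f"selected_{int(t * 100)}.txt").write_text(
                "\n".join(map(str, ids)) + "\n")

    def target_read(d: Path):
        target_compute()

    stage_and_check("targeting", sel_cfg, target_compute, target_write, target_read)

    for t in config.thresholds:
        fit_model(f"selboa{int(t * 100)}", "SELBOA",
                  selected=ctx["selected"][t].snp_index)

    # ---- cross-validation -------------------------------------------------
    def cv_compute():
        ctx["cv"] = cross_validate(
            config, data, pooled, pure, cross, origins, phenos,
            {tag: fits[tag] for tag in fits},
        )

    def cv_write(d: Path):
        ctx["cv"]["folds"].assignment.to_csv(d / "folds.csv", index=False)
        ctx["cv"]["accuracy"].to_csv(d / "accuracy.tsv", sep="\t", index=False)
        ctx["cv"]["drp"].to_csv(d / "drp.csv", index=False)

    def cv_read(d: Path):
        ctx["cv"] = {"folds": None,
                     "accuracy": pd.read_csv(d / "accuracy.tsv", sep="\t"),
                     "drp": pd.read_csv(d / "drp.csv")}

    stage_and_check("crossval", [config.k_folds], cv_compute, cv_write, cv_read)
    summary["accuracy"] = ctx["cv"]["accuracy"]
    summary["fits"] = {tag: fits[tag][1] for tag in fits}
    summary["selected"] = ctx.get("selected")
    return summary


def cross_validate(config: RunConfig, data, pooled, pure, cross, origins,
                   phenos, fits: dict) -> dict:
    """K-fold validation of every fitted model's purebred GEBV."""
    g = vanraden_g(pooled)
    populations = {}
    for b in BREEDS:
        for a in pure[b].animal_ids:
            populations[a] = b
    for a in cross.animal_ids:
        populations[a] = CROSSBRED
    folds = make_folds(g, populations, k=config.k_folds, seed=config.seed)
    # per-fold DRP from pedigree BLUP on the fold's crossbred phenotypes
    g_fit = fits["g"][1]
    sigma_a = crossbred_variance(
        {b: 0.0 for b in BREEDS},
        nonsel=float(g_fit.varcomps["across-all"].loc["CB", "CB"]))
    sigma_u = float(g_fit.litter_var[CROSSBRED])
    sigma_e = float(g_fit.residual_var[CROSSBRED])
    h2 = sigma_a / (sigma_a + sigma_u + sigma_e)
    rows = []
    drp_frames = []
    for fold in range(config.k_folds):
        cb_val = folds.animals(CROSSBRED, fold)
        cb_ph = phenos[(phenos["population"] == CROSSBRED)
                       & (phenos["animal_id"].isin(cb_val))]
        train_ph = phenos[~phenos["animal_id"].isin(
            set(cb_val) | {a for b in BREEDS for a in folds.animals(b, fold)}
        )].reset_index(drop=True)
        # validation pseudo-phenotypes are shared across models; one MME
        # per fold covers the validation purebreds of all three breeds
        val_by_breed = {b: folds.animals(b, fold) for b in BREEDS}
        all_val = [a for b in BREEDS for a in val_by_breed[b]]
        ebv = pedigree_ebv(cb_ph, data.pedigree, sigma_a, sigma_u,
                           sigma_e, all_val)
        drp_all = deregress(ebv, data.pedigree, h2, fold=fold)
        drp_frames.append(drp_all.table)
        drps = {}
        for b in BREEDS:
            sub = drp_all.table[drp_all.table["animal"].isin(val_by_breed[b])]
            drps[b] = type(drp_all)(sub.reset_index(drop=True))
        # refit every model on the training split
        for tag, (spec, _, _) in fits.items():
            kind = {"g": "G", "boa": "BOA"}.get(tag, "SELBOA")
            tspec = build_model_spec(kind, pooled, pure, cross, origins,
                                     selected_index=spec.selected_snps)
            tfit = reml_fit(tspec, train_ph, tol=max(config.reml_tol, 1e-6),
                            max_iter=config.reml_max_iter)
            gebv = predict_gebv(tfit, tspec)["gebv_cb"]
            for b in BREEDS:
                try:
                    r, se, n = weighted_accuracy(drps[b], gebv)
                except ValueError:
                    continue
                rows.append((b, fold, tag, r, se, n))
    acc = pd.DataFrame(rows, columns=["breed", "fold", "model", "r", "se", "n"])
    drp = (pd.concat(drp_frames, ignore_index=True)
           if drp_frames else pd.DataFrame(
               columns=["animal", "drp", "weight", "reliability", "fold"]))
    return {"folds": folds, "accuracy": acc, "drp": drp}
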