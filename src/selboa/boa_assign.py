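"""Breed-of-origin assignment for crossbred alleles.

Three steps, operating on phased haplotypes (phasing is taken as given:
the simulator emits truth phase; external data must arrive pre-phased):

1. enumerate haplotype windows over multiple core lengths, each with and
   without a half-core offset, so every allele is covered by several
   overlapping views;
2. build a library of the distinct purebred haplotypes per window and
   assign a window haplotype to a breed when at least 80% of its copies
   are observed in that breed;
3. vote the library assignments of all windows covering each crossbred
   allele, masked by the breed composition of a three-way cross (the
   paternal gamete can only be of sire-line origin; the maternal gamete
   only of one of the two maternal lines); unresolved alleles stay
   missing.

Quality filters then remove SNP with a low per-gamete assignment rate,
crossbred animals with a poorly assigned genome, and SNP at which an
allele is observed fewer than five times within some breed of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

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
    "DEFAULT_CORE_LENGTHS",
    "HaplotypeLibrary",
    "AssignmentReport",
    "window_spans",
    "build_library",
    "assign_origins",
    "apply_filters",
    "restrict_to_assignment",
]

# Nine core lengths (in SNP), each used with and without a half-core
# offset = 18 window views. The exact lengths are configuration, not
# doctrine; these defaults span short to long cores.
DEFAULT_CORE_LENGTHS: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 175, 200, 250)


def default_window_specs() -> list[tuple[int, bool]]:
    return [(core, off) for core in DEFAULT_CORE_LENGTHS for off in (False, True)]


def window_spans(chrom_bounds: list[tuple[int, int]], core: int, offset: bool,
                 ) -> list[tuple[int, int]]:
    """Half-open [start, stop) windows tiling each chromosome.

    With ``offset`` the tiling starts half a core into the chromosome and
    the leading partial window is kept, so all loci stay covered.
    """
    spans = []
    for lo, hi in chrom_bounds:
        start = lo + (core // 2 if offset else 0)
        if offset and start > lo:
            spans.append((lo, min(start, hi)))
        s = start
        while s < hi:
            spans.append((s, min(s + core, hi)))
            s += core
    return [sp for sp in spans if sp[1] > sp[0]]


def _chrom_bounds(geno: PhasedGenotypes) -> list[tuple[int, int]]:
    bounds = []
    start = 0
    for _, grp in geno.marker_map.groupby("chrom", sort=False):
        bounds.append((start, start + len(grp)))
        start += len(grp)
    return bounds


@dataclass
class HaplotypeLibrary:
    """Distinct purebred window haplotypes with breed tallies and assignments."""

    window_specs: list[tuple[int, bool]]
    spans: list[list[tuple[int, int]]]   # per spec, list of (start, stop)
    entries: list[list[dict]]            # per spec, per window: hap bytes -> (counts, breed|None)
    purity: float = 0.8
    min_copies: int = 1

    @property
    def n_views(self) -> int:
        return len(self.window_specs)


def build_library(purebreds: dict[str, PhasedGenotypes],
                  window_specs: list[tuple[int, bool]] | None = None,
                  purity: float = 0.8, min_copies: int = 1) -> HaplotypeLibrary:
    """Tally every distinct purebred haplotype within every window view.

    A haplotype is assigned to a breed iff at least ``purity`` (default
    80%) of its observed copies come from that breed and it was seen at
    least ``min_copies`` times.
    """
    if not purebreds or any(p.n_animals == 0 for p in purebreds.values()):
        raise ValueError("purebred populations must be non-empty")
    if window_specs is None:
        window_specs = default_window_specs()
    ref = next(iter(purebreds.values()))
    bounds = _chrom_bounds(ref)
    all_spans, all_entries = [], []
    hap_stacks = {
        b: np.concatenate([p.haplotypes[:, 0, :], p.haplotypes[:, 1, :]], axis=0)
        for b, p in purebreds.items()
    }
    for core, offset in window_specs:
        spans = window_spans(bounds, core, offset)
        entries = []
        for lo, hi in spans:
            tally: dict[bytes, np.ndarray] = {}
            for b, stack in hap_stacks.items():
                bi = BREED_CODE[b]
                win = stack[:, lo:hi]
                keys, counts = np.unique(win, axis=0, return_counts=True)
                for k, cnt in zip(keys, counts):
                    kb = k.tobytes()
                    if kb not in tally:
                        tally[kb] = np.zeros(len(BREEDS), dtype=np.int64)
                    tally[kb][bi] += cnt
            assigned = {}
            for kb, counts in tally.items():
                tot = counts.sum()
                best = int(counts.argmax())
                breed = best if (tot >= min_copies and counts[best] >= purity * tot) else None
                assigned[kb] = (counts, breed)
            entries.append(assigned)
        all_spans.append(spans)
        all_entries.append(entries)
    return HaplotypeLibrary(window_specs=list(window_specs), spans=all_spans,
                            entries=all_entries, purity=purity, min_copies=min_copies)


def assign_origins(crossbreds: PhasedGenotypes, library: HaplotypeLibrary,
                   ) -> OriginAssignment:
    """Per-allele plurality vote over all window views, composition-masked.

    Each window view whose purebred library assigns the crossbred's
    window haplotype to a breed casts one vote for every locus in the
    window. Votes incompatible with the cross structure (non-S on the
    paternal gamete, S on the maternal gamete) are discarded; plurality
    wins, ties and empty votes give missing.
    """
    n, _, m = crossbreds.haplotypes.shape
    votes = np.zeros((n, 2, m, len(BREEDS)), dtype=np.int16)
    for spans, entries in zip(library.spans, library.entries):
        for (lo, hi), table in zip(spans, entries):
            for gam in (PATERNAL, MATERNAL):
                win = crossbreds.haplotypes[:, gam, lo:hi]
                keys, inverse = np.unique(win, axis=0, return_inverse=True)
                for ki, k in enumerate(keys):
                    hit = table.get(k.tobytes())
                    if hit is None or hit[1] is None:
                        continue
                    rows = inverse == ki
                    votes[rows, gam, lo:hi, hit[1]] += 1
    # composition mask: paternal -> S only, maternal -> LR/LW only
    votes[:, PATERNAL, :, BREED_CODE["LR"]] = 0
    votes[:, PATERNAL, :, BREED_CODE["LW"]] = 0
    votes[:, MATERNAL, :, BREED_CODE["S"]] = 0
    best = votes.argmax(axis=3).astype(np.int8)
    top = votes.max(axis=3)
    runner = np.sort(votes, axis=3)[:, :, :, -2]
    labels = np.where((top > 0) & (top > runner), best, np.int8(MISSING))
    return OriginAssignment(
        animal_ids=list(crossbreds.animal_ids),
        snp_ids=crossbreds.snp_ids,
        labels=labels,
    )


@dataclass
class AssignmentReport:
    """Removal bookkeeping and per-SNP/animal assignment statistics."""

    snp_rate_paternal: dict = field(default_factory=dict)
    snp_rate_maternal: dict = field(default_factory=dict)
    animal_assigned_fraction: dict = field(default_factory=dict)
    removed_snps: dict = field(default_factory=dict)      # snp_id -> reason
    removed_animals: dict = field(default_factory=dict)   # animal_id -> reason
    passes: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_snps": self.removed_snps,
            "removed_animals": self.removed_animals,
            "n_removed_snps": len(self.removed_snps),
            "n_removed_animals": len(self.removed_animals),
            "passes": self.passes,
        }


def apply_filters(assignment: OriginAssignment,
                  purebreds: dict[str, PhasedGenotypes],
                  crossbreds: PhasedGenotypes,
                  snp_rate: float = 0.9, animal_fraction: float = 0.9,
                  min_allele_count: int = 5,
                  ) -> tuple[OriginAssignment, AssignmentReport]:
    """Apply the three quality filters to a fixpoint.

    Per pass, in order: (1) drop SNP whose paternal or maternal allele is
    assigned in < ``snp_rate`` of crossbreds; (2) drop crossbreds with
    < ``animal_fraction`` of their genome assigned; (3) drop SNP at which
    either allele is observed < ``min_allele_count`` times within some
    breed of origin (purebreds of that breed plus matching crossbred
    gametes). Rates are recomputed after each pass; passes repeat until
    nothing changes, which makes the whole operation idempotent.
    """
    report = AssignmentReport()
    cur = assignment
    geno = {a: i for i, a in enumerate(crossbreds.animal_ids)}
    gsnp = {s: i for i, s in enumerate(crossbreds.snp_ids)}
    pure_dosage = {b: purebreds[b].dosage() for b in BREEDS}
    pure_snp = {s: i for i, s in enumerate(next(iter(purebreds.values())).snp_ids)}

    while True:
        changed = False
        # 1. per-gamete SNP assignment rate
        if cur.n_animals == 0:
            raise ValueError("all crossbred animals removed by filters; "
                             f"report: {report.to_dict()}")
        rate = (cur.labels != MISSING).mean(axis=0)  # (2, n_snp)
        keep = (rate[PATERNAL] >= snp_rate) & (rate[MATERNAL] >= snp_rate)
        for sid, rp, rm in zip(cur.snp_ids[~keep], rate[PATERNAL][~keep],
                               rate[MATERNAL][~keep]):
            report.removed_snps[str(sid)] = (
                f"assignment rate paternal={rp:.3f} maternal={rm:.3f} < {snp_rate}"
            )
        if not keep.all():
            cur = cur.subset(snp_index=np.flatnonzero(keep))
            changed = True
        if cur.n_snp == 0:
            raise ValueError("all SNP removed by assignment-rate filter; "
                             f"report: {report.to_dict()}")
        # 2. per-animal assigned fraction over retained SNP
        frac = cur.assigned_fraction()
        keep_a = frac >= animal_fraction
        for aid, fr in zip(np.array(cur.animal_ids)[~keep_a], frac[~keep_a]):
            report.removed_animals[str(aid)] = (
                f"assigned genome fraction {fr:.3f} < {animal_fraction}"
            )
        if not keep_a.all():
            cur = cur.subset(animal_index=np.flatnonzero(keep_a))
            changed = True
        # 3. per-origin allele counts
        if cur.n_animals:
            rows = np.array([geno[a] for a in cur.animal_ids])
            cols = np.array([gsnp[s] for s in cur.snp_ids])
            haps = crossbreds.haplotypes[rows][:, :, cols]
            keep_c = np.ones(cur.n_snp, dtype=bool)
            pcols = np.array([pure_snp[s] for s in cur.snp_ids])
            for b, bi in BREED_CODE.items():
                dos = pure_dosage[b][:, pcols]
                ones = dos.sum(axis=0)
                total = 2.0 * dos.shape[0]
                mask = cur.labels == bi
                ones = ones + np.where(mask, haps, 0).sum(axis=(0, 1))
                tot = total + mask.sum(axis=(0, 1))
                zeros = tot - ones
                bad = (ones < min_allele_count) | (zeros < min_allele_count)
                for sid, o, z in zip(cur.snp_ids[bad & keep_c], ones[bad & keep_c],
                                     zeros[bad & keep_c]):
                    report.removed_snps[str(sid)] = (
                        f"origin-{b} allele counts 1:{int(o)} 0:{int(z)} < {min_allele_count}"
                    )
                keep_c &= ~bad
            if not keep_c.all():
                cur = cur.subset(snp_index=np.flatnonzero(keep_c))
                changed = True
        if cur.n_snp == 0:
            raise ValueError("all SNP removed by allele-count filter; "
                             f"report: {report.to_dict()}")
        report.passes += 1
        if not changed:
            break

    rate = (cur.labels != MISSING).mean(axis=0)
    report.snp_rate_paternal = dict(zip(map(str, cur.snp_ids), rate[PATERNAL]))
    report.snp_rate_maternal = dict(zip(map(str, cur.snp_ids), rate[MATERNAL]))
    report.animal_assigned_fraction = dict(
        zip(map(str, cur.animal_ids), cur.assigned_fraction())
    )
    return cur, report


def restrict_to_assignment(origins: OriginAssignment,
                           purebreds: dict[str, PhasedGenotypes],
                           crossbreds: PhasedGenotypes,
                           phenotypes=None):
    """Subset genotypes (and optionally phenotypes) to the retained panel.

    After ``apply_filters`` the assignment covers a subset of SNP and
    crossbred animals; every downstream matrix must be built on exactly
    that panel. Returns ``(purebreds, crossbreds[, phenotypes])`` cut to
    the origins' SNP and animals.
    """
    import pandas as pd

    ref = next(iter(purebreds.values()))
    keep_snp = np.flatnonzero(pd.Index(ref.snp_ids).isin(origins.snp_ids))
    pure = {b: p.subset_snps(keep_snp) for b, p in purebreds.items()}
    retained = set(origins.animal_ids)
    keep_cb = np.array([i for i, a in enumerate(crossbreds.animal_ids)
                        if a in retained])
    cross = crossbreds.subset_animals(keep_cb).subset_snps(keep_snp)
    if phenotypes is None:
        return pure, cross
    kept_ids = set().union(*[p.animal_ids for p in pure.values()],
                           cross.animal_ids)
    ph = phenotypes[phenotypes["animal_id"].isin(kept_ids)].reset_index(drop=True)
    return pure, cross, ph
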