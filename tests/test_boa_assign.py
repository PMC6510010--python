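"""Breed-of-origin assignment: library purity rule, voting, filters."""

import numpy as np
import pytest

from selboa.boa_assign import (
    apply_filters,
    assign_origins,
    build_library,
    window_spans,
)
from selboa.containers import BREEDS, MATERNAL, MISSING, PATERNAL
from selboa.simdata import SimConfig, simulate

from conftest import make_genotypes, make_origins, small_config


def brute_force_windows(n_snp, core, offset):
    """Independent enumeration of window spans for a single chromosome."""
    spans = []
    start = core // 2 if offset else 0
    if offset and start > 0:
        spans.append((0, start))
    s = start
    while s < n_snp:
        spans.append((s, min(s + core, n_snp)))
        s += core
    return spans


@pytest.mark.parametrize("core,offset", [(3, False), (3, True), (4, True)])
def test_window_spans_cover_all_loci(core, offset):
    spans = window_spans([(0, 10)], core, offset)
    assert spans == brute_force_windows(10, core, offset)
    covered = sorted(j for lo, hi in spans for j in range(lo, hi))
    assert covered == list(range(10))


def test_library_purity_rule():
    """9 LR copies vs 1 LW copy (90%) assigns LR; 7 vs 3 (70%) stays unassigned."""
    m = 3
    hapA = np.array([1, 0, 1], dtype=np.uint8)
    hapB = np.array([0, 1, 0], dtype=np.uint8)

    def pop(counts_a, counts_b, prefix):
        # counts are gamete counts; two gametes per animal
        haps = []
        for _ in range(counts_a):
            haps.append(hapA)
        for _ in range(counts_b):
            haps.append(hapB)
        arr = np.array(haps, dtype=np.uint8).reshape(-1, 2, m)
        return make_genotypes(arr, ids=[f"{prefix}{i}" for i in range(len(arr))])

    # hapA: LR 9 copies, LW 1 copy -> 90% LR; hapB: LR 7, LW 3 -> 70%
    lr = pop(9, 7, "lr")
    lw = pop(1, 3, "lw")
    s = pop(0, 0, "s")
    s = make_genotypes(np.zeros((1, 2, m), dtype=np.uint8), ids=["s0"])
    lib = build_library({"S": s, "LR": lr, "LW": lw}, window_specs=[(3, False)])
    table = lib.entries[0][0]
    counts_a, breed_a = table[hapA.tobytes()]
    counts_b, breed_b = table[hapB.tobytes()]
    assert breed_a == BREEDS.index("LR") and counts_a[1] == 9
    assert breed_b is None  # 70% < 80%


def test_library_matches_exhaustive_enumeration():
    """4 animals x 6 SNP, window length 3, both offsets: tally every window."""
    rng = np.random.default_rng(0)
    pops = {b: make_genotypes(rng.integers(0, 2, (4, 2, 6)).astype(np.uint8),
                              ids=[f"{b}{i}" for i in range(4)])
            for b in BREEDS}
    lib = build_library(pops, window_specs=[(3, False), (3, True)])
    for spec_i, (core, offset) in enumerate(lib.window_specs):
        spans = brute_force_windows(6, core, offset)
        assert lib.spans[spec_i] == spans
        for w, (lo, hi) in enumerate(spans):
            # exhaustive tally
            tally = {}
            for bi, b in enumerate(BREEDS):
                for i in range(4):
                    for g in range(2):
                        key = pops[b].haplotypes[i, g, lo:hi].tobytes()
                        tally.setdefault(key, np.zeros(3, int))[bi] += 1
            lib_table = lib.entries[spec_i][w]
            assert set(lib_table) == set(tally)
            for key, counts in tally.items():
                np.testing.assert_array_equal(lib_table[key][0], counts)


def test_composition_mask_rejects_non_sire_paternal_votes():
    """A paternal haplotype identical to an LR library haplotype -> missing."""
    m = 4
    hap_lr = np.array([1, 1, 0, 0], dtype=np.uint8)
    hap_lw = np.array([0, 0, 1, 1], dtype=np.uint8)
    hap_s = np.array([1, 0, 1, 0], dtype=np.uint8)
    pops = {
        "S": make_genotypes(np.tile(hap_s, (3, 2, 1)), ids=["s0", "s1", "s2"]),
        "LR": make_genotypes(np.tile(hap_lr, (3, 2, 1)), ids=["l0", "l1", "l2"]),
        "LW": make_genotypes(np.tile(hap_lw, (3, 2, 1)), ids=["w0", "w1", "w2"]),
    }
    lib = build_library(pops, window_specs=[(4, False)])
    cb = np.empty((1, 2, m), dtype=np.uint8)
    cb[0, PATERNAL] = hap_lr  # paternal gamete looks LR -> masked to missing
    cb[0, MATERNAL] = hap_lw
    asg = assign_origins(make_genotypes(cb, ids=["c0"]), lib)
    assert (asg.labels[0, PATERNAL] == MISSING).all()
    assert (asg.labels[0, MATERNAL] == BREEDS.index("LW")).all()


def test_assignment_accuracy_on_simulated_data(small_sim):
    """>= 95% of assigned labels match the simulator truth."""
    lib = build_library(small_sim.purebreds)
    asg = assign_origins(small_sim.crossbreds, lib)
    agree = asg.agreement(small_sim.truth.true_origin)
    assert agree >= 0.95, agree


def test_accuracy_monotone_in_fst():
    """Assignment accuracy non-decreasing across three F_ST levels."""
    levels = [0.06, 0.12, 0.2]
    acc = []
    for f in levels:
        vals = []
        for seed in (1, 2, 3):
            cfg = small_config(
                seed=seed,
                fst_target={frozenset(("S", "LR")): f, frozenset(("S", "LW")): f,
                            frozenset(("LW", "LR")): f})
            d = simulate(cfg)
            lib = build_library(d.purebreds)
            asg = assign_origins(d.crossbreds, lib)
            vals.append(asg.agreement(d.truth.true_origin))
        acc.append(np.mean(vals))
    assert acc[0] <= acc[1] + 0.01 and acc[1] <= acc[2] + 0.01, acc


def _constructed_assignment():
    """20 crossbreds x 10 SNP with known filter-triggering patterns."""
    n, m = 20, 10
    rng = np.random.default_rng(1)
    lab = np.zeros((n, 2, m), dtype=np.int8)
    lab[:, PATERNAL, :] = 0
    lab[:, MATERNAL, :] = np.where(rng.uniform(size=(n, m)) < 0.5, 1, 2)
    # SNP 0: paternal assignment rate 0.85 (3 of 20 missing)
    lab[:3, PATERNAL, 0] = MISSING
    # animal 0: 88% of genome assigned (beyond SNP-0 removals)
    lab[0, :, 1:4] = MISSING
    hap = rng.integers(0, 2, size=(n, 2, m)).astype(np.uint8)
    pure = {b: make_genotypes(
        rng.integers(0, 2, size=(6, 2, m)).astype(np.uint8),
        ids=[f"{b}{i}" for i in range(6)]) for b in BREEDS}
    cb = make_genotypes(hap, ids=[f"c{i}" for i in range(n)])
    asg = make_origins(lab, ids=[f"c{i}" for i in range(n)])
    return asg, pure, cb


def test_filters_reproduce_their_rules():
    asg, pure, cb = _constructed_assignment()
    filtered, report = apply_filters(asg, pure, cb, min_allele_count=0)
    assert "s0" in report.removed_snps            # 0.85 < 0.90 paternal rate
    assert "c0" in report.removed_animals         # 88% assigned after SNP pass
    assert "s0" not in set(filtered.snp_ids)
    assert "c0" not in filtered.animal_ids


def test_allele_count_filter_removes_rare_origin_allele():
    """An allele observed 4 times within one origin removes the SNP."""
    m = 2
    rng = np.random.default_rng(2)
    # purebred LR carries exactly 4 copies of allele 1 at SNP 0 and a
    # balanced SNP 1; other breeds are balanced everywhere
    lr = np.zeros((10, 2, m), dtype=np.uint8)
    lr[:2, :, 0] = 1                        # 4 copies of allele 1
    lr[:5, :, 1] = 1
    pure = {
        "LR": make_genotypes(lr, ids=[f"l{i}" for i in range(10)]),
        "S": make_genotypes(
            np.tile(np.array([[1], [0]], np.uint8), (10, 1, 2)),
            ids=[f"s{i}" for i in range(10)]),
        "LW": make_genotypes(
            np.tile(np.array([[1], [0]], np.uint8), (10, 1, 2)),
            ids=[f"w{i}" for i in range(10)]),
    }
    n = 12
    lab = np.zeros((n, 2, m), dtype=np.int8)
    lab[:, MATERNAL, :] = 2                 # all maternal LW: LR gets no CB copies
    hap = rng.integers(0, 2, size=(n, 2, m)).astype(np.uint8)
    cb = make_genotypes(hap, ids=[f"c{i}" for i in range(n)])
    asg = make_origins(lab, ids=[f"c{i}" for i in range(n)])
    filtered, report = apply_filters(asg, pure, cb)
    assert "s0" in report.removed_snps
    assert "origin-LR" in report.removed_snps["s0"]


def test_filters_idempotent():
    asg, pure, cb = _constructed_assignment()
    once, _ = apply_filters(asg, pure, cb, min_allele_count=0)
    twice, rep2 = apply_filters(once, pure, cb, min_allele_count=0)
    assert list(once.snp_ids) == list(twice.snp_ids)
    assert once.animal_ids == twice.animal_ids
    np.testing.assert_array_equal(once.labels, twice.labels)


def test_retained_labels_respect_composition(small_sim):
    lib = build_library(small_sim.purebreds)
    asg = assign_origins(small_sim.crossbreds, lib)
    filt, _ = apply_filters(asg, small_sim.purebreds, small_sim.crossbreds)
    pat = filt.labels[:, PATERNAL, :]
    mat = filt.labels[:, MATERNAL, :]
    assert np.isin(pat, [BREEDS.index("S"), MISSING]).all()
    assert np.isin(mat, [BREEDS.index("LR"), BREEDS.index("LW"), MISSING]).all()
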