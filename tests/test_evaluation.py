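"""Cross-validation: folds, pedigree BLUP, deregression, weighted accuracy."""

import numpy as np
import pandas as pd
import pytest

from selboa.containers import BREEDS, CROSSBRED
from selboa.evaluation import (
    DrpTable,
    deregress,
    make_folds,
    pedigree_a_matrix,
    pedigree_ebv,
    weighted_accuracy,
)
from selboa.grm import GenomicMatrix, vanraden_g


def _planted_g(k=4, fam=10, within=0.6, between=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = k * fam
    g = np.full((n, n), between)
    for f in range(k):
        sl = slice(f * fam, (f + 1) * fam)
        g[sl, sl] = within
    g += np.diag(1.0 - np.diag(g))
    g += rng.normal(0, 0.01, (n, n))
    g = (g + g.T) / 2
    ids = [f"cb{i}" for i in range(n)]
    return g, ids


def test_make_folds_recovers_planted_families():
    """4 equal crossbred families with strong within-family relationship."""
    gcb, cb_ids = _planted_g(seed=1)
    # add purebred families mirroring the crossbred ones
    k, fam = 4, 6
    npure = k * fam
    rng = np.random.default_rng(2)
    n = len(cb_ids)
    full = np.full((n + 3 * npure, n + 3 * npure), 0.02)
    full[:n, :n] = gcb
    ids = list(cb_ids)
    pops = {a: CROSSBRED for a in cb_ids}
    off = n
    for b in BREEDS:
        for f in range(k):
            sl = slice(off + f * fam, off + (f + 1) * fam)
            full[sl, sl] = 0.5
            # purebred family f relates to crossbred family f
            cb_sl = slice(f * 10, (f + 1) * 10)
            full[sl, cb_sl] = 0.3
            full[cb_sl, sl] = 0.3
        for i in range(npure):
            ids.append(f"{b}{i}")
            pops[f"{b}{i}"] = b
        off += npure
    np.fill_diagonal(full, 1.0)
    g = GenomicMatrix(animal_ids=ids, values=full, scaling_factor=1.0,
                      freq=np.array([]), snp_ids=np.array([]))
    folds = make_folds(g, pops, k=4, seed=0)
    # crossbred fold sizes within +-10% of n/k
    sizes = folds.assignment[folds.assignment["population"] == CROSSBRED][
        "fold"].value_counts()
    assert sizes.sum() == len(cb_ids)
    assert (abs(sizes - len(cb_ids) / 4) <= 0.1 * len(cb_ids) / 4 + 1).all()
    # planted partition recovered: every crossbred family maps to one fold
    asg = folds.assignment.set_index("animal")
    for f in range(4):
        fam_folds = {asg.loc[f"cb{i}", "fold"] for i in range(f * 10, (f + 1) * 10)}
        assert len(fam_folds) == 1
    # pairing is a bijection per breed
    for b in BREEDS:
        assert sorted(folds.pairing[b].keys()) == [0, 1, 2, 3]
        assert sorted(folds.pairing[b].values()) == [0, 1, 2, 3]


def test_make_folds_rejects_small_population():
    g = GenomicMatrix(animal_ids=["a", "b"], values=np.eye(2),
                      scaling_factor=1.0, freq=np.array([]), snp_ids=np.array([]))
    with pytest.raises(ValueError):
        make_folds(g, {"a": "S", "b": "S"}, k=4)


def test_a_matrix_trio_hand_values():
    """Sire-dam-offspring trio: unit diagonal, 0.5 parent-offspring."""
    ped = pd.DataFrame({
        "animal": ["s", "d", "o"], "sire": ["0", "0", "s"], "dam": ["0", "0", "d"],
    })
    a, order = pedigree_a_matrix(ped)
    i = {x: k for k, x in enumerate(order)}
    assert a[i["o"], i["o"]] == pytest.approx(1.0)
    assert a[i["s"], i["o"]] == pytest.approx(0.5)
    assert a[i["d"], i["o"]] == pytest.approx(0.5)
    assert a[i["s"], i["d"]] == pytest.approx(0.0)
    # full sibs from the same trio parents have a = 0.5, inbred child of
    # half sibs picks up 0.25 * a(parents)
    ped2 = pd.DataFrame({
        "animal": ["s", "d", "o1", "o2", "x"],
        "sire": ["0", "0", "s", "s", "o1"],
        "dam": ["0", "0", "d", "d", "o2"],
    })
    a2, order2 = pedigree_a_matrix(ped2)
    j = {x: k for k, x in enumerate(order2)}
    assert a2[j["o1"], j["o2"]] == pytest.approx(0.5)
    assert a2[j["x"], j["x"]] == pytest.approx(1.25)


def test_pedigree_ebv_zero_phenotypes_zero_ebv():
    ped = pd.DataFrame({
        "animal": ["s", "d", "o1", "o2"], "sire": ["0", "0", "s", "s"],
        "dam": ["0", "0", "d", "d"],
    })
    ph = pd.DataFrame({
        "animal_id": ["o1", "o2"], "trait_value": [0.0, 0.0],
        "fixed_level": ["l", "l"], "covariate": [0.0, 0.0],
        "litter_id": ["L1", "L1"],
    })
    out = pedigree_ebv(ph, ped, sigma_a=100.0, sigma_litter=20.0, sigma_e=300.0,
                       target_animals=["s"])
    assert out["ebv"].iloc[0] == pytest.approx(0.0, abs=1e-10)


def test_pedigree_ebv_parent_more_reliable_than_stranger():
    rng = np.random.default_rng(4)
    sires = [f"s{i}" for i in range(3)]
    rows = [(s, "0", "0") for s in sires] + [("lone", "0", "0")]
    ph_rows = []
    for i in range(30):
        rows.append((f"o{i}", sires[i % 3], "0"))
        ph_rows.append((f"o{i}", rng.normal(500, 30), "l", 0.0, f"L{i % 6}"))
    ped = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    ph = pd.DataFrame(ph_rows, columns=["animal_id", "trait_value",
                                        "fixed_level", "covariate", "litter_id"])
    out = pedigree_ebv(ph, ped, sigma_a=400.0, sigma_litter=100.0, sigma_e=900.0,
                       target_animals=sires + ["lone"]).set_index("animal")
    assert (out.loc[sires, "reliability"] > out.loc["lone", "reliability"]).all()


def test_deregress_no_relatives_recovers_ebv_over_r2():
    ped = pd.DataFrame({"animal": ["a"], "sire": ["0"], "dam": ["0"]})
    tab = pd.DataFrame({"animal": ["a"], "ebv": [10.0], "reliability": [0.4]})
    drp = deregress(tab, ped, h2=0.3)
    assert drp.table["drp"].iloc[0] == pytest.approx(10.0 / 0.4)
    # r2 -> 1 limit: DRP -> EBV
    tab2 = pd.DataFrame({"animal": ["a"], "ebv": [10.0], "reliability": [0.999999]})
    drp2 = deregress(tab2, ped, h2=0.3)
    assert drp2.table["drp"].iloc[0] == pytest.approx(10.0, rel=1e-4)


def test_deregress_removes_parent_average():
    ped = pd.DataFrame({"animal": ["s", "d", "o"], "sire": ["0", "0", "s"],
                        "dam": ["0", "0", "d"]})
    tab = pd.DataFrame({"animal": ["s", "d", "o"],
                        "ebv": [4.0, 2.0, 5.0],
                        "reliability": [0.5, 0.5, 0.6]})
    drp = deregress(tab, ped, h2=0.3).table.set_index("animal")
    pa = 3.0
    r2_pa = (0.5 + 0.5) / 4.0
    info_own = 0.6 / 0.4 - r2_pa / (1 - r2_pa)
    r2_own = info_own / (1 + info_own)
    assert drp.loc["o", "drp"] == pytest.approx(pa + (5.0 - pa) / r2_own)
    assert drp.loc["o", "reliability"] == pytest.approx(r2_own)


def test_weighted_accuracy_equal_weights_is_pearson():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    y = 0.6 * x + rng.normal(size=20)
    t = DrpTable(pd.DataFrame({"animal": [f"a{i}" for i in range(20)],
                               "drp": x, "weight": 1.0, "reliability": 0.5,
                               "fold": 0}))
    gebv = pd.Series(y, index=[f"a{i}" for i in range(20)])
    r, se, n = weighted_accuracy(t, gebv)
    assert r == pytest.approx(np.corrcoef(x, y)[0, 1])
    assert se == pytest.approx((1 - r**2) / np.sqrt(20))
    assert n == 20


def test_weighted_accuracy_perfect_agreement():
    x = np.arange(5, dtype=float)
    t = DrpTable(pd.DataFrame({"animal": list("abcde"), "drp": x,
                               "weight": [1, 2, 3, 4, 5], "reliability": 0.5,
                               "fold": 0}))
    r, se, n = weighted_accuracy(t, pd.Series(x, index=list("abcde")))
    assert r == pytest.approx(1.0)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_weighted_accuracy_hand_fixture():
    """6-point fixture with unequal weights vs a spreadsheet-style oracle."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.5, 1.0, 3.5, 3.0, 6.0, 5.0])
    w = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 2.0])
    ids = list("abcdef")
    t = DrpTable(pd.DataFrame({"animal": ids, "drp": x, "weight": w,
                               "reliability": 0.5, "fold": 0}))
    # independent oracle: explicit weighted moments
    wm = w / w.sum()
    mx, my = wm @ x, wm @ y
    r_hand = (wm @ ((x - mx) * (y - my))
              / np.sqrt((wm @ (x - mx) ** 2) * (wm @ (y - my) ** 2)))
    r, se, n = weighted_accuracy(t, pd.Series(y, index=ids))
    assert r == pytest.approx(r_hand)


def test_weighted_accuracy_needs_three_points():
    t = DrpTable(pd.DataFrame({"animal": ["a", "b"], "drp": [1.0, 2.0],
                               "weight": [1.0, 1.0], "reliability": 0.5,
                               "fold": 0}))
    with pytest.raises(ValueError):
        weighted_accuracy(t, pd.Series([1.0, 2.0], index=["a", "b"]))


def test_no_validation_leakage_canary(small_sim):
    """Corrupting a validation-fold crossbred phenotype leaves training
    fits untouched: validation records never enter the training data."""
    from selboa.containers import CROSSBRED
    from selboa.grm import vanraden_g
    from selboa.mixedmodel import build_model_spec, predict_gebv, reml_fit

    d = small_sim
    pops = {a: b for b in BREEDS for a in d.purebreds[b].animal_ids}
    pops.update({a: CROSSBRED for a in d.crossbreds.animal_ids})
    g = vanraden_g(d.pooled_genotypes())
    folds = make_folds(g, pops, k=4, seed=0)
    fold0_cb = set(folds.animals(CROSSBRED, 0))
    fold0_pure = {a for b in BREEDS for a in folds.animals(b, 0)}
    canary = next(iter(fold0_cb))

    def train_fit(phenos):
        train = phenos[~phenos["animal_id"].isin(fold0_cb | fold0_pure)]
        spec = build_model_spec("G", d.pooled_genotypes(), d.purebreds,
                                d.crossbreds, d.truth.true_origin)
        fit = reml_fit(spec, train.reset_index(drop=True), tol=1e-5, max_iter=10)
        return predict_gebv(fit, spec)["gebv_cb"]

    base = train_fit(d.phenotypes)
    poisoned = d.phenotypes.copy()
    poisoned.loc[poisoned["animal_id"] == canary, "trait_value"] += 1e6
    after = train_fit(poisoned)
    pd.testing.assert_series_equal(base, after)
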