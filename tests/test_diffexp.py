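import dataclasses

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cdnorm import ExperimentDesign, GeneratorSpec, balance, evaluate, generate, ttest_treatment
from cdnorm.simulate import SyntheticTruth


def _design_tc():
    condition_of = {f"c{k}_r{r}": f"c{k}" for k in range(2) for r in range(3)}
    return ExperimentDesign(condition_of=condition_of, control_of={"c1": "c0"})


def _truth(de: dict, direction: dict, genes) -> SyntheticTruth:
    de_frame = pd.DataFrame({"c1": pd.Series(de).reindex(genes, fill_value=False)})
    dir_frame = pd.DataFrame({"c1": pd.Series(direction).reindex(genes, fill_value=0)})
    return SyntheticTruth(
        de_indicator=de_frame.astype(bool),
        direction=dir_frame.astype(int),
        reserved_null_genes=(),
        true_offsets=pd.Series(dtype=float),
        deg_fractions=pd.Series({"c1": de_frame["c1"].mean()}),
        spec=GeneratorSpec(g=len(genes)),
    )


def test_identical_groups_not_called():
    d = _design_tc()
    m = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g1"],
                     columns=list(d.condition_of))
    t = ttest_treatment(m, d, "c1")
    assert t.loc["g1", "pvalue"] == pytest.approx(1.0)
    assert not t.loc["g1", "call"]


def test_constant_identical_groups_degenerate_p_one():
    d = _design_tc()
    m = pd.DataFrame([[2.0] * 6], index=["g1"], columns=list(d.condition_of))
    t = ttest_treatment(m, d, "c1")
    assert t.loc["g1", "pvalue"] == 1.0


def test_log2fc_is_mean_difference():
    d = _design_tc()
    m = pd.DataFrame([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]], index=["g1"],
                     columns=list(d.condition_of))
    t = ttest_treatment(m, d, "c1")
    assert t.loc["g1", "log2fc"] == pytest.approx(1.0)  # 2-fold change


def test_adjusted_pvalues_are_bh():
    rng = np.random.default_rng(0)
    d = _design_tc()
    m = pd.DataFrame(rng.normal(size=(30, 6)), columns=list(d.condition_of))
    t = ttest_treatment(m, d, "c1")
    _, expected, _, _ = multipletests(t["pvalue"].to_numpy(), method="fdr_bh")
    assert np.allclose(t["adjusted_pvalue"], expected)
    assert (t["adjusted_pvalue"] >= t["pvalue"] - 1e-15).all()


def _brute_force_bh(p):
    """Literal step-up procedure: find the largest k with p_(k) <= k/m * q,
    adjusted p_i = min over j >= rank(i) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj[order[rank - 1]] = running
    return adj


def test_bh_matches_brute_force_step_up():
    rng = np.random.default_rng(1)
    for n in range(1, 11):
        for _ in range(30):
            p = rng.uniform(size=n)
            if rng.random() < 0.3:
                p[rng.integers(n)] = p[0]  # force ties sometimes
            _, sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(sm, _brute_force_bh(p), atol=1e-12)


def test_bh_hand_example():
    adj = _brute_force_bh([0.01, 0.02, 0.04, 0.9])
    assert np.allclose(adj, [0.04, 0.04, 16 / 300, 0.9])
    _, sm, _, _ = multipletests([0.01, 0.02, 0.04, 0.9], method="fdr_bh")
    assert np.allclose(sm, adj)
    assert (adj <= 0.05).sum() == 2


def test_welch_option_changes_statistic():
    rng = np.random.default_rng(2)
    d = _design_tc()
    m = pd.DataFrame(rng.normal(size=(20, 6)) * [1, 1, 1, 4, 4, 4],
                     columns=list(d.condition_of))
    pooled = ttest_treatment(m, d, "c1", equal_var=True)
    welch = ttest_treatment(m, d, "c1", equal_var=False)
    assert not np.allclose(pooled["pvalue"], welch["pvalue"])


def test_balance_arithmetic():
    t = pd.DataFrame({
        "log2fc": [1.0, 2.0, 0.5, -1.0, 3.0],
        "call": [True, True, True, True, False],
    })
    assert balance(t) == pytest.approx(0.5)  # 3 over, 1 under
    t_all_over = pd.DataFrame({"log2fc": [1.0, 2.0], "call": [True, True]})
    assert balance(t_all_over) == 1.0
    t_under = pd.DataFrame({"log2fc": [-1, -1, -1, 1, 1], "call": [True] * 5})
    assert balance(t_under) == pytest.approx(-0.2)  # 60% under-expressed
    assert np.isnan(balance(pd.DataFrame({"log2fc": [1.0], "call": [False]})))


def test_evaluate_hand_built_counts():
    genes = [f"g{i}" for i in range(10)]
    truth = _truth(
        de={g: g in {"g0", "g1", "g2", "g3"} for g in genes},
        direction={"g0": 1, "g1": 1, "g2": -1, "g3": 1},
        genes=genes,
    )
    table = pd.DataFrame(
        {
            "statistic": 0.0,
            "pvalue": [0.001, 0.002, 0.5, 0.6, 0.003, 0.7, 0.8, 0.9, 0.95, 0.99],
            "adjusted_pvalue": [0.01, 0.01, 0.9, 0.9, 0.01, 0.9, 0.9, 0.9, 0.9, 0.99],
            "log2fc": [1.0, 1.5, -1.0, 1.0, 0.5, 0, 0, 0, 0, 0],
            "call": [True, True, False, False, True, False, False, False, False, False],
        },
        index=genes,
    )
    r = evaluate(table, truth, "c1")
    assert r.n_detected == 3
    assert r.n_true_positives == 2  # g0, g1
    assert r.n_false_positives == 1  # g4
    assert r.tpr == pytest.approx(2 / 4)
    assert r.fdr == pytest.approx(1 / 3)
    assert r.balance == 1.0  # all detected have positive fold change


def test_evaluate_perfect_and_null_callers():
    genes = [f"g{i}" for i in range(6)]
    truth = _truth({g: g in {"g0", "g1"} for g in genes},
                   {"g0": 1, "g1": -1}, genes)
    perfect = pd.DataFrame(
        {
            "statistic": 0.0,
            "pvalue": [1e-6, 1e-6, 0.9, 0.9, 0.9, 0.9],
            "adjusted_pvalue": [1e-5, 1e-5, 0.9, 0.9, 0.9, 0.9],
            "log2fc": [2.0, -2.0, 0, 0, 0, 0],
            "call": [True, True, False, False, False, False],
        },
        index=genes,
    )
    r = evaluate(perfect, truth, "c1")
    assert r.tpr == 1.0 and r.fdr == 0.0
    # a caller firing on pure-null truth has FDR 1 whenever it calls
    null_truth = _truth({g: False for g in genes}, {}, genes)
    r2 = evaluate(perfect, null_truth, "c1")
    assert r2.fdr == 1.0
    # calling nothing yields FDR 0 by convention
    nothing = perfect.assign(call=False)
    assert evaluate(nothing, null_truth, "c1").fdr == 0.0


def test_evaluate_known_gene_restriction():
    genes = [f"g{i}" for i in range(8)]
    truth = _truth({g: g in {"g0", "g1"} for g in genes}, {"g0": 1, "g1": 1}, genes)
    table = pd.DataFrame(
        {
            "statistic": 0.0,
            "pvalue": 0.5,
            "adjusted_pvalue": 0.9,
            "log2fc": 0.0,
            "call": [True, False, False, False, True, False, False, False],
        },
        index=genes,
    )
    full = evaluate(table, truth, "c1")
    known = evaluate(table, truth, "c1", known_genes=pd.Index(["g0", "g1", "g2"]))
    assert full.n_detected == 2 and known.n_detected == 1
    assert known.n_treatment_positives == 2


def test_roc_is_monotone():
    spec = GeneratorSpec(g=800, n_treatments=2, n_controls=2, n_replicates=4,
                         deg_fraction_range=(0.3, 0.5), seed=3)
    m, d, truth = generate(spec)
    trt = d.treatments[0]
    table = ttest_treatment(m, d, trt)
    r = evaluate(table, truth, trt)
    assert (np.diff(r.roc["tpr"]) >= 0).all()
    assert (np.diff(r.roc["fpr"]) >= 0).all()
    assert r.roc["tpr"].iloc[-1] == pytest.approx(1.0)
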