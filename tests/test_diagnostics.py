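"""Decision-tree evaluation: cohort arithmetic, costs, and an independent
individual-level Monte-Carlo oracle of the tree logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynchcea import ParameterSet, eligible_cohort, run_strategy, strategy_comparison_table
from lynchcea.diagnostics import STRATEGIES, strategy_paths


def _override(params, **updates) -> ParameterSet:
    doc = params.model_dump(mode="python")
    doc.update(updates)
    return ParameterSet(**doc)


def _override_test(params, test, **fields) -> ParameterSet:
    doc = params.model_dump(mode="python")
    doc["test_performance"][test].update(fields)
    return ParameterSet(**doc)


def test_eligible_cohort_reproduces_published_count(params):
    tested, ls_pos, ls_neg = eligible_cohort(params)
    assert tested == pytest.approx(49000 * 0.848)
    assert ls_pos == pytest.approx(41552 * 0.0281)
    assert int(ls_pos) == 1167  # published detected count for universal sequencing
    assert ls_pos + ls_neg == pytest.approx(tested)


def test_zero_uptake_and_pure_ls_edge_cases(params):
    assert eligible_cohort(_override(params, uptake_proband=0.0)) == (0.0, 0.0, 0.0)
    tested, ls_pos, _ = eligible_cohort(_override(params, ls_share=1.0))
    assert ls_pos == tested


def test_universal_sequencing_volume_and_cost(params):
    r = run_strategy("s1", params)
    assert r.tests_performed == {"sequencing": pytest.approx(41552.0)}
    assert r.screening_cost == pytest.approx(41552 * 250.0)
    assert r.screening_cost == pytest.approx(10_388_000.0)
    assert r.reported_cases == 1167


def test_path_weights_form_probability_distributions(params):
    for sid, strat in STRATEGIES.items():
        ls, sporadic = strategy_paths(strat, params)
        assert sum(w for w, _, _ in ls) == pytest.approx(1.0, abs=1e-12), sid
        assert sum(w for w, _, _ in sporadic) == pytest.approx(1.0, abs=1e-12), sid
        assert not any(d for _, _, d in sporadic), "sporadic probands are never true positives"


def test_dead_tree_when_ihc_sensitivity_zero(params):
    p = _override_test(_override_test(params, "ihc", sensitivity=0.0), "ihc", specificity=1.0)
    r = run_strategy("s2", p)
    assert r.true_positive_probands == 0.0
    assert set(r.tests_performed) == {"ihc"}


def test_age_gate_inert_when_nobody_is_70(params):
    p = _override(params, prop_age_ge70=0.0)
    s2 = run_strategy("s2", p)
    s3 = run_strategy("s3", p)
    assert s3.true_positive_probands == pytest.approx(s2.true_positive_probands)
    assert s3.screening_cost == pytest.approx(s2.screening_cost)
    assert {t: pytest.approx(n) for t, n in s2.tests_performed.items()} == s3.tests_performed


def test_detection_ordering_and_tp_fn_balance(params):
    results = {s: run_strategy(s, params) for s in ("s1", "s2", "s3")}
    assert (
        results["s1"].true_positive_probands
        >= results["s2"].true_positive_probands
        >= results["s3"].true_positive_probands
    )
    _, ls_pos, _ = eligible_cohort(params)
    for r in results.values():
        assert r.true_positive_probands + r.false_negative_probands == pytest.approx(ls_pos)


def test_cost_is_exact_dot_product_of_volumes_and_unit_costs(params):
    for sid in STRATEGIES:
        r = run_strategy(sid, params)
        expected = sum(
            n * params.test_performance[t].unit_cost for t, n in r.tests_performed.items()
        )
        assert r.screening_cost == expected


@settings(max_examples=20, derandomize=True, deadline=None)
@given(sens=st.floats(min_value=0.0, max_value=1.0))
def test_detections_monotone_in_ihc_sensitivity(sens):
    from lynchcea import default_parameters

    params = default_parameters()
    lo = run_strategy("s2", _override_test(params, "ihc", sensitivity=sens))
    hi = run_strategy("s2", _override_test(params, "ihc", sensitivity=min(1.0, sens + 0.05)))
    assert hi.true_positive_probands >= lo.true_positive_probands - 1e-9


def test_comparison_table_layout(params):
    results = [run_strategy(s, params) for s in ("no_screening", "s3", "s2", "s1")]
    df = strategy_comparison_table(results)
    assert list(df["strategy"]) == ["no_screening", "s3", "s2", "s1"]
    assert df.loc[0, "ls_cases_detected"] == 0
    assert df.loc[0, "screening_cost_eur"] == 0.0
    assert df["ls_cases_detected"].is_monotonic_increasing


def _simulate_strategy(sid: str, params: ParameterSet, n: int, seed: int):
    """Individual-proband Monte-Carlo rerun of the tree logic, written
    independently of the path-enumeration engine."""
    rng = np.random.default_rng(seed)
    tp = params.test_performance
    genes = list(params.gene_distribution)
    gp = np.array([params.gene_distribution[g] for g in genes])

    is_ls = rng.random(n) < params.ls_share
    gene = rng.choice(len(genes), size=n, p=gp)
    methylated = rng.random(n) < params.sporadic_mlh1_methylation_share
    old = rng.random(n) < params.prop_age_ge70

    detected = np.zeros(n, bool)
    cost = np.zeros(n)
    counts = {t: 0 for t in tp}
    for i in range(n):
        do_triage = True
        if sid == "s1":
            counts["sequencing"] += 1
            cost[i] += tp["sequencing"].unit_cost
            detected[i] = is_ls[i] and rng.random() < tp["sequencing"].sensitivity
            continue
        if sid == "s3" and old[i]:
            counts["bethesda"] += 1
            cost[i] += tp["bethesda"].unit_cost
            fulfilled = (
                rng.random() < tp["bethesda"].sensitivity
                if is_ls[i]
                else rng.random() > tp["bethesda"].specificity
            )
            do_triage = fulfilled
        if not do_triage:
            continue
        counts["ihc"] += 1
        cost[i] += tp["ihc"].unit_cost
        if is_ls[i]:
            absent = rng.random() < tp["ihc"].sensitivity
            pattern_mlh1 = genes[gene[i]] == "MLH1"
            tumor_methylated = False
        else:
            if methylated[i]:
                absent = rng.random() < tp["ihc"].sensitivity
                pattern_mlh1, tumor_methylated = True, True
            else:
                absent = rng.random() > tp["ihc"].specificity
                pattern_mlh1 = genes[gene[i]] == "MLH1"
                tumor_methylated = False
        if not absent:
            continue
        if pattern_mlh1:
            counts["ms_mlpa"] += 1
            cost[i] += tp["ms_mlpa"].unit_cost
            called_methylated = (
                rng.random() < tp["ms_mlpa"].sensitivity
                if tumor_methylated
                else rng.random() > tp["ms_mlpa"].specificity
            )
            if called_methylated:
                continue
        counts["sequencing"] += 1
        cost[i] += tp["sequencing"].unit_cost
        if is_ls[i] and rng.random() < tp["sequencing"].sensitivity:
            detected[i] = True
    return detected, cost, counts


@pytest.mark.parametrize("sid", ["s1", "s2", "s3"])
def test_expected_value_engine_matches_monte_carlo_oracle(params, sid):
    n = 120_000
    detected, cost, counts = _simulate_strategy(sid, params, n, seed=2024)
    r = run_strategy(sid, params)
    tested, _, _ = eligible_cohort(params)

    rate_engine = r.true_positive_probands / tested
    rate_mc = detected.mean()
    se = detected.std(ddof=1) / np.sqrt(n)
    assert abs(rate_engine - rate_mc) < 3 * se + 1e-12

    cost_engine = r.screening_cost / tested
    se_cost = cost.std(ddof=1) / np.sqrt(n)
    assert abs(cost_engine - cost.mean()) <= 3 * se_cost + 1e-9

    for t, n_engine in r.tests_performed.items():
        frac = counts[t] / n
        se_t = np.sqrt(frac * (1 - frac) / n)
        assert abs(n_engine / tested - frac) < 3.5 * se_t + 1e-9, t
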