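"""Subgroups, hierarchy aggregation, differential tables."""

import math

import numpy as np
import pandas as pd
import pytest

import cellfie as cf
from cellfie.errors import CellFieError


def _props(values, column="group"):
    return cf.SampleProperties(pd.DataFrame({column: values}))


def _result(mts, binary, task_ids, sample_ids):
    return cf.CellFieResult(
        mts=pd.DataFrame(np.asarray(mts, float), index=task_ids, columns=sample_ids),
        binary=pd.DataFrame(np.asarray(binary, int), index=task_ids, columns=sample_ids),
    )


def _model(task_specs):
    """task_specs: list of (id, subsystem, system)."""
    return cf.TaskModel(
        tasks=[cf.TaskInfo(t, t, sys, sub) for t, sub, sys in task_specs],
        task_reactions={t: [] for t, _, _ in task_specs},
        gpr_rules={},
    )


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def test_split_by_property_partitions_samples():
    groups = cf.split_by_property(_props(["a", "a", "b"]), "group",
                                  sample_ids=["s1", "s2", "s3"])
    by_name = {g.name: g.sample_ids for g in groups}
    assert by_name == {"a": ["s1", "s2"], "b": ["s3"]}
    assert all(g.origin == "property-split" for g in groups)


def test_split_constant_column_single_group():
    groups = cf.split_by_property(_props(["x", "x"]), "group")
    assert len(groups) == 1 and len(groups[0].sample_ids) == 2


def test_split_many_labels_is_a_partition():
    rng = np.random.default_rng(0)
    labels = [f"cell{i}" for i in range(18)]
    assignment = [labels[i] for i in rng.integers(0, 18, size=120)]
    groups = cf.split_by_property(_props(assignment), "group")
    assert len(groups) == len(set(assignment))
    all_ids = [s for g in groups for s in g.sample_ids]
    assert len(all_ids) == 120 and len(set(all_ids)) == 120


def test_split_unknown_column_rejected():
    with pytest.raises(CellFieError):
        cf.split_by_property(_props(["a"]), "nope")


def test_custom_subgroup_union_and_dedup():
    a = cf.Subgroup("basophil", ["s1", "s2"])
    b = cf.Subgroup("eosinophil", ["s3"])
    c = cf.Subgroup("neutrophil", ["s2", "s4"])
    g = cf.custom_subgroup("Granulocytes", [a, b, c])
    assert g.sample_ids == ["s1", "s2", "s3", "s4"]
    with pytest.raises(CellFieError):
        cf.custom_subgroup("empty")


def test_granulocyte_style_union_matches_label_filter(seeded_fixture):
    _, m, props = seeded_fixture
    groups = {g.name: g for g in cf.split_by_property(props, "group",
                                                      sample_ids=m.sample_ids)}
    union = cf.custom_subgroup("all", list(groups.values()))
    assert sorted(union.sample_ids) == sorted(m.sample_ids)


# ---------------------------------------------------------------------------
# depth aggregation
# ---------------------------------------------------------------------------

@pytest.fixture
def hier():
    model = _model([("T1", "U1", "S1"), ("T2", "U1", "S1"),
                    ("T3", "U2", "S1"), ("T4", "U3", "S2")])
    result = _result([[2, 1], [4, 3], [6, 5], [8, 7]],
                     [[1, 0], [0, 0], [1, 1], [1, 0]],
                     ["T1", "T2", "T3", "T4"], ["a", "b"])
    return model, result


def test_depth3_is_identity(hier):
    model, result = hier
    out = cf.aggregate_depth(result, model, 3)
    pd.testing.assert_frame_equal(out, result.mts)


def test_depth2_mean_of_member_tasks(hier):
    model, result = hier
    out = cf.aggregate_depth(result, model, 2)
    assert list(out.index) == ["U1", "U2", "U3"]
    assert out.at["U1", "a"] == pytest.approx(3.0)  # mean of 2 and 4


def test_activity_aggregates_to_fraction(hier):
    model, result = hier
    out = cf.aggregate_depth(result, model, 1, value_kind="activity")
    # S1 holds T1,T2,T3 with activities {1,0,1} in sample a
    assert out.at["S1", "a"] == pytest.approx(2 / 3)


def test_depth1_equals_direct_task_mean(hier):
    """Tower property under the per-task mean definition: depth 1 equals
    aggregating tasks directly by system."""
    model, result = hier
    out = cf.aggregate_depth(result, model, 1)
    sys_of = {t.id: t.system for t in model.tasks}
    for system in out.index:
        member = [t for t in result.task_ids if sys_of[t] == system]
        np.testing.assert_allclose(out.loc[system].to_numpy(),
                                   result.mts.loc[member].mean(axis=0).to_numpy())


def test_nan_scores_skipped_in_aggregation(hier):
    model, result = hier
    result.mts.at["T1", "a"] = np.nan
    out = cf.aggregate_depth(result, model, 2)
    assert out.at["U1", "a"] == pytest.approx(4.0)  # only T2 remains


def test_bad_depth_and_value_kind_rejected(hier):
    model, result = hier
    with pytest.raises(CellFieError):
        cf.aggregate_depth(result, model, 4)
    with pytest.raises(CellFieError):
        cf.aggregate_depth(result, model, 3, value_kind="zscore")


# ---------------------------------------------------------------------------
# differential
# ---------------------------------------------------------------------------

def _two_group_case(a_vals, b_vals):
    n_a, n_b = len(a_vals), len(b_vals)
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    model = _model([("T1", "U1", "S1")])
    result = _result([list(a_vals) + list(b_vals)], [[0] * (n_a + n_b)],
                     ["T1"], samples)
    ga = cf.Subgroup("A", samples[:n_a])
    gb = cf.Subgroup("B", samples[n_a:])
    return result, model, ga, gb


def test_log2fc_of_group_means():
    result, model, ga, gb = _two_group_case([4, 4], [2, 2])
    table = cf.differential(result, model, ga, gb)
    assert table.at["T1", "log2fc"] == pytest.approx(1.0)
    assert table.at["T1", "mean_a"] == 4 and table.at["T1", "mean_b"] == 2


def test_identical_groups_give_zero_fc_p_one():
    result, model, ga, gb = _two_group_case([3, 3, 3], [3, 3, 3])
    table = cf.differential(result, model, ga, gb)
    assert table.at["T1", "log2fc"] == 0.0
    assert table.at["T1", "p_value"] == 1.0
    assert not table.at["T1", "significant"]


def test_mannwhitney_exact_small_sample():
    # fully separated 3 vs 3: U = 0 is 1 of C(6,3) = 20 assignments per tail
    result, model, ga, gb = _two_group_case([1, 2, 3], [4, 5, 6])
    table = cf.differential(result, model, ga, gb)
    assert table.at["T1", "p_value"] == pytest.approx(0.1)


def test_antisymmetric_in_group_order():
    result, model, ga, gb = _two_group_case([1.0, 2.0, 4.0], [3.0, 5.0, 8.0])
    fwd = cf.differential(result, model, ga, gb)
    rev = cf.differential(result, model, gb, ga)
    assert rev.at["T1", "log2fc"] == pytest.approx(-fwd.at["T1", "log2fc"])
    assert rev.at["T1", "p_value"] == pytest.approx(fwd.at["T1", "p_value"])


def test_nonpositive_mean_yields_missing_fc():
    result, model, ga, gb = _two_group_case([0.0, 0.0], [1.0, 2.0])
    table = cf.differential(result, model, ga, gb)
    assert math.isnan(table.at["T1", "log2fc"])
    assert not table.at["T1", "significant"]


def test_single_sample_group_p_undefined():
    result, model, ga, gb = _two_group_case([5.0], [1.0, 2.0])
    table = cf.differential(result, model, ga, gb)
    assert math.isnan(table.at["T1", "p_value"])


def test_significance_needs_both_p_and_fc():
    # large separation but tiny fold change -> not significant at fc 1.5
    result, model, ga, gb = _two_group_case([10.0, 10.1, 10.2, 10.3, 10.05],
                                            [10.4, 10.5, 10.6, 10.7, 10.8])
    table = cf.differential(result, model, ga, gb, alpha=0.05, fc_threshold=1.5)
    assert table.at["T1", "p_value"] < 0.05
    assert not table.at["T1", "significant"]


def test_overlapping_groups_warn():
    result, model, ga, _ = _two_group_case([1, 2, 3], [4, 5, 6])
    with pytest.warns(UserWarning, match="overlap"):
        cf.differential(result, model, ga, ga)


def test_welch_and_bh_options_run():
    result, model, ga, gb = _two_group_case([1, 2, 3], [4, 5, 6])
    t = cf.differential(result, model, ga, gb, test="welch", adjust="bh")
    assert 0 <= t.at["T1", "p_value"] <= 1
    assert t.at["T1", "p_adjusted"] >= t.at["T1", "p_value"] - 1e-15


def test_unknown_samples_rejected():
    result, model, ga, gb = _two_group_case([1, 2], [3, 4])
    with pytest.raises(CellFieError):
        cf.differential(result, model, cf.Subgroup("x", ["zz"]), gb)


def test_null_calibration_smoke():
    """Two groups drawn i.i.d. from the same distribution: the p<0.05 rate
    stays near the nominal level (full-size check lives in the acceptance
    suite)."""
    rng = np.random.default_rng(0)
    n_items, n = 300, 12
    vals = rng.normal(loc=10.0, size=(n_items, 2 * n))
    task_ids = [f"T{i}" for i in range(n_items)]
    samples = [f"s{j}" for j in range(2 * n)]
    model = _model([(t, "U", "S") for t in task_ids])
    result = _result(vals, np.zeros_like(vals), task_ids, samples)
    table = cf.differential(result, model, cf.Subgroup("A", samples[:n]),
                            cf.Subgroup("B", samples[n:]))
    frac = float((table["p_value"] < 0.05).mean())
    assert 0.01 <= frac <= 0.10


# ---------------------------------------------------------------------------
# group summary
# ---------------------------------------------------------------------------

def test_group_summary_singleton_and_parents(hier):
    model, result = hier
    s = cf.group_summary(result, model, cf.Subgroup("one", ["a"]), "T1")
    assert s["mean_score"] == pytest.approx(2.0)
    assert s["parents"] == {"subsystem": "U1", "system": "S1"}
    assert s["sample_values"] == {"a": 2.0}


def test_group_summary_all_active_fraction(hier):
    model, result = hier
    s = cf.group_summary(result, model, cf.Subgroup("both", ["a", "b"]), "T3")
    assert s["active_fraction"] == 1.0


def test_group_summary_subsystem_parent(hier):
    model, result = hier
    s = cf.group_summary(result, model, cf.Subgroup("both", ["a", "b"]), "U1", depth=2)
    assert s["parents"] == {"system": "S1"}
    with pytest.raises(CellFieError):
        cf.group_summary(result, model, cf.Subgroup("both", ["a"]), "nope", depth=2)
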