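"""Subgroup construction and differential task-activity tables.

Tasks live in a three-level hierarchy — system (depth 1), subsystem (depth
2), task (depth 3). Scores aggregate upward by the unweighted per-sample
mean of member tasks (binary activity aggregates to the active fraction in
[0, 1]). Two subgroups of samples are compared item-by-item at a chosen
depth: group means, log2 fold change of the means, and a two-sided
Mann–Whitney U p-value (Welch's t-test optionally). These tables are the
data behind volcano plots and grouped heatmaps.

MTS values are not comparable across tasks within a sample, so tables are
always organised per item across samples, never ranked across items.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CellFieError
from .model_io import CellFieResult, SampleProperties, TaskModel

__all__ = [
    "Subgroup",
    "split_by_property",
    "custom_subgroup",
    "aggregate_depth",
    "differential",
    "group_summary",
]


@dataclass
class Subgroup:
    name: str
    sample_ids: list
    origin: str = "custom"  # "property-split" | "custom"

    def __post_init__(self):
        if not self.sample_ids:
            raise CellFieError(f"subgroup {self.name!r} is empty")


def split_by_property(props: SampleProperties, column: str,
                      sample_ids=None) -> list:
    """One subgroup per distinct value of a properties column, named by the
    value; the groups partition all samples. ``sample_ids`` supplies the
    sample names aligned with the properties rows (defaults to the row
    positions as S1..Sn)."""
    if column not in props.property_names:
        raise CellFieError(
            f"unknown properties column {column!r}; available: {props.property_names}"
        )
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(props))]
    if len(sample_ids) != len(props):
        raise CellFieError(
            f"{len(sample_ids)} samples but {len(props)} properties rows"
        )
    groups: dict = {}
    for sid, value in zip(sample_ids, props.table[column]):
        groups.setdefault(value, []).append(sid)
    return [Subgroup(name=v, sample_ids=members, origin="property-split")
            for v, members in groups.items()]


def custom_subgroup(name: str, member_groups=None, sample_ids=None) -> Subgroup:
    """Union of existing subgroups and/or explicit sample ids, deduplicated
    with first-seen order."""
    seen, members = set(), []
    for src in (member_groups or []):
        for sid in src.sample_ids:
            if sid not in seen:
                seen.add(sid)
                members.append(sid)
    for sid in (sample_ids or []):
        if sid not in seen:
            seen.add(sid)
            members.append(sid)
    if not members:
        raise CellFieError(f"custom subgroup {name!r} would be empty")
    return Subgroup(name=name, sample_ids=members, origin="custom")


# ---------------------------------------------------------------------------
# Depth aggregation
# ---------------------------------------------------------------------------

def _depth_key(model: TaskModel, depth: int) -> dict:
    if depth == 3:
        return {t.id: t.id for t in model.tasks}
    if depth == 2:
        return {t.id: t.subsystem for t in model.tasks}
    if depth == 1:
        return {t.id: t.system for t in model.tasks}
    raise CellFieError(f"depth must be 1, 2 or 3, got {depth}")


def aggregate_depth(result: CellFieResult, model: TaskModel, depth: int,
                    value_kind: str = "score") -> pd.DataFrame:
    """Items × samples matrix at the requested hierarchy depth.

    Depth 3 returns the task matrix unchanged; depths 2/1 take the
    NaN-skipping per-sample mean over member tasks. ``value_kind="activity"``
    aggregates the binary matrix, so depths 2/1 give the active fraction.
    Item order follows first appearance in the task metadata.
    """
    if value_kind == "score":
        mat = result.mts
    elif value_kind == "activity":
        mat = result.binary.astype(float)
    else:
        raise CellFieError(f"value_kind must be 'score' or 'activity', got {value_kind!r}")
    key = _depth_key(model, depth)
    if depth == 3:
        return mat.copy()
    labels = [key[tid] for tid in result.task_ids]
    order = list(dict.fromkeys(labels))
    agg = mat.groupby(pd.Index(labels, name="item"), sort=False).mean()
    return agg.reindex(order)


# ---------------------------------------------------------------------------
# Differential table
# ---------------------------------------------------------------------------

def _p_value(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # no distributional difference at all
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise CellFieError(f"test must be 'mannwhitney' or 'welch', got {test!r}")


def differential(result: CellFieResult, model: TaskModel,
                 group_a: Subgroup, group_b: Subgroup, *,
                 depth: int = 3, value_kind: str = "score",
                 alpha: float = 0.05, fc_threshold: float = 1.5,
                 test: str = "mannwhitney", adjust: str = "none") -> pd.DataFrame:
    """Per-item group comparison at a hierarchy depth.

    Columns: ``mean_a``, ``mean_b``, ``log2fc`` (of the group means; NaN when
    either mean is ≤ 0), ``p_value`` (two-sided, NaN when a group has < 2
    samples), ``p_adjusted`` (Benjamini–Hochberg when ``adjust="bh"``, else a
    copy), ``significant`` (adjusted p < alpha and linear fold change ≥
    ``fc_threshold`` in either direction). Swapping the groups negates
    ``log2fc`` and leaves p-values unchanged.
    """
    for g in (group_a, group_b):
        missing = [s for s in g.sample_ids if s not in result.sample_ids]
        if missing:
            raise CellFieError(f"subgroup {g.name!r} references unknown samples {missing}")
    if set(group_a.sample_ids) & set(group_b.sample_ids):
        warnings.warn(
            f"subgroups {group_a.name!r} and {group_b.name!r} overlap; "
            "p-values assume independent groups",
            stacklevel=2,
        )
    if adjust not in ("none", "bh"):
        raise CellFieError(f"adjust must be 'none' or 'bh', got {adjust!r}")

    mat = aggregate_depth(result, model, depth, value_kind)
    rows = []
    for item in mat.index:
        a = mat.loc[item, group_a.sample_ids].to_numpy(dtype=float)
        b = mat.loc[item, group_b.sample_ids].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        mean_a = float(np.mean(a)) if a.size else float("nan")
        mean_b = float(np.mean(b)) if b.size else float("nan")
        if mean_a > 0 and mean_b > 0:
            log2fc = math.log2(mean_a / mean_b)
        else:
            log2fc = float("nan")
        rows.append((item, mean_a, mean_b, log2fc, _p_value(a, b, test)))

    table = pd.DataFrame(rows, columns=["item", "mean_a", "mean_b", "log2fc", "p_value"])
    table = table.set_index("item")

    p = table["p_value"].to_numpy()
    p_adj = p.copy()
    if adjust == "bh":
        ok = ~np.isnan(p)
        if ok.any():
            p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table["p_adjusted"] = p_adj
    with np.errstate(invalid="ignore"):
        big_enough_fc = np.abs(table["log2fc"].to_numpy()) >= math.log2(fc_threshold)
    table["significant"] = (table["p_adjusted"].to_numpy() < alpha) & big_enough_fc
    return table


def group_summary(result: CellFieResult, model: TaskModel,
                  group: Subgroup, item: str, depth: int = 3) -> dict:
    """Summary of one hierarchy item over one subgroup: mean score, active
    fraction, per-sample values, and the item's parent terms."""
    scores = aggregate_depth(result, model, depth, "score")
    activity = aggregate_depth(result, model, depth, "activity")
    if item not in scores.index:
        raise CellFieError(f"unknown item {item!r} at depth {depth}")
    vals = scores.loc[item, group.sample_ids].to_numpy(dtype=float)
    act = activity.loc[item, group.sample_ids].to_numpy(dtype=float)

    parents: dict = {}
    if depth == 3:
        t = model.task_by_id(item)
        parents = {"subsystem": t.subsystem, "system": t.system}
    elif depth == 2:
        systems = {t.system for t in model.tasks if t.subsystem == item}
        parents = {"system": sorted(systems)[0]}
    return {
        "item": item,
        "depth": depth,
        "group": group.name,
        "mean_score": float(np.nanmean(vals)) if vals.size else float("nan"),
        "active_fraction": float(np.nanmean(act)) if act.size else float("nan"),
        "sample_values": {s: float(v) for s, v in zip(group.sample_ids, vals)},
        "parents": parents,
    }
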