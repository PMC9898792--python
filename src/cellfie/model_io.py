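"""Input/output for expression data, sample properties, task-model bundles
and result files.

Expression matrices are comma-separated text with gene identifiers
(Entrez-style integer strings, typically) in the first column, one column per
sample, and an optional header row of sample names. The task model is a
bundle of three comma-separated files:

``taskInfo.csv``       — ``id,name,system,subsystem`` (one row per task)
``taskReactions.csv``  — ``task_id,reaction_id`` (ordered reaction list per task)
``gprRules.csv``       — ``reaction_id,rule_text`` (rule may be blank)

Result files follow the canonical four-file layout: headerless ``score.csv``
and ``scoreBinary.csv`` (rows in taskInfo order, columns in input sample
order), ``taskInfo.csv`` metadata, and ``detailScoring.csv`` with one
8-column block per sample concatenated horizontally.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpr
from .errors import FormatError, GPRSyntaxError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "SampleProperties",
    "TaskInfo",
    "TaskModel",
    "DetailRecord",
    "CellFieResult",
    "read_expression",
    "write_expression",
    "collapse_duplicate_genes",
    "add_pseudocount",
    "read_properties",
    "write_properties",
    "read_task_model",
    "write_task_model",
    "write_results",
    "read_score_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of nonnegative expression values (e.g. TPM).

    ``data`` is a DataFrame with gene-id strings as index and sample-id
    strings as columns. Duplicate gene ids are permitted until
    :func:`collapse_duplicate_genes`; duplicate sample ids never are.
    """

    data: pd.DataFrame

    def __post_init__(self):
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dup = sorted({c for c in cols if cols.count(c) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative expression value {vals[i, j]} for gene "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SampleProperties:
    """Per-sample phenotype annotations, row-aligned with the expression
    matrix's sample columns."""

    table: pd.DataFrame  # one row per sample, columns = property names

    @property
    def property_names(self) -> list:
        return list(self.table.columns)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class TaskInfo:
    id: str
    name: str
    system: str
    subsystem: str


@dataclass
class TaskModel:
    """Task hierarchy + task→reaction map + reaction→GPR rules."""

    tasks: list  # of TaskInfo, defining row order of the score matrices
    task_reactions: dict  # task id -> ordered list of reaction ids
    gpr_rules: dict  # reaction id -> GPRRule

    @property
    def task_ids(self) -> list:
        return [t.id for t in self.tasks]

    @property
    def reaction_ids(self) -> list:
        seen, out = set(), []
        for tid in self.task_ids:
            for rid in self.task_reactions.get(tid, []):
                if rid not in seen:
                    seen.add(rid)
                    out.append(rid)
        return out

    @property
    def gene_universe(self) -> set:
        out: set = set()
        for rule in self.gpr_rules.values():
            out |= gpr.genes_in(rule)
        return out

    def task_by_id(self, tid: str) -> TaskInfo:
        for t in self.tasks:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def validate(self) -> None:
        ids = self.task_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate task ids in task metadata")
        for tid in self.task_reactions:
            if tid not in set(ids):
                raise ValidationError(f"task_reactions references unknown task {tid!r}")
        missing = [
            rid
            for rids in self.task_reactions.values()
            for rid in rids
            if rid not in self.gpr_rules
        ]
        if missing:
            raise ValidationError(
                "reactions missing from the GPR rule file: " + ", ".join(sorted(set(missing)))
            )
        # a subsystem may not sit under two systems (3-level hierarchy)
        sub_sys: dict = {}
        for t in self.tasks:
            prev = sub_sys.setdefault(t.subsystem, t.system)
            if prev != t.system:
                raise ValidationError(
                    f"subsystem {t.subsystem!r} appears under systems {prev!r} and {t.system!r}"
                )


@dataclass(frozen=True)
class DetailRecord:
    """One (sample, task, essential reaction) record of the detail output."""

    sample_id: str
    task_id: str
    task_score: float
    binary_score: int
    reaction_id: str
    ral: float
    determinant_gene: str
    original_expression: float


@dataclass
class CellFieResult:
    """Pipeline output: task × sample score matrices plus per-reaction detail.

    ``mts`` may contain NaN where a task has no evaluable reaction; the
    binary matrix is 0 there.
    """

    mts: pd.DataFrame  # tasks × samples, NaN = undefined
    binary: pd.DataFrame  # tasks × samples in {0,1}
    details: list = field(default_factory=list)  # of DetailRecord

    @property
    def task_ids(self) -> list:
        return list(self.mts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.mts.columns)


# ---------------------------------------------------------------------------
# Expression matrix I/O and preprocessing
# ---------------------------------------------------------------------------

def _is_number(s: str) -> bool:
    try:
        float(s)
    except (TypeError, ValueError):
        return False
    return True


def read_expression(path, has_header="auto") -> ExpressionMatrix:
    """Read a comma-separated expression matrix.

    First column: gene identifiers. Remaining columns: one per sample.
    ``has_header`` may be True, False, or ``"auto"``: auto treats the first
    row as a header iff any cell beyond column 1 is non-numeric. Without a
    header, samples are named ``S1..Sn``.
    """
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    if width < 2:
        raise FormatError(f"{path}: need at least one sample column")
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {width}"
            )

    if has_header == "auto":
        has_header = any(not _is_number(c) for c in rows[0][1:])
    if has_header:
        sample_ids = [c.strip() for c in rows[0][1:]]
        data_rows = rows[1:]
    else:
        sample_ids = [f"S{i + 1}" for i in range(width - 1)]
        data_rows = rows

    if not data_rows:
        raise FormatError(f"{path}: no data rows")

    gene_ids, values = [], []
    for i, row in enumerate(data_rows):
        gene_ids.append(row[0].strip())
        vals = []
        for j, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at data row {i + 1}, "
                    f"column {sample_ids[j]!r}"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"{path}: negative value {v} at data row {i + 1} "
                    f"(gene {row[0].strip()!r}), column {sample_ids[j]!r}"
                )
            vals.append(v)
        values.append(vals)

    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(df)


def _fmt_float(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NaN"
    f = float(v)
    if f == int(f) and abs(f) < 1e16:
        return str(int(f))
    return repr(f)  # shortest round-trip decimal


def write_expression(m: ExpressionMatrix, path, header: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(["gene"] + m.sample_ids)
        for gid, row in zip(m.gene_ids, m.values):
            w.writerow([gid] + [_fmt_float(v) for v in row])


def collapse_duplicate_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Aggregate duplicate gene ids by the per-sample maximum, keeping the
    first-occurrence row order. Idempotent."""
    if m.data.index.is_unique:
        return ExpressionMatrix(m.data.copy())
    collapsed = m.data.groupby(level=0, sort=False).max()
    return ExpressionMatrix(collapsed)


def add_pseudocount(m: ExpressionMatrix, eps: float = 1e-5) -> ExpressionMatrix:
    """Shift every value by ``eps`` ≥ 0 so downstream logs of zeros are
    avoided (the standard fix for all-zero genes)."""
    if eps < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {eps}")
    return ExpressionMatrix(m.data + eps)


# ---------------------------------------------------------------------------
# Sample properties
# ---------------------------------------------------------------------------

def read_properties(path) -> SampleProperties:
    table = pd.read_csv(path, dtype=str)
    if table.shape[1] == 0:
        raise FormatError(f"{path}: properties file has no columns")
    return SampleProperties(table)


def write_properties(props: SampleProperties, path) -> None:
    props.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Task-model bundle
# ---------------------------------------------------------------------------

def _read_csv_checked(path, required_cols):
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_task_model(task_info_path, task_reactions_path, gpr_path) -> TaskModel:
    """Read and cross-validate the three model files."""
    info = _read_csv_checked(task_info_path, ["id", "name", "system", "subsystem"])
    tr = _read_csv_checked(task_reactions_path, ["task_id", "reaction_id"])
    rules_df = _read_csv_checked(gpr_path, ["reaction_id", "rule_text"])

    tasks = [
        TaskInfo(r["id"], r["name"], r["system"], r["subsystem"])
        for _, r in info.iterrows()
    ]
    task_reactions: dict = {t.id: [] for t in tasks}
    for _, r in tr.iterrows():
        tid = r["task_id"]
        if tid not in task_reactions:
            raise ValidationError(
                f"{task_reactions_path}: reaction {r['reaction_id']!r} references "
                f"unknown task {tid!r}"
            )
        task_reactions[tid].append(r["reaction_id"])

    gpr_rules: dict = {}
    for _, r in rules_df.iterrows():
        rid = r["reaction_id"]
        try:
            gpr_rules[rid] = gpr.parse_gpr(r["rule_text"])
        except GPRSyntaxError as exc:
            raise GPRSyntaxError(f"reaction {rid!r}: {exc}") from exc

    model = TaskModel(tasks=tasks, task_reactions=task_reactions, gpr_rules=gpr_rules)
    model.validate()
    return model


def write_task_model(model: TaskModel, out_dir) -> tuple:
    """Write the three-file model bundle; returns the three paths."""
    os.makedirs(out_dir, exist_ok=True)
    info_path = os.path.join(out_dir, "taskInfo.csv")
    tr_path = os.path.join(out_dir, "taskReactions.csv")
    gpr_path = os.path.join(out_dir, "gprRules.csv")
    with open(info_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "system", "subsystem"])
        for t in model.tasks:
            w.writerow([t.id, t.name, t.system, t.subsystem])
    with open(tr_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["task_id", "reaction_id"])
        for tid in model.task_ids:
            for rid in model.task_reactions[tid]:
                w.writerow([tid, rid])
    with open(gpr_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reaction_id", "rule_text"])
        for rid, rule in model.gpr_rules.items():
            w.writerow([rid, rule.source_text])
    return info_path, tr_path, gpr_path


# ---------------------------------------------------------------------------
# Result files
# ---------------------------------------------------------------------------

_DETAIL_COLS = [
    "sample",
    "task",
    "score",
    "binary",
    "reaction",
    "RAL",
    "determinant",
    "expression",
]


def write_results(result: CellFieResult, model: TaskModel, out_dir,
                  detail_header: bool = True) -> tuple:
    """Write the four result files into ``out_dir``.

    ``score.csv`` / ``scoreBinary.csv`` are headerless, rows in taskInfo
    order and columns in input sample order; undefined scores serialize as
    ``NaN`` (score) and ``0`` (binary). ``detailScoring.csv`` carries one row
    per (task, essential reaction) with an 8-column block per sample
    concatenated left to right in sample order (columns 9–16 describe sample
    2, and so on).
    """
    if list(result.mts.index) != model.task_ids:
        raise ValidationError("result task order does not match the model's taskInfo order")
    os.makedirs(out_dir, exist_ok=True)
    score_path = os.path.join(out_dir, "score.csv")
    binary_path = os.path.join(out_dir, "scoreBinary.csv")
    info_path = os.path.join(out_dir, "taskInfo.csv")
    detail_path = os.path.join(out_dir, "detailScoring.csv")

    with open(score_path, "w", newline="") as fh:
        w = csv.writer(fh)
        for row in result.mts.to_numpy():
            w.writerow([_fmt_float(v) for v in row])
    with open(binary_path, "w", newline="") as fh:
        w = csv.writer(fh)
        for row in result.binary.to_numpy():
            w.writerow([str(int(v)) for v in row])
    with open(info_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "system", "subsystem"])
        for t in model.tasks:
            w.writerow([t.id, t.name, t.system, t.subsystem])

    # group detail records by (task, reaction); one output row per pair
    by_pair: dict = {}
    for rec in result.details:
        by_pair.setdefault((rec.task_id, rec.reaction_id), {})[rec.sample_id] = rec
    samples = result.sample_ids
    with open(detail_path, "w", newline="") as fh:
        w = csv.writer(fh)
        if detail_header:
            header = []
            for k in range(1, len(samples) + 1):
                header.extend(f"{c}_{k}" for c in _DETAIL_COLS)
            w.writerow(header)
        for tid in model.task_ids:
            for rid in model.task_reactions[tid]:
                per_sample = by_pair.get((tid, rid))
                if not per_sample:
                    continue  # reaction not evaluable (empty rule / no scored gene)
                row = []
                for sid in samples:
                    rec = per_sample.get(sid)
                    if rec is None:
                        row.extend([sid, tid, "NaN", "0", rid, "NaN", "", "NaN"])
                    else:
                        row.extend([
                            rec.sample_id,
                            rec.task_id,
                            _fmt_float(rec.task_score),
                            str(int(rec.binary_score)),
                            rec.reaction_id,
                            _fmt_float(rec.ral),
                            rec.determinant_gene,
                            _fmt_float(rec.original_expression),
                        ])
                w.writerow(row)
    return score_path, binary_path, info_path, detail_path


def read_score_matrix(path) -> np.ndarray:
    """Read a headerless numeric score matrix back into an array."""
    with open(path, newline="") as fh:
        rows = [[float(c) for c in row] for row in csv.reader(fh) if row]
    if not rows:
        raise FormatError(f"{path}: empty score matrix")
    return np.array(rows, dtype=float)
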