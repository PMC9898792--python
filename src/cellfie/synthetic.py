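"""Deterministic toy fixtures and independent brute-force oracles.

The generators emulate the structure of real inputs at toy scale: a task
model (3-level hierarchy, task→reaction map, random GPR rules) and an
expression matrix with planted group structure — designated tasks' genes are
drawn from a high log-normal component in one group of samples and a low
component in another, so the expected binary activity matrix is known by
construction. Log-normal components mimic the skew of TPM-like data.

Edge cases are planted deliberately so degenerate paths need no handcrafted
fixtures: at least one gene shared between two tasks (promiscuous, exercising
the specificity weight), one empty-rule reaction, and one rule gene absent
from the expression matrix (exercising the missing-gene policy).

The oracles (`evaluate_rule_tree`, `oracle_pipeline`) are straight-line,
loop-based re-derivations that share no code with the parser or the scoring
pipeline; they exist only to cross-check the implementation in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpr
from .errors import CellFieError
from .model_io import ExpressionMatrix, SampleProperties, TaskInfo, TaskModel
from .thresholding import ThresholdSpec

__all__ = [
    "FixtureDesign",
    "generate_model",
    "generate_expression",
    "random_rule_tree",
    "render_rule",
    "evaluate_rule_tree",
    "oracle_pipeline",
]

ORPHAN_GENE = "999"  # appears in one rule but never in the expression matrix


@dataclass
class FixtureDesign:
    """Parameters of a synthetic study.

    ``planted_activity`` maps (task id, group name) to ``"high"`` or
    ``"low"``; when None, an alternating pattern over tasks × groups is used.
    ``high_tpm``/``low_tpm``/``background_tpm`` are the log-normal medians of
    the three expression components (100-fold high/low separation by
    default); ``noise_sd`` is the Gaussian sd on the log scale.
    """

    n_genes: int = 60
    n_reactions: int = 24
    n_tasks: int = 8
    n_systems: int = 2
    n_subsystems: int = 4
    rule_depth_max: int = 3
    samples_per_group: dict = field(default_factory=lambda: {"A": 4, "B": 4})
    planted_activity: dict | None = None
    noise_sd: float = 0.25
    high_tpm: float = 200.0
    low_tpm: float = 2.0
    background_tpm: float = 20.0
    seed: int = 7

    def __post_init__(self):
        if min(self.n_genes, self.n_reactions, self.n_tasks,
               self.n_systems, self.n_subsystems) <= 0:
            raise CellFieError("all fixture counts must be positive")
        if self.n_tasks < self.n_subsystems or self.n_subsystems < self.n_systems:
            raise CellFieError("need n_tasks >= n_subsystems >= n_systems")
        if self.n_reactions < self.n_tasks:
            raise CellFieError("need at least one reaction per task")
        if self.n_genes < 3 * self.n_tasks:
            raise CellFieError("need at least 3 genes per task")
        if self.noise_sd < 0:
            raise CellFieError("noise_sd must be nonnegative")
        if not self.samples_per_group or min(self.samples_per_group.values()) <= 0:
            raise CellFieError("each group needs at least one sample")

    @property
    def task_ids(self) -> list:
        return [f"T{i + 1:02d}" for i in range(self.n_tasks)]

    @property
    def groups(self) -> list:
        return list(self.samples_per_group)

    @property
    def gene_ids(self) -> list:
        return [str(1001 + i) for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list:
        return [f"{g}_{i + 1}" for g in self.groups
                for i in range(self.samples_per_group[g])]

    def planted(self) -> dict:
        """Full (task, group) → high|low design, defaulting to an
        alternating checkerboard."""
        if self.planted_activity is not None:
            return dict(self.planted_activity)
        out = {}
        for i, tid in enumerate(self.task_ids):
            for j, g in enumerate(self.groups):
                out[(tid, g)] = "high" if (i + j) % 2 == 0 else "low"
        return out


# ---------------------------------------------------------------------------
# Model generation
# ---------------------------------------------------------------------------

def _task_gene_pools(d: FixtureDesign) -> dict:
    """Disjoint per-task gene pools (leftover genes stay background-only).
    The first gene of one pool is additionally shared into a second task with
    the same planted pattern, making it promiscuous without breaking the
    planted design."""
    pool_size = d.n_genes // d.n_tasks
    genes = d.gene_ids
    return {tid: genes[i * pool_size:(i + 1) * pool_size]
            for i, tid in enumerate(d.task_ids)}


def _pattern_of(d: FixtureDesign, tid: str) -> tuple:
    planted = d.planted()
    return tuple(planted.get((tid, g)) for g in d.groups)


def _promiscuous_pair(d: FixtureDesign) -> tuple:
    """Two distinct tasks with identical planted pattern, if any; otherwise
    the first two tasks (sharing is still guaranteed, exact recovery only
    with compatible patterns)."""
    tids = d.task_ids
    for i in range(len(tids)):
        for j in range(i + 1, len(tids)):
            if _pattern_of(d, tids[i]) == _pattern_of(d, tids[j]):
                return tids[i], tids[j]
    return tids[0], tids[1]


def _random_rule_text(rng, pool: list, depth_max: int) -> str:
    """One random rule over a task's gene pool: single gene, AND chain, OR
    alternation, or OR-of-ANDs depending on the allowed depth."""
    forms = ["single"]
    if depth_max >= 2 and len(pool) >= 2:
        forms += ["and", "or"]
    if depth_max >= 3 and len(pool) >= 4:
        forms += ["or_of_ands"]
    form = forms[rng.integers(len(forms))]
    pick = lambda k: [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    if form == "single":
        return pick(1)[0]
    if form == "and":
        return " and ".join(pick(int(rng.integers(2, min(4, len(pool) + 1)))))
    if form == "or":
        return " or ".join(pick(2))
    g = pick(4)
    return f"({g[0]} and {g[1]}) or ({g[2]} and {g[3]})"


def generate_model(d: FixtureDesign) -> TaskModel:
    """Seeded toy task model. Same design → identical model every time."""
    rng = np.random.default_rng(d.seed)
    subsystems = [f"SUBSYS{i + 1}" for i in range(d.n_subsystems)]
    systems = [f"SYS{i % d.n_systems + 1}" for i in range(d.n_subsystems)]
    tasks = []
    for i, tid in enumerate(d.task_ids):
        k = i % d.n_subsystems
        tasks.append(TaskInfo(id=tid, name=f"Synthetic task {i + 1}",
                              system=systems[k], subsystem=subsystems[k]))

    # reactions round-robin over tasks
    task_reactions = {tid: [] for tid in d.task_ids}
    rxn_ids = [f"R{i + 1:03d}" for i in range(d.n_reactions)]
    for i, rid in enumerate(rxn_ids):
        task_reactions[d.task_ids[i % d.n_tasks]].append(rid)

    pools = _task_gene_pools(d)
    t_shared_src, t_shared_dst = _promiscuous_pair(d)
    shared_gene = pools[t_shared_src][0]

    rules = {}
    for tid in d.task_ids:
        pool = pools[tid]
        for k, rid in enumerate(task_reactions[tid]):
            rules[rid] = _random_rule_text(rng, pool, d.rule_depth_max)
            if tid == t_shared_src and k == 0:
                # guarantee the shared gene occurs in its home task too
                rules[rid] = f"{shared_gene} or {rules[rid]}"
            if tid == t_shared_dst and k == 0:
                # plant the promiscuous gene as an isozyme alternative
                rules[rid] = f"{pool[0]} or {shared_gene}"
            if tid == d.task_ids[1 % d.n_tasks] and k == 0 and tid != t_shared_dst:
                rules[rid] = f"{pool[0]} or {ORPHAN_GENE}"
    # a gene referenced by a rule but absent from the expression matrix
    if not any(ORPHAN_GENE in r for r in rules.values()):
        first = task_reactions[d.task_ids[0]][0]
        rules[first] = f"{rules[first]} or {ORPHAN_GENE}" if rules[first] else ORPHAN_GENE
    # one empty-rule reaction, planted in a task that keeps other reactions
    for tid in d.task_ids:
        if len(task_reactions[tid]) >= 2:
            rules[task_reactions[tid][-1]] = ""
            break

    gpr_rules = {rid: gpr.parse_gpr(text) for rid, text in rules.items()}
    model = TaskModel(tasks=tasks, task_reactions=task_reactions, gpr_rules=gpr_rules)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

def generate_expression(model: TaskModel, d: FixtureDesign):
    """Seeded expression matrix + properties table with planted structure.

    Genes of a task planted high in a group draw from the high log-normal
    component in that group's samples, low from the low component; genes in
    no planted task (or in no rule at all) draw from the background
    component. The orphan rule gene is deliberately left out of the matrix.
    """
    rng = np.random.default_rng(d.seed + 1)
    planted = d.planted()

    # gene → planted tasks containing it
    gene_tasks: dict = {}
    for tid in model.task_ids:
        task_genes = set()
        for rid in model.task_reactions[tid]:
            task_genes |= gpr.genes_in(model.gpr_rules[rid])
        for g in task_genes:
            gene_tasks.setdefault(g, []).append(tid)

    genes = d.gene_ids  # excludes the orphan by construction
    samples, groups_of = [], []
    for g in d.groups:
        for i in range(d.samples_per_group[g]):
            samples.append(f"{g}_{i + 1}")
            groups_of.append(g)

    def median_for(gene: str, group: str) -> float:
        for tid in gene_tasks.get(gene, []):
            level = planted.get((tid, group))
            if level == "high":
                return d.high_tpm
            if level == "low":
                return d.low_tpm
        return d.background_tpm

    values = np.empty((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        for j, (sid, grp) in enumerate(zip(samples, groups_of)):
            med = median_for(gene, grp)
            values[i, j] = med * math.exp(rng.normal(0.0, d.noise_sd))

    m = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    props = SampleProperties(pd.DataFrame({"sample_id": samples, "group": groups_of}))
    return m, props


def expected_binary(model: TaskModel, d: FixtureDesign) -> pd.DataFrame:
    """The planted (task × sample) binary design matrix, with tasks having no
    evaluable reaction forced to 0 — what a noise-free run should reproduce."""
    planted = d.planted()
    groups_of = {sid: sid.rsplit("_", 1)[0] for sid in d.sample_ids}
    out = pd.DataFrame(0, index=model.task_ids, columns=d.sample_ids, dtype=int)
    for tid in model.task_ids:
        evaluable = any(
            gpr.genes_in(model.gpr_rules[rid]) - {ORPHAN_GENE}
            for rid in model.task_reactions[tid]
        )
        for sid in d.sample_ids:
            level = planted.get((tid, groups_of[sid]))
            out.at[tid, sid] = int(evaluable and level == "high")
    return out


# ---------------------------------------------------------------------------
# Random rule trees + brute-force evaluator (GPR oracle)
# ---------------------------------------------------------------------------

def random_rule_tree(rng, max_depth: int = 4, max_genes: int = 8):
    """A random GPR expression as nested tuples ('and'|'or', children) with
    gene-id strings at the leaves — built directly, no parser involved."""
    genes = [f"G{i}" for i in range(1, max_genes + 1)]

    def build(depth):
        if depth >= max_depth or rng.random() < 0.4:
            return genes[rng.integers(len(genes))]
        op = "and" if rng.random() < 0.5 else "or"
        n = int(rng.integers(2, 4))
        return (op, tuple(build(depth + 1) for _ in range(n)))

    tree = build(0)
    if isinstance(tree, str) and rng.random() < 0.5:
        tree = ("or", (tree, genes[rng.integers(len(genes))]))
    return tree


def render_rule(tree) -> str:
    """Rule text for a tree, parenthesizing only where precedence requires
    (an OR child inside an AND)."""
    if isinstance(tree, str):
        return tree
    op, children = tree
    parts = []
    for c in children:
        text = render_rule(c)
        if op == "and" and isinstance(c, tuple) and c[0] == "or":
            text = f"({text})"
        parts.append(text)
    return f" {op} ".join(parts)


def evaluate_rule_tree(tree, scores: dict, missing_policy: str = "drop"):
    """Brute-force recursive interpreter over the tuple tree: AND = min,
    OR = max, ties to the lexicographically smallest determinant. Returns
    (value, determinant) or None. Independent of the parser and evaluator."""
    if isinstance(tree, str):
        if tree in scores:
            return float(scores[tree]), tree
        if missing_policy == "zero":
            return 0.0, tree
        return None
    op, children = tree
    results = [r for r in (evaluate_rule_tree(c, scores, missing_policy)
                           for c in children) if r is not None]
    if not results:
        return None
    pick = min if op == "and" else max
    best_value = pick(v for v, _ in results)
    best_gene = min(g for v, g in results if v == best_value)
    return best_value, best_gene


# ---------------------------------------------------------------------------
# End-to-end brute-force pipeline (oracle)
# ---------------------------------------------------------------------------

def _oracle_percentile(values: list, p: float) -> float:
    """Linear interpolation between closest ranks, inclusive."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    rank = p / 100.0 * (len(xs) - 1)
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def _oracle_eval_node(node, scores, policy):
    if isinstance(node, gpr.GeneRef):
        if node.gene in scores:
            return float(scores[node.gene]), node.gene
        if policy == "zero":
            return 0.0, node.gene
        return None
    results = [r for r in (_oracle_eval_node(c, scores, policy)
                           for c in node.children) if r is not None]
    if not results:
        return None
    pick = min if isinstance(node, gpr.AndNode) else max
    best = pick(v for v, _ in results)
    return best, min(g for v, g in results if v == best)


def oracle_pipeline(m: ExpressionMatrix, model: TaskModel, spec: ThresholdSpec,
                    missing_policy: str = "drop", log_base: str = "e"):
    """Loop-based re-derivation of thresholds → gene scores → RAL →
    specificity → MTS/binary, for cross-checking at toy scale (≤200 genes).
    Returns (mts, binary) as plain ndarrays in task/sample order."""
    base = {"e": math.e, "2": 2.0, "10": 10.0}[log_base]
    genes = m.gene_ids
    samples = m.sample_ids
    expr = {(g, s): float(m.data.at[g, s]) for g in genes for s in samples}
    pooled = [expr[(g, s)] for g in genes for s in samples]

    # thresholds
    thr = {}
    for g in genes:
        if spec.family == "global":
            if spec.global_mode == "value":
                t = float(spec.global_value)
            else:
                t = _oracle_percentile(pooled, spec.global_percentile)
        else:
            mean = sum(expr[(g, s)] for s in samples) / len(samples)
            if spec.local_mode == "mean":
                t = mean
            else:
                if spec.bound_mode == "value":
                    lo, hi = spec.lower, spec.upper
                else:
                    lo = _oracle_percentile(pooled, spec.lower)
                    hi = _oracle_percentile(pooled, spec.upper)
                t = min(max(mean, lo), hi)
        thr[g] = max(t, 1e-12)

    # gene scores
    gs = {(g, s): 5.0 * math.log(1.0 + expr[(g, s)] / thr[g], base)
          for g in genes for s in samples}

    # reaction activity
    ral, det = {}, {}
    for rid, rule in model.gpr_rules.items():
        for s in samples:
            scores = {g: gs[(g, s)] for g in genes}
            r = None if rule.root is None else _oracle_eval_node(rule.root, scores, missing_policy)
            if r is not None:
                ral[(rid, s)] = r[0]
                det[(rid, s)] = r[1]

    # specificity: distinct tasks per (gene, sample)
    s_weight = {}
    for s in samples:
        counts = {}
        for tid in model.task_ids:
            for rid in model.task_reactions[tid]:
                if (rid, s) in det:
                    counts.setdefault(det[(rid, s)], set()).add(tid)
        for g, ts in counts.items():
            s_weight[(g, s)] = 1.0 / len(ts)

    # task scores
    cutoff = 5.0 * math.log(2.0, base)
    mts = np.full((len(model.task_ids), len(samples)), np.nan)
    binary = np.zeros((len(model.task_ids), len(samples)), dtype=int)
    for i, tid in enumerate(model.task_ids):
        for j, s in enumerate(samples):
            vals, weighted = [], []
            for rid in model.task_reactions[tid]:
                if (rid, s) in ral:
                    v = ral[(rid, s)]
                    vals.append(v)
                    weighted.append(s_weight[(det[(rid, s)], s)] * v)
            if vals:
                mts[i, j] = sum(weighted) / len(vals)
                binary[i, j] = int(sum(vals) / len(vals) > cutoff)
    return mts, binary
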