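"""The core scoring pipeline.

Five steps turn an expression matrix into per-sample metabolic task scores:

1. **Gene score** — for each gene g and sample j, with threshold t(g),

       GeneScore = 5 * log(1 + e / t)

   (natural log by default; the base is configurable and also rescales the
   binary cutoff below). The score is 0 at e = 0 and equals 5*log(2) exactly
   at the threshold.

2. **Reaction activity level (RAL)** — gene scores are mapped onto each
   reaction by evaluating its GPR rule with AND = min / OR = max. The gene
   that survives the collapse is the reaction's *main determinant* and its
   score is the RAL.

3. **Specificity S** — promiscuous genes (main determinant in several tasks)
   are down-weighted: S(g) = 1 / (# distinct tasks in which g acts as main
   determinant of at least one evaluable essential reaction). Counted per
   sample by default, since determinants are sample-dependent; a pooled
   dataset-wide scope is available.

4. **Metabolic task score (MTS)** — the mean scaled RAL over the task's
   evaluable essential reactions:  MTS = Σ S*RAL / #reactions.

5. **Binary activity** — a task is called active when the *unweighted* mean
   of its RALs is strictly greater than 5*log(2).

MTS values are comparable across samples but not across tasks within a
sample (tasks differ in baseline gene expression); the binary form exists
for intra-sample comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gpr
from .errors import CellFieError
from .model_io import CellFieResult, DetailRecord, ExpressionMatrix, TaskModel
from .thresholding import DEFAULT_SPEC, GeneThresholds, ThresholdSpec, compute_thresholds

__all__ = [
    "LOG_BASES",
    "binary_cutoff",
    "gene_score",
    "gene_score_matrix",
    "ReactionActivityTable",
    "reaction_activity",
    "SpecificityTable",
    "specificity",
    "task_scores",
    "run_cellfie",
]

logger = logging.getLogger("cellfie")

LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


def _resolve_base(log_base) -> float:
    if isinstance(log_base, str):
        try:
            return LOG_BASES[log_base]
        except KeyError:
            raise ValueError(f"log_base must be one of {sorted(LOG_BASES)} or a float, got {log_base!r}") from None
    b = float(log_base)
    if b <= 0 or b == 1:
        raise ValueError(f"invalid logarithm base {b}")
    return b


def binary_cutoff(log_base="e") -> float:
    """The activity cutoff 5*log(2) in the configured base."""
    return 5.0 * math.log(2.0, _resolve_base(log_base))


def gene_score(e: float, t: float, log_base="e") -> float:
    """5*log(1 + e/t): 0 at e=0, 5*log(2) at e=t, strictly increasing in e."""
    if t <= 0:
        raise ValueError(f"threshold must be positive, got {t}")
    if e < 0:
        raise ValueError(f"expression must be nonnegative, got {e}")
    return 5.0 * math.log(1.0 + e / t, _resolve_base(log_base))


def gene_score_matrix(m: ExpressionMatrix, thresholds: GeneThresholds,
                      log_base="e") -> pd.DataFrame:
    """Vectorized gene scores for every (gene, sample)."""
    t = thresholds.per_gene.reindex(m.data.index)
    if t.isna().any():
        missing = list(t.index[t.isna()])[:5]
        raise CellFieError(f"thresholds missing for genes {missing}")
    base = _resolve_base(log_base)
    ratio = m.data.div(t, axis=0)
    return 5.0 * np.log1p(ratio) / math.log(base)


# ---------------------------------------------------------------------------
# Reaction activity
# ---------------------------------------------------------------------------

@dataclass
class ReactionActivityTable:
    """Per (reaction, sample): RAL and main determinant.

    ``ral`` is NaN and ``determinant`` is None where the reaction is not
    evaluable (empty rule, or no rule gene scored under the drop policy).
    """

    ral: pd.DataFrame  # reactions × samples, float
    determinant: pd.DataFrame  # reactions × samples, object

    @property
    def evaluable(self) -> pd.DataFrame:
        return self.ral.notna()


def reaction_activity(model: TaskModel, gs: pd.DataFrame,
                      missing_policy: str = "drop") -> ReactionActivityTable:
    """Evaluate every reaction's GPR rule over each sample's gene scores."""
    rxns = model.reaction_ids
    samples = list(gs.columns)
    ral = pd.DataFrame(np.nan, index=rxns, columns=samples, dtype=float)
    det = pd.DataFrame(np.full((len(rxns), len(samples)), None, dtype=object),
                       index=rxns, columns=samples)
    for sid in samples:
        scores = gs[sid].to_dict()
        for rid in rxns:
            res = gpr.evaluate(model.gpr_rules[rid], scores, missing_policy)
            if res is not None:
                ral.at[rid, sid] = res.value
                det.at[rid, sid] = res.determinant
    return ReactionActivityTable(ral=ral, determinant=det)


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

@dataclass
class SpecificityTable:
    """Per (gene, sample) specificity weight S = 1/k, k = number of distinct
    tasks in which the gene is main determinant of ≥1 evaluable essential
    reaction. Genes with k = 0 are absent (NaN)."""

    s: pd.DataFrame  # genes × samples, float, NaN where gene never determines


def specificity(model: TaskModel, ra: ReactionActivityTable,
                scope: str = "sample") -> SpecificityTable:
    if scope not in ("sample", "dataset"):
        raise ValueError(f"scope must be 'sample' or 'dataset', got {scope!r}")
    samples = list(ra.ral.columns)
    # tasks in which each gene acts as a determinant, per sample
    per_sample_tasks: dict = {sid: {} for sid in samples}
    for tid in model.task_ids:
        for rid in model.task_reactions[tid]:
            for sid in samples:
                g = ra.determinant.at[rid, sid]
                if g is not None:
                    per_sample_tasks[sid].setdefault(g, set()).add(tid)

    genes = sorted({g for d in per_sample_tasks.values() for g in d})
    s = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)
    if scope == "dataset":
        pooled: dict = {}
        for d in per_sample_tasks.values():
            for g, ts in d.items():
                pooled.setdefault(g, set()).update(ts)
        for sid in samples:
            for g in per_sample_tasks[sid]:
                s.at[g, sid] = 1.0 / len(pooled[g])
    else:
        for sid in samples:
            for g, ts in per_sample_tasks[sid].items():
                s.at[g, sid] = 1.0 / len(ts)
    return SpecificityTable(s=s)


# ---------------------------------------------------------------------------
# Task scores
# ---------------------------------------------------------------------------

def task_scores(model: TaskModel, ra: ReactionActivityTable,
                st: SpecificityTable, log_base="e") -> tuple:
    """MTS and binary activity per (task, sample).

    MTS is the specificity-weighted mean RAL over the task's evaluable
    essential reactions; the binary call uses the unweighted mean RAL with a
    strict ``> 5*log(2)`` cutoff. A task with no evaluable reaction gets
    MTS = NaN and binary = 0.
    """
    samples = list(ra.ral.columns)
    cutoff = binary_cutoff(log_base)
    mts = pd.DataFrame(np.nan, index=model.task_ids, columns=samples, dtype=float)
    binary = pd.DataFrame(0, index=model.task_ids, columns=samples, dtype=int)
    warned = set()
    for tid in model.task_ids:
        rxns = model.task_reactions[tid]
        for sid in samples:
            vals, weighted = [], []
            for rid in rxns:
                v = ra.ral.at[rid, sid]
                if np.isnan(v):
                    continue
                g = ra.determinant.at[rid, sid]
                vals.append(v)
                weighted.append(st.s.at[g, sid] * v)
            if not vals:
                if tid not in warned:
                    logger.warning("task %s has no evaluable reaction; score undefined", tid)
                    warned.add(tid)
                continue
            mts.at[tid, sid] = sum(weighted) / len(vals)
            binary.at[tid, sid] = int(sum(vals) / len(vals) > cutoff)
    return mts, binary


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_cellfie(m: ExpressionMatrix, model: TaskModel,
                spec: ThresholdSpec = DEFAULT_SPEC, *,
                missing_policy: str = "drop", log_base="e",
                specificity_scope: str = "sample") -> CellFieResult:
    """Full pipeline: thresholds → gene scores → RAL → specificity → MTS.

    ``m`` should already have duplicate genes collapsed (and a pseudo-count
    added if it contains zeros). Raises when the expression gene ids share
    nothing with the model's gene universe — usually a sign the identifiers
    are not in the namespace the model uses (e.g. not Entrez ids).
    """
    if not m.data.index.is_unique:
        raise CellFieError("expression matrix contains duplicate gene ids; "
                           "run collapse_duplicate_genes first")
    universe = model.gene_universe
    overlap = universe & set(m.gene_ids)
    if not overlap:
        raise CellFieError(
            "no overlap between expression gene ids and the model's genes; "
            "check that the genes are given in the model's namespace "
            "(Entrez IDs for the standard models)"
        )
    logger.info("expression covers %d/%d model genes", len(overlap), len(universe))

    thresholds = compute_thresholds(m, spec)
    gs = gene_score_matrix(m, thresholds, log_base)
    ra = reaction_activity(model, gs, missing_policy)
    st = specificity(model, ra, specificity_scope)
    mts, binary = task_scores(model, ra, st, log_base)

    details = []
    for tid in model.task_ids:
        for rid in model.task_reactions[tid]:
            for sid in m.sample_ids:
                v = ra.ral.at[rid, sid]
                if np.isnan(v):
                    continue
                g = ra.determinant.at[rid, sid]
                orig = float(m.data.at[g, sid]) if g in m.data.index else float("nan")
                details.append(DetailRecord(
                    sample_id=sid,
                    task_id=tid,
                    task_score=float(mts.at[tid, sid]),
                    binary_score=int(binary.at[tid, sid]),
                    reaction_id=rid,
                    ral=float(v),
                    determinant_gene=g,
                    original_expression=orig,
                ))
    return CellFieResult(mts=mts, binary=binary, details=details)
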