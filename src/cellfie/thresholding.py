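"""Gene-activity thresholds.

The gene score compares expression against a threshold that decides when a
gene counts as active. Two families are supported:

global
    one threshold shared by all genes, either a user value or a percentile
    of the pooled distribution of every expression value in the dataset
    (all genes × all samples flattened).
local
    a gene-specific threshold:

    mean
        the gene's mean expression across samples.
    minmaxmean
        the gene's mean clamped to ``[lower, upper]`` bounds, given either
        as values or as pooled percentiles. Clamping guarantees that genes
        sitting below the lower bound in every sample can never exceed their
        threshold (never called active), and genes above the upper bound
        everywhere always are.

Defaults are the conventional choice for multi-sample data: local
min-max-mean with pooled percentile bounds 25 and 75. All thresholds are
floored at a tiny ε so an all-zero gene never divides by zero; adding a
pseudo-count to the expression data remains the user-facing fix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import ExpressionMatrix

__all__ = ["ThresholdSpec", "GeneThresholds", "DEFAULT_SPEC",
           "pooled_percentile", "compute_thresholds", "THRESHOLD_FLOOR"]

THRESHOLD_FLOOR = 1e-12


@dataclass(frozen=True)
class ThresholdSpec:
    """Configuration of the thresholding strategy.

    Exactly the fields of the chosen branch are consulted:
    ``family="global"`` uses ``global_mode`` with ``global_value`` or
    ``global_percentile``; ``family="local"`` uses ``local_mode`` and, for
    ``minmaxmean``, ``bound_mode`` with ``lower``/``upper``.
    """

    family: str = "local"
    global_mode: str = "percentile"
    global_value: float | None = None
    global_percentile: float | None = None
    local_mode: str = "minmaxmean"
    bound_mode: str = "percentile"
    lower: float | None = 25.0
    upper: float | None = 75.0

    def __post_init__(self):
        if self.family not in ("global", "local"):
            raise ValueError(f"family must be 'global' or 'local', got {self.family!r}")
        if self.family == "global":
            if self.global_mode not in ("value", "percentile"):
                raise ValueError(f"global_mode must be 'value' or 'percentile', got {self.global_mode!r}")
            if self.global_mode == "value":
                if self.global_value is None:
                    raise ValueError("global value thresholding requires global_value")
            else:
                p = self.global_percentile
                if p is None or not 0 <= p <= 100:
                    raise ValueError(f"global_percentile must be in [0, 100], got {p}")
        else:
            if self.local_mode not in ("mean", "minmaxmean"):
                raise ValueError(f"local_mode must be 'mean' or 'minmaxmean', got {self.local_mode!r}")
            if self.local_mode == "minmaxmean":
                if self.bound_mode not in ("value", "percentile"):
                    raise ValueError(f"bound_mode must be 'value' or 'percentile', got {self.bound_mode!r}")
                if self.lower is None or self.upper is None:
                    raise ValueError("minmaxmean requires lower and upper bounds")
                if self.lower > self.upper:
                    raise ValueError(f"lower bound {self.lower} exceeds upper bound {self.upper}")
                if self.bound_mode == "percentile":
                    for b in (self.lower, self.upper):
                        if not 0 <= b <= 100:
                            raise ValueError(f"percentile bound {b} outside [0, 100]")

    # convenience constructors ------------------------------------------------
    @classmethod
    def global_by_value(cls, value: float) -> "ThresholdSpec":
        return cls(family="global", global_mode="value", global_value=value)

    @classmethod
    def global_by_percentile(cls, p: float) -> "ThresholdSpec":
        return cls(family="global", global_mode="percentile", global_percentile=p)

    @classmethod
    def local_mean(cls) -> "ThresholdSpec":
        return cls(family="local", local_mode="mean")

    @classmethod
    def local_minmaxmean(cls, lower: float = 25.0, upper: float = 75.0,
                         bound_mode: str = "percentile") -> "ThresholdSpec":
        return cls(family="local", local_mode="minmaxmean",
                   bound_mode=bound_mode, lower=lower, upper=upper)


DEFAULT_SPEC = ThresholdSpec()


@dataclass
class GeneThresholds:
    """Per-gene activity thresholds plus the pooled percentile values used
    (empty when no percentile was involved)."""

    per_gene: pd.Series  # gene id -> threshold, every matrix gene present
    pooled_stats: dict

    def __getitem__(self, gene: str) -> float:
        return float(self.per_gene[gene])


def pooled_percentile(m: ExpressionMatrix, p: float) -> float:
    """Linear-interpolation percentile over all matrix entries pooled
    (genes × samples flattened)."""
    if not 0 <= p <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    vals = m.values.ravel()
    if vals.size == 0:
        raise ValueError("cannot take a percentile of an empty matrix")
    return float(np.percentile(vals, p))


def compute_thresholds(m: ExpressionMatrix, spec: ThresholdSpec = DEFAULT_SPEC) -> GeneThresholds:
    """Resolve a :class:`ThresholdSpec` against the data into per-gene
    thresholds (a scalar strategy is broadcast to every gene)."""
    if m.values.size == 0:
        raise ValueError("cannot compute thresholds on an empty matrix")
    genes = m.data.index
    pooled: dict = {}

    if spec.family == "global":
        if spec.global_mode == "value":
            t = float(spec.global_value)
        else:
            t = pooled_percentile(m, spec.global_percentile)
            pooled[f"p{spec.global_percentile:g}"] = t
        per_gene = pd.Series(t, index=genes, dtype=float)
    else:
        means = m.data.mean(axis=1)
        if spec.local_mode == "mean":
            per_gene = means
        else:
            if spec.bound_mode == "value":
                lo, hi = float(spec.lower), float(spec.upper)
            else:
                lo = pooled_percentile(m, spec.lower)
                hi = pooled_percentile(m, spec.upper)
                pooled[f"p{spec.lower:g}"] = lo
                pooled[f"p{spec.upper:g}"] = hi
            per_gene = means.clip(lower=lo, upper=hi)

    per_gene = per_gene.clip(lower=THRESHOLD_FLOOR).astype(float)
    return GeneThresholds(per_gene=per_gene, pooled_stats=pooled)
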