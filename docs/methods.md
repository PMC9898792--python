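# Methods

## Model

The package scores *metabolic tasks* — curated modules of reactions whose
joint capability is to produce defined outputs from defined inputs — from an
expression matrix overlaid on a task model. The task model contributes three
things: a 3-level hierarchy (system → subsystem → task), an ordered list of
essential reactions per task, and a boolean gene–protein–reaction (GPR) rule
per reaction (AND = enzyme complex, OR = isozymes).

The scoring chain is deterministic and purely algebraic:

1. **Gene score** `5·log(1 + e/t)` with per-gene threshold `t`. The constant
   5 and the `log(1+x)` form compress the dynamic range of expression; the
   score is 0 at zero expression and `5·log 2` exactly at the threshold.
2. **Reaction activity level (RAL)**: the rule collapses gene scores by
   min (AND) / max (OR); the surviving *main determinant*'s score is the
   RAL. Evaluation is n-ary (associative chains flattened), `or` binds
   looser than `and`, and ties select the lexicographically smallest gene id
   so runs are exactly reproducible.
3. **Specificity** `S = 1/k`, where `k` counts the *distinct tasks* in which
   the gene is main determinant of at least one evaluable essential
   reaction. `k` is counted per sample by default because determinants are
   sample-dependent; a pooled, dataset-wide scope is available
   (`specificity_scope="dataset"`) for users who want one weight per gene.
4. **Metabolic task score** `MTS = Σ S·RAL / n`, with `n` the number of
   evaluable essential reactions of the task (reactions with an empty rule,
   or — under the drop policy — no scored gene, do not count).
5. **Binary activity**: active iff the *unweighted* mean RAL is strictly
   greater than `5·log 2`. The unweighted mean follows the definition of the
   binary form as an average of the task's RALs; the boundary case (mean
   exactly at the cutoff, e.g. a constant gene under a local mean threshold)
   is inactive.

MTS is comparable across samples for one task, not across tasks within a
sample — tasks relying on constitutively low-expressed genes score low
regardless of state. Comparison tables are therefore always organised per
item across samples; nothing in the package ranks tasks within a sample by
raw MTS.

## Thresholds

* **global / value**: one user value for all genes — for single-sample data
  or externally justified cutoffs.
* **global / percentile**: a percentile of the pooled distribution of *all*
  matrix entries (genes × samples flattened). Pooling over the whole matrix,
  not per gene, is deliberate: the global threshold describes the dataset's
  overall expression distribution.
* **local / mean**: per-gene mean across samples — a relative,
  across-sample notion of activity.
* **local / min-max mean** (default, bounds = pooled percentiles 25 and 75):
  the per-gene mean clamped into `[lower, upper]`. The lower clamp stops
  uniformly silent genes from being called active by their own tiny mean;
  the upper clamp lets uniformly high genes clear their threshold. Bounds
  may also be absolute values.

Percentiles use linear interpolation between closest ranks (the dominant
numerical convention; the test oracle recomputes it independently).
Thresholds are floored at ε = 1e-12 so an all-zero gene cannot divide by
zero; the user-facing fix for zero-inflated data remains a pseudo-count
(`add_pseudocount`, CLI `--pseudocount`, conventionally 1e-5), which also
repairs degenerate log2 fold changes downstream.

Defaults (local, min-max mean, percentiles 25/75) are the conventional
settings for multi-sample data. The local mean includes zeros; it does not
skip them.

## Design choices in the open

* **Logarithm base**: the formulas say "log" without a base; the base
  rescales score and cutoff together (at `e = t` the score equals the cutoff
  in every base) but does not cancel elsewhere, so it is exposed
  (`--log-base {e,2,10}`), defaulting to natural log.
* **Missing genes** (in a rule but not in the data): default `drop` — the
  gene contributes nothing to an isozyme alternation instead of forcing a
  zero through a complex; `zero` substitution is available. A rule with no
  scored gene is *undefined*, not an error; a task with no evaluable
  reaction gets NaN MTS and binary 0, with a logged warning.
* **Significance test**: two-sided Mann–Whitney U (scipy; exact for small
  untied samples, normal approximation with tie correction otherwise),
  chosen for distribution-freeness on scores with no known sampling model;
  Welch's t-test by flag. No multiple-testing correction by default — the
  conventional volcano thresholds (alpha 0.05 or 0.01, fold change ≥ 1.5)
  are raw levels — with Benjamini–Hochberg under `--adjust bh`.
* **log2 fold change of group means** (not mean of per-sample log ratios),
  undefined (reported missing) when either mean is ≤ 0.
* **Depth aggregation** by unweighted NaN-skipping mean over member tasks;
  binary values aggregate to the active fraction in [0, 1].
* **Serialization**: `score.csv` / `scoreBinary.csv` are headerless, rows in
  task-metadata order, columns in input sample order; undefined MTS is
  written `NaN` (binary `0`). Floats use the shortest round-trip decimal
  representation, so write→read is lossless. `detailScoring.csv` carries one
  row per (task, essential reaction) with an 8-column block per sample
  concatenated horizontally (columns 9–16 = sample 2); it gets a header row
  by default (`--no-detail-header` disables it). Duplicate sample names are
  rejected; duplicate gene rows must be collapsed (per-sample maximum)
  before scoring.
* **Header auto-detection** for expression files: the first row is a header
  iff any cell beyond the first column is non-numeric; explicit flags
  override.

## Synthetic fixtures

`FixtureDesign`/`generate_model`/`generate_expression` build the study
conditions used throughout the tests: an 8-task model over two systems and
four subsystems, 24 reactions with random GPR rules (single genes, AND
chains, OR-of-ANDs), and two groups of 4 samples. Expression is log-normal —
mimicking the skew of TPM data — with three components: planted-high genes
(median 200), planted-low (median 2, a 100-fold separation), background
(median 20), and Gaussian noise of sd 0.25 on the log scale (0 for
noise-free recovery checks). Edge cases are planted by construction: a gene
shared between two tasks of identical planted pattern (promiscuous,
exercising the specificity weight without breaking the design), one
empty-rule reaction, and one rule gene deliberately absent from the matrix.

What the generator does **not** emulate: real co-expression structure,
count noise, batch effects, or the biology of any real tissue atlas — so
passing recovery tests demonstrates correctness of the scoring chain under
its own assumptions, not performance on real data. One intrinsic caveat the
fixtures expose: a gene expressed uniformly (no across-sample contrast)
under a *local* threshold sits exactly at its mean, scoring exactly at the
cutoff — only the min-max-mean clamp (with percentile bounds that fall in
the background component) can call such genes, which is why mixed designs
with always-active tasks use a large background gene pool.

The independent oracles — a recursive interpreter over rule trees built
without the parser, and a straight-line loop re-derivation of the whole
five-step pipeline including its own closest-rank percentile — live in the
same module and are used only in tests and the acceptance script.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run entirely on generated data:
1000 random rules for the evaluator cross-check, ten fixtures (40–76 genes,
6–9 tasks, 6–9 samples) for pipeline-vs-oracle equivalence (max relative
MTS deviation observed ≈ 7e-15; binary identical), noise-free planted
recovery (exact), scale invariance under ×0.1/×10 (≈ 4e-16), and a
1000-item null calibration of the Mann–Whitney rate at alpha 0.05 (slightly
conservative, as expected from the rank test's discreteness at n = 12 per
group). These sizes keep any run comfortably in seconds while covering all
rule shapes and degenerate paths.

## Limitations

* Scores are expression overlays: no flux balance, stoichiometric
  feasibility or pathway thermodynamics enters the calculation.
* Comparisons are strictly pairwise; multi-group designs need repeated
  pairwise tables or external tooling on the raw matrices.
* Identifier mapping (e.g. Ensembl → Entrez) is out of scope; expression
  gene ids must already be in the task model's namespace — a run aborts if
  the two gene sets are disjoint.
* The task-model bundle format (three relational CSV files) is defined by
  this package; curated species models are content the user supplies.
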