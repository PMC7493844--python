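# Methods

## Model and assumptions

The package infers ceRNA (miRNA-sponge) interactions from three inputs: a
gene expression matrix covering protein-coding genes, lncRNAs and
pseudogenes; a miRNA expression matrix on the same samples; and a catalog
of miRNA→target edges. Expression is assumed to be log-scale, normalized
abundance; every statistic used downstream is correlation-based, so any
monotone variance-stabilising transform is acceptable. An optional
`log2(x+1)` switch (default off) covers raw-scale inputs. Zero-variance
features are dropped with a warning before any correlation is computed.
Identifier matching is exact string equality; alias resolution is treated
as data preparation, out of scope. circRNA and tsRNA biotypes are rejected
by validation — the method is defined over protein-coding, lncRNA,
pseudogene and miRNA features only.

Samples are aligned by id intersection, preserving the gene-matrix column
order; the operation is deterministic and idempotent.

## Step A: hypergeometric overlap

For a pair (ceRNA-A, ceRNA-B) — A protein-coding, B in the sponge-eligible
set {protein_coding, lncRNA, pseudogene} — the shared-miRNA count x is
referred to the hypergeometric upper tail P(X ≥ x) with parameters N
(available miRNAs), K (regulators of A) and O (regulators of B). The tail
is summed directly over i = x..min(K,O) in log-space via log-gamma, which
is exact to ~1e-14 and does not overflow for catalogs of thousands of
miRNAs.

Choices:

* **N** counts catalog miRNAs that are also present in the miRNA
  expression matrix, and target neighborhoods are restricted the same way
  — only expressed miRNAs can participate in the downstream correlation
  stages.
* Each unordered pair is tested once, oriented with the protein-coding
  partner as ceRNA-A (lexicographic for coding–coding pairs).
* Multiplicity: Benjamini–Hochberg across all tested pairs at alpha 0.05
  by default; `adjust="none"` thresholds raw p-values instead.
* `min_shared` defaults to 1 — a single shared miRNA can carry a genuine
  interaction.

## Step B: anti-correlation filter

A repressive miRNA–target edge should show anti-correlated expression. Each
edge is tested with (i) the Pearson sign condition r < 0 and (ii) an
omnibus score statistic for association between the target and a miRNA
covariate set: with the target standardized to y_s and covariate columns
standardized to X_s,

    Q = ||X_sᵀ y_s||² / (p·n),

whose null distribution is obtained by permuting the sample labels of y
(add-one p-value, default 1000 permutations). Standardizing the covariate
columns makes Q = n·r² in the single-covariate case, so edge rankings by Q
and by squared correlation coincide. The omnibus statistic is sign-free,
hence the separate sign condition. By default each edge is tested with its
single miRNA as covariate; a `joint=True` mode tests each target against
all of its catalog miRNAs at once, for users who prefer the grouped
semantics. A moment-matched gamma approximation
(`global_test_asymptotic`) is provided as an experimental fast path; the
permutation route is the reference.

Per-edge permutation seeds are derived from the stage seed and a hash of
the edge ids, so results do not depend on edge iteration order.

## Step C: mscor and the stratified empirical null

For each surviving candidate, the shared-miRNA set is intersected with the
step-B survivors of both endpoints (candidates left empty are dropped),
and the pair is scored with

    mscor = cor(a, b) − pcor(a, b | M).

Partial correlation is computed from the inverse of the joint correlation
matrix; an independent residual-regression route is exposed for
cross-checking and the two agree to 1e-10 on well-conditioned data. When
the correlation matrix's condition number exceeds 1e12 the pseudo-inverse
is used with a warning (or an error in strict mode). Arguments are
canonicalized before evaluation so pcor and mscor are bitwise symmetric
in (a, b).

The sampling spread of mscor depends on the number of conditioning miRNAs
m and on the gene–gene correlation, so empirical p-values come from a null
stratified on (m, cor): m-bins 1..8 with m > 8 capped into a "8+" bin
(simulated at m = 9), and correlation bins of width 0.1 over (0, 1]. Each
stratum simulates gene pairs as bivariate normal at the bin-midpoint
correlation with m miRNAs independent of both genes — the no-competition
null, under which mscor is centred at zero — and the p-value is the
upper-tail proportion with an add-one correction. Only positive mscor can
be called significant (one-sided test), and a reported pair must have
cor(a, b) > 0, since the ceRNA signature requires positively correlated
partners. Negative or zero pair correlations are never scored: the null
covers (0, 1] only.

Strata are generated lazily with per-stratum seeds derived from the master
seed and the stratum key, so a pipeline run only simulates the strata its
candidates actually touch, and lazy and eager builds hold identical draws.
Null-model serialization is JSON, keeping every artifact of a run as plain
text. Default draws per stratum: 10,000 when building a reusable null
archive; tests and the acceptance script use 500–1000, which bounds the
smallest attainable p at ~1e-3 — sufficient against alpha = 0.05. No
additional multiplicity correction is applied at step C by default.

## Pipeline orchestration

Steps run strictly A → B → C. Step B evaluates only edges referenced by
some step-A candidate — result-equivalent to testing the whole catalog and
much cheaper. One master seed lives in the run config; stage seeds are
derived by hashing the stage name, so each stage is individually
reproducible. Runs with identical inputs and seed produce byte-identical
TSV/JSON artifacts; for that reason run reports carry a config hash but no
wall-clock timestamps. A failed stage aborts with a stage-named error and
removes partial outputs.

The result store mirrors service-style queries over completed runs: pair
lookup across tissues with a cross-tissue support count, absence markers
annotated with the stage that removed a pair (step_A if never a candidate;
step_B if no shared miRNA survived the edge filter for both endpoints;
step_C otherwise), and per-miRNA retained-target listings.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
read counts: miRNA profiles are i.i.d. normal; each planted pair's targets
are `base − β·Σ m_j + ε` with independent noise, giving population pair
correlation `s·β²σ_m² / (s·β²σ_m² + σ_ε²)` for s shared miRNAs and
anti-correlated miRNA–target edges; decoy pairs replicate the catalog
topology with no expression coupling; background genes are pure noise.
ceRNA-B biotypes cycle through lncRNA, pseudogene and protein-coding so
every eligibility branch is exercised. Background catalog edges are
sprinkled at density 0.02 per (miRNA, gene) slot, but only onto genes
outside planted pairs, so the overlap counts of planted and decoy pairs
equal their configured shared sets and ground truth stays exactly
interpretable.

Defaults are the benchmark conditions used throughout the tests: n = 200
samples, 150 miRNAs, 5 true triplets and 20 decoys with 2 shared miRNAs
each, β = 0.8, unit noise and miRNA variance, baseline 8 (a typical
log2-scale expression level). The 150-miRNA universe and 0.02 background
density were chosen once as a realistic catalog sparsity for a
desk-scale benchmark.

What the generator does **not** emulate: count noise (negative binomial),
batch effects, non-linear regulation, tumour-vs-normal differential
structure (run it twice with different β for that). Passing tests
therefore demonstrate correctness of the statistical machinery on data
satisfying the model's assumptions, not performance on real cohorts.

## Numerical choices and edge cases

* Hypergeometric tail in log-space (log-gamma), upper tail summed
  directly rather than via 1 − lower-tail, preserving accuracy for small p.
* Permutation and empirical p-values use the add-one convention; p = 0 is
  impossible.
* Pearson correlation requires n ≥ 3 and non-constant vectors; partial
  correlation requires n > |M| + 2.
* Condition-number threshold 1e12 separates "invert" from "pseudo-inverse
  with warning".
* Expression TSVs are re-read with correctly-rounded float parsing, so
  write→read round-trips are bit-exact.
* Ties in result ordering break lexicographically on the pair ids, making
  output order total and stable.

## Known limitations

* The empirical null conditions on the *sample* correlation's bin while
  simulating at the bin midpoint; with 0.1-wide bins this produces a small
  calibration error (measured rejection rate at the 0.05 level stays
  within the binomial 95% band at 1000 pairs).
* Step B's per-edge test treats each miRNA separately by default; miRNAs
  with correlated expression can pass or fail together.
* No elastic-net pre-selection of miRNA covariates; candidate selection is
  entirely the overlap and anti-correlation filters.
* The generator's Gaussian model means recovery rates reported here do not
  translate directly to count data.
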