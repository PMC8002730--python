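# Methods

## Scope and data flow

The pipeline identifies a condition-specific genome-wide genetic and
epigenetic network (GWGEN) from (a) an expression matrix (nodes × samples,
log-intensity scale) and (b) a Boolean candidate network — symmetric
protein–protein interaction (PPI) pairs over protein-like nodes (proteins,
receptors, TFs) plus directed regulator→target edges from TFs, lncRNAs and
miRNAs onto genes, lncRNAs and miRNAs.  Candidate networks are normally
database-derived; here they are either read from edge-list TSVs or planted
by the synthetic module.  Downstream stages extract the core subnetwork by
principal network projection (PNP), compare two condition cores, and
filter a drug catalog against the resulting biomarker signature.

## Generating model and identification

Each node owns one static equation.  For protein *i*:
p_i = Σ_j λ_ij·p_i·p_j + ψ_i + θ_i, giving the regression row
[p_i·p_j1, …, p_i·p_jk, 1].  For a gene/lncRNA/miRNA target x:
g_x = Σ α·t + Σ β·l − Σ γ·m·g_x + ψ_x + θ_x, giving the row
[t…, l…, g_x·m…, 1] with column order (TFs, lncRNAs, miRNAs, basal).  The
miRNA slots carry the coefficient −γ and are constrained non-positive;
those fits use bounded-variable least squares (`scipy.optimize.lsq_linear`,
BVLS), unconstrained fits use the normal least-squares solution.  The
bilinear terms (response appearing inside its own regressors) are fitted
as plain linear regression on the constructed columns, exactly as the
model is written; no errors-in-variables correction is attempted.

### Order detection

The full candidate model is fitted once; regressors are ranked by
|coefficient| × sd(regressor column) (ties by node id, coefficients pinned
to zero by an active constraint are excluded); the nested family
k = 0…K is refitted and the k minimising

AIC(k) = log₁₀(max(RSS/N, 10⁻¹²)) + 2(k+1)/N

is kept, ties going to the smaller k.  Two numerical choices matter:

- **Variance floor 10⁻¹²**: zero-residual fits would otherwise give
  log(0); with the floor, all perfect fits share the same likelihood term
  and the parsimony penalty alone decides, so the smallest exact model is
  selected.  This is what makes noise-free recovery exact.
- **Logarithm base 10.** The penalty strength of this criterion depends on
  the base: with the natural log a spurious regressor is admitted whenever
  its incremental χ² exceeds ≈2, i.e. for ≈16% of null candidates, which
  both floods the identified network with decoys at decoy-ratio 2 and
  makes the null rejection rate far too low for a pruning-oriented
  pipeline.  Base 10 (at N = 100, numerically equivalent to a
  BIC-strength penalty, admission threshold χ² ≈ 4.5, ≈3.4% null
  admission) gives the intended behaviour: ≥90% of pure-noise equations
  select order 0 and noisy edge-recovery F1 stays above 0.9.  The base and
  the floor are exposed as parameters (`log_base`, `variance_floor`).

The nested ranked family is an O(K)-refit approximation to the exhaustive
subset search; on noiseless instances with ≤5 candidates the two agree in
≥95% of cases (measured: 100%).  Per-kind orders (numbers of selected
TFs/lncRNAs/miRNAs) are read off the globally selected set rather than
searched on a 3-D grid.

### Degree cap

Each equation keeps at most N − 2 candidate regressors (parameters + basal
< sample count), dropping candidates with the smallest |Pearson
correlation| between the constructed regressor and the response (ties by
node id).  The selection criterion (correlation, rather than variance or
database confidence) is this package's choice; it is deterministic and
cheap.  The cap is applied per equation, so a symmetric PPI edge may
survive in one endpoint's equation only; the capped network records
per-equation regulator lists and keeps an edge while any equation retains
it.

## Synthetic data

The generator is the package's test instrument: it emulates a
database-mined candidate network with a planted truth and microarray-like
samples, not any particular real dataset.

- **Two-layer scheme.** The coupled equations are made exactly satisfiable
  by splitting nodes into *sources* (receptors, TFs, half of the plain
  proteins, half of the lncRNAs and miRNAs) drawn i.i.d. from a log-normal
  (location 0, scale 0.5, truncated at ±2.5σ on the log scale) and
  *targets* computed from the rearranged closed forms, e.g.
  p = (ψ+θ)/(1 − Σλp_partner) and g = (Σαt + Σβl + ψ + θ)/(1 + Σγm).
  Noise is injected inside the numerator, so each equation holds exactly
  with the drawn θ.  Condition-distinctive PPI edges connect two computed
  proteins in lexicographic (DAG) order, so both endpoints stay computed
  in both conditions.
- **Stability.** Coefficient magnitudes are uniform on [0.2, 1.0] (bounded
  away from 0 so order selection is well-posed); signs are random, but a
  protein-target's positive-λ budget is capped (largest positive λ flipped
  negative until Σλ⁺·p_max ≤ 0.85) and computed-protein partners always
  enter negatively, guaranteeing |1 − Σλp| ≥ 0.15 for every realization
  rather than resampling after the fact.  Basal levels are uniform on
  [2, 6]; miRNA-target basals are raised to keep their numerators
  non-negative, and the per-sample noise of miRNA targets is redrawn when
  it would push expression below zero (a truncation that only matters at
  implausibly large noise).
- **Degeneracy guard.** Every computed protein receives at least one
  source partner: a regulator-free protein would be constant across
  samples, and a constant protein inside another equation's bilinear term
  p_i·p_j makes that regressor proportional to the response — an exactly
  confounded decoy no criterion can reject.  For the same reason decoy
  edges (and candidate edges generally) never attach to the *equation of a
  source node* beyond its true symmetric PPI edges: a source has no
  generating equation, and any candidate regressor sharing its factor is
  statistically inseparable from signal.  Decoy PPI edges therefore join
  two computed proteins, and decoy regulations point at computed targets.
  In the two-condition generator each computed protein keeps one *anchor*
  PPI edge in the common set, which puts a floor on feasible
  `shared_truth_fraction` values (an infeasible fraction raises a
  parameter error).
- **What is not emulated.** Probe effects, normalisation artefacts,
  between-sample correlation, batch structure, and realistic expression
  marginals.  Passing recovery tests therefore shows the estimator is
  correct and well-conditioned under its own model, not that real
  microarray GWGENs would be recovered at these rates.

## Principal network projection

The combined matrix W has one row per equation-owning node (block order:
proteins, genes, lncRNAs, miRNAs) and one column per upstream-capable node
(proteins/receptors, TFs, lncRNAs, miRNAs); W[target, regulator] is the
estimated ability.  Protein columns are separate from the regulatory
blocks, so all estimated parameters appear exactly once.  W = T·D·Hᵀ by
SVD; right singular vectors are sign-fixed (largest-|·| entry positive)
for reproducibility.  Columns live in row space, so a downstream node's
projection onto component s is t_sᵀ·w_:,c = d_s·h_s[c], and a row projects
as w_r,:·h_s = d_s·t_s[r]; scores are the 2-norms of the first S
projections, with S the minimal rank whose cumulative eigenexpression
fraction reaches the energy threshold (default 0.85).  At full rank the
downstream score of a column equals its 2-norm (Parseval), which the tests
assert to 10⁻⁸.  A node active in both roles is ranked by the larger of
its two scores, and the top-k nodes (default 2000) with their induced
edges form the core.  The 0.85 threshold applies to SVD energy; the node
cut is a plain top-k — both configurable.

## Comparison and drug filtering

Core comparison is set algebra; overlap percentages use the named
condition's own core as denominator.  Direction labels compare mean
expression (case vs control) with an optional minimum-difference
threshold; an exact tie labels 'down' so the rule is deterministic.  The
drug filters are the sign rule (score ≤ −s for upregulated biomarkers,
≥ +s for downregulated; default s = 0.5) and a closed LD50 bound (default
500 mg/kg); both thresholds are exposed because only the direction rules,
not numeric cut-offs, are inherent to the method.  The multi-molecule
proposal is a greedy weighted set cover (most new targets, then larger
summed |score|, larger LD50, drug name); it is within the harmonic bound
of the optimum in general and equals it on the packaged fixtures.

## Problem sizes and determinism

The default study uses 50 proteins (20% receptors, 20% TFs), 100 genes,
20 miRNAs, 5 lncRNAs, true edge density 0.1, decoy ratio 2 (≈970 candidate
edges), 80 samples noise-free and 100 samples at noise sd = 0.1 × the
signal sd — sizes at which the full pipeline runs in seconds on one CPU
while leaving every stage non-trivially exercised.  All randomness flows
through `numpy.random.default_rng` seeds; identical seeds give
byte-identical artifacts, which the pipeline manifest (SHA-256 per file)
makes checkable.

## Known limitations

- The bilinear protein and miRNA terms reuse the response inside a
  regressor; with noisy data this biases coefficients (the fit is least
  squares on constructed columns, not a structural estimator).
- The nested AIC family can miss the exhaustive optimum when regressors
  are strongly collinear.
- PNP scores carry no significance calibration; the top-k cut is a rank
  cut, not a test.
- Overlap percentages and drug proposals depend on the chosen top-k and
  thresholds; no uncertainty is propagated into them.
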