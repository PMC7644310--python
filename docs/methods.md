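# Methods

`goegcn` analyses a two-group (control vs experiment) expression study in
two branches that share a common front end. This note records the models,
the defaults and why they are set as they are, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Front end: filtering, normalisation, differential expression

Genes are filtered on the linear scale: keep mean ≥ `mean_min` (default
0.2) and variance ≥ `var_min` (default 2) across all samples. Values are
then log2-transformed with a pseudocount of 1 (the common convention;
configurable). Both cutoffs are inclusive.

Differential expression uses an empirical-Bayes moderated t-statistic on
the log2 values. For gene *g* with group sizes *n_c*, *n_e*:

* logFC_g = mean(experiment) − mean(control);
* pooled residual variance s²_g on d_g = n_c + n_e − 2 df;
* a scaled inverse-chi-square prior (d₀, s₀²) is fitted by moment
  matching on log s²_g (mean and excess variance of
  z = log s² − ψ(d_g/2) + log(d_g/2), trigamma inverse by Newton
  iteration); when the observed spread of log-variances does not exceed
  its sampling expectation, d₀ = ∞ and s₀² is the mean sample variance;
* posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g); moderated
  t = logFC / (s̃_g √(1/n_c + 1/n_e)), two-sided against t with
  d₀ + d_g df (capped at the summed residual df across genes);
* Benjamini–Hochberg adjustment across all tested genes.

This is the standard moderated-t model without precision weights; mean–
variance trends of counts are therefore not modelled. The engine is
pluggable: any externally produced DE table with `log_fc` and
`adj_p_value` columns can be loaded (`read_de_table`) and fed to the same
DEG rule. Genes with zero variance in both groups receive p = 1 and stay
in the multiple-testing denominator. DEGs are genes with |logFC| ≥ 0.5
and adjusted p ≤ 0.01, both bounds inclusive.

During development the engine was checked against an independent
reference implementation of the same model; frozen reference t- and
p-values for a fixed Gaussian fixture are asserted in the test suite at
1e-9.

## Regulatory gene weights

On a directed regulator→target network over N genes the weight of gene
*g_i* is the fixed point of

    W(g_i) = (1 − d)/N + d · Σ_{g_j ∈ T(g_i)} W(g_j) / L(g_j)

where T(g_i) are the targets of g_i, L(g_j) the number of regulators of
g_j, and d the damping factor (default 0.85, the standard damping
convention; tolerance 1e-10, max 1,000 sweeps, uniform 1/N start). A
gene that (transitively) regulates many targets accumulates weight;
genes with no targets sit at the restart value (1 − d)/N.

This is deliberately *not* canonical PageRank: there is no dangling-node
redistribution and no renormalisation, so weights need not sum to 1.
Convergence is nevertheless guaranteed: each column j of the propagation
matrix holds L(g_j) entries of value 1/L(g_j), so every column sum is at
most 1, the spectral radius is ≤ 1, and the damped map contracts with
factor d. Self-loops are rejected (self-regulation is undefined in the
recurrence). Ranking is by descending weight with ties broken by
ascending gene id; *weighted DEGs* are the intersection of the DEG set
with the top-M ranking (M = 1,000 for classification features, 3,000 for
the enrichment branch), returned sorted by gene id for reproducibility.

## Differential coexpression

For the weighted DEGs, each group's coexpression network is the upper
triangle of the Pearson correlation matrix of log2 values, pruned at a
hard threshold (default: signed PCC ≥ 0.3; absolute-value mode is a
flag, since |PCC| thresholds are also common practice). Undefined
correlations (zero-variance genes) are set to 0 — they can never form an
edge. Comparing the two pruned structures by edge presence (correlation
magnitudes are ignored) yields three disjoint classes: *inhibited*
couples (control-only), *activated* couples (experiment-only) and
*shared* couples. At least 3 samples per group are required.

## Edge-level term enrichment

A gene-level hypergeometric over-representation screen (universe =
annotation genes present in the filtered matrix; BH-adjusted p ≤ 0.05)
selects candidate terms from the weighted DEGs. Each candidate is then
re-tested per side at the edge level with the quadruple

* N — edges of the group's pruned network (the background),
* K — differential edges in the background (inhibited for the control
  side, activated for the experiment side),
* n — background edges with both endpoints annotated to the term,
* k — differential edges among those n,

and p = P(X ≥ k) for X hypergeometric(N, K, n). The upper tail is used
because a point probability P(X = k) is not a valid enrichment p-value;
a `point_mass` flag computes the literal single-term formula for
comparison. k = 0 gives p = 1 exactly. BH runs separately within each
side (the two sides are separate test families); records with adjusted
p ≤ 0.05 are kept, sorted by (adjusted p, raw p, term_id), and a term
passing on both sides is labelled *common*. The background defaults to
the full pruned group network including shared edges; a `background =
"differential"` option restricts it to the differential subset. Terms
with n = 0 are reported with p = 1 rather than dropped, so the
denominator is auditable. The annotation is any GMT file, so pathway
collections work identically to GO term collections.

## Classification harness

The weighted DEGs (top-1,000 intersection) are features for a binary
classifier evaluated by stratified k-fold cross-validation (default 5
folds × 100 repeats; examples and tests use fewer repeats — the metric
means stabilise long before 100). Class imbalance is handled by SMOTE:
each synthetic minority sample is x + u(x_nn − x) with x a random
minority sample, x_nn one of its k = 5 nearest minority neighbours
(Euclidean, k capped at minority size − 1) and u ~ Uniform(0,1), the
minority class being raised to parity with the majority. SMOTE is
applied inside the CV loop to the training portion only — applying it
before splitting would leak synthetic copies of test points into
training, so the safe placement is the default and the harness asserts
(via provenance-tagged features in the tests) that no synthetic row ever
reaches a held-out fold.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy,
precision TP/(TP+FP), F1, and the rank-based (Mann–Whitney) AUC with
half credit for ties. Undefined denominators are flagged as NaN, never
silently zeroed. Metrics are averaged over all folds of all repeats
(NaN folds skipped per metric); confusion counts are summed. A Gaussian
naive-Bayes classifier (variance floor 1e-9, posterior log-odds scores)
is built in as the reference model; any estimator with
`fit`/`predict` and one of `score_samples`/`predict_proba`/
`decision_function` plugs in, which covers scikit-learn's random forest
and RBF-SVM.

## Synthetic data

The generators produce data with exactly the structure the method
assumes, so planted truth is recoverable:

* **Counts** — baseline means log-normal (log2 mean 5, sd 1.5), counts
  negative-binomial with variance μ + φμ² (default dispersion φ = 0.1,
  typical of bulk RNA-seq; φ = 0 is Poisson). Planted DE genes shift the
  experiment mean by ±2 on the log2 scale.
* **Coexpression modules** — per module, one standard-normal latent
  factor per active sample, added to member genes with loadings
  factor_strength × Uniform(0.5, 1) on the log2 scale. This induces
  within-module correlation only in the active group(s), composes with
  the count layer, and is positive-definite by construction.
* **Regulatory network** — edges grown by out-degree preferential
  attachment (weight out_deg^hub_bias + 1), giving hub regulators;
  saturation-aware target sampling, no self-loops or duplicates.
* **Annotation** — uniform random background terms (sizes 10–40) plus
  one aligned term per module (module ∪ 15 random padding genes).

`simulate_dataset` composes these into the default study: 1,000 genes,
50 samples/group, five disjoint 15-gene modules (three active in both
groups, one experiment-only, one control-only) at factor_strength 2,
12% planted DE genes always covering the module genes, a 3,000-edge
regulatory network, and 50 background terms. The three shared modules
matter: real coexpression networks share most structure between groups,
and without common background edges essentially every edge is
differential (K ≈ N), leaving the edge-level test no contrast. Module
genes are planted as DE so they survive the DEG gate and reach the
network stage. The module overlay is applied on the log2 scale and
mapped back to the linear scale (clipped at zero) so that the pipeline's
own log2 step recovers the planted correlation.

What the generator does **not** emulate: library-size variation and
normalisation artefacts, mean–variance trends in dispersion, correlated
(non-factor) noise, overlapping modules, hierarchical annotation
structure (terms are flat sets), and hub-target coupling between the
regulatory network and the expression values (weights and DE are
independent in the simulation). Passing tests therefore demonstrate the
machinery is correct under the assumed model, not that the thresholds
are optimal for any real dataset.

## Problem sizes and determinism

The test suite and the acceptance script run everything at reduced but
structure-preserving sizes chosen as standard desk-scale simulation
settings: 2,000 genes for DE calibration (null p<0.05 rate 0.05 ± 0.015),
20 replicates of the 1,000-gene end-to-end recovery study, 10 null
replicates, 200-node random networks for the fixed-point check, and CV
on 100–200 samples. Every stochastic step takes an explicit seed; seeded
runs are byte-reproducible, and the CLI writes a manifest (config echo,
seed, package version, input checksums) with every output.

## Known limitations

* The moderated-t engine ignores count-level mean–variance structure;
  for heavily heteroskedastic count data an external DE table is the
  better input.
* Signed PCC pruning discards strong negative correlations by design
  (the literal threshold rule); use absolute mode if anti-correlation
  matters.
* The edge-level test conditions on the pruned networks; uncertainty in
  the correlation estimates themselves (sample size of each group) is
  not propagated.
* With very unequal group sizes the two backgrounds N^c, N^e differ in
  reliability; the method does not correct for this.
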