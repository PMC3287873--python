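# Methods

`bndissect` implements a joint-modelling pipeline for simulated
complex-disease cohorts: rare variants are collapsed into annotation-aware
gene burden scores, genes are pre-selected by a replicate-stability screen,
the dependency structure among environment, gene scores, quantitative traits
and disease is learned as a constrained linear-Gaussian Bayesian network by
structure MCMC, replicate networks are aggregated into an edge-confidence
consensus, and the consensus network selects the predictors of a disease risk
model. This note records the model, the defaults, and the design decisions
behind each stage.

## Synthetic cohort model

The generator emulates a GAW17-style mini-exome study: a single genotype
matrix shared by many phenotype *replicates*, so that genetic effects are
fixed while environmental and stochastic components are re-drawn.

**Genotypes.** Each gene carries `variants_per_gene` (default 3–10) variants;
MAFs are drawn from a Beta(0.3, 4) density rescaled into `maf_bounds`
(default 5×10⁻⁴–0.1), giving a heavily rare-skewed spectrum (~75% of variants
below 1% MAF at the defaults). Genotypes are independent
Binomial(2, q) draws (Hardy–Weinberg, no linkage disequilibrium — a stated
non-goal). Each variant is nonsynonymous independently with probability 0.7.

**Phenotypes.** Age ~ U(20, 80) (entering effects centred), sex ~
Bernoulli(0.5), smoking ~ Bernoulli(0.3). Each quantitative trait is

    Q_t = Σ_env β_{t,e}·e + effect_size · Σ_{g ∈ causal(t)} z(NS_g) + N(0, 1),

where `z(NS_g)` is the z-scored nonsynonymous weighted-sum burden of causal
gene *g* — causal effects act through nonsynonymous variation by default, with
defaults Q1 ← smoking, Q4 ← age + smoking and no causal genes for Q4. Disease
is a liability threshold:

    L = 0.5·Q1 + 0.5·Q2 + 0.3·Q4 + 0.8·smoking + 0.5·sex + 0.015·age_c + N(0, σ_latent²),
    affected = 1 iff L > quantile(L, 1 − prevalence),

with σ_latent = 1 and prevalence 0.3. The threshold is the empirical quantile
of the replicate's own liability sample, so the affected fraction is
calibrated by construction; the latent term represents an unobserved
liability component that deliberately violates the no-hidden-node assumption
of the downstream network model. The realized liability is kept as a column
for oracle evaluations only.

**What the generator does not emulate.** Pedigree/population structure,
linkage disequilibrium, locus heterogeneity in annotation quality, and
covariate-genotype dependence. Passing tests therefore demonstrate
correctness of the machinery and its behaviour under the stated generating
model, not performance on real exome data.

A consequence worth knowing: because genotypes are fixed across replicates,
a non-causal gene whose score is by sampling accident correlated with the
(fixed) causal burden is associated with the trait in *every* replicate.
Replicate-stability screening cannot remove such proxy genes; the retained
set is expected to contain them, and the consensus network occasionally
carries their edges.

## Gene scores and the annotation weight

The burden score of gene *i* for an individual is Σ_j w(q_j)·g_j over the
gene's variants passing the annotation filter, with the Madsen–Browning
weight w(q) = 1/√(n·q(1−q)) (alternatives 1/q and 1/√(q(1−q)) are pluggable).
By default q is estimated from the analysis sample with the pseudo-count form
(m+1)/(2n+2) so monomorphic variants never divide by zero; the variant
table's MAF column can be used instead (`maf_source="table"`).

Synonymous and nonsynonymous scores S_i and NS_i are blended into a combined
score w·NS_i + (1−w)·S_i. The weight is estimated from data: per-annotation
gene-level disease p-values are converted to z = Φ⁻¹(1−p) and a two-group
fit with a theoretical N(0,1) null estimates the null proportion by central
matching (the count of |z| ≤ 1 against the standard-normal central mass;
Storey's λ = 0.5 tail estimator is available as an alternative). The
proportions of true-positive genes P_s and P_ns give

    w = P_ns / (P_s + P_ns)   ("nonsyn_share", default),

with the alternative ratio P_s/(P_s+P_ns) ("as_printed") available; both are
reported. Genes whose annotation-restricted score is constant in the sample
are excluded before the fit — their p-values are pinned at 1, which maps to
z = −∞ and corrupts the central-matching estimate. The fit refuses fewer
than 50 genes; small panels fall back to w = 0.5, flagged in the output.

## Screening

Each gene is tested per replicate in `response ~ intercept + score + smoking`
(OLS for Q1/Q2/Q4, logistic with a flagged linear-probability fallback for
disease); a gene is retained for a response when p < 0.1 in strictly more
than half of the replicates ("greater than 100 of 200" read as strict, and
scaled as `n_replicates // 2` at other replicate counts). The bootstrap
variant resamples individuals of the pooled sample with replacement and
treats the resamples as replicates. No multiple-testing correction is applied
inside the screen: the raw cutoff plus cross-replicate stability is the error
control (a truly null gene passes the 100-of-200 rule with probability
below 10⁻¹⁰). The network gene set is the union of retained sets over
Q1, Q2, Q4 and disease, truncated to the most stable `max_network_genes`
(default 15) to bound the structure search.

## Network model and structure MCMC

Every node (environment, gene score, trait, disease — binary columns enter
as 0/1 values) is linear Gaussian given its parents:
X | u₁..u_K ~ N(a₀ + Σ a_k u_k, σ²). Columns are z-scored before scoring so
BIC comparisons are scale-free; σ² is floored at 10⁻¹⁶ and collinear parents
fall back to a tiny ridge.

The per-node score is the maximized Gaussian log-likelihood, penalized by
default as BIC: ℓ − (K+2)/2·ln n (intercept, K coefficients, variance). The
raw likelihood is available (`score_kind="loglik"`), but it makes every edge
addition non-decreasing, so the chain saturates at the parent cap; BIC is
the default for that reason.
The network score decomposes over nodes, so a move re-scores only the
affected children, with per-(node, parent-set) caching backed by a
precomputed Gram matrix (each fit is a K×K solve, independent of n).

Structure search is Metropolis–Hastings over DAGs with add/delete/reverse
edge moves drawn uniformly from the *legal* neighborhood. Legality enforces:
acyclicity (maintained via a transitive-closure matrix); a parent cap
(default 5, to bound fits at moderate n); and the role constraints — no
edges from traits or disease into genes, none between genes and environment,
none among genes; environment nodes are additionally exogenous (no incoming
edges) by default, switchable off (`raw_mode` relaxes it together with the
score and acceptance choices). A move is
accepted with probability min(1, e^Δ·|N|/|N′|); the neighborhood-size ratio
makes the stationary distribution exactly ∝ e^score, verified in the tests
against exhaustive enumeration of all 25 three-node DAGs (total-variation
distance ≤ 0.05 over a 200k-step chain). The literal acceptance rule without
the Hastings ratio is available (`hastings=False`).

Chains start from a random legal DAG (random topological order, each allowed
forward edge included with probability 0.1), track the best structure visited
(first visited wins score ties, deterministic given the seed), and stop at
the iteration cap or when the best score improves by less than a relative
10⁻⁶ over a 1000-iteration window. Default iteration budgets in the shipped
scenarios are 3000–4000 steps per replicate network, which at ≤ 25 nodes is
comfortably past where the best score stabilizes.

## Consensus and cycle handling

The confidence of a directed edge is the count of replicate (or bootstrap)
networks containing it; the final network keeps edges with count ≥ cutoff
("at least five" is inclusive). At 200 replicates the conventional cutoff is
5 (2.5%); scaled-down runs use max(2, ⌈fraction·R⌉). Thresholding
direction-sensitive counts can leave directed cycles (typically a 2-cycle of
opposing orientations); the lowest-count edge in each cycle is dropped
deterministically and logged, so the final object is always a DAG for
parameter fitting. An undirected-skeleton counting mode is deliberately not
the default: the confidence score counts directed edges.

## Prediction

QTL genes are the gene nodes with a retained edge into a quantitative trait
(edges into the disease node do not qualify). The risk model is an RBF-kernel
SVM on standardized features with C = 1 and γ = 'scale'; a small
cross-validated grid is available behind `tune=True` but is off by default —
at desk scale the experiment fits dozens of SVMs and the fixed
hyperparameters are stable. An L1-penalized logistic model with
cross-validated penalty is the alternative. AUC is the Mann–Whitney rank
statistic with ties averaged (cross-checked against an independent
implementation in the tests). Trait features, when included, are the
*observed* Q1/Q2/Q4 values — prognostic-style prediction, not pre-symptomatic.

The annotation experiment splits replicates half/half (seeded), rebuilds
screen + consensus per annotation on the training half only, and averages
held-out AUC per feature set (genes; genes+environment;
genes+environment+traits). When an annotation yields no QTL gene (typical
for synonymous-only scores, which carry no causal signal), the screened gene
set is used as the gene features so the contrast stays defined. The
joint-vs-marginal comparison ranks genes by their maximum gene→trait edge
count and, for the marginal side, by the maximum absolute LassoCV coefficient
over per-trait fits on the pooled standardized scores.

## Scenario sizes

The shipped scenarios (`bndissect.scenarios`) are desk-scale analogs chosen
as study designs: structure recovery uses 20 genes / 5 causal at 0.5 SD,
n = 1000, 20 replicates, cutoff 3; weight recovery uses 150 genes / 30
causal at 0.75 SD, n = 1000; the annotation experiment uses 40 genes /
16 causal at 0.6 SD, n = 400, 16 replicates; the pleiotropic ranking
comparison uses 20 genes / 8 causal at a weak 0.15 SD (n = 400, 8
replicates) precisely so that neither ranking method saturates at AUC 1.0
and the comparison is informative.

## Known limitations

- The liability threshold makes disease a deterministic function of a latent
  Gaussian; the Gaussian node model for the 0/1 disease column is therefore
  misspecified by design, as in the emulated study, and the sampler is
  expected to recover its Markov blanket rather than calibrated parameters.
- π₁ estimation needs wide gene panels; below 50 informative genes the
  weight falls back to 0.5.
- Proxy genes (see above) are an intrinsic property of fixed-genotype
  replicate designs, not a bug of the screen.
- Only structure is aggregated across replicates; parameters are fit once on
  the final consensus DAG.
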