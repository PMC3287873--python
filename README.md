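# bndissect

Bayesian-network dissection of a simulated complex-disease cohort: who
regulates whom among environmental exposures, rare-variant gene burdens,
quantitative traits, and a binary disease outcome — and how well does the
learned network predict disease risk?

The package is written for statistical geneticists and methods developers
who want a fully testable, ground-truth-controlled implementation of the
joint-modelling workflow used on GAW17-style simulated mini-exome data: a
fixed genotype matrix of mostly rare variants shared by many phenotype
replicates. Since the original workshop data are access-restricted, a
first-class synthetic generator reproduces the study design (rare-skewed MAF
spectrum, synonymous/nonsynonymous annotation, trait equations driven by
smoking/sex/age and nonsynonymous burden, a latent liability component, and
a liability-threshold disease) with recorded ground truth, so every stage
can be validated.

## The method

1. **Gene scores.** Per gene, the weighted-sum burden
   `Σ_j g_ij / √(n·q_j(1−q_j))` over its variants (Madsen–Browning
   weights emphasize rare variants), computed separately from synonymous
   (S_i) and nonsynonymous (NS_i) variants and combined as
   `w·NS_i + (1−w)·S_i`. The weight w is estimated from the data:
   per-annotation proportions of true-positive genes P_s, P_ns come from a
   local-FDR style two-group fit on z = Φ⁻¹(1−p), and w = P_ns/(P_s+P_ns).
2. **Screening.** Per replicate, `response ~ score + smoking` simple
   regressions; a gene survives when p < 0.1 in more than half the
   replicates (a bootstrap over the pooled sample substitutes when
   replicates don't exist); the union over Q1, Q2, Q4 and disease enters the
   network.
3. **Structure learning.** A Bayesian network with linear Gaussian node
   densities X|u ~ N(a₀+Σa_k u_k, σ²), learned by Metropolis–Hastings MCMC
   over DAGs (add/delete/reverse edge moves, BIC-penalized score,
   neighborhood-corrected acceptance), under biological edge bans: no
   trait→gene, no gene↔environment, no gene↔gene edges.
4. **Consensus.** Edge confidence = number of replicate networks containing
   the directed edge; edges at or above the cutoff form the final network.
5. **Prediction.** An SVM on the network-selected QTL genes (genes with an
   edge into a quantitative trait) plus environment — and optionally the
   traits — predicts disease; performance is held-out AUC averaged over
   evaluation replicates.

## Worked example

The numbered scripts under `analysis/` run the full study at desk scale
(697 individuals, 120 genes of which 18 are causal, 20 phenotype
replicates) and write their tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
  794 variants in 120 genes; 75% with MAF < 1%; 71% nonsynonymous
  20 phenotype replicates; affected fraction 0.300 (target 0.3)

$ python analysis/02_gene_scores.py
  pi1(syn) = 0.043, pi1(nonsyn) = 0.243
  w = 0.849 (estimated, formula nonsyn_share)

$ python analysis/03_screen_genes.py
  screen retained 32 genes across responses; 15 selected for the network
  causal recovered: 18/18; non-causal (proxy) genes retained: 14

$ python analysis/04_learn_networks.py
  consensus over 20 replicates, cutoff 2: 39 edges kept
  ground-truth edges recovered: 24/24 (among representable ones)

$ python analysis/05_predict_risk.py
  held-out AUC = 0.802 +- 0.025 over 10 replicates
```

Reading these numbers: the two-group fit correctly attributes the signal to
nonsynonymous variation (π₁ of 0.24 vs 0.04, hence w ≈ 0.85 — the generator
routes all causal effects through nonsynonymous burden); the replicate
screen keeps every causal gene but also stable "proxy" genes whose fixed
scores happen to correlate with the causal burden (an intrinsic feature of
shared-genotype replicate designs); the consensus network recovers all
representable ground-truth edges; and the network-selected predictors reach
AUC 0.80 on held-out replicates.

`analysis/06_annotation_experiment.py` repeats the pipeline per annotation
class and feature set. On its scenario the held-out AUC rises
0.71 → 0.80 → 0.89 as environment and then traits join the gene features,
and synonymous-only gene features stay at chance (0.50) — and the
edge-confidence gene ranking (AUC 0.92) edges out a pooled LASSO ranking
(0.89).

There is also a CLI over the same stages:

```
bn-dissect run --config cfg.yaml --seed 7 --out-dir out/
bn-dissect {simulate,score,screen,learn,consensus,predict,fixtures} ...
```

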