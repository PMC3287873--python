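"""Network-guided disease risk prediction and the annotation/feature experiments.

The consensus network selects predictors: the *QTL genes* are the gene nodes
with a retained directed edge into a quantitative trait.  A support vector
machine (RBF kernel on standardized features) is trained on the training
replicates to predict binary disease status and evaluated by AUC on each
held-out replicate; an L1-penalized logistic model is available as an
alternative.  AUC is the Mann-Whitney rank statistic with ties averaged.

``run_annotation_experiment`` reruns the whole pipeline per annotation class
(nonsynonymous-only vs synonymous-only scores) and per feature set (genes;
genes + environment; genes + environment + traits), training on half the
replicates and averaging AUC over the other half.  It also runs the marginal
LASSO comparator for gene ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .bayesnet import ConstraintSet, Dag, McmcConfig, NodeSpec
from .consensus import EdgeConfidenceTable, consensus_over_replicates
from .errors import DataError
from .gene_scores import GeneScoreMatrix, score_all_genes
from .screening import screen_replicates, union_over_responses
from .synthetic_data import DISEASE, ENVIRONMENT_VARIABLES, TRAITS, ReplicateSet

__all__ = [
    "FeatureSet",
    "PredictionReport",
    "rank_auc",
    "select_features",
    "build_feature_frame",
    "train_predictor",
    "evaluate",
    "gene_ranking_auc",
    "lasso_gene_ranking",
    "AnnotationExperimentConfig",
    "run_annotation_experiment",
]


def rank_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic (ties averaged)."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class FeatureSet:
    """Predictor names grouped by class; classes are disjoint by construction."""

    environment: tuple[str, ...] = ()
    qtl_genes: tuple[str, ...] = ()
    traits: tuple[str, ...] = ()

    @property
    def all_features(self) -> tuple[str, ...]:
        return self.environment + self.qtl_genes + self.traits

    def __post_init__(self) -> None:
        if not self.all_features:
            raise DataError("empty feature set")


def select_features(
    consensus_dag: Dag,
    node_specs: Sequence[NodeSpec],
    include_traits: bool = False,
    include_env: bool = True,
) -> FeatureSet:
    """QTL genes (gene nodes with an edge into a quantitative trait) plus toggles.

    Edges into the disease node do not qualify a gene as a QTL: only the
    quantitative traits count.
    """
    roles = {s.name: s.role for s in node_specs}
    qtl = sorted(
        {
            u
            for u, v in consensus_dag.edges()
            if roles.get(u) == "gene" and roles.get(v) == "trait"
        }
    )
    return FeatureSet(
        environment=tuple(ENVIRONMENT_VARIABLES) if include_env else (),
        qtl_genes=tuple(qtl),
        traits=tuple(TRAITS) if include_traits else (),
    )


def build_feature_frame(
    phenotypes: pd.DataFrame,
    scores: GeneScoreMatrix,
    features: FeatureSet,
) -> pd.DataFrame:
    """Predictor matrix for one replicate (gene features come from the shared scores)."""
    cols: dict[str, np.ndarray] = {}
    for v in features.environment:
        cols[v] = phenotypes[v].to_numpy(dtype=float)
    for g in features.qtl_genes:
        cols[g] = scores.data[g].to_numpy(dtype=float)
    for t in features.traits:
        cols[t] = phenotypes[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=phenotypes.index)


def train_predictor(
    X: pd.DataFrame,
    y,
    model: str = "svm",
    seed: int = 0,
    tune: bool = False,
):
    """Fit the risk model; returns an estimator with ``decision_function``.

    ``svm``: RBF-kernel SVC on standardized features (C=1, gamma='scale';
    ``tune=True`` cross-validates C and gamma on a small grid).
    ``lasso_logistic``: L1 logistic regression with cross-validated penalty.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import GridSearchCV
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    if model == "svm":
        est = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        )
        if tune:
            est = GridSearchCV(
                est,
                {"svc__C": [0.3, 1.0, 3.0], "svc__gamma": ["scale", 0.1]},
                cv=3,
                scoring="roc_auc",
                n_jobs=1,
            )
    elif model == "lasso_logistic":
        est = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                Cs=7, cv=3, l1_ratios=(1.0,), solver="saga", scoring="neg_log_loss",
                max_iter=2_000, random_state=seed, use_legacy_attributes=False,
            ),
        )
    else:
        raise ValueError(f"unknown model: {model!r}")
    est.fit(X.to_numpy(), y)
    return est


@dataclass
class PredictionReport:
    """Held-out AUC per evaluation replicate with its mean and SD."""

    per_replicate: pd.Series
    feature_set: FeatureSet
    model: str
    skipped: list[int] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(self.per_replicate.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.per_replicate.std(ddof=1)) if len(self.per_replicate) > 1 else 0.0


def evaluate(
    predictor,
    test_sets: Sequence[tuple[pd.DataFrame, np.ndarray]],
    features: FeatureSet,
    model: str = "svm",
) -> PredictionReport:
    """AUC of the decision score against disease status, per test replicate."""
    aucs = {}
    skipped = []
    for r, (X, y) in enumerate(test_sets):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            skipped.append(r)
            continue
        score = predictor.decision_function(X.to_numpy())
        aucs[r] = rank_auc(score, y)
    if not aucs:
        raise DataError("no evaluable test replicates")
    return PredictionReport(
        per_replicate=pd.Series(aucs, name="auc"),
        feature_set=features,
        model=model,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# gene-ranking comparison (joint network confidence vs marginal LASSO)
# ---------------------------------------------------------------------------


def gene_ranking_auc(
    table: EdgeConfidenceTable,
    gene_names: Sequence[str],
    causal_genes: Sequence[str],
) -> float:
    """AUC of ranking genes by their maximum gene->trait edge count."""
    counts = {g: 0 for g in gene_names}
    for _, row in table.counts.iterrows():
        if row["source"] in counts and row["target"] in TRAITS:
            counts[row["source"]] = max(counts[row["source"]], int(row["count"]))
    genes = list(gene_names)
    truth = np.array([1 if g in set(causal_genes) else 0 for g in genes])
    return rank_auc(np.array([counts[g] for g in genes]), truth)


def lasso_gene_ranking(
    pooled_scores: pd.DataFrame,
    pooled_phenotypes: pd.DataFrame,
    causal_genes: Sequence[str],
    seed: int = 0,
) -> float:
    """Marginal comparator: per-trait L1 fits over all gene scores.

    Each quantitative trait is regressed on all (standardized) gene scores
    with LassoCV; genes are ranked by their maximum absolute coefficient over
    the traits and scored by AUC against the causal set.
    """
    from sklearn.linear_model import LassoCV
    from sklearn.preprocessing import StandardScaler

    X = StandardScaler().fit_transform(pooled_scores.to_numpy())
    genes = list(pooled_scores.columns)
    strength = np.zeros(len(genes))
    for trait in TRAITS:
        y = pooled_phenotypes[trait].to_numpy(dtype=float)
        fit = LassoCV(cv=3, random_state=seed, alphas=30).fit(X, y)
        strength = np.maximum(strength, np.abs(fit.coef_))
    truth = np.array([1 if g in set(causal_genes) else 0 for g in genes])
    return rank_auc(strength, truth)


def compare_gene_rankings(
    replicates: ReplicateSet,
    mcmc_config: McmcConfig | None = None,
    master_seed: int = 0,
    constraints: ConstraintSet | None = None,
) -> dict:
    """Joint (network edge-confidence) vs marginal (LASSO) causal-gene ranking.

    Uses the nonsynonymous scores of *all* genes as network nodes (no screen,
    so every gene can be ranked), learns one network per replicate, ranks
    genes by their maximum gene->trait edge count, and compares the AUC
    against ground truth with the pooled LASSO ranking.
    """
    scores = score_all_genes(replicates.genotypes, replicates.variants, "nonsynonymous")
    table, _, _ = consensus_over_replicates(
        replicates,
        scores,
        scores.genes,
        mcmc_config=mcmc_config or McmcConfig(iterations=3_000),
        constraints=constraints,
        cutoff=2,
        master_seed=master_seed,
    )
    causal = sorted(replicates.truth.all_causal_genes)
    net_auc = gene_ranking_auc(table, scores.genes, causal)
    pooled_ph = pd.concat(replicates.phenotypes)
    pooled_sc = pd.concat([scores.data for _ in replicates.phenotypes])
    lasso_auc = lasso_gene_ranking(
        pooled_sc, pooled_ph, causal, seed=derive_seed(master_seed, "lasso")
    )
    return {"network_auc": net_auc, "lasso_auc": lasso_auc, "n_causal": len(causal)}


# ---------------------------------------------------------------------------
# the annotation x feature-set experiment (train/test over replicates)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationExperimentConfig:
    """Knobs of the scaled-down annotation/feature-set experiment."""

    mcmc: McmcConfig = McmcConfig(iterations=4_000)
    p_cutoff: float = 0.1
    consensus_cutoff_fraction: float = 0.2  # of the training replicates, min 2
    max_network_genes: int = 15
    fallback_top_genes: int = 8
    model: str = "svm"
    max_train_rows: int = 2_000
    split_seed: int = 0
    responses: tuple[str, ...] = ("Q1", "Q2", "Q4", DISEASE)


def _train_test_split_replicates(
    n_replicates: int, seed: int
) -> tuple[list[int], list[int]]:
    rng = np.random.default_rng(derive_seed(seed, "split"))
    perm = rng.permutation(n_replicates)
    half = n_replicates // 2
    return sorted(perm[:half].tolist()), sorted(perm[half:].tolist())


def _screen_and_select(
    replicates: ReplicateSet,
    scores: GeneScoreMatrix,
    train_idx: Sequence[int],
    cfg: AnnotationExperimentConfig,
) -> tuple[list[str], pd.Series]:
    """Run the per-replicate screen on the training half; pick the gene node set.

    If the retained union is empty (typical for pure-noise annotations) the
    top ``fallback_top_genes`` genes by total retention count are used so the
    downstream contrast stays defined; an over-large union is truncated to the
    ``max_network_genes`` most stable genes.
    """
    train_set = ReplicateSet(
        variants=replicates.variants,
        genotypes=replicates.genotypes,
        phenotypes=[replicates.phenotypes[i] for i in train_idx],
        truth=replicates.truth,
        config=replicates.config,
    )
    results = [
        screen_replicates(train_set, scores, response, p_cutoff=cfg.p_cutoff)
        for response in cfg.responses
    ]
    union = union_over_responses(results)
    total_counts = sum(r.retention_counts for r in results)
    if not union:
        selected = list(total_counts.sort_values(ascending=False).index[: cfg.fallback_top_genes])
    else:
        ranked = total_counts.loc[sorted(union)].sort_values(ascending=False)
        selected = list(ranked.index[: cfg.max_network_genes])
    return sorted(selected), total_counts


@dataclass
class AnnotationExperimentResult:
    reports: dict  # (annotation, feature_set_name) -> PredictionReport
    summary: pd.DataFrame
    network_ranking_auc: float
    lasso_ranking_auc: float
    selected_genes: dict
    consensus_tables: dict
    train_replicates: list[int]
    test_replicates: list[int]


def run_annotation_experiment(
    replicates: ReplicateSet,
    cfg: AnnotationExperimentConfig | None = None,
    constraints: ConstraintSet | None = None,
    master_seed: int = 0,
) -> AnnotationExperimentResult:
    """Annotation-stratified, feature-set-stratified risk-prediction experiment.

    Half the replicates (seeded random split) train the screen, the consensus
    network and the risk model; the other half are evaluation replicates.  The
    three feature sets are nested: QTL genes; + environment; + quantitative
    traits.  Also computes the joint (network confidence) vs marginal (LASSO)
    gene-ranking AUCs on the training half, using the nonsynonymous scores.
    """
    cfg = cfg or AnnotationExperimentConfig()
    train_idx, test_idx = _train_test_split_replicates(
        replicates.n_replicates, cfg.split_seed ^ master_seed
    )
    n_train = len(train_idx)
    cutoff = max(2, math.ceil(cfg.consensus_cutoff_fraction * n_train))

    reports: dict[tuple[str, str], PredictionReport] = {}
    selected_genes: dict[str, list[str]] = {}
    tables: dict[str, EdgeConfidenceTable] = {}
    ranking_net = ranking_lasso = float("nan")

    for annotation in ("nonsynonymous", "synonymous"):
        scores = score_all_genes(replicates.genotypes, replicates.variants, annotation)
        selected, _ = _screen_and_select(replicates, scores, train_idx, cfg)
        selected_genes[annotation] = selected
        table, final_dag, _ = consensus_over_replicates(
            replicates,
            scores,
            selected,
            mcmc_config=cfg.mcmc,
            constraints=constraints,
            cutoff=cutoff,
            master_seed=derive_seed(master_seed, "consensus", annotation),
            replicate_indices=train_idx,
        )
        tables[annotation] = table
        from .consensus import build_node_specs

        specs = build_node_specs(selected)
        try:
            base = select_features(final_dag, specs, include_traits=False, include_env=False)
            qtl_genes = base.qtl_genes
        except DataError:
            # no QTL genes in the consensus network: fall back to the screened
            # set so the annotation contrast stays defined
            qtl_genes = tuple(selected)
        feature_variants = {
            "genes": FeatureSet(qtl_genes=qtl_genes),
            "genes+env": FeatureSet(
                environment=tuple(ENVIRONMENT_VARIABLES), qtl_genes=qtl_genes
            ),
            "genes+env+traits": FeatureSet(
                environment=tuple(ENVIRONMENT_VARIABLES),
                qtl_genes=qtl_genes,
                traits=tuple(TRAITS),
            ),
        }
        for fs_name, fs in feature_variants.items():
            X_train = pd.concat(
                [build_feature_frame(replicates.phenotypes[i], scores, fs) for i in train_idx]
            )
            y_train = np.concatenate(
                [replicates.phenotypes[i][DISEASE].to_numpy() for i in train_idx]
            )
            if len(y_train) > cfg.max_train_rows:
                rng = np.random.default_rng(derive_seed(master_seed, "subsample", annotation, fs_name))
                pick = rng.choice(len(y_train), size=cfg.max_train_rows, replace=False)
                X_train = X_train.iloc[pick]
                y_train = y_train[pick]
            predictor = train_predictor(
                X_train, y_train, model=cfg.model,
                seed=derive_seed(master_seed, "train", annotation, fs_name),
            )
            test_sets = [
                (
                    build_feature_frame(replicates.phenotypes[i], scores, fs),
                    replicates.phenotypes[i][DISEASE].to_numpy(),
                )
                for i in test_idx
            ]
            reports[(annotation, fs_name)] = evaluate(predictor, test_sets, fs, cfg.model)

        if annotation == "nonsynonymous":
            causal = sorted(replicates.truth.all_causal_genes)
            ranking_net = gene_ranking_auc(table, scores.genes, causal)
            pooled_ph = pd.concat([replicates.phenotypes[i] for i in train_idx])
            pooled_sc = pd.concat([scores.data for _ in train_idx])
            ranking_lasso = lasso_gene_ranking(
                pooled_sc, pooled_ph, causal, seed=derive_seed(master_seed, "lasso")
            )

    rows = [
        {
            "annotation": ann,
            "features": fs_name,
            "mean_auc": rep.mean_auc,
            "sd_auc": rep.sd_auc,
            "n_test_replicates": len(rep.per_replicate),
        }
        for (ann, fs_name), rep in reports.items()
    ]
    return AnnotationExperimentResult(
        reports=reports,
        summary=pd.DataFrame(rows),
        network_ranking_auc=ranking_net,
        lasso_ranking_auc=ranking_lasso,
        selected_genes=selected_genes,
        consensus_tables=tables,
        train_replicates=train_idx,
        test_replicates=test_idx,
    )
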