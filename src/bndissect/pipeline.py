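"""End-to-end orchestration: simulate -> score -> screen -> learn -> consensus -> predict.

Each stage reads the previous stage's plain-text artifacts from the output
directory and writes its own, so stages can be re-run in isolation; every
stochastic stage derives its seed from the master seed plus the stage name.
``run_pipeline`` chains the stages and writes a manifest with sha256 checksums
of every artifact; a failing stage aborts with its name after persisting the
partial manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from ._utils import derive_seed
from .bayesnet import McmcConfig, default_constraints, fit_parameters, write_dot, write_graphml
from .consensus import assemble_network_frame, build_node_specs, consensus_over_replicates
from .errors import BnDissectError, ConfigurationError, DataError
from .gene_scores import (
    combine_scores,
    estimate_true_positive_proportion,
    estimate_weight,
    score_all_genes,
)
from .prediction import (
    FeatureSet,
    build_feature_frame,
    evaluate,
    select_features,
    train_predictor,
)
from .screening import batch_marginal_pvalues, screen_bootstrap, screen_replicates, union_over_responses
from .synthetic_data import (
    DISEASE,
    ENVIRONMENT_VARIABLES,
    TRAITS,
    GeneratorConfig,
    ReplicateSet,
    generate_replicate_set,
)

__all__ = [
    "ScreenConfig",
    "ConsensusConfig",
    "PredictionConfig",
    "PipelineConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_score",
    "stage_screen",
    "stage_learn_consensus",
    "stage_predict",
]


@dataclass(frozen=True)
class ScreenConfig:
    mode: str = "replicates"  # or "bootstrap"
    p_cutoff: float = 0.1
    retention_threshold: int | None = None  # default: half the replicates
    responses: tuple[str, ...] = TRAITS + (DISEASE,)
    n_bootstrap: int = 200
    max_network_genes: int = 15


@dataclass(frozen=True)
class ConsensusConfig:
    cutoff: int | None = None  # default: max(2, ceil(0.025 * replicates)), >= 5 at 200
    cutoff_fraction: float = 0.025
    mode: str = "replicates"  # or "bootstrap"
    n_bootstrap: int = 20


@dataclass(frozen=True)
class PredictionConfig:
    model: str = "svm"
    features: str = "genes+env"  # genes | genes+env | genes+env+traits
    train_fraction: float = 0.5
    max_train_rows: int = 2_000


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    score_annotation: str = "combined"  # syn | nonsyn | all | combined
    weight_formula: str = "nonsyn_share"
    weight_override: float | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(iterations=4_000))
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    master_seed: int = 0
    raw_mode: bool = False  # raw likelihood, no Hastings ratio, env not exogenous

    @staticmethod
    def from_dict(payload: dict) -> "PipelineConfig":
        def build(cls, sub):
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(sub) - known
            if bad:
                raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(bad)}")
            for key in ("variants_per_gene", "maf_bounds", "maf_shape", "age_range", "responses"):
                if key in sub and isinstance(sub[key], list):
                    sub[key] = tuple(sub[key])
            if "causal_genes" in sub:
                sub["causal_genes"] = {t: tuple(g) for t, g in sub["causal_genes"].items()}
            return cls(**sub)

        payload = dict(payload)
        kwargs = {}
        for name, cls in (
            ("generator", GeneratorConfig),
            ("screen", ScreenConfig),
            ("mcmc", McmcConfig),
            ("consensus", ConsensusConfig),
            ("prediction", PredictionConfig),
        ):
            if name in payload:
                kwargs[name] = build(cls, dict(payload.pop(name)))
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        bad = set(payload) - known
        if bad:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(bad)}")
        kwargs.update(payload)
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        return PipelineConfig.from_dict(payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise DataError(f"missing required input file(s): {missing}")


def _load_replicate_set(config: PipelineConfig, out: Path) -> ReplicateSet:
    _require(out, "variants.tsv", "genotypes.tsv", "phenotypes.tsv", "ground_truth.json")
    return ReplicateSet(
        variants=bio.read_variant_table(out / "variants.tsv"),
        genotypes=bio.read_genotype_matrix(out / "genotypes.tsv"),
        phenotypes=bio.read_phenotypes(out / "phenotypes.tsv"),
        truth=bio.read_ground_truth(out / "ground_truth.json"),
        config=config.generator,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    if gen.seed == 0 and config.master_seed != 0:
        gen = gen.with_(seed=derive_seed(config.master_seed, "simulate"))
    rs = generate_replicate_set(gen)
    files = bio.replicate_set_to_dir(rs, out)
    return {"files": files, "generator_seed": gen.seed}


def _disease_pvalues(rs: ReplicateSet, scores) -> np.ndarray:
    """Disease p-values of the informative genes of one annotation (for pi1)."""
    from .gene_scores import informative_genes

    genes = informative_genes(scores)
    ph = rs.phenotypes[0]
    return batch_marginal_pvalues(
        scores.data[genes].to_numpy(),
        ph["smoking"].to_numpy(),
        ph[DISEASE].to_numpy(),
        "binary",
    )


def stage_score(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    rs = _load_replicate_set(config, out)
    syn = score_all_genes(rs.genotypes, rs.variants, "synonymous")
    nonsyn = score_all_genes(rs.genotypes, rs.variants, "nonsynonymous")
    bio.write_gene_scores(syn, out / "scores_synonymous.tsv")
    bio.write_gene_scores(nonsyn, out / "scores_nonsynonymous.tsv")
    info: dict = {"weight_formula": config.weight_formula}
    if config.weight_override is not None:
        w = float(config.weight_override)
        info["w_source"] = "override"
    elif len(syn.genes) >= 50:
        p_syn = np.clip(_disease_pvalues(rs, syn), 1e-300, 1.0)
        p_nonsyn = np.clip(_disease_pvalues(rs, nonsyn), 1e-300, 1.0)
        pi1_s = estimate_true_positive_proportion(p_syn)
        pi1_ns = estimate_true_positive_proportion(p_nonsyn)
        try:
            est = estimate_weight(pi1_s, pi1_ns, formula=config.weight_formula)
            w = est.w
            info["w_source"] = "estimated"
        except BnDissectError:
            w = 0.5
            info["w_source"] = "fallback_equal"
        info.update({"pi1_synonymous": pi1_s, "pi1_nonsynonymous": pi1_ns})
        alt = "as_printed" if config.weight_formula == "nonsyn_share" else "nonsyn_share"
        info["w_alternative_formula"] = {alt: 1.0 - w if pi1_s + pi1_ns > 0 else 0.5}
    else:
        w = 0.5
        info["w_source"] = "fallback_too_few_genes"
    combined = combine_scores(syn, nonsyn, w)
    bio.write_gene_scores(combined, out / "scores_combined.tsv")
    info["w"] = w
    (out / "weight.json").write_text(json.dumps(info, indent=2) + "\n")
    return info


_SCORE_FILE = {
    "syn": "scores_synonymous.tsv",
    "nonsyn": "scores_nonsynonymous.tsv",
    "combined": "scores_combined.tsv",
}


def _load_scores(config: PipelineConfig, out: Path):
    name = _SCORE_FILE.get(config.score_annotation, "scores_combined.tsv")
    _require(out, name)
    return bio.read_gene_scores(out / name)


def stage_screen(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    rs = _load_replicate_set(config, out)
    scores = _load_scores(config, out)
    sc = config.screen
    results = []
    for response in sc.responses:
        if sc.mode == "replicates":
            res = screen_replicates(
                rs, scores, response, p_cutoff=sc.p_cutoff,
                retention_threshold=sc.retention_threshold,
            )
        elif sc.mode == "bootstrap":
            pooled_ph = pd.concat(rs.phenotypes)
            pooled_sc = pd.concat([scores.data for _ in rs.phenotypes])
            res = screen_bootstrap(
                pooled_sc, pooled_ph, response, n_bootstrap=sc.n_bootstrap,
                p_cutoff=sc.p_cutoff, retention_threshold=sc.retention_threshold,
                seed=derive_seed(config.master_seed, "screen", response),
            )
        else:
            raise ConfigurationError(f"unknown screen mode: {sc.mode!r}")
        bio.write_screen_result(
            res, out / f"screen_{response}.tsv", out / f"screen_{response}.json"
        )
        results.append(res)
    union = union_over_responses(results)
    total_counts = sum(r.retention_counts for r in results)
    if union:
        ranked = total_counts.loc[sorted(union)].sort_values(ascending=False)
        selected = sorted(ranked.index[: sc.max_network_genes])
    else:
        selected = sorted(
            total_counts.sort_values(ascending=False).index[: min(5, len(total_counts))]
        )
    payload = {"union": sorted(union), "selected": selected, "mode": sc.mode}
    (out / "selection.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def stage_learn_consensus(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    rs = _load_replicate_set(config, out)
    scores = _load_scores(config, out)
    _require(out, "selection.json")
    selected = json.loads((out / "selection.json").read_text())["selected"]
    mcmc = config.mcmc
    constraints = default_constraints(exogenous_environment=not config.raw_mode)
    if config.raw_mode:
        mcmc = dataclasses.replace(mcmc, score_kind="loglik", hastings=False)
    cc = config.consensus
    if cc.mode == "bootstrap":
        n_networks = cc.n_bootstrap
    elif cc.mode == "replicates":
        n_networks = rs.n_replicates
    else:
        raise ConfigurationError(f"unknown consensus mode: {cc.mode!r}")
    cutoff = cc.cutoff
    if cutoff is None:
        cutoff = max(2, math.ceil(cc.cutoff_fraction * n_networks))
    if cc.mode == "bootstrap":
        from .consensus import consensus_over_bootstrap

        table, final, networks = consensus_over_bootstrap(
            rs,
            scores,
            selected,
            n_bootstrap=cc.n_bootstrap,
            mcmc_config=mcmc,
            constraints=constraints,
            cutoff=cutoff,
            master_seed=derive_seed(config.master_seed, "consensus"),
        )
    else:
        table, final, networks = consensus_over_replicates(
            rs,
            scores,
            selected,
            mcmc_config=mcmc,
            constraints=constraints,
            cutoff=cutoff,
            master_seed=derive_seed(config.master_seed, "consensus"),
        )
    bio.write_edge_table(table, out / "edge_confidence.tsv", cutoff=cutoff)
    specs = build_node_specs(selected)
    roles = [s.role for s in specs]
    write_graphml(final, out / "final_network.graphml", roles=roles)
    labels = {
        (r["source"], r["target"]): int(r["count"]) for _, r in table.counts.iterrows()
    }
    write_dot(final, out / "final_network.dot", roles=roles, edge_labels=labels)
    frame = pd.concat(
        [assemble_network_frame(ph, scores, selected) for ph in rs.phenotypes]
    )
    params = fit_parameters(final, frame)
    (out / "parameters.json").write_text(
        json.dumps(
            {
                node: {
                    "parents": list(p.coefficients),
                    "intercept": p.intercept,
                    "coefficients": p.coefficients,
                    "sigma": p.sigma,
                }
                for node, p in params.items()
            },
            indent=2,
        )
        + "\n"
    )
    return {"cutoff": cutoff, "n_edges": final.n_edges, "selected": selected}


def stage_predict(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    rs = _load_replicate_set(config, out)
    scores = _load_scores(config, out)
    _require(out, "selection.json", "final_network.graphml")
    selected = json.loads((out / "selection.json").read_text())["selected"]
    import networkx as nx

    from .bayesnet import Dag

    specs = build_node_specs(selected)
    node_names = tuple(s.name for s in specs)
    g = nx.read_graphml(out / "final_network.graphml")
    final = Dag(node_names, edges=list(g.edges()))
    pc = config.prediction
    include_env = pc.features in ("genes+env", "genes+env+traits")
    include_traits = pc.features == "genes+env+traits"
    try:
        fs = select_features(final, specs, include_traits=include_traits, include_env=include_env)
    except DataError:
        fs = FeatureSet(
            environment=tuple(ENVIRONMENT_VARIABLES) if include_env else (),
            qtl_genes=tuple(selected),
            traits=tuple(TRAITS) if include_traits else (),
        )
    rng = np.random.default_rng(derive_seed(config.master_seed, "predict-split"))
    perm = rng.permutation(rs.n_replicates)
    half = max(1, int(pc.train_fraction * rs.n_replicates))
    train_idx, test_idx = sorted(perm[:half]), sorted(perm[half:])
    if not test_idx:
        raise DataError("prediction needs at least one held-out replicate")
    X_train = pd.concat(
        [build_feature_frame(rs.phenotypes[i], scores, fs) for i in train_idx]
    )
    y_train = np.concatenate([rs.phenotypes[i][DISEASE].to_numpy() for i in train_idx])
    if len(y_train) > pc.max_train_rows:
        pick = rng.choice(len(y_train), size=pc.max_train_rows, replace=False)
        X_train, y_train = X_train.iloc[pick], y_train[pick]
    predictor = train_predictor(
        X_train, y_train, model=pc.model, seed=derive_seed(config.master_seed, "train")
    )
    test_sets = [
        (build_feature_frame(rs.phenotypes[i], scores, fs), rs.phenotypes[i][DISEASE].to_numpy())
        for i in test_idx
    ]
    report = evaluate(predictor, test_sets, fs, pc.model)
    report.per_replicate.rename_axis("replicate").reset_index().to_csv(
        out / "prediction_report.tsv", sep="\t", index=False
    )
    payload = {
        "mean_auc": report.mean_auc,
        "sd_auc": report.sd_auc,
        "model": pc.model,
        "features": pc.features,
        "qtl_genes": list(fs.qtl_genes),
        "train_replicates": [int(i) for i in train_idx],
        "test_replicates": [int(i) for i in test_idx],
    }
    (out / "prediction_report.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload


_STAGES = (
    ("simulate", stage_simulate),
    ("score", stage_score),
    ("screen", stage_screen),
    ("learn_consensus", stage_learn_consensus),
    ("predict", stage_predict),
)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages in order and write ``manifest.json``.

    The manifest records the configuration, per-stage summaries, and sha256
    checksums of every artifact; on a stage failure the partial manifest is
    persisted with the failing stage's name before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "master_seed": config.master_seed,
        "stages": {},
    }
    try:
        for name, fn in _STAGES:
            manifest["stages"][name] = fn(config, out)
    except Exception as exc:
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        raise
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
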