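"""Synthetic mini-exome cohort generator with phenotype replicates.

Emulates a GAW17-style simulated dataset: a fixed genotype matrix of mostly
rare variants grouped into genes, each variant annotated synonymous or
nonsynonymous, and many phenotype *replicates* that share the genotypes but
re-draw covariates, quantitative traits and disease status.  Causal genes act
on quantitative traits through their (standardized) nonsynonymous weighted-sum
burden score; disease is a liability-threshold trait whose liability combines
the quantitative traits, environmental covariates and an unobserved latent
component.

Ground truth (causal gene sets and the true edge list of the generating
model) is recorded on every :class:`ReplicateSet` so downstream stages can be
scored against it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "TRAITS",
    "ENVIRONMENT_VARIABLES",
    "DISEASE",
    "GeneratorConfig",
    "GroundTruth",
    "ReplicateSet",
    "generate_variants",
    "generate_genotypes",
    "simulate_phenotypes",
    "generate_replicate_set",
    "default_gene_ids",
]

TRAITS = ("Q1", "Q2", "Q4")
ENVIRONMENT_VARIABLES = ("age", "sex", "smoking")
DISEASE = "affected"

# rng stream labels (kept distinct so stages can be re-run in isolation)
_STREAM_VARIANTS = "variants"
_STREAM_GENOTYPES = "genotypes"
_STREAM_PHENOTYPES = "phenotypes"


def default_gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def _default_causal_genes() -> dict[str, tuple[str, ...]]:
    ids = default_gene_ids(10)
    return {"Q1": tuple(ids[:6]), "Q2": tuple(ids[6:10])}


def _default_env_effects() -> dict[str, dict[str, float]]:
    # Age enters centred at the midpoint of ``age_range`` so intercepts stay 0.
    return {
        "Q1": {"smoking": 0.5},
        "Q2": {},
        "Q4": {"age": 0.02, "smoking": 0.5},
        "liability": {"smoking": 0.8, "sex": 0.5, "age": 0.015},
    }


def _default_liability_weights() -> dict[str, float]:
    return {"Q1": 0.5, "Q2": 0.5, "Q4": 0.3}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults follow the emulated workshop design where it is documented
    (697 individuals, 200 phenotype replicates, ~30% affected, rare-skewed
    MAF spectrum, disease driven predominantly by nonsynonymous variation);
    everything else is a free parameter of the generator.
    """

    n_individuals: int = 697
    n_genes: int = 60
    variants_per_gene: tuple[int, int] = (3, 10)
    fraction_nonsynonymous: float = 0.7
    maf_bounds: tuple[float, float] = (5e-4, 0.1)
    #: Beta(a, b) shape of the MAF density before truncation to ``maf_bounds``;
    #: the default is heavily rare-skewed.
    maf_shape: tuple[float, float] = (0.3, 4.0)
    causal_genes: Mapping[str, tuple[str, ...]] = field(
        default_factory=_default_causal_genes
    )
    #: per-causal-gene coefficient, in trait-SD units, applied to the
    #: standardized nonsynonymous burden score of that gene.
    effect_size: float = 0.5
    env_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_env_effects
    )
    liability_weights: Mapping[str, float] = field(
        default_factory=_default_liability_weights
    )
    latent_liability_sd: float = 1.0
    prevalence: float = 0.3
    n_replicates: int = 200
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 80.0)
    sex_prob: float = 0.5
    smoking_prob: float = 0.3

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigurationError("counts must be >= 1")
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("variants_per_gene must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.fraction_nonsynonymous <= 1.0:
            raise ConfigurationError("fraction_nonsynonymous must lie in [0, 1]")
        mlo, mhi = self.maf_bounds
        if not (0.0 < mlo <= mhi <= 0.5):
            raise ConfigurationError("maf_bounds must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.latent_liability_sd < 0:
            raise ConfigurationError("latent_liability_sd must be >= 0")
        gene_ids = set(default_gene_ids(self.n_genes))
        for trait, genes in self.causal_genes.items():
            if trait not in TRAITS:
                raise ConfigurationError(f"unknown trait in causal_genes: {trait!r}")
            missing = set(genes) - gene_ids
            if missing:
                raise ConfigurationError(
                    f"causal genes for {trait} not among generated genes: {sorted(missing)}"
                )

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Functional update (``dataclasses.replace`` convenience)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: causal genes and the true edge list."""

    causal_genes: Mapping[str, tuple[str, ...]]
    true_edges: tuple[tuple[str, str], ...]

    @property
    def all_causal_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.causal_genes.values():
            out.update(genes)
        return frozenset(out)


@dataclass
class ReplicateSet:
    """Shared genotypes plus per-replicate phenotype tables and ground truth."""

    variants: pd.DataFrame
    genotypes: pd.DataFrame
    phenotypes: list[pd.DataFrame]
    truth: GroundTruth
    config: GeneratorConfig

    @property
    def n_replicates(self) -> int:
        return len(self.phenotypes)

    def pooled_phenotypes(self) -> pd.DataFrame:
        """All replicates stacked, with a ``replicate`` column and unique index."""
        frames = []
        for r, ph in enumerate(self.phenotypes):
            f = ph.copy()
            f.insert(0, "replicate", r)
            f.index = [f"{ind}_r{r}" for ind in ph.index]
            frames.append(f)
        return pd.concat(frames, axis=0)

    def genotype_checksum(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.genotypes.to_numpy()).tobytes()
        ).hexdigest()


def generate_variants(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the variant table: gene assignment, MAF spectrum and annotation.

    MAFs are Beta(a, b) rescaled into ``maf_bounds`` (rare-skewed by default);
    each variant is nonsynonymous independently with probability
    ``fraction_nonsynonymous``.
    """
    config.validate()
    from ._utils import rng_for

    rng = rng_for(config.seed, _STREAM_VARIANTS)
    lo, hi = config.variants_per_gene
    counts = rng.integers(lo, hi, size=config.n_genes, endpoint=True)
    gene_ids = np.repeat(default_gene_ids(config.n_genes), counts)
    m = int(counts.sum())
    mlo, mhi = config.maf_bounds
    a, b = config.maf_shape
    maf = mlo + (mhi - mlo) * rng.beta(a, b, size=m)
    annotation = np.where(
        rng.random(m) < config.fraction_nonsynonymous,
        "nonsynonymous",
        "synonymous",
    )
    return pd.DataFrame(
        {
            "variant_id": [f"V{j:06d}" for j in range(m)],
            "gene_id": gene_ids,
            "maf": maf,
            "annotation": annotation,
        }
    )


def generate_genotypes(
    variants: pd.DataFrame, n_individuals: int, seed: int
) -> pd.DataFrame:
    """Minor-allele count matrix, each entry Binomial(2, maf) (Hardy-Weinberg)."""
    if n_individuals < 1:
        raise ConfigurationError("n_individuals must be >= 1")
    from ._utils import rng_for

    rng = rng_for(seed, _STREAM_GENOTYPES)
    maf = variants["maf"].to_numpy()
    mat = rng.binomial(2, maf[None, :], size=(n_individuals, maf.size))
    index = [f"I{i:05d}" for i in range(n_individuals)]
    return pd.DataFrame(
        mat.astype(np.int8), index=index, columns=variants["variant_id"].tolist()
    )


def _standardized_nonsyn_burdens(
    genotypes: pd.DataFrame, variants: pd.DataFrame, genes: Sequence[str]
) -> dict[str, np.ndarray]:
    """Z-scored nonsynonymous weighted-sum burden per causal gene.

    Uses the variant table's true MAFs as weights (the generating model knows
    them); a gene whose nonsynonymous burden is constant in the sample
    contributes nothing.
    """
    from .gene_scores import weighted_sum_score

    out: dict[str, np.ndarray] = {}
    for gene in genes:
        s = weighted_sum_score(
            genotypes, variants, gene, annotation_filter="nonsynonymous",
            maf_source="table",
        ).to_numpy(dtype=float)
        sd = s.std()
        out[gene] = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    return out


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    config: GeneratorConfig,
    replicate_index: int = 0,
) -> pd.DataFrame:
    """One phenotype replicate for a fixed genotype matrix.

    Covariates, trait noise and the latent liability component are re-drawn per
    ``replicate_index``; genotypes never are.  Disease status is a liability
    threshold: ``affected = 1`` iff liability exceeds its empirical
    (1 - prevalence) quantile in this replicate, so the affected fraction is
    calibrated to ``prevalence`` by construction.  The realized liability is
    kept as a column (it is latent: downstream models must not use it, but
    oracle evaluations may).
    """
    config.validate()
    known_genes = set(variants["gene_id"])
    for trait, genes in config.causal_genes.items():
        missing = set(genes) - known_genes
        if missing:
            raise ConfigurationError(
                f"causal genes for {trait} absent from variant table: {sorted(missing)}"
            )
    from ._utils import rng_for

    rng = rng_for(config.seed, _STREAM_PHENOTYPES, replicate_index)
    n = genotypes.shape[0]
    age_lo, age_hi = config.age_range
    age = rng.uniform(age_lo, age_hi, size=n)
    sex = (rng.random(n) < config.sex_prob).astype(int)
    smoking = (rng.random(n) < config.smoking_prob).astype(int)
    age_c = age - 0.5 * (age_lo + age_hi)
    env = {"age": age_c, "sex": sex.astype(float), "smoking": smoking.astype(float)}

    causal_union = sorted(
        {g for genes in config.causal_genes.values() for g in genes}
    )
    burdens = _standardized_nonsyn_burdens(genotypes, variants, causal_union)

    traits: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        y = np.zeros(n)
        for var, coef in config.env_effects.get(trait, {}).items():
            y += coef * env[var]
        for gene in config.causal_genes.get(trait, ()):
            y += config.effect_size * burdens[gene]
        y += rng.standard_normal(n)
        traits[trait] = y

    liability = np.zeros(n)
    for trait, w in config.liability_weights.items():
        liability += w * traits[trait]
    for var, coef in config.env_effects.get("liability", {}).items():
        liability += coef * env[var]
    liability += config.latent_liability_sd * rng.standard_normal(n)
    threshold = np.quantile(liability, 1.0 - config.prevalence)
    affected = (liability > threshold).astype(int)

    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "Q1": traits["Q1"],
            "Q2": traits["Q2"],
            "Q4": traits["Q4"],
            "affected": affected,
            "liability": liability,
        },
        index=genotypes.index,
    )


def _true_edges(config: GeneratorConfig) -> tuple[tuple[str, str], ...]:
    edges: list[tuple[str, str]] = []
    for trait in TRAITS:
        for var, coef in config.env_effects.get(trait, {}).items():
            if coef != 0:
                edges.append((var, trait))
        for gene in config.causal_genes.get(trait, ()):
            edges.append((gene, trait))
    for trait, w in config.liability_weights.items():
        if w != 0:
            edges.append((trait, DISEASE))
    for var, coef in config.env_effects.get("liability", {}).items():
        if coef != 0:
            edges.append((var, DISEASE))
    return tuple(edges)


def generate_replicate_set(config: GeneratorConfig) -> ReplicateSet:
    """Full synthetic dataset: variants, genotypes, all phenotype replicates."""
    config.validate()
    variants = generate_variants(config)
    genotypes = generate_genotypes(variants, config.n_individuals, config.seed)
    phenotypes = [
        simulate_phenotypes(genotypes, variants, config, replicate_index=r)
        for r in range(config.n_replicates)
    ]
    truth = GroundTruth(
        causal_genes={t: tuple(g) for t, g in config.causal_genes.items()},
        true_edges=_true_edges(config),
    )
    return ReplicateSet(
        variants=variants,
        genotypes=genotypes,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )


def check_replicate_set(rs: ReplicateSet) -> None:
    """Raise :class:`DataError` if the replicate set is internally inconsistent."""
    if list(rs.genotypes.columns) != rs.variants["variant_id"].tolist():
        raise DataError("genotype columns do not match variant table order")
    for ph in rs.phenotypes:
        if not ph.index.equals(rs.genotypes.index):
            raise DataError("phenotype replicate indexes a different cohort")
    known = set(rs.variants["gene_id"])
    for trait, genes in rs.truth.causal_genes.items():
        if not set(genes) <= known:
            raise DataError(f"ground-truth genes for {trait} missing from variants")
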