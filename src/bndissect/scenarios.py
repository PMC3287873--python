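"""Canonical study scenarios used by the analysis scripts and the test suite.

Each function returns a :class:`GeneratorConfig` (plus, where relevant, the
matching experiment knobs) describing one simulated study design at desk
scale.  The numbers here are the study conditions themselves — sample sizes,
effect sizes and replicate counts a rare-variant cohort analysis of this kind
would plausibly have — and the rest of the package treats them as fixed
inputs.
"""

from __future__ import annotations

from .bayesnet import McmcConfig
from .prediction import AnnotationExperimentConfig
from .synthetic_data import GeneratorConfig, default_gene_ids

__all__ = [
    "structure_recovery_scenario",
    "weight_recovery_scenario",
    "annotation_experiment_scenario",
    "pleiotropic_ranking_scenario",
    "null_scenario",
]


def structure_recovery_scenario(seed: int = 0) -> GeneratorConfig:
    """20 genes, 5 causal for Q1 at 0.5 SD per gene, n = 1000, 20 replicates."""
    ids = default_gene_ids(20)
    return GeneratorConfig(
        n_individuals=1_000,
        n_genes=20,
        n_replicates=20,
        causal_genes={"Q1": tuple(ids[:5])},
        effect_size=0.5,
        seed=seed,
    )


def weight_recovery_scenario(seed: int = 0) -> GeneratorConfig:
    """150 genes, 30 causal (Q1/Q2) with nonsynonymous effects, n = 1000.

    One phenotype replicate suffices: the annotation weight is estimated from
    a single cohort's per-gene disease p-values.
    """
    ids = default_gene_ids(150)
    return GeneratorConfig(
        n_individuals=1_000,
        n_genes=150,
        n_replicates=1,
        causal_genes={"Q1": tuple(ids[:15]), "Q2": tuple(ids[15:30])},
        effect_size=0.75,
        seed=seed,
    )


def annotation_experiment_scenario(
    seed: int = 0,
) -> tuple[GeneratorConfig, AnnotationExperimentConfig]:
    """Scaled-down annotation x feature-set prediction design.

    16 phenotype replicates split half/half into training and evaluation;
    8 + 8 causal genes on Q1/Q2 acting through nonsynonymous burden; the
    environment contributes to the traits and directly to the liability, so
    the three feature sets carry strictly nested information.
    """
    ids = default_gene_ids(40)
    gen = GeneratorConfig(
        n_individuals=400,
        n_genes=40,
        n_replicates=16,
        causal_genes={"Q1": tuple(ids[:8]), "Q2": tuple(ids[8:16])},
        effect_size=0.6,
        seed=seed,
    )
    exp = AnnotationExperimentConfig(
        mcmc=McmcConfig(iterations=3_000, convergence_window=1_000),
        consensus_cutoff_fraction=0.25,
        max_network_genes=18,
        fallback_top_genes=8,
        max_train_rows=2_000,
    )
    return gen, exp


def pleiotropic_ranking_scenario(seed: int = 0) -> GeneratorConfig:
    """Gene-ranking comparison design: pleiotropic and trait-specific QTLs.

    20 genes; 4 affect both Q1 and Q2, 2 affect only Q1, 2 only Q2, at a
    weak 0.15 SD per-gene effect so neither ranking method saturates.
    """
    ids = default_gene_ids(20)
    pleio, q1_only, q2_only = ids[:4], ids[4:6], ids[6:8]
    return GeneratorConfig(
        n_individuals=400,
        n_genes=20,
        n_replicates=8,
        causal_genes={
            "Q1": tuple(pleio + q1_only),
            "Q2": tuple(pleio + q2_only),
        },
        effect_size=0.15,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_genes: int = 50) -> GeneratorConfig:
    """No causal genes at all: every gene-trait association is spurious."""
    return GeneratorConfig(
        n_individuals=1_000,
        n_genes=n_genes,
        n_replicates=20,
        causal_genes={},
        effect_size=0.0,
        seed=seed,
    )
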