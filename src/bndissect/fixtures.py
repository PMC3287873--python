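"""Small canonical datasets used across the test suite and docs.

Every fixture is generated programmatically and deterministically from a
seed; nothing is stored on disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayesnet import Dag, NodeSpec

FIXTURE_IDS = ("three_node_mcmc", "burden_toy", "seven_dag_confidence")

__all__ = ["FIXTURE_IDS", "make_fixtures", "three_node_mcmc", "burden_toy", "seven_dag_confidence"]


def three_node_mcmc(seed: int = 0, n: int = 200):
    """Three mildly-dependent Gaussian columns for sampler-correctness checks.

    Y leans on X (coefficient 0.4); Z is independent noise.  Small enough that
    all 25 three-node DAGs can be enumerated and scored exactly.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 0.4 * x + rng.standard_normal(n)
    z = rng.standard_normal(n)
    frame = pd.DataFrame({"X": x, "Y": y, "Z": z})
    nodes = [NodeSpec("X", "trait"), NodeSpec("Y", "trait"), NodeSpec("Z", "trait")]
    return frame, nodes


def burden_toy():
    """One gene, one variant with table MAF 0.1, 100 individuals.

    The first individual is homozygous for the minor allele, so its
    Madsen-Browning burden score is 2 / sqrt(100 * 0.1 * 0.9) = 2/3.
    """
    variants = pd.DataFrame(
        {
            "variant_id": ["V0"],
            "gene_id": ["G0"],
            "maf": [0.1],
            "annotation": ["nonsynonymous"],
        }
    )
    g = np.zeros((100, 1), dtype=np.int8)
    g[0, 0] = 2
    genotypes = pd.DataFrame(
        g, index=[f"I{i:03d}" for i in range(100)], columns=["V0"]
    )
    return variants, genotypes


def seven_dag_confidence():
    """Seven small DAGs over {A, B, C} with hand-countable edge overlaps.

    Expected directed-edge tallies over the seven networks:
    A->B: 5, B->C: 4, A->C: 2, C->B: 1.
    """
    names = ("A", "B", "C")
    edge_lists = [
        [("A", "B"), ("B", "C")],
        [("A", "B"), ("B", "C")],
        [("A", "B"), ("A", "C")],
        [("A", "B"), ("B", "C")],
        [("A", "B")],
        [("B", "C"), ("A", "C")],
        [("C", "B")],
    ]
    dags = [Dag(names, edges=e) for e in edge_lists]
    expected_counts = {("A", "B"): 5, ("B", "C"): 4, ("A", "C"): 2, ("C", "B"): 1}
    return dags, expected_counts


def make_fixtures(seed: int = 0) -> dict:
    """The documented fixture bundle, identical across runs for one seed."""
    return {
        "three_node_mcmc": three_node_mcmc(seed=seed),
        "burden_toy": burden_toy(),
        "seven_dag_confidence": seven_dag_confidence(),
    }
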