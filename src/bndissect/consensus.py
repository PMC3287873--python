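"""Edge-confidence aggregation of replicate-learned networks.

The confidence score of a directed edge is the count of replicate (or
bootstrap) networks containing it; the final network keeps edges whose count
reaches the cutoff ("at least five replicates" is inclusive).  Thresholding
can in principle leave a directed cycle; when it does, the lowest-count edge
in each cycle is dropped deterministically and the conflict is flagged, so the
final object is always a DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .bayesnet import (
    ConstraintSet,
    Dag,
    GaussianNetworkData,
    MCMCChain,
    McmcConfig,
    NodeSpec,
)
from .errors import DataError
from .gene_scores import GeneScoreMatrix
from .synthetic_data import DISEASE, ENVIRONMENT_VARIABLES, TRAITS, ReplicateSet

__all__ = [
    "EdgeConfidenceTable",
    "edge_confidence",
    "threshold_network",
    "consensus_over_replicates",
    "consensus_over_bootstrap",
    "build_node_specs",
    "assemble_network_frame",
]


@dataclass
class EdgeConfidenceTable:
    """Per-directed-edge replicate counts (edges absent everywhere are omitted)."""

    counts: pd.DataFrame  # columns: source, target, count
    n_networks: int
    node_names: tuple[str, ...]
    dropped_edges: list = field(default_factory=list)  # cycle-resolution log

    def count(self, source: str, target: str) -> int:
        m = self.counts[
            (self.counts["source"] == source) & (self.counts["target"] == target)
        ]
        return 0 if m.empty else int(m["count"].iloc[0])

    def retained(self, cutoff: int) -> pd.DataFrame:
        return self.counts[self.counts["count"] >= cutoff]


def edge_confidence(networks: Sequence[Dag]) -> EdgeConfidenceTable:
    """Count, for every directed edge, the networks that contain it."""
    if not networks:
        raise DataError("need at least one network")
    universe = networks[0].names
    tally: dict[tuple[str, str], int] = {}
    for g in networks:
        if g.names != universe:
            raise DataError("networks must share the same node universe")
        for e in g.edges():
            tally[e] = tally.get(e, 0) + 1
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = pd.DataFrame(
        [(s, t, c) for (s, t), c in rows], columns=["source", "target", "count"]
    )
    return EdgeConfidenceTable(
        counts=counts, n_networks=len(networks), node_names=universe
    )


def threshold_network(table: EdgeConfidenceTable, cutoff: int = 5) -> Dag:
    """Keep edges with count >= cutoff; break any residual directed cycles.

    Cycle resolution drops the lowest-count edge of each cycle (ties broken
    lexicographically on (source, target)), recorded in
    ``table.dropped_edges``.
    """
    if cutoff < 1:
        raise DataError("cutoff must be >= 1")
    import networkx as nx

    kept = table.retained(cutoff)
    g = nx.DiGraph()
    g.add_nodes_from(table.node_names)
    for _, row in kept.iterrows():
        g.add_edge(row["source"], row["target"], count=int(row["count"]))
    table.dropped_edges = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        worst = min(
            cycle, key=lambda e: (g.edges[e[0], e[1]]["count"], e[0], e[1])
        )
        table.dropped_edges.append(
            (worst[0], worst[1], g.edges[worst[0], worst[1]]["count"])
        )
        g.remove_edge(worst[0], worst[1])
    return Dag(table.node_names, edges=list(g.edges()))


def build_node_specs(gene_names: Sequence[str]) -> list[NodeSpec]:
    """Standard node set: environment + selected genes + traits + disease."""
    specs = [NodeSpec(v, "environment") for v in ENVIRONMENT_VARIABLES]
    specs += [NodeSpec(g, "gene") for g in sorted(gene_names)]
    specs += [NodeSpec(t, "trait") for t in TRAITS]
    specs.append(NodeSpec(DISEASE, "disease"))
    return specs


def assemble_network_frame(
    phenotypes: pd.DataFrame,
    scores: GeneScoreMatrix,
    gene_names: Sequence[str],
) -> pd.DataFrame:
    """One replicate's node-data frame: covariates, gene scores, traits, disease."""
    missing = [g for g in gene_names if g not in scores.data.columns]
    if missing:
        raise DataError(f"selected genes missing from score matrix: {missing}")
    cols = {v: phenotypes[v].to_numpy(dtype=float) for v in ENVIRONMENT_VARIABLES}
    for g in sorted(gene_names):
        cols[g] = scores.data[g].to_numpy(dtype=float)
    for t in TRAITS:
        cols[t] = phenotypes[t].to_numpy(dtype=float)
    cols[DISEASE] = phenotypes[DISEASE].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=phenotypes.index)


def consensus_over_replicates(
    replicates: ReplicateSet,
    scores: GeneScoreMatrix,
    selected_genes: Sequence[str],
    mcmc_config: McmcConfig | None = None,
    constraints: ConstraintSet | None = None,
    cutoff: int = 5,
    master_seed: int = 0,
    replicate_indices: Sequence[int] | None = None,
) -> tuple[EdgeConfidenceTable, Dag, list[Dag]]:
    """Learn one network per replicate, aggregate edge counts, threshold.

    Gene scores are shared across replicates (genotypes are fixed); each
    replicate's chain gets a seed derived from ``master_seed`` and its index.
    Returns (confidence table, final DAG, per-replicate best DAGs).
    """
    mcmc_config = mcmc_config or McmcConfig()
    specs = build_node_specs(selected_genes)
    indices = (
        list(range(replicates.n_replicates))
        if replicate_indices is None
        else list(replicate_indices)
    )
    networks: list[Dag] = []
    for r in indices:
        frame = assemble_network_frame(replicates.phenotypes[r], scores, selected_genes)
        data = GaussianNetworkData(frame, specs, standardize=mcmc_config.standardize)
        rng = np.random.default_rng(derive_seed(master_seed, "mcmc", r))
        chain = MCMCChain(data, constraints=constraints, config=mcmc_config, rng=rng)
        chain.run()
        networks.append(chain.best_dag())
    table = edge_confidence(networks)
    final = threshold_network(table, cutoff=cutoff)
    return table, final, networks


def consensus_over_bootstrap(
    replicates: ReplicateSet,
    scores: GeneScoreMatrix,
    selected_genes: Sequence[str],
    n_bootstrap: int = 200,
    mcmc_config: McmcConfig | None = None,
    constraints: ConstraintSet | None = None,
    cutoff: int = 5,
    master_seed: int = 0,
) -> tuple[EdgeConfidenceTable, Dag, list[Dag]]:
    """Replicate-free variant: edge confidence from bootstrap resamples.

    The replicates are pooled into one sample (gene-score rows repeated per
    replicate), each bootstrap draws individuals with replacement at the size
    of one replicate, and the resamples are treated exactly like replicates.
    """
    mcmc_config = mcmc_config or McmcConfig()
    specs = build_node_specs(selected_genes)
    frames = [
        assemble_network_frame(ph, scores, selected_genes)
        for ph in replicates.phenotypes
    ]
    pooled = pd.concat(frames, ignore_index=True)
    n_draw = len(frames[0])
    networks: list[Dag] = []
    for b in range(n_bootstrap):
        rng = np.random.default_rng(derive_seed(master_seed, "bootstrap-mcmc", b))
        idx = rng.integers(0, len(pooled), size=n_draw)
        data = GaussianNetworkData(
            pooled.iloc[idx].reset_index(drop=True), specs,
            standardize=mcmc_config.standardize,
        )
        chain = MCMCChain(data, constraints=constraints, config=mcmc_config, rng=rng)
        chain.run()
        networks.append(chain.best_dag())
    table = edge_confidence(networks)
    final = threshold_network(table, cutoff=cutoff)
    return table, final, networks
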