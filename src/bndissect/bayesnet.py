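"""Constrained Bayesian-network structure learning with linear-Gaussian scores.

Nodes are typed (environment, gene, trait, disease) and each node's
conditional density given its parents is linear Gaussian:
``X | u1..uK ~ Normal(a0 + sum_k ak uk, sigma^2)``.  The network score is the
sum of per-node scores (maximized Gaussian log-likelihood, or BIC by default:
``loglik - (K + 2)/2 * ln n`` per node, counting intercept, K coefficients and
the variance), so it decomposes over nodes and structure moves re-score only
the affected children.

Structure search is a Metropolis-Hastings random walk over DAGs with three
move types — add, delete, reverse an edge — proposed uniformly from the legal
neighborhood.  Legality enforces acyclicity, a parent cap, and a role-based
edge ban list: no edges from traits or disease into genes, no edges between
genes and environmental variables, no edges among genes; by default
environmental nodes are additionally exogenous (no incoming edges).  A move is
accepted with probability ``min(1, exp(delta) * |N|/|N'|)``; the neighborhood
ratio can be switched off (``hastings=False``) together with the raw
likelihood score for an uncorrected random-walk variant of the sampler.

Binary columns (sex, smoking, disease status) enter as 0/1 continuous values
under the Gaussian model.  All columns are z-scored before scoring by default
so BIC comparisons are scale-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "ROLES",
    "NodeSpec",
    "ConstraintSet",
    "default_constraints",
    "Dag",
    "Move",
    "McmcConfig",
    "GaussianNetworkData",
    "NodeParams",
    "node_score",
    "network_score",
    "propose_move",
    "mh_step",
    "MCMCChain",
    "run_mcmc",
    "random_legal_dag",
    "fit_parameters",
    "to_networkx",
    "write_graphml",
    "write_dot",
]

ROLES = ("environment", "gene", "trait", "disease")

_SIGMA2_FLOOR = 1e-16  # sigma >= 1e-8
_RIDGE = 1e-8


@dataclass(frozen=True)
class NodeSpec:
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown node role: {self.role!r}")


# (source role, target role) pairs banned by the biological edge rules.
_DEFAULT_BANNED: frozenset[tuple[str, str]] = frozenset(
    {
        ("trait", "gene"),
        ("disease", "gene"),
        ("gene", "gene"),
        ("gene", "environment"),
        ("environment", "gene"),
    }
)


@dataclass(frozen=True)
class ConstraintSet:
    """Role-pair edge bans plus optional exogenous roles (no incoming edges)."""

    banned_pairs: frozenset[tuple[str, str]] = _DEFAULT_BANNED
    exogenous_roles: frozenset[str] = frozenset()

    def allows(self, source_role: str, target_role: str) -> bool:
        if target_role in self.exogenous_roles:
            return False
        return (source_role, target_role) not in self.banned_pairs


def default_constraints(exogenous_environment: bool = True) -> ConstraintSet:
    """The standard ban list; environment nodes exogenous unless disabled."""
    exo = frozenset({"environment"}) if exogenous_environment else frozenset()
    return ConstraintSet(banned_pairs=_DEFAULT_BANNED, exogenous_roles=exo)


def allowed_matrix(roles: Sequence[str], constraints: ConstraintSet) -> np.ndarray:
    V = len(roles)
    allowed = np.zeros((V, V), dtype=bool)
    for i, ri in enumerate(roles):
        for j, rj in enumerate(roles):
            if i != j and constraints.allows(ri, rj):
                allowed[i, j] = True
    return allowed


class Dag:
    """Immutable-by-convention DAG over named nodes, backed by a bool matrix."""

    __slots__ = ("names", "_index", "A")

    def __init__(
        self,
        names: Sequence[str],
        edges: Iterable[tuple[str, str]] = (),
        adjacency: np.ndarray | None = None,
    ):
        self.names: tuple[str, ...] = tuple(names)
        self._index = {n: i for i, n in enumerate(self.names)}
        if len(self._index) != len(self.names):
            raise DataError("node names must be unique")
        V = len(self.names)
        if adjacency is not None:
            A = np.array(adjacency, dtype=bool)
            if A.shape != (V, V):
                raise DataError("adjacency shape mismatch")
        else:
            A = np.zeros((V, V), dtype=bool)
            for u, v in edges:
                A[self._index[u], self._index[v]] = True
        if np.diag(A).any():
            raise DataError("self-loops are not allowed")
        self.A = A
        if not self.is_acyclic():
            raise DataError("edge set contains a directed cycle")

    # -- queries ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())

    def has_edge(self, u: str, v: str) -> bool:
        return bool(self.A[self._index[u], self._index[v]])

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.names[i], self.names[j]) for i, j in np.argwhere(self.A)
        ]

    def parents(self, v: str) -> list[str]:
        j = self._index[v]
        return [self.names[i] for i in np.flatnonzero(self.A[:, j])]

    def parent_indices(self, j: int) -> tuple[int, ...]:
        return tuple(np.flatnonzero(self.A[:, j]))

    def is_acyclic(self) -> bool:
        # Kahn's algorithm
        indeg = self.A.sum(axis=0).astype(int)
        stack = list(np.flatnonzero(indeg == 0))
        seen = 0
        A = self.A
        while stack:
            u = stack.pop()
            seen += 1
            for v in np.flatnonzero(A[u]):
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(int(v))
        return seen == self.n_nodes

    def key(self) -> bytes:
        """Hashable snapshot of the structure (for state histograms)."""
        return np.packbits(self.A).tobytes()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and self.names == other.names
            and np.array_equal(self.A, other.A)
        )

    def __hash__(self) -> int:
        return hash((self.names, self.key()))

    def __repr__(self) -> str:
        return f"Dag({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class Move:
    kind: str  # "add" | "delete" | "reverse"
    source: str
    target: str


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _gaussian_loglik(n: int, sigma2: float) -> float:
    sigma2 = max(sigma2, _SIGMA2_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def node_score(
    child_data,
    parent_data=None,
    score_kind: str = "bic",
) -> float:
    """Linear-Gaussian node score from raw data vectors.

    Fits ``child ~ intercept + parents`` by least squares; ``loglik`` is the
    maximized Gaussian log-likelihood (sigma^2 at its MLE, RSS/n), ``bic``
    subtracts ``(K + 2)/2 * ln n``.  Collinear parents fall back to a tiny
    ridge, with a warning.
    """
    y = np.asarray(child_data, dtype=float)
    n = y.shape[0]
    if parent_data is None:
        U = np.empty((n, 0))
    else:
        U = np.asarray(parent_data, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
    K = U.shape[1]
    if n < K + 2:
        raise DataError(f"need n >= K + 2 observations (n={n}, K={K})")
    X = np.column_stack([np.ones(n), U])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < K + 1:
        warnings.warn("collinear parents; ridge fallback", RuntimeWarning, stacklevel=2)
        G = X.T @ X + _RIDGE * np.eye(K + 1)
        beta = np.linalg.solve(G, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    ll = _gaussian_loglik(n, sigma2)
    if score_kind == "loglik":
        return ll
    if score_kind == "bic":
        return ll - 0.5 * (K + 2) * math.log(n)
    raise ValueError(f"unknown score_kind: {score_kind!r}")


class GaussianNetworkData:
    """Column data prepared for fast repeated node scoring.

    Columns are centred (and z-scored unless ``standardize=False``); the Gram
    matrix of the prepared columns lets any node score be computed from a
    small K x K solve, independent of n, and results are cached per
    (child, parent set, score kind).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        nodes: Sequence[NodeSpec],
        standardize: bool = True,
    ):
        self.nodes = tuple(nodes)
        self.names = tuple(s.name for s in self.nodes)
        self.roles = tuple(s.role for s in self.nodes)
        missing = [n for n in self.names if n not in frame.columns]
        if missing:
            raise DataError(f"data is missing node columns: {missing}")
        X = frame.loc[:, list(self.names)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise DataError("node data contains non-finite values")
        self.n = X.shape[0]
        mu = X.mean(axis=0)
        Xc = X - mu
        if standardize:
            sd = Xc.std(axis=0)
            sd[sd == 0.0] = 1.0  # constant columns stay constant
            Xc = Xc / sd
        self.standardized = standardize
        self.X = Xc
        self.gram = Xc.T @ Xc
        self._cache: dict[tuple, float] = {}
        self.cache_misses = 0

    def index(self, name: str) -> int:
        return self.names.index(name)

    def node_score_idx(
        self, child: int, parents: tuple[int, ...], score_kind: str = "bic"
    ) -> float:
        key = (child, parents, score_kind)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.cache_misses += 1
        val = self._compute(child, parents, score_kind)
        self._cache[key] = val
        return val

    def _compute(self, child: int, parents: tuple[int, ...], score_kind: str) -> float:
        n = self.n
        K = len(parents)
        if n < K + 2:
            raise DataError(f"need n >= K + 2 observations (n={n}, K={K})")
        scc = self.gram[child, child]
        if K == 0:
            sigma2 = scc / n
        else:
            ix = np.asarray(parents)
            Spp = self.gram[np.ix_(ix, ix)]
            spc = self.gram[ix, child]
            try:
                sol = np.linalg.solve(Spp, spc)
            except np.linalg.LinAlgError:
                sol = np.linalg.solve(Spp + _RIDGE * np.eye(K), spc)
            sigma2 = (scc - spc @ sol) / n
        ll = _gaussian_loglik(n, max(sigma2, 0.0))
        if score_kind == "loglik":
            return ll
        if score_kind == "bic":
            return ll - 0.5 * (K + 2) * math.log(n)
        raise ValueError(f"unknown score_kind: {score_kind!r}")


def network_score(
    dag: Dag,
    data: GaussianNetworkData,
    score_kind: str = "bic",
    fresh: bool = False,
) -> float:
    """Decomposable network score: sum of node scores given their parents.

    ``fresh=True`` bypasses the cache (used to audit incremental updates).
    """
    if dag.names != data.names:
        raise DataError("dag nodes do not match data columns")
    total = 0.0
    for j in range(dag.n_nodes):
        parents = dag.parent_indices(j)
        if fresh:
            total += data._compute(j, parents, score_kind)
        else:
            total += data.node_score_idx(j, parents, score_kind)
    return total


# ---------------------------------------------------------------------------
# neighborhood
# ---------------------------------------------------------------------------


def _closure_strict(A: np.ndarray) -> np.ndarray:
    """Strict transitive closure (paths of length >= 1) by boolean squaring."""
    R = A.astype(np.uint8)
    while True:
        R2 = (((R @ R) > 0) | R.astype(bool)).astype(np.uint8)
        if np.array_equal(R2, R):
            return R.astype(bool)
        R = R2


class _Neighborhood:
    """Legal moves from one DAG state: add / delete / reverse candidate lists."""

    __slots__ = ("adds", "deletes", "reverses")

    def __init__(self, adds: np.ndarray, deletes: np.ndarray, reverses: np.ndarray):
        self.adds = adds
        self.deletes = deletes
        self.reverses = reverses

    @property
    def size(self) -> int:
        return len(self.adds) + len(self.deletes) + len(self.reverses)

    def move(self, k: int) -> tuple[str, int, int]:
        na, nd = len(self.adds), len(self.deletes)
        if k < na:
            return ("add", int(self.adds[k, 0]), int(self.adds[k, 1]))
        k -= na
        if k < nd:
            return ("delete", int(self.deletes[k, 0]), int(self.deletes[k, 1]))
        k -= nd
        return ("reverse", int(self.reverses[k, 0]), int(self.reverses[k, 1]))


def _neighborhood(
    A: np.ndarray,
    R: np.ndarray,
    allowed: np.ndarray,
    indeg: np.ndarray,
    max_parents: int,
) -> _Neighborhood:
    # adds: allowed pair, no existing edge, no back-path (cycle), target under cap
    add_mask = allowed & ~A & ~R.T & (indeg < max_parents)[None, :]
    adds = np.argwhere(add_mask)
    edges = np.argwhere(A)
    if len(edges):
        us, vs = edges[:, 0], edges[:, 1]
        # reversing u->v is cyclic iff u still reaches v through another child
        alt = np.einsum(
            "ij,ji->i", A[us].astype(np.uint8), R[:, vs].astype(np.uint8)
        ) - (A[us, vs] & R[vs, vs]).astype(np.uint8)
        rev_ok = allowed[vs, us] & (indeg[us] < max_parents) & (alt == 0)
        reverses = edges[rev_ok]
    else:
        reverses = edges
    return _Neighborhood(adds, edges, reverses)


def random_legal_dag(
    nodes: Sequence[NodeSpec],
    constraints: ConstraintSet,
    rng: np.random.Generator,
    density: float = 0.1,
    max_parents: int = 5,
) -> Dag:
    """Random constraint-satisfying DAG: random topological order, each allowed
    forward edge included independently with probability ``density``."""
    names = [s.name for s in nodes]
    roles = [s.role for s in nodes]
    allowed = allowed_matrix(roles, constraints)
    V = len(names)
    order = rng.permutation(V)
    pos = np.empty(V, dtype=int)
    pos[order] = np.arange(V)
    A = np.zeros((V, V), dtype=bool)
    indeg = np.zeros(V, dtype=int)
    for i in range(V):
        for j in range(V):
            if (
                pos[i] < pos[j]
                and allowed[i, j]
                and indeg[j] < max_parents
                and rng.random() < density
            ):
                A[i, j] = True
                indeg[j] += 1
    return Dag(names, adjacency=A)


def propose_move(
    dag: Dag,
    constraints: ConstraintSet,
    rng: np.random.Generator,
    roles: Sequence[str] | None = None,
    max_parents: int = 5,
) -> Move | None:
    """Uniform draw from the legal add/delete/reverse neighborhood (None if empty)."""
    if roles is None:
        raise DataError("propose_move needs the node roles")
    allowed = allowed_matrix(roles, constraints)
    indeg = dag.A.sum(axis=0)
    nb = _neighborhood(dag.A, _closure_strict(dag.A), allowed, indeg, max_parents)
    if nb.size == 0:
        return None
    kind, u, v = nb.move(int(rng.integers(nb.size)))
    return Move(kind, dag.names[u], dag.names[v])


def legal_moves(
    dag: Dag,
    constraints: ConstraintSet,
    roles: Sequence[str],
    max_parents: int = 5,
) -> list[Move]:
    """The full legal neighborhood, for enumeration-style tests."""
    allowed = allowed_matrix(roles, constraints)
    indeg = dag.A.sum(axis=0)
    nb = _neighborhood(dag.A, _closure_strict(dag.A), allowed, indeg, max_parents)
    out = []
    for k in range(nb.size):
        kind, u, v = nb.move(k)
        out.append(Move(kind, dag.names[u], dag.names[v]))
    return out


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 20_000
    seed: int = 0
    max_parents: int = 5
    score_kind: str = "bic"
    hastings: bool = True
    convergence_window: int = 1_000
    convergence_tol: float = 1e-6
    thin: int = 1
    init_density: float = 0.1
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.max_parents < 1:
            raise ConfigurationError("iterations and max_parents must be >= 1")
        if self.score_kind not in ("bic", "loglik"):
            raise ConfigurationError(f"unknown score_kind: {self.score_kind!r}")


class MCMCChain:
    """Metropolis-Hastings random walk over legal DAGs.

    Keeps the current structure, its per-node scores and its legal
    neighborhood incrementally; re-scores only the children affected by a
    move and tracks the best structure visited (first-visited wins ties).
    """

    def __init__(
        self,
        data: GaussianNetworkData,
        constraints: ConstraintSet | None = None,
        config: McmcConfig | None = None,
        init_dag: Dag | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.data = data
        self.config = config or McmcConfig()
        self.constraints = constraints if constraints is not None else default_constraints()
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        self.allowed = allowed_matrix(data.roles, self.constraints)
        nodes = [NodeSpec(n, r) for n, r in zip(data.names, data.roles)]
        if init_dag is None:
            init_dag = random_legal_dag(
                nodes,
                self.constraints,
                self.rng,
                density=self.config.init_density,
                max_parents=self.config.max_parents,
            )
        if init_dag.names != data.names:
            raise DataError("initial DAG nodes do not match data columns")
        self.A = init_dag.A.copy()
        self.indeg = self.A.sum(axis=0).astype(int)
        self.R = _closure_strict(self.A)
        kind = self.config.score_kind
        self.node_scores = np.array(
            [
                data.node_score_idx(j, tuple(np.flatnonzero(self.A[:, j])), kind)
                for j in range(len(data.names))
            ]
        )
        self.score = float(self.node_scores.sum())
        self.nbhd = _neighborhood(
            self.A, self.R, self.allowed, self.indeg, self.config.max_parents
        )
        self.best_score = self.score
        self.best_A = self.A.copy()
        self.trace: list[float] = [self.score]
        self.n_steps = 0
        self.n_accepted = 0

    # -- snapshots -------------------------------------------------------
    def dag(self) -> Dag:
        return Dag(self.data.names, adjacency=self.A.copy())

    def best_dag(self) -> Dag:
        return Dag(self.data.names, adjacency=self.best_A.copy())

    def state_key(self) -> bytes:
        return np.packbits(self.A).tobytes()

    # -- stepping --------------------------------------------------------
    def step(self) -> bool:
        """One MH step; returns True when the proposal was accepted."""
        self.n_steps += 1
        nb = self.nbhd
        N = nb.size
        if N == 0:
            self.trace.append(self.score)
            return False
        kind_move, u, v = nb.move(int(self.rng.integers(N)))
        A2 = self.A.copy()
        if kind_move == "add":
            A2[u, v] = True
            affected = (v,)
        elif kind_move == "delete":
            A2[u, v] = False
            affected = (v,)
        else:  # reverse
            A2[u, v] = False
            A2[v, u] = True
            affected = (u, v)
        score_kind = self.config.score_kind
        new_scores = {
            c: self.data.node_score_idx(c, tuple(np.flatnonzero(A2[:, c])), score_kind)
            for c in affected
        }
        delta = sum(new_scores[c] - self.node_scores[c] for c in affected)
        indeg2 = A2.sum(axis=0).astype(int)
        R2 = _closure_strict(A2)
        nb2 = _neighborhood(A2, R2, self.allowed, indeg2, self.config.max_parents)
        log_ratio = delta
        if self.config.hastings:
            log_ratio += math.log(N) - math.log(nb2.size)
        accept = log_ratio >= 0.0 or self.rng.random() < math.exp(log_ratio)
        if accept:
            self.A = A2
            self.R = R2
            self.indeg = indeg2
            self.nbhd = nb2
            for c, s in new_scores.items():
                self.node_scores[c] = s
            self.score = float(self.score + delta)
            self.n_accepted += 1
            if self.score > self.best_score:
                self.best_score = self.score
                self.best_A = self.A.copy()
        self.trace.append(self.score)
        return accept

    def run(self, iterations: int | None = None) -> "MCMCChain":
        """Run with the configured convergence rule (windowed best-score change)."""
        total = self.config.iterations if iterations is None else iterations
        window = self.config.convergence_window
        tol = self.config.convergence_tol
        prev_best = self.best_score
        for i in range(1, total + 1):
            self.step()
            if window and i % window == 0:
                rel = (self.best_score - prev_best) / max(1.0, abs(prev_best))
                if rel < tol:
                    break
                prev_best = self.best_score
        return self


def mh_step(
    dag: Dag,
    data: GaussianNetworkData,
    config: McmcConfig,
    rng: np.random.Generator,
    constraints: ConstraintSet | None = None,
) -> tuple[Dag, bool, float]:
    """Single-step functional interface: (next_dag, accepted, score of next_dag).

    On rejection the returned DAG is the *same object* that was passed in.
    """
    chain = MCMCChain(data, constraints=constraints, config=config, init_dag=dag, rng=rng)
    accepted = chain.step()
    if accepted:
        return chain.dag(), True, chain.score
    return dag, False, chain.score


@dataclass
class McmcResult:
    best_dag: Dag
    best_score: float
    trace: list[float]
    params: Mapping[str, "NodeParams"]
    n_iterations: int
    converged: bool
    chain: MCMCChain = field(repr=False, default=None)


def run_mcmc(
    frame: pd.DataFrame,
    nodes: Sequence[NodeSpec],
    constraints: ConstraintSet | None = None,
    config: McmcConfig | None = None,
) -> McmcResult:
    """Learn a structure: run the chain, return the best DAG with fitted params."""
    config = config or McmcConfig()
    data = GaussianNetworkData(frame, nodes, standardize=config.standardize)
    chain = MCMCChain(data, constraints=constraints, config=config)
    chain.run()
    best = chain.best_dag()
    params = fit_parameters(best, frame)
    return McmcResult(
        best_dag=best,
        best_score=chain.best_score,
        trace=chain.trace,
        params=params,
        n_iterations=chain.n_steps,
        converged=chain.n_steps < config.iterations,
        chain=chain,
    )


# ---------------------------------------------------------------------------
# parameters & export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeParams:
    """Linear-Gaussian parameters of one node: X = a0 + sum ak uk + N(0, sigma^2)."""

    intercept: float
    coefficients: Mapping[str, float]
    sigma: float


def fit_parameters(dag: Dag, frame: pd.DataFrame) -> dict[str, NodeParams]:
    """Per-node least-squares fit on the raw (unstandardized) columns.

    The residual SD uses the MLE normalization (divide by n).
    """
    out: dict[str, NodeParams] = {}
    n = frame.shape[0]
    for name in dag.names:
        parents = dag.parents(name)
        y = frame[name].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(n)] + [frame[p].to_numpy(dtype=float) for p in parents]
        )
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            G = X.T @ X + _RIDGE * np.eye(X.shape[1])
            beta = np.linalg.solve(G, X.T @ y)
        resid = y - X @ beta
        sigma = math.sqrt(max(float(resid @ resid) / n, _SIGMA2_FLOOR))
        out[name] = NodeParams(
            intercept=float(beta[0]),
            coefficients={p: float(b) for p, b in zip(parents, beta[1:])},
            sigma=sigma,
        )
    return out


def to_networkx(dag: Dag, roles: Sequence[str] | None = None):
    import networkx as nx

    g = nx.DiGraph()
    for i, name in enumerate(dag.names):
        attrs = {"role": roles[i]} if roles is not None else {}
        g.add_node(name, **attrs)
    g.add_edges_from(dag.edges())
    return g


def write_graphml(dag: Dag, path, roles: Sequence[str] | None = None) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(dag, roles), path)


def write_dot(
    dag: Dag,
    path,
    roles: Sequence[str] | None = None,
    edge_labels: Mapping[tuple[str, str], object] | None = None,
) -> None:
    """Plain-text DOT export (role as node attribute, optional edge labels)."""
    lines = ["digraph bn {"]
    for i, name in enumerate(dag.names):
        role = f' [role="{roles[i]}"]' if roles is not None else ""
        lines.append(f'  "{name}"{role};')
    for u, v in dag.edges():
        label = ""
        if edge_labels and (u, v) in edge_labels:
            label = f' [label="{edge_labels[(u, v)]}"]'
        lines.append(f'  "{u}" -> "{v}"{label};')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
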