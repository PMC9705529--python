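"""Multilayer modularity and generalized Louvain community detection.

A trial's sliding-window connectivity stack is treated as a weighted
multilayer graph: each time window is a layer with the WPLI matrix as
intralayer weights, and each node is coupled to itself in adjacent layers
with uniform strength ``omega`` (ordinal interlayer coupling, the standard
convention for temporally ordered layers).  Community structure is found by
maximizing the multilayer modularity

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma * k_il k_jl / (2 m_l)) delta_lr
                               + delta_ij * omega * adj(l, r) ] * delta(g_il, g_jr)

where ``k_il`` is the intralayer strength of node ``i`` in layer ``l``,
``m_l`` the total intralayer weight of layer ``l``, ``gamma`` the resolution
parameter of the per-layer Newman–Girvan null, ``adj(l, r)`` indicates
adjacent layers, and ``2mu`` sums all node-layer strengths including the
interlayer couplings.

The optimizer is a generalized Louvain heuristic: greedy single-vertex moves
over randomly ordered node-layer vertices until no move increases Q, then
aggregation of communities into super-vertices, repeated to convergence.
The heuristic is non-deterministic across seeds; analyses therefore run it
repeatedly (an ensemble) and average all downstream metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from ._accel import louvain_sweep, max_partition_pair_sum


class GraphError(ValueError):
    """Raised for invalid multilayer-graph inputs."""


@dataclass(frozen=True)
class MultilayerGraph:
    """Weighted multilayer graph with ordinal interlayer coupling.

    Parameters
    ----------
    intralayer:
        Array of shape (n_layers, n_nodes, n_nodes); each layer symmetric,
        non-negative, zero diagonal.
    gamma:
        Resolution of the per-layer Newman–Girvan null model (> 0).
    omega:
        Uniform coupling of node i in layer l to node i in layers l±1 (>= 0).
    """

    intralayer: np.ndarray
    gamma: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        A = np.asarray(self.intralayer, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise GraphError("intralayer must have shape (n_layers, n_nodes, n_nodes)")
        if not np.isfinite(A).all():
            raise GraphError("intralayer weights must be finite")
        if (A < 0).any():
            raise GraphError("intralayer weights must be non-negative")
        if not np.allclose(A, A.transpose(0, 2, 1)):
            raise GraphError("each intralayer matrix must be symmetric")
        if np.abs(np.diagonal(A, axis1=1, axis2=2)).max(initial=0.0) > 0:
            raise GraphError("intralayer diagonals must be zero")
        if not self.gamma > 0:
            raise GraphError("gamma must be > 0")
        if self.omega < 0:
            raise GraphError("omega must be >= 0")
        object.__setattr__(self, "intralayer", A)

    @classmethod
    def from_stack(cls, stack, gamma: float = 1.0, omega: float = 1.0) -> "MultilayerGraph":
        """Build from a :class:`~dynmodnet.connectivity.ConnectivityStack`."""
        return cls(intralayer=stack.values, gamma=gamma, omega=omega)

    @property
    def n_layers(self) -> int:
        return self.intralayer.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.intralayer.shape[1]

    @property
    def strengths(self) -> np.ndarray:
        """Intralayer strengths k_il, shape (n_layers, n_nodes)."""
        return self.intralayer.sum(axis=2)

    @property
    def layer_totals(self) -> np.ndarray:
        """2*m_l per layer (sum of all intralayer weights)."""
        return self.intralayer.sum(axis=(1, 2))

    @property
    def twomu(self) -> float:
        """Normalization 2*mu: all node-layer strengths plus interlayer couplings."""
        n_adj = np.full(self.n_layers, 2.0)
        if self.n_layers >= 1:
            n_adj[0] = n_adj[-1] = 1.0
        if self.n_layers == 1:
            n_adj[:] = 0.0
        coupling = self.omega * n_adj.sum() * self.n_nodes
        return float(self.layer_totals.sum() + coupling)

    def modularity_matrix(self) -> np.ndarray:
        """Dense supra-modularity matrix over node-layer vertices.

        Vertex (i, l) maps to index l * n_nodes + i.  Entry B[u, v] is the
        intralayer modularity term for same-layer pairs and omega for
        same-node adjacent-layer pairs; Q(g) = sum_{uv} B[u,v] delta(g_u,g_v) / 2mu.
        """
        L, N = self.n_layers, self.n_nodes
        B = np.zeros((N * L, N * L))
        k = self.strengths
        twom = self.layer_totals
        for l in range(L):
            sl = slice(l * N, (l + 1) * N)
            null = np.zeros((N, N))
            if twom[l] > 0:
                null = self.gamma * np.outer(k[l], k[l]) / twom[l]
            B[sl, sl] = self.intralayer[l] - null
        idx = np.arange(N)
        for l in range(L - 1):
            B[l * N + idx, (l + 1) * N + idx] += self.omega
            B[(l + 1) * N + idx, l * N + idx] += self.omega
        return B


@dataclass(frozen=True)
class Partition:
    """Node-by-layer community labels with the modularity value they achieve.

    Labels are positive integers 1..K, canonicalized by first appearance in
    node-major scan order.
    """

    labels: np.ndarray     # (n_nodes, n_layers), int
    q: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", canonicalize_labels(self.labels))


@dataclass(frozen=True)
class PartitionEnsemble:
    """Repeated community detection on one graph.

    ``labels`` stacks per-repetition node-by-layer label arrays; downstream
    allegiance metrics average over all (repetition, layer) observations.
    """

    labels: np.ndarray     # (n_reps, n_nodes, n_layers), int
    qs: np.ndarray         # (n_reps,)
    base_seed: int | None = None

    @property
    def n_reps(self) -> int:
        return self.labels.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[1]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[2]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities to 1..K by first appearance (node-major order)."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    out = np.empty_like(flat)
    seen: dict[int, int] = {}
    for i, g in enumerate(flat):
        g = int(g)
        if g not in seen:
            seen[g] = len(seen) + 1
        out[i] = seen[g]
    return out.reshape(labels.shape)


def modularity(graph: MultilayerGraph, labels: np.ndarray) -> float:
    """Multilayer modularity Q of a node-by-layer labelling.

    Evaluates the quality function directly from the intralayer weights,
    per-layer Newman–Girvan null terms and ordinal interlayer couplings
    (independent of the supra-matrix path used by the optimizer).
    """
    labels = np.asarray(labels)
    L, N = graph.n_layers, graph.n_nodes
    if labels.shape != (N, L):
        raise GraphError(
            f"partition shape {labels.shape} does not match graph (n_nodes={N}, n_layers={L})"
        )
    twomu = graph.twomu
    if twomu == 0:
        return 0.0
    k = graph.strengths
    twom = graph.layer_totals
    total = 0.0
    for l in range(L):
        same = labels[:, l][:, None] == labels[:, l][None, :]
        contrib = graph.intralayer[l].copy()
        if twom[l] > 0:
            contrib -= graph.gamma * np.outer(k[l], k[l]) / twom[l]
        total += contrib[same].sum()
    for l in range(L - 1):
        total += 2.0 * graph.omega * np.count_nonzero(labels[:, l] == labels[:, l + 1])
    return float(total / twomu)


def _vertex_to_node_layer(vert_labels: np.ndarray, n_nodes: int, n_layers: int) -> np.ndarray:
    return vert_labels.reshape(n_layers, n_nodes).T


def genlouvain(
    graph: MultilayerGraph,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> Partition:
    """One seeded run of the generalized Louvain heuristic.

    Greedy node-move sweeps over randomly permuted node-layer vertices until
    no single move increases Q, then aggregation into super-vertices and
    repetition on the aggregated matrix until convergence.  Deterministic
    for a given graph and seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = graph.modularity_matrix()
    twomu = graph.twomu
    nv = B.shape[0]
    vert_labels = np.arange(nv)

    Bcur = B
    while True:
        n = Bcur.shape[0]
        level_labels = np.arange(n)
        any_moves = False
        while True:
            order = rng.permutation(n)
            moves = louvain_sweep(Bcur, level_labels, order)
            if moves == 0:
                break
            any_moves = True
        # compress level labels to 0..K-1
        uniq, compact = np.unique(level_labels, return_inverse=True)
        K = len(uniq)
        vert_labels = compact[vert_labels]
        if not any_moves or K == n:
            break
        # aggregate: B'[a, b] = sum of Bcur over vertices with labels a, b
        M = np.zeros((n, K))
        M[np.arange(n), compact] = 1.0
        Bcur = M.T @ Bcur @ M

    same = vert_labels[:, None] == vert_labels[None, :]
    q = float(B[same].sum() / twomu) if twomu > 0 else 0.0
    node_layer = _vertex_to_node_layer(vert_labels, graph.n_nodes, graph.n_layers)
    return Partition(labels=node_layer, q=q)


def ensemble(
    graph: MultilayerGraph,
    n_reps: int = 500,
    base_seed: int = 0,
) -> PartitionEnsemble:
    """Run :func:`genlouvain` ``n_reps`` times with independent child seeds.

    Seeds are spawned from ``base_seed`` via ``numpy.random.SeedSequence``
    (one child stream per repetition), so the full ensemble is reproducible
    from the single base seed.
    """
    if n_reps < 1:
        raise GraphError("n_reps must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_reps)
    labels = np.empty((n_reps, graph.n_nodes, graph.n_layers), dtype=np.int64)
    qs = np.empty(n_reps)
    for r, child in enumerate(children):
        part = genlouvain(graph, np.random.default_rng(child))
        labels[r] = part.labels
        qs[r] = part.q
    return PartitionEnsemble(labels=labels, qs=qs, base_seed=base_seed)


def exhaustive_max_modularity(graph: MultilayerGraph) -> Partition:
    """Globally optimal partition by full enumeration of set partitions.

    Brute-force oracle for validating the heuristic on tiny graphs; refuses
    graphs with more than 13 node-layer vertices (Bell-number blow-up).
    """
    nv = graph.n_nodes * graph.n_layers
    if nv > 13:
        raise GraphError(f"exhaustive search limited to <=13 node-layer vertices, got {nv}")
    B = graph.modularity_matrix()
    twomu = graph.twomu
    best_pair_sum, vert_labels = max_partition_pair_sum(B)
    q = float((2.0 * best_pair_sum + np.trace(B)) / twomu) if twomu > 0 else 0.0
    node_layer = _vertex_to_node_layer(vert_labels, graph.n_nodes, graph.n_layers)
    return Partition(labels=node_layer, q=q)


def best_of(graph: MultilayerGraph, n_runs: int, base_seed: int = 0) -> Partition:
    """Best-Q partition over ``n_runs`` seeded genlouvain restarts."""
    ens = ensemble(graph, n_reps=n_runs, base_seed=base_seed)
    r = int(np.argmax(ens.qs))
    return Partition(labels=ens.labels[r], q=float(ens.qs[r]))
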