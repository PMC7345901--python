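"""Antibody interaction network: construction, degree exponent, fractal dimension.

Nodes are B-cell clones (antibodies); a directed link means antigen is handed
from a lower-energy binder to a higher-energy binder within the same
structural subnetwork.  Long-lived plasma cells (LLPC) sit at the top of each
subnetwork and connect to every member below them; memory B cells occupy
intermediate energy shells and B1 cells the lowest.

Identifying the network degree with the system equilibrium constant
(k = K_sys, integerised as max(1, round(K_sys))) makes the degree
distribution inherit the double-Pareto upper tail p(k) ~ k^(−γ) with
γ = 1 + λ.  Fractality is quantified by greedy box covering: the number of
boxes of diameter < l_B needed to tile the network scales as
N_B(l_B) ~ l_B^(−d_B), and for a self-similar scale-free network the two
exponents are tied by

    d_B = (γ − 1)/(γ − 2)

whose fixed point γ = d_B is the golden-ratio value φ + 1 = φ² ≈ 2.618.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .distributions import InsufficientTailError, TailFit, fit_tail_exponent

__all__ = [
    "AntibodyNode",
    "InteractionNetwork",
    "NetworkMetrics",
    "BoxCoverResult",
    "GOLDEN_RATIO",
    "degrees_from_ksys",
    "roles_from_ksys",
    "build_hierarchical_network",
    "fit_degree_exponent",
    "box_covering_dimension",
    "eq10_box_dimension",
    "ideal_exponent",
    "grow_preferential_attachment",
    "flower_graph",
    "save_network",
    "load_network",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

ROLES = ("B1", "naive", "MBC", "LLPC")


class NetworkError(ValueError):
    """Invalid network input or failed metric computation."""


@dataclass(frozen=True)
class AntibodyNode:
    """View of one node: a clone with its system constant and hierarchy role."""

    id: str
    k_sys: float = 1.0
    degree: int = 0
    role: Optional[str] = None
    shell: Optional[int] = None
    subnetwork: Optional[str] = None


@dataclass
class InteractionNetwork:
    """Directed antigen-transfer network over antibody nodes.

    Thin wrapper around a :class:`networkx.DiGraph`; node attributes carry
    ``k_sys``, ``role``, ``shell`` and ``subnetwork``.  Metrics operate on the
    undirected view.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)

    def degree_sequence(self) -> np.ndarray:
        und = self.graph.to_undirected(as_view=True)
        return np.array([d for _, d in und.degree()], dtype=int)

    def node(self, node_id: str) -> AntibodyNode:
        data = self.graph.nodes[node_id]
        und = self.graph.to_undirected(as_view=True)
        return AntibodyNode(
            id=str(node_id),
            k_sys=float(data.get("k_sys", 1.0)),
            degree=int(und.degree(node_id)),
            role=data.get("role"),
            shell=data.get("shell"),
            subnetwork=data.get("subnetwork"),
        )


@dataclass(frozen=True)
class BoxCoverResult:
    """Box-covering outcome: N_B per box size and the fitted dimension."""

    d_b_hat: float
    stderr: float
    n_boxes_by_lb: Dict[int, int]
    n_nodes: int


@dataclass(frozen=True)
class NetworkMetrics:
    """Degree exponent, box dimension, and their consistency prediction."""

    gamma_hat: Optional[TailFit] = None
    box_cover: Optional[BoxCoverResult] = None
    eq_d_b: Optional[float] = None

    @property
    def d_b_hat(self) -> Optional[float]:
        return None if self.box_cover is None else self.box_cover.d_b_hat


def degrees_from_ksys(ksys_values: Iterable[float]) -> np.ndarray:
    """Map continuous system constants to integer degrees, k = max(1, round(K_sys)).

    Every clone keeps at least one link — a node with no interaction at all
    would leave the system.  Rounding preserves ordering and the power-law
    tail index.
    """
    k = np.asarray(list(ksys_values), dtype=float)
    if k.size and (np.any(k <= 0) or not np.all(np.isfinite(k))):
        raise NetworkError("K_sys values must be positive and finite")
    return np.maximum(1, np.round(k)).astype(int)


def roles_from_ksys(
    ksys_values: Sequence[float], *, llpc_quantile: float = 0.9
) -> list[str]:
    """Assign hierarchy roles from affinity alone.

    K_sys ≤ 1 → B1/naive tier (reported as ``"B1"``), top decile → ``"LLPC"``,
    remainder → ``"MBC"``.  The underlying model fixes only the ordering
    (LLPC hubs above MBC above B1); these cutoffs are conventional defaults.
    """
    k = np.asarray(ksys_values, dtype=float)
    if k.size == 0:
        return []
    hi = np.quantile(k, llpc_quantile)
    roles = []
    for v in k:
        if v <= 1.0:
            roles.append("B1")
        elif v >= hi and v > 1.0:
            roles.append("LLPC")
        else:
            roles.append("MBC")
    return roles


def build_hierarchical_network(clones: pd.DataFrame) -> InteractionNetwork:
    """Assemble the subnetwork-star + shell-chain interaction network.

    ``clones`` needs columns ``id``, ``subnetwork`` and ``shell``; optional
    ``role``, ``k_sys`` and ``direction`` (unit vectors, used to pick the
    angularly nearest target in the shell above; ties and missing directions
    fall back to lowest id).

    Within each subnetwork the LLPC (or, with a warning, the max-shell node
    when no LLPC is present) is linked to every other member, and every node
    additionally links to one node in the next occupied shell above it.
    Links are directed from the lower-shell node to the higher-shell node;
    no self-links or duplicates are created and no link crosses subnetworks.
    """
    required = {"id", "subnetwork", "shell"}
    missing = required - set(clones.columns)
    if missing:
        raise NetworkError(f"clones table missing columns: {sorted(missing)}")

    g = nx.DiGraph()
    has_dir = "direction" in clones.columns
    for _, row in clones.iterrows():
        attrs = {"subnetwork": str(row["subnetwork"]), "shell": int(row["shell"])}
        if "role" in clones.columns:
            attrs["role"] = str(row["role"])
        if "k_sys" in clones.columns:
            attrs["k_sys"] = float(row["k_sys"])
        g.add_node(str(row["id"]), **attrs)

    directions = {}
    if has_dir:
        for _, row in clones.iterrows():
            d = row["direction"]
            if d is not None:
                directions[str(row["id"])] = np.asarray(d, dtype=float)

    def add_link(a: str, b: str) -> None:
        """Directed low-shell → high-shell; ties broken by id."""
        if a == b:
            return
        sa, sb = g.nodes[a]["shell"], g.nodes[b]["shell"]
        if (sa, a) > (sb, b):
            a, b = b, a
        if not g.has_edge(a, b):
            g.add_edge(a, b)

    for sub, grp in clones.groupby("subnetwork", sort=True):
        ids = [str(i) for i in grp["id"]]
        if len(ids) < 2:
            continue
        shells = {str(r["id"]): int(r["shell"]) for _, r in grp.iterrows()}
        roles = (
            {str(r["id"]): str(r.get("role", "")) for _, r in grp.iterrows()}
            if "role" in grp.columns
            else {i: "" for i in ids}
        )
        llpcs = sorted(i for i in ids if roles[i] == "LLPC")
        if llpcs:
            center = max(llpcs, key=lambda i: (shells[i], i))
        else:
            warnings.warn(
                f"subnetwork {sub!r} has no LLPC; using the max-shell node as hub",
                stacklevel=2,
            )
            center = min(i for i in ids if shells[i] == max(shells.values()))
        for i in ids:
            add_link(i, center)

        occupied = sorted(set(shells.values()))
        for i in ids:
            above = [s for s in occupied if s > shells[i]]
            if not above:
                continue
            nxt = above[0]
            candidates = sorted(j for j in ids if shells[j] == nxt and j != i)
            if not candidates:
                continue
            if directions and i in directions:
                with_dir = [j for j in candidates if j in directions]
                if with_dir:
                    di = directions[i]
                    # max cosine similarity; ties resolved by id order
                    sims = {j: float(np.dot(di, directions[j])) for j in with_dir}
                    top = max(sims.values())
                    best = min(j for j in with_dir if sims[j] == top)
                    add_link(i, best)
                    continue
            add_link(i, candidates[0])

    return InteractionNetwork(graph=g)


def fit_degree_exponent(
    network: "InteractionNetwork | nx.Graph | Sequence[int]", k_min: int = 3
) -> TailFit:
    """Power-law MLE for the degree exponent γ of p(k) ~ k^(−γ).

    Uses the Hill estimator with the continuous approximation for integer
    degrees: the cutoff is shifted to k_min − ½ so that

        γ̂ = 1 + n / Σ ln(kᵢ / (k_min − ½))     over kᵢ ≥ k_min.

    Requires at least 10 nodes with degree ≥ k_min.  The shifted-cutoff
    approximation is accurate for k_min ≥ 3.
    """
    if isinstance(network, InteractionNetwork):
        degrees = network.degree_sequence()
    elif isinstance(network, (nx.Graph, nx.DiGraph)):
        und = network.to_undirected(as_view=True)
        degrees = np.array([d for _, d in und.degree()], dtype=int)
    else:
        degrees = np.asarray(network, dtype=int)
    if k_min < 2:
        raise NetworkError("k_min must be >= 2 for a tail fit")
    n_tail = int(np.sum(degrees >= k_min))
    if n_tail < 10:
        raise InsufficientTailError(
            f"only {n_tail} nodes with degree >= {k_min}; need at least 10"
        )
    return fit_tail_exponent(degrees[degrees >= 1].astype(float), k_min - 0.5)


def _greedy_box_count(
    dist: np.ndarray, lb: int, rng: np.random.Generator, n_restarts: int
) -> int:
    """Minimum over restarts of greedy-coloring box covering.

    Nodes in one box are pairwise closer than ``lb``; equivalently boxes are
    color classes of the auxiliary graph linking nodes at distance ≥ lb,
    colored greedily in random order.
    """
    n = dist.shape[0]
    conflict = dist >= lb  # auxiliary adjacency
    best = n
    for _ in range(n_restarts):
        order = rng.permutation(n)
        colors = np.full(n, -1, dtype=int)
        n_colors = 0
        for node in order:
            used = set(colors[conflict[node] & (colors >= 0)])
            c = 0
            while c in used:
                c += 1
            colors[node] = c
            n_colors = max(n_colors, c + 1)
        best = min(best, n_colors)
    return best


def greedy_box_count(
    graph: "InteractionNetwork | nx.Graph",
    lb: int,
    *,
    n_restarts: int = 10,
    seed: int = 0,
) -> int:
    """N_B for a single box size: greedy cover by boxes of diameter < lb."""
    g = graph.undirected() if isinstance(graph, InteractionNetwork) else nx.Graph(graph)
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        raise NetworkError("empty network")
    if lb < 1:
        raise NetworkError("box size l_B must be >= 1")
    if lb == 1:
        return n
    index = {u: i for i, u in enumerate(nodes)}
    dist = np.full((n, n), n + 1, dtype=np.int32)
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, d in lengths.items():
            dist[index[u], index[v]] = d
    return _greedy_box_count(dist, lb, np.random.default_rng(seed), n_restarts)


def box_covering_dimension(
    network: "InteractionNetwork | nx.Graph",
    lb_values: Sequence[int],
    *,
    n_restarts: int = 10,
    seed: int = 0,
) -> BoxCoverResult:
    """Greedy box-covering estimate of the fractal dimension d_B.

    For each box size l_B, N_B is the (approximately minimal) number of boxes
    of diameter < l_B tiling the network; d_B is the negative slope of
    log N_B against log l_B, fitted only where 1 < N_B < N (the saturated
    ends carry no scaling information).  Disconnected input is reduced to its
    largest component with a warning.
    """
    g = network.undirected() if isinstance(network, InteractionNetwork) else nx.Graph(network)
    if g.number_of_nodes() == 0:
        raise NetworkError("empty network")
    if not nx.is_connected(g):
        warnings.warn(
            "network is disconnected; box covering runs on the largest component",
            stacklevel=2,
        )
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    nodes = list(g.nodes())
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    dist = np.full((n, n), n + 1, dtype=np.int32)
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        iu = index[u]
        for v, d in lengths.items():
            dist[iu, index[v]] = d

    lb_values = sorted(set(int(l) for l in lb_values))
    if any(l < 1 for l in lb_values):
        raise NetworkError("box sizes l_B must be >= 1")
    rng = np.random.default_rng(seed)
    n_boxes: Dict[int, int] = {}
    for lb in lb_values:
        if lb == 1:
            n_boxes[lb] = n
        else:
            n_boxes[lb] = _greedy_box_count(dist, lb, rng, n_restarts)

    usable = [(lb, nb) for lb, nb in n_boxes.items() if 1 < nb < n]
    if len(usable) < 3:
        raise NetworkError(
            f"only {len(usable)} box sizes with 1 < N_B < N; need >= 3 for a fit"
        )
    x = np.log([lb for lb, _ in usable])
    y = np.log([nb for _, nb in usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(len(x) - 2, 1)
    sx = float(np.sum((x - x.mean()) ** 2))
    stderr = float(np.sqrt(np.sum(resid**2) / dof / sx)) if sx > 0 else float("nan")
    return BoxCoverResult(
        d_b_hat=float(-slope), stderr=stderr, n_boxes_by_lb=n_boxes, n_nodes=n
    )


def eq10_box_dimension(gamma: float) -> float:
    """Predicted box dimension of a self-similar scale-free network, (γ−1)/(γ−2).

    Diverges as γ → 2⁺; returns ``inf`` for γ ≤ 2.  The map is an involution
    on (2, ∞) with fixed point γ = φ + 1 = φ².
    """
    if not math.isfinite(gamma):
        raise NetworkError(f"gamma must be finite, got {gamma}")
    if gamma <= 2.0:
        return float("inf")
    return (gamma - 1.0) / (gamma - 2.0)


def ideal_exponent(tol: float = 1e-12) -> float:
    """Degree exponent of the ideal network with γ = d_B, solved numerically.

    Bisection on (2, 4) for the fixed point of γ ↦ (γ−1)/(γ−2); the result
    equals φ + 1 = φ² with φ the golden ratio, verified to 1e−10.
    """
    lo, hi = 2.0 + 1e-9, 4.0

    def f(g: float) -> float:
        return g - eq10_box_dimension(g)

    if not (f(lo) < 0 < f(hi)):
        raise NetworkError("fixed point not bracketed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    gamma = 0.5 * (lo + hi)
    assert abs(gamma - (GOLDEN_RATIO + 1.0)) < 1e-10
    return gamma


def grow_preferential_attachment(
    n_nodes: int, m_links_per_node: int, seed: int = 0
) -> InteractionNetwork:
    """Degree-proportional attachment growth (Barabási–Albert).

    A new clone attaches preferentially to well-connected subnetworks; the
    emergent degree exponent is ≈ 3 asymptotically, which users can contrast
    with the ideal-network value φ² ≈ 2.618 — the two growth pictures are
    provided side by side, neither is claimed to produce the other's exponent.
    """
    if m_links_per_node < 1 or n_nodes < m_links_per_node:
        raise NetworkError("need n_nodes >= m_links_per_node >= 1")
    g = nx.barabasi_albert_graph(n_nodes, m_links_per_node, seed=seed)
    dg = nx.DiGraph()
    dg.add_nodes_from((str(u), {"k_sys": float(max(1, d))}) for u, d in g.degree())
    dg.add_edges_from((str(u), str(v)) for u, v in g.edges())
    return InteractionNetwork(graph=dg)


def flower_graph(u: int = 2, v: int = 2, generations: int = 4) -> nx.Graph:
    """(u, v)-flower: a deterministic hierarchical fractal network.

    Start from a single edge; at each generation replace every edge (a, b)
    by two parallel paths of u and v edges between a and b.  For u = v = 2
    the box dimension is ln(u+v)/ln(u) = 2, making it a standard reference
    topology for box-covering estimators.
    """
    if u < 1 or v < 1 or u + v < 3:
        raise NetworkError("need u, v >= 1 with u + v >= 3")
    g = nx.Graph()
    g.add_edge(0, 1)
    next_id = 2
    for _ in range(generations):
        new = nx.Graph()
        new.add_nodes_from(g.nodes())
        for a, b in g.edges():
            for path_len in (u, v):
                prev = a
                for _ in range(path_len - 1):
                    new.add_edge(prev, next_id)
                    prev = next_id
                    next_id += 1
                new.add_edge(prev, b)
        g = new
    return g


def save_network(network: InteractionNetwork, path: str) -> None:
    """Write a network to GraphML (``.graphml``) or an edge-list CSV (``.csv``).

    GraphML preserves typed node attributes; the CSV form writes
    ``source,target`` pairs only.
    """
    p = str(path)
    if p.endswith(".graphml"):
        nx.write_graphml(network.graph, p)
    elif p.endswith(".csv"):
        pd.DataFrame(
            [(u, v) for u, v in network.graph.edges()], columns=["source", "target"]
        ).to_csv(p, index=False)
    else:
        raise NetworkError(f"unsupported network format: {p}")


def load_network(path: str) -> InteractionNetwork:
    """Read a network written by :func:`save_network`."""
    p = str(path)
    if p.endswith(".graphml"):
        g = nx.read_graphml(p)
        return InteractionNetwork(graph=nx.DiGraph(g))
    if p.endswith(".csv"):
        df = pd.read_csv(p, dtype=str)
        g = nx.DiGraph()
        g.add_edges_from(df.itertuples(index=False, name=None))
        return InteractionNetwork(graph=g)
    raise NetworkError(f"unsupported network format: {p}")
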