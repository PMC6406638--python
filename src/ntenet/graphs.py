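"""Graph-theoretic characterization of directed functional brain networks.

An NTE matrix becomes a binary digraph by thresholding (default 0.001,
removing only negligible connections); the weighted matrix itself feeds
node strength. Measures: connectivity density, 3-node motif census (13
weakly-connected classes), directed clustering coefficients (Fagiolo
form), characteristic path length, and the small-world index sigma
against degree-preserving random references.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .channels import CHANNELS
from .connectivity import NTEMatrix

DEFAULT_THRESHOLD = 0.001
DEFAULT_N_RANDOM = 100

# ---------------------------------------------------------------------------
# Binary digraph


@dataclass
class BinaryDigraph:
    """Boolean adjacency with ``adjacency[i, j]`` = edge j -> i."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.node_labels)
        if self.adjacency.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}")
        if np.diagonal(self.adjacency).any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> list[tuple[int, int]]:
        """(source, target) index pairs."""
        tgt, src = np.nonzero(self.adjacency)
        return list(zip(src.tolist(), tgt.tolist()))


def binarize(m: NTEMatrix | np.ndarray,
             threshold: float = DEFAULT_THRESHOLD) -> BinaryDigraph:
    """Edge j -> i iff the weight strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = m.values if isinstance(m, NTEMatrix) else np.asarray(m)
    labels = m.channel_labels if isinstance(m, NTEMatrix) else \
        tuple(f"n{i}" for i in range(values.shape[0]))
    adj = values > threshold
    np.fill_diagonal(adj, False)
    return BinaryDigraph(adj, labels)


def connectivity_density(g: BinaryDigraph) -> float:
    """Realized fraction of the n(n-1) possible directed edges."""
    n = g.n_nodes
    return g.n_edges / (n * (n - 1))


# ---------------------------------------------------------------------------
# Motifs

_EDGE_BITS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def _canonical_code(code: int) -> int:
    """Smallest edge-bitmask over the 6 relabelings of a 3-node digraph."""
    present = [(a, b) for bit, (a, b) in enumerate(_EDGE_BITS)
               if code >> bit & 1]
    best = 63
    for perm in itertools.permutations(range(3)):
        c = 0
        for a, b in present:
            c |= 1 << _EDGE_BITS.index((perm[a], perm[b]))
        best = min(best, c)
    return best


def _build_motif_tables() -> tuple[tuple[int, ...], np.ndarray]:
    """Canonical codes of the 13 weakly-connected classes, and a lookup
    from any of the 64 edge configurations to its class index (-1 when the
    underlying graph is disconnected)."""
    classes: dict[int, None] = {}
    lut = np.full(64, -1, dtype=np.int64)
    canon = np.empty(64, dtype=np.int64)
    for code in range(64):
        canon[code] = _canonical_code(code)
        pairs = {frozenset(_EDGE_BITS[b]) for b in range(6) if code >> b & 1}
        if len(pairs) >= 2:  # 3 nodes: weakly connected iff >= 2 pairs linked
            classes.setdefault(canon[code])
    # Canonical class order: by edge count, then by canonical code.
    ordered = tuple(sorted(classes, key=lambda c: (bin(c).count("1"), c)))
    rank = {c: i for i, c in enumerate(ordered)}
    for code in range(64):
        if canon[code] in rank:
            lut[code] = rank[canon[code]]
    return ordered, lut


#: Canonical edge-bitmask of each weakly-connected 3-node class, in the
#: fixed class order used everywhere (motif ids 1..13).
MOTIF_CLASS_CODES, _MOTIF_LUT = _build_motif_tables()
N_MOTIF_CLASSES = len(MOTIF_CLASS_CODES)


@dataclass
class MotifCensus:
    """Counts of each 3-node motif class over all node triples."""

    counts: np.ndarray  # length 13, class order MOTIF_CLASS_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {i + 1: int(c) for i, c in enumerate(self.counts)}


def motif_census(g: BinaryDigraph) -> MotifCensus:
    """Classify the induced subgraph of every node triple.

    Triples whose underlying undirected graph is disconnected are not
    counted; each triple contributes to at most one class.
    """
    a = g.adjacency
    n = g.n_nodes
    trip = np.array(list(itertools.combinations(range(n), 3)))
    if len(trip) == 0:
        return MotifCensus(np.zeros(N_MOTIF_CLASSES, dtype=np.int64))
    i, j, k = trip[:, 0], trip[:, 1], trip[:, 2]
    # Bit order matches _EDGE_BITS with local labels (0,1,2) = (i,j,k);
    # adjacency[t, s] holds edge s -> t.
    code = (a[j, i] * 1 + a[i, j] * 2 + a[k, i] * 4 + a[i, k] * 8
            + a[k, j] * 16 + a[j, k] * 32)
    cls = _MOTIF_LUT[code]
    counts = np.bincount(cls[cls >= 0], minlength=N_MOTIF_CLASSES)
    return MotifCensus(counts)


# ---------------------------------------------------------------------------
# Clustering, path length, small-world


def clustering_coefficients(g: BinaryDigraph) -> np.ndarray:
    """Directed clustering coefficient of each node (Fagiolo form).

    C_i = (1/2) [(A + A^T)^3]_ii / [d_tot,i (d_tot,i - 1) - 2 d_bidir,i];
    nodes with a zero denominator get 0. Reduces to the familiar
    Watts-Strogatz coefficient on symmetric graphs.
    """
    a = g.adjacency.astype(float)
    sym = a + a.T
    tri = np.diagonal(np.linalg.matrix_power(sym, 3)) / 2.0
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = np.diagonal(a @ a)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def transitivity(g: BinaryDigraph) -> float:
    """Global (transitive) clustering: pooled triangles over pooled
    possible triangles, the directed analogue of undirected transitivity."""
    a = g.adjacency.astype(float)
    sym = a + a.T
    tri = np.trace(np.linalg.matrix_power(sym, 3)) / 2.0
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = np.diagonal(a @ a)
    denom = float(np.sum(d_tot * (d_tot - 1) - 2 * d_bi))
    return tri / denom if denom > 0 else 0.0


@dataclass
class PathLengthResult:
    """Characteristic path length with unreachable-pair bookkeeping."""

    value: float                 # mean over finite ordered pairs (hops)
    unreachable_fraction: float  # fraction of ordered pairs with no path
    defined: bool                # False when no pair is reachable


def characteristic_path_length(g: BinaryDigraph) -> PathLengthResult:
    """Mean directed shortest-path length over reachable ordered pairs."""
    n = g.n_nodes
    # csgraph convention is row -> column, ours is column -> row.
    d = shortest_path(g.adjacency.T.astype(float), method="D",
                      unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = n * (n - 1)
    frac_unreachable = 1.0 - finite.sum() / n_pairs
    if not finite.any():
        return PathLengthResult(float("nan"), 1.0, False)
    return PathLengthResult(float(d[finite].mean()), float(frac_unreachable),
                            True)


def random_reference(
    g: BinaryDigraph, n_random: int = DEFAULT_N_RANDOM, seed: int = 0,
    swap_factor: int = 10,
) -> tuple[float, float]:
    """Mean transitivity and path length of degree-matched random graphs.

    Each realization rewires the graph by seeded directed edge swaps
    ((a->b, c->d) becomes (a->d, c->b)), preserving every node's in- and
    out-degree; ``swap_factor * n_edges`` swap attempts per realization.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if g.n_edges < 2:
        warnings.warn("graph has fewer than 2 edges; random reference "
                      "equals the graph itself", stacklevel=2)
        return transitivity(g), characteristic_path_length(g).value
    rng = np.random.default_rng(seed)
    c_vals, l_vals = [], []
    for _ in range(n_random):
        rewired = rewire_preserving_degrees(g, rng, swap_factor)
        c_vals.append(transitivity(rewired))
        l_vals.append(characteristic_path_length(rewired).value)
    return float(np.mean(c_vals)), float(np.nanmean(l_vals))


def rewire_preserving_degrees(
    g: BinaryDigraph, rng: np.random.Generator | int = 0,
    swap_factor: int = 10,
) -> BinaryDigraph:
    """One degree-preserving randomization of ``g`` by directed edge
    swaps; every node keeps its in- and out-degree."""
    rng = rng if isinstance(rng, np.random.Generator) else \
        np.random.default_rng(rng)
    adj = g.adjacency.copy()
    edges = g.edges()
    n_e = len(edges)
    for _ in range(swap_factor * n_e):
        e1, e2 = rng.integers(0, n_e, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if a == d or c == b:
            continue
        if adj[d, a] or adj[b, c]:  # new edges already present
            continue
        adj[b, a] = adj[d, c] = False
        adj[d, a] = adj[b, c] = True
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    return BinaryDigraph(adj, g.node_labels)


@dataclass
class SmallWorldResult:
    """Small-world comparison of a digraph to matched random networks."""

    C_d: float
    C_rand: float
    L_d: float
    L_rand: float
    sigma: float
    n_random: int
    degenerate: bool = False


def small_world_index(
    g: BinaryDigraph, n_random: int = DEFAULT_N_RANDOM, seed: int = 0
) -> SmallWorldResult:
    """sigma = (C_d / C_rand) / (L_d / L_rand); sigma > 1 marks a
    small-world topology (clustered yet short-pathed)."""
    c_d = transitivity(g)
    l_d = characteristic_path_length(g).value
    c_rand, l_rand = random_reference(g, n_random, seed)
    degenerate = not (c_rand > 0 and l_rand > 0 and np.isfinite(l_d))
    sigma = float("nan") if degenerate else \
        (c_d / c_rand) / (l_d / l_rand)
    return SmallWorldResult(c_d, c_rand, l_d, l_rand, sigma, n_random,
                            degenerate)


# ---------------------------------------------------------------------------
# Weighted measure


@dataclass
class NodeStrengths:
    """Total incoming + outgoing NTE weight at each node (no threshold)."""

    strengths: np.ndarray
    node_labels: tuple[str, ...] = CHANNELS

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_labels, self.strengths.tolist()))


def node_strengths(m: NTEMatrix | np.ndarray) -> NodeStrengths:
    """strength_i = sum_j w_ij + sum_j w_ji on the weighted matrix."""
    values = m.values if isinstance(m, NTEMatrix) else np.asarray(m)
    labels = m.channel_labels if isinstance(m, NTEMatrix) else \
        tuple(f"n{i}" for i in range(values.shape[0]))
    return NodeStrengths(values.sum(axis=0) + values.sum(axis=1), labels)


# ---------------------------------------------------------------------------
# Export


def to_networkx(g: BinaryDigraph):
    """Convert to a networkx DiGraph (nodes labelled by channel name)."""
    import networkx as nx

    out = nx.DiGraph()
    out.add_nodes_from(g.node_labels)
    for src, tgt in g.edges():
        out.add_edge(g.node_labels[src], g.node_labels[tgt])
    return out


def write_graphml(g: BinaryDigraph, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(g), path)


def write_edge_list(g: BinaryDigraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for src, tgt in g.edges():
            fh.write(f"{g.node_labels[src]}\t{g.node_labels[tgt]}\n")
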