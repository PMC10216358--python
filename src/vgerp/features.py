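"""Graph-theoretic features of visibility graphs.

Eleven single-channel features are computed per visibility graph:

* average clustering coefficient ``C = mean_i 2|E_i| / (k_i (k_i - 1))``
  (nodes with fewer than two neighbours contribute 0);
* global efficiency ``E_glob = mean over ordered pairs of 1/d_ij``;
* local efficiency — per node, the mean inverse *full-graph* distance over
  ordered pairs of its neighbours, normalised by ``|V_gi|(|V_gi|-1)``;
  shortest paths may leave the neighbourhood;
* small-worldness ``S = (C/C_r) / (L/L_r)`` against a fixed Erdős–Rényi
  reference shared by every graph in a cohort;
* graph index complexity ``GIC = 4c(1-c)`` with
  ``c = (lmax - 2cos(pi/(n+1))) / (n - 1 - 2cos(pi/(n+1)))``;
* max-clique size and independence number via the deterministic
  Boppana–Halldórsson Ramsey-type approximation (returned values are sizes
  of verified cliques / independent sets, hence lower bounds);
* a metric-TSP tour cost: MST of the BFS metric closure rooted at the first
  time point, preorder walk, return to root (a 2-approximation);
* edge density ``D = 2|E| / (|V|(|V|-1))``;
* exact global minimum cut (Stoer–Wagner);
* greedy coloring number, vertices in non-increasing degree order.

The single cross-channel feature is the edge count of the channel network
whose nodes are channels and whose edges join channels with clustering
coefficient sequence similarity (CCSS — absolute Pearson correlation of the
two clustering sequences) above a threshold, 0.25 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .visibility import build_vg

__all__ = [
    "SINGLE_FEATURES",
    "CROSS_FEATURE",
    "SmallWorldRef",
    "make_small_world_ref",
    "clustering_sequence",
    "average_clustering",
    "global_efficiency",
    "local_efficiency",
    "small_worldness",
    "graph_index_complexity",
    "max_clique",
    "max_clique_size",
    "maximum_independent_set",
    "tsp_cost",
    "density",
    "independence_number",
    "min_cut_size",
    "coloring_number",
    "ccss",
    "vg_features",
    "channel_network_edges",
    "extract_features",
    "read_feature_matrix",
]

SINGLE_FEATURES = (
    "clustering",
    "global_efficiency",
    "local_efficiency",
    "small_worldness",
    "gic",
    "max_clique",
    "tsp",
    "density",
    "independence",
    "min_cut",
    "coloring",
)

CROSS_FEATURE = "ccss_edges"


def _distances(g: nx.Graph) -> np.ndarray:
    """Unweighted all-pairs shortest-path matrix (inf where disconnected)."""
    n = g.number_of_nodes()
    adj = nx.to_scipy_sparse_array(g, nodelist=range(n), format="csr")
    if n == 1:
        return np.zeros((1, 1))
    return shortest_path(csr_array(adj), method="D", unweighted=True)


def _adjacency(g: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(g, nodelist=range(g.number_of_nodes()))


def clustering_sequence(g: nx.Graph) -> np.ndarray:
    """Per-node clustering coefficients in node order; 0 for degree < 2."""
    return _clustering_from_adjacency(_adjacency(g))


def _clustering_from_adjacency(adj: np.ndarray) -> np.ndarray:
    # closed triples through i = (A^3)_ii / 2; possible = k_i (k_i - 1) / 2
    k = adj.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", adj, adj, adj)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def average_clustering(g: nx.Graph) -> float:
    return float(clustering_sequence(g).mean())


def global_efficiency(g: nx.Graph, dist: np.ndarray | None = None) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    d = _distances(g) if dist is None else dist
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        raise ValueError("global efficiency of a disconnected graph")
    return float((1.0 / d[off]).mean())


def local_efficiency(g: nx.Graph, dist: np.ndarray | None = None) -> float:
    """Neighbourhood efficiency with full-graph shortest paths.

    For each node with at least two neighbours, average 1/d(j,k) over
    ordered neighbour pairs (j, k), where d is the distance in the whole
    graph; other nodes contribute 0.  Mean over all nodes.
    """
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    d = _distances(g) if dist is None else dist
    total = 0.0
    for i in g.nodes:
        nbrs = list(g.neighbors(i))
        k = len(nbrs)
        if k < 2:
            continue
        sub = d[np.ix_(nbrs, nbrs)]
        off = ~np.eye(k, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = 1.0 / sub[off]
        total += inv[np.isfinite(inv)].sum() / (k * (k - 1))
    return total / n


def _avg_path_length(dist: np.ndarray) -> float:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(dist[off].mean())


@dataclass(frozen=True)
class SmallWorldRef:
    """A fixed Erdős–Rényi reference for small-worldness normalisation."""

    graph: nx.Graph
    c_r: float
    l_r: float
    p: float
    seed: int

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()


def make_small_world_ref(n: int, p: float, seed: int = 0, max_tries: int = 1000) -> SmallWorldRef:
    """Connected ER reference graph with its clustering and path length.

    Resamples (advancing the seed) until the draw is connected, so the same
    arguments always give the same reference.
    """
    for k in range(max_tries):
        g = nx.gnp_random_graph(n, p, seed=seed + k)
        if n == 1 or nx.is_connected(g):
            return SmallWorldRef(
                graph=g,
                c_r=float(average_clustering(g)),
                l_r=_avg_path_length(_distances(g)),
                p=p,
                seed=seed + k,
            )
    raise RuntimeError(f"no connected ER graph found for n={n}, p={p}")


def small_worldness(
    g: nx.Graph,
    ref: SmallWorldRef,
    dist: np.ndarray | None = None,
    clustering: float | None = None,
) -> float:
    if ref.n != g.number_of_nodes():
        raise ValueError("reference node count differs from graph")
    if ref.c_r == 0:
        raise ValueError("degenerate reference: zero clustering")
    d = _distances(g) if dist is None else dist
    c = average_clustering(g) if clustering is None else clustering
    length = _avg_path_length(d)
    return (c / ref.c_r) / (length / ref.l_r)


def graph_index_complexity(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("GIC needs at least two nodes")
    adj = nx.to_numpy_array(g, nodelist=range(n))
    lmax = float(np.linalg.eigvalsh(adj)[-1])
    lo = 2.0 * np.cos(np.pi / (n + 1))
    c = (lmax - lo) / (n - 1 - lo)
    return float(4.0 * c * (1.0 - c))


def _ramsey(adj: list, nodes: frozenset) -> tuple[set, set]:
    """Ramsey-type recursion: a clique and an independent set of the induced
    subgraph, pivoting on the lowest-index node (deterministic)."""
    if not nodes:
        return set(), set()
    v = min(nodes)
    nbrs = adj[v] & nodes
    non = nodes - adj[v] - {v}
    c1, i1 = _ramsey(adj, frozenset(nbrs))
    c2, i2 = _ramsey(adj, frozenset(non))
    c1.add(v)
    i2.add(v)
    return (c1 if len(c1) >= len(c2) else c2), (i1 if len(i1) >= len(i2) else i2)


def _clique_removal(adj: list, n: int) -> tuple[set, list]:
    """Boppana–Halldórsson: best independent set found while repeatedly
    removing Ramsey cliques; also returns the cliques removed."""
    remaining = frozenset(range(n))
    clique, best_iset = _ramsey(adj, remaining)
    cliques = [clique]
    remaining = remaining - clique
    while remaining:
        clique, iset = _ramsey(adj, remaining)
        cliques.append(clique)
        if len(iset) > len(best_iset):
            best_iset = iset
        remaining = remaining - clique
    return best_iset, cliques


def _neighbor_sets(g: nx.Graph) -> list:
    n = g.number_of_nodes()
    return [frozenset(g.neighbors(i)) for i in range(n)]


def max_clique(g: nx.Graph) -> set:
    """Clique found by the deterministic Ramsey-type approximation.

    Runs the independent-set approximation on the complement graph; the
    returned set is a verified clique of ``g`` (a lower bound on the true
    maximum clique).
    """
    n = g.number_of_nodes()
    if n == 0:
        return set()
    all_nodes = frozenset(range(n))
    comp_adj = [all_nodes - nbrs - {i} for i, nbrs in enumerate(_neighbor_sets(g))]
    iset, _ = _clique_removal(comp_adj, n)
    return iset


def max_clique_size(g: nx.Graph) -> int:
    return len(max_clique(g))


def maximum_independent_set(g: nx.Graph) -> set:
    """Independent set found by the Ramsey-type clique-removal approximation."""
    n = g.number_of_nodes()
    if n == 0:
        return set()
    iset, _ = _clique_removal(_neighbor_sets(g), n)
    return iset


def independence_number(g: nx.Graph) -> int:
    return len(maximum_independent_set(g))


def tsp_cost(g: nx.Graph, dist: np.ndarray | None = None) -> int:
    """Double-tree 2-approximate tour cost in the BFS metric closure.

    Prim MST of the metric closure rooted at node 0 (lowest-index
    tie-breaking), preorder walk, return to the root; the cost is the sum
    of metric distances along the walk.  At least ``n`` and at most twice
    the optimal metric tour.
    """
    n = g.number_of_nodes()
    d = _distances(g) if dist is None else dist
    if np.isinf(d).any():
        raise ValueError("TSP tour of a disconnected graph")
    if n == 1:
        return 0
    # Prim from node 0; np.argmin takes the lowest index on ties
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    key = d[0].copy()
    parent = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for _ in range(n - 1):
        masked = np.where(in_tree, np.inf, key)
        v = int(np.argmin(masked))
        in_tree[v] = True
        children[parent[v]].append(v)
        closer = d[v] < key
        key = np.where(closer & ~in_tree, d[v], key)
        parent = np.where(closer & ~in_tree, v, parent)
    # preorder walk (children already in discovery order = lowest index first)
    order = []
    stack = [0]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(children[u]))
    cost = sum(d[order[i], order[i + 1]] for i in range(n - 1)) + d[order[-1], 0]
    return int(round(cost))


def density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least two nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def min_cut_size(g: nx.Graph) -> int:
    """Exact global minimum cut (Stoer–Wagner) of the unit-weight graph."""
    if g.number_of_nodes() < 2:
        raise ValueError("minimum cut needs at least two nodes")
    if not nx.is_connected(g):
        raise ValueError("minimum cut of a disconnected graph is zero (signalled)")
    value, _ = nx.stoer_wagner(g)
    return int(value)


def coloring_number(g: nx.Graph) -> int:
    """Greedy proper coloring, largest degree first (stable index tie-break)."""
    if g.number_of_nodes() == 0:
        return 0
    colors = nx.greedy_color(g, strategy="largest_first")
    return len(set(colors.values()))


def ccss(x: nx.Graph | np.ndarray, y: nx.Graph | np.ndarray) -> float:
    """Clustering coefficient sequence similarity: |Pearson r| of the CCS.

    Accepts graphs or precomputed clustering sequences.  Returns 0 when
    either sequence has zero variance.
    """
    cx = clustering_sequence(x) if isinstance(x, nx.Graph) else np.asarray(x, dtype=float)
    cy = clustering_sequence(y) if isinstance(y, nx.Graph) else np.asarray(y, dtype=float)
    if cx.shape != cy.shape:
        raise ValueError("clustering sequences of unequal length")
    if cx.std() == 0 or cy.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(cx, cy)[0, 1]))


def channel_network_edges(vgs: list, theta: float = 0.25) -> int:
    """Edge count of the channel graph with edges where CCSS > theta.

    ``vgs`` holds one visibility graph (or clustering sequence) per channel;
    all must share the node count.
    """
    seqs = [
        clustering_sequence(v) if isinstance(v, nx.Graph) else np.asarray(v, dtype=float)
        for v in vgs
    ]
    n = {len(s) for s in seqs}
    if len(n) > 1:
        raise ValueError("channel visibility graphs differ in size")
    count = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if ccss(seqs[i], seqs[j]) > theta:
                count += 1
    return count


def vg_features(g: nx.Graph, ref: SmallWorldRef) -> dict:
    """All eleven single-channel features of one visibility graph."""
    d = _distances(g)
    c_mean = average_clustering(g)
    return {
        "clustering": c_mean,
        "global_efficiency": global_efficiency(g, d),
        "local_efficiency": local_efficiency(g, d),
        "small_worldness": small_worldness(g, ref, d, clustering=c_mean),
        "gic": graph_index_complexity(g),
        "max_clique": max_clique_size(g),
        "tsp": tsp_cost(g, d),
        "density": density(g),
        "independence": independence_number(g),
        "min_cut": min_cut_size(g),
        "coloring": coloring_number(g),
    }


def extract_features(
    cohort,
    theta: float = 0.25,
    ref: SmallWorldRef | None = None,
    ref_seed: int = 0,
) -> tuple[pd.DataFrame, SmallWorldRef]:
    """Cohort feature matrix: one row per subject, one column per grid cell.

    Columns are named ``feature__band__condition__channel`` for the eleven
    single-channel features and ``ccss_edges__band__condition`` for the
    cross-channel network edge count (emitted only when the cohort has at
    least two channels), plus a ``group`` column.  At the full default grid
    (15 channels, 6 bands, 6 conditions) this is 5976 feature columns.

    The small-worldness reference defaults to a single connected ER graph
    with the cohort's node count and edge probability equal to the mean
    density of all cohort visibility graphs.
    """
    ns = len(cohort.subject_groups)
    conds = cohort.condition_names
    bands = cohort.band_names
    chans = cohort.channel_names

    # pass 1: build all VGs (and clustering sequences) once
    vgs = {}
    densities = []
    for s in range(ns):
        for c, cond in enumerate(conds):
            for b, band in enumerate(bands):
                for ch in range(len(chans)):
                    series = cohort.data[s, c, b, ch]
                    g = build_vg(series)
                    vgs[(s, c, b, ch)] = g
                    densities.append(density(g))

    if ref is None:
        n_nodes = cohort.data.shape[-1]
        ref = make_small_world_ref(n_nodes, float(np.mean(densities)), seed=ref_seed)

    columns: dict[str, np.ndarray] = {}
    for b, band in enumerate(bands):
        for c, cond in enumerate(conds):
            for ch, chan in enumerate(chans):
                per_subj = [
                    vg_features(vgs[(s, c, b, ch)], ref) for s in range(ns)
                ]
                for feat in SINGLE_FEATURES:
                    columns[f"{feat}__{band}__{cond}__{chan}"] = np.array(
                        [row[feat] for row in per_subj], dtype=float
                    )
            if len(chans) >= 2:
                columns[f"{CROSS_FEATURE}__{band}__{cond}"] = np.array(
                    [
                        channel_network_edges(
                            [vgs[(s, c, b, ch)] for ch in range(len(chans))],
                            theta=theta,
                        )
                        for s in range(ns)
                    ],
                    dtype=float,
                )

    df = pd.DataFrame(columns)
    df.insert(0, "group", list(cohort.subject_groups))
    return df, ref


def read_feature_matrix(path, expected_columns: int | None = None) -> pd.DataFrame:
    """Round-trip reader for a feature-matrix CSV; optionally validates width."""
    df = pd.read_csv(path, index_col=0)
    if "group" not in df.columns:
        raise ValueError("feature matrix lacks a 'group' column")
    n_feat = df.shape[1] - 1
    if expected_columns is not None and n_feat != expected_columns:
        raise ValueError(f"expected {expected_columns} feature columns, found {n_feat}")
    if df.drop(columns="group").isna().any().any():
        raise ValueError("missing values in feature matrix")
    return df
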