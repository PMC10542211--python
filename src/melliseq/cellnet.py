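"""Pearson k-NN graph construction, Markov clustering, small-cluster merging.

Cells (or genes — the same machinery builds the gene coexpression network)
are connected to their k most similar neighbours by Pearson correlation,
subject to a hard similarity threshold; the directed k-NN relation is
symmetrized by union.  The graph is clustered with the Markov Cluster
algorithm (MCL): the column-stochastic transition matrix is alternately
expanded (matrix power) and inflated (entrywise power + renormalization)
until it converges to a union of attractor systems, which are read off as
clusters.  Clusters smaller than a minimum size are merged into the
neighbouring cluster with the highest total edge weight.

Clusterings are represented as a pandas Series mapping node name to an
integer cluster id; ids are contiguous from 1 in order of descending
cluster size (ties broken by smallest member name).
"""

from __future__ import annotations

import warnings

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "pairwise_pearson",
    "build_knn_graph",
    "prune_low_degree",
    "mcl_cluster",
    "merge_small_clusters",
    "relabel_by_size",
]


def pairwise_pearson(profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation between the rows of an entities x features matrix.

    Returns a symmetric matrix with unit diagonal.  Zero-variance profiles
    cannot be correlated and get similarity 0 to every other entity (with a
    warning).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 features per entity")
    sd = profiles.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(profiles)
    sim = np.atleast_2d(sim)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance profile(s); similarity set to 0")
        sim[degenerate, :] = 0.0
        sim[:, degenerate] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def build_knn_graph(
    sim: np.ndarray,
    names: list[str] | pd.Index,
    k: int = 20,
    r_min: float = 0.77,
) -> igraph.Graph:
    """Thresholded k-nearest-neighbour graph from a similarity matrix.

    Each node nominates its ``k`` most similar partners (similarity >=
    ``r_min``, self excluded); an undirected edge exists if either endpoint
    nominates the other (union symmetrization).  Edge weight is the
    similarity.  Ties at the k-th neighbour are broken by node order so
    construction is deterministic.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    sim = np.asarray(sim)
    n = sim.shape[0]
    names = list(names)
    if len(names) != n:
        raise ValueError("names length does not match similarity matrix")

    edges: set[tuple[int, int]] = set()
    idx = np.arange(n)
    for u in range(n):
        # sort by (-similarity, node index): deterministic tie-break
        order = np.lexsort((idx, -sim[u]))
        count = 0
        for v in order:
            if v == u:
                continue
            if sim[u, v] < r_min:
                break
            edges.add((min(u, v), max(u, v)))
            count += 1
            if count == k:
                break

    g = igraph.Graph()
    g.add_vertices(names)
    edge_list = sorted(edges)
    g.add_edges(edge_list)
    g.es["weight"] = [float(sim[a, b]) for a, b in edge_list]
    return g


def prune_low_degree(g: igraph.Graph, min_degree: int = 3) -> igraph.Graph:
    """Remove poorly connected nodes in a single pass.

    Degrees are evaluated once on the input graph; all nodes below
    ``min_degree`` are removed together with their incident edges.  The
    pass is not iterated, so surviving nodes may end up below the
    threshold afterwards.
    """
    g = g.copy()
    deg = np.array(g.degree())
    g.delete_vertices(np.flatnonzero(deg < min_degree).tolist())
    return g


def _read_clusters(M: sp.csr_matrix, n: int) -> list[set[int]]:
    """Interpret a converged MCL matrix: attractor rows -> clusters, merged on overlap."""
    diag = M.diagonal()
    attractors = np.flatnonzero(diag > 1e-7)
    if attractors.size == 0:  # pathological; treat strongest row per column as attractor
        attractors = np.unique(np.asarray(M.argmax(axis=0)).ravel())
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    covered = np.zeros(n, dtype=bool)
    Mr = M.tocsr()
    for i in attractors:
        row = Mr.getrow(i)
        members = row.indices[row.data > 1e-7]
        covered[members] = True
        covered[i] = True
        for j in members:
            union(int(i), int(j))
    # nodes never claimed by an attractor: attach to the heaviest row of their column
    Mc = M.tocsc()
    for j in np.flatnonzero(~covered):
        col = Mc.getcol(j)
        if col.nnz:
            i = int(col.indices[np.argmax(col.data)])
            union(i, int(j))
    groups: dict[int, set[int]] = {}
    for x in range(n):
        groups.setdefault(find(x), set()).add(x)
    return list(groups.values())


def mcl_cluster(
    g: igraph.Graph,
    inflation: float = 1.6,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> pd.Series:
    """Markov Cluster algorithm on a weighted graph.

    The weighted adjacency matrix gets a self-loop per node (weight = the
    node's maximum incident edge weight, or 1 for isolated nodes) and is
    column-normalized.  Iteration alternates expansion (matrix power),
    inflation (entrywise power + column renormalization) and pruning of
    entries below ``prune``, until the largest entrywise change falls
    below ``tol`` or ``max_iter`` is reached (then a warning is issued and
    the current state is used).  Clusters are the attractor systems of the
    converged matrix; disconnected graph components never share a cluster.
    """
    n = g.vcount()
    if n == 0:
        raise ValueError("cannot cluster an empty graph")
    names = g.vs["name"] if "name" in g.vs.attributes() else [str(i) for i in range(n)]

    rows, cols, data = [], [], []
    loop = np.zeros(n)
    for e in g.es:
        w = float(e["weight"])
        rows += [e.source, e.target]
        cols += [e.target, e.source]
        data += [w, w]
        loop[e.source] = max(loop[e.source], w)
        loop[e.target] = max(loop[e.target], w)
    loop[loop == 0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    data += loop.tolist()
    M = sp.csc_matrix((data, (rows, cols)), shape=(n, n))

    def normalize(A: sp.csc_matrix) -> sp.csc_matrix:
        colsum = np.asarray(A.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        D = sp.diags(1.0 / colsum)
        return (A @ D).tocsc()

    M = normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M.copy()
        P = M
        for _ in range(expansion - 1):
            P = P @ M
        P = P.tocsc()
        P.data **= inflation
        P.data[P.data < prune] = 0.0
        P.eliminate_zeros()
        M = normalize(P)
        delta = abs(M - prev).max() if (M - prev).nnz else 0.0
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge in {max_iter} iterations; using current state")

    clusters = _read_clusters(M.tocsr(), n)
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters):
        labels[list(members)] = cid
    assignment = pd.Series(labels, index=pd.Index(names, name="node"))
    return relabel_by_size(assignment)


def relabel_by_size(assignment: pd.Series) -> pd.Series:
    """Relabel cluster ids contiguously from 1, descending size, ties by smallest member."""
    groups = assignment.groupby(assignment).groups
    keyed = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(map(str, kv[1]))))
    mapping = {old: new + 1 for new, (old, _) in enumerate(keyed)}
    return assignment.map(mapping).astype(int)


def _intercluster_weights(g: igraph.Graph, assignment: pd.Series) -> dict[tuple[int, int], float]:
    names = g.vs["name"]
    asg = assignment.reindex(names)
    w: dict[tuple[int, int], float] = {}
    for e in g.es:
        ca, cb = int(asg.iloc[e.source]), int(asg.iloc[e.target])
        if ca == cb:
            continue
        key = (min(ca, cb), max(ca, cb))
        w[key] = w.get(key, 0.0) + float(e["weight"])
    return w


def merge_small_clusters(assignment: pd.Series, g: igraph.Graph, min_size: int = 10) -> pd.Series:
    """Merge clusters of fewer than ``min_size`` nodes into their best neighbour.

    Small clusters are processed in ascending size order; each is
    reassigned wholesale to the neighbouring cluster with the highest
    summed weight of connecting edges.  After every merge sizes are
    re-evaluated (a merge may lift its target above the threshold).  A
    small cluster with no external edges is left unchanged.  Final ids are
    relabelled by descending size.
    """
    asg = assignment.copy()
    while True:
        sizes = asg.value_counts()
        weights = _intercluster_weights(g, asg)
        candidates = [
            c for c in sizes.index[sizes < min_size]
            if any(c in key for key in weights)
        ]
        if not candidates:
            break
        # smallest first; ties by cluster id for determinism
        c = min(candidates, key=lambda c: (sizes[c], c))
        best, best_w = None, -1.0
        for (a, b), w in weights.items():
            if c not in (a, b):
                continue
            other = b if a == c else a
            if w > best_w or (w == best_w and (best is None or other < best)):
                best, best_w = other, w
        asg[asg == c] = best
    return relabel_by_size(asg)
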