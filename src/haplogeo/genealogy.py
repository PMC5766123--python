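"""Haplotype genealogy: median-joining networks, interior (ancestral)
haplotype identification, and neighbor-joining trees.

The median-joining construction follows Bandelt's scheme: ordered multistate
(SSR) characters are expanded to stepwise binary indicators, median (Steiner)
vectors of triplets attached to feasible links of the minimum-spanning
network are added iteratively, obsolete medians are pruned, and the final
graph is the minimum-spanning network over observed haplotypes plus the
retained median vectors.  Under coalescent reasoning, older haplotypes tend
to occupy interior, high-degree network positions.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .model import (
    INDEL,
    SSR,
    SUBSTITUTION,
    DistanceModel,
    HaplotypeMatrix,
)

__all__ = ["mj_network", "interior_rank", "nj_tree", "nj_from_distances",
           "bipartitions"]


# ---------------------------------------------------------------------------
# binary expansion

def _binary_expansion(matrix: HaplotypeMatrix, model: DistanceModel):
    """Expand haplotypes to weighted binary columns whose weighted Hamming
    distance equals :func:`~haplogeo.model.pairwise_steps`.

    Returns ``(vectors, weights, column_sites)`` where ``vectors`` is an
    (n_hap, n_col) 0/1 array, ``weights`` the per-column step weights and
    ``column_sites`` the 1-based source site id of each column.
    """
    cols, weights, col_sites = [], [], []
    for idx in matrix.site_columns(model.kinds):
        site = matrix.sites[idx]
        states = [h.states[idx] for h in matrix.haplotypes]
        if site.kind == SUBSTITUTION:
            uniq = sorted(set(states))
            if len(uniq) > 2:
                raise ValueError(
                    f"site {site.site_id}: >2 substitution states; the "
                    "median-joining expansion handles binary substitutions only"
                )
            if len(uniq) == 2:
                cols.append([1 if s == uniq[1] else 0 for s in states])
                weights.append(1.0)
                col_sites.append(site.site_id)
        elif site.kind == INDEL:
            uniq = sorted(set(states))
            if len(uniq) == 2:
                cols.append([1 if s == uniq[1] else 0 for s in states])
                weights.append(model.indel_weight)
                col_sites.append(site.site_id)
        else:  # ssr: stepwise indicators over the observed repeat range
            counts = [s.count for s in states]
            rmin, rmax = min(counts), max(counts)
            for level in range(rmin, rmax):
                cols.append([1 if c > level else 0 for c in counts])
                weights.append(model.ssr_step_weight)
                col_sites.append(site.site_id)
            flanks = sorted({s.flank for s in states})
            if len(flanks) == 2:
                cols.append([1 if s.flank == flanks[1] else 0 for s in states])
                weights.append(1.0)
                col_sites.append(site.site_id)
            elif len(flanks) > 2:
                raise ValueError(f"site {site.site_id}: >2 SSR flank variants")
    if not cols:
        vectors = np.zeros((len(matrix), 0), dtype=int)
    else:
        vectors = np.array(cols, dtype=int).T
    return vectors, np.array(weights), col_sites


def _pdist(vectors, weights):
    diff = vectors[:, None, :] != vectors[None, :, :]
    return (diff * weights).sum(axis=2)


def _msn_edges(d: np.ndarray, eps: float = 0.0):
    """Edges of the epsilon-relaxed minimum spanning network: pairs whose
    distance is within eps of their bottleneck (minimax-path) distance."""
    n = d.shape[0]
    if n < 2:
        return []
    # bottleneck distances via an MST (max edge along the unique MST path)
    g = nx.Graph()
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=d[i, j])
    mst = nx.minimum_spanning_tree(g)
    bottleneck = np.zeros((n, n))
    for src in range(n):
        # DFS carrying the running max edge weight
        stack = [(src, -np.inf)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nb in mst[node]:
                if nb not in seen:
                    seen.add(nb)
                    w = max(mx, mst[node][nb]["weight"])
                    bottleneck[src, nb] = w
                    stack.append((nb, w))
    return [
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if d[i, j] <= bottleneck[i, j] + eps + 1e-9
    ]


def mj_network(matrix: HaplotypeMatrix, frequencies: dict | None = None,
               model: DistanceModel = DistanceModel(), epsilon: float = 0.0,
               max_rounds: int = 25) -> nx.Graph:
    """Median-joining network of a haplotype matrix.

    Nodes are observed haplotypes (``observed=True``, with ``frequency``)
    plus inferred median vectors ``mv1, mv2, ...``; edges carry ``steps``
    (the weighted step distance of their endpoints) and ``sites`` (the
    1-based ids of the mutated sites).  ``epsilon`` relaxes which links and
    medians are admitted (0 = strict minimum spanning network).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if len(matrix) == 0:
        return nx.Graph()
    vectors, weights, col_sites = _binary_expansion(matrix, model)
    names = list(matrix.labels)
    observed = set(names)
    vecs = [vectors[i] for i in range(len(names))]
    n_mv = 0

    for _ in range(max_rounds):
        arr = np.array(vecs)
        d = _pdist(arr, weights)
        links = set(_msn_edges(d, epsilon))
        linked = {i: set() for i in range(len(vecs))}
        for i, j in links:
            linked[i].add(j)
            linked[j].add(i)
        existing = {tuple(v) for v in vecs}
        candidates = {}
        for u, v, w in itertools.combinations(range(len(vecs)), 3):
            nlinks = ((u, v) in links or (v, u) in links) + \
                     ((u, w) in links or (w, u) in links) + \
                     ((v, w) in links or (w, v) in links)
            if nlinks < 2:
                continue
            med = np.median(arr[[u, v, w]], axis=0).astype(int)
            key = tuple(med)
            if key in existing:
                continue
            cost = sum(np.sum((med != arr[x]) * weights) for x in (u, v, w))
            if key not in candidates or cost < candidates[key]:
                candidates[key] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = [k for k, c in candidates.items() if c <= lam + epsilon + 1e-9]
        for key in new:
            n_mv += 1
            names.append(f"mv{n_mv}")
            vecs.append(np.array(key, dtype=int))

    # prune obsolete medians: unobserved nodes of degree <= 2 in the MSN
    while True:
        arr = np.array(vecs)
        d = _pdist(arr, weights)
        deg = {i: 0 for i in range(len(vecs))}
        for i, j in _msn_edges(d, epsilon):
            deg[i] += 1
            deg[j] += 1
        drop = [i for i in range(len(vecs))
                if names[i] not in observed and deg[i] <= 2]
        if not drop:
            break
        for i in sorted(drop, reverse=True):
            del names[i]
            del vecs[i]

    arr = np.array(vecs)
    d = _pdist(arr, weights)
    graph = nx.Graph()
    freq = frequencies or {}
    for i, name in enumerate(names):
        graph.add_node(name, observed=name in observed,
                       frequency=int(freq.get(name, 0)),
                       vector=tuple(int(x) for x in arr[i]))
    if len(names) > 1:
        for i, j in _msn_edges(d, epsilon):
            muts = sorted({col_sites[c] for c in np.flatnonzero(arr[i] != arr[j])})
            graph.add_edge(names[i], names[j], steps=float(d[i, j]), sites=muts)
    return graph


def interior_rank(network: nx.Graph, tolerance: int = 1):
    """Rank observed haplotypes by network interiority.

    Eccentricity is counted in network links (hops, medians included as
    nodes), the way interior positions are read off a haplotype-network
    figure; ranking is by eccentricity ascending, then degree descending.
    Because hop eccentricity is coarsely quantised on sparse networks, the
    returned ``interior_set`` collects the observed nodes within
    ``tolerance`` links of the minimal eccentricity (ties are thereby
    reported, never broken silently).  On very small or star-shaped
    networks this set degenerates to all nodes.

    Returns ``(ranking, interior_set)`` where ``ranking`` is a list of
    ``(label, eccentricity, degree)``.
    """
    if network.number_of_nodes() == 0:
        return [], set()
    if not nx.is_connected(network):
        raise ValueError("network must be connected")
    ecc = nx.eccentricity(network)
    obs = [n for n, a in network.nodes(data=True) if a.get("observed", True)]
    ranking = sorted(
        ((n, ecc[n], network.degree(n)) for n in obs),
        key=lambda t: (t[1], -t[2], t[0]),
    )
    emin = min(e for _, e, _ in ranking)
    interior = {n for n, e, _ in ranking if e <= emin + tolerance}
    return ranking, interior


# ---------------------------------------------------------------------------
# neighbor-joining

def nj_from_distances(d: np.ndarray, labels):
    """Neighbor-joining tree (unrooted) from a symmetric distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    d = np.asarray(d, dtype=float)
    if d.shape != (len(labels), len(labels)) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) == 2:
        # skbio's nj needs >= 3 taxa; two taxa split the distance evenly
        from skbio import TreeNode
        return TreeNode.read(
            [f"({labels[0]}:{d[0, 1] / 2},{labels[1]}:{d[0, 1] / 2});"]
        )
    return nj(DistanceMatrix(d, ids=list(labels)))


def _site_step_tensor(matrix: HaplotypeMatrix, model: DistanceModel):
    from .model import _site_steps

    k = len(matrix)
    cols = matrix.site_columns(model.kinds)
    tensor = np.zeros((len(cols), k, k))
    for c, idx in enumerate(cols):
        site = matrix.sites[idx]
        for i, j in itertools.combinations(range(k), 2):
            st = _site_steps(site, matrix.haplotypes[i].states[idx],
                             matrix.haplotypes[j].states[idx], model)
            tensor[c, i, j] = tensor[c, j, i] = st
    return tensor


def nj_tree(matrix: HaplotypeMatrix, model: DistanceModel = DistanceModel(),
            bootstrap: int = 0, seed: int | None = None):
    """Neighbor-joining tree of a haplotype matrix under a distance model.

    With ``bootstrap > 0``, mutation columns are resampled with replacement
    and bipartition support fractions are attached to internal nodes (and
    returned as ``{frozenset(tip subset): fraction}``).

    Returns ``(tree, supports)`` — an unrooted ``skbio.TreeNode`` and the
    support dict (empty without bootstrapping).
    """
    labels = list(matrix.labels)
    tensor = _site_step_tensor(matrix, model)
    tree = nj_from_distances(tensor.sum(axis=0), labels)
    supports: dict[frozenset, float] = {}
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        target = bipartitions(tree, labels)
        tally = {bp: 0 for bp in target}
        nsites = tensor.shape[0]
        for _ in range(bootstrap):
            sample = rng.integers(0, nsites, size=nsites)
            bt = nj_from_distances(tensor[sample].sum(axis=0), labels)
            got = bipartitions(bt, labels)
            for bp in tally:
                if bp in got:
                    tally[bp] += 1
        supports = {bp: c / bootstrap for bp, c in tally.items()}
        for node in tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            bp = _canonical_bipartition(tips, labels)
            if bp in supports:
                node.name = f"{supports[bp]:.2f}"
    return tree, supports


def _canonical_bipartition(tips: frozenset, labels):
    other = frozenset(labels) - tips
    return min(tips, other, key=lambda s: (len(s), sorted(s)))


def bipartitions(tree, labels=None) -> set:
    """Non-trivial bipartitions of an (unrooted) tree as canonical frozensets."""
    if labels is None:
        labels = [t.name for t in tree.tips()]
    out = set()
    for node in tree.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if 1 < len(tips) < len(labels) - 1:
            out.add(_canonical_bipartition(tips, labels))
    return out
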