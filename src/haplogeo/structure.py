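"""Distance-based AMOVA and spatial AMOVA (SAMOVA).

AMOVA decomposes the total molecular variance of a pairwise individual
distance matrix into hierarchical components (Excoffier-style sums of
squares with the standard expected-mean-square coefficients for unequal
sample sizes).  Individuals are expanded implicitly from haplotype counts;
the distance between two individuals defaults to the number of differing
substitution sites between their haplotypes, used directly as the squared
molecular distance — the convention of the standard AMOVA tools for
sequence haplotypes, which drop alignment columns containing gaps or
length variants before counting pairwise differences.  Both the distance
model and squaring are configurable.

SAMOVA searches, by simulated annealing with restarts, for the partition of
populations into K geographically contiguous groups (contiguity from a
Delaunay triangulation of the population coordinates) that maximises the
among-group fixation index F_CT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Dataset, DistanceModel, distance_matrix

__all__ = [
    "AmovaResult",
    "PartitionResult",
    "delaunay_adjacency",
    "amova",
    "evaluate_partition",
    "samova",
    "k_sweep",
    "AnnealingSchedule",
]


# ---------------------------------------------------------------------------
# shared machinery

def _cross_matrix(dataset: Dataset, model: DistanceModel, squared: bool) -> np.ndarray:
    """cross[k, l] = sum over ordered individual pairs (i in k, j in l) of
    the (squared) haplotype distance; cross[k, k] is twice the within-pop
    unordered pair sum."""
    d = distance_matrix(dataset.matrix, model)
    if squared:
        d = d ** 2
    counts = dataset.count_matrix().astype(float)
    return counts @ d @ counts.T


@dataclass
class _SSParts:
    ss_total: float
    ss_wp: float
    sizes: np.ndarray
    cross: np.ndarray

    @classmethod
    def build(cls, dataset, model, squared):
        cross = _cross_matrix(dataset, model, squared)
        sizes = np.array([p.n for p in dataset.populations], dtype=float)
        n_total = sizes.sum()
        ss_total = cross.sum() / 2.0 / n_total
        ss_wp = float(np.sum(np.diag(cross) / 2.0 / sizes))
        return cls(ss_total, ss_wp, sizes, cross)

    def ss_within_groups(self, assign: np.ndarray, k: int) -> float:
        out = 0.0
        for g in range(k):
            idx = np.flatnonzero(assign == g)
            ng = self.sizes[idx].sum()
            out += self.cross[np.ix_(idx, idx)].sum() / 2.0 / ng
        return out


def _one_level_components(parts: _SSParts):
    sizes, n_total, s = parts.sizes, parts.sizes.sum(), len(parts.sizes)
    ss_among = parts.ss_total - parts.ss_wp
    df_a, df_w = s - 1, n_total - s
    sigma_w = parts.ss_wp / df_w
    n_prime = (n_total - np.sum(sizes ** 2) / n_total) / df_a
    sigma_a = (ss_among / df_a - sigma_w) / n_prime
    return ss_among, sigma_a, sigma_w, df_a, df_w


def _three_level_components(parts: _SSParts, assign: np.ndarray, k: int):
    sizes, n_total, s = parts.sizes, parts.sizes.sum(), len(parts.sizes)
    ss_wg = parts.ss_within_groups(assign, k)
    ss_ag = parts.ss_total - ss_wg
    ss_sc = ss_wg - parts.ss_wp
    df_a, df_b, df_c = k - 1, s - k, n_total - s
    sigma_c = parts.ss_wp / df_c
    group_sizes = np.array([sizes[assign == g].sum() for g in range(k)])
    sum_n2_over_ng = sum(
        np.sum(sizes[assign == g] ** 2) / group_sizes[g] for g in range(k)
    )
    if df_b > 0:
        n1 = (n_total - sum_n2_over_ng) / df_b
        sigma_b = (ss_sc / df_b - sigma_c) / n1
    else:
        sigma_b = 0.0
    n2 = (sum_n2_over_ng - np.sum(sizes ** 2) / n_total) / df_a
    n3 = (n_total - np.sum(group_sizes ** 2) / n_total) / df_a
    sigma_a = (ss_ag / df_a - sigma_c - n2 * sigma_b) / n3
    return (ss_ag, ss_sc), (sigma_a, sigma_b, sigma_c), (df_a, df_b, df_c)


def _phi_from_sigmas(sigma_a, sigma_b, sigma_c, has_middle: bool):
    total = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / total
    f_st = (sigma_a + sigma_b) / total
    f_sc = sigma_b / (sigma_b + sigma_c) if has_middle else float("nan")
    return f_ct, f_sc, f_st


# ---------------------------------------------------------------------------
# AMOVA

@dataclass(frozen=True)
class AmovaResult:
    """Variance components (one dict per level: source, df, SS, variance,
    percent), Phi fixation indices, and permutation p-values."""

    levels: tuple
    phi: dict
    p_values: dict

    @property
    def percent_among_populations(self) -> float:
        for lev in self.levels:
            if lev["source"] == "among populations":
                return lev["percent"]
        raise KeyError("no flat among-population level in a grouped AMOVA")


def _expand_individuals(dataset: Dataset):
    """Per-individual haplotype index and population index arrays."""
    counts = dataset.count_matrix()
    hap_idx, pop_idx = [], []
    for k in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            hap_idx.extend([j] * counts[k, j])
            pop_idx.extend([k] * counts[k, j])
    return np.array(hap_idx), np.array(pop_idx)


def amova(dataset: Dataset, model: DistanceModel | None = None,
          grouping: dict | None = None, n_perm: int = 1000,
          seed: int | None = None, squared: bool = False) -> AmovaResult:
    """Hierarchical AMOVA from haplotype counts and step distances.

    Without ``grouping``: two levels (among / within populations) with a
    permutation test of Phi_ST obtained by shuffling individuals among
    populations.  With ``grouping`` (population label -> group id): three
    levels with permutation tests for Phi_ST (individuals among all
    populations), Phi_SC (individuals among populations within groups) and
    Phi_CT (whole populations among groups).  Set ``n_perm=0`` to skip the
    permutation tests.
    """
    if len(dataset.populations) < 2:
        raise ValueError("need at least two populations")
    model = model if model is not None else DistanceModel.substitutions_only()
    parts = _SSParts.build(dataset, model, squared)
    if parts.ss_total == 0:
        raise ValueError("all individuals identical: variance components all zero")
    rng = np.random.default_rng(seed)
    if grouping is None:
        return _amova_flat(dataset, parts, model, squared, n_perm, rng)
    assign, k = _assignment_array(dataset, grouping)
    return _amova_grouped(dataset, parts, assign, k, model, squared, n_perm, rng)


def _amova_flat(dataset, parts, model, squared, n_perm, rng):
    ss_among, sigma_a, sigma_w, df_a, df_w = _one_level_components(parts)
    total = sigma_a + sigma_w
    phi_st = sigma_a / total
    levels = (
        {"source": "among populations", "df": df_a, "SS": ss_among,
         "variance": sigma_a, "percent": 100 * sigma_a / total},
        {"source": "within populations", "df": df_w, "SS": parts.ss_wp,
         "variance": sigma_w, "percent": 100 * sigma_w / total},
    )
    p = {}
    if n_perm:
        p["Phi_ST"] = _perm_individuals(dataset, model, squared, phi_st, n_perm, rng)
    return AmovaResult(levels, {"Phi_ST": phi_st}, p)


def _amova_grouped(dataset, parts, assign, k, model, squared, n_perm, rng):
    (ss_ag, ss_sc), (sa, sb, sc), (df_a, df_b, df_c) = _three_level_components(
        parts, assign, k
    )
    f_ct, f_sc, f_st = _phi_from_sigmas(sa, sb, sc, df_b > 0)
    total = sa + sb + sc
    levels = (
        {"source": "among groups", "df": df_a, "SS": ss_ag,
         "variance": sa, "percent": 100 * sa / total},
        {"source": "among populations within groups", "df": df_b, "SS": ss_sc,
         "variance": sb, "percent": 100 * sb / total},
        {"source": "within populations", "df": df_c, "SS": parts.ss_wp,
         "variance": sc, "percent": 100 * sc / total},
    )
    phi = {"Phi_CT": f_ct, "Phi_SC": f_sc, "Phi_ST": f_st}
    p = {}
    if n_perm:
        p["Phi_CT"] = _perm_populations(parts, assign, k, f_ct, n_perm, rng)
        p["Phi_SC"] = _perm_within_groups(dataset, model, squared, assign, k,
                                          f_sc, n_perm, rng)
        p["Phi_ST"] = _perm_individuals(dataset, model, squared, f_st, n_perm, rng,
                                        grouping=(assign, k))
    return AmovaResult(levels, phi, p)


def _assignment_array(dataset, grouping: dict):
    labels = [p.label for p in dataset.populations]
    missing = [l for l in labels if l not in grouping]
    if missing:
        raise ValueError(f"grouping misses populations: {missing}")
    group_ids = sorted({grouping[l] for l in labels}, key=str)
    mapping = {g: i for i, g in enumerate(group_ids)}
    return np.array([mapping[grouping[l]] for l in labels]), len(group_ids)


def _individual_distance(dataset, model, squared):
    d = distance_matrix(dataset.matrix, model)
    if squared:
        d = d ** 2
    hap_idx, pop_idx = _expand_individuals(dataset)
    return d[np.ix_(hap_idx, hap_idx)], pop_idx


def _ss_from_masks(dind, pop_idx, s):
    groups = [np.flatnonzero(pop_idx == k) for k in range(s)]
    ss_wp = sum(dind[np.ix_(g, g)].sum() / 2.0 / len(g) for g in groups)
    return ss_wp


def _perm_individuals(dataset, model, squared, observed, n_perm, rng, grouping=None):
    """Permute individuals among populations; recompute Phi_ST."""
    dind, pop_idx = _individual_distance(dataset, model, squared)
    n = len(pop_idx)
    s = len(dataset.populations)
    sizes = np.array([p.n for p in dataset.populations], dtype=float)
    ss_total = dind.sum() / 2.0 / n
    df_a, df_w = s - 1, n - s
    n_prime = (n - np.sum(sizes ** 2) / n) / df_a
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pidx = pop_idx[perm]
        ss_wp = _ss_from_masks(dind, pidx, s)
        sigma_w = ss_wp / df_w
        sigma_a = ((ss_total - ss_wp) / df_a - sigma_w) / n_prime
        stat = sigma_a / (sigma_a + sigma_w) if sigma_a + sigma_w > 0 else 0.0
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _perm_within_groups(dataset, model, squared, assign, k, observed, n_perm, rng):
    """Permute individuals among populations within their group; recompute Phi_SC."""
    if math.isnan(observed):
        return float("nan")
    dind, pop_idx = _individual_distance(dataset, model, squared)
    s = len(dataset.populations)
    group_of_ind = assign[pop_idx]
    sizes = np.array([p.n for p in dataset.populations], dtype=float)
    n = len(pop_idx)
    df_b, df_c = s - k, n - s
    group_sizes = np.array([sizes[assign == g].sum() for g in range(k)])
    sum_n2_over_ng = sum(
        np.sum(sizes[assign == g] ** 2) / group_sizes[g] for g in range(k)
    )
    n1 = (n - sum_n2_over_ng) / df_b
    # pooled within-group SS is invariant under within-group shuffles
    ss_wg = 0.0
    for g in range(k):
        idx = np.flatnonzero(group_of_ind == g)
        ss_wg += dind[np.ix_(idx, idx)].sum() / 2.0 / len(idx)
    hits = 0
    for _ in range(n_perm):
        pidx = pop_idx.copy()
        for g in range(k):
            idx = np.flatnonzero(group_of_ind == g)
            pidx[idx] = pidx[idx][rng.permutation(len(idx))]
        ss_wp = _ss_from_masks(dind, pidx, s)
        sigma_c = ss_wp / df_c
        sigma_b = ((ss_wg - ss_wp) / df_b - sigma_c) / n1
        stat = sigma_b / (sigma_b + sigma_c) if sigma_b + sigma_c > 0 else 0.0
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _perm_populations(parts, assign, k, observed, n_perm, rng):
    """Permute whole populations among groups; recompute Phi_CT."""
    hits = 0
    for _ in range(n_perm):
        perm_assign = assign[rng.permutation(len(assign))]
        if len(np.unique(perm_assign)) < k:
            continue
        _, (sa, sb, sc), (_, df_b, _) = _three_level_components(parts, perm_assign, k)
        stat = sa / (sa + sb + sc) if sa + sb + sc > 0 else 0.0
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def evaluate_partition(dataset: Dataset, model: DistanceModel | None = None,
                       grouping: dict | None = None, squared: bool = False):
    """Deterministic three-level AMOVA for a fixed grouping.

    Returns ``(F_CT, F_SC, F_ST)``.  ``grouping`` maps population label to
    group id; with every population its own group F_SC is undefined (NaN)
    and F_CT equals F_ST.
    """
    if grouping is None:
        raise ValueError("evaluate_partition requires a grouping")
    model = model if model is not None else DistanceModel.substitutions_only()
    assign, k = _assignment_array(dataset, grouping)
    if k < 2:
        raise ValueError("F_CT undefined for a single group")
    parts = _SSParts.build(dataset, model, squared)
    _, (sa, sb, sc), (_, df_b, _) = _three_level_components(parts, assign, k)
    return _phi_from_sigmas(sa, sb, sc, df_b > 0)


# ---------------------------------------------------------------------------
# SAMOVA

def delaunay_adjacency(dataset: Dataset) -> dict:
    """Neighbour pairs from a Delaunay triangulation of (longitude, latitude).

    Returns {population label: set of neighbour labels}.  With fewer than
    three (or collinear) populations, falls back to a nearest-neighbour
    chain so the graph stays connected.
    """
    from scipy.spatial import Delaunay, QhullError

    labels = [p.label for p in dataset.populations]
    pts = np.array([[p.longitude, p.latitude] for p in dataset.populations])
    adj = {l: set() for l in labels}
    try:
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i in range(3):
                for j in range(i + 1, 3):
                    a, b = labels[simplex[i]], labels[simplex[j]]
                    adj[a].add(b)
                    adj[b].add(a)
    except (QhullError, ValueError):
        order = np.argsort(pts[:, 0] + pts[:, 1])
        for i in range(len(order) - 1):
            a, b = labels[order[i]], labels[order[i + 1]]
            adj[a].add(b)
            adj[b].add(a)
    return adj


@dataclass(frozen=True)
class AnnealingSchedule:
    """Simulated-annealing configuration for :func:`samova`."""

    n_restarts: int = 100
    n_proposals: int = 10_000
    cooling: float = 0.9
    cooling_every: int = 200
    t0_moves: int = 100   # random moves used to set the initial temperature


@dataclass(frozen=True)
class PartitionResult:
    K: int
    groups: dict            # population label -> group index
    F_CT: float
    F_SC: float
    F_ST: float
    sa_trace: tuple = ()    # best objective per restart


def _connected(members: set, adj: dict) -> bool:
    if not members:
        return False
    seen = {next(iter(members))}
    stack = [next(iter(members))]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y in members and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen == members


class _Objective:
    """Fast F_CT evaluation for candidate assignments."""

    def __init__(self, dataset, model, squared):
        self.parts = _SSParts.build(dataset, model, squared)
        self.labels = [p.label for p in dataset.populations]

    def f_ct(self, assign: np.ndarray, k: int) -> float:
        _, (sa, sb, sc), _ = _three_level_components(self.parts, assign, k)
        total = sa + sb + sc
        return sa / total if total > 0 else -np.inf


def _random_contiguous_partition(labels, adj, k, rng):
    idx = {l: i for i, l in enumerate(labels)}
    seeds = rng.choice(len(labels), size=k, replace=False)
    assign = np.full(len(labels), -1)
    frontier = []
    for g, s in enumerate(seeds):
        assign[s] = g
        frontier.append(list(adj[labels[s]]))
    unassigned = set(range(len(labels))) - set(seeds)
    while unassigned:
        progressed = False
        for g in rng.permutation(k):
            cands = [idx[l] for l in frontier[g] if idx[l] in unassigned]
            if cands:
                pick = cands[rng.integers(len(cands))]
                assign[pick] = g
                unassigned.discard(pick)
                frontier[g].extend(adj[labels[pick]])
                progressed = True
        if not progressed:     # disconnected leftovers: attach arbitrarily
            pick = unassigned.pop()
            assign[pick] = rng.integers(k)
    return assign


def samova(dataset: Dataset, model: DistanceModel | None = None, K: int = 2,
           schedule: AnnealingSchedule = AnnealingSchedule(),
           seed: int | None = None, adjacency: dict | None = None,
           enforce_contiguity: bool = True, squared: bool = False) -> PartitionResult:
    """Search for the K-group partition maximising F_CT.

    Groups are constrained to be connected in the adjacency graph
    (Delaunay neighbours by default).  Simulated annealing with restarts;
    the proposal moves one boundary population to an adjacent group,
    rejecting moves that would empty or disconnect its source group.
    Reproducible under a fixed ``seed``.
    """
    model = model if model is not None else DistanceModel.substitutions_only()
    s = len(dataset.populations)
    if not 2 <= K <= s:
        raise ValueError(f"K must be in [2, {s}]")
    labels = [p.label for p in dataset.populations]
    adj = adjacency if adjacency is not None else delaunay_adjacency(dataset)
    obj = _Objective(dataset, model, squared)
    rng = np.random.default_rng(seed)
    idx_of = {l: i for i, l in enumerate(labels)}

    def moves(assign):
        out = []
        for i, l in enumerate(labels):
            for nb in adj[l]:
                g_to = assign[idx_of[nb]]
                if g_to != assign[i]:
                    out.append((i, g_to))
        return out

    def legal(assign, i, g_to):
        g_from = assign[i]
        members = {labels[j] for j in np.flatnonzero(assign == g_from)} - {labels[i]}
        if not members:
            return False
        return (not enforce_contiguity) or _connected(members, adj)

    best_assign, best_f, trace = None, -np.inf, []
    for _ in range(schedule.n_restarts):
        assign = _random_contiguous_partition(labels, adj, K, rng)
        f = obj.f_ct(assign, K)
        # initial temperature from the spread of objective changes
        deltas = []
        for _ in range(schedule.t0_moves):
            cand = moves(assign)
            if not cand:
                break
            i, g_to = cand[rng.integers(len(cand))]
            if legal(assign, i, g_to):
                trial = assign.copy()
                trial[i] = g_to
                deltas.append(obj.f_ct(trial, K) - f)
        temp = max(float(np.std(deltas)) if deltas else 0.01, 1e-4)
        cur, cur_f = assign.copy(), f
        loc_best, loc_best_f = cur.copy(), cur_f
        for step in range(schedule.n_proposals):
            cand = moves(cur)
            if not cand:
                break
            i, g_to = cand[rng.integers(len(cand))]
            if not legal(cur, i, g_to):
                continue
            trial = cur.copy()
            trial[i] = g_to
            trial_f = obj.f_ct(trial, K)
            delta = trial_f - cur_f
            if delta >= 0 or rng.random() < math.exp(delta / temp):
                cur, cur_f = trial, trial_f
                if cur_f > loc_best_f:
                    loc_best, loc_best_f = cur.copy(), cur_f
            if (step + 1) % schedule.cooling_every == 0:
                temp *= schedule.cooling
        trace.append(loc_best_f)
        if loc_best_f > best_f:
            best_assign, best_f = loc_best, loc_best_f

    grouping = {l: int(best_assign[i]) for i, l in enumerate(labels)}
    f_ct, f_sc, f_st = evaluate_partition(dataset, model, grouping, squared)
    return PartitionResult(K=K, groups=grouping, F_CT=f_ct, F_SC=f_sc,
                           F_ST=f_st, sa_trace=tuple(trace))


def k_sweep(dataset: Dataset, model: DistanceModel | None = None,
            k_range=range(2, 8), schedule: AnnealingSchedule = AnnealingSchedule(),
            seed: int | None = None, adjacency: dict | None = None,
            max_singleton_groups: int = 1, rel_tol: float = 0.01):
    """Run :func:`samova` over a range of K and flag the supported K.

    The diagnostic operationalises the usual SAMOVA model-choice reasoning:
    partitions whose best solution contains more than
    ``max_singleton_groups`` single-population groups are considered
    over-split (the search is dismembering structure rather than finding
    it) and excluded; among the rest, the smallest K whose F_CT is within
    ``rel_tol`` (relative) of the maximum eligible F_CT is selected —
    i.e. the coarsest partition that already captures the among-group
    variance, which is also where F_SC bottoms out before group sizes
    collapse.

    Returns ``(results, chosen_k)`` where ``results`` is {K: PartitionResult}.
    """
    rng = np.random.default_rng(seed)
    results = {}
    for k in k_range:
        results[k] = samova(dataset, model, K=k, schedule=schedule,
                            seed=int(rng.integers(2 ** 31 - 1)), adjacency=adjacency)
    eligible = {}
    for k, res in results.items():
        sizes = {}
        for pop, g in res.groups.items():
            sizes[g] = sizes.get(g, 0) + 1
        if sum(1 for v in sizes.values() if v == 1) <= max_singleton_groups:
            eligible[k] = res.F_CT
    pool = eligible if eligible else {k: r.F_CT for k, r in results.items()}
    best = max(pool.values())
    chosen = min(k for k, f in pool.items() if f >= best * (1 - rel_tol))
    return results, chosen
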