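"""Within-population and total diversity estimators, and GST/NST
differentiation with a permutation comparison.

Per-population statistics follow Nei (1987): unbiased gene (haplotype)
diversity h = n/(n-1)(1 - sum p_i^2) with its sampling standard error, and
nucleotide diversity pi = mean pairwise substitution differences per site.

The hierarchical partition follows Pons & Petit: populations are treated as
a sample of size ``s`` from a universe of demes, so total diversity is
estimated from between-population gene comparisons,

    hT = 1 - (1/(s(s-1))) * sum_{k != l} sum_i x_ki x_li ,

which is unbiased for the expected diversity of two genes drawn from two
distinct demes (the cross-product of frequencies from independent
populations needs no small-sample correction).  hS is the unweighted mean
of per-population unbiased diversities.  vS and vT are the ordered-allele
analogues in which haplotype pairs are weighted by their mutation-step
distance; GST = (hT-hS)/hT and NST = (vT-vS)/vT.  NST > GST indicates
phylogeographic structure: closely related haplotypes co-occur within
populations more than expected from frequencies alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Dataset, DistanceModel, distance_matrix

__all__ = [
    "EFFECTIVE_LENGTH",
    "PopDiversity",
    "DiversityPartition",
    "nei_h",
    "nei_h_se",
    "nucleotide_diversity",
    "pop_diversity",
    "pons_petit",
    "permut_nst_gst",
    "nm_from_gst",
]

#: Default effective length (bp) for per-site nucleotide diversity: the
#: combined aligned spacer length (832+670+761 = 2263 bp) minus the columns
#: occupied by indel events and length-variable repeat tracts.
EFFECTIVE_LENGTH = 2248


def nei_h(counts) -> float:
    """Nei's unbiased gene diversity, n/(n-1) * (1 - sum p_i^2)."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("gene diversity is undefined for n < 2")
    p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - p2)


def nei_h_se(counts) -> float:
    """Standard error of :func:`nei_h` (Nei 1987, eq. 8.12 sampling variance)."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("gene diversity is undefined for n < 2")
    p = [c / n for c in counts]
    s2 = sum(x * x for x in p)
    s3 = sum(x ** 3 for x in p)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 * s2) + s2 - s2 * s2)
    return math.sqrt(max(var, 0.0))


def nucleotide_diversity(counts: dict, matrix, effective_length: float = EFFECTIVE_LENGTH,
                         model: DistanceModel | None = None) -> float:
    """Unbiased nucleotide diversity per site from haplotype counts.

    ``counts`` maps haplotype label -> count.  Pairwise differences default
    to substitution steps only (the convention under which the bundled
    dataset's published values are reproduced); ``effective_length`` is the
    number of sites used for normalisation.
    """
    if effective_length <= 0:
        raise ValueError("effective length must be positive")
    model = model or DistanceModel.substitutions_only()
    labels = [l for l, c in counts.items() if c > 0]
    n = sum(counts[l] for l in labels)
    if n < 2:
        raise ValueError("nucleotide diversity is undefined for n < 2")
    total = 0.0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d = _steps(matrix, labels[i], labels[j], model)
            total += counts[labels[i]] * counts[labels[j]] * d
    npairs = n * (n - 1) / 2
    return total / npairs / effective_length


def _steps(matrix, a, b, model):
    from .model import pairwise_steps

    return pairwise_steps(matrix[a], matrix[b], matrix, model)


@dataclass(frozen=True)
class PopDiversity:
    label: str
    n: int
    n_haplotypes: int
    h: float
    h_se: float
    pi: float
    pi_se: float | None = None


def pop_diversity(dataset: Dataset, effective_length: float = EFFECTIVE_LENGTH):
    """Per-population diversity table (one :class:`PopDiversity` per population)."""
    out = []
    for p in dataset.populations:
        counts = {k: v for k, v in p.counts.items() if v > 0}
        out.append(
            PopDiversity(
                label=p.label,
                n=p.n,
                n_haplotypes=len(counts),
                h=nei_h(counts.values()),
                h_se=nei_h_se(counts.values()),
                pi=nucleotide_diversity(counts, dataset.matrix, effective_length),
            )
        )
    return out


@dataclass(frozen=True)
class DiversityPartition:
    hS: float
    hT: float
    vS: float
    vT: float
    GST: float
    NST: float
    Nm: float
    n_harmonic: float
    p_NST_gt_GST: float | None = None


def _frequencies(dataset: Dataset) -> np.ndarray:
    arr = dataset.count_matrix().astype(float)
    return arr / arr.sum(axis=1, keepdims=True)


def _partition_stats(freqs: np.ndarray, sizes: np.ndarray, dmat: np.ndarray):
    """(hS, hT, vS, vT) from population frequency rows and a haplotype
    distance matrix (identity matrix distances -> unordered h statistics)."""
    s = freqs.shape[0]
    # within-population, unbiased per population then unweighted mean
    quad = np.einsum("ki,ij,kj->k", freqs, dmat, freqs)
    corr = sizes / (sizes - 1.0)
    vS = float(np.mean(corr * quad))
    # between-population mean over ordered pairs k != l
    total = np.einsum("i,ij,j->", freqs.sum(axis=0), dmat, freqs.sum(axis=0))
    vT = float((total - quad.sum()) / (s * (s - 1)))
    return vS, vT


def pons_petit(dataset: Dataset, model: DistanceModel = DistanceModel()) -> DiversityPartition:
    """Pons & Petit diversity partition: hS/hT, vS/vT, GST/NST and Nm.

    The unordered statistics use the "all distinct haplotypes are equally
    different" matrix; the ordered statistics weight haplotype pairs by
    mutation steps under ``model`` (default: substitutions + single-event
    indels + SSR unit steps, matching the network's step counts).
    """
    if len(dataset.populations) < 2:
        raise ValueError("need at least two populations")
    sizes = np.array([p.n for p in dataset.populations], dtype=float)
    if (sizes < 2).any():
        raise ValueError("every population needs n >= 2")
    freqs = _frequencies(dataset)
    k = freqs.shape[1]
    ident = 1.0 - np.eye(k)
    hS, hT = _partition_stats(freqs, sizes, ident)
    dmat = distance_matrix(dataset.matrix, model)
    vS, vT = _partition_stats(freqs, sizes, dmat)
    if hT <= 0:
        raise ValueError("hT = 0: GST undefined (all populations monomorphic and identical)")
    gst = (hT - hS) / hT
    nst = (vT - vS) / vT if vT > 0 else float("nan")
    return DiversityPartition(
        hS=hS, hT=hT, vS=vS, vT=vT, GST=gst, NST=nst,
        Nm=nm_from_gst(gst) if gst > 0 else float("inf"),
        n_harmonic=float(len(sizes) / np.sum(1.0 / sizes)),
    )


def permut_nst_gst(dataset: Dataset, model: DistanceModel = DistanceModel(),
                   n_perm: int = 2000, seed: int | None = None) -> DiversityPartition:
    """Permutation test of NST > GST.

    Haplotype identities are shuffled against the distance matrix (the
    frequency table is untouched), NST is recomputed each time, and the
    p-value is the add-one proportion of permuted NST >= observed NST.
    Under the null that haplotype relatedness is unrelated to geographic
    co-occurrence, NST is exchangeable with its permuted values.
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    obs = pons_petit(dataset, model)
    if len(dataset.matrix) < 2:
        raise ValueError("NST undefined with a single haplotype")
    rng = np.random.default_rng(seed)
    sizes = np.array([p.n for p in dataset.populations], dtype=float)
    freqs = _frequencies(dataset)
    dmat = distance_matrix(dataset.matrix, model)
    k = dmat.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        dp = dmat[np.ix_(perm, perm)]
        vS, vT = _partition_stats(freqs, sizes, dp)
        nst = (vT - vS) / vT if vT > 0 else -np.inf
        if nst >= obs.NST:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return DiversityPartition(**{**obs.__dict__, "p_NST_gt_GST": p})


def nm_from_gst(gst: float) -> float:
    """Migrants per generation for a haploid, maternally inherited marker:
    Nm = (1 - GST) / (2 GST)."""
    if not 0 < gst <= 1:
        raise ValueError("GST must be in (0, 1] (GST = 0 implies unbounded gene flow)")
    return (1.0 - gst) / (2.0 * gst)
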