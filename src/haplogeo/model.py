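"""Core data model for typed haplotype mutation matrices.

A chloroplast haplotype is a combination of states across typed mutation
sites called from one or more aligned non-coding regions.  Three site kinds
are distinguished:

``substitution``
    a nucleotide substitution; states are base letters.
``indel``
    an insertion/deletion event of arbitrary length, treated as a single
    mutation regardless of its span in base pairs; states are ``-`` (absent)
    and ``+`` (present), or any two raw tokens.
``ssr``
    a mono-/di-nucleotide simple-sequence repeat (cpSSR); states are integer
    repeat counts, optionally carrying a short flanking-variant suffix
    (e.g. ``5T`` = five repeats plus a flanking base substitution attached
    to the same site).

Distances between haplotypes are mutation *steps*: one step per differing
substitution, one (weighted) step per indel event, and one step per
repeat-unit difference at an SSR site (plus one step when exactly one of
the two states carries a flanking-variant suffix).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SUBSTITUTION",
    "INDEL",
    "SSR",
    "MutationSite",
    "Haplotype",
    "HaplotypeMatrix",
    "Population",
    "Dataset",
    "DistanceModel",
    "SsrState",
    "parse_state",
    "pairwise_steps",
    "distance_matrix",
    "collapse",
    "solve_counts",
]

SUBSTITUTION = "substitution"
INDEL = "indel"
SSR = "ssr"
_KINDS = (SUBSTITUTION, INDEL, SSR)

_SSR_RE = re.compile(r"^(?:\((?P<motif>[ACGTacgt]+)\))?(?P<count>\d+)\s*(?P<flank>[ACGTacgt]*)$")


@dataclass(frozen=True)
class SsrState:
    """State of an SSR site: a repeat count plus an optional flanking variant."""

    count: int
    flank: str = ""

    def __str__(self) -> str:
        return f"{self.count}{self.flank}"


def parse_state(token: str, kind: str):
    """Parse a raw table token into the internal state for a site ``kind``.

    Substitution and indel states are case-normalised strings; SSR states
    become :class:`SsrState` (``"9"`` -> 9 repeats, ``"(AT)5 T"``/``"5T"``
    -> 5 repeats with flank ``T``).
    """
    token = token.strip()
    if not token:
        raise ValueError("empty state token")
    if kind == SSR:
        m = _SSR_RE.match(token)
        if not m:
            raise ValueError(f"cannot parse SSR state token {token!r}")
        return SsrState(int(m.group("count")), m.group("flank").upper())
    return token.upper()


@dataclass(frozen=True)
class MutationSite:
    """One typed polymorphic site (1-based ``site_id`` follows input order)."""

    site_id: int
    region: str
    kind: str
    motif: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown site kind {self.kind!r} (site {self.site_id})")


@dataclass(frozen=True)
class Haplotype:
    label: str
    states: tuple

    def __len__(self) -> int:
        return len(self.states)


class HaplotypeMatrix:
    """Haplotype labels x typed mutation sites.

    Parameters
    ----------
    sites
        Ordered mutation sites.
    haplotypes
        One :class:`Haplotype` per row; state vectors must match the site
        list in length and no two rows may be identical over all sites.
    aligned_lengths
        Optional mapping region -> aligned length in bp (used to derive the
        effective length for per-site nucleotide diversity).
    """

    def __init__(self, sites, haplotypes, aligned_lengths=None):
        self.sites: tuple[MutationSite, ...] = tuple(sites)
        self.haplotypes: tuple[Haplotype, ...] = tuple(haplotypes)
        self.aligned_lengths: dict[str, int] = dict(aligned_lengths or {})
        labels = [h.label for h in self.haplotypes]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate haplotype labels: {dup}")
        for h in self.haplotypes:
            if len(h.states) != len(self.sites):
                raise ValueError(
                    f"haplotype {h.label!r} has {len(h.states)} states for "
                    f"{len(self.sites)} sites"
                )
        seen: dict[tuple, str] = {}
        for h in self.haplotypes:
            if h.states in seen:
                raise ValueError(
                    "identical state vector: haplotypes "
                    f"{seen[h.states]!r} and {h.label!r}"
                )
            seen[h.states] = h.label

    # -- mapping-style access ------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(h.label for h in self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(h.label == label for h in self.haplotypes)

    def site_columns(self, kinds=None):
        """Indices of sites whose kind is in ``kinds`` (all when None)."""
        if kinds is None:
            return list(range(len(self.sites)))
        return [i for i, s in enumerate(self.sites) if s.kind in kinds]


@dataclass(frozen=True)
class Population:
    """A sampled population: location, sample size and haplotype counts."""

    label: str
    latitude: float
    longitude: float
    counts: dict

    def __post_init__(self):
        for hap, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"negative/non-integer count for {hap!r} in {self.label}")

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class Dataset:
    """A haplotype matrix plus an ordered list of populations."""

    matrix: HaplotypeMatrix
    populations: tuple

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        for p in self.populations:
            for hap, c in p.counts.items():
                if c > 0 and hap not in self.matrix:
                    raise ValueError(
                        f"population {p.label!r} counts unknown haplotype {hap!r}"
                    )

    @property
    def total_n(self) -> int:
        return sum(p.n for p in self.populations)

    def population(self, label: str) -> Population:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    def subset(self, labels) -> "Dataset":
        labels = list(labels)
        pops = [self.population(l) for l in labels]
        return Dataset(self.matrix, pops)

    def global_counts(self) -> dict:
        out = {lab: 0 for lab in self.matrix.labels}
        for p in self.populations:
            for hap, c in p.counts.items():
                out[hap] += c
        return out

    def count_matrix(self) -> np.ndarray:
        """Populations x haplotypes integer count array (matrix label order)."""
        labels = self.matrix.labels
        arr = np.zeros((len(self.populations), len(labels)), dtype=int)
        for i, p in enumerate(self.populations):
            for j, lab in enumerate(labels):
                arr[i, j] = p.counts.get(lab, 0)
        return arr


@dataclass(frozen=True)
class DistanceModel:
    """Policy object: which site kinds count and how events are weighted.

    ``indel_weight`` is the number of steps per indel *event* (1 regardless
    of span in bp); ``ssr_step_weight`` the steps per repeat-unit difference.
    ``ssr_saturate`` caps each SSR site's contribution at one step.
    """

    include_substitutions: bool = True
    include_indels: bool = True
    include_ssrs: bool = True
    indel_weight: float = 1.0
    ssr_step_weight: float = 1.0
    ssr_saturate: bool = False

    def __post_init__(self):
        if self.indel_weight < 0 or self.ssr_step_weight < 0:
            raise ValueError("weights must be non-negative")
        if not (self.include_substitutions or self.include_indels or self.include_ssrs):
            raise ValueError("at least one site kind must be included")

    @property
    def kinds(self) -> tuple:
        out = []
        if self.include_substitutions:
            out.append(SUBSTITUTION)
        if self.include_indels:
            out.append(INDEL)
        if self.include_ssrs:
            out.append(SSR)
        return tuple(out)

    @classmethod
    def substitutions_only(cls) -> "DistanceModel":
        return cls(include_indels=False, include_ssrs=False)


def _site_steps(site: MutationSite, a, b, model: DistanceModel) -> float:
    if site.kind == SUBSTITUTION:
        if not model.include_substitutions:
            return 0.0
        return 0.0 if a == b else 1.0
    if site.kind == INDEL:
        if not model.include_indels:
            return 0.0
        return 0.0 if a == b else model.indel_weight
    if not model.include_ssrs:
        return 0.0
    steps = abs(a.count - b.count) * model.ssr_step_weight
    if a.flank != b.flank:
        steps += 1.0
    if model.ssr_saturate:
        steps = min(steps, 1.0)
    return steps


def pairwise_steps(h1: Haplotype, h2: Haplotype, matrix: HaplotypeMatrix,
                   model: DistanceModel = DistanceModel()) -> float:
    """Number of mutation steps separating two haplotypes under ``model``."""
    if len(h1.states) != len(matrix.sites) or len(h2.states) != len(matrix.sites):
        raise ValueError("haplotypes do not match the matrix site list")
    return sum(
        _site_steps(site, a, b, model)
        for site, a, b in zip(matrix.sites, h1.states, h2.states)
    )


def distance_matrix(matrix: HaplotypeMatrix,
                    model: DistanceModel = DistanceModel()) -> np.ndarray:
    """Symmetric step-distance matrix over the matrix's haplotypes."""
    k = len(matrix)
    d = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        d[i, j] = d[j, i] = pairwise_steps(
            matrix.haplotypes[i], matrix.haplotypes[j], matrix, model
        )
    return d


def collapse(matrix: HaplotypeMatrix, model: DistanceModel = DistanceModel()):
    """Partition haplotypes into classes identical under the included sites.

    Returns a list of tuples of haplotype labels (zero-distance equivalence
    classes); with every site kind included each class is a singleton
    because the matrix forbids duplicate state vectors.
    """
    cols = matrix.site_columns(model.kinds)
    groups: dict[tuple, list] = {}
    for h in matrix.haplotypes:
        key = tuple(h.states[i] for i in cols)
        groups.setdefault(key, []).append(h.label)
    return [tuple(v) for v in groups.values()]


def _unbiased_h(counts) -> float:
    n = sum(counts)
    p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - p2)


def solve_counts(n: int, k: int, h_printed: float, pi_printed=None,
                 distances=None, effective_length=None, pi_resolution: float = 1e-6):
    """Back-solve integer haplotype counts from printed diversity values.

    Searches all compositions of ``n`` into ``k`` positive parts and keeps
    those whose unbiased gene diversity rounds to ``h_printed`` at its
    printed precision.  When ``pi_printed`` (per-site nucleotide diversity),
    ``distances`` (mapping frozenset({label_i, label_j}) -> steps) and
    ``effective_length`` are supplied, the assignment of counts to labels is
    additionally constrained to match the printed nucleotide diversity to
    within half of ``pi_resolution`` (the resolution at which pi was
    printed, e.g. 1e-6 for values printed as multiples of 0.001e-3).

    Returns a list of solutions: sorted count tuples, or label->count dicts
    when label assignment is constrained.
    """
    if not (n >= k >= 1):
        raise ValueError("need n >= k >= 1")
    decimals = _printed_decimals(h_printed)
    sols = []
    for comp in _compositions(n, k):
        if round(_unbiased_h(comp), decimals) == round(h_printed, decimals) or (
            k == 1 and h_printed == 0
        ):
            sols.append(comp)
    if pi_printed is None or distances is None:
        return sorted(set(tuple(sorted(s, reverse=True)) for s in sols), reverse=True)
    labels = sorted({lab for pair in distances for lab in pair})
    if len(labels) != k:
        raise ValueError("distances must involve exactly k labels")
    out = []
    npairs = n * (n - 1) / 2
    for comp in set(tuple(sorted(s, reverse=True)) for s in sols):
        for perm in set(itertools.permutations(comp)):
            assign = dict(zip(labels, perm))
            diff = sum(
                assign[a] * assign[b] * distances[frozenset((a, b))]
                for a, b in itertools.combinations(labels, 2)
            )
            pi = diff / npairs / (effective_length or 1.0)
            if abs(pi - pi_printed) <= pi_resolution / 2.0 and assign not in out:
                out.append(assign)
    return out


def _compositions(n, k):
    """All compositions of n into k positive parts (order matters)."""
    if k == 1:
        yield (n,)
        return
    for first in range(1, n - k + 2):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _printed_decimals(x) -> int:
    s = f"{x!r}"
    if "e" in s or "E" in s:
        # printed like 0.074e-3; fall back to significant rounding
        return max(0, -int(math.floor(math.log10(abs(x)))) + 3)
    return len(s.split(".")[1]) if "." in s else 0
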