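"""Conservation-priority scoring of populations.

Haplotypes are classified into five categories — ancestral (network-interior),
derived, endemic (private to one population), rare, and common — each worth a
fixed score (defaults 7, 3, 5, 5, 3).  A population's genetic-importance
score sums the category scores of the haplotypes it carries plus a
nucleotide-diversity term:

    H = Ha + Hd + He + Hr + Hc + 10 * pi_i / pi

Populations with H above a threshold (default 10) are flagged as priority
protection units.  Category assignments can be rule-derived
(:func:`categorize`) or supplied per population (e.g. a published component
table), because rule application in source material is not always
self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .diversity import EFFECTIVE_LENGTH, nucleotide_diversity
from .genealogy import interior_rank
from .model import Dataset

__all__ = ["CategoryScheme", "CategoryAssignment", "PriorityScore",
           "categorize", "h_score", "rank_priority", "scores_from_components"]


@dataclass(frozen=True)
class CategoryScheme:
    """Category scores and the rules deriving category membership."""

    values: dict = field(default_factory=lambda: {
        "ancestral": 7, "endemic": 5, "rare": 5, "derived": 3, "common": 3,
    })
    rare_count_threshold: int = 4      # max global count for "rare"
    rare_requires_private: bool = True
    common_min_populations: int = 2

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ValueError("category scores must be non-negative")


@dataclass(frozen=True)
class CategoryAssignment:
    """Per-haplotype category flags (ancestral/derived exclusive;
    endemic/common exclusive)."""

    flags: dict                       # label -> set of category names
    provenance: str = "rule-derived"

    def categories(self, label: str) -> set:
        return self.flags[label]

    def of(self, category: str) -> set:
        return {l for l, f in self.flags.items() if category in f}


def categorize(dataset: Dataset, network, scheme: CategoryScheme = CategoryScheme()
               ) -> CategoryAssignment:
    """Rule-derived category assignment for every haplotype in the dataset.

    ancestral = the network's minimal-eccentricity (most interior) set;
    derived = the complement; endemic = present in exactly one population;
    common = present in >= ``common_min_populations`` populations; rare =
    global count <= ``rare_count_threshold`` (and endemic, by default).
    """
    obs = {n for n, a in network.nodes(data=True) if a.get("observed", True)}
    if obs != set(dataset.matrix.labels):
        raise ValueError("network haplotypes do not match the dataset")
    _, interior = interior_rank(network)
    global_counts = dataset.global_counts()
    pops_with = {
        lab: sum(1 for p in dataset.populations if p.counts.get(lab, 0) > 0)
        for lab in dataset.matrix.labels
    }
    flags = {}
    for lab in dataset.matrix.labels:
        f = set()
        f.add("ancestral" if lab in interior else "derived")
        if pops_with[lab] == 1:
            f.add("endemic")
        elif pops_with[lab] >= scheme.common_min_populations:
            f.add("common")
        if global_counts[lab] <= scheme.rare_count_threshold and (
            not scheme.rare_requires_private or "endemic" in f
        ):
            f.add("rare")
        flags[lab] = f
    return CategoryAssignment(flags)


_COMPONENT_OF = {"ancestral": "Ha", "derived": "Hd", "endemic": "He",
                 "rare": "Hr", "common": "Hc"}


@dataclass(frozen=True)
class PriorityScore:
    population: str
    Ha: float
    Hd: float
    He: float
    Hr: float
    Hc: float
    pi_ratio: float
    threshold: float = 10.0

    @property
    def H(self) -> float:
        return self.Ha + self.Hd + self.He + self.Hr + self.Hc + self.pi_ratio

    @property
    def priority(self) -> bool:
        return self.H > self.threshold


def h_score(population, assignment: CategoryAssignment,
            scheme: CategoryScheme = CategoryScheme(),
            pi_i: float = 0.0, pi_total: float | None = None,
            pi_ratio: float | None = None, threshold: float = 10.0) -> PriorityScore:
    """Genetic-importance score H for one population.

    Every haplotype present contributes its category scores to the matching
    components; the diversity term is ``10 * pi_i / pi_total`` (or an
    explicit ``pi_ratio``), defined as 0 when the total diversity is 0.
    """
    comp = {"Ha": 0.0, "Hd": 0.0, "He": 0.0, "Hr": 0.0, "Hc": 0.0}
    for hap, c in population.counts.items():
        if c <= 0:
            continue
        if hap not in assignment.flags:
            raise ValueError(f"haplotype {hap!r} missing from the category assignment")
        for cat in assignment.categories(hap):
            comp[_COMPONENT_OF[cat]] += scheme.values[cat]
    if pi_ratio is None:
        if pi_total is None:
            raise ValueError("supply pi_total or pi_ratio")
        pi_ratio = 10.0 * pi_i / pi_total if pi_total > 0 else 0.0
    return PriorityScore(population.label, threshold=threshold, pi_ratio=pi_ratio, **comp)


def scores_from_components(components, threshold: float = 10.0):
    """Score populations from a user-supplied per-population component table.

    ``components`` is a DataFrame (or list of dicts) with columns
    ``label, Ha, Hd, He, Hr, Hc, pi_ratio`` whose component cells may be
    sums written as ``7+7``.  Supports published component assignments that
    are not derivable from the categorisation rules.  Returns
    ``(scores, priority_set)`` as in :func:`rank_priority`.
    """
    import pandas as pd

    df = pd.DataFrame(components)
    scores = []
    for _, row in df.iterrows():
        comp = {c: _eval_sum(row[c]) for c in ("Ha", "Hd", "He", "Hr", "Hc")}
        scores.append(PriorityScore(row["label"], pi_ratio=_eval_sum(row["pi_ratio"]),
                                    threshold=threshold, **comp))
    scores.sort(key=lambda s: -s.H)
    return scores, {s.population for s in scores if s.priority}


def _eval_sum(cell) -> float:
    return sum(float(part) for part in str(cell).split("+"))


def rank_priority(dataset: Dataset, assignment: CategoryAssignment,
                  scheme: CategoryScheme = CategoryScheme(),
                  effective_length: float = EFFECTIVE_LENGTH,
                  threshold: float = 10.0):
    """Score every population and rank by descending H.

    Returns ``(scores, priority_set)``; ``scores`` is H-sorted (ties keep
    dataset order) and ``priority_set`` the labels with H > threshold.
    """
    pooled = dataset.global_counts()
    pi_total = nucleotide_diversity(pooled, dataset.matrix, effective_length)
    scores = []
    for pop in dataset.populations:
        pi_i = (nucleotide_diversity(pop.counts, dataset.matrix, effective_length)
                if pop.n >= 2 else 0.0)
        scores.append(h_score(pop, assignment, scheme, pi_i=pi_i,
                              pi_total=pi_total, threshold=threshold))
    scores.sort(key=lambda s: -s.H)
    return scores, {s.population for s in scores if s.priority}
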