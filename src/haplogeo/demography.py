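"""Neutrality tests and mismatch distributions for population subsets.

All statistics are computed from substitution sites only (indel and cpSSR
columns are excluded), the convention of the sequence-polymorphism tools
this module mirrors.  Tajima's D contrasts the mean number of pairwise
differences (k̄) with the Watterson estimate S/a1; Fu & Li's D* and F*
(no-outgroup versions) contrast total and singleton mutation counts, with
the corrected variance coefficients.  All three are undefined when a
subset segregates no substitution site.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import Dataset, DistanceModel, SUBSTITUTION

__all__ = [
    "NeutralitySummary",
    "MismatchHistogram",
    "site_summary",
    "tajima_d",
    "fu_li",
    "neutrality_tests",
    "mismatch",
    "tajima_constants",
    "fu_li_constants",
    "tajima_d_p_value",
]


@dataclass(frozen=True)
class NeutralitySummary:
    label: str
    n: int
    S: int
    k_bar: float
    eta: int
    eta_s: int
    D: float | None = None
    D_star: float | None = None
    F_star: float | None = None

    @property
    def defined(self) -> bool:
        return self.S > 0


def _subset_columns(dataset: Dataset, labels):
    """Per-individual substitution-state rows for the pooled subset."""
    sub = dataset.subset(labels) if labels is not None else dataset
    cols = dataset.matrix.site_columns((SUBSTITUTION,))
    counts = sub.global_counts()
    rows, weights = [], []
    for hap, c in counts.items():
        if c > 0:
            rows.append(tuple(dataset.matrix[hap].states[i] for i in cols))
            weights.append(c)
    return rows, weights


def site_summary(dataset: Dataset, labels=None) -> NeutralitySummary:
    """n, S, k̄, η and η_s for a subset of populations (all when None)."""
    rows, weights = _subset_columns(dataset, labels)
    n = sum(weights)
    if n < 2:
        raise ValueError("need at least two individuals")
    ncols = len(rows[0]) if rows else 0
    S = eta = eta_s = 0
    for j in range(ncols):
        tallies: dict[str, int] = {}
        for row, w in zip(rows, weights):
            tallies[row[j]] = tallies.get(row[j], 0) + w
        states = [s for s, c in tallies.items() if c > 0]
        if len(states) > 1:
            S += 1
            eta += len(states) - 1
            eta_s += sum(1 for s in states if tallies[s] == 1)
    k_bar = 0.0
    for (r1, w1), (r2, w2) in itertools.combinations(zip(rows, weights), 2):
        diff = sum(a != b for a, b in zip(r1, r2))
        k_bar += w1 * w2 * diff
    k_bar /= n * (n - 1) / 2
    name = "+".join(labels) if labels is not None else "all"
    return NeutralitySummary(name, n, S, k_bar, eta, eta_s)


def tajima_constants(n: int) -> dict:
    """Tajima's a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1 ** 2 + a2)}


def fu_li_constants(n: int) -> dict:
    """Corrected no-outgroup variance coefficients for Fu & Li's D* and F*."""
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i ** 2 for i in range(1, n))
    a1 = a + 1.0 / n          # a_{n+1}
    c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n
    )
    v_d = ((n / (n - 1.0)) ** 2 * b + a ** 2 * d
           - 2 * n * a * (a + 1) / (n - 1.0) ** 2) / (a ** 2 + b)
    u_d = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v_d
    v_f = (d + 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
           - (2.0 / (n - 1)) * (4 * b - 6 + 8.0 / n)) / (a ** 2 + b)
    u_f = ((4 * n ** 2 + 19 * n + 3 - 12 * (n + 1) * a1)
           / (3.0 * n * (n - 1))) / a - v_f
    return {"a": a, "b": b, "c": c, "d": d,
            "uD": u_d, "vD": v_d, "uF": u_f, "vF": v_f}


def tajima_d(dataset: Dataset, labels=None) -> NeutralitySummary:
    """Tajima's D for a subset (D left None when S = 0, as printed '—').

    The variance coefficients degenerate below n = 4, so D is also left
    undefined for smaller samples.
    """
    s = site_summary(dataset, labels)
    if s.S == 0 or s.n < 4:
        return s
    k = tajima_constants(s.n)
    var = k["e1"] * s.S + k["e2"] * s.S * (s.S - 1)
    d = (s.k_bar - s.S / k["a1"]) / math.sqrt(var)
    return NeutralitySummary(**{**s.__dict__, "D": d})


def fu_li(dataset: Dataset, labels=None) -> NeutralitySummary:
    """Fu & Li's D* and F* (no outgroup) for a subset (undefined below
    n = 4 or without segregating sites)."""
    s = site_summary(dataset, labels)
    if s.S == 0 or s.n < 4:
        return s
    k = fu_li_constants(s.n)
    n = s.n
    d_star = ((n / (n - 1.0)) * s.eta - k["a"] * s.eta_s) / math.sqrt(
        k["uD"] * s.eta + k["vD"] * s.eta ** 2
    )
    f_star = (s.k_bar - ((n - 1.0) / n) * s.eta_s) / math.sqrt(
        k["uF"] * s.eta + k["vF"] * s.eta ** 2
    )
    return NeutralitySummary(**{**s.__dict__, "D_star": d_star, "F_star": f_star})


def neutrality_tests(dataset: Dataset, labels=None) -> NeutralitySummary:
    """D, D* and F* together (None when undefined)."""
    s = fu_li(dataset, labels)
    if s.S == 0 or s.n < 4:
        return s
    d = tajima_d(dataset, labels).D
    return NeutralitySummary(**{**s.__dict__, "D": d})


def tajima_d_p_value(d: float, n: int) -> float:
    """Two-sided p-value for Tajima's D from the beta approximation.

    D is rescaled onto its theoretical range [Dmin, Dmax] and compared to a
    beta distribution with matching mean 0 and variance 1.
    """
    from scipy.stats import beta as beta_dist

    k = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    dmax = ((n + 1.0) / (2.0 * n) - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    rng_ = dmax - dmin
    alpha = (1.0 + dmin * dmax) * dmin / rng_
    bparam = -(1.0 + dmin * dmax) * dmax / rng_
    x = (d - dmin) / rng_
    x = min(max(x, 0.0), 1.0)
    cdf = beta_dist.cdf(x, alpha, bparam)
    return 2.0 * min(cdf, 1.0 - cdf)


@dataclass(frozen=True)
class MismatchHistogram:
    label: str
    counts: dict      # pairwise-difference value -> number of individual pairs

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        tot = self.total_pairs
        return sum(k * v for k, v in self.counts.items()) / tot if tot else 0.0

    @property
    def n_modes(self) -> int:
        """Number of local maxima of the histogram over its full support
        (missing difference values count as zeros; plateaus merged)."""
        if not self.counts:
            return 0
        support = range(0, max(self.counts) + 1)
        ys = [self.counts.get(i, 0) for i in support]
        # merge plateaus
        comp = [ys[0]]
        for y in ys[1:]:
            if y != comp[-1]:
                comp.append(y)
        modes = 0
        for i, y in enumerate(comp):
            left = comp[i - 1] if i > 0 else -1
            right = comp[i + 1] if i < len(comp) - 1 else -1
            if y > left and y > right:
                modes += 1
        return modes

    @property
    def unimodal(self) -> bool:
        return self.n_modes <= 1


def mismatch(dataset: Dataset, labels=None) -> MismatchHistogram:
    """Exact pairwise-difference histogram for a subset (substitutions only)."""
    rows, weights = _subset_columns(dataset, labels)
    n = sum(weights)
    if n < 2:
        raise ValueError("need at least two individuals")
    counts: dict[int, int] = {}
    for (r, w) in zip(rows, weights):
        if w >= 2:
            counts[0] = counts.get(0, 0) + w * (w - 1) // 2
    for (r1, w1), (r2, w2) in itertools.combinations(zip(rows, weights), 2):
        diff = sum(a != b for a, b in zip(r1, r2))
        counts[diff] = counts.get(diff, 0) + w1 * w2
    name = "+".join(labels) if labels is not None else "all"
    return MismatchHistogram(name, dict(sorted(counts.items())))
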