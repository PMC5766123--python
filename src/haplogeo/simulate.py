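"""Synthetic multi-population haplotype datasets with controllable
structure, plus a minimal neutral-coalescent mode.

The structured generator is parametric and graph-based: group "backbone"
haplotypes are laid out on a mutation ladder so that adjacent groups are
``between_group_steps`` apart, each group carries a pool of local variants
``within_group_steps`` from its backbone, and populations draw haplotype
frequencies from a Dirichlet around their group's pool (optionally admixed
with the global pool).  Coordinates cluster groups spatially so contiguity-
constrained searches can recover the planted structure.  This exercises
every pipeline stage; it does not emulate recombination, selection or
sequence-level mutation processes.

The neutral mode simulates a single panmictic population under the standard
coalescent (via msprime, infinite sites) and is used to calibrate
neutrality-test behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    Dataset,
    Haplotype,
    HaplotypeMatrix,
    MutationSite,
    Population,
    SsrState,
    INDEL,
    SSR,
    SUBSTITUTION,
)

__all__ = ["GeneratorConfig", "generate", "neutral_coalescent_counts"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design for the structured generator.

    ``within_group_steps``/``between_group_steps`` are the step distances
    from a group backbone to its local variants and between adjacent group
    backbones.  ``haplotype_freq_concentration`` is the symmetric Dirichlet
    concentration for within-population frequencies (``inf`` = identical,
    even frequencies in every population); ``admixture`` is the probability
    that a sampled individual carries a haplotype from the global rather
    than the group-local pool (a migration-like mixing level).
    """

    n_populations: int = 12
    samples_per_population: int = 12
    n_groups: int = 2
    haplotypes_per_group: int = 3
    site_kinds: dict = field(default_factory=lambda: {
        SUBSTITUTION: 0.6, INDEL: 0.2, SSR: 0.2,
    })
    within_group_steps: int = 1
    between_group_steps: int = 4
    haplotype_freq_concentration: float = 1.0
    admixture: float = 0.0
    coordinates: str = "grid"        # or "random"
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.n_populations < self.n_groups:
            raise ValueError("need 1 <= n_groups <= n_populations")
        if self.between_group_steps < self.within_group_steps:
            raise ValueError("between_group_steps must be >= within_group_steps")
        if not 0 <= self.admixture <= 1:
            raise ValueError("admixture must be in [0, 1]")


def _typed_sites(n_columns: int, kind_weights: dict, rng):
    kinds = list(kind_weights)
    probs = np.array([kind_weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    chosen = rng.choice(kinds, size=n_columns, p=probs)
    sites, zero, one = [], [], []
    for i, kind in enumerate(chosen, start=1):
        if kind == SUBSTITUTION:
            sites.append(MutationSite(i, "sim", SUBSTITUTION))
            zero.append("C")
            one.append("T")
        elif kind == INDEL:
            sites.append(MutationSite(i, "sim", INDEL))
            zero.append("-")
            one.append("+")
        else:
            sites.append(MutationSite(i, "sim", SSR, "A"))
            zero.append(SsrState(5))
            one.append(SsrState(6))
    return sites, zero, one


def generate(config: GeneratorConfig) -> Dataset:
    """Generate a structured multi-population dataset (bit-reproducible
    under a fixed config/seed)."""
    rng = np.random.default_rng(config.seed)
    g, p = config.n_groups, config.haplotypes_per_group
    ladder = (g - 1) * config.between_group_steps
    private = g * p * config.within_group_steps
    n_cols = max(ladder + private, 1)
    sites, zero, one = _typed_sites(n_cols, config.site_kinds, rng)

    # binary layout: ladder columns encode group backbones, private columns
    # encode within-group variants
    haplotypes, pools = [], []
    col = ladder
    for grp in range(g):
        pool = []
        backbone = np.zeros(n_cols, dtype=int)
        backbone[: grp * config.between_group_steps] = 1
        for j in range(p):
            vec = backbone.copy()
            vec[col: col + config.within_group_steps] = 1
            col += config.within_group_steps
            label = f"G{grp + 1}H{j + 1}"
            states = tuple(one[i] if vec[i] else zero[i] for i in range(n_cols))
            haplotypes.append(Haplotype(label, states))
            pool.append(label)
        pools.append(pool)
    matrix = HaplotypeMatrix(sites, haplotypes, {"sim": n_cols * 10})
    all_labels = [h.label for h in haplotypes]

    # spatially clustered coordinates: group centres far apart, populations
    # jittered around their centre
    centres = [(10.0 * (grp % 3), 10.0 * (grp // 3)) for grp in range(g)]
    pops = []
    group_of = [i * g // config.n_populations for i in range(config.n_populations)]
    for i in range(config.n_populations):
        grp = group_of[i]
        pool = pools[grp]
        if np.isinf(config.haplotype_freq_concentration):
            base = np.full(len(pool), 1.0 / len(pool))
            counts = _round_counts(base * config.samples_per_population)
            count_map = dict(zip(pool, counts))
        else:
            freqs = rng.dirichlet(
                np.full(len(pool), config.haplotype_freq_concentration)
            )
            draws = rng.multinomial(config.samples_per_population, freqs)
            count_map = dict(zip(pool, draws))
            if config.admixture > 0:
                migrated = rng.binomial(config.samples_per_population,
                                        config.admixture)
                # replace migrant individuals with draws from the global pool
                _remove_individuals(count_map, migrated, rng)
                for lab in rng.choice(all_labels, size=migrated):
                    count_map[lab] = count_map.get(lab, 0) + 1
        cx, cy = centres[grp]
        if config.coordinates == "grid":
            within = [idx for idx, gg in enumerate(group_of) if gg == grp].index(i)
            dx, dy = (within % 3) * 1.0, (within // 3) * 1.0
        else:
            dx, dy = rng.uniform(0, 2, size=2)
        pops.append(Population(
            label=f"P{i + 1:02d}",
            latitude=cy + dy, longitude=cx + dx,
            counts={k: int(v) for k, v in count_map.items() if v > 0},
        ))
    return Dataset(matrix, pops)


def _round_counts(expected: np.ndarray):
    """Largest-remainder rounding to integers preserving the total."""
    floor = np.floor(expected).astype(int)
    remainder = int(round(expected.sum())) - floor.sum()
    order = np.argsort(-(expected - floor))
    floor[order[:remainder]] += 1
    return floor


def _remove_individuals(count_map: dict, k: int, rng):
    for _ in range(k):
        labels = [l for l, c in count_map.items() if c > 0]
        weights = np.array([count_map[l] for l in labels], dtype=float)
        pick = rng.choice(labels, p=weights / weights.sum())
        count_map[pick] -= 1


def neutral_coalescent_counts(n: int, theta: float, seed: int) -> Dataset:
    """One panmictic population simulated under the neutral coalescent.

    ``theta`` is the population mutation rate (expected pairwise
    differences); mutations follow the infinite-sites model.  Returns a
    single-population :class:`Dataset` whose sites are all substitutions,
    suitable for the neutrality tests.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, sequence_length=1.0,
        random_seed=(seed % (2 ** 31 - 2)) + 1,
    )
    ts = msprime.sim_mutations(
        ts, rate=theta / 2.0, discrete_genome=False,
        model=msprime.BinaryMutationModel(),
        random_seed=((seed + 7) % (2 ** 31 - 2)) + 1,
    )
    geno = ts.genotype_matrix().T       # samples x sites
    nsites = geno.shape[1]
    sites = [MutationSite(i + 1, "coalescent", SUBSTITUTION) for i in range(nsites)]
    vecs, counts = np.unique(geno, axis=0, return_counts=True)
    haplotypes = [
        Haplotype(f"H{i + 1}", tuple("T" if x else "C" for x in vec))
        for i, vec in enumerate(vecs)
    ]
    matrix = HaplotypeMatrix(sites, haplotypes, {"coalescent": max(nsites, 1)})
    pop = Population("P1", 0.0, 0.0,
                     {f"H{i + 1}": int(c) for i, c in enumerate(counts)})
    return Dataset(matrix, [pop])
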