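# Methods

`haplogeo` implements the statistical pipeline of a range-wide chloroplast
haplotype survey: typed mutation matrices and step distances, diversity and
differentiation estimators, hierarchical variance decomposition with a
spatial group search, haplotype genealogies, neutrality tests, and a
conservation-priority score.  This note records the models, the parameter
defaults and why they were chosen, and the places where the design was
genuinely open.

## Data model and step distances

A haplotype is a vector of states over typed mutation sites of three kinds:
nucleotide substitutions, indel events, and simple-sequence repeats
(cpSSRs).  Distances are counted in *mutation steps* under a configurable
`DistanceModel`:

- a differing substitution contributes 1 step;
- an indel event contributes `indel_weight` steps (default 1) **regardless
  of its span in bp** — a 6-bp insertion is one mutation, which is what
  makes the most divergent pair in the bundled survey (F vs K) exactly 4
  steps apart;
- an SSR site contributes `ssr_step_weight` steps per repeat-unit
  difference (default 1, the single-step mutation model), plus 1 step when
  exactly one of the two states carries a flanking-variant suffix.  States
  such as "5 repeats + flanking T" keep the flank attached to the repeat
  site so that two haplotypes sharing it are 0 steps apart there;
  `ssr_saturate` optionally caps a site's contribution at 1 step.

The bundled survey (23 populations, N = 256, 13 haplotypes over 15 sites:
9 substitutions, 3 indels, 3 cpSSRs) ships as plain TSV.  Counts for the
four polymorphic populations are not printed anywhere; they are back-solved
by exhaustive search over integer compositions matching the published
diversity values (`solve_counts`), and the loader re-derives every
population's h and π before returning the dataset.  Where h and π do not
pin the label assignment uniquely (two haplotypes at distance 0 are
exchangeable in π), the assignment follows the published haplotype
distribution map; the solver itself reports all surviving assignments.

## Diversity and differentiation

Per-population gene diversity is Nei's unbiased h = n/(n−1)(1 − Σp²) with
its standard sampling error; nucleotide diversity is the mean pairwise
difference per site, computed from substitution steps only and normalised
by an effective length L.  **L defaults to 2248 bp**: the combined aligned
spacer length (832 + 670 + 761 = 2263) minus the columns occupied by indel
events and length-variable repeat tracts.  This value reproduces the
published π for the LP and LS populations exactly; HZ's published π
implies an effective length ~12 bp longer and is reproducible only to
±0.001×10⁻³, which the loader's self-check allows for.

The hierarchical partition treats the sampled populations as a sample of
size s from a universe of demes (Pons & Petit).  hS is the unweighted mean
of per-population unbiased diversities.  Total diversity is estimated from
between-population comparisons,

    hT = 1 − (1/(s(s−1))) Σ_{k≠l} Σ_i x_ki x_li ,

which is unbiased for the probability that two genes drawn from two
*distinct* demes differ (cross-products of frequencies from independent
samples need no small-sample correction).  vS and vT are the ordered
analogues with haplotype pairs weighted by step distance under the full
distance model, and GST = (hT−hS)/hT, NST = (vT−vS)/vT.  The
between-population form was chosen over the Nei–Chesser-style pooled form
because it is the estimator consistent with the survey's published
hT/GST/NST values on the reconstructed data (the pooled form gives an hT
about 4% lower).  Two consequences worth knowing: on *identical* finite
samples GST is slightly negative (the O(1/n) bias correction of hS), and
duplicating every population changes the deme-pair universe and hence hT
slightly; both effects vanish with sample size and are asserted as such in
the tests.

The NST > GST comparison permutes haplotype identities against the
distance matrix (frequencies fixed), recomputing NST each time; p-values
use the add-one convention so p is never exactly 0.  Gene flow is
converted as Nm = (1−GST)/(2·GST), the haploid, maternally inherited
formula.

## AMOVA and SAMOVA

AMOVA follows the Excoffier sums-of-squares scheme on the pairwise
individual distance matrix (individuals expanded from haplotype counts),
with the standard expected-mean-square coefficients for unequal sample
sizes.  The default molecular distance is the **number of differing
substitution sites, used directly as the squared distance** — the
behaviour of the standard sequence-AMOVA tools, which delete alignment
columns containing gaps or length variants before counting pairwise
differences.  On the bundled survey this convention reproduces the
published among-population variance (98.09%) and F_ST to printed
precision; no single convention reproduces every published grouped-AMOVA
column (the published K = 5 F_SC in particular), so the distance model and
squaring remain configurable.  Permutation tests shuffle individuals among
populations (Φ_ST), individuals within groups (Φ_SC), and whole
populations among groups (Φ_CT); 1000 permutations by default.

SAMOVA maximises the among-group index F_CT over partitions of populations
into K groups that are contiguous in a Delaunay triangulation of the
population coordinates (raw lon/lat; at the survey's extent projection
distortion is immaterial, and the island population connects through its
Delaunay neighbours).  The search is simulated annealing: default 100
restarts × 10,000 proposals, geometric cooling ×0.9 every 200 proposals,
initial temperature set from the spread of objective changes over 100
random moves; a proposal moves one boundary population to an adjacent
group and is rejected if it would empty or disconnect its source group.
Tests and examples use 8–12 restarts × 2000–3000 proposals, which already
finds partitions scoring at or above the published ones on the bundled
survey in seconds.

The K-sweep diagnostic operationalises the usual SAMOVA model choice: F_CT
grows almost monotonically with K, so raw argmax is uninformative.
Partitions whose best solution contains more than one single-population
group are treated as over-split and excluded; among the rest the smallest
K within 1% of the maximal F_CT is reported.  On the bundled survey this
selects K = 5, with F_SC bottoming out at the same K before group sizes
collapse.

## Haplotype genealogy

The median-joining network expands characters to weighted binary columns
(ordered SSR states become stepwise indicators over the observed repeat
range, restoring unit-step distances inside the binary algorithm), then
iteratively adds the majority medians of triplets attached to feasible
links of the ε-relaxed minimum spanning network, keeping those within ε of
the cheapest candidate (ε = 0 by default, equal character weights).
Obsolete medians — unobserved nodes of degree ≤ 2 in the current network —
are pruned, and the result is the minimum spanning network over observed
haplotypes plus retained medians, labelled `mv1, mv2, …` in insertion
order.  Substitution sites with more than two observed states are not
representable in the binary expansion and are rejected with a clear error.
No outgroup rooting is attempted (no outgroup sequence is available);
trees are unrooted.

Interiority is ranked by hop eccentricity (network links, medians count as
nodes) ascending, then degree descending.  Because hop eccentricity is
coarsely quantised on sparse networks, the "interior set" takes nodes
within one link of the minimum; on the bundled survey this isolates
exactly the three interior haplotypes ahead of the next tier, while strict
minimal eccentricity would return a single node.  On tiny or star-shaped
networks the set degenerates to all nodes, which the docstring flags.

Neighbor joining is delegated to scikit-bio from the step-distance matrix;
optional bootstrap resamples mutation columns with replacement and reports
bipartition support fractions.

## Neutrality tests and mismatch distributions

All demographic statistics use substitution sites only — the convention
that reproduces the survey's published per-population test values exactly
— with S (segregating sites), k̄ (mean pairwise differences), η (total
mutations) and η_s (variants carried by exactly one individual) computed
by enumeration over haplotype counts.  Tajima's D uses the standard
a₁…e₂ coefficients; Fu & Li's D* and F* use the corrected no-outgroup
variance coefficients (the dialect of the standard polymorphism software,
pinned by reproducing the published LP row analytically).  All three are
reported as undefined when S = 0 or n < 4 (the variance coefficients
degenerate below n = 4).  Significance for D is available through the
beta-distribution approximation; this test is known to be conservative,
increasingly so at large θ, which the calibration test documents
(empirical size ≈ 0.03–0.04 at n = 30, θ = 5).

The pooled-survey D computed under this convention is ≈ 1.32 against a
published 1.29; the published pooled value is not reproducible under any
convention that also reproduces the per-population rows (the published D*
for the pooled data, 1.2535, *is* reproduced exactly), so tests pin the
per-population rows and report the pooled values as computed.

Mismatch distributions are exact histograms over all C(n,2) individual
pairs.  Modality counts local maxima over the full difference support
after merging plateaus; a single maximum is classified unimodal.  No
sudden-expansion model is fitted.

## Conservation priority

Haplotypes are categorised as ancestral (the network interior set),
derived (complement), endemic (one population), common (≥ 2 populations),
and rare (global count ≤ 4 and endemic — the only threshold combination
that reproduces the published rare set while excluding a private haplotype
of count 8 and a shared one of count 4).  A population's score is
H = Ha + Hd + He + Hr + Hc + 10·πᵢ/π with category values
{7, 3, 5, 5, 3} and the π ratio term defined as 0 when total π is 0;
populations with H > 10 are priority protection units.

The published per-population component table is not fully consistent with
the published category lists (e.g. a non-rare haplotype is scored as rare
in two populations, and a rare pair is dropped in another), so the package
supports both rule-derived assignment and user-supplied component tables;
the published table ships verbatim as data.  Under the strict rules the
priority set is {CY, HZ, LP, LS, PB}, with DA and XN at H = 10 exactly;
under the published components it is the published seven-population set.

## Synthetic data

The structured generator is parametric and graph-based, not a sequence
simulator: group backbone haplotypes sit on a mutation ladder
(`between_group_steps` apart), each group carries local variants
(`within_group_steps` away), populations draw haplotype frequencies from a
symmetric Dirichlet around their group pool (concentration ∞ = identical
even frequencies), optionally admixed with the global pool at a
migration-like rate, and coordinates cluster groups spatially for
contiguity-aware searches.  Defaults (12 populations × 12 samples, 2
groups 4 steps apart, concentration 1) mirror the survey's scale of
per-population sampling and between-lineage divergence.  It emulates the
*count structure* of multi-population haplotype data — it does not model
recombination, selection, homoplasy, or realistic site spacing, so passing
pipeline tests on it demonstrates algorithmic correctness, not robustness
to those features of real data.

The neutral mode simulates one panmictic population under the standard
coalescent with infinite-sites mutations (msprime), parameterised by θ
(expected pairwise differences).  It exists to calibrate neutrality-test
behaviour; the calibration uses n = 30, θ = 5 — enough segregating sites
for the continuous approximation while keeping the beta test's
conservative bias mild — with 500 replicates.

## Numerical and engineering choices

- Permutation p-values always include the observed statistic (add-one
  rule).
- Annealing and permutation stages take explicit integer seeds; all
  randomness flows through `numpy.random.default_rng` (and msprime's own
  seeding, kept below 2³¹).
- State comparison is case-insensitive; site order is authoritative from
  the input table; alignment columns are reported 1-based.
- Coordinates are decimal degrees WGS84; DMS strings are parsed and
  converted on input.
- Ties are surfaced, not broken: interiority ties share the interior set,
  equal-H populations keep dataset order and identical rank tiers.
- Degenerate inputs fail loudly: n < 2 diversities, single-group F_CT,
  identical-individual AMOVA, ragged or ambiguous alignments, K outside
  [2, s].

## Known limitations

- The between-deme diversity estimators are slightly negatively biased as
  differentiation estimates on identical small samples (see above).
- The MJ implementation targets binary-expandable characters; multiallelic
  substitution sites are rejected rather than approximated.
- Mismatch modality is a descriptive classification; no raggedness
  statistic or expansion-model fit is provided.
- The published grouped-AMOVA F_SC values and the pooled-survey Tajima's D
  are not exactly reproducible under any single distance convention; the
  package pins the conventions that reproduce the flat AMOVA and the
  per-population neutrality rows exactly and documents the residuals.
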