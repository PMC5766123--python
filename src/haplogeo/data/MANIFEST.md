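# Bundled reference dataset

The *Bretschneidera sinensis* range-wide cpDNA survey: 256 individuals from
23 Chinese populations, typed at 15 mutation sites across three chloroplast
intergenic spacers (*rps8–rps11*, *rps16–trnQ*, *trnT–trnL*; aligned lengths
832, 670, 761 bp).

| file | contents |
|---|---|
| `haplotypes.tsv` | 13 haplotypes × 15 typed sites (9 substitutions, 3 indels, 3 cpSSRs) |
| `populations.tsv` | 23 populations: decimal WGS84 coordinates, sample sizes, haplotype counts |
| `partitions.tsv` | published SAMOVA groupings for K = 2..7 (long format: k, population, group) |
| `regions.tsv` | named geographic group memberships used in the neutrality-test tables |
| `priority_components.tsv` | published per-population conservation-score components (verbatim, including their internal inconsistencies; see docs/methods.md) |

Provenance notes:

- Haplotype counts for the four polymorphic populations (CY 7/4, LP 10/1/1,
  LS 9/3, HZ 6/3/3) are **derived**, not printed: the survey reports only
  per-population diversity statistics, and the counts were back-solved with
  `haplogeo.model.solve_counts` by exhaustive search over integer
  compositions matching the published haplotype diversity *h* (and, where
  needed for label assignment, nucleotide diversity π) at printed precision.
  Monomorphic populations carry their full sample size on the single listed
  haplotype.
- The published K=4 grouping lists one group label twice; the evident intent
  (QY separate; CH+HZ a fourth group) is encoded.
- Loading the dataset through `haplogeo.bretschneidera.load_dataset()` runs a
  self-check that recomputes every population's *h* (and π where defined)
  and asserts agreement with the published values at printed precision.
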