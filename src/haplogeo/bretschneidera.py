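"""The bundled *Bretschneidera sinensis* range-wide cpDNA survey dataset.

256 individuals from 23 Chinese populations of an endangered relict tree,
typed at 15 chloroplast mutation sites defining 13 haplotypes (see
``data/MANIFEST.md`` for file-by-file provenance).  Haplotype counts for
the four polymorphic populations are back-solved from the published
per-population diversity statistics; :func:`load_dataset` re-derives every
population's h (and pi where defined) and refuses to return a corrupted
fixture.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diversity import EFFECTIVE_LENGTH, nei_h, nucleotide_diversity
from .io import read_haplotype_table, read_population_table
from .model import Dataset, HaplotypeMatrix

__all__ = [
    "ALIGNED_LENGTHS",
    "PUBLISHED_DIVERSITY",
    "load_matrix",
    "load_dataset",
    "load_partition",
    "load_regions",
    "load_priority_components",
]

ALIGNED_LENGTHS = {"rps8-rps11": 832, "rps16-trnQ": 670, "trnT-trnL": 761}

#: Published per-population (h, pi x 1e-3) pairs used by the loader's
#: self-check.  pi entries are None where the survey prints 0 with gaps
#: excluded but the population is monomorphic anyway; HZ's printed pi is
#: reproducible only to +/-0.001e-3 (its implied effective length differs
#: slightly from the pinned 2248 bp).
PUBLISHED_DIVERSITY = {
    "CY": (0.5091, 0.0),
    "LP": (0.3182, 0.074),
    "LS": (0.4091, 0.182),
    "HZ": (0.6818, 0.181),
}

_PI_TOL = {"HZ": 0.0015}


def _read(name: str) -> str:
    return resources.files("haplogeo.data").joinpath(name).read_text()


def load_matrix() -> HaplotypeMatrix:
    """The 13-haplotype x 15-site typed mutation matrix."""
    return read_haplotype_table(_read("haplotypes.tsv"), ALIGNED_LENGTHS)


def load_dataset(self_check: bool = True) -> Dataset:
    """The full 23-population dataset (total N = 256), self-checked."""
    dataset = read_population_table(_read("populations.tsv"), load_matrix())
    if self_check:
        _verify(dataset)
    return dataset


def _verify(dataset: Dataset) -> None:
    if dataset.total_n != 256:
        raise AssertionError(f"fixture total N = {dataset.total_n}, expected 256")
    if len(dataset.matrix) != 13 or len(dataset.populations) != 23:
        raise AssertionError("fixture shape mismatch")
    for pop in dataset.populations:
        counts = {k: v for k, v in pop.counts.items() if v > 0}
        h = nei_h(counts.values()) if pop.n >= 2 else 0.0
        ref = PUBLISHED_DIVERSITY.get(pop.label, (0.0, 0.0))
        if round(h, 4) != ref[0]:
            raise AssertionError(
                f"fixture self-check: {pop.label} h = {h:.4f}, published {ref[0]}"
            )
        pi = nucleotide_diversity(counts, dataset.matrix, EFFECTIVE_LENGTH) * 1e3
        if abs(pi - ref[1]) > _PI_TOL.get(pop.label, 0.0005 + 1e-12):
            raise AssertionError(
                f"fixture self-check: {pop.label} pi = {pi:.4f}e-3, published {ref[1]}e-3"
            )


def load_partition(k: int) -> dict:
    """Published SAMOVA grouping for ``k`` groups: {population: group_id}."""
    df = pd.read_csv(_as_buffer("partitions.tsv"), sep="\t", dtype=str)
    sub = df[df["k"] == str(k)]
    if sub.empty:
        raise KeyError(f"no bundled partition for k = {k}")
    return dict(zip(sub["population"], sub["group"]))


def load_regions() -> dict:
    """Named geographic groups: {region name: [population, ...]}."""
    df = pd.read_csv(_as_buffer("regions.tsv"), sep="\t", dtype=str)
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        out.setdefault(row["region"], []).append(row["population"])
    return out


def load_priority_components() -> pd.DataFrame:
    """Published per-population conservation-score components, verbatim.

    Component cells are printed sums such as ``7+7``; the ``H`` column is
    the printed total.  These assignments are not fully derivable from the
    categorisation rules (see docs/methods.md) and are kept as data so the
    score arithmetic is testable independently of the rules.
    """
    return pd.read_csv(_as_buffer("priority_components.tsv"), sep="\t", dtype=str)


def _as_buffer(name: str):
    from io import StringIO

    return StringIO(_read(name))
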