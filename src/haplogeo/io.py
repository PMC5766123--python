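"""Reading and writing the package's table formats, plus haplotype calling
from aligned FASTA.

Haplotype-definition table (tab-separated)::

    site    1            2    ...
    region  rps8-rps11   ...
    kind    substitution indel ssr ...
    motif   .            .    AT ...
    A       C            -    6  ...
    B       ...

The first four lines are metadata rows keyed by their first field; remaining
rows are haplotypes (first column = label).  SSR states are integer repeat
counts with an optional flanking-variant suffix (``5T``).

Population table (tab-separated): columns ``label``, ``lat``, ``lon``, ``n``,
then one column per haplotype label holding integer counts.  Coordinates are
decimal degrees (WGS84); degree-minute-second strings such as ``25°40'55"``
are also accepted and converted.
"""

from __future__ import annotations

import re

import pandas as pd
from Bio import SeqIO

from .model import (
    INDEL,
    SSR,
    SUBSTITUTION,
    Dataset,
    Haplotype,
    HaplotypeMatrix,
    MutationSite,
    Population,
    parse_state,
)

__all__ = [
    "read_haplotype_table",
    "write_haplotype_table",
    "read_population_table",
    "write_population_table",
    "read_partition",
    "write_partition",
    "dms_to_decimal",
    "call_haplotypes",
]

_KIND_ALIASES = {
    "substitution": SUBSTITUTION, "sub": SUBSTITUTION, "snp": SUBSTITUTION,
    "indel": INDEL, "ssr": SSR, "cpssr": SSR,
}


def read_haplotype_table(text: str, aligned_lengths=None) -> HaplotypeMatrix:
    """Parse a haplotype-definition table into a :class:`HaplotypeMatrix`.

    Raises ``ValueError`` naming the offending row/site for illegal state
    tokens, and for duplicate state vectors (via the matrix invariant).
    """
    rows = [line.split("\t") for line in text.strip().splitlines()
            if line.strip() and not line.startswith("#")]
    meta = {}
    hap_rows = []
    for row in rows:
        key = row[0].strip().lower()
        if key in ("site", "region", "kind", "motif"):
            meta[key] = [c.strip() for c in row[1:]]
        else:
            hap_rows.append(row)
    if "kind" not in meta:
        raise ValueError("haplotype table must declare a 'kind' metadata row")
    kinds = [_KIND_ALIASES.get(k.lower()) for k in meta["kind"]]
    if any(k is None for k in kinds):
        bad = meta["kind"][kinds.index(None)]
        raise ValueError(f"unknown site kind {bad!r}")
    nsites = len(kinds)
    regions = meta.get("region", ["?"] * nsites)
    motifs = [None if m in (".", "", "-") else m.upper()
              for m in meta.get("motif", ["."] * nsites)]
    ids = [int(i) for i in meta["site"]] if "site" in meta else list(range(1, nsites + 1))
    sites = [MutationSite(i, r, k, m) for i, r, k, m in zip(ids, regions, kinds, motifs)]

    haplotypes = []
    for row in hap_rows:
        label = row[0].strip()
        tokens = [c.strip() for c in row[1:]]
        if len(tokens) != nsites:
            raise ValueError(
                f"haplotype {label!r} has {len(tokens)} states for {nsites} sites"
            )
        states = []
        for site, tok in zip(sites, tokens):
            try:
                states.append(parse_state(tok, site.kind))
            except ValueError as e:
                raise ValueError(
                    f"illegal state {tok!r} at site {site.site_id} "
                    f"in haplotype row {label!r}"
                ) from e
        haplotypes.append(Haplotype(label, tuple(states)))
    return HaplotypeMatrix(sites, haplotypes, aligned_lengths)


def write_haplotype_table(matrix: HaplotypeMatrix) -> str:
    lines = [
        "site\t" + "\t".join(str(s.site_id) for s in matrix.sites),
        "region\t" + "\t".join(s.region for s in matrix.sites),
        "kind\t" + "\t".join(s.kind for s in matrix.sites),
        "motif\t" + "\t".join(s.motif or "." for s in matrix.sites),
    ]
    for h in matrix.haplotypes:
        lines.append(h.label + "\t" + "\t".join(str(s) for s in h.states))
    return "\n".join(lines) + "\n"


def read_population_table(text: str, matrix: HaplotypeMatrix) -> Dataset:
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    hap_cols = [c for c in df.columns if c not in ("label", "lat", "lon", "n")]
    pops = []
    for _, row in df.iterrows():
        counts = {c: int(row[c]) for c in hap_cols if str(row[c]) not in ("nan", "0", "")}
        pop = Population(
            label=row["label"],
            latitude=dms_to_decimal(row["lat"]),
            longitude=dms_to_decimal(row["lon"]),
            counts=counts,
        )
        if "n" in df.columns and pop.n != int(row["n"]):
            raise ValueError(
                f"population {pop.label!r}: counts sum to {pop.n}, table says {row['n']}"
            )
        pops.append(pop)
    return Dataset(matrix, pops)


def write_population_table(dataset: Dataset) -> str:
    labels = dataset.matrix.labels
    lines = ["label\tlat\tlon\tn\t" + "\t".join(labels)]
    for p in dataset.populations:
        counts = "\t".join(str(p.counts.get(l, 0)) for l in labels)
        lines.append(f"{p.label}\t{p.latitude:.6f}\t{p.longitude:.6f}\t{p.n}\t{counts}")
    return "\n".join(lines) + "\n"


def read_partition(text: str) -> dict:
    """Two-column text (population, group-id) -> {population: group}."""
    out = {}
    for line in text.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pop, grp = line.split()[:2]
        out[pop] = grp
    return out


def write_partition(groups: dict) -> str:
    return "\n".join(f"{p}\t{g}" for p, g in groups.items()) + "\n"


_DMS_RE = re.compile(
    r"""^\s*(?P<deg>-?\d+(?:\.\d+)?)\s*(?:[°d]\s*(?P<min>\d+(?:\.\d+)?)?
        \s*(?:['m]\s*(?P<sec>\d+(?:\.\d+)?)?\s*(?:["s])?)?)?\s*(?P<hemi>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def dms_to_decimal(value) -> float:
    """Convert ``25°40'55"``-style coordinates (or plain floats) to decimal degrees."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _DMS_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse coordinate {value!r}")
    deg = float(m.group("deg"))
    out = abs(deg)
    if m.group("min"):
        out += float(m.group("min")) / 60
    if m.group("sec"):
        out += float(m.group("sec")) / 3600
    if deg < 0 or (m.group("hemi") or "").upper() in ("S", "W"):
        out = -out
    return out


def call_haplotypes(fasta_handle, ssr_intervals=None, region="alignment",
                    absorb_ssr_flanks=True):
    """Call a typed haplotype matrix from an aligned multi-FASTA.

    Contiguous gap columns are merged into single indel events; columns
    falling in ``ssr_intervals`` (0-based half-open ``(start, stop, motif)``
    triples) are scored as one SSR site by repeat count; the remaining
    polymorphic columns become substitutions.  With ``absorb_ssr_flanks``
    (default), a gap-free polymorphic column immediately following an SSR
    interval is attached to that site as a flanking variant (the majority
    base carries no suffix) rather than typed as a separate substitution,
    matching how repeat tracts with a flanking substitution are scored as
    one site.

    Returns ``(matrix, assignment)`` where ``assignment`` maps each input
    sequence id to its haplotype label (labels ``H1``, ``H2``, ... in order
    of first appearance).
    """
    records = list(SeqIO.parse(fasta_handle, "fasta"))
    if not records:
        raise ValueError("no sequences in alignment")
    seqs = [str(r.seq).upper() for r in records]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    for r, s in zip(records, seqs):
        bad = [i for i, c in enumerate(s) if c not in "ACGT-"]
        if bad:
            raise ValueError(
                f"ambiguity code in sequence {r.id!r} at positions "
                f"{[i + 1 for i in bad[:5]]}"
            )

    ssr_intervals = list(ssr_intervals or [])
    in_ssr = [False] * length
    for start, stop, _motif in ssr_intervals:
        for i in range(start, stop):
            in_ssr[i] = True

    sites: list[MutationSite] = []
    columns: list[list] = []   # one parsed state list per site

    # SSR sites: repeat count of the motif within the interval (gaps shorten it)
    for start, stop, motif in ssr_intervals:
        counts = []
        for s in seqs:
            seg = s[start:stop].replace("-", "")
            counts.append(len(seg) // len(motif))
        flanks = [""] * len(seqs)
        if absorb_ssr_flanks and stop < length and not in_ssr[stop]:
            col = [s[stop] for s in seqs]
            if "-" not in col and len(set(col)) > 1:
                majority = max(set(col), key=col.count)
                flanks = ["" if c == majority else c for c in col]
                in_ssr[stop] = True
        if len(set(counts)) > 1 or len(set(flanks)) > 1:
            sites.append(MutationSite(0, region, SSR, motif))
            columns.append([parse_state(f"{c}{f}", SSR)
                            for c, f in zip(counts, flanks)])

    # indel events: maximal runs of columns where some sequence is gapped
    i = 0
    while i < length:
        if any(s[i] == "-" for s in seqs) and not in_ssr[i]:
            j = i
            while j < length and any(s[j] == "-" for s in seqs) and not in_ssr[j]:
                j += 1
            states = ["-" if set(s[i:j]) == {"-"} else "+" for s in seqs]
            if len(set(states)) > 1:
                sites.append(MutationSite(0, region, INDEL, None))
                columns.append(states)
            i = j
        else:
            i += 1

    # substitutions: remaining polymorphic columns
    for i in range(length):
        if in_ssr[i] or any(s[i] == "-" for s in seqs):
            continue
        col = [s[i] for s in seqs]
        if len(set(col)) > 1:
            sites.append(MutationSite(0, region, SUBSTITUTION, None))
            columns.append(col)

    sites = [MutationSite(k + 1, s.region, s.kind, s.motif) for k, s in enumerate(sites)]
    vectors = [tuple(col[r] for col in columns) for r in range(len(seqs))]
    labels: dict[tuple, str] = {}
    assignment = {}
    for rec, vec in zip(records, vectors):
        if vec not in labels:
            labels[vec] = f"H{len(labels) + 1}"
        assignment[rec.id] = labels[vec]
    haplotypes = [Haplotype(lab, vec) for vec, lab in labels.items()]
    matrix = HaplotypeMatrix(sites, haplotypes, {region: length})
    return matrix, assignment
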