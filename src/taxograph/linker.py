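"""Cross-resource linking by equi-join on shared external identifiers.

Two resources are linked without comparing a single name string: each is
flattened to a lookup table, and the tables are joined on the external
identifiers they both carry.  If Wikidata's Q140 (*Panthera leo*) points to
ITIS:183803 and some GloBI taxon also points to ITIS:183803, the two taxa
are inferred to denote the same concept, and the Wikidata ID can be
appended to the GloBI graph as one more external pointer.

The join is a hash join keyed on the serialized external ID — linear in
table size — and is deliberately *not* transitive: linking A–B and B–C in
separate calls never manufactures an A–C link, because each pairwise join
stands on its own identifier evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

from .idmodel import ExternalId, SchemeRegistry, default_registry, parse_curie
from .readers import LookupTable

__all__ = ["CrossLink", "join_graphs", "merge_links", "write_links", "read_links"]


@dataclass(frozen=True, slots=True, order=True)
class CrossLink:
    """An inferred equivalence between taxa of two resources.

    ``shared`` is the complete, non-empty set of external identifiers both
    taxa carry (within the join's scheme set); it is the evidence for the
    link, kept so downstream audits can weigh or reject it.
    """

    taxon_a: ExternalId
    taxon_b: ExternalId
    shared: frozenset[ExternalId]

    def swapped(self) -> "CrossLink":
        return CrossLink(self.taxon_b, self.taxon_a, self.shared)


def join_graphs(
    a: LookupTable,
    b: LookupTable,
    schemes: Iterable[str] | None = None,
    *,
    allow_same_resource: bool = False,
) -> set[CrossLink]:
    """Join two lookup tables on shared external identifiers.

    Emits one :class:`CrossLink` per (taxon in ``a``, taxon in ``b``) pair
    that shares at least one external ID whose scheme is in ``schemes``
    (default: the registry's seven join schemes).  Many-to-many matches are
    all retained — a single external ID shared by several taxa on either
    side links every combination, which is how synonymous entries propagate.

    Joining a table against itself is an error (use the consistency audit
    for self-checks) unless ``allow_same_resource`` is set, a relaxed mode
    for testing against renamed copies.
    """
    if a.resource == b.resource and not allow_same_resource:
        raise ValueError(
            f"both tables belong to resource {a.resource!r}; "
            "self-joins are not meaningful — audit consistency instead"
        )
    wanted = frozenset(schemes) if schemes is not None else default_registry().join_schemes

    # hash join: external ID -> taxa that carry it, per side
    taxa_by_ext_a: dict[ExternalId, set[ExternalId]] = {}
    for taxon, exts in a.by_taxon(wanted).items():
        for ext in exts:
            taxa_by_ext_a.setdefault(ext, set()).add(taxon)
    taxa_by_ext_b: dict[ExternalId, set[ExternalId]] = {}
    for taxon, exts in b.by_taxon(wanted).items():
        for ext in exts:
            taxa_by_ext_b.setdefault(ext, set()).add(taxon)

    shared_by_pair: dict[tuple[ExternalId, ExternalId], set[ExternalId]] = {}
    for ext, left_taxa in taxa_by_ext_a.items():
        right_taxa = taxa_by_ext_b.get(ext)
        if not right_taxa:
            continue
        for ta in left_taxa:
            for tb in right_taxa:
                shared_by_pair.setdefault((ta, tb), set()).add(ext)

    return {
        CrossLink(ta, tb, frozenset(shared))
        for (ta, tb), shared in shared_by_pair.items()
    }


def merge_links(
    base: LookupTable,
    links: Iterable[CrossLink],
    source_side: str = "a",
) -> tuple[LookupTable, int]:
    """Append inferred cross-links to a base lookup table.

    ``source_side`` names which end of each :class:`CrossLink` belongs to
    ``base`` (``"a"`` or ``"b"``); the opposite end's taxon ID is appended
    as one new external-ID row per distinct (base taxon, foreign taxon)
    pair.  Merging is idempotent — repeating a merge appends nothing.
    Returns ``(merged table, rows appended)``; the input table is not
    mutated.

    Raises
    ------
    ValueError
        If any link's base-side taxon is absent from ``base`` (all
        offenders are listed).
    """
    if source_side not in ("a", "b"):
        raise ValueError(f"source_side must be 'a' or 'b', got {source_side!r}")
    pairs = []
    missing = []
    for link in links:
        base_taxon = link.taxon_a if source_side == "a" else link.taxon_b
        foreign_taxon = link.taxon_b if source_side == "a" else link.taxon_a
        if base_taxon not in base:
            missing.append(base_taxon)
            continue
        pairs.append((base_taxon, foreign_taxon))
    if missing:
        listed = ", ".join(sorted(str(t) for t in set(missing)))
        raise ValueError(f"cross-link taxa absent from base table {base.resource!r}: {listed}")

    merged = base.copy()
    appended = 0
    for base_taxon, foreign_taxon in sorted(pairs, key=lambda p: (str(p[0]), str(p[1]))):
        if merged.add(base_taxon, foreign_taxon, base.name_of(base_taxon)):
            appended += 1
    return merged, appended


def write_links(links: Iterable[CrossLink], sink) -> int:
    """Write cross-links as TSV: taxonIdA, taxonIdB, sharedIds (pipe-separated
    CURIEs, sorted); rows sorted for byte-stable output.  Returns row count."""
    from pathlib import Path

    rows = sorted(links, key=lambda l: (str(l.taxon_a), str(l.taxon_b)))
    if isinstance(sink, (str, Path)):
        fh: IO[str] = open(sink, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh, close = sink, False
    try:
        fh.write("taxonIdA\ttaxonIdB\tsharedIds\n")
        for link in rows:
            shared = "|".join(sorted(str(e) for e in link.shared))
            fh.write(f"{link.taxon_a}\t{link.taxon_b}\t{shared}\n")
    finally:
        if close:
            fh.close()
    return len(rows)


def read_links(source, registry: SchemeRegistry | None = None) -> set[CrossLink]:
    """Read a TSV written by :func:`write_links`."""
    from pathlib import Path

    reg = registry or default_registry()
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["taxonIdA", "taxonIdB", "sharedIds"]:
            raise ValueError("not a cross-link TSV (expected taxonIdA/taxonIdB/sharedIds header)")
        links = set()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ta, tb, shared_s = line.split("\t")[:3]
            shared = frozenset(parse_curie(s, reg) for s in shared_s.split("|") if s)
            links.add(CrossLink(parse_curie(ta, reg), parse_curie(tb, reg), shared))
        return links
    finally:
        if close:
            fh.close()
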