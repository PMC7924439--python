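"""Overlap, consistency, Venn, and per-scheme count metrics.

Two taxon graphs *overlap* when taxa from each share at least one external
identifier; a taxon is *inconsistent* when it carries two or more distinct
identifiers from the same scheme (e.g. two different GBIF keys), which
signals synonymy, an outdated name, or a name-resolution bug rather than a
clean one-to-one concept mapping.  Overlap measures how similar two graphs
are; consistency measures their relative quality.

All metrics count distinct (scheme, value) pairs, never table rows, so
duplicated rows can not inflate them.  By default they are restricted to
the four audit schemes (NCBI, GBIF, IF, WoRMS) that all three reference
resources maintain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .idmodel import ExternalId, default_registry
from .linker import CrossLink
from .readers import LookupTable

__all__ = [
    "InconsistencyRecord",
    "OverlapReport",
    "VennPartition",
    "consistency_audit",
    "pairwise_consistency",
    "overlap_metrics",
    "venn_partition",
    "scheme_counts",
    "SchemeCountTable",
]


@dataclass(frozen=True, slots=True, order=True)
class InconsistencyRecord:
    """A taxon ID carrying ≥2 distinct external IDs in one scheme.

    ``names`` collects the name strings attached to the offending rows;
    disagreeing names are reported but do not themselves flag
    inconsistency — only same-scheme ID multiplicity does.  ``partner`` is
    set by the pairwise audit to the linked taxon on the other side.
    """

    taxon_id: ExternalId
    scheme: str
    values: frozenset[str]
    names: frozenset[str] = frozenset()
    partner: ExternalId | None = None

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("an inconsistency needs at least two distinct values")


@dataclass(frozen=True, slots=True)
class OverlapReport:
    """Distinct external-ID counts of two tables and their intersection."""

    resource_a: str
    resource_b: str
    count_a: int
    count_b: int
    shared: int
    schemes: frozenset[str]

    @property
    def fraction_a(self) -> float:
        """Fraction of A's external IDs also present in B (0 when A empty)."""
        return self.shared / self.count_a if self.count_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.shared / self.count_b if self.count_b else 0.0


@dataclass(frozen=True, slots=True)
class VennPartition:
    """Seven-region decomposition of three resources' external-ID sets.

    Region counts are exclusive (``ab`` excludes the triple region) and sum
    to the union cardinality.  ``abc_by_scheme`` breaks the triple
    intersection down per identifier scheme.
    """

    resources: tuple[str, str, str]
    only_a: int
    only_b: int
    only_c: int
    ab: int
    ac: int
    bc: int
    abc: int
    abc_by_scheme: Mapping[str, int] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return self.only_a + self.only_b + self.only_c + self.ab + self.ac + self.bc + self.abc

    def as_dict(self) -> dict[str, int]:
        a, b, c = self.resources
        return {
            f"{a} only": self.only_a,
            f"{b} only": self.only_b,
            f"{c} only": self.only_c,
            f"{a}&{b} only": self.ab,
            f"{a}&{c} only": self.ac,
            f"{b}&{c} only": self.bc,
            f"{a}&{b}&{c}": self.abc,
        }


def _audit_ids(table: LookupTable, schemes: Iterable[str] | None) -> frozenset[str]:
    if schemes is not None:
        return frozenset(schemes)
    return default_registry().audit_schemes


def consistency_audit(
    table: LookupTable, schemes: Iterable[str] | None = None
) -> list[InconsistencyRecord]:
    """Find taxa linking to ≥2 distinct external IDs in one scheme.

    Returns one record per offending (taxon, scheme) pair, ordered by
    taxon ID then scheme; the order is invariant under input row order.
    """
    wanted = _audit_ids(table, schemes)
    values: dict[tuple[ExternalId, str], set[str]] = {}
    names: dict[tuple[ExternalId, str], set[str]] = {}
    for row in table.rows:
        if row.external_id.scheme not in wanted:
            continue
        key = (row.taxon_id, row.external_id.scheme)
        values.setdefault(key, set()).add(row.external_id.value)
        if row.name:
            names.setdefault(key, set()).add(row.name)
    records = [
        InconsistencyRecord(
            taxon_id=taxon,
            scheme=scheme,
            values=frozenset(vals),
            names=frozenset(names.get((taxon, scheme), ())),
        )
        for (taxon, scheme), vals in values.items()
        if len(vals) >= 2
    ]
    records.sort(key=lambda r: (str(r.taxon_id), r.scheme))
    return records


def pairwise_consistency(
    links: Iterable[CrossLink],
    a: LookupTable,
    b: LookupTable,
    schemes: Iterable[str] | None = None,
) -> list[InconsistencyRecord]:
    """Audit linked taxon pairs for same-scheme identifier clashes.

    For each cross-link the full external-ID sets of both taxa (restricted
    to the audit schemes) are pooled; any scheme contributing ≥2 distinct
    values across the pool yields one record, reported on the A-side taxon
    with the B-side taxon as ``partner``.  A pair whose pooled identifiers
    agree scheme-by-scheme — like two entries that both point to the same
    NCBI, WoRMS, and GBIF records — is consistent and yields nothing.
    """
    wanted = _audit_ids(a, schemes)
    records = []
    for link in sorted(links, key=lambda l: (str(l.taxon_a), str(l.taxon_b))):
        pooled = a.ids_of(link.taxon_a, wanted) | b.ids_of(link.taxon_b, wanted)
        by_scheme: dict[str, set[str]] = {}
        for ext in pooled:
            by_scheme.setdefault(ext.scheme, set()).add(ext.value)
        pooled_names = {
            n
            for n in (a.name_of(link.taxon_a), b.name_of(link.taxon_b))
            if n
        }
        for scheme in sorted(by_scheme):
            vals = by_scheme[scheme]
            if len(vals) >= 2:
                records.append(
                    InconsistencyRecord(
                        taxon_id=link.taxon_a,
                        scheme=scheme,
                        values=frozenset(vals),
                        names=frozenset(pooled_names),
                        partner=link.taxon_b,
                    )
                )
    return records


def overlap_metrics(
    a: LookupTable, b: LookupTable, schemes: Iterable[str] | None = None
) -> OverlapReport:
    """Distinct external-ID overlap between two tables, both directions."""
    wanted = _audit_ids(a, schemes)
    ids_a = a.external_ids(wanted)
    ids_b = b.external_ids(wanted)
    return OverlapReport(
        resource_a=a.resource,
        resource_b=b.resource,
        count_a=len(ids_a),
        count_b=len(ids_b),
        shared=len(ids_a & ids_b),
        schemes=frozenset(wanted),
    )


def venn_partition(
    a: LookupTable,
    b: LookupTable,
    c: LookupTable,
    schemes: Iterable[str] | None = None,
) -> VennPartition:
    """Exclusive seven-region decomposition of three external-ID sets."""
    wanted = _audit_ids(a, schemes)
    sa, sb, sc = (t.external_ids(wanted) for t in (a, b, c))
    abc = sa & sb & sc
    part = VennPartition(
        resources=(a.resource, b.resource, c.resource),
        only_a=len(sa - sb - sc),
        only_b=len(sb - sa - sc),
        only_c=len(sc - sa - sb),
        ab=len((sa & sb) - sc),
        ac=len((sa & sc) - sb),
        bc=len((sb & sc) - sa),
        abc=len(abc),
        abc_by_scheme={
            s: sum(1 for e in abc if e.scheme == s) for s in sorted({e.scheme for e in abc})
        },
    )
    # conservation: the seven exclusive regions must tile the union
    assert part.union_size == len(sa | sb | sc)
    return part


@dataclass(frozen=True)
class SchemeCountTable:
    """Per-resource, per-scheme distinct-ID counts with reference percentages.

    Percentages use the reference resource's per-scheme totals as
    denominators (the reference row reads 100% throughout) and are a
    relative size estimate, not a measure of overlapping IDs.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    reference: str

    def to_text(self) -> str:
        cells = self.counts.astype(object).copy()
        for res in cells.index:
            for col in cells.columns:
                cells.loc[res, col] = f"{self.counts.loc[res, col]:,} ({self.percentages.loc[res, col]:.0f}%)"
        return cells.to_string()


def scheme_counts(
    tables: Iterable[LookupTable],
    reference: LookupTable,
    schemes: Iterable[str] | None = None,
) -> SchemeCountTable:
    """Count distinct external IDs per (resource, scheme) with percentages.

    The matrix has one row per table (the reference is prepended when not
    already among them), one column per scheme plus a ``Combined`` column
    summing the scheme columns; percentages are relative to the reference
    row, which is 100% by construction.
    """
    wanted = sorted(_audit_ids(reference, schemes))
    if not wanted:
        raise ValueError("scheme set must be non-empty")
    table_list = list(tables)
    if all(t.resource != reference.resource for t in table_list):
        table_list.insert(0, reference)

    counts = pd.DataFrame(
        {
            scheme: [len(t.external_ids([scheme])) for t in table_list]
            for scheme in wanted
        },
        index=[t.resource for t in table_list],
        dtype=int,
    )
    counts["Combined"] = counts[wanted].sum(axis=1)
    ref_row = counts.loc[reference.resource]
    percentages = counts.div(ref_row.where(ref_row != 0, other=1), axis=1) * 100.0
    # the reference is 100% by definition, even for a scheme it has no IDs in
    percentages.loc[reference.resource] = 100.0
    return SchemeCountTable(counts=counts, percentages=percentages, reference=reference.resource)
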