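"""Readers that flatten each source's taxon graph into a lookup table.

A resource's taxon graph — its internal taxa plus their pointers into
external databases — is flattened to rows of ``(local taxon ID, external
ID)``.  That two-column table is the unit of exchange throughout this
package: it is what gets joined, audited, and written to disk as TSV with
columns ``taxonId``, ``taxonName``, ``externalId``.

Three source dialects are supported:

* the Wikidata JSON entity dump (one JSON entity per line inside a JSON
  array), streamed in constant memory;
* the Open Tree of Life reference taxonomy ``taxonomy.tsv`` (fields
  separated by the literal three-character delimiter tab-pipe-tab, with a
  comma-separated ``sourceinfo`` column of lowercase CURIEs);
* the GloBI taxon-graph TSV (``providedTaxonId`` / ``providedTaxonName`` /
  ``resolvedTaxonId`` / ``resolvedTaxonName`` columns).

Every reader returns ``(LookupTable, stats)`` where the stats object
carries conservation counters: records scanned equals rows emitted plus
records skipped, so nothing disappears silently from a multi-gigabyte
input.
"""

from __future__ import annotations

import bz2
import csv
import gzip
import io
import json
import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple

from .idmodel import (
    CurieParseError,
    ExternalId,
    SchemeRegistry,
    default_registry,
    parse_curie,
)

__all__ = [
    "Row",
    "LookupTable",
    "ExtractionStats",
    "ReaderStats",
    "DEFAULT_WIKIDATA_PROPERTY_MAP",
    "extract_wikidata_taxa",
    "read_ott_taxonomy",
    "read_globi_taxon_graph",
    "write_lookup_table",
    "read_lookup_table",
]


class Row(NamedTuple):
    """One lookup-table row: a local taxon, its name, one external pointer."""

    taxon_id: ExternalId
    name: str | None
    external_id: ExternalId


class LookupTable:
    """A resource's taxon graph flattened to (taxon ID, external ID) rows.

    Rows are deduplicated on ``(taxon_id, external_id)`` at ingest; the
    first-seen name wins.  For every row the external scheme differs from
    the owning resource, and — except for GLOBI, which mints no identifiers
    of its own and therefore keys its taxa by provided or synthesized
    foreign IDs — the taxon ID's scheme equals the owning resource.
    """

    def __init__(self, resource: str, provenance: str = "") -> None:
        self.resource = resource
        self.provenance = provenance
        # (taxon_id, external_id) -> first-seen name
        self._rows: dict[tuple[ExternalId, ExternalId], str | None] = {}
        self._names: dict[ExternalId, str | None] = {}

    def add(self, taxon_id: ExternalId, external_id: ExternalId, name: str | None = None) -> bool:
        """Add one row; returns False for an exact duplicate pair."""
        if external_id.scheme == self.resource:
            raise ValueError(
                f"external ID {external_id} has the owning resource's scheme {self.resource!r}"
            )
        if self.resource != "GLOBI" and taxon_id.scheme != self.resource:
            raise ValueError(
                f"taxon ID {taxon_id} does not belong to resource {self.resource!r}"
            )
        key = (taxon_id, external_id)
        if key in self._rows:
            return False
        self._rows[key] = name
        self._names.setdefault(taxon_id, name)
        return True

    @property
    def rows(self) -> list[Row]:
        return [Row(t, self._names.get(t), e) for (t, e) in self._rows]

    def __len__(self) -> int:
        return len(self._rows)

    def __contains__(self, taxon_id: ExternalId) -> bool:
        return taxon_id in self._names

    def taxa(self) -> set[ExternalId]:
        """The distinct local taxon IDs appearing in at least one row."""
        return set(self._names)

    def name_of(self, taxon_id: ExternalId) -> str | None:
        return self._names.get(taxon_id)

    def external_ids(self, schemes: Iterable[str] | None = None) -> set[ExternalId]:
        """Distinct external identifiers, optionally restricted to schemes."""
        wanted = None if schemes is None else frozenset(schemes)
        return {
            e for (_, e) in self._rows if wanted is None or e.scheme in wanted
        }

    def ids_of(self, taxon_id: ExternalId, schemes: Iterable[str] | None = None) -> set[ExternalId]:
        """Distinct external identifiers attached to one taxon."""
        wanted = None if schemes is None else frozenset(schemes)
        return {
            e
            for (t, e) in self._rows
            if t == taxon_id and (wanted is None or e.scheme in wanted)
        }

    def by_taxon(self, schemes: Iterable[str] | None = None) -> dict[ExternalId, set[ExternalId]]:
        """taxon → set of external IDs, restricted to ``schemes`` if given."""
        wanted = None if schemes is None else frozenset(schemes)
        out: dict[ExternalId, set[ExternalId]] = {}
        for (t, e) in self._rows:
            if wanted is None or e.scheme in wanted:
                out.setdefault(t, set()).add(e)
        return out

    def copy(self) -> "LookupTable":
        dup = LookupTable(self.resource, self.provenance)
        dup._rows = dict(self._rows)
        dup._names = dict(self._names)
        return dup

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LookupTable):
            return NotImplemented
        return self.resource == other.resource and self._rows == other._rows

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LookupTable({self.resource!r}, rows={len(self)}, taxa={len(self._names)})"


@dataclass
class ReaderStats:
    """Conservation counters for a single-file reader.

    ``records_scanned == rows_emitted_gross + records_skipped`` where the
    gross row count includes duplicates collapsed by the table.
    """

    records_scanned: int = 0
    rows_emitted: int = 0
    duplicate_rows: int = 0
    records_skipped: int = 0
    skipped_by_reason: Counter = field(default_factory=Counter)
    per_scheme_link_counts: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return self.records_scanned == (
            self.rows_emitted + self.duplicate_rows + self.records_skipped
        )


@dataclass
class ExtractionStats:
    """Counters for the Wikidata entity-dump extraction.

    The histogram maps the number of external links a taxon carries (0, 1,
    2, …) to how many taxa carry that many; its values sum to
    ``taxa_extracted`` and its weighted sum equals the rows emitted.
    """

    entities_scanned: int = 0
    taxa_extracted: int = 0
    malformed_lines: int = 0
    links_per_taxon_histogram: Counter = field(default_factory=Counter)
    per_scheme_link_counts: Counter = field(default_factory=Counter)

    @property
    def rows_emitted(self) -> int:
        return sum(k * n for k, n in self.links_per_taxon_histogram.items())

    def conserved(self) -> bool:
        return sum(self.links_per_taxon_histogram.values()) == self.taxa_extracted


#: Wikidata statement keys, overridable from a config file so a drifted dump
#: or an added scheme needs no code change.  ``instance_of``/``taxon_class``
#: select taxon items, ``taxon_name`` supplies the name column, and
#: ``external_ids`` maps identifier properties to canonical schemes.
DEFAULT_WIKIDATA_PROPERTY_MAP: Mapping[str, object] = {
    "instance_of": "P31",
    "taxon_class": "Q16521",
    "taxon_name": "P225",
    "external_ids": {
        "P685": "NCBI",
        "P815": "ITIS",
        "P846": "GBIF",
        "P830": "EOL",
        "P1391": "IF",
        "P938": "FISHBASE",
        "P850": "WORMS",
    },
}


def _open_maybe_compressed(path: str | Path) -> IO[str]:
    p = Path(path)
    if p.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8")
    if p.suffix == ".bz2":
        return io.TextIOWrapper(bz2.open(p, "rb"), encoding="utf-8")
    return open(p, "r", encoding="utf-8")


def _iter_entity_lines(source: str | Path | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with _open_maybe_compressed(source) as fh:
            yield from fh
    else:
        yield from source


def _claim_values(entity: dict, prop: str) -> list[str]:
    """String values of preferred/normal-rank statements for one property."""
    values: list[str] = []
    for claim in entity.get("claims", {}).get(prop, []):
        if claim.get("rank") == "deprecated":
            continue
        snak = claim.get("mainsnak", {})
        datavalue = snak.get("datavalue")
        if datavalue is None:
            continue
        values.append(datavalue.get("value"))
    return values


def extract_wikidata_taxa(
    source: str | Path | Iterable[str],
    registry: SchemeRegistry | None = None,
    property_map: Mapping[str, object] | None = None,
    provenance: str = "wikidata-json-dump",
) -> tuple[LookupTable, ExtractionStats]:
    """Stream a Wikidata JSON entity dump and extract the taxon graph.

    ``source`` is a path (``.gz``/``.bz2`` transparently decompressed) or
    any iterable of lines; processing is single-pass and constant-memory in
    the dump size.  An entity is a taxon when it carries an instance-of
    statement targeting the Wikidata taxon class; each of its external
    identifier statements becomes one row ``(WD:Qid, taxon name,
    SCHEME:value)``.  Taxa with no external links still count in the
    histogram's 0 bin.  Malformed JSON lines are counted and skipped — one
    bad line in a 40-million-entity dump must not abort the run.
    """
    reg = registry or default_registry()
    pmap = dict(DEFAULT_WIKIDATA_PROPERTY_MAP)
    if property_map:
        pmap.update(property_map)
    instance_of = str(pmap["instance_of"])
    taxon_class = str(pmap["taxon_class"])
    name_prop = str(pmap["taxon_name"])
    id_props: Mapping[str, str] = dict(pmap["external_ids"])  # type: ignore[arg-type]

    table = LookupTable("WD", provenance)
    stats = ExtractionStats()

    for raw_line in _iter_entity_lines(source):
        line = raw_line.strip()
        if not line or line in ("[", "]"):
            continue
        line = line.rstrip(",")
        try:
            entity = json.loads(line)
        except json.JSONDecodeError:
            stats.malformed_lines += 1
            continue
        stats.entities_scanned += 1

        is_taxon = any(
            isinstance(v, dict) and v.get("id") == taxon_class
            for v in _claim_values(entity, instance_of)
        )
        if not is_taxon:
            continue
        qid = entity.get("id")
        if not qid:
            stats.malformed_lines += 1
            continue
        taxon = ExternalId("WD", str(qid))
        names = [v for v in _claim_values(entity, name_prop) if isinstance(v, str)]
        name = names[0] if names else None

        n_links = 0
        for prop, scheme_token in id_props.items():
            scheme = reg.normalize(str(scheme_token))
            for value in _claim_values(entity, prop):
                if value is None:
                    continue
                if table.add(taxon, ExternalId(scheme, str(value)), name):
                    n_links += 1
                    stats.per_scheme_link_counts[scheme] += 1
        stats.taxa_extracted += 1
        stats.links_per_taxon_histogram[n_links] += 1

    return table, stats


_OTT_DELIMITER = "\t|\t"


def _split_ott_line(line: str) -> list[str]:
    # lines end with a bare "\t|" terminator; strip exactly that, never the
    # (possibly empty) trailing fields themselves
    return line.rstrip("\n").removesuffix("\t|").split(_OTT_DELIMITER)


def read_ott_taxonomy(
    source: str | Path,
    registry: SchemeRegistry | None = None,
    include_all_schemes: bool = False,
    provenance: str = "ott-taxonomy",
) -> tuple[LookupTable, ReaderStats]:
    """Read an Open Tree reference-taxonomy ``taxonomy.tsv`` file.

    ``source`` may be the file itself or the unpacked release directory
    containing it.  Fields are separated by the literal tab-pipe-tab
    delimiter; the ``sourceinfo`` field holds comma-separated lowercase
    CURIEs (``ncbi:…``, ``gbif:…``, ``worms:…``, ``if:…``, ``irmng:…``,
    ``silva:…``).  One row is emitted per (uid, sourceinfo entry) whose
    scheme normalizes into the registry's join schemes; other recognized
    schemes are tallied in the stats and, with ``include_all_schemes``,
    emitted as rows too.  Conservation is counted per sourceinfo entry.
    """
    reg = registry or default_registry()
    path = Path(source)
    if path.is_dir():
        path = path / "taxonomy.tsv"
    table = LookupTable("OTT", provenance)
    stats = ReaderStats()

    with _open_maybe_compressed(path) as fh:
        header_line = fh.readline()
        if _OTT_DELIMITER not in header_line:
            raise ValueError(
                f"{path}: not an OTT taxonomy file (missing tab-pipe-tab delimiter in header)"
            )
        header = [h.strip() for h in _split_ott_line(header_line)]
        try:
            uid_col = header.index("uid")
            name_col = header.index("name")
            source_col = header.index("sourceinfo")
        except ValueError as exc:
            raise ValueError(f"{path}: OTT header is missing a required field: {exc}") from None

        for line in fh:
            fields = _split_ott_line(line)
            if len(fields) <= max(uid_col, name_col, source_col):
                stats.records_scanned += 1
                stats.records_skipped += 1
                stats.skipped_by_reason["short-line"] += 1
                continue
            taxon = ExternalId("OTT", fields[uid_col].strip())
            name = fields[name_col].strip() or None
            sourceinfo = fields[source_col].strip()
            if not sourceinfo:
                continue
            for entry in sourceinfo.split(","):
                stats.records_scanned += 1
                try:
                    ext = parse_curie(entry, reg)
                except CurieParseError:
                    stats.records_skipped += 1
                    stats.skipped_by_reason["unparsable-sourceinfo"] += 1
                    continue
                stats.per_scheme_link_counts[ext.scheme] += 1
                if not include_all_schemes and ext.scheme not in reg.join_schemes:
                    stats.records_skipped += 1
                    stats.skipped_by_reason["non-target-scheme"] += 1
                    continue
                if table.add(taxon, ext, name):
                    stats.rows_emitted += 1
                else:
                    stats.duplicate_rows += 1
    return table, stats


_GLOBI_REQUIRED = ("providedTaxonId", "providedTaxonName", "resolvedTaxonId", "resolvedTaxonName")


def read_globi_taxon_graph(
    source: str | Path | IO[str],
    registry: SchemeRegistry | None = None,
    provenance: str = "globi-taxon-graph",
) -> tuple[LookupTable, ReaderStats]:
    """Read a GloBI taxon-graph TSV into a lookup table.

    Each record maps a provided taxon (the name/ID as it arrived from a
    source dataset) to an identifier already resolved within GloBI.  The
    provided side keys the row; when the provided ID is empty or the
    literal ``null``, a stable joinable key ``GLOBI:null@<providedName>`` is
    synthesized, because GloBI mints no identifiers of its own.  Records
    whose resolved side is not a parsable CURIE are counted and skipped.
    """
    reg = registry or default_registry()
    table = LookupTable("GLOBI", provenance)
    stats = ReaderStats()

    if isinstance(source, (str, Path)):
        fh: IO[str] = _open_maybe_compressed(source)
        close = True
    else:
        fh, close = source, False
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _GLOBI_REQUIRED if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"GloBI taxon-graph file is missing column(s): {', '.join(missing)}")
        for record in reader:
            stats.records_scanned += 1
            provided_id = (record.get("providedTaxonId") or "").strip()
            provided_name = (record.get("providedTaxonName") or "").strip()
            resolved_id = (record.get("resolvedTaxonId") or "").strip()

            if not provided_id or provided_id.lower() == "null":
                if not provided_name:
                    stats.records_skipped += 1
                    stats.skipped_by_reason["no-provided-key"] += 1
                    continue
                taxon = ExternalId("GLOBI", f"null@{provided_name}")
            else:
                try:
                    taxon = parse_curie(provided_id, reg)
                except CurieParseError:
                    taxon = ExternalId("GLOBI", f"null@{provided_id}")
            try:
                ext = parse_curie(resolved_id, reg)
            except CurieParseError:
                stats.records_skipped += 1
                stats.skipped_by_reason["unparsable-resolved-id"] += 1
                continue
            if ext.scheme == "GLOBI":
                stats.records_skipped += 1
                stats.skipped_by_reason["self-referential"] += 1
                continue
            if table.add(taxon, ext, provided_name or None):
                stats.rows_emitted += 1
                stats.per_scheme_link_counts[ext.scheme] += 1
            else:
                stats.duplicate_rows += 1
    finally:
        if close:
            fh.close()
    return table, stats


def write_lookup_table(table: LookupTable, sink: str | Path | IO[str]) -> int:
    """Write a lookup table as TSV (``taxonId``, ``taxonName``,
    ``externalId``), sorted by (taxonId, externalId) for byte-stable output.
    Returns the number of data rows written."""
    rows = sorted(table.rows, key=lambda r: (str(r.taxon_id), str(r.external_id)))
    if isinstance(sink, (str, Path)):
        fh: IO[str] = open(sink, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh, close = sink, False
    try:
        fh.write("taxonId\ttaxonName\texternalId\n")
        for row in rows:
            fh.write(f"{row.taxon_id}\t{row.name or ''}\t{row.external_id}\n")
    finally:
        if close:
            fh.close()
    return len(rows)


def read_lookup_table(
    source: str | Path | IO[str],
    resource: str | None = None,
    registry: SchemeRegistry | None = None,
    provenance: str = "",
) -> LookupTable:
    """Read a TSV written by :func:`write_lookup_table` back into memory.

    ``resource`` defaults to the scheme of the first row's taxon ID, which
    is correct for any table written by this package.
    """
    reg = registry or default_registry()
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["taxonId", "taxonName", "externalId"]:
            raise ValueError("not a lookup-table TSV (expected taxonId/taxonName/externalId header)")
        parsed: list[tuple[ExternalId, str | None, ExternalId]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            taxon_s, name_s, ext_s = line.split("\t")[:3]
            parsed.append((parse_curie(taxon_s, reg), name_s or None, parse_curie(ext_s, reg)))
        if resource is None:
            resource = parsed[0][0].scheme if parsed else "GLOBI"
        table = LookupTable(resource, provenance)
        for taxon, name, ext in parsed:
            table.add(taxon, ext, name)
        return table
    finally:
        if close:
            fh.close()
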