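"""End-to-end pipeline: extract → join → merge → audit, with a JSON report.

This wires the readers, linker, and audit metrics into the single run a
user performs against the archived inputs: extract the Wikidata taxon
graph, read the Open Tree taxonomy and the GloBI taxon graph, join
Wikidata to GloBI over the seven join schemes, append the inferred
Wikidata links to the GloBI table, and compute the overlap / Venn /
per-scheme / consistency metrics over the four audit schemes.  Outputs are
deterministic byte-for-byte for the same inputs and configuration; the
report's provenance timestamp is the only run-varying field and is kept
out of every data file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

from . import __version__
from .audit import (
    consistency_audit,
    overlap_metrics,
    pairwise_consistency,
    scheme_counts,
    venn_partition,
)
from .idmodel import AUDIT_SCHEMES, JOIN_SCHEMES, SchemeRegistry
from .linker import join_graphs, merge_links, write_links
from .readers import (
    extract_wikidata_taxa,
    read_globi_taxon_graph,
    read_ott_taxonomy,
    write_lookup_table,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("taxograph")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration, loadable from a single JSON file.

    Unknown keys in the file are rejected by name, so a typo in a config
    never silently falls back to a default.
    """

    scheme_aliases: Mapping[str, str] = field(default_factory=dict)
    wikidata_property_map: Mapping[str, object] = field(default_factory=dict)
    join_schemes: tuple[str, ...] = tuple(sorted(JOIN_SCHEMES))
    audit_schemes: tuple[str, ...] = tuple(sorted(AUDIT_SCHEMES))
    log_level: str = "INFO"
    output_dir: str = "taxograph-out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        for seq_key in ("join_schemes", "audit_schemes"):
            if seq_key in raw:
                raw[seq_key] = tuple(raw[seq_key])
        return cls(**raw)

    def registry(self) -> SchemeRegistry:
        return SchemeRegistry(
            aliases=self.scheme_aliases,
            join_schemes=self.join_schemes,
            audit_schemes=self.audit_schemes,
        )


def run_pipeline(
    config: RunConfig,
    wd_dump: str | Path,
    ott_path: str | Path,
    globi_tsv: str | Path,
) -> dict:
    """Run the full linking-and-audit pipeline and write a report bundle.

    Writes, under ``config.output_dir``: the three lookup tables, the
    WD↔GloBI cross-links, the merged GloBI table, per-resource
    inconsistency reports, and ``report.json`` with every metric and the
    input provenance strings.  Returns the report dict.
    """
    logging.basicConfig(level=config.log_level)
    registry = config.registry()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("extracting Wikidata taxon graph from %s", wd_dump)
    wd, wd_stats = extract_wikidata_taxa(
        wd_dump, registry, property_map=dict(config.wikidata_property_map) or None
    )
    logger.info(
        "wikidata: %d entities scanned, %d taxa, %d rows, %d malformed lines",
        wd_stats.entities_scanned, wd_stats.taxa_extracted, len(wd), wd_stats.malformed_lines,
    )
    ott, ott_stats = read_ott_taxonomy(ott_path, registry)
    logger.info("ott: %d sourceinfo entries scanned, %d rows", ott_stats.records_scanned, len(ott))
    globi, globi_stats = read_globi_taxon_graph(globi_tsv, registry)
    logger.info("globi: %d records scanned, %d rows", globi_stats.records_scanned, len(globi))

    for name, table in (("wikidata", wd), ("ott", ott), ("globi", globi)):
        write_lookup_table(table, out / f"{name}.tsv")

    join_schemes = tuple(config.join_schemes)
    audit_schemes = tuple(config.audit_schemes)

    links = join_graphs(wd, globi, join_schemes)
    write_links(links, out / "links-wd-globi.tsv")
    merged, appended = merge_links(globi, links, source_side="b")
    write_lookup_table(merged, out / "globi-merged.tsv")
    logger.info("join: %d cross-links, %d rows appended to GloBI", len(links), appended)

    inconsistencies = {}
    for name, table in (("wikidata", wd), ("ott", ott), ("globi", globi)):
        recs = consistency_audit(table, audit_schemes)
        inconsistencies[name] = recs
        with open(out / f"inconsistent-{name}.tsv", "w", encoding="utf-8") as fh:
            fh.write("taxonId\tscheme\tvalues\tnames\n")
            for r in recs:
                fh.write(
                    f"{r.taxon_id}\t{r.scheme}\t{'|'.join(sorted(r.values))}"
                    f"\t{'|'.join(sorted(r.names))}\n"
                )
    pair_recs = pairwise_consistency(links, wd, globi, audit_schemes)

    overlaps = {
        "WD_vs_OTT": overlap_metrics(wd, ott, audit_schemes),
        "GLOBI_vs_OTT": overlap_metrics(globi, ott, audit_schemes),
        "GLOBI_vs_WD": overlap_metrics(globi, wd, audit_schemes),
    }
    venn = venn_partition(ott, wd, globi, audit_schemes)
    counts = scheme_counts([ott, wd, globi], reference=ott, schemes=audit_schemes)

    report = {
        "taxograph_version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "wikidata": str(wd_dump),
            "ott": str(ott_path),
            "globi": str(globi_tsv),
        },
        "extraction": {
            "wikidata_entities_scanned": wd_stats.entities_scanned,
            "wikidata_taxa": wd_stats.taxa_extracted,
            "wikidata_rows": len(wd),
            "wikidata_links_per_taxon": {
                str(k): v for k, v in sorted(wd_stats.links_per_taxon_histogram.items())
            },
            "ott_rows": len(ott),
            "globi_rows": len(globi),
        },
        "linking": {
            "schemes": list(join_schemes),
            "cross_links": len(links),
            "appended_rows": appended,
        },
        "audit": {
            "schemes": list(audit_schemes),
            "inconsistent_taxa": {k: len(v) for k, v in inconsistencies.items()},
            "pairwise_inconsistencies_wd_globi": len(pair_recs),
            "overlap": {
                key: {
                    "count_a": r.count_a,
                    "count_b": r.count_b,
                    "shared": r.shared,
                    "fraction_a_pct": round(100.0 * r.fraction_a, 1),
                    "fraction_b_pct": round(100.0 * r.fraction_b, 1),
                }
                for key, r in overlaps.items()
            },
            "venn": venn.as_dict(),
            "venn_abc_by_scheme": dict(venn.abc_by_scheme),
            "scheme_counts": {
                res: {
                    col: int(counts.counts.loc[res, col]) for col in counts.counts.columns
                }
                for res in counts.counts.index
            },
        },
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
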