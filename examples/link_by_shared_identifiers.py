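"""Link two resources by joining their lookup tables on shared external IDs.

Builds the micro-tables for *Panthera leo* and the midge genus *Procladius*
and joins Wikidata against the Open Tree taxonomy: two taxa are inferred to
be the same concept when they carry at least one identical external
identifier (here an NCBI, WoRMS or GBIF record), without comparing a
single name string.
"""

from taxograph import ExternalId, example_fixtures, join_graphs, merge_links

fx = example_fixtures()

# Give GloBI a Panthera leo entry that also points at ITIS:183803, the
# Integrated Taxonomic Information System record for the lion.
globi = fx["globi"]
globi.add(ExternalId("GLOBI", "null@Panthera leo"), ExternalId("ITIS", "183803"), "Panthera leo")

links = join_graphs(fx["wd"], globi)
print(f"WD <-> GloBI cross-links: {len(links)}")
for link in sorted(links):
    shared = ", ".join(sorted(str(e) for e in link.shared))
    print(f"  {link.taxon_a}  <->  {link.taxon_b}   via {shared}")

merged, appended = merge_links(globi, links, source_side="b")
print(f"rows appended to the GloBI table: {appended}")
print("GloBI's lion entry now carries:",
      ", ".join(sorted(str(e) for e in merged.ids_of(ExternalId("GLOBI", "null@Panthera leo")))))

# Each cross-link means the two local taxon IDs denote the same concept; the
# appended row makes the foreign (Wikidata) ID queryable from inside GloBI.
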