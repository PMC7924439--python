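"""Flag taxa whose graph carries several identifiers from one scheme.

A taxon that points at two different GBIF keys (or six different NCBI taxa)
is *inconsistent*: the multiplicity signals a synonym, an outdated name, or
a name-resolution bug.  The GloBI fixture contains both published
pathologies — the provisional name *Procladius sp1 M_PL_014* and the
outdated name *Senecio pectinatus*.
"""

from taxograph import consistency_audit, example_fixtures, join_graphs, pairwise_consistency

fx = example_fixtures()

records = consistency_audit(fx["globi"])
print(f"inconsistent (taxon, scheme) pairs in the GloBI fixture: {len(records)}")
for r in records:
    print(f"  {r.taxon_id}  {r.scheme} x{len(r.values)}: {', '.join(sorted(r.values))}")

# Pairwise variant: pool the identifiers of two LINKED taxa and check the
# pooled set.  Wikidata's and Open Tree's Procladius entries carry the same
# NCBI/WoRMS/GBIF triple, so the pair is consistent.
links = join_graphs(fx["wd"], fx["ott"])
clashes = pairwise_consistency(links, fx["wd"], fx["ott"])
print(f"pairwise clashes on the WD<->OTT link: {len(clashes)} (0 = overlapping AND consistent)")
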