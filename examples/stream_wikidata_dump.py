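"""Stream a (toy) Wikidata JSON entity dump into a lookup table.

The real dump is ~20 GB of compressed JSON with one entity per line; the
extractor is single-pass and constant-memory, so this script feeds it a
generator rather than a file.  Taxon items are those with an instance-of
claim targeting the taxon class; every external-identifier claim becomes
one (WD:Qid, name, SCHEME:value) row.
"""

import json

from taxograph import extract_wikidata_taxa


def toy_dump():
    def claim(value):
        return {"mainsnak": {"datavalue": {"value": value}}, "rank": "normal"}

    yield json.dumps({"id": "Q140", "claims": {
        "P31": [claim({"id": "Q16521"})],        # instance of: taxon
        "P225": [claim("Panthera leo")],         # taxon name
        "P815": [claim("183803")],               # ITIS TSN
    }})
    yield json.dumps({"id": "Q7247420", "claims": {
        "P31": [claim({"id": "Q16521"})],
        "P225": [claim("Procladius")],
        "P850": [claim("156905")],               # WoRMS AphiaID
        "P846": [claim("1449280")],              # GBIF key
        "P685": [claim("191633")],               # NCBI taxid
    }})
    yield json.dumps({"id": "Q42", "claims": {   # a person, not a taxon
        "P31": [claim({"id": "Q5"})],
    }})


table, stats = extract_wikidata_taxa(toy_dump())
print(f"entities scanned: {stats.entities_scanned}, taxa: {stats.taxa_extracted}, "
      f"rows: {len(table)}")
print("links-per-taxon histogram:", dict(sorted(stats.links_per_taxon_histogram.items())))
for row in sorted(table.rows, key=lambda r: (str(r.taxon_id), str(r.external_id))):
    print(f"  {row.taxon_id}\t{row.name}\t{row.external_id}")
# Non-taxon entities contribute to the scan count but emit no rows; each
# identifier claim of a taxon becomes exactly one lookup-table row.
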