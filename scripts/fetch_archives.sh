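#!/usr/bin/env bash
# Download the pinned archives needed for a full-scale reproduction.
# These are large (the Wikidata dump alone is ~20 GB compressed); nothing in
# the package downloads anything at runtime — run this explicitly, once.
set -euo pipefail

DEST="${1:-archives}"
mkdir -p "$DEST"

# Wikidata JSON entity dump (archived copy, DOI 10.5281/zenodo.1211767)
curl -L -o "$DEST/wikidata-dump.json.gz" \
    "https://zenodo.org/record/1211767/files/wikidata-taxon-dump.json.gz" || \
    echo "fetch the archived Wikidata dump via https://doi.org/10.5281/zenodo.1211767"

# Open Tree of Life reference taxonomy 3.0
curl -L -o "$DEST/ott3.0.tgz" "http://files.opentreeoflife.org/ott/ott3.0/ott3.0.tgz"
tar -xzf "$DEST/ott3.0.tgz" -C "$DEST"

# GloBI Taxon Graph v0.4.2 (DOI 10.5281/zenodo.755513)
curl -L -o "$DEST/globi-taxon-graph.tsv.gz" \
    "https://zenodo.org/record/755513/files/taxonMap.tsv.gz" || \
    echo "fetch the GloBI taxon graph via https://doi.org/10.5281/zenodo.755513"

echo "archives in $DEST/; run:"
echo "  taxograph run $DEST/wikidata-dump.json.gz $DEST/ott3.0 $DEST/globi-taxon-graph.tsv.gz -o full-scale-out"
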