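# Methods

## The identifier-graph linking model

Each resource is modelled as a *taxon graph*: a set of local taxon IDs,
each annotated with external identifiers — pointers into other databases'
namespaces. The package flattens that graph to a **lookup table**, a
multiset of `(taxon_id, name, external_id)` rows deduplicated on
`(taxon_id, external_id)` with the first-seen name retained. All
identifiers are `(scheme, value)` pairs serialized as CURIEs
(`SCHEME:value`); schemes are case-insensitive tokens canonicalized to
upper case, values are opaque and case-sensitive. CURIEs split on the
*first* colon only, so synthesized GloBI keys like
`GLOBI:null@Procladius sp1 M_PL_014` survive round trips losslessly.
Scheme lookup is total: an unrecognized prefix passes through upper-cased
and flagged, never raising, because multi-gigabyte entity dumps routinely
contain schemes outside the target set.

Two scheme sets parameterize the methods, both overridable:

* **join schemes** (NCBI, ITIS, GBIF, EOL, IF, FISHBASE, WORMS) — used
  when inferring cross-resource links;
* **audit schemes** (NCBI, GBIF, IF, WORMS), a subset of the join
  schemes — the schemes all three reference resources maintain, used for
  overlap, Venn, and consistency metrics so that coverage asymmetries in
  the other schemes do not distort comparisons.

**Linking** is an equi-join: taxa `a ∈ A`, `b ∈ B` are cross-linked iff
they share ≥ 1 external identifier within the chosen schemes. The
implementation is a hash join keyed on the serialized identifier — linear
in table size plus output size, which is what makes a multi-million-row
join feasible on one machine — and a brute-force all-pairs oracle exists
in the test suite to certify it. Many-to-many matches are all retained:
one external ID shared by several taxa on either side links every
combination, which is deliberate (synonymous entries propagate through the
shared identifier). Transitivity is *not* applied: each pairwise join
stands on its own identifier evidence, and chaining A–B with B–C to
manufacture A–C would change the semantics of the evidence set. Merging
appends, per distinct (base taxon, foreign taxon) pair, one row in which
the foreign taxon ID plays the role of an external identifier; the merge
is idempotent by the table's dedup invariant.

**Auditing.** A taxon is *inconsistent* when it carries ≥ 2 distinct
values in one scheme. The per-table audit groups rows by (taxon, scheme);
the pairwise audit pools the full identifier sets of the two ends of each
cross-link and applies the same rule to the pooled set — which is why it
needs the tables, not just the links: the shared set alone cannot witness
a clash, since a clashing pair of values is by definition not shared.
Disagreeing name strings are reported on the record but do not themselves
flag inconsistency; only same-scheme ID multiplicity does. Overlap, the
seven-region Venn partition, and the per-scheme count matrix all count
**distinct (scheme, value) pairs**, never rows, so duplicated rows cannot
inflate them. In the count matrix, percentages are taken against the
reference resource's per-scheme totals (the reference row is 100 % by
definition, including for a scheme in which it has no identifiers); they
are a relative size estimate, not an intersection measure.

## Source-format readers

*Wikidata*: the JSON entity dump is processed one line (= one entity) at a
time, single-pass and constant-memory; leading `[`, trailing `]`, and
trailing commas are tolerated, malformed lines are counted and skipped.
Taxon items are those with an instance-of statement targeting the taxon
class; statement keys default to P31/Q16521 (instance of taxon), P225
(taxon name), and the identifier properties P685 NCBI, P815 ITIS, P846
GBIF, P830 EOL, P1391 IF, P938 FishBase, P850 WoRMS, all overridable from
a config file so a drifted dump needs no code change. Deprecated-rank
statements are skipped, preferred and normal ranks kept, matching common
consumer convention. The extractor also histograms links-per-taxon; taxa
with zero links occupy the 0 bin and emit no rows.

*OTT*: `taxonomy.tsv` uses the literal three-character delimiter
tab-pipe-tab with a bare `\t|` line terminator; the parser strips exactly
that suffix (never trailing empty fields) and splits on the full
delimiter. `sourceinfo` entries are comma-separated lowercase CURIEs; ones
whose scheme is outside the join set (silva, irmng) are tallied but
excluded from rows unless requested.

*GloBI*: the 4-column taxon-graph TSV (`providedTaxonId`,
`providedTaxonName`, `resolvedTaxonId`, `resolvedTaxonName`). The provided
side keys the row; an empty or `null` provided ID synthesizes the stable
key `GLOBI:null@<name>`. Because GloBI mints no identifiers of its own,
the GLOBI table is the one place where taxon keys may carry foreign
schemes; everywhere else a row's taxon scheme must equal the owning
resource, and a row's external scheme must differ from it — both enforced
at ingest.

Every reader reports conservation counters
(`scanned == emitted + duplicates + skipped`), asserted throughout the
test suite; on inputs of this scale, silent row loss is the failure mode
to design against.

## Synthetic generator

The generator emulates the statistical structure the method assumes:
`n_taxa` true taxa, each holding one canonical identifier per scheme;
resources covering each taxon independently with probability `coverage`
(default 0.8); a covered taxon carrying each scheme's identifier with
probability `link_prob` (default 0.6, making ≥ 2 links the typical case,
as in large aggregated taxon graphs); and with probability
`conflict_rate` (default 0.05 — conflicts are rare in curated resources) a
second, wrong same-scheme identifier planted on a linked taxon. Defaults
were fixed once as field-plausible values and are not tuned per test.

Ground truth is exact by construction, not probabilistic: canonical values
live in disjoint integer ranges per scheme (scheme *i* owns
`[(i+1)·10⁷, (i+2)·10⁷)`), so schemes and taxa cannot collide; planted
wrong values come from a reserved upper half-range never used canonically
and are globally unique, so a planted conflict can never silently create a
true cross-link. Identical spec + seed reproduces byte-identical tables
(`random.Random`, no global state).

What the generator does **not** emulate: taxonomic hierarchy, realistic
name strings, scheme-correlated coverage, or resolution noise that
produces *partially* overlapping identifier sets for distinct concepts.
Passing the synthetic suite therefore certifies the algorithmic machinery
(join correctness, audit completeness, metric conservation), not the
biological interpretation of links on real archives.

## Numerical and design choices

* All outputs are byte-deterministic: rows sort by (taxonId, externalId),
  links by (taxonIdA, taxonIdB), audit records by (taxon, scheme); the
  pipeline report's provenance timestamp is the only run-varying field and
  appears in no data file.
* Empty inputs are valid everywhere and produce empty outputs, exit 0.
* Degenerate joins: joining a table with itself is rejected (a
  consistency audit is the meaningful self-check); a relaxed flag exists
  for testing against renamed copies.
* Overlap fractions with an empty denominator are defined as 0; the
  reference row of the count matrix is pinned at 100 %.
* The full-scale pipeline run against the pinned archives (Wikidata dump,
  OTT 3.0, GloBI taxon graph v0.4.2, fetched by
  `scripts/fetch_archives.sh`) is implemented by `run_pipeline` /
  `taxograph run` but is not part of the test suite: it requires ≈ 20 GB
  of downloads and hours of streaming. Desk-scale validation instead uses
  the worked micro-examples and the synthetic ground truth, at sizes
  chosen to keep the whole suite under a minute: 200 random worlds of
  ≤ 100 taxa for oracle equivalence, 20 worlds of 500 taxa for recovery,
  4 000 taxa for the conflict-rate convergence check.

## Known limitations

* The pairwise audit attributes each clash to the A-side taxon with the
  B-side as partner; it does not adjudicate which side is wrong —
  authority ranking is out of scope.
* Identifier values are compared verbatim; URL-form identifiers are not
  auto-converted to CURIEs (readers are responsible for emitting CURIEs).
* Only the 4-column GloBI taxon-graph dialect is read; other files in the
  GloBI release (taxonCache variants) would need additional readers.
* Name-string similarity plays no role anywhere by design; resources whose
  graphs share no external identifiers cannot be linked by this method.
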