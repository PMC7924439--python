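"""Synthetic multi-resource taxon graphs with exact ground truth.

The generator emulates the statistical structure the linking and auditing
methods assume: a pool of true underlying taxa, each holding one canonical
external identifier per scheme; several resources that each cover a random
subset of the taxa and record a random subset of each covered taxon's
scheme links; and occasional planted conflicts, where a resource attaches a
second, wrong same-scheme identifier to a taxon (emulating synonymy and
name-resolution bugs).

Two constructions make the ground truth exact rather than probabilistic:

* canonical identifier values are drawn from disjoint integer ranges per
  scheme, so two schemes (or two taxa) can never collide by accident;
* conflicting second identifiers come from a reserved "wrong" range that is
  never used as a canonical value, so a planted conflict can never silently
  create a true cross-link.

The module also ships ``example_fixtures()``: three micro-tables encoding
well-known worked examples (*Panthera leo* WD:Q140 → ITIS:183803, the
consistent Procladius triple WD:Q7247420 / OTT:1087695, and the
inconsistent GloBI keys for *Procladius sp1 M_PL_014* and *Senecio
pectinatus*) that exercise every code path end to end on inspectable data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .audit import InconsistencyRecord
from .idmodel import JOIN_SCHEMES, ExternalId
from .linker import CrossLink
from .readers import LookupTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "example_fixtures"]

# Disjoint value ranges: scheme i owns [(i+1)*10^7, (i+2)*10^7); within a
# scheme, canonical values sit below the +5*10^6 midpoint and planted-wrong
# values above it, so wrong IDs never equal any canonical ID.
_SCHEME_BLOCK = 10_000_000
_WRONG_OFFSET = 5_000_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-resource world.

    coverage:
        Probability a true taxon appears in a resource (scalar, or a
        mapping per resource token).  Default 0.8 — the reference
        resources each cover most but not all of the shared taxon space.
    link_prob:
        Probability a covered taxon carries an identifier in a given scheme
        (scalar or per-scheme mapping).  Default 0.6, which makes two or
        more links per taxon the typical case, as observed in large
        aggregated taxon graphs.
    conflict_rate:
        Probability a covered, linked taxon additionally receives a wrong
        same-scheme identifier.  Default 0.05 — inconsistencies are rare
        relative to clean links in curated resources.
    """

    n_taxa: int = 500
    resources: Sequence[str] = ("R1", "R2", "R3")
    coverage: float | Mapping[str, float] = 0.8
    link_prob: float | Mapping[str, float] = 0.6
    schemes: Sequence[str] = tuple(sorted(JOIN_SCHEMES))
    conflict_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not self.resources:
            raise ValueError("at least one resource is required")
        if len(set(self.resources)) != len(self.resources):
            raise ValueError("resource tokens must be distinct")
        if not self.schemes:
            raise ValueError("at least one scheme is required")
        for p in (*self._coverages().values(), *self._link_probs().values(), self.conflict_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")

    def _coverages(self) -> dict[str, float]:
        if isinstance(self.coverage, Mapping):
            return {r: self.coverage.get(r, 0.0) for r in self.resources}
        return {r: float(self.coverage) for r in self.resources}

    def _link_probs(self) -> dict[str, float]:
        if isinstance(self.link_prob, Mapping):
            return {s: self.link_prob.get(s, 0.0) for s in self.schemes}
        return {s: float(self.link_prob) for s in self.schemes}


@dataclass(frozen=True)
class GroundTruth:
    """The generator's bookkeeping: what a perfect analysis must recover."""

    #: (resource_a, resource_b) → the exact cross-link set a join must find.
    cross_links: Mapping[tuple[str, str], frozenset[CrossLink]]
    #: resource → the planted same-scheme conflicts, as audit records.
    conflicts: Mapping[str, tuple[InconsistencyRecord, ...]]


def _canonical_value(scheme_index: int, taxon: int) -> str:
    return str((scheme_index + 1) * _SCHEME_BLOCK + taxon)


def generate(spec: SyntheticSpec) -> tuple[list[LookupTable], GroundTruth]:
    """Generate one lookup table per resource plus exact ground truth.

    Identical spec (including seed) yields byte-identical tables.  The
    ground truth enumerates, for every ordered resource pair, the
    cross-links an identifier join over ``spec.schemes`` must produce, and,
    per resource, the planted conflicts a consistency audit must flag.
    """
    rng = random.Random(spec.seed)
    coverages = spec._coverages()
    link_probs = spec._link_probs()
    scheme_index = {s: i for i, s in enumerate(spec.schemes)}

    tables: dict[str, LookupTable] = {}
    # resource -> taxon index -> {scheme: canonical ExternalId}
    linked: dict[str, dict[int, dict[str, ExternalId]]] = {}
    conflicts: dict[str, list[InconsistencyRecord]] = {r: [] for r in spec.resources}
    wrong_counter = 0

    for resource in spec.resources:
        table = LookupTable(resource, provenance=f"synthetic seed={spec.seed}")
        linked[resource] = {}
        for t in range(spec.n_taxa):
            if rng.random() >= coverages[resource]:
                continue
            taxon = ExternalId(resource, str(t + 1))
            name = f"Taxon synthetica {t + 1}"
            taxon_links: dict[str, ExternalId] = {}
            for scheme in spec.schemes:
                if rng.random() < link_probs[scheme]:
                    ext = ExternalId(scheme, _canonical_value(scheme_index[scheme], t))
                    table.add(taxon, ext, name)
                    taxon_links[scheme] = ext
            if taxon_links:
                linked[resource][t] = taxon_links
                if rng.random() < spec.conflict_rate:
                    scheme = rng.choice(sorted(taxon_links))
                    wrong_counter += 1
                    wrong = ExternalId(
                        scheme,
                        str(
                            (scheme_index[scheme] + 1) * _SCHEME_BLOCK
                            + _WRONG_OFFSET
                            + wrong_counter
                        ),
                    )
                    table.add(taxon, wrong, name)
                    conflicts[resource].append(
                        InconsistencyRecord(
                            taxon_id=taxon,
                            scheme=scheme,
                            values=frozenset({taxon_links[scheme].value, wrong.value}),
                            names=frozenset({name}),
                        )
                    )
        tables[resource] = table

    cross_links: dict[tuple[str, str], frozenset[CrossLink]] = {}
    for i, ra in enumerate(spec.resources):
        for rb in spec.resources[i + 1 :]:
            links = set()
            for t, links_a in linked[ra].items():
                links_b = linked[rb].get(t)
                if not links_b:
                    continue
                shared = {
                    links_a[s] for s in links_a.keys() & links_b.keys()
                }
                if shared:
                    links.add(
                        CrossLink(
                            ExternalId(ra, str(t + 1)),
                            ExternalId(rb, str(t + 1)),
                            frozenset(shared),
                        )
                    )
            cross_links[(ra, rb)] = frozenset(links)
            cross_links[(rb, ra)] = frozenset(l.swapped() for l in links)

    truth = GroundTruth(
        cross_links=cross_links,
        conflicts={r: tuple(v) for r, v in conflicts.items()},
    )
    return [tables[r] for r in spec.resources], truth


def example_fixtures() -> dict[str, LookupTable]:
    """Three micro-tables of well-known taxa for worked examples and tests.

    * ``wd``: *Panthera leo* (WD:Q140 → ITIS:183803) and the midge genus
      *Procladius* (WD:Q7247420 → WoRMS, GBIF, and NCBI records);
    * ``ott``: the same *Procladius* concept (OTT:1087695) carrying the
      identical three external identifiers — overlapping and consistent;
    * ``globi``: two name-resolution pathologies — the provisional name
      *Procladius sp1 M_PL_014* mapped to six distinct NCBI taxa, and the
      outdated name *Senecio pectinatus* mapped to two GBIF keys — both of
      which a consistency audit must flag.
    """
    wd = LookupTable("WD", "example fixture")
    q140 = ExternalId("WD", "Q140")
    wd.add(q140, ExternalId("ITIS", "183803"), "Panthera leo")
    q7247420 = ExternalId("WD", "Q7247420")
    for ext in (("WORMS", "156905"), ("GBIF", "1449280"), ("NCBI", "191633")):
        wd.add(q7247420, ExternalId(*ext), "Procladius")

    ott = LookupTable("OTT", "example fixture")
    ott_procladius = ExternalId("OTT", "1087695")
    for ext in (("NCBI", "191633"), ("WORMS", "156905"), ("GBIF", "1449280")):
        ott.add(ott_procladius, ExternalId(*ext), "Procladius")

    globi = LookupTable("GLOBI", "example fixture")
    procladius_sp1 = ExternalId("GLOBI", "null@Procladius sp1 M_PL_014")
    for value in ("1981571", "1981569", "1981572", "1981573", "1981574", "1981570"):
        globi.add(procladius_sp1, ExternalId("NCBI", value), "Procladius sp1 M_PL_014")
    senecio = ExternalId("GLOBI", "null@Senecio pectinatus")
    for value in ("8317096", "8414746"):
        globi.add(senecio, ExternalId("GBIF", value), "Senecio pectinatus")

    return {"wd": wd, "ott": ott, "globi": globi}
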