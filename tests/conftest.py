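"""Shared fixtures: in-memory source-file builders and the brute-force join oracle."""

from __future__ import annotations

import json

import pytest

from taxograph import ExternalId, LookupTable, example_fixtures
from taxograph.linker import CrossLink


def wd_entity(
    qid: str,
    taxon: bool = True,
    name: str | None = None,
    ids: dict[str, list[str]] | None = None,
    deprecated: dict[str, list[str]] | None = None,
) -> str:
    """One Wikidata entity as a dump line. ``ids`` maps property → values."""

    def claim(value, rank="normal"):
        return {"mainsnak": {"datavalue": {"value": value}}, "rank": rank}

    claims: dict[str, list] = {}
    if taxon:
        claims["P31"] = [claim({"id": "Q16521"})]
    else:
        claims["P31"] = [claim({"id": "Q5"})]
    if name is not None:
        claims["P225"] = [claim(name)]
    for prop, values in (ids or {}).items():
        claims.setdefault(prop, []).extend(claim(v) for v in values)
    for prop, values in (deprecated or {}).items():
        claims.setdefault(prop, []).extend(claim(v, rank="deprecated") for v in values)
    return json.dumps({"id": qid, "claims": claims})


def make_table(resource: str, rows: list[tuple[str, str | None, str]]) -> LookupTable:
    """Build a LookupTable from ("SCHEME:val", name, "SCHEME:val") triples."""
    from taxograph import parse_curie

    table = LookupTable(resource, "test")
    for taxon_s, name, ext_s in rows:
        table.add(parse_curie(taxon_s), parse_curie(ext_s), name)
    return table


def brute_force_join(a: LookupTable, b: LookupTable, schemes) -> set[CrossLink]:
    """O(n²) all-pairs oracle: compare every taxon pair's external-ID sets."""
    wanted = frozenset(schemes)
    out = set()
    for ta in a.taxa():
        ids_a = a.ids_of(ta, wanted)
        for tb in b.taxa():
            shared = ids_a & b.ids_of(tb, wanted)
            if shared:
                out.add(CrossLink(ta, tb, frozenset(shared)))
    return out


@pytest.fixture
def fixtures() -> dict[str, LookupTable]:
    return example_fixtures()


@pytest.fixture
def wd_table(fixtures):
    return fixtures["wd"]


@pytest.fixture
def ott_table(fixtures):
    return fixtures["ott"]


@pytest.fixture
def globi_table(fixtures):
    return fixtures["globi"]
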