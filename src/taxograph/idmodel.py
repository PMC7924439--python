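"""Canonical identifier model shared by every reader and metric.

Biodiversity resources label the same taxon with identifiers minted by many
different databases: an NCBI taxid, an ITIS TSN, a GBIF usage key, an EOL
page ID, an Index Fungorum number, a FishBase species code, a WoRMS AphiaID.
Everything in this package manipulates those identifiers as CURIEs —
compact ``SCHEME:value`` strings such as ``ITIS:183803`` — after the scheme
prefix has been normalized to a canonical token.  This module defines the
identifier atom (:class:`ExternalId`), the normalization rules
(:class:`SchemeRegistry`), and the two scheme sets the methods operate on:

* *join schemes* — NCBI, ITIS, GBIF, EOL, IF, FISHBASE, WORMS — used when
  two resources' lookup tables are equi-joined on shared identifiers;
* *audit schemes* — NCBI, GBIF, IF, WORMS — the subset used for the
  overlap, Venn, and consistency metrics.

Values are opaque strings and case-sensitive; scheme tokens are
case-insensitive on input and canonicalized to upper case.  Unknown scheme
prefixes are never an error: they pass through upper-cased and flagged, so
a drifted input file degrades to countable noise rather than an abort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "JOIN_SCHEMES",
    "AUDIT_SCHEMES",
    "RESOURCE_SCHEMES",
    "ExternalId",
    "SchemeRegistry",
    "CurieParseError",
    "parse_curie",
    "normalize_scheme",
]

#: The seven schemes used when joining two lookup tables.
JOIN_SCHEMES = frozenset({"NCBI", "ITIS", "GBIF", "EOL", "IF", "FISHBASE", "WORMS"})

#: The four schemes used for overlap / Venn / consistency metrics.
AUDIT_SCHEMES = frozenset({"NCBI", "GBIF", "IF", "WORMS"})

#: Schemes that name whole resources (they mint the local taxon IDs).
RESOURCE_SCHEMES = frozenset({"WD", "OTT", "GLOBI"})

#: Schemes that occur in source files but are neither joined nor audited by
#: default (they are still recognized so they can be counted).
AUXILIARY_SCHEMES = frozenset({"SILVA", "IRMNG", "INATURALIST"})

_KNOWN_SCHEMES = JOIN_SCHEMES | AUDIT_SCHEMES | RESOURCE_SCHEMES | AUXILIARY_SCHEMES

#: Raw-token → canonical-token alias table.  Lookup is case-insensitive, so
#: only aliases that differ by more than case need an entry.
DEFAULT_ALIASES: Mapping[str, str] = {
    "indexfungorum": "IF",
    "index fungorum": "IF",
    "fb": "FISHBASE",
    "wikidata": "WD",
    "opentree": "OTT",
    "inat": "INATURALIST",
}


class CurieParseError(ValueError):
    """Raised when a string cannot be interpreted as ``SCHEME:value``."""


@dataclass(frozen=True, slots=True, order=True)
class ExternalId:
    """A single identifier: a (scheme, value) pair such as (ITIS, "183803").

    Equality and hashing are plain field equality, so two identifiers with
    the same serialization compare equal.  The value is opaque: numeric for
    most schemes, ``Q``-prefixed for Wikidata items, and free text for
    synthesized GloBI keys like ``GLOBI:null@Procladius sp1 M_PL_014``.
    """

    scheme: str
    value: str

    def __str__(self) -> str:
        return f"{self.scheme}:{self.value}"

    @property
    def curie(self) -> str:
        """The ``SCHEME:value`` text form used on disk and on the CLI."""
        return str(self)


class SchemeRegistry:
    """Maps raw scheme tokens from source files onto canonical tokens.

    The registry is total: a token it does not recognize is returned
    upper-cased and flagged unknown rather than raising, because entity
    dumps routinely contain identifier schemes outside the target set.

    Parameters
    ----------
    aliases:
        Extra raw→canonical entries merged over :data:`DEFAULT_ALIASES`.
    join_schemes, audit_schemes:
        Override the default scheme sets; audit schemes must be a subset of
        join schemes.
    """

    def __init__(
        self,
        aliases: Mapping[str, str] | None = None,
        join_schemes: Iterable[str] = JOIN_SCHEMES,
        audit_schemes: Iterable[str] = AUDIT_SCHEMES,
    ) -> None:
        self._aliases = {k.strip().lower(): v for k, v in DEFAULT_ALIASES.items()}
        if aliases:
            self._aliases.update({k.strip().lower(): v.strip().upper() for k, v in aliases.items()})
        self.join_schemes = frozenset(join_schemes)
        self.audit_schemes = frozenset(audit_schemes)
        if not self.audit_schemes <= self.join_schemes:
            raise ValueError(
                "audit schemes must be a subset of join schemes: "
                f"{sorted(self.audit_schemes - self.join_schemes)} are not"
            )
        self._known = frozenset(_KNOWN_SCHEMES | self.join_schemes | set(self._aliases.values()))

    def normalize(self, raw: str) -> str:
        """Canonical scheme token for ``raw`` (case-insensitive; total)."""
        token, _ = self.normalize_flagged(raw)
        return token

    def normalize_flagged(self, raw: str) -> tuple[str, bool]:
        """Like :meth:`normalize` but also reports whether the token is known.

        Returns ``(token, known)``; unknown raw tokens pass through
        upper-cased with ``known=False``.
        """
        key = raw.strip()
        if not key:
            raise ValueError("scheme token must be non-empty")
        token = self._aliases.get(key.lower(), key.upper())
        return token, token in self._known

    def is_known(self, token: str) -> bool:
        return token in self._known


_DEFAULT_REGISTRY = SchemeRegistry()


def default_registry() -> SchemeRegistry:
    """The registry with the stock alias table and scheme sets."""
    return _DEFAULT_REGISTRY


def normalize_scheme(raw: str, registry: SchemeRegistry | None = None) -> str:
    """Normalize a raw scheme token; unknown tokens pass through upper-cased."""
    return (registry or _DEFAULT_REGISTRY).normalize(raw)


def parse_curie(text: str, registry: SchemeRegistry | None = None) -> ExternalId:
    """Parse ``SCHEME:value`` into an :class:`ExternalId`.

    The split is on the FIRST colon only, so values may themselves contain
    colons, ``@`` or spaces (GloBI synthesizes keys like
    ``GLOBI:null@Procladius sp1 M_PL_014``).  Scheme and value are trimmed
    of leading/trailing whitespace; interior whitespace is preserved.

    Raises
    ------
    CurieParseError
        If there is no colon, or the prefix or value is empty.
    """
    reg = registry or _DEFAULT_REGISTRY
    head, sep, tail = text.partition(":")
    scheme_raw = head.strip()
    value = tail.strip()
    if not sep or not scheme_raw or not value:
        raise CurieParseError(f"not a SCHEME:value identifier: {text!r}")
    return ExternalId(reg.normalize(scheme_raw), value)
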