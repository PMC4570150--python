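"""Two-level disambiguation of sequence-metadata location strings.

A country qualifier is assumed to follow the ``Country: Location`` layout of
the public nucleotide databases. Resolution runs in two passes:

1. *Country*: the part before the first colon is matched against country
   names and alternatives. Historical countries (Yugoslavia, USSR, ...) are
   rescued through the location part when it names a place in a successor
   country, otherwise discarded. Water bodies are discarded unless the
   location part itself names a country — and discarded outright when the
   location part is also a water body.
2. *Region*: the location part is split into candidate substrings (each
   comma/semicolon-delimited chunk, plus the chunk's individual whitespace
   tokens) and each candidate is matched against the tiered place dictionary;
   the highest-tier match wins. At equal tier, a whole-chunk match beats a
   single-token match, then the leftmost candidate wins.

Countries with no administrative divisions skip the region pass.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .gazetteer import TIER_RANK, CountryKind, Gazetteer

logger = logging.getLogger(__name__)

_CHUNK_SEP = re.compile(r"[,;:]")


class Status(str, Enum):
    COUNTRY_AND_REGION = "country_and_region"
    COUNTRY_ONLY = "country_only"
    DISCARDED = "discarded"


class Reason(str, Enum):
    OK = "ok"
    HISTORICAL_UNRESOLVABLE = "historical_unresolvable"
    WATER_BODY = "water_body"
    NO_MATCH = "no_match"
    NO_REGION_COUNTRY = "no_region_country"


@dataclass(frozen=True)
class LocationAssignment:
    raw: str
    country: str | None
    region: str | None
    status: Status
    reason: Reason


def split_location(raw: str) -> tuple[str, str | None]:
    """Split ``"Country: Location"`` at the first colon; both parts trimmed.
    Without a colon the whole string is the country part."""
    head, sep, tail = raw.partition(":")
    if not sep:
        return head.strip(), None
    return head.strip(), tail.strip() or None


def _candidates(location_part: str) -> list[tuple[str, bool]]:
    """Candidate substrings as (text, is_whole_chunk), left to right; each
    delimiter-bounded chunk first, then its individual tokens."""
    out: list[tuple[str, bool]] = []
    for chunk in _CHUNK_SEP.split(location_part):
        chunk = chunk.strip()
        if not chunk:
            continue
        out.append((chunk, True))
        tokens = chunk.split()
        if len(tokens) > 1:
            out.extend((tok, False) for tok in tokens)
    return out


class Geolocator:
    def __init__(self, gazetteer: Gazetteer) -> None:
        self.gazetteer = gazetteer

    def resolve(self, raw: str) -> LocationAssignment:
        """Full two-level resolution of one raw country-qualifier string."""
        country_part, location_part = split_location(raw)
        country, reason = self.resolve_country(country_part, location_part)
        if country is None:
            return LocationAssignment(raw, None, None, Status.DISCARDED, reason)
        if not self.gazetteer.has_regions(country):
            return LocationAssignment(
                raw, country, None, Status.COUNTRY_ONLY, Reason.NO_REGION_COUNTRY
            )
        if location_part is None:
            return LocationAssignment(raw, country, None, Status.COUNTRY_ONLY, Reason.OK)
        region = self.resolve_region(country, location_part)
        if region is None:
            return LocationAssignment(raw, country, None, Status.COUNTRY_ONLY, Reason.OK)
        return LocationAssignment(raw, country, region, Status.COUNTRY_AND_REGION, Reason.OK)

    def resolve_country(
        self, country_part: str, location_part: str | None
    ) -> tuple[str | None, Reason]:
        """Country-level pass; returns (canonical country or None, reason)."""
        gaz = self.gazetteer
        match = gaz.lookup_country(country_part)
        if match is None:
            return None, Reason.NO_MATCH
        if match.kind == CountryKind.COUNTRY:
            self._log_contradiction(match.canonical, location_part)
            return match.canonical, Reason.OK
        if match.kind == CountryKind.HISTORICAL:
            if location_part:
                resolved = self._successor_country(match.successors, location_part)
                if resolved is not None:
                    return resolved, Reason.OK
            return None, Reason.HISTORICAL_UNRESOLVABLE
        # water body
        if location_part:
            country_hit: str | None = None
            for cand, _ in _candidates(location_part):
                if gaz.is_water_body(cand):
                    return None, Reason.WATER_BODY
                cm = gaz.lookup_country(cand)
                if cm is not None and cm.kind == CountryKind.COUNTRY and country_hit is None:
                    country_hit = cm.canonical
            if country_hit is not None:
                return country_hit, Reason.OK
        return None, Reason.WATER_BODY

    def resolve_region(self, country: str, location_part: str) -> str | None:
        """Tiered region pass within a resolved country."""
        best: tuple[int, int, int, str] | None = None
        for idx, (cand, is_chunk) in enumerate(_candidates(location_part)):
            for match in self.gazetteer.lookup_place(cand, country)[:1]:
                key = (TIER_RANK[match.tier], 0 if is_chunk else 1, idx, match.region)
                if best is None or key < best:
                    best = key
        return best[3] if best else None

    def _successor_country(
        self, successors: tuple[str, ...], location_part: str
    ) -> str | None:
        """Identify a present-day country from the location part of a
        historical-country string: the leftmost candidate naming a successor
        country, or a place within one, wins."""
        gaz = self.gazetteer
        for cand, _ in _candidates(location_part):
            cm = gaz.lookup_country(cand)
            if cm is not None and cm.kind == CountryKind.COUNTRY and cm.canonical in successors:
                return cm.canonical
            for successor in successors:
                if gaz.lookup_place(cand, successor):
                    return successor
        return None

    def _log_contradiction(self, country: str, location_part: str | None) -> None:
        """Rare ambiguous tags like "USA: Japan" resolve by the country part;
        the contradiction is logged for audit."""
        if not location_part:
            return
        for cand, is_chunk in _candidates(location_part):
            if not is_chunk:
                continue
            cm = self.gazetteer.lookup_country(cand)
            if cm is not None and cm.kind == CountryKind.COUNTRY and cm.canonical != country:
                logger.warning(
                    "location part %r names country %s but tag country is %s; keeping %s",
                    cand, cm.canonical, country, country,
                )
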