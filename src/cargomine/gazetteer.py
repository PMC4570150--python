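"""Geographic dictionary: countries (with alternative and historical names
and water bodies) and tiered sub-country place names mapped to their first
administrative division ("region").

Input is a TSV with columns ``name, tier, country, region, mesh_listed``:

* ``country`` rows: one row per name; ``country`` holds the canonical name
  (so alternative names are extra rows pointing at it); ``mesh_listed`` is
  1 on the canonical row when the country is a MeSH heading.
* ``historical_country`` rows: the ``country`` column holds a
  semicolon-joined list of present-day successor countries, in priority
  order. (Which successors to use is configuration, carried in the data.)
* ``water_body`` rows: no country, no region.
* place rows (``admin1``, ``capital``, ``admin2``, ``admin3``, ``city``,
  ``town``, ``village``, ``state_code``): ``country`` and ``region`` name
  the owning country and admin1 region. ``state_code`` entries match only as
  raw uppercase 2-3 letter tokens and resolve at admin1 rank.

A country with no place rows at all is treated as having no administrative
divisions (region identification is skipped for it).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from ._text import normalize


class Tier(str, Enum):
    COUNTRY = "country"
    HISTORICAL_COUNTRY = "historical_country"
    WATER_BODY = "water_body"
    STATE_CODE = "state_code"
    ADMIN1 = "admin1"
    CAPITAL = "capital"
    ADMIN2 = "admin2"
    ADMIN3 = "admin3"
    CITY = "city"
    TOWN = "town"
    VILLAGE = "village"


#: matching priority among sub-country tiers; lower = higher priority.
#: state codes resolve at admin1 rank.
TIER_RANK: dict[Tier, int] = {
    Tier.ADMIN1: 0,
    Tier.STATE_CODE: 0,
    Tier.CAPITAL: 1,
    Tier.ADMIN2: 2,
    Tier.ADMIN3: 3,
    Tier.CITY: 4,
    Tier.TOWN: 5,
    Tier.VILLAGE: 6,
}


@dataclass(frozen=True)
class GazetteerEntry:
    name: str
    tier: Tier
    country: str | None = None
    region: str | None = None
    mesh_listed: bool = False


class CountryKind(str, Enum):
    COUNTRY = "country"
    HISTORICAL = "historical"
    WATER_BODY = "water_body"


@dataclass(frozen=True)
class CountryMatch:
    kind: CountryKind
    canonical: str | None = None
    successors: tuple[str, ...] = ()


@dataclass(frozen=True)
class PlaceMatch:
    tier: Tier
    region: str


@dataclass
class _CountryInfo:
    canonical: str
    mesh_listed: bool = False
    names: list[str] = field(default_factory=list)  # official first, then alternatives


class Gazetteer:
    def __init__(self) -> None:
        self._countries: dict[str, str] = {}  # normalized name -> canonical
        self._country_info: dict[str, _CountryInfo] = {}  # canonical -> info
        self._historical: dict[str, tuple[str, tuple[str, ...]]] = {}
        self._water: dict[str, str] = {}
        # canonical country -> normalized place name -> [(rank, order, PlaceMatch)]
        self._places: dict[str, dict[str, list[tuple[int, int, PlaceMatch]]]] = {}
        self._state_codes: dict[str, dict[str, str]] = {}  # country -> CODE -> region
        self._order = 0

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Gazetteer":
        gaz = cls()
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                row = row + [""] * (5 - len(row))
                name, tier, country, region, mesh = (c.strip() for c in row[:5])
                gaz.add_entry(
                    GazetteerEntry(
                        name=name,
                        tier=Tier(tier),
                        country=country or None,
                        region=region or None,
                        mesh_listed=mesh in ("1", "true", "True"),
                    )
                )
        return gaz

    def add_entry(self, entry: GazetteerEntry) -> None:
        if entry.tier == Tier.COUNTRY:
            canonical = entry.country or entry.name
            self._countries[normalize(entry.name)] = canonical
            info = self._country_info.setdefault(canonical, _CountryInfo(canonical))
            if entry.name == canonical:
                info.mesh_listed = info.mesh_listed or entry.mesh_listed
                info.names.insert(0, entry.name)
            else:
                info.names.append(entry.name)
        elif entry.tier == Tier.HISTORICAL_COUNTRY:
            successors = tuple(
                s.strip() for s in (entry.country or "").split(";") if s.strip()
            )
            self._historical[normalize(entry.name)] = (entry.name, successors)
        elif entry.tier == Tier.WATER_BODY:
            self._water[normalize(entry.name)] = entry.name
        else:
            if entry.country is None or entry.region is None:
                raise ValueError(f"place entry {entry.name!r} needs country and region")
            if entry.tier == Tier.STATE_CODE:
                self._state_codes.setdefault(entry.country, {})[entry.name] = entry.region
            else:
                bucket = self._places.setdefault(entry.country, {})
                match = PlaceMatch(tier=entry.tier, region=entry.region)
                bucket.setdefault(normalize(entry.name), []).append(
                    (TIER_RANK[entry.tier], self._order, match)
                )
                self._order += 1

    # -- lookups ----------------------------------------------------------

    def lookup_country(self, token: str) -> CountryMatch | None:
        """Classify a token as a country, historical country or water body.

        Alternative country names resolve to the canonical name; no match
        returns None (a valid outcome, not an error).
        """
        key = normalize(token)
        if not key:
            return None
        if key in self._countries:
            return CountryMatch(CountryKind.COUNTRY, canonical=self._countries[key])
        if key in self._historical:
            name, successors = self._historical[key]
            return CountryMatch(CountryKind.HISTORICAL, canonical=name, successors=successors)
        if key in self._water:
            return CountryMatch(CountryKind.WATER_BODY, canonical=self._water[key])
        return None

    def lookup_place(self, token: str, country: str) -> list[PlaceMatch]:
        """All place entries matching ``token`` within ``country``, highest
        tier first (ties broken by insertion order).

        State codes are consulted only when the raw token is a whole
        uppercase 2-3 letter string, before normalisation, so that e.g. the
        "ma" inside "Palma" can never hit MA/Massachusetts.
        """
        results: list[tuple[int, int, PlaceMatch]] = []
        if 2 <= len(token) <= 3 and token.isalpha() and token.isupper():
            region = self._state_codes.get(country, {}).get(token)
            if region is not None:
                results.append((TIER_RANK[Tier.STATE_CODE], -1, PlaceMatch(Tier.STATE_CODE, region)))
        bucket = self._places.get(country, {})
        results.extend(bucket.get(normalize(token), []))
        results.sort(key=lambda t: (t[0], t[1]))
        return [m for _, _, m in results]

    def has_regions(self, country: str) -> bool:
        """False for countries with no sub-country entries (no administrative
        divisions / small countries), for which region lookup is skipped."""
        return bool(self._places.get(country)) or bool(self._state_codes.get(country))

    def mesh_listed(self, country: str) -> bool:
        return self._country_info[country].mesh_listed

    def country_names(self, country: str) -> list[str]:
        """Official name first, then alternative names, insertion order."""
        return list(self._country_info[country].names)

    def countries(self) -> list[str]:
        return list(self._country_info)

    def regions_of(self, country: str) -> list[str]:
        seen: dict[str, None] = {}
        for matches in self._places.get(country, {}).values():
            for _, _, m in sorted(matches, key=lambda t: (t[0], t[1])):
                seen.setdefault(m.region)
        for region in self._state_codes.get(country, {}).values():
            seen.setdefault(region)
        return list(seen)

    def is_water_body(self, token: str) -> bool:
        return normalize(token) in self._water
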