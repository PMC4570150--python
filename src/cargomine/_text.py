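"""Text normalisation shared by the taxonomy and gazetteer matchers.

Sequence metadata qualifiers are free text, so every dictionary match key is
reduced to a canonical form: diacritics stripped, case-folded, outer
punctuation removed, internal whitespace collapsed. Normalisation is
idempotent (``normalize(normalize(s)) == normalize(s)``), which the matching
code relies on: an already-normalised key looks itself up unchanged.
"""

from __future__ import annotations

import re
import string
import unicodedata

_WS = re.compile(r"\s+")
_EDGE = string.punctuation + string.whitespace


def strip_diacritics(text: str) -> str:
    """Decompose to NFKD and drop combining marks ("São" -> "Sao")."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize(text: str) -> str:
    """Canonical match key: fold case, strip accents and outer punctuation,
    collapse runs of whitespace to single spaces."""
    text = strip_diacritics(text).casefold()
    text = text.strip(_EDGE)
    return _WS.sub(" ", text)
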