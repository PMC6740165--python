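"""Preprocessing rules for raw categorical laboratory result values.

Three rule families are applied before any categorization or matching:

1. **General cleaning** — lowercase, strip outer whitespace, collapse internal
   whitespace runs, and normalize dash variants (en/em dash, Unicode minus)
   to the ASCII hyphen, the only dash in the vectorization scheme.
2. **Rh abbreviation correction** — in blood-type test context, a bare ``-``
   or ``+`` result is an Rh finding and is rewritten ``rh-`` / ``rh+`` so it
   cannot collide with the ``-``/``+`` notations of other tests.
3. **Dipstick grade formatting** — urinalysis grades written ``1+``..``4+``
   are rewritten to the repeated-plus form (``4+`` -> ``++++``).

All rules are total and idempotent; junk values (``****``, ``_^``) pass
through unchanged and are handled downstream as unmappable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["CleanValue", "general_clean", "rh_correct", "dipstick_format", "clean_pipeline"]

# en dash, em dash, figure dash, horizontal bar, hyphen variants, minus sign
_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")

_WS_RUN = re.compile(r"\s+")
# a digit grade 1-4 followed by '+', as its own whitespace-delimited token
_GRADE_TOKEN = re.compile(r"(?<!\S)([1-4])\+(?!\S)")


@dataclass(frozen=True)
class CleanValue:
    """A normalized result string plus the ordered rule names applied to it."""

    text: str
    provenance: tuple[str, ...] = field(default=())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def _clean_text(raw: str) -> str:
    return _WS_RUN.sub(" ", raw.translate(_DASHES).lower()).strip()


def general_clean(raw: str | CleanValue) -> CleanValue:
    """Lowercase, trim, collapse whitespace and normalize dashes.

    Total: any input (including the empty string) yields a ``CleanValue``.
    """
    text = raw.text if isinstance(raw, CleanValue) else raw
    return CleanValue(_clean_text(text), ("general_clean",))


def rh_correct(value: CleanValue, blood_type_context: bool) -> CleanValue:
    """Rewrite a bare ``-``/``+`` to ``rh-``/``rh+`` for blood-type tests.

    Scoped strictly to blood-type test context and to values that are exactly
    one sign character; everything else is returned unchanged.
    """
    if blood_type_context and value.text in ("-", "+"):
        return CleanValue("rh" + value.text, value.provenance + ("rh_correct",))
    return value


def dipstick_format(value: CleanValue) -> CleanValue:
    """Rewrite digit-grade dipstick tokens: ``4+`` -> ``++++``, ``250 4+`` -> ``250 ++++``.

    Only whole tokens of the form *k*``+`` with k in 1..4 are rewritten;
    concentration prefixes and all other tokens are untouched.
    """
    text = _GRADE_TOKEN.sub(lambda m: "+" * int(m.group(1)), value.text)
    if text == value.text:
        return value
    return CleanValue(text, value.provenance + ("dipstick_format",))


def clean_pipeline(raw: str | CleanValue, blood_type_context: bool = False) -> CleanValue:
    """Full preprocessing pass: general cleaning, Rh correction, dipstick formatting."""
    return dipstick_format(rh_correct(general_clean(raw), blood_type_context))
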