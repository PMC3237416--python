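"""The four-point ordinal causality scale shared by both instruments.

Adverse drug reaction (ADR) causality instruments place each suspected
case on the ordered scale Unlikely < Possible < Probable < Definite.
Both the Naranjo questionnaire and the Liverpool decision tree report on
this scale, which is what makes cross-instrument agreement statistics
meaningful.
"""

from __future__ import annotations

import enum


class CausalityCategory(enum.IntEnum):
    """Ordinal causality category; integer codes 1-4 give ordinal distance."""

    UNLIKELY = 1
    POSSIBLE = 2
    PROBABLE = 3
    DEFINITE = 4

    @property
    def label(self) -> str:
        return self.name.capitalize()

    def __str__(self) -> str:  # pragma: no cover - display sugar
        return self.label


#: Categories in ascending ordinal order.
CATEGORIES: tuple[CausalityCategory, ...] = tuple(CausalityCategory)

#: Number of scale points.
N_CATEGORIES: int = len(CATEGORIES)

_ALIASES = {c.name.lower(): c for c in CausalityCategory}
_ALIASES.update({str(int(c)): c for c in CausalityCategory})
# "doubtful" is the historical Naranjo label for the lowest category.
_ALIASES["doubtful"] = CausalityCategory.UNLIKELY


class CategoryParseError(ValueError):
    """An input token is not a recognised causality category."""


def parse_category(token: object) -> CausalityCategory:
    """Parse a category token (name, historical alias, or code 1-4).

    Matching is case-insensitive and ignores surrounding whitespace.

    Raises
    ------
    CategoryParseError
        If the token is not an admissible category.
    """
    if isinstance(token, CausalityCategory):
        return token
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        if float(token).is_integer() and 1 <= int(token) <= N_CATEGORIES:
            return CausalityCategory(int(token))
        raise CategoryParseError(f"unknown causality category code: {token!r}")
    key = str(token).strip().lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise CategoryParseError(
            f"unknown causality category token: {token!r} "
            f"(expected one of {sorted(set(a for a in _ALIASES if not a.isdigit()))} "
            f"or a code 1-{N_CATEGORIES})"
        ) from None


def ordinal_distance(a: CausalityCategory, b: CausalityCategory) -> int:
    """Number of scale steps between two categories (0-3)."""
    return abs(int(a) - int(b))
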