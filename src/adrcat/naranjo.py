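"""Scoring engine for the Naranjo ADR probability questionnaire.

The Naranjo instrument asks ten fixed questions about a suspected
adverse drug reaction; each answer (yes / no / don't-know) carries an
integer weight and the total score is mapped to the four-point causality
scale. The weight matrix and the score-to-category boundaries are data,
not code: the package ships the classical 1981 matrix as the default,
but variant dialects can be loaded from JSON.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .categories import CATEGORIES, CausalityCategory

QUESTION_IDS: tuple[str, ...] = tuple(f"Q{i}" for i in range(1, 11))


class Answer(enum.Enum):
    """Three-valued questionnaire answer."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


_ANSWER_ALIASES = {
    "yes": Answer.YES,
    "y": Answer.YES,
    "no": Answer.NO,
    "n": Answer.NO,
    "unknown": Answer.UNKNOWN,
    "dont know": Answer.UNKNOWN,
    "don't know": Answer.UNKNOWN,
    "dk": Answer.UNKNOWN,
    "na": Answer.UNKNOWN,
}


class AnswerSheetError(ValueError):
    """An answer sheet is incomplete or contains an inadmissible token."""


def parse_answer(token: object, question: str | None = None) -> Answer:
    """Parse a yes/no/unknown token (case-insensitive, whitespace-stripped)."""
    if isinstance(token, Answer):
        return token
    key = str(token).strip().lower()
    try:
        return _ANSWER_ALIASES[key]
    except KeyError:
        where = f" for question {question}" if question else ""
        raise AnswerSheetError(
            f"inadmissible answer token {token!r}{where}; expected yes, no or unknown"
        ) from None


@dataclass(frozen=True)
class NaranjoAnswerSheet:
    """Answers to all ten Naranjo questions for one case assessment."""

    answers: Mapping[str, Answer]

    def __post_init__(self) -> None:
        parsed = {}
        for qid in QUESTION_IDS:
            if qid not in self.answers:
                raise AnswerSheetError(f"missing answer for question {qid}")
            parsed[qid] = parse_answer(self.answers[qid], qid)
        extra = set(self.answers) - set(QUESTION_IDS)
        if extra:
            raise AnswerSheetError(f"unexpected question ids: {sorted(extra)}")
        object.__setattr__(self, "answers", parsed)

    @classmethod
    def uniform(cls, answer: Answer | str) -> "NaranjoAnswerSheet":
        """A sheet giving the same answer to every question (testing aid)."""
        a = parse_answer(answer)
        return cls({qid: a for qid in QUESTION_IDS})


@dataclass(frozen=True)
class NaranjoWeightTable:
    """Weight matrix plus score-to-category boundaries.

    ``weights[qid][answer]`` is the integer contribution of giving
    ``answer`` to question ``qid``. ``upper_bounds`` holds the inclusive
    upper total-score bound of each category except the highest, in
    ascending scale order.
    """

    weights: Mapping[str, Mapping[Answer, int]]
    upper_bounds: tuple[int, ...]
    name: str = "custom"
    questions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for qid in QUESTION_IDS:
            if qid not in self.weights:
                raise ValueError(f"weight table missing question {qid}")
            for ans in Answer:
                if ans not in self.weights[qid]:
                    raise ValueError(f"weight table missing ({qid}, {ans.value})")
        if len(self.upper_bounds) != len(CATEGORIES) - 1:
            raise ValueError(
                f"expected {len(CATEGORIES) - 1} category boundaries, "
                f"got {len(self.upper_bounds)}"
            )
        if any(b >= c for b, c in zip(self.upper_bounds, self.upper_bounds[1:])):
            raise ValueError("category boundaries must be strictly increasing")
        lo, hi = self.score_range()
        if not (lo <= self.upper_bounds[0] and self.upper_bounds[-1] < hi):
            raise ValueError(
                "boundaries do not partition the achievable score range "
                f"[{lo}, {hi}] into four non-empty cells"
            )

    def score_range(self) -> tuple[int, int]:
        """Minimum and maximum achievable totals under this table."""
        lo = sum(min(w.values()) for w in self.weights.values())
        hi = sum(max(w.values()) for w in self.weights.values())
        return lo, hi

    @classmethod
    def from_dict(cls, doc: Mapping) -> "NaranjoWeightTable":
        weights = {
            qid: {parse_answer(tok, qid): int(w) for tok, w in row.items()}
            for qid, row in doc["weights"].items()
        }
        bounds = doc["boundaries"]
        upper = tuple(int(bounds[c.name.lower()]) for c in CATEGORIES[:-1])
        return cls(
            weights=weights,
            upper_bounds=upper,
            name=doc.get("name", "custom"),
            questions=doc.get("questions", {}),
        )

    @classmethod
    def from_json(cls, path) -> "NaranjoWeightTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "NaranjoWeightTable":
        """The packaged classical weight matrix and boundaries."""
        doc = json.loads(
            resources.files("adrcat.data").joinpath("naranjo_default.json").read_text()
        )
        return cls.from_dict(doc)


@dataclass(frozen=True)
class NaranjoResult:
    """Total score and the causality category it maps to."""

    total: int
    category: CausalityCategory


def naranjo_score(
    sheet: NaranjoAnswerSheet, weights: NaranjoWeightTable | None = None
) -> int:
    """Total Naranjo score: the sum of the per-question answer weights."""
    weights = weights or NaranjoWeightTable.default()
    return sum(weights.weights[qid][sheet.answers[qid]] for qid in QUESTION_IDS)


def naranjo_categorise(
    total: int, weights: NaranjoWeightTable | None = None
) -> CausalityCategory:
    """Map a total score to its causality category via the boundary partition."""
    weights = weights or NaranjoWeightTable.default()
    lo, hi = weights.score_range()
    if not lo <= total <= hi:
        raise ValueError(
            f"total {total} outside the achievable score range [{lo}, {hi}]"
        )
    for category, bound in zip(CATEGORIES, weights.upper_bounds):
        if total <= bound:
            return category
    return CATEGORIES[-1]


def naranjo_assess(
    sheet: NaranjoAnswerSheet, weights: NaranjoWeightTable | None = None
) -> NaranjoResult:
    """Score a sheet and categorise the total in one step."""
    weights = weights or NaranjoWeightTable.default()
    total = naranjo_score(sheet, weights)
    return NaranjoResult(total=total, category=naranjo_categorise(total, weights))
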