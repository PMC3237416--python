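"""Collation of causality category assignments and instrument comparison.

A collated table lists, per assessor, how many cases they placed in each
causality category, with column totals and percentages of the grand
total — the standard way multi-rater causality studies summarise how an
instrument utilises the scale (e.g. whether raters ever reach
'Definite'). Comparison summaries set two instruments' collations and
global kappas side by side over the same case x rater grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .agreement import GlobalAgreement, fleiss_kappa
from .categories import CATEGORIES, CausalityCategory
from .ratings import RatingsMatrix

CATEGORY_LABELS = [c.label for c in CATEGORIES]


@dataclass(frozen=True)
class CategoryCountTable:
    """Per-assessor category counts with totals and percentages."""

    per_assessor: pd.DataFrame  # index = assessor id, columns = category labels
    pct_digits: int = 1

    @property
    def totals(self) -> pd.Series:
        return self.per_assessor.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.per_assessor.to_numpy().sum())

    @property
    def percentages(self) -> pd.Series:
        return (100.0 * self.totals / self.grand_total).round(self.pct_digits)

    def count(self, category) -> int:
        return int(self.totals[CausalityCategory(category).label])

    def percentage(self, category) -> float:
        return float(self.percentages[CausalityCategory(category).label])

    def to_frame(self) -> pd.DataFrame:
        out = self.per_assessor.copy()
        out.loc["Total"] = self.totals
        out.loc["Percent"] = self.percentages
        return out

    def to_markdown(self) -> str:
        header = "| Assessor | " + " | ".join(CATEGORY_LABELS) + " |"
        lines = [header, "|" + "---|" * (len(CATEGORY_LABELS) + 1)]
        for rater, row in self.per_assessor.iterrows():
            lines.append(
                f"| {rater} | " + " | ".join(str(int(v)) for v in row) + " |"
            )
        lines.append(
            "| **Total (%)** | "
            + " | ".join(
                f"{int(t)} ({p:.{self.pct_digits}f})"
                for t, p in zip(self.totals, self.percentages)
            )
            + " |"
        )
        return "\n".join(lines)


def collate_categories(
    results: RatingsMatrix | Mapping | pd.DataFrame, pct_digits: int = 1
) -> CategoryCountTable:
    """Collate ratings (or pre-counted per-assessor 4-vectors) into a table.

    ``results`` may be a :class:`RatingsMatrix`, a mapping
    ``assessor id -> 4-vector of counts`` in ascending scale order, or
    an equivalent DataFrame with category-labelled columns.
    """
    if isinstance(results, RatingsMatrix):
        counts = {
            rater: [
                int((results.codes[rater] == float(int(c))).sum()) for c in CATEGORIES
            ]
            for rater in results.rater_ids
        }
        frame = pd.DataFrame.from_dict(
            counts, orient="index", columns=CATEGORY_LABELS
        )
    elif isinstance(results, pd.DataFrame):
        if list(results.columns) != CATEGORY_LABELS:
            raise ValueError(
                f"count frame columns must be {CATEGORY_LABELS}, "
                f"got {list(results.columns)}"
            )
        frame = results.astype(int)
    elif isinstance(results, Mapping):
        rows = {}
        for rater, vec in results.items():
            arr = np.asarray(vec)
            if arr.shape != (len(CATEGORIES),) or (arr < 0).any():
                raise ValueError(
                    f"assessor {rater!r}: expected a 4-vector of non-negative "
                    f"counts, got {vec!r}"
                )
            rows[rater] = arr.astype(int)
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=CATEGORY_LABELS)
    else:
        raise TypeError(f"cannot collate {type(results).__name__}")
    if frame.empty or frame.to_numpy().sum() == 0:
        raise ValueError("nothing to collate: no assessments")
    return CategoryCountTable(per_assessor=frame, pct_digits=pct_digits)


def load_study_counts() -> dict:
    """The packaged per-assessor category counts of the published
    development/validation study of the Liverpool instrument."""
    return json.loads(
        resources.files("adrcat.data").joinpath("study_counts.json").read_text()
    )


def study_arm_table(arm: str, pct_digits: int = 1) -> CategoryCountTable:
    """Collated table for one arm of the packaged study counts."""
    doc = load_study_counts()
    try:
        per_assessor = doc["arms"][arm]["per_assessor"]
    except KeyError:
        raise KeyError(
            f"unknown study arm {arm!r}; available: {sorted(doc['arms'])}"
        ) from None
    return collate_categories(per_assessor, pct_digits=pct_digits)


# ---------------------------------------------------------------------------
# Instrument comparison
# ---------------------------------------------------------------------------


class BundleError(ValueError):
    """Instruments in a bundle do not share the same case x rater grid."""


@dataclass(frozen=True)
class StudyBundle:
    """Named instruments' ratings over one shared case x rater grid."""

    instruments: Mapping[str, RatingsMatrix]

    def __post_init__(self) -> None:
        if len(self.instruments) < 2:
            raise BundleError("a bundle needs at least two instruments")
        items = list(self.instruments.items())
        ref_name, ref = items[0]
        problems = []
        for name, m in items[1:]:
            missing_cases = set(ref.case_ids) ^ set(m.case_ids)
            missing_raters = set(ref.rater_ids) ^ set(m.rater_ids)
            if missing_cases:
                problems.append(
                    f"{name!r} vs {ref_name!r}: unmatched cases {sorted(missing_cases)}"
                )
            if missing_raters:
                problems.append(
                    f"{name!r} vs {ref_name!r}: unmatched raters {sorted(missing_raters)}"
                )
        if problems:
            raise BundleError("misaligned grids:\n- " + "\n- ".join(problems))


@dataclass(frozen=True)
class InstrumentComparison:
    counts: Mapping[str, CategoryCountTable]
    global_agreement: Mapping[str, GlobalAgreement]
    shift_distribution: pd.Series  # index = code shift (-3..3), values = cell counts
    n_unique_pairs: int       # case x rater cells, counted once
    n_instrument_assessments: int  # cells summed over instruments

    def to_dict(self) -> dict:
        return {
            "counts": {
                name: {
                    "totals": [int(v) for v in t.totals],
                    "percentages": [float(v) for v in t.percentages],
                }
                for name, t in self.counts.items()
            },
            "global_kappa": {
                name: None if g.degenerate else g.kappa_fleiss
                for name, g in self.global_agreement.items()
            },
            "band": {name: g.band for name, g in self.global_agreement.items()},
            "shift_distribution": {
                str(k): int(v) for k, v in self.shift_distribution.items()
            },
            "n_unique_pairs": self.n_unique_pairs,
            "n_instrument_assessments": self.n_instrument_assessments,
        }


def compare_instruments(bundle: StudyBundle) -> InstrumentComparison:
    """Side-by-side collation, global kappas, and the per-cell category
    shift distribution between the bundle's first two instruments.

    The assessment-count conventions differ on purpose: a case x rater
    pair assessed with several instruments counts once in
    ``n_unique_pairs`` but once per instrument in
    ``n_instrument_assessments``.
    """
    names = list(bundle.instruments)
    counts = {n: collate_categories(bundle.instruments[n]) for n in names}
    global_agreement = {n: fleiss_kappa(bundle.instruments[n]) for n in names}

    a = bundle.instruments[names[0]].codes
    b = bundle.instruments[names[1]].codes.loc[a.index, a.columns]
    diff = (b - a).to_numpy().ravel()
    diff = diff[~np.isnan(diff)].astype(int)
    shift = pd.Series(diff).value_counts().reindex(range(-3, 4), fill_value=0)

    cells = a.notna().to_numpy().sum()
    return InstrumentComparison(
        counts=counts,
        global_agreement=global_agreement,
        shift_distribution=shift,
        n_unique_pairs=int(cells),
        n_instrument_assessments=int(
            sum(m.codes.notna().to_numpy().sum() for m in bundle.instruments.values())
        ),
    )
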