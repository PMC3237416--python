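"""Cases x raters grids of ordinal causality ratings.

The canonical in-memory container is a pandas ``DataFrame`` whose index
holds case ids, whose columns hold rater ids, and whose cells hold
integer category codes 1-4 (``NaN`` for a missing rating). The CSV
serialisation uses the category names, so files remain human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import (
    CategoryParseError,
    CausalityCategory,
    parse_category,
)


class RatingsError(ValueError):
    """A ratings grid violates the container invariants."""


@dataclass(frozen=True)
class RatingsMatrix:
    """Immutable cases x raters grid of causality categories.

    Parameters
    ----------
    codes
        DataFrame of float codes in {1, 2, 3, 4, NaN}; index = case ids,
        columns = rater ids.
    """

    codes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.codes
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise RatingsError(
                f"need >=1 case and >=2 raters, got shape {df.shape}"
            )
        if df.columns.duplicated().any() or df.index.duplicated().any():
            raise RatingsError("case ids and rater ids must be unique")
        values = df.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | np.isin(values, [1.0, 2.0, 3.0, 4.0]))
        if bad.any():
            raise RatingsError(
                f"non-category codes present: {sorted(set(values[bad]))}"
            )
        object.__setattr__(self, "codes", df.astype(float))

    # -- construction ---------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatingsMatrix":
        """Parse a DataFrame of category tokens (names, aliases or codes)."""

        def cell(v):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return np.nan
            if isinstance(v, str) and not v.strip():
                return np.nan
            return float(int(parse_category(v)))

        return cls(frame.map(cell))

    @classmethod
    def from_codes(cls, array, case_ids=None, rater_ids=None) -> "RatingsMatrix":
        arr = np.asarray(array, dtype=float)
        n_cases, n_raters = arr.shape
        return cls(
            pd.DataFrame(
                arr,
                index=list(case_ids) if case_ids is not None
                else [f"case{i + 1}" for i in range(n_cases)],
                columns=list(rater_ids) if rater_ids is not None
                else [f"rater{j + 1}" for j in range(n_raters)],
            )
        )

    @classmethod
    def from_csv(cls, path) -> "RatingsMatrix":
        """Read a ratings CSV: first column = case id, one column per rater."""
        raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        parsed = {}
        for col in raw.columns:
            column = []
            for lineno, (case, v) in enumerate(raw[col].items(), start=2):
                if v is None or not str(v).strip():
                    column.append(np.nan)
                    continue
                try:
                    column.append(float(int(parse_category(v))))
                except CategoryParseError as exc:
                    raise RatingsError(f"{path}, line {lineno}: {exc}") from None
            parsed[col] = column
        return cls(pd.DataFrame(parsed, index=raw.index))

    # -- accessors ------------------------------------------------------
    @property
    def case_ids(self) -> list:
        return list(self.codes.index)

    @property
    def rater_ids(self) -> list:
        return list(self.codes.columns)

    @property
    def n_cases(self) -> int:
        return self.codes.shape[0]

    @property
    def n_raters(self) -> int:
        return self.codes.shape[1]

    def labels(self) -> pd.DataFrame:
        """DataFrame of category names ('' for missing)."""
        return self.codes.map(
            lambda v: "" if np.isnan(v) else CausalityCategory(int(v)).label
        )

    def to_csv(self, path) -> None:
        self.labels().rename_axis("case_id").to_csv(path)

    def complete_cases(self) -> "RatingsMatrix":
        """Submatrix of cases rated by every rater."""
        kept = self.codes.dropna(axis=0, how="any")
        if kept.shape[0] < 1:
            raise RatingsError("no complete cases")
        return RatingsMatrix(kept)

    def pair_codes(self, rater_a, rater_b) -> tuple[np.ndarray, np.ndarray]:
        """Integer codes of the two raters on their jointly rated cases."""
        sub = self.codes[[rater_a, rater_b]].dropna(axis=0, how="any")
        return (
            sub[rater_a].to_numpy(dtype=int),
            sub[rater_b].to_numpy(dtype=int),
        )
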