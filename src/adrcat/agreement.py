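"""Inter-rater reliability battery for ordinal causality ratings.

For each rater pair: exact agreement percentage (%EA), extreme
disagreement percentage (%ED, ratings more than one scale step apart),
and the linear weighted kappa with its 95% confidence interval. Across
the whole panel: Fleiss' multi-rater kappa (nominal-scale chance
correction) with its 95% CI and an Altman verbal band.

Standard-error conventions
--------------------------
* Pairwise weighted kappa: the Fleiss-Cohen-Everitt (1969) large-sample
  non-null variance.
* Fleiss kappa: the Fleiss (1971) variance (derived under the chance
  null, the conventional choice for its CI).

Both estimates are chance-corrected, so a panel that is constant in the
same category has a zero denominator; such results are flagged
``degenerate`` (kappa = NaN) rather than raised as errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .categories import N_CATEGORIES
from .ratings import RatingsMatrix

Z95 = 1.959963984540054  # normal 97.5% quantile

#: Altman (1991) verbal bands: inclusive upper kappa edge -> label.
ALTMAN_EDGES: tuple[tuple[float, str], ...] = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


class InsufficientDataError(ValueError):
    """Too few complete ratings to compute the requested statistic."""


@dataclass(frozen=True)
class PairwiseAgreement:
    rater_a: object
    rater_b: object
    n_cases: int
    pct_exact_agreement: float
    pct_extreme_disagreement: float
    kappa_w: float
    se: float
    ci95: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class GlobalAgreement:
    kappa_fleiss: float
    se: float
    ci95: tuple[float, float]
    band: str
    n_cases: int
    n_raters: int
    n_excluded_cases: int = 0
    degenerate: bool = False


def altman_band(kappa: float, edges=ALTMAN_EDGES) -> str:
    """Verbal interpretation of a kappa value.

    Bands are half-open on the full-precision value (<=0.20 poor,
    <=0.40 fair, <=0.60 moderate, <=0.80 good, <=1 very good); values
    below zero fall in 'poor'. Banding precedes display rounding.
    """
    if np.isnan(kappa):
        return "undefined"
    if kappa > 1.0 + 1e-12:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    for edge, label in edges:
        if kappa <= edge + 1e-12:
            return label
    return edges[-1][1]


def linear_weights(k: int = N_CATEGORIES) -> np.ndarray:
    """Agreement weights w_ij = 1 - |i-j|/(k-1)."""
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def contingency_table(x, y, k: int = N_CATEGORIES) -> np.ndarray:
    """k x k table of joint rating counts from two integer code vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    table = np.zeros((k, k))
    np.add.at(table, (x - 1, y - 1), 1.0)
    return table


def weighted_kappa_from_table(
    table: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float, bool]:
    """(kappa_w, SE, degenerate) from a square contingency table.

    SE is the Fleiss-Cohen-Everitt (1969) large-sample standard error of
    the weighted kappa (non-null form).
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n < 2:
        raise InsufficientDataError(
            f"need >=2 jointly rated cases, got {int(n)}"
        )
    w = linear_weights(table.shape[0]) if weights is None else np.asarray(weights)
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if abs(1.0 - pe) < 1e-12:
        return float("nan"), float("nan"), True
    kappa = (po - pe) / (1.0 - pe)

    wbar_row = w @ col          # E_j[w_ij] for each row category i
    wbar_col = row @ w          # E_i[w_ij] for each column category j
    inner = (
        p
        * (w * (1.0 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - po)) ** 2
    ).sum()
    var = (inner - (po * pe - 2.0 * pe + po) ** 2) / (n * (1.0 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return float(kappa), se, False


def _clip_ci(lo: float, hi: float) -> tuple[float, float]:
    return (float(max(lo, -1.0)), float(min(hi, 1.0)))


def exact_agreement_pct(ratings: RatingsMatrix, pair=None) -> float:
    """%EA: 100 x (identically rated cases) / (jointly rated cases)."""
    x, y = _pair(ratings, pair)
    if x.size < 1:
        raise InsufficientDataError("no jointly rated cases")
    return float(100.0 * np.mean(x == y))


def extreme_disagreement_pct(ratings: RatingsMatrix, pair=None) -> float:
    """%ED: 100 x (cases more than one scale step apart) / (jointly rated)."""
    x, y = _pair(ratings, pair)
    if x.size < 1:
        raise InsufficientDataError("no jointly rated cases")
    return float(100.0 * np.mean(np.abs(x - y) >= 2))


def _pair(ratings: RatingsMatrix, pair):
    if pair is None:
        if ratings.n_raters != 2:
            raise ValueError(
                "matrix has more than two raters; pass pair=(rater_a, rater_b)"
            )
        pair = tuple(ratings.rater_ids)
    return ratings.pair_codes(*pair)


def linear_weighted_kappa(ratings: RatingsMatrix, pair=None) -> PairwiseAgreement:
    """Full pairwise battery for one rater pair (complete pairs only)."""
    if pair is None and ratings.n_raters == 2:
        pair = tuple(ratings.rater_ids)
    x, y = _pair(ratings, pair)
    if x.size < 2:
        raise InsufficientDataError(
            f"need >=2 jointly rated cases for pair {pair}, got {x.size}"
        )
    kappa, se, degenerate = weighted_kappa_from_table(contingency_table(x, y))
    if degenerate:
        ci = (float("nan"), float("nan"))
    else:
        ci = _clip_ci(kappa - Z95 * se, kappa + Z95 * se)
    return PairwiseAgreement(
        rater_a=pair[0],
        rater_b=pair[1],
        n_cases=int(x.size),
        pct_exact_agreement=float(100.0 * np.mean(x == y)),
        pct_extreme_disagreement=float(100.0 * np.mean(np.abs(x - y) >= 2)),
        kappa_w=kappa,
        se=se,
        ci95=ci,
        degenerate=degenerate,
    )


def fleiss_counts(ratings: RatingsMatrix, k: int = N_CATEGORIES) -> np.ndarray:
    """Cases x categories count matrix from the complete-case submatrix."""
    codes = ratings.complete_cases().codes.to_numpy(dtype=int)
    counts = np.zeros((codes.shape[0], k))
    for j in range(k):
        counts[:, j] = (codes == j + 1).sum(axis=1)
    return counts


def fleiss_kappa_from_counts(counts: np.ndarray) -> tuple[float, float, bool]:
    """(kappa, SE, degenerate) from a cases x categories count matrix.

    Implements Fleiss' (1971) multi-rater kappa and its variance. All
    rows must sum to the same number of raters n >= 2.
    """
    counts = np.asarray(counts, dtype=float)
    n_cases = counts.shape[0]
    if n_cases < 2:
        raise InsufficientDataError(f"need >=2 complete cases, got {n_cases}")
    row_sums = counts.sum(axis=1)
    n = row_sums[0]
    if not np.allclose(row_sums, n):
        raise ValueError("every case must be rated by the same number of raters")
    if n < 2:
        raise InsufficientDataError("need >=2 raters per case")

    p_j = counts.sum(axis=0) / (n_cases * n)
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())
    if abs(1.0 - p_e) < 1e-12:
        return float("nan"), float("nan"), True
    kappa = (p_bar - p_e) / (1.0 - p_e)
    var = (
        2.0
        / (n_cases * n * (n - 1))
        * (p_e - (2.0 * n - 3.0) * p_e**2 + 2.0 * (n - 2.0) * (p_j**3).sum())
        / (1.0 - p_e) ** 2
    )
    return float(kappa), float(np.sqrt(max(var, 0.0))), False


def fleiss_kappa(ratings: RatingsMatrix) -> GlobalAgreement:
    """Global multi-rater kappa over the complete-case submatrix."""
    complete = ratings.complete_cases()
    counts = fleiss_counts(complete)
    kappa, se, degenerate = fleiss_kappa_from_counts(counts)
    if degenerate:
        ci = (float("nan"), float("nan"))
    else:
        ci = _clip_ci(kappa - Z95 * se, kappa + Z95 * se)
    return GlobalAgreement(
        kappa_fleiss=kappa,
        se=se,
        ci95=ci,
        band=altman_band(kappa),
        n_cases=complete.n_cases,
        n_raters=complete.n_raters,
        n_excluded_cases=ratings.n_cases - complete.n_cases,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class AgreementReport:
    """All pairwise batteries plus the panel-level global kappa."""

    pairwise: tuple[PairwiseAgreement, ...]
    global_: GlobalAgreement
    rater_ids: tuple

    def pair(self, a, b) -> PairwiseAgreement:
        for p in self.pairwise:
            if {p.rater_a, p.rater_b} == {a, b}:
                return p
        raise KeyError((a, b))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "raters": list(self.rater_ids),
            "pairwise": [
                {
                    "rater_a": p.rater_a,
                    "rater_b": p.rater_b,
                    "n_cases": p.n_cases,
                    "pct_exact_agreement": p.pct_exact_agreement,
                    "pct_extreme_disagreement": p.pct_extreme_disagreement,
                    "kappa_w": None if p.degenerate else p.kappa_w,
                    "se": None if p.degenerate else p.se,
                    "ci95": None if p.degenerate else list(p.ci95),
                    "degenerate": p.degenerate,
                }
                for p in self.pairwise
            ],
            "global": {
                "kappa_fleiss": None if self.global_.degenerate
                else self.global_.kappa_fleiss,
                "se": None if self.global_.degenerate else self.global_.se,
                "ci95": None if self.global_.degenerate else list(self.global_.ci95),
                "band": self.global_.band,
                "n_cases": self.global_.n_cases,
                "n_raters": self.global_.n_raters,
                "n_excluded_cases": self.global_.n_excluded_cases,
            },
        }

    def to_markdown(self) -> str:
        """Pairwise matrix in the conventional layout: %EA/%ED on one
        line and kappa (95% CI) beneath, upper triangle only."""
        raters = list(self.rater_ids)
        header = "| | " + " | ".join(str(r) for r in raters[1:]) + " |"
        sep = "|" + "---|" * len(raters)
        lines = [header, sep]
        for i, a in enumerate(raters[:-1]):
            ea_cells, ka_cells = [], []
            for b in raters[1:]:
                j = raters.index(b)
                if j <= i:
                    ea_cells.append("")
                    ka_cells.append("")
                    continue
                p = self.pair(a, b)
                ea_cells.append(
                    f"{p.pct_exact_agreement:.1f}/{p.pct_extreme_disagreement:.1f}%"
                )
                ka_cells.append(
                    "degenerate" if p.degenerate
                    else f"{p.kappa_w:.2f} ({p.ci95[0]:.2f}, {p.ci95[1]:.2f})"
                )
            lines.append(f"| **{a}** %EA/%ED | " + " | ".join(ea_cells) + " |")
            lines.append("| kappa (95% CI) | " + " | ".join(ka_cells) + " |")
        g = self.global_
        if g.degenerate:
            lines.append("\nGlobal kappa: degenerate (no chance-corrected variation)")
        else:
            lines.append(
                f"\nGlobal kappa: {g.kappa_fleiss:.2f} "
                f"(95% CI {g.ci95[0]:.2f}, {g.ci95[1]:.2f}) — {g.band} agreement "
                f"[{g.n_cases} cases x {g.n_raters} raters]"
            )
        return "\n".join(lines)

    def summary(self) -> str:
        return self.to_markdown()


def agreement_report(ratings: RatingsMatrix) -> AgreementReport:
    """Full battery: every rater pair plus the global Fleiss kappa."""
    pairs = tuple(
        linear_weighted_kappa(ratings, pair=(a, b))
        for a, b in itertools.combinations(ratings.rater_ids, 2)
    )
    return AgreementReport(
        pairwise=pairs,
        global_=fleiss_kappa(ratings),
        rater_ids=tuple(ratings.rater_ids),
    )
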