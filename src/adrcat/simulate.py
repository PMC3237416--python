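"""Synthetic multi-rater causality panels with known latent truth.

No per-case ratings from real causality studies are publicly deposited,
so the statistics and instrument engines are exercised on simulated
panels. The generative model is deliberately minimal:

* each case carries a latent true category drawn i.i.d. from a
  prevalence vector over the four-point scale;
* each rater independently reports the latent category with probability
  ``fidelity``; otherwise the report lands on another category with
  probability proportional to ``spillover_decay ** d`` where ``d`` is
  the ordinal distance, renormalised over the other three categories.

A single ``fidelity`` knob therefore controls panel agreement, and the
geometric spillover keeps most disagreements one scale step apart — the
pattern real causality panels show. Liverpool answer sheets consistent
with any reported category are produced by inverse path sampling on the
decision tree, so sheet-level round trips are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import CATEGORIES, N_CATEGORIES, CausalityCategory
from .liverpool import DecisionTree, enumerate_paths
from .ratings import RatingsMatrix

#: Default prevalence: the qualitative mix seen when a panel applies the
#: Liverpool instrument to suspected-ADR admissions (few Unlikely, many
#: Probable/Definite, because cases are pre-selected as suspected ADRs).
DEFAULT_PREVALENCE: tuple[float, ...] = (0.01, 0.22, 0.33, 0.44)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of a simulated panel.

    Defaults mirror a seven-rater, forty-case assessment round.
    """

    n_cases: int = 40
    n_raters: int = 7
    prevalence: tuple[float, ...] = DEFAULT_PREVALENCE
    fidelity: float = 0.7
    spillover_decay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_raters < 2:
            raise ValueError("need n_cases >= 1 and n_raters >= 2")
        prev = np.asarray(self.prevalence, dtype=float)
        if prev.shape != (N_CATEGORIES,) or (prev < 0).any():
            raise ValueError(
                f"prevalence must be {N_CATEGORIES} non-negative probabilities"
            )
        if abs(prev.sum() - 1.0) > 1e-12:
            raise ValueError(f"prevalence must sum to 1, got {prev.sum()!r}")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError("fidelity must lie in [0, 1]")
        if not 0.0 < self.spillover_decay <= 1.0:
            raise ValueError("spillover_decay must lie in (0, 1]")
        object.__setattr__(self, "prevalence", tuple(prev))


@dataclass(frozen=True)
class SimulatedPanel:
    """Latent truth, the observed ratings grid, and optional answer sheets."""

    latent: np.ndarray  # per-case true category codes (1-4)
    ratings: RatingsMatrix
    config: SimulationConfig
    sheets: dict | None = field(default=None)  # (case_id, rater_id) -> answers

    @property
    def latent_categories(self) -> list[CausalityCategory]:
        return [CausalityCategory(int(c)) for c in self.latent]


def misclassification_kernel(config: SimulationConfig) -> np.ndarray:
    """Row-stochastic 4x4 matrix: P(reported = j | latent = i)."""
    k = N_CATEGORIES
    kernel = np.zeros((k, k))
    for i in range(k):
        off = np.array(
            [config.spillover_decay ** abs(i - j) if j != i else 0.0 for j in range(k)]
        )
        kernel[i] = (1.0 - config.fidelity) * off / off.sum()
        kernel[i, i] = config.fidelity
    return kernel


def simulate_ratings(config: SimulationConfig) -> SimulatedPanel:
    """Draw a latent-truth panel and its noisy ratings matrix."""
    rng = np.random.default_rng(config.seed)
    latent = rng.choice(N_CATEGORIES, size=config.n_cases, p=config.prevalence) + 1
    kernel = misclassification_kernel(config)
    # one uniform per cell, inverted through the latent row's CDF
    cdf = kernel.cumsum(axis=1)
    u = rng.random((config.n_cases, config.n_raters))
    reported = (u[:, :, None] > cdf[latent - 1][:, None, :]).sum(axis=2) + 1
    ratings = RatingsMatrix.from_codes(reported.astype(float))
    return SimulatedPanel(latent=latent, ratings=ratings, config=config)


def sample_answer_sheet(
    tree: DecisionTree,
    target: CausalityCategory,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Uniformly sample one root-to-leaf path ending in ``target``.

    Returns the answers along that path, i.e. a minimal sheet for which
    :func:`adrcat.liverpool.assess` reproduces ``target`` exactly.
    """
    matching = [
        path for path, cat in enumerate_paths(tree) if cat is CausalityCategory(target)
    ]
    if not matching:
        raise ValueError(
            f"category {CausalityCategory(target).label} has no reachable leaf "
            f"in tree {tree.name!r}"
        )
    path = matching[rng.integers(len(matching))]
    return {node_id: answer for node_id, answer in path}


def simulate_study(
    config: SimulationConfig, tree: DecisionTree
) -> SimulatedPanel:
    """Simulate a full assessment round including Liverpool answer sheets.

    Ratings come from :func:`simulate_ratings`; each rating is then
    realised as a concrete traversal of ``tree`` via inverse path
    sampling, so re-assessing every emitted sheet reproduces the ratings
    matrix cell for cell.
    """
    panel = simulate_ratings(config)
    # independent stream so ratings are identical with/without sheets
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sheets = {}
    codes = panel.ratings.codes
    for case_id in panel.ratings.case_ids:
        for rater_id in panel.ratings.rater_ids:
            category = CausalityCategory(int(codes.at[case_id, rater_id]))
            sheets[(case_id, rater_id)] = sample_answer_sheet(tree, category, rng)
    return SimulatedPanel(
        latent=panel.latent, ratings=panel.ratings, config=config, sheets=sheets
    )


def prevalence_from_counts(counts) -> tuple[float, ...]:
    """Normalise a 4-vector of category counts into a prevalence vector."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (len(CATEGORIES),) or (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("counts must be 4 non-negative numbers with positive sum")
    return tuple(arr / arr.sum())
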