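"""Partial credit model: category probabilities, score moments, cohort simulation.

Under the PCM the probability that a person with ability theta scores
category k (k = 0..m) on an item with step thresholds delta_1..delta_m is

    P(X = k) = exp( sum_{j<=k} (theta - delta_j) ) / sum_h exp( sum_{j<=h} (theta - delta_j) )

with the empty sum for k = 0 equal to zero.  All items share a common
discrimination (pure Rasch PCM, not the generalized PCM).  The item score
variance at theta is the item's Fisher information, and test information is
the sum over items.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .item_bank import Item, ItemBank

__all__ = [
    "category_probabilities",
    "score_moments",
    "CohortData",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
]


def _padded_thresholds(items: Sequence[Item]) -> np.ndarray:
    """(n_items, max_steps) threshold matrix, padded with +inf.

    Padding sends the cumulative logit of nonexistent categories to -inf, so
    they get probability zero and one matrix expression serves mixed-format
    items.
    """
    m = max(it.n_steps for it in items)
    delta = np.full((len(items), m), np.inf)
    for i, it in enumerate(items):
        delta[i, : it.n_steps] = it.step_thresholds
    return delta


def _prob_matrix(theta: np.ndarray, delta_pad: np.ndarray) -> np.ndarray:
    """Category probabilities, shape theta.shape + (n_items, max_steps + 1).

    Overflow-safe via max-subtraction before exponentiation.
    """
    theta = np.asarray(theta, dtype=float)
    cum = np.cumsum(theta[..., None, None] - delta_pad, axis=-1)
    cum = np.concatenate([np.zeros(cum.shape[:-1] + (1,)), cum], axis=-1)
    cum -= cum.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):  # -inf padding -> exp 0
        e = np.exp(cum)
    return e / e.sum(axis=-1, keepdims=True)


def _moments(theta: np.ndarray, delta_pad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected score and score variance (information) per item."""
    p = _prob_matrix(theta, delta_pad)
    k = np.arange(p.shape[-1])
    mean = p @ k
    var = p @ (k * k) - mean**2
    return mean, var


def category_probabilities(theta: float, item: Item) -> np.ndarray:
    """PCM category probabilities at ability ``theta`` for one item.

    Returns a vector of length ``n_steps + 1`` (categories 0..n_steps),
    nonnegative and summing to one.
    """
    if not np.all(np.isfinite(theta)):
        raise ValueError(f"theta must be finite, got {theta}")
    delta = np.asarray(item.step_thresholds, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(float(theta) - delta)])
    cum -= cum.max()
    e = np.exp(cum)
    return e / e.sum()


def score_moments(theta: float, item: Item) -> tuple[float, float]:
    """Expected item score and item information (score variance) at ``theta``.

    Information equals d(expected score)/d(theta) — the standard Rasch
    identity — and is strictly positive for finite theta.
    """
    p = category_probabilities(theta, item)
    k = np.arange(item.n_steps + 1)
    mean = float(p @ k)
    var = float(p @ (k * k) - mean**2)
    return mean, var


@dataclass(frozen=True)
class CohortData:
    """A simulated respondent cohort over a bank's pool items.

    ``responses[i, j]`` is person i's category score on ``item_ids[j]``;
    ``true_theta[i]`` is the generating ability in logits.
    """

    true_theta: np.ndarray
    responses: np.ndarray
    item_ids: tuple[int, ...]
    seed: int
    theta_mean: float
    theta_sd: float

    def __post_init__(self):
        if self.responses.shape != (len(self.true_theta), len(self.item_ids)):
            raise ValueError("responses shape does not match cohort dimensions")

    @property
    def n_persons(self) -> int:
        return len(self.true_theta)

    def person_responses(self, i: int) -> dict[int, int]:
        """Person i's responses as an item_id -> category map."""
        return {iid: int(x) for iid, x in zip(self.item_ids, self.responses[i])}


def simulate_cohort(
    bank: ItemBank,
    n_persons: int,
    theta_mean: float = 0.0,
    theta_sd: float = 1.0,
    seed: int = 0,
) -> CohortData:
    """Simulate a cohort answering every pool item under the PCM.

    Abilities are drawn i.i.d. Normal(theta_mean, theta_sd); each response is
    drawn by inverse-CDF sampling from the item's category distribution at the
    person's true ability.  Person i uses its own deterministic substream
    (``default_rng([seed, i])``), so person i's ability and responses do not
    change when the cohort grows.
    """
    if n_persons < 1:
        raise ValueError(f"n_persons must be >= 1, got {n_persons}")
    if not np.isfinite(theta_mean) or not np.isfinite(theta_sd) or theta_sd < 0:
        raise ValueError(f"invalid ability distribution N({theta_mean}, {theta_sd})")

    items = bank.pool_items()
    delta_pad = _padded_thresholds(items)
    theta = np.empty(n_persons)
    responses = np.empty((n_persons, len(items)), dtype=np.int64)
    for i in range(n_persons):
        rng = np.random.default_rng([seed, i])
        theta[i] = theta_mean + theta_sd * rng.standard_normal()
        p = _prob_matrix(np.asarray(theta[i]), delta_pad)  # (n_items, K+1)
        cdf = np.cumsum(p, axis=-1)
        u = rng.random(len(items))
        responses[i] = (u[:, None] > cdf[:, :-1]).sum(axis=1)
    return CohortData(
        true_theta=theta,
        responses=responses,
        item_ids=tuple(it.item_id for it in items),
        seed=seed,
        theta_mean=theta_mean,
        theta_sd=theta_sd,
    )


def save_cohort(cohort: CohortData, path: str | Path) -> None:
    """Export as delimited text: one row per person, true_theta then item columns."""
    frame = pd.DataFrame(cohort.responses, columns=[f"item_{i}" for i in cohort.item_ids])
    frame.insert(0, "true_theta", cohort.true_theta)
    frame.to_csv(path, index=False)


def load_cohort(path: str | Path, seed: int = -1) -> CohortData:
    """Re-import a cohort written by :func:`save_cohort`.

    The generator config is not stored in the file; ``seed`` defaults to a
    sentinel and the distribution echo is recomputed from the sample.
    """
    frame = pd.read_csv(path)
    item_ids = tuple(int(c.removeprefix("item_")) for c in frame.columns[1:])
    theta = frame["true_theta"].to_numpy()
    return CohortData(
        true_theta=theta,
        responses=frame.iloc[:, 1:].to_numpy(dtype=np.int64),
        item_ids=item_ids,
        seed=seed,
        theta_mean=float(theta.mean()),
        theta_sd=float(theta.std(ddof=1)) if len(theta) > 1 else 0.0,
    )
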