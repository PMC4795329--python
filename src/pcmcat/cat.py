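"""Adaptive test administration: selection, stopping, routing, imputation.

The engine administers pool items one at a time.  The first item is drawn at
random from the pool; afterwards the un-administered pool item with maximal
information (score variance) at the provisional ability is presented, ability
being re-estimated by MLE after every response.  Administration stops when
person reliability reaches its target, when the ability trace has settled
(mean of the last five changes below threshold, after a minimum number of
items), or when the pool is exhausted.

Conditional-path (skip) items live outside the pool: :func:`route_next_item`
follows an item's route map — the answer category chosen determines the next
questionnaire item — falling back to sequential order for ordinary items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import (
    FitStats,
    PersonEstimate,
    estimate_theta,
    person_fit,
    reliability_from_sem,
    trend_diagnostics,
)
from .item_bank import ItemBank
from .pcm import _moments, _padded_thresholds, category_probabilities

__all__ = [
    "StopRules",
    "CatSession",
    "PoolExhaustedError",
    "select_next_item",
    "should_stop",
    "run_cat",
    "route_next_item",
    "impute_unanswered",
    "make_model_respondent",
    "session_trace",
]


class PoolExhaustedError(RuntimeError):
    """Raised when item selection is requested from an empty remaining pool."""


@dataclass(frozen=True)
class StopRules:
    """Termination rules for an adaptive session (OR-combined).

    min_items:
        Minimum administered items before the residual rule may fire.
    reliability_target:
        Person reliability at which to stop (ungated by min_items).
    residual_threshold:
        Stop when the mean absolute ability change over the last ``window``
        updates falls below this (logits).
    max_items:
        Hard cap on administered items; defaults to the pool size.
    """

    min_items: int = 5
    reliability_target: float = 0.80
    residual_threshold: float = 0.05
    window: int = 5
    max_items: int | None = None

    def __post_init__(self):
        if self.min_items < 1:
            raise ValueError("min_items must be >= 1")
        if not 0.0 < self.reliability_target < 1.0:
            raise ValueError("reliability_target must be in (0, 1)")
        if self.residual_threshold <= 0:
            raise ValueError("residual_threshold must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class CatSession:
    """Bookkeeping for one adaptive administration."""

    administered: list[int] = field(default_factory=list)
    responses: dict[int, int] = field(default_factory=dict)
    theta_history: list[float] = field(default_factory=list)
    sem_history: list[float] = field(default_factory=list)
    pool_size: int = 0
    stop_reason: str | None = None
    final: PersonEstimate | None = None
    fit: FitStats | None = None


def select_next_item(
    provisional_theta: float,
    administered: Iterable[int],
    bank: ItemBank,
    rng: np.random.Generator | None = None,
    first: bool = False,
) -> int:
    """Choose the next pool item.

    The first item is uniform-random from the pool; afterwards the remaining
    pool item with maximal information at the provisional ability is chosen,
    ties broken by lowest item_id.
    """
    administered = set(administered)
    remaining = [iid for iid in bank.pool_ids if iid not in administered]
    if not remaining:
        raise PoolExhaustedError("no pool items remain")
    if first:
        if rng is None:
            rng = np.random.default_rng()
        return int(remaining[rng.integers(len(remaining))])
    items = [bank[iid] for iid in remaining]
    _, info = _moments(np.asarray(float(provisional_theta)), _padded_thresholds(items))
    best_iid, _ = max(zip(remaining, info), key=lambda t: (t[1], -t[0]))
    return int(best_iid)


def should_stop(
    session: CatSession,
    rules: StopRules,
    *,
    reliability_form: str = "paper",
) -> tuple[bool, str | None]:
    """Evaluate the stop rules on the current session state.

    Precedence: (a) reliability target met, (b) residual settled after
    min_items, (c) pool exhausted / item cap reached.
    """
    n = len(session.administered)
    if n < 1:
        return False, None
    rel = reliability_from_sem(session.sem_history[-1], reliability_form)
    if rel >= rules.reliability_target:
        return True, "reliability"
    if n >= rules.min_items and len(session.theta_history) >= rules.window + 1:
        diag = trend_diagnostics(session.theta_history, rules.window)
        if diag.residual < rules.residual_threshold:
            return True, "residual"
    if session.pool_size and n >= session.pool_size:
        return True, "pool_exhausted"
    max_items = rules.max_items if rules.max_items is not None else session.pool_size
    if max_items and n >= max_items:
        return True, "max_items"
    return False, None


def run_cat(
    respondent: Callable[[int], int],
    bank: ItemBank,
    rules: StopRules | None = None,
    seed: int | Sequence[int] = 0,
    *,
    theta_bound: float = 4.0,
    reliability_form: str = "paper",
) -> CatSession:
    """Run one adaptive session against an answer oracle.

    ``respondent`` maps an item_id to a category score.  The loop is
    select -> answer -> re-estimate -> check stop rules; the provisional
    ability before any response is 0.0 (pool-centred start).  Deterministic
    given ``seed`` and the respondent.
    """
    rules = rules or StopRules()
    rng = np.random.default_rng(seed)
    session = CatSession(pool_size=len(bank.pool_ids))
    theta = 0.0
    while True:
        item_id = select_next_item(
            theta, session.administered, bank, rng, first=not session.administered
        )
        answer = respondent(item_id)
        item = bank[item_id]
        if not isinstance(answer, (int, np.integer)) or not (0 <= answer <= item.n_steps):
            raise ValueError(
                f"respondent returned invalid category {answer!r} for item "
                f"{item_id} (valid: 0..{item.n_steps})"
            )
        session.administered.append(item_id)
        session.responses[item_id] = int(answer)
        est = estimate_theta(
            session.responses,
            bank,
            theta_bound,
            start=theta,
            reliability_form=reliability_form,
        )
        theta = est.theta
        session.theta_history.append(est.theta)
        session.sem_history.append(est.sem)
        stop, reason = should_stop(session, rules, reliability_form=reliability_form)
        if stop:
            session.stop_reason = reason
            session.final = est
            break
    session.fit = person_fit(session.responses, bank, session.final.theta)
    return session


def route_next_item(bank: ItemBank, current: int, answer: int) -> int | None:
    """Next questionnaire item after answering ``current`` with ``answer``.

    Skip items redirect according to their route map; ordinary items fall
    through to the next item in bank order; None at the end of the form.
    """
    item = bank[current]
    if not (0 <= answer <= item.n_steps):
        raise ValueError(
            f"answer {answer} invalid for item {current} (valid: 0..{item.n_steps})"
        )
    if answer in item.route_map:
        return item.route_map[answer]
    return bank.next_in_order(current)


def impute_unanswered(session: CatSession, bank: ItemBank) -> dict[int, int]:
    """Fill in expected responses for pool items the session never asked.

    Each unanswered pool item receives its expected score at the final
    ability, rounded half-up and clipped to the item's category range;
    answered items keep their observed categories.  The result covers the
    whole pool, recovering full-questionnaire information from a short
    adaptive session.
    """
    if session.final is None:
        raise ValueError("session has not finished")
    theta = session.final.theta
    out: dict[int, int] = {}
    for iid in bank.pool_ids:
        if iid in session.responses:
            out[iid] = session.responses[iid]
        else:
            item = bank[iid]
            p = category_probabilities(theta, item)
            expected = float(p @ np.arange(item.n_steps + 1))
            out[iid] = int(np.clip(np.floor(expected + 0.5), 0, item.n_steps))
    return out


def make_model_respondent(
    true_theta: float, bank: ItemBank, seed: int | Sequence[int] = 0
) -> Callable[[int], int]:
    """Answer oracle drawing model-consistent responses at a fixed ability.

    Each item's response is drawn once (inverse-CDF on a per-item substream)
    and cached, so repeated asks are consistent within a session.
    """
    cache: dict[int, int] = {}

    def respond(item_id: int) -> int:
        if item_id not in cache:
            rng = np.random.default_rng([*np.atleast_1d(seed), item_id])
            p = category_probabilities(true_theta, bank[item_id])
            cache[item_id] = int((rng.random() > np.cumsum(p)[:-1]).sum())
        return cache[item_id]

    return respond


def session_trace(session: CatSession, window: int = 5) -> pd.DataFrame:
    """Step-by-step session record: item, answer, ability, SEM, diagnostics.

    The residual and trend-correlation columns are NaN until enough steps
    exist (window + 1 ability values).
    """
    rows = []
    for step, iid in enumerate(session.administered, start=1):
        hist = session.theta_history[:step]
        if len(hist) >= window + 1:
            diag = trend_diagnostics(hist, window)
            resi, corr = diag.residual, diag.trend_corr
        else:
            resi, corr = np.nan, np.nan
        rows.append(
            {
                "step": step,
                "item_id": iid,
                "answer": session.responses[iid],
                "theta": session.theta_history[step - 1],
                "sem": session.sem_history[step - 1],
                "residual": resi,
                "trend_corr": corr,
            }
        )
    return pd.DataFrame(rows)
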