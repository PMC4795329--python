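"""Person-measure estimation, fit statistics and session trend diagnostics.

Ability is estimated by maximum likelihood: safeguarded Newton iterations on
the score equation sum_i (x_i - E_i(theta)) = 0, where E_i is the expected
item score under the PCM.  The standard error of measurement is
SEM = 1 / sqrt(sum_i information_i(theta_hat)), information being the item
score variance.  Person reliability follows the survey engine's stopping
formula (1 - SEM)^2 by default; the conventional Rasch form
1 - SEM^2 / var(theta) is available as a switch.

Fit statistics use standardized score residuals z_i = (x_i - E_i) / sqrt(W_i):
outfit MNSQ is the unweighted mean of z_i^2, infit MNSQ the
information-weighted form sum (x_i - E_i)^2 / sum W_i.  An outfit of 2.0 or
greater flags a possibly aberrant response pattern (careless or random
responding, guessing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .item_bank import ItemBank
from .pcm import _moments, _padded_thresholds

__all__ = [
    "PersonEstimate",
    "FitStats",
    "TrendDiagnostics",
    "reliability_from_sem",
    "estimate_theta",
    "person_fit",
    "item_fit",
    "trend_diagnostics",
]

OUTFIT_ABERRANT = 2.0


@dataclass(frozen=True)
class PersonEstimate:
    """MLE person measure with its precision summary.

    ``at_bound`` marks extreme (all-minimum or all-maximum) response vectors,
    clamped to +/- the estimation bound, and estimates that ran into the bound.
    """

    theta: float
    sem: float
    reliability: float
    n_items: int
    converged: bool
    at_bound: bool


@dataclass(frozen=True)
class FitStats:
    """Person-fit mean squares; ``aberrant`` iff outfit >= 2.0."""

    infit_mnsq: float
    outfit_mnsq: float
    aberrant: bool


@dataclass(frozen=True)
class TrendDiagnostics:
    """End-of-session convergence diagnostics over the ability trace.

    ``residual`` is the mean absolute change over the last ``window`` ability
    updates; ``trend_corr`` the Pearson correlation of the last ``window``
    ability values with their step numbers (0 for a flat, zero-variance trace).
    """

    residual: float
    trend_corr: float


def reliability_from_sem(
    sem: float, form: str = "paper", theta_var: float = 1.0
) -> float:
    """Person reliability from the standard error of measurement.

    form="paper": (1 - SEM)^2 with (1 - SEM) clipped to [0, 1] first, so a
    SEM above one logit yields zero rather than curving back upward.
    form="conventional": 1 - SEM^2 / var(theta), clipped to [0, 1].
    """
    if form == "paper":
        return float(np.clip(1.0 - sem, 0.0, 1.0) ** 2)
    if form == "conventional":
        return float(np.clip(1.0 - sem**2 / theta_var, 0.0, 1.0))
    raise ValueError(f"unknown reliability form {form!r}")


def _check_responses(responses: Mapping[int, int], bank: ItemBank):
    if not responses:
        raise ValueError("at least one response is required")
    items, xs = [], []
    for iid, x in responses.items():
        if iid not in bank:
            raise KeyError(f"unknown item_id {iid}")
        it = bank[iid]
        if not (0 <= x <= it.n_steps):
            raise ValueError(
                f"item {iid}: category {x} outside 0..{it.n_steps}"
            )
        items.append(it)
        xs.append(int(x))
    return items, np.asarray(xs)


def estimate_theta(
    responses: Mapping[int, int],
    bank: ItemBank,
    theta_bound: float = 4.0,
    *,
    start: float = 0.0,
    reliability_form: str = "paper",
    tol: float = 1e-5,
    max_iter: int = 50,
) -> PersonEstimate:
    """Maximum-likelihood ability estimate from an item_id -> category map.

    Newton steps on the score equation are clamped to 1.0 logit per iteration
    and the estimate is confined to [-theta_bound, theta_bound]; convergence
    when the proposed step falls below ``tol``.  Extreme response vectors
    (all-minimum or all-maximum) have no finite maximizer and are clamped to
    the bound with ``at_bound`` set.
    """
    items, xs = _check_responses(responses, bank)
    delta_pad = _padded_thresholds(items)
    total = int(xs.sum())
    max_total = sum(it.n_steps for it in items)

    if total == 0 or total == max_total:
        theta = -theta_bound if total == 0 else theta_bound
        _, info = _moments(np.asarray(theta), delta_pad)
        sem = 1.0 / np.sqrt(info.sum())
        return PersonEstimate(
            theta=float(theta),
            sem=float(sem),
            reliability=reliability_from_sem(sem, reliability_form),
            n_items=len(items),
            converged=True,
            at_bound=True,
        )

    theta = float(np.clip(start, -theta_bound, theta_bound))
    converged = False
    for _ in range(max_iter):
        mean, info = _moments(np.asarray(theta), delta_pad)
        score = float((xs - mean).sum())
        step = float(np.clip(score / info.sum(), -1.0, 1.0))
        theta = float(np.clip(theta + step, -theta_bound, theta_bound))
        if abs(step) < tol:
            converged = True
            break

    _, info = _moments(np.asarray(theta), delta_pad)
    sem = float(1.0 / np.sqrt(info.sum()))
    return PersonEstimate(
        theta=theta,
        sem=sem,
        reliability=reliability_from_sem(sem, reliability_form),
        n_items=len(items),
        converged=converged,
        at_bound=abs(theta) >= theta_bound,
    )


_ZERO_INFO = 1e-12


def person_fit(
    responses: Mapping[int, int], bank: ItemBank, theta: float
) -> FitStats:
    """Infit/outfit MNSQ of one response vector at ability ``theta``.

    Items with numerically zero information at theta carry no residual
    information and are excluded from the sums (with a warning).
    """
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    items, xs = _check_responses(responses, bank)
    mean, info = _moments(np.asarray(float(theta)), _padded_thresholds(items))
    keep = info > _ZERO_INFO
    if not keep.all():
        dropped = [it.item_id for it, k in zip(items, keep) if not k]
        warnings.warn(
            f"items {dropped} have ~zero information at theta={theta:.2f}; "
            "excluded from fit statistics"
        )
    if not keep.any():
        raise ValueError("no item carries information at this theta")
    resid = (xs - mean)[keep]
    w = info[keep]
    outfit = float(np.mean(resid**2 / w))
    infit = float((resid**2).sum() / w.sum())
    return FitStats(
        infit_mnsq=infit,
        outfit_mnsq=outfit,
        aberrant=outfit >= OUTFIT_ABERRANT,
    )


def item_fit(
    responses: np.ndarray,
    thetas: Sequence[float],
    bank: ItemBank,
    item_ids: Sequence[int],
) -> "pd.DataFrame":
    """Item-level infit/outfit MNSQ, pooling person residuals per item.

    ``responses`` is a persons x items score matrix aligned with ``item_ids``
    and ``thetas``.  Returns a DataFrame indexed by item_id with columns
    infit_mnsq / outfit_mnsq.
    """
    import pandas as pd

    items = [bank[i] for i in item_ids]
    delta_pad = _padded_thresholds(items)
    mean, info = _moments(np.asarray(thetas, dtype=float), delta_pad)
    resid2 = (np.asarray(responses) - mean) ** 2
    keep = info > _ZERO_INFO
    resid2 = np.where(keep, resid2, 0.0)
    z2 = np.where(keep, resid2 / np.where(keep, info, 1.0), np.nan)
    outfit = np.nanmean(z2, axis=0)
    infit = resid2.sum(axis=0) / np.where(keep, info, 0.0).sum(axis=0)
    return pd.DataFrame(
        {"infit_mnsq": infit, "outfit_mnsq": outfit},
        index=pd.Index(list(item_ids), name="item_id"),
    )


def trend_diagnostics(
    theta_history: Sequence[float], window: int = 5
) -> TrendDiagnostics:
    """Convergence diagnostics over an ability trace.

    Requires at least ``window + 1`` values (``window`` changes).  The
    residual is the mean absolute change across the last ``window``
    consecutive updates; the trend correlation is the Pearson correlation of
    the last ``window`` ability values with their step indices, defined as 0
    when the values have zero variance.
    """
    hist = np.asarray(theta_history, dtype=float)
    if len(hist) < window + 1:
        raise ValueError(
            f"insufficient steps: need >= {window + 1} ability values, got {len(hist)}"
        )
    tail = hist[-(window + 1):]
    residual = float(np.mean(np.abs(np.diff(tail))))
    last = hist[-window:]
    if np.ptp(last) == 0.0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(np.arange(window), last)[0, 1])
    return TrendDiagnostics(residual=residual, trend_corr=corr)
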