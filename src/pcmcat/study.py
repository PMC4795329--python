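"""Scenario study: adaptive testing vs full-form and random short-form.

One simulated cohort (abilities ~ Normal, responses under the PCM) is scored
three ways:

* AAI — answering all pool items (the full long form);
* RSM — a fresh uniformly-drawn subset of ``rsm_k`` pool items per person
  (random short form);
* CAT — an adaptive session per person, played against that person's
  pre-simulated responses as the answer oracle.

CAT final scores are computed either from the administered items only or
after expected-response imputation of the unanswered pool items
(``cat_scoring``).  The report mirrors the accuracy/efficiency comparison
tables used for such designs: Pearson correlations among true abilities, the
three estimate sets and the raw summation scores, plus per-column means, SDs
and mean administered item counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cat import StopRules, impute_unanswered, run_cat
from .estimation import estimate_theta
from .item_bank import ItemBank
from .pcm import CohortData, simulate_cohort

__all__ = ["ScenarioComparison", "run_scenarios", "correlation_table", "write_report"]

# Correlation-table layout: true ability, then estimates, then raw sums.
_CORR_COLUMNS = ["true", "cat_est", "aai_est", "rsm_est", "rsm_sum", "aai_sum"]

# Tagged substream labels so study-level draws never collide with the
# per-person cohort substreams [seed, i].
_RSM_TAG = 999_999_937
_CAT_TAG = 888_888_887


@dataclass(frozen=True)
class ScenarioComparison:
    """Per-person results and config echo for one three-scenario run."""

    persons: pd.DataFrame
    seed: int
    rules: StopRules
    rsm_k: int
    cat_scoring: str

    @property
    def mean_items(self) -> dict[str, float]:
        return {
            s: float(self.persons[f"{s}_n"].mean()) for s in ("aai", "rsm", "cat")
        }


def run_scenarios(
    bank: ItemBank,
    n_persons: int = 1000,
    seed: int = 0,
    rules: StopRules | None = None,
    rsm_k: int = 12,
    cat_scoring: str = "administered_only",
    *,
    theta_mean: float = 0.0,
    theta_sd: float = 1.0,
    theta_bound: float = 4.0,
    cohort: CohortData | None = None,
) -> ScenarioComparison:
    """Score one simulated cohort under the three scenarios.

    The same cohort (same responses) feeds every scenario; the CAT oracle
    simply looks answers up in the person's pre-simulated response row.
    With ``cat_scoring="imputed"`` the unanswered pool items are filled with
    expected responses at the final ability and the person is re-scored from
    the completed pool.  Deterministic given ``seed``.
    """
    rules = rules or StopRules()
    if cat_scoring not in ("administered_only", "imputed"):
        raise ValueError(f"unknown cat_scoring {cat_scoring!r}")
    pool = list(bank.pool_ids)
    if rsm_k > len(pool):
        raise ValueError(f"rsm_k={rsm_k} exceeds pool size {len(pool)}")
    if cohort is None:
        cohort = simulate_cohort(bank, n_persons, theta_mean, theta_sd, seed)

    rsm_rng = np.random.default_rng([seed, _RSM_TAG])
    rows = []
    for i in range(cohort.n_persons):
        full = cohort.person_responses(i)

        aai = estimate_theta(full, bank, theta_bound)
        row = {
            "true_theta": cohort.true_theta[i],
            "aai_theta": aai.theta,
            "aai_sum": sum(full.values()),
            "aai_n": len(full),
            "aai_at_bound": aai.at_bound,
        }

        subset = sorted(rsm_rng.choice(pool, size=rsm_k, replace=False).tolist())
        rsm_resp = {iid: full[iid] for iid in subset}
        rsm = estimate_theta(rsm_resp, bank, theta_bound)
        row.update(
            rsm_theta=rsm.theta,
            rsm_sum=sum(rsm_resp.values()),
            rsm_n=rsm_k,
            rsm_at_bound=rsm.at_bound,
        )

        session = run_cat(
            lambda iid: full[iid],
            bank,
            rules,
            seed=[seed, _CAT_TAG, i],
            theta_bound=theta_bound,
        )
        if cat_scoring == "imputed":
            completed = impute_unanswered(session, bank)
            cat_est = estimate_theta(completed, bank, theta_bound)
            cat_theta, cat_sum = cat_est.theta, sum(completed.values())
            cat_bound = cat_est.at_bound
        else:
            cat_theta = session.final.theta
            cat_sum = sum(session.responses.values())
            cat_bound = session.final.at_bound
        row.update(
            cat_theta=cat_theta,
            cat_sum=cat_sum,
            cat_n=len(session.administered),
            cat_at_bound=cat_bound,
            cat_stop_reason=session.stop_reason,
        )
        rows.append(row)

    return ScenarioComparison(
        persons=pd.DataFrame(rows),
        seed=seed,
        rules=rules,
        rsm_k=rsm_k,
        cat_scoring=cat_scoring,
    )


def correlation_table(comparison: ScenarioComparison) -> pd.DataFrame:
    """Pearson correlations among true ability, estimates and raw sums.

    Bounded (extreme-score) estimates are included.  A zero-variance column
    yields NaN entries, pandas' undefined-correlation marker.
    """
    p = comparison.persons
    if len(p) < 3:
        raise ValueError("need at least 3 persons for a correlation table")
    frame = pd.DataFrame(
        {
            "true": p["true_theta"],
            "cat_est": p["cat_theta"],
            "aai_est": p["aai_theta"],
            "rsm_est": p["rsm_theta"],
            "rsm_sum": p["rsm_sum"],
            "aai_sum": p["aai_sum"],
        }
    )[_CORR_COLUMNS]
    return frame.corr(method="pearson")


def summary_table(comparison: ScenarioComparison) -> pd.DataFrame:
    """Column means, SDs, and mean administered item counts."""
    p = comparison.persons
    cols = {
        "true": p["true_theta"],
        "cat_est": p["cat_theta"],
        "aai_est": p["aai_theta"],
        "rsm_est": p["rsm_theta"],
        "rsm_sum": p["rsm_sum"],
        "aai_sum": p["aai_sum"],
    }
    mean_items = comparison.mean_items
    items_row = {
        "cat_est": mean_items["cat"],
        "aai_est": mean_items["aai"],
        "rsm_est": mean_items["rsm"],
        "rsm_sum": mean_items["rsm"],
        "aai_sum": mean_items["aai"],
    }
    return pd.DataFrame(
        {
            name: {
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)),
                "mean_items": items_row.get(name, np.nan),
            }
            for name, s in cols.items()
        }
    ).T[["mean", "sd", "mean_items"]]


def write_report(comparison: ScenarioComparison, path: str | Path) -> dict[str, Path]:
    """Write the study report to a directory.

    Emits ``persons.csv`` (one row per person: true ability and each
    scenario's estimate, raw sum and item count), ``correlations.csv`` (the
    correlation matrix with mean/SD/mean-item rows appended) and
    ``run_log.json`` (seed and configuration).  Two runs with the same seed
    produce byte-identical files.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    persons_path = outdir / "persons.csv"
    corr_path = outdir / "correlations.csv"
    log_path = outdir / "run_log.json"

    comparison.persons.to_csv(persons_path, index=False)

    corr = correlation_table(comparison)
    summary = summary_table(comparison).T  # rows: mean, sd, mean_items
    block = pd.concat([corr, summary.reindex(columns=corr.columns)])
    block.to_csv(corr_path, index_label="")

    rules = comparison.rules
    log = {
        "seed": comparison.seed,
        "n_persons": int(len(comparison.persons)),
        "rsm_k": comparison.rsm_k,
        "cat_scoring": comparison.cat_scoring,
        "stop_rules": {
            "min_items": rules.min_items,
            "reliability_target": rules.reliability_target,
            "residual_threshold": rules.residual_threshold,
            "window": rules.window,
            "max_items": rules.max_items,
        },
        "mean_items": comparison.mean_items,
    }
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return {"persons": persons_path, "correlations": corr_path, "log": log_path}
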