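"""Flow-comparison metrics and period-split evaluation summaries.

Two metrics compare a generated flow vector y^g with an observed one y^r
over the same set of OD pairs:

* CPC (Common Part of Commuters, the Sorensen-Dice index)
      CPC = 2 * sum_i min(g_i, r_i) / (sum_i g_i + sum_i r_i)
  in [0, 1], symmetric, scale-invariant; when the two totals agree it equals
  the fraction of unit trips allocated to the correct destination.

* Information Gain (a KL-style non-negative error, natural log)
      IG = sum_i (r_i / N) * log(r_i / g_i),   N = sum_i r_i
  with the 0*log(0) = 0 convention for r_i = 0; zero generated entries are
  floored at a small epsilon (reported) to keep IG finite.

The evaluation protocol computes both per day over the pairs observed that
day and summarises with mean/max/min CPC over the full window, mean CPC over
two sub-periods (P1: before widespread interventions, default
2020-03-05..2020-03-15; P2: the rest), and mean IG.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import FlowPanel
from .errors import AlignmentError, ValidationError

#: marker for a metric that is undefined on its input (e.g. two all-zero vectors)
UNDEFINED = float("nan")

DEFAULT_P1_END = _dt.date(2020, 3, 15)
DEFAULT_IG_FLOOR = 1e-10


def cpc(generated, real) -> float:
    """Common Part of Commuters between two flow vectors on the same pairs.

    Returns NaN (the undefined marker) when both totals are zero.
    """
    g = np.asarray(generated, dtype=float)
    r = np.asarray(real, dtype=float)
    if g.shape != r.shape:
        raise ValidationError(f"flow vectors differ in shape: {g.shape} vs {r.shape}")
    denom = g.sum() + r.sum()
    if denom == 0:
        return UNDEFINED
    return float(2.0 * np.minimum(g, r).sum() / denom)


def information_gain(real, generated, floor: float = DEFAULT_IG_FLOOR) -> tuple[float, int]:
    """Information gain of the observed flows relative to the generated ones.

    Natural logarithm; observed zeros contribute nothing; generated entries
    below *floor* are clipped up to it to keep the sum finite.  Returns
    ``(ig, n_floored)``; ig is NaN when the observed total is zero.
    """
    r = np.asarray(real, dtype=float)
    g = np.asarray(generated, dtype=float)
    if g.shape != r.shape:
        raise ValidationError(f"flow vectors differ in shape: {g.shape} vs {r.shape}")
    n_total = r.sum()
    if n_total == 0:
        return UNDEFINED, 0
    floored = int(((g < floor) & (r > 0)).sum())
    g = np.maximum(g, floor)
    mask = r > 0
    ig = float(np.sum((r[mask] / n_total) * np.log(r[mask] / g[mask])))
    return ig, floored


def relative_improvement(new_value: float, baseline_value: float) -> float:
    """rel(new, baseline) = (new - baseline) / baseline; NaN for zero baseline.

    When applied to daily metric series, compute it per day and average the
    ratios (average-of-ratios, not ratio-of-averages).
    """
    if baseline_value == 0:
        return UNDEFINED
    return (new_value - baseline_value) / baseline_value


@dataclass
class EvaluationResult:
    """Per-day metric series and the period-split summary table."""

    daily: pd.DataFrame  # model, date, cpc, ig, n_pairs, n_floored
    summary: pd.DataFrame  # model, mu_cpc, max_cpc, min_cpc, mu_cpc_p1, mu_cpc_p2, mu_ig


def _prediction_frame(pred) -> pd.DataFrame:
    df = pred.df if isinstance(pred, FlowPanel) else pred
    needed = {"date", "origin", "destination", "flow"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"prediction table needs columns {sorted(needed)}")
    return df


def evaluate(
    predictions: dict[str, pd.DataFrame | FlowPanel],
    observed: FlowPanel,
    p1_end: _dt.date = DEFAULT_P1_END,
    ig_floor: float = DEFAULT_IG_FLOOR,
) -> EvaluationResult:
    """Per-day CPC and IG of each model against the observed panel.

    The pair universe each day is the set of (origin, destination) pairs
    present in the observed panel that day; a prediction for a pair outside
    that universe is an error, and predicted pairs may not miss observed
    days.  Missing predictions within the universe count as zero flow.
    """
    obs = observed.df
    obs_dates = set(obs["date"])
    daily_rows = []
    for model, pred in predictions.items():
        pdf = _prediction_frame(pred)
        missing_days = sorted(obs_dates - set(pdf["date"]))
        if missing_days:
            raise AlignmentError(
                f"model {model!r} predicts no flows for observed day(s) "
                f"{[d.isoformat() for d in missing_days[:5]]}"
            )
        merged = obs.merge(
            pdf,
            on=["date", "origin", "destination"],
            how="outer",
            suffixes=("_obs", "_pred"),
            indicator=True,
        )
        extra = merged["_merge"] == "right_only"
        if extra.any():
            bad = merged.loc[extra].iloc[0]
            raise ValidationError(
                f"model {model!r} predicts pair ({bad.origin}, {bad.destination}) on "
                f"{bad.date}, which is absent from the observed panel"
            )
        merged["flow_pred"] = merged["flow_pred"].fillna(0.0)
        for date, day in merged.groupby("date"):
            ig, floored = information_gain(day["flow_obs"], day["flow_pred"], floor=ig_floor)
            daily_rows.append(
                {
                    "model": model,
                    "date": date,
                    "cpc": cpc(day["flow_pred"], day["flow_obs"]),
                    "ig": ig,
                    "n_pairs": len(day),
                    "n_floored": floored,
                }
            )
    daily = pd.DataFrame(daily_rows).sort_values(["model", "date"]).reset_index(drop=True)

    summary_rows = []
    for model, sub in daily.groupby("model", sort=False):
        in_p1 = sub["date"] <= p1_end
        summary_rows.append(
            {
                "model": model,
                "mu_cpc": sub["cpc"].mean(),
                "max_cpc": sub["cpc"].max(),
                "min_cpc": sub["cpc"].min(),
                "mu_cpc_p1": sub.loc[in_p1, "cpc"].mean() if in_p1.any() else UNDEFINED,
                "mu_cpc_p2": sub.loc[~in_p1, "cpc"].mean() if (~in_p1).any() else UNDEFINED,
                "mu_ig": sub["ig"].mean(),
            }
        )
    summary = pd.DataFrame(summary_rows)
    return EvaluationResult(daily=daily, summary=summary)


def mean_relative_improvement(daily: pd.DataFrame, model: str, baseline: str) -> float:
    """Average per-day relative improvement of one model's CPC over another's.

    Matches the reporting convention: rel() is computed for each day's CPC
    pair and the daily ratios are averaged.
    """
    a = daily.loc[daily["model"] == model].set_index("date")["cpc"]
    b = daily.loc[daily["model"] == baseline].set_index("date")["cpc"]
    if set(a.index) != set(b.index):
        raise AlignmentError(f"models {model!r} and {baseline!r} cover different days")
    idx = sorted(a.index)
    rels = [relative_improvement(a[d], b[d]) for d in idx]
    rels = [x for x in rels if not math.isnan(x)]
    return float(np.mean(rels)) if rels else UNDEFINED
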