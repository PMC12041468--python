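"""Progression-free survival derivation and expression-quartile stratification.

PFS is the time to death or new tumor event, censored at last follow-up.
Samples are stratified into a high group (expression strictly above the 75th
percentile) and a low group (strictly below the 25th percentile); ties at the
quartile boundaries are excluded.  The two groups are compared with the
two-group log-rank test (chi-square, 1 df, two-sided) and Kaplan-Meier
estimates are returned for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


def derive_pfs(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive PFS time/event from clinical follow-up fields.

    Expected columns (missing values allowed): ``days_to_last_follow_up``,
    ``death_days_to``, ``new_tumor_event``.  Event = 1 when a death or new
    tumor event day is recorded; time = earliest event day, otherwise last
    follow-up with event = 0.  Rows with nonpositive or missing time are
    dropped (count logged).
    """
    needed = {"days_to_last_follow_up", "death_days_to", "new_tumor_event"}
    missing_cols = needed - set(clinical.columns)
    if missing_cols:
        raise ValueError(f"clinical table lacks columns {sorted(missing_cols)}")
    rows = []
    dropped = 0
    for sample, row in clinical.iterrows():
        death = pd.to_numeric(row["death_days_to"], errors="coerce")
        relapse = pd.to_numeric(row["new_tumor_event"], errors="coerce")
        follow = pd.to_numeric(row["days_to_last_follow_up"], errors="coerce")
        event_times = [t for t in (death, relapse) if pd.notna(t)]
        if event_times:
            time, event = min(event_times), 1
        elif pd.notna(follow):
            time, event = follow, 0
        else:
            dropped += 1
            continue
        if time <= 0:
            dropped += 1
            continue
        rows.append({"sample": sample, "time": float(time), "event": int(event)})
    if dropped:
        logger.info("derive_pfs: dropped %d rows with missing/nonpositive times", dropped)
    if not rows:
        raise ValueError("no usable survival rows")
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class QuartileLogrankResult:
    statistic: float
    p_value: float
    high_samples: list
    low_samples: list
    km_high: pd.DataFrame  # Kaplan-Meier survival estimate, high group
    km_low: pd.DataFrame


def quartile_logrank(
    values: pd.Series,
    survival: pd.DataFrame,
    quantile: float = 0.25,
) -> QuartileLogrankResult:
    """Compare PFS between top- and bottom-quartile expression groups.

    High = samples with value strictly above the (1 - quantile) quantile,
    low = strictly below the ``quantile`` quantile; boundary ties are
    excluded.  Returns the log-rank chi-square (1 df), two-sided p, the
    group memberships and KM survival curves.
    """
    shared = values.index.intersection(survival.index)
    if len(shared) < 8:
        raise ValueError("need at least 8 samples with both expression and survival")
    v = values.loc[shared].astype(float)
    # midpoint interpolation keeps both groups non-empty for bimodal values
    q_low = v.quantile(quantile, interpolation="midpoint")
    q_high = v.quantile(1 - quantile, interpolation="midpoint")
    high = v.index[v > q_high].tolist()
    low = v.index[v < q_low].tolist()
    if not high or not low:
        raise ValueError(
            "a quartile group is empty after boundary-tie exclusion; "
            "consider a different quantile method or cutoff"
        )
    th, eh = survival.loc[high, "time"], survival.loc[high, "event"]
    tl, el = survival.loc[low, "time"], survival.loc[low, "event"]
    res = logrank_test(th, tl, event_observed_A=eh, event_observed_B=el)

    def km(t, e):
        fitter = KaplanMeierFitter()
        fitter.fit(t, e)
        return fitter.survival_function_.rename(columns={"KM_estimate": "survival"})

    return QuartileLogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        high_samples=high,
        low_samples=low,
        km_high=km(th, eh),
        km_low=km(tl, el),
    )
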