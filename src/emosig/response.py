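"""Responder / non-responder classification from emotionality change.

An animal responds to treatment when its composite emotionality score
drops by at least ``threshold_pct`` percent between a baseline round and
a follow-up round (the clinical ">= 50% improvement" convention; the
boundary counts as response).  Percent change of a signed score is
ill-defined near zero, so animals whose baseline does not exceed a small
positive floor are reported as ``indeterminate`` rather than classified
from an unstable ratio.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import SchemaError, StatsPreconditionError

logger = logging.getLogger(__name__)

CALLS = ("responder", "non_responder", "indeterminate")


def classify_responders(
    scores: pd.DataFrame,
    baseline_session: str = "W5",
    followup_session: str = "W10",
    threshold_pct: float = 50.0,
    baseline_floor: float = 0.1,
    groups: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each animal from its score change between two sessions.

    Returns ``(calls, exclusions)``.  ``calls`` has one row per animal
    present at both sessions: ``animal, group, baseline, followup,
    percent_reduction, call``.  ``exclusions`` lists animals missing a
    session, with the reason — they are reported, not silently dropped.

    ``groups`` optionally restricts classification to the treated arms.
    """
    if not 0 < threshold_pct <= 100:
        raise SchemaError("threshold_pct must be in (0, 100]")
    required = {"animal", "group", "session", "emotionality"}
    missing = required - set(scores.columns)
    if missing:
        raise SchemaError(f"score table missing columns: {sorted(missing)}")

    sub = scores if groups is None else scores[scores["group"].isin(groups)]
    wide = sub.pivot_table(
        index=["animal", "group"], columns="session", values="emotionality", aggfunc="first"
    )

    calls, exclusions = [], []
    for (animal, group), row in wide.iterrows():
        base = row.get(baseline_session)
        follow = row.get(followup_session)
        if pd.isna(base) or pd.isna(follow):
            which = baseline_session if pd.isna(base) else followup_session
            exclusions.append(
                {"animal": animal, "group": group, "reason": f"missing session {which}"}
            )
            continue
        pct = 100.0 * (base - follow) / base if base != 0 else float("nan")
        if base <= baseline_floor:
            call = "indeterminate"
        elif pct >= threshold_pct:
            call = "responder"
        else:
            call = "non_responder"
        calls.append(
            {
                "animal": animal,
                "group": group,
                "baseline": float(base),
                "followup": float(follow),
                "percent_reduction": float(pct),
                "call": call,
            }
        )
    calls_df = pd.DataFrame(
        calls, columns=["animal", "group", "baseline", "followup", "percent_reduction", "call"]
    )
    excl_df = pd.DataFrame(exclusions, columns=["animal", "group", "reason"])
    return calls_df, excl_df


def response_rate(calls: pd.DataFrame) -> float:
    """Fraction of determinate animals classified as responders.

    Indeterminate animals are excluded from the denominator (logged);
    raises :class:`StatsPreconditionError` when no determinate call
    exists.
    """
    counts = calls["call"].value_counts()
    n_resp = int(counts.get("responder", 0))
    n_non = int(counts.get("non_responder", 0))
    n_ind = int(counts.get("indeterminate", 0))
    if n_resp + n_non == 0:
        raise StatsPreconditionError("no determinate responder calls")
    if n_ind:
        logger.info("excluding %d indeterminate animals from the response rate", n_ind)
    return n_resp / (n_resp + n_non)


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary: counts per call plus the response rate."""
    counts = calls["call"].value_counts()
    rows = [{"metric": f"n_{c}", "value": int(counts.get(c, 0))} for c in CALLS]
    try:
        rows.append({"metric": "response_rate", "value": response_rate(calls)})
    except StatsPreconditionError:
        pass
    return pd.DataFrame(rows)
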