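"""Composite behavioral emotionality scoring.

Each raw measure is z-standardized against the vehicle (control) group of
the same behavioral round, z = (x - mu) / sigma, and signed so that a
larger value always means greater anxio-depressive behavior: less time
and fewer entries in the open arms of the elevated plus maze, a longer
latency to feed in novelty-suppressed feeding, and less grooming in the
splash test.  Signed z-scores are averaged within each test first and
then across the three tests, weighting the tests equally, to give one
composite emotionality score per animal per session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, SchemaError, StatsPreconditionError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasureSpec:
    """A scored behavioral measure: which test it belongs to and the sign
    that maps it onto the emotionality axis (+1 if larger raw values mean
    more emotionality, -1 otherwise)."""

    test: str
    measure: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise SchemaError(f"direction must be +1 or -1, got {self.direction}")


#: The default battery: EPM contributes two measures, NSF and ST one
#: each.  Home-cage food consumption is an appetite control, not a score
#: component, and is deliberately absent.
DEFAULT_MEASURES: tuple[MeasureSpec, ...] = (
    MeasureSpec("EPM", "open_arm_time", -1),
    MeasureSpec("EPM", "open_arm_entries", -1),
    MeasureSpec("NSF", "latency_to_feed", +1),
    MeasureSpec("ST", "grooming_duration", -1),
)


def reference_stats(
    data: pd.DataFrame,
    control_group: str,
    session: str,
    specs: Sequence[MeasureSpec] = DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Per-measure control-group mean and SD for one session.

    Returns a DataFrame indexed by measure with columns ``mu``, ``sigma``
    and ``n``; sigma uses the sample (n-1) convention.  Raises
    :class:`DegenerateReferenceError` naming the measure if any control
    SD is zero, and :class:`StatsPreconditionError` if fewer than two
    control animals carry a measure.
    """
    wanted = {s.measure for s in specs}
    ctrl = data[
        (data["group"] == control_group)
        & (data["session"] == session)
        & (data["measure"].isin(wanted))
    ]
    if ctrl.empty:
        raise StatsPreconditionError(
            f"no rows for control group {control_group!r} in session {session!r}"
        )
    out = {}
    for measure in sorted(wanted):
        vals = ctrl.loc[ctrl["measure"] == measure, "value"].dropna().to_numpy(float)
        if len(vals) < 2:
            raise StatsPreconditionError(
                f"control group {control_group!r} has fewer than 2 values for "
                f"measure {measure!r} in session {session!r}"
            )
        mu = float(np.mean(vals))
        sigma = float(np.std(vals, ddof=1))
        if sigma == 0.0:
            raise DegenerateReferenceError(
                f"control SD is zero for measure {measure!r} in session {session!r}"
            )
        out[measure] = (mu, sigma, len(vals))
    df = pd.DataFrame.from_dict(out, orient="index", columns=["mu", "sigma", "n"])
    df.index.name = "measure"
    return df


def zscore(x: float, mu: float, sigma: float, direction: int) -> float:
    """Signed standard score ``direction * (x - mu) / sigma``.

    Missing observations propagate as NaN, never as zero.
    """
    if sigma <= 0:
        raise DegenerateReferenceError("sigma must be positive")
    return direction * (x - mu) / sigma


def emotionality_scores(
    data: pd.DataFrame,
    specs: Sequence[MeasureSpec] = DEFAULT_MEASURES,
    control_group: str = "Veh/Veh",
    sessions: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Compute per-animal composite emotionality scores.

    For each session, measures are z-scored against that session's
    control group, averaged within test, then across tests.  Animals
    missing single measures have them dropped from the within-test mean;
    an animal missing an entire test gets a composite over the remaining
    tests and a logged warning.

    Returns a DataFrame with columns ``animal, group, session``, one
    ``z_<TEST>`` column per test, and ``emotionality``.
    """
    required = {"animal", "group", "session", "measure", "value"}
    missing_cols = required - set(data.columns)
    if missing_cols:
        raise SchemaError(f"behavior table missing columns: {sorted(missing_cols)}")
    if control_group not in set(data["group"]):
        raise SchemaError(f"control group {control_group!r} not present in data")

    spec_by_measure = {s.measure: s for s in specs}
    tests = sorted({s.test for s in specs})
    sessions = list(sessions) if sessions is not None else sorted(data["session"].unique())

    records = []
    for session in sessions:
        ref = reference_stats(data, control_group, session, specs)
        sub = data[(data["session"] == session) & (data["measure"].isin(spec_by_measure))]
        for (animal, group), rows in sub.groupby(["animal", "group"], sort=True):
            per_test: dict[str, float] = {}
            for test in tests:
                zs = []
                for _, r in rows.iterrows():
                    spec = spec_by_measure[r["measure"]]
                    if spec.test != test or pd.isna(r["value"]):
                        continue
                    zs.append(
                        zscore(
                            float(r["value"]),
                            ref.loc[r["measure"], "mu"],
                            ref.loc[r["measure"], "sigma"],
                            spec.direction,
                        )
                    )
                per_test[test] = float(np.mean(zs)) if zs else np.nan
            available = [v for v in per_test.values() if not np.isnan(v)]
            if len(available) < len(tests):
                logger.warning(
                    "animal %s session %s: missing %d test(s); composite over %d",
                    animal,
                    session,
                    len(tests) - len(available),
                    len(available),
                )
            composite = float(np.mean(available)) if available else np.nan
            rec = {"animal": animal, "group": group, "session": session}
            rec.update({f"z_{t}": per_test[t] for t in tests})
            rec["emotionality"] = composite
            records.append(rec)
    return pd.DataFrame.from_records(records)
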