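"""Behavioral inference: normality-gated location tests and censored
latency analysis.

The novelty-suppressed-feeding latency is right-censored at the end of
the 10-minute window, so group comparisons use the Kaplan-Meier
product-limit estimator ("fraction that have not eaten") and the
Mantel-Cox log-rank test.  Other behavioral endpoints go through a
Shapiro-Wilk normality gate that selects a parametric (Student t /
one-way ANOVA with Fisher's LSD) or non-parametric (Mann-Whitney /
Kruskal-Wallis with Dunn) path; if ANY group fails the gate the
non-parametric path is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import StatsPreconditionError

ALPHA = 0.05  # study-wide significance threshold


@dataclass
class TestReport:
    name: str
    statistic: float
    df: float | None
    pvalue: float
    parametric: bool | None = None
    shapiro_p: dict[str, float] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def to_row(self) -> dict:
        gate = "" if self.parametric is None else ("parametric" if self.parametric else "nonparametric")
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df if self.df is not None else "",
            "pvalue": self.pvalue,
            "gate": gate,
            "shapiro_p": ";".join(f"{g}={p:.4g}" for g, p in self.shapiro_p.items()),
        }


def _check_latencies(lat: np.ndarray, cens: np.ndarray, group: str, cap: float | None) -> None:
    if lat.size == 0:
        raise StatsPreconditionError(f"empty latency group {group!r}")
    if np.any(lat <= 0):
        raise StatsPreconditionError(f"non-positive latency in group {group!r}")
    if cap is not None and np.any(cens & (lat != cap)):
        raise StatsPreconditionError(
            f"censored latency differs from the cap in group {group!r}"
        )


def km_estimate(
    samples: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    cap: float | None = 600.0,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    ``samples`` maps group -> (latencies, censored flags); censored
    animals never count as events.  Each returned DataFrame is a step
    table ``time, survival, at_risk`` starting at (0, 1).
    """
    out = {}
    for group, (lat, cens) in samples.items():
        lat = np.asarray(lat, float)
        cens = np.asarray(cens, bool)
        _check_latencies(lat, cens, group, cap)
        kmf = KaplanMeierFitter()
        kmf.fit(lat, event_observed=~cens)
        tbl = kmf.event_table
        surv = kmf.survival_function_
        df = pd.DataFrame(
            {
                "time": surv.index.to_numpy(float),
                "survival": surv.iloc[:, 0].to_numpy(float),
                "at_risk": tbl["at_risk"].reindex(surv.index).fillna(0).to_numpy(int),
            }
        )
        out[group] = df.reset_index(drop=True)
    return out


def logrank_test(
    latencies_a: Sequence[float],
    censored_a: Sequence[bool],
    latencies_b: Sequence[float],
    censored_b: Sequence[bool],
) -> TestReport:
    """Mantel-Cox log-rank comparison of two censored latency samples.

    Chi-square statistic with 1 df; requires at least one observed event
    overall.
    """
    la, ca = np.asarray(latencies_a, float), np.asarray(censored_a, bool)
    lb, cb = np.asarray(latencies_b, float), np.asarray(censored_b, bool)
    _check_latencies(la, ca, "A", None)
    _check_latencies(lb, cb, "B", None)
    if int((~ca).sum() + (~cb).sum()) == 0:
        raise StatsPreconditionError("log-rank test requires at least one event")
    res = _ll_logrank(la, lb, event_observed_A=~ca, event_observed_B=~cb)
    return TestReport(
        name="logrank",
        statistic=float(res.test_statistic),
        df=1,
        pvalue=float(res.p_value),
    )


def _fisher_lsd(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Unprotected pairwise t-tests using the pooled ANOVA error term."""
    names = list(groups)
    ns = {g: len(groups[g]) for g in names}
    n_total = sum(ns.values())
    k = len(names)
    ssw = sum(float(np.sum((groups[g] - groups[g].mean()) ** 2)) for g in names)
    dfe = n_total - k
    mse = ssw / dfe
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = groups[a].mean() - groups[b].mean()
            se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
            t = diff / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), dfe) if np.isfinite(t) else np.nan
            rows.append({"group_a": a, "group_b": b, "statistic": t, "pvalue": p})
    return pd.DataFrame(rows)


def _dunn(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests (tie-corrected, uncorrected p)."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    mean_ranks, sizes, pos = {}, {}, 0
    for g in names:
        m = len(groups[g])
        mean_ranks[g] = ranks[pos : pos + m].mean()
        sizes[g] = m
        pos += m
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(base_var * (1 / sizes[a] + 1 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"group_a": a, "group_b": b, "statistic": z, "pvalue": p})
    return pd.DataFrame(rows)


def gated_location_test(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
) -> TestReport:
    """Two- or k-group location comparison behind a Shapiro-Wilk gate.

    All groups normal at ``alpha`` -> Student t (2 groups) or one-way
    ANOVA with Fisher's LSD post-hoc (k > 2); otherwise Mann-Whitney or
    Kruskal-Wallis with Dunn post-hoc.  The report records the gate
    decision and per-group normality p-values.
    """
    arrays = {g: np.asarray(v, float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise StatsPreconditionError("need at least two groups")
    for g, v in arrays.items():
        if len(v) < 3:
            raise StatsPreconditionError(
                f"group {g!r} has n={len(v)} < 3; the normality gate needs >= 3"
            )
    shapiro_p = {g: float(stats.shapiro(v).pvalue) for g, v in arrays.items()}
    parametric = all(p >= alpha for p in shapiro_p.values())
    vals = list(arrays.values())
    posthoc = None
    if len(arrays) == 2:
        if parametric:
            res = stats.ttest_ind(vals[0], vals[1], equal_var=True)
            name, df = "student_t", len(vals[0]) + len(vals[1]) - 2
        else:
            res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
            name, df = "mann_whitney", None
    else:
        if parametric:
            res = stats.f_oneway(*vals)
            name, df = "one_way_anova", len(arrays) - 1
            posthoc = _fisher_lsd(arrays)
        else:
            res = stats.kruskal(*vals)
            name, df = "kruskal_wallis", len(arrays) - 1
            posthoc = _dunn(arrays)
    return TestReport(
        name=name,
        statistic=float(res.statistic),
        df=df,
        pvalue=float(res.pvalue),
        parametric=parametric,
        shapiro_p=shapiro_p,
        posthoc=posthoc,
    )
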