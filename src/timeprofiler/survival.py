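"""Kaplan-Meier estimation and the Gehan-Wilcoxon two-group comparison.

The survival contrast of interest is immune-activated tumors versus the
pooled suppressed + absent tumors (unclassified samples are excluded). The
two-group test is Gehan's generalized Wilcoxon (Gehan-Breslow): a weighted
log-rank with weight w_i = n_i, the total number at risk at each event time,
which emphasizes early deaths. Statistic:

    X^2 = [ sum_i w_i (d_iA - e_iA) ]^2 / sum_i w_i^2 v_i

with hypergeometric expectation e and variance v per event time, referred to
a chi-square with 1 df. Setting w_i = 1 recovers the standard log-rank test
(``weighting='logrank'``).

Ties follow the standard convention: samples censored at t are counted as at
risk through t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "km_estimate",
    "gehan_wilcoxon_test",
    "TwoGroupTestResult",
    "compare_activated_vs_rest",
]


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns ``time``,
    ``n_risk``, ``n_event``, ``n_censored``, ``survival`` and
    ``greenwood_var``. S(t) multiplies (1 - d_i/n_i) over event times <= t;
    a censored-only dataset gives S == 1 throughout.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    greenwood = 0.0
    n_risk = t.size
    for time in np.unique(t):
        at = t == time
        d = int(e[at].sum())
        c = int(at.sum()) - d
        if d > 0:
            surv *= 1.0 - d / n_risk
            if n_risk > d:
                greenwood += d / (n_risk * (n_risk - d))
        rows.append(
            {
                "time": float(time),
                "n_risk": n_risk,
                "n_event": d,
                "n_censored": c,
                "survival": surv,
                "greenwood_var": surv**2 * greenwood,
            }
        )
        n_risk -= int(at.sum())
    return pd.DataFrame(rows)


@dataclass
class TwoGroupTestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    weighting: str = "wilcoxon"


def gehan_wilcoxon_test(
    times_a,
    events_a,
    times_b,
    events_b,
    *,
    weighting: str = "wilcoxon",
) -> TwoGroupTestResult:
    """Weighted log-rank test; ``wilcoxon`` weights w_i = n_i, ``logrank`` 1.

    p is two-sided from the chi-square(1) reference. With no events (or no
    variance) in either group the statistic is 0 and p = 1.
    """
    if weighting not in ("wilcoxon", "logrank"):
        raise ValueError(f"unknown weighting {weighting!r}")
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")

    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])

    u = 0.0
    var = 0.0
    for time in np.unique(t[e == 1]):
        at_risk = t >= time
        n_i = int(at_risk.sum())
        n_ia = int((at_risk & (g == 0)).sum())
        dying = (t == time) & (e == 1)
        d_i = int(dying.sum())
        d_ia = int((dying & (g == 0)).sum())
        e_ia = d_i * n_ia / n_i
        if n_i > 1:
            v_ia = (
                d_i
                * (n_ia / n_i)
                * (1.0 - n_ia / n_i)
                * (n_i - d_i)
                / (n_i - 1)
            )
        else:
            v_ia = 0.0
        w = float(n_i) if weighting == "wilcoxon" else 1.0
        u += w * (d_ia - e_ia)
        var += w * w * v_ia

    if var == 0.0:
        return TwoGroupTestResult(0.0, 1.0, ta.size, tb.size, weighting)
    chi2 = u * u / var
    p = float(stats.chi2.sf(chi2, df=1))
    return TwoGroupTestResult(float(chi2), p, ta.size, tb.size, weighting)


def compare_activated_vs_rest(
    assignment: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str = "os",
    *,
    weighting: str = "wilcoxon",
) -> tuple[dict[str, pd.DataFrame], TwoGroupTestResult]:
    """KM curves + Gehan-Wilcoxon test: activated vs pooled suppressed+absent.

    Unclassified samples are excluded from both arms. ``endpoint`` selects
    the ``os_time``/``os_event`` or ``dfs_time``/``dfs_event`` columns.
    """
    if endpoint not in ("os", "dfs"):
        raise ValueError("endpoint must be 'os' or 'dfs'")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in clinical.columns or ecol not in clinical.columns:
        raise ValueError(f"clinical table lacks {tcol}/{ecol}")

    classified = assignment[assignment != "unclassified"]
    ids = classified.index.intersection(clinical.index)
    sub = clinical.loc[ids, [tcol, ecol]].dropna()
    labels = classified.loc[sub.index]

    act = sub.loc[labels == "activated"]
    rest = sub.loc[labels != "activated"]
    if act.empty or rest.empty:
        raise ValueError("need >= 1 activated and >= 1 non-activated sample "
                         "with the endpoint recorded")
    curves = {
        "activated": km_estimate(act[tcol], act[ecol]),
        "suppressed+absent": km_estimate(rest[tcol], rest[ecol]),
    }
    result = gehan_wilcoxon_test(
        act[tcol], act[ecol], rest[tcol], rest[ecol], weighting=weighting
    )
    return curves, result
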