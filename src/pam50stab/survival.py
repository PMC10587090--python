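"""Survival stratification of classification-derived groups.

Kaplan-Meier estimation, log-rank comparison, and univariate Cox regression
with a designated reference stratum, on the OS (overall survival) or DRFI
(distant recurrence-free interval) endpoints of the clinical table. Cox ties
are handled by lifelines' Efron approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .datatypes import ClinicalTable, ValidationError

ENDPOINTS = {"os": ("os_time", "os_event"), "drfi": ("drfi_time", "drfi_event")}


@dataclass
class KMResult:
    """Per-stratum Kaplan-Meier curves plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]       # columns: time, survival, at_risk
    logrank_statistic: float | None
    logrank_p: float | None
    n_per_stratum: dict[str, int] = field(default_factory=dict)
    events_per_stratum: dict[str, int] = field(default_factory=dict)


def _endpoint_frame(clinical: ClinicalTable, endpoint: str) -> pd.DataFrame:
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}; use 'os' or 'drfi'")
    tcol, ecol = ENDPOINTS[endpoint]
    df = clinical.indexed()[[tcol, ecol]].rename(columns={tcol: "time", ecol: "event"})
    return df.dropna()


def _collect(strata: dict[str, list[str]], surv: pd.DataFrame) -> pd.DataFrame:
    frames = []
    seen: set[str] = set()
    for label, sample_ids in strata.items():
        ids = [s for s in sample_ids if s in surv.index]
        overlap = seen & set(ids)
        if overlap:
            raise ValidationError(
                f"strata overlap: {sorted(overlap)[:5]} in more than one stratum")
        seen |= set(ids)
        if not ids:
            warnings.warn(f"stratum {label!r} has no usable samples; dropped",
                          stacklevel=3)
            continue
        sub = surv.loc[ids].copy()
        sub["stratum"] = label
        frames.append(sub)
    if not frames:
        raise ValidationError("no usable strata")
    return pd.concat(frames)


def km_logrank(
    strata: dict[str, list[str]],
    clinical: ClinicalTable,
    endpoint: str = "os",
) -> KMResult:
    """Kaplan-Meier curves per stratum and the log-rank test across strata.

    Empty strata are dropped with a warning. The (two-sided) log-rank test
    needs at least two usable strata; with fewer, curves are still returned
    and the test fields are None.
    """
    surv = _endpoint_frame(clinical, endpoint)
    data = _collect(strata, surv)
    curves: dict[str, pd.DataFrame] = {}
    n_per, ev_per = {}, {}
    for label, sub in data.groupby("stratum", sort=False):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(label))
        at_risk = kmf.event_table["at_risk"]
        curves[str(label)] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": at_risk.reindex(kmf.survival_function_.index).to_numpy(),
        })
        n_per[str(label)] = len(sub)
        ev_per[str(label)] = int(sub["event"].sum())
    if len(curves) < 2:
        warnings.warn("fewer than two usable strata; log-rank test skipped",
                      stacklevel=2)
        stat = p = None
    else:
        res = multivariate_logrank_test(data["time"], data["stratum"], data["event"])
        stat, p = float(res.test_statistic), float(res.p_value)
    return KMResult(curves=curves, logrank_statistic=stat, logrank_p=p,
                    n_per_stratum=n_per, events_per_stratum=ev_per)


def cox_univariate(
    strata: dict[str, list[str]],
    clinical: ClinicalTable,
    reference_label: str,
    endpoint: str = "drfi",
) -> pd.DataFrame:
    """Univariate Cox model of stratum membership against a reference stratum.

    Fits a proportional-hazards model with the stratum as a single
    categorical covariate (reference = ``reference_label``; Efron tie
    handling; Wald CIs). Returns one row per non-reference stratum with
    ``hr``, ``ci_lower``, ``ci_upper``, ``p``, ``n``, ``events`` and an
    ``unstable`` flag raised on zero events in a stratum or non-convergence.
    """
    if reference_label not in strata:
        raise ValidationError(f"reference stratum {reference_label!r} not given")
    surv = _endpoint_frame(clinical, endpoint)
    data = _collect(strata, surv)
    if reference_label not in set(data["stratum"]):
        raise ValidationError(f"reference stratum {reference_label!r} is empty")
    ref = data[data["stratum"] == reference_label]
    if ref["event"].sum() < 1:
        raise ValidationError("reference stratum has no events")

    rows = []
    for label in [s for s in strata if s != reference_label]:
        sub = data[data["stratum"].isin([reference_label, label])].copy()
        if label not in set(sub["stratum"]):
            continue
        sub["x"] = (sub["stratum"] == label).astype(float)
        n = int(sub["x"].sum())
        events = int(sub.loc[sub["x"] == 1, "event"].sum())
        unstable = events == 0
        hr = lo = hi = p = np.nan
        if not unstable:
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(sub[["time", "event", "x"]], duration_col="time",
                            event_col="event")
                s = cph.summary.loc["x"]
                hr = float(s["exp(coef)"])
                lo = float(s["exp(coef) lower 95%"])
                hi = float(s["exp(coef) upper 95%"])
                p = float(s["p"])
                if not np.isfinite([hr, lo, hi]).all() or hr > 1e6 or hr < 1e-6:
                    unstable = True
            except Exception:  # noqa: BLE001 - separation / convergence failure
                unstable = True
        rows.append({"stratum": label, "hr": hr, "ci_lower": lo, "ci_upper": hi,
                     "p": p, "n": n, "events": events, "unstable": unstable})
    return pd.DataFrame(rows).set_index("stratum")
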