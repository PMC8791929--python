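"""Survival endpoints, Kaplan-Meier estimation and Cox modelling.

Endpoints (all in months from the start of therapy unless noted):

* PFS — time to first progression or death;
* OS — time to death;
* PFS2 — time to second progression or death;
* 2nd PFS — time from first progression to second progression or death
  (defined only for patients with a first progression).

Kaplan-Meier medians are the earliest time the survival curve drops to
0.5 or below; a curve that never does has an explicitly encoded
"not reached" median (None), never a sentinel number.

Cox proportional-hazards models are fitted by lifelines with Efron tie
handling. The multivariable model uses backward elimination at p < 0.05
with the staging adjustment covariate (ISS) always retained; the
elimination order is returned so the selection is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "ClinicalRecord",
    "CollinearityError",
    "CoxResult",
    "DataIntegrityError",
    "ENDPOINTS",
    "KMResult",
    "SurvivalEndpoint",
    "cox_multivariable",
    "cox_univariable",
    "km_fit",
    "make_endpoints",
]

ENDPOINTS = ("PFS", "OS", "PFS2", "PFS_2ND")

DAYS_PER_MONTH = 30.4375


class DataIntegrityError(ValueError):
    """Negative or unordered clinical intervals."""


class CollinearityError(ValueError):
    """Covariate matrix is rank deficient."""


@dataclass(frozen=True)
class ClinicalRecord:
    """Times (months from start of therapy) of one patient's events.

    ``None`` marks an event that was not observed. ``last_followup`` is the
    censoring time used for any unobserved event.
    """

    patient_id: str
    last_followup: float
    first_progression: float | None = None
    second_progression: float | None = None
    death: float | None = None

    def __post_init__(self) -> None:
        times = [
            ("last_followup", self.last_followup),
            ("first_progression", self.first_progression),
            ("second_progression", self.second_progression),
            ("death", self.death),
        ]
        for name, t in times:
            if t is not None and (not np.isfinite(t) or t < 0):
                raise DataIntegrityError(f"{name} must be a non-negative time, got {t}")
        if self.second_progression is not None:
            if self.first_progression is None:
                raise DataIntegrityError(
                    "second progression recorded without a first progression"
                )
            if self.second_progression < self.first_progression:
                raise DataIntegrityError("progressions out of order")
        for name, t in times[1:]:
            if t is not None and t > self.last_followup:
                raise DataIntegrityError(
                    f"{name} ({t}) after last follow-up ({self.last_followup})"
                )


@dataclass(frozen=True)
class SurvivalEndpoint:
    patient_id: str
    endpoint: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.time < 0:
            raise DataIntegrityError("endpoint time must be >= 0")


def make_endpoints(record: ClinicalRecord) -> dict[str, SurvivalEndpoint]:
    """Construct every defined endpoint for one patient."""

    def first_of(*times: float | None) -> float | None:
        observed = [t for t in times if t is not None]
        return min(observed) if observed else None

    out: dict[str, SurvivalEndpoint] = {}
    pid = record.patient_id
    fu = record.last_followup

    pfs_t = first_of(record.first_progression, record.death)
    out["PFS"] = SurvivalEndpoint(
        pid, "PFS", pfs_t if pfs_t is not None else fu, int(pfs_t is not None)
    )

    out["OS"] = SurvivalEndpoint(
        pid,
        "OS",
        record.death if record.death is not None else fu,
        int(record.death is not None),
    )

    pfs2_t = first_of(record.second_progression, record.death)
    out["PFS2"] = SurvivalEndpoint(
        pid, "PFS2", pfs2_t if pfs2_t is not None else fu, int(pfs2_t is not None)
    )

    if record.first_progression is not None:
        origin = record.first_progression
        t2 = first_of(record.second_progression, record.death)
        if t2 is not None:
            out["PFS_2ND"] = SurvivalEndpoint(pid, "PFS_2ND", t2 - origin, 1)
        else:
            out["PFS_2ND"] = SurvivalEndpoint(pid, "PFS_2ND", fu - origin, 0)
    return out


@dataclass
class KMResult:
    """Kaplan-Meier fit with an explicit not-reached median encoding."""

    median: float | None
    median_reached: bool
    n: int
    n_events: int
    survival: pd.DataFrame  # columns: time, survival

    def to_dict(self) -> dict:
        return {
            "median_months": self.median,
            "median_reached": self.median_reached,
            "n": self.n,
            "events": self.n_events,
        }


def km_fit(time: Sequence[float], event: Sequence[int]) -> KMResult:
    """Product-limit estimate with median (None when never reached)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("km_fit needs at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    med = kmf.median_survival_time_
    reached = np.isfinite(med)
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "survival"]
    return KMResult(
        median=float(med) if reached else None,
        median_reached=bool(reached),
        n=len(time),
        n_events=int(event.sum()),
        survival=surv,
    )


@dataclass
class CoxResult:
    """Hazard ratios with Wald CIs and p-values for one fitted model."""

    model_type: str
    variables: list
    hr: dict
    ci_low: dict
    ci_high: dict
    p: dict
    n: int
    n_events: int
    converged: bool
    note: str = ""
    elimination_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_type": self.model_type,
            "n": self.n,
            "events": self.n_events,
            "converged": self.converged,
            "note": self.note,
            "variables": {
                v: {
                    "hr": self.hr[v],
                    "ci95": [self.ci_low[v], self.ci_high[v]],
                    "p": self.p[v],
                }
                for v in self.variables
            },
            "elimination_trace": self.elimination_trace,
        }


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def _result_from_fit(
    cph: CoxPHFitter, model_type: str, n: int, n_events: int, trace=None
) -> CoxResult:
    summary = cph.summary
    return CoxResult(
        model_type=model_type,
        variables=list(summary.index),
        hr={v: float(summary.loc[v, "exp(coef)"]) for v in summary.index},
        ci_low={
            v: float(summary.loc[v, "exp(coef) lower 95%"]) for v in summary.index
        },
        ci_high={
            v: float(summary.loc[v, "exp(coef) upper 95%"]) for v in summary.index
        },
        p={v: float(summary.loc[v, "p"]) for v in summary.index},
        n=n,
        n_events=n_events,
        converged=True,
        elimination_trace=trace or [],
    )


def _failed_result(model_type: str, n: int, n_events: int, note: str) -> CoxResult:
    return CoxResult(
        model_type=model_type,
        variables=[],
        hr={},
        ci_low={},
        ci_high={},
        p={},
        n=n,
        n_events=n_events,
        converged=False,
        note=note,
    )


def cox_univariable(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[int],
    adjust: pd.DataFrame | None = None,
) -> CoxResult:
    """Cox model of a binary group indicator (optionally adjusted).

    Monotone-likelihood situations (e.g. a group without events) are
    returned as a flagged non-convergence result rather than raised.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "group": np.asarray(group, dtype=float),
        }
    )
    if adjust is not None:
        for col in adjust.columns:
            df[col] = np.asarray(adjust[col], dtype=float)
    n, n_events = len(df), int(df["event"].sum())
    groups = df["group"].unique()
    if len(groups) < 2:
        return _failed_result("univariable", n, n_events, "single group supplied")
    events_per_group = df.groupby("group")["event"].sum()
    if (events_per_group == 0).any():
        return _failed_result(
            "univariable",
            n,
            n_events,
            "monotone likelihood: a group has no events",
        )
    try:
        cph = _fit_cox(df, "time", "event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return _failed_result("univariable", n, n_events, f"non-convergence: {exc}")
    return _result_from_fit(cph, "univariable", n, n_events)


def cox_multivariable(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    forced: Sequence[str] = ("iss",),
    alpha: float = 0.05,
) -> CoxResult:
    """Backward elimination at ``p < alpha`` with forced adjustment covariates.

    Fits the full model, iteratively drops the eliminable covariate with
    the largest p-value above ``alpha``, and stops when all remaining
    eliminable covariates are significant. ``forced`` covariates (the
    staging adjustment) are never dropped. Raises
    :class:`CollinearityError` when the design matrix is rank deficient
    after dropping constant columns.
    """
    covariates = list(covariates)
    forced = [f for f in forced if f in data.columns]
    all_vars = list(dict.fromkeys(covariates + forced))
    df = data[[duration_col, event_col] + all_vars].astype(float).copy()

    non_constant = [v for v in all_vars if df[v].nunique() > 1]
    dropped_constant = [v for v in all_vars if v not in non_constant]
    X = df[non_constant].to_numpy()
    if X.shape[1] and np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise CollinearityError(
            "covariate matrix is rank deficient (collinear covariates)"
        )

    current = [v for v in non_constant]
    trace: list[dict] = [
        {"step": "drop_constant", "variable": v} for v in dropped_constant
    ]
    n, n_events = len(df), int(df[event_col].sum())

    while True:
        try:
            cph = _fit_cox(
                df[[duration_col, event_col] + current], duration_col, event_col
            )
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            result = _failed_result(
                "multivariable", n, n_events, f"non-convergence: {exc}"
            )
            result.elimination_trace = trace
            return result
        pvals = cph.summary["p"]
        eliminable = [v for v in current if v not in forced]
        candidates = {v: pvals[v] for v in eliminable if pvals[v] > alpha}
        if not candidates:
            return _result_from_fit(cph, "multivariable", n, n_events, trace)
        worst = max(candidates, key=candidates.get)
        trace.append(
            {"step": "eliminate", "variable": worst, "p": float(candidates[worst])}
        )
        current.remove(worst)
        if not current:
            result = _failed_result(
                "multivariable", n, n_events, "all covariates eliminated"
            )
            result.elimination_trace = trace
            return result
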