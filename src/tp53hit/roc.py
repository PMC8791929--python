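"""Cumulative/dynamic time-dependent ROC under right censoring, and the
CCF-threshold scan that derives the prognostic deletion-call cutoff.

At horizon ``t`` the cases are subjects with an event by ``t`` and the
controls are subjects event-free past ``t``. Censoring is handled by
inverse-probability-of-censoring weighting (IPCW): each contributing
subject is weighted by ``1 / G(min(T_i, t))`` where ``G`` is the
Kaplan-Meier estimate of the censoring survival function; subjects censored
before ``t`` without an event contribute nothing. With no censoring the
estimator reduces exactly to the Mann-Whitney statistic.

The cutoff scan dichotomizes patients at each copy-number grid value ``c``
(from 2.0 downward in steps of 0.05, i.e. deletion CCF thresholds from 0
upward in steps of 5 percentage points: deleted iff ``tumor_cn < c``,
equivalently ``CCF > (2 - c) * 100``), computes the AUC at each horizon
with a seeded percentile-bootstrap confidence interval, and selects per
endpoint the smallest CCF threshold whose 95% CI excludes 0.5 at any
horizon. The per-endpoint limits are reconciled to a single adopted cutoff
by rounding to the nearest multiple of 5 and, when they disagree, taking
the larger (conservative) value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DegenerateCensoringError",
    "ROCScanResult",
    "UndefinedAUCError",
    "cd_auc",
    "censoring_survival",
    "ipcw_weights",
    "reconcile_cutoffs",
    "threshold_scan",
]


class DegenerateCensoringError(ValueError):
    """Censoring KM reaches 0 before a required evaluation time."""


class UndefinedAUCError(ValueError):
    """No cases or no controls at the requested horizon."""


def censoring_survival(
    time: np.ndarray, event: np.ndarray, eval_at: np.ndarray
) -> np.ndarray:
    """Kaplan-Meier estimate of the censoring survival function G.

    Censoring (``event == 0``) is the "event" here; observed events are the
    censored observations. At tied times, events are taken to precede
    censorings, so subjects with an event at ``u`` remain in the risk set
    for censoring at ``u`` (the standard reverse-KM convention). The
    returned values are the right-continuous G evaluated at ``eval_at``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    cens_times = np.sort(time[event == 0])
    if len(cens_times) == 0:
        return np.ones(np.shape(eval_at), dtype=float)
    uniq, counts = np.unique(cens_times, return_counts=True)
    sorted_all = np.sort(time)
    # at risk for censoring at u: everyone with T >= u
    n_risk = len(time) - np.searchsorted(sorted_all, uniq, side="left")
    factors = 1.0 - counts / n_risk
    surv = np.cumprod(factors)
    idx = np.searchsorted(uniq, np.asarray(eval_at, dtype=float), side="right")
    g = np.where(idx == 0, 1.0, surv[np.maximum(idx - 1, 0)])
    return g


def ipcw_weights(
    time: Sequence[float], event: Sequence[int], horizon: float
) -> np.ndarray:
    """Per-subject IPCW weights at a horizon.

    Cases (event by the horizon) get ``1/G(T_i)``; controls (followed past
    the horizon) get ``1/G(horizon)``; subjects censored before the horizon
    without an event get 0.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    eval_times = np.where(case, time, horizon)
    g = censoring_survival(time, event, eval_times)
    needed = case | control
    if np.any(needed & (g <= 0.0)):
        raise DegenerateCensoringError(
            "censoring survival is 0 at a required evaluation time"
        )
    if not np.any(needed):
        raise DegenerateCensoringError(
            f"no subject contributes at horizon {horizon}"
        )
    weights = np.zeros(len(time), dtype=float)
    weights[needed] = 1.0 / g[needed]
    return weights


def _weighted_auc(
    marker: np.ndarray, case: np.ndarray, control: np.ndarray, weights: np.ndarray
) -> float:
    m_case, w_case = marker[case], weights[case]
    m_ctrl, w_ctrl = marker[control], weights[control]
    order = np.argsort(m_ctrl, kind="stable")
    mc = m_ctrl[order]
    cw = np.concatenate(([0.0], np.cumsum(w_ctrl[order])))
    lo = np.searchsorted(mc, m_case, side="left")
    hi = np.searchsorted(mc, m_case, side="right")
    less = cw[lo]
    eq = cw[hi] - cw[lo]
    num = float(np.sum(w_case * (less + 0.5 * eq)))
    return num / (w_case.sum() * cw[-1])


def cd_auc(
    time: Sequence[float],
    event: Sequence[int],
    marker: Sequence[float],
    horizon: float,
) -> float:
    """Cumulative/dynamic AUC at a horizon under IPCW.

    The IPCW-weighted probability that a case (event by the horizon) has a
    higher marker value than a control (event-free past the horizon); ties
    count one half.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    marker = np.asarray(marker, dtype=float)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if not case.any() or not control.any():
        raise UndefinedAUCError(
            f"AUC undefined at horizon {horizon}: "
            f"{int(case.sum())} cases, {int(control.sum())} controls"
        )
    weights = ipcw_weights(time, event, horizon)
    return _weighted_auc(marker, case, control, weights)


def _binary_auc_grid(
    ccf: np.ndarray,
    case: np.ndarray,
    control: np.ndarray,
    weights: np.ndarray,
    thresholds_ccf: np.ndarray,
) -> np.ndarray:
    """AUC of the dichotomized marker ``ccf > thr`` for every threshold.

    For a binary marker the weighted AUC is
    ``P(case+)P(ctrl-) + 0.5*(P(case+)P(ctrl+) + P(case-)P(ctrl-))`` with
    weighted class probabilities, computed for the whole grid at once via
    sorted prefix sums. Grid points where every patient falls on one side
    (degenerate dichotomization) are NaN.
    """
    out = np.full(len(thresholds_ccf), np.nan)
    w_case_tot = weights[case].sum()
    w_ctrl_tot = weights[control].sum()
    if w_case_tot <= 0 or w_ctrl_tot <= 0:
        return out

    order = np.argsort(ccf, kind="stable")
    ccf_sorted = ccf[order]
    wcase_cum = np.concatenate(([0.0], np.cumsum((weights * case)[order])))
    wctrl_cum = np.concatenate(([0.0], np.cumsum((weights * control)[order])))
    # index of last ccf <= thr: prefix weight of marker-negative subjects
    idx = np.searchsorted(ccf_sorted, thresholds_ccf, side="right")
    case_neg = wcase_cum[idx]
    ctrl_neg = wctrl_cum[idx]
    case_pos = w_case_tot - case_neg
    ctrl_pos = w_ctrl_tot - ctrl_neg

    n_pos = len(ccf) - idx  # subject counts, for degeneracy detection
    degenerate = (n_pos == 0) | (n_pos == len(ccf))
    auc = (
        case_pos * ctrl_neg + 0.5 * (case_pos * ctrl_pos + case_neg * ctrl_neg)
    ) / (w_case_tot * w_ctrl_tot)
    out = np.where(degenerate, np.nan, auc)
    return out


@dataclass
class ROCScanResult:
    """AUC grid over CN thresholds x horizons and the selected cutoff."""

    grid_cn: np.ndarray
    grid_ccf: np.ndarray
    timepoints: np.ndarray
    auc: dict
    ci_low: dict
    ci_high: dict
    significant: dict
    per_endpoint_cutoff_ccf: dict
    adopted_cutoff_ccf: float | None
    rationale: dict
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        def clean(a):
            return np.where(np.isnan(a), None, np.round(a, 6)).tolist()

        return {
            "grid_cn": np.round(self.grid_cn, 6).tolist(),
            "grid_ccf": np.round(self.grid_ccf, 6).tolist(),
            "timepoints_months": self.timepoints.tolist(),
            "auc": {k: clean(v) for k, v in self.auc.items()},
            "ci_low": {k: clean(v) for k, v in self.ci_low.items()},
            "ci_high": {k: clean(v) for k, v in self.ci_high.items()},
            "per_endpoint_cutoff_ccf": self.per_endpoint_cutoff_ccf,
            "adopted_cutoff_ccf": self.adopted_cutoff_ccf,
            "rationale": self.rationale,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _round_to_multiple(x: float, base: float = 5.0) -> float:
    return float(np.floor(x / base + 0.5) * base)


def reconcile_cutoffs(*limits: float, base: float = 5.0) -> float:
    """Reconcile per-endpoint CCF limits into one adopted cutoff.

    Each limit is rounded to the nearest multiple of ``base`` (half up);
    if the rounded values agree that value is adopted, otherwise the larger
    (more conservative) one.
    """
    if not limits:
        raise ValueError("at least one limit required")
    rounded = [_round_to_multiple(x, base) for x in limits]
    return float(max(rounded))


def threshold_scan(
    ccf: Sequence[float],
    endpoints: Mapping[str, tuple],
    *,
    grid_step: float = 0.05,
    timepoints: Sequence[float] = tuple(range(12, 97, 12)),
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ROCScanResult:
    """Scan deletion-call CCF thresholds for prognostic value.

    For each endpoint (e.g. PFS, OS, given as ``(time, event)`` arrays) and
    each copy-number grid value, the cohort is dichotomized and the
    cumulative/dynamic AUC computed at every horizon, with a percentile
    bootstrap CI. Grid points where the dichotomization is degenerate or
    the AUC undefined are recorded as missing. The chosen per-endpoint
    cutoff is the smallest CCF threshold significant (CI excluding 0.5) at
    any horizon; limits are reconciled via :func:`reconcile_cutoffs`.
    """
    ccf = np.asarray(ccf, dtype=float)
    n = len(ccf)
    grid_cn = np.round(np.arange(2.0, -grid_step / 2.0, -grid_step), 10)
    grid_ccf = np.round((2.0 - grid_cn) * 100.0, 10)
    timepoints = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)

    auc: dict[str, np.ndarray] = {}
    ci_low: dict[str, np.ndarray] = {}
    ci_high: dict[str, np.ndarray] = {}
    significant: dict[str, np.ndarray] = {}
    per_endpoint: dict[str, float | None] = {}
    rationale: dict[str, dict] = {}

    def scan_once(time, event, idx=None):
        """AUC[grid, horizon] for one (re)sample of the cohort."""
        t = time if idx is None else time[idx]
        e = event if idx is None else event[idx]
        c = ccf if idx is None else ccf[idx]
        mat = np.full((len(grid_ccf), len(timepoints)), np.nan)
        for j, horizon in enumerate(timepoints):
            case = (t <= horizon) & (e == 1)
            control = t > horizon
            if not case.any() or not control.any():
                continue
            try:
                w = ipcw_weights(t, e, horizon)
            except DegenerateCensoringError:
                continue
            mat[:, j] = _binary_auc_grid(c, case, control, w, grid_ccf)
        return mat

    for name, (time, event) in endpoints.items():
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        observed = scan_once(time, event)
        boot = np.empty((n_boot, len(grid_ccf), len(timepoints)))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot[b] = scan_once(time, event, idx)
        # a grid x horizon cell needs enough defined resamples for a CI
        n_defined = np.sum(~np.isnan(boot), axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
            lo = np.nanpercentile(boot, 100 * (alpha / 2), axis=0)
            hi = np.nanpercentile(boot, 100 * (1 - alpha / 2), axis=0)
        usable = ~np.isnan(observed) & (n_defined >= max(20, n_boot // 2))
        sig = usable & (lo > 0.5)

        auc[name] = observed
        ci_low[name] = np.where(usable, lo, np.nan)
        ci_high[name] = np.where(usable, hi, np.nan)
        significant[name] = sig

        sig_any_t = sig.any(axis=1)
        if sig_any_t.any():
            i = int(np.argmax(sig_any_t))  # smallest CCF = first grid row
            j = int(np.argmax(sig[i]))
            per_endpoint[name] = float(grid_ccf[i])
            rationale[name] = {
                "endpoint": name,
                "timepoint_months": float(timepoints[j]),
                "auc": float(observed[i, j]),
                "ci": [float(lo[i, j]), float(hi[i, j])],
            }
        else:
            per_endpoint[name] = None
            rationale[name] = {"endpoint": name, "note": "no significant threshold"}

    found = [v for v in per_endpoint.values() if v is not None]
    adopted = reconcile_cutoffs(*found) if len(found) == len(per_endpoint) else None

    return ROCScanResult(
        grid_cn=grid_cn,
        grid_ccf=grid_ccf,
        timepoints=timepoints,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        per_endpoint_cutoff_ccf=per_endpoint,
        adopted_cutoff_ccf=adopted,
        rationale=rationale,
        n_boot=n_boot,
        seed=seed,
    )
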