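"""Paired diagnosis/relapse TP53 status: transitions, frequency and CCF shifts.

Each patient re-assessed at relapse gets a transition class comparing the
collapsed allelic burden (wt < single < double):

* ``stable_wt`` — wild-type at both timepoints;
* ``acquired_del`` / ``acquired_mut`` — wild-type to a single deletion or
  mutation;
* ``acquired_double`` — any non-double state to a double hit;
* ``stable_altered`` — an altered state staying at the same burden level
  (including e.g. a single deletion replaced by a single mutation);
* ``regressed`` — burden decreasing (altered to wild-type, or double to
  single); not expected biologically at relapse but representable, since
  purity/sampling artifacts can produce it.

Cohort-level shifts are tested with the unpaired two-proportion chi-square
(continuity corrected) for aberration frequency — matching how the
diagnosis (n=143) and relapse (n=53) denominators differ — with McNemar's
test on the paired subset emitted alongside, and with the unpaired
Mann-Whitney U for the carrier CCF distribution (paired Wilcoxon emitted
alongside for patients who are carriers at both timepoints).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar

from .allelic import AllelicStatus, collapse_status, round_half_away

__all__ = [
    "ACQUISITION_CLASSES",
    "EvolutionRecord",
    "acquisition_summary",
    "aberration_frequency_shift",
    "ccf_shift",
    "classify_transition",
    "mcnemar_paired_shift",
    "pair_statuses",
]

ACQUISITION_CLASSES = (
    "stable_wt",
    "acquired_del",
    "acquired_mut",
    "acquired_double",
    "stable_altered",
    "regressed",
)

_BURDEN = {"wt": 0, "single": 1, "double": 2}


class UnpairedPatientError(ValueError):
    """A timepoint is missing for a paired analysis."""


def classify_transition(status_dx: str, status_rel: str) -> str:
    """Map an ordered pair of detailed statuses to an acquisition class."""
    b_dx = _BURDEN[collapse_status(status_dx)]
    b_rel = _BURDEN[collapse_status(status_rel)]
    if b_dx == 0 and b_rel == 0:
        return "stable_wt"
    if b_rel == 2 and b_dx < 2:
        return "acquired_double"
    if b_dx == 0 and b_rel == 1:
        return "acquired_del" if status_rel == "SINGLE_DEL" else "acquired_mut"
    if b_rel < b_dx:
        return "regressed"
    return "stable_altered"


@dataclass(frozen=True)
class EvolutionRecord:
    """Paired diagnosis/relapse assessment of one patient."""

    patient_id: str
    status_dx: AllelicStatus
    status_rel: AllelicStatus
    acquisition: str
    ccf_dx: float | None = None
    ccf_rel: float | None = None


def pair_statuses(
    diagnosis: Iterable[AllelicStatus], relapse: Iterable[AllelicStatus]
) -> list[EvolutionRecord]:
    """Join statuses by patient id; relapse patients must exist at diagnosis."""
    dx_by_id = {s.patient_id: s for s in diagnosis}
    records = []
    for rel in relapse:
        dx = dx_by_id.get(rel.patient_id)
        if dx is None:
            raise UnpairedPatientError(
                f"patient {rel.patient_id!r} has no diagnosis assessment"
            )
        records.append(
            EvolutionRecord(
                patient_id=rel.patient_id,
                status_dx=dx,
                status_rel=rel,
                acquisition=classify_transition(dx.status, rel.status),
                ccf_dx=dx.deletion_ccf if dx.deletion_ccf > 0 else None,
                ccf_rel=rel.deletion_ccf if rel.deletion_ccf > 0 else None,
            )
        )
    return records


def acquisition_summary(records: Sequence[EvolutionRecord]) -> dict:
    """Counts per acquisition class over the paired cohort."""
    if not records:
        raise ValueError("no paired records to summarize")
    counts = Counter(r.acquisition for r in records)
    for k in ACQUISITION_CLASSES:
        counts.setdefault(k, 0)
    total_acquired = (
        counts["acquired_del"] + counts["acquired_mut"] + counts["acquired_double"]
    )
    return {
        "n_pairs": len(records),
        "counts": dict(counts),
        "total_acquired": total_acquired,
    }


def aberration_frequency_shift(
    n_alt_dx: int, n_dx: int, n_alt_rel: int, n_rel: int
) -> dict:
    """Two-proportion chi-square test (continuity corrected) of carrier rates."""
    if n_dx <= 0 or n_rel <= 0:
        raise ValueError("denominators must be positive")
    if n_alt_dx > n_dx or n_alt_rel > n_rel:
        raise ValueError("counts exceed denominators")
    table = np.array(
        [[n_alt_dx, n_dx - n_alt_dx], [n_alt_rel, n_rel - n_alt_rel]]
    )
    if n_alt_dx / n_dx == n_alt_rel / n_rel:
        p = 1.0  # identical proportions: no evidence of a shift
        chi2 = 0.0
    else:
        res = stats.chi2_contingency(table, correction=True)
        chi2, p = float(res.statistic), float(res.pvalue)
    return {
        "proportion_dx": n_alt_dx / n_dx,
        "proportion_rel": n_alt_rel / n_rel,
        "percent_dx": round_half_away(100.0 * n_alt_dx / n_dx),
        "percent_rel": round_half_away(100.0 * n_alt_rel / n_rel),
        "difference": n_alt_rel / n_rel - n_alt_dx / n_dx,
        "chi2": chi2,
        "p": p,
    }


def mcnemar_paired_shift(records: Sequence[EvolutionRecord]) -> dict:
    """Exact McNemar test of carrier status on the paired subset.

    Supplementary to the unpaired frequency comparison: the paired design
    is statistically the appropriate one for the re-assessed patients.
    """
    b = sum(
        1
        for r in records
        if r.status_dx.status == "WT" and r.status_rel.status != "WT"
    )
    c = sum(
        1
        for r in records
        if r.status_dx.status != "WT" and r.status_rel.status == "WT"
    )
    both = sum(
        1
        for r in records
        if r.status_dx.status != "WT" and r.status_rel.status != "WT"
    )
    neither = len(records) - b - c - both
    table = np.array([[neither, b], [c, both]])
    res = mcnemar(table, exact=True)
    return {"b_wt_to_alt": b, "c_alt_to_wt": c, "p": float(res.pvalue)}


def ccf_shift(
    ccf_carriers_dx: Sequence[float], ccf_carriers_rel: Sequence[float]
) -> dict:
    """Medians/ranges of carrier CCFs and the Mann-Whitney two-sided p.

    Unpaired by design: the carrier sets differ between timepoints.
    """
    a = np.asarray(ccf_carriers_dx, dtype=float)
    b = np.asarray(ccf_carriers_rel, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each timepoint needs at least one carrier CCF")
    if len(a) == len(b) and np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0  # identical samples: no evidence of a shift
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {
        "median_dx": float(np.median(a)),
        "median_rel": float(np.median(b)),
        "range_dx": [float(a.min()), float(a.max())],
        "range_rel": [float(b.min()), float(b.max())],
        "p": p,
    }


def paired_ccf_shift(records: Sequence[EvolutionRecord]) -> dict | None:
    """Wilcoxon signed-rank test on patients who are carriers at both
    timepoints; None when fewer than two such pairs exist or all
    differences are zero."""
    pairs = [
        (r.ccf_dx, r.ccf_rel)
        for r in records
        if r.ccf_dx is not None and r.ccf_rel is not None
    ]
    if len(pairs) < 2:
        return None
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    if np.all(a == b):
        return {"n_pairs": len(pairs), "p": 1.0}
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return {"n_pairs": len(pairs), "p": float(res.pvalue)}
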