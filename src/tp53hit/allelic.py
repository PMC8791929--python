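"""Per-patient TP53 allelic status and cohort summaries.

A patient's TP53 state combines the gene-level copy-number call with the
retained pathogenic mutations:

* ``DOUBLE_HOMDEL`` — homozygous deletion (both copies lost);
* ``DOUBLE_DELMUT`` — deletion plus >=1 pathogenic mutation;
* ``SINGLE_DEL`` — deletion only (CCF at or above the call cutoff);
* ``SINGLE_MUT`` — >=1 pathogenic mutation on a diploid background;
* ``WT`` — neither lesion.

Double-hit means biallelic inactivation: homozygous deletion or deletion
plus mutation. Two mutations without a deletion are conservatively kept as
single-hit (mutation phase is unknown from bulk data).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .copy_number import GeneCNCall
from .variant_filtering import ConsensusVariant

__all__ = [
    "AllelicStatus",
    "CohortSummary",
    "EmptyCohortError",
    "STATUSES",
    "classify_patient",
    "cohort_summary",
    "collapse_status",
    "round_half_away",
]

STATUSES = ("WT", "SINGLE_DEL", "SINGLE_MUT", "DOUBLE_HOMDEL", "DOUBLE_DELMUT")

_COLLAPSE = {
    "WT": "wt",
    "SINGLE_DEL": "single",
    "SINGLE_MUT": "single",
    "DOUBLE_HOMDEL": "double",
    "DOUBLE_DELMUT": "double",
}


class EmptyCohortError(ValueError):
    """Summary requested for an empty cohort."""


class IncompleteRecordError(ValueError):
    """Patient lacks a copy-number call."""


def collapse_status(status: str) -> str:
    """Collapse a detailed status to {wt, single, double}."""
    return _COLLAPSE[status]


@dataclass(frozen=True)
class AllelicStatus:
    """TP53 allelic state of one patient at one timepoint."""

    patient_id: str
    status: str
    timepoint: str = "diagnosis"
    deletion_ccf: float = 0.0
    n_pathogenic_mutations: int = 0
    max_vaf: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def collapsed(self) -> str:
        return collapse_status(self.status)


def classify_patient(
    cn_call: GeneCNCall | None,
    retained_mutations: Sequence[ConsensusVariant] = (),
    *,
    timepoint: str = "diagnosis",
    patient_id: str | None = None,
) -> AllelicStatus:
    """Combine the CN call and retained mutations into an allelic status."""
    if cn_call is None:
        raise IncompleteRecordError("patient has no TP53 copy-number call")
    retained = [m for m in retained_mutations if m.retained]
    has_mut = len(retained) > 0

    if cn_call.is_homdel:
        status = "DOUBLE_HOMDEL"
    elif cn_call.is_deleted and has_mut:
        status = "DOUBLE_DELMUT"
    elif cn_call.is_deleted:
        status = "SINGLE_DEL"
    elif has_mut:
        status = "SINGLE_MUT"
    else:
        status = "WT"

    return AllelicStatus(
        patient_id=patient_id if patient_id is not None else cn_call.sample_id,
        status=status,
        timepoint=timepoint,
        deletion_ccf=cn_call.deletion_ccf if cn_call.is_deleted else 0.0,
        n_pathogenic_mutations=len(retained),
        max_vaf=max((m.vaf for m in retained), default=0.0),
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CohortSummary:
    """Counts and rounded percentages of TP53 states over a cohort.

    ``deletion_carriers`` counts every patient whose tumor carries a
    deletion (single-hit deletions, homozygous deletions and
    deletion+mutation double hits); ``mutation_only`` counts patients whose
    only lesion is a mutation. ``any_alteration`` is everyone not wild-type.
    """

    n: int
    status_counts: dict
    collapsed_counts: dict
    deletion_carriers: int
    mutation_only: int
    any_alteration: int

    def percent(self, count: int) -> int:
        return round_half_away(100.0 * count / self.n)

    @property
    def status_percents(self) -> dict:
        return {k: self.percent(v) for k, v in self.status_counts.items()}

    @property
    def collapsed_percents(self) -> dict:
        return {k: self.percent(v) for k, v in self.collapsed_counts.items()}

    @property
    def deletion_carrier_percent(self) -> int:
        return self.percent(self.deletion_carriers)

    @property
    def mutation_only_percent(self) -> int:
        return self.percent(self.mutation_only)

    @property
    def any_alteration_percent(self) -> int:
        return self.percent(self.any_alteration)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "status_counts": dict(self.status_counts),
            "status_percents": self.status_percents,
            "collapsed_counts": dict(self.collapsed_counts),
            "collapsed_percents": self.collapsed_percents,
            "deletion_carriers": self.deletion_carriers,
            "deletion_carrier_percent": self.deletion_carrier_percent,
            "mutation_only": self.mutation_only,
            "mutation_only_percent": self.mutation_only_percent,
            "any_alteration": self.any_alteration,
            "any_alteration_percent": self.any_alteration_percent,
        }


def cohort_summary(statuses: Iterable[AllelicStatus]) -> CohortSummary:
    """Tabulate statuses; percentages round half away from zero."""
    statuses = list(statuses)
    if not statuses:
        raise EmptyCohortError("cannot summarize an empty cohort")
    status_counts = Counter(s.status for s in statuses)
    collapsed_counts = Counter(s.collapsed for s in statuses)
    for k in STATUSES:
        status_counts.setdefault(k, 0)
    for k in ("wt", "single", "double"):
        collapsed_counts.setdefault(k, 0)
    deletion_carriers = (
        status_counts["SINGLE_DEL"]
        + status_counts["DOUBLE_HOMDEL"]
        + status_counts["DOUBLE_DELMUT"]
    )
    n = len(statuses)
    return CohortSummary(
        n=n,
        status_counts=dict(status_counts),
        collapsed_counts=dict(collapsed_counts),
        deletion_carriers=deletion_carriers,
        mutation_only=status_counts["SINGLE_MUT"],
        any_alteration=n - status_counts["WT"],
    )
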