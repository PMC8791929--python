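"""Multi-caller somatic variant consensus, filtering and pathogenicity labels.

Raw calls from three callers (Mutect2, Sophia DDM, Shearwater) are merged by
a normalized variant key, a 2-of-3 caller consensus is required, and the
surviving variants pass through tool-specific filters, laboratory depth/VAF
thresholds, a pathogenicity-labeling rule, and a population-frequency /
clinical-database confirmation step:

* Mutect2 calls pass only with an unqualified PASS filter field.
* Shearwater calls pass only with quality score > 30.
* Sophia DDM calls pass only when flagged PASS.
* Laboratory thresholds: depth > 250x and VAF > 5% (strict).
* Pathogenic label: loss-of-function consequence (missense, nonsense,
  frameshift), or clinical-database pathogenic status with strong in-silico
  support.
* Final retention: pathogenic, population frequency <= 1%, and confirmed in
  a clinical database (ClinVar pathogenic/likely-pathogenic or COSMIC).

Annotations (consequence, database status, in-silico support, population
frequency) are input fields, not live database queries.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationMissingError",
    "CALLERS",
    "ConsensusVariant",
    "RawCall",
    "UnknownCallerError",
    "VariantAnnotation",
    "VariantKey",
    "VariantParseError",
    "consensus",
    "filter_variants",
    "final_retention",
    "lab_thresholds",
    "label_pathogenicity",
    "normalize_and_key",
    "tool_filter",
]

CALLERS = frozenset({"mutect2", "sophia", "shearwater"})

LOF_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift"})
CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "synonymous", "other"}
)
CLINVAR_STATUSES = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "benign", "absent"}
)
INSILICO_LEVELS = frozenset({"strong", "weak", "none"})

DEFAULT_MIN_DEPTH = 250
DEFAULT_MIN_VAF = 0.05
DEFAULT_MAX_POPULATION_FREQ = 0.01


class VariantParseError(ValueError):
    """Malformed variant alleles."""


class UnknownCallerError(ValueError):
    """Caller name not one of the configured three."""


class AnnotationMissingError(KeyError):
    """A consensus variant has no annotation record."""


@dataclass(frozen=True)
class VariantKey:
    """Normalized (chrom, pos, ref, alt) identity of a variant.

    ``ref``/``alt`` may be empty after trimming (pure insertion/deletion
    representation); the key is only used for matching, never re-emitted
    as VCF without re-anchoring.
    """

    chromosome: str
    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class RawCall:
    """One variant call from one caller."""

    caller: str
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    vaf: float
    depth: int
    quality: float = float("nan")
    filter_flags: frozenset = frozenset({"PASS"})
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise UnknownCallerError(
                f"unknown caller {self.caller!r}; expected one of {sorted(CALLERS)}"
            )
        if not (0.0 <= self.vaf <= 1.0):
            raise VariantParseError(f"VAF must be in [0, 1], got {self.vaf}")
        if self.depth < 0:
            raise VariantParseError("depth must be >= 0")
        object.__setattr__(self, "filter_flags", frozenset(self.filter_flags))

    @property
    def key(self) -> VariantKey:
        return normalize_and_key(self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional/clinical annotation of a variant (supplied as input)."""

    consequence: str
    clinvar_status: str = "absent"
    cosmic_present: bool = False
    insilico_support: str = "none"
    population_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise VariantParseError(f"unknown consequence {self.consequence!r}")
        if self.clinvar_status not in CLINVAR_STATUSES:
            raise VariantParseError(f"unknown clinvar status {self.clinvar_status!r}")
        if self.insilico_support not in INSILICO_LEVELS:
            raise VariantParseError(
                f"unknown in-silico support {self.insilico_support!r}"
            )
        if not (0.0 <= self.population_freq <= 1.0):
            raise VariantParseError("population_freq must be in [0, 1]")


@dataclass(frozen=True)
class ConsensusVariant:
    """A keyed variant with its supporting callers and filter audit trail."""

    key: VariantKey
    supporting_callers: frozenset
    vaf: float
    depth: float
    filter_verdicts: tuple = ()
    pathogenicity: str | None = None
    retained: bool = False
    sample_id: str = ""

    def verdict(self, name: str) -> bool | None:
        for n, ok in self.filter_verdicts:
            if n == name:
                return ok
        return None


def _validate_allele(allele: str) -> str:
    allele = allele.upper()
    if not allele or any(b not in "ACGT" for b in allele):
        raise VariantParseError(f"malformed allele {allele!r}")
    return allele


def normalize_and_key(
    chromosome: str, position: int, ref: str, alt: str
) -> VariantKey:
    """Trim shared suffix then prefix so equivalent events share one key.

    The shared suffix is removed first, then the shared prefix (advancing
    the position by one base per trimmed prefix base). Alleles may become
    empty — e.g. ``(100, ATT, AT)`` and ``(101, TT, T)`` both normalize to
    ``(101, T, '')``. Full left-alignment through repeat tracts would need
    the reference sequence and is out of scope.
    """
    ref = _validate_allele(ref)
    alt = _validate_allele(alt)
    if ref == alt:
        raise VariantParseError(f"ref and alt are identical ({ref!r})")
    pos = int(position)

    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chromosome, pos, ref, alt)


def tool_filter(call: RawCall) -> bool:
    """Caller-specific pass rule.

    Mutect2: every filter flag must be PASS. Shearwater: quality > 30.
    Sophia: a PASS flag must be present.
    """
    if call.caller == "mutect2":
        return call.filter_flags == frozenset({"PASS"})
    if call.caller == "shearwater":
        return call.quality > 30
    if call.caller == "sophia":
        return "PASS" in call.filter_flags
    raise UnknownCallerError(call.caller)


def consensus(calls: Iterable[RawCall]) -> list[ConsensusVariant]:
    """Group calls by normalized key and apply the 2-of-3 caller consensus.

    A variant survives when at least two distinct callers pass their
    tool-specific filter for its key. Consensus VAF and depth are the
    medians over the passing callers. Groups failing consensus are still
    returned (with the failing verdict) for audit purposes.
    """
    groups: dict[tuple[str, VariantKey], list[RawCall]] = defaultdict(list)
    for call in calls:
        groups[(call.sample_id, call.key)].append(call)

    out: list[ConsensusVariant] = []
    for (sample_id, key), group in groups.items():
        passing = [c for c in group if tool_filter(c)]
        callers = frozenset(c.caller for c in passing)
        ok = len(callers) >= 2
        pool = passing if passing else group
        out.append(
            ConsensusVariant(
                key=key,
                supporting_callers=callers,
                vaf=float(median(c.vaf for c in pool)),
                depth=float(median(c.depth for c in pool)),
                filter_verdicts=(("consensus_2of3", ok),),
                sample_id=sample_id,
            )
        )
    return out


def lab_thresholds(
    variant: ConsensusVariant,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> bool:
    """Laboratory-defined thresholds: depth > 250x and VAF > 5%, strictly."""
    return variant.depth > min_depth and variant.vaf > min_vaf


def label_pathogenicity(annotation: VariantAnnotation | None) -> str:
    """Assign a pathogenicity label from the annotation fields.

    Pathogenic if (rule 1) the consequence is a biological loss of function
    (missense, nonsense, frameshift), or (rule 2) the variant is reported
    pathogenic in a clinical database (ClinVar pathogenic/likely-pathogenic
    or present in COSMIC) with strong in-silico support. Benign if ClinVar
    says benign and rule 1 does not apply; otherwise VUS.
    """
    if annotation is None:
        raise AnnotationMissingError("variant must be annotated before labeling")
    rule1 = annotation.consequence in LOF_CONSEQUENCES
    in_db = (
        annotation.clinvar_status in ("pathogenic", "likely_pathogenic")
        or annotation.cosmic_present
    )
    rule2 = in_db and annotation.insilico_support == "strong"
    if rule1 or rule2:
        return "pathogenic"
    if annotation.clinvar_status == "benign":
        return "benign"
    return "vus"


def final_retention(
    variant: ConsensusVariant,
    annotation: VariantAnnotation,
    *,
    db_confirm: bool = True,
    max_population_freq: float = DEFAULT_MAX_POPULATION_FREQ,
) -> bool:
    """Final retention rule applied after pathogenicity labeling.

    Retained variants are pathogenic, not common in the population
    (frequency <= 1%) and — unless ``db_confirm`` is disabled — confirmed
    in a clinical database (ClinVar pathogenic/likely-pathogenic or COSMIC).
    The database-confirmation step intentionally also drops loss-of-function
    variants absent from the databases, mirroring the stated cascade order.
    """
    if variant.pathogenicity != "pathogenic":
        return False
    if annotation.population_freq > max_population_freq:
        return False
    if db_confirm:
        return (
            annotation.clinvar_status in ("pathogenic", "likely_pathogenic")
            or annotation.cosmic_present
        )
    return True


def filter_variants(
    calls: Iterable[RawCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    *,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
    db_confirm: bool = True,
    max_population_freq: float = DEFAULT_MAX_POPULATION_FREQ,
    blacklist: frozenset | set = frozenset(),
) -> list[ConsensusVariant]:
    """Run the full consensus + filter cascade and return audited variants.

    ``blacklist`` models matched-normal subtraction as a set of variant
    keys (optionally ``(sample_id, key)`` pairs) to exclude. Every keyed
    group is returned with its ordered filter verdicts; ``retained`` is
    True only when all verdicts pass and the variant is pathogenic.
    """
    results: list[ConsensusVariant] = []
    for cv in consensus(calls):
        verdicts = list(cv.filter_verdicts)
        not_blacklisted = (
            cv.key not in blacklist and (cv.sample_id, cv.key) not in blacklist
        )
        verdicts.append(("not_in_normal_blacklist", not_blacklisted))
        lab_ok = lab_thresholds(cv, min_depth=min_depth, min_vaf=min_vaf)
        verdicts.append(("lab_depth_vaf", lab_ok))

        annotation = annotations.get(cv.key)
        label = label_pathogenicity(annotation)
        verdicts.append(("pathogenic", label == "pathogenic"))
        verdicts.append(
            ("population_freq", annotation.population_freq <= max_population_freq)
        )
        if db_confirm:
            verdicts.append(
                (
                    "db_confirmed",
                    annotation.clinvar_status in ("pathogenic", "likely_pathogenic")
                    or annotation.cosmic_present,
                )
            )
        consensus_ok = cv.verdict("consensus_2of3")
        retained = (
            bool(consensus_ok)
            and not_blacklisted
            and lab_ok
            and final_retention(
                ConsensusVariant(
                    key=cv.key,
                    supporting_callers=cv.supporting_callers,
                    vaf=cv.vaf,
                    depth=cv.depth,
                    pathogenicity=label,
                    sample_id=cv.sample_id,
                ),
                annotation,
                db_confirm=db_confirm,
                max_population_freq=max_population_freq,
            )
        )
        results.append(
            ConsensusVariant(
                key=cv.key,
                supporting_callers=cv.supporting_callers,
                vaf=cv.vaf,
                depth=cv.depth,
                filter_verdicts=tuple(verdicts),
                pathogenicity=label,
                retained=retained,
                sample_id=cv.sample_id,
            )
        )
    return results
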