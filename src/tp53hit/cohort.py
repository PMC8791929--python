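"""Synthetic myeloma cohorts with known TP53 ground truth.

The generator emits everything the pipeline consumes — segmented
copy-number profiles with purity dilution, three imperfect caller outputs
with annotations, clinical covariates and proportional-hazards survival
times, and paired relapse re-assessments — so every stage is testable
against a known truth without external data.

The stated world follows the frequencies and effects reported for newly
diagnosed myeloma: ~24% deletion carriers / ~8% mutation-only / ~5% double
hit at diagnosis, purity 0.4-1.0, a 63% CCF clonal boundary (carrier CCFs a
50/50 mixture of subclonal U(10,63) and clonal U(63,100)), wild-type median
PFS 41.2 months, hazard ratios 1.63 (single hit) and 3.34 (double hit),
and relapse acquisition rates of 8/4/2 per 53 re-assessed pairs with
carrier CCFs drifting toward the relapse median (62.9 -> 82.4 guides the
default shrink factor of 0.5 toward 100).

A deterministic mode (exact class counts, zero probe noise, exact read
fractions, fully sensitive callers) reproduces a fixed composition through
the entire pipeline; it exists so that cohort-level worked examples have
exact expected counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_number import TP53_LOCUS, GenomicInterval, tumor_cn_to_logratio

__all__ = [
    "CohortConfig",
    "FIXTURE_COMPOSITION_143",
    "FIXTURE_RELAPSE_ACQUISITIONS",
    "SyntheticCohort",
    "diagnosis_fixture_config",
    "generate_cohort",
    "generate_relapse_pairs",
]

PATIENT_CLASSES = ("wt", "del_only", "mut_only", "del_plus_mut", "homdel")

#: Exact 143-patient composition used by cohort-level worked examples:
#: 34 deletion carriers (of whom 5 also mutated and 2 homozygously
#: deleted), 12 mutation-only carriers, 97 wild-type.
FIXTURE_COMPOSITION_143 = {
    "wt": 97,
    "del_only": 27,
    "mut_only": 12,
    "del_plus_mut": 5,
    "homdel": 2,
}

#: Exact acquisition pattern for the 53-pair relapse worked example.
FIXTURE_RELAPSE_ACQUISITIONS = {
    "acquired_del": 8,
    "acquired_mut": 4,
    "acquired_double": 2,
}

# small bank of TP53 coding positions used for simulated pathogenic SNVs
_MUTATION_BANK = [
    ("chr17", 7_577_120, "C", "T", "missense"),
    ("chr17", 7_577_538, "C", "T", "missense"),
    ("chr17", 7_578_406, "C", "T", "missense"),
    ("chr17", 7_578_190, "T", "C", "missense"),
    ("chr17", 7_577_094, "G", "A", "nonsense"),
    ("chr17", 7_578_442, "T", "C", "missense"),
    ("chr17", 7_579_312, "C", "A", "nonsense"),
    ("chr17", 7_577_556, "CG", "C", "frameshift"),
]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort (see module docstring)."""

    n_patients: int = 143
    seed: int = 0
    composition: Mapping[str, float] = field(
        default_factory=lambda: {
            "wt": 0.68,
            "del_only": 0.19,
            "mut_only": 0.08,
            "del_plus_mut": 0.035,
            "homdel": 0.015,
        }
    )
    #: exact class counts; overrides random composition draws when set
    deterministic_counts: Mapping[str, int] | None = None
    purity_range: tuple = (0.4, 1.0)
    subclonal_ccf: tuple = (10.0, 63.0)
    clonal_ccf: tuple = (63.0, 100.0)
    p_clonal: float = 0.5
    homdel_cn: tuple = (0.1, 0.5)
    probe_noise_sd: float = 0.1
    n_probes_locus: int = 100
    locus: GenomicInterval = TP53_LOCUS
    #: binomial read resampling of VAFs; disable for exact deterministic runs
    read_sampling: bool = True
    depth_mean: float = 1000.0
    caller_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {"mutect2": 0.95, "sophia": 0.95, "shearwater": 0.90}
    )
    #: expected false-positive calls per sample per caller
    caller_fpr: float = 0.05
    #: fraction of false positives emitted below retention thresholds
    fp_subthreshold_prob: float = 0.8
    pfs_median_wt: float = 41.2
    os_median_wt: float = 120.0
    hr_single: float = 1.63
    hr_double: float = 3.34
    censor_fraction: float = 0.3
    followup_max: float = 192.0
    pair_fraction: float = 53.0 / 143.0
    p_acquire_del: float = 8.0 / 53.0
    p_acquire_mut: float = 4.0 / 53.0
    p_acquire_double: float = 2.0 / 53.0
    #: relapse carrier CCF drift toward 100: ccf' = 100 - (100-ccf)*shrink
    relapse_ccf_shrink: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"composition must sum to 1, got {total}")
        if set(self.composition) != set(PATIENT_CLASSES):
            raise ValueError(f"composition must cover {PATIENT_CLASSES}")
        if self.deterministic_counts is not None:
            if sum(self.deterministic_counts.values()) != self.n_patients:
                raise ValueError("deterministic counts must sum to n_patients")
        if not (0.0 <= self.pair_fraction <= 1.0):
            raise ValueError("pair_fraction must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Ground truth plus every observable table for one timepoint."""

    config: CohortConfig
    timepoint: str
    truth: pd.DataFrame
    segments: pd.DataFrame
    purity: pd.DataFrame
    calls: pd.DataFrame
    annotations: pd.DataFrame
    clinical: pd.DataFrame


def _draw_ccf(rng: np.random.Generator, config: CohortConfig) -> float:
    if rng.random() < config.p_clonal:
        return float(rng.uniform(*config.clonal_ccf))
    return float(rng.uniform(*config.subclonal_ccf))


def _patient_classes(rng: np.random.Generator, config: CohortConfig) -> list[str]:
    if config.deterministic_counts is not None:
        classes: list[str] = []
        for cls in PATIENT_CLASSES:
            classes.extend([cls] * config.deterministic_counts.get(cls, 0))
        return classes
    probs = [config.composition[c] for c in PATIENT_CLASSES]
    idx = rng.choice(len(PATIENT_CLASSES), size=config.n_patients, p=probs)
    return [PATIENT_CLASSES[i] for i in idx]


def _segments_for_patient(
    sample_id: str,
    tumor_cn: float,
    purity: float,
    rng: np.random.Generator,
    config: CohortConfig,
) -> list[dict]:
    """Three chr17 segments: neutral flank, locus-spanning, neutral flank."""
    locus = config.locus
    spans = [
        (locus.start - 600_000, locus.start - 50_001, 2.0, 400),
        (locus.start - 50_000, locus.end + 50_000, tumor_cn, config.n_probes_locus),
        (locus.end + 50_001, locus.end + 600_000, 2.0, 400),
    ]
    rows = []
    for start, end, cn, n_probes in spans:
        lr = tumor_cn_to_logratio(cn, purity)
        if config.probe_noise_sd > 0:
            lr += rng.normal(0.0, config.probe_noise_sd / math.sqrt(n_probes))
        rows.append(
            {
                "sample": sample_id,
                "chromosome": locus.chromosome,
                "start": start,
                "end": end,
                "log2_ratio": float(lr),
                "n_probes": n_probes,
            }
        )
    return rows


def _emit_variant_calls(
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    true_vaf: float,
    rng: np.random.Generator,
    config: CohortConfig,
    *,
    force_detect: bool = False,
) -> list[dict]:
    """Per-caller observed calls of one true variant."""
    depth = (
        int(rng.poisson(config.depth_mean))
        if config.read_sampling
        else int(config.depth_mean)
    )
    if config.read_sampling:
        obs_vaf = rng.binomial(depth, true_vaf) / depth if depth > 0 else 0.0
    else:
        obs_vaf = true_vaf
    rows = []
    for caller, sens in config.caller_sensitivity.items():
        detected = force_detect or rng.random() < sens
        if not detected or obs_vaf <= 0:
            continue
        quality = float(rng.uniform(35, 95)) if config.read_sampling else 60.0
        rows.append(
            {
                "sample": sample_id,
                "caller": caller,
                "chromosome": chrom,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "vaf": float(obs_vaf),
                "depth": depth,
                "quality": quality,
                "filter": "PASS",
            }
        )
    return rows


def _emit_false_positives(
    sample_id: str, rng: np.random.Generator, config: CohortConfig
) -> tuple[list[dict], list[dict]]:
    """Sporadic single-caller artifacts, mostly failing a filter branch."""
    calls, annots = [], []
    callers = list(config.caller_sensitivity)
    n_fp = rng.poisson(config.caller_fpr * len(callers))
    for _ in range(n_fp):
        caller = callers[rng.integers(len(callers))]
        pos = int(rng.integers(config.locus.start, config.locus.end))
        ref, alt = ("G", "T") if rng.random() < 0.5 else ("A", "C")
        sub = rng.random() < config.fp_subthreshold_prob
        mode = rng.integers(4) if sub else -1
        vaf = float(rng.uniform(0.005, 0.04)) if mode == 0 else float(
            rng.uniform(0.06, 0.15)
        )
        depth = int(rng.uniform(40, 200)) if mode == 1 else int(
            rng.uniform(300, 800)
        )
        quality = float(rng.uniform(5, 29)) if mode == 2 else float(
            rng.uniform(35, 95)
        )
        filt = "artifact" if mode == 3 else "PASS"
        calls.append(
            {
                "sample": sample_id,
                "caller": caller,
                "chromosome": config.locus.chromosome,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "vaf": vaf,
                "depth": depth,
                "quality": quality,
                "filter": filt,
            }
        )
        annots.append(
            {
                "chromosome": config.locus.chromosome,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "consequence": "synonymous" if rng.random() < 0.5 else "other",
                "clinvar_status": "absent",
                "cosmic_present": False,
                "insilico_support": "none",
                "population_freq": float(rng.uniform(0.0, 0.05)),
            }
        )
    return calls, annots


def _mutation_vaf(ccf_mut: float, tumor_cn: float, purity: float) -> float:
    """Expected VAF of one mutated copy at the given mutation CCF.

    Reads from the locus mix tumor (purity, local CN ``tumor_cn``) and
    normal (CN 2); the mutated allele is on one copy in the carrier
    fraction ``ccf_mut``.
    """
    total_copies = purity * tumor_cn + 2.0 * (1.0 - purity)
    return purity * (ccf_mut / 100.0) * 1.0 / total_copies


def _survival_times(
    rng: np.random.Generator, hazard_mult: float, config: CohortConfig
) -> dict:
    """Exponential PH survival with uniform-ish administrative censoring."""
    lam_pfs = math.log(2.0) / config.pfs_median_wt * hazard_mult
    lam_os = math.log(2.0) / config.os_median_wt * hazard_mult
    prog1 = rng.exponential(1.0 / lam_pfs)
    prog2 = prog1 + rng.exponential(1.0 / lam_pfs)
    death = rng.exponential(1.0 / lam_os)
    if rng.random() < config.censor_fraction:
        cens = rng.uniform(4.0, config.followup_max)
    else:
        cens = config.followup_max
    end = min(death, cens)
    return {
        "first_progression": round(prog1, 3) if prog1 < end else np.nan,
        "second_progression": (
            round(prog2, 3) if prog1 < end and prog2 < end else np.nan
        ),
        "death": round(death, 3) if death < cens else np.nan,
        "last_followup": round(end, 3),
    }


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a diagnosis-timepoint cohort from the config's seed."""
    rng = np.random.default_rng(config.seed)
    classes = _patient_classes(rng, config)

    truth_rows, seg_rows, purity_rows = [], [], []
    call_rows, annot_rows, clin_rows = [], [], []
    deterministic = config.deterministic_counts is not None

    for i, cls in enumerate(classes):
        pid = f"P{i + 1:04d}"
        purity = float(rng.uniform(*config.purity_range))

        if cls == "homdel":
            tumor_cn = float(rng.uniform(*config.homdel_cn))
            del_ccf = 100.0
        elif cls in ("del_only", "del_plus_mut"):
            if deterministic and cls == "del_plus_mut":
                # clonal deletion keeps the co-occurring mutation's VAF
                # safely above the 5% retention threshold, so the fixture
                # composition survives the pipeline exactly
                del_ccf = float(rng.uniform(*config.clonal_ccf))
            else:
                del_ccf = _draw_ccf(rng, config)
            tumor_cn = 2.0 - del_ccf / 100.0
        else:
            tumor_cn, del_ccf = 2.0, 0.0

        seg_rows.extend(_segments_for_patient(pid, tumor_cn, purity, rng, config))
        purity_rows.append(
            {"sample": pid, "purity": purity, "confidence": "high"}
        )

        mut_vaf = 0.0
        mut_ccf = 0.0
        if cls in ("mut_only", "del_plus_mut"):
            chrom, pos, ref, alt, consequence = _MUTATION_BANK[
                int(rng.integers(len(_MUTATION_BANK)))
            ]
            if deterministic:
                mut_ccf = float(rng.uniform(*config.clonal_ccf))
            else:
                mut_ccf = _draw_ccf(rng, config)
            if cls == "del_plus_mut":
                mut_ccf = min(mut_ccf, del_ccf)  # mutation within the deleted clone
            mut_vaf = _mutation_vaf(mut_ccf, tumor_cn, purity)
            call_rows.extend(
                _emit_variant_calls(
                    pid, chrom, pos, ref, alt, mut_vaf, rng, config,
                    force_detect=deterministic,
                )
            )
            annot_rows.append(
                {
                    "chromosome": chrom,
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "consequence": consequence,
                    "clinvar_status": "pathogenic",
                    "cosmic_present": True,
                    "insilico_support": "strong",
                    "population_freq": 0.0,
                }
            )
        if not deterministic:
            fp_calls, fp_annots = _emit_false_positives(pid, rng, config)
            call_rows.extend(fp_calls)
            annot_rows.extend(fp_annots)

        collapsed = (
            "wt"
            if cls == "wt"
            else "double" if cls in ("del_plus_mut", "homdel") else "single"
        )
        hazard = {"wt": 1.0, "single": config.hr_single, "double": config.hr_double}[
            collapsed
        ]
        surv = _survival_times(rng, hazard, config)
        clin_rows.append(
            {
                "patient_id": pid,
                "iss": int(rng.choice([1, 2, 3], p=[0.35, 0.35, 0.30])),
                "del17p_conventional": int(
                    rng.random() < (0.9 if del_ccf > 40 else 0.02)
                ),
                "del1p": int(rng.random() < 0.10),
                "amp1q": int(rng.random() < 0.30),
                "del13q": int(rng.random() < 0.45),
                "t_4_14": int(rng.random() < 0.12),
                **surv,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_class": cls,
                "true_collapsed": collapsed,
                "true_del_ccf": del_ccf,
                "true_tumor_cn": tumor_cn,
                "true_mut_ccf": mut_ccf,
                "true_mut_vaf": mut_vaf,
                "purity": purity,
                "hazard_mult": hazard,
            }
        )

    annotations = pd.DataFrame(
        annot_rows,
        columns=[
            "chromosome", "position", "ref", "alt", "consequence",
            "clinvar_status", "cosmic_present", "insilico_support",
            "population_freq",
        ],
    ).drop_duplicates(subset=["chromosome", "position", "ref", "alt"])
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "sample", "caller", "chromosome", "position", "ref", "alt",
            "vaf", "depth", "quality", "filter",
        ],
    )
    return SyntheticCohort(
        config=config,
        timepoint="diagnosis",
        truth=pd.DataFrame(truth_rows),
        segments=pd.DataFrame(seg_rows),
        purity=pd.DataFrame(purity_rows),
        calls=calls,
        annotations=annotations,
        clinical=pd.DataFrame(clin_rows),
    )


def _relapse_class(
    cls: str, rng: np.random.Generator, config: CohortConfig
) -> str:
    """Apply stochastic acquisition events to a diagnosis class."""
    u = rng.random()
    if cls == "wt":
        if u < config.p_acquire_del:
            return "del_only"
        if u < config.p_acquire_del + config.p_acquire_mut:
            return "mut_only"
        if u < config.p_acquire_del + config.p_acquire_mut + config.p_acquire_double:
            return "del_plus_mut"
        return "wt"
    if cls == "del_only" and u < config.p_acquire_double:
        return "del_plus_mut"
    if cls == "mut_only" and u < config.p_acquire_double:
        return "del_plus_mut"
    return cls


def generate_relapse_pairs(
    cohort: SyntheticCohort,
    *,
    deterministic_acquisitions: Mapping[str, int] | None = None,
    n_pairs: int | None = None,
    n_altered: int | None = None,
) -> SyntheticCohort:
    """Re-assess a paired subset of the cohort at relapse.

    In the default stochastic mode a uniform subset of patients is
    re-sampled, acquisition events are applied at the configured
    probabilities and carrier CCFs drift toward the relapse distribution.
    With ``deterministic_acquisitions`` (counts per acquisition class,
    applied to wild-type patients in order) the transition pattern is
    exact, for worked examples.
    """
    config = cohort.config
    seed = (config.seed * 1_000_003 + 53) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    truth = cohort.truth
    if n_pairs is None:
        n_pairs = int(round(config.pair_fraction * len(truth)))
    if n_pairs > len(truth):
        raise ValueError("pair fraction exceeds the cohort size")

    deterministic = deterministic_acquisitions is not None
    if deterministic:
        needed_wt = sum(deterministic_acquisitions.values())
        wt_ids = truth.loc[truth["true_class"] == "wt", "patient_id"].tolist()
        alt_ids = truth.loc[truth["true_class"] != "wt", "patient_id"].tolist()
        if needed_wt > len(wt_ids):
            raise ValueError("not enough wild-type patients for the pattern")
        if n_altered is None:
            n_altered = min(len(alt_ids), n_pairs - needed_wt)
        if n_altered > len(alt_ids) or needed_wt + n_altered > n_pairs:
            raise ValueError("acquisition pattern does not fit the pairing")
        n_wt = n_pairs - n_altered
        pair_ids = wt_ids[:n_wt] + alt_ids[:n_altered]
        acquisition_plan: dict[str, str] = {}
        cursor = 0
        for acq, count in deterministic_acquisitions.items():
            target = {
                "acquired_del": "del_only",
                "acquired_mut": "mut_only",
                "acquired_double": "del_plus_mut",
            }[acq]
            for pid in wt_ids[cursor : cursor + count]:
                acquisition_plan[pid] = target
            cursor += count
    else:
        pair_ids = list(
            rng.choice(truth["patient_id"], size=n_pairs, replace=False)
        )
        acquisition_plan = {}

    sub_config = replace(
        config,
        n_patients=n_pairs,
        deterministic_counts=None,
    )
    truth_rows, seg_rows, purity_rows = [], [], []
    call_rows, annot_rows, clin_rows = [], [], []

    truth_by_id = truth.set_index("patient_id")
    clinical_by_id = cohort.clinical.set_index("patient_id")

    for pid in pair_ids:
        dx = truth_by_id.loc[pid]
        cls_dx = dx["true_class"]
        if deterministic:
            cls_rel = acquisition_plan.get(pid, cls_dx)
        else:
            cls_rel = _relapse_class(cls_dx, rng, sub_config)

        purity = float(dx["purity"])  # same sample source; purity re-drawn mildly
        if not deterministic:
            purity = float(
                np.clip(purity + rng.normal(0, 0.05), *config.purity_range)
            )

        if cls_rel == "homdel":
            tumor_cn = float(dx["true_tumor_cn"])
            del_ccf = 100.0
        elif cls_rel in ("del_only", "del_plus_mut"):
            if cls_dx in ("del_only", "del_plus_mut") and dx["true_del_ccf"] > 0:
                del_ccf = 100.0 - (100.0 - float(dx["true_del_ccf"])) * (
                    config.relapse_ccf_shrink
                )
            else:  # newly acquired deletion: relapse-like CCF
                del_ccf = float(rng.uniform(25.5, 100.0)) if not deterministic else 70.0
            tumor_cn = 2.0 - del_ccf / 100.0
        else:
            tumor_cn, del_ccf = 2.0, 0.0

        seg_rows.extend(
            _segments_for_patient(pid, tumor_cn, purity, rng, sub_config)
        )
        purity_rows.append({"sample": pid, "purity": purity, "confidence": "high"})

        mut_vaf = mut_ccf = 0.0
        if cls_rel in ("mut_only", "del_plus_mut"):
            chrom, pos, ref, alt, consequence = _MUTATION_BANK[
                int(rng.integers(len(_MUTATION_BANK)))
            ]
            if deterministic:
                mut_ccf = 80.0
            else:
                base = (
                    float(dx["true_mut_ccf"])
                    if cls_dx in ("mut_only", "del_plus_mut")
                    else _draw_ccf(rng, sub_config)
                )
                mut_ccf = 100.0 - (100.0 - base) * config.relapse_ccf_shrink
            if cls_rel == "del_plus_mut":
                mut_ccf = min(mut_ccf, del_ccf)
            mut_vaf = _mutation_vaf(mut_ccf, tumor_cn, purity)
            call_rows.extend(
                _emit_variant_calls(
                    pid, chrom, pos, ref, alt, mut_vaf, rng, sub_config,
                    force_detect=deterministic,
                )
            )
            annot_rows.append(
                {
                    "chromosome": chrom,
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "consequence": consequence,
                    "clinvar_status": "pathogenic",
                    "cosmic_present": True,
                    "insilico_support": "strong",
                    "population_freq": 0.0,
                }
            )
        if not deterministic:
            fp_calls, fp_annots = _emit_false_positives(pid, rng, sub_config)
            call_rows.extend(fp_calls)
            annot_rows.extend(fp_annots)

        collapsed = (
            "wt"
            if cls_rel == "wt"
            else "double" if cls_rel in ("del_plus_mut", "homdel") else "single"
        )
        clin_rows.append(clinical_by_id.loc[pid].to_dict() | {"patient_id": pid})
        truth_rows.append(
            {
                "patient_id": pid,
                "true_class": cls_rel,
                "true_class_dx": cls_dx,
                "true_collapsed": collapsed,
                "true_del_ccf": del_ccf,
                "true_tumor_cn": tumor_cn,
                "true_mut_ccf": mut_ccf,
                "true_mut_vaf": mut_vaf,
                "purity": purity,
            }
        )

    annotations = pd.concat(
        [
            cohort.annotations,
            pd.DataFrame(
                annot_rows, columns=list(cohort.annotations.columns)
            ),
        ],
        ignore_index=True,
    ).drop_duplicates(subset=["chromosome", "position", "ref", "alt"])
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "sample", "caller", "chromosome", "position", "ref", "alt",
            "vaf", "depth", "quality", "filter",
        ],
    )
    return SyntheticCohort(
        config=sub_config,
        timepoint="relapse",
        truth=pd.DataFrame(truth_rows),
        segments=pd.DataFrame(seg_rows),
        purity=pd.DataFrame(purity_rows),
        calls=calls,
        annotations=annotations,
        clinical=pd.DataFrame(clin_rows),
    )


def diagnosis_fixture_config(seed: int = 0) -> CohortConfig:
    """Noise-free deterministic config reproducing the 143-patient
    reference composition exactly through the full pipeline."""
    return CohortConfig(
        n_patients=143,
        seed=seed,
        deterministic_counts=FIXTURE_COMPOSITION_143,
        purity_range=(0.7, 1.0),
        probe_noise_sd=0.0,
        read_sampling=False,
        caller_sensitivity={"mutect2": 1.0, "sophia": 1.0, "shearwater": 1.0},
        caller_fpr=0.0,
    )
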