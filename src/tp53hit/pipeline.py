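"""End-to-end orchestration: simulate -> callcn -> variants -> classify ->
rocscan -> survival -> longitudinal -> report.

The analysis stages are plain functions over in-memory tables so they can
be driven either from the file-based runner (:func:`run_pipeline`, which
also writes a manifest with content digests and seeds) or directly from
tests. Identical config and seed reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .allelic import AllelicStatus, classify_patient, cohort_summary
from .cohort import CohortConfig, SyntheticCohort, generate_cohort, generate_relapse_pairs
from .copy_number import DEFAULT_CCF_CUTOFF, GeneCNCall, TP53_LOCUS, gene_level_call
from .longitudinal import (
    aberration_frequency_shift,
    acquisition_summary,
    ccf_shift,
    mcnemar_paired_shift,
    pair_statuses,
    paired_ccf_shift,
)
from .roc import threshold_scan
from .survival import cox_univariable, km_fit, make_endpoints
from .variant_filtering import RawCall, filter_variants

__all__ = [
    "RunManifest",
    "call_gene_cn",
    "classify_cohort",
    "consensus_variants",
    "endpoint_arrays",
    "run_pipeline",
    "survival_report",
]


def call_gene_cn(
    segments_by_sample: Mapping[str, list],
    purity: Mapping[str, object],
    *,
    locus=TP53_LOCUS,
    ccf_cutoff: float = DEFAULT_CCF_CUTOFF,
) -> list[GeneCNCall]:
    """Gene-level CN calls for every sample with a purity estimate."""
    calls = []
    for sample_id, segs in sorted(segments_by_sample.items()):
        if sample_id not in purity:
            raise KeyError(f"no purity estimate for sample {sample_id!r}")
        calls.append(
            gene_level_call(
                segs,
                purity[sample_id],
                locus=locus,
                ccf_cutoff=ccf_cutoff,
                sample_id=sample_id,
            )
        )
    return calls


def _calls_from_table(calls_df: pd.DataFrame) -> list[RawCall]:
    return [
        RawCall(
            caller=r.caller,
            chromosome=r.chromosome,
            position=int(r.position),
            ref=r.ref,
            alt=r.alt,
            vaf=float(r.vaf),
            depth=int(r.depth),
            quality=float(r.quality),
            filter_flags=frozenset(str(r.filter).split(";")),
            sample_id=r.sample,
        )
        for r in calls_df.itertuples(index=False)
    ]


def consensus_variants(
    calls_df: pd.DataFrame,
    annotations: Mapping,
    **filter_kwargs,
) -> list:
    """Run the consensus/filter cascade over a long-format call table."""
    return filter_variants(_calls_from_table(calls_df), annotations, **filter_kwargs)


def classify_cohort(
    cn_calls: Sequence[GeneCNCall],
    variants: Sequence,
    *,
    timepoint: str = "diagnosis",
) -> list[AllelicStatus]:
    by_sample: dict[str, list] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    return [
        classify_patient(
            call, by_sample.get(call.sample_id, ()), timepoint=timepoint
        )
        for call in cn_calls
    ]


def endpoint_arrays(
    clinical_df: pd.DataFrame, endpoint: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(time, event, patient_ids) arrays for one endpoint."""
    times, events, ids = [], [], []
    for rec in tio.clinical_records(clinical_df):
        eps = make_endpoints(rec)
        if endpoint in eps:
            times.append(eps[endpoint].time)
            events.append(eps[endpoint].event)
            ids.append(rec.patient_id)
    return np.asarray(times), np.asarray(events), ids


def survival_report(
    statuses: Sequence[AllelicStatus],
    clinical_df: pd.DataFrame,
    endpoints: Sequence[str] = ("PFS", "OS", "PFS2"),
) -> dict:
    """KM medians and Cox HRs (unadjusted and ISS-adjusted) per comparison.

    Comparisons mirror the usual reporting: deletion carriers vs wild-type,
    any single hit vs wild-type, double hit vs wild-type.
    """
    collapsed = {s.patient_id: s.collapsed for s in statuses}
    status_by_id = {s.patient_id: s.status for s in statuses}
    iss_by_id = (
        dict(zip(clinical_df["patient_id"], clinical_df["iss"]))
        if "iss" in clinical_df.columns
        else {}
    )

    def deletion_carrier(pid):
        return status_by_id.get(pid) in ("SINGLE_DEL", "DOUBLE_HOMDEL", "DOUBLE_DELMUT")

    comparisons = {
        "deletion_vs_wt": lambda pid: (
            True if deletion_carrier(pid) else (None if collapsed[pid] != "wt" else False)
        ),
        "single_vs_wt": lambda pid: (
            True
            if collapsed.get(pid) == "single"
            else (False if collapsed.get(pid) == "wt" else None)
        ),
        "double_vs_wt": lambda pid: (
            True
            if collapsed.get(pid) == "double"
            else (False if collapsed.get(pid) == "wt" else None)
        ),
    }

    report: dict = {}
    for endpoint in endpoints:
        times, events, ids = endpoint_arrays(clinical_df, endpoint)
        ep_report: dict = {}
        for name, selector in comparisons.items():
            mask, group = [], []
            for pid in ids:
                sel = selector(pid) if pid in collapsed else None
                mask.append(sel is not None)
                group.append(1 if sel else 0)
            mask = np.asarray(mask)
            group = np.asarray(group)[mask]
            t, e = times[mask], events[mask]
            if len(np.unique(group)) < 2:
                ep_report[name] = {"note": "degenerate grouping"}
                continue
            km_alt = km_fit(t[group == 1], e[group == 1])
            km_wt = km_fit(t[group == 0], e[group == 0])
            unadjusted = cox_univariable(t, e, group)
            iss = pd.DataFrame(
                {"iss": [iss_by_id.get(pid, 2) for pid, m in zip(ids, mask) if m]}
            )
            adjusted = cox_univariable(t, e, group, adjust=iss)
            ep_report[name] = {
                "km_altered": km_alt.to_dict(),
                "km_wt": km_wt.to_dict(),
                "cox_unadjusted": unadjusted.to_dict(),
                "cox_iss_adjusted": adjusted.to_dict(),
            }
        report[endpoint] = ep_report
    return report


def annotations_from_table(annotations_df: pd.DataFrame) -> dict:
    """Annotation table -> mapping keyed by normalized variant key."""
    from .variant_filtering import VariantAnnotation, normalize_and_key

    out = {}
    for r in annotations_df.itertuples(index=False):
        key = normalize_and_key(r.chromosome, int(r.position), r.ref, r.alt)
        out[key] = VariantAnnotation(
            consequence=r.consequence,
            clinvar_status=r.clinvar_status,
            cosmic_present=bool(r.cosmic_present),
            insilico_support=r.insilico_support,
            population_freq=float(r.population_freq),
        )
    return out


def analyze_cohort(cohort: SyntheticCohort) -> tuple[list, list, list]:
    """Run callcn + variants + classify in memory over a synthetic cohort.

    Returns ``(gene_cn_calls, audited_variants, allelic_statuses)``.
    """
    from .copy_number import PurityEstimate, Segment

    segs: dict[str, list] = {}
    for r in cohort.segments.itertuples(index=False):
        segs.setdefault(r.sample, []).append(
            Segment(
                r.chromosome, int(r.start), int(r.end),
                float(r.log2_ratio), int(r.n_probes),
            )
        )
    purity = {
        r.sample: PurityEstimate(r.sample, float(r.purity), r.confidence)
        for r in cohort.purity.itertuples(index=False)
    }
    cn_calls = call_gene_cn(segs, purity)
    variants = consensus_variants(
        cohort.calls, annotations_from_table(cohort.annotations)
    )
    statuses = classify_cohort(
        cn_calls, [v for v in variants if v.retained], timepoint=cohort.timepoint
    )
    return cn_calls, variants, statuses


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Traceability record of one pipeline run."""

    version: str
    seed: int
    config: dict
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def digests(self) -> dict:
        return {
            out: digest
            for stage in self.stages
            for out, digest in stage["outputs"].items()
        }

    def to_dict(self) -> dict:
        return asdict(self)


def _write_cohort_inputs(cohort: SyntheticCohort, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tio.write_seg(cohort.segments, out / "segments.tsv")
    tio.write_purity(cohort.purity, out / "purity.tsv")
    tio.write_annotations(cohort.annotations, out / "annotations.tsv")
    tio.write_clinical(cohort.clinical, out / "clinical.tsv")
    cohort.truth.round(6).to_csv(out / "truth.tsv", sep="\t", index=False)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for (sample, caller), group in sorted(
        cohort.calls.groupby(["sample", "caller"], sort=True)
    ):
        tio.write_vcf(group, vcf_dir / f"{sample}.{caller}.vcf")
    for name in ["segments", "purity", "annotations", "clinical", "truth"]:
        paths[f"{name}.tsv"] = _sha256(out / f"{name}.tsv")
    for p in sorted(vcf_dir.glob("*.vcf")):
        paths[f"vcf/{p.name}"] = _sha256(p)
    return paths


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    *,
    n_boot: int = 200,
    roc_timepoints: Sequence[float] = tuple(range(12, 97, 12)),
) -> RunManifest:
    """Run every stage on a synthetic cohort and write all artifacts.

    Returns the manifest; stage outputs are traceable through its content
    digests. Rerunning with the same config and seed reproduces identical
    digests (timestamps live only in the manifest).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config={
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(config).items()
            if k != "locus"
        },
        started=datetime.now(timezone.utc).isoformat(),
    )

    # 1. simulate
    cohort = generate_cohort(config)
    relapse = generate_relapse_pairs(cohort)
    inputs = _write_cohort_inputs(cohort, out / "diagnosis")
    inputs |= {
        f"relapse/{k}": v
        for k, v in _write_cohort_inputs(relapse, out / "relapse").items()
    }
    manifest.add_stage("simulate", inputs)

    results: dict[str, dict] = {}
    statuses_by_tp: dict[str, list[AllelicStatus]] = {}
    cn_by_tp: dict[str, list[GeneCNCall]] = {}

    for timepoint, data in (("diagnosis", cohort), ("relapse", relapse)):
        tp_dir = out / timepoint
        # 2. callcn
        seg_df = tio.read_seg(tp_dir / "segments.tsv")
        purity = tio.read_purity(tp_dir / "purity.tsv")
        cn_calls = call_gene_cn(tio.segments_by_sample(seg_df), purity)
        tio.write_gene_calls(cn_calls, tp_dir / "gene_calls.tsv")
        cn_by_tp[timepoint] = cn_calls

        # 3. variants
        annotations = tio.read_annotations(tp_dir / "annotations.tsv")
        raw_calls = []
        for p in sorted((tp_dir / "vcf").glob("*.vcf")):
            sample, caller = p.stem.rsplit(".", 1)
            raw_calls.extend(tio.read_vcf(p, caller, sample_id=sample))
        variants = filter_variants(raw_calls, annotations)
        tio.write_variants(variants, tp_dir / "variants.tsv")

        # 4. classify
        statuses = classify_cohort(
            cn_calls, [v for v in variants if v.retained], timepoint=timepoint
        )
        statuses_by_tp[timepoint] = statuses
        tio.write_status(statuses, tp_dir / "status.tsv")
        summary = cohort_summary(statuses)
        tio.write_json(summary.to_dict(), tp_dir / "summary.json")

    for stage, fname in (
        ("callcn", "gene_calls.tsv"),
        ("variants", "variants.tsv"),
        ("classify", "status.tsv"),
    ):
        manifest.add_stage(
            stage,
            {
                f"{tp}/{fname}": _sha256(out / tp / fname)
                for tp in ("diagnosis", "relapse")
            },
        )

    # 5. rocscan (diagnosis deletion CCF vs PFS and OS)
    clinical = tio.read_clinical(out / "diagnosis" / "clinical.tsv")
    ccf = np.array([c.deletion_ccf for c in cn_by_tp["diagnosis"]])
    pfs_t, pfs_e, _ = endpoint_arrays(clinical, "PFS")
    os_t, os_e, _ = endpoint_arrays(clinical, "OS")
    scan = threshold_scan(
        ccf,
        {"PFS": (pfs_t, pfs_e), "OS": (os_t, os_e)},
        timepoints=roc_timepoints,
        n_boot=n_boot,
        seed=config.seed,
    )
    tio.write_json(scan.to_dict(), out / "rocscan.json")
    manifest.add_stage("rocscan", {"rocscan.json": _sha256(out / "rocscan.json")})

    # 6. survival
    surv = survival_report(statuses_by_tp["diagnosis"], clinical)
    tio.write_json(surv, out / "survival.json")
    manifest.add_stage("survival", {"survival.json": _sha256(out / "survival.json")})

    # 7. longitudinal
    records = pair_statuses(statuses_by_tp["diagnosis"], statuses_by_tp["relapse"])
    acq = acquisition_summary(records)
    dx_summary = cohort_summary(statuses_by_tp["diagnosis"])
    rel_summary = cohort_summary(statuses_by_tp["relapse"])
    freq = aberration_frequency_shift(
        dx_summary.any_alteration, dx_summary.n,
        rel_summary.any_alteration, rel_summary.n,
    )
    dx_ccfs = [s.deletion_ccf for s in statuses_by_tp["diagnosis"] if s.deletion_ccf > 0]
    rel_ccfs = [s.deletion_ccf for s in statuses_by_tp["relapse"] if s.deletion_ccf > 0]
    longitudinal = {
        "acquisition": acq,
        "frequency_shift": freq,
        "mcnemar_paired": mcnemar_paired_shift(records),
        "ccf_shift": (
            ccf_shift(dx_ccfs, rel_ccfs) if dx_ccfs and rel_ccfs else None
        ),
        "paired_ccf_shift": paired_ccf_shift(records),
    }
    tio.write_json(longitudinal, out / "longitudinal.json")
    manifest.add_stage(
        "longitudinal", {"longitudinal.json": _sha256(out / "longitudinal.json")}
    )

    # 8. report
    report = _render_report(dx_summary, rel_summary, scan, surv, longitudinal)
    (out / "report.txt").write_text(report)
    manifest.add_stage("report", {"report.txt": _sha256(out / "report.txt")})

    manifest.finished = datetime.now(timezone.utc).isoformat()
    tio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def _render_report(dx_summary, rel_summary, scan, surv, longitudinal) -> str:
    lines = [
        "TP53 allelic status pipeline report",
        "===================================",
        "",
        f"Diagnosis cohort: n={dx_summary.n}",
        f"  deletion carriers: {dx_summary.deletion_carriers} "
        f"({dx_summary.deletion_carrier_percent}%)",
        f"  mutation-only:     {dx_summary.mutation_only} "
        f"({dx_summary.mutation_only_percent}%)",
        f"  double-hit:        {dx_summary.collapsed_counts['double']} "
        f"({dx_summary.collapsed_percents['double']}%)",
        f"  wild-type:         {dx_summary.status_counts['WT']}",
        "",
        f"Adopted deletion-call CCF cutoff: {scan.adopted_cutoff_ccf}",
        f"  per endpoint: {scan.per_endpoint_cutoff_ccf}",
        "",
        "Survival (PFS, double vs wt):",
    ]
    try:
        cox = surv["PFS"]["double_vs_wt"]["cox_unadjusted"]["variables"]["group"]
        lines.append(
            f"  HR {cox['hr']:.2f} (95% CI {cox['ci95'][0]:.2f}-{cox['ci95'][1]:.2f}, "
            f"p={cox['p']:.3g})"
        )
    except (KeyError, TypeError):
        lines.append("  not estimable")
    acq = longitudinal["acquisition"]
    lines += [
        "",
        f"Relapse pairs: n={acq['n_pairs']}, total acquired {acq['total_acquired']} "
        f"(del {acq['counts']['acquired_del']}, mut {acq['counts']['acquired_mut']}, "
        f"double {acq['counts']['acquired_double']})",
        f"Carrier frequency: {longitudinal['frequency_shift']['percent_dx']}% -> "
        f"{longitudinal['frequency_shift']['percent_rel']}% "
        f"(p={longitudinal['frequency_shift']['p']:.3g})",
        "",
    ]
    return "\n".join(lines)
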