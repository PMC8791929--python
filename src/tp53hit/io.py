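"""Readers and writers for the pipeline's interchange formats.

Tables travel as TSV with fixed, versioned headers; variant call sets as
minimal VCF 4.2 (one file per sample per caller, read back through cyvcf2
with multi-allelic records decomposed per alternate allele). SEG-like
coordinates are 1-based inclusive on disk and stay 1-based inclusive in
:class:`~tp53hit.copy_number.Segment`.

Validation errors name the offending rows.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .copy_number import GeneCNCall, PurityEstimate, Segment
from .survival import ClinicalRecord
from .variant_filtering import (
    ConsensusVariant,
    RawCall,
    VariantAnnotation,
    normalize_and_key,
)

__all__ = [
    "SchemaError",
    "read_annotations",
    "read_clinical",
    "read_purity",
    "read_seg",
    "read_vcf",
    "write_annotations",
    "write_clinical",
    "write_gene_calls",
    "write_purity",
    "write_seg",
    "write_status",
    "write_variants",
    "write_vcf",
]

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "log2_ratio", "n_probes"]
PURITY_COLUMNS = ["sample", "purity", "confidence"]
CLINICAL_COLUMNS = [
    "patient_id", "iss", "del17p_conventional", "del1p", "amp1q", "del13q",
    "t_4_14", "first_progression", "second_progression", "death",
    "last_followup",
]
ANNOTATION_COLUMNS = [
    "chromosome", "position", "ref", "alt", "consequence", "clinvar_status",
    "cosmic_present", "insilico_support", "population_freq",
]
GENE_CALL_COLUMNS = [
    "sample", "gene", "tumor_cn", "cn_class", "deletion_ccf", "is_deleted",
    "is_homdel", "purity",
]
STATUS_COLUMNS = [
    "patient_id", "timepoint", "status", "collapsed", "deletion_ccf",
    "n_pathogenic_mutations", "max_vaf",
]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def _require_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _offenders(mask: pd.Series) -> str:
    rows = [str(i + 2) for i in mask[mask].index[:10]]  # +2: header + 1-based
    return ", ".join(rows)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read and validate a SEG-like TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SEG_COLUMNS, f"SEG file {path}")
    bad = df["start"] > df["end"]
    if bad.any():
        raise SchemaError(f"SEG file {path}: start > end at file rows {_offenders(bad)}")
    bad = df["n_probes"] < 1
    if bad.any():
        raise SchemaError(f"SEG file {path}: n_probes < 1 at file rows {_offenders(bad)}")
    return df[SEG_COLUMNS]


def segments_by_sample(seg_df: pd.DataFrame) -> dict[str, list[Segment]]:
    out: dict[str, list[Segment]] = {}
    for row in seg_df.itertuples(index=False):
        out.setdefault(row.sample, []).append(
            Segment(
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                log2_ratio=float(row.log2_ratio),
                n_probes=int(row.n_probes),
            )
        )
    return out


def write_seg(df: pd.DataFrame, path: str | Path) -> None:
    df[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_purity(path: str | Path) -> dict[str, PurityEstimate]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PURITY_COLUMNS, f"purity file {path}")
    bad = ~((df["purity"] > 0) & (df["purity"] <= 1))
    if bad.any():
        raise SchemaError(
            f"purity file {path}: purity outside (0, 1] at file rows {_offenders(bad)}"
        )
    return {
        row.sample: PurityEstimate(row.sample, float(row.purity), row.confidence)
        for row in df.itertuples(index=False)
    }


def write_purity(df: pd.DataFrame, path: str | Path) -> None:
    df[PURITY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["patient_id", "last_followup"], f"clinical file {path}")
    return df


def clinical_records(df: pd.DataFrame) -> list[ClinicalRecord]:
    def opt(v) -> float | None:
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return [
        ClinicalRecord(
            patient_id=row.patient_id,
            last_followup=float(row.last_followup),
            first_progression=opt(getattr(row, "first_progression", None)),
            second_progression=opt(getattr(row, "second_progression", None)),
            death=opt(getattr(row, "death", None)),
        )
        for row in df.itertuples(index=False)
    ]


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_annotations(path: str | Path) -> dict:
    """Annotation TSV keyed by normalized variant key."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ANNOTATION_COLUMNS, f"annotation file {path}")
    out = {}
    for row in df.itertuples(index=False):
        key = normalize_and_key(row.chromosome, int(row.position), row.ref, row.alt)
        out[key] = VariantAnnotation(
            consequence=row.consequence,
            clinvar_status=row.clinvar_status,
            cosmic_present=bool(row.cosmic_present),
            insilico_support=row.insilico_support,
            population_freq=float(row.population_freq),
        )
    return out


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


VCF_HEADER = """##fileformat=VCFv4.2
##source=tp53hit-synthetic
##contig=<ID={contig}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=VAF,Number=A,Type=Float,Description="Variant allele fraction">
{filters}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Iterable[RawCall] | pd.DataFrame, path: str | Path) -> None:
    """Write calls of one sample+caller as a minimal VCF 4.2 file."""
    if isinstance(calls, pd.DataFrame):
        rows = [
            dict(
                chromosome=r.chromosome, position=int(r.position), ref=r.ref,
                alt=r.alt, vaf=float(r.vaf), depth=int(r.depth),
                quality=float(r.quality), filter_flags=str(r.filter).split(";"),
            )
            for r in calls.itertuples(index=False)
        ]
    else:
        rows = [
            dict(
                chromosome=c.chromosome, position=c.position, ref=c.ref,
                alt=c.alt, vaf=c.vaf, depth=c.depth, quality=c.quality,
                filter_flags=sorted(c.filter_flags),
            )
            for c in calls
        ]
    rows.sort(key=lambda r: (r["chromosome"], r["position"], r["ref"], r["alt"]))
    contig = rows[0]["chromosome"] if rows else "chr17"
    filter_ids = sorted(
        {f for r in rows for f in r["filter_flags"] if f and f != "PASS"}
    )
    filter_lines = "".join(
        f'##FILTER=<ID={fid},Description="Caller-specific failure">\n'
        for fid in filter_ids
    )
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=contig, filters=filter_lines))
        for r in rows:
            qual = "." if math.isnan(r["quality"]) else f"{r['quality']:.1f}"
            filt = ";".join(r["filter_flags"]) or "PASS"
            fh.write(
                f"{r['chromosome']}\t{r['position']}\t.\t{r['ref']}\t{r['alt']}\t"
                f"{qual}\t{filt}\t"
                f"DP={r['depth']};VAF={r['vaf']:.6f}\n"
            )


def read_vcf(path: str | Path, caller: str, sample_id: str = "") -> list[RawCall]:
    """Read a VCF into raw calls, decomposing multi-allelic records.

    VAF and depth come from the ``VAF``/``DP`` INFO fields; the FILTER
    column becomes the filter-flag set (cyvcf2 reports PASS as None).
    """
    calls: list[RawCall] = []
    for variant in VCF(str(path)):
        flags = frozenset((variant.FILTER or "PASS").split(";"))
        depth = int(variant.INFO.get("DP", 0) or 0)
        vaf = variant.INFO.get("VAF", 0.0)
        vafs = list(vaf) if isinstance(vaf, (tuple, list)) else [float(vaf or 0.0)]
        if len(vafs) < len(variant.ALT):
            vafs = vafs * len(variant.ALT)
        qual = float(variant.QUAL) if variant.QUAL is not None else float("nan")
        for alt, v in zip(variant.ALT, vafs):
            calls.append(
                RawCall(
                    caller=caller,
                    chromosome=variant.CHROM,
                    position=int(variant.POS),
                    ref=variant.REF,
                    alt=alt,
                    vaf=float(v),
                    depth=depth,
                    quality=qual,
                    filter_flags=flags,
                    sample_id=sample_id,
                )
            )
    return calls


def write_gene_calls(calls: Iterable[GeneCNCall], path: str | Path) -> None:
    rows = [
        {
            "sample": c.sample_id,
            "gene": c.gene,
            "tumor_cn": round(c.tumor_cn, 6),
            "cn_class": c.cn_class,
            "deletion_ccf": round(c.deletion_ccf, 6),
            "is_deleted": c.is_deleted,
            "is_homdel": c.is_homdel,
            "purity": round(c.purity, 6),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=GENE_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_calls(path: str | Path) -> list[GeneCNCall]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, GENE_CALL_COLUMNS, f"gene-call file {path}")
    return [
        GeneCNCall(
            sample_id=r.sample,
            gene=r.gene,
            tumor_cn=float(r.tumor_cn),
            cn_class=r.cn_class,
            deletion_ccf=float(r.deletion_ccf),
            is_deleted=bool(r.is_deleted),
            is_homdel=bool(r.is_homdel),
            purity=float(r.purity),
        )
        for r in df.itertuples(index=False)
    ]


def write_variants(variants: Iterable[ConsensusVariant], path: str | Path) -> None:
    """Full audit TSV: one row per keyed variant with per-filter verdicts."""
    rows = []
    for v in variants:
        rows.append(
            {
                "sample": v.sample_id,
                "chromosome": v.key.chromosome,
                "position": v.key.position,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "callers": ";".join(sorted(v.supporting_callers)),
                "vaf": round(v.vaf, 6),
                "depth": v.depth,
                "pathogenicity": v.pathogenicity,
                "retained": v.retained,
                "verdicts": ";".join(
                    f"{name}={'pass' if ok else 'fail'}"
                    for name, ok in v.filter_verdicts
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "sample", "chromosome", "position", "ref", "alt", "callers",
            "vaf", "depth", "pathogenicity", "retained", "verdicts",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_status(statuses, path: str | Path) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "timepoint": s.timepoint,
            "status": s.status,
            "collapsed": s.collapsed,
            "deletion_ccf": round(s.deletion_ccf, 6),
            "n_pathogenic_mutations": s.n_pathogenic_mutations,
            "max_vaf": round(s.max_vaf, 6),
        }
        for s in statuses
    ]
    pd.DataFrame(rows, columns=STATUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_status(path: str | Path):
    from .allelic import AllelicStatus

    df = pd.read_csv(path, sep="\t")
    _require_columns(df, STATUS_COLUMNS, f"status file {path}")
    return [
        AllelicStatus(
            patient_id=r.patient_id,
            status=r.status,
            timepoint=r.timepoint,
            deletion_ccf=float(r.deletion_ccf),
            n_pathogenic_mutations=int(r.n_pathogenic_mutations),
            max_vaf=float(r.max_vaf),
        )
        for r in df.itertuples(index=False)
    ]


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
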