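"""Gene-level copy-number calling from segmented SNP-array log2 ratios.

The observed log2 ratio of a tumor sample is modelled as a two-population
mixture of tumor cells (fraction = purity ``p``) at integer-ish copy number
``c`` and admixed normal cells at copy number 2::

    L = log2( (p * c + 2 * (1 - p)) / 2 )

Inverting this gives the purity-corrected tumor copy number, from which a
cancer cell fraction (CCF) for a hemizygous single-copy deletion follows as
``CCF = clamp(2 - c, 0, 1) * 100``: a clonal single-copy loss (c = 1) has
CCF 100%, a diploid locus CCF 0%.

Copy-number classes use fixed thresholds on the corrected copy number
(0.6 homozygous loss, 1.9 single loss, 2.1 single gain, 3.4 multi gain).
Values exactly at 1.9 or 2.1 are neutral; exactly 0.6 is homozygous loss;
exactly 3.4 is multi gain.

A lightweight recursive binary segmenter over probe-level log ratios is
provided for inputs that are not already segmented; its split criterion is
the two-sample t test at a configurable significance threshold (default
1e-7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CN_CLASSES",
    "CNThresholds",
    "CopyNumberError",
    "GeneCNCall",
    "GenomicInterval",
    "InvalidPurityError",
    "MissingCoverageError",
    "ProbeTrack",
    "PurityEstimate",
    "Segment",
    "TP53_LOCUS",
    "classify_cn",
    "deletion_ccf",
    "gene_level_call",
    "logratio_to_tumor_cn",
    "segment_probes",
    "tumor_cn_to_logratio",
]


class CopyNumberError(ValueError):
    """Invalid input to a copy-number operation."""


class InvalidPurityError(CopyNumberError):
    """Purity outside (0, 1]."""


class MissingCoverageError(CopyNumberError):
    """No segment overlaps the requested locus."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CopyNumberError(
                f"interval start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if disjoint or other chromosome)."""
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


#: TP53 gene body on GRCh37/hg19.
TP53_LOCUS = GenomicInterval("chr17", 7_565_097, 7_590_856)

#: Default CCF (percent) above which a deletion is called.
DEFAULT_CCF_CUTOFF = 10.0


@dataclass(frozen=True)
class Segment:
    """One segment of a segmented copy-number profile.

    Coordinates are 1-based inclusive (SEG dialect).
    """

    chromosome: str
    start: int
    end: int
    log2_ratio: float
    n_probes: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CopyNumberError(f"segment start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise CopyNumberError("segment must be supported by >= 1 probe")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end)


@dataclass(frozen=True)
class PurityEstimate:
    """Tumor cell fraction of a sample, as estimated upstream (e.g. ASCAT)."""

    sample_id: str
    purity: float
    confidence: str = "high"  # {high, low, manual_review}

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise InvalidPurityError(
                f"purity must be in (0, 1], got {self.purity}"
            )


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered probe positions and log2 ratios for one chromosome (arm)."""

    chromosome: str
    positions: np.ndarray
    log2_ratios: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        lr = np.asarray(self.log2_ratios, dtype=float)
        if pos.shape != lr.shape or pos.ndim != 1:
            raise CopyNumberError("positions and log2_ratios must be 1-D and equal length")
        if len(pos) >= 2 and not np.all(np.diff(pos) > 0):
            raise CopyNumberError("probe positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "log2_ratios", lr)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CNThresholds:
    """Copy-number class boundaries on purity-corrected copy number."""

    homozygous_loss: float = 0.6
    single_loss: float = 1.9
    single_gain: float = 2.1
    multi_gain: float = 3.4


CN_CLASSES = (
    "homozygous_loss",
    "single_loss",
    "neutral",
    "single_gain",
    "multi_gain",
)

DELETION_CLASSES = frozenset({"homozygous_loss", "single_loss"})


@dataclass(frozen=True)
class GeneCNCall:
    """Absolute copy number, class and deletion CCF of one gene in one sample."""

    sample_id: str
    gene: str
    tumor_cn: float
    cn_class: str
    deletion_ccf: float
    is_deleted: bool
    is_homdel: bool
    purity: float = float("nan")

    def __post_init__(self) -> None:
        if self.tumor_cn < 0:
            raise CopyNumberError("tumor_cn must be >= 0")
        if not (0.0 <= self.deletion_ccf <= 100.0):
            raise CopyNumberError("deletion_ccf must be in [0, 100]")
        if self.is_homdel and not self.is_deleted:
            raise CopyNumberError("homozygous deletion implies a deletion call")


def _check_purity(purity: float) -> float:
    purity = float(purity)
    if not (0.0 < purity <= 1.0):
        raise InvalidPurityError(f"purity must be in (0, 1], got {purity}")
    return purity


def tumor_cn_to_logratio(tumor_cn, purity: float):
    """Forward mixture model: expected log2 ratio of tumor CN at given purity."""
    purity = _check_purity(purity)
    cn = np.asarray(tumor_cn, dtype=float)
    if np.any(cn < 0):
        raise CopyNumberError("tumor_cn must be >= 0")
    observed = purity * cn + 2.0 * (1.0 - purity)
    with np.errstate(divide="ignore"):  # cn 0 at purity 1 -> -inf, by design
        out = np.log2(observed / 2.0)
    return float(out) if np.isscalar(tumor_cn) else out


def logratio_to_tumor_cn(log2_ratio, purity: float):
    """Purity-corrected tumor copy number from an observed log2 ratio.

    Inverts the mixture model; the result is clamped below at 0 (heavy
    negative log ratios at low purity can otherwise invert to slightly
    negative copy numbers).
    """
    purity = _check_purity(purity)
    lr = np.asarray(log2_ratio, dtype=float)
    n_obs = 2.0 * np.exp2(lr)
    cn = (n_obs - 2.0 * (1.0 - purity)) / purity
    cn = np.maximum(cn, 0.0)
    return float(cn) if np.isscalar(log2_ratio) else cn


def classify_cn(tumor_cn: float, thresholds: CNThresholds = CNThresholds()) -> str:
    """Map a purity-corrected copy number to its CN class.

    Boundary convention: values exactly at the loss/gain thresholds
    (1.9, 2.1) are neutral, exactly at 0.6 is homozygous loss and exactly
    at 3.4 is multi gain.
    """
    cn = float(tumor_cn)
    if cn < 0 or math.isnan(cn):
        raise CopyNumberError(f"tumor_cn must be a non-negative number, got {cn}")
    t = thresholds
    if cn <= t.homozygous_loss:
        return "homozygous_loss"
    if cn < t.single_loss:
        return "single_loss"
    if cn <= t.single_gain:
        return "neutral"
    if cn < t.multi_gain:
        return "single_gain"
    return "multi_gain"


def deletion_ccf(tumor_cn: float) -> float:
    """Cancer cell fraction (percent) of a hemizygous single-copy deletion.

    Under the single-copy loss model the tumor copy number is a mixture of
    deleted cells (CN 1) and intact cells (CN 2), so the carrier fraction is
    ``2 - tumor_cn``, clamped to [0, 1]. Copy numbers below 1 (nested or
    homozygous losses) saturate at 100%.
    """
    cn = float(tumor_cn)
    if cn < 0 or math.isnan(cn):
        raise CopyNumberError(f"tumor_cn must be a non-negative number, got {cn}")
    return float(np.clip(2.0 - cn, 0.0, 1.0) * 100.0)


def gene_level_call(
    segments: Sequence[Segment],
    purity: float | PurityEstimate,
    locus: GenomicInterval = TP53_LOCUS,
    ccf_cutoff: float = DEFAULT_CCF_CUTOFF,
    *,
    sample_id: str = "",
    gene: str = "TP53",
    thresholds: CNThresholds = CNThresholds(),
) -> GeneCNCall:
    """Summarize overlapping segments into a single gene-level CN call.

    The locus log2 ratio is the overlap-length-weighted mean over the
    segment portions intersecting the locus. If any single overlapping
    segment alone corrects to a homozygous loss, the call is homozygous
    loss with that (minimal) copy number — a focal biallelic loss must not
    be averaged away by flanking neutral segments.
    """
    if isinstance(purity, PurityEstimate):
        if not sample_id:
            sample_id = purity.sample_id
        purity = purity.purity
    purity = _check_purity(purity)

    overlapping = [(seg, seg.interval.overlap(locus)) for seg in segments]
    overlapping = [(seg, ov) for seg, ov in overlapping if ov > 0]
    if not overlapping:
        raise MissingCoverageError(
            f"no segment overlaps {locus.chromosome}:{locus.start}-{locus.end}"
        )

    seg_cns = [logratio_to_tumor_cn(seg.log2_ratio, purity) for seg, _ in overlapping]
    homdel_cns = [
        cn for cn in seg_cns if classify_cn(cn, thresholds) == "homozygous_loss"
    ]
    if homdel_cns:
        tumor_cn = min(homdel_cns)
    else:
        total = sum(ov for _, ov in overlapping)
        mean_lr = sum(seg.log2_ratio * ov for seg, ov in overlapping) / total
        tumor_cn = logratio_to_tumor_cn(mean_lr, purity)

    cn_class = classify_cn(tumor_cn, thresholds)
    ccf = deletion_ccf(tumor_cn)
    is_homdel = cn_class == "homozygous_loss"
    is_deleted = cn_class in DELETION_CLASSES and ccf >= ccf_cutoff
    return GeneCNCall(
        sample_id=sample_id,
        gene=gene,
        tumor_cn=tumor_cn,
        cn_class=cn_class,
        deletion_ccf=ccf,
        is_deleted=is_deleted,
        is_homdel=is_homdel,
        purity=purity,
    )


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best 2-way split of ``x`` by two-sample t statistic.

    Returns ``(k, p)``: the split index (left part ``x[:k]``) maximizing
    |t|, and its two-sided p-value. A 1-vs-1 split has no residual degrees
    of freedom; its p-value is set to the indeterminate 0.5 so that it is
    permitted at alpha = 1 but never at stringent thresholds.
    """
    n = len(x)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(1, n)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = cs[k - 1]
    s2 = cs[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    rss = (css[k - 1] - n1 * m1**2) + ((css[-1] - css[k - 1]) - n2 * m2**2)
    rss = np.maximum(rss, 0.0)  # guard fp cancellation
    df = n - 2
    if df < 1:
        # single candidate split 1 vs 1
        return 1, (1.0 if x[0] == x[1] else 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = rss / df
        tstat = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tstat = np.abs(tstat)
    # equal means with zero residual variance -> 0/0: no evidence to split
    tstat = np.where(np.isnan(tstat), 0.0, tstat)
    best = int(np.argmax(tstat))
    t_best = tstat[best]
    p = 0.0 if np.isinf(t_best) else 2.0 * stats.t.sf(t_best, df)
    return best + 1, float(p)


def segment_probes(
    track: ProbeTrack, alpha: float = 1e-7
) -> list[Segment]:
    """Recursive binary segmentation of a probe-level log-ratio track.

    At each step the split maximizing the two-sample t statistic of the
    mean log ratio is taken if its p-value is below ``alpha``; otherwise
    the region is emitted as one segment. The returned segments partition
    the track, each probe belonging to exactly one segment.
    """
    if len(track) < 2:
        raise CopyNumberError("segmentation needs at least 2 probes")

    pos = np.asarray(track.positions)
    lr = np.asarray(track.log2_ratios, dtype=float)

    segments: list[Segment] = []

    def recurse(lo: int, hi: int) -> None:  # half-open probe index range
        n = hi - lo
        if n >= 2:
            k, p = _best_split(lr[lo:hi])
            if p < alpha:
                recurse(lo, lo + k)
                recurse(lo + k, hi)
                return
        segments.append(
            Segment(
                chromosome=track.chromosome,
                start=int(pos[lo]),
                end=int(pos[hi - 1]),
                log2_ratio=float(np.mean(lr[lo:hi])),
                n_probes=n,
            )
        )

    recurse(0, len(track))
    return segments
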