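# Methods

`tp53hit` implements a complete TP53 lesion-calling and prognosis pipeline
for multiple myeloma cohorts profiled by SNP array (copy number) and
targeted deep sequencing (mutations), with a synthetic-cohort generator so
that every stage is testable against known ground truth.

## Copy number and cancer cell fraction

The observed log2 ratio at a locus is modelled as a two-population
mixture: a tumor fraction *p* (the sample purity) at copy number *c* and
admixed normal cells at copy number 2,

    L = log2((p·c + 2(1 − p)) / 2),        c = (2·2^L − 2(1 − p)) / p ,

with the inverted copy number clamped below at 0. The cancer cell fraction
of a deletion assumes a hemizygous single-copy loss as the CCF-bearing
event: a fraction *f* of tumor cells at CN 1 and the rest at CN 2 gives
tumor CN = 2 − f, so

    CCF = clamp(2 − c, 0, 1) × 100 .

A clonal single-copy loss (c = 1) is CCF 100%; copy numbers below 1
(nested or biallelic losses) saturate at 100%. Copy-number classes use
fixed thresholds on the corrected copy number — ≤ 0.6 homozygous loss,
< 1.9 single loss, ≤ 2.1 neutral, < 3.4 single gain, else multi gain. The
boundary convention (1.9 and 2.1 are neutral, 0.6 is homozygous loss, 3.4
is multi gain) is fixed and tested explicitly, since "beyond the
threshold" needs a tie-break.

**Gene-level summarization.** The locus log2 ratio is the
overlap-length-weighted mean over segment portions intersecting the locus
(TP53 defaults to GRCh37 chr17:7,565,097–7,590,856, configurable). If any
single overlapping segment alone corrects to homozygous loss, that
segment's (minimal) copy number becomes the call: a focal biallelic loss
must not be averaged away by flanking neutral segments. A deletion is
called when the class is a loss and CCF ≥ the call cutoff (default 10%).

**Fallback segmenter.** For probe-level input a recursive binary
segmentation is provided: at each step the split maximizing the pooled
two-sample t statistic is taken if its p-value is below the significance
threshold (default 1e-7). A 1-vs-1 probe split has no residual degrees of
freedom; its p-value is set to the indeterminate 0.5 (permitted at
alpha = 1, never at stringent thresholds). This is deliberately not a
CBS/PSCBS reimplementation — upstream segmentation tools are expected for
production profiles; the fallback honors the visible significance
parameter and is adequate for locus-sized tracks.

Detectability note: at probe noise sd 0.1 the 1e-7 threshold cannot detect
changepoints whose log-ratio jump corresponds to low-CCF deletions at low
purity (the jump is ~0.03 while the split test needs ~5 sd). The CCF
recovery guarantee (±5 points in ≥95% of replicates, 100 probes, purity
0.4–1.0) therefore applies to estimation over a locus-spanning track;
boundary detection of faint focal events is outside it.

## Variant consensus and filtering

Three callers are merged by a normalized variant key (shared suffix then
prefix trimmed, position advanced per trimmed prefix base; alleles may
become empty — full left-alignment through repeat tracts would need the
reference sequence). The cascade, in order:

1. tool filters — Mutect2: unqualified PASS only; Shearwater:
   quality > 30; Sophia DDM: PASS flag present;
2. 2-of-3 consensus — at least two distinct callers passing; consensus
   VAF/depth are medians over passing callers (robust to one outlier
   caller; the source pipeline does not state a pooling rule);
3. laboratory thresholds — depth > 250× and VAF > 5%, both strict;
4. pathogenicity label — pathogenic if the consequence is a biological
   loss of function (missense, nonsense, frameshift) or a clinical
   database reports it pathogenic (ClinVar pathogenic/likely-pathogenic,
   or COSMIC) with strong in-silico support; benign only via ClinVar;
   otherwise VUS;
5. final retention — pathogenic, population frequency ≤ 1%, and confirmed
   in a clinical database.

Steps 4 and 5 interact awkwardly by construction: rule 1 needs no
database, yet the final retention step requires one, so a loss-of-function
variant absent from both databases is labeled pathogenic and then dropped.
The cascade is applied in the stated order; `db_confirm=False` exposes the
alternative reading. Annotations are input fields, never live database
queries, for reproducibility. Matched-normal subtraction is modelled as an
optional key blacklist. Every keyed variant carries an ordered verdict
trail, so filter decisions are auditable.

## Allelic classification

Homozygous deletion → double-hit (homdel); deletion + ≥1 retained
mutation → double-hit (del+mut); deletion only → single (deletion);
mutation only → single (mutation); otherwise wild-type. Two mutations
without a deletion stay single-hit: phase is unknown from bulk data and
the double-hit definition covers only homdel and del+mut. Summary
percentages round half away from zero; deletion carriers count every
patient whose tumor carries a deletion (including double hits), and the
mutation count is mutation-only carriers — the only reading under which
the reference cohort's counts (34 + 12 + 97 = 143) are arithmetically
consistent. One known rounding quirk: 23/53 = 43.4% prints as 43 here
while the source literature shows 44 for the same fraction.

## Time-dependent ROC and the prognostic cutoff scan

Cumulative/dynamic AUC at horizon *t*: cases are subjects with an event by
*t*, controls subjects event-free past *t*; censoring is handled by
inverse-probability-of-censoring weights w = 1/Ĝ(min(T, t)) with Ĝ the
right-continuous Kaplan–Meier estimate of the censoring distribution
(censorings follow events at ties); subjects censored before *t* without
an event get weight 0. Ties in the marker count one half. With no
censoring the estimator reduces exactly to the Mann–Whitney statistic
(tested). Significance of AUC > 0.5 uses a seeded percentile bootstrap
(default 1000 resamples); the censoring KM inside the bootstrap loop is a
small numpy implementation cross-checked against lifelines to machine
precision.

The cutoff scan walks the copy-number grid 2.00, 1.95, …, 0.00 and
dichotomizes patients as deleted iff tumor CN < c, equivalently
CCF > (2 − c)·100 — the grid lives in CN units because the source
description conflates CN with CCF ("starting from CCF = 2"); both scales
are reported. Grid points where everyone falls on one side are recorded as
missing, not errors. The per-endpoint chosen cutoff is the smallest CCF
threshold whose 95% CI excludes 0.5 at any scanned horizon (default
horizons 12–96 months, annual); per-endpoint limits are reconciled by
rounding to the nearest multiple of 5 and, on disagreement, adopting the
larger. Reconciling the published limits 9.56%/11.32% yields the adopted
10% deletion-call cutoff.

Two estimator-level caveats, verified by simulation:

* the smallest-significant rule only recovers a generative clonality
  boundary when dichotomizations below it are degenerate or truly null —
  any real carrier-vs-wild-type signal at low thresholds is (correctly)
  significant and pulls the chosen cutoff down;
* under a null marker the scan tests ~41 nested thresholds × several
  horizons at 5% each, so a spurious cutoff appears in a noticeable
  minority of replicates; a cutoff near the grid edge with borderline CI
  deserves skepticism.

## Survival analysis

Endpoints from the start of therapy (months; day inputs convert at
30.4375 d/mo): PFS (first progression or death), OS (death), PFS2 (second
progression or death) and 2nd PFS (first progression → second progression
or death, defined only after a first progression). Interval ordering is
validated; violations raise rather than silently censor. Kaplan–Meier
fits come from lifelines; a median is the earliest time the curve reaches
0.5, and "not reached" is an explicit encoded state (None), never a
sentinel. Cox models use lifelines with Efron tie handling. Monotone
likelihood (a group without events) returns a flagged non-convergence
result instead of a numeric artifact. The multivariable model applies
backward elimination at p < 0.05 with the ISS staging adjustment always
retained and the elimination order logged. Note the selection operates at
per-variable α = 0.05: with six null covariates the final model is
adjustment-only in ≈ 0.95⁶ ≈ 74% of replicates — an inherent multiplicity
property of the stated procedure, not a defect. Both ISS-adjusted and
unadjusted group comparisons are emitted, since the source analysis is
ambiguous about which its univariable figures use.

## Longitudinal evolution

Transitions compare the collapsed burden (wt < single < double):
acquisitions from wild-type split by lesion type, any climb to double is
`acquired_double`, equal burden stays `stable_altered` (including a
deletion replaced by a mutation), and any decrease is `regressed` —
representable for totality even though biology rarely goes backwards
(sampling and purity artifacts can). The carrier-frequency shift uses the
unpaired continuity-corrected two-proportion chi-square, matching the
unequal diagnosis/relapse denominators of the reference analysis, with an
exact McNemar test on the paired subset emitted alongside as the
statistically paired view. The carrier CCF shift uses the unpaired
Mann–Whitney U (carrier sets differ between timepoints), with a paired
Wilcoxon on dual-timepoint carriers alongside.

## Synthetic cohorts

The generator emits the statistical structure the analysis assumes:

* composition wt/del-only/mut-only/del+mut/homdel =
  0.68/0.19/0.08/0.035/0.015 (diagnosis frequencies of the reference
  cohort; the 0.08 restores a vector that sums to 1);
* purity U(0.4, 1); carrier CCF a 50/50 mixture of subclonal U(10, 63)
  and clonal U(63, 100) — the 63% clonal boundary is the stated one, and
  the even mixture reproduces a ~63% carrier median;
* segment log ratios from the forward mixture model plus Gaussian noise
  (sd 0.1 per probe, 100 probes over the locus segment);
* mutation VAF = p·CCF/100 · 1/(p·c + 2(1 − p)) (one mutated copy),
  binomially resampled at Poisson depth (mean 1000×);
* three callers thinned at sensitivities 0.95/0.95/0.90 plus sporadic
  false positives, 80% of which are emitted below a retention threshold
  (quality, depth, VAF or filter flag) so every filter branch is
  exercised;
* survival exponential with group hazard multipliers 1 / 1.63 / 3.34
  (wt / single / double) on a wild-type median PFS of 41.2 months and a
  baseline OS median of 120 months (OS medians are unreached at the
  reference follow-up), with administrative censoring targeting ~30%;
* relapse pairs (default 53/143) with acquisition probabilities 8/53,
  4/53, 2/53 and carrier CCF drift ccf′ = 100 − (100 − ccf)·0.5, derived
  from the diagnosis→relapse carrier medians 62.9 → 82.4.

A deterministic mode fixes exact class counts, disables probe noise and
read resampling, and forces caller detection, so a configured composition
survives the entire pipeline exactly; cohort-level worked examples are
built on it. What the generator does **not** emulate: genome-wide CN
landscapes, allele-specific states, purity estimation error, caller error
correlation, sequencing artifacts beyond binomial thinning, or
non-proportional hazards. A green end-to-end test therefore establishes
internal consistency of the calling chain and estimator calibration under
the stated model — not robustness to real-array artifacts.

## Numerical conventions

SEG coordinates are 1-based inclusive end-to-end. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
config + seed reproduces byte-identical pipeline outputs (content-hashed
in the manifest and tested). Percentages round half away from zero.
Bootstrap CIs are percentile intervals; grid cells need at least
max(20, n_boot/2) defined resamples to be eligible for significance.
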