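# tp53hit

TP53 lesion calling and prognosis for multiple myeloma cohorts.

Conventional FISH underestimates TP53 impairment: focal deletions,
sub-clonal deletions and point mutations all escape it, yet biallelic
("double-hit") TP53 inactivation marks the worst-prognosis patients.
`tp53hit` is a pipeline for cohorts profiled by SNP array and targeted
deep sequencing that

* converts segmented log2 ratios plus tumor purity into an absolute TP53
  copy number and a deletion **cancer cell fraction**
  (CCF = clamp(2 − c, 0, 1)·100 under a hemizygous-loss mixture model,
  with c the purity-corrected copy number);
* merges somatic calls from three callers (Mutect2, Sophia DDM,
  Shearwater) under a 2-of-3 consensus, tool filters, depth > 250× /
  VAF > 5% laboratory thresholds, and a pathogenicity-labeling rule with
  population-frequency and clinical-database confirmation;
* classifies each patient as wild-type, single-hit (deletion or
  mutation), or double-hit (homozygous deletion, or deletion + mutation);
* derives the prognostic deletion-call CCF cutoff by scanning
  dichotomization thresholds with an IPCW cumulative/dynamic
  time-dependent ROC under right censoring (the published limits
  9.56%/11.32% reconcile to the adopted 10%);
* quantifies survival impact (PFS, OS, PFS2, 2nd PFS; Kaplan–Meier
  medians and Cox hazard ratios with backward-eliminated multivariable
  models, ISS-adjusted);
* tracks evolution between diagnosis and relapse (acquisition classes,
  carrier-frequency and CCF shifts);
* generates synthetic cohorts with known ground truth — purity-diluted
  copy-number signals, imperfect three-caller outputs, proportional-
  hazards survival — so the whole chain is testable without patient data.

See `docs/methods.md` for the models, conventions and caveats.

## Worked example

Run the full pipeline on a simulated 143-patient cohort:

```sh
tp53hit run --n 143 --seed 17 --boot 200 --out results/demo
```

which prints (numbers are from this exact seed):

```
TP53 allelic status pipeline report
===================================

Diagnosis cohort: n=143
  deletion carriers: 27 (19%)
  mutation-only:     7 (5%)
  double-hit:        3 (2%)
  wild-type:         109

Adopted deletion-call CCF cutoff: 5.0
  per endpoint: {'PFS': 5.0, 'OS': 5.0}

Survival (PFS, double vs wt):
  HR 2.30 (95% CI 0.72-7.34, p=0.159)

Relapse pairs: n=53, total acquired 15 (del 10, mut 4, double 1)
Carrier frequency: 24% -> 51% (p=0.000511)
```

Reading it: of 143 simulated patients, 27 carry a TP53 deletion at CCF ≥
the call cutoff, 7 carry only a pathogenic mutation and 3 carry both hits
(or a homozygous deletion). The ROC scan adopts 5% as the smallest
CCF dichotomization whose AUC confidence interval excludes 0.5 — in this
cohort even faint sub-clonal deletions carry hazard, so the scan
bottoms out one grid step above zero. The double-hit hazard ratio
estimate (2.30) is noisy at 3 carriers, as the wide CI shows; the
generative value is 3.34. At relapse, 15 of 53 re-assessed patients
acquired a new lesion and the carrier frequency roughly doubled.

Individual stages are exposed both as library functions
(`tp53hit.gene_level_call`, `tp53hit.filter_variants`,
`tp53hit.threshold_scan`, ...) and as CLI subcommands operating on files
(`tp53hit callcn`, `variants`, `classify`, `rocscan`, `survival`,
`longitudinal`, `simulate`).

```python
from tp53hit import Segment, gene_level_call

call = gene_level_call(
    [Segment("chr17", 7_500_000, 7_650_000, log2_ratio=-0.211, n_probes=80)],
    purity=0.6,
)
print(call.tumor_cn, call.deletion_ccf, call.is_deleted)
# 1.5464606246675905 45.35393753324095 True
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 17 --out results/acceptance.json
```

regenerates the deterministic reference cohorts (the 143-patient
composition and the 53-pair relapse re-assessment), pushes their emitted
observables through the complete calling pipeline, reconciles the printed
per-endpoint CCF limits into the adopted cutoff, runs a stochastic
end-to-end pipeline at the study scale, and writes the recomputed
cohort-composition, acquisition and cutoff quantities as JSON.
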