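# Methods

This note records the modelling assumptions, default parameters and numerical
choices behind `qbgs`, and what the synthetic-data tests do and do not
establish.

## Assay model

The pipeline models top-strand (sense) bisulfite PCR of a single promoter
amplicon. Bisulfite conversion is idealised as deterministic: under the
`fully_unmethylated` assumption every cytosine reads T; under
`fully_methylated` a CpG cytosine is protected and reads C. Real conversion
failures are handled downstream as a per-molecule QC quantity, not in the
conversion model itself.

**Primer conventions.** A primer pair is interpreted with the forward primer
matching the converted sense strand and the reverse primer matching the
reverse complement of a converted-sense segment — the usual listing
convention, and the one the methylation-specific PCR pairs follow. Some
published amplicon primer listings instead print the reverse primer's
*binding site* (top-strand orientation). The two conventions are mechanically
distinguishable: a converted top strand cannot contain a non-CpG cytosine, so
a "reverse primer" whose reverse complement contains one (e.g. the nested
sequencing pair shipped in `qbgs.mgmt`) can only be a top-strand listing.
`predict_amplicon` therefore tries the reverse-complement convention first,
falls back to the direct orientation, and raises on ambiguity. Matching is
exact by default (`max_mismatch=0`); no tolerance is assumed because none is
published.

**Coordinates.** All public types use 1-based inclusive positions; slicing is
0-based internally. CpG sites are labelled `CpG1..CpGn` on the sequencing
amplicon in 5'→3' order and the labels are global: excluding a site never
renumbers the rest, and the shorter test amplicon's sites are addressed by
the same labels (CpG51–CpG74), matched by reference coordinate.

**Synthetic stand-in reference.** The natural promoter sequence cannot be
redistributed, so `synthetic_mgmt_reference()` deterministically constructs a
sequence in which the published primer binding sites occur uniquely at the
published geometry: 93- and 81-bp MSP amplicons, a 662-bp sequencing amplicon
containing exactly 78 CpG sites with a CpG-sparse middle segment
(CpG28–CpG50), and a 216-bp nested amplicon whose 24 sites are the classifier
window. Primer-derived bases are real assay sequence; everything else is
filler over {A, T, G} plus placed CpGs. Tests that assert the published
fragment/site numbers therefore validate the matching and enumeration
machinery at the true geometry, not the accession sequence itself. The one
CpG site excluded from analysis in the emulated assay is not identified in
print, so the exclusion is user-supplied configuration (default: none).

## Methylation quantification

Clones and reads are aligned to the *original* reference with a global
affine-gap aligner (Biopython's `PairwiseAligner`) under a conversion-aware
substitution matrix: reference C versus query T scores as a match, so fully
converted and methylated molecules align equally well; both query
orientations are tried and the better-scoring one kept. Alignment identity
(match-class columns over all columns, gaps counting against) below 0.8
rejects the molecule.

At each CpG column a clone/read C is a methylated observation, T
unmethylated, and anything else (gap, A, G, N) uninformative — artifact bases
are excluded from both numerator and denominator because the methylation
proportion is defined over methylated-vs-unmethylated observations only.
Per-clone conversion efficiency is T/(C+T) over the aligned non-CpG reference
cytosines; a molecule with no informative column defaults to 1.0 (it cannot
fail a QC it carries no evidence about).

Defaults, all configurable and none published for the emulated assay:
minimum conversion efficiency 0.95; read-mode minimum depth 100 (conservative
against the emulated study's mean depth of ~8×10⁴); minimum base quality 20.
Cells failing depth are missing (NaN), never silently zero, and denominators
are recorded per cell.

## Survival machinery

Univariate Cox models are fitted by Newton iteration on the Breslow partial
likelihood (months-resolution survival ties heavily; Breslow is the simplest
documented convention), vectorised across covariate columns: at most 50
steps, convergence at |Δ log-likelihood| < 1e-9, step-halving on overshoot,
coefficients capped at |β| = 20 with a monotone-likelihood flag. A constant
covariate or an event-free table yields an unconverged fit with p = 1; the
information at β = 0 is compared against a rounding-noise floor so that
numerically-zero information is treated as degenerate.

Per-site screening p-values are the **score test at β = 0**, which for a
grouped covariate *is* the classical log-rank statistic — the only reading
under which per-site "log-rank p values" from a continuous-covariate Cox
model are coherent. Wald p-values are also exposed. Screening applies no
multiple-testing correction, faithfully to the emulated design; interpret
selected-site counts accordingly.

The log-rank test uses the hypergeometric variance with the standard
(n−d)/(n−1) tie correction; on untied data it agrees with the Cox score test
on a binary covariate to numerical precision (an acceptance test asserts
1e-8 over random tables, and lifelines agrees to ~1e-15). Kaplan-Meier
curves follow the product-limit convention with censored-at-event-time
samples at risk through the event time.

## The M-score classifier

The score is linear, `M = Σ A_i X_i`, with `A_i` the full-training-cohort
univariate Cox coefficient of PFS at site *i* (an unconverged site
contributes 0, with a warning). Threshold selection scans the observed
scores as candidates, splits at `score ≤ τ` versus `> τ` (equality on the ≤
side, consistently everywhere), skips candidates emptying a group (minimum
group size 1 by default, configurable) and minimises the log-rank p;
candidates tied exactly on p resolve to their median (mean of the two middle
values at even counts). Because the published sign convention of the weights
cannot be reconstructed, which side of τ is "good prognosis" is *learned*:
the side with the longer Kaplan-Meier median survival in the training split,
restricted-mean survival as the tie-break.

LOOCV refits weights, threshold and orientation on every fold's n−1 samples;
the held-out sample is scored with fold parameters only (a fold perturbation
test verifies the held-out survival record is never read). The deployable
model combines full-cohort weights with the arithmetic mean of the
non-degenerate fold thresholds, and the majority fold orientation. The same
PFS-derived weights are reused when evaluating OS splits, as in the emulated
design. Missing subset proportions are mean-imputed from the training
cohort when at most 25% of window sites are missing; beyond that the sample
is unscorable and reported as such.

**Calibration caveat.** Testing the pooled LOOCV-predicted classes by
log-rank is anti-conservative: fold models share n−2 samples, so the
predicted classes largely reproduce the full-data optimised split. On null
cohorts (no methylation–survival link, n = 50) the acceptance suite measures
a ~20% rejection rate at nominal 5% — the procedure's honest optimism, not an
implementation artifact (the underlying log-rank test is calibrated to
within Monte-Carlo error on fixed splits). Cross-validated p-values from
threshold-optimised survival splits should be read as descriptive, not as
calibrated type-I-error statements; an outer permutation test would be the
remedy but is outside the emulated procedure.

## Clustering

Ward clustering runs on raw (unstandardised) proportions, as in the emulated
analysis. The default dialect is Ward.D2 (scipy's `ward` on observations);
`dialect="D"` emulates the classic Ward.D recurrence by feeding the
Lance-Williams update the unsquared distances, since the emulated analysis
does not state its dialect. Clusters are relabelled 1..k by descending mean
methylation so "cluster 1 = most methylated" holds regardless of dendrogram
order; the flat cut is at k = 4 by default. Pairwise cluster survival uses
uncorrected two-group log-rank tests.

## Synthetic cohort generator

The generator emulates the statistical structure of a quantitative
bisulfite-sequencing survival study, with defaults stating that world:

| parameter | default | rationale |
|---|---|---|
| samples | 53 (training) / 32 (test) | emulated cohort sizes |
| CpG sites | 77 | analyzed sites after the one-site exclusion |
| archetypes | 4 (strong 0.85, moderate 0.55, slight 0.25, unmethylated 0.04) | the four observed methylation-level clusters |
| middle segment | sites 28–50 scaled ×0.4 | depressed methylation upstream of the TSS |
| clones/sample | uniform 25–81 | published molecule counts (median ≈ 51) |
| Beta concentration | 30 | sample-level biological spread around archetypes |
| prognostic sites | {54, 56, 59–65, 68} | progression-associated sites inside the classifier window |
| baseline hazards | PFS 0.12/mo, OS 0.06/mo | median PFS ≈ 6, OS ≈ 12 months at η = 0 |
| censoring | uniform on (0, 96] months | accrual-length follow-up window |
| conversion failure / seq. error | 0.01 / 0.005 | typical bisulfite + sequencer error scales |
| read depth | 1000 | desk-scale stand-in for very deep amplicon sequencing |

Archetype profiles are piecewise-constant idealisations, not digitised from
any figure. Survival attaches to the *truth-level* propensities, not the
clone-realised fractions, so biological effect and measurement noise remain
separable in tests. Exponential baseline hazards and uniform censoring were
chosen for closed-form checkability (the censoring fraction and the
median-halving property are asserted against closed forms).

Named presets state three worlds: `null_config` (β = 0),
`strong_signal_config` (β = −ln 4 per prognostic site — hazard ratio 4
across a site's full proportion range, protective), and
`graded_hazard_config` (summed effect ln 27 across the archetype range,
i.e. hazard ≈ 3× per methylation level, with the baseline raised so every
stratum accrues events inside follow-up — an ordering claim over clusters is
information-starved if the most-protected stratum never progresses).

**What a green test does not establish.** Archetype correlation makes *all*
sites co-vary, so site screening on strong-signal cohorts selects far more
than the causal sites (as global methylation studies do in reality);
recovery is asserted for the causal set, not sparsity. The generator has no
tumour-purity gradient, no realistic sequencer error spectra, no paired-read
structure and no non-proportional hazards; conclusions about those regimes
are out of scope.

## Known limitations

* The published per-site p-values, the 20 selected sites, τ = 2.2 and the
  patient-level Figure results are not reproducible anywhere: the cohort was
  never deposited. All statistical validation is against synthetic truth and
  independent oracles.
* The stand-in reference validates machinery at the published geometry, not
  the accession sequence.
* Only top-strand, single-amplicon assays are modelled; no genome-scale
  bisulfite alignment, duplicate marking or multi-amplicon demultiplexing.
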