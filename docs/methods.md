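# Methods

## The monitoring model

The package treats a patient's plasma as a mixture of normal cell-free
DNA (cfDNA) and tumor-derived fragments (ctDNA). Each tracked somatic
mutation `m` has a cellular prevalence ("clonal fraction") `c_m ∈ (0,1]`
in the tumor; under a heterozygous-diploid assumption, when the tumor
contributes fraction `f(t)` of the plasma DNA at time `t`, the expected
variant allele fraction (VAF) at that site is

    E[VAF_m(t)] = f(t) · c_m / 2 + ε

where ε is the per-base background error rate of library preparation
and sequencing. Observed alt-read counts are modelled as
`Binomial(depth, E[VAF])`. The estimator reports raw mean VAF (and its
product with the cfDNA concentration); it deliberately does not invert
the `/2` diploid factor, because the clinical quantity of interest is
the relative trajectory, not an absolute tumor fraction. VAF is defined
as alt_count/depth (mpileup-style counting); at panel depths the
difference from alt/(alt+ref) is negligible, but the convention is fixed
so results are reproducible.

## Marker panel and burden estimate

The tracked panel is the union of (a) nonsynonymous somatic tissue
variants — tumor calls minus matched-germline (PBL) calls by exact
(chrom, pos, ref, alt) key — and (b) every variant independently
detected in any plasma sample (*de novo* plasma mutations). The panel is
built once per patient and applied retrospectively to all time points.
A variant seen in plasma but present in tissue only below the somatic
caller's threshold is treated as de novo.

Detection of a marker in one plasma sample is an exact binomial test:
detected iff `P[Bin(depth, ε) ≥ alt] ≤ α` and `alt ≥ min_alt_reads`.
Defaults: ε = 10⁻³, α = 0.01, min_alt_reads = 3. The min-alt floor
guards the low-depth regime where two error reads can already be
nominally significant. These are decisions, not reconstructions of any
particular caller's internals; all three are exposed as function
arguments and CLI flags.

Per time point the burden is the arithmetic mean VAF over the panel with
VAF = 0 imputed for markers that are absent from the count table or not
detected (`union_imputed`, the default: a fixed denominator makes points
comparable over time). The alternative `detected_only` mode averages
only detected markers; it estimates the typical VAF of what is visible
and is biased high when few markers clear background, which is why both
modes exist and are reported separately. In `detected_only` mode a time
point with no detected marker is assigned burden 0 rather than an error
when a whole series is built: nothing visible is the ground state of a
cured patient, and a series must remain defined there. Absolute ctDNA
content is `mean VAF × cfDNA concentration` (ng per mL plasma), so it
can never exceed the cfDNA concentration.

## Relapse flagging

For each post-operative point after the first, the baseline is the
minimum post-operative load among strictly earlier points — the running
nadir, which is robust to transient fluctuation during adjuvant
chemotherapy. A point is flagged iff

    load ≥ fold_threshold × nadir   AND   load ≥ min_abs_level

with defaults fold_threshold = 5 and min_abs_level = 0.02 ng/mL. A zero
nadir makes the fold infinite; the absolute arm then decides alone,
avoiding division-by-zero semantics. The absolute floor exists because
with a zero or near-zero nadir any error-level signal would otherwise
produce an unbounded fold.

A *patient-level* molecular relapse is called only when two consecutive
draws flag (`MonitoringReport.relapse_confirmed`). The rationale is
structural: a true recurrence grows roughly exponentially, so once it
clears the flagging rule it stays above it at every later draw, whereas
an isolated error-driven detection — a 3-read fluctuation at the shallow
end of the depth range, occasionally enough to lift one time point's
imputed-mean load past the absolute floor — does not repeat. Requiring
confirmation on the next draw is the standard clinical convention for
serial tumor-marker testing and is the call the operating
characteristics below are quoted on. Per-point flags are retained
unchanged in the output so single-draw behaviour remains inspectable.

Serum biomarkers are compared per time point with standard clinical
reference limits, CEA > 5 μg/L and CA 19-9 > 37 kU/L (both
configurable); missing measurements count as negative.

## Substitution spectrum

Single-base substitutions are collapsed into the six strand-symmetric
categories conventional in cancer genomics (pyrimidine-reference
notation): a G>T equals a C>A on the opposite strand. No trinucleotide
context is modelled — the monitoring analysis only uses the spectrum as
a catalog summary, not for signature decomposition.

## The synthetic cohort generator

`SimulationConfig` defaults encode the study conditions the pipeline is
meant for (a small surgical CRC cohort on a ~545-gene capture panel):

| parameter | default | meaning |
| --- | --- | --- |
| n_mutations_range | (6, 45) | nonsynonymous tissue mutations per patient |
| indel_fraction | 0.11 | indel share of the catalog (rest SNVs) |
| spectrum_weights | 0.47 C>A/G>T, 0.30 C>T/G>A, 0.08 C>G/G>C, 0.07 T>C/A>G, 0.05 T>A/A>T, 0.03 T>G/A>C | collapsed substitution spectrum |
| preop_tumor_fraction_range | (0.004, 0.02) | plateau f before surgery |
| postop_residual_fraction | 5·10⁻⁴ | residual f after R0 resection |
| relapse_growth_fold_per_month | 2.0 | exponential regrowth rate |
| relapse_onset_range_days | (180, 540) | relapse start, uniform |
| plasma_depth_range | (308, 1436) | per-site plasma depth, uniform |
| error_rate | 10⁻³ | per-base background error |
| tissue_plasma_overlap | (0.5, 0.9) | shed fraction of tissue markers |
| de_novo_plasma_rate | 1.0 | Poisson mean of plasma-only mutations |
| cfdna_conc_median / sigma | 25 ng/mL, 0.5 | log-normal cfDNA concentration |
| purity_range | (0.3, 0.7) | tissue tumor purity |
| biomarker_sensitivity | 0.3 | P(a serum marker responds at all) |
| sampling_times | −7, 30, then every 90 d to 750 d | collection schedule |

Only the dominant spectrum weight is anchored to the conditions above;
the remaining five weights were chosen once as a plausible
CRC-like split (transitions second) and are fully configurable. The
relapse growth rate is likewise a one-time choice: monthly doubling
reaches order-of-ten-fold increases within a few follow-up intervals,
the scale at which monitoring is clinically interesting, and the
trajectory is capped at f = 1.

The latent trajectory is piecewise: `f(t) = f_pre` for `t < 0`,
`f(t) = f_res` for `t ≥ 0`, and for relapsing patients
`f(t) = min(1, f_res · g^((t−t_rel)/30))` from onset `t_rel`. Relapse
status is assigned deterministically by stride so that the configured
fraction of patients relapse; every stochastic per-patient draw comes
from an independent RNG substream (`SeedSequence(seed, spawn_key=(i,))`),
so enlarging a cohort never changes earlier patients, and cohort output
is byte-identical across re-runs at a fixed seed.

Each plasma sample draws binomial alt counts for every tracked marker
(shed markers at `f·c/2 + ε`, unshed and 50 decoy sites at ε alone);
tissue and PBL calls are written as VCFs with germline variants present
in both, so germline subtraction is exercised end to end. Serum
biomarkers respond to tumor fraction only in Bernoulli-selected
"responder" patients, which is how the generator reproduces relapse with
normal CEA/CA 19-9.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: trinucleotide- or fragment-context error
structure (real error is not flat across sites), clonal evolution
between resection and relapse (clonal fractions are fixed), depth
correlation across sites within a library, sample-to-sample
contamination, and CHIP-like germline/blood artifacts beyond clean PBL
subtraction.

## Numerical choices and degenerate inputs

* Binomial tails come from `scipy.stats.binom.sf(alt−1, depth, ε)`; the
  test suite cross-checks them against an independent log-space direct
  summation to 10⁻⁹ relative tolerance.
* Zero-depth observations are rejected at read time (counted in the
  reader's envelope, never silently kept); alt+ref > depth is an error.
* An empty marker panel has no defined mean VAF (error); an all-zero
  imputed column yields burden 0.
* Fewer than two post-operative points leave fold fields undefined and
  nothing flagged.
* Result tables round-trip through their reader at 6 significant
  digits; missing biomarker values are empty fields, never 0.
* Matrix columns are strictly ordered by collection time; duplicate
  plasma collection times within a patient are rejected at the sample
  sheet.

## Problem sizes used by the acceptance script

The script runs a six-patient cohort for study-scale summaries (the
scale such monitoring studies actually have), 10,000 error-only sites
for the type-I error estimate, and a 200-patient half-relapsing cohort
for the recovery regression (~1,000 plasma samples with ≥1 detected
marker) and the relapse-call operating characteristics. All randomness
derives from the `--seed` argument.

## Known limitations

* The binomial error model ignores overdispersion; real hotspot error
  sites would need site-specific error rates or duplex/UMI suppression.
* Marker panels admit any plasma-detected variant, so at α = 0.01 a
  long follow-up accumulates a few error-derived panel members; the
  absolute-floor and confirmation rules absorb this downstream, but a
  production assay would add recurrence-based blacklisting.
* Tumor fraction is reported only through mean VAF; no copy-number or
  purity correction is attempted.
* The de novo/tissue provenance of a marker is decided by the somatic
  caller's threshold on tissue, not by re-genotyping tissue at plasma
  sites.
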