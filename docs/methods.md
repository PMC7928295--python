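# Methods

## Segregation model and classifier

A Robertsonian trivalent can resolve as alternate, adjacent or 3:0,
yielding eight gamete karyotypes (2 alternate, 4 adjacent, 2 of 3:0).
After fertilisation by a euploid gamete, an embryo's constitutional
whole-chromosome dosage deviations (dA, dB) on the carrier's two
translocation chromosomes determine the call deterministically:
(0,0) → alternate; exactly one deviation of ±1 → adjacent, with the
specific product identified; (+1,+1) or (−1,−1) → 3:0; every other
non-zero pattern (opposite signs, |d| ≥ 2) is binned with 3:0 into a
"3:0/others" bucket so the three reportable categories stay exhaustive.

Assumptions and consequences:

* **Copy number cannot separate the two alternate products** (normal vs
  balanced carrier); alternate calls therefore carry no product object.
  Distinguishing them requires SNP-haplotype phasing, which is out of
  scope.
* **Mosaic- or segmental-only signal on a translocation chromosome gives
  no meiotic call.** A mitotic origin cannot be excluded for such
  patterns, so the embryo is flagged `unclassifiable` and removed from
  segregation denominators (it still participates in the ICE analysis).
  This is a conservative choice; the classifier surfaces the reason
  string and the tables report the excluded count.
* **Non-translocation abnormalities never affect the segregation call** —
  the trivalent and the ICE dimensions are analysed independently.
* Parental origin and meiosis I vs II are not inferred.

## ICE categorisation

Per embryo, considering only non-excluded chromosomes (a carrier's own
translocation pair is excluded; controls exclude nothing):

1. any constitutional whole-chromosome gain/loss **or segmental
   imbalance** → `aneuploid`;
2. else any mosaic call with aneuploid-cell fraction **strictly greater**
   than the threshold (default 0.20) → `mosaic`;
3. else `normal`; sub-threshold mosaic calls are treated as noise.

Precedence aneuploid > mosaic > normal makes the three rows a partition,
matching published three-row tables that sum to cohort totals. Folding
segmental imbalances into `aneuploid` is a design choice (the source
tables have no separate segmental row); it is recorded in the run log.
Raising the threshold can only shrink the mosaic class (monotonicity,
property-tested).

The per-chromosome spectrum counts contributing chromosomes over 1–22,
X, Y with the number of embryos as denominator, separately for aneuploid
and supra-threshold mosaic calls.

## Contingency statistics

* **Odds ratio**: cross-product (a·d)/(b·c). Any empty cell triggers the
  Haldane–Anscombe correction (+0.5 to all four cells), flagged in the
  result. The 95% CI is the Woolf logit interval
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); the source tables print no CIs,
  so the interval is labelled as an extension in reports.
* **Test selection** (Cochran's rule): Fisher's exact test when any
  expected count < 5 or the grand total < 40, else uncorrected Pearson
  χ². Yates' correction is off by default (it does not change the OR and
  the uncorrected statistic reproduces the published significance calls)
  but available via `yates=True` / `--yates`.
* **Fisher two-sided p**: point-probability method (sum of all
  fixed-margin tables whose hypergeometric probability does not exceed
  the observed table's) — the dominant convention in general statistical
  software. The test suite checks it exhaustively against a brute-force
  enumeration oracle for every 2×2 table with total ≤ 60.
* All p-values are two-sided; no multiple-testing correction is applied,
  matching the source analysis.

Known discrepancy: the published overall male-vs-female segregation ORs
(2.95 and 0.33) and the overall ICE "normal" OR (0.76) are not the
cross-product odds ratios of their own printed counts (which give ≈2.75,
≈0.36 and 0.7547 → 0.75); the estimator behind those printed values is
not stated. This package always reports the standard cross-product OR.

## Synthetic-cohort generator

The generator emulates the study conditions: 977 carrier and 785 control
blastocysts; male-carrier embryo share 473/977; carrier age band < 35
with probability 836/977 (controls 621/785); translocation mix rob(13;14)
55.3%, rob(14;21) 10.6%, the remaining eight D;G fusions sharing the rest
equally. Ages are drawn uniformly within band (25–34 / 35–42 completed
years); embryos are grouped into patients of ~4.5 embryos on average, and
covariates are drawn at the patient level.

Per carrier embryo: a segregation mode is drawn from the per-gender
probabilities — alternate/adjacent/3:0 = 0.8245/0.1712/0.0042 (male) and
0.6310/0.3611/0.0079 (female), the observed per-gender category
proportions, normalised; per-(gender, translocation) overrides are
supported — then a product uniformly within the mode (no published
within-mode split exists at the blastocyst stage, so uniform is an
explicit assumption). Background whole-chromosome errors hit each
eligible autosome independently with rate λ, gain or loss equiprobable;
λ solves 1−(1−λ)^k = target aneuploidy proportion with k = 20 eligible
autosomes for carriers (24.77%) and k = 22 for controls (20.25%).
Background errors are never placed on a carrier's translocation
chromosomes, so segregation ground truth stays well defined — the real
assay cannot separate such events either, which is a stated limitation of
the design, not a convenience. One mosaic event per embryo occurs with a
rate chosen so the *post-precedence* mosaic proportion hits its target
(6.55% carriers, 5.35% controls): rate = target / (1 − aneuploidy
proportion). Mosaic fractions are uniform on (0.2, 0.8), rounded to two
decimals by the karyotype dialect, so essentially all simulated mosaics
exceed the 20% call threshold; both bounds are configurable.
Sex-chromosome background errors are off by default and can be enabled
for the control arm only (`include_sex_chromosomes_control`), mirroring
the inclusion of X/Y in control abnormality spectra.

Every record carries truth labels derived from the generating events and
asserted against the classifiers at generation time. All randomness flows
from one `numpy` Generator seeded by `SimulationConfig.seed`; the draw
order (carrier patients → carrier embryos → control patients → control
embryos) is fixed, so identical seeds give byte-identical cohort files.

What the generator does **not** emulate: recombination within the
trivalent, meiotic drive, embryo attrition between cleavage and
blastocyst, maternal-age effects on the background rate, multi-chromosome
mosaicism, and segmental abnormalities (it never emits `seg±N` calls,
although the parser and both classifiers handle them). Passing recovery
tests therefore shows the pipeline is self-consistent under binomial
sampling at the study's sample sizes — not that real cohorts satisfy the
independence assumptions.

## Numerical and interface choices

* Karyotype dialect: mosaic fractions print with two decimals in
  parentheses (locale-safe), and the writer emits a canonical ordering
  (chromosome order; constitutional before segmental before mosaic), so
  parse∘format is the identity on the model.
* Percentages print to 2 decimals in tables and 1 decimal in prose
  summaries; ORs to 2 decimals. Empty strata produce NaN percentages
  rather than a division error.
* The age boundary is 35 completed years, bands "<35" and ">=35",
  applied to the carrier's age (the control couple's female age for the
  control arm).
* In stratified ICE comparisons the control arm is filtered only on
  covariates controls possess (age band); carrier-only covariates
  (gender, translocation type) reuse the full control column, mirroring
  the published table layout.
* Problem sizes in the test suite: simulation-based checks use cohorts of
  0.3–1.8 k embryos and 400–2,000 replicate null tables, sizes at which
  the 3σ binomial envelopes being tested are a few percentage points
  wide.

## Limitations

* Normal and balanced-carrier embryos are indistinguishable here; both
  appear as `46,XX`/`46,XY`.
* Segmental calls carry no breakpoints — a single boolean flag.
* The test-selection rule and the exact-p convention are deterministic
  but not guaranteed to match any particular commercial package's
  defaults, so published p-values are reproduced qualitatively, not
  digit-for-digit; odds ratios recomputable from counts are reproduced
  exactly.
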