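# Methods

`riskstrat` evaluates risk-stratified breast-cancer screening — offering the
standard triennial mammography programme only to women above a chosen
percentile of polygenic risk, and no screening below it — against universal
age-based screening and no screening, for a cohort of 364 500 women (the
2009 population of 50-year-old women in England and Wales) followed from age
50 to 85.

## Risk distribution

Relative risk (RR) of breast cancer is log-normal across the population:
ln RR ~ N(μ, σ²) with σ² = 0.43 by default (the combined variance of the
known susceptibility loci and epidemiological risk factors; 0.26 for the
known loci alone is a supported sensitivity value). The package fixes
μ = −σ²/2, so E[RR] = 1 exactly. This normalization is what makes "multiply
the population rates by the group's mean RR" coherent: any other μ would
change the population totals when the cohort is split into risk strata.

Cases are distributed as the population density tilted by RR (a woman's
chance of becoming a case is proportional to her RR), i.e. log-normal with
log-mean μ + σ². All stratification quantities are closed forms in the
normal CDF Φ:

* RR at percentile p: exp(μ + σ Φ⁻¹(p/100));
* population fraction above threshold t: 1 − Φ((ln t − μ)/σ);
* case fraction above t: 1 − Φ((ln t − μ − σ²)/σ);
* mean RR above/below a percentile: case fraction over population fraction,
  which conserves the population mean, q·E[RR|above] + (1−q)·E[RR|below] = 1.

The test suite verifies every closed form against adaptive quadrature of
the density to 1e−8 and the conservation identity to 1e−10.

10-year absolute risk for a woman at relative risk rr uses the hazard
transform 1 − exp(−rr·Λ₁₀), Λ₁₀ = −ln(1 − 0.0285), anchored to the 2.85%
average 10-year risk of a 50-year-old UK woman. This keeps probabilities
below 1 at any rr (naive multiplication would not) and reproduces the
published extreme-percentile risks well (0.51%/10.2% here at σ² = 0.43).

## Life-table model

Each strategy is simulated as one or two homogeneous strata (size × mean RR
from the truncated distribution) in discrete annual cycles, ages 50–84,
with four states: alive cancer-free, alive with diagnosed breast cancer
(clinically arising or overdiagnosed), dead of breast cancer, dead of other
causes. Cycle order: screening costs at screen ages (50, 53, …, 68), then
incident diagnoses, then breast-cancer deaths, then other-cause deaths; no
half-cycle correction; person-years and QALYs accrue to end-of-cycle
survivors. Women alive at 85 contribute nothing further.

Rate semantics, chosen deliberately:

* **Incidence** is an annual diagnosis probability for cancer-free women,
  multiplied by the stratum RR.
* **Breast-cancer mortality** is a population-level death rate per
  woman-year, also multiplied by the stratum RR, and by the screening
  mortality-reduction factor for attending screened women (from first
  screen onward by default; a switch restricts it to the screening period).
  Deaths are drawn from the clinically diagnosed pool (capped at its size)
  for state accounting. The alternative — a case-fatality hazard on the
  diagnosed pool — was implemented first and rejected: it makes stratum
  deaths scale with RR² (incidence × fatality), breaks the two-strata
  splitting equivalence, and inflates the QALY gain per counted death
  averted because deaths postponed within the horizon accrue person-years
  without reducing the cumulative death count.
* **Overdiagnosis is risk-independent.** During the screening period,
  attending cancer-free women acquire an extra screen-detected-only
  diagnosis hazard of `overdiagnosis_fraction ×` the *baseline*
  (RR-unmultiplied) incidence. Overdiagnosed cases count as diagnoses,
  incur treatment cost and the post-diagnosis utility decrement, and never
  die of breast cancer. Making the per-woman overdiagnosis probability
  independent of risk is what produces the characteristic harm–benefit
  curve: overdiagnoses scale with the *population* fraction screened while
  deaths averted scale with the *case* fraction, so the ratio of harms to
  benefits deteriorates as screening extends to lower-risk women.

With these choices both screening outcomes are linear in RR, and summing
two strata built from a conservation-respecting group summary reproduces
the single average-risk run. The residual nonlinearity is cancer-free-pool
depletion (cumulative incidence ~12% by 85): diagnosis-linked totals agree
to about 1–2% at the packaged rates and to 0.5% at one-fifth the rates; the
relevant tests carry exactly these tolerances.

## Strategies and outcome accounting

* `none`: one unscreened stratum, RR = 1.
* `age_based`: one screened stratum, RR = 1.
* `risk_stratified(p)`: risk assessment for the whole cohort at age 50
  (cost charged to everyone, undiscounted year 0), a screened stratum of
  size 1 − p/100 at the upper truncated mean RR, an unscreened stratum
  below. Percentiles 0 and 100 are accepted as limiting cases and equal
  age-based (plus assessment cost) and no screening (plus assessment cost)
  exactly.

Adherence (default 1.0) splits a screened stratum into attenders (screen
costs, mortality reduction, overdiagnosis) and invited non-attenders
(invitation cost only). Invitations and screens go to cancer-free women.

Per-10 000 figures are cohort totals × 10 000/364 500 — the scaling that
reproduces the published per-10 000 numbers from the published cohort
totals (1913 × 10 000/364 500 = 52.5). Percent differences use the
age-based comparator as denominator. The harm–benefit ratio is
overdiagnoses per breast-cancer death averted, undefined (NaN) when no
deaths are averted.

## Economics

Discounting at 3.5%/yr for costs and QALYs, from age 50. QALYs weight
person-years by age-declining utilities, with a constant post-diagnosis
decrement regardless of stage, applied for the rest of life. ICER is the
cost difference over the QALY difference, with standard dominance flags;
NMB = QALY × WTP − cost; the CEAC is the fraction of PSA draws with
positive incremental NMB versus no screening; the optimal strategy at a WTP
is the NMB argmax (ties to lower cost, then higher threshold).

## Default parameters and calibration

The original input table (a supplement of the source evaluation) is not
shipped. The packaged defaults are synthetic but anchored, with provenance
labels on every field:

| parameter | default | basis |
|---|---|---|
| cohort size | 364 500 | printed ("panel-anchored") |
| σ² of log RR | 0.43 | printed |
| baseline 10-yr risk at 50 | 2.85% | printed |
| discount rate | 3.5%/yr | printed |
| incidence curve | 1 + 0.022(a−50) shape, scaled so 10-yr risk at 50 = 2.85% | anchored scale, synthetic shape |
| BC mortality rate | 0.000431·exp(0.045(a−50)) per woman-yr | UK-like age gradient; level set so the unscreened cohort has 291.5 BC deaths/10 000 (the published age-based deaths plus deaths averted) |
| other-cause mortality | 0.0022·exp(0.092(a−50)) | Gompertz at UK scale (survival 50→85 ≈ 56%) |
| screening mortality RR | 0.8193 | calibrated (below); consistent with the ~20% programme-level mortality reduction |
| overdiagnosis fraction | 0.1884 | calibrated (below) |
| cost per screen / invitation | £13 / £2 | synthetic NHS scale |
| risk assessment | £45/woman | synthetic; the published incremental-cost intercept across thresholds (£17.2M at 1% screened) pins the cohort-wide assessment cost near this value |
| treatment per case | £6 300 | synthetic; with the screening costs above, the cohort incremental cost of age-based screening lands at £44M against the published £41.9M |
| utility healthy | 0.85 → 0.72 (linear in age) | EQ-5D-like norms |
| utility decrement after diagnosis | 0.129 | set by root-finding so the discounted QALY increment of age-based vs no screening equals the published 1916 |
| adherence | 1.0 | sensitivity parameter |

`calibrate()` adjusts the screening mortality-reduction factor and the
overdiagnosis fraction by one-dimensional root finding (Brent) on the full
pipeline so the age-based-versus-none comparison reproduces named
per-10 000 targets (defaults: 52 deaths averted, 105 overdiagnoses) to 1%;
the packaged defaults ship already at the calibrated solution, so
`calibrate()` is a fixed point there. Residuals are recorded on
`calibrate.last_residuals`.

PSA distributions follow standard family choices — beta for probabilities
and utilities, gamma for costs, lognormal for relative risks and rate
scales — with moment-matched hyperparameters. Spreads: the mortality-RR sd
is 25% of (1 − RR), which propagates to a 95% interval on cohort deaths
averted of roughly 900–2900, matching the published 842–2714; the
overdiagnosis-fraction sd of 0.04 matches the published overdiagnosis
interval similarly; costs and the utility decrement carry 20–25% relative
sd; rate scales 2–8%. Draws are truncated to parameter domains by
inverse-CDF on the truncated uniform. Common random numbers are shared
across strategies within a draw so incremental NMB distributions are
paired (configurable off by passing per-strategy parameter sets).

## What the synthetic defaults do and do not emulate

They emulate the structure of the original inputs — smooth age-specific
rates, a programme-level mortality reduction, a fixed overdiagnosis share,
NHS-scale unit costs, utilities with a post-diagnosis decrement, and
uncertainty around each — and are calibrated to the published headline
outcomes. They are not the original values: the incidence shape, mortality
gradients, the cost split between screening and treatment, and the exact
uncertainty families are plausible reconstructions. Consequently,
quantities that depend only on the calibrated anchors and the risk
distribution (per-10 000 outcomes, harm–benefit curve, deaths-averted
intervals) reproduce the published results closely, while quantities
sensitive to the unpublished uncertainty inputs (notably the probability
that the optimal threshold strategy is cost-effective at £20 000/QALY) can
differ: this package computes ~90% where ~72% was published, with matching
means — the gap sits in distribution choices the main text does not pin
down. Passing tests therefore demonstrate internal correctness and
anchor-level reproduction, not parameter-level replication; users holding
the original input table can supply it as a YAML parameter file for the
latter.

## Numerical choices

* Annual probabilities are used directly (no rate-to-probability
  conversion); RR-multiplied probabilities are clipped at 1 and event flows
  at pool sizes, so conservation of women holds for any inputs.
* Degenerate risk distribution (σ² = 0): all RRs are 1 and case fractions
  equal population fractions.
* ICER conventions: Δcost = 0 → 0; ΔQALY = 0 with nonzero Δcost →
  "undefined"; strictly cheaper and more effective → "dominant".
* The percentile grid for the sweep is 1–99 (integers); all operations
  accept continuous percentiles.
* PSA parameter draws are taken in sorted name order from a single
  `numpy.random.Generator`, so results depend only on the seed, not on
  dict insertion order; identical seeds give bit-identical outputs.

## Problem sizes

The deterministic pipeline is fast: one stratum-run is ~0.2 ms, the full
101-strategy sweep ~0.2 s, a 2000-draw PSA over four strategies ~12 s, and
a full 101-strategy × 2000-draw PSA about 5 minutes on one CPU. The test
suite runs the 2000-draw PSA once and otherwise uses 20–1200 draws.

## Limitations

No tumour natural history, sojourn time, stage structure, or screening
sensitivity is modelled; the mortality reduction is a programme-level
multiplier, and overdiagnosis a fixed fraction, both from first screen
onward. Overdiagnosis probability is assumed independent of risk. Screening
intervals and modalities are not tailored by risk — the model compares
"screen above threshold, nothing below" only. Costs are programme-level
NHS costs; utilities do not vary by stage or time since diagnosis. The
within-stratum population is treated as homogeneous at the truncated mean
RR, which is exact for linear outcomes and ~1–2% off for diagnosis totals.
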