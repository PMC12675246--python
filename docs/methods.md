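# Methods

This note documents the models, parameter choices and numerical conventions
behind `sarcostage`, and what the synthetic-data tests do and do not show.

## Questionnaire scoring and psychometrics

The 12 items are summed without weighting; band cut-offs are 0–8 / 9–16 /
17–24 / ≥ 25. Missing responses are never imputed: any missing item routes
the record to the screening module's missing-data exclusion, mirroring the
design in which incomplete surveys are dropped before analysis.

Cronbach's α uses sample variances (n − 1 denominator) throughout; subscale
αs apply the same formula to each 3-item domain block. KMO is computed from
the anti-image partial correlations `q_ij = −R⁻¹_ij / √(R⁻¹_ii R⁻¹_jj)`;
a singular correlation matrix or an all-zero off-diagonal (perfectly
uncorrelated items, a 0/0 form) raises a degenerate-input error rather than
returning a number. Bartlett's statistic is
`−(n − 1 − (2k + 5)/6)·ln det(R)` with `df = k(k − 1)/2`; p-values are
reported to machine precision with no multiple-testing correction.

## Screening funnel

Gates run in the fixed order missing → comorbidity → threshold. Comorbidity
exclusion is any-flag: both clinically confirmed and
symptomatic-undiagnosed statuses exclude. When a participant carries several
category flags the recorded category is the highest-priority one under the
fixed category order (largest, mechanistically grouped categories first);
the priority affects only attribution, never the final count, and a property
test asserts that swapping the comorbidity and threshold gates leaves
`n_final` unchanged. The 9-point threshold uses the same 12-item total as
banding (a single scoring path).

## Staging

The band→stage mapping is a deterministic default, configurable by the
caller: pre-sarcopenia → A; high-risk → B when ADL ≥ 95 (fully independent)
else C; disabling → D. The four stages are a behavioural classification
(compensation → attenuation → decompensation → dependence), so the mapping
is a modelling convenience rather than a clinical standard. SARC-F
(0–1/2–3/4–6/7–10) and ALMI cut-points for the alternative staging routes
are monotone, configurable defaults — the DXA thresholds in particular are
synthetic placeholders, and tests assert only the mapping mechanics, never
clinical validity. Boundary values map to the higher-severity side.

SES bands: income < 4,000 / 4,000–9,000 / > 9,000 CNY per month, education
≤ 6 / 7–12 / > 12 years, occupation manual/skilled/professional, each scored
1–3; totals 3–4 / 5–6 / 7–9 give Low / Medium / High.

## AHP engine

Priorities use the eigenvector method: power iteration from the uniform
vector, convergence tolerance 1e−12 on the weight vector, 10,000-iteration
budget, λ_max as the mean Rayleigh ratio. The row-geometric-mean
approximation is retained as an independent cross-check. CI is defined 0
for n ≤ 2; CR uses Saaty's random-index table
(0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49 for n = 1..10) and is
0 whenever RI is 0. Expert aggregation is the entry-wise geometric mean,
reciprocal by construction; raw single-expert entries can optionally be
validated against the discrete Saaty scale, aggregates cannot (they leave
the scale).

The shipped expert matrices in `expert_fixtures` are **synthetic**: the
original panels are not published, so three mock experts are built by
perturbing the canonical weight ratios by fixed factors (0.8, 1.0, 1.25) and
snapping to the Saaty scale. They exercise the full aggregation/consistency
pipeline (aggregated CR < 0.01 at every level) but are not survey data.

The default hierarchy has 8 secondary indicators (2 physiological leaves +
the self-care node, 3 psychological, 2 external) and 7 tertiary self-care
leaves, 14 leaves in total. Source descriptions of the hierarchy disagree on
whether there are eight or nine secondary indicators; the composite-weight
table resolves to eight, which is what the package ships.

## Dynamic weighting and grading

Stage-invariant local leaf weights are back-derived once from the Stage A
composite weights (composite ÷ dimension weight) and frozen as the canonical
configuration. Because the published composites are rounded to 3 decimals,
the raw physiological locals sum to 0.9986; `derive_local_weights` therefore
has two documented variants:

* `normalize=False` — the raw ratios, which recompose the published table
  cells exactly as printed (used for table-reproduction checks);
* `normalize=True` (default) — per-dimension rescaling to sum exactly 1,
  which keeps the intervention score exactly on the 1–4 rating scale
  (uniform ratings r give score r exactly).

Three printed cells sit one rounding step from the back-derived product —
Stage C self-efficacy (0.0495 → printed 0.049), Stage D social engagement
(0.10325 → 0.104) and Stage D self-efficacy (0.05775 → 0.057). All are
exact- or near-half-way products of rounded inputs; they reproduce within
±0.002 and are asserted as documented exceptions, not silently corrected.
Composite weights used in scoring are un-rounded products; 3-decimal values
are display rounding (round-half-up).

Grade boundaries follow the stated windows with inclusive middle: score
exactly 2 → Grade II, exactly 3.2 → Grade II. Instrument→rating cut-points
(SARC-F 0–1/2–3/4–6/7–10 → 1–4; ADL ≥ 95/75/50; FES-I 20/28/39;
HADS 8/15/22; GSES 30/25/18 reverse-scored; SES 8/6/4 reverse-scored) are
documented defaults, fully overridable; the tested surface is the monotone
banding mechanics, with boundaries mapping to the higher-severity rating.
Weights sum to 1, so the score needs no normalisation by indicator count.

## Synthetic cohort generator

The generator reproduces the *statistical shape* the pipeline assumes, not
sarcopenia biology.

**Item model.** Latent severity θ ∈ [0, 1]; item responses follow a graded
cumulative-logistic model `P(item ≥ k) = logistic((θ − τ_k)/s)` with shared
thresholds τ = (0.25, 0.50, 0.75) and noise scale s = 0.07. One uniform
draw per item realises the ordered response, making item scores monotone in
θ for a fixed draw. A shared θ is the simplest mechanism producing the
strongly correlated items the reliability statistics require (simulated
full-cohort α ≈ 0.95, somewhat above typical survey values — the model has
no item-specific trait variance).

**Band severity.** Each latent band draws θ from a Beta distribution with
concentration κ = 200 and a mean solved numerically (Gauss–Legendre in
quantile space + Brent root-finding) so the band's expected total equals its
score-range midpoint (4 / 12.5 / 20.5 / 28.5). This calibration makes band
membership and questionnaire banding agree for ≈ 89% of participants under
the default config; the agreement threshold asserted in tests (≥ 80%) is
configurable. An age band may instead pin a single calibrated severity
distribution via `mean_total_target`; the 31–40 default uses 8.2 (the
published mean for that group), and the ground-truth band label is then the
band whose score range contains E[total | θ].

**Age structure.** The default age mix uses the per-band survey counts
(281/171/274/344/447/103/63 over bands ≤30 … ≥81, n = 1,683); per-band
demographics (sex ratio, education, insurance, income) follow the published
baseline table. Default latent mixtures encode the published narrative:
≤ 30 all healthy, 51–60 split 42.9/28.6/28.5% across
Healthy/Pre-Sarcopenia/High-Risk, 61–70 entirely above the pre-sarcopenia
threshold, ≥ 81 heavily high-risk/disabling; bands without published
mixtures (41–50, 71–80) interpolate monotonically between their neighbours.

**Comorbidity and missingness.** Category flags are independent Bernoulli
draws with marginal rates equal to the published category counts over 1,683
(confirmed and symptomatic-undiagnosed separately); because flags are
non-exclusive, the simulated overall exclusion fraction is slightly below
the published 950/1,683. Missingness is item-level, independent, at rate
r = 1 − (1 − 45/1728)^(1/12) ≈ 0.0022, so the expected share of participants
with ≥ 1 missing item equals the published 45/1,728.

**Instruments.** Truncated Gaussians around band-specific means (e.g. SARC-F
0.5/1.5/4.5/8.0, ADL 99/96/78/45 across the four bands), clipped to each
instrument's range. These are internally consistent with the staging and
rating defaults but are not fitted to any real instrument distribution.

**What passing tests show.** Calibration tests demonstrate that the pipeline
recovers the structure the generator encodes (band mixtures, mean scores,
funnel arithmetic). They cannot validate the questionnaire's real-world
reliability (the published α = 0.89 on survey data is not reproducible
without that data) nor any clinical cut-point; real-data properties are out
of reach by construction.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.Generator` seeded from explicit
config fields; the pipeline fans one top-level seed into per-stage child
seeds via `SeedSequence.spawn`, and two runs with the same config and seed
produce byte-identical files. Calibration checks and the acceptance script
use n = 1,000 single-band cohorts and the n = 1,728 default cohort — large
enough for 3-binomial-SD checks while keeping the full suite around ten
seconds.

## Known limitations

* Stage assignment from band + ADL is one deterministic choice among several
  defensible mappings; triangulation defaults (SARC-F/DXA cut-points) are
  placeholders.
* The generator's comorbidity flags are independent across categories;
  real multi-morbidity is correlated.
* No factor extraction or rotation is provided (only adequacy statistics),
  and no fuzzy-AHP/ANP or rank-reversal analysis.
* Intervention grades are the terminal output; intervention content design
  is out of scope.
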