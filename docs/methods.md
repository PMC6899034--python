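# Methods

## The assay model

The package models a growth-restoration screen: mutant larvae dispensed
into multiwell plates arrest under proteasome-inhibitor stress, and the
imaging readout is the total organism area per well (worms additionally
amplify the signal by producing progeny when rescued to adulthood; flies
do not, so the fly readout is area normalized per larva). A well's
noise-free expected area is linear in the net growth fraction *r*:

    E[area] = max(0, arrest + r · (full − arrest))

with *r* = 1 for positive controls (no drug), 0 for negative controls
(drug, no compound), and for test wells the compound's rescue fraction
minus its toxicity fraction. Defaults: `arrest_area_AU = 500`,
`full_area_AU = 5000`. The 10× span folds in the progeny amplification of
a fully rescued worm well (≈33 AU per arrested L1 larva × 15 larvae at
baseline); it is a single knob, not a brood model.

Observed area is the expectation times multiplicative lognormal noise,
`LogNormal(0, σ)` with σ = 0.15 by default: growth readouts have
scale-proportional spread and areas must stay positive. A Gaussian
multiplicative option (`noise_model="gaussian"`) exists for calibration
experiments where exact normal tail behaviour is the point of the test.
Animal counts are deterministic given the growth state: dispensed larvae
plus progeny proportional to clamped rescue (progeny multiplier 9 per
animal for worms, 0 for flies).

## Compound effect classes

Ground truth assigns each library compound one behaviour class:

* **inactive** — r = 0 everywhere;
* **suppressor** — rescue fraction drawn U(0.5, 1), active in every
  paradigm of its active species (both species by default);
* **enhancer_toxic** — toxicity fraction U(0.05, 0.3) pushing wells
  below the arrest baseline (clamped at zero);
* **bzb_inactivator** — rescues only in bortezomib-containing paradigms
  (a chemical false positive: the compound neutralizes the drug, so it
  fails carfilzomib and no-drug counter-screens);
* **species_restricted** — a suppressor active in exactly one species
  (coin flip), a binary stand-in for non-conserved targets.

A minority of true suppressors (15% by default) additionally carry an
NRF2-reporter EC50 drawn log-uniformly inside the 2–30 µM activity
window. With `plant_all_assay_active=True` the first compound is forced
to be a dual-species suppressor (rescue 0.9) with an in-window reporter
EC50 of 10 µM and every other compound is denied an in-window EC50 —
the configuration used to test uniqueness of the all-assay-active call.

## Plate geometry and layout

Worm plates are 384-well (A01–P24) with 32 positive and 32 negative
controls; fly plates are 96-well (A01–H12) with 8+8 controls — the fly
counts are chosen proportional to the worm control density, since only
their existence is a stated fact of the assay. Controls occupy the two
leftmost and two rightmost columns, alternating roles down each column so
both roles sample all rows. Compounds fill the remaining test wells in
row-major order; every replicate reuses the same well assignment on its
own physical plate. Same seed ⇒ byte-identical truth, layout and
measurement tables.

## Image rendering and quantification

Rendered wells paint each larva as a persistent random-walk stroke
stamped with a diamond brush (width 3 px) on a dark background; painting
stops the step the pixel budget is met, so total painted area lands
within one stamp (≤ ~2 px) of the target. Because the painted set is a
union of full brush stamps, it is invariant under morphological opening
with the same footprint — the noise-free segmentation round trip is
therefore pixel-exact by construction, and the imaging tests exploit
that. Background noise is Gaussian at a configurable SNR (foreground
contrast / noise s.d.).

Quantification: Otsu global threshold (histogram-based, hence invariant
to positive intensity rescaling; uniform illumination is assumed),
opening with a diamond of radius 1, removal of components under 9 px,
labeling with 8-connectivity (diagonal larvae fragment under
4-connectivity). Artifact rules mimic manual well curation as exclusion,
never correction: any single component over 20× the expected animal
area, total foreground over half the image, or foreground occupying more
than 25% of the border pixels flags the well. Touching larvae count as
one object — an acknowledged bias; there is no pose or stage
classification.

## Plate statistics

Per control group (positive, negative) the 1.5×IQR Tukey fence is
applied with type-7 linear-interpolation quantiles; the fence interval
is closed, so a zero-IQR group retains everything. Fences are two-sided
by default with an `upper`-only switch — abnormally small control wells
are as artifactual as large ones, but the one-sided reading is
supported. `sd_neg` is the sample (n−1) standard deviation of retained
negative controls; both conventions are test-locked. Z-scores are always
per plate (each plate carries its own controls), computed only for test
wells; artifact wells are excluded with no score. Outlier elimination
applies to control wells only — test wells are never fence-eliminated,
only artifact-excluded. Plate QC requires positive/negative mean
separation ≥ 3 and ≤ 25% of control wells eliminated; failing plates are
dropped from hit calling with a logged reason.

## Hit calling

Consensus rules are (threshold, comparator, m-of-n): worm suppressors
Z ≥ 2.0 in 3 of 3 (inclusive), fly suppressors Z > 2.5 in 2 of 3
(strict), enhancers Z ≤ −2.0 in 3 of 3. The enhancer threshold is
negative: enhancer wells sit below the negative controls, and a positive
reading would sweep in near-threshold suppressors. A missing or
artifact-excluded replicate counts as failing its rule — exclusions can
never create a hit. Hit rates and all printed percentages round half
away from zero. Venn regions are exclusive membership-pattern counts;
the triple region under the worm rule equals the 3-of-3 consensus set by
construction, which is asserted in tests.

## Dose-response

The 4PL family is fitted by bounded least squares (`scipy`
`curve_fit`) in (bottom, top, log10 EC50, hill) with EC50 constrained to
[min positive dose / 100, max dose × 100], hill in [−10, 10], and
initialization at the empirical extremes with |hill| = 1. Zero doses are
anchored to the no-drug asymptote (top for falling curves, bottom for
rising ones) rather than placed on the log grid. A flat signal — spread
of per-dose means at or below twice the pooled replicate standard error
— returns a no-effect result with `converged=False` instead of chasing
noise. Curves are stored with top ≥ bottom; the hill sign carries the
orientation. Screening-dose selection inverts the fitted curve in closed
form at a target reduction (default 85% of the top asymptote);
fold-sensitivity is the reference/test EC50 ratio; reporter ranking is
the integer percent of the positive-control activator's fitted
amplitude. Reporter activity requires EC50 ≤ 30 µM; the 2 µM lower
bound brackets the observed actives and is descriptive by default
(configurable to exclusionary). No replicate weighting is applied — no
variance model is assumed.

## Validation cascade

Outcomes are binary pass/fail per (compound, paradigm) at a stated dose
— retests are reported qualitatively, not refit. Conflicting duplicate
records are an error; untested cells are `not_tested` and drop out of
stage denominators. Status logic: `validated_worm` = pass both worm
paradigms; `validated_fly` = pass both fly paradigms;
`cross_validated_all4` = all four; `bzb_inactivator_candidate` = pass
every tested bortezomib paradigm and fail every tested non-bortezomib
paradigm (at least one of each tested) — provably disjoint from the
validated sets; `all_assay_active` = all four plus reporter activity.
Stage summaries always count from the matrix.

## Calibration and power experiments

`larvascreen.benchmarks` runs the package's own calibration studies at
fixed problem sizes (chosen once as the package's standard benchmark
sizes):

* **Null calibration** — all-inactive 20,240-compound triplicate
  campaigns with Gaussian well noise. The per-replicate tail probability
  p = P(Z ≥ 2) is estimated from the simulated test wells themselves
  (it exceeds the normal tail value because each plate's control moments
  are estimated from 32 wells after fence cleanup), and the observed
  3-of-3 consensus rate is compared to p³. One campaign's expected
  consensus count is below one, so twelve seeded campaigns are pooled to
  make the Poisson-distributed count informative; the observed/expected
  ratio sits near 1 (factor-3 agreement asserted).
* **Recovery** — twenty 640-compound campaigns at σ = 0.15 (10%
  suppressors): recall of suppressors with rescue ≥ 0.8 (≈100%) and the
  suppressor false-call rate on inactive compounds (≪ 0.1%).
* **Imaging round trip** — rendered wells: exact areas noise-free,
  ≤ 5% area error and exact counts at SNR 10.
* **EC50 recovery** — 200 fits of (bottom 0, top 100, EC50 205, hill 1)
  at σ = 0.1, 8 doses × 4 replicates: median relative EC50 error ≈ 9%.
* **Fold-sensitivity** — median EC50 ratio over ten simulated
  heterozygote/wild-type experiment pairs (truth 2×).
* **End-to-end** — twenty 320-compound campaigns with one planted
  all-paradigm + reporter active: the all-assay-active set is exactly
  that compound in every run.

## What the synthetic data does and does not show

The generator reproduces the structural features the analytics depend on
— control layout, effect classes, paradigm-dependent rescue,
scale-proportional noise, genotype-shifted dose-response — but not
spatial plate effects (edge evaporation, dispense gradients), well-level
count stochasticity, brood dynamics, compound solubility/stability, or
correlated replicate failures. Passing tests therefore demonstrate that
the statistics are implemented correctly and are well calibrated under
the stated noise model, not that real campaigns will achieve the same
recall; the B-score/median-polish machinery real spatial artifacts would
demand is deliberately out of scope, as the assay's own analysis relies
on per-plate controls instead.

## Degenerate inputs and tie-breaks

Tukey fences need ≥ 4 values; zero negative-control spread is a
degenerate-plate error (not a silent pass); a constant image segments to
an empty mask (not an error); count-zero wells become `no_animals`
artifacts rather than division errors; curve inversion outside the open
(bottom, top) interval is a domain error; empty cascade denominators are
errors. Ties on fence boundaries are retained (closed interval).
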