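# Methods

## Densitometric model

Hydrostatic weighing measures the mass of water a body displaces.  With
dry mass in air `MA` (kg), equilibrium in-water mass `MW` (kg) and water
density `DW` (kg/L), the submerged volume is `(MA − MW)/DW` litres.  Two
gas spaces inflate that volume beyond tissue: the lungs (TLC during
maximal-inhale trials, RV during maximal-exhale trials) and a
conventional 0.1 L gastrointestinal allowance.  When the head stays
above water its volume `HV_pred` never displaces water and is added
back.  Tissue volume `V` is therefore

    V = (MA − MW)/DW − V_lung − 0.1            (head below water)
    V = (MA − MW)/DW + HV_pred − V_lung − 0.1  (head above water)

and `Db = MA/V`.  Percent body fat uses the Brozek two-compartment
transform `PBF = (4.570/Db − 4.142)·100`, which assumes fixed fat and
fat-free-mass densities; `density_from_pbf` is its exact inverse.

A useful identity used throughout the validation: `1/Db = V/MA`, so PBF
is *exactly linear* in the computed tissue volume.  Any volume
mis-estimate ΔV (litres) shifts PBF by exactly `457·ΔV/MA` percentage
points.  Injected-effect checks compare pipeline output against this
delta; it is exact, not first-order, up to trial-selection noise.

Supporting predictions:

* **Head volume** (L): sex-specific linear function of head girth and
  face girth (cm) and `MA` (kg).  The equations' source does not state
  units; cm/cm/kg is adopted because it yields anatomically plausible
  3.9–4.3 L volumes at the cohort mean profiles.  Values outside 2–7 L
  warn.
* **Lung volumes** (L): sex-specific linear reference equations, TLC
  from height (m), RV from height and age.  Adult ranges are enforced
  (height 1.0–2.5 m, age 18–100), matching the study population; no
  pediatric extrapolation.
* **Water density** (kg/L): Kell's (1975) rational polynomial for
  air-free water at 1 atm, restricted to 0–40 °C.  Default tank
  temperature 32.5 °C (midpoint of the 31–34 °C protocol band),
  overridable per participant or per run.

## Measurement protocol as implemented

* **Girth QC** (`qc_girth`): among up to four repeated measurements
  (mm), average the pair with the smallest absolute difference that is
  within 5 mm, ties broken by acquisition order.  No qualifying pair
  after four attempts is a QC failure; after fewer, a "needs another
  measurement" status.  The protocol's wording ("the average of two
  measurements within 5 mm") does not pin down behaviour when several
  pairs qualify; choosing the tightest pair is deterministic and uses
  the most mutually consistent data.
* **Sample window** (`select_sample_window`): among all contiguous
  load-cell windows of 100 ± 2 samples, the one with the smallest
  within-window standard deviation (population SD; ties prefer the
  longer window, then the earlier start) defines the trial weight as its
  mean.
* **Trial consistency** (`select_consistent_trials`): the tightest
  3-subset of trial weights with range ≤ 100 g is averaged
  (lexicographically earliest on ties); failing that the tightest
  2-subset ("pair" quality); failing that the condition yields no
  estimate.  Trials are capped at 7 (TLC conditions) and 5 (RV).
  Pair-quality estimates are retained by default, as in the study,
  with the tier recorded; `include_pairs=False` (CLI `--strict`)
  excludes them.
* **Weighted belt**: the 2.1 kg belt worn during TLC trials is assumed
  tared by the acquisition system.  For systems that do not tare it,
  `ProtocolConfig(belt_correction=True)` subtracts the belt's net
  in-water weight `belt_mass·(1 − DW/belt_density)` (default belt
  density 7.8 kg/L, steel) from TLC-condition weights.

All tolerances (5 mm, 100 g, 100 ± 2 samples, trial caps) are
`ProtocolConfig` fields defaulting to the printed protocol.

## Agreement statistics

Three comparisons are reported, signed as "first − second": HBW@TLC −
HAW@TLC (head position only), HBW@RV − HBW@TLC (lung volume only), and
HBW@RV − HAW@TLC (both), each for the combined cohort and per sex.
Pairing is pairwise-complete: a participant missing one condition still
contributes to the comparisons not involving it; strata with fewer than
three pairs are skipped with a warning.

Per pair of series `a`, `b` (difference `d = a − b`):

* paired t-test on `d`, two-sided; a zero-variance nonzero-mean
  difference vector is reported as p = 0 with a degeneracy warning.
* Bland-Altman: limits of agreement `mean(d) ± 1.96·sd(d)` with the
  n−1 SD denominator; the 1.96 multiplier is configurable.
* proportional bias: OLS of `d` on the pair mean `(a+b)/2` (the
  standard Bland-Altman regressor), slope tested at α = 0.05.  An
  exactly constant difference (zero slope, zero residuals) is reported
  as p = 1.
* Lin's concordance correlation coefficient with biased 1/n moments
  (Lin's 1989 convention).  The SD conventions differ deliberately:
  n−1 for limits of agreement, 1/n inside the CCC.
* leave-one-out sensitivity: the proportional-bias p-value recomputed
  with each pair left out, flagging single participants who drive an
  apparent bias.

## Synthetic cohort generator

`generate_cohort` draws, per sex, height, mass, age, head/face girth and
true PBF from independent truncated normals (±3.5 SD for body size, the
observed 18–70/18–65 ranges for age, 3–50 % for PBF).  Demographic
defaults are the study cohort's marginals (64 males: height 182.1 ± 7.9
cm, mass 90.6 ± 14.7 kg, HG 58.3 ± 1.6 cm, FG 67.7 ± 2.1 cm; 58
females: 168.7 ± 6.2, 68.5 ± 12.1, 56.2 ± 1.6, 63.0 ± 2.1).  True-PBF
distributions (male 18 ± 6 %, female 28 ± 7 %) are generator
conveniences chosen as typical young-adult values, not study estimates.
True density follows from true PBF by the exact Brozek inverse; body
volume is `MA/Db`.

Latent volumes: true head volume is the girth-equation prediction plus
`hv_bias_l` plus N(0, `hv_sd_l`) scatter; true lung volumes are the
reference predictions plus `tlc_offset_l` / `rv_offset_l`.  **Offsets
are true minus predicted**: a negative offset means the prediction
overestimates the participant, which *lowers* that condition's fat
estimate by `457·|offset|/MA` points.  All effect knobs default to 0 so
recovery tests are non-circular; systematic effects are injected
explicitly per experiment.

Forward simulation runs Archimedes in reverse: `MW = MA − DW·V_sub`
with `V_sub = body volume + true lung gas + 0.1 − true head volume (HAW
only)`, plus iid N(0, `trial_noise_kg`) noise per trial (default 30 g —
the protocol states only the 100 g consistency criterion, and 30 g makes
three-trial consistency typical, matching the study's reported mix of
triple- and pair-quality outcomes).  Girth truths are generated on the
instrument's 1 mm grid; measurements add N(0, `girth_noise_mm`) (default
2 mm, a plausible inter-technician error) and round to the nearest mm,
following the 2→3→4-measurement protocol.  Trial counts default to 5
(TLC) and 4 (RV), inside the protocol caps.  Negative in-water masses
(buoyant participants) are passed through.

What the generator does **not** emulate: posture and wave perturbation,
breath-hold failure, correlated technician error, within-person
day-to-day variation, non-normal body-size distributions, and any
dependence of true lung or head volume on body size beyond the
reference equations.  Passing recovery tests therefore demonstrates the
*analysis chain* is correct and well-calibrated, not that the weighing
protocol itself is accurate in the field.

## Validation design and problem sizes

* Hand-derived equation substitutions at the cohort mean profiles are
  asserted to 1e-9.
* Zero-noise recovery: 50 participants; the pipeline must return every
  true PBF to 1e-6 and all comparison mean differences to 1e-6.
* Noisy recovery: 200 participants at 30 g / 2 mm noise; mean absolute
  PBF error below 1.0 points with bias below 0.3 (observed ≈ 0.12 and
  ≈ 0.01).
* Selection rules are checked against naive exhaustive-enumeration
  oracles over all weight sequences of length ≤ 7 (girth series ≤ 4)
  on coarse value grids; the concordance coefficient against a
  from-definition loop implementation on 1000 random pairs to 1e-12.
* Calibration: paired-t null rejection 0.05 ± 0.01 (5000 replicates,
  n = 30), limits-of-agreement coverage within [94.3 %, 95.7 %]
  (10 000 normal differences), proportional-bias null p-values uniform
  (KS distance < 0.03).
* Injected-effect deltas: a −0.8 L TLC offset and a −0.4 L head-volume
  bias must reproduce the expected signs (lung-volume over-prediction
  lowers TLC-condition fat; head-volume over-prediction raises the
  HAW estimate) and match the `457·ΔV/MA` delta within 10 %.

Simulation sizes were chosen so the whole suite runs in seconds while
keeping Monte-Carlo standard errors well inside the asserted bands.

## Numerical and design notes

* Equation inputs/outputs are plain floats; no rounding is applied
  anywhere in the analysis chain (girth mm-rounding happens only in the
  *simulator*, mimicking the instrument).
* `body_density` validates its volume budget and raises a
  `DensityComputationError` naming the offending volumes when the
  tissue volume is non-positive.
* The pipeline is fail-soft at participant granularity: schema problems
  abort the run with itemized messages, but a participant whose girth
  QC fails or whose trials are inconsistent is logged and skipped.
* Determinism: every stochastic component takes a NumPy `Generator` or
  integer seed; identical seeds give byte-identical fixture bundles.

## Limitations

* The reference lung-volume equations carry their own population error,
  which the pipeline cannot see; recovered "truth" in real data is
  conditional on those predictions.
* Only the Brozek fat transform is provided; populations whose fat-free
  mass density departs from its assumptions (e.g. athletes, older
  adults) would need a different transform.
* The agreement report treats participants as exchangeable; no
  repeated-measures or mixed-effects structure is modelled.
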