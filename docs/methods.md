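# Methods

## Assay geometry and cycle structure

The package models a 24-well islet microplate (rows A–D × columns 1–6).
Four wells — A1, B3, C4, D6 by default — are specimen-free temperature
controls; the other 20 hold embryos under capture screens. A run consists of
measurement cycles with a fixed template: 2 min mix, 1 min wait, 1.5 min
measure (4.5 min per cycle). Six basal cycles precede up to four port
injections; the standard stress-test schedule injects oligomycin at cycle 7,
FCCP at cycle 13 and sodium azide at cycle 19 of a 24-cycle run, giving six
post-injection cycles per agent. Post-injection windows are bounded by the
next injection cycle. Each well is filled with 700 µL of medium; wells are
identified case-insensitively and emitted upper-case; time is minutes from
assay start (0-based), cycles are 1-based.

The stage lookup covers the six assayed timepoints only (3, 7, 12, 24, 30,
48 hpf) with plating densities 3/2/2/2/2/1 embryos per well and the
stage-banded working concentrations (oligomycin 9.4 µM; FCCP 1.875 µM up to
12 hpf and 2.5 µM from 24 hpf; azide 6.25 mM up to 30 hpf, 1.25 mM at
48 hpf). Lookup refuses non-tabulated stages rather than interpolating:
development is not smooth in the quantities the table encodes.

## Microchamber O₂ model

During a measure phase, with the sensor down, chamber O₂ tension `O_ch`
(mmHg) follows

    dO_ch/dt = −OCR/(V_ch·k_O2) + k_w (O_w − O_ch) + k_a (O_atm − O_ch)
    dO_w/dt  = k_w' (O_ch − O_w)

where `O_w` is a plate-wall compartment that stores and returns dissolved
O₂, and the `k_a` term is atmospheric leak. Defaults (all
config-overridable via `ChamberPhysics`): `V_ch` = 7 µL, `k_O2` =
1.4 pmol·µL⁻¹·mmHg⁻¹ (≈ O₂ solubility of fresh water at 28.5 °C),
`O_atm` = 155 mmHg, `k_w = k_w'` = 0.06 min⁻¹, `k_a` = 0.02 min⁻¹. The
microchamber volume of the islet plate is not a published constant, so it is
a configuration field, not a claim.

With OCR constant over a phase the system is linear and is integrated
exactly with matrix exponentials (`scipy.linalg.expm` on the augmented
system, valid also when the rate constants are zero). Mix phases fully
re-homogenise the well: at each measure-phase start, chamber and wall are
set equal to the well-bulk tension, which itself relaxes toward atmosphere
(surface-exchange constant 0.5 min⁻¹) while being drawn down by respiration
in the full 700 µL volume. This equilibrated-at-mix convention is also the
initial condition the estimator assumes, which is what makes
generator/estimator recovery an exact check rather than an approximation.

## Rate estimation

Two estimators per measure phase:

- **slope** — OCR = −(dO/dt)·V_ch·k_O2 from ordinary least squares. Ignores
  the refill terms, hence biased low whenever the chamber runs below its
  surroundings (the bias grows with the depletion depth).
- **compartment** (default) — fits the two-compartment model. Because the
  exact solution is *affine* in (OCR, O₀) once the physics constants are
  fixed, the per-cycle fit is solved in closed form by linear least squares:
  same optimum a nonlinear solver would reach, with no iteration or
  tolerance knobs. The generator and estimator share this model
  deliberately, so recovery tests are exact in the noiseless limit; model
  mismatch is probed in the tests by perturbing `k_w`/`k_a`.

ECAR is the negated OLS pH slope (mpH/min). Cycles with fewer than three
measure samples are flagged invalid with NaN rates — never silently dropped
— and flat phases are flagged degenerate with R² defined as 1. Hypoxia QC
fails any cycle whose measure-phase O₂ dips below 100 mmHg (overridable).

Clark-electrode traces are closed-system declines; OCR per embryo is
−slope × chamber volume / embryo count, and a slope that is positive beyond
three standard errors is rejected as physically impossible.

## Calibration

Buffer capacity is titrated by stepwise additions of 0.1 N HCl (default
five additions of 1000 nmol ≈ 10 µL each) into a known volume; the raw
slope (mpH per nmol) is rescaled by titrated-volume / chamber-volume so that
`PPR = ECAR / BC_chamber` holds literally regardless of whether the
titration was done in the full well or the microchamber. Cross-calibration
of absolute plate OCR against a Clark electrode is the ratio of mean
per-embryo rates, applied after rate estimation and before partitioning;
fraction-of-total results are exactly invariant under it, so the ordering is
observable only in absolute rates. In the synthetic pipeline the default
factor is 1: the generator's truth is already on the calibrated scale.

## Partitioning

Basal rate = mean of cycles 5 and 6 (all six basal cycles must exist; if
cycle 5 or 6 failed QC, the latest two consecutive valid basal cycles are
used, with a warning). Treatment rate = two-consecutive-cycle mean at the
post-injection extreme; the extreme cycle is paired with whichever adjacent
valid cycle gives the more extreme mean, earlier pair on ties. Components
follow the subtraction scheme in the README; negative components (common for
leak early in development, where oligomycin-derived leak estimates scatter
around zero) are flagged but never clipped, so tests against zero stay
meaningful. No correction is applied for the oligomycin-hyperpolarization
over-estimate of leak; it is a documented caveat of the subtraction method.

Normalisations: per-embryo division by plating density, and optional
division of the mitochondrial and maximal-uncoupled rates by a COX IV /
beta-actin densitometry index anchored to 1 at 3 hpf (a mitochondrial-
content proxy). Two accounting bounds are provided: cumulative O₂ → maximal
carbon loss under carbohydrate stoichiometry (1 mol C per mol O₂, 12 ng/nmol)
and the lactate-detection-limit ceiling on the lactate share of PPR
(limit[µM] × volume[mL] / (duration[min] × embryos), one H⁺ per lactate).

## Statistics

One-way ANOVA (F and p cross-checked against `scipy.stats.f_oneway` in the
tests) followed by the Student–Newman–Keuls step-down: groups ordered by
mean; a pair spanning r rank positions is tested on the studentized range
`q = |Δmean| / sqrt(MSE/n_h)` against `q(α, r, df_error)` from
`scipy.stats.studentized_range` (verified against printed q-tables at
α = 0.05); pairs inside a non-significant span are not tested. Unequal group
sizes use the harmonic mean of the pair's sizes, which preserves the exact
equivalence of the k = 2 case with the pooled two-sample t-test
(q = t·√2). Under the complete null the family-wise error equals the level
of the widest-span test, i.e. α. Homogeneous-subset letters are read off the
maximal non-significant spans. The leak-vs-zero check is a two-sided
one-sample t-test. Titration dose selection returns the smallest non-lethal
dose within 5 % (configurable) of the maximal non-lethal response —
"maximum change in respiration without inducing death" with a plateau
resolved to the lowest dose.

## Synthetic generator: what it emulates, and what it does not

Per stage, ground truth is a per-embryo basal OCR, the three basal fractions
(non-mitochondrial, leak, ATP-linked; summing to 1), an FCCP fold-increase
applied to the mitochondrial share, and a per-embryo basal PPR. Defaults:

| hpf | OCR (pmol/min/embryo) | f_nonmito | f_leak | f_ATP | FCCP fold | PPR (nmol/min/embryo) |
|----:|----:|----:|----:|----:|----:|----:|
| 3  | 15.0  | 0.55 | 0.00  | 0.45  | 1.5 | 0.20 |
| 7  | 26.3  | 0.40 | 0.00  | 0.60  | 1.8 | 0.36 |
| 12 | 40.3  | 0.25 | 0.27  | 0.48  | 1.7 | 0.56 |
| 24 | 74.1  | 0.25 | 0.27  | 0.48  | 1.6 | 1.04 |
| 30 | 91.0  | 0.25 | 0.18  | 0.57  | 1.5 | 1.28 |
| 48 | 141.7 | 0.25 | 0.094 | 0.656 | 1.4 | 2.00 |

The OCR column is a straight line in hpf anchored at 91 pmol/min/embryo at
30 hpf (the Clark cross-calibration stage) with ≈ 15 pmol/min at 3 hpf; the
leak fractions are the stage profile the pipeline is designed to recover
(zero leak through gastrulation, a segmentation-period maximum of 27 %,
declining to 18 % and 9.4 % approaching hatching). The non-mitochondrial
share is elevated at 3 hpf and flat from 12 hpf on; the FCCP fold peaks at
gastrulation. PPR rises linearly (0.04·hpf + 0.08). OCR/PPR magnitudes other
than the 30 hpf anchor and the leak fractions are declared defaults, not
measured values. The FCCP-phase PPR multiplier defaults to 1 (no claimed
magnitude exists for it).

Noise: one lognormal multiplicative factor per well (CV 10 %) times one per
clutch/plate (CV 10 %), applied identically to all of a well's true rates
(an embryo-size-like effect), plus additive Gaussian sensor noise on O₂
(SD 0.2 mmHg) and pH (SD 0.0005). Temperature-control wells carry zero
respiration plus sensor noise. All simulators take explicit integer seeds;
there is no hidden global RNG state.

Drug titration curves are Hill-shaped in |ΔOCR| with a death-threshold dose;
the EC50/slope/threshold defaults are set so that the maximal non-lethal
response lands on the stage-banded working concentrations above, making dose
selection testable end to end.

Not emulated: 3-D diffusion through the chorion, temperature drift, CO₂/
bicarbonate buffering chemistry, drug off-target kinetics, or any mechanistic
link between OCR and PPR beyond their shared well factor. Because the
estimator shares the generator's compartment model, noiseless recovery shows
internal consistency of the pipeline arithmetic — it does not validate the
physics constants against a real instrument, and passing recovery tests
bound only the estimation error under the stated noise model, not biological
variability beyond it.

## Problem sizes and determinism

The default profile simulates one 24-cycle, 24-well plate per stage
(8 samples per measure phase, ≈ 5 800 rows per plate); the developmental-
trend demonstration uses eight clutches per stage, matching the n = 8
replication of the standard design. The SNK family-wise-error simulation
uses 2 000 replicates of a 6-group, n = 8 null. Pipeline runs are fully
deterministic given the config seed: per-stage, per-clutch plate seeds are
derived as `seed·1000 + plate index`, and repeated runs produce
byte-identical reports.

## Known limitations

- The instrument vendor's rate algorithm is proprietary; the compartment
  estimator here is a declared surrogate sharing its cited structure (plate
  diffusion + atmospheric leak), not a re-derivation of its coefficients,
  and carries no V7-plate parameterization.
- Clutch effects are treated as independent multiplicative noise, not as a
  mixed-effects grouping factor; stages are compared treating wells/clutches
  as replicates.
- Leak estimates inherit the oligomycin hyperpolarization over-estimate by
  construction; values near zero should be read through the t-test, not at
  face value.
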