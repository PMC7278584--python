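# Methods

This note documents the models, numerical choices and limitations behind
`oliveqc`: the GC-IMS heat-map simulator, the 25-signal feature extraction,
the chemometric building blocks, the screening cascade, and the
method-performance procedures.

## Heat-map simulator

A measurement is rendered on a grid covering the 32-minute GC program
(retention time 0–1920 s, 1 s steps) and the IMS drift window (7–16 ms,
0.01 ms steps); a coarse variant (5 s × 0.02 ms) is provided for large
simulated cohorts where single-spot resolution is not under study. All grid
and shape parameters live in `GridSpec` and are configurable.

**Reactant ion peak (RIP).** A Gaussian ridge (σ = 0.05 ms) at 8.5 ms spans
all retention times with nominal apex 2000 mV. Analyte ionization depletes
the reactant ions, so the per-row RIP amplitude is reduced by 0.6 mV per mV
of analyte signal eluting at that retention time, floored at 10% of nominal.

**Analyte spots.** Each compound contributes a 2-D Gaussian monomer spot at
its (rt, dt) coordinate with σ_dt = 0.03 ms and σ_rt = max(2 s, 0.5% · rt)
(peaks broaden with retention under the flow-ramp program). Inside the
compound's linear range the spot **apex** equals its calibration line
`slope · c + intercept` (mV); the rendered amplitude is apex − baseline, so
the measured maximum reproduces the calibration equation exactly. The flat
baseline is 5 mV — deliberately below the smallest calibration intercept
(7.3 mV), which is what makes the apex identity well defined for every
compound.

**Saturation.** Above the linear-range top `hi` the response approaches a
plateau exponentially, continuous in value and slope at the junction:
`R(c) = y0 + h·(1 − exp(−slope·(c−hi)/h))` with `y0 = slope·hi + intercept`
and headroom `h = 0.1·slope·hi`. The narrow headroom makes saturation bite
within roughly one dilution step of the onset. A Michaelis-type hyperbola
was considered and rejected: once its curvature is pinned by slope
continuity it departs from linearity by only a few percent several dilution
steps past the onset, which makes the configured linear range unrecoverable
by any calibration-fit criterion — the simulator would then be silently
inconsistent with the linearity module it is meant to exercise.

**Dimers and the ghost spot.** Ten of the fifteen compounds form a dimer
spot at a drift time 1.0 ms beyond the monomer (dimer drift times are not
tabulated for this instrument; the offset is configurable, as is the set of
dimer-forming compounds — the default monomer-only set is propanoic acid,
acetic acid, (E,E)-2,4-hexadienal, (Z)-3-hexenyl acetate and nonanal, the
low-response/late-eluting markers). Dimer intensity grows quadratically in
concentration — dimers appear at high analyte abundance — scaled so the
dimer apex is 40% of the monomer apex at the linear-range midpoint, with the
same exponential plateau above the range. Under isothermal IMS operation a
spurious "ghost" spot partially co-elutes with the ethanol dimer; it is
rendered at a fixed offset (+15 s, +0.12 ms) with half the dimer amplitude,
and extraction sums the two window maxima, since the instrument cannot
resolve them.

**Noise.** Intensity noise is i.i.d. multiplicative Gaussian over the whole
grid with coefficient of variation `noise_cv` (default 1.5%, the intra-day
repeatability scale of such instruments). Inter-day response drift is one
shared multiplicative log-normal factor per day applied to all analyte
amplitudes (`day_effect_cv`, default 2%), which guarantees inter-day RSD ≥
intra-day RSD in expectation.

## Synthetic study population

Concentrations are class-conditional log-normals per compound (default log
scale 0.45, i.e. a geometric SD of ≈1.6 within a class). A neutral baseline
profile is modulated by additive log-scale contrasts:

* **EVOO**: (E)-2-hexenal +1.2, hexanal +0.5, (Z)-3-hexenyl acetate +0.4,
  1-hexanol +0.3 (fruity, lipoxygenase-derived).
* **VOO**: attenuated fruitiness (+0.4/+0.2) plus mild ethanol/ethyl acetate.
* **LOO**: low fruitiness ((E)-2-hexenal −0.8, hexanal −0.3) and a general
  fermentative background (ethanol, acetic acid +0.4).
* **Defects**: fusty → 3-methyl-1-butanol +1.6, ethyl propanoate +1.4,
  propanoic acid +1.2; musty → 1-octen-3-ol +1.8; rancid → nonanal +1.4,
  (E)-2-heptenal +1.3, hexanal +1.2, (E,E)-2,4-hexadienal +0.6; winey →
  ethanol and ethyl acetate +1.3, acetic acid +1.0.

A defective sample's profile is the element-wise **maximum** of its grade
profile and its defect profiles: a defect can raise a marker, never mask
it. Defect contrasts are applied at full strength in LOOs and at 60%
strength in VOOs (defects are perceived but milder below the lampante
cut-off). Deliberately, the LOO grade contrast itself does *not* include the
defect markers: lampante oils are lampante *because* of the defects they
carry, so a non-fusty LOO has unremarkable fusty markers — this keeps the
defect classifiers identifiable instead of confounding them with grade.

Defects are drawn independently per defective (VOO/LOO) sample with
prevalences fusty 0.49, musty 0.29, rancid 0.44 — samples often carry
several. Because a virgin or lampante grade logically requires at least one
perceived defect, the vocabulary includes the winey-vinegary defect (drawn
at 0.35, and assigned whenever no other defect fires). This keeps the three
modeled defects exactly at their configured marginal prevalences while never
producing a defect-free VOO/LOO. Winey is part of the labels only; no
classifier is built for it.

A single `effect_scale` knob multiplies every contrast; `effect_scale=0`
collapses all classes onto one distribution, giving an exchangeable null
population on which any downstream classifier must perform at chance — the
test suite uses this to verify that apparent skill cannot come from the
pipeline itself.

All randomness flows from one integer seed through `numpy` seed sequences;
identical designs reproduce bit-identical labels and (at zero noise) maps.

## Feature extraction

Each drift spectrum (row at fixed retention time) is divided by its own RIP
apex — the common GC-IMS normalization dialect. Row-wise division makes
features dimensionless, idempotent under re-normalization, and exactly
invariant to any global intensity rescaling. A corrupt map (non-positive RIP
apex) is rejected with the offending retention time named.

Signal windows are nominal rt ± max(6 s, 1.5% · rt) and dt ± 0.08 ms; the
closest drift-time pair in the library (12.128 / 12.203 ms) is safely
separated because the compounds elute > 1200 s apart. The feature value is
the in-window maximum; an absent spot simply yields the in-window
baseline-level value — the 25-column matrix has no missing-value mechanism.
The windows of 1-octen-3-ol and 6-methyl-5-hepten-2-one overlap slightly in
both dimensions; the resulting few-percent cross-talk at high loads is
accepted as realistic spectral overlap (the two never co-occur in a
calibration mixture).

## Chemometrics

* **PLS1 / NIPALS** with X-deflation; weights unit-norm; per-component
  regression vectors `b_A = W_A (P_A' W_A)^{-1} q_A`. At full rank the
  predictions coincide with ordinary least squares, which the tests use as
  an oracle (alongside scikit-learn's implementation). Degenerate inputs
  (zero-variance X, exhausted covariance) raise.
* **Bayes threshold**: per-class Gaussians on calibration ŷ (ddof = 1),
  priors = class frequencies, threshold = the posterior-0.5 crossing found
  by Brent's method between the class means. Fallbacks: (near-)zero
  within-class variance, or no crossing between the means (possible under
  extreme priors or near-coincident classes), fall back to the midpoint of
  the class means and log the fact. Each class needs ≥ 3 calibration
  samples.
* **VIP** with unit-norm weights, so Σ VIP² = p holds identically.
* **Kennard-Stone**: distances are Euclidean on mean-centered features; the
  first two picks are the most distant pair, ties broken to the lowest
  index; the selection order is preserved so CV folds can be interleaved
  across the design space.
* **Venetian blinds**: fold f holds positions f, f+10, f+20, … of the
  calibration set in Kennard-Stone order; every fold refits the Bayes
  threshold; the selected component count is the smallest minimizer of the
  pooled misclassification rate (capped at 10 and at min(n−1, p)).
* **ROC/AUC** by threshold sweep with tied scores collapsed, trapezoid
  area; equals the Mann-Whitney U statistic normalized by n₁n₀.

## Screening cascade and evaluation

Scheme B (recommended): stage 1 isolates LOO; samples with stage-1
posterior ≥ 0.5 are lampante, the rest go to the EVOO-vs-VOO stage fitted
only on the stage-1 calibration rows of those two grades. The reported
probability is that of the deciding stage alone (no chaining), and the
confidence flag compares it with the user threshold (default 0.70).
External-validation rows never enter any fit, threshold, or
component-selection step. The evaluation report gives percent-correct per
category for calibration, cross-validation and external validation, external
ROC curves with the Bayes operating point, VIP per model, and the fraction
of samples of each category classified with probability above 0.70.

Kennard-Stone puts the most spread-out samples into calibration, and in a
strongly separated synthetic cohort those are disproportionately the
defective ones; external sets can therefore be short of (or even lack) a
rare class for some seeds, in which case the affected percentage is
undefined and omitted rather than imputed.

## Method performance

**Linearity.** Responses are raw (mV) monomer window maxima, matching how
calibration equations are expressed. The linear range is the widest
contiguous run of ≥ 4 dilution levels, starting from the lowest feasible
level, that (i) extends greedily while each next level stays within
max(3·s_pred, 5% · prediction) of the extrapolated line, (ii) achieves
R² ≥ 0.93, and (iii) shows actual response variation; ties go to the higher
R². The sequential prediction-residual stop is essential: the overall R² of
an over-extended run remains high long after saturation (a run reaching
five-fold past a sharp onset can still exceed 0.98), so R² alone cannot
localize the onset, while a pure relative-deviation rule would be blind to
noise. With the default settings, simulated 12/15-level series at 1% noise
recover all 15 slopes within 5% and every saturation onset within one
dilution step.

**Repeatability.** RSD% (100 · SD/mean, ddof = 1) of the raw maximum dimer
intensity of two markers per grade — (E)-2-hexenal and hexanal for EVOO,
ethanol and ethyl acetate for VOO, ethyl propanoate and 3-methyl-1-butanol
for LOO — over exactly 7 same-day replicates (intra) or 7 daily analyses
(inter). A flag switches to RIP-normalized values, which cancels the shared
day factor by construction.

## Problem sizes

The test suite and the acceptance script use: the default 198-sample study
on the full grid; 500-sample null cohorts on the coarse grid (two
independent cohorts, so chance-level AUC is measured on data no model ever
saw); 12/15-level dilution series; and 200 repeats of the 7-replicate
repeatability comparison on a trimmed grid (rt ≤ 450 s covers all six
markers). These sizes were chosen so every statistical band tested (AUC,
RSD, slope recovery) has comfortable margin at the configured noise levels.

## Limitations

The simulator reproduces the *structural* features the analysis relies on —
RIP normalization, spot geometry, calibration response, saturation, dimers,
the ghost signal, multiplicative noise, day effects — but not real
instrument physics: no retention/drift-time jitter or alignment errors, no
competitive ionization (analytes deplete the RIP independently), no
matrix effects between compounds, Gaussian spots without tailing, and
class-conditional log-normal chemistry rather than real olive-oil
biochemistry. Absolute concentration scales per grade are plausible
inventions calibrated only to produce realistic separations. Passing tests
therefore demonstrate correctness and internal consistency of the method,
not field performance on commercial oils; the headline percentages the
acceptance script prints characterize the synthetic cohort, and their
agreement with published screening studies is qualitative (lampante
detection easiest, EVOO-vs-VOO hardest).
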