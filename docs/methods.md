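# Methods

## Scope

`petkin` quantifies the binding of a receptor-targeted PET tracer from
dynamic time-activity curves (TACs): an arterial plasma input function, a
tissue curve per region, and per-animal metadata (injected dose, body
weight, implanted CD25+ cell count). The workflow mirrors a small-animal
xenograft study of an IL-2-based tracer: plasma modelling, compartment
fitting, graphical analysis, AIC model selection, SUV, cohort regression
and a limit-of-detection (LOD) calculation. All inputs are assumed
decay-corrected and calibrated; image reconstruction and metabolite
chromatography are out of scope (the tracer is stable in plasma, so total
plasma activity serves as the input function without metabolite
correction).

Canonical units: minutes, kBq/ml, MBq injected dose, grams body weight,
cell counts in units of 10^6. Times are frame midpoints.

## Input function

Plasma clearance after an i.v. bolus is modelled as a biexponential,

    Cp(t) = A [ f e^(-λ1 t) + (1-f) e^(-λ2 t) ],    λi = ln 2 / t½,i

with `f` the *amplitude* fraction of the fast (distribution) phase. The
literature this emulates reports clearance fractions as percentages of
injected activity; whether those are amplitude or dose fractions is
ambiguous, and amplitude fractions are implemented here. Fitting uses
bounded trust-region least squares started from exponential peeling
(log-linear tail fit for the slow phase, peeled residual for the fast
phase); results are always reported with phases ordered by half-time. A
minimum of 5 samples is required; the 14-point arterial sampling schedule
(15 s – 60 min) identifies both phases to better than 0.1% without noise.

The bolus is treated as instantaneous: activity is zero before t = 0 and
the fitted curve is anchored at the first sample (the true plasma peak
occurs before the first draw and is not modelled). Sampled plasma curves
are interpolated piecewise-linearly with zero activity assumed before the
first sample; running integrals of a fitted biexponential are evaluated in
closed form.

## Compartment models

Two reversible configurations are supported: one-tissue (1TCMR; K1, k2)
and two-tissue (2TCMR; K1, k2, k3, k4). The tissue curve is the
convolution of the input with the impulse response; for the 2TCMR the
response is a sum of two exponentials with eigen-rates

    θ1,2 = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)] / 2 ,

always real and nonnegative since the discriminant equals
(k2−k4)² + k3² + 2k3(k2+k4). Convolution with a biexponential input is
evaluated exponential-by-exponential in closed form; a sampled input is
handled by exact per-segment integration of its piecewise-linear
interpolant, so no result depends on an auxiliary grid. Setting k4 = 0
yields the irreversible trapping mode used to validate Patlak analysis;
it is a simulation mode only, not a production fit model. No blood-volume
fraction term is modelled (vB = 0).

Derived measures are constructed from the fitted rates, never re-derived:
Vd = K1/k2 (1TCMR) or (K1/k2)(1+BP) with BP = k3/k4 (2TCMR).

Fitting is bounded nonlinear least squares (rates in [10⁻⁴, 50]) with
three starts — a fixed physiological heuristic, the geometric mid-bounds
point, and a perturbed heuristic — keeping the lowest-RSS solution.
Weights are uniform by default; optional √(frame duration) weighting is
available as a count-statistics surrogate. Model comparison uses the
Gaussian-likelihood AIC, n ln(RSS/n) + 2p, without small-sample
correction; only the preference order between models on identical data is
meaningful, not the absolute AIC magnitude (which depends on frame count
and the AIC variant). Ties are reported explicitly.

## Graphical analyses

Logan: OLS of ∫Ct/Ct against ∫Cp/Ct for t ≥ t* (default 3 min); the slope
estimates Vd for reversible binding. Patlak: OLS of Ct/Cp against ∫Cp/Cp
for t ≥ t* (default 15 min); the slope estimates the influx constant
Ki = K1k3/(k2+k3) for irreversible trapping. The sample at exactly t* is
included. R² is computed on the transformed points. Ordinary (not total)
least squares is used — the canonical published form of both analyses.
`choose_t_star` automates the delay-time inspection: it returns the
smallest sample time past which the maximum residual of the linear fit,
scaled by the span of the transformed ordinate, falls below a threshold
(default 10%). The span scaling keeps the criterion defined where the
ordinate crosses zero.

## Quantification

SUV = tissue concentration (MBq/g) / [dose (MBq) / weight (g)], with unit
tissue density (1 g/ml) assumed when converting from kBq/ml. Cohort
correlations are simple OLS regressions of a PET measure on the CD25+
cell count; the p-value is the regression F-test (identical to the slope
t-test in simple regression), and a correlation is flagged significant
when R² > 0.5 and p < 0.05. The LOD is the mean control-tissue BP plus
2 sample standard deviations (n−1 denominator; conservative for small
control groups), inverted through the BP-versus-cells line to a minimum
detectable cell number, reported at two significant figures.

## ROI tools

Lesion delineation on a dynamic volume: all frames are summed (optionally
duration-weighted, which yields the time integral), a region is grown from
the hottest voxel keeping voxels strictly above 50% of the maximum inside
the grown region (the reference maximum is iterated to a fixpoint, so the
threshold tracks the lesion maximum rather than the seed), and the mask is
applied to the original frames to read out the mean TAC. Connectivity is
6-neighbour (faces only) by default — the stricter, reproducible choice —
with 18/26 configurable. The relative threshold makes the mask invariant
under global intensity rescaling. Volumes and masks round-trip through
NIfTI.

## Synthetic cohort generator

The generator emulates the statistical structure of an 11-animal rat
cohort with subcutaneous lesions of 0.17–1.9 × 10⁶ CD25+ cells:

* **Plasma**: biexponential with amplitude fraction 0.25 and half-times
  0.71 / 8.4 min, sampled at the 14 blood-draw times. The t = 0 amplitude
  default of 800 kBq/ml corresponds to a ~17 MBq dose diluted in roughly
  20 ml of rat plasma volume and is scaled per animal by the actual dose.
* **Lesions**: 2TCMR curves on a 24-frame/60-min schedule (6×30 s,
  6×1 min, 6×2.5 min, 6×6 min) whose true binding potential follows
  BP = 4.06·cells + 0.17; k3 = BP·k4.
* **Cohort**: cell counts log-uniformly spaced across the printed range
  (endpoints included, so the regression design is deterministic); doses
  from a truncated normal 17.1 ± 1.2 MBq; weights 300 ± 25 g. Control
  regions are null lesions simulated at 0 cells (BP equal to the
  nonspecific intercept).
* **Noise**: multiplicative Gaussian. For framed tissue curves the CV is
  scaled by the inverse square root of the relative frame duration, a
  standard surrogate for PET count statistics. Generators are
  bit-reproducible under a fixed seed and every record carries its
  generating ground truth.

### Rate-constant defaults and calibration

The base rates K1 = 0.125 ml·cm⁻³·min⁻¹, k2 = 0.25 min⁻¹, k4 = 0.12 min⁻¹
were chosen, once, to satisfy simultaneously: (a) nonspecific distribution
volume K1/k2 = 0.5, the value observed for zero-cell uptake; (b) a
one-phase lesion washout half-time near 37 min at mid-cohort cell counts
(the default gives 31 min); (c) Logan slope within 2% of the analytic Vd
at a 3-min delay over a 60-min window with R² ≥ 0.97, and Patlak R² below
Logan R² on the same reversible curve; and (d) identifiability of BP from
a 4-parameter fit at the default noise level. These constraints pull
against each other — slower washout pushes the slow eigen-rate down, which
both biases the finite-window Logan slope and flattens the likelihood in
the (K1/k2, k3) direction — so the defaults are a deliberate compromise,
and all are exposed as tunable fields of `CohortSpec`.

The tissue noise CV default is 0.5% (plasma 2%). This is an ROI-mean
noise level, appropriate for averaging over a ~200 µl lesion; at ≥1% CV
the 2TCMR binding potential of high-BP animals becomes practically
unidentifiable within a 60-min scan (the global least-squares optimum can
sit at a near-one-tissue solution far from the generating rates even
though the total Vd is well determined), which would say more about
4-parameter fit pathology than about the pipeline. The default keeps BP
estimable while still exercising noise-dependent behaviour (AIC
preference, regression scatter).

### What the generator does not emulate

Plasma peak shape before the first sample; frame-to-frame correlated
noise; partial-volume effects on real lesions (only the Gaussian-blur
phantom exercises this qualitatively); inter-animal kinetic heterogeneity
beyond the BP–cells line (K1, k2, k4 are identical across animals); cell
migration out of the lesion. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to every property of real scanner data.

## Pipeline

`run_pipeline` composes the stages per animal (input fit → both
compartment fits → AIC comparison → Logan/Patlak → SUV → control fit) and
at cohort level (regressions of SUV/Vd/BP on cells, LOD from control
BPs). Any per-animal stage failure is recorded and the run continues —
partial results are a contract, not an accident. Reports (per-animal CSV,
regressions CSV, LOD block, structured log with config hash) are
byte-identical across reruns with the same inputs. With fewer than 3
usable animals, regressions are skipped with an explicit notice while
per-animal fits are still emitted.

## Numerical choices

* Near-coincident eigen-rates in the convolution use the t·e^(−λt) limit
  (threshold 10⁻¹⁰ relative); θ = 0 (irreversible) uses the exact
  (1−e^(−λt))/λ form.
* RSS of numerically perfect fits is floored at 10⁻³⁰⁰ before the AIC log.
* Optimizer tolerances are 10⁻¹² (compartment) and 10⁻¹⁴ (exponential)
  on xtol/ftol/gtol; bounds keep all rates positive.
* Simulated tissue values are clipped at 0 (concentrations are
  nonnegative by construction).
* TAC text I/O writes 17 significant digits and reads with round-trip
  float parsing, so write∘read is the identity.

## Problem sizes

Simulation studies in the tests and the acceptance script use 100
replicates for plasma-fit recovery, 20 replicate cohorts (11 animals
each) for noisy slope recovery, and 20–25 replicates for AIC preference —
sizes at which the Monte-Carlo error is comfortably below the tolerances
being asserted.

## Known limitations

* BP identifiability degrades sharply with noise for slow-washout
  kinetics; real studies mitigate this with longer scans, population
  constraints, or coupled fitting, none of which are implemented.
* Absolute AIC values are not comparable across software; only
  within-dataset preference order is reproduced.
* The Logan estimate carries the well-known noise-dependent negative bias;
  no multilinear bias-corrected variant is provided.
* No partial-volume correction, no blood-to-plasma ratio modelling, no
  dispersion/delay correction of the sampling line.
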