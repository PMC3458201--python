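# petkin

Kinetic analysis of dynamic PET time-activity curves, built around the
quantification of a receptor-targeted tracer in small-animal inflammation
imaging: an IL-2-based radioligand binding CD25, the α-subunit of the
IL-2 receptor overexpressed on activated T lymphocytes. Given an arterial
plasma curve, tissue curves and per-animal metadata, the package answers
the question a molecular-imaging scientist actually asks: *how many
activated lymphocytes are in this lesion, and what is the smallest number
the scan can detect?*

## What it computes

* **Input function** — biexponential plasma clearance
  `Cp(t) = A[f·e^(−λ₁t) + (1−f)·e^(−λ₂t)]`, fitted by bounded least
  squares with exponential-peeling starts.
* **Compartment models** — reversible one-tissue (1TCMR: K1, k2) and
  two-tissue (2TCMR: K1, k2, k3, k4) fits via closed-form convolution,
  with distribution volume `Vd = K1/k2·(1+BP)` and binding potential
  `BP = k3/k4`, compared by the Akaike information criterion
  `AIC = n·ln(RSS/n) + 2p`.
* **Graphical analyses** — Logan (slope = Vd, delay 3 min) and Patlak
  (slope = Ki = K1k3/(k2+k3), delay 15 min) plots with automated
  delay-time selection.
* **Quantification** — SUV, cohort regressions of SUV/Vd/BP against the
  implanted CD25+ cell count (significant when R² > 0.5 and p < 0.05),
  and the limit of detection: mean control-tissue BP + 2 SD, inverted
  through the BP-versus-cells line to a minimum detectable cell number.
* **ROI tools** — 50%-threshold region growing on summed dynamic volumes
  and TAC extraction.
* **Synthetic cohorts** — a seeded generator emulating an 11-animal rat
  xenograft study (lesions of 0.17–1.9 × 10⁶ CD25+ cells, doses
  17.1 ± 1.2 MBq, true BP = 4.06·cells + 0.17), so the full pipeline is
  testable without any data download.

The fit-shaped operations are also exposed as scikit-learn style
estimators (`BiexponentialInput`, `CompartmentModel`, `LoganPlot`,
`PatlakPlot`) with `fit`/`predict`, `get_params`/`set_params` and
trailing-underscore fitted attributes, so they compose with sklearn
tooling.

## Worked example

Generate a synthetic cohort at the default study conditions and run the
full analysis:

```python
from petkin import AnalysisConfig, CohortSpec, make_cohort, run_pipeline, write_report

cohort = make_cohort(CohortSpec(seed=5))
report = run_pipeline(cohort, AnalysisConfig())
write_report(report, "report")
print(open("report/summary.txt").read())
```

prints

```
cohort analysis summary
=======================
suv vs cells: slope=2.641 intercept=0.2538 R2=0.985 p=1.75e-09 significant
vd_2tc vs cells: slope=1.967 intercept=0.5975 R2=1.000 p=1.93e-17 significant
logan_vd vs cells: slope=1.939 intercept=0.5878 R2=1.000 p=4.48e-17 significant
bp vs cells: slope=4.752 intercept=-0.1604 R2=0.993 p=6.36e-11 significant
model preference (AIC): {'2TCMR': 11}
LOD: control BP 0.47 +/- 0.23 -> BP 0.92 -> ~230,000 cells
```

Reading this: every PET measure correlates with the implanted cell count,
but SUV and Vd carry a nonspecific offset (intercepts ≈ 0.25 and ≈ 0.59 —
uptake present even with zero target cells), while the BP line passes
near the origin, which is why BP is the preferred specific measure. AIC
selects the two-tissue reversible model for all 11 animals. The control
(uninflamed) shoulder shows background BP 0.47 ± 0.23; mean + 2 SD gives
a detection threshold of BP 0.92, and inverting the fitted BP-versus-cells
line puts the smallest reliably detectable lesion at roughly 2 × 10⁵
activated cells. At this noise level the BP regression slope scatters
around the generating value of 4.06 from cohort to cohort — binding
potential from a 4-parameter fit is the least stable of the reported
measures (see `docs/methods.md`).

The same workflow is available from the shell:

```bash
petkin simulate --out cohort --seed 5
petkin run cohort/cohort.csv --out report
petkin logan cohort/rat06_lesion.csv cohort/rat06_plasma.csv --t-star 3
```

## Layout

```
src/petkin/
  tac.py             TAC/cohort containers, CSV I/O, units
  input_function.py  biexponential input model + estimator
  compartment.py     1TCMR/2TCMR simulation, fitting, AIC
  graphical.py       Logan and Patlak analyses
  quantify.py        SUV, regression, limit of detection
  roi.py             region growing, frame summation, TAC extraction
  simulate.py        synthetic cohort and phantom generators
  pipeline.py        cohort orchestration and reports
  cli.py             command-line interface
docs/methods.md      model assumptions, calibration, limitations
```
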