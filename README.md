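# cocompare

Method-comparison statistics for cardiac-output monitors validated against
transthoracic echocardiography:

* **Hemodynamics** — Mosteller body surface area, cardiac index, Doppler
  stroke volume (aortic cross-section × VTI), replicate-trace averaging.
* **Agreement** — Bland–Altman bias, precision, limits of agreement (LoA)
  with 95% CIs, mean percentage error (MPE) against the 30% criterion, plus
  four robustness checks: Shapiro–Wilk normality with percentile LoA,
  repeated-measures variance-component correction, combined repeatability,
  and a mixed-model proportional-bias slope.
* **Trending** — between-timepoint change pairs, four-quadrant concordance
  with a central exclusion zone, and polar-plot statistics (mean polar
  angle, angular sd, radial LoA).
* **Simulation** — a synthetic paired-study generator with known ground
  truth (per-timepoint means, patient-level shifts, device bias,
  proportional bias, per-method noise, replicate echo traces, missingness),
  fully seeded and bit-reproducible.
* **Reporting** — an assembled validation report with interchangeability
  and trending verdicts, canonical JSON / text renderings, and functional
  Bland–Altman, four-quadrant and polar plots.

Packaged fixtures encode the study's per-timepoint cardiac-index summary
grid and the cohort biometric profile.

## CLI

```sh
# simulate a study and write a long-format pairs CSV
cocompare simulate --n-patients 55 --seed 17 --bias 0.02 \
    --sigma-ref 0.14 --sigma-test 0.14 --missing-rate 0.00727 \
    --out pairs.csv --echo echo.csv

# agreement analysis with robustness checks
cocompare agree --pairs pairs.csv --z 1.96 --mpe-threshold 30 --out report.json

# trending analysis
cocompare trend --pairs pairs.csv --zone-fraction 0.15 --polar-scale 1.5 \
    --policy consecutive_only --out trend.json

# all-in-one report (JSON + text summary + three plots)
cocompare report --pairs pairs.csv --out-dir out/
```

`pairs.csv` columns: `patient_id,timepoint,method,co_l_min` with optional
`height_cm,weight_kg` (cardiac output is then indexed by Mosteller BSA) and
an optional explicit `ci_l_min_m2` column used for lossless round-trips.
`method` is `test` or `reference`; timepoints are labelled 1–5.

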