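# graftsize

Pre-operative prediction of hamstring autograft diameter for ACL
reconstruction, and the statistics used to validate such a prediction rule.

When an anterior cruciate ligament is reconstructed with a doubled
semitendinosus + gracilis (ST + GT) four-strand graft, the final graft
diameter is patient-dependent and only known intraoperatively — yet grafts
thinner than 8 mm carry a higher re-rupture risk, so surgeons want the size
before deciding on the graft. The rule implemented here predicts it from
measurements that already exist: the tendons' major (D) and minor (d)
cross-sectional diameters on the diagnostic knee MRI (0.1-mm resolution).

The predicted graft diameter (PGD) is

```
PGD = (D_St + d_St)/2 + (D_Gr + d_Gr)/2 ,   rounded UP to the next full mm
```

The ceiling rounding is deliberate: a graft fits through a bigger tunnel
but not a smaller one. Because inputs carry one decimal, each tendon mean
is exact at two decimals and no intermediate rounding occurs (the package
does all of this in integer tenths/hundredths of a mm).

For validating such a rule against surgical reports the package provides:

* **agreement** — concordant / under- / over-prediction classification,
  exact (Clopper–Pearson) binomial confidence intervals, and linearly
  weighted Cohen's κ over the integer-mm grid, with the McHugh verbal band
  applied to κ rounded to two decimals;
* **reproducibility** — Bland–Altman bias and coefficient of repeatability
  (CoR = 1.96 × SD of paired differences) for intra-reader (t0 vs 1 month)
  and inter-reader (reader 1 vs 2) comparisons, per tendon;
* **descriptives** — median/IQR summaries and the Wilcoxon signed-rank
  comparison of predicted vs actual sizes;
* **synthetic cohorts** — a seeded generator producing study-structured
  data (2 readers × 2 sessions × 2 tendons per patient, 0.1-mm quantized
  measurements, reader noise, integer surgical sizes concentrated on
  7–9 mm) so the whole pipeline is testable without patient data.

## Worked example

```bash
graftsize simulate --out cohort.csv --seed 42
graftsize report cohort.csv --json report.json --markdown report.md --no-timestamp
```

`report.md` then reads (numbers printed by the code):

```
Patients: 92 (M 72 / F 20; left 56 / right 36)
Median predicted (raw) 7.45 mm (IQR 7.04–7.80 mm)
Median actual 8.00 mm (IQR 7.00–8.00 mm)

Concordance: 78/92 85% (95% CI 76–91%)
Under-prediction: 6/92 7% (95% CI 2–14%)
Over-prediction: 8/92 9% (95% CI 4–16%)
Linearly weighted κ = 0.77 (Moderate)
Wilcoxon signed-rank (rounded predicted vs actual graft diameter): n.s.

ST intra-reader: bias -0.00 mm, CoR 0.07 mm
GT intra-reader: bias 0.00 mm, CoR 0.07 mm
```

Reading: in this simulated 92-patient cohort the rounded prediction equals
the surgical size in 78/92 cases (85%, exact 95% CI 76–91%); when it
misses, it is mostly off by a single millimetre, and repeated MRI readings
of the same tendon agree to within ±0.07 mm (95% of differences). The same
statistics can be computed for any cohort CSV in the documented schema
(`patient_id, age_years, sex, side, actual_graft_mm, reader, session,
tendon, major_mm, minor_mm`, one measurement per row).

The same pipeline is available as a library:

```python
import graftsize as gs

cohort = gs.simulate_cohort(gs.calibrated_default_config(seed=42))
report = gs.build_report(cohort)          # plain dict, JSON-serialisable
print(report["agreement"]["kappa"])
```

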