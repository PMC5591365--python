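# gbmgrade

Surgical-complexity grading of supratentorial glioblastoma (GBM) from
pre-operative MRI, for neurosurgeons and imaging researchers who need a
simple, objective, reproducible description of tumour anatomy in
comparative-effectiveness work.

Five features of the contrast-enhancing tumour (CER) on contrast-enhanced
T1-weighted MRI each score one point:

1. **periventricular or deep location** — CER within 10 mm of the ventricles
   (strictly less than 10 mm scores the point);
2. **corpus callosum or bilateral location** — CER extends into the corpus
   callosum or crosses the midsagittal plane;
3. **eloquent location** — CER extends into motor/sensory cortex, language
   cortex, insula or basal ganglia;
4. **size** — maximal diameter ≥ 40 mm;
5. **associated oedema** — oedema extending ≥ 10 mm beyond the CER margin.

The total score S = Σᵢ xᵢ ∈ {0,…,5} stratifies lesions into **low (0–1)**,
**moderate (2–3)** and **high (4–5)** complexity. The package measures the
features from co-registered binary segmentation masks (NIfTI-1), applies
the score, and reproduces the cohort-validation statistics: feature
prevalence and grade-by-outcome tables, Pearson χ² association tests
(grade vs. complete resection, grade vs. major complication = Clavien-
Dindo > 3a), and two-rater agreement via Cohen's κ = (p₀ − pₑ)/(1 − pₑ)
with its large-sample standard error. Synthetic phantoms with analytic
ground truth and seeded cohort simulators provide all test data. See
`docs/methods.md` for model details and limitations.

## Worked example

```python
from gbmgrade import (PhantomSpec, make_phantom, extract_features, grade,
                      cohort_from_outcome_counts, summarize_grades, crosstab,
                      pearson_chi2)

# a synthetic subject: 44 x 28 x 20 mm ellipsoid tumour, 6 mm from the
# ventricles, 12 mm oedema shell, inside eloquent cortex
phantom = make_phantom(PhantomSpec(semi_axes_mm=(22, 14, 10), ventricle_gap_mm=6,
                                   oedema_thickness_mm=12, eloquent_overlap=True))
feats = extract_features(phantom.tumour, phantom.oedema, phantom.atlas)
result = grade(feats)
print(f"diameter {feats.max_diameter_mm:.1f} mm, "
      f"ventricle distance {feats.ventricle_distance_mm:.1f} mm")
print(f"score {result.score} -> {result.complexity} complexity")
```

```
diameter 43.3 mm, ventricle distance 6.0 mm
score 4 -> high complexity
```

The tumour collects points for location (6 < 10 mm), eloquence, size
(43.3 ≥ 40 mm) and oedema (12 ≥ 10 mm) — four points, a high-complexity
lesion.

Cohort analysis on the 88-patient validation table (14 low / 45 moderate /
29 high):

```python
cohort = cohort_from_outcome_counts()
print(summarize_grades(cohort).to_string(index=False))
work = cohort.assign(complete_resection=cohort.complete_resection.astype(bool))
res = pearson_chi2(crosstab(work, "complexity", "complete_resection"))
print(f"chi2 = {res.statistic:.2f}, df = {res.df}, p = {res.p:.4f}")
```

```
complexity  n  complete_resection_n  complete_resection_pct  major_complication_n  major_complication_pct
       low 14                     7                    50.0                     0                     0.0
  moderate 45                     7                    15.6                     1                     2.2
      high 29                     1                     3.4                     2                     6.9
     total 88                    15                    17.0                     3                     3.4
chi2 = 14.61, df = 2, p = 0.0007
```

Complete resection falls from 50.0% of low-complexity lesions to 3.4% of
high-complexity ones, and the association is significant at p = 0.0007.

## Command line

```sh
gbmgrade simulate-phantom --out-dir phantoms/sub01 --gap 12 --oedema-thickness 15
gbmgrade extract phantoms/ --out features.csv
gbmgrade grade features.csv --out graded.csv
gbmgrade summarize cohort.csv --out-dir summaries/
gbmgrade agreement cohort.csv --out kappa.json
gbmgrade simulate-cohort --n 88 --seed 1 --rater-flip 0.1 --out cohort.csv
```

Masks are NIfTI-1, tables are CSV (booleans as 0/1), statistics are JSON;
`--config` accepts a YAML file whose values CLI flags override.

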