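# hipshape

Statistical shape modelling of the hip from DXA landmark data, with
radiographic osteoarthritis (OA) outcome construction and
covariate-adjusted association analysis.

## What problem this solves

Hip morphology — in particular cam-type (aspherical femoral head–neck
junction) and pincer-type (acetabular over-coverage) variation — is a
suspected contributor to hip OA. Quantifying it from 2D DXA
projections uses the classic statistical shape model (SSM): an ordered
set of P = 58 landmark points per hip is superimposed by generalized
Procrustes analysis (removing translation, rotation and scale), and
principal component analysis of the aligned coordinates yields
independent **hip shape modes** (HSMs). Each individual's score on
mode j is expressed in cohort SD units:

    x_i  ≈  x̄ + Σ_j  b_ij · v_j ,      z_ij = (b_ij − mean_j) / sd_j

where v_j are the orthonormal eigenvectors and x̄ the Procrustes mean.
Radiographic hip OA (RHOA) is defined from component grades
(osteophytes, joint space narrowing, sclerosis, cysts, head deformity)
through the Croft 0–5 aggregate, with Croft ≥ 2 the primary case
definition. Associations are estimated per mode as odds ratios per SD
from logistic regression (binary outcomes) or proportional-odds
regression (WOMAC 0–20), unadjusted and adjusted for age, height,
weight and race, with a Bonferroni threshold of 0.05/10 = 0.005 for
the ten top-variance modes.

The package is aimed at biostatisticians and musculoskeletal
epidemiologists who need a tested, reproducible implementation of this
pipeline. Because no landmark-level cohort is publicly deposited, it
ships a synthetic cohort generator with *planted* cam/pincer
deformation fields and known effect sizes, so every stage — alignment,
mode fitting, scoring, outcome grading, regression — can be verified
end to end against ground truth.

## Worked example

```python
import numpy as np
from hipshape import (SimulationConfig, generate_cohort, gpa,
                      fit_shape_model, score_shapes, flag_outliers,
                      run_association_battery)
import pandas as pd

cohort = generate_cohort(SimulationConfig(n=4100, seed=7))
aligned = gpa(cohort.landmarks)                  # Procrustes superimposition
model = fit_shape_model(aligned, k=10)           # PCA point-distribution model
scores = score_shapes(model, aligned)            # SD-unit mode scores

print(f"converged in {aligned.iterations} iterations")
print(f"top-10 modes explain {model.variance_explained():.1f}% of variance")
print(f"{len(flag_outliers(scores))} scores beyond 4 SD flagged for review")

scores_df = pd.DataFrame([s.scores for s in scores],
                         columns=[f"mode_{j+1}" for j in range(10)])
scores_df.insert(0, "image_id", [s.image_id for s in scores])
outcomes = cohort.readings.merge(cohort.pain, on="image_id")
results = run_association_battery(scores_df, outcomes, cohort.covariates)
top = results.query("outcome == 'rhoa_croft2' and adjusted") \
             .nsmallest(3, "p")[["exposure", "or", "ci_low", "ci_high", "p"]]
print(top.round(4).to_string(index=False))
```

prints (about half a minute; the full battery is 340 regression cells)

```
converged in 3 iterations
top-10 modes explain 80.5% of variance
2 scores beyond 4 SD flagged for review
exposure     or  ci_low  ci_high      p
  mode_2 1.3036  1.1532   1.4735 0.0000
  mode_1 0.8217  0.7282   0.9273 0.0015
  mode_9 1.1223  0.9944   1.2667 0.0616
```

The alignment converges in a few iterations; the ten retained modes
carry ~81% of total shape variance (the four planted deformation
fields dominate, the remainder is landmark noise). The battery output
is one row per (mode × outcome × adjustment). Here fitted mode 2 has
absorbed the planted cam-like field (adjusted OR 1.30 per SD against
the planted 1.37) and fitted mode 1 the pincer-like field with its
eigenvector sign flipped, so its OR sits on the inverse side (0.82 ≈
1/1.23) — exactly how a mode can be "negatively associated" with a
deformity. Both survive the Bonferroni threshold of 0.005; the
nuisance and noise modes do not.

A full run — simulation, alignment, model fit, ±2 SD mode-shape SVGs,
outcome grading, association battery, run log — is one command:

```bash
hipshape run --out-dir demo_run --n 500 --seed 1
```

Other subcommands (`hipshape simulate / validate / align / fit / score /
reconstruct / qc / outcomes / associate`) expose each stage separately
over CSV/JSON files; see `hipshape --help`.

## Layout

- `src/hipshape/io.py` — landmark configurations, template, CSV/JSON I/O,
  left-to-right mirroring
- `src/hipshape/procrustes.py` — pairwise and generalized Procrustes
  (`GeneralizedProcrustesAlignment`)
- `src/hipshape/model.py` — PCA point-distribution model
  (`PointDistributionModel`), SD-unit scoring, reconstruction, outlier flags
- `src/hipshape/qc.py` — inter-operator placement accuracy (≤ 3 px rule)
- `src/hipshape/outcomes.py` — Croft grading, RHOA definitions, binary
  features, pain outcomes, prevalence arithmetic
- `src/hipshape/association.py` — logistic / proportional-odds OR per SD,
  Bonferroni, the association battery
- `src/hipshape/simulate.py` — template, planted deformation fields,
  synthetic cohorts with calibrated outcome models
- `src/hipshape/pipeline.py`, `src/hipshape/cli.py` — orchestration and the
  `hipshape` command

See `docs/methods.md` for the modelling assumptions, numerical choices
and the generator's design in detail.
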