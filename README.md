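# dentage

Dental age estimation from tooth developmental staging, for forensic
odontology and pediatric dentistry workflows: given per-tooth stage
readings of the seven left mandibular permanent teeth (FDI 31–37) from a
panoramic radiograph, estimate a child's dental age (DA) and quantify how
well an estimation method agrees with chronological age (CA).

The package implements:

* **Demirjian and Nolla scoring** — stage vocabularies (A–H; 0–10 with
  fractional readings), sex-specific maturity/sum scores, and score→age
  conversion by interpolation in age-norm tables;
* **a sex-specific quadratic calibration** — the "new method": fit
  `S = a + b·CA + c·CA²` to Nolla sum scores by least squares per sex and
  estimate DA by the analytic inverse
  `DA = v − sqrt((S_v − S)/(−c))` on the rising branch of the curve
  (vertex `v = −b/(2c)`, maximum `S_v = a − b²/4c`), with conversion-table
  export. Reference coefficients: males `S = 4.916 + 7.783·CA − 0.232·CA²`,
  females `S = −2.751 + 9.785·CA − 0.331·CA²`;
* **the agreement-evaluation protocol** — per sex × 1-year age group:
  mean CA/DA, MD = mean(DA − CA) with SD and 95% CI, MAD = mean|DA − CA|,
  a Kolmogorov–Smirnov-gated paired t / Wilcoxon signed-rank test (exact
  under ties for n ≤ 25), and Cohen's kappa for observer agreement;
* **a synthetic cohort generator** — a 535-child study design (nine 1-year
  bins × sex, 7:3 train/test split) whose Nolla sums follow the
  sex-specific quadratics plus noise, used to exercise the pipeline end to
  end.

See `docs/methods.md` for the model, assumptions, and limitations —
notably that the packaged Demirjian/Nolla lookup tables are synthetic
surrogates with the correct structure, not the historical norms.

## Worked example

```python
import numpy as np
from dentage import (GeneratorConfig, generate_cohort, split_train_test,
                     fit_quadratic, estimate_da_new_method, evaluate_method)
from dentage.io import records_from_frame

config = GeneratorConfig(seed=42)
cohort = generate_cohort(config)                      # 535 subjects
train, test = split_train_test(cohort, config.design, seed=42)

models = {}
for sex in ("male", "female"):
    sub = train[train.sex == sex]
    models[sex] = fit_quadratic(list(zip(sub.ca_years, sub.nolla_sum)), sex=sex)
    m = models[sex]
    print(f"{sex}: score = {m.a:.3f} + {m.b:.3f}*CA {m.c:+.3f}*CA^2   R^2 = {m.r_squared:.3f}")

test = test.assign(da_new=[e.age for e in
                           estimate_da_new_method(records_from_frame(test), models)])
report = evaluate_method(test, da_col="da_new")
totals = report[report.age_group == "total"]
print(totals[["sex", "n", "md", "mad", "p_value", "test_used"]].round(3).to_string(index=False))
```

prints

```
male: score = 4.115 + 8.094*CA -0.254*CA^2   R^2 = 0.901
female: score = -2.995 + 9.823*CA -0.337*CA^2   R^2 = 0.913
   sex   n    md   mad  p_value test_used
  male  89 0.070 0.738    0.503  paired_t
female  88 0.126 0.848    0.327  paired_t
   all 177 0.098 0.793    0.561  wilcoxon
```

The fitted coefficients recover the generating curves to within sampling
noise (R² ≈ 0.9 at the default score-noise SD of 2.5). On the held-out
test split the calibrated method is nearly unbiased — grand-total MD of
0.098 yr, not significantly different from zero (p = 0.56) — while MAD
(0.79 yr) reflects the noise the generator injects, concentrated in the
oldest age bins where the score–age curve is nearly flat.

The same pipeline is available from the shell:

```bash
dentage simulate --seed 42 --out cohort.csv
dentage score     --in cohort.csv --out scored.csv
dentage calibrate --in scored.csv --out-dir models/
dentage estimate  --in scored.csv --models models/ --out estimated.csv
dentage evaluate  --in estimated.csv --da-column da_new --split test --out report.csv
dentage tables    --models models/ --out-dir tables/
```

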