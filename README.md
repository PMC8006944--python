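# ocmm — Oral C-peptide Minimal Model toolkit

Model-based assessment of pancreatic insulin secretion from oral-test
(OGTT/MMTT) C-peptide data, aimed at populations — such as
post-gastric-bypass patients with postprandial hyperinsulinemic
hypoglycemia (PHH) — in which standard population kinetics may not
apply.

C-peptide is co-secreted with insulin but not cleared by the liver, so
its plasma concentration is the standard window onto β-cell secretion.
The package implements the oral C-peptide minimal model (OCMM): linear
two-compartment kinetics

```
dCP1/dt = -(k01 + k21)·CP1 + k12·CP2 + SR(t)      CP1(0) = 0
dCP2/dt =  k21·CP1 - k12·CP2                      CP2(0) = 0
SR(t)   =  Y(t) + k_d·max(dG/dt, 0)
dY/dt   = -α·[Y - β·(G(t) - h)]                   Y(0) = 0
```

with the β-cell responsivity indices Φ_s = β, Φ_d = k_d,
Φ_b = k01·CP1b/G_b and the total index
Φ_tot = [Φ_d(G_max−G_b) + Φ_s∫(G−h)dt + T·Φ_b·G_b] / ∫G dt (T = 300 min),
all on the conventional 10⁻⁹ scale.

Subject-level parameters are estimated by Bayesian maximum a posteriori
under three prior regimes:

* **VC** — C-peptide kinetics (k01, k12, k21) fixed to the Van Cauter
  population model (predicted from age and normal/obese/NIDDM class);
  only the secretion parameters are estimated.
* **DB** — all six parameters estimated from the data, with log-normal
  kinetic priors centred at the Van Cauter prediction.
* **PHH** — as DB, with a joint empirical cohort prior for the
  kinetics.

The package also ships the supporting machinery: a regularized
(Tikhonov/discrepancy) estimator of the glucose time derivative, a
synthetic post-bypass cohort generator (early glucose peak, late
below-basal nadir, kinetics faster than the population prediction), and
an in-silico parameter-recovery study that scores the three approaches
by MARD with Kruskal–Wallis / Dunn–Šidák comparisons. See
`docs/methods.md` for the full model and design notes.

## Worked example

```python
import numpy as np
from ocmm import fit_subject, FitConfig
from ocmm.synthetic import cohort1_spec, generate_cohort

records, truths = generate_cohort(cohort1_spec(n_subjects=1, seed=3))
rec, tru = records[0], truths[0]

fit = fit_subject(rec, "DB", config=FitConfig(n_starts=3))
print(f"true MCR  {tru.kinetics.k01:.4f} min^-1")
print(f"fit  MCR  {fit.estimates['k01']:.4f} min^-1 "
      f"(CV {fit.cv_percent['k01']:.0f}%)")
print(f"phi_tot   {fit.indices.phi_tot:.1f} x10^-9 min^-1")
```

prints

```
true MCR  0.0640 min^-1
fit  MCR  0.0617 min^-1 (CV 10%)
phi_tot   20.3 x10^-9 min^-1
```

— the generated subject clears C-peptide ~13% faster than the Van
Cauter prediction for its demographics (0.0568 min⁻¹); the data-based
fit recovers most of that excess clearance from the C-peptide data
alone, with ~10% precision on the clearance estimate, and a total
β-cell responsivity in the expected post-bypass range.

The same pipeline is available from the shell:

```bash
ocmm synth --cohort 1 --seed 3 --out cohort/        # subject CSVs + truths.json
ocmm fit cohort/S01.csv --approach db --out fits/   # FitResult JSON + tidy CSV
ocmm insilico --replicates 5 --seed 1 --out study/  # MARD tables + summary
ocmm report study/mard_table.csv                    # markdown median [IQR] table
```

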