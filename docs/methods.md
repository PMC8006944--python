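# Methods

## The model

Plasma C-peptide is secreted equimolarly with insulin and is not
extracted by the liver, so its plasma concentration is the standard
window onto pancreatic secretion. The package implements the oral
C-peptide minimal model: linear two-compartment kinetics

    dCP1/dt = -(k01 + k21)·CP1 + k12·CP2 + SR(t),   CP1(0) = 0
    dCP2/dt =  k21·CP1 - k12·CP2,                   CP2(0) = 0

with CP1, CP2 the above-basal central and peripheral concentrations
(pmol/L), k01 the fractional metabolic clearance rate (MCR, min⁻¹), and
SR the above-basal secretion normalized by the central distribution
volume. Secretion is the sum of a static component — the provision Y(t)
relaxing with rate α (min⁻¹) toward β·(G − h), with h fixed at basal
glucose — and a dynamic component k_d·dG/dt active only while glucose
rises. From the parameters the β-cell responsivity indices follow:
Φ_s = β, Φ_d = k_d, Φ_b = SR_b/G_b with SR_b = k01·CP1b, and

    Φ_tot = [Φ_d·(Gmax − Gb) + Φ_s·∫(G − h)dt + T·Φ_b·Gb] / ∫G dt

over T = 300 min, the horizon at which the system is assumed back at
steady state. Working units are fixed project-wide (G in mmol/L, CP in
pmol/L, time in min); because pmol/L ÷ mmol/L = 10⁻⁹ in molar terms, the
raw numerical values of β, k_d and the Φ indices coincide with the
conventional "×10⁻⁹" display scale and no rescaling is applied.

## Inputs

Glucose and its time derivative enter the model as known, error-free
inputs. Because oral tests sample glucose only every 15–30 min, the
derivative is estimated on a 1-min virtual grid by regularized
deconvolution: the derivative u minimizes the measurement-weighted
misfit of its running (trapezoid) integral to the sampled excursion
plus γ·‖Δ²u‖², with γ chosen by the discrepancy criterion (weighted
residual sum ≈ number of residuals). This discrepancy-based tuning is a
deliberate, simpler stand-in for maximum-likelihood regularization
tuning; for the smooth, densely-identifiable profiles used here the two
give nearly identical derivatives. The continuous G(t) is the
monotone-preserving piecewise cubic (PCHIP) through the samples,
extended past the last sample by a linear relaxation to basal over
60 min (then held) so the Φ_tot integrals are defined out to 300 min;
the derivative input is zero outside the sampled window. Both choices
are modelling conventions where the data end, and they matter only for
the tail of the Φ_tot integrals.

## Population kinetics

The Van Cauter population model predicts the kinetic triplet from
demographics: a class lookup (normal / obese / NIDDM) gives the short
half-life a and fast fraction F; the long half-life is b = 0.14·age +
29.2 min; and k12 = F·λ_l + (1−F)·λ_s, k01 = λ_s·λ_l/k12,
k21 = λ_s + λ_l − k01 − k12 with λ = ln2/half-life. This reconstruction
makes the model's decay eigenvalues exactly ln2/a and ln2/b (asserted
in tests). Note the linear-in-age form of b: the alternative reading
0.14·(age + 29.2) gives b ≈ 10 min and a median MCR ≈ 0.11 min⁻¹,
inconsistent with the ≈0.059 min⁻¹ this model is known to produce for
middle-aged adults, so the linear-in-age form is used. Obesity is
classified at BMI ≥ 30 (WHO convention); NIDDM only by explicit flag.

## Identification

Parameters p = [k_d, α, β, k01, k12, k21] are estimated per subject by
maximum a posteriori: minimize ½Σ(yᵢ − ŷᵢ)²/σᵢ² − log prior, with
independent Gaussian measurement error of constant CV (default 5%,
σᵢ = cv·yᵢ). Three prior regimes:

* **VC** — kinetics fixed at the population prediction; k_d, β flat;
  α log-normal (median 0.05 min⁻¹, geometric CV 50%), a weakly
  informative stabilizer for sparse schedules.
* **DB** — all six free; independent log-normal priors on the kinetic
  parameters centred at the population prediction with 30% geometric CV
  (the spread is a package choice, configurable).
* **PHH** — as DB but the kinetic prior is a joint log-normal with full
  covariance taken from an empirical cohort distribution.

Log-normal prior terms are centred quadratics in log space, so a
prior-consistent estimate adds nothing to the objective. Optimization
runs on the logs of the free parameters (positivity for free) with a
jittered multi-start (default 5 starts, ±30% in log space, fixed seed),
each start refined by L-BFGS-B then Nelder-Mead. Failed simulations
return a large penalty rather than raising. Precision is the
per-parameter CV (%) from the inverse curvature (finite-difference
Hessian) of the negative log posterior at the optimum in log space,
where the log-space SD is first-order the relative SD.

Basal values are the t = 0 samples; the model is fitted to total
C-peptide with basal added to the prediction, which keeps the data
positive through the late hypoglycemic tail.

### Numerical integration

The model is linear and time-invariant in its three states with inputs
(max(dG/dt, 0), G − h). Two integrators are provided: adaptive RK45
(rtol 1e-8, atol 1e-10) with restarts at sign changes of dG/dt, where
the dynamic-secretion switch makes the right-hand side non-smooth; and
an exact first-order-hold matrix-exponential discretization on a 1-min
grid (Van Loan block form), which is exact for piecewise-linear inputs
and agrees with RK45 to ~2×10⁻⁴ relative on the test profiles. The
estimation inner loop uses the discretized propagator (~50× faster);
truth trajectories in the simulation studies are generated with RK45 so
the generation and fitting paths are numerically distinct.

## Synthetic cohorts

No individual-level data exist for this population, so the generator
emulates the published phenotype. Glucose curves are basal plus a fast
gamma-shaped rise (peak jittered in 32–45 min) minus a slower
gamma-shaped dip (trough in 125–148 min), amplitudes solved by fixed
point so maximum and minimum hit the requested peak (median 9.5 mmol/L)
and below-basal nadir (median 2.7 mmol/L); the curve is back within ~5%
of basal by 300 min. Demographics are truncated normals at the study
summaries (OGTT cohort: n=12, 42±9 y, 28.3±6.9 kg/m²; MMTT cohort:
n=10, 43±11 y, 27.5±4.2 kg/m²; age ≥ 18, BMI ≥ 18.5). True kinetics are
the Van Cauter prediction scaled by a configurable offset (default
1.15 — the regime of interest, ~15% faster clearance than the
population model predicts) with independent log-normal jitter
(geometric CV 0.12, back-derived from the published data-based MCR
interquartile range). Secretion parameters are independent log-normals;
their medians (k_d 3750, β 16, α 0.03 min⁻¹, basal C-peptide
340 pmol/L) were calibrated once so the pooled cohort's Φ_tot median
lands near 16×10⁻⁹ min⁻¹ with Φ_b ≈ 5×10⁻⁹ min⁻¹ and then frozen.
C-peptide samples at the test schedule get additive zero-mean Gaussian
noise with SD proportional to the concentration (default CV 5%);
non-positive draws are redrawn rather than clipped, preserving
positivity without a point mass at zero. Everything is reproducible
from the cohort seed via per-subject substreams.

What the generator does **not** emulate: gastric emptying and incretin
physiology (the glucose curve is a shape, not a mechanism), correlated
secretion parameters, rescue-dextrose artifacts, assay drift, or
missing samples. Passing tests therefore demonstrate the estimation
machinery under the stated phenotype, not robustness to those
real-data features.

## Simulation study (parameter recovery)

The validation loop summarizes a cohort's kinetic triplets as a joint
log-normal (log-space sample mean and covariance), draws virtual
subjects — random triplets paired with each source subject's secretion
parameters, glucose curve, demographics and schedule — simulates and
noise-corrupts their C-peptide, re-identifies each virtual subject
under VC / DB / PHH (the PHH prior being the generating population
itself), and scores recovery by the mean absolute relative difference
(MARD, %) for the clearance rate, Φ_tot, and the pooled estimated
parameters. Approaches are compared by Kruskal–Wallis with Dunn–Šidák
post-hoc (rank-based z with tie correction; Šidák-adjusted p-values).
The desk-scale default is 22 sources × 5 replicates (110 virtual
subjects, 330 fits, a few minutes on one CPU) with 2 optimizer starts
per sweep fit — 5-start spot checks reproduce the same medians; the
full 50-replicate design is one flag away.

A degenerate `population="per-source"` mode reuses each source's own
triplet for its replicates; with offset 1.0 and zero jitter this is the
null configuration in which the population prediction is correct by
construction and fixing kinetics cannot be beaten.

## Design choices and known limitations

* With informative priors centred away from the truth, the MAP mode is
  a deliberate likelihood–prior compromise; even at zero noise the
  kinetic estimates sit between truth and prior centre. Exact-recovery
  oracles therefore use prior-consistent truths; the off-centre case is
  checked against a 2% band for a 15%-inflated clearance.
* Under the default conditions the empirical-prior (PHH) approach
  recovers kinetics somewhat better than DB — its prior is both
  correctly centred and tight — while both clearly beat fixing the
  kinetics (VC). How closely DB and PHH agree depends on the DB prior
  spread relative to the cohort's true kinetic dispersion.
* The measurement-error CV (5%) follows common C-peptide assay
  performance and is configurable; all CV-precision figures scale with
  it.
* Tie-breaks and degenerate inputs: a zero population covariance is
  legal (virtual draws collapse onto the mean); glucose at or below
  zero, non-increasing times, or a missing basal sample are rejected
  with row-level diagnostics rather than repaired.
* Insulin kinetics and hepatic insulin extraction are out of scope, as
  is non-parametric (deconvolution-based) secretion reconstruction.
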