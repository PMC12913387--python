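# melomap

Grid-section analysis of **neuromelanin-sensitive MRI (NM-MRI)** in ex
vivo human midbrain tissue.

In Parkinson's disease the neuromelanin (NM)-containing dopaminergic
neurons of the substantia nigra (SN) die, lowering tissue NM and raising
iron (Fe); NM-MRI is the in vivo proxy for this pathology. To ground the
proxy, post mortem midbrain slices are scanned, stamped with a 3.5 × 3.5
mm dissection grid, and cut into grid sections in which NM (μg/mg wet
tissue) and Fe (ng/mg) are measured chemically. `melomap` implements the
image-analysis and statistics pipeline for this design, for researchers
validating NM-MRI contrast against tissue neurochemistry:

* a **synthetic-specimen generator** ("phantom") producing image volumes
  and matched concentration tables for a realistic cohort (7 Alzheimer's
  + 4 Parkinson's specimens, 221 grid sections) with known ground truth;
* **voxel cleaning**: low-signal thresholding via the minimum between
  the two modes of a kernel-smoothed intensity histogram, 2D flattening,
  unconditional removal of a 2-voxel-dilated specimen border, removal of
  high-CNR edge artifacts in a 5-voxel band (sparing SN sections), and
  per-section Cook's-distance outlier rejection;
* **CNR normalization** against the mode of the crus cerebri (CC)
  reference region, `CNR_v = (I_v − mode(I_RR)) / mode(I_RR)`, expressed
  in percent;
* **grid registration and aggregation** into a per-section table (mean
  CNR, SN-voxel fraction at CNR > 10 %, concentrations);
* **statistics**: the random-intercept linear mixed model

  `CNR̄_gs = β₀ + β₁·[NM̄]_gs + β₂·[Fē]_gs + β₃·diagnosis_s + b0_s + ε_gs`

  fitted by profiled maximum likelihood (central-anterior and posterior
  midbrain separately), and a Bayesian hierarchical group comparison
  (`y = α + δ·diagnosis + b0_s + ε`) per region and metric, sampled by
  ensemble MCMC with split-R̂ convergence checks.

The phantom's generating coefficients default to the published estimates
(β₁ = 7.37 %CNR per μg NM/mg, β₂ = 0.050 %CNR per ng Fe/mg), so the full
pipeline is validated by parameter recovery. See `docs/methods.md` for
the model, the calibration of the noise defaults, and the package's
known limitations (notably: a single diagnosis offset cannot reproduce
region-specific NM-MRI group differences).

## Worked example

```python
from melomap import run_cohort, fit_mixed, fit_group_difference

result = run_cohort(seed=1)            # phantom -> clean -> aggregate
fit = fit_mixed(result.sections, subset="central_anterior")
print(f"n = {fit.n_sections} sections, df = {fit.df}")
print(f"NM slope  b1 = {fit.beta[1]:.2f}  (95% CI {fit.ci95[1,0]:.2f} to "
      f"{fit.ci95[1,1]:.2f}, t = {fit.t[1]:.2f}, p = {fit.p[1]:.3g})")
print(f"Fe slope  b2 = {fit.beta[2]:.4f} (95% CI {fit.ci95[2,0]:.4f} to "
      f"{fit.ci95[2,1]:.4f}, t = {fit.t[2]:.2f}, p = {fit.p[2]:.4g})")
print(f"fixed-effect R2 = {fit.r2:.2f}")

diff = fit_group_difference(result.sections, region="SN",
                            metric="fe_conc", seed=1)
print(f"SN Fe difference (PD - AD): {diff.estimate:.1f} ng/mg "
      f"(95% CrI {diff.ci95[0]:.1f} to {diff.ci95[1]:.1f}), "
      f"max R-hat {max(diff.rhat.values()):.3f}")
```

prints

```
n = 163 sections, df = 159
NM slope  b1 = 7.65  (95% CI 3.50 to 11.80, t = 3.64, p = 0.000372)
Fe slope  b2 = 0.0502 (95% CI 0.0295 to 0.0709, t = 4.79, p = 3.722e-06)
fixed-effect R2 = 0.27
SN Fe difference (PD - AD): 35.8 ng/mg (95% CrI 13.8 to 57.3), max R-hat 1.002
```

Reading: from one synthetic cohort, 163 usable central-anterior grid
sections enter the mixed model; both tissue NM and Fe make independent,
significant contributions to the NM-MRI signal (slopes near the
generating values 7.37 and 0.050), the fixed effects explain ≈ 27 % of
section-CNR variance, and SN sections of the PD group carry ≈ 36 ng/mg
more iron, with a credible interval excluding zero.

The same stages are scriptable from the shell:

```sh
melomap phantom --seed 1 --out run/          # volumes + truth tables
melomap clean --volume run/AD01.nii --grid run/AD01.grid.json --out run/
melomap run --out run/                       # full pipeline + report
```

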