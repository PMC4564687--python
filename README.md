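# impactnmr

Distributions of pico- to nanosecond backbone motions in proteins — especially
intrinsically disordered proteins (IDPs) and regions (IDRs) — from multi-field
¹⁵N spin relaxation.

## The problem

Backbone amide ¹⁵N relaxation rates (longitudinal R₁, the ¹⁵N-{¹H} NOE, and the
CSA/dipole-dipole cross-correlated cross-relaxation rates η_z and η_xy) are
linear combinations of the spectral density function J(ω) of the N–H bond
vector, sampled at frequencies set by the static field.  In a folded protein
the classic model-free decomposition into overall tumbling plus internal motion
works well; in an IDR there is no single overall correlation time, motions span
three decades (tens of ps to tens of ns), and fits with two or three
correlation times become hard to interpret.

This package implements the projection approach: instead of fitting
correlation times, it fixes an array of n correlation times equally spaced on
a logarithmic scale,

    τᵢ = α^(i−1)·τ_max,      α = (τ_min/τ_max)^(1/(n−1)),

and represents the measured spectral density as a sum of Lorentzians with
non-negative, normalized weights:

    J(ω) = (2/5) Σᵢ Aᵢ τᵢ / (1 + (ωτᵢ)²),      Aᵢ ≥ 0,  Σᵢ Aᵢ = 1,

so each residue contributes n−1 free parameters and the fitted weights read as
a discrete distribution of correlation times.  The pipeline is:

1. **Reduced spectral density mapping** (no proton auto-relaxation):
   J(0.87·ω_H) from R₁ and the NOE at each field; a two-parameter
   high-frequency model J(ω) = λ + μ/ω² fitted across fields supplies the
   small corrections needed to extract J(ω_N) from R₁; J(0) from the
   η_xy/η_z ratio at the highest field — deliberately avoiding R₂ and its
   chemical-exchange contamination.  Five fields give 11 spectral-density
   points per residue, three fields give 7.
2. **Array optimization**: (τ_min, τ_max, n) chosen globally by Akaike's
   information criterion over all residues, with τ_max/τ_min = 10³ fixed
   (the window to which ¹⁵N relaxation between 400 and 1000 MHz is sensitive).
3. **Simplex-constrained fit** of the weights Aᵢ per residue (a small convex
   QP solved to machine precision), with Monte Carlo errors from perturbing
   the input rates and re-running mapping + fit (510 draws by default).
4. **2CT/3CT comparison**: conventional two/three-Lorentzian (model-free
   style) fits with small-sample AICc model selection, for side-by-side
   display via weights B_a = S², B_b = S_f² − S², B_c = 1 − S_f².
5. **Barcode rendering**: per-residue bars at each τᵢ with widths Aᵢ on a
   log-τ axis, with bands marking the frequency windows actually constrained
   by the experiment.

A synthetic-data module generates multi-field datasets with known ground
truth (folded-like, IDR-like and terminus-like residues; Gaussian noise;
optional exchange broadening of R₂ only), so every stage is testable without
experimental data.

## Worked example

```python
import numpy as np
from impactnmr import build_grid, effective_tm, monte_carlo_errors
from impactnmr.synthetic import engrailed_like_profile, simulate_dataset

# simulate a partially disordered 108-residue protein at five fields
truth = engrailed_like_profile(n_res=108, seed=7)
dataset = simulate_dataset(truth)
rid = 230                              # residue inside the folded domain
records = [r for r in dataset.records if r.residue_id == rid]

grid = build_grid(21e-12, 21e-9, 6)    # 21 ps ... 21 ns, six times
result = monte_carlo_errors(records, grid, n_steps=510, seed=7)

print("tau (ns):   ", np.round(grid.taus_ns, 3))
print("A:          ", np.round(result.A, 3))
print("sigma_A:    ", np.round(result.sigma_A, 3))
print("chi2:       ", round(result.chi2, 2))
print("tau_m (ns): ", round(effective_tm(result.A, grid.taus) * 1e9, 2))
```

prints

```
tau (ns):    [21.     5.275  1.325  0.333  0.084  0.021]
A:           [0.083 0.73   0.07   0.001  0.034  0.084]
sigma_A:     [0.016 0.019  0.015  0.01   0.017  0.018]
chi2:        4.05
tau_m (ns):  6.87
```

The weight distribution is dominated by the 5.27 ns term with a small 21 ns
correction — a folded-domain signature — and the effective overall correlation
time τ_m ≈ (A₁τ₁ + A₂τ₂)/(A₁ + A₂) comes out near the 7 ns tumbling time the
residue was simulated with (true weights for this residue:
`[0.095 0.706 0.078 0.009 0.01 0.101]`).  Weight sitting instead on the
~1.3 ns and ~0.3 ns terms is the IDR signature.

The same stages are available from the shell:

```sh
impactnmr simulate -o rates.tsv --n-res 108 --seed 7
impactnmr map rates.tsv -o map.tsv
impactnmr gridsearch rates.tsv -o aic.tsv
impactnmr fit rates.tsv -o coefficients.tsv
impactnmr score coefficients.tsv rates.tsv.truth.json
impactnmr barcode coefficients.tsv -o barcode.tsv --render barcode.svg
impactnmr run config.yaml          # full pipeline from a config file
```

## Notes

- The high-frequency point is placed at the exact effective frequency implied
  by the gyromagnetic ratio (0.87007·ω_H for the default constants), the
  unrounded version of the conventional 0.87·ω_H.
- An older per-field approximation chain for J(ω_N) (effective-frequency
  substitutions applied rate-by-rate) is intentionally not implemented: the
  λ + μ/ω² route supersedes it and the two agree to about the measurement
  precision (~2%).
- R₂ is accepted on input and simulated (with optional exchange broadening)
  but never used by the mapping stage, which takes J(0) from the η ratio
  precisely to stay exchange-free.
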