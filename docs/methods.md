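# Methods

## Observables and forward model

For an isolated ¹⁵N–¹H spin pair with axially symmetric ¹⁵N CSA, the
observables handled here are

    R1   = (d²/4)[3J(ω_N) + 6J(ω_H−|ω_N|) + J(ω_H+|ω_N|)] + c²·J(ω_N)
    NOE  = 1 + (d²/4)(γ_H/γ_N)[6J(ω_H−|ω_N|) − J(ω_H+|ω_N|)] / R1
    η_z  = √3·d·c·P₂(cosθ)·J(ω_N)
    η_xy = (√3/6)·d·c·P₂(cosθ)·[4J(0) + 3J(ω_N)]
    R2   = (d²/8)[4J(0) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H−|ω_N|) + J(ω_H+|ω_N|)]
           + (c²/6)[4J(0) + 3J(ω_N)] + R_ex

with d = (μ₀/4π)·ħ·γ_H·γ_N/r_NH³ and c = γ_N·B₀·Δσ/3.  Because γ_N < 0, the
frequency conventionally written ω_H + ω_N is numerically ω_H − |ω_N|; the
factor 6 belongs to that lower frequency.  This sign convention is load-
bearing: it is what makes the effective-frequency identities below hold, and
it is exercised by the round-trip tests.

Constants (configurable): γ_H = 2.6752218744e8, γ_N = −2.7116e7 rad s⁻¹ T⁻¹,
ħ = 1.054571817e-34 J s, r_NH = 1.02 Å, Δσ = 160 ppm, θ (CSA tilt) = 0° so
P₂(cosθ) = 1.  θ cancels in the η_xy/η_z ratio and therefore never affects
the mapping; it only scales synthetic η magnitudes.  Small differences in the
assumed constants shift absolute J scales but not the fitted weight
distributions, which depend on the shape of J only.

## Reduced spectral density mapping

Per residue and field, R₁ and the NOE give the effective high-frequency point

    J(ω_eff) = 4·γ_N·R1·(NOE−1) / (5·d²·γ_H).

ω_eff is computed exactly from r = |γ_N|/γ_H as
ω_eff/ω_H = sqrt(5/(6/(1−r)² − 1/(1+r)²)) = 0.87007 for the default ratios —
the unrounded version of the conventional 0.87.  With the exact value, a
spectral density whose high-frequency tail is exactly λ + μ/ω² maps back to
itself at machine precision; with the rounded 0.87 a systematic ~7·10⁻⁵
relative error appears.  The package uses the exact frequency everywhere and
reports it as the "high" point.

The per-field high points are fitted to J(ω) = λ + μ/ω² (λ, μ ≥ 0) by
weighted least squares, solved in closed form with non-negativity enforced by
boundary projection (exact for two parameters).  Weights are inverse-variance
from first-order propagation of the rate sigmas; uniform when noiseless.  The
fitted model supplies J at ω_H ± |ω_N| in

    J(ω_N) = R1/(3d²/4 + c²) − [6J(ω_H−|ω_N|) + J(ω_H+|ω_N|)]/(3 + 4c²/d²),

and J(0) comes from the exchange-free cross-correlation ratio

    J(0) = J(ω_N)·(3/4)·(2·η_xy/η_z − 1)

at a single designated field — the highest field whose η_z is at least 2σ
from zero; lower fields are tried in order as fallback, and a residue with no
usable η pair is excluded and listed in the run report.  R₂ is read and
simulated but never used in mapping, because chemical exchange inflates it.

Accuracy: the only approximation in the chain is the λ + μ/ω² form of the
high-frequency density.  Noiseless round trips recover J to ~0.2% for
folded-like densities and within ~2% for smooth multi-modal densities; the
error grows to ~3–4% when the distribution puts dominant weight in the
100–500 ps range, where 1/ω² is a poor description of J near ω_H ± ω_N.
That worst case propagates into absolute coefficient errors of up to ~0.1 on
individual weights for strongly disordered profiles, an ill-conditioning
effect of the overlapping Lorentzian basis (neighbouring coefficients are
anticorrelated, which the Monte Carlo draw matrix makes visible) — not a
solver deficiency: the fit in J-space is accurate to the mapping error.

## The projection fit

The τ array is geometric between τ_min and τ_max (descending, τ₁ = τ_max).
The default analysis array is (21 ps, 21 ns, n = 6), whose interior times are
5.27 ns, 1.33 ns, 333 ps and 83.6 ps (3 s.f.).  Per residue the weights
minimize Σⱼ wⱼ(J_obs(ωⱼ) − J_fit(ωⱼ))² with wⱼ = 1/σⱼ² (σ from the mapping
Monte Carlo; uniform when noiseless) subject to A ≥ 0, ΣA = 1.  This is a
tiny convex QP; it is solved by non-negative least squares with a stiff
penalty row for the normalization, followed by an exact KKT solve on the
resulting active set (SLSQP fallback if dual feasibility fails).  Tests check
global optimality against exhaustive enumeration of the discretized simplex.
Degenerate inputs: an all-non-positive map is fitted anyway (the QP is still
well-posed) and flagged; ties within 1e-12 in χ² return the deterministic
solver's vertex.

Coefficient uncertainties: each of 510 Monte Carlo steps perturbs the *input
rates* with their Gaussian sigmas, re-runs the full mapping, and refits, so
mapping nonlinearity is inside the estimate; σ_A is the per-coefficient
sample standard deviation and the full draw matrix is kept for correlation
diagnostics.  510 steps is treated as a default, not a constraint.  All
random streams derive from explicit seeds (default 20150901); per-residue
substreams come from a SeedSequence so results do not depend on residue
order.  Linear scaling of σ_A with input noise holds while the non-negativity
constraints stay inactive; weights pinned near zero show half-Gaussian
truncation instead, which is physically meaningful rather than an artifact.

The effective overall correlation time is summarized as
τ_m ≈ (A₁τ₁ + A₂τ₂)/(A₁ + A₂), sensible for residues whose slow dynamics is
dominated by tumbling of a folded domain.

## Array optimization

Candidates fix τ_max/τ_min = 10³ — between 400 and 1000 MHz the sampled
frequencies constrain roughly three decades of correlation times: a 40 ns
Lorentzian retains only 1% of J(0) at 40 MHz, an 18 ps Lorentzian still 99%
at 870 MHz — and scan τ_min over a geometric ladder (default 13 points,
1 → 100 ps, step 10^(1/6)) and n from 4 to 9.  Each candidate is scored by

    AIC = n_exp·ln(Σ_k χ²_k / n_exp) + 2·n_model,   C = 0,

with n_exp the total number of map points and n_model = (n−1)·n_res.
Residues that cannot constrain the largest candidate are excluded from all
candidates to keep the pooled χ² comparable.  The full surface is stored at
integer n only, with 4-neighbour local minima flagged; ΔAIC converts to a
relative likelihood exp(ΔAIC/2).  Per-segment optima are obtained by running
on a residue subset via configuration, not by separate code paths.

## 2CT/3CT comparison

The two- and three-Lorentzian spectral densities use the primed-time
composition 1/τ_b' = 1/τ_a + 1/τ_b (and 1/τ_c' = 1/τ_a + 1/τ_c); fits are in
(S², S_f², τ_a, τ_b, τ_c) with primes derived, never fitted directly.  The
parameterization (S², g, log₁₀τ_a, δ_b, δ_c) with S_f² = S² + g(1−S²) and
τ_b = τ_a·10^(−δ_b) builds 0 ≤ S² ≤ S_f² ≤ 1 and τ_a > τ_b > τ_c into box
bounds.  A deterministic multi-start (τ_a ∈ {2, 5, 10, 20} ns,
τ_b ∈ {0.1, 0.5, 1, 2} ns, τ_c ∈ {20, 50, 100} ps) feeds a trust-region
least-squares solver; bounds τ_a ≤ 100 ns and τ_c ≥ 1 ps reflect the limits
of sampled sensitivity.  Model selection uses the second-order criterion
AICc = n_J·ln(χ²/n_J) + 2k + 2k(k+1)/(n_J−k−1) with k = 3 or 5.  Two
numerical choices matter in edge cases: χ² is floored at n_J·10⁻²⁰ so that
noiseless nested fits compare at "equal fit" and the parameter penalty
decides (otherwise the comparison is between machine-noise residuals), and
among starts with χ² equal at that floor the higher-S² branch is kept — in
the single-Lorentzian limit (S² → 1, τ_a) and (S² → 0, τ_b' ≡ τ_a/2) describe
the same density and the interpretable branch is preferred.  If the SI-style
AICc used elsewhere differs from this standard form, selections could differ
at the margin for residues with nearly equal fits.

## Synthetic data

The generator emulates a partially disordered protein studied at
400/500/600/800/1000 MHz (108 residues numbered from 146 by default).  Three
archetypes are defined as weight vectors on the default (21 ps, 21 ns, 6)
array: folded-like (dominant 5.27 ns weight plus a fast mode; effective τ_m
≈ 7 ns by construction), IDR-like (dominant ~1.3 ns mode with substantial
sub-ns weight), and terminus-like (weight spread over all sub-ns times).
The chain layout blends archetypes linearly across segment boundaries — a
terminus ramp, a disordered region containing a small ordered cluster (with
3 s⁻¹ exchange broadening on R₂ only), a linker, a folded domain, and a
C-terminal tail — and a seeded log-normal jitter (σ = 0.05) individualizes
residues.  Continuous distributions are supported as log-normal mixtures
discretized on 64 log-spaced quadrature points (J error < 10⁻⁶ relative
versus 1024 points).

Noise defaults (one σ): 1.5% on R₁, ±0.02 absolute on the NOE, 4% on η_z, 2%
on η_xy, 2% on R₂.  These were chosen once to make η_z the precision
bottleneck at low field, which is the realistic situation for
cross-correlation measurements; records carry the true sigmas.  What the
generator does *not* emulate: field-dependent peak overlap, systematic
miscalibration between spectrometers, anisotropic tumbling, temperature
drifts, and any correlation of noise across observables.  Passing recovery
tests therefore demonstrate the correctness and conditioning of the
inference chain under stated noise, not robustness to those systematics.

## Problem sizes used in the test suite

Stochastic checks run at sizes chosen to exercise the statistics decisively:
array recovery on a seeded 50-residue dataset (and a 30-residue variant in
the unit suite), Monte Carlo scaling at the full 510 draws, coverage of the
truth within 3σ_A at 60 residues × 192 draws, and model-selection consistency
at 12 seeded replicates per truth.  All are deterministic given their fixed
seeds.

## Known limitations

- Isotropic-equivalent treatment only: no diffusion-tensor deconvolution, no
  proton or deuterium relaxation, no R_ex estimation from R₂ dispersion.
- Mapping accuracy degrades (to ~3–4% in J) for densities dominated by
  100–500 ps motions, as discussed above; the fitted weights remain the best
  simplex representation of the mapped points, but their systematic error
  then exceeds the Monte Carlo precision at low noise.
- The weight distribution is a statistical projection: a nonzero A₁ means
  density beyond τ₂ exists, not that motion at exactly τ₁ was detected, and
  the fastest weight aggregates everything faster than the sampled window
  (its basis term is flat to ~1.3% across the sampled band).
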