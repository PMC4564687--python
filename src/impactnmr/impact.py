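"""IMPACT inversion: project mapped spectral densities onto a fixed τ array.

The correlation-time array is a geometric series τ_i = α^(i−1)·τ_max with
α = (τ_min/τ_max)^(1/(n−1)) (equally spaced on a log scale).  Per residue the
spectral density is modelled as J(ω) = (2/5)·Σ A_i·τ_i/(1+(ωτ_i)²) with
A_i ≥ 0 and Σ A_i = 1, so only n−1 parameters are free.  The fit is a small
convex quadratic program over the probability simplex, solved to machine
precision; coefficient uncertainties come from Monte Carlo perturbation of
the input rates followed by re-mapping and re-fitting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .relaxation import DEFAULT_CONSTANTS, PhysicalConstants, RelaxationRecord
from .sdm import DEFAULT_MC_STEPS, DEFAULT_SEED, SpectralDensityMap, map_residue

__all__ = [
    "ImpactGrid",
    "ImpactResult",
    "build_grid",
    "impact_spectral_density",
    "design_matrix",
    "fit_impact",
    "monte_carlo_errors",
    "effective_tm",
    "brute_force_simplex",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactGrid:
    """Geometric array of correlation times, descending (τ₁ = τ_max … τ_n = τ_min)."""

    tau_min: float
    tau_max: float
    n: int
    taus: np.ndarray
    alpha: float

    @property
    def taus_ns(self) -> np.ndarray:
        return self.taus * 1e9


def build_grid(tau_min: float, tau_max: float, n: int) -> ImpactGrid:
    """Build the τ array: τ_i = α^(i−1)·τ_max, α = (τ_min/τ_max)^(1/(n−1)).

    ``tau_min``/``tau_max`` in seconds, 0 < tau_min < tau_max, n ≥ 2.
    """
    if not (0.0 < tau_min < tau_max):
        raise ValueError("require 0 < tau_min < tau_max")
    if n < 2:
        raise ValueError("need at least two correlation times")
    alpha = (tau_min / tau_max) ** (1.0 / (n - 1))
    taus = tau_max * alpha ** np.arange(n)
    taus[-1] = tau_min  # geometric endpoint, exact
    return ImpactGrid(tau_min=float(tau_min), tau_max=float(tau_max), n=int(n), taus=taus, alpha=float(alpha))


def impact_spectral_density(grid: ImpactGrid, A: Sequence[float], omega):
    """Evaluate J(ω) = (2/5)·Σ A_i·τ_i/(1+(ωτ_i)²) for coefficients on the grid."""
    a = np.asarray(A, dtype=float)
    om = np.asarray(omega, dtype=float)
    val = 0.4 * np.sum(a * grid.taus / (1.0 + np.square(np.multiply.outer(om, grid.taus))), axis=-1)
    return float(val) if np.isscalar(omega) or om.ndim == 0 else val


def design_matrix(grid: ImpactGrid, omega: np.ndarray) -> np.ndarray:
    """Basis matrix M[j, i] = (2/5)·τ_i/(1+(ω_j·τ_i)²)."""
    return 0.4 * grid.taus / (1.0 + np.square(np.outer(omega, grid.taus)))


@dataclass
class ImpactResult:
    """Fitted coefficients for one residue on one grid."""

    residue_id: int
    A: np.ndarray
    chi2: float
    n_points: int
    sigma_A: Optional[np.ndarray] = None
    draws: Optional[np.ndarray] = None
    flags: list[str] = dc_field(default_factory=list)


def _weights_from_map(smap: SpectralDensityMap) -> np.ndarray:
    """χ² weights 1/σ²; uniform (in units of the data scale) when noiseless."""
    sig = smap.sigma
    if np.any(sig > 0.0):
        floor = np.min(sig[sig > 0.0])
        return 1.0 / np.square(np.where(sig > 0.0, sig, floor))
    scale = max(float(np.max(np.abs(smap.J))), 1e-30)
    return np.full_like(smap.J, 1.0 / scale**2)


def _solve_simplex_ls(M: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Minimize Σ w_j (M A − y)²_j subject to A ≥ 0, Σ A = 1.

    Strategy: non-negative least squares with a stiff penalty row enforcing
    the normalization gives the active set; an equality-constrained KKT solve
    on that support then restores machine precision.  If the KKT conditions
    fail (rare, near-degenerate supports) an SLSQP polish is used instead.
    Returns (A, chi2, fallback_used).
    """
    n = M.shape[1]
    sw = np.sqrt(w)
    Mw = M * sw[:, None]
    yw = y * sw
    scale = max(float(np.max(np.abs(Mw))), 1e-300)
    rho = 1e7 * scale
    A_aug = np.vstack([Mw, rho * np.ones((1, n))])
    b_aug = np.concatenate([yw, [rho]])
    a0, _ = optimize.nnls(A_aug, b_aug)

    def chi2_of(a: np.ndarray) -> float:
        r = Mw @ a - yw
        return float(r @ r)

    # exact KKT refinement on the penalty solution's support
    support = a0 > 1e-12
    if support.sum() == 0:
        support[int(np.argmax(a0))] = True
    for _ in range(n + 1):
        S = np.flatnonzero(support)
        Ms = Mw[:, S]
        H = 2.0 * Ms.T @ Ms
        g = 2.0 * Ms.T @ yw
        k = len(S)
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = H
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([g, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            break
        a_s, nu = sol[:k], sol[k]
        if np.any(a_s < -1e-10):
            # drop the most negative coordinate and retry
            support[S[int(np.argmin(a_s))]] = False
            if support.sum() == 0:
                break
            continue
        a = np.zeros(n)
        a[S] = np.clip(a_s, 0.0, None)
        # dual feasibility on the inactive set: gradient − ν ≥ 0
        grad = 2.0 * Mw.T @ (Mw @ a - yw)
        inactive = ~support
        if np.all(grad[inactive] - nu >= -1e-9 * max(scale**2, abs(nu), 1.0)):
            a /= a.sum()
            return a, chi2_of(a), False
        # release the most violating inactive coordinate
        viol = np.where(inactive, grad - nu, np.inf)
        support[int(np.argmin(viol))] = True

    # fallback: SLSQP with exact constraint
    res = optimize.minimize(
        chi2_of,
        np.clip(a0, 0.0, None) / max(a0.sum(), 1e-12),
        jac=lambda a: 2.0 * Mw.T @ (Mw @ a - yw),
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0, "jac": lambda a: np.ones(n)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-16},
    )
    a = np.clip(res.x, 0.0, None)
    a /= a.sum()
    return a, chi2_of(a), True


def fit_impact(
    smap: SpectralDensityMap,
    grid: ImpactGrid,
    weights: Optional[np.ndarray] = None,
) -> ImpactResult:
    """Fit simplex-constrained coefficients A to one residue's map points.

    Minimizes Σ_j w_j·(J_obs(ω_j) − J_fit(ω_j))² with w_j = 1/σ_j² (uniform
    if the map is noiseless) over {A ≥ 0, Σ A = 1}.  Deterministic.
    """
    flags: list[str] = []
    if smap.n_points < grid.n - 1:
        flags.append("under-determined")
        logger.warning(
            "residue %d: %d map points for %d free parameters",
            smap.residue_id,
            smap.n_points,
            grid.n - 1,
        )
    w = _weights_from_map(smap) if weights is None else np.asarray(weights, dtype=float)
    if np.all(smap.J <= 0.0):
        flags.append("degenerate-nonpositive-map")
    M = design_matrix(grid, smap.omega)
    A, chi2, fallback = _solve_simplex_ls(M, smap.J, w)
    if fallback:
        flags.append("slsqp-fallback")
    return ImpactResult(
        residue_id=smap.residue_id, A=A, chi2=chi2, n_points=smap.n_points, flags=flags
    )


def monte_carlo_errors(
    records: Sequence[RelaxationRecord],
    grid: ImpactGrid,
    n_steps: int = DEFAULT_MC_STEPS,
    seed: int = DEFAULT_SEED,
    j0_field_mhz: Optional[float] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ImpactResult:
    """Coefficient fit with Monte Carlo uncertainties for one residue.

    Each step perturbs the *input rates* by their Gaussian uncertainties,
    reruns the full mapping, and refits the coefficients, so the mapping
    nonlinearity is inside the error estimate.  Returns the central fit with
    ``sigma_A`` (per-coefficient sample standard deviation) and the full draw
    matrix for correlation diagnostics (consecutive coefficients are expected
    to be anticorrelated because neighbouring basis functions overlap).
    """
    if n_steps < 2:
        raise ValueError("need at least two Monte Carlo steps")
    central_map = map_residue(
        records, j0_field_mhz=j0_field_mhz, n_mc=n_steps, seed=seed, constants=constants
    )
    w = _weights_from_map(central_map)
    central = fit_impact(central_map, grid, weights=w)
    if not any(
        sig > 0.0
        for r in records
        for _, sig in (r.get(o) for o in RelaxationRecord.OBSERVABLES)
    ):
        central.sigma_A = np.zeros(grid.n)
        central.draws = np.tile(central.A, (n_steps, 1))
        return central

    rng = np.random.default_rng(seed)
    draws = np.empty((n_steps, grid.n))
    for k in range(n_steps):
        pert = [r.perturbed(rng) for r in records]
        try:
            pmap = map_residue(
                pert, j0_field_mhz=j0_field_mhz, n_mc=0, seed=seed, constants=constants
            )
            draws[k] = fit_impact(pmap, grid, weights=w).A
        except ValueError:
            draws[k] = central.A  # degenerate draw: count as no displacement
    central.sigma_A = np.std(draws, axis=0, ddof=1)
    central.draws = draws
    return central


def effective_tm(A: Sequence[float], taus: Sequence[float]) -> float:
    """Effective overall correlation time τm ≈ (A₁τ₁ + A₂τ₂)/(A₁ + A₂).

    Weighted mean of the two slowest grid times; meaningful for residues whose
    slow motion is dominated by rotational diffusion of a folded domain.
    """
    a = np.asarray(A, dtype=float)
    t = np.asarray(taus, dtype=float)
    if a[0] + a[1] <= 0.0:
        raise ValueError("effective tau_m undefined: A1 + A2 = 0")
    return float((a[0] * t[0] + a[1] * t[1]) / (a[0] + a[1]))


def brute_force_simplex(
    M: np.ndarray, y: np.ndarray, w: np.ndarray, step: float = 0.02
) -> tuple[np.ndarray, float]:
    """Exhaustive search over the discretized simplex (testing oracle).

    Enumerates all coefficient vectors with entries that are multiples of
    ``step`` summing to one and returns the best (A, chi2).  Exponential in
    the number of grid times — intended for n ≤ 4 cross-checks only.
    """
    n = M.shape[1]
    m = round(1.0 / step)
    best_chi2 = np.inf
    best = None
    sw = np.sqrt(w)
    Mw = M * sw[:, None]
    yw = y * sw
    for comp in itertools.combinations(range(m + n - 1), n - 1):
        # stars-and-bars composition of m into n parts
        parts = []
        prev = -1
        for c in comp:
            parts.append(c - prev - 1)
            prev = c
        parts.append(m + n - 2 - prev)
        a = np.array(parts, dtype=float) * step
        r = Mw @ a - yw
        chi2 = float(r @ r)
        if chi2 < best_chi2:
            best_chi2 = chi2
            best = a
    return best, best_chi2
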