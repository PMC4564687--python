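"""Conventional two- and three-correlation-time (2CT/3CT) spectral densities.

These are model-free–style descriptions fitted per residue for comparison
with the fixed-array projection.  The 2CT form is

    J(ω) = (2/5)·[S²·τa/(1+(ωτa)²) + (1−S²)·τb'/(1+(ωτb')²)],
    1/τb' = 1/τa + 1/τb,

and the 3CT form adds a fast component with weight 1−Sf² at τc'
(1/τc' = 1/τa + 1/τc), with 0 ≤ S² ≤ Sf² ≤ 1 and τa > τb > τc.  Model
selection uses the small-sample (second-order) Akaike criterion

    AICc = n_J·ln(χ²/n_J) + 2k + 2k(k+1)/(n_J − k − 1),

with k = 3 (2CT) or k = 5 (3CT) free parameters.  For barcode-style displays
the 3CT weights are reported as Ba = S², Bb = Sf² − S², Bc = 1 − Sf².
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .sdm import SpectralDensityMap

__all__ = [
    "TwoCTParams",
    "ThreeCTParams",
    "ModelSelection",
    "j_2ct",
    "j_3ct",
    "aicc",
    "b_coefficients",
    "fit_2ct",
    "fit_3ct",
    "fit_modelfree",
]

logger = logging.getLogger(__name__)

# deterministic multi-start ladders (seconds)
TAU_A_STARTS = (2e-9, 5e-9, 10e-9, 20e-9)
TAU_B_STARTS = (0.1e-9, 0.5e-9, 1e-9, 2e-9)
TAU_C_STARTS = (20e-12, 50e-12, 100e-12)

TAU_A_BOUNDS = (1e-11, 1e-7)  # 10 ps .. 100 ns
_DELTA_BOUNDS = (1e-3, 6.0)  # log10 separation between consecutive times


@dataclass(frozen=True)
class TwoCTParams:
    """2CT parameters: weight S², long time τa, short time τb (seconds)."""

    S2: float
    tau_a: float
    tau_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.S2 <= 1.0):
            raise ValueError("S2 must lie in [0, 1]")
        if not (self.tau_a > self.tau_b > 0.0):
            raise ValueError("require tau_a > tau_b > 0")

    @property
    def tau_b_prime(self) -> float:
        return 1.0 / (1.0 / self.tau_a + 1.0 / self.tau_b)


@dataclass(frozen=True)
class ThreeCTParams:
    """3CT parameters: weights S² ≤ Sf², times τa > τb > τc (seconds)."""

    S2: float
    Sf2: float
    tau_a: float
    tau_b: float
    tau_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.S2 <= self.Sf2 <= 1.0):
            raise ValueError("require 0 <= S2 <= Sf2 <= 1")
        if not (self.tau_a > self.tau_b > self.tau_c > 0.0):
            raise ValueError("require tau_a > tau_b > tau_c > 0")

    @property
    def tau_b_prime(self) -> float:
        return 1.0 / (1.0 / self.tau_a + 1.0 / self.tau_b)

    @property
    def tau_c_prime(self) -> float:
        return 1.0 / (1.0 / self.tau_a + 1.0 / self.tau_c)


def _lorentz(tau: float, omega: np.ndarray) -> np.ndarray:
    return tau / (1.0 + np.square(omega * tau))


def j_2ct(params: TwoCTParams, omega):
    """Evaluate the 2CT spectral density at ω (rad/s, scalar or array)."""
    om = np.asarray(omega, dtype=float)
    tbp = params.tau_b_prime
    val = 0.4 * (params.S2 * _lorentz(params.tau_a, om) + (1.0 - params.S2) * _lorentz(tbp, om))
    return float(val) if np.isscalar(omega) or om.ndim == 0 else val


def j_3ct(params: ThreeCTParams, omega):
    """Evaluate the 3CT spectral density at ω (rad/s, scalar or array)."""
    om = np.asarray(omega, dtype=float)
    val = 0.4 * (
        params.S2 * _lorentz(params.tau_a, om)
        + (params.Sf2 - params.S2) * _lorentz(params.tau_b_prime, om)
        + (1.0 - params.Sf2) * _lorentz(params.tau_c_prime, om)
    )
    return float(val) if np.isscalar(omega) or om.ndim == 0 else val


def aicc(chi2: float, n_J: int, k: int) -> float:
    """Second-order Akaike criterion; +inf when the correction denominator vanishes.

    χ² is floored at n_J·1e-20 (weighted residuals below ~1e-10 per point are
    numerical noise); this makes noiseless fits of nested models compare at
    "equal fit", so the parameter penalty decides.
    """
    if chi2 < 0.0:
        raise ValueError("chi2 must be non-negative")
    if n_J - k - 1 <= 0:
        return math.inf
    chi2 = max(chi2, n_J * 1e-20)
    return n_J * math.log(chi2 / n_J) + 2.0 * k + 2.0 * k * (k + 1) / (n_J - k - 1)


def b_coefficients(params: ThreeCTParams) -> tuple[float, float, float]:
    """Simplex weights (Ba, Bb, Bc) = (S², Sf²−S², 1−Sf²) for barcode display."""
    return params.S2, params.Sf2 - params.S2, 1.0 - params.Sf2


def _map_arrays(smap: SpectralDensityMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    om = smap.omega
    y = smap.J
    sig = smap.sigma
    if np.any(sig > 0.0):
        floor = np.min(sig[sig > 0.0])
        s = np.where(sig > 0.0, sig, floor)
    else:
        s = np.full_like(y, max(float(np.max(np.abs(y))), 1e-30))
    return om, y, s


def fit_2ct(smap: SpectralDensityMap) -> tuple[Optional[TwoCTParams], float]:
    """Weighted least-squares 2CT fit with a deterministic multi-start.

    Parameterized as (S², log10 τa, δb) with τb = τa·10^(−δb), which builds
    the ordering constraint into the box bounds.  Returns (params, χ²);
    params is None if no start converges.
    """
    om, y, s = _map_arrays(smap)
    lo = (0.0, math.log10(TAU_A_BOUNDS[0]), _DELTA_BOUNDS[0])
    hi = (1.0, math.log10(TAU_A_BOUNDS[1]), _DELTA_BOUNDS[1])

    def resid(theta):
        s2, lta, db = theta
        p = TwoCTParams(S2=s2, tau_a=10.0**lta, tau_b=10.0 ** (lta - db))
        return (j_2ct(p, om) - y) / s

    best = None
    best_chi2 = math.inf
    for ta, tb in itertools.product(TAU_A_STARTS, TAU_B_STARTS):
        if tb >= ta:
            continue
        for s2_0 in (0.5, 0.9):
            x0 = np.clip(
                [s2_0, math.log10(ta), math.log10(ta / tb)],
                lo,
                hi,
            )
            try:
                res = optimize.least_squares(
                    resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:
                continue
            chi2 = 2.0 * res.cost
            if not res.success:
                continue
            # deterministic tie-break among equivalent optima: in the
            # single-Lorentzian limit (S2, τa) and (1−S2, τb' branch) fit
            # identically; prefer the interpretable high-S2 branch.
            # χ² below the numerical noise floor counts as zero.
            floor = len(y) * 1e-20
            c_eff = max(chi2, floor)
            b_eff = max(best_chi2, floor) if best is not None else math.inf
            if c_eff < b_eff * (1.0 - 1e-9) or (
                best is not None and c_eff <= b_eff * (1.0 + 1e-9) and res.x[0] > best[0]
            ):
                best_chi2 = min(chi2, best_chi2)
                best = res.x
    if best is None:
        return None, math.inf
    s2, lta, db = best
    return TwoCTParams(S2=min(max(s2, 0.0), 1.0), tau_a=10.0**lta, tau_b=10.0 ** (lta - db)), best_chi2


def fit_3ct(smap: SpectralDensityMap) -> tuple[Optional[ThreeCTParams], float]:
    """Weighted least-squares 3CT fit with a deterministic multi-start.

    Parameterized as (S², g, log10 τa, δb, δc) with Sf² = S² + g·(1−S²),
    τb = τa·10^(−δb), τc = τb·10^(−δc), so ordering and weight constraints
    hold by construction.
    """
    om, y, s = _map_arrays(smap)
    lo = (0.0, 0.0, math.log10(TAU_A_BOUNDS[0]), _DELTA_BOUNDS[0], _DELTA_BOUNDS[0])
    hi = (1.0, 1.0, math.log10(TAU_A_BOUNDS[1]), _DELTA_BOUNDS[1], _DELTA_BOUNDS[1])

    def unpack(theta):
        s2, g, lta, db, dc = theta
        sf2 = s2 + g * (1.0 - s2)
        return ThreeCTParams(
            S2=s2,
            Sf2=min(max(sf2, s2), 1.0),
            tau_a=10.0**lta,
            tau_b=10.0 ** (lta - db),
            tau_c=10.0 ** (lta - db - dc),
        )

    def resid(theta):
        return (j_3ct(unpack(theta), om) - y) / s

    best = None
    best_chi2 = math.inf
    for ta, tb, tc in itertools.product(TAU_A_STARTS, TAU_B_STARTS, TAU_C_STARTS):
        if not (ta > tb > tc):
            continue
        x0 = np.clip(
            [0.6, 0.75, math.log10(ta), math.log10(ta / tb), math.log10(tb / tc)],
            lo,
            hi,
        )
        try:
            res = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        chi2 = 2.0 * res.cost
        if res.success and chi2 < best_chi2:
            best_chi2 = chi2
            best = res.x
    if best is None:
        return None, math.inf
    params = unpack(best)
    if params.tau_c < 1e-12:
        logger.info("residue %d: 3CT tau_c below 1 ps sensitivity bound", smap.residue_id)
    return params, best_chi2


@dataclass
class ModelSelection:
    """Per-residue 2CT/3CT comparison with AICc-based choice."""

    residue_id: int
    model: str  # "2CT", "3CT" or "failed"
    params_2ct: Optional[TwoCTParams]
    chi2_2ct: float
    aicc_2ct: float
    params_3ct: Optional[ThreeCTParams]
    chi2_3ct: float
    aicc_3ct: float
    B: tuple[float, float, float]

    @property
    def flags(self) -> list[str]:
        out = []
        if self.params_2ct is None:
            out.append("2ct-failed")
        if self.params_3ct is None:
            out.append("3ct-failed")
        return out


def fit_modelfree(smap: SpectralDensityMap, mode: str = "auto") -> ModelSelection:
    """Fit 2CT and/or 3CT to one residue's map and select by AICc.

    ``mode`` is "2CT", "3CT" or "auto" (fit both, keep the lower AICc).
    The B weights reported correspond to the selected model; for 2CT they are
    (S², 1−S², 0).  Residues where no start converges are flagged, with no
    values invented.
    """
    if mode not in {"2CT", "3CT", "auto"}:
        raise ValueError("mode must be '2CT', '3CT' or 'auto'")
    n_J = smap.n_points
    if n_J < 5:
        raise ValueError("need at least 5 map points for a 2CT fit")

    p2, chi2_2 = (None, math.inf)
    p3, chi2_3 = (None, math.inf)
    if mode in {"2CT", "auto"}:
        p2, chi2_2 = fit_2ct(smap)
    if mode in {"3CT", "auto"}:
        if n_J < 7:
            logger.info("residue %d: too few points for 3CT", smap.residue_id)
        else:
            p3, chi2_3 = fit_3ct(smap)

    a2 = aicc(chi2_2, n_J, 3) if p2 is not None else math.inf
    a3 = aicc(chi2_3, n_J, 5) if p3 is not None else math.inf

    if p2 is None and p3 is None:
        return ModelSelection(smap.residue_id, "failed", None, chi2_2, a2, None, chi2_3, a3, (0.0, 0.0, 0.0))
    if mode == "2CT" or (mode == "auto" and a2 <= a3):
        chosen = "2CT"
        B = (p2.S2, 1.0 - p2.S2, 0.0)
    else:
        chosen = "3CT"
        B = b_coefficients(p3)
    return ModelSelection(
        residue_id=smap.residue_id,
        model=chosen,
        params_2ct=p2,
        chi2_2ct=chi2_2,
        aicc_2ct=a2,
        params_3ct=p3,
        chi2_3ct=chi2_3,
        aicc_3ct=a3,
        B=B,
    )
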