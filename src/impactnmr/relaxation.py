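"""Physical constants, per-field frequency bookkeeping, and forward relaxation rates.

The observables handled throughout the package are backbone amide ¹⁵N rates:
longitudinal relaxation R1, the steady-state ¹⁵N-{¹H} NOE, the longitudinal and
transverse CSA/dipole-dipole cross-correlated cross-relaxation rates η_z and
η_xy, and (optionally) the transverse rate R2.  All of them are linear
combinations of the spectral density function J(ω) of the N-H bond-vector
orientational correlation function, evaluated at a handful of frequencies set
by the static field.

Frequency-sign convention
-------------------------
γ(¹⁵N) is negative, so the signed nitrogen Larmor frequency is negative and the
"sum" frequency ωH + ωN of the relaxation literature is numerically
ωH − |ωN| ≈ 0.899·ωH.  This module stores magnitudes and keeps the convention
explicit: the factor 6 in R1/NOE/R2 multiplies J(ωH − |ωN|) (attribute
``omega_diff``), and J(ωH + |ωN|) (``omega_sum``) carries the factor 1.  That
choice is what makes the classic effective-high-frequency identities hold:
for J ∝ 1/ω², (6·J(ωH−|ωN|) − J(ωH+|ωN|))/5 = J(0.870·ωH) and
(6·J(ωH−|ωN|) + J(ωH+|ωN|))/7 = J(0.921·ωH).

A single-correlation-time spectral density uses the normalization
J(ω) = (2/5)·τ/(1+(ωτ)²), so J(0) of a normalized distribution is (2/5)·⟨τ⟩.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "FieldContext",
    "RelaxationRecord",
    "make_field_context",
    "effective_high_freq_ratio",
    "interaction_constants",
    "forward_rates",
    "lorentzian_j",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the ¹⁵N-¹H spin pair.

    Attributes
    ----------
    gamma_H, gamma_N:
        Gyromagnetic ratios in rad s⁻¹ T⁻¹; γN carries its physical negative
        sign so that cross-relaxation sign conventions come out right.
    hbar:
        Reduced Planck constant, J s.
    mu0_over_4pi:
        μ0/4π, T m A⁻¹ (exactly 1e-7 in SI to excellent accuracy).
    r_NH:
        Amide N-H internuclear distance, m (default 1.02 Å).
    delta_sigma:
        Axially symmetric ¹⁵N CSA as a dimensionless fraction
        (default 160 ppm = 160e-6).
    theta_csa_deg:
        Angle between the CSA symmetry axis and the N-H vector, degrees.
        Enters cross-correlated rates through P2(cos θ); default collinear.
    """

    gamma_H: float = 2.6752218744e8
    gamma_N: float = -2.7116e7
    hbar: float = 1.054571817e-34
    mu0_over_4pi: float = 1.0e-7
    r_NH: float = 1.02e-10
    delta_sigma: float = 160.0e-6
    theta_csa_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gamma_N < 0.0 < self.gamma_H):
            raise ValueError("require gamma_N < 0 < gamma_H")
        if self.r_NH <= 0.0:
            raise ValueError("r_NH must be positive")
        if self.delta_sigma <= 0.0:
            raise ValueError("delta_sigma must be positive")
        for name in ("gamma_H", "gamma_N", "hbar", "mu0_over_4pi", "r_NH", "delta_sigma", "theta_csa_deg"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def p2_cos_theta(self) -> float:
        """Second Legendre polynomial of cos(theta_csa)."""
        c = math.cos(math.radians(self.theta_csa_deg))
        return 0.5 * (3.0 * c * c - 1.0)

    @classmethod
    def from_config(cls, overrides: Optional[dict] = None) -> "PhysicalConstants":
        """Build constants from a config override block.

        Recognized keys: gamma_h, gamma_n, r_nh_angstrom, delta_sigma_ppm,
        theta_csa_deg.  Unknown keys are rejected.
        """
        overrides = dict(overrides or {})
        kwargs = {}
        if "gamma_h" in overrides:
            kwargs["gamma_H"] = float(overrides.pop("gamma_h"))
        if "gamma_n" in overrides:
            kwargs["gamma_N"] = float(overrides.pop("gamma_n"))
        if "r_nh_angstrom" in overrides:
            kwargs["r_NH"] = float(overrides.pop("r_nh_angstrom")) * 1e-10
        if "delta_sigma_ppm" in overrides:
            kwargs["delta_sigma"] = float(overrides.pop("delta_sigma_ppm")) * 1e-6
        if "theta_csa_deg" in overrides:
            kwargs["theta_csa_deg"] = float(overrides.pop("theta_csa_deg"))
        if overrides:
            raise ValueError(f"unknown constants override keys: {sorted(overrides)}")
        return cls(**kwargs)


DEFAULT_CONSTANTS = PhysicalConstants()


def effective_high_freq_ratio(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Exact effective-high-frequency ratio ωeff/ωH.

    For a spectral density of the form λ + μ/ω² the cross-relaxation
    combination (6·J(ωH−|ωN|) − J(ωH+|ωN|))/5 equals J(ωeff) exactly at

        ωeff/ωH = sqrt(5 / (6/(1−r)² − 1/(1+r)²)),   r = |γN|/γH,

    which is 0.87007 for the default gyromagnetic ratios — the conventionally
    quoted 0.87, unrounded.  Using the exact value keeps noiseless round trips
    through the mapping at machine precision.
    """
    r = abs(constants.gamma_N) / constants.gamma_H
    return math.sqrt(5.0 / (6.0 / (1.0 - r) ** 2 - 1.0 / (1.0 + r) ** 2))


@dataclass(frozen=True)
class FieldContext:
    """All angular frequencies (rad/s, magnitudes) derived from one static field.

    ``omega_diff`` = ωH − |ωN| is the frequency written "ωH + ωN" in the
    signed-γ literature convention (it carries the factor 6 in rate
    expressions); ``omega_sum`` = ωH + |ωN|.
    """

    proton_mhz: float
    B0: float
    omega_H: float
    omega_N: float
    omega_eff: float
    omega_diff: float
    omega_sum: float

    @property
    def nitrogen_mhz(self) -> float:
        return self.omega_N / TWO_PI / 1e6

    @property
    def eff_mhz(self) -> float:
        return self.omega_eff / TWO_PI / 1e6


def make_field_context(
    proton_mhz: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> FieldContext:
    """Frequency bookkeeping for one static field given its proton Larmor frequency."""
    if not (proton_mhz > 0.0 and math.isfinite(proton_mhz)):
        raise ValueError(f"proton Larmor frequency must be positive and finite, got {proton_mhz}")
    omega_H = TWO_PI * proton_mhz * 1e6
    omega_N = omega_H * abs(constants.gamma_N) / constants.gamma_H
    return FieldContext(
        proton_mhz=float(proton_mhz),
        B0=omega_H / constants.gamma_H,
        omega_H=omega_H,
        omega_N=omega_N,
        omega_eff=effective_high_freq_ratio(constants) * omega_H,
        omega_diff=omega_H - omega_N,
        omega_sum=omega_H + omega_N,
    )


def interaction_constants(
    field: FieldContext, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Dipolar (d) and CSA (c) interaction constants in rad/s, signs carried.

    d = (μ0/4π)·ħ·γH·γN/r_NH³  (negative for ¹⁵N since γN < 0; only d² enters
    auto-relaxation, the sign matters for cross-correlated rates),
    c = γN·B0·Δσ/3.
    """
    d = constants.mu0_over_4pi * constants.hbar * constants.gamma_H * constants.gamma_N / constants.r_NH**3
    c = constants.gamma_N * field.B0 * constants.delta_sigma / 3.0
    return d, c


@dataclass
class RelaxationRecord:
    """Measured (or simulated) rates for one residue at one field.

    Missing observables are ``None`` (never zero-filled); each value carries a
    one-sigma uncertainty.  NOE is the dimensionless intensity ratio.
    """

    residue_id: int
    field: FieldContext
    R1: Optional[float] = None
    sigma_R1: float = 0.0
    NOE: Optional[float] = None
    sigma_NOE: float = 0.0
    eta_z: Optional[float] = None
    sigma_eta_z: float = 0.0
    eta_xy: Optional[float] = None
    sigma_eta_xy: float = 0.0
    R2: Optional[float] = None
    sigma_R2: float = 0.0

    OBSERVABLES = ("R1", "NOE", "eta_z", "eta_xy", "R2")

    def __post_init__(self) -> None:
        for obs in self.OBSERVABLES:
            sig = getattr(self, f"sigma_{obs}")
            if sig < 0.0:
                raise ValueError(f"sigma_{obs} must be >= 0")
        if self.R1 is not None and self.R1 <= 0.0:
            raise ValueError("R1 must be positive when present")

    def has(self, observable: str) -> bool:
        return getattr(self, observable) is not None

    def get(self, observable: str) -> tuple[Optional[float], float]:
        return getattr(self, observable), getattr(self, f"sigma_{observable}")

    def perturbed(self, rng: np.random.Generator) -> "RelaxationRecord":
        """Gaussian-perturbed copy (values drawn as N(value, sigma))."""
        kwargs = {}
        for obs in self.OBSERVABLES:
            val, sig = self.get(obs)
            if val is not None and sig > 0.0:
                kwargs[obs] = val + sig * rng.standard_normal()
        new = replace(self, **kwargs)
        # re-validate R1 positivity leniently: clip at a tiny positive value
        if new.R1 is not None and new.R1 <= 0.0:
            new = replace(new, R1=1e-6)
        return new


def forward_rates(
    J: Callable[[float], float],
    field: FieldContext,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    rex: float = 0.0,
    residue_id: int = 0,
) -> RelaxationRecord:
    """Noiseless observable rates from an arbitrary spectral density function.

    Standard expressions for an isolated ¹⁵N-¹H pair with axially symmetric
    ¹⁵N CSA (frequencies as magnitudes; factor 6 on ωH − |ωN|, see module
    docstring):

        R1   = (d²/4)[3J(ωN) + 6J(ωH−|ωN|) + J(ωH+|ωN|)] + c²·J(ωN)
        NOE  = 1 + (d²/4)(γH/γN)[6J(ωH−|ωN|) − J(ωH+|ωN|)] / R1
        R2   = (d²/8)[4J(0) + 3J(ωN) + 6J(ωH) + 6J(ωH−|ωN|) + J(ωH+|ωN|)]
               + (c²/6)[4J(0) + 3J(ωN)] + Rex
        η_z  = √3·d·c·P2(cosθ)·J(ωN)
        η_xy = (√3/6)·d·c·P2(cosθ)·[4J(0) + 3J(ωN)]

    Rex is a chemical-exchange contribution added to R2 only.
    """
    if rex < 0.0:
        raise ValueError("Rex must be non-negative")
    d, c = interaction_constants(field, constants)
    d2 = d * d
    c2 = c * c
    j0 = float(J(0.0))
    jn = float(J(field.omega_N))
    jh = float(J(field.omega_H))
    jm = float(J(field.omega_diff))  # carries the factor 6
    jp = float(J(field.omega_sum))

    r1 = (d2 / 4.0) * (3.0 * jn + 6.0 * jm + jp) + c2 * jn
    if r1 <= 0.0:
        raise ValueError("forward R1 is non-positive; NOE undefined")
    noe = 1.0 + (d2 / 4.0) * (constants.gamma_H / constants.gamma_N) * (6.0 * jm - jp) / r1
    r2 = (
        (d2 / 8.0) * (4.0 * j0 + 3.0 * jn + 6.0 * jh + 6.0 * jm + jp)
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn)
        + rex
    )
    p2 = constants.p2_cos_theta
    eta_z = math.sqrt(3.0) * d * c * p2 * jn
    eta_xy = (math.sqrt(3.0) / 6.0) * d * c * p2 * (4.0 * j0 + 3.0 * jn)
    return RelaxationRecord(
        residue_id=residue_id,
        field=field,
        R1=r1,
        NOE=noe,
        eta_z=eta_z,
        eta_xy=eta_xy,
        R2=r2,
    )


def lorentzian_j(
    taus: np.ndarray | list[float], weights: np.ndarray | list[float]
) -> Callable[[float], float]:
    """Multi-Lorentzian spectral density J(ω) = (2/5)·Σ w_i·τ_i/(1+(ωτ_i)²).

    ``taus`` in seconds; ``weights`` non-negative (normalized weights give
    J(0) = (2/5)·⟨τ⟩).  Returns a callable accepting scalar or array ω.
    """
    t = np.asarray(taus, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape:
        raise ValueError("taus and weights must have the same shape")
    if np.any(t <= 0.0):
        raise ValueError("correlation times must be positive")
    if np.any(w < 0.0):
        raise ValueError("weights must be non-negative")

    def j(omega):
        om = np.asarray(omega, dtype=float)
        val = 0.4 * np.sum(w * t / (1.0 + np.square(np.multiply.outer(om, t))), axis=-1)
        return float(val) if np.isscalar(omega) or om.ndim == 0 else val

    return j
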