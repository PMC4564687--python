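"""Reduced spectral density mapping without proton auto-relaxation.

Per residue, multi-field R1/NOE pairs give the effective high-frequency
spectral density J(ωeff ≈ 0.87·ωH) at each field; those points are fitted to
the two-parameter high-frequency model J(ω) = λ + μ/ω² (λ, μ ≥ 0), which
supplies the small J(ωH−|ωN|), J(ωH+|ωN|) corrections needed to extract J(ωN)
from R1.  J(0) is taken from the ratio of the CSA/DD cross-correlated rates
η_xy/η_z at a single designated field (highest available), deliberately
avoiding R2 and its chemical-exchange contamination.  Uncertainties are
propagated by Monte Carlo perturbation of the input rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .relaxation import (
    DEFAULT_CONSTANTS,
    FieldContext,
    PhysicalConstants,
    RelaxationRecord,
    interaction_constants,
)

__all__ = [
    "HighFreqModel",
    "SpectralDensityMap",
    "j_high",
    "fit_high_freq",
    "j_at_wn",
    "j_zero",
    "map_residue",
    "map_dataset",
    "DEFAULT_MC_STEPS",
    "DEFAULT_SEED",
]

logger = logging.getLogger(__name__)

DEFAULT_MC_STEPS = 510
DEFAULT_SEED = 20150901


@dataclass(frozen=True)
class HighFreqModel:
    """High-frequency model J(ω) = λ + μ/ω² with λ, μ ≥ 0."""

    lam: float
    mu: float
    ssr: float = 0.0
    boundary: bool = False

    def __call__(self, omega):
        om2 = np.square(np.asarray(omega, dtype=float))
        with np.errstate(divide="ignore"):
            return self.lam + self.mu / om2


@dataclass
class SpectralDensityMap:
    """Mapped spectral density points for one residue.

    ``labels`` entries are 'high' (J(ωeff)), 'nitrogen' (J(ωN)) or 'zero'
    (J(0)); exactly one zero-frequency point is present.  J values and sigmas
    in seconds, frequencies in rad/s.
    """

    residue_id: int
    omega: np.ndarray
    J: np.ndarray
    sigma: np.ndarray
    labels: np.ndarray
    j0_field_mhz: float
    fields_mhz: tuple[float, ...]
    hf: Optional[HighFreqModel] = None
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.omega)

    @property
    def freq_mhz(self) -> np.ndarray:
        return self.omega / (2.0 * math.pi) / 1e6

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_id,
                "label": self.labels,
                "freq_mhz": self.freq_mhz,
                "J_ns": self.J * 1e9,
                "sigma_J_ns": self.sigma * 1e9,
            }
        )


def j_high(
    R1,
    NOE,
    field: FieldContext,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Effective high-frequency spectral density from R1 and the NOE.

    J(ωeff) = 4·γN·R1·(NOE−1) / (5·d²·γH); with γN < 0 the result is
    positive for the physically normal NOE < 1.  Accepts scalars or arrays.
    """
    r1 = np.asarray(R1, dtype=float)
    if np.any(r1 <= 0.0):
        raise ValueError("R1 must be positive")
    d, _ = interaction_constants(field, constants)
    out = 4.0 * constants.gamma_N * r1 * (np.asarray(NOE, dtype=float) - 1.0) / (5.0 * d * d * constants.gamma_H)
    return float(out) if out.ndim == 0 else out


def _fit_lam_mu(omega: np.ndarray, jvals: np.ndarray, weights: np.ndarray):
    """Closed-form weighted least squares of J = λ + μ/ω² with λ, μ ≥ 0.

    ``jvals`` may carry leading batch dimensions (Monte Carlo draws); the fit
    is vectorized over them.  Non-negativity is enforced by comparing the
    unconstrained optimum with the two boundary solutions — exact for this
    two-parameter problem.  Returns (lam, mu, ssr, boundary_mask).
    """
    x = 1.0 / np.square(omega)
    w = weights
    s0 = np.sum(w)
    sx = np.sum(w * x)
    sxx = np.sum(w * x * x)
    det = s0 * sxx - sx * sx
    if det <= 1e-12 * s0 * sxx:
        raise ValueError("high-frequency fit is rank-deficient (all points at one frequency)")
    b0 = np.sum(w * jvals, axis=-1)
    bx = np.sum(w * x * jvals, axis=-1)

    lam_u = (sxx * b0 - sx * bx) / det
    mu_u = (s0 * bx - sx * b0) / det

    def ssr(lam, mu):
        resid = jvals - lam[..., None] - mu[..., None] * x
        return np.sum(w * resid * resid, axis=-1)

    lam_b = np.clip(b0 / s0, 0.0, None)  # mu = 0 boundary
    mu_c = np.clip(bx / sxx, 0.0, None)  # lam = 0 boundary
    zeros = np.zeros_like(lam_b)
    ssr_b = ssr(lam_b, zeros)
    ssr_c = ssr(zeros, mu_c)

    feasible = (lam_u >= 0.0) & (mu_u >= 0.0)
    use_b = ssr_b <= ssr_c
    lam = np.where(feasible, lam_u, np.where(use_b, lam_b, 0.0))
    mu = np.where(feasible, mu_u, np.where(use_b, 0.0, mu_c))
    out_ssr = np.where(feasible, ssr(np.asarray(lam_u), np.asarray(mu_u)), np.where(use_b, ssr_b, ssr_c))
    return lam, mu, out_ssr, ~feasible


def fit_high_freq(
    omega_eff: Sequence[float],
    j_values: Sequence[float],
    sigmas: Optional[Sequence[float]] = None,
) -> HighFreqModel:
    """Fit the λ + μ/ω² model to per-field J(ωeff) points (≥ 2 distinct fields).

    Inverse-variance weights when sigmas are supplied and positive, uniform
    otherwise.  With two exact points whose interpolating solution is
    non-negative, the fit reproduces them exactly.
    """
    om = np.asarray(omega_eff, dtype=float)
    jv = np.asarray(j_values, dtype=float)
    if om.ndim != 1 or om.shape != jv.shape:
        raise ValueError("omega_eff and j_values must be 1-D and the same length")
    if len(om) < 2:
        raise ValueError("need at least two fields to fit the high-frequency model")
    if sigmas is not None and np.any(np.asarray(sigmas) > 0.0):
        sig = np.asarray(sigmas, dtype=float)
        sig = np.where(sig > 0.0, sig, np.min(sig[sig > 0.0]))
        w = 1.0 / np.square(sig)
    else:
        w = np.ones_like(om)
    lam, mu, ssr, boundary = _fit_lam_mu(om, jv, w)
    return HighFreqModel(lam=float(lam), mu=float(mu), ssr=float(ssr), boundary=bool(boundary))


def j_at_wn(
    R1,
    field: FieldContext,
    hf: HighFreqModel,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """J(ωN) from R1 with the fitted high-frequency correction.

    J(ωN) = R1/(3d²/4 + c²) − (6·Jhf(ωH−|ωN|) + Jhf(ωH+|ωN|))/(3 + 4c²/d²),
    the factor 6 multiplying the lower of the two proton-side frequencies
    (signed-γ convention, see the relaxation module).  Exactly inverts the
    forward R1 whenever the model matches the true high-frequency density.
    """
    d, c = interaction_constants(field, constants)
    d2, c2 = d * d, c * c
    r1 = np.asarray(R1, dtype=float)
    corr = (6.0 * hf(field.omega_diff) + hf(field.omega_sum)) / (3.0 + 4.0 * c2 / d2)
    out = r1 / (0.75 * d2 + c2) - corr
    return float(out) if out.ndim == 0 else out


def j_zero(J_wn, eta_xy, eta_z, sigma_eta_z: float = 0.0):
    """J(0) from the cross-correlated rate ratio: J(0) = J(ωN)·(3/4)·(2·η_xy/η_z − 1).

    Refuses η_z values indistinguishable from zero (within 2σ) — at low field
    the η rates are not precise enough to anchor J(0).
    """
    ez = np.asarray(eta_z, dtype=float)
    exy = np.asarray(eta_xy, dtype=float)
    if np.any(ez == 0.0):
        raise ValueError("eta_z is zero; J(0) undefined")
    if np.isscalar(eta_z) or ez.ndim == 0:
        if abs(float(ez)) < 2.0 * sigma_eta_z:
            raise ValueError("eta_z within 2 sigma of zero; J(0) unreliable")
        if float(ez) * float(exy) < 0.0:
            raise ValueError("eta_z and eta_xy have opposite signs; inconsistent record")
    out = np.asarray(J_wn, dtype=float) * 0.75 * (2.0 * exy / ez - 1.0)
    return float(out) if out.ndim == 0 else out


def _hf_sigma_weights(j_sig: np.ndarray) -> np.ndarray:
    """Inverse-variance weights for the high-frequency fit, uniform if noiseless."""
    if np.any(j_sig > 0.0):
        floor = np.min(j_sig[j_sig > 0.0])
        return 1.0 / np.square(np.where(j_sig > 0.0, j_sig, floor))
    return np.ones_like(j_sig)


def map_residue(
    records: Sequence[RelaxationRecord],
    j0_field_mhz: Optional[float] = None,
    n_mc: int = DEFAULT_MC_STEPS,
    seed: int = DEFAULT_SEED,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SpectralDensityMap:
    """Map one residue's multi-field rates to spectral-density points.

    Returns one J(ωeff) and one J(ωN) point per complete field plus a single
    J(0) point from the designated field (default: highest field with a usable
    η_z/η_xy pair; lower fields are tried as fallback).  Point uncertainties
    come from ``n_mc`` Gaussian perturbations of the input rates; rates with
    zero sigma yield zero-sigma points.
    """
    if not records:
        raise ValueError("no records supplied")
    rid = records[0].residue_id
    if any(r.residue_id != rid for r in records):
        raise ValueError("records must all belong to one residue")
    recs = sorted(records, key=lambda r: r.field.proton_mhz)
    warnings: list[str] = []

    high_recs = [r for r in recs if r.has("R1") and r.has("NOE")]
    if len(high_recs) < 2:
        raise ValueError(
            f"residue {rid}: need R1+NOE at >= 2 fields to fit the high-frequency model, "
            f"got {len(high_recs)}"
        )
    r1_recs = [r for r in recs if r.has("R1")]

    # --- central values ---------------------------------------------------
    om_eff = np.array([r.field.omega_eff for r in high_recs])
    jh_central = np.array([j_high(r.R1, r.NOE, r.field, constants) for r in high_recs])
    jh_sig_analytic = np.array(
        [
            abs(4.0 * constants.gamma_N / (5.0 * interaction_constants(r.field, constants)[0] ** 2 * constants.gamma_H))
            * math.hypot((r.NOE - 1.0) * r.sigma_R1, r.R1 * r.sigma_NOE)
            for r in high_recs
        ]
    )
    hf_w = _hf_sigma_weights(jh_sig_analytic)
    lam, mu, ssr, boundary = _fit_lam_mu(om_eff, jh_central, hf_w)
    hf = HighFreqModel(lam=float(lam), mu=float(mu), ssr=float(ssr), boundary=bool(boundary))

    jn_central = np.array([j_at_wn(r.R1, r.field, hf, constants) for r in r1_recs])

    # designated J(0) field: highest with usable eta pair (and R1 for J(ωN))
    eta_candidates = [
        r for r in r1_recs if r.has("eta_z") and r.has("eta_xy") and r.eta_z != 0.0
    ]
    j0_rec = None
    if j0_field_mhz is not None:
        for r in eta_candidates:
            if abs(r.field.proton_mhz - j0_field_mhz) < 1e-6:
                j0_rec = r
                break
        if j0_rec is None:
            warnings.append(
                f"residue {rid}: requested J(0) field {j0_field_mhz} MHz has no usable eta pair; "
                "falling back to highest available"
            )
            logger.warning(warnings[-1])
    if j0_rec is None:
        for r in reversed(eta_candidates):
            if abs(r.eta_z) >= 2.0 * r.sigma_eta_z:
                j0_rec = r
                break
            warnings.append(
                f"residue {rid}: eta_z at {r.field.proton_mhz:g} MHz within 2 sigma of zero; "
                "trying next field"
            )
            logger.warning(warnings[-1])
    if j0_rec is None:
        raise ValueError(f"residue {rid}: no field provides a reliable eta_z/eta_xy pair for J(0)")

    j0_idx = r1_recs.index(j0_rec)
    j0_central = j_zero(jn_central[j0_idx], j0_rec.eta_xy, j0_rec.eta_z, j0_rec.sigma_eta_z)

    # --- Monte Carlo sigmas (vectorized over draws) ------------------------
    any_noise = any(
        sig > 0.0
        for r in recs
        for _, sig in (r.get(o) for o in ("R1", "NOE", "eta_z", "eta_xy"))
    )
    if any_noise and n_mc >= 2:
        rng = np.random.default_rng(seed)
        r1_draws_high = np.stack(
            [np.clip(r.R1 + r.sigma_R1 * rng.standard_normal(n_mc), 1e-6, None) for r in high_recs],
            axis=-1,
        )
        noe_draws = np.stack(
            [r.NOE + r.sigma_NOE * rng.standard_normal(n_mc) for r in high_recs], axis=-1
        )
        jh_draws = np.stack(
            [
                j_high(r1_draws_high[:, i], noe_draws[:, i], r.field, constants)
                for i, r in enumerate(high_recs)
            ],
            axis=-1,
        )
        lam_d, mu_d, _, _ = _fit_lam_mu(om_eff, jh_draws, hf_w)

        jn_draws = []
        r1_draws_all = {}
        for r in r1_recs:
            if r in high_recs:
                r1d = r1_draws_high[:, high_recs.index(r)]
            else:
                r1d = np.clip(r.R1 + r.sigma_R1 * rng.standard_normal(n_mc), 1e-6, None)
            r1_draws_all[id(r)] = r1d
            d, c = interaction_constants(r.field, constants)
            d2, c2 = d * d, c * c
            corr = (
                6.0 * (lam_d + mu_d / r.field.omega_diff**2)
                + (lam_d + mu_d / r.field.omega_sum**2)
            ) / (3.0 + 4.0 * c2 / d2)
            jn_draws.append(r1d / (0.75 * d2 + c2) - corr)
        jn_draws = np.stack(jn_draws, axis=-1)

        ez_d = j0_rec.eta_z + j0_rec.sigma_eta_z * rng.standard_normal(n_mc)
        exy_d = j0_rec.eta_xy + j0_rec.sigma_eta_xy * rng.standard_normal(n_mc)
        ez_d = np.where(np.abs(ez_d) < 1e-12, 1e-12, ez_d)
        j0_draws = jn_draws[:, j0_idx] * 0.75 * (2.0 * exy_d / ez_d - 1.0)

        jh_sig = np.std(jh_draws, axis=0, ddof=1)
        jn_sig = np.std(jn_draws, axis=0, ddof=1)
        j0_sig = float(np.std(j0_draws, ddof=1))
    else:
        jh_sig = np.zeros_like(jh_central)
        jn_sig = np.zeros_like(jn_central)
        j0_sig = 0.0

    omega = np.concatenate(
        [
            [r.field.omega_eff for r in high_recs],
            [r.field.omega_N for r in r1_recs],
            [0.0],
        ]
    )
    jvals = np.concatenate([jh_central, jn_central, [j0_central]])
    sig = np.concatenate([jh_sig, jn_sig, [j0_sig]])
    labels = np.array(["high"] * len(high_recs) + ["nitrogen"] * len(r1_recs) + ["zero"])

    neg = jvals + 3.0 * np.where(sig > 0, sig, np.inf) < 0.0
    if np.any(neg & (sig < np.inf)):
        warnings.append(f"residue {rid}: mapped J < -3 sigma at some points; record may be inconsistent")
        logger.warning(warnings[-1])

    return SpectralDensityMap(
        residue_id=rid,
        omega=omega,
        J=jvals,
        sigma=sig,
        labels=labels,
        j0_field_mhz=j0_rec.field.proton_mhz,
        fields_mhz=tuple(r.field.proton_mhz for r in recs),
        hf=hf,
        warnings=warnings,
    )


def map_dataset(
    records: Sequence[RelaxationRecord],
    j0_field_mhz: Optional[float] = None,
    n_mc: int = DEFAULT_MC_STEPS,
    seed: int = DEFAULT_SEED,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[dict[int, SpectralDensityMap], dict[int, str]]:
    """Map every residue in a dataset; returns (maps, excluded-with-reason).

    Each residue gets an independent Monte Carlo substream derived from
    ``seed`` so the result does not depend on residue ordering.
    """
    by_res: dict[int, list[RelaxationRecord]] = {}
    for r in records:
        by_res.setdefault(r.residue_id, []).append(r)
    maps: dict[int, SpectralDensityMap] = {}
    excluded: dict[int, str] = {}
    ss = np.random.SeedSequence(seed)
    for rid, child in zip(sorted(by_res), ss.spawn(len(by_res))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            maps[rid] = map_residue(
                by_res[rid], j0_field_mhz=j0_field_mhz, n_mc=n_mc, seed=sub_seed, constants=constants
            )
        except ValueError as exc:
            excluded[rid] = str(exc)
            logger.info("residue %d excluded from mapping: %s", rid, exc)
    return maps, excluded
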