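"""Global optimization of the IMPACT τ array (τ_min, τ_max, n) by AIC.

Every candidate array is fitted to every residue's spectral-density map and
the pooled fit quality is scored with Akaike's information criterion

    AIC = n_exp·ln(Σ_k χ²_k / n_exp) + 2·n_model,      (constant C = 0)

where n_exp is the total number of mapped spectral-density points and
n_model = (n−1)·n_res the number of free coefficients.  The τ_max/τ_min ratio
is fixed to 10³ by construction — the window of correlation times to which
multi-field ¹⁵N relaxation is actually sensitive spans roughly three decades.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .impact import ImpactGrid, build_grid, fit_impact
from .sdm import SpectralDensityMap

__all__ = [
    "AicSurface",
    "aic_total",
    "relative_likelihood",
    "default_tau_min_ladder",
    "search_grids",
]

logger = logging.getLogger(__name__)

DEFAULT_RATIO = 1.0e3
_CHI2_FLOOR = 1e-290


def aic_total(
    chi2_per_residue: Sequence[float], n_J: int, n_res: int, n_grid: int
) -> float:
    """Pooled AIC for one candidate array (C = 0).

    ``n_J`` is the number of spectral-density points per residue, ``n_grid``
    the number of correlation times in the array.  A zero total χ² is floored
    at the machine-log threshold rather than returning −∞.
    """
    if n_J <= 0 or n_res <= 0 or n_grid < 2:
        raise ValueError("counts must be positive and n_grid >= 2")
    chi2 = np.asarray(chi2_per_residue, dtype=float)
    if np.any(chi2 < 0.0):
        raise ValueError("chi2 values must be non-negative")
    n_exp = n_J * n_res
    total = float(np.sum(chi2))
    if total < n_exp * _CHI2_FLOOR:
        logger.warning("total chi2 underflows the AIC log; flooring")
        total = n_exp * _CHI2_FLOOR
    return n_exp * math.log(total / n_exp) + 2.0 * (n_grid - 1) * n_res


def relative_likelihood(delta_aic: float) -> float:
    """Relative likelihood exp(ΔAIC/2) of the higher-AIC model being as good."""
    return math.exp(delta_aic / 2.0)


def default_tau_min_ladder(
    tau_min_low: float = 1e-12, tau_min_high: float = 100e-12, count: int = 13
) -> np.ndarray:
    """Log-spaced candidate τ_min values, 1 ps … 100 ps inclusive by default."""
    return np.geomspace(tau_min_low, tau_min_high, count)


@dataclass
class AicSurface:
    """AIC over the (τ_min, n) candidate plane (τ_max = ratio·τ_min)."""

    table: pd.DataFrame
    ratio: float
    excluded_residues: dict[int, str] = dc_field(default_factory=dict)

    @property
    def best(self) -> pd.Series:
        return self.table.loc[self.table["aic"].idxmin()]

    @property
    def best_grid(self) -> ImpactGrid:
        row = self.best
        return build_grid(row["tau_min"], row["tau_min"] * self.ratio, int(row["n"]))

    @property
    def local_minima(self) -> pd.DataFrame:
        return self.table[self.table["is_local_min"]].sort_values("aic")


def _mark_local_minima(table: pd.DataFrame) -> None:
    """Flag entries whose AIC is <= all 4-neighbours in the (τ_min index, n) plane."""
    aic = {}
    for _, row in table.iterrows():
        aic[(int(row["i_tau"]), int(row["n"]))] = row["aic"]
    flags = []
    for _, row in table.iterrows():
        i, n = int(row["i_tau"]), int(row["n"])
        neighbours = [(i - 1, n), (i + 1, n), (i, n - 1), (i, n + 1)]
        flags.append(all(row["aic"] <= aic[k] for k in neighbours if k in aic))
    table["is_local_min"] = flags


def search_grids(
    maps: dict[int, SpectralDensityMap],
    tau_min_values: Optional[Sequence[float]] = None,
    ratio: float = DEFAULT_RATIO,
    n_values: Sequence[int] = range(4, 10),
) -> AicSurface:
    """Fit every residue on every candidate array and score each array by AIC.

    Residues whose maps cannot support the largest candidate array (fewer
    points than n−1 free parameters) are excluded from *all* candidates so
    the pooled χ² stays comparable.  Returns the full surface with local
    minima and ΔAIC relative to the optimum.
    """
    if not maps:
        raise ValueError("no residue maps supplied")
    taus_min = np.asarray(
        default_tau_min_ladder() if tau_min_values is None else tau_min_values, dtype=float
    )
    n_values = sorted(int(n) for n in n_values)
    if min(n_values) < 2:
        raise ValueError("candidate n must be >= 2")

    n_max = max(n_values)
    excluded: dict[int, str] = {}
    usable: dict[int, SpectralDensityMap] = {}
    for rid, smap in sorted(maps.items()):
        if smap.n_points < n_max - 1:
            excluded[rid] = (
                f"{smap.n_points} map points cannot constrain the largest candidate array (n={n_max})"
            )
            logger.info("residue %d excluded from grid search: %s", rid, excluded[rid])
        else:
            usable[rid] = smap
    if not usable:
        raise ValueError("no residue has enough map points for the grid search")

    points_per_res = {rid: m.n_points for rid, m in usable.items()}
    n_J_values = set(points_per_res.values())
    if len(n_J_values) > 1:
        logger.info("map point counts vary across residues: %s", sorted(n_J_values))
    n_res = len(usable)
    n_exp = sum(points_per_res.values())

    rows = []
    for i_tau, tmin in enumerate(taus_min):
        for n in n_values:
            grid = build_grid(tmin, tmin * ratio, n)
            chi2 = [fit_impact(smap, grid).chi2 for smap in usable.values()]
            total = float(np.sum(chi2))
            floored = max(total, n_exp * _CHI2_FLOOR)
            aic = n_exp * math.log(floored / n_exp) + 2.0 * (n - 1) * n_res
            rows.append(
                {
                    "i_tau": i_tau,
                    "tau_min": tmin,
                    "tau_min_ps": tmin * 1e12,
                    "tau_max": tmin * ratio,
                    "tau_max_ns": tmin * ratio * 1e9,
                    "n": n,
                    "total_chi2": total,
                    "n_exp": n_exp,
                    "n_model": (n - 1) * n_res,
                    "aic": aic,
                }
            )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    _mark_local_minima(table)
    return AicSurface(table=table, ratio=float(ratio), excluded_residues=excluded)
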