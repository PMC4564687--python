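"""Barcode representation: per-residue coefficient widths on a log-τ axis.

For each residue a stack of bars is drawn at the grid correlation times, the
width of each bar proportional to its coefficient.  Horizontal bands mark the
ranges of correlation times whose reciprocal frequencies τ = 1/(2πν) fall in
the windows actually constrained by the experiment — between the lowest and
highest nitrogen Larmor frequencies and between the lowest and highest
effective proton frequencies of the supplied field list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .impact import ImpactGrid, ImpactResult
from .modelfree import ModelSelection
from .relaxation import DEFAULT_CONSTANTS, PhysicalConstants, make_field_context

__all__ = [
    "BarcodeTable",
    "constrained_bands",
    "barcode",
    "barcode_modelfree",
    "read_regions",
    "render_barcode",
]

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


def constrained_bands(
    fields_mhz: Sequence[float], constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> list[dict]:
    """Frequency windows (MHz) sampled by the field list and their τ bands (s).

    Returns two bands: [min ωN, max ωN] and [min ωeff, max ωeff], each with
    the corresponding correlation-time range τ = 1/(2πν).  For 400–1000 MHz
    these are the familiar ~40–101 MHz and ~348–870 MHz windows.
    """
    if not fields_mhz:
        raise ValueError("field list is empty")
    ctxs = [make_field_context(f, constants) for f in fields_mhz]
    bands = []
    for name, freqs in (
        ("nitrogen", [c.omega_N for c in ctxs]),
        ("high", [c.omega_eff for c in ctxs]),
    ):
        lo, hi = min(freqs), max(freqs)
        # τ = 1/(2πν) = 1/ω: high-frequency edge maps to the short-τ edge
        bands.append(
            {
                "name": name,
                "nu_lo_mhz": lo / TWO_PI / 1e6,
                "nu_hi_mhz": hi / TWO_PI / 1e6,
                "tau_lo_s": 1.0 / hi,
                "tau_hi_s": 1.0 / lo,
            }
        )
    return bands


@dataclass
class BarcodeTable:
    """Long-form (residue, τ, width) table plus the constrained-frequency bands."""

    table: pd.DataFrame  # columns: residue, tau_s, width
    bands: list[dict]
    regions: Optional[pd.DataFrame] = None
    meta: dict = dc_field(default_factory=dict)


def barcode(
    results: Sequence[ImpactResult],
    grid: ImpactGrid,
    fields_mhz: Sequence[float],
    regions: Optional[pd.DataFrame] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> BarcodeTable:
    """Build the barcode table from fitted coefficients (one result per residue)."""
    if len({r.residue_id for r in results}) != len(results):
        raise ValueError("expect exactly one result per residue")
    rows = []
    for res in results:
        for tau, a in zip(grid.taus, res.A):
            rows.append({"residue": res.residue_id, "tau_s": tau, "width": a})
    if not rows:
        logger.warning("barcode: empty result list")
        df = pd.DataFrame(columns=["residue", "tau_s", "width"])
    else:
        df = pd.DataFrame(rows)
    return BarcodeTable(
        table=df,
        bands=constrained_bands(fields_mhz, constants),
        regions=regions,
        meta={"kind": "impact", "n": grid.n},
    )


def barcode_modelfree(
    selections: Sequence[ModelSelection],
    fields_mhz: Sequence[float],
    regions: Optional[pd.DataFrame] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> BarcodeTable:
    """Barcode table from 2CT/3CT fits: bars at the fitted times with B widths."""
    rows = []
    for s in selections:
        if s.model == "3CT" and s.params_3ct is not None:
            p = s.params_3ct
            for tau, b in zip((p.tau_a, p.tau_b, p.tau_c), s.B):
                rows.append({"residue": s.residue_id, "tau_s": tau, "width": b})
        elif s.params_2ct is not None:
            p = s.params_2ct
            for tau, b in zip((p.tau_a, p.tau_b), (p.S2, 1.0 - p.S2)):
                rows.append({"residue": s.residue_id, "tau_s": tau, "width": b})
    df = pd.DataFrame(rows, columns=["residue", "tau_s", "width"])
    return BarcodeTable(
        table=df,
        bands=constrained_bands(fields_mhz, constants),
        regions=regions,
        meta={"kind": "modelfree"},
    )


def read_regions(path: Path | str) -> pd.DataFrame:
    """Read a segment-annotation file: three columns start, end, label.

    Positions are 1-based and inclusive on both ends, matching protein residue
    numbering (unlike BED, which is 0-based half-open).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected three columns (start, end, label)")
    df = df.iloc[:, :3]
    df.columns = ["start", "end", "label"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: region start must be <= end")
    return df


def render_barcode(bt: BarcodeTable, path: Path | str, min_width: float = 0.02) -> None:
    """Render the barcode to SVG/PNG with matplotlib (data and drawing separated)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for band in bt.bands:
        ax.axhspan(band["tau_lo_s"] * 1e9, band["tau_hi_s"] * 1e9, color="lightblue", alpha=0.5, zorder=0)
    df = bt.table
    for rid, grp in df.groupby("residue"):
        for _, row in grp.iterrows():
            w = row["width"]
            if w < min_width:
                continue
            ax.plot(
                [rid - 0.45 * w, rid + 0.45 * w],
                [row["tau_s"] * 1e9] * 2,
                lw=3,
                color="darkred",
                solid_capstyle="butt",
            )
    if bt.regions is not None:
        for _, reg in bt.regions.iterrows():
            ax.axvspan(reg["start"] - 0.5, reg["end"] + 0.5, color="gray", alpha=0.2)
    ax.set_yscale("log")
    ax.set_xlabel("residue")
    ax.set_ylabel("correlation time (ns)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
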