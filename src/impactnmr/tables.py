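"""Delimited-text readers and writers for rates, maps, coefficients and results.

The rate-table interchange format is long-form with one row per
residue × field × observable:

    residue, field_mhz, observable, value, sigma

with ``observable`` one of R1, R2, NOE, eta_z, eta_xy.  Comma or tab
separation is auto-detected; decimal points only; UTF-8.  Output tables are
tab-separated and carry a header comment with tool version, seed and config
hash so runs can be traced.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .impact import ImpactGrid, ImpactResult
from .modelfree import ModelSelection
from .relaxation import DEFAULT_CONSTANTS, PhysicalConstants, RelaxationRecord, make_field_context
from .sdm import SpectralDensityMap

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "write_map_table",
    "write_coefficients_table",
    "read_coefficients_table",
    "write_modelfree_table",
    "write_aic_table",
    "header_comment",
]

logger = logging.getLogger(__name__)

_OBSERVABLES = set(RelaxationRecord.OBSERVABLES)
_RATE_COLUMNS = ["residue", "field_mhz", "observable", "value", "sigma"]


def header_comment(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    """Provenance header line(s) prepended to every output table."""
    parts = [f"impactnmr {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
        parts.append(f"config_sha256={digest}")
    return "# " + " ".join(parts) + "\n"


def _write_df(df: pd.DataFrame, path: Path | str, seed=None, config=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_comment(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=False)


def read_rate_table(
    path: Path | str, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> list[RelaxationRecord]:
    """Read a long-form rate table into validated records.

    Duplicate (residue, field, observable) rows and malformed rows are
    rejected with the offending line numbers; missing observables are simply
    absent from the resulting records.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data_lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    if not any(ln.strip() for ln in data_lines):
        raise ValueError(f"{path}: empty rate table")
    sep = "\t" if "\t" in data_lines[0] else ","
    df = pd.read_csv(
        io.StringIO("\n".join(data_lines)), sep=sep, skipinitialspace=True, float_precision="round_trip"
    )
    missing = [c for c in _RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    # line numbers in the original file (1-based; +1 for the header row)
    comment_offsets = [i for i, ln in enumerate(text.splitlines()) if ln.lstrip().startswith("#")]
    line_no = df.index + 2 + len([o for o in comment_offsets if o < df.index.max() + 2])

    bad = df.index[~df["observable"].isin(_OBSERVABLES)]
    if len(bad) > 0:
        raise ValueError(
            f"{path}: unknown observable(s) at line(s) {sorted(line_no[bad].tolist())}; "
            f"expected one of {sorted(_OBSERVABLES)}"
        )
    for col in ("value", "sigma"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad) > 0:
            raise ValueError(f"{path}: non-numeric '{col}' at line(s) {sorted(line_no[bad].tolist())}")
        df[col] = vals
    dup = df.duplicated(subset=["residue", "field_mhz", "observable"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (residue, field, observable) rows at line(s) "
            f"{sorted(line_no[df.index[dup]].tolist())}"
        )

    field_cache: dict[float, object] = {}
    records: list[RelaxationRecord] = []
    for (rid, fmhz), grp in df.groupby(["residue", "field_mhz"], sort=True):
        fmhz = float(fmhz)
        if fmhz not in field_cache:
            field_cache[fmhz] = make_field_context(fmhz, constants)
        kwargs: dict = {"residue_id": int(rid), "field": field_cache[fmhz]}
        for _, row in grp.iterrows():
            obs = row["observable"]
            kwargs[obs] = float(row["value"])
            kwargs[f"sigma_{obs}"] = float(row["sigma"])
        records.append(RelaxationRecord(**kwargs))
    return records


def write_rate_table(
    records: Iterable[RelaxationRecord], path: Path | str, seed=None, config=None
) -> None:
    """Write records in the long-form interchange format (lossless round trip)."""
    rows = []
    for r in records:
        for obs in RelaxationRecord.OBSERVABLES:
            val, sig = r.get(obs)
            if val is not None:
                rows.append(
                    {
                        "residue": r.residue_id,
                        "field_mhz": r.field.proton_mhz,
                        "observable": obs,
                        "value": repr(val),
                        "sigma": repr(sig),
                    }
                )
    _write_df(pd.DataFrame(rows, columns=_RATE_COLUMNS), path, seed=seed, config=config)


def write_map_table(
    maps: Sequence[SpectralDensityMap], path: Path | str, seed=None, config=None
) -> None:
    """Write mapped spectral-density points (J in ns) for all residues."""
    df = pd.concat([m.as_dataframe() for m in maps], ignore_index=True)
    _write_df(df, path, seed=seed, config=config)


def write_coefficients_table(
    results: Sequence[ImpactResult], grid: ImpactGrid, path: Path | str, seed=None, config=None
) -> None:
    """Write per-residue coefficients A_i (columns named by τ_i in ns) and χ²."""
    tau_cols = [f"A_{i+1}" for i in range(grid.n)]
    sig_cols = [f"sigma_A_{i+1}" for i in range(grid.n)]
    rows = []
    for res in results:
        row = {"residue": res.residue_id}
        row.update({c: res.A[i] for i, c in enumerate(tau_cols)})
        sig = res.sigma_A if res.sigma_A is not None else np.full(grid.n, np.nan)
        row.update({c: sig[i] for i, c in enumerate(sig_cols)})
        row["chi2"] = res.chi2
        row["n_points"] = res.n_points
        row["flags"] = ";".join(res.flags)
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_comment(seed=seed, config=config))
        fh.write("# tau_ns\t" + "\t".join(f"{t:.6g}" for t in grid.taus_ns) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_coefficients_table(path: Path | str) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a coefficients table back; returns (dataframe, tau array in ns)."""
    path = Path(path)
    taus = None
    for ln in path.read_text(encoding="utf-8").splitlines():
        if ln.startswith("# tau_ns"):
            taus = np.array([float(x) for x in ln.split("\t")[1:]])
            break
    df = pd.read_csv(path, sep="\t", comment="#")
    if taus is None:
        raise ValueError(f"{path}: no '# tau_ns' header found")
    return df, taus


def write_modelfree_table(
    selections: Sequence[ModelSelection], path: Path | str, seed=None, config=None
) -> None:
    """Write per-residue 2CT/3CT parameters, AICc values and B weights."""
    rows = []
    for s in selections:
        p2, p3 = s.params_2ct, s.params_3ct
        rows.append(
            {
                "residue": s.residue_id,
                "model": s.model,
                "S2": p2.S2 if p2 else np.nan,
                "tau_a_ns_2ct": p2.tau_a * 1e9 if p2 else np.nan,
                "tau_b_ns_2ct": p2.tau_b * 1e9 if p2 else np.nan,
                "S2_3ct": p3.S2 if p3 else np.nan,
                "Sf2": p3.Sf2 if p3 else np.nan,
                "tau_a_ns": p3.tau_a * 1e9 if p3 else np.nan,
                "tau_b_ns": p3.tau_b * 1e9 if p3 else np.nan,
                "tau_c_ps": p3.tau_c * 1e12 if p3 else np.nan,
                "aicc_2ct": s.aicc_2ct,
                "aicc_3ct": s.aicc_3ct,
                "Ba": s.B[0],
                "Bb": s.B[1],
                "Bc": s.B[2],
                "flags": ";".join(s.flags),
            }
        )
    _write_df(pd.DataFrame(rows), path, seed=seed, config=config)


def write_aic_table(surface, path: Path | str, seed=None, config=None) -> None:
    """Write the AIC surface (tau_min_ps, n, aic, delta_aic, is_local_min)."""
    cols = ["tau_min_ps", "tau_max_ns", "n", "total_chi2", "n_exp", "n_model", "aic", "delta_aic", "is_local_min"]
    _write_df(surface.table[cols], path, seed=seed, config=config)
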