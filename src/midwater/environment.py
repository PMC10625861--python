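"""Coupling CTD profiles to net samples and per-taxon environmental ranges.

Each net's mean environment is the average of the province's 1-m CTD bins
across the net's depth interval; a taxon's environmental range for a
variable is the max minus min of those net means over every
(province, stratum) cell in which the taxon occurred.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io import ReadMatrix

__all__ = [
    "ENV_VARIABLES",
    "EnvRange",
    "net_environment",
    "taxon_env_range",
    "env_range_table",
]

#: variable name -> column in the net-environment table
ENV_VARIABLES = {
    "temperature": "mean_temperature_C",
    "oxygen": "mean_oxygen",
    "chla": "mean_chla",
}

_PROFILE_COLS = {"temperature": "temperature_C", "oxygen": "oxygen", "chla": "chla"}


@dataclass(frozen=True)
class EnvRange:
    taxon_id: str
    variable: str
    range: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_cells == 1 and self.range != 0.0:
            raise ValueError("single-cell occupancy must have zero range")


def net_environment(
    profiles: Mapping[str, pd.DataFrame], meta: pd.DataFrame
) -> pd.DataFrame:
    """Mean CTD values over each (province, stratum) depth interval.

    Depth intervals are half-open [upper, lower) against integer 1-m bins;
    the deepest stratum is closed at its lower bound.  Day and night tows
    at a station share the same environment (one CTD cast per location).
    """
    cells = (
        meta[["province", "stratum_index", "stratum_upper_m", "stratum_lower_m"]]
        .drop_duplicates()
        .sort_values(["province", "stratum_index"])
    )
    deepest = meta["stratum_index"].max()
    rows = []
    for cell in cells.itertuples(index=False):
        if cell.province not in profiles:
            raise ValueError(f"no CTD profile for province {cell.province!r}")
        prof = profiles[cell.province].set_index("depth_m")
        last = int(cell.stratum_lower_m) if cell.stratum_index == deepest else int(
            cell.stratum_lower_m) - 1
        bins = np.arange(int(cell.stratum_upper_m), last + 1)
        missing = np.setdiff1d(bins, prof.index.to_numpy())
        if missing.size:
            raise ValueError(
                f"CTD profile for {cell.province!r} has no bins at depths "
                f"{missing[:5].tolist()}... inside stratum "
                f"{cell.stratum_upper_m}-{cell.stratum_lower_m} m"
            )
        sub = prof.loc[bins]
        rows.append(
            {
                "province": cell.province,
                "stratum_index": int(cell.stratum_index),
                "stratum_upper_m": cell.stratum_upper_m,
                "stratum_lower_m": cell.stratum_lower_m,
                "n_bins": len(bins),
                "mean_temperature_C": float(sub["temperature_C"].mean()),
                "mean_oxygen": float(sub["oxygen"].mean()),
                "mean_chla": float(sub["chla"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _occupied_cells(matrix: ReadMatrix, meta: pd.DataFrame, taxon_id: str):
    """(province, stratum_index) cells with >= 1 read, pooled over tows."""
    if taxon_id not in matrix.data.index:
        raise KeyError(f"unknown taxon {taxon_id!r}")
    m = meta.set_index("sample_id")
    row = matrix.data.loc[taxon_id]
    cells = {
        (m.loc[s, "province"], int(m.loc[s, "stratum_index"]))
        for s in matrix.data.columns
        if row[s] > 0 and s in m.index
    }
    return cells


def taxon_env_range(
    matrix: ReadMatrix,
    meta: pd.DataFrame,
    envs: pd.DataFrame,
    taxon_id: str,
    variable: str,
) -> EnvRange:
    """Max minus min of the net-mean variable over a taxon's occupied cells."""
    if variable not in ENV_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    cells = _occupied_cells(matrix, meta, taxon_id)
    if not cells:
        raise ValueError(f"taxon {taxon_id!r} occurs in no sample")
    env = envs.set_index(["province", "stratum_index"])
    values = [env.loc[c, ENV_VARIABLES[variable]] for c in sorted(cells)]
    return EnvRange(
        taxon_id=taxon_id,
        variable=variable,
        range=float(max(values) - min(values)),
        n_cells=len(cells),
    )


def env_range_table(
    matrix: ReadMatrix, meta: pd.DataFrame, envs: pd.DataFrame
) -> pd.DataFrame:
    """Environmental ranges for every observed taxon and every variable."""
    env = envs.set_index(["province", "stratum_index"])
    m = meta.set_index("sample_id")
    cols = [s for s in matrix.data.columns if s in m.index]
    cell_of = [(m.loc[s, "province"], int(m.loc[s, "stratum_index"])) for s in cols]
    present = matrix.data[cols].to_numpy() > 0
    rows = []
    for i, taxon in enumerate(matrix.data.index):
        cells = sorted({cell_of[j] for j in np.flatnonzero(present[i])})
        if not cells:
            continue
        row = {"taxon_id": taxon, "n_cells": len(cells)}
        for var, col in ENV_VARIABLES.items():
            values = env.loc[cells, col]
            row[f"{var}_range"] = float(values.max() - values.min())
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon_id")
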