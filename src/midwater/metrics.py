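"""Per-taxon vertical statistics.

Mean depth of occurrence (MDO): the average of net midpoints over all nets
in which a taxon was observed, weighted by the taxon's relative read
abundance within each net.  Taxa are classified as epipelagic (MDO <= 200 m)
or mesopelagic (MDO > 200 m), and diel vertical migration is inferred from
day/night read-depth shifts through a four-criterion rule:

C1  observed in at least two nets in the day tow and two in the night tow;
C2  tow-level relative abundances (taxon reads / tow total reads) no more
    than twofold different between day and night;
C3  the taxon holds at least 0.01% of the study's total reads (per marker);
C4  the weighted mean depth shifts by at least two sampling strata between
    day and night.

A taxon is a migrator if all four criteria hold at one or more stations.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io import ReadMatrix, stratum_index_for_depth, to_relative
from .stats import spearman

__all__ = [
    "DvmCriteria",
    "DvmStationDiagnostics",
    "DvmResult",
    "mdo",
    "mdo_table",
    "classify_habitat",
    "detect_dvm",
    "dvm_table",
    "size_depth_correlation",
    "taxon_metrics_table",
]

HABITAT_BOUNDARY_M = 200.0


def _relative(matrix: ReadMatrix) -> ReadMatrix:
    return matrix if matrix.mode == "relative" else to_relative(matrix)


def mdo(
    matrix: ReadMatrix,
    meta: pd.DataFrame,
    taxon_id: str,
    station: str | None = None,
    tow_period: str | None = None,
) -> float:
    """Mean depth of occurrence for one taxon (metres), NaN if never observed.

    MDO = sum(r_i * mid_i) / sum(r_i) over nets i where the taxon occurs,
    with r_i its relative abundance in net i and mid_i the stratum midpoint.
    ``station``/``tow_period`` restrict the scope (per-tow MDO); by default
    all nets from all stations and tows are pooled.
    """
    rel = _relative(matrix)
    if taxon_id not in rel.data.index:
        raise KeyError(f"unknown taxon {taxon_id!r}")
    scope = meta
    if station is not None:
        scope = scope[scope["station"] == station]
    if tow_period is not None:
        scope = scope[scope["tow_period"] == tow_period]
    cols = [s for s in scope["sample_id"] if s in rel.data.columns]
    r = rel.data.loc[taxon_id, cols].to_numpy(dtype=float)
    mids = scope.set_index("sample_id").loc[cols, "stratum_midpoint_m"].to_numpy()
    total = r.sum()
    if total == 0:
        return float("nan")
    return float((r * mids).sum() / total)


def mdo_table(matrix: ReadMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Overall and per-(station, tow) MDO for every taxon, vectorised."""
    rel = _relative(matrix)
    cols = [s for s in meta["sample_id"] if s in rel.data.columns]
    r = rel.data[cols].to_numpy(dtype=float)
    m = meta.set_index("sample_id").loc[cols]
    mids = m["stratum_midpoint_m"].to_numpy()

    def weighted(mask: np.ndarray) -> np.ndarray:
        w = r[:, mask]
        tot = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, (w * mids[mask]).sum(axis=1) / tot, np.nan)

    out = pd.DataFrame(index=rel.data.index)
    out["mdo_overall_m"] = weighted(np.ones(len(cols), dtype=bool))
    for (station, period), sub in m.groupby(["station", "tow_period"], sort=True):
        mask = np.asarray([(s in set(sub.index)) for s in cols])
        out[f"mdo_{station}_{period}_m"] = weighted(mask)
    return out


def classify_habitat(
    mdo_overall_m: float, boundary_m: float = HABITAT_BOUNDARY_M
) -> str | None:
    """'mesopelagic' iff MDO > boundary, else 'epipelagic'; None for missing.

    The boundary itself counts as epipelagic (strict inequality for the
    mesopelagic class).
    """
    if mdo_overall_m is None or np.isnan(mdo_overall_m):
        return None
    return "mesopelagic" if mdo_overall_m > boundary_m else "epipelagic"


@dataclass(frozen=True)
class DvmCriteria:
    """Thresholds of the four-criterion migration rule."""

    min_nets_per_tow: int = 2
    max_fold_change: float = 2.0
    min_study_share: float = 1e-4
    min_stratum_shift: int = 2


@dataclass(frozen=True)
class DvmStationDiagnostics:
    station: str
    c1_nets: bool
    c2_abundance: bool
    c4_shift: bool
    nets_day: int
    nets_night: int
    share_day: float
    share_night: float
    wmd_day_m: float
    wmd_night_m: float
    stratum_shift: int | None


@dataclass(frozen=True)
class DvmResult:
    taxon_id: str
    dvm: bool
    c3_study_share: bool
    study_share: float
    stations: tuple[DvmStationDiagnostics, ...]


def detect_dvm(
    matrix_counts: ReadMatrix,
    meta: pd.DataFrame,
    taxon_id: str,
    criteria: DvmCriteria | None = None,
    matrix_rel: ReadMatrix | None = None,
) -> DvmResult:
    """Evaluate the four-criterion day/night migration rule for one taxon.

    C1, C2 and C4 are assessed per station (every station with both a day
    and a night tow); C3 is study-wide within the marker.  The taxon is a
    migrator if some station satisfies C1, C2 and C4 while C3 holds.
    """
    criteria = criteria or DvmCriteria()
    if matrix_counts.mode != "counts":
        raise ValueError("detect_dvm needs the counts matrix for tow totals")
    if taxon_id not in matrix_counts.data.index:
        raise KeyError(f"unknown taxon {taxon_id!r}")
    rel = matrix_rel if matrix_rel is not None else to_relative(matrix_counts)

    counts = matrix_counts.data
    study_total = counts.to_numpy().sum()
    study_share = float(counts.loc[taxon_id].sum() / study_total) if study_total else 0.0
    c3 = study_share >= criteria.min_study_share

    strata = (
        meta[["stratum_index", "stratum_upper_m", "stratum_lower_m"]]
        .drop_duplicates()
        .sort_values("stratum_index")
    )
    strata_bounds = list(zip(strata["stratum_upper_m"], strata["stratum_lower_m"]))

    diagnostics = []
    paired = False
    for station, sub in meta.groupby("station"):
        periods = set(sub["tow_period"])
        if not {"day", "night"} <= periods:
            continue
        paired = True
        day_ids = sub.loc[sub["tow_period"] == "day", "sample_id"].tolist()
        night_ids = sub.loc[sub["tow_period"] == "night", "sample_id"].tolist()

        nets_day = int((counts.loc[taxon_id, day_ids] > 0).sum())
        nets_night = int((counts.loc[taxon_id, night_ids] > 0).sum())
        c1 = (nets_day >= criteria.min_nets_per_tow
              and nets_night >= criteria.min_nets_per_tow)

        tow_day_total = counts[day_ids].to_numpy().sum()
        tow_night_total = counts[night_ids].to_numpy().sum()
        share_day = (counts.loc[taxon_id, day_ids].sum() / tow_day_total
                     if tow_day_total else 0.0)
        share_night = (counts.loc[taxon_id, night_ids].sum() / tow_night_total
                       if tow_night_total else 0.0)
        if share_day > 0 and share_night > 0:
            fold = max(share_day, share_night) / min(share_day, share_night)
            c2 = fold <= criteria.max_fold_change
        else:
            c2 = False

        wmd_day = mdo(rel, meta, taxon_id, station=station, tow_period="day")
        wmd_night = mdo(rel, meta, taxon_id, station=station, tow_period="night")
        if np.isnan(wmd_day) or np.isnan(wmd_night):
            shift = None
            c4 = False
        else:
            shift = abs(
                stratum_index_for_depth(wmd_day, strata_bounds)
                - stratum_index_for_depth(wmd_night, strata_bounds)
            )
            c4 = shift >= criteria.min_stratum_shift
        diagnostics.append(
            DvmStationDiagnostics(
                station=str(station), c1_nets=c1, c2_abundance=c2, c4_shift=c4,
                nets_day=nets_day, nets_night=nets_night,
                share_day=float(share_day), share_night=float(share_night),
                wmd_day_m=float(wmd_day), wmd_night_m=float(wmd_night),
                stratum_shift=shift,
            )
        )
    if not paired:
        raise ValueError("no station has paired day and night tows")
    dvm = c3 and any(d.c1_nets and d.c2_abundance and d.c4_shift for d in diagnostics)
    return DvmResult(taxon_id=taxon_id, dvm=dvm, c3_study_share=c3,
                     study_share=study_share, stations=tuple(diagnostics))


def dvm_table(
    matrix_counts: ReadMatrix,
    meta: pd.DataFrame,
    criteria: DvmCriteria | None = None,
) -> pd.DataFrame:
    """DVM call plus per-criterion diagnostics for every taxon."""
    rel = to_relative(matrix_counts)
    rows = []
    for taxon in matrix_counts.taxa:
        res = detect_dvm(matrix_counts, meta, taxon, criteria, matrix_rel=rel)
        best = max(
            res.stations,
            key=lambda d: (d.c1_nets + d.c2_abundance + d.c4_shift,
                           d.stratum_shift or 0),
        )
        rows.append(
            {
                "taxon_id": taxon,
                "dvm": "yes" if res.dvm else "no",
                "c1_min_nets": best.c1_nets,
                "c2_fold_change": best.c2_abundance,
                "c3_study_share": res.c3_study_share,
                "c4_stratum_shift": best.c4_shift,
                "study_share": res.study_share,
                "best_station": best.station,
                "wmd_day_m": best.wmd_day_m,
                "wmd_night_m": best.wmd_night_m,
                "stratum_shift": best.stratum_shift,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def size_depth_correlation(
    body_size_mm: pd.Series, mdo_m: pd.Series
) -> tuple[float, float] | None:
    """Ties-corrected Spearman correlation of body size against MDO.

    Pairs with either value missing are dropped; returns None when fewer
    than three complete pairs remain (result flagged missing).
    """
    df = pd.DataFrame({"size": body_size_mm, "mdo": mdo_m}).dropna()
    if len(df) < 3:
        return None
    return spearman(df["size"].to_numpy(), df["mdo"].to_numpy())


def taxon_metrics_table(
    matrix_counts: ReadMatrix,
    meta: pd.DataFrame,
    boundary_m: float = HABITAT_BOUNDARY_M,
    criteria: DvmCriteria | None = None,
) -> pd.DataFrame:
    """Combined per-taxon metrics: MDO, habitat, DVM, occupancy, share."""
    mdos = mdo_table(matrix_counts, meta)
    dvm = dvm_table(matrix_counts, meta, criteria)
    counts = matrix_counts.data
    total = counts.to_numpy().sum()
    present = counts > 0
    prov_of = meta.set_index("sample_id")["province"]
    occupancy = [
        ";".join(sorted(set(prov_of[s] for s in counts.columns[present.loc[t]])))
        for t in counts.index
    ]
    out = pd.DataFrame(index=counts.index)
    out.index.name = "taxon_id"
    out["marker"] = matrix_counts.marker
    for col in mdos.columns:
        out[col] = mdos[col]
    out["habitat"] = [classify_habitat(v, boundary_m) for v in out["mdo_overall_m"]]
    out["dvm"] = dvm["dvm"]
    out["occupancy"] = occupancy
    out["n_provinces"] = [len(o.split(";")) if o else 0 for o in occupancy]
    out["global_share"] = counts.sum(axis=1) / total if total else 0.0
    for col in ("c1_min_nets", "c2_fold_change", "c3_study_share",
                "c4_stratum_shift", "wmd_day_m", "wmd_night_m", "stratum_shift"):
        out[col] = dvm[col]
    return out
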