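"""Canonical data containers and plain-text readers/writers.

The pipeline operates on four tables: a taxon-by-sample read-count matrix
per molecular marker, a sample-metadata table describing the survey design
(province, station, day/night tow, depth stratum), per-province CTD
profiles binned to 1 m, and a trait table keyed by taxonomic name.  All
files are plain TSV/CSV; readers validate the type invariants and raise
:class:`ParseError` pointing at the offending row/column.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_STRATA",
    "TOW_PERIODS",
    "ParseError",
    "ReadMatrix",
    "TaxonTraits",
    "TRAIT_VOCABULARY",
    "build_sample_meta",
    "combine_markers",
    "lookup_traits",
    "merge_replicates",
    "read_profiles",
    "read_read_matrix",
    "read_sample_meta",
    "read_trait_table",
    "stratum_index_for_depth",
    "to_relative",
    "validate_profiles",
    "validate_sample_meta",
    "write_profiles",
    "write_read_matrix",
    "write_sample_meta",
    "write_trait_table",
]

#: The survey's eight depth strata, shallow to deep, as (upper, lower) metres.
DEFAULT_STRATA: tuple[tuple[float, float], ...] = (
    (0.0, 25.0),
    (25.0, 50.0),
    (50.0, 100.0),
    (100.0, 200.0),
    (200.0, 400.0),
    (400.0, 600.0),
    (600.0, 800.0),
    (800.0, 1000.0),
)

TOW_PERIODS: tuple[str, str] = ("day", "night")

#: Allowed states per categorical trait.
TRAIT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "diet": ("carnivore", "omnivore", "herbivore"),
    "feeding": ("ambush", "cruise", "parasitoid", "suspension"),
    "spawning": ("broadcast", "brooding"),
    "asexual": ("yes", "no"),
    "composition": ("gelatinous", "intermediate", "non-gelatinous"),
    "dvm": ("yes", "no"),
}

META_COLUMNS = (
    "sample_id",
    "province",
    "station",
    "tow_period",
    "stratum_upper_m",
    "stratum_lower_m",
    "stratum_index",
    "stratum_midpoint_m",
)


class ParseError(ValueError):
    """A file violated a type invariant; the message locates the offence."""


# ---------------------------------------------------------------------------
# Read matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadMatrix:
    """Taxon-by-sample abundance matrix for one molecular marker.

    Parameters
    ----------
    data
        DataFrame with taxon ids as the index and sample ids as columns.
        Non-negative integers in ``counts`` mode; in ``relative`` mode every
        non-empty column sums to 1 within 1e-9.
    marker
        Marker label, e.g. ``"COI"`` or ``"18S"``.
    mode
        ``"counts"`` or ``"relative"``.
    zero_samples
        Sample ids whose column is entirely zero (degenerate but allowed).
    """

    data: pd.DataFrame
    marker: str
    mode: str = "counts"
    zero_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown matrix mode {self.mode!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate taxon ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            t, s = np.argwhere(values < 0)[0]
            raise ParseError(
                f"negative abundance for taxon {idx[t]!r} in sample {cols[s]!r}"
            )
        if self.mode == "counts":
            if values.size and not np.array_equal(values, np.floor(values)):
                t, s = np.argwhere(values != np.floor(values))[0]
                raise ParseError(
                    f"non-integer count for taxon {idx[t]!r} in sample {cols[s]!r}"
                )
        else:
            sums = values.sum(axis=0)
            bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1.0) > 1e-9))
            if bad.size:
                raise ParseError(
                    f"relative-abundance column {cols[bad[0]]!r} sums to "
                    f"{sums[bad[0]]!r}, expected 1"
                )
        object.__setattr__(self, "zero_samples", tuple(self.zero_samples))

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_read_matrix(path: str | Path, marker: str) -> ReadMatrix:
    """Read a taxon × sample count matrix from TSV.

    The file has a header row of sample ids and a first column named
    ``taxon_id``.  Cells must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str))
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            taxon = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric cell for taxon {taxon!r} in sample {col!r} of {path}"
            )
        out[col] = converted
    return ReadMatrix(out.astype(np.int64, errors="ignore"), marker=marker)


def write_read_matrix(matrix: ReadMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def merge_replicates(
    matrices: Sequence[ReadMatrix],
    replicate_map: Mapping[str, str],
) -> ReadMatrix:
    """Sum technical replicates into one column per biological sample.

    All matrices must share marker and taxon set; every replicate column must
    appear in exactly one input matrix and map to exactly one biological id.
    Total reads are conserved.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    marker = matrices[0].marker
    taxa = matrices[0].taxa
    seen: set[str] = set()
    for m in matrices:
        if m.marker != marker:
            raise ValueError(f"marker mismatch: {m.marker!r} != {marker!r}")
        if m.taxa != taxa:
            raise ValueError("matrices to merge must share an identical taxon list")
        overlap = seen & set(m.samples)
        if overlap:
            raise ValueError(
                f"replicate(s) {sorted(overlap)} appear in multiple matrices "
                "(would map to two biological samples)"
            )
        seen |= set(m.samples)
    wide = pd.concat([m.data for m in matrices], axis=1)
    unmapped = [s for s in wide.columns if s not in replicate_map]
    if unmapped:
        raise ValueError(f"replicates with no biological id: {unmapped}")
    grouped = wide.T.groupby([replicate_map[s] for s in wide.columns]).sum().T
    return ReadMatrix(grouped, marker=marker)


def to_relative(matrix: ReadMatrix) -> ReadMatrix:
    """Convert counts to within-sample relative abundance (no rarefying).

    All-zero columns are left all-zero and flagged in ``zero_samples``.
    """
    if matrix.mode != "counts":
        raise ValueError("to_relative expects a counts-mode matrix")
    values = matrix.data.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    zero = sums == 0
    safe = np.where(zero, 1.0, sums)
    rel = values / safe
    out = pd.DataFrame(rel, index=matrix.data.index, columns=matrix.data.columns)
    flagged = tuple(np.asarray(matrix.samples)[zero])
    return ReadMatrix(out, marker=matrix.marker, mode="relative", zero_samples=flagged)


def combine_markers(matrices: Sequence[ReadMatrix]) -> ReadMatrix:
    """Stack matrices from different markers row-wise.

    Each OTU/ASV is kept as an independent observation: taxon ids are
    prefixed with their marker and no cross-marker deduplication is
    attempted, so the same taxonomy string occurring at two markers yields
    two rows.  Sample sets must match exactly.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    if len(matrices) == 1:
        m = matrices[0]
        renamed = m.data.rename(index=lambda t: f"{m.marker}:{t}")
        return ReadMatrix(renamed, marker="combined", mode=m.mode,
                          zero_samples=m.zero_samples)
    ref = set(matrices[0].samples)
    for m in matrices[1:]:
        if set(m.samples) != ref:
            diff = sorted(ref ^ set(m.samples))
            raise ValueError(f"sample sets differ between markers: {diff}")
    mode = matrices[0].mode
    if any(m.mode != mode for m in matrices):
        raise ValueError("all matrices must share a mode to be combined")
    order = matrices[0].samples
    parts = [
        m.data[order].rename(index=lambda t, mk=m.marker: f"{mk}:{t}")
        for m in matrices
    ]
    stacked = pd.concat(parts, axis=0)
    zero = tuple(s for s in order
                 if all(s in m.zero_samples for m in matrices))
    if mode == "relative":
        # Renormalise: each marker column summed to 1, the stack sums to k.
        stacked = stacked / max(len(matrices), 1)
        sums = stacked.sum(axis=0)
        nonzero = sums > 0
        stacked.loc[:, nonzero] = stacked.loc[:, nonzero] / sums[nonzero]
    return ReadMatrix(stacked, marker="combined", mode=mode, zero_samples=zero)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def stratum_index_for_depth(depth_m: float, strata: Sequence[tuple[float, float]]) -> int:
    """Index of the stratum containing ``depth_m``.

    Strata are half-open ``[upper, lower)``; the deepest stratum is closed at
    its lower bound so the full sampled column is covered.
    """
    for i, (upper, lower) in enumerate(strata):
        if upper <= depth_m < lower:
            return i
    last_upper, last_lower = strata[-1]
    if depth_m == last_lower:
        return len(strata) - 1
    raise ValueError(f"depth {depth_m} m outside the sampled strata")


def build_sample_meta(
    provinces: Sequence[str],
    strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    tow_periods: Sequence[str] = TOW_PERIODS,
    stations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One metadata row per (province, tow period, stratum) net sample.

    By default one station per province, named after the province.
    """
    _check_strata(strata)
    rows = []
    for prov in provinces:
        station = stations.get(prov, prov) if stations else prov
        for period in tow_periods:
            for i, (upper, lower) in enumerate(strata):
                rows.append(
                    {
                        "sample_id": f"{prov}_{period}_s{i}",
                        "province": prov,
                        "station": station,
                        "tow_period": period,
                        "stratum_upper_m": float(upper),
                        "stratum_lower_m": float(lower),
                        "stratum_index": i,
                        "stratum_midpoint_m": (upper + lower) / 2.0,
                    }
                )
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    validate_sample_meta(meta)
    return meta


def _check_strata(strata: Sequence[tuple[float, float]]) -> None:
    if not strata:
        raise ValueError("empty strata list")
    prev_lower = None
    for upper, lower in strata:
        if not 0 <= upper < lower:
            raise ValueError(f"invalid stratum ({upper}, {lower})")
        if prev_lower is not None and upper != prev_lower:
            raise ValueError("strata must be contiguous and sorted shallow to deep")
        prev_lower = lower


def validate_sample_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in metadata")
    bad = meta[~(meta["stratum_upper_m"] < meta["stratum_lower_m"])]
    if len(bad):
        raise ParseError(f"stratum upper >= lower for sample {bad['sample_id'].iloc[0]!r}")
    mid = (meta["stratum_upper_m"] + meta["stratum_lower_m"]) / 2.0
    if not np.allclose(mid, meta["stratum_midpoint_m"]):
        raise ParseError("stratum midpoint inconsistent with bounds")
    if meta.duplicated(["province", "station", "tow_period", "stratum_index"]).any():
        raise ParseError("more than one sample per (province, station, tow, stratum)")
    if not meta["tow_period"].isin(TOW_PERIODS).all():
        raise ParseError("tow_period must be 'day' or 'night'")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    validate_sample_meta(meta)
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CTD profiles
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ("province", "depth_m", "temperature_C", "oxygen", "chla")


def validate_profiles(profiles: Mapping[str, pd.DataFrame]) -> None:
    for prov, df in profiles.items():
        for col in ("depth_m", "temperature_C", "oxygen", "chla"):
            if col not in df.columns:
                raise ParseError(f"profile for {prov!r} missing column {col!r}")
        depths = df["depth_m"].to_numpy()
        if len(depths) < 2 or not np.array_equal(np.diff(depths), np.ones(len(depths) - 1)):
            raise ParseError(f"profile for {prov!r} is not on a 1-m grid")


def read_profiles(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read CTD profiles from long-format CSV (one row per province × depth)."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"profile file missing columns: {missing}")
    out = {
        str(prov): sub.sort_values("depth_m").reset_index(drop=True)[
            list(PROFILE_COLUMNS[1:])
        ]
        for prov, sub in df.groupby("province")
    }
    validate_profiles(out)
    return out


def write_profiles(profiles: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    parts = []
    for prov, df in profiles.items():
        part = df.copy()
        part.insert(0, "province", prov)
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonTraits:
    """Trait states for one taxon; ``None`` marks a missing assignment."""

    body_size_mm: float | None = None
    diet: str | None = None
    feeding: str | None = None
    spawning: str | None = None
    asexual: str | None = None
    composition: str | None = None
    dvm: str | None = None  # computed downstream, never read from disk

    def __post_init__(self) -> None:
        if self.body_size_mm is not None and not self.body_size_mm > 0:
            raise ValueError("body_size_mm must be positive")
        for name, vocab in TRAIT_VOCABULARY.items():
            value = getattr(self, name)
            if value is not None and value not in vocab:
                raise ValueError(f"{name}={value!r} not in {vocab}")


TRAIT_COLUMNS = ("name", "body_size_mm", "diet", "feeding", "spawning",
                 "asexual", "composition")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Trait table indexed by taxonomic name; '' and 'NA' become missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["", "NA"])
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"trait table missing columns: {missing}")
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ParseError(f"duplicate trait-table name {dup!r}")
    df = df.set_index("name")
    df["body_size_mm"] = pd.to_numeric(df["body_size_mm"], errors="raise")
    for name in ("diet", "feeding", "spawning", "asexual", "composition"):
        bad = df[name].dropna()[~df[name].dropna().isin(TRAIT_VOCABULARY[name])]
        if len(bad):
            raise ParseError(
                f"trait {name!r} has value {bad.iloc[0]!r} outside its vocabulary"
            )
    return df


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> None:
    out = traits.copy()
    out.index.name = "name"
    out.to_csv(path, sep="\t", na_rep="NA")


def lookup_traits(taxonomy: str, trait_table: pd.DataFrame) -> TaxonTraits:
    """Match a semicolon-delimited taxonomy string against the trait table.

    The most specific rank present in the table wins (species before genus
    before family, walking the string right to left).  Curating trait
    uniformity within higher ranks is the table curator's job; this function
    matches by name only.
    """
    for rank in reversed([r.strip() for r in taxonomy.split(";") if r.strip()]):
        if rank in trait_table.index:
            row = trait_table.loc[rank]
            return TaxonTraits(
                body_size_mm=None if pd.isna(row["body_size_mm"]) else float(row["body_size_mm"]),
                **{
                    k: (None if pd.isna(row[k]) else str(row[k]))
                    for k in ("diet", "feeding", "spawning", "asexual", "composition")
                },
            )
    return TaxonTraits()
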