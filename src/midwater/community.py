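"""Richness, rarefaction, occupancy partitions, community distances,
non-metric MDS, and beta-dispersion.

The depth-zone split at 200 m follows stratum boundaries (the survey's
strata abut exactly at 200 m), so no net straddles the epipelagic /
mesopelagic divide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .io import ReadMatrix, to_relative

__all__ = [
    "ZONE_BOUNDARY_M",
    "DistanceMatrix",
    "OccupancyPartition",
    "NmdsResult",
    "BetaDispersionResult",
    "zone_of_sample",
    "richness",
    "expected_rarefied_richness",
    "rarefy_monte_carlo",
    "occupancy_partition",
    "distance_matrix",
    "nmds",
    "beta_dispersion",
]

ZONE_BOUNDARY_M = 200.0


def zone_of_sample(meta: pd.DataFrame, boundary_m: float = ZONE_BOUNDARY_M) -> pd.Series:
    """'epipelagic' for strata wholly above the boundary, else 'mesopelagic'."""
    return pd.Series(
        np.where(meta["stratum_lower_m"] <= boundary_m, "epipelagic", "mesopelagic"),
        index=meta["sample_id"].to_numpy(),
        name="zone",
    )


# ---------------------------------------------------------------------------
# Richness and rarefaction
# ---------------------------------------------------------------------------


def expected_rarefied_richness(counts: np.ndarray, rarefy_to: int) -> float:
    """Expected richness under without-replacement subsampling to ``rarefy_to``.

    Hypergeometric closed form: E[S] = sum_i 1 - C(N - n_i, m) / C(N, m),
    evaluated with log-gamma for numerical stability.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if rarefy_to > total:
        raise ValueError("rarefy_to exceeds the sample's total reads")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    prob_absent = np.zeros(len(counts))
    feasible = rest >= rarefy_to
    prob_absent[feasible] = np.exp(
        log_comb(rest[feasible], rarefy_to) - log_comb(np.float64(total), rarefy_to)
    )
    return float(np.sum(1.0 - prob_absent))


def rarefy_monte_carlo(
    counts: np.ndarray, rarefy_to: int, n_iter: int, rng: np.random.Generator
) -> float:
    """Mean richness over seeded without-replacement subsamples."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    if rarefy_to > counts.sum():
        raise ValueError("rarefy_to exceeds the sample's total reads")
    hits = 0
    for _ in range(n_iter):
        draw = rng.multivariate_hypergeometric(counts, rarefy_to)
        hits += int((draw > 0).sum())
    return hits / n_iter


def richness(
    matrix: ReadMatrix,
    meta: pd.DataFrame | None = None,
    group_by: str = "sample",
    rarefy_to: int | None = None,
    method: str = "analytic",
    n_iter: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Presence-based richness per sample, depth zone, or province.

    Groups other than ``sample`` pool read counts across their member
    samples before counting presences.  With ``rarefy_to`` set the table
    gains an expected rarefied richness column (analytic hypergeometric by
    default, Monte-Carlo with ``method='monte_carlo'``); groups with fewer
    total reads than ``rarefy_to`` are flagged and their rarefied value is
    left missing.
    """
    if group_by not in ("sample", "zone", "province"):
        raise ValueError(f"unknown grouping {group_by!r}")
    if rarefy_to is not None and matrix.mode != "counts":
        raise ValueError("rarefaction requires a counts matrix")
    data = matrix.data
    if group_by == "sample":
        grouped = data
    else:
        if meta is None:
            raise ValueError("meta required for zone/province grouping")
        key = (
            zone_of_sample(meta)
            if group_by == "zone"
            else meta.set_index("sample_id")["province"]
        )
        grouped = data.T.groupby([key[s] for s in data.columns]).sum().T
    rng = np.random.default_rng(seed)
    rows = []
    for group in grouped.columns:
        col = grouped[group].to_numpy()
        row = {"group": group, "richness": int((col > 0).sum()),
               "total_reads": int(col.sum())}
        if rarefy_to is not None:
            if col.sum() < rarefy_to:
                row["rarefied_richness"] = np.nan
                row["rarefaction_excluded"] = True
            else:
                row["rarefaction_excluded"] = False
                if method == "analytic":
                    row["rarefied_richness"] = expected_rarefied_richness(col, rarefy_to)
                elif method == "monte_carlo":
                    row["rarefied_richness"] = rarefy_monte_carlo(col, rarefy_to,
                                                                  n_iter, rng)
                else:
                    raise ValueError(f"unknown rarefaction method {method!r}")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Occupancy partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccupancyPartition:
    """Counts of taxa per province subset within a depth scope."""

    depth_scope: str
    per_taxon: Mapping[str, frozenset[str]]
    subset_counts: Mapping[frozenset[str], int]
    endemism: Mapping[str, float]
    cosmopolitan_fraction: float
    total_taxa: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"provinces": ";".join(sorted(subset)), "n_provinces": len(subset),
             "n_taxa": count, "depth_scope": self.depth_scope}
            for subset, count in sorted(
                self.subset_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows)


def occupancy_partition(
    matrix: ReadMatrix,
    meta: pd.DataFrame,
    depth_scope: str = "full",
    boundary_m: float = ZONE_BOUNDARY_M,
) -> OccupancyPartition:
    """Partition observed taxa by the set of provinces they occupy.

    ``depth_scope`` restricts occurrence to epipelagic nets (stratum lower
    bound <= 200 m), mesopelagic nets (upper bound >= 200 m), or the full
    column.  Endemism per province is the fraction of that province's taxa
    found nowhere else; cosmopolitan taxa occupy every province.
    """
    if depth_scope not in ("full", "epipelagic", "mesopelagic"):
        raise ValueError(f"unknown depth scope {depth_scope!r}")
    m = meta.set_index("sample_id")
    provinces = sorted(m["province"].unique())
    if len(provinces) < 2:
        raise ValueError("occupancy partition needs at least two provinces")
    if depth_scope == "epipelagic":
        keep = m["stratum_lower_m"] <= boundary_m
    elif depth_scope == "mesopelagic":
        keep = m["stratum_upper_m"] >= boundary_m
    else:
        keep = pd.Series(True, index=m.index)
    cols = [s for s in matrix.data.columns if s in m.index and keep[s]]
    prov_of = m.loc[cols, "province"].to_numpy()
    present = matrix.data[cols].to_numpy() > 0
    per_taxon: dict[str, frozenset[str]] = {}
    for i, taxon in enumerate(matrix.data.index):
        occ = frozenset(prov_of[present[i]])
        if occ:
            per_taxon[taxon] = occ
    subset_counts: dict[frozenset, int] = {}
    for occ in per_taxon.values():
        subset_counts[occ] = subset_counts.get(occ, 0) + 1
    endemism = {}
    for prov in provinces:
        in_prov = [occ for occ in per_taxon.values() if prov in occ]
        only = sum(1 for occ in in_prov if occ == frozenset({prov}))
        endemism[prov] = only / len(in_prov) if in_prov else float("nan")
    total = len(per_taxon)
    cosmo = subset_counts.get(frozenset(provinces), 0)
    return OccupancyPartition(
        depth_scope=depth_scope,
        per_taxon=per_taxon,
        subset_counts=subset_counts,
        endemism=endemism,
        cosmopolitan_fraction=cosmo / total if total else float("nan"),
        total_taxa=total,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    metric: str
    flagged_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(matrix: ReadMatrix, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray–Curtis (on relative abundances) or Jaccard (on presence).

    Bray–Curtis: d = sum|x_i - y_i| / sum(x_i + y_i).  Jaccard:
    d = 1 - |X ∩ Y| / |X ∪ Y| on presence/absence.  A pair of all-zero
    samples gets distance 0 and is flagged.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    if metric == "bray_curtis":
        rel = matrix if matrix.mode == "relative" else to_relative(matrix)
        x = rel.data.to_numpy(dtype=float).T  # samples x taxa
        num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    elif metric == "jaccard":
        b = (matrix.data.to_numpy() > 0).astype(float).T
        inter = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        num, den = union - inter, union
    else:
        raise ValueError(f"unknown metric {metric!r}")
    flagged = []
    ids = tuple(matrix.samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    zero_pairs = np.argwhere(den == 0)
    for i, j in zero_pairs:
        if i < j:
            flagged.append((ids[i], ids[j]))
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(ids=ids, values=d, metric=metric,
                          flagged_pairs=tuple(flagged))


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1 of the returned configuration


def _kruskal_stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 after monotone (isotonic) regression of fitted distances."""
    iu = np.triu_indices(len(coords), k=1)
    fitted = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    obs, fit = d_obs[iu], fitted[iu]
    order = np.argsort(obs, kind="stable")
    disparities = IsotonicRegression().fit_transform(np.arange(len(order)), fit[order])
    resid = fit[order] - disparities
    denom = (fit**2).sum()
    return float(np.sqrt((resid**2).sum() / denom)) if denom > 0 else 0.0


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric MDS by iterative monotone regression (SMACOF).

    Runs ``n_starts`` seeded random initialisations and keeps the
    configuration with the lowest Kruskal stress-1.
    """
    n = len(d.ids)
    if n < k + 1:
        raise ValueError("need at least k + 1 samples")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(d.values)
    stress = _kruskal_stress1(d.values, coords)
    if stress > 0.3:
        warnings.warn(f"nMDS stress {stress:.3f} indicates a poor fit", stacklevel=2)
    frame = pd.DataFrame(coords, index=d.ids,
                         columns=[f"nmds{i + 1}" for i in range(k)])
    return NmdsResult(coordinates=frame, stress=stress)


# ---------------------------------------------------------------------------
# Beta-dispersion (PERMDISP-style, centroid variant)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaDispersionResult:
    f_statistic: float
    df: tuple[int, int]
    p_anova: float
    p_permutation: float | None
    distances: pd.Series  # per-sample distance to its group centroid
    group_means: Mapping[str, float]


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    groups = [values[labels == g] for g in np.unique(labels)]
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(values) - len(groups)
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / dfb) / (ssw / dfw))


def beta_dispersion(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> BetaDispersionResult:
    """Compare within-group multivariate dispersion between groups.

    Samples are embedded by principal-coordinates analysis of the distance
    matrix; squared distance of a sample to its group centroid is the
    real-axis contribution minus the imaginary-axis contribution (the
    standard correction for non-Euclidean distances), floored at zero.
    Group dispersions (distances to centroid) are compared with a one-way
    ANOVA F, plus an optional permutation p-value from seeded relabelings
    of the per-sample distances.
    """
    labels = np.asarray([groups[s] for s in d.ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than two samples")

    n = len(d.ids)
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    tol = 1e-10 * max(abs(eigval).max(), 1.0)
    keep = np.abs(eigval) > tol
    lam, vec = eigval[keep], eigvec[:, keep]
    coords = vec * np.sqrt(np.abs(lam))
    positive = lam > 0

    z = np.empty(n)
    for gname in uniq:
        idx = np.flatnonzero(labels == gname)
        centroid = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - centroid) ** 2
        sq = delta2[:, positive].sum(axis=1) - delta2[:, ~positive].sum(axis=1)
        z[idx] = np.sqrt(np.maximum(sq, 0.0))

    f_obs = _anova_f(z, labels)
    dfb, dfw = len(uniq) - 1, n - len(uniq)
    p_anova = float(sps.f.sf(f_obs, dfb, dfw)) if np.isfinite(f_obs) else 0.0

    p_perm = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            f_p = _anova_f(z, rng.permutation(labels))
            if f_p >= f_obs:
                exceed += 1
        p_perm = (exceed + 1) / (n_perm + 1)

    return BetaDispersionResult(
        f_statistic=f_obs,
        df=(dfb, dfw),
        p_anova=p_anova,
        p_permutation=p_perm,
        distances=pd.Series(z, index=d.ids, name="dist_to_centroid"),
        group_means={g_: float(z[labels == g_].mean()) for g_ in uniq},
    )
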