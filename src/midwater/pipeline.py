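"""End-to-end orchestration: simulate or ingest, then metrics, environment,
biogeography, and the statistical contrast battery, with a deterministic
run manifest.

Per-taxon analyses (MDO, habitat, DVM, environmental ranges) are computed
within each marker — each OTU/ASV is an independent observation, and the
within-net relative abundances that drive these statistics are invariant
to stacking markers — then concatenated with marker-prefixed taxon ids to
form the combined table used by the community-level analyses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    beta_dispersion,
    distance_matrix,
    nmds,
    occupancy_partition,
    richness,
    zone_of_sample,
)
from .environment import env_range_table, net_environment
from .io import (
    ReadMatrix,
    combine_markers,
    lookup_traits,
    read_profiles,
    read_read_matrix,
    read_sample_meta,
    read_trait_table,
    to_relative,
)
from .metrics import DvmCriteria, size_depth_correlation, taxon_metrics_table
from .stats import chi_square_independence, dunn_posthoc, kruskal_wallis
from .synthetic import PlantingConfig, SurveyDesign, simulate_survey, write_survey

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "trait_contrasts"]

CONTRAST_RESPONSES = ("temperature_range", "chla_range", "oxygen_range",
                      "n_provinces")
TRAITS_TESTED = ("diet", "feeding", "spawning", "asexual", "composition")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; defaults are the survey's values.

    Either simulate (``input_dir is None``) with the given design and
    planting parameters, or ingest a directory of tables written in the
    formats of :mod:`midwater.io`.
    """

    seed: int = 0
    n_taxa: int = 100
    input_dir: str | None = None
    design: SurveyDesign = field(default_factory=SurveyDesign)
    planting: PlantingConfig = field(default_factory=PlantingConfig)
    habitat_boundary_m: float = 200.0
    dvm: DvmCriteria = field(default_factory=DvmCriteria)
    rarefy_policy: str | int | None = "min"
    nmds_starts: int = 20
    n_permutations: int = 999
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.habitat_boundary_m <= 0:
            raise ValueError("habitat boundary must be positive")
        for name in ("min_nets_per_tow", "max_fold_change", "min_study_share",
                     "min_stratum_shift"):
            if getattr(self.dvm, name) <= 0:
                raise ValueError(f"DVM threshold {name} must be positive")
        if self.nmds_starts < 1 or self.n_permutations < 0:
            raise ValueError("invalid nmds_starts / n_permutations")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = SurveyDesign(**{
            **raw.get("design", {}),
            "strata": tuple(map(tuple, raw["design"]["strata"]))
            if "strata" in raw.get("design", {}) else SurveyDesign().strata,
        }) if "design" in raw else SurveyDesign()
        planting = PlantingConfig(**raw.get("planting", {}))
        dvm = DvmCriteria(**raw.get("dvm", {}))
        top = {k: v for k, v in raw.items()
               if k not in ("design", "planting", "dvm")}
        return cls(design=design, planting=planting, dvm=dvm, **top)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    manifest: dict
    partitions: dict
    dispersions: dict


def _load_inputs(input_dir: Path):
    matrices = {}
    for path in sorted(input_dir.glob("reads_*.tsv")):
        marker = path.stem.removeprefix("reads_")
        matrices[marker] = read_read_matrix(path, marker)
    if not matrices:
        raise FileNotFoundError(f"no reads_*.tsv in {input_dir}")
    meta = read_sample_meta(input_dir / "sample_meta.tsv")
    profiles = read_profiles(input_dir / "ctd_profiles.csv")
    traits_path = input_dir / "traits.tsv"
    traits = read_trait_table(traits_path) if traits_path.exists() else None
    truth_path = input_dir / "ground_truth.tsv"
    truth = (pd.read_csv(truth_path, sep="\t", index_col=0)
             if truth_path.exists() else None)
    return matrices, meta, profiles, traits, truth


def _join_traits(table: pd.DataFrame, traits: pd.DataFrame | None) -> pd.DataFrame:
    """Attach trait states by matching the taxon's name against the table."""
    if traits is None:
        return table
    cols = {"body_size_mm": [], "diet": [], "feeding": [], "spawning": [],
            "asexual": [], "composition": []}
    for taxon in table.index:
        base = taxon.split(":", 1)[-1]  # strip marker prefix
        tr = lookup_traits(base, traits)
        for k in cols:
            cols[k].append(getattr(tr, k))
    for k, v in cols.items():
        table[k] = v
    return table


def trait_contrasts(
    table: pd.DataFrame, scope: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal–Wallis (plus Dunn when >2 states) of each trait against each
    environmental-range variable and the number of occupied provinces.

    ``scope`` filters taxa by habitat class ('epipelagic'/'mesopelagic');
    'all' uses the full water column, which is how the migration trait is
    contrasted since migrators straddle both zones.  Trait states with no
    taxa are dropped; traits left with a single state are flagged untested.
    """
    if scope not in ("all", "epipelagic", "mesopelagic"):
        raise ValueError(f"unknown scope {scope!r}")
    sub = table if scope == "all" else table[table["habitat"] == scope]
    rows, pairwise_rows = [], []
    traits = [t for t in (*TRAITS_TESTED, "dvm") if t in sub.columns]
    for trait in traits:
        for response in CONTRAST_RESPONSES:
            if response not in sub.columns:
                continue
            data = sub[[trait, response]].dropna()
            states = data[trait].unique()
            row = {"scope": scope, "trait": trait, "response": response,
                   "n": len(data), "n_states": len(states)}
            if len(states) < 2:
                row.update(statistic=np.nan, df=np.nan, p=np.nan, tested=False)
                rows.append(row)
                continue
            res = kruskal_wallis(data[response].to_numpy(), data[trait].to_numpy())
            row.update(statistic=res.statistic, df=res.df, p=res.p, tested=True)
            rows.append(row)
            if len(states) > 2:
                dunn = dunn_posthoc(data[response].to_numpy(),
                                    data[trait].to_numpy())
                for pw in dunn.pairwise:
                    pairwise_rows.append(
                        {"scope": scope, "trait": trait, "response": response,
                         "state_a": pw.pair[0], "state_b": pw.pair[1],
                         "z": pw.z, "p_raw": pw.p_raw,
                         "p_adjusted": pw.p_adjusted}
                    )
    return pd.DataFrame(rows), pd.DataFrame(pairwise_rows)


def _range_by_occupancy(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Env-range differences across occupancy classes (1, 2, ... provinces),
    within each habitat, KW plus Dunn."""
    rows, pairwise_rows = [], []
    for habitat in ("epipelagic", "mesopelagic"):
        sub = table[table["habitat"] == habitat]
        for response in ("temperature_range", "chla_range", "oxygen_range"):
            data = sub[[response, "n_provinces"]].dropna()
            classes = data["n_provinces"].unique()
            row = {"habitat": habitat, "response": response, "n": len(data),
                   "n_classes": len(classes)}
            if len(classes) < 2:
                row.update(statistic=np.nan, df=np.nan, p=np.nan, tested=False)
                rows.append(row)
                continue
            res = kruskal_wallis(data[response].to_numpy(),
                                 data["n_provinces"].to_numpy())
            row.update(statistic=res.statistic, df=res.df, p=res.p, tested=True)
            rows.append(row)
            if len(classes) > 2:
                dunn = dunn_posthoc(data[response].to_numpy(),
                                    data["n_provinces"].to_numpy())
                for pw in dunn.pairwise:
                    pairwise_rows.append(
                        {"habitat": habitat, "response": response,
                         "class_a": pw.pair[0], "class_b": pw.pair[1],
                         "z": pw.z, "p_raw": pw.p_raw,
                         "p_adjusted": pw.p_adjusted}
                    )
    return pd.DataFrame(rows), pd.DataFrame(pairwise_rows)


def _range_by_habitat(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for response in ("temperature_range", "chla_range", "oxygen_range"):
        data = table[[response, "habitat"]].dropna()
        res = kruskal_wallis(data[response].to_numpy(), data["habitat"].to_numpy())
        medians = data.groupby("habitat")[response].median()
        rows.append(
            {"response": response, "statistic": res.statistic, "df": res.df,
             "p": res.p,
             "median_epipelagic": medians.get("epipelagic", np.nan),
             "median_mesopelagic": medians.get("mesopelagic", np.nan)}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis deterministically for the configured seed."""
    warnings_log: list[str] = []
    design = replace(config.design, seed=config.seed)

    if config.input_dir is None:
        survey = simulate_survey(config.n_taxa, design, config.planting)
        matrices, meta, profiles = survey.matrices, survey.meta, survey.profiles
        traits, truth = survey.traits, survey.truth
    else:
        matrices, meta, profiles, traits, truth = _load_inputs(Path(config.input_dir))

    markers = sorted(matrices)
    tables: dict[str, pd.DataFrame] = {}

    # --- per-taxon metrics and environmental ranges, per marker -----------
    envs = net_environment(profiles, meta)
    tables["net_environment"] = envs
    per_marker = []
    for marker in markers:
        m = matrices[marker]
        tm = taxon_metrics_table(m, meta, config.habitat_boundary_m, config.dvm)
        er = env_range_table(m, meta, envs)
        joined = tm.join(er, how="left")
        joined.index = [f"{marker}:{t}" for t in joined.index]
        per_marker.append(joined)
    taxon_table = pd.concat(per_marker)
    taxon_table = _join_traits(taxon_table, traits)
    if truth is not None:
        base_ids = [t.split(":", 1)[-1] for t in taxon_table.index]
        for col in truth.columns:
            taxon_table[f"true_{col}"] = [
                truth[col].get(b, np.nan) for b in base_ids
            ]
    tables["taxon_metrics"] = taxon_table

    # --- combined matrix ---------------------------------------------------
    combined = combine_markers([matrices[m] for m in markers])
    combined_rel = to_relative(combined)

    # --- occupancy partitions ----------------------------------------------
    partitions = {
        scope: occupancy_partition(combined, meta, scope)
        for scope in ("full", "epipelagic", "mesopelagic")
    }
    tables["occupancy_partition"] = pd.concat(
        [p.to_frame() for p in partitions.values()], ignore_index=True
    )
    tables["endemism"] = pd.DataFrame(
        [
            {"depth_scope": scope, "province": prov, "endemism": val,
             "cosmopolitan_fraction": part.cosmopolitan_fraction}
            for scope, part in partitions.items()
            for prov, val in part.endemism.items()
        ]
    )

    # --- richness -----------------------------------------------------------
    rich_parts = []
    for label, matrix in [*matrices.items(), ("combined", combined)]:
        colsums = matrix.data.sum(axis=0)
        if config.rarefy_policy == "min":
            nonzero = colsums[colsums > 0]
            rarefy_to = int(nonzero.min()) if len(nonzero) else None
        elif isinstance(config.rarefy_policy, int):
            rarefy_to = config.rarefy_policy
        else:
            rarefy_to = None
        for group_by in ("sample", "zone", "province"):
            r = richness(matrix, meta, group_by=group_by,
                         rarefy_to=rarefy_to if group_by == "sample" else None,
                         seed=config.seed)
            r.insert(0, "marker", label)
            r.insert(1, "group_by", group_by)
            rich_parts.append(r)
    tables["richness"] = pd.concat(rich_parts, ignore_index=True)

    # --- distances, ordination, dispersion ----------------------------------
    zones = zone_of_sample(meta)
    dispersions = {}
    disp_rows = []
    nmds_frames = []
    for label, matrix in [*matrices.items(), ("combined", combined)]:
        rel = to_relative(matrix) if matrix.mode == "counts" else matrix
        for metric in ("bray_curtis", "jaccard"):
            dm = distance_matrix(rel if metric == "bray_curtis" else matrix, metric)
            tables[f"distance_{metric}_{label}"] = dm.to_frame()
            disp = beta_dispersion(dm, zones.to_dict(),
                                   n_perm=config.n_permutations, seed=config.seed)
            dispersions[(label, metric)] = disp
            disp_rows.append(
                {"marker": label, "metric": metric,
                 "F": disp.f_statistic, "df1": disp.df[0], "df2": disp.df[1],
                 "p_anova": disp.p_anova, "p_permutation": disp.p_permutation,
                 **{f"mean_{g}": v for g, v in disp.group_means.items()}}
            )
            if metric == "bray_curtis":
                ord_res = nmds(dm, k=2, n_starts=config.nmds_starts,
                               seed=config.seed)
                coords = ord_res.coordinates.copy()
                coords.insert(0, "marker", label)
                coords["stress"] = ord_res.stress
                nmds_frames.append(coords)
    tables["beta_dispersion"] = pd.DataFrame(disp_rows)
    tables["nmds_coordinates"] = pd.concat(nmds_frames)

    # --- statistical contrasts ----------------------------------------------
    hab_table = taxon_table.dropna(subset=["habitat"])
    contingency = pd.crosstab(hab_table["habitat"], hab_table["n_provinces"])
    chi = chi_square_independence(contingency.to_numpy())
    tables["habitat_occupancy_chisq"] = pd.DataFrame(
        [{"statistic": chi.statistic, "df": chi.df, "p": chi.p,
          "mean_n_provinces_epipelagic": hab_table.loc[
              hab_table["habitat"] == "epipelagic", "n_provinces"].mean(),
          "mean_n_provinces_mesopelagic": hab_table.loc[
              hab_table["habitat"] == "mesopelagic", "n_provinces"].mean()}]
    )
    tables["range_by_habitat"] = _range_by_habitat(hab_table)
    occ_rows, occ_pairwise = _range_by_occupancy(hab_table)
    tables["range_by_occupancy"] = occ_rows
    tables["range_by_occupancy_pairwise"] = occ_pairwise
    contrast_parts, pairwise_parts = [], []
    for scope in ("epipelagic", "mesopelagic"):
        rows, pw = trait_contrasts(
            hab_table.drop(columns=["dvm"]), scope
        )
        contrast_parts.append(rows)
        pairwise_parts.append(pw)
    dvm_rows, dvm_pw = trait_contrasts(hab_table[["dvm", "habitat",
                                                  *CONTRAST_RESPONSES]], "all")
    contrast_parts.append(dvm_rows)
    pairwise_parts.append(dvm_pw)
    tables["trait_contrasts"] = pd.concat(contrast_parts, ignore_index=True)
    tables["trait_contrasts_pairwise"] = pd.concat(
        [p for p in pairwise_parts if len(p)], ignore_index=True
    ) if any(len(p) for p in pairwise_parts) else pd.DataFrame()

    # --- size-depth correlations ---------------------------------------------
    corr_rows = []
    stations = meta[["station", "province", "tow_period"]].drop_duplicates()
    for row in stations.itertuples(index=False):
        col = f"mdo_{row.station}_{row.tow_period}_m"
        if col not in taxon_table.columns or "body_size_mm" not in taxon_table:
            continue
        res = size_depth_correlation(taxon_table["body_size_mm"],
                                     taxon_table[col])
        n_pairs = int(taxon_table[["body_size_mm", col]].dropna().shape[0])
        if res is None:
            corr_rows.append({"province": row.province,
                              "tow_period": row.tow_period, "n": n_pairs,
                              "rho": np.nan, "p": np.nan, "tested": False})
        else:
            corr_rows.append({"province": row.province,
                              "tow_period": row.tow_period, "n": n_pairs,
                              "rho": res[0], "p": res[1], "tested": True})
    tables["size_depth_correlation"] = pd.DataFrame(corr_rows)

    # --- manifest -------------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": {
            "taxon_metrics": "mdo/classify_habitat/detect_dvm + env_range",
            "net_environment": "net_environment",
            "occupancy_partition": "occupancy_partition",
            "endemism": "occupancy_partition",
            "richness": "richness",
            "beta_dispersion": "distance_matrix + beta_dispersion",
            "nmds_coordinates": "distance_matrix + nmds",
            "habitat_occupancy_chisq": "chi_square_independence",
            "range_by_habitat": "kruskal_wallis",
            "range_by_occupancy": "kruskal_wallis + dunn_posthoc",
            "trait_contrasts": "kruskal_wallis + dunn_posthoc",
            "size_depth_correlation": "spearman",
        },
        "warnings": warnings_log,
    }

    result = PipelineResult(tables=tables, manifest=manifest,
                            partitions=partitions, dispersions=dispersions)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            sep = "," if name.startswith("distance_") else "\t"
            suffix = "csv" if sep == "," else "tsv"
            frame.to_csv(outdir / f"{name}.{suffix}", sep=sep,
                         index=not frame.index.equals(pd.RangeIndex(len(frame))))
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return result
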