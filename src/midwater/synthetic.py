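"""Synthetic survey generator with planted, recoverable structure.

Emulates a depth-stratified MOCNESS metabarcoding survey: three
biogeochemical provinces, paired day/night tows, eight discrete depth
strata from the surface to 1000 m, and multinomial read sampling at a
fixed sequencing depth per net.  Every taxon is planted with a known
vertical distribution (truncated Gaussian), day/night depth centres
(diel vertical migration when they differ), province occupancy, traits,
and a global abundance share, so downstream estimators can be scored
against ground truth.

Randomness is fully deterministic given the design's master seed: each
component (CTD noise, taxon planting, marker assignment, read sampling)
draws from its own :class:`numpy.random.SeedSequence` substream, spawned
from the master seed with a fixed, documented ``spawn_key``.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_STRATA,
    TOW_PERIODS,
    ReadMatrix,
    TaxonTraits,
    build_sample_meta,
    write_profiles,
    write_read_matrix,
    write_sample_meta,
    write_trait_table,
)

__all__ = [
    "DEFAULT_PROVINCES",
    "SurveyDesign",
    "ProvinceCurves",
    "EnvFieldSpec",
    "PlantingConfig",
    "PlantedTaxon",
    "SimulatedSurvey",
    "default_env_spec",
    "generate_profiles",
    "generate_taxa",
    "sample_reads",
    "simulate_survey",
    "stratum_masses",
    "expected_read_counts",
    "ground_truth_frame",
    "trait_frame",
    "write_survey",
]

DEFAULT_PROVINCES = ("Subarctic", "Transition", "Subtropical")

# SeedSequence spawn keys, one per randomness consumer.
PROFILE_STREAM = 0
TAXA_STREAM = 1
MARKER_STREAM = 2
READS_STREAM = 3


def component_rng(seed: int, stream: int) -> np.random.Generator:
    """Seeded generator for one named component of the simulation."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Survey design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling design: who sampled where, how deep, and how hard.

    Defaults mirror the study design the generator emulates: three North
    Pacific provinces, one station each, paired day/night tows, the eight
    canonical strata between 0 and 1000 m, and ~5 x 10^4 reads per net.
    """

    provinces: tuple[str, ...] = DEFAULT_PROVINCES
    strata: tuple[tuple[float, float], ...] = DEFAULT_STRATA
    tow_periods: tuple[str, str] = TOW_PERIODS
    reads_per_sample: int = 50_000
    n_markers: int = 1
    marker_overlap: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 0.0 <= self.marker_overlap <= 1.0:
            raise ValueError("marker_overlap must be in [0, 1]")
        prev = None
        for upper, lower in self.strata:
            if not 0 <= upper < lower:
                raise ValueError(f"invalid stratum ({upper}, {lower})")
            if prev is not None and upper != prev:
                raise ValueError("strata must be contiguous, sorted shallow to deep")
            prev = lower

    @property
    def max_depth_m(self) -> float:
        return self.strata[-1][1]


# ---------------------------------------------------------------------------
# Environmental fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProvinceCurves:
    """Parametric depth curves for one province's water column.

    Temperature is a descending logistic between a surface and a deep
    value centred at the thermocline; oxygen declines smoothly from its
    surface value across the oxycline to a minimum (the OMZ core) and
    stays there; chlorophyll-a is a Gaussian peak in the euphotic zone
    and is effectively zero below ~200 m.  Any curve can be overridden
    with an arbitrary callable of depth for testing or custom scenarios.
    """

    temp_surface_C: float = 15.0
    thermocline_depth_m: float = 40.0
    thermocline_width_m: float = 20.0
    temp_deep_C: float = 3.0
    oxygen_surface: float = 260.0
    oxycline_depth_m: float = 80.0
    oxygen_min: float = 15.0
    oxygen_min_depth_m: float = 700.0
    chla_peak: float = 1.5
    chla_peak_depth_m: float = 40.0
    chla_width_m: float = 25.0
    temperature_fn: Callable[[np.ndarray], np.ndarray] | None = None
    oxygen_fn: Callable[[np.ndarray], np.ndarray] | None = None
    chla_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def temperature(self, z: np.ndarray) -> np.ndarray:
        if self.temperature_fn is not None:
            return np.asarray(self.temperature_fn(z), dtype=float)
        span = self.temp_surface_C - self.temp_deep_C
        s = 1.0 / (1.0 + np.exp(-(self.thermocline_depth_m - z) / self.thermocline_width_m))
        return self.temp_deep_C + span * s

    def oxygen(self, z: np.ndarray) -> np.ndarray:
        if self.oxygen_fn is not None:
            return np.asarray(self.oxygen_fn(z), dtype=float)
        t = np.clip(
            (z - self.oxycline_depth_m)
            / max(self.oxygen_min_depth_m - self.oxycline_depth_m, 1e-9),
            0.0,
            1.0,
        )
        smooth = 3 * t**2 - 2 * t**3  # monotone smoothstep
        return self.oxygen_surface - (self.oxygen_surface - self.oxygen_min) * smooth

    def chla(self, z: np.ndarray) -> np.ndarray:
        if self.chla_fn is not None:
            return np.asarray(self.chla_fn(z), dtype=float)
        return self.chla_peak * np.exp(-((z - self.chla_peak_depth_m) ** 2)
                                       / (2 * self.chla_width_m**2))


@dataclass(frozen=True)
class EnvFieldSpec:
    """Per-province water-column curves plus measurement noise (1 SD)."""

    curves: Mapping[str, ProvinceCurves]
    noise_sd_temperature: float = 0.05
    noise_sd_oxygen: float = 1.0
    noise_sd_chla: float = 0.02


def default_env_spec() -> EnvFieldSpec:
    """Fields shaped like the study region's CTD climatology.

    Warm, stratified, oligotrophic subtropical water with a deep
    chlorophyll maximum and a deep oxycline; cold subarctic water with a
    shallow thermocline, a shallow and intense oxygen minimum zone, and a
    strong surface chlorophyll peak; the transition province in between.
    """
    return EnvFieldSpec(
        curves={
            "Subarctic": ProvinceCurves(
                temp_surface_C=12.0, thermocline_depth_m=30.0,
                thermocline_width_m=15.0, temp_deep_C=2.5,
                oxygen_surface=280.0, oxycline_depth_m=60.0,
                oxygen_min=10.0, oxygen_min_depth_m=600.0,
                chla_peak=2.5, chla_peak_depth_m=20.0, chla_width_m=20.0,
            ),
            "Transition": ProvinceCurves(
                temp_surface_C=16.0, thermocline_depth_m=40.0,
                thermocline_width_m=20.0, temp_deep_C=3.0,
                oxygen_surface=260.0, oxycline_depth_m=80.0,
                oxygen_min=15.0, oxygen_min_depth_m=700.0,
                chla_peak=1.5, chla_peak_depth_m=40.0, chla_width_m=25.0,
            ),
            "Subtropical": ProvinceCurves(
                temp_surface_C=24.0, thermocline_depth_m=60.0,
                thermocline_width_m=20.0, temp_deep_C=3.0,
                oxygen_surface=220.0, oxycline_depth_m=100.0,
                oxygen_min=20.0, oxygen_min_depth_m=800.0,
                chla_peak=0.5, chla_peak_depth_m=90.0, chla_width_m=30.0,
            ),
        }
    )


def generate_profiles(
    spec: EnvFieldSpec, design: SurveyDesign
) -> dict[str, pd.DataFrame]:
    """One 1-m binned CTD profile per province: curve plus Gaussian noise."""
    missing = [p for p in design.provinces if p not in spec.curves]
    if missing:
        raise ValueError(f"no environmental curves defined for provinces {missing}")
    rng = component_rng(design.seed, PROFILE_STREAM)
    depths = np.arange(0, int(design.max_depth_m) + 1)
    out = {}
    for prov in design.provinces:
        c = spec.curves[prov]
        out[prov] = pd.DataFrame(
            {
                "depth_m": depths,
                "temperature_C": c.temperature(depths)
                + rng.normal(0.0, 1.0, len(depths)) * spec.noise_sd_temperature,
                "oxygen": c.oxygen(depths)
                + rng.normal(0.0, 1.0, len(depths)) * spec.noise_sd_oxygen,
                "chla": c.chla(depths)
                + rng.normal(0.0, 1.0, len(depths)) * spec.noise_sd_chla,
            }
        )
    return out


# ---------------------------------------------------------------------------
# Taxon planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantingConfig:
    """Parameters governing the planted community.

    A quarter of taxa are vertical migrators by default (deep by day,
    shallow by night); the remainder split evenly between epipelagic and
    mesopelagic residents.  Epipelagic residents are mostly endemic to a
    single province while mesopelagic residents (and migrators) are mostly
    shared across provinces, and mesopelagic vertical distributions are
    broader than epipelagic ones — the structural features of the survey
    the generator emulates.
    """

    migrator_fraction: float = 0.15
    epipelagic_fraction: float = 0.5
    epi_center_range_m: tuple[float, float] = (20.0, 150.0)
    epi_sd_range_m: tuple[float, float] = (20.0, 40.0)
    # Mesopelagic vertical spread scales with depth below the 200-m
    # boundary (sd = meso_sd_headroom_fraction x (centre - 200), clipped to
    # meso_sd_range_m): residents are bounded above by the permanent
    # thermocline, and vertical ranges broaden with depth.
    meso_center_range_m: tuple[float, float] = (350.0, 900.0)
    meso_sd_range_m: tuple[float, float] = (30.0, 160.0)
    meso_sd_headroom_fraction: float = 0.25
    # Migrator vertical spread scales with the stratum widths of the zone it
    # occupies (deep strata are 200 m, shallow ones 25-100 m) so a migrator
    # covers a comparable number of nets by day and by night; per-net read
    # normalisation then conserves its tow-level relative abundance.
    migrator_day_center_range_m: tuple[float, float] = (550.0, 750.0)
    migrator_night_center_range_m: tuple[float, float] = (60.0, 90.0)
    migrator_day_sd_m: float = 80.0
    migrator_night_sd_m: float = 20.0
    migration_min_separation_m: float = 200.0
    #: P(occupying 1, 2, ... all provinces), keyed by planted habitat.
    epi_occupancy_probs: tuple[float, ...] = (0.75, 0.2, 0.05)
    meso_occupancy_probs: tuple[float, ...] = (0.05, 0.2, 0.75)
    share_sigma: float = 0.8
    #: Epipelagic residents get proportionally larger abundance shares,
    #: reflecting the read dominance of surface communities; this keeps
    #: per-net denominators comparable across depth zones so within-net
    #: relative abundances mean the same thing shallow and deep.
    epipelagic_share_multiplier: float = 2.5
    size_depth_slope: float = 1.5
    size_sigma: float = 0.6
    diet_probs: tuple[float, float, float] = (0.2, 0.55, 0.25)
    feeding_probs: tuple[float, float, float, float] = (0.15, 0.3, 0.05, 0.5)
    spawning_probs: tuple[float, float] = (0.8, 0.2)
    asexual_fraction: float = 0.3
    composition_probs: tuple[float, float, float] = (0.1, 0.15, 0.75)
    asexual_cosmopolitan_boost: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.migrator_fraction <= 1.0:
            raise ValueError("migrator_fraction must be in [0, 1]")
        lo_day = self.migrator_day_center_range_m[0]
        hi_night = self.migrator_night_center_range_m[1]
        if lo_day - hi_night < self.migration_min_separation_m:
            raise ValueError(
                "migrator day/night centre ranges violate the minimum "
                "planted migration amplitude"
            )


@dataclass(frozen=True)
class PlantedTaxon:
    """Ground truth for one simulated taxon."""

    taxon_id: str
    depth_center_day_m: float
    depth_center_night_m: float
    depth_sd_day_m: float
    depth_sd_night_m: float
    province_occupancy: frozenset[str]
    global_share: float
    is_migrator: bool
    habitat: str  # planted habitat implied by the depth centres
    traits: TaxonTraits

    def __post_init__(self) -> None:
        if not self.province_occupancy:
            raise ValueError("province_occupancy must be non-empty")
        if not 0.0 < self.global_share <= 1.0:
            raise ValueError("global_share must be in (0, 1]")


def generate_taxa(
    n_taxa: int,
    design: SurveyDesign,
    config: PlantingConfig | None = None,
) -> list[PlantedTaxon]:
    """Plant ``n_taxa`` taxa with known depth, occupancy, and trait structure.

    Deterministic given ``design.seed``.  The draw order is documented so
    individual draws can be replayed: (1) migrator indicators, a single
    ``rng.random(n_taxa) < migrator_fraction`` on the taxa substream;
    (2) per-taxon depth parameters, occupancy, and traits in taxon order;
    (3) raw lognormal abundance shares, one ``rng.normal(0, share_sigma,
    n_taxa)`` vector, normalised to sum to one.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    config = config or PlantingConfig()
    rng = component_rng(design.seed, TAXA_STREAM)
    boundary = 200.0
    n_prov = len(design.provinces)

    is_migrator = rng.random(n_taxa) < config.migrator_fraction

    taxa_partial: list[dict] = []
    for i in range(n_taxa):
        if is_migrator[i]:
            day_c = rng.uniform(*config.migrator_day_center_range_m)
            night_c = rng.uniform(*config.migrator_night_center_range_m)
            day_sd, night_sd = config.migrator_day_sd_m, config.migrator_night_sd_m
            habitat = "mesopelagic" if (day_c + night_c) / 2 > boundary else "epipelagic"
        else:
            epi = rng.random() < config.epipelagic_fraction
            if epi:
                day_c = night_c = rng.uniform(*config.epi_center_range_m)
                day_sd = night_sd = rng.uniform(*config.epi_sd_range_m)
            else:
                day_c = night_c = rng.uniform(*config.meso_center_range_m)
                lo, hi = config.meso_sd_range_m
                day_sd = night_sd = float(
                    np.clip(config.meso_sd_headroom_fraction * (day_c - 200.0),
                            lo, hi)
                )
            habitat = "epipelagic" if epi else "mesopelagic"

        probs = np.asarray(
            config.epi_occupancy_probs if habitat == "epipelagic"
            else config.meso_occupancy_probs,
            dtype=float,
        )
        if len(probs) != n_prov:
            raise ValueError(
                "occupancy probability vector length must equal the number "
                f"of provinces ({n_prov})"
            )
        k = int(rng.choice(np.arange(1, n_prov + 1), p=probs / probs.sum()))
        occupied = frozenset(rng.choice(design.provinces, size=k, replace=False))

        mean_center = (day_c + night_c) / 2.0
        size = float(
            np.exp(rng.normal(0.5 + config.size_depth_slope * mean_center / 1000.0,
                              config.size_sigma))
        )
        asexual = "yes" if rng.random() < config.asexual_fraction else "no"
        if (
            asexual == "yes"
            and rng.random() < config.asexual_cosmopolitan_boost
        ):
            occupied = frozenset(design.provinces)
        traits = TaxonTraits(
            body_size_mm=size,
            diet=str(rng.choice(["carnivore", "omnivore", "herbivore"],
                                p=config.diet_probs)),
            feeding=str(rng.choice(["ambush", "cruise", "parasitoid", "suspension"],
                                   p=config.feeding_probs)),
            spawning=str(rng.choice(["broadcast", "brooding"],
                                    p=config.spawning_probs)),
            asexual=asexual,
            composition=str(rng.choice(["gelatinous", "intermediate", "non-gelatinous"],
                                       p=config.composition_probs)),
        )
        taxa_partial.append(
            dict(
                taxon_id=f"t{i:04d}",
                depth_center_day_m=float(day_c),
                depth_center_night_m=float(night_c),
                depth_sd_day_m=float(day_sd),
                depth_sd_night_m=float(night_sd),
                province_occupancy=occupied,
                is_migrator=bool(is_migrator[i]),
                habitat=habitat,
                traits=traits,
            )
        )

    raw = np.exp(rng.normal(0.0, config.share_sigma, n_taxa))
    for i, partial in enumerate(taxa_partial):
        if partial["habitat"] == "epipelagic" and not partial["is_migrator"]:
            raw[i] *= config.epipelagic_share_multiplier
    shares = raw / raw.sum()
    taxa = [
        PlantedTaxon(global_share=float(s), **partial)
        for partial, s in zip(taxa_partial, shares)
    ]
    for t in taxa:
        sep = abs(t.depth_center_day_m - t.depth_center_night_m)
        if t.is_migrator != (sep >= config.migration_min_separation_m):
            raise RuntimeError(
                f"planted migration amplitude inconsistent for {t.taxon_id}"
            )
    return taxa


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------


def stratum_masses(
    center_m: float,
    sd_m: float,
    strata: Sequence[tuple[float, float]],
    max_depth_m: float = 1000.0,
) -> np.ndarray:
    """Per-stratum mass of a truncated Gaussian depth preference.

    The Gaussian is truncated to [0, max_depth] and integrated numerically
    over 1-m cells; cell ``k`` covers [k, k+1) m.  Returns one mass per
    stratum, summing to 1 over the full column.
    """
    if sd_m <= 0:
        raise ValueError("depth_sd must be positive")
    cells = np.arange(0.0, max_depth_m) + 0.5
    logp = -0.5 * ((cells - center_m) / sd_m) ** 2
    pdf = np.exp(logp - logp.max())  # stable for sd much smaller than 1 m
    pdf /= pdf.sum()
    out = np.empty(len(strata))
    for i, (upper, lower) in enumerate(strata):
        out[i] = pdf[int(upper) : int(lower)].sum()
    return out


def _marker_assignment(
    taxa: Sequence[PlantedTaxon], design: SurveyDesign
) -> dict[str, list[int]]:
    """Assign taxa to markers: a shared overlap, the rest split evenly."""
    n = len(taxa)
    markers = [f"M{k + 1}" for k in range(design.n_markers)]
    if design.n_markers == 1:
        return {markers[0]: list(range(n))}
    rng = component_rng(design.seed, MARKER_STREAM)
    perm = rng.permutation(n)
    n_shared = int(round(design.marker_overlap * n))
    shared = list(perm[:n_shared])
    rest = perm[n_shared:]
    assign: dict[str, list[int]] = {m: list(shared) for m in markers}
    for j, idx in enumerate(rest):
        assign[markers[j % design.n_markers]].append(int(idx))
    return {m: sorted(v) for m, v in assign.items()}


def _weight_matrix(
    taxa: Sequence[PlantedTaxon],
    design: SurveyDesign,
    meta: pd.DataFrame,
) -> np.ndarray:
    """Expected (unnormalised) taxon weight per sample.

    weight = global_share x truncated-Gaussian mass over the stratum
    (day centres for day tows, night centres for night tows) x province
    occupancy indicator.
    """
    masses = {}
    for t in taxa:
        masses[(t.taxon_id, "day")] = stratum_masses(
            t.depth_center_day_m, t.depth_sd_day_m, design.strata, design.max_depth_m
        )
        masses[(t.taxon_id, "night")] = stratum_masses(
            t.depth_center_night_m, t.depth_sd_night_m, design.strata,
            design.max_depth_m
        )
    w = np.zeros((len(taxa), len(meta)))
    for j, row in enumerate(meta.itertuples(index=False)):
        for i, t in enumerate(taxa):
            if row.province not in t.province_occupancy:
                continue
            w[i, j] = t.global_share * masses[(t.taxon_id, row.tow_period)][
                row.stratum_index
            ]
    return w


def sample_reads(
    taxa: Sequence[PlantedTaxon],
    design: SurveyDesign,
) -> tuple[dict[str, ReadMatrix], pd.DataFrame]:
    """Draw multinomial read counts for every net sample, per marker.

    Each (province, tow period, stratum) cell is one sample; counts are a
    single multinomial draw of ``reads_per_sample`` trials over the
    marker's taxa with probabilities proportional to the planted weights.
    Samples in which every taxon has zero weight stay all-zero and are
    flagged on the returned matrix.
    """
    if not taxa:
        raise ValueError("no taxa to sample")
    meta = build_sample_meta(design.provinces, design.strata, design.tow_periods)
    assign = _marker_assignment(taxa, design)
    weights = _weight_matrix(taxa, design, meta)
    rng = component_rng(design.seed, READS_STREAM)
    matrices: dict[str, ReadMatrix] = {}
    for marker in sorted(assign):
        idx = assign[marker]
        sub = weights[idx, :]
        counts = np.zeros_like(sub, dtype=np.int64)
        zero_samples = []
        for j, sample_id in enumerate(meta["sample_id"]):
            colsum = sub[:, j].sum()
            if colsum == 0:
                zero_samples.append(sample_id)
                continue
            counts[:, j] = rng.multinomial(design.reads_per_sample,
                                           sub[:, j] / colsum)
        df = pd.DataFrame(
            counts,
            index=[taxa[i].taxon_id for i in idx],
            columns=meta["sample_id"].tolist(),
        )
        matrices[marker] = ReadMatrix(df, marker=marker,
                                      zero_samples=tuple(zero_samples))
    return matrices, meta


def expected_read_counts(
    taxa: Sequence[PlantedTaxon],
    design: SurveyDesign,
) -> dict[str, pd.DataFrame]:
    """Expected counts per taxon x sample for each marker (no sampling noise)."""
    meta = build_sample_meta(design.provinces, design.strata, design.tow_periods)
    assign = _marker_assignment(taxa, design)
    weights = _weight_matrix(taxa, design, meta)
    out = {}
    for marker in sorted(assign):
        idx = assign[marker]
        sub = weights[idx, :]
        colsums = sub.sum(axis=0)
        probs = np.divide(sub, colsums, out=np.zeros_like(sub),
                          where=colsums > 0)
        out[marker] = pd.DataFrame(
            probs * design.reads_per_sample,
            index=[taxa[i].taxon_id for i in idx],
            columns=meta["sample_id"].tolist(),
        )
    return out


# ---------------------------------------------------------------------------
# Bundling and output
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSurvey:
    """Everything a downstream analysis needs, plus the ground truth."""

    design: SurveyDesign
    planting: PlantingConfig
    taxa: list[PlantedTaxon]
    matrices: dict[str, ReadMatrix]
    meta: pd.DataFrame
    profiles: dict[str, pd.DataFrame]
    traits: pd.DataFrame
    truth: pd.DataFrame


def ground_truth_frame(taxa: Sequence[PlantedTaxon]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [t.taxon_id for t in taxa],
            "is_migrator": [t.is_migrator for t in taxa],
            "habitat": [t.habitat for t in taxa],
            "occupancy": [";".join(sorted(t.province_occupancy)) for t in taxa],
            "depth_center_day_m": [t.depth_center_day_m for t in taxa],
            "depth_center_night_m": [t.depth_center_night_m for t in taxa],
            "depth_sd_day_m": [t.depth_sd_day_m for t in taxa],
            "depth_sd_night_m": [t.depth_sd_night_m for t in taxa],
            "global_share": [t.global_share for t in taxa],
        }
    ).set_index("taxon_id")


def trait_frame(taxa: Sequence[PlantedTaxon]) -> pd.DataFrame:
    """Trait table keyed by taxon name (here, the taxon id itself)."""
    rows = []
    for t in taxa:
        tr = t.traits
        rows.append(
            {
                "name": t.taxon_id,
                "body_size_mm": tr.body_size_mm,
                "diet": tr.diet,
                "feeding": tr.feeding,
                "spawning": tr.spawning,
                "asexual": tr.asexual,
                "composition": tr.composition,
            }
        )
    return pd.DataFrame(rows).set_index("name")


def simulate_survey(
    n_taxa: int = 100,
    design: SurveyDesign | None = None,
    planting: PlantingConfig | None = None,
    env_spec: EnvFieldSpec | None = None,
) -> SimulatedSurvey:
    """Generate a complete synthetic survey with its ground truth."""
    design = design or SurveyDesign()
    planting = planting or PlantingConfig()
    env_spec = env_spec or default_env_spec()
    taxa = generate_taxa(n_taxa, design, planting)
    matrices, meta = sample_reads(taxa, design)
    profiles = generate_profiles(env_spec, design)
    return SimulatedSurvey(
        design=design,
        planting=planting,
        taxa=taxa,
        matrices=matrices,
        meta=meta,
        profiles=profiles,
        traits=trait_frame(taxa),
        truth=ground_truth_frame(taxa),
    )


def write_survey(survey: SimulatedSurvey, outdir: str | Path) -> None:
    """Write the full survey bundle as plain TSV/CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for marker, matrix in survey.matrices.items():
        write_read_matrix(matrix, outdir / f"reads_{marker}.tsv")
    write_sample_meta(survey.meta, outdir / "sample_meta.tsv")
    write_profiles(survey.profiles, outdir / "ctd_profiles.csv")
    write_trait_table(survey.traits, outdir / "traits.tsv")
    truth = survey.truth.copy()
    truth.index.name = "taxon_id"
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
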