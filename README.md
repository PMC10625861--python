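# midwater

Analysis tools for depth-stratified zooplankton metabarcoding surveys:
per-taxon vertical statistics, diel-vertical-migration (DVM) detection
from paired day/night tows, environmental-range estimation from CTD
profiles, province-scale occupancy and endemism, community distances and
beta-dispersion, and the nonparametric statistical battery that ties them
together. A synthetic-survey generator with planted ground truth makes
every stage testable end to end.

## The problem

Multinet (MOCNESS) surveys sample the water column in discrete depth
strata — here eight nets between 0 and 1000 m — with one daytime and one
nighttime tow per station, across several biogeochemical provinces
(Subarctic, Transition, Subtropical). Metabarcoding each net yields a
taxon-by-sample read-count table per molecular marker (e.g. 18S and COI).
From those counts, community ecologists want to know where each taxon
lives vertically, whether it migrates daily, how broad an environmental
envelope it occupies, and how vertical habitat relates to horizontal
(biogeographic) range.

## The statistics at its core

**Mean depth of occurrence.** For taxon *t* with relative read abundance
*rᵢ* in net *i* (midpoint depth *mᵢ*),

    MDO(t) = Σᵢ rᵢ mᵢ / Σᵢ rᵢ

over all nets where the taxon occurs. Taxa with MDO > 200 m are
classified mesopelagic, otherwise epipelagic.

**DVM detection.** A taxon is scored as a diel vertical migrator when, at
some station with paired tows, all four criteria hold:

1. observed in ≥ 2 nets in the day tow and ≥ 2 in the night tow;
2. day and night tow-level relative abundances within twofold;
3. ≥ 0.01 % of the marker's total reads in the study;
4. the weighted mean depth shifts by ≥ 2 sampling strata between tows.

**Environmental range.** CTD casts binned to 1 m are averaged over each
net's depth interval; a taxon's range for a variable (temperature,
dissolved oxygen, Chl-a) is the max − min of those net means over all
(province, stratum) cells where it occurred.

**Community statistics.** Presence-based richness with analytic
(hypergeometric) rarefaction; occupancy partitions and endemism across
provinces; Bray–Curtis and Jaccard distances; non-metric MDS (Kruskal
stress-1); PERMDISP-style beta-dispersion (distance to group centroid in
principal-coordinate space, negative-eigenvalue corrected, compared by
one-way ANOVA); Kruskal–Wallis with tie correction, Dunn's post-hoc with
Bonferroni, ties-corrected Spearman, and the chi-square test of
independence.

## Worked example

```python
from midwater.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=42, n_taxa=200))

metrics = result.tables["taxon_metrics"]
print("taxa analysed:", len(metrics))
print("migrators detected:", (metrics["dvm"] == "yes").sum())

disp = result.tables["beta_dispersion"]
row = disp[(disp.marker == "combined") & (disp.metric == "bray_curtis")].iloc[0]
print(f"beta-dispersion F = {row.F:.2f}, p = {row.p_anova:.4f}")
print(f"mean distance to centroid: epipelagic {row.mean_epipelagic:.3f}, "
      f"mesopelagic {row.mean_mesopelagic:.3f}")

chi = result.tables["habitat_occupancy_chisq"].iloc[0]
print(f"habitat x provinces chi2 = {chi.statistic:.2f}, p = {chi.p:.2e}")
```

prints

```
taxa analysed: 200
migrators detected: 36
beta-dispersion F = 11.40, p = 0.0015
mean distance to centroid: epipelagic 0.518, mesopelagic 0.456
habitat x provinces chi2 = 115.45, p = 8.52e-26
```

All 36 planted migrators are recovered with no false positives; the
mesopelagic samples are significantly more homogeneous across provinces
than the epipelagic ones (lower dispersion); and mesopelagic taxa occupy
significantly more provinces than epipelagic taxa — the planted
structure, read back out by the pipeline.

The same pipeline runs from the shell:

```bash
midwater simulate --n-taxa 100 --seed 2 --out survey/
midwater run --input-dir survey/ --seed 2 --out run/
midwater report --run-dir run/
```

`run/` then holds the full report bundle as TSV/CSV tables plus a
machine-readable `manifest.json` (config hash, seed, versions, and the
operation that produced each table).

## Layout

| module                 | contents                                              |
| ---------------------- | ----------------------------------------------------- |
| `midwater.io`          | containers + TSV/CSV readers/writers, replicate merging, relative abundance, marker combination |
| `midwater.synthetic`   | survey generator with planted ground truth            |
| `midwater.metrics`     | MDO, habitat classification, DVM detector, size–depth correlation |
| `midwater.environment` | net-mean environments, per-taxon environmental ranges |
| `midwater.community`   | richness/rarefaction, occupancy partitions, distances, nMDS, beta-dispersion |
| `midwater.stats`       | Kruskal–Wallis, Dunn, Spearman, chi-square            |
| `midwater.pipeline`    | end-to-end orchestration and report bundle            |
| `midwater.experiments` | planted-recovery and calibration experiments          |
| `midwater.cli`         | the `midwater` command (`simulate`, `run`, `report`)  |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
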