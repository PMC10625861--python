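# Methods

This note documents the models, conventions, and parameter choices
behind `midwater`: what each estimator assumes, what the synthetic
survey generator does and does not emulate, and where the design was
genuinely open.

## Survey model and conventions

A survey is a set of *nets*: one sample per (province, station, tow
period, depth stratum). Defaults follow the emulated design — three
North Pacific provinces (Subarctic, Transition, Subtropical), one
station per province, one day and one night tow per station, and eight
strata: 0–25, 25–50, 50–100, 100–200, 200–400, 400–600, 600–800,
800–1000 m. Strata abut exactly at 200 m, so the epipelagic (0–200 m) /
mesopelagic (200–1000 m) split never divides a net.

Conventions used throughout:

- **Presence** means ≥ 1 read after technical-replicate merging. No
  abundance floor is applied (configurable nowhere downstream; analyses
  that need robustness to rare detections should filter their input).
- **Depth intervals** are half-open [upper, lower) against integer 1-m
  CTD bins; the deepest stratum is closed at 1000 m. This prevents
  double-counting boundary bins: the 800–1000 m stratum averages 201
  bins, every other stratum exactly (lower − upper) bins.
- **Habitat boundary**: MDO of exactly 200 m is epipelagic; the
  mesopelagic class requires a strict MDO > 200 m.
- **Relative abundance** is within-net: each count column divided by its
  sum; all-zero nets stay zero and are flagged. Counts are never
  rarefied before relative-abundance conversion; rarefaction exists only
  for richness comparisons.
- **Markers** are treated as independent observation channels. Per-taxon
  statistics (MDO, DVM, environmental range) are computed within each
  marker and concatenated with marker-prefixed taxon ids; this is
  exactly equivalent to computing them on the row-stacked combined
  matrix, because all of them depend only on within-net relative
  abundances, which are invariant to stacking. No cross-marker
  deduplication is attempted: two markers detecting the same species
  yield two rows.

## Per-taxon estimators

**MDO** is the relative-read-abundance-weighted mean of stratum
midpoints over occupied nets. The overall MDO pools every net from every
station and tow into a single weighted mean; per-tow MDOs restrict to
one (station, tow period). Weighting by relative abundance makes MDO
invariant to rescaling a taxon's abundances by a constant, and confines
it to [shallowest occupied midpoint, deepest occupied midpoint].

**DVM detection** applies four criteria, evaluated per station for every
station with paired tows (C1, C2, C4) or study-wide within the marker
(C3): C1 presence in ≥ 2 nets per tow; C2 tow-level relative abundances
(taxon reads ÷ tow total reads) within a symmetric twofold ratio; C3
study share ≥ 10⁻⁴; C4 per-tow weighted mean depths falling ≥ 2 strata
apart. "Two strata" is an index difference on the stratum containing
each WMD — strata have unequal metric widths, so a fixed metre threshold
would not mean "strata". A taxon is a migrator when any station passes
C1∧C2∧C4 while C3 holds; the outcome of each criterion at each station
is kept as diagnostics. Whether the criteria ought to hold at
every station or at least one is not determinable from the emulated
protocol; *at least one* is implemented, since the trait is assigned
once per taxon, and the thresholds are all configurable
(`DvmCriteria`).

**Environmental ranges** use province-level net environments: all 1-m
CTD bins inside a stratum are averaged, and day and night tows share the
result (casts are per location, not per tow). A taxon's range for a
variable is max − min of net-mean values over occupied (province,
stratum) cells, pooled over tow periods; a single occupied cell gives
range 0. Chl-a below 200 m is retained as measured (near zero), not
masked.

## Statistical battery

Kruskal–Wallis (midrank ties, tie-corrected H, chi-square p on k − 1
df), ties-corrected Spearman (Pearson on midranks, two-sided t-based p)
and the chi-square test of independence (no continuity correction by
default; Yates is opt-in and relevant only to 2×2 tables) are computed
via SciPy, which implements these exact forms. Dunn's post-hoc z uses
the mean-rank difference over a standard error with the pooled tie
correction, two-sided normal p-values, and Bonferroni adjustment capped
at 1. Every one of these is checked against an independently coded
brute-force oracle in the test suite, and the suite also verifies
frequentist calibration: empirical Kruskal–Wallis size 0.05 ± 0.01 and
Dunn familywise error ≤ α over 10,000 null simulations.

Beta-dispersion embeds the distance matrix by principal coordinates
(eigendecomposition of the double-centred −½D²), keeps axes with
non-negligible eigenvalues of either sign, and computes each sample's
squared distance to its group centroid as the positive-axis contribution
minus the negative-axis contribution, floored at zero — the standard
correction for semi-metric distances like Bray–Curtis. Group centroids
(not spatial medians) are used, matching the ANOVA-on-distances framing;
the F test is complemented by an optional seeded permutation p obtained
by relabeling the per-sample distances. Non-metric MDS delegates to
scikit-learn's SMACOF with isotonic (monotone) regression, 20 random
starts by default; Kruskal stress-1 is recomputed from the returned
configuration by isotonic regression of fitted distances on observed
dissimilarity ranks.

Rarefied richness uses the exact hypergeometric expectation
E[S] = Σᵢ (1 − C(N − nᵢ, m)/C(N, m)), evaluated with log-gamma for
stability; a Monte-Carlo variant (multivariate hypergeometric draws) is
available and agrees with the closed form within sampling error.

## The synthetic survey generator

The generator plants a community whose structure the pipeline must
recover. Each taxon has a truncated-Gaussian depth preference on
[0, 1000] m (numerically integrated over 1-m cells to per-stratum mass),
day and night depth centres, a province-occupancy set, a global
abundance share, and a trait vector. Expected weight of a taxon in a net
is share × stratum mass (day centres for day tows) × occupancy
indicator; counts are one multinomial draw of `reads_per_sample`
(default 5 × 10⁴, the emulated per-sample sequencing depth) per net. All
randomness flows from one master seed through named `SeedSequence`
substreams (profiles, taxa, marker assignment, reads), so runs are
bit-reproducible and individual draws replayable.

CTD fields are parametric per province: a descending logistic
temperature profile (surface value, thermocline depth/width, deep
value), a smoothstep oxygen decline from the surface value across the
oxycline to an oxygen-minimum-zone value, and a Gaussian Chl-a peak in
the euphotic zone, each plus seeded Gaussian noise. Defaults place the
strongest temperature and Chl-a gradients in the upper 100–200 m and the
oxycline in the mesopelagic, warmest/most stratified in the Subtropical
province and coldest with the shallowest, most intense OMZ in the
Subarctic.

The default planted community encodes the structural features the
emulated survey reported, chosen from the ecology of the system:

- **Epipelagic residents** (half of non-migrators): centres 20–150 m,
  sd 20–40 m, mostly endemic (P(1/2/3 provinces) = 0.75/0.2/0.05), and
  with 2.5× larger abundance shares — surface communities dominate read
  abundance, which also keeps per-net compositional denominators
  comparable across depth zones so that within-net relative abundance
  means the same thing shallow and deep.
- **Mesopelagic residents**: centres 350–900 m, mostly shared across
  provinces (0.05/0.2/0.75). Vertical spread scales with depth below the
  200-m boundary (sd = 0.25 × (centre − 200 m), clipped to 30–160 m):
  residents are bounded above by the permanent thermocline, and the
  ~4σ clearance means a 5 × 10⁴-read net does not register
  surface-stratum tail occurrences that would smear presence-based
  temperature/Chl-a ranges; deeper taxa spread more broadly, giving the
  vertical overlap that makes mesopelagic samples compositionally
  similar.
- **Migrators** (15 % of taxa by default; experiments that study the
  detector itself plant 50 %): day residence 550–750 m (sd 80 m), night
  residence 60–90 m (sd 20 m) — strong, metridinid-like migration of
  ≥ 3 strata. The spread scales with the stratum widths of the occupied
  zone so a migrator covers a comparable number of nets by day and by
  night; per-net read normalisation then conserves its tow-level
  abundance, as the twofold criterion assumes of a true migrator. Night
  centres sit inside the densely populated 50–100 m layer rather than
  the sparsely populated surface net. The ~50 % figure sometimes quoted
  for migratory communities refers to reads, not taxa; migrators here
  are abundant cosmopolitans, so a modest taxon fraction carries a large
  read share.
- **Traits**: body size lognormal with a positive depth trend (so the
  size–depth rank correlation is recoverable), categorical traits drawn
  from fixed frequencies, and an optional planted effect linking asexual
  reproduction to cosmopolitan occupancy for contrast-recovery tests.
- **Markers**: optionally ≥ 2 markers as independent multinomial
  resamplings of overlapping taxon subsets (default overlap 0.2).

What the generator does **not** emulate: sequence-level artifacts (PCR
and primer bias, chimeras, misassignment), patchiness and tow-to-tow
variance beyond multinomial noise, multiple stations per province,
seasonal or interannual change, and life-stage structure. Passing
recovery tests therefore demonstrates that the estimators invert the
generative model faithfully at realistic sample sizes — not that they
are robust to molecular artifacts the model omits.

## Problem sizes in the validation experiments

Per-taxon recovery experiments (migration detection, habitat/occupancy
recovery) use 100 taxa at 5 × 10⁴ reads per net. The community-level
directional experiment uses 200 taxa: its contrasts are rank tests
across taxa, and the surveys it emulates resolve on the order of a
thousand taxa, so the richer community is the more faithful (and more
powerful) setting. Null calibrations use 10,000 simulations of three
groups of 20. The oracle sweep uses 100 random fixtures per estimator.

## Known limitations

- The DVM rule is evaluated on the same day/night read shifts the
  generator plants; it cannot distinguish migration from systematic
  day/night catch bias, which the model does not simulate.
- Environmental ranges are presence-based and therefore sensitive to
  single-read detections; with very deep sequencing, Gaussian-tail
  occurrences of abundant taxa can widen ranges sharply.
- Beta-dispersion compares distances to centroids; with strongly
  unbalanced group sizes the ANOVA p-value can be anticonservative, and
  the permutation p is the safer report.
- nMDS minimises stress from random starts; different platforms may
  return reflected/rotated configurations (stress, not coordinates, is
  the stable output).
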