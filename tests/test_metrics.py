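import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from midwater.io import DEFAULT_STRATA, ReadMatrix, build_sample_meta, to_relative
from midwater.metrics import (
    DvmCriteria,
    classify_habitat,
    detect_dvm,
    dvm_table,
    mdo,
    mdo_table,
    size_depth_correlation,
    taxon_metrics_table,
)


def _matrix_from_counts(meta, rows: dict[str, dict[str, int]]) -> ReadMatrix:
    data = pd.DataFrame(
        0, index=list(rows), columns=meta["sample_id"].tolist(), dtype=int
    )
    for taxon, cells in rows.items():
        for sample, count in cells.items():
            data.loc[taxon, sample] = count
    return ReadMatrix(data, marker="M1")


class TestMdo:
    def test_single_net_weight_cancels(self):
        meta = build_sample_meta(("A",))
        m = _matrix_from_counts(meta, {"tx": {"A_day_s3": 40}, "bg": {"A_day_s0": 10}})
        assert mdo(m, meta, "tx") == pytest.approx(150.0)

    def test_equal_abundance_symmetry(self):
        meta = build_sample_meta(("A",))
        m = _matrix_from_counts(
            meta,
            {"tx": {"A_day_s0": 10, "A_day_s1": 10},
             "bg": {"A_day_s0": 90, "A_day_s1": 90}},
        )
        assert mdo(m, meta, "tx") == pytest.approx(25.0)

    def test_hand_computed_weighted_mean(self):
        # r = 0.10 at midpoint 150 m and 0.03 at midpoint 700 m
        meta = build_sample_meta(("A",))
        m = _matrix_from_counts(
            meta,
            {"tx": {"A_day_s3": 10, "A_day_s6": 3},
             "bg": {"A_day_s3": 90, "A_day_s6": 97}},
        )
        assert mdo(m, meta, "tx") == pytest.approx((0.10 * 150 + 0.03 * 700) / 0.13)

    def test_missing_when_never_observed(self):
        meta = build_sample_meta(("A",))
        m = _matrix_from_counts(meta, {"tx": {}, "bg": {"A_day_s0": 5}})
        assert np.isnan(mdo(m, meta, "tx"))

    def test_unknown_taxon_raises(self):
        meta = build_sample_meta(("A",))
        m = _matrix_from_counts(meta, {"tx": {"A_day_s0": 1}})
        with pytest.raises(KeyError):
            mdo(m, meta, "nope")

    def test_bounded_by_occupied_midpoints_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        meta = build_sample_meta(("A", "B"))
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, len(meta)))
            m = ReadMatrix(
                pd.DataFrame(counts, index=list("wxyz"),
                             columns=meta["sample_id"].tolist()),
                marker="M1",
            )
            mids = meta.set_index("sample_id")["stratum_midpoint_m"]
            for taxon in m.taxa:
                value = mdo(m, meta, taxon)
                occupied = m.data.loc[taxon] > 0
                if not occupied.any():
                    assert np.isnan(value)
                    continue
                assert mids[occupied].min() - 1e-9 <= value <= mids[occupied].max() + 1e-9

    def test_rescaling_relative_abundances_preserves_mdo(self):
        # two-taxon relative matrix: halving one taxon's relative abundances
        # (the other absorbing the remainder) leaves its MDO unchanged
        meta = build_sample_meta(("A",))
        cols = meta["sample_id"].tolist()
        r = np.linspace(0.1, 0.8, len(cols))
        base = pd.DataFrame([r, 1 - r], index=["tx", "bg"], columns=cols)
        scaled = pd.DataFrame([r / 2, 1 - r / 2], index=["tx", "bg"], columns=cols)
        m1 = ReadMatrix(base, "M1", mode="relative")
        m2 = ReadMatrix(scaled, "M1", mode="relative")
        assert mdo(m1, meta, "tx") == pytest.approx(mdo(m2, meta, "tx"), abs=1e-12)

    def test_table_matches_scalar_calls(self, small_survey):
        m = small_survey.matrices["M1"]
        table = mdo_table(m, small_survey.meta)
        for taxon in m.taxa[:10]:
            expected = mdo(m, small_survey.meta, taxon)
            got = table.loc[taxon, "mdo_overall_m"]
            assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)


class TestHabitat:
    @pytest.mark.parametrize(
        "value,expected",
        [(250.0, "mesopelagic"), (150.0, "epipelagic"), (200.0, "epipelagic")],
    )
    def test_boundary_convention(self, value, expected):
        assert classify_habitat(value) == expected

    def test_missing_mdo_flagged(self):
        assert classify_habitat(float("nan")) is None


def _paired_day_night_matrix(meta, day_counts, night_counts, background=None):
    """Build a two-taxon matrix with 'tx' given per-stratum day/night counts."""
    rows = {"tx": {}, "bg": background or {}}
    for i, c in enumerate(day_counts):
        if c:
            rows["tx"][f"A_day_s{i}"] = c
    for i, c in enumerate(night_counts):
        if c:
            rows["tx"][f"A_night_s{i}"] = c
    if background is None:
        rows["bg"] = {s: 100 for s in meta["sample_id"]}
    return _matrix_from_counts(meta, rows)


class TestDetectDvm:
    def test_single_day_net_fails_c1(self):
        meta = build_sample_meta(("A",))
        m = _paired_day_night_matrix(meta, [50, 0, 0, 0, 0, 0, 0, 0],
                                     [20, 20, 0, 0, 0, 0, 0, 0])
        res = detect_dvm(m, meta, "tx")
        assert not res.dvm
        assert not res.stations[0].c1_nets

    def test_threefold_abundance_fails_c2(self):
        meta = build_sample_meta(("A",))
        # day share 0.06 (tx 60 / 1000), night share 0.02: ratio 3 > 2
        rows = {
            "tx": {"A_day_s0": 30, "A_day_s1": 30,
                   "A_night_s0": 10, "A_night_s1": 10},
            "bg": {**{f"A_day_s{i}": 940 // 8 + (1 if i < 940 % 8 else 0)
                      for i in range(8)},
                   **{f"A_night_s{i}": 980 // 8 + (1 if i < 980 % 8 else 0)
                      for i in range(8)}},
        }
        m = _matrix_from_counts(meta, rows)
        res = detect_dvm(m, meta, "tx")
        d = res.stations[0]
        assert d.c1_nets and not d.c2_abundance and not res.dvm
        assert max(d.share_day, d.share_night) / min(d.share_day, d.share_night) \
            == pytest.approx(3.0, abs=0.15)

    def test_planted_migrator_passes_all_four(self):
        # day mass deep (stratum 5, WMD ~500 m), night shallow (stratum 1),
        # 3 nets per tow, tow shares within twofold, study share ~0.5 %
        meta = build_sample_meta(("A",))
        rows = {
            "tx": {"A_day_s4": 10, "A_day_s5": 40, "A_day_s6": 10,
                   "A_night_s0": 12, "A_night_s1": 30, "A_night_s2": 8},
            "bg": {s: 10_000 for s in meta["sample_id"]},
        }
        m = _matrix_from_counts(meta, rows)
        res = detect_dvm(m, meta, "tx")
        d = res.stations[0]
        # hand check each criterion on the same counts
        assert d.nets_day == 3 and d.nets_night == 3 and d.c1_nets
        share_day = 60 / (60 + 8 * 10_000)
        share_night = 50 / (50 + 8 * 10_000)
        assert d.share_day == pytest.approx(share_day)
        assert share_day / share_night <= 2 and d.c2_abundance
        assert res.study_share == pytest.approx(110 / (110 + 16 * 10_000))
        assert res.study_share >= 1e-4 and res.c3_study_share
        assert 400 <= d.wmd_day_m <= 600 and 25 <= d.wmd_night_m < 50
        assert d.stratum_shift == 4 and d.c4_shift
        assert res.dvm

    def test_symmetric_under_day_night_relabel(self):
        meta = build_sample_meta(("A",))
        rows = {
            "tx": {"A_day_s4": 10, "A_day_s5": 40, "A_day_s6": 10,
                   "A_night_s0": 12, "A_night_s1": 30, "A_night_s2": 8},
            "bg": {s: 10_000 for s in meta["sample_id"]},
        }
        m = _matrix_from_counts(meta, rows)
        swapped_meta = meta.copy()
        swapped_meta["tow_period"] = swapped_meta["tow_period"].map(
            {"day": "night", "night": "day"}
        )
        a = detect_dvm(m, meta, "tx")
        b = detect_dvm(m, swapped_meta, "tx")
        assert a.dvm == b.dvm
        assert a.stations[0].stratum_shift == b.stations[0].stratum_shift
        assert a.stations[0].wmd_day_m == pytest.approx(b.stations[0].wmd_night_m)

    def test_rare_taxon_fails_c3(self):
        meta = build_sample_meta(("A",))
        rows = {
            "tx": {"A_day_s4": 2, "A_day_s5": 2, "A_night_s0": 2, "A_night_s1": 2},
            "bg": {s: 50_000 for s in meta["sample_id"]},
        }
        m = _matrix_from_counts(meta, rows)
        res = detect_dvm(m, meta, "tx")
        assert not res.c3_study_share and not res.dvm

    def test_no_paired_tows_is_error(self):
        meta = build_sample_meta(("A",), tow_periods=("day",))
        m = _matrix_from_counts(meta, {"tx": {"A_day_s0": 5}})
        with pytest.raises(ValueError, match="paired"):
            detect_dvm(m, meta, "tx")

    def test_table_consistent_with_scalar(self, small_survey):
        m = small_survey.matrices["M1"]
        table = dvm_table(m, small_survey.meta)
        for taxon in m.taxa[:8]:
            res = detect_dvm(m, small_survey.meta, taxon)
            assert (table.loc[taxon, "dvm"] == "yes") == res.dvm


class TestSizeDepthCorrelation:
    def test_perfect_monotonicity(self):
        sizes = pd.Series([1.0, 2.0, 3.0, 4.0])
        depths = pd.Series([10.0, 50.0, 200.0, 600.0])
        rho, _ = size_depth_correlation(sizes, depths)
        assert rho == pytest.approx(1.0)
        rho_rev, _ = size_depth_correlation(sizes, depths.iloc[::-1].reset_index(drop=True))
        assert rho_rev == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self):
        rng = np.random.default_rng(3)
        sizes = pd.Series(rng.integers(1, 6, 20).astype(float))
        depths = pd.Series(rng.integers(1, 8, 20).astype(float))
        rho, _ = size_depth_correlation(sizes, depths)
        oracle = np.corrcoef(sps.rankdata(sizes), sps.rankdata(depths))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_too_few_pairs_flagged_missing(self):
        assert size_depth_correlation(pd.Series([1.0, 2.0]),
                                      pd.Series([3.0, 4.0])) is None


class TestMetricsTable:
    def test_recovers_planted_centres_within_one_stratum(self, small_survey):
        m = small_survey.matrices["M1"]
        table = taxon_metrics_table(m, small_survey.meta)
        truth = small_survey.truth
        from midwater.io import stratum_index_for_depth

        strata = small_survey.design.strata
        checked = 0
        for taxon in table.index:
            if truth.loc[taxon, "global_share"] < 1e-3:
                continue
            if truth.loc[taxon, "is_migrator"]:
                continue  # day/night centres differ; handled by the DVM tests
            planted = truth.loc[taxon, "depth_center_day_m"]
            got = table.loc[taxon, "mdo_overall_m"]
            if np.isnan(got):
                continue
            diff = abs(stratum_index_for_depth(got, strata)
                       - stratum_index_for_depth(min(planted, 1000.0), strata))
            assert diff <= 1, f"{taxon}: planted {planted}, got {got}"
            checked += 1
        assert checked > 10
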