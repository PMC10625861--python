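import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from midwater.community import (
    beta_dispersion,
    distance_matrix,
    expected_rarefied_richness,
    nmds,
    occupancy_partition,
    rarefy_monte_carlo,
    richness,
    zone_of_sample,
)
from midwater.io import ReadMatrix, build_sample_meta, to_relative

from conftest import random_count_matrix


def exact_rarefaction(counts, m):
    """Independent oracle: exact hypergeometric expectation with Fractions."""
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    expect = Fraction(0)
    for n_i in counts:
        if total - n_i >= m:
            absent = Fraction(math.comb(total - n_i, m), math.comb(total, m))
        else:
            absent = Fraction(0)
        expect += 1 - absent
    return float(expect)


class TestRichness:
    def test_empty_matrix_zero_richness(self):
        m = ReadMatrix(pd.DataFrame(0, index=["a", "b"], columns=["s1"]), "M1")
        out = richness(m)
        assert out["richness"].tolist() == [0]

    def test_rarefied_never_exceeds_observed(self):
        rng = np.random.default_rng(2)
        m = random_count_matrix(rng, 12, [f"s{i}" for i in range(5)], max_count=40)
        out = richness(m, rarefy_to=20)
        ok = ~out["rarefaction_excluded"]
        assert (out.loc[ok, "rarefied_richness"]
                <= out.loc[ok, "richness"] + 1e-12).all()

    def test_analytic_matches_exact_combinatorics(self):
        counts = np.array([10, 5, 3, 1, 1])
        got = expected_rarefied_richness(counts, 10)
        assert got == pytest.approx(exact_rarefaction(counts, 10), abs=1e-10)

    def test_analytic_matches_monte_carlo(self):
        counts = np.array([10, 5, 3, 1, 1])
        analytic = expected_rarefied_richness(counts, 10)
        rng = np.random.default_rng(123)
        n_iter = 10_000
        mc = rarefy_monte_carlo(counts, 10, n_iter, rng)
        # per-draw richness variance bounds the Monte-Carlo SE
        se = 1.5 / np.sqrt(n_iter) * np.sqrt(len(counts))
        assert abs(mc - analytic) < 3 * max(se, 0.05)

    def test_undersized_samples_flagged(self):
        m = ReadMatrix(pd.DataFrame({"s1": [5, 5], "s2": [1, 0]},
                                    index=["a", "b"]), "M1")
        out = richness(m, rarefy_to=5).set_index("group")
        assert not out.loc["s1", "rarefaction_excluded"]
        assert out.loc["s2", "rarefaction_excluded"]
        assert np.isnan(out.loc["s2", "rarefied_richness"])

    def test_zone_grouping_pools_reads(self, small_survey):
        m = small_survey.matrices["M1"]
        out = richness(m, small_survey.meta, group_by="zone").set_index("group")
        zones = zone_of_sample(small_survey.meta)
        for zone in ("epipelagic", "mesopelagic"):
            cols = zones[zones == zone].index
            pooled = m.data[cols].sum(axis=1)
            assert out.loc[zone, "richness"] == int((pooled > 0).sum())


class TestOccupancyPartition:
    def test_hand_enumerated_partition(self):
        meta = build_sample_meta(("A", "B", "C"))
        data = pd.DataFrame(0, index=["t1", "t2", "t3"],
                            columns=meta["sample_id"].tolist())
        data.loc["t1", "A_day_s0"] = 1
        data.loc["t2", ["A_day_s0", "B_day_s0"]] = 1
        data.loc["t3", ["A_day_s0", "B_day_s0", "C_day_s0"]] = 1
        part = occupancy_partition(ReadMatrix(data, "M1"), meta, "full")
        assert part.subset_counts[frozenset({"A"})] == 1
        assert part.subset_counts[frozenset({"A", "B"})] == 1
        assert part.subset_counts[frozenset({"A", "B", "C"})] == 1
        assert part.endemism["A"] == pytest.approx(1 / 3)
        assert part.cosmopolitan_fraction == pytest.approx(1 / 3)

    def test_counts_sum_to_observed_taxa_and_match_brute_force(self):
        rng = np.random.default_rng(5)
        meta = build_sample_meta(("A", "B", "C"))
        for _ in range(5):
            m = random_count_matrix(rng, 20, meta["sample_id"].tolist(), max_count=2)
            part = occupancy_partition(m, meta, "full")
            assert sum(part.subset_counts.values()) == part.total_taxa
            prov_of = meta.set_index("sample_id")["province"]
            for taxon, occ in part.per_taxon.items():
                brute = frozenset(
                    prov_of[s] for s in m.samples if m.data.loc[taxon, s] > 0
                )
                assert occ == brute

    def test_depth_scopes_restrict_nets(self):
        meta = build_sample_meta(("A", "B"))
        data = pd.DataFrame(0, index=["shallow", "deep"],
                            columns=meta["sample_id"].tolist())
        data.loc["shallow", "A_day_s0"] = 1  # 0-25 m
        data.loc["deep", "B_day_s7"] = 1  # 800-1000 m
        m = ReadMatrix(data, "M1")
        epi = occupancy_partition(m, meta, "epipelagic")
        meso = occupancy_partition(m, meta, "mesopelagic")
        assert set(epi.per_taxon) == {"shallow"}
        assert set(meso.per_taxon) == {"deep"}


class TestDistances:
    def test_identical_columns_zero(self):
        df = pd.DataFrame({"s1": [3, 1], "s2": [3, 1]}, index=["a", "b"])
        for metric in ("bray_curtis", "jaccard"):
            d = distance_matrix(ReadMatrix(df, "M1"), metric)
            assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        df = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]}, index=["a", "b"])
        for metric in ("bray_curtis", "jaccard"):
            d = distance_matrix(ReadMatrix(df, "M1"), metric)
            assert d.values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        rel = pd.DataFrame({"s1": [0.6, 0.4], "s2": [0.2, 0.8]}, index=["a", "b"])
        d = distance_matrix(ReadMatrix(rel, "M1", mode="relative"), "bray_curtis")
        assert d.values[0, 1] == pytest.approx(0.4)

    def test_all_zero_pair_flagged_zero(self):
        df = pd.DataFrame({"s1": [0, 0], "s2": [0, 0], "s3": [1, 1]},
                          index=["a", "b"])
        d = distance_matrix(ReadMatrix(df, "M1"), "jaccard")
        assert d.values[0, 1] == 0.0
        assert ("s1", "s2") in d.flagged_pairs

    def test_matches_formula_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_count_matrix(rng, 8, [f"s{i}" for i in range(6)],
                                    max_count=20)
            rel = to_relative(m)
            bc = distance_matrix(rel, "bray_curtis").values
            jc = distance_matrix(m, "jaccard").values
            x = rel.data.to_numpy()
            b = m.data.to_numpy() > 0
            for i in range(6):
                for j in range(6):
                    num = np.abs(x[:, i] - x[:, j]).sum()
                    den = (x[:, i] + x[:, j]).sum()
                    expected_bc = num / den if den else 0.0
                    assert bc[i, j] == pytest.approx(expected_bc, abs=1e-12)
                    union = (b[:, i] | b[:, j]).sum()
                    inter = (b[:, i] & b[:, j]).sum()
                    expected_jc = 1 - inter / union if union else 0.0
                    assert jc[i, j] == pytest.approx(expected_jc, abs=1e-12)


class TestNmds:
    def test_embeddable_configuration_low_stress(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d /= d.max()
        from midwater.community import DistanceMatrix

        dm = DistanceMatrix(tuple(f"s{i}" for i in range(12)), d, "bray_curtis")
        res = nmds(dm, k=2, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_duplicate_samples_nearly_coincide(self):
        df = pd.DataFrame(
            {"s1": [5, 1, 0], "s2": [5, 1, 0], "s3": [0, 2, 6], "s4": [1, 5, 2]},
            index=["a", "b", "c"],
        )
        rel = to_relative(ReadMatrix(df, "M1"))
        dm = distance_matrix(rel, "bray_curtis")
        res = nmds(dm, k=2, n_starts=8, seed=1)
        c = res.coordinates
        gap = np.linalg.norm(c.loc["s1"] - c.loc["s2"])
        spread = np.linalg.norm(c.loc["s1"] - c.loc["s3"])
        assert gap < 0.1 * max(spread, 1e-9)

    def test_more_iterations_never_raise_best_stress(self):
        rng = np.random.default_rng(6)
        m = random_count_matrix(rng, 10, [f"s{i}" for i in range(9)], max_count=15)
        dm = distance_matrix(to_relative(m), "bray_curtis")
        short = nmds(dm, k=2, n_starts=4, seed=2, max_iter=5)
        long = nmds(dm, k=2, n_starts=4, seed=2, max_iter=300)
        assert long.stress <= short.stress + 1e-9


class TestBetaDispersion:
    @staticmethod
    def _two_cluster_matrix(rng, n_per, noise_a=0.02, noise_b=0.02):
        base_a = np.array([5.0, 1.0, 0.2, 0.0, 0.0, 0.0])
        base_b = np.array([0.0, 0.0, 0.2, 1.0, 5.0, 2.0])
        cols, labels = {}, {}
        for i in range(n_per):
            cols[f"a{i}"] = np.maximum(base_a + rng.normal(0, noise_a * 5, 6), 0)
            labels[f"a{i}"] = "A"
        for i in range(n_per):
            cols[f"b{i}"] = np.maximum(base_b + rng.normal(0, noise_b * 5, 6), 0)
            labels[f"b{i}"] = "B"
        df = pd.DataFrame(cols, index=[f"t{k}" for k in range(6)])
        df = df / df.sum(axis=0)
        return ReadMatrix(df, "M1", mode="relative"), labels

    def test_identical_group_members_zero_distance(self):
        df = pd.DataFrame(
            {"a1": [1, 0], "a2": [1, 0], "b1": [0.5, 0.5], "b2": [0.2, 0.8]},
            index=["t1", "t2"],
        )
        rel = ReadMatrix(df / df.sum(axis=0), "M1", mode="relative")
        dm = distance_matrix(rel, "bray_curtis")
        res = beta_dispersion(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                              n_perm=99, seed=0)
        assert res.distances[["a1", "a2"]].max() == pytest.approx(0.0, abs=1e-9)

    def test_f_matches_anova_by_hand(self):
        rng = np.random.default_rng(8)
        m, labels = self._two_cluster_matrix(rng, 8, 0.05, 0.2)
        dm = distance_matrix(m, "bray_curtis")
        res = beta_dispersion(dm, labels, n_perm=0)
        z = res.distances
        groups = [z[[s for s, g in labels.items() if g == lab]].to_numpy()
                  for lab in ("A", "B")]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f_ref, abs=1e-10)
        assert res.p_anova == pytest.approx(p_ref, abs=1e-10)

    def test_planted_extra_dispersion_detected(self):
        rng = np.random.default_rng(9)
        m, labels = self._two_cluster_matrix(rng, 12, noise_a=0.02, noise_b=0.10)
        dm = distance_matrix(m, "bray_curtis")
        res = beta_dispersion(dm, labels, n_perm=499, seed=1)
        assert res.group_means["B"] > res.group_means["A"]
        assert res.p_anova < 0.05
        assert res.p_permutation < 0.05

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"s1": [1, 0], "s2": [0, 1], "s3": [1, 1]},
                          index=["a", "b"])
        dm = distance_matrix(ReadMatrix(df, "M1"), "jaccard")
        with pytest.raises(ValueError, match="fewer than two"):
            beta_dispersion(dm, {"s1": "A", "s2": "A", "s3": "B"}, n_perm=0)
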