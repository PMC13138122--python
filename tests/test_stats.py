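"""Proportions, Kruskal–Wallis/Dunn/Holm/Bonferroni cascade, trends, MFI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import naivegate as ng
from naivegate.stats import subset_group_test


def hand_kruskal(groups):
    """Independent rank-formula recomputation of the ties-corrected H."""
    pooled = np.concatenate(list(groups.values()))
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offset = 0
    h = 0.0
    for v in groups.values():
        r = ranks[offset: offset + len(v)]
        h += r.sum() ** 2 / len(v)
        offset += len(v)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / ties


def hand_dunn(groups):
    """Independent recomputation of Dunn z from mean ranks and the pooled
    ties-corrected variance."""
    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, offset = {}, {}, 0
    for k in names:
        sizes[k] = len(groups[k])
        mean_ranks[k] = ranks[offset: offset + sizes[k]].mean()
        offset += sizes[k]
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = np.sum(counts**3 - counts)
    out = {}
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)))
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out[(a, b)] = (z, 2 * sps.norm.sf(abs(z)))
    return out


FIXTURE = {
    "A": np.array([1.2, 3.4]),
    "B": np.array([2.2, 5.6, 7.1]),
    "C": np.array([8.0, 9.5]),
}


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        groups = {"A": np.ones(4), "B": np.ones(3), "C": np.ones(5)}
        H, df, p = ng.kruskal_wallis(groups)
        assert H == 0.0 and p == 1.0 and df == 2

    def test_matches_hand_rank_formula(self):
        H, df, p = ng.kruskal_wallis(FIXTURE)
        assert H == pytest.approx(hand_kruskal(FIXTURE), abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(H, df), abs=1e-12)

    def test_with_ties_matches_hand_formula(self):
        groups = {"A": np.array([1.0, 2.0, 2.0]), "B": np.array([2.0, 3.0]),
                  "C": np.array([3.0, 4.0, 4.0])}
        H, _, _ = ng.kruskal_wallis(groups)
        assert H == pytest.approx(hand_kruskal(groups), abs=1e-10)

    def test_chi2_p_close_to_permutation_null(self):
        """On a moderately sized fixture the chi-square p is close to a
        20,000-rep permutation p (vectorized rank shuffles)."""
        rng = np.random.default_rng(14)
        groups = {k: rng.normal(0, 1, 12) for k in "ABC"}
        H_obs, df, p_chi2 = ng.kruskal_wallis(groups)
        pooled = np.concatenate(list(groups.values()))
        n = len(pooled)
        ranks = sps.rankdata(pooled)
        sizes = [12, 12, 12]
        reps = 20_000
        perms = np.array([rng.permutation(ranks) for _ in range(reps)])
        h = np.zeros(reps)
        offset = 0
        for size in sizes:
            h += perms[:, offset: offset + size].sum(axis=1) ** 2 / size
            offset += size
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        p_perm = np.mean(h >= H_obs - 1e-12)
        assert abs(p_perm - p_chi2) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ng.kruskal_wallis({"A": np.array([1.0]), "B": np.array([])})


class TestDunn:
    def test_matches_hand_formula(self):
        expected = hand_dunn(FIXTURE)
        got = {(c.group_a, c.group_b): (c.z, c.p_raw)
               for c in ng.dunn_posthoc(FIXTURE)}
        for pair, (z, p) in expected.items():
            assert got[pair][0] == pytest.approx(z, abs=1e-10)
            assert got[pair][1] == pytest.approx(p, abs=1e-10)

    def test_null_groups_produce_moderate_z(self):
        rng = np.random.default_rng(15)
        groups = {k: rng.normal(size=20) for k in "ABCDE"}
        zs = [abs(c.z) for c in ng.dunn_posthoc(groups)]
        assert len(zs) == 10
        assert max(zs) < 4.0

    def test_holm_matches_statsmodels(self):
        rng = np.random.default_rng(30)
        groups = {k: rng.normal(0.3 * i, 1, 9) for i, k in enumerate("ABCDE")}
        pairs = ng.dunn_posthoc(groups)
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests([c.p_raw for c in pairs],
                                          method="holm")
        for c, p in zip(pairs, expected):
            assert c.p_holm == pytest.approx(p, abs=1e-12)

    def test_holm_monotone_and_dominating(self):
        rng = np.random.default_rng(16)
        groups = {"A": rng.normal(0, 1, 10), "B": rng.normal(1, 1, 10),
                  "C": rng.normal(2, 1, 10)}
        pairs = ng.dunn_posthoc(groups)
        assert all(c.p_holm >= c.p_raw - 1e-15 for c in pairs)
        ordered = sorted(pairs, key=lambda c: c.p_raw)
        holm = [c.p_holm for c in ordered]
        assert all(a <= b + 1e-15 for a, b in zip(holm, holm[1:]))

    def test_empty_group_skipped_with_flag(self):
        pairs = ng.dunn_posthoc({"A": np.array([1.0, 2.0]),
                                 "B": np.array([2.0, 3.0]),
                                 "C": np.array([])})
        flagged = [c for c in pairs if not np.isfinite(c.p_raw)]
        assert len(flagged) == 1 and flagged[0].group_a == "C"


class TestBonferroni:
    @pytest.mark.parametrize("p_holm,m,expected", [
        (0.01, 4, 0.04), (0.5, 4, 1.0), (0.2, 1, 0.2),
    ])
    def test_cap_and_identity(self, p_holm, m, expected):
        res = ng.TestResult("s", 1.0, 1, 0.5, [
            ng.stats.PairwiseComparison("A", "B", 1.0, p_holm, p_holm=p_holm)
        ])
        ng.bonferroni_by_subpopulations([res], m=m)
        assert res.pairwise[0].p_final == pytest.approx(expected)

    def test_correction_chain_ordering(self):
        rng = np.random.default_rng(17)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("ABCD")}
        res = ng.TestResult("s", *ng.kruskal_wallis(groups),
                            pairwise=ng.dunn_posthoc(groups))
        ng.bonferroni_by_subpopulations([res], m=4)
        for c in res.pairwise:
            assert c.p_final >= c.p_holm - 1e-15 >= c.p_raw - 1e-15


class TestProportions:
    def test_arithmetic_and_partition(self):
        labels = {"d1": np.array(["CD38++"] * 50 + ["mature"] * 950)}
        meta = pd.DataFrame([{"donor_id": "d1", "age": 30.0, "group": "A"}])
        table = ng.subset_proportions(labels, meta)
        by = table.set_index("subset")["proportion"]
        assert by["CD38++"] == pytest.approx(0.05)
        assert table["proportion"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_flagged_na(self):
        labels = {"d1": np.array([]), "d2": np.array(["mature"])}
        meta = pd.DataFrame([
            {"donor_id": "d1", "age": 30.0, "group": "A"},
            {"donor_id": "d2", "age": 40.0, "group": "B"},
        ])
        table = ng.subset_proportions(labels, meta)
        d1 = table[table["donor_id"] == "d1"]
        assert d1["proportion"].isna().all()
        assert (d1["flag"] == "empty_denominator").all()

    def test_group_test_runs_on_table(self, cohort_config):
        table = ng.simulate_proportion_cohort(cohort_config, seed=19)
        res = subset_group_test(table, "cd8_naive_cd38")
        assert res.df == 4
        assert len(res.pairwise) == 10


class TestAgeTrend:
    def test_perfect_negative_correlation(self):
        ages = np.array([25.0, 35, 45, 55, 65])
        tr = ng.age_trend(10 - 0.1 * ages, ages)
        assert tr.r == pytest.approx(-1.0)

    def test_hand_fixture_covariance_ratio(self):
        x = np.array([1.0, 2, 3, 4, 10])
        y = np.array([2.0, 1, 4, 3, 9])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        tr = ng.age_trend(y, x)
        assert tr.r == pytest.approx(r_hand, abs=1e-12)

    def test_permutation_significance_of_planted_trend(self, cohort_config):
        """|r| of age-permuted data exceeds the planted-trend |r| in < 5%
        of 200 seeded permutations."""
        table = ng.simulate_proportion_cohort(cohort_config, seed=20)
        sub = table[table["subset"] == "cd4_naive_cd25"]
        y = sub["proportion"].to_numpy()
        x = sub["age"].to_numpy()
        r_obs = abs(ng.age_trend(y, x).r)
        rng = np.random.default_rng(21)
        exceed = sum(
            abs(ng.age_trend(y, rng.permutation(x)).r) >= r_obs
            for _ in range(200)
        )
        assert exceed / 200 < 0.05

    def test_band_contains_fit_line(self):
        rng = np.random.default_rng(22)
        x = rng.uniform(25, 85, 40)
        y = 5 - 0.03 * x + rng.normal(0, 0.3, 40)
        tr = ng.age_trend(y, x)
        lo, hi = tr.band(np.linspace(25, 85, 10))
        line = tr.intercept + tr.slope * np.linspace(25, 85, 10)
        assert np.all(lo < line) and np.all(line < hi)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ng.age_trend(np.ones(5), np.arange(5.0))


class TestMfiAndClipping:
    def test_median_odd_length(self):
        m = ng.EventMatrix(np.array([[1.0], [2.0], [100.0]]), ["Fas"],
                           scale="asinh", cofactor=3000.0)
        assert ng.mfi_median(m, "Fas") == 2.0

    def test_empty_population_nan(self):
        m = ng.EventMatrix(np.array([[1.0]]), ["Fas"], scale="asinh",
                           cofactor=3000.0)
        assert np.isnan(ng.mfi_median(m, "Fas", np.array([False])))

    def test_permutation_invariance(self, donor_20k_asinh):
        rng = np.random.default_rng(23)
        mask = rng.random(donor_20k_asinh.n_events) < 0.3
        a = ng.mfi_median(donor_20k_asinh, "Fas", mask)
        perm = rng.permutation(np.where(mask)[0])
        b = float(np.median(donor_20k_asinh.column("Fas")[perm]))
        assert a == b

    def test_clip_rules(self):
        rng = np.random.default_rng(24)
        v = rng.normal(1, 2, 10_000)
        clipped = ng.clip_for_plot(v)
        p99 = np.quantile(v, 0.99)
        assert clipped.min() >= 0.0
        assert clipped.max() == pytest.approx(p99)
        inside = (v >= 0) & (v <= p99)
        assert np.array_equal(clipped[inside], v[inside])
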