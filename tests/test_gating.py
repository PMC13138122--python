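"""Cluster-selection rules, density thresholds, the gating tree end to end."""

import numpy as np
import pandas as pd
import pytest

import naivegate as ng
from naivegate.gating import ThresholdFailure
from naivegate.graph import ClusterProfile

from conftest import coarse_truth, f1_score


def _profile(medians: dict) -> ClusterProfile:
    frame = pd.DataFrame(medians)
    frame.index.name = "cluster"
    return ClusterProfile(medians=frame, sizes=np.ones(len(frame), dtype=int))


class TestSelectClusters:
    def test_quantile_high_rule(self):
        profile = _profile({"CD3": [4.0, 0.2, 0.3]})
        rule = ng.MarkerRule("CD3", "high", "cluster_median_quantile", 0.5)
        assert ng.select_clusters(profile, [rule]) == [0]

    def test_naive_like_conjunction(self):
        profile = _profile({
            "CD45RA": [3.1, 0.5, 3.0, 0.4],
            "CCR7": [2.9, 0.6, 0.5, 2.8],
            "Fas": [0.4, 2.5, 2.6, 2.4],
        })
        rules = [
            ng.MarkerRule("CD45RA", "high", "fixed_threshold", 2.0),
            ng.MarkerRule("CCR7", "high", "fixed_threshold", 2.0),
            ng.MarkerRule("Fas", "low", "fixed_threshold", 1.5),
        ]
        assert ng.select_clusters(profile, rules) == [0]

    def test_conjunctive_exclude_group(self):
        profile = _profile({
            "CD25": [3.0, 1.8, 0.4],
            "CD127": [0.3, 2.4, 2.5],
        })
        treg = [ng.MarkerRule("CD25", "high", "fixed_threshold", 2.2),
                ng.MarkerRule("CD127", "low", "fixed_threshold", 1.2)]
        assert ng.select_clusters(profile, exclude_rules=[treg]) == [1, 2]

    def test_empty_selection_is_empty_list(self):
        profile = _profile({"CD3": [0.1, 0.2]})
        rule = ng.MarkerRule("CD3", "high", "fixed_threshold", 2.0)
        assert ng.select_clusters(profile, [rule]) == []


class TestGaussianIntersect:
    def test_symmetric_case_is_zero(self):
        assert ng.gaussian_intersect(1.0, -1.0, 0.5, 1.0, 1.0, 0.5) == pytest.approx(
            0.0, abs=1e-3
        )

    def test_matches_grid_scan_oracle(self):
        """Analytic intersect equals a dense grid-scan root between the
        means on randomized parameter sets."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            mu1 = rng.uniform(-2, 0)
            mu2 = rng.uniform(1.5, 4)
            s1, s2 = rng.uniform(0.2, 0.6, 2)
            a1, a2 = rng.uniform(0.5, 2.0, 2)
            analytic = ng.gaussian_intersect(a1, mu1, s1, a2, mu2, s2)

            def diff(x):
                return a1 * np.exp(-((x - mu1) ** 2) / (2 * s1**2)) - a2 * np.exp(
                    -((x - mu2) ** 2) / (2 * s2**2)
                )

            coarse = np.linspace(mu1, mu2, 4001)
            signs = np.sign(diff(coarse))
            flips = np.where(np.diff(signs) != 0)[0]
            assert flips.size
            lo, hi = coarse[flips[0]], coarse[flips[0] + 1]
            fine = np.arange(lo, hi, 1e-6)
            root = fine[np.argmin(np.abs(diff(fine)))]
            assert abs(analytic - root) <= 1e-5

    def test_no_interior_root_signals_failure(self):
        # one component dominates everywhere between the means
        with pytest.raises(ThresholdFailure):
            ng.gaussian_intersect(1e9, 0.0, 5.0, 1e-9, 0.5, 0.01)


class TestDensityThresholds:
    def test_two_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(9)
        values = np.concatenate(
            [rng.normal(0, 0.5, 25_000), rng.normal(3, 0.5, 25_000)]
        )
        fit, threshold = ng.fit_two_gaussian_intersect(values)
        assert threshold == pytest.approx(1.5, abs=0.1)
        (a1, m1, s1), (a2, m2, s2) = fit.components
        assert m1 < m2

    def test_mu_plus_sigma_recovery(self):
        rng = np.random.default_rng(10)
        fit, threshold = ng.fit_gaussian_mu_sigma(rng.normal(0, 1, 50_000))
        assert threshold == pytest.approx(1.0, abs=0.05)

    def test_mu_plus_sigma_location_equivariance(self):
        rng = np.random.default_rng(11)
        values = rng.normal(2, 0.5, 20_000)
        _, t0 = ng.fit_gaussian_mu_sigma(values)
        _, t1 = ng.fit_gaussian_mu_sigma(values + 1.5)
        assert t1 - t0 == pytest.approx(1.5, abs=0.02)

    def test_too_few_values_rejected(self):
        with pytest.raises(ThresholdFailure):
            ng.fit_two_gaussian_intersect(np.zeros(100))
        with pytest.raises(ThresholdFailure):
            ng.fit_gaussian_mu_sigma(np.zeros(100))

    def test_unimodal_input_signals_failure(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ThresholdFailure):
            ng.fit_two_gaussian_intersect(rng.normal(1.0, 0.3, 5_000))


class TestNaiveCd4Gate:
    @pytest.fixture(scope="class")
    def cd4_pool(self, donor_20k, donor_20k_asinh):
        coarse = coarse_truth(donor_20k.truth)
        mask = np.isin(coarse, ["cd4_naive", "cd4_mem", "treg"])
        return (
            donor_20k_asinh.select_events(np.where(mask)[0]),
            coarse[mask],
        )

    def test_precision_recall_on_synthetic_pool(self, cd4_pool):
        events, truth = cd4_pool
        mask, thresholds, _ = ng.gate_naive_cd4(events)
        naive_like = np.isin(truth, ["cd4_naive", "treg"])  # Tregs removed later
        p, r, f1 = f1_score(mask, naive_like)
        assert p >= 0.9 and r >= 0.8 and f1 >= 0.9

    def test_conjunction_of_thresholds(self, cd4_pool):
        events, _ = cd4_pool
        mask, thresholds, _ = ng.gate_naive_cd4(events)
        cd45ra = events.column("CD45RA")
        fas = events.column("Fas")
        assert not np.any(mask & (cd45ra <= thresholds["CD45RA"]))
        assert not np.any(mask & (fas >= thresholds["Fas"]))


class TestAssignSubsets:
    @staticmethod
    def _events(rows):
        return ng.EventMatrix(
            np.array(rows, dtype=float), ["CXCR3", "CD38", "CD25"],
            scale="asinh", cofactor=3000.0,
        )

    def test_precedence_cxcr3_first(self):
        events = self._events([[2.5, 2.5, 0.2]])
        labels = ng.assign_naive_subsets(events, ng.default_subset_thresholds())
        assert labels[0] == "CXCR3hi"

    def test_leftover_is_mature(self):
        events = self._events([[0.1, 0.1, 0.1]])
        labels = ng.assign_naive_subsets(events, ng.default_subset_thresholds())
        assert labels[0] == "mature"

    def test_partition_exact(self, donor_20k_asinh):
        sub = donor_20k_asinh.select_events(np.arange(5000))
        labels = ng.assign_naive_subsets(sub, ng.default_subset_thresholds())
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == 5000
        assert set(counts.index) <= {"CXCR3hi", "CD38++", "CD25lo", "mature"}

    def test_cd25_skipped_for_cd8(self):
        events = self._events([[0.1, 0.1, 2.5]])
        labels = ng.assign_naive_subsets(
            events, ng.default_subset_thresholds(), include_cd25=False
        )
        assert labels[0] == "mature"

    def test_missing_threshold_rejected(self):
        events = self._events([[0.1, 0.1, 0.1]])
        empty = ng.ThresholdSet()
        with pytest.raises(KeyError):
            ng.assign_naive_subsets(events, empty)


class TestCcr9Helper:
    def test_advisory_threshold_tracks_reference_low_tail(self):
        rng = np.random.default_rng(13)
        n = 4000
        ccr9 = np.concatenate([rng.normal(2.5, 0.3, n // 4),
                               rng.normal(0.3, 0.2, 3 * n // 4)])
        cd38 = np.concatenate([rng.normal(3.0, 0.3, n // 4),
                               rng.normal(0.5, 0.3, 3 * n // 4)])
        events = ng.EventMatrix(np.column_stack([ccr9, cd38]),
                                ["CCR9", "CD38"], scale="asinh", cofactor=3000.0)
        proposal = ng.gating.propose_cd38_threshold_from_ccr9(events, 1.5)
        assert 2.0 < proposal < 3.0


class TestGatingTree:
    def test_hierarchy_nesting_and_dead_removal(self, donor_20k, gating_20k):
        """Every step's selection nests inside its parent's (events removed
        at a step never reappear), and the debris/dead filter removes
        essentially all dead and debris events."""
        from naivegate.gating import default_gating_tree

        masks = gating_20k.masks
        for step in default_gating_tree():
            if step.parent is None or step.name not in masks:
                continue
            parent = masks[step.parent]
            assert np.all(parent[masks[step.name]]), step.name
        dead_or_debris = np.isin(donor_20k.truth, ["dead", "debris"])
        kept = masks["1_debris"]
        assert np.sum(kept & dead_or_debris) < 0.02 * dead_or_debris.sum()
        # whatever survives step 1 is all any later step ever sees
        for name, mask in masks.items():
            assert not np.any(mask & ~kept), name

    def test_treg_cluster_removed(self, donor_20k, gating_20k):
        treg = donor_20k.truth == "treg"
        pre = gating_20k.masks["4_2a_naive_cd4"]
        post = gating_20k.masks["4_2b_treg_removal"]
        assert np.sum(post & treg) < 0.1 * max(np.sum(pre & treg), 1)

    def test_memory_complement_consistent(self, gating_20k):
        """Memory CD8 = step-3 CD8 clusters not selected as naive, minus
        γδ/MAIT-like clusters: it must be disjoint from naive CD8 and live
        inside the CD8 parent."""
        mem = gating_20k.masks["memory_cd8"]
        naive = gating_20k.masks["4_1_naive_cd8"]
        parent = gating_20k.masks["3_cd8"]
        assert not np.any(mem & naive)
        assert np.all(parent[mem])

    def test_naive_recovery_f1(self, donor_20k, gating_20k):
        coarse = coarse_truth(donor_20k.truth)
        for mask, label in ((gating_20k.naive_cd8, "cd8_naive"),
                            (gating_20k.naive_cd4, "cd4_naive")):
            _, _, f1 = f1_score(mask, coarse == label)
            assert f1 >= 0.9, label

    def test_idempotent_on_own_selection(self, donor_20k_asinh, gating_20k):
        """Re-running the T cell selection step on its own output keeps
        every event: the selection is a fixed point."""
        from naivegate.gating import default_gating_tree

        step = next(s for s in default_gating_tree() if s.name == "2_tcells")
        step.parent = None
        sub = donor_20k_asinh.select_events(
            np.where(gating_20k.masks["2_tcells"])[0]
        )
        rerun = ng.run_gating_tree(sub, [step], seed=7)
        kept = rerun.masks["2_tcells"].mean()
        assert kept >= 0.99

    def test_thresholds_are_per_sample(self, cohort_config):
        """Another donor processed before/after does not change this donor's
        thresholds (threshold construction is per sample)."""
        d1 = ng.simulate_donor(("P1", 30.0, "A"), cohort_config, 6000, seed=21)
        d2 = ng.simulate_donor(("P2", 70.0, "E"), cohort_config, 6000, seed=22)
        out = {}
        for order in ((d1, d2), (d2, d1)):
            for d in order:
                asinh = ng.asinh_transform(d.events, cohort_config.cofactor)
                res = ng.run_gating_tree(asinh, seed=5)
                tset = res.thresholds.get("4_2a_naive_cd4")
                out.setdefault(d.donor_id, []).append(
                    tuple(sorted(tset.thresholds.items())) if tset else None
                )
        for donor_id, runs in out.items():
            assert runs[0] == runs[1], donor_id

    def test_empty_parent_flags_and_skips(self, donor_20k_asinh):
        tree = [
            ng.GatingStep("never", None, ["CD3"],
                          include_rules=[ng.MarkerRule("CD3", "high",
                                                       "fixed_threshold", 99.0)],
                          k=10),
            ng.GatingStep("child", "never", ["CD4"], k=10),
        ]
        sub = donor_20k_asinh.select_events(np.arange(2000))
        res = ng.run_gating_tree(sub, tree, seed=1)
        assert "child" not in res.masks
        assert any("never" in f for f in res.flags)
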