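import itertools
import math

import numpy as np
import pandas as pd
import pytest

from elevassembly import (
    OtuTable,
    ValidationError,
    bootstrap_pd_null,
    clade_divergence_test,
    cohens_d,
    indval,
    normalize,
    patristic_matrix,
    preferred_elevation,
    read_tree,
    root_to_tip,
    shared_otu_abundance_test,
)

from conftest import brute_force_patristic, random_tree


def norm_table(rows, index, columns=None):
    t = OtuTable(pd.DataFrame(rows, index=index, columns=columns))
    return normalize(t, "tss")


class TestIndval:
    def test_perfect_indicator_scores_one(self):
        t = norm_table(
            [[5, 1], [7, 1], [0, 1], [0, 1]], index=list("abcd")
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        res = indval(t, groups, n_perm=99, seed=0)
        row = res.loc[res.index[0]]
        assert row["A"] == 1.0 and row["B"] == 1.0
        assert row["indval"] == 1.0

    def test_even_spread_gives_root_half(self):
        # equal mean abundance in both groups, present everywhere:
        # A = 0.5, B = 1, IndVal = sqrt(0.5)
        t = OtuTable(
            pd.DataFrame([[4.0], [4.0], [4.0], [4.0]], index=list("abcd"),
                         columns=["O1"]),
            normalized=True, norm_method="tss",
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        res = indval(t, groups, n_perm=9, seed=0)
        assert res.loc["O1", "indval"] == pytest.approx(math.sqrt(0.5))

    def test_raw_table_is_refused_unless_opted_in(self):
        t = OtuTable(pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"]))
        groups = pd.Series(["g1", "g2"], index=["a", "b"])
        with pytest.raises(ValidationError, match="normalize"):
            indval(t, groups)
        indval(t, groups, n_perm=9, seed=0, allow_raw=True)

    def test_specificity_is_sensitive_to_per_sample_scaling(self):
        # doubling one sample's counts shifts A: this is why the entry
        # point demands normalized input
        base = pd.DataFrame([[10, 0], [10, 10], [0, 10], [5, 10]],
                            index=list("abcd"), columns=["O1", "O2"])
        scaled = base.copy()
        scaled.loc["a"] *= 10
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        r1 = indval(OtuTable(base), groups, n_perm=9, seed=0, allow_raw=True)
        r2 = indval(OtuTable(scaled), groups, n_perm=9, seed=0, allow_raw=True)
        assert r1.loc["O1", "A"] != pytest.approx(r2.loc["O1", "A"])

    def test_permutation_p_matches_exhaustive_assignment_enumeration(self):
        counts = pd.DataFrame(
            [[8, 1], [6, 2], [7, 1], [1, 5], [0, 6], [2, 4]],
            index=[f"s{i}" for i in range(6)], columns=["O1", "O2"],
        )
        t = normalize(OtuTable(counts), "tss")
        labels = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
        groups = pd.Series(labels, index=t.sample_ids)
        x = t.values

        def max_indval(lab):
            out = []
            for g in ("g1", "g2"):
                mean = x[lab == g].mean(axis=0)
                pres = (x[lab == g] > 0).mean(axis=0)
                out.append(mean)
            tot = out[0] + out[1]
            ivs = []
            for g_i, g in enumerate(("g1", "g2")):
                A = np.where(tot > 0, out[g_i] / tot, 0)
                B = (x[lab == g] > 0).mean(axis=0)
                ivs.append(np.sqrt(A * B))
            return np.maximum(ivs[0], ivs[1])

        obs = max_indval(labels)
        # enumerate all C(6,3) = 20 balanced label assignments
        exact_exceed = np.zeros(2)
        n_assign = 0
        for pick in itertools.combinations(range(6), 3):
            lab = np.array(["g2"] * 6)
            lab[list(pick)] = "g1"
            exact_exceed += max_indval(lab) >= obs - 1e-12
            n_assign += 1
        exact_p = exact_exceed / n_assign
        n_perm = 4999
        res = indval(t, groups, n_perm=n_perm, seed=1)
        for i, otu in enumerate(["O1", "O2"]):
            se = math.sqrt(exact_p[i] * (1 - exact_p[i]) / n_perm)
            assert abs(res.loc[otu, "p"] - exact_p[i]) < 4 * se + 2 / n_perm

    def test_empty_group_errors(self):
        t = norm_table([[1, 2], [3, 4]], index=["a", "b"])
        with pytest.raises(ValidationError):
            indval(t, pd.Series(["g1", "g1"], index=["a", "b"]))


class TestPreferredElevation:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {"elevation": [400.0, 700.0, 1200.0]},
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )

    def test_single_detection_site(self, meta):
        t = OtuTable(
            pd.DataFrame([[0], [5], [0]], index=["s1", "s2", "s3"],
                         columns=["O1"])
        )
        pe = preferred_elevation(t, meta)
        assert pe.loc["O1", "preferred_elevation"] == 700.0

    def test_weighted_mean(self, meta):
        t = OtuTable(
            pd.DataFrame([[10], [0], [30]], index=["s1", "s2", "s3"],
                         columns=["O1"])
        )
        pe = preferred_elevation(t, meta)
        assert pe.loc["O1", "preferred_elevation"] == pytest.approx(1000.0)

    def test_scale_invariance(self, meta):
        counts = pd.DataFrame([[10, 3], [4, 0], [30, 9]],
                              index=["s1", "s2", "s3"])
        a = preferred_elevation(OtuTable(counts), meta)
        b = preferred_elevation(OtuTable(counts * 2), meta)
        pd.testing.assert_series_equal(
            a["preferred_elevation"], b["preferred_elevation"]
        )

    def test_bounds_property(self, meta):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 20, size=(3, 15))
        counts[0, 0] += 1
        t = OtuTable(pd.DataFrame(counts, index=["s1", "s2", "s3"]))
        pe = preferred_elevation(t, meta)
        elev = meta["elevation"]
        for otu in t.otu_ids:
            col = t.counts[otu]
            if col.sum() == 0:
                continue
            detected = elev[col > 0]
            val = pe.loc[otu, "preferred_elevation"]
            assert detected.min() - 1e-9 <= val <= detected.max() + 1e-9

    def test_absent_otu_is_missing_with_warning(self, meta):
        t = OtuTable(
            pd.DataFrame([[0, 1], [0, 1], [0, 1]], index=["s1", "s2", "s3"])
        )
        with pytest.warns(UserWarning):
            pe = preferred_elevation(t, meta)
        assert np.isnan(pe.iloc[0]["preferred_elevation"])


class TestPatristic:
    def test_cherry_distance(self):
        dm = patristic_matrix(read_tree("(A:1,B:2);"))
        assert dm[dm.index("A"), dm.index("B")] == 3.0

    def test_ultrametric_cross_root_pairs_equidistant(self):
        dm = patristic_matrix(read_tree("((A:1,B:1):1,(C:1,D:1):1);"))
        for a, b in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
            assert dm[dm.index(a), dm.index(b)] == 4.0

    def test_matches_brute_force_on_random_tree(self):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, 8)
        oracle = brute_force_patristic(tree)
        dm = patristic_matrix(tree)
        for (a, b), d in oracle.items():
            assert dm[dm.index(a), dm.index(b)] == pytest.approx(d)


class TestBootstrapPdNull:
    def test_self_comparison_is_unremarkable(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 12)
        ids = [t.name for t in tree.tips()]
        bn = bootstrap_pd_null(ids, ids, tree, n_boot=400, seed=0)
        pool_mean = patristic_matrix(tree).condensed_form().mean()
        assert bn.observed == pytest.approx(pool_mean)
        assert 0.4 <= bn.p_lower <= 0.6

    def test_closest_pair_is_detected_as_clustered(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            tree = random_tree(rng, 20)
            dm = patristic_matrix(tree)
            ids = list(dm.ids)
            tri = np.triu_indices(len(ids), k=1)
            best = np.argmin(dm.data[tri])
            pair = [ids[tri[0][best]], ids[tri[1][best]]]
            bn = bootstrap_pd_null(pair, ids, tree, n_boot=500, seed=s)
            hits += bn.observed < bn.ci_low
        assert hits == 5

    def test_deterministic_interval(self):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, 10)
        ids = [t.name for t in tree.tips()]
        a = bootstrap_pd_null(ids[:4], ids, tree, n_boot=200, seed=5)
        b = bootstrap_pd_null(ids[:4], ids, tree, n_boot=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_indicators_errors(self):
        tree = read_tree("(A:1,B:1);")
        with pytest.raises(ValidationError):
            bootstrap_pd_null(["A"], ["A", "B"], tree)


class TestCladeDivergence:
    def test_zero_length_cherry_has_zero_divergence(self):
        tree = read_tree("((A:0,B:0):1,(C:1,D:3):1);")
        labels = {"A": "high", "B": "high", "C": "low", "D": "low"}
        report, _ = clade_divergence_test(
            tree, labels, clades=[["A", "B"], ["C", "D"]], n_perm=19, seed=0
        )
        row = report[report["members"].str.contains("A")]
        assert row["mean_pairwise_distance"].iloc[0] == 0.0
        assert row["type"].iloc[0] == "high_only"

    def test_identical_divergences_give_p_one(self):
        tree = read_tree(
            "((A:1,B:1):1,((C:1,D:1):0.5,(E:1,F:1):0.5):0.5);"
        )
        labels = {x: "high" for x in "AB"}
        labels.update({x: "low" for x in "CDEF"})
        clades = [["A", "B"], ["C", "D"], ["E", "F"]]
        report, comp = clade_divergence_test(
            tree, labels, clades=clades, n_perm=99, seed=0
        )
        # every clade is a cherry with total tip depth 2 -> equal means
        assert comp["p"].iloc[0] == 1.0

    def test_mixed_clades_spanning_deep_splits_are_more_divergent(self):
        # six shallow pure cherries vs six deep mixed pairs: the
        # permutation t-test over clade labels should flag mixed > pure
        def join(parts):
            while len(parts) > 1:
                parts = [
                    f"({parts[i]}:1,{parts[i + 1]}:1)"
                    if i + 1 < len(parts)
                    else parts[i]
                    for i in range(0, len(parts), 2)
                ]
            return parts[0] + ";"

        detected = 0
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(500 + s)
            parts, clades, labels = [], [], {}
            for i in range(6):
                d = rng.uniform(0.05, 0.2)
                parts.append(f"(P{i}a:{d:.3f},P{i}b:{d:.3f})")
                clades.append([f"P{i}a", f"P{i}b"])
                labels[f"P{i}a"] = labels[f"P{i}b"] = (
                    "high" if i % 2 else "low"
                )
            for i in range(6):
                d = rng.uniform(4.0, 6.0)
                parts.append(f"(H{i}:{d:.3f},L{i}:{d:.3f})")
                clades.append([f"H{i}", f"L{i}"])
                labels[f"H{i}"] = "high"
                labels[f"L{i}"] = "low"
            tree = read_tree(join(parts))
            report, comp = clade_divergence_test(
                tree, labels, clades=clades, n_perm=499, seed=s
            )
            mixed = report[report["type"] == "mixed"]
            pure = report[report["type"] != "mixed"]
            assert (
                mixed["mean_pairwise_distance"].mean()
                > pure["mean_pairwise_distance"].mean()
            )
            sig = comp[
                (comp["type_a"] == "mixed") | (comp["type_b"] == "mixed")
            ]
            detected += (sig["p_corrected"] <= 0.05).any()
        assert detected >= int(0.9 * n_seeds)

    def test_overlapping_clades_error(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        labels = {x: "high" for x in "ABCD"}
        with pytest.raises(ValidationError):
            clade_divergence_test(
                tree, labels, clades=[["A", "B"], ["B", "C"]]
            )


class TestRootToTip:
    def test_hand_path_sums(self):
        tree = read_tree("(A:1,(B:1,C:3):1);")
        r2t = root_to_tip(tree)
        assert r2t.loc["A", "distance"] == 1.0
        assert r2t.loc["B", "distance"] == 2.0
        assert r2t.loc["C", "distance"] == 4.0

    def test_ultrametric_tree_gives_p_one(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        groups = pd.Series({"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        _, summary, p = root_to_tip(tree, groups=groups)
        assert p == 1.0
        assert summary["mean"].nunique() == 1

    def test_scaling_one_groups_branches_increases_its_mean(self):
        t1 = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_tree("((A:2,B:2):1,(C:1,D:1):1);")
        groups = pd.Series({"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        _, s1, _ = root_to_tip(t1, groups=groups)
        _, s2, _ = root_to_tip(t2, groups=groups)
        assert s2.loc["g1", "mean"] > s1.loc["g1", "mean"]
        assert s2.loc["g2", "mean"] == s1.loc["g2", "mean"]

    def test_unknown_tip_errors(self):
        tree = read_tree("(A:1,B:1);")
        with pytest.raises(ValidationError):
            root_to_tip(tree, tip_ids=["A", "X"])


class TestSharedOtus:
    def test_subset_table_shares_its_whole_richness(self):
        a = OtuTable(pd.DataFrame([[5, 3, 2, 1]], index=["s1"],
                                  columns=list("wxyz")))
        b = OtuTable(pd.DataFrame([[1, 2]], index=["t1"], columns=["w", "x"]))
        res = shared_otu_abundance_test(a, b, n_perm=99, seed=0)
        assert res["n_shared"] == 2

    def test_most_abundant_shared_otus_are_significant(self):
        rng = np.random.default_rng(0)
        n = 40
        abund = np.sort(rng.lognormal(0, 1.5, n))[::-1] * 100
        a = OtuTable(pd.DataFrame([abund.astype(int) + 1], index=["s1"]))
        cols = a.otu_ids
        b_counts = np.zeros(n, dtype=int)
        b_counts[:5] = 50  # shares exactly the five most abundant
        b = OtuTable(pd.DataFrame([b_counts], index=["t1"], columns=cols))
        res = shared_otu_abundance_test(a, b, n_perm=999, seed=1)
        assert res["p"] <= 0.01

    def test_disjoint_tables_share_nothing(self):
        a = OtuTable(pd.DataFrame([[1, 1, 0, 0]], index=["s1"]))
        b = OtuTable(pd.DataFrame([[0, 0, 2, 2]], index=["t1"],
                                  columns=a.otu_ids))
        res = shared_otu_abundance_test(a, b, n_perm=9, seed=0)
        assert res["n_shared"] == 0 and res["p"] is None


class TestCohensD:
    def test_identical_groups_give_zero(self):
        res = cohens_d([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["d"] == 0.0

    def test_sign_follows_mean_difference(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, 50)
        b = rng.normal(1, 0.01, 50)
        res = cohens_d(a, b)
        assert res["d"] < -10

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValidationError):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_tiny_groups_error(self):
        with pytest.raises(ValidationError):
            cohens_d([1.0], [2.0, 3.0])
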