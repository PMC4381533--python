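"""SAM statistics, signature derivation and clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

import sam_oracle
from mascsig import diffexpr, syndata
from mascsig.core import GeneSignature


def _two_groups(n1=3, n2=3):
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    groups = pd.Series(["grp1"] * n1 + ["grp2"] * n2, index=samples)
    return samples, groups


class TestFilterProbesets:
    def test_rule_application(self):
        samples = ["s1", "s2"]
        matrix = pd.DataFrame(
            [[1, 1], [2, 2], [5, 5], [3, 3], [4, 4]],
            index=["p_unmapped", "p_multi", "p_a_hi", "p_a_lo", "p_b"],
            columns=samples, dtype=float,
        )
        mapping = pd.DataFrame({
            "probeset": ["p_multi", "p_multi", "p_a_hi", "p_a_lo", "p_b"],
            "gene": ["A", "B", "A", "A", "B"],
        })
        out = diffexpr.filter_probesets(matrix, mapping)
        assert sorted(out.index) == ["A", "B"]
        assert out.loc["A", "s1"] == 5  # higher-mean probeset wins
        assert out.loc["B", "s1"] == 4

    def test_identity_when_uniquely_mapped(self, small_matrix):
        mapping = pd.DataFrame({
            "probeset": list(small_matrix.index),
            "gene": [f"G_{p}" for p in small_matrix.index],
        })
        out = diffexpr.filter_probesets(small_matrix, mapping)
        assert out.shape == small_matrix.shape
        assert set(out.index) == {f"G_{p}" for p in small_matrix.index}

    def test_matches_bruteforce_row_filter(self):
        rng = np.random.default_rng(0)
        n = 1000
        probes = [f"p{i}" for i in range(n)]
        matrix = pd.DataFrame(rng.normal(size=(n, 4)), index=probes,
                              columns=list("wxyz"))
        rows = []
        for i, p in enumerate(probes):
            u = rng.uniform()
            if u < 0.10:
                continue  # unmapped
            if u < 0.15:
                rows += [(p, f"gene{i}"), (p, f"gene{i}_alt")]  # multimapped
            else:
                rows.append((p, f"gene{i % 600}"))
        mapping = pd.DataFrame(rows, columns=["probeset", "gene"])
        out = diffexpr.filter_probesets(matrix, mapping)
        # brute force: probes with exactly one gene, best mean per gene
        per_probe = {}
        for p, g in rows:
            per_probe.setdefault(p, set()).add(g)
        ok = {p: next(iter(gs)) for p, gs in per_probe.items() if len(gs) == 1}
        expect = {}
        for p, g in ok.items():
            mu = matrix.loc[p].mean()
            if g not in expect or mu > expect[g][1]:
                expect[g] = (p, mu)
        assert len(out) == len(expect)
        for g, (p, _) in expect.items():
            assert np.allclose(out.loc[g], matrix.loc[p])

    def test_empty_result_is_an_error(self, small_matrix):
        mapping = pd.DataFrame({"probeset": ["nope"], "gene": ["A"]})
        with pytest.raises(ValueError, match="unmapped|survive"):
            diffexpr.filter_probesets(small_matrix, mapping)


class TestSamTwoClass:
    def test_zero_numerator_gives_zero_d(self):
        samples, groups = _two_groups()
        rng = np.random.default_rng(1)
        half = rng.normal(size=(10, 3))
        matrix = pd.DataFrame(np.hstack([half, half]), columns=samples,
                              index=[f"g{i}" for i in range(10)])
        res = diffexpr.sam_two_class(matrix, groups, n_perm=20, seed=0)
        assert np.allclose(res.table["d"], 0.0)

    def test_planted_gene_dominates_exhaustive_null(self):
        samples, groups = _two_groups()
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.5, size=(40, 6))
        values[0] = [0, 0.1, -0.1, 2.0, 2.1, 1.9]
        matrix = pd.DataFrame(values, columns=samples,
                              index=[f"g{i}" for i in range(40)])
        res = diffexpr.sam_two_class(matrix, groups, n_perm=20, seed=0)
        tab = res.table
        assert res.n_perm == 20  # exhaustive C(6,3)
        assert tab["d"].abs().idxmax() == "g0"
        assert tab.loc["g0", "q_global"] <= tab["q_global"].drop("g0").min()

    def test_q_matches_bruteforce_enumeration(self):
        """Permutation q and local FDR agree with an independent
        loop-based enumeration of all 20 relabellings."""
        samples, groups = _two_groups()
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=(25, 6))
        values[:3, 3:] += 3.0
        matrix = pd.DataFrame(values, columns=samples,
                              index=[f"g{i}" for i in range(25)])
        res = diffexpr.sam_two_class(matrix, groups, n_perm=20, seed=0)

        d_perm = sam_oracle.exhaustive_null(values, 3, res.s0)
        d_obs, _, _ = sam_oracle.d_statistic(
            values, [False] * 3 + [True] * 3, res.s0)
        assert np.allclose(d_obs, res.table["d"], atol=1e-12)
        pi0 = sam_oracle.pi0_estimate(d_obs, d_perm)
        q = sam_oracle.q_values(d_obs, d_perm, pi0)
        fdr = sam_oracle.local_fdr(d_obs, d_perm, pi0)
        assert np.allclose(q, res.table["q_global"], atol=1e-12)
        assert np.allclose(fdr, res.table["fdr_local"], atol=1e-12)

    def test_label_swap_negates_d_keeps_q(self, small_matrix):
        samples = small_matrix.columns
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=samples)
        flipped = pd.Series(["y"] * 6 + ["x"] * 6, index=samples)
        r1 = diffexpr.sam_two_class(small_matrix, groups, n_perm=500, seed=0)
        r2 = diffexpr.sam_two_class(small_matrix, flipped, n_perm=500, seed=0)
        assert np.allclose(r1.table["d"], -r2.table["d"])
        assert np.allclose(r1.table["q_global"], r2.table["q_global"])

    def test_row_shift_changes_only_own_fold(self, small_matrix):
        samples = small_matrix.columns
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=samples)
        shifted = small_matrix.copy()
        shifted.loc["g0", groups == "y"] += 1.5
        r1 = diffexpr.sam_two_class(small_matrix, groups, n_perm=100, seed=0,
                                    s0=0.1)
        r2 = diffexpr.sam_two_class(shifted, groups, n_perm=100, seed=0,
                                    s0=0.1)
        assert r2.table.loc["g0", "fold_change"] == pytest.approx(
            r1.table.loc["g0", "fold_change"] * 2**1.5)
        others = [g for g in small_matrix.index if g != "g0"]
        assert np.allclose(r1.table.loc[others, "d"],
                           r2.table.loc[others, "d"])
        assert np.allclose(r1.table.loc[others, "fold_change"],
                           r2.table.loc[others, "fold_change"])

    def test_rejects_small_groups(self, small_matrix):
        groups = pd.Series(["x"] + ["y"] * 11, index=small_matrix.columns)
        with pytest.raises(ValueError, match=">= 2"):
            diffexpr.sam_two_class(small_matrix, groups)


class TestSamMulticlass:
    def test_dominant_group_shift_ranks_first(self):
        samples = [f"s{i}" for i in range(8)]
        groups = pd.Series(["a", "a", "b", "b", "c", "c", "d", "d"],
                           index=samples)
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.3, size=(30, 8))
        values[0, 2:4] += 4.0
        matrix = pd.DataFrame(values, columns=samples,
                              index=[f"g{i}" for i in range(30)])
        res = diffexpr.sam_multiclass(matrix, groups, n_perm=200, seed=0)
        assert res.table["d"].idxmax() == "g0"
        assert res.table["fold_change"].idxmax() == "g0"

    def test_null_calibration(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(9)]
            groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                               index=samples)
            matrix = pd.DataFrame(rng.normal(size=(200, 9)), columns=samples,
                                  index=[f"g{i}" for i in range(200)])
            res = diffexpr.sam_multiclass(matrix, groups, n_perm=100,
                                          seed=seed)
            hits.append((res.table["q_global"] < 0.05).mean())
        assert np.mean(hits) <= 0.10

    def test_two_level_statistic_tracks_two_class(self, small_matrix):
        # with the fudge factor pinned, the k=2 multiclass d equals |d|
        # of the two-class statistic up to a constant factor of 1
        samples = small_matrix.columns
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=samples)
        two = diffexpr.sam_two_class(small_matrix, groups, n_perm=50,
                                     seed=0, s0=0.2)
        values = small_matrix.to_numpy()
        codes = np.array([0] * 6 + [1] * 6)
        r, s, _ = diffexpr._multiclass_stats(values, codes, 2)
        d_multi = r / (s + 0.2)
        assert np.allclose(d_multi, two.table["d"].abs(), atol=1e-10)

    def test_rejects_two_levels(self, small_matrix):
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=small_matrix.columns)
        with pytest.raises(ValueError, match="3"):
            diffexpr.sam_multiclass(small_matrix, groups)


def _derive_from_design(design):
    from mascsig.pipelines import RunConfig, pipeline_derive

    matrix, labels, truth = syndata.simulate_populations(design)
    cfg = RunConfig(n_perm=200, seed=design.seed)
    return pipeline_derive(matrix, labels, cfg), truth


class TestDeriveSignature:
    def test_recovers_planted_excludes_shared(self):
        design = syndata.PopulationDesign(seed=1)
        result, truth = _derive_from_design(design)
        sig = result["signature"]
        classes = truth.loc[list(sig.genes), "gene_class"]
        assert (classes == "masc_up").sum() >= 90
        assert (classes == "basal_shared").sum() == 0
        assert (classes == "luminal_up").sum() == 0

    def test_monotone_in_thresholds(self):
        design = syndata.PopulationDesign(n_genes=400, n_masc_up=40,
                                          n_basal_shared=40, n_luminal_up=40,
                                          seed=2)
        matrix, labels, truth = syndata.simulate_populations(design)
        comps = {}
        for other in ("MYO", "LumERneg", "LumERpos"):
            keep = labels.isin([other, "MaSC"])
            grp = labels[keep].map(
                lambda p, o=other: "0_other" if p == o else p)
            comps[other] = diffexpr.sam_two_class(
                matrix.loc[:, labels.index[keep]], grp, n_perm=150, seed=0)
        strict = diffexpr.derive_signature(comps, fdr_max=0.01, fc_min=2.0)
        loose = diffexpr.derive_signature(comps, fdr_max=0.05, fc_min=1.5)
        assert strict is None or set(strict.genes) <= set(loose.genes)

    def test_fold_gate_excludes_small_folds(self):
        # a gene below 1.5-fold in one arm never enters the signature
        samples, groups = _two_groups(4, 4)
        rng = np.random.default_rng(0)
        values = rng.normal(0, 0.05, size=(60, 8))
        values[0, 4:] += np.log2(1.4)  # strong but < 1.5-fold
        values[1, 4:] += np.log2(4.0)
        matrix = pd.DataFrame(values, columns=samples,
                              index=[f"g{i}" for i in range(60)])
        res = diffexpr.sam_two_class(matrix, groups, n_perm=70, seed=0)
        sig = diffexpr.derive_signature({"only": res})
        assert "g0" not in sig.genes
        assert "g1" in sig.genes


class TestRefineTopSignature:
    def test_reference_fold_table_fully_retained(self):
        """Every row of the packaged 69-gene reference table passes the
        2.5-fold / FDR<5% refinement rule."""
        folds = diffexpr.load_top_signature_folds()
        assert len(folds) == 69
        sig = GeneSignature(genes=list(folds.index))
        comps = {}
        for arm, fc_col, fdr_col in (
            ("vs_MYO", "fc_myo", "fdr_myo_pct"),
            ("vs_luminal_combined", "fc_lum", "fdr_lum_pct"),
        ):
            table = pd.DataFrame(
                {
                    "d": 1.0,
                    "s": 1.0,
                    "fold_change": folds[fc_col],
                    "q_global": 0.0,
                    "fdr_local": folds[fdr_col] / 100.0,
                    "direction": 1,
                },
                index=folds.index,
            )
            comps[arm] = diffexpr.SamResult(table=table, s0=0.0, n_perm=1,
                                            seed=0, groups=("a", "b"))
        top = diffexpr.refine_top_signature(sig, comps)
        assert list(top.genes) == list(folds.index)
        # spot value: the strongest fold in the table
        assert folds["fc_myo"].max() == pytest.approx(21.41)
        assert folds.loc["Tnc", "fc_lum"] == pytest.approx(2.65)

    def test_one_failing_arm_drops_gene(self):
        sig = GeneSignature(genes=["A", "B"])
        def mk(fc_a, fc_b):
            table = pd.DataFrame(
                {"d": 1.0, "s": 1.0, "fold_change": [fc_a, fc_b],
                 "q_global": 0.0, "fdr_local": 0.01, "direction": 1},
                index=["A", "B"])
            return diffexpr.SamResult(table=table, s0=0.0, n_perm=1, seed=0,
                                      groups=("a", "b"))
        comps = {"vs_MYO": mk(3.0, 21.41), "vs_lum": mk(2.4, 2.65)}
        top = diffexpr.refine_top_signature(sig, comps)
        assert top.genes == ["B"]  # A fails the luminal arm at 2.4


class TestHierarchicalCluster:
    def test_duplicated_blocks_split_first(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = a + rng.normal(0, 0.01, 50)
        for i in range(3):
            cols[f"b{i}"] = b + rng.normal(0, 0.01, 50)
        matrix = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
        linkage, leaves, coph = diffexpr.hierarchical_cluster(matrix)
        top_split = sch.fcluster(linkage, t=2, criterion="maxclust")
        grp = {s: c for s, c in zip(matrix.columns, top_split)}
        assert len({grp["a0"], grp["a1"], grp["a2"]}) == 1
        assert len({grp["b0"], grp["b1"], grp["b2"]}) == 1
        assert grp["a0"] != grp["b0"]

    def test_three_leaf_merge_order_matches_manual_trace(self):
        # hand-set correlations: r(x,y)=.9, r(x,z)=.1, r(y,z)=.2
        # -> first merge (x,y) at 1-.9=.1, then z joins at the average of
        #    1-.1=.9 and 1-.2=.8, i.e. 0.85
        import scipy.spatial.distance as ssd
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        e1, e2 = rng.normal(size=200), rng.normal(size=200)
        x = base
        y = 0.9 * base + np.sqrt(1 - 0.81) * e1
        matrix = pd.DataFrame({"x": x, "y": y, "z": e2})
        linkage, leaves, coph = diffexpr.hierarchical_cluster(matrix)
        corr = np.corrcoef(matrix.to_numpy().T)
        d = 1 - corr
        # manual average-linkage on the realised correlations
        first = min([(d[0, 1], "xy"), (d[0, 2], "xz"), (d[1, 2], "yz")])
        assert first[1] == "xy"
        assert linkage[0, 3] == 2  # first merge joins two leaves
        expected_second = (d[0, 2] + d[1, 2]) / 2
        assert linkage[1, 2] == pytest.approx(expected_second)
        assert coph.loc["x", "z"] == pytest.approx(expected_second)

    def test_population_replicates_form_clades(self, population_data):
        matrix, labels, _ = population_data
        linkage, leaves, _ = diffexpr.hierarchical_cluster(matrix)
        clusters = sch.fcluster(linkage, t=4, criterion="maxclust")
        assign = pd.Series(clusters, index=matrix.columns)
        # MaSC replicates land in one cluster at the planted effect sizes
        assert assign[labels == "MaSC"].nunique() == 1

    def test_constant_sample_is_an_error(self, small_matrix):
        bad = small_matrix.copy()
        bad["s0"] = 1.0
        with pytest.raises(ValueError, match="s0"):
            diffexpr.hierarchical_cluster(bad)
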