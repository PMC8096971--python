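"""Consensus peaksets, moderated differential test, ranking, and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fatebind.differential import (
    binding_pca,
    classify_specificity,
    consensus_peakset,
    differential_test,
    rank_by_change,
)
from fatebind.genomic_io import PeakSet
from fatebind.normalization import SignalMatrix


def make_peaks(rows, score=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "site_id"])
    if score is not None:
        df["score"] = score
    return PeakSet(df)


def null_matrix(seed, n_sites=2000, reps=3, dispersion=0.1):
    rng = np.random.default_rng(seed)
    base = 2.0 ** rng.normal(5.5, 0.5, n_sites)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(
        r, r / (r + base[:, None] * np.ones(2 * reps))
    ).astype(float)
    values = pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_sites)],
        columns=[f"c{j}" for j in range(2 * reps)],
    )
    samples = pd.DataFrame(
        {"condition": ["A"] * reps + ["B"] * reps, "timepoint": "t",
         "replicate": list(range(1, reps + 1)) * 2,
         "depth": counts.sum(axis=0), "frip": 0.5},
        index=values.columns,
    )
    return SignalMatrix(values=values, samples=samples)


class TestConsensus:
    def test_single_set_is_recentered_copy(self):
        ps = make_peaks([("chr1", 100, 700, "a"), ("chr2", 0, 400, "b")])
        out = consensus_peakset([ps], min_support=1, width=500)
        assert len(out) == 2
        assert (out.df["end"] - out.df["start"] == 500).all()
        assert out.df.iloc[0]["start"] == 400 - 250  # midpoint 400

    def test_disjoint_sets_with_min_support_two_is_empty(self):
        a = make_peaks([("chr1", 0, 100, "a")])
        b = make_peaks([("chr1", 500, 600, "b")])
        assert len(consensus_peakset([a, b], min_support=2, width=100)) == 0

    def test_min_support_exceeding_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus_peakset([make_peaks([("chr1", 0, 10, "a")])], min_support=2)

    def test_clusters_match_graph_component_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(0)
        sets = []
        for s in range(3):
            rows = []
            for i in range(100):
                start = int(rng.integers(0, 50_000))
                rows.append(("chr1", start, start + int(rng.integers(100, 400)), f"s{s}p{i}"))
            sets.append(make_peaks(rows))
        out = consensus_peakset(sets, min_support=1, width=200)
        # oracle: connected components of the >=1bp-overlap graph
        g = nx.Graph()
        allp = [(r.site_id, r.start, r.end, s) for s, ps in enumerate(sets)
                for r in ps.df.itertuples()]
        g.add_nodes_from(p[0] for p in allp)
        for i, (ni, si, ei, _) in enumerate(allp):
            for nj, sj, ej, _ in allp[i + 1:]:
                if si < ej and sj < ei:
                    g.add_edge(ni, nj)
        assert len(out) == nx.number_connected_components(g)

    def test_min_support_counts_distinct_sets(self):
        a = make_peaks([("chr1", 0, 100, "a1"), ("chr1", 50, 150, "a2")])
        b = make_peaks([("chr1", 1000, 1100, "b1")])
        out = consensus_peakset([a, b], min_support=2, width=100)
        assert len(out) == 0  # the two a-peaks overlap but come from one set


class TestDifferentialTest:
    def test_identical_groups_give_zero_lfc_common(self):
        values = pd.DataFrame(
            np.tile(np.array([10.0, 100.0, 7.0]), (4, 1)).T,
            index=["s1", "s2", "s3"], columns=["a1", "a2", "b1", "b2"],
        )
        samples = pd.DataFrame(
            {"condition": ["A", "A", "B", "B"], "timepoint": "t",
             "replicate": [1, 2, 1, 2], "depth": 1e6, "frip": 0.5},
            index=values.columns,
        )
        res = differential_test(SignalMatrix(values=values, samples=samples),
                                ["a1", "a2"], ["b1", "b2"])
        assert (res["log2fc"] == 0).all()
        assert (res["label"] == "common").all()

    def test_single_replicate_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="replicates"):
            differential_test(toy_matrix, ["a1"], ["b1", "b2"])

    def test_site_order_permutation_invariance(self):
        m = null_matrix(0, n_sites=200)
        res = differential_test(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        perm = np.random.default_rng(1).permutation(200)
        m2 = SignalMatrix(values=m.values.iloc[perm], samples=m.samples)
        res2 = differential_test(m2, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        merged = res.set_index("site_id").join(res2.set_index("site_id"), rsuffix="_p")
        assert np.allclose(merged["pvalue"], merged["pvalue_p"])
        assert np.allclose(merged["qvalue"], merged["qvalue_p"])

    def test_null_type_one_error_small(self):
        fracs = [
            (differential_test(null_matrix(seed), ["c0", "c1", "c2"],
                               ["c3", "c4", "c5"])["qvalue"] < 0.05).mean()
            for seed in range(3)
        ]
        assert np.mean(fracs) <= 0.05

    def test_null_pvalues_roughly_uniform(self):
        res = differential_test(null_matrix(11), ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_planted_shift_detected(self):
        m = null_matrix(7)
        vals = m.values.copy()
        vals.iloc[:200, :3] *= 8
        res = differential_test(SignalMatrix(values=vals, samples=m.samples),
                                ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert (res["label"].iloc[:200] == "A_specific").mean() >= 0.90

    def test_bh_qvalues_monotone_in_pvalues(self):
        res = differential_test(null_matrix(3), ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        ordered = res.sort_values("pvalue")
        assert (np.diff(ordered["qvalue"]) >= -1e-12).all()


class TestClassify:
    BASE = pd.DataFrame(
        {"site_id": ["a", "b", "c"],
         "log2fc": [3.0, 3.0, -1.0],
         "stat": [5.0, 5.0, -4.0],
         "pvalue": [1e-6, 0.5, 1e-6],
         "qvalue": [1e-6, 0.5, 1e-6]}
    )

    def test_threshold_rules(self):
        res = classify_specificity(self.BASE)
        assert list(res["label"]) == ["A_specific", "common", "B_specific"]

    def test_boundary_inclusive_on_lfc(self):
        res = classify_specificity(self.BASE.assign(log2fc=[1.0, -1.0, 0.99]))
        assert list(res["label"]) == ["A_specific", "common", "common"]

    def test_partition_exhaustive_exclusive(self):
        rng = np.random.default_rng(0)
        res = classify_specificity(pd.DataFrame({
            "site_id": [f"s{i}" for i in range(500)],
            "log2fc": rng.normal(0, 2, 500),
            "stat": rng.normal(0, 2, 500),
            "pvalue": rng.uniform(0, 1, 500),
            "qvalue": rng.uniform(0, 1, 500),
        }))
        assert set(res["label"]) <= {"A_specific", "B_specific", "common"}
        assert res["label"].notna().all()


class TestRankByChange:
    def test_examples(self):
        rng = np.random.default_rng(0)
        res = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(10)],
            "log2fc": np.arange(10, dtype=float),
            "pvalue": rng.uniform(size=10),
        })
        assert rank_by_change(res, "decreased", 0.2) == ["s0", "s1"]
        assert rank_by_change(res, "increased", 0.2) == ["s9", "s8"]
        assert len(rank_by_change(res, "decreased", 1.0)) == 10

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(1)
        res = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(97)],
            "log2fc": rng.choice([-1.0, 0.0, 1.0, 2.5], size=97),
            "pvalue": rng.choice([0.1, 0.5], size=97),
        })
        got = rank_by_change(res, "increased", 0.25)
        expected = sorted(
            res.itertuples(), key=lambda r: (-r.log2fc, r.pvalue, r.site_id)
        )[: int(np.ceil(0.25 * 97))]
        assert got == [r.site_id for r in expected]

    def test_bad_fraction_rejected(self):
        res = pd.DataFrame({"site_id": ["a"], "log2fc": [0.0], "pvalue": [1.0]})
        with pytest.raises(ValueError):
            rank_by_change(res, "decreased", 0.0)
        with pytest.raises(ValueError):
            rank_by_change(res, "sideways", 0.5)


class TestBindingPca:
    def test_rank_one_structure_on_pc1(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 100, 300)
        cols = {}
        for i in range(3):
            cols[f"hi{i}"] = base * 4
            cols[f"lo{i}"] = base
        values = pd.DataFrame(cols, index=[f"s{i}" for i in range(300)])
        samples = pd.DataFrame(
            {"condition": ["H", "L"] * 3, "timepoint": "t", "replicate": 1,
             "depth": 1e6, "frip": 0.5}, index=values.columns)
        res = binding_pca(SignalMatrix(values=values, samples=samples, norm="depth"))
        assert res.variance_fraction[0] > 0.99
        assert (np.diff(res.variance_fraction) <= 1e-12).all()
        assert res.variance_fraction.sum() <= 1 + 1e-9

    def test_sign_convention_first_sample_nonnegative(self, small_workspace):
        from fatebind.normalization import normalize_matrix

        res = binding_pca(normalize_matrix(small_workspace.binding, "depth"))
        assert (res.coordinates.iloc[0] >= -1e-9).all()

    def test_constant_matrix_rejected(self):
        values = pd.DataFrame(np.ones((10, 4)), columns=["a", "b", "c", "d"])
        samples = pd.DataFrame(
            {"condition": "x", "timepoint": "t", "replicate": 1,
             "depth": 1e6, "frip": 0.5}, index=values.columns)
        with pytest.raises(ValueError, match="constant|variance"):
            binding_pca(SignalMatrix(values=values, samples=samples, norm="depth"))

    def test_two_factor_structure(self, small_workspace):
        from fatebind.normalization import normalize_matrix
        from fatebind.synth import generate_two_factor_binding

        m = generate_two_factor_binding(small_workspace.cfg, n_sites=1000)
        res = binding_pca(normalize_matrix(m, "depth"))
        assert res.variance_fraction[0] > res.variance_fraction[1]
        tord = m.samples["timepoint"].map({"t0": 0, "t1": 1, "t2": 2})
        rho = stats.spearmanr(res.coordinates["PC1"], tord).statistic
        assert abs(rho) > 0.9
        pc2 = res.coordinates["PC2"]
        a = pc2[m.samples["condition"] == "A"]
        b = pc2[m.samples["condition"] == "B"]
        assert a.min() > b.max() or b.min() > a.max()
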