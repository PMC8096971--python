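"""Lineage/housekeeping deconvolution, kinetic classes, opposite-fate gains."""

import numpy as np
import pandas as pd
import pytest

from fatebind.genomic_io import PeakSet
from fatebind.taxonomy import (
    airway_low_subset,
    assemble_taxonomy,
    deconvolve_common,
    kinetic_classes,
    kinetic_profiles,
    opposite_fate_gain,
    ranking_agreement,
)


def acc_table(rows):
    return pd.DataFrame(
        rows, columns=["epithelial", "endothelial", "immune", "mesenchymal", "airway"],
        index=[f"s{i}" for i in range(len(rows))],
    )


class TestDeconvolve:
    def test_rule_examples(self):
        acc = acc_table([
            (16, 2, 2, 2, 16),   # lineage: log2(17/3) = 2.5 >= 1 vs all
            (8, 8, 8, 8, 8),     # equal everywhere -> housekeeping
            (16, 2, 16, 2, 16),  # equal to immune -> ALL-quantifier fails
        ])
        out = deconvolve_common(["s0", "s1", "s2"], acc)
        assert list(out) == ["lineage", "housekeeping", "housekeeping"]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        acc = acc_table(rng.integers(0, 200, size=(100, 5)))
        out = deconvolve_common(list(acc.index), acc)
        assert set(out.unique()) <= {"lineage", "housekeeping"}
        assert len(out) == 100 and out.index.is_unique

    def test_missing_lineage_column_rejected(self):
        acc = acc_table([(1, 1, 1, 1, 1)]).drop(columns="immune")
        with pytest.raises(ValueError, match="immune"):
            deconvolve_common(["s0"], acc)

    def test_missing_site_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_common(["nope"], acc_table([(1, 1, 1, 1, 1)]))


class TestAirwaySubset:
    def test_examples(self):
        acc = acc_table([(8, 0, 0, 0, 0), (8, 0, 0, 0, 8)])
        assert airway_low_subset(["s0", "s1"], acc) == ["s0"]

    def test_airway_column_required(self):
        acc = acc_table([(8, 0, 0, 0, 0)]).drop(columns="airway")
        with pytest.raises(ValueError, match="airway"):
            airway_low_subset(["s0"], acc)

    def test_planted_fraction_recovered(self, small_workspace):
        truth = small_workspace.truth.set_index("site_id")
        lineage = list(truth.index[truth["class"] == "lineage"])
        got = airway_low_subset(lineage, small_workspace.accessibility)
        planted = set(truth.index[truth["airway_low"]])
        assert abs(len(got) / len(lineage) - 0.3) <= 0.05
        agreement = np.mean([(s in planted) == (s in set(got)) for s in lineage])
        assert agreement >= 0.95


class TestKineticClasses:
    def ten_sites(self):
        return pd.DataFrame({
            "site_id": [f"s{i}" for i in range(10)],
            "log2fc": np.linspace(-2, 2, 10),
        })

    def test_window_sizes(self):
        kin = kinetic_classes(self.ten_sites(), fraction=0.2)
        counts = kin.value_counts()
        assert counts["acquired"] == 2 and counts["retained"] == 2
        assert counts["intermediate"] == 6
        # largest gain -> acquired, least -> retained
        assert kin["s9"] == "acquired" and kin["s0"] == "retained"

    def test_half_fraction_is_exhaustive_bipartition(self):
        kin = kinetic_classes(self.ten_sites(), fraction=0.5)
        assert "intermediate" not in set(kin)
        assert (kin == "acquired").sum() == 5

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            kinetic_classes(self.ten_sites(), fraction=0.6)

    def test_tie_break_deterministic(self):
        df = pd.DataFrame({"site_id": ["b", "a", "c", "d"], "log2fc": [1.0] * 4})
        kin = kinetic_classes(df, fraction=0.25)
        assert kin["a"] == "acquired" and kin["d"] == "retained"

    def test_disjoint_windows_cover_2k_sites(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"site_id": [f"s{i}" for i in range(37)],
                           "log2fc": rng.normal(size=37)})
        kin = kinetic_classes(df, fraction=0.2)
        k = int(np.ceil(0.2 * 37))
        assert ((kin == "acquired").sum(), (kin == "retained").sum()) == (k, k)

    def test_fold_change_and_presence_rankings_agree(self, small_workspace):
        """The mature-over-progenitor ranking and the low-progenitor-presence
        ranking coincide on cell-type-specific sites."""
        from fatebind.differential import differential_test
        from fatebind.normalization import SignalMatrix, normalize_matrix

        ws = small_workspace
        truth = ws.truth.set_index("site_id")
        ids = list(truth.index[truth["specificity"] == "A_specific"])
        m = normalize_matrix(ws.binding, "depth")
        res = differential_test(
            SignalMatrix(m.values.loc[ids], m.samples, norm=m.norm),
            m.sample_ids(condition="A", timepoint="t2"),
            m.sample_ids(timepoint="t0"),
        )
        prog = m.values.loc[ids, m.sample_ids(timepoint="t0")].mean(axis=1)
        # global rank agreement is diluted by within-class noise; the
        # decision-relevant half-split must coincide almost exactly
        assert ranking_agreement(res, prog) > 0.75
        by_lfc = kinetic_classes(res, fraction=0.5)
        pres = pd.DataFrame({"site_id": prog.index, "log2fc": -prog.to_numpy()})
        by_presence = kinetic_classes(pres, fraction=0.5)
        assert (by_lfc == by_presence.loc[by_lfc.index]).mean() >= 0.95

    def test_planted_kinetics_recovered(self, small_workspace):
        from fatebind.differential import differential_test
        from fatebind.normalization import SignalMatrix, normalize_matrix

        ws = small_workspace
        truth = ws.truth.set_index("site_id")
        m = normalize_matrix(ws.binding, "depth")
        for fate in ("A", "B"):
            ids = list(truth.index[truth["specificity"] == f"{fate}_specific"])
            res = differential_test(
                SignalMatrix(m.values.loc[ids], m.samples, norm=m.norm),
                m.sample_ids(condition=fate, timepoint="t2"),
                m.sample_ids(timepoint="t0"),
            )
            halves = kinetic_classes(res, fraction=0.5)
            assert (halves == truth.loc[halves.index, "kinetics"]).mean() >= 0.9
            top = kinetic_classes(res, fraction=0.2)
            assigned = top[top != "intermediate"]
            assert (assigned == truth.loc[assigned.index, "kinetics"]).mean() >= 0.9


class TestKineticProfiles:
    def test_requires_two_timepoints(self, toy_matrix):
        classes = pd.Series("acquired", index=toy_matrix.values.index)
        with pytest.raises(ValueError):
            kinetic_profiles(toy_matrix, classes, ["t"])

    def test_constant_signal_zero_lfc(self):
        values = pd.DataFrame(5.0, index=["s1", "s2"], columns=["p1", "m1"])
        samples = pd.DataFrame(
            {"condition": ["progenitor", "A"], "timepoint": ["t0", "t1"],
             "replicate": 1, "depth": 1e6, "frip": 0.5}, index=values.columns)
        from fatebind.normalization import SignalMatrix

        m = SignalMatrix(values=values, samples=samples, norm="depth")
        classes = pd.Series("acquired", index=values.index)
        prof = kinetic_profiles(m, classes, ["t0", "t1"])
        assert (prof["log2fc_vs_t0"] == 0).all()

    def test_planted_kinetics_shapes(self, small_workspace):
        from fatebind.normalization import normalize_matrix

        ws = small_workspace
        truth = ws.truth.set_index("site_id")
        m = normalize_matrix(ws.binding, "depth")
        kin = truth.loc[truth["specificity"] == "A_specific", "kinetics"]
        target = kinetic_profiles(m, kin, ["t0", "t1", "t2"], condition="A")
        alt = kinetic_profiles(m, kin, ["t0", "t1", "t2"], condition="B")

        def series(prof, cls):
            return prof[prof["kinetics"] == cls].sort_values("timepoint")["mean_signal"].to_numpy()

        acq_t = series(target, "acquired")
        assert (np.diff(acq_t) > 0).all()  # strictly increasing in target fate
        ret_t = series(target, "retained")
        assert abs(np.log2(ret_t[-1] / ret_t[0])) < 0.5  # flat in target fate
        ret_a = series(alt, "retained")
        assert (np.diff(ret_a) < 0).all()  # decreasing in alternative fate


class TestOppositeFateGain:
    def peaks(self, rows):
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "site_id"]))

    def test_label_priority(self):
        gains = self.peaks([("chr1", 100, 200, "g1"), ("chr1", 1000, 1100, "g2"),
                            ("chr1", 5000, 5100, "g3")])
        own = self.peaks([("chr1", 1050, 1200, "own1")])
        opp = self.peaks([("chr1", 150, 260, "opp1")])
        labels, fractions = opposite_fate_gain(gains, own, opp)
        assert labels["g1"] == "opposite_bound"
        assert labels["g2"] == "same_bound"
        assert labels["g3"] == "unbound"
        assert fractions["opposite_bound"] == pytest.approx(1 / 3)

    def test_planted_fraction_within_binomial_ci(self):
        from fatebind.synth import GeneratorConfig, generate_opposite_fate_gains, plan_sites

        cfg = GeneratorConfig(seed=9, perturbation="tf_loss")
        truth = plan_sites(cfg)
        gains, gain_truth = generate_opposite_fate_gains(cfg, truth)
        tr = truth.set_index("site_id")
        def subset(spec):
            sub = tr.loc[tr.specificity == spec, ["chrom", "start", "end"]]
            return PeakSet(sub.reset_index().rename(columns={"index": "site_id"}))

        own, opp = subset("A_specific"), subset("B_specific")
        labels, fractions = opposite_fate_gain(gains, own, opp)
        n = len(gains)
        ci = 1.96 * np.sqrt(0.12 * 0.88 / n)
        assert abs(fractions["opposite_bound"] - 0.12) <= ci + 1e-9
        got = labels.reset_index(drop=True)
        assert (got == gain_truth["gain_class"]).all()


class TestAssemble:
    def test_subclass_only_on_common(self):
        spec = pd.Series({"s1": "common", "s2": "A_specific"})
        sub = pd.Series({"s2": "lineage"})
        with pytest.raises(ValueError):
            assemble_taxonomy(spec, sub)

    def test_neutral_fills(self):
        spec = pd.Series({"s1": "common", "s2": "A_specific"})
        tax = assemble_taxonomy(spec, pd.Series({"s1": "lineage"}))
        assert tax.loc["s2", "common_subclass"] == "none"
        assert tax.loc["s1", "kinetics"] == "not_applicable"
        assert tax.loc["s2", "locale"] == "unannotated"
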