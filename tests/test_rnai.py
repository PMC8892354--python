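import numpy as np
import pandas as pd
import pytest
from scipy import stats

import odomorph as om

# region counts printed for the NES and AES Venn diagrams
NES_COUNTS = {
    frozenset({"Kr-h1"}): 9,
    frozenset({"broad"}): 11,
    frozenset({"E93"}): 47,
    frozenset({"Kr-h1", "broad"}): 27,
    frozenset({"Kr-h1", "E93"}): 30,
    frozenset({"broad", "E93"}): 6,
    frozenset({"Kr-h1", "broad", "E93"}): 24,
    frozenset(): 12,
}
AES_COUNTS = {
    frozenset({"Kr-h1"}): 129,
    frozenset({"broad"}): 3,
    frozenset({"E93"}): 153,
    frozenset({"Kr-h1", "broad"}): 100,
    frozenset({"Kr-h1", "E93"}): 57,
    frozenset({"broad", "E93"}): 7,
    frozenset({"Kr-h1", "broad", "E93"}): 128,
    frozenset(): 33,
}


class TestPairSamples:
    def test_default_design_pairs(self, design):
        pairs = om.pair_samples(design)
        assert dict(pairs["target"].value_counts()) == {"Kr-h1": 3, "broad": 4, "E93": 3}
        assert len(pairs) == 10
        # both members of a pair come from the same individual
        merged = pairs.merge(design, left_on="rnai_sample", right_on="sample_id")
        assert (merged["individual_x"] == merged["individual_y"]).all()

    def test_unpaired_sample_excluded_with_warning(self, design):
        broken = design[design["sample_id"] != "control_Kr-h1_1"]
        with pytest.warns(UserWarning, match="unpaired"):
            pairs = om.pair_samples(broken)
        assert (pairs["target"] == "Kr-h1").sum() == 2

    def test_duplicate_rnai_sample_rejected(self, design):
        dup = design[design["sample_id"] == "rnai_E93_1"].assign(sample_id="rnai_E93_1b")
        with pytest.raises(ValueError, match="duplicate"):
            om.pair_samples(pd.concat([design, dup]))

    def test_empty_design(self, design):
        assert om.pair_samples(design[design["block"] == "development"]).empty


def _pairs_tpm(ratios_by_target, control=10.0):
    """TPM frame + pairs with given per-pair rnai/control ratios for one feature."""
    rows, data = [], {}
    for target, ratios in ratios_by_target.items():
        for i, ratio in enumerate(ratios):
            r_id, c_id = f"r_{target}_{i}", f"c_{target}_{i}"
            rows.append({"individual": f"{target}{i}", "target": target,
                         "rnai_sample": r_id, "control_sample": c_id})
            data[r_id] = [control * ratio]
            data[c_id] = [control]
    tpm = pd.DataFrame(data, index=["f"])
    return tpm, pd.DataFrame(rows)


class TestClassifyEffect:
    def test_unanimous_up(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (2.0, 1.8, 1.6)})
        eff = om.classify_effect(tpm, pairs)
        row = eff.iloc[0]
        assert row["direction"] == "up" and row["unanimous"]
        assert row["mean_ratio"] == pytest.approx(1.8)

    def test_non_unanimous_is_none(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (2.0, 0.5, 2.0)})
        assert om.classify_effect(tpm, pairs).iloc[0]["direction"] == "none"

    def test_below_fold_threshold_is_none(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (1.2, 1.3, 1.4)})
        assert om.classify_effect(tpm, pairs).iloc[0]["direction"] == "none"

    def test_down_uses_two_thirds(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (0.6, 0.65, 0.7)})
        eff = om.classify_effect(tpm, pairs)  # mean 0.65 < 2/3, all below 1
        assert eff.iloc[0]["direction"] == "down"
        tpm2, pairs2 = _pairs_tpm({"Kr-h1": (0.68, 0.69, 0.7)})
        assert om.classify_effect(tpm2, pairs2).iloc[0]["direction"] == "none"

    def test_pair_rescaling_invariance(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (2.0, 1.8, 1.6)})
        scaled = tpm.copy()
        for i in range(3):  # rescale both members of each pair equally
            scaled[[f"r_Kr-h1_{i}", f"c_Kr-h1_{i}"]] *= 3.7
        a = om.classify_effect(tpm, pairs)
        b = om.classify_effect(scaled, pairs)
        assert a.iloc[0]["direction"] == b.iloc[0]["direction"]
        assert a.iloc[0]["mean_ratio"] == pytest.approx(b.iloc[0]["mean_ratio"])

    def test_zero_control_flags_infinite_up(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (1.0, 1.0)}, control=0.0)
        tpm[["r_Kr-h1_0", "r_Kr-h1_1"]] = 5.0
        eff = om.classify_effect(tpm, pairs)
        assert np.isinf(eff.iloc[0]["mean_ratio"])
        assert eff.iloc[0]["direction"] == "up"

    def test_requires_two_pairs(self):
        tpm, pairs = _pairs_tpm({"Kr-h1": (2.0,)})
        with pytest.raises(ValueError, match="pairs"):
            om.classify_effect(tpm, pairs)


class TestTTests:
    def test_paired_symmetric_differences(self):
        t, p = om.paired_t([1.0, -1.0], [0.0, 0.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_paired_hand_example(self):
        # differences (1,2,3): mean 2, sd 1, t = 2*sqrt(3), df 2
        t, p = om.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2))
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_paired_scale_invariance(self):
        a, b = np.array([3.0, 5.0, 4.0]), np.array([1.0, 2.0, 1.5])
        assert om.paired_t(a, b)[1] == pytest.approx(om.paired_t(7 * a, 7 * b)[1])

    def test_paired_degenerate(self):
        assert om.paired_t([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)
        t, p = om.paired_t([2.0, 3.0], [1.0, 2.0])  # constant nonzero diff
        assert p == 0.0 and np.isinf(t)

    def test_student_identical_groups(self):
        assert om.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[1] == pytest.approx(1.0)

    def test_student_hand_example(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        t, p = om.student_t(a, b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        expect_t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expect_t)
        assert p == pytest.approx(2 * stats.t.sf(abs(expect_t), df=4))

    def test_student_separated_groups(self):
        _, p = om.student_t([0.0, 0.001, -0.001], [1.0, 1.001, 0.999])
        assert p < 0.01

    def test_paired_t_statistic_equals_student_on_differences(self):
        # same t statistic (dfs differ) when the second group is all zeros
        d = np.array([0.3, 1.2, 0.9, 1.4])
        t_paired, _ = om.paired_t(d, np.zeros(4))
        t_student, _ = om.student_t(d, np.zeros(4) + 1e-15)
        assert t_paired == pytest.approx(t_student, rel=1e-6)


class TestVenn:
    def _effects(self, directions):
        return pd.DataFrame(
            [{"feature_id": f, "target": t, "mean_ratio": 1.0, "unanimous": True,
              "direction": d, "paired_t_p": 0.5}
             for f, by_target in directions.items() for t, d in by_target.items()]
        )

    def test_triple_region_assignment(self):
        eff = self._effects(
            {"nes013": {"Kr-h1": "down", "broad": "down", "E93": "up"},
             "idle": {"Kr-h1": "none", "broad": "none", "E93": "none"}}
        )
        part = om.venn_partition(
            eff, expected_direction={"Kr-h1": "down", "broad": "down", "E93": "up"}
        )
        assert part.loc["nes013", "subset"] == frozenset({"Kr-h1", "broad", "E93"})
        assert part.loc["idle", "subset"] == frozenset()
        assert part["consistent"].all()

    def test_missing_target_rejected(self):
        eff = self._effects({"f": {"Kr-h1": "up", "broad": "none"}})
        with pytest.raises(ValueError, match="E93"):
            om.venn_partition(eff)

    def test_summary_reproduces_printed_totals(self):
        nes = om.venn_summary(NES_COUNTS)
        assert nes["broad_involved"] == 68  # 24 + 27 + 6 + 11
        assert nes["non_broad_affected"] == 86  # 9 + 47 + 30
        assert nes["total"] == 166
        aes = om.venn_summary(AES_COUNTS)
        assert aes["broad_involved"] == 238  # 128 + 100 + 7 + 3
        assert aes["non_broad_affected"] == 339  # 129 + 153 + 57
        assert aes["total"] == 610

    def test_summary_partition_completeness(self):
        for counts in (NES_COUNTS, AES_COUNTS):
            s = om.venn_summary(counts)
            assert sum(s["region_counts"].values()) == s["total"]
            assert s["broad_involved"] + s["non_broad_affected"] + s["unaffected"] == s["total"]

    def test_all_unaffected_pct_zero(self):
        eff = self._effects({"f": {"Kr-h1": "none", "broad": "none", "E93": "none"}})
        s = om.venn_summary(om.venn_partition(eff))
        assert s["affected_pct"] == 0.0
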