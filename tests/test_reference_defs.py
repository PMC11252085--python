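import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quartetqc import (
    OmicsTypeConfig,
    ValidationError,
    build_def_reference,
    call_defs,
    evaluate_defs,
    intrabatch_qc_filter,
)
from quartetqc.core_data import ReferenceDEFSet
from conftest import make_dataset

CFG = OmicsTypeConfig()  # p<0.05, |lfc|>=0.5, presence 0.7, cv 0.3


def welch_oracle(x, y):
    """Direct-formula Welch t-test (statistic, Satterthwaite df, two-sided p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def dataset_for_groups(group1, group2, donors=("D5", "F7")):
    values = np.array([list(group1) + list(group2)])
    labels = [donors[0]] * len(group1) + [donors[1]] * len(group2)
    return make_dataset(values, labels)


class TestIntrabatchQCFilter:
    def _ds(self, rows, donors):
        return make_dataset(rows, donors)

    def test_cv_rule_on_linear_scale(self):
        # construct linear replicate triples with CV just above/below 0.3
        def log_triple(cv):
            lin = np.array([1.0 - cv, 1.0, 1.0 + cv]) * 100  # sample sd = cv*100
            return np.log2(lin)
        donors = ["D5"] * 3 + ["F7"] * 3
        rows = np.array([
            list(log_triple(0.31)) + list(np.log2([100, 100, 100])),
            list(log_triple(0.29)) + list(np.log2([100, 100, 100])),
        ])
        out = intrabatch_qc_filter(self._ds(rows, donors), CFG)
        assert out.feature_ids == ["f1"]

    def test_methylation_cutoff_is_stricter(self):
        def log_triple(cv):
            return np.log2(np.array([1.0 - cv, 1.0, 1.0 + cv]) * 100)
        donors = ["D5"] * 3 + ["F7"] * 3
        rows = np.array([list(log_triple(0.16)) + list(np.log2([100] * 3))])
        meth_cfg = OmicsTypeConfig(cv_cutoff=0.15, def_lfc_cutoff=2.0)
        out = intrabatch_qc_filter(self._ds(rows, donors), meth_cfg)
        assert out.n_features == 0

    def test_missing_in_more_than_one_replicate_drops_feature(self):
        donors = ["D5"] * 3 + ["F7"] * 3
        rows = np.array([
            [np.nan, np.nan, 1.0, 1.0, 1.0, 1.0],   # 2 of 3 missing in D5
            [np.nan, 1.0, 1.0, 1.0, 1.0, 1.0],      # only 1 missing: kept
        ])
        out = intrabatch_qc_filter(self._ds(rows, donors), CFG)
        assert out.feature_ids == ["f1"]

    def test_multiple_batches_rejected(self):
        ds = make_dataset(np.ones((1, 4)), ["D5", "D5", "D5", "D5"],
                          replicates=[1, 2, 1, 2], batches=["B1", "B1", "B2", "B2"])
        with pytest.raises(ValidationError, match="single batch"):
            intrabatch_qc_filter(ds, CFG)

    def test_single_replicate_group_rejected(self):
        ds = make_dataset(np.ones((1, 3)), ["D5", "D5", "F7"])
        with pytest.raises(ValidationError, match="fewer than 2"):
            intrabatch_qc_filter(ds, CFG)


class TestCallDefs:
    def test_hand_case_down_regulated(self):
        ds = dataset_for_groups([0.9, 1.0, 1.1], [1.9, 2.0, 2.1])
        calls = call_defs(ds, ("D5", "F7"), CFG)
        row = calls.iloc[0]
        assert row["lfc"] == pytest.approx(-1.0)
        assert row["p_value"] < 0.01
        assert row["direction"] == "down"

    def test_small_fold_change_is_not_a_def(self):
        ds = dataset_for_groups([1.00, 1.01, 0.99], [1.30, 1.31, 1.29])
        calls = call_defs(ds, ("D5", "F7"), CFG)
        assert calls.iloc[0]["p_value"] < 0.05
        assert calls.iloc[0]["direction"] == "none"  # |lfc| 0.3 < 0.5

    def test_constant_identical_groups_flagged_degenerate(self):
        ds = dataset_for_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        calls = call_defs(ds, ("D5", "F7"), CFG)
        assert bool(calls.iloc[0]["degenerate"])
        assert calls.iloc[0]["direction"] == "none"

    def test_pvalues_match_direct_formula_oracle(self):
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(100):
            n1, n2 = rng.integers(3, 8), rng.integers(3, 8)
            x = rng.normal(0, 1 + rng.random(), n1)
            y = rng.normal(rng.normal(), 1 + rng.random(), n2)
            ds = dataset_for_groups(x, y)
            p_pkg = call_defs(ds, ("D5", "F7"), CFG).iloc[0]["p_value"]
            _, _, p_ref = welch_oracle(x, y)
            worst = max(worst, abs(p_pkg - p_ref))
        assert worst < 1e-10

    def test_too_few_replicates_rejected(self):
        ds = dataset_for_groups([1.0], [2.0, 3.0])
        with pytest.raises(ValidationError, match="replicates"):
            call_defs(ds, ("D5", "F7"), CFG)


def calls_frame(features):
    """Build a per-batch call table from {feature: (lfc, direction)}."""
    return pd.DataFrame([
        {"feature_id": f, "lfc": lfc, "p_value": 0.001 if d != "none" else 0.5,
         "direction": d, "degenerate": False}
        for f, (lfc, d) in features.items()
    ])


class TestBuildDefReference:
    def test_worked_voting_example(self):
        # up in 4 of 5 batches (lfcs 0.6, 0.8, 1.0, 0.6), quantifiable in all 5
        batches = [
            ("B1", calls_frame({"f": (0.6, "up")})),
            ("B2", calls_frame({"f": (0.8, "up")})),
            ("B3", calls_frame({"f": (1.0, "up")})),
            ("B4", calls_frame({"f": (0.6, "up")})),
            ("B5", calls_frame({"f": (0.1, "none")})),
        ]
        ref = build_def_reference(batches, CFG, ("D5", "F7"))
        rec = ref.records.iloc[0]
        assert rec["reference_lfc"] == pytest.approx(0.75)
        assert rec["support_fraction"] == pytest.approx(0.8)
        assert rec["direction"] == "up"

    def test_three_of_five_excluded(self):
        batches = [(f"B{i}", calls_frame({"f": (0.8, "up" if i <= 3 else "none")}))
                   for i in range(1, 6)]
        ref = build_def_reference(batches, CFG, ("D5", "F7"))
        assert len(ref.records) == 0  # 3/5 = 0.6, not > 0.7

    def test_conflicting_directions_excluded(self):
        dirs = ["up", "up", "up", "down", "down"]
        batches = [(f"B{i}", calls_frame({"f": (0.8 if d == "up" else -0.8, d)}))
                   for i, d in enumerate(dirs)]
        ref = build_def_reference(batches, CFG, ("D5", "F7"))
        assert len(ref.records) == 0  # max same-direction fraction 0.6

    def test_presence_rate_gate(self):
        # feature quantifiable in only 3 of 5 batches (0.6 <= 0.7): excluded
        # even though called up in all three
        batches = [(f"B{i}", calls_frame({"f": (0.8, "up")})) for i in range(3)]
        batches += [(f"B{i}", calls_frame({"g": (0.0, "none")})) for i in range(3, 5)]
        ref = build_def_reference(batches, CFG, ("D5", "F7"))
        assert len(ref.records) == 0

    def test_quantifiable_denominator_vs_all(self):
        # up in 3 batches, quantifiable in only those 3 of 5:
        # quantifiable denominator -> excluded by presence gate; with
        # presence rate lowered, support 3/3 > 0.7 passes, but 'all'
        # denominator gives 3/5 = 0.6 and fails
        lax = OmicsTypeConfig(batch_presence_rate=0.5)
        batches = [(f"B{i}", calls_frame({"f": (0.8, "up")})) for i in range(3)]
        batches += [(f"B{i}", calls_frame({"g": (0.0, "none")})) for i in range(3, 5)]
        ref_q = build_def_reference(batches, lax, ("D5", "F7"))
        ref_all = build_def_reference(batches, lax, ("D5", "F7"),
                                      denominator="all")
        assert len(ref_q.records) == 1 and len(ref_all.records) == 0

    def test_vote_is_batch_order_invariant(self):
        rng = np.random.default_rng(8)
        batches = [
            (f"B{i}", calls_frame({
                "f": (0.6 + 0.1 * i, "up"),
                "g": (-0.9, "down" if i % 2 else "none"),
            }))
            for i in range(5)
        ]
        ref1 = build_def_reference(batches, CFG, ("D5", "F7"))
        shuffled = [batches[i] for i in rng.permutation(5)]
        ref2 = build_def_reference(shuffled, CFG, ("D5", "F7"))
        pd.testing.assert_frame_equal(ref1.records, ref2.records)

    def test_fewer_than_three_batches_rejected(self):
        batches = [("B1", calls_frame({"f": (0.8, "up")}))] * 2
        with pytest.raises(ValidationError, match="3 batches"):
            build_def_reference(batches, CFG, ("D5", "F7"))


class TestEvaluateDefs:
    def _reference(self):
        rec = pd.DataFrame([{"feature_id": "f1", "direction": "up",
                             "reference_lfc": 1.0, "support_fraction": 1.0}])
        return ReferenceDEFSet(contrast=("D5", "F7"), records=rec)

    def test_identity_gives_zero(self):
        assert evaluate_defs({"f1": 1.0}, self._reference()).value == 0.0

    def test_single_residual(self):
        assert evaluate_defs({"f1": 0.0}, self._reference()).value == pytest.approx(1.0)

    def test_reversed_contrast_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            evaluate_defs({"f1": 1.0}, self._reference(), contrast=("F7", "D5"))
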