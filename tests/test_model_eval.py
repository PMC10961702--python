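"""Binarization, confusion metrics, qualification and assay analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arbattery.model_eval import (
    AlignmentError,
    ConfusionSummary,
    QualificationCriteria,
    agreement_table,
    align_calls,
    assay_prevalence,
    binarize_auc,
    confusion,
    evaluate_all_models,
    leave_one_out_max_sensitivity,
    qualify_models,
)
from arbattery.synthetic_data import table1_calls


def _series(values, prefix="c"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestBinarize:
    @pytest.mark.parametrize("auc,call", [(0.1, 1), (0.099, 0), (0.0, 0), (2.5, 1)])
    def test_scalar(self, auc, call):
        assert binarize_auc(auc) == call

    def test_array(self):
        out = binarize_auc(np.array([0.0, 0.1, 0.0999, 1.2]))
        assert list(out) == [0, 1, 0, 1]

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            binarize_auc(-0.01)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            binarize_auc(0.5, cutoff=0.0)


class TestConfusion:
    def test_worked_sensitivity(self):
        # 238 true positives and 12 false negatives give sensitivity 0.952
        ref = _series([1] * 250 + [0] * 100)
        pred = _series([1] * 238 + [0] * 12 + [0] * 100)
        cs = confusion(pred, ref)
        assert (cs.tp, cs.fn) == (238, 12)
        assert cs.sensitivity == pytest.approx(0.952)

    def test_perfect_agreement(self):
        ref = _series([1, 0, 1, 0, 1])
        cs = confusion(ref, ref)
        assert cs.sensitivity == cs.specificity == cs.mcc == 1.0

    def test_model_agreement_cells_antagonist(self):
        # both-active 173, one-sided 74 and 10, both-inactive 1,560
        pred, ref = table1_calls("antagonist")
        cs = confusion(pred, ref)
        assert (cs.tp, cs.fp, cs.fn, cs.tn) == (173, 74, 10, 1560)
        assert round(cs.mcc, 2) == 0.79

    def test_mcc_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        a = _series(rng.integers(0, 2, 80))
        b = _series(rng.integers(0, 2, 80))
        assert confusion(a, b).mcc == pytest.approx(confusion(b, a).mcc)

    def test_mcc_against_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(12)
        for _ in range(5):
            a = rng.integers(0, 2, 60)
            b = rng.integers(0, 2, 60)
            ours = confusion(_series(a), _series(b)).mcc
            assert ours == pytest.approx(matthews_corrcoef(b, a), abs=1e-12)

    def test_mcc_zero_denominator_is_zero(self):
        assert ConfusionSummary(tp=5, fp=0, tn=0, fn=0).mcc == 0.0

    def test_balanced_accuracy_is_mean(self):
        cs = ConfusionSummary(tp=8, fp=3, tn=17, fn=2)
        assert cs.balanced_accuracy == pytest.approx((cs.sensitivity + cs.specificity) / 2)

    def test_alignment_error_lists_missing(self):
        a = _series([1, 0, 1])
        b = _series([1, 0, 1], prefix="x")
        with pytest.raises(AlignmentError, match="x0"):
            confusion(a, b)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        a = _series(rng.integers(0, 2, 40))
        b = _series(rng.integers(0, 2, 40))
        shuffled = a.sample(frac=1.0, random_state=1)
        assert confusion(a, b) == confusion(shuffled, b)

    def test_align_calls_intersects_explicitly(self):
        a = pd.Series([1, 0, 1], index=["c1", "c2", "c3"])
        b = pd.Series([1, 1], index=["c2", "c3"])
        aa, bb = align_calls(a, b)
        assert list(aa.index) == ["c2", "c3"]
        assert confusion(aa, bb).n == 2

    def test_reference_chemical_truth_set(self):
        # external in vivo truth: every active called, 23 of 27 inactives correct
        truth = _series([1] * 12 + [0] * 27)
        pred = _series([1] * 12 + [1] * 4 + [0] * 23)
        cs = confusion(pred, truth)
        assert cs.sensitivity == 1.0
        assert round(100 * cs.specificity, 1) == 85.2


class TestAgreement:
    def test_antagonist_cells(self):
        a14, a11 = table1_calls("antagonist")
        t = agreement_table(a14, a11)
        assert (t.both_active, t.a_only, t.b_only, t.both_inactive) == (173, 74, 10, 1560)
        assert t.agreement == 1733
        assert t.n == 1817

    def test_agonist_cells(self):
        a14, a11 = table1_calls("agonist")
        t = agreement_table(a14, a11)
        assert t.agreement == 1798
        assert t.n == 1817
        assert t.mcc == pytest.approx(0.68, abs=0.01)

    def test_identical_vectors(self):
        v = _series([1, 0, 0, 1, 1, 0])
        t = agreement_table(v, v)
        assert t.agreement == len(v)


class TestEvaluateAllModels:
    def _toy_table(self):
        # three chemicals, reference plus two subset models with hand-set AUCs
        rows = []
        aucs = {
            "A11111111111111": [0.5, 0.05, 0.3],
            "A11000000000011": [0.4, 0.02, 0.05],  # misses chem3 -> 1 FN
            "A00000000001111": [0.2, 0.15, 0.25],  # calls chem2 -> 1 FP
        }
        for model, vals in aucs.items():
            for chem, auc in zip(["c1", "c2", "c3"], vals):
                rows.append({"chemical_id": chem, "model_name": model, "mode": "antagonist", "auc": auc})
        return pd.DataFrame(rows)

    def test_hand_tabulated_counts(self):
        out = evaluate_all_models(self._toy_table(), "A11111111111111", "antagonist")
        m1 = out.loc["A11000000000011"]
        assert (m1.tp, m1.fp, m1.tn, m1.fn) == (1, 0, 1, 1)
        m2 = out.loc["A00000000001111"]
        assert (m2.tp, m2.fp, m2.tn, m2.fn) == (2, 1, 0, 0)

    def test_reference_equals_itself(self):
        table = self._toy_table()
        clone = table[table.model_name == "A11111111111111"].assign(model_name="A11111111111110")
        out = evaluate_all_models(pd.concat([table, clone]), "A11111111111111", "antagonist")
        row = out.loc["A11111111111110"]
        assert row.sensitivity == 1.0 and row.specificity == 1.0

    def test_missing_reference(self):
        with pytest.raises(ValueError, match="reference"):
            evaluate_all_models(self._toy_table(), "A01111111111111", "antagonist")

    def test_matches_brute_force_on_synthetic_data(self, small_dataset):
        """Vectorized evaluation equals per-model confusion() re-tabulation."""
        from arbattery.subset_models import parse_model_name

        models = [parse_model_name(n) for n in ("A11111111111111", "A00001000001111", "A00101011101000", "A10000000001111")]
        table = small_dataset.auc_table(models, modes=("antagonist",))
        out = evaluate_all_models(table, "A11111111111111", "antagonist")
        wide = table.pivot(index="chemical_id", columns="model_name", values="auc")
        ref = (wide["A11111111111111"] >= 0.1).astype(int)
        for name in out.index:
            expected = confusion((wide[name] >= 0.1).astype(int), ref)
            got = out.loc[name]
            assert (got.tp, got.fp, got.tn, got.fn) == (expected.tp, expected.fp, expected.tn, expected.fn)


class TestQualification:
    def _summaries(self, rows):
        return pd.DataFrame(
            rows, columns=["sensitivity", "specificity"],
            index=pd.Index([f"A{i:014b}" for i in range(3, 3 + len(rows))], name="model_name"),
        )

    def test_printed_metrics_qualify(self):
        s = self._summaries([[0.952, 0.934]])
        assert qualify_models(s) == set(s.index)

    def test_strict_boundary(self):
        s = self._summaries([[0.95, 0.99]])
        assert qualify_models(s, QualificationCriteria(strict=True)) == set()
        assert qualify_models(s, QualificationCriteria(strict=False)) == set(s.index)

    def test_matches_brute_force_filter(self, small_summaries):
        crit = QualificationCriteria()
        got = qualify_models(small_summaries["antagonist"], crit)
        expected = {
            name
            for name, row in small_summaries["antagonist"].iterrows()
            if row.sensitivity > crit.min_sensitivity and row.specificity > crit.min_specificity
        }
        assert got == expected

    @given(st.floats(0.5, 0.99), st.floats(0.5, 0.99))
    def test_tightening_never_grows(self, s_lo, s_hi):
        lo, hi = sorted([s_lo, s_hi])
        rng = np.random.default_rng(7)
        summaries = self._summaries(rng.uniform(0.4, 1.0, size=(40, 2)))
        loose = qualify_models(summaries, QualificationCriteria(lo, 0.6))
        tight = qualify_models(summaries, QualificationCriteria(hi, 0.6))
        assert tight <= loose

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            QualificationCriteria(min_sensitivity=1.5)


class TestAssayPrevalence:
    def test_fraction_of_models_containing_assay(self):
        # 47 of 109 models contain A14 -> 43.12%
        with_a14 = [f"A{i:013b}1" for i in range(1, 48)]
        without = [f"A{i:013b}0" for i in range(3, 65)]
        prev = assay_prevalence(with_a14 + without)
        assert round(100 * prev["A14"], 2) == 43.12

    def test_everywhere_and_nowhere(self):
        names = ["A10000000001111", "A11000000001111"]
        prev = assay_prevalence(names)
        assert prev["A1"] == 1.0
        assert prev["A3"] == 0.0

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            assay_prevalence([])


class TestLeaveOneOut:
    def test_matches_brute_force(self, small_summaries):
        from arbattery.subset_models import parse_model_name

        summaries = small_summaries["antagonist"]
        for excluded in (12, 13, 14, 1):
            got = leave_one_out_max_sensitivity(summaries, excluded)
            keep = [n for n in summaries.index if excluded not in parse_model_name(n).assays]
            assert got.max_sensitivity == pytest.approx(summaries.loc[keep, "sensitivity"].max())

    def test_excluding_irrelevant_assay_keeps_global_max(self, small_summaries):
        summaries = small_summaries["agonist"]
        best = summaries["sensitivity"].max()
        # A13 is antagonist-specific: dropping it cannot hurt the agonist max
        got = leave_one_out_max_sensitivity(summaries, 13)
        assert got.max_sensitivity == pytest.approx(best)

    def test_exhausting_exclusion_is_an_error(self):
        df = pd.DataFrame({"sensitivity": [0.9]}, index=pd.Index(["A11000000000000"], name="model_name"))
        with pytest.raises(ValueError, match="no subset models"):
            leave_one_out_max_sensitivity(df, [1, 2])
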