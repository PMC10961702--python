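"""Pair enumeration, battery minimization and exclusion analyses."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from arbattery.battery_optimizer import (
    InfeasibleBatteryError,
    constrained_battery_search,
    enumerate_pairs,
    exclude_assay_analysis,
    minimal_battery,
)
from arbattery.model_eval import QualificationCriteria, evaluate_call_matrix, qualify_models
from arbattery.subset_models import SubsetModel, parse_model_name, union_size
from arbattery.synthetic_data import TABLE4_AGONIST_MODEL, table4_pairs


def _random_summaries(n_models, seed, mode="antagonist"):
    rng = np.random.default_rng(seed)
    masks = rng.choice(np.arange(3, 1 << 14), size=n_models, replace=False)
    names = [SubsetModel.from_mask(int(m)).name for m in masks if int(m).bit_count() >= 2]
    df = pd.DataFrame(
        {
            "mode": mode,
            "sensitivity": rng.uniform(0.5, 1.0, len(names)),
            "specificity": rng.uniform(0.5, 1.0, len(names)),
        },
        index=pd.Index(names, name="model_name"),
    )
    return df


class TestEnumeratePairs:
    def test_cross_product_count(self):
        ag = {"A11000000000000"}
        ant = {"A00000000000011"}
        assert len(enumerate_pairs(ag, ant)) == 1

    def test_small_cross_product_matches_set_oracle(self):
        ag = ["A11000000000000", "A00110000000000", "A00001100000000"]
        ant = ["A00000000000011", "A00000000001100", "A10000000000001", "A01000000000010"]
        pairs = enumerate_pairs(ag, ant)
        assert len(pairs) == 12
        for row in pairs.itertuples():
            a = parse_model_name(row.agonist_model).assays
            b = parse_model_name(row.antagonist_model).assays
            assert row.union_size == len(a | b)
            assert row.hamming == len(a ^ b)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            enumerate_pairs(set(), {"A00000000000011"})

    def test_metrics_joined_from_summaries(self):
        ant = _random_summaries(5, seed=1)
        ag = _random_summaries(5, seed=2, mode="agonist")
        pairs = enumerate_pairs(set(ag.index), set(ant.index), agonist_summaries=ag, antagonist_summaries=ant)
        row = pairs.iloc[0]
        assert row.antagonist_sensitivity == ant.loc[row.antagonist_model, "sensitivity"]
        assert row.agonist_specificity == ag.loc[row.agonist_model, "specificity"]


class TestMinimalBattery:
    def test_printed_nine_assay_battery(self):
        """The 13 printed antagonist models pair with one agonist model at union 9."""
        fixture = table4_pairs()
        pairs = enumerate_pairs(
            {TABLE4_AGONIST_MODEL},
            set(fixture["antagonist_model"]),
            antagonist_summaries=fixture.set_index("antagonist_model").rename(
                columns={"antagonist_sensitivity": "sensitivity", "antagonist_specificity": "specificity"}
            ),
        )
        result = minimal_battery(pairs)
        assert result.union_size == 9
        assert len(result.pairs) == 13
        assert set(result.pairs["agonist_model"]) == {TABLE4_AGONIST_MODEL}
        # printed per-pair values hold for every row
        merged = result.pairs.merge(fixture, on=["agonist_model", "antagonist_model"])
        assert len(merged) == 13
        assert (merged["union_size"] == 9).all()
        # sorted by Hamming distance: closest pair (3) first, farthest (7) last
        assert result.pairs["hamming"].iloc[0] == 3
        assert result.pairs["hamming"].iloc[-1] == 7

    def test_invariant_to_row_order(self):
        ant = _random_summaries(30, seed=3)
        ag = _random_summaries(10, seed=4, mode="agonist")
        pairs = enumerate_pairs(set(ag.index), set(ant.index), agonist_summaries=ag, antagonist_summaries=ant)
        shuffled = pairs.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r1, r2 = minimal_battery(pairs), minimal_battery(shuffled)
        assert r1.union_size == r2.union_size
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)

    def test_contained_agonist_model(self):
        ag = parse_model_name("A00001000001000")
        ant = parse_model_name("A00001000001111")
        pairs = enumerate_pairs({ag.name}, {ant.name})
        assert minimal_battery(pairs).union_size == ant.size

    def test_matches_exhaustive_scan(self):
        ag = _random_summaries(25, seed=5, mode="agonist")
        ant = _random_summaries(40, seed=6)
        pairs = enumerate_pairs(set(ag.index), set(ant.index))
        best = minimal_battery(pairs).union_size
        oracle = min(
            union_size(parse_model_name(a), parse_model_name(b))
            for a in ag.index
            for b in ant.index
        )
        assert best == oracle

    def test_monotone_in_qualifying_sets(self):
        ag = _random_summaries(20, seed=7, mode="agonist")
        ant = _random_summaries(20, seed=8)
        small = minimal_battery(enumerate_pairs(set(ag.index[:5]), set(ant.index[:5]))).union_size
        large = minimal_battery(enumerate_pairs(set(ag.index), set(ant.index))).union_size
        assert large <= small


class TestConstrainedBatterySearch:
    @staticmethod
    def _oracle(ant_summaries, ag_summaries, k, criteria):
        """Exhaustive scan over all C(14, k) assay sets and all submodels."""
        qualifying = {
            parse_model_name(n).assays: n
            for n in qualify_models(ant_summaries, criteria)
        }
        ag_by_assays = {parse_model_name(n).assays: n for n in ag_summaries.index}
        best = None
        for combo in combinations(range(1, 15), k):
            battery = frozenset(combo)
            if not any(q <= battery for q in qualifying):
                continue
            contained = [
                (ag_summaries.loc[n, "sensitivity"], ag_summaries.loc[n, "specificity"], n)
                for a, n in ag_by_assays.items()
                if a <= battery
            ]
            if not contained:
                continue
            sens, spec, name = max(contained, key=lambda t: (t[0], t[1]))
            bname = SubsetModel.from_assays(battery).name
            key = (sens, spec, tuple(-ord(c) for c in bname))
            if best is None or key > best[0]:
                best = (key, battery, name)
        return best

    def test_matches_exhaustive_oracle(self):
        criteria = QualificationCriteria(min_sensitivity=0.8, min_specificity=0.6)
        ant = _random_summaries(60, seed=10)
        ag = _random_summaries(60, seed=11, mode="agonist")
        for k in (5, 6, 7):
            oracle = self._oracle(ant, ag, k, criteria)
            if oracle is None:
                with pytest.raises(InfeasibleBatteryError):
                    constrained_battery_search(ant, ag, k, criteria)
                continue
            got = constrained_battery_search(ant, ag, k, criteria)
            assert got.assays == oracle[1]
            assert got.agonist_model == oracle[2]

    def test_full_battery_recovers_global_best(self):
        criteria = QualificationCriteria(min_sensitivity=0.7, min_specificity=0.5)
        ant = _random_summaries(40, seed=12)
        ag = _random_summaries(40, seed=13, mode="agonist")
        got = constrained_battery_search(ant, ag, 14, criteria)
        best = ag.sort_values(["sensitivity", "specificity"], ascending=False).index[0]
        assert got.agonist_model == best

    def test_infeasible_size_reported(self):
        ant = _random_summaries(10, seed=14)
        ant["sensitivity"] = 0.2  # nothing qualifies
        ag = _random_summaries(10, seed=15, mode="agonist")
        with pytest.raises(InfeasibleBatteryError):
            constrained_battery_search(ant, ag, 6, QualificationCriteria())


class TestExcludeAssayAnalysis:
    def test_empty_exclusion_equals_global(self, small_summaries):
        crit = QualificationCriteria()
        reports = exclude_assay_analysis(small_summaries, excluded=(), criteria=crit)
        for mode, summaries in small_summaries.items():
            assert reports[mode].n_models == len(summaries)
            assert set(reports[mode].qualifying) == qualify_models(summaries, crit)

    def test_matches_brute_force_filter_then_qualify(self):
        crit = QualificationCriteria(min_sensitivity=0.8, min_specificity=0.6)
        summaries = {"antagonist": _random_summaries(80, seed=16)}
        excluded = {1, 2, 3}
        reports = exclude_assay_analysis(summaries, excluded, crit)
        keep = [n for n in summaries["antagonist"].index if not (parse_model_name(n).assays & excluded)]
        sub = summaries["antagonist"].loc[keep]
        assert reports["antagonist"].max_sensitivity == pytest.approx(sub["sensitivity"].max())
        assert set(reports["antagonist"].qualifying) == qualify_models(sub, crit)

    def test_binding_assays_unique_agonist_detectors(self):
        """Agonists detected only by receptor binding are lost when A1-A3 go.

        Constructed scenario: a subclass of agonists fires only a binding
        assay, so removing all three binding assays caps agonist sensitivity
        below threshold while antagonist detection is unaffected.
        """
        from arbattery.subset_models import enumerate_subset_models

        rng = np.random.default_rng(17)
        n = 120
        hits = np.zeros((n, 14), dtype=int)
        potency_ag = rng.uniform(0.0, 0.09, n)
        potency_ant = rng.uniform(0.0, 0.09, n)
        # 12 broad agonists, 6 binding-only agonists, 30 broad antagonists
        hits[:12, :11] = 1
        potency_ag[:12] = rng.uniform(0.3, 1.0, 12)
        binding = rng.integers(1, 4, 6) - 1
        hits[np.arange(12, 18), binding] = 1
        potency_ag[12:18] = rng.uniform(1.2, 1.4, 6)
        hits[18:48, [0, 1, 2, 3, 4, 5, 11, 12, 13]] = 1
        potency_ant[18:48] = rng.uniform(0.3, 1.0, 30)

        from arbattery.synthetic_data import surrogate_auc_matrix

        models = enumerate_subset_models()
        names = [m.name for m in models]
        full = names.index("A" + "1" * 14)
        summaries = {}
        for mode, potency in (("agonist", potency_ag), ("antagonist", potency_ant)):
            auc = surrogate_auc_matrix(hits, potency, models, mode)
            calls = auc >= 0.1
            cols = [i for i in range(len(names)) if i != full]
            summaries[mode] = evaluate_call_matrix(
                calls[:, cols], [names[i] for i in cols], calls[:, full], mode
            )
        reports = exclude_assay_analysis(summaries, excluded={1, 2, 3})
        assert reports["agonist"].max_sensitivity < 0.95
        assert reports["antagonist"].max_sensitivity > 0.95
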