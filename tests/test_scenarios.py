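"""Class decomposition and exposure-reduction scenario calculus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wqsmix.chemicals import class_map, default_chemicals
from wqsmix.scenarios import (
    NAMED_SCENARIOS,
    ScenarioSpec,
    apply_scenario,
    class_contributions,
    fraction_below_target,
    scenario_battery,
    target_value,
)
from wqsmix.wqs import WeightSet, compute_index


@pytest.fixture
def toy_decomp(rng):
    """10-subject toy with uniform weights over the default 26-chemical panel."""
    chems = default_chemicals()
    names = [c.name for c in chems]
    q = pd.DataFrame(rng.integers(0, 10, size=(10, 26)).astype(float), columns=names)
    sex = rng.integers(0, 2, size=10)
    w = WeightSet(np.full((2, 26), 1 / 52), chemicals=names)
    return class_contributions(q, w, sex, class_map(chems)), q, w, sex


class TestTargetValue:
    def test_reference_cohort_arithmetic(self):
        # mean 2.24, sample SD 0.50 -> target 1.74
        index = 2.24 + 0.50 * np.array([-1.0, 0.0, 1.0])
        assert target_value(index) == pytest.approx(1.74)

    def test_mean_minus_sd(self, rng):
        index = rng.normal(10.0, 1.0, size=20000)
        assert target_value(index) == pytest.approx(9.0, abs=0.05)

    def test_standardized_index_gives_minus_one(self, rng):
        v = rng.normal(size=500)
        v = (v - v.mean()) / v.std(ddof=1)
        assert target_value(v) == pytest.approx(-1.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            target_value(np.ones(5))


class TestClassContributions:
    def test_single_pfas_weight_means_fully_persistent(self, rng):
        chems = default_chemicals()
        names = [c.name for c in chems]
        w = np.zeros((2, 26))
        j = names.index("PFOA")
        w[0, j] = w[1, j] = 0.5
        ws = WeightSet(w, chemicals=names)
        q = pd.DataFrame(rng.integers(1, 10, size=(8, 26)).astype(float), columns=names)
        sex = rng.integers(0, 2, size=8)
        decomp = class_contributions(q, ws, sex, class_map(chems))
        assert np.allclose(decomp.persistent_fraction(), 1.0)

    def test_uniform_weights_equal_scores_class_size_fractions(self):
        chems = default_chemicals()
        names = [c.name for c in chems]
        ws = WeightSet(np.full((2, 26), 1 / 52), chemicals=names)
        q = pd.DataFrame(np.full((4, 26), 5.0), columns=names)
        sex = np.array([0, 0, 1, 1])
        decomp = class_contributions(q, ws, sex, class_map(chems))
        assert np.allclose(decomp.persistent_fraction(), 10 / 26)
        assert np.allclose(decomp.fractions["plasticizer"], 9 / 26)

    def test_contributions_sum_to_index_exactly(self, toy_decomp):
        decomp, q, w, sex = toy_decomp
        index = compute_index(q, w, sex)
        assert np.allclose(decomp.contributions.sum(axis=1), index, atol=1e-10)
        assert np.allclose(decomp.fractions.sum(axis=1), 1.0, atol=1e-10)

    def test_unmapped_chemical_named(self, rng):
        chems = default_chemicals()
        names = [c.name for c in chems]
        ws = WeightSet(np.full((2, 26), 1 / 52), chemicals=names)
        classes = class_map(chems)
        del classes["BPA"]
        q = pd.DataFrame(np.ones((3, 26)), columns=names)
        with pytest.raises(ValueError, match="BPA"):
            class_contributions(q, ws, np.array([0, 1, 0]), classes)


class TestApplyScenario:
    def test_identity_when_all_retained(self, toy_decomp):
        decomp, *_ = toy_decomp
        spec = ScenarioSpec(retain={cl: 1.0 for cl in decomp.contributions.columns})
        assert np.allclose(apply_scenario(decomp, spec), decomp.index)

    def test_zero_retention_zero_index(self, toy_decomp):
        decomp, *_ = toy_decomp
        spec = ScenarioSpec(retain={cl: 0.0 for cl in decomp.contributions.columns})
        assert np.allclose(apply_scenario(decomp, spec), 0.0)

    def test_seventy_percent_cut_formula(self, toy_decomp):
        decomp, *_ = toy_decomp
        spec = ScenarioSpec(retain=NAMED_SCENARIOS["cut70_nonpersistent"])
        adjusted = apply_scenario(decomp, spec)
        persistent = decomp.contributions[["pfas", "persistent_chlorinated"]].sum(axis=1)
        nonpersistent = decomp.index - persistent
        assert np.allclose(adjusted, persistent + 0.30 * nonpersistent, atol=1e-12)

    def test_multiplier_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(retain={"phenol": 1.2})


class TestFractionBelowTarget:
    def test_all_below(self):
        assert fraction_below_target(np.array([0.1, 0.2]), 1.0) == 1.0

    def test_counting_with_boundary(self):
        # strictly below: the value equal to the target does not count
        assert fraction_below_target(np.array([1.0, 2.0, 3.0]), 2.0) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_below_target(np.array([]), 0.0)


class TestScenarioProperties:
    def test_monotone_in_every_retain_multiplier(self, toy_decomp):
        """Exhaustive check on the 10-subject toy: the below-target fraction
        is nonincreasing in each class's retain multiplier."""
        decomp, *_ = toy_decomp
        target = float(np.median(decomp.index))
        classes = list(decomp.contributions.columns)
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for varied in classes:
            fracs = []
            for m in grid:
                retain = {cl: 1.0 for cl in classes}
                retain[varied] = m
                adj = apply_scenario(decomp, ScenarioSpec(retain=retain))
                fracs.append(fraction_below_target(adj, target))
            assert all(a >= b for a, b in zip(fracs, fracs[1:])), varied

    def test_superset_elimination_never_worse(self, toy_decomp):
        decomp, *_ = toy_decomp
        target = float(np.median(decomp.index))
        classes = list(decomp.contributions.columns)
        results = {}
        for r in range(len(classes) + 1):
            for combo in itertools.combinations(classes, r):
                retain = {cl: (0.0 if cl in combo else 1.0) for cl in classes}
                adj = apply_scenario(decomp, ScenarioSpec(retain=retain))
                results[frozenset(combo)] = fraction_below_target(adj, target)
        for a, fa in results.items():
            for b, fb in results.items():
                if a < b:
                    assert fb >= fa

    def test_adjusted_never_exceeds_original(self, toy_decomp, rng):
        decomp, *_ = toy_decomp
        for _ in range(20):
            retain = {cl: rng.uniform() for cl in decomp.contributions.columns}
            adj = apply_scenario(decomp, ScenarioSpec(retain=retain))
            assert np.all(adj <= decomp.index + 1e-12)


class TestScenarioBattery:
    def test_baseline_scenario_matches_raw_fraction(self, toy_decomp):
        decomp, *_ = toy_decomp
        target = float(np.median(decomp.index))
        spec = ScenarioSpec(
            retain={cl: 1.0 for cl in decomp.contributions.columns}, name="baseline"
        )
        results = scenario_battery(decomp, target, extra=[spec])
        by_name = {r.spec.name: r for r in results}
        assert by_name["baseline"].fraction_below == pytest.approx(
            fraction_below_target(decomp.index, target)
        )

    def test_named_scenarios_ordered_by_retained_weight(self, toy_decomp):
        """With uniform weights the four named scenarios retain 10/26 + x of
        the index; fractions below target must follow the retained order."""
        decomp, *_ = toy_decomp
        target = float(np.median(decomp.index))
        results = {r.spec.name: r.fraction_below for r in scenario_battery(decomp, target)}
        # eliminating plasticizers+phenols retains less than plasticizers alone
        assert results["eliminate_plasticizers_phenols"] >= results["eliminate_plasticizers"]
        assert results["eliminate_plasticizers_short_lived"] >= results["eliminate_plasticizers"]

    def test_histogram_counts_sum_to_n(self, toy_decomp):
        decomp, *_ = toy_decomp
        for r in scenario_battery(decomp, target=1.0):
            counts, edges = r.histogram
            assert counts.sum() == len(decomp.index)
            assert len(edges) == len(counts) + 1
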