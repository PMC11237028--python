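"""Fuzzy core: partitions, membership evaluation, rule enumeration,
Wang-Mendel learning, FBF inference, swarm distribution, and alarming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfabt.fuzzy import (
    AlarmDecision,
    FBFSystem,
    FuzzyPartition,
    FuzzyRule,
    RuleBase,
    TriangularMF,
    UncoveredInputError,
    alarm,
    build_system,
    complete_rule_base,
    default_partitions,
    enumerate_rule_space,
    learn_rules,
)


class TestPartitions:
    def test_default_centers_and_labels(self):
        hgb, pao2, ph, out = default_partitions()
        assert hgb.centers == (8.0, 10.25, 14.1, 16.6)
        assert hgb.labels == ("Very Low", "Low", "Normal", "High")
        assert pao2.centers == (30.0, 47.5, 65.75, 90.0)
        assert ph.centers == (7.35, 7.4, 7.45)
        assert out.centers == (0.25, 0.75)
        assert out.labels == ("Low", "Normal")

    def test_completeness_grid_scan(self):
        for part in default_partitions():
            assert part.is_complete(n_grid=1000), part.variable

    def test_partition_of_unity_between_extreme_centers(self):
        for part in default_partitions():
            grid = np.linspace(part.centers[0], part.centers[-1], 1000)
            total = part.membership_matrix(grid).sum(axis=1)
            np.testing.assert_allclose(total, 1.0, atol=1e-9)

    @given(
        centers=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2, max_size=6, unique=True,
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_partition_of_unity_for_arbitrary_centers(self, centers):
        centers = sorted(centers)
        if min(b - a for a, b in zip(centers, centers[1:])) < 1e-3:
            return  # degenerate spacing
        part = FuzzyPartition.from_centers(
            "v", (centers[0] - 1, centers[-1] + 1), centers,
            [f"m{k}" for k in range(len(centers))],
        )
        grid = np.linspace(centers[0], centers[-1], 200)
        np.testing.assert_allclose(part.membership_matrix(grid).sum(axis=1), 1.0, atol=1e-9)
        assert part.is_complete()

    def test_membership_peak_foot_and_midpoint(self):
        hgb = default_partitions()[0]
        assert hgb.membership(0, 8.0) == 1.0
        assert hgb.membership(0, 10.25) == 0.0
        assert hgb.membership(0, 9.125) == pytest.approx(0.5)

    def test_shoulders_saturate(self):
        hgb = default_partitions()[0]
        assert hgb.membership(0, 7.0) == 1.0  # below lowest center
        assert hgb.membership(3, 16.6) == 1.0

    def test_bad_mf_geometry_rejected(self):
        with pytest.raises(ValueError):
            TriangularMF("x", center=1.0, left_foot=2.0, right_foot=3.0)
        with pytest.raises(IndexError):
            default_partitions()[0].membership(9, 8.0)


class TestRuleSpace:
    @pytest.mark.parametrize(
        "inputs,expected",
        [(("hgb", "pao2"), 32), (("hgb", "ph"), 24), (("hgb",), 8)],
    )
    def test_candidate_rule_counts(self, inputs, expected):
        rules, count = enumerate_rule_space(build_system(inputs))
        assert count == expected == len(rules)
        assert len({(r.antecedent, r.consequent) for r in rules}) == count

    def test_duplicate_antecedent_rejected(self):
        sys2 = build_system(("hgb", "pao2"))
        rb = RuleBase([FuzzyRule((0, 0), 0), FuzzyRule((0, 0), 1)])
        with pytest.raises(ValueError, match="duplicate"):
            FBFSystem(sys2.input_partitions, sys2.output_partition, rb)


class TestFuzzyBasis:
    def test_peak_cell_gives_one(self):
        sys2 = build_system(("hgb", "pao2"))
        # "Very Low" hemoglobin center 8; "Severe Hypoxemia" is the MF at center 90
        assert sys2.fuzzy_basis((0, 3), [8.0, 90.0]) == pytest.approx(1.0)

    def test_product_of_memberships(self):
        sys2 = build_system(("hgb", "pao2"))
        z = [9.125, 38.75]  # midpoints: memberships 0.5 each
        assert sys2.fuzzy_basis((0, 0), z) == pytest.approx(0.25)

    def test_zero_outside_support(self):
        sys2 = build_system(("hgb", "pao2"))
        assert sys2.fuzzy_basis((0, 0), [14.1, 47.5]) == 0.0


def _grid_system(inputs=("hgb", "pao2"), seed=0, normalize=True):
    """Complete grid rule base with seeded random consequents."""
    system = build_system(inputs, normalize=normalize)
    rng = np.random.default_rng(seed)
    cells, _ = enumerate_rule_space(system)
    seen = {}
    for r in cells:
        seen[r.antecedent] = FuzzyRule(r.antecedent, int(rng.integers(0, 2)))
    system.rules = RuleBase(list(seen.values()))
    return system


def _brute_force_centroid(system, z):
    """Independent oracle: explicit loop over rules, singleton fuzzifier,
    product inference, centroid defuzzifier."""
    num = den = 0.0
    for rule in system.rules:
        d = 1.0
        for j, part in enumerate(system.input_partitions):
            d *= part.membership(rule.antecedent[j], z[j])
        num += d * system.thetas[rule.consequent]
        den += d
    return num / den


class TestInference:
    def test_single_active_rule_returns_theta(self):
        system = _grid_system(seed=1)
        # grid point (center, center): exactly one rule active
        target = next(r for r in system.rules if r.antecedent == (1, 1))
        f = system.infer([10.25, 47.5])
        assert f == pytest.approx(system.thetas[target.consequent])

    def test_midway_equal_weights_average(self):
        system = build_system(("hgb",) )
        system.rules = RuleBase([FuzzyRule((0,), 0), FuzzyRule((1,), 1)])
        f = system.infer([9.125])  # halfway between centers 8 and 10.25
        assert f == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        system = _grid_system(seed=2)
        rng = np.random.default_rng(3)
        Z = np.column_stack([
            rng.uniform(p.centers[0], p.centers[-1], 200) for p in system.input_partitions
        ])
        f = system.infer(Z)
        oracle = np.array([_brute_force_centroid(system, z) for z in Z])
        np.testing.assert_allclose(f, oracle, atol=1e-9)

    def test_normalized_equals_unnormalized_on_complete_grid(self):
        a = _grid_system(seed=4, normalize=True)
        b = _grid_system(seed=4, normalize=False)
        rng = np.random.default_rng(5)
        Z = np.column_stack([
            rng.uniform(p.centers[0], p.centers[-1], 200) for p in a.input_partitions
        ])
        np.testing.assert_allclose(a.infer(Z), b.infer(Z), atol=1e-9)

    def test_output_bounds(self):
        system = _grid_system(seed=6)
        rng = np.random.default_rng(7)
        Z = np.column_stack([rng.uniform(0, 120, 500), rng.uniform(0, 150, 500)])
        f = system.infer(Z)
        assert f.min() >= 0.25 - 1e-12 and f.max() <= 0.75 + 1e-12

    def test_monotone_response_with_canonical_rules(self):
        """Low-hemoglobin cells -> Low consequent: f non-increasing as Hgb falls."""
        system = build_system(("hgb",))
        system.rules = RuleBase(
            [FuzzyRule((0,), 0), FuzzyRule((1,), 0), FuzzyRule((2,), 1), FuzzyRule((3,), 1)]
        )
        grid = np.linspace(6.0, 18.0, 400)[:, None]
        f = system.infer(grid)
        assert np.all(np.diff(f) >= -1e-12)

    def test_uncovered_input_raises(self):
        system = build_system(("hgb", "pao2"))
        system.rules = RuleBase([FuzzyRule((0, 0), 0)])
        with pytest.raises(UncoveredInputError):
            system.infer([16.6, 90.0])

    def test_round_trip_serialization(self, tmp_path):
        system = _grid_system(seed=8)
        p = tmp_path / "rules.json"
        system.save(str(p))
        back = FBFSystem.load(str(p))
        z = [9.0, 50.0]
        assert back.infer(z) == system.infer(z)


class TestWangMendel:
    def test_single_grid_point_sample(self):
        system = build_system(("hgb", "pao2"))
        rb = learn_rules(system, [(np.array([8.0, 30.0]), 0.25)])
        assert len(rb) == 1
        (rule,) = rb.rules
        assert rule.antecedent == (0, 0) and rule.consequent == 0
        assert rule.degree == pytest.approx(1.0)

    def test_conflict_resolved_by_degree(self):
        system = build_system(("hgb", "pao2"))
        # both samples fall in cell (0,0); the first has higher memberships
        data = [
            (np.array([8.0, 30.0]), 0.25),    # degree 1.0 -> consequent Low
            (np.array([8.5, 33.0]), 0.75),    # lower degree -> loses
        ]
        rb = learn_rules(system, data)
        assert len(rb) == 1
        assert rb.rules[0].consequent == 0

    def test_full_coverage_learns_one_rule_per_cell(self):
        system = build_system(("hgb", "pao2"))
        centers_h = system.input_partitions[0].centers
        centers_p = system.input_partitions[1].centers
        data = [
            (np.array([ch, cp]), 0.25) for ch in centers_h for cp in centers_p
        ]
        rb = learn_rules(system, data)
        assert len(rb) == 16  # product of input MF counts

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            learn_rules(build_system(("hgb",)), [])

    def test_out_of_universe_clipped_with_warning(self, caplog):
        import logging

        system = build_system(("hgb",))
        with caplog.at_level(logging.WARNING, logger="nfabt.fuzzy"):
            rb = learn_rules(system, [(np.array([2.0]), 0.25)])
        assert any("clipped" in m for m in caplog.messages)
        assert rb.rules[0].antecedent == (0,)

    def test_completion_covers_every_cell(self):
        system = build_system(("hgb", "pao2"))
        rb = learn_rules(system, [(np.array([8.0, 30.0]), 0.25)])
        full = complete_rule_base(system, rb)
        assert len(full) == 16
        assert {r.consequent for r in full} == {0}  # inherited from the one rule


class TestSwarm:
    def test_degenerate_swarm_equals_infer(self):
        system = _grid_system(seed=9)
        z = [9.3, 55.0]
        f, partials = system.swarm_infer(z, swarm_size=1)
        assert f == pytest.approx(system.infer(z), abs=1e-15)
        assert len(partials) == 1

    @pytest.mark.parametrize("size", [2, 4, 16])
    def test_round_robin_matches_centralized(self, size):
        system = _grid_system(seed=10)
        z = [11.0, 70.0]
        f, partials = system.swarm_infer(z, swarm_size=size)
        assert f == pytest.approx(system.infer(z), abs=1e-12)
        assert sum(p["rules"] for p in partials) == len(system.rules)

    def test_assignment_permutation_invariance(self):
        system = _grid_system(seed=11)
        z = [9.0, 45.0]
        rng = np.random.default_rng(12)
        a1 = rng.integers(0, 4, len(system.rules))
        a2 = rng.permutation(a1)
        f1, _ = system.swarm_infer(z, swarm_size=4, assignment=a1)
        f2, _ = system.swarm_infer(z, swarm_size=4, assignment=a2)
        assert f1 == pytest.approx(f2, abs=1e-15)

    def test_bad_assignment_rejected(self):
        system = _grid_system(seed=13)
        with pytest.raises(ValueError):
            system.swarm_infer([9.0, 45.0], swarm_size=2, assignment=[0])


class TestAlarm:
    @pytest.mark.parametrize(
        "value,label,fires", [(0.25, "Low", True), (0.75, "Normal", False), (0.5, "Normal", False)]
    )
    def test_decision_boundary(self, value, label, fires):
        d = alarm(value)
        assert d.state_label == label and d.alarm is fires
        assert d.message["state_value"] == value

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_alarm_iff_low(self, v):
        d = alarm(v)
        assert d.alarm == (d.state_label == "Low")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            alarm(1.2)

    def test_message_carries_inputs(self):
        d = alarm(0.3, inputs={"hgb": 8.1, "pao2": 44.0})
        assert d.message["inputs"]["hgb"] == 8.1
        assert d.message["event"] == "transfusion_alarm"
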