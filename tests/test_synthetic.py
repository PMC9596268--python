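"""Synthetic generator: determinism, planted structure, closed-form oracle."""

import math

import numpy as np
import pytest

from acumine.apriori import MiningConfig, mine_frequent, support_count
from acumine.rules import compute_metrics, generate_rules
from acumine.synthetic import GeneratorConfig, PlantedRule, expected_metrics, generate


def test_identical_seed_identical_db():
    a = generate(GeneratorConfig(seed=11))
    b = generate(GeneratorConfig(seed=11))
    assert a == b
    assert a != generate(GeneratorConfig(seed=12))


def test_default_shape():
    db = generate(GeneratorConfig(seed=0))
    assert db.N == 33
    assert all(p.items for p in db.prescriptions)
    assert set(db.universe) <= set(GeneratorConfig().core_items) | set(
        GeneratorConfig().filler_items()
    )


def test_deterministic_planted_rule_forces_confidence_one():
    config = GeneratorConfig(
        planted_rules=(PlantedRule(("HT7",), ("RN12",), 1.0),), seed=3
    )
    for seed in range(5):
        db = generate(GeneratorConfig(planted_rules=config.planted_rules, seed=seed))
        if support_count(db, {"HT7"}):
            assert compute_metrics(db, {"HT7"}, {"RN12"}).confidence == 1


def test_degenerate_config_single_universal_item():
    config = GeneratorConfig(
        core_items={"ST36": 1.0, "RN12": 0.0},
        planted_rules=(),
        background_rate=0.0,
        seed=5,
    )
    db = generate(config)
    assert all(p.items == frozenset({"ST36"}) for p in db.prescriptions)


def test_expected_metrics_closed_forms():
    config = GeneratorConfig(
        core_items={"AA1": 0.5, "BB1": 0.5, "CC1": 0.3},
        planted_rules=(),
        seed=0,
    )
    support, conf, lift = expected_metrics(config, ("AA1",), ("BB1",))
    assert (support, conf, lift) == (0.25, 0.5, 1.0)

    planted = GeneratorConfig(
        core_items={"AA1": 0.5, "BB1": 0.3},
        planted_rules=(PlantedRule(("AA1",), ("BB1",), 0.9),),
        seed=0,
    )
    support, conf, lift = expected_metrics(planted, ("AA1",), ("BB1",))
    assert conf == 0.9
    assert support == pytest.approx(0.45)
    assert lift == pytest.approx(0.9 / (0.5 * 0.9 + 0.5 * 0.3))


def test_expected_metrics_refuses_overlapping_rules():
    config = GeneratorConfig(
        core_items={"AA1": 0.5, "BB1": 0.3, "CC1": 0.4},
        planted_rules=(
            PlantedRule(("AA1",), ("BB1",), 0.9),
            PlantedRule(("CC1",), ("BB1",), 0.8),
        ),
        seed=0,
    )
    with pytest.raises(ValueError, match="no closed form"):
        expected_metrics(config, ("AA1",), ("BB1",))


def _empirical(db, lhs, rhs):
    r = compute_metrics(db, lhs, rhs)
    return float(r.support), float(r.confidence), float(r.lift), r.lhs_count


def test_monte_carlo_agrees_with_closed_form_at_scale():
    """Empirical confidence/lift of covered pairs within 3 SE at n = 100k."""
    config = GeneratorConfig(n_transactions=100_000, seed=91)
    db = generate(config)
    for lhs, rhs in [(("HT7",), ("RN12",)), (("RN4",), ("SP6",)), (("PC6",), ("DU20",))]:
        support, conf, lift = expected_metrics(config, lhs, rhs)
        emp_s, emp_c, emp_l, n_lhs = _empirical(db, lhs, rhs)
        se_conf = math.sqrt(max(conf * (1 - conf), 1e-12) / n_lhs)
        assert abs(emp_c - conf) <= 3 * se_conf + 1e-9
        se_support = math.sqrt(support * (1 - support) / config.n_transactions)
        assert abs(emp_s - support) <= 3 * se_support + 1e-9


def test_parameter_recovery_and_no_spurious_lift():
    """Mining a 10k-transaction draw recovers the planted rules and finds no
    significant lift among pure-background core pairs (Bonferroni 3-sigma)."""
    config = GeneratorConfig(n_transactions=10_000, seed=17)
    db = generate(config)
    frequent = mine_frequent(db, MiningConfig(min_support=0.2, min_confidence=0.7))
    rules = {
        (tuple(sorted(r.lhs)), tuple(sorted(r.rhs))): r
        for r in generate_rules(
            frequent, db, MiningConfig(min_support=0.2, min_confidence=0.7)
        )
    }
    for planted in config.planted_rules:
        key = (tuple(sorted(planted.lhs)), tuple(sorted(planted.rhs)))
        assert key in rules
        r = rules[key]
        se = math.sqrt(planted.p_cond * (1 - planted.p_cond) / r.lhs_count + 1e-12)
        assert abs(float(r.confidence) - planted.p_cond) <= 3 * se + 1e-9

    background = ["ST36", "SP6", "PC6", "DU20"]  # pairwise independent under the model
    pairs = [(a, b) for i, a in enumerate(background) for b in background[i + 1 :]]
    z_crit = 3.0 + math.log(len(pairs))  # crude Bonferroni widening
    for a, b in pairs:
        r = compute_metrics(db, (a,), (b,))
        p_b = float(r.expected_confidence)
        se = math.sqrt(p_b * (1 - p_b) / r.lhs_count)
        assert abs(float(r.confidence) - p_b) <= z_crit * se


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(core_items={"AA1": 1.5})
    with pytest.raises(ValueError):
        GeneratorConfig(background_rate=-0.1)
    with pytest.raises(ValueError):
        PlantedRule(("AA1",), ("AA1",), 0.5)
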