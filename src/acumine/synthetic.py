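"""Synthetic prescription databases with planted association structure.

The generator emulates the shape of the real corpus: a handful of core
acupoints with high marginal inclusion probabilities (two of them in roughly
73% and 67% of prescriptions), a long tail of rare filler points, a median
prescription size of four, and a few planted antecedent->consequent
dependencies that create rules with known support, confidence and lift.

Generative model, per transaction (independent across transactions):

1. every core item enters independently with its marginal probability;
2. for each planted rule (L, R, p_cond), in order: if L is fully present,
   the membership of each item of R is *resampled* as Bernoulli(p_cond) —
   so the conditional probability of R given L is exactly p_cond;
3. every filler item enters independently at ``background_rate``;
4. empty transactions are rejected and redrawn.

Closed-form metrics under this model are available for singleton pairs
touched by at most one planted rule (:func:`expected_metrics`), which gives
the simulation its independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .prescriptions import Prescription, TransactionDB


@dataclass(frozen=True)
class PlantedRule:
    lhs: tuple[str, ...]
    rhs: tuple[str, ...]
    p_cond: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_cond <= 1:
            raise ValueError(f"p_cond must be in [0,1], got {self.p_cond}")
        if set(self.lhs) & set(self.rhs):
            raise ValueError("planted rule lhs and rhs overlap")


def _default_core() -> dict[str, float]:
    # marginals of the real corpus' seven core acupoints (counts / 33)
    return {
        "ST36": 24 / 33,
        "RN12": 22 / 33,
        "SP6": 14 / 33,
        "RN4": 13 / 33,
        "PC6": 13 / 33,
        "HT7": 9 / 33,
        "DU20": 9 / 33,
    }


def _default_planted() -> tuple[PlantedRule, ...]:
    # one deterministic dependency (as observed for HT7 -> RN12) and one
    # strong stochastic one (RN4 -> SP6 at the observed confidence 11/13)
    return (
        PlantedRule(("HT7",), ("RN12",), 1.0),
        PlantedRule(("RN4",), ("SP6",), 11 / 13),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 33 transactions over a 38-item universe.

    ``background_rate`` = 0.04 puts ~1.2 filler items per prescription on
    top of ~3.2 core items, matching the published median size of four.
    """

    n_transactions: int = reference.N_FORMULAS
    universe_size: int = reference.UNIVERSE_SIZE
    core_items: dict[str, float] = field(default_factory=_default_core)
    planted_rules: tuple[PlantedRule, ...] = field(default_factory=_default_planted)
    background_rate: float = 0.04
    size_target: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for item, p in self.core_items.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marginal for {item} out of [0,1]: {p}")
        if not 0 <= self.background_rate <= 1:
            raise ValueError(f"background_rate out of [0,1]: {self.background_rate}")
        if self.universe_size < len(self.core_items):
            raise ValueError("universe_size smaller than the core item list")

    def filler_items(self) -> list[str]:
        n_filler = self.universe_size - len(self.core_items)
        return [f"XX{i + 1}" for i in range(n_filler)]


def generate(config: GeneratorConfig | None = None) -> TransactionDB:
    """Draw a synthetic transaction database; identical seed, identical DB."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    core = list(config.core_items)
    fillers = config.filler_items()
    prescriptions = []
    width = len(str(config.n_transactions))
    for i in range(config.n_transactions):
        while True:
            items = {c for c in core if rng.random() < config.core_items[c]}
            for rule in config.planted_rules:
                if set(rule.lhs) <= items:
                    for r in rule.rhs:
                        present = rng.random() < rule.p_cond
                        if present:
                            items.add(r)
                        else:
                            items.discard(r)
            items |= {f for f in fillers if rng.random() < config.background_rate}
            if items:
                break
        prescriptions.append(
            Prescription(f"t{i + 1:0{width}d}", f"sim{i + 1:0{width}d}", frozenset(items))
        )
    return TransactionDB(tuple(prescriptions))


def _rules_touching(config: GeneratorConfig, items: set[str]) -> list[PlantedRule]:
    return [
        r for r in config.planted_rules if (set(r.lhs) | set(r.rhs)) & items
    ]


def marginal(config: GeneratorConfig, item: str) -> float:
    """Marginal inclusion probability of a single core item under the model."""
    if item not in config.core_items:
        if item in config.filler_items():
            return config.background_rate
        raise ValueError(f"unknown item {item!r}")
    p = config.core_items[item]
    covering = [r for r in config.planted_rules if item in r.rhs]
    if not covering:
        return p
    if len(covering) > 1:
        raise ValueError(f"no closed form: {item} is consequent of several planted rules")
    (rule,) = covering
    if len(rule.lhs) != 1:
        raise ValueError("no closed form: planted antecedent is not a singleton")
    p_lhs = config.core_items[rule.lhs[0]]
    return p_lhs * rule.p_cond + (1 - p_lhs) * p


def expected_metrics(
    config: GeneratorConfig, lhs: tuple[str, ...], rhs: tuple[str, ...]
) -> tuple[float, float, float]:
    """Exact (support, confidence, lift) for a singleton pair under the model.

    Tractable only when lhs and rhs are singleton core items jointly covered
    by at most one planted rule; anything else raises ``ValueError``.
    """
    if len(lhs) != 1 or len(rhs) != 1:
        raise ValueError("no closed form: only singleton lhs/rhs supported")
    a, b = lhs[0], rhs[0]
    if a not in config.core_items or b not in config.core_items:
        raise ValueError("no closed form: items must be core items")
    touching = _rules_touching(config, {a, b})
    if len(touching) > 1:
        raise ValueError("no closed form: overlapping planted rules")
    for r in touching:
        involves_a = a in r.lhs or a in r.rhs
        involves_b = b in r.lhs or b in r.rhs
        if involves_a and involves_b and (len(r.lhs) != 1 or len(r.rhs) != 1):
            raise ValueError("no closed form: planted rule on this pair is not singleton")
    p_b = marginal(config, b)
    rule_ab = [r for r in touching if tuple(r.lhs) == (a,) and b in r.rhs]
    rule_ba = [r for r in touching if tuple(r.lhs) == (b,) and a in r.rhs]
    if rule_ab:
        conf = rule_ab[0].p_cond
    elif rule_ba:
        # dependency runs the other way; P(b | a) via the pair's joint probability
        conf = config.core_items[b] * rule_ba[0].p_cond / marginal(config, a)
    else:
        # a rule touching only one of the two items leaves the pair independent
        conf = p_b
    p_a = marginal(config, a)
    support = p_a * conf
    lift = conf / p_b if p_b > 0 else 0.0
    return support, conf, lift
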