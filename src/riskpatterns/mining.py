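"""Class-association-rule mining for a rare death outcome.

Rules have a fixed consequent (in-hospital death); an antecedent is a
conjunctive pattern of ``variable=level`` items.  Because deaths are rare
(<1% of deliveries), frequency pruning uses *local support* — the pattern's
support within the death class, P(pattern | death) = a/D — rather than plain
support a/N.  Local support is anti-monotone in the antecedent, which is what
licenses Apriori level-wise pruning, and plain support can always be
recovered as local_support * D/N.

Measures for a pattern A with counts (a, m, D, N):

    support        = a / N          P(A and death)
    local support  = a / D          P(A | death)
    confidence     = a / m          P(death | A)
    relative risk  = (a/m) / ((D-a)/(N-m))

``mine_risk_rules`` is the level-wise miner; ``brute_force_rules`` enumerates
every pattern up to the length cap and is the testing oracle.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cohort import Codebook, Dataset, Item, Pattern

__all__ = [
    "MiningError",
    "NoDeathsError",
    "UndefinedMeasureError",
    "MiningParams",
    "RuleStats",
    "Rule",
    "pattern_counts",
    "rule_measures",
    "rule_for_pattern",
    "mine_risk_rules",
    "brute_force_rules",
    "rules_to_json",
    "rules_from_json",
    "save_rules",
    "load_rules",
]


class MiningError(Exception):
    pass


class NoDeathsError(MiningError):
    """Local support is undefined when the dataset has no deaths."""


class UndefinedMeasureError(MiningError):
    """Confidence (m=0) or relative risk (N=m) has no defined value."""


@dataclass(frozen=True)
class MiningParams:
    """Thresholds of one grid point: (min local support, min confidence,
    max antecedent length).  ``max_len`` counts antecedent items only;
    ``max_len=0`` yields an empty rule set."""

    min_local_support: float
    min_confidence: float
    max_len: int

    def __post_init__(self) -> None:
        if not (0.0 < self.min_local_support <= 1.0):
            raise ValueError("min_local_support must be in (0, 1]")
        if not (0.0 < self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_len < 0:
            raise ValueError("max_len must be >= 0")


@dataclass(frozen=True)
class RuleStats:
    """Exact counts and the derived measures of one rule on one dataset."""

    a: int  # matches pattern AND died
    m: int  # matches pattern
    D: int  # total deaths
    N: int  # total records

    def __post_init__(self) -> None:
        if not (0 <= self.a <= min(self.m, self.D) and self.m <= self.N and self.D <= self.N):
            raise ValueError(f"inconsistent counts {(self.a, self.m, self.D, self.N)}")

    @property
    def support(self) -> float:
        return self.a / self.N

    @property
    def local_support(self) -> float:
        if self.D == 0:
            raise NoDeathsError("local support undefined with D=0")
        return self.a / self.D

    @property
    def confidence(self) -> float:
        if self.m == 0:
            raise UndefinedMeasureError("confidence undefined with m=0")
        return self.a / self.m

    @property
    def rr(self) -> float:
        """Relative risk versus patients outside the pattern; +inf when every
        death is inside the pattern (D-a = 0, a > 0)."""
        if self.m == 0:
            raise UndefinedMeasureError("rr undefined with m=0")
        if self.N == self.m:
            raise UndefinedMeasureError("rr undefined with no comparison group")
        baseline = (self.D - self.a) / (self.N - self.m)
        if baseline == 0.0:
            return math.inf if self.a > 0 else math.nan
        return self.confidence / baseline


@dataclass(frozen=True)
class Rule:
    """An antecedent pattern with its stats on a named dataset; the consequent
    is always the death class."""

    pattern: Pattern
    stats: RuleStats
    rr_ci: tuple[float, float] | None = None
    flags: tuple[tuple[str, str], ...] = ()

    def with_flag(self, key: str, value: str) -> "Rule":
        return replace(self, flags=self.flags + ((key, value),))

    def key(self) -> frozenset[Item]:
        return self.pattern.items


def pattern_counts(pattern: Pattern, dataset: Dataset) -> tuple[int, int, int, int]:
    """Exact (a, m, D, N) for a pattern by full vectorised scan."""
    pattern.validate(dataset.codebook)
    mask = dataset.pattern_mask(pattern)
    death = dataset.death_mask
    return (
        int((mask & death).sum()),
        int(mask.sum()),
        int(death.sum()),
        dataset.n,
    )


def rule_measures(counts: tuple[int, int, int, int]) -> RuleStats:
    """Wrap raw counts; derived measures raise on their undefined cases."""
    a, m, D, N = counts
    stats = RuleStats(a, m, D, N)
    # trigger the undefined-measure contracts eagerly
    stats.confidence
    stats.rr
    return stats


def rule_for_pattern(pattern: Pattern, dataset: Dataset) -> Rule:
    return Rule(pattern, rule_measures(pattern_counts(pattern, dataset)))


def _item_order(codebook: Codebook) -> list[Item]:
    return codebook.items()  # already sorted by (variable, level)


def mine_risk_rules(dataset: Dataset, params: MiningParams) -> list[Rule]:
    """Level-wise Apriori over the death-class sub-table.

    Candidates of size k are lexicographic prefix joins of frequent (k-1)
    patterns on the fixed (variable, level) item order, skipping joins that
    would repeat a variable; a candidate is kept only if local support meets
    the threshold (anti-monotone, so subset pruning is sound).  Confidence is
    a final emission filter, never a pruning criterion.  Rules with rr <= 1
    are emitted; risk-direction filtering belongs to the selection stage.
    Patterns matching the whole dataset (m = N, e.g. a constant column) have
    no comparison group and are never emitted.
    Output is sorted by (length, items) and independent of enumeration order.
    """
    D = dataset.n_deaths
    if D == 0:
        raise NoDeathsError("cannot mine risk rules from a cohort with no deaths")
    N = dataset.n
    if params.max_len == 0:
        return []

    death_rows = np.flatnonzero(dataset.death_mask)
    items = _item_order(dataset.codebook)
    # masks restricted to death rows drive frequency; full masks give m
    death_masks = {it: dataset.item_mask(it)[death_rows] for it in items}
    min_a = params.min_local_support * D

    rules: list[Rule] = []

    def emit(pattern_items: tuple[Item, ...], a: int) -> None:
        pattern = Pattern(frozenset(pattern_items))
        m = int(dataset.pattern_mask(pattern).sum())
        if m == N:  # matches everyone: no comparison group, rr undefined
            return
        stats = RuleStats(a, m, D, N)
        if m > 0 and stats.confidence >= params.min_confidence:
            rules.append(Rule(pattern, stats))

    # level 1
    frontier: dict[tuple[Item, ...], np.ndarray] = {}
    for it in items:
        dm = death_masks[it]
        a = int(dm.sum())
        if a >= min_a and a > 0:
            frontier[(it,)] = dm
            emit((it,), a)

    k = 2
    while frontier and k <= params.max_len:
        keys = sorted(frontier)
        next_frontier: dict[tuple[Item, ...], np.ndarray] = {}
        # group by (k-2)-prefix for the lexicographic join
        for _, group in itertools.groupby(keys, key=lambda t: t[:-1]):
            group = list(group)
            for i, left in enumerate(group):
                for right in group[i + 1 :]:
                    last = right[-1]
                    if last.variable in {it.variable for it in left}:
                        continue
                    cand = left + (last,)
                    # all (k-1)-subsets must be frequent
                    if any(
                        cand[:j] + cand[j + 1 :] not in frontier
                        for j in range(len(cand) - 2)
                    ):
                        continue
                    dm = frontier[left] & death_masks[last]
                    a = int(dm.sum())
                    if a >= min_a and a > 0:
                        next_frontier[cand] = dm
                        emit(cand, a)
        frontier = next_frontier
        k += 1

    rules.sort(key=lambda r: (len(r.pattern), r.pattern.sorted_items))
    return rules


def brute_force_rules(
    dataset: Dataset, params: MiningParams, guard: int = 1 << 20
) -> list[Rule]:
    """Testing oracle: enumerate every valid pattern up to ``max_len`` and
    filter by the same thresholds.  Refuses instances whose candidate count
    exceeds ``guard``."""
    D = dataset.n_deaths
    if D == 0:
        raise NoDeathsError("cannot mine risk rules from a cohort with no deaths")
    variables = dataset.codebook.variables
    n_candidates = 0
    for r in range(1, params.max_len + 1):
        for combo in itertools.combinations(variables, r):
            prod = 1
            for v in combo:
                prod *= len(v.levels)
            n_candidates += prod
            if n_candidates > guard:
                raise MiningError(f"candidate count exceeds guard {guard}")

    min_a = params.min_local_support * D
    rules: list[Rule] = []
    for r in range(1, params.max_len + 1):
        for combo in itertools.combinations(variables, r):
            for levels in itertools.product(*(v.levels for v in combo)):
                pattern = Pattern(
                    frozenset(Item(v.name, lev) for v, lev in zip(combo, levels))
                )
                a, m, D_, N = pattern_counts(pattern, dataset)
                if a == 0 or a < min_a or m == 0 or m == N:
                    continue
                stats = RuleStats(a, m, D_, N)
                if stats.confidence >= params.min_confidence:
                    rules.append(Rule(pattern, stats))
    rules.sort(key=lambda r: (len(r.pattern), r.pattern.sorted_items))
    return rules


# -- serialization ---------------------------------------------------------


def _rule_to_dict(rule: Rule) -> dict:
    s = rule.stats
    return {
        "antecedent": [[it.variable, it.level] for it in rule.pattern],
        "counts": {"a": s.a, "m": s.m, "D": s.D, "N": s.N},
        "measures": {
            "support": s.support,
            "local_support": s.local_support,
            "confidence": s.confidence,
            "rr": None if not math.isfinite(s.rr) else s.rr,
        },
        "rr_ci": list(rule.rr_ci) if rule.rr_ci is not None else None,
        "flags": dict(rule.flags),
    }


def _rule_from_dict(d: dict) -> Rule:
    c = d["counts"]
    rr_ci = tuple(d["rr_ci"]) if d.get("rr_ci") else None
    return Rule(
        pattern=Pattern(frozenset(Item(v, l) for v, l in d["antecedent"])),
        stats=RuleStats(c["a"], c["m"], c["D"], c["N"]),
        rr_ci=rr_ci,
        flags=tuple(sorted(d.get("flags", {}).items())),
    )


def rules_to_json(rules: Sequence[Rule]) -> str:
    return json.dumps([_rule_to_dict(r) for r in rules], indent=2)


def rules_from_json(text: str) -> list[Rule]:
    return [_rule_from_dict(d) for d in json.loads(text)]


def save_rules(rules: Sequence[Rule], path: str | Path) -> None:
    Path(path).write_text(rules_to_json(rules) + "\n")


def load_rules(path: str | Path) -> list[Rule]:
    return rules_from_json(Path(path).read_text())
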