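"""Pruning mined rules to a non-redundant set and validating them out of sample.

Redundancy is relative-risk dominance by a strict generalization: a rule is
redundant when some rule with a strictly smaller antecedent already carries at
least the same relative risk, so the extra conditions buy nothing.  Validation
recomputes each surviving rule on a held-out split and retains it only if it
still clears the mining thresholds there and its relative-risk confidence
interval excludes 1.  RR intervals are log-scale Wald (Katz):

    exp( ln RR  +/-  z * sqrt(1/a - 1/m + 1/(D-a) - 1/(N-m)) )
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .cohort import Dataset
from .mining import MiningParams, Rule, RuleStats, pattern_counts

__all__ = [
    "SelectionError",
    "UndefinedCIError",
    "SelectionParams",
    "prune_redundant",
    "rr_confidence_interval",
    "validate_rules",
]


class SelectionError(Exception):
    pass


class UndefinedCIError(SelectionError):
    """A zero cell makes the log-Wald RR interval undefined."""


@dataclass(frozen=True)
class SelectionParams:
    rr_ci_level: float = 0.95
    recheck_thresholds: bool = True
    require_rr_ci_above_one: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.rr_ci_level < 1.0):
            raise ValueError("rr_ci_level must be in (0, 1)")


def prune_redundant(rules: Sequence[Rule]) -> list[Rule]:
    """Drop every rule dominated by a strict generalization in the input.

    A rule R is kept iff no input rule R' satisfies antecedent(R') being a
    strict subset of antecedent(R) with rr(R') >= rr(R).  Idempotent and
    independent of input order; the empty pattern never appears in rule sets,
    so size-1 rules are always kept.
    """
    if not rules:
        return []
    dims = {(r.stats.D, r.stats.N) for r in rules}
    if len(dims) > 1:
        raise SelectionError(f"rules computed on mismatched datasets: {sorted(dims)}")
    kept = []
    for r in rules:
        dominated = any(
            other.pattern.is_strict_subset(r.pattern) and other.stats.rr >= r.stats.rr
            for other in rules
        )
        if not dominated:
            kept.append(r)
    kept.sort(key=lambda r: (len(r.pattern), r.pattern.sorted_items))
    return kept


def rr_confidence_interval(
    counts: tuple[int, int, int, int], level: float = 0.95
) -> tuple[float, float]:
    """Log-scale Wald (Katz) confidence interval for the relative risk."""
    a, m, D, N = counts
    if a < 1 or D - a < 1 or m < 1 or N - m < 1:
        raise UndefinedCIError(f"zero cell in counts {(a, m, D, N)}")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    rr = RuleStats(a, m, D, N).rr
    var = 1.0 / a - 1.0 / m + 1.0 / (D - a) - 1.0 / (N - m)
    var = max(var, 0.0)  # guard FP cancellation at a=m, D-a=N-m
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(var)
    return (rr * math.exp(-half), rr * math.exp(half))


def validate_rules(
    rules: Sequence[Rule],
    validation: Dataset,
    params: MiningParams,
    sel: SelectionParams = SelectionParams(),
) -> list[Rule]:
    """Recompute rules on the validation split and keep the ones that hold up.

    Retention requires (i) validation local support >= min_local_support,
    (ii) validation confidence >= min_confidence (both only when
    ``sel.recheck_thresholds``), and (iii) the lower bound of the validation
    RR interval > 1 (when ``sel.require_rr_ci_above_one``).  Retained rules
    carry their validation stats and interval.
    """
    if validation.n == 0:
        raise SelectionError("empty validation split")
    retained: list[Rule] = []
    for rule in rules:
        counts = pattern_counts(rule.pattern, validation)
        a, m, D, N = counts
        if a == 0 or m == 0 or D == 0:
            continue
        stats = RuleStats(a, m, D, N)
        if sel.recheck_thresholds and (
            stats.local_support < params.min_local_support
            or stats.confidence < params.min_confidence
        ):
            continue
        try:
            ci = rr_confidence_interval(counts, sel.rr_ci_level)
        except UndefinedCIError:
            if sel.require_rr_ci_above_one:
                continue
            ci = None
        if sel.require_rr_ci_above_one and ci is not None and ci[0] <= 1.0:
            continue
        retained.append(Rule(rule.pattern, stats, rr_ci=ci))
    retained.sort(key=lambda r: (len(r.pattern), r.pattern.sorted_items))
    return retained
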