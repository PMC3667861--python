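"""Redundancy pruning, RR confidence intervals, and validation filtering."""

from __future__ import annotations

import numpy as np
import pytest

from riskpatterns.cohort import Item, Pattern
from riskpatterns.mining import MiningParams, Rule, RuleStats, mine_risk_rules
from riskpatterns.selection import (
    SelectionError,
    SelectionParams,
    UndefinedCIError,
    prune_redundant,
    rr_confidence_interval,
    validate_rules,
)

from conftest import make_f1, random_dataset


def mk_rule(items, a, m, D=50, N=1000):
    return Rule(Pattern(frozenset(Item(v, l) for v, l in items)), RuleStats(a, m, D, N))


def rule_with_rr(items, rr, D=100, N=10000):
    """Build a rule whose RR is approximately ``rr`` (m fixed at 100)."""
    # choose a so that (a/m)/((D-a)/(N-m)) ~ rr
    m = 100
    for a in range(1, min(m, D)):
        if RuleStats(a, m, D, N).rr >= rr:
            return Rule(Pattern(frozenset(Item(v, l) for v, l in items)),
                        RuleStats(a, m, D, N))
    raise AssertionError("cannot reach requested rr")


class TestPruneRedundant:
    def test_dominated_specialization_dropped(self):
        general = rule_with_rr([("A", "1")], 5.0)
        special = rule_with_rr([("A", "1"), ("B", "1")], 4.0)
        assert special.stats.rr < general.stats.rr
        kept = prune_redundant([general, special])
        assert [r.pattern.items for r in kept] == [general.pattern.items]

    def test_strictly_better_specialization_kept(self):
        general = rule_with_rr([("A", "1")], 3.0)
        special = rule_with_rr([("A", "1"), ("B", "1")], 6.0)
        assert special.stats.rr > general.stats.rr
        kept = prune_redundant([general, special])
        assert {r.pattern.items for r in kept} == {
            general.pattern.items,
            special.pattern.items,
        }

    def test_matches_quadratic_dominance_oracle(self):
        """Output equals a brute-force filter over all subset pairs on mined
        rule sets from random cohorts."""
        for seed in range(6):
            ds = random_dataset(np.random.default_rng(2000 + seed), 6, 150)
            rules = mine_risk_rules(ds, MiningParams(0.08, 0.05, 3))
            kept = prune_redundant(rules)
            expected = [
                r
                for r in rules
                if not any(
                    o.pattern.items < r.pattern.items and o.stats.rr >= r.stats.rr
                    for o in rules
                )
            ]
            assert {r.pattern.items for r in kept} == {
                r.pattern.items for r in expected
            }

    def test_idempotent_and_order_independent(self):
        rules = [
            rule_with_rr([("A", "1")], 5.0),
            rule_with_rr([("A", "1"), ("B", "1")], 4.0),
            rule_with_rr([("C", "1")], 2.0),
            rule_with_rr([("C", "1"), ("D", "0")], 8.0),
        ]
        once = prune_redundant(rules)
        assert prune_redundant(once) == once
        reversed_out = prune_redundant(list(reversed(rules)))
        assert {r.pattern.items for r in reversed_out} == {
            r.pattern.items for r in once
        }

    def test_size_one_rules_always_survive(self):
        rules = [mk_rule([("A", "1")], 5, 50), mk_rule([("B", "0")], 40, 600)]
        assert len(prune_redundant(rules)) == 2

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(SelectionError):
            prune_redundant(
                [mk_rule([("A", "1")], 5, 50, D=50, N=1000),
                 mk_rule([("B", "1")], 5, 50, D=60, N=1000)]
            )


class TestRRConfidenceInterval:
    def test_hand_computed_log_wald(self):
        """(10,100,20,1000): rr=9, var = 1/10 - 1/100 + 1/10 - 1/900 = 0.18889,
        CI = exp(ln 9 +/- 1.96*sqrt(var)) ~ (3.84, 21.10)."""
        lo, hi = rr_confidence_interval((10, 100, 20, 1000), 0.95)
        assert lo == pytest.approx(3.84, abs=0.01)
        assert hi == pytest.approx(21.10, abs=0.01)

    def test_collapses_to_rr_as_level_shrinks(self):
        rr = RuleStats(10, 100, 20, 1000).rr
        lo, hi = rr_confidence_interval((10, 100, 20, 1000), 1e-12)
        assert lo == pytest.approx(rr, rel=1e-6)
        assert hi == pytest.approx(rr, rel=1e-6)

    def test_equal_risks_interval_contains_one(self):
        # a/m = 0.1 inside, (D-a)/(N-m) = 0.1 outside -> rr = 1
        lo, hi = rr_confidence_interval((10, 100, 100, 1000), 0.95)
        assert lo < 1.0 < hi

    def test_zero_cell_raises(self):
        with pytest.raises(UndefinedCIError):
            rr_confidence_interval((0, 100, 20, 1000), 0.95)
        with pytest.raises(UndefinedCIError):
            rr_confidence_interval((20, 100, 20, 1000), 0.95)

    def test_coverage_calibration(self):
        """95% log-Wald interval covers the true RR in 93-97% of simulated
        2x2 tables (n=2,000 per table)."""
        rng = np.random.default_rng(314159)
        pi, p1, p0, n = 0.3, 0.2, 0.1, 2000
        true_rr = p1 / p0
        covered = total = 0
        for _ in range(1000):
            m = rng.binomial(n, pi)
            a = rng.binomial(m, p1)
            c = rng.binomial(n - m, p0)
            if a < 1 or c < 1 or m < 1 or n - m < 1:
                continue
            lo, hi = rr_confidence_interval((a, m, a + c, n), 0.95)
            total += 1
            covered += lo <= true_rr <= hi
        assert total >= 990
        assert 0.93 <= covered / total <= 0.97


class TestValidateRules:
    def setup_method(self):
        self.f1 = make_f1()
        self.params = MiningParams(0.5, 0.5, 2)

    def test_rule_absent_from_validation_dropped(self):
        # X=1&Y=1 matches one record in F1; a rule on a pattern with no
        # matches in the validation data cannot satisfy the thresholds
        rule = mk_rule([("X", "1"), ("Y", "0")], 1, 4, D=4, N=10)
        survivors = f1_validate = validate_rules([rule], self.f1,
                                                 MiningParams(0.9, 0.9, 2))
        assert survivors == []

    def test_kept_rule_carries_validation_stats_and_ci(self):
        mined = mine_risk_rules(self.f1, self.params)
        kept = validate_rules(
            mined, self.f1, self.params,
            SelectionParams(require_rr_ci_above_one=False),
        )
        y1 = next(r for r in kept if r.pattern.items == frozenset({Item("Y", "1")}))
        assert y1.stats == RuleStats(3, 4, 4, 10)
        assert y1.rr_ci is not None and y1.rr_ci[0] < 4.5 < y1.rr_ci[1]

    def test_ci_lower_bound_rule(self):
        """A genuine risk pattern in a large cohort passes the CI>1 gate; a
        null pattern does not."""
        rng = np.random.default_rng(99)
        ds = random_dataset(rng, 4, 4000)
        # v0 has 3 levels; make a strong synthetic signal on v1=0
        frame = ds.frame.copy()
        sig = frame["v1"] == "0"
        frame["death"] = (np.asarray(sig) & (rng.random(len(frame)) < 0.3)) | (
            ~np.asarray(sig) & (rng.random(len(frame)) < 0.02)
        )
        ds2 = type(ds)(frame, ds.codebook)
        strong = mk_rule([("v1", "0")], *[
            int((np.asarray(sig) & ds2.death_mask).sum()),
            int(np.asarray(sig).sum()),
        ], D=ds2.n_deaths, N=ds2.n)
        weak_var = "v3"
        weak_mask = np.asarray(ds2.frame[weak_var] == "0")
        weak = mk_rule([(weak_var, "0")],
                       int((weak_mask & ds2.death_mask).sum()),
                       int(weak_mask.sum()), D=ds2.n_deaths, N=ds2.n)
        kept = validate_rules(
            [strong, weak], ds2, MiningParams(1e-6, 1e-6, 2), SelectionParams()
        )
        assert strong.pattern.items in {r.pattern.items for r in kept}
        assert weak.pattern.items not in {r.pattern.items for r in kept}

    def test_monotone_in_thresholds(self):
        mined = mine_risk_rules(self.f1, MiningParams(0.25, 0.25, 2))
        sel = SelectionParams(require_rr_ci_above_one=False)
        loose = validate_rules(mined, self.f1, MiningParams(0.25, 0.25, 2), sel)
        tight = validate_rules(mined, self.f1, MiningParams(0.5, 0.5, 2), sel)
        assert {r.pattern.items for r in tight} <= {r.pattern.items for r in loose}

    def test_empty_validation_split_raises(self):
        empty = self.f1.subset(np.array([], dtype=int))
        with pytest.raises(SelectionError):
            validate_rules([], empty, self.params)
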