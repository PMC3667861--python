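"""Union-of-rules classifier, 2x2 evaluation, the parameter grid and ROC-style
selection.

The classifier predicts death for a patient iff at least one retained risk
pattern matches — a plain rule union, no weighting.  Each grid point
(min local support, min confidence, max length) yields one classifier; the
grid of classifiers traces a ROC cloud on the validation split and the
optimal point maximises Youden's J = Se + Sp - 1, with ties broken by lower
misclassification rate, then fewer rules, then grid order.  The test split is
touched exactly once, after selection.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cohort import Dataset, PatientRecord, SizeError, match, split_three
from .mining import MiningParams, Rule, mine_risk_rules
from .selection import SelectionParams, prune_redundant, validate_rules

__all__ = [
    "EvaluationError",
    "UnionClassifier",
    "ConfusionMatrix",
    "GridPoint",
    "classify",
    "confusion_matrix",
    "wald_binomial_ci",
    "default_grid",
    "run_grid",
    "select_optimal",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class UnionClassifier:
    """Predict death iff any retained rule's antecedent matches."""

    rules: tuple[Rule, ...]
    params: MiningParams | None = None

    def predict_mask(self, dataset: Dataset) -> np.ndarray:
        mask = np.zeros(dataset.n, dtype=bool)
        for rule in self.rules:
            mask |= dataset.pattern_mask(rule.pattern)
        return mask


def classify(classifier: UnionClassifier, record: PatientRecord) -> bool:
    if not classifier.rules:
        warnings.warn("classifying with an empty rule set: always negative")
        return False
    return any(match(rule.pattern, record) for rule in classifier.rules)


def wald_binomial_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation interval p +/- z*sqrt(p(1-p)/n), clipped to [0,1]."""
    if n < 1:
        raise EvaluationError("wald_binomial_ci needs n >= 1")
    p = successes / n
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    se_ci: tuple[float, float] | None = None
    sp_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def se(self) -> float:
        if self.tp + self.fn == 0:
            raise EvaluationError("sensitivity undefined: no observed deaths")
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        if self.tn + self.fp == 0:
            raise EvaluationError("specificity undefined: no observed survivors")
        return self.tn / (self.tn + self.fp)

    @property
    def youden(self) -> float:
        return self.se + self.sp - 1.0

    @property
    def misclassification(self) -> float:
        return (self.fn + self.fp) / self.n

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, fp: int, tn: int, ci_level: float = 0.95
    ) -> "ConfusionMatrix":
        cm = cls(tp, fn, fp, tn)
        se_ci = wald_binomial_ci(tp, tp + fn, ci_level) if tp + fn > 0 else None
        sp_ci = wald_binomial_ci(tn, tn + fp, ci_level) if tn + fp > 0 else None
        return replace(cm, se_ci=se_ci, sp_ci=sp_ci)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "se": self.se if self.tp + self.fn else None,
            "sp": self.sp if self.tn + self.fp else None,
            "se_ci": list(self.se_ci) if self.se_ci else None,
            "sp_ci": list(self.sp_ci) if self.sp_ci else None,
        }


def confusion_matrix(
    classifier: UnionClassifier, dataset: Dataset, ci_level: float = 0.95
) -> ConfusionMatrix:
    """Exact 2x2 counts of the rule union against observed vital status."""
    if dataset.n == 0:
        raise EvaluationError("empty dataset")
    pred = classifier.predict_mask(dataset)
    obs = dataset.death_mask
    tp = int((pred & obs).sum())
    fn = int((~pred & obs).sum())
    fp = int((pred & ~obs).sum())
    tn = int((~pred & ~obs).sum())
    return ConfusionMatrix.from_counts(tp, fn, fp, tn, ci_level)


def default_grid() -> list[MiningParams]:
    """The 18-point training grid: local support {9,10,15}% x confidence
    {2.1,2.8,3.5}% x max length {3,4}."""
    return [
        MiningParams(ls, conf, ml)
        for ls, conf, ml in itertools.product(
            (0.09, 0.10, 0.15), (0.021, 0.028, 0.035), (3, 4)
        )
    ]


@dataclass(frozen=True)
class GridPoint:
    params: MiningParams
    n_mined: int = 0
    n_pruned: int = 0
    n_validated: int = 0
    classifier: UnionClassifier | None = None
    cm_validation: ConfusionMatrix | None = None
    cm_test: ConfusionMatrix | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def run_grid(
    train: Dataset,
    validation: Dataset,
    grid: Sequence[MiningParams] | None = None,
    sel: SelectionParams = SelectionParams(),
    ci_level: float = 0.95,
) -> list[GridPoint]:
    """Mine -> prune -> validate -> evaluate on validation, per grid point.

    A failing grid point is flagged and does not abort the rest of the grid.
    """
    if train.n == 0 or validation.n == 0:
        raise EvaluationError("empty split")
    if grid is None:
        grid = default_grid()
    points: list[GridPoint] = []
    for params in grid:
        try:
            mined = mine_risk_rules(train, params)
            pruned = prune_redundant(mined)
            validated = validate_rules(pruned, validation, params, sel)
            clf = UnionClassifier(tuple(validated), params)
            cm = confusion_matrix(clf, validation, ci_level)
            point = GridPoint(
                params=params,
                n_mined=len(mined),
                n_pruned=len(pruned),
                n_validated=len(validated),
                classifier=clf,
                cm_validation=cm,
            )
            logger.info(
                "grid point ls>=%.3f conf>=%.3f len<=%d: mined=%d pruned=%d "
                "validated=%d se=%.3f sp=%.3f",
                params.min_local_support,
                params.min_confidence,
                params.max_len,
                len(mined),
                len(pruned),
                len(validated),
                cm.se,
                cm.sp,
            )
        except Exception as exc:  # flagged, grid continues
            logger.warning("grid point %s failed: %s", params, exc)
            point = GridPoint(params=params, error=f"{type(exc).__name__}: {exc}")
        points.append(point)
    return points


def select_optimal(points: Sequence[GridPoint]) -> GridPoint:
    """Pick the grid point with maximal validation Youden's J; ties go to the
    lower misclassification rate, then the smaller rule set, then grid order."""
    live = [
        (i, p) for i, p in enumerate(points) if not p.failed and p.cm_validation
    ]
    if not live:
        raise EvaluationError("all grid points failed")
    return min(
        live,
        key=lambda ip: (
            -ip[1].cm_validation.youden,
            ip[1].cm_validation.misclassification,
            ip[1].n_validated,
            ip[0],
        ),
    )[1]


@dataclass(frozen=True)
class PipelineResult:
    train: Dataset
    validation: Dataset
    test: Dataset
    points: list[GridPoint]
    selected: GridPoint


def run_pipeline(
    dataset: Dataset,
    seed: int,
    grid: Sequence[MiningParams] | None = None,
    sel: SelectionParams = SelectionParams(),
    ci_level: float = 0.95,
) -> PipelineResult:
    """Split -> grid on train/validation -> select -> single test evaluation.

    The test split is evaluated exactly once, for the selected point only
    (leakage guard: no other stage ever sees it).
    """
    train, validation, test = split_three(dataset, seed)
    logger.info(
        "split N=%d into %d/%d/%d (deaths %d/%d/%d)",
        dataset.n, train.n, validation.n, test.n,
        train.n_deaths, validation.n_deaths, test.n_deaths,
    )
    points = run_grid(train, validation, grid, sel, ci_level)
    selected = select_optimal(points)
    assert selected.cm_test is None  # leakage guard: test untouched until here
    cm_test = confusion_matrix(selected.classifier, test, ci_level)
    selected = replace(selected, cm_test=cm_test)
    logger.info(
        "selected ls>=%.3f conf>=%.3f len<=%d with %d rules: test se=%.4f sp=%.4f",
        selected.params.min_local_support,
        selected.params.min_confidence,
        selected.params.max_len,
        selected.n_validated,
        cm_test.se,
        cm_test.sp,
    )
    return PipelineResult(train, validation, test, points, selected)
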