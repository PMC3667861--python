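"""Human-readable outputs: pattern summary tables, prefix-tree views of the
rule set, and per-stratum cohort descriptions.

Percentages in *formatted* reports round half-up to two decimals; DataFrames
and JSON artifacts keep full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Dataset, Item, Pattern
from .mining import Rule, RuleStats, pattern_counts
from .selection import UndefinedCIError, rr_confidence_interval

__all__ = [
    "round_half_up",
    "pattern_summary",
    "format_pattern_summary",
    "TreeNode",
    "RuleTree",
    "rules_to_tree",
    "tree_to_text",
    "tree_to_dot",
    "descriptive_summary",
]


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), for report columns only."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pattern_summary(
    rules: Sequence[Rule], dataset: Dataset, ci_level: float = 0.95
) -> pd.DataFrame:
    """One row per rule, recomputed on ``dataset``: pattern prevalence among
    all patients (m/N %), among deaths (a/D %), and RR with its CI; sorted by
    RR descending.  Full precision; see :func:`format_pattern_summary` for
    the rounded view."""
    rows = []
    for rule in rules:
        a, m, D, N = pattern_counts(rule.pattern, dataset)
        stats = RuleStats(a, m, D, N)
        try:
            lo, hi = rr_confidence_interval((a, m, D, N), ci_level)
        except UndefinedCIError:
            lo = hi = np.nan
        rows.append(
            {
                "pattern": str(rule.pattern),
                "prevalence_all_pct": 100.0 * m / N if N else np.nan,
                "prevalence_deaths_pct": 100.0 * a / D if D else np.nan,
                "rr": stats.rr if m and N > m else np.nan,
                "rr_ci_low": lo,
                "rr_ci_high": hi,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pattern",
            "prevalence_all_pct",
            "prevalence_deaths_pct",
            "rr",
            "rr_ci_low",
            "rr_ci_high",
        ],
    )
    if len(table):
        table = table.sort_values("rr", ascending=False, kind="stable").reset_index(
            drop=True
        )
    return table


def format_pattern_summary(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        if col != "pattern":
            out[col] = [
                round_half_up(v) if np.isfinite(v) else v for v in out[col]
            ]
    return out


# -- rule tree ---------------------------------------------------------------


@dataclass
class TreeNode:
    item: Item | None  # None at the root
    children: list["TreeNode"] = field(default_factory=list)
    rr: float | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RuleTree:
    """Prefix tree of rule antecedents.

    Each rule terminates at the node carrying its relative risk (``rr`` set);
    a terminal may be internal when one rule's antecedent is a prefix of
    another's, so the number of terminals — not of graph leaves — equals the
    rule count."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        """Rule-terminal nodes (rr annotated), in depth-first order."""
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.rr is not None:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def paths(self) -> list[tuple[Item, ...]]:
        out: list[tuple[Item, ...]] = []

        def walk(node: TreeNode, prefix: tuple[Item, ...]) -> None:
            here = prefix + ((node.item,) if node.item is not None else ())
            if node.rr is not None:
                out.append(here)
            for c in node.children:
                walk(c, here)

        walk(self.root, ())
        return out


def rules_to_tree(rules: Sequence[Rule]) -> RuleTree:
    """Merge antecedents into a prefix tree.

    Items inside each antecedent are ordered by descending frequency of the
    item across all rules (ties lexicographic), so heavily shared conditions
    sit near the root.  Identical antecedents are merged with a warning (the
    first rule's RR is kept).
    """
    if not rules:
        raise ValueError("rules_to_tree needs a non-empty rule set")
    freq: dict[Item, int] = {}
    for rule in rules:
        for it in rule.pattern:
            freq[it] = freq.get(it, 0) + 1

    def order(pattern: Pattern) -> tuple[Item, ...]:
        return tuple(
            sorted(pattern.items, key=lambda it: (-freq[it], it.variable, it.level))
        )

    root = TreeNode(item=None)
    seen: set[frozenset[Item]] = set()
    for rule in rules:
        key = rule.pattern.items
        if key in seen:
            warnings.warn(f"duplicate antecedent merged: {rule.pattern}")
            continue
        seen.add(key)
        node = root
        for it in order(rule.pattern):
            for child in node.children:
                if child.item == it:
                    node = child
                    break
            else:
                child = TreeNode(item=it)
                node.children.append(child)
                node = child
        node.rr = rule.stats.rr
    return RuleTree(root)


def tree_to_text(tree: RuleTree) -> str:
    lines: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        if node.item is not None:
            label = str(node.item)
            if node.rr is not None:
                label += f"  [RR {node.rr:.2f}]"
            lines.append("  " * (depth - 1) + label)
        for c in node.children:
            walk(c, depth + 1)

    walk(tree.root, 0)
    return "\n".join(lines) + "\n"


def tree_to_dot(tree: RuleTree) -> str:
    """Graphviz DOT export of the tree structure (layout left to Graphviz)."""
    lines = ["digraph risk_patterns {", '  node [shape=box];', '  n0 [label="cohort"];']
    counter = [0]

    def walk(node: TreeNode, parent: str) -> None:
        for c in node.children:
            counter[0] += 1
            name = f"n{counter[0]}"
            label = str(c.item)
            if c.rr is not None:
                label += f"\\nRR {c.rr:.2f}"
            lines.append(f'  {name} [label="{label}"];')
            lines.append(f"  {parent} -> {name};")
            walk(c, name)

    walk(tree.root, "n0")
    lines.append("}")
    return "\n".join(lines) + "\n"


def descriptive_summary(
    dataset: Dataset, prevalence_items: Sequence[Item] = ()
) -> pd.DataFrame:
    """Per-stratum N and in-hospital mortality (%), with an overall row and
    optional prevalence columns for chosen items."""
    death = dataset.death_mask
    strata = dataset.frame["stratum"]
    rows = []
    order = list(dict.fromkeys(strata))  # first-appearance order
    for label in order + ["__overall__"]:
        mask = np.ones(dataset.n, dtype=bool) if label == "__overall__" else (
            strata == label
        ).to_numpy()
        n = int(mask.sum())
        d = int((mask & death).sum())
        row = {
            "stratum": "overall" if label == "__overall__" else label,
            "n": n,
            "deaths": d,
            "mortality_pct": 100.0 * d / n if n else 0.0,
        }
        for it in prevalence_items:
            im = dataset.item_mask(it)
            row[f"{it}_pct"] = 100.0 * int((mask & im).sum()) / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
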