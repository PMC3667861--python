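"""Patient-level cohort model.

A cohort is a table of deliveries: one row per patient, a small set of
categorical covariates defined by a :class:`Codebook`, a hospital stratum
label, and a binary in-hospital death outcome.  Raw numeric fields (age,
parity, number of antenatal visits) are discretised into clinical levels at
load time via the codebook's derivation rules; everything downstream operates
on ``variable=level`` items and conjunctive patterns of them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortError",
    "SchemaError",
    "LevelError",
    "IntegrityError",
    "SizeError",
    "Derivation",
    "VariableDef",
    "Codebook",
    "Item",
    "Pattern",
    "PatientRecord",
    "Dataset",
    "load_dataset",
    "match",
    "split_three",
    "MISSING_LEVEL",
]

#: Level assigned to missing raw values when a variable allows them.  The
#: missing level is never part of the minable item universe.
MISSING_LEVEL = "missing"


class CohortError(Exception):
    """Base class for cohort-model errors."""


class SchemaError(CohortError):
    """A required column is absent or the file layout is wrong."""


class LevelError(CohortError):
    """A value is outside the allowed levels after derivation."""


class IntegrityError(CohortError):
    """Duplicate record identifiers."""


class SizeError(CohortError):
    """A dataset is too small for the requested operation."""


@dataclass(frozen=True)
class Derivation:
    """Threshold binning of a raw numeric field into ordered levels.

    ``breaks`` are ascending cut points; a value v maps to level index
    ``#{b in breaks : b <= v}``, i.e. bins are left-closed on the break.
    With breaks (35,) and levels ("<35", ">=35"), 35 maps to ">=35".
    """

    breaks: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.breaks or list(self.breaks) != sorted(self.breaks):
            raise ValueError("derivation breaks must be non-empty and ascending")

    def level_index(self, value: float) -> int:
        return int(np.searchsorted(np.asarray(self.breaks), value, side="right"))


@dataclass(frozen=True)
class VariableDef:
    name: str
    levels: tuple[str, ...]
    derive: Derivation | None = None
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"variable {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate levels")
        if self.derive is not None and len(self.derive.breaks) != len(self.levels) - 1:
            raise ValueError(
                f"variable {self.name!r}: {len(self.levels)} levels need "
                f"{len(self.levels) - 1} derivation breaks"
            )
        if self.allow_missing and MISSING_LEVEL in self.levels:
            raise ValueError(f"variable {self.name!r}: reserve {MISSING_LEVEL!r}")

    @property
    def effective_levels(self) -> tuple[str, ...]:
        """Allowed stored levels, including the missing level if permitted."""
        if self.allow_missing:
            return self.levels + (MISSING_LEVEL,)
        return self.levels


@dataclass(frozen=True)
class Codebook:
    """Variable definitions, derivation rules and the outcome name."""

    variables: tuple[VariableDef, ...]
    outcome: str = "death"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("codebook variable names must be unique")
        if self.outcome in names:
            raise ValueError("outcome name collides with a covariate")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def items(self) -> list["Item"]:
        """The minable item universe: every (variable, level) pair, in the
        fixed (variable name, level) order used by the miner.  Missing levels
        are excluded."""
        out = [Item(v.name, lev) for v in self.variables for lev in v.levels]
        out.sort(key=lambda it: (it.variable, it.level))
        return out

    def coerce(self, name: str, raw: str, row: int) -> str:
        """Map a raw CSV string to a level (1-based ``row`` for messages)."""
        v = self[name]
        raw = raw.strip()
        if raw == "" or raw.lower() in {"na", "nan"}:
            if v.allow_missing:
                return MISSING_LEVEL
            raise LevelError(f"row {row}, variable {name!r}: missing value")
        if raw in v.effective_levels:
            return raw
        if v.derive is not None:
            try:
                num = float(raw)
            except ValueError:
                raise LevelError(
                    f"row {row}, variable {name!r}: {raw!r} is neither a level "
                    "nor numeric"
                ) from None
            return v.levels[v.derive.level_index(num)]
        raise LevelError(
            f"row {row}, variable {name!r}: {raw!r} not in levels {v.levels}"
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "variables": [
                {
                    "name": v.name,
                    "levels": list(v.levels),
                    **(
                        {"breaks": list(v.derive.breaks)}
                        if v.derive is not None
                        else {}
                    ),
                    **({"allow_missing": True} if v.allow_missing else {}),
                }
                for v in self.variables
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        variables = tuple(
            VariableDef(
                name=v["name"],
                levels=tuple(v["levels"]),
                derive=Derivation(tuple(v["breaks"])) if "breaks" in v else None,
                allow_missing=bool(v.get("allow_missing", False)),
            )
            for v in d["variables"]
        )
        return cls(variables=variables, outcome=d.get("outcome", "death"))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True, order=True)
class Item:
    """A single ``variable=level`` condition."""

    variable: str
    level: str

    def __str__(self) -> str:
        return f"{self.variable}={self.level}"


@dataclass(frozen=True)
class Pattern:
    """A conjunction of items, at most one per variable.

    The empty pattern matches every record (vacuous conjunction); rule sets
    never contain it, but measures are defined for it.
    """

    items: frozenset[Item] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))
        variables = [it.variable for it in self.items]
        if len(set(variables)) != len(variables):
            raise ValueError("pattern repeats a variable")

    @classmethod
    def of(cls, *pairs: tuple[str, str]) -> "Pattern":
        return cls(frozenset(Item(v, l) for v, l in pairs))

    @property
    def sorted_items(self) -> tuple[Item, ...]:
        return tuple(sorted(self.items))

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self.sorted_items)

    def is_strict_subset(self, other: "Pattern") -> bool:
        return self.items < other.items

    def validate(self, codebook: Codebook) -> None:
        for it in self.items:
            if it.variable not in codebook:
                raise LevelError(f"unknown variable {it.variable!r}")
            if it.level not in codebook[it.variable].effective_levels:
                raise LevelError(f"invalid level {it!s}")

    def __str__(self) -> str:
        return "{" + ", ".join(str(it) for it in self.sorted_items) + "}"


@dataclass(frozen=True)
class PatientRecord:
    record_id: str
    stratum: str
    attributes: Mapping[str, str]
    death: bool


class Dataset:
    """An ordered cohort with its codebook.

    Backed by a :class:`pandas.DataFrame` with columns ``record_id``,
    ``stratum``, one level-valued column per codebook variable, and a boolean
    ``death`` column named after the codebook outcome.  Item masks are cached
    boolean arrays so pattern counting is a handful of vectorised ANDs.
    """

    def __init__(self, frame: pd.DataFrame, codebook: Codebook):
        required = ["record_id", "stratum", *codebook.names, codebook.outcome]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if frame["record_id"].duplicated().any():
            dup = frame["record_id"][frame["record_id"].duplicated()].iloc[0]
            raise IntegrityError(f"duplicate record_id {dup!r}")
        self.frame = frame.reset_index(drop=True)
        self.codebook = codebook
        self._mask_cache: dict[Item, np.ndarray] = {}

    # -- basic facts -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def death_mask(self) -> np.ndarray:
        return self.frame[self.codebook.outcome].to_numpy(dtype=bool)

    @property
    def n_deaths(self) -> int:
        return int(self.death_mask.sum())

    # -- masks -------------------------------------------------------------

    def item_mask(self, item: Item) -> np.ndarray:
        cached = self._mask_cache.get(item)
        if cached is None:
            if item.variable not in self.codebook:
                raise LevelError(f"unknown variable {item.variable!r}")
            cached = (self.frame[item.variable] == item.level).to_numpy()
            self._mask_cache[item] = cached
        return cached

    def pattern_mask(self, pattern: Pattern) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        for item in pattern:
            mask = mask & self.item_mask(item)
        return mask

    # -- record access -----------------------------------------------------

    def record(self, i: int) -> PatientRecord:
        row = self.frame.iloc[i]
        return PatientRecord(
            record_id=str(row["record_id"]),
            stratum=str(row["stratum"]),
            attributes={name: row[name] for name in self.codebook.names},
            death=bool(row[self.codebook.outcome]),
        )

    def records(self) -> Iterator[PatientRecord]:
        return (self.record(i) for i in range(self.n))

    @classmethod
    def from_records(
        cls, records: Sequence[PatientRecord], codebook: Codebook
    ) -> "Dataset":
        rows = [
            {
                "record_id": r.record_id,
                "stratum": r.stratum,
                **{name: r.attributes[name] for name in codebook.names},
                codebook.outcome: bool(r.death),
            }
            for r in records
        ]
        frame = pd.DataFrame(
            rows, columns=["record_id", "stratum", *codebook.names, codebook.outcome]
        )
        return cls(frame, codebook)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out[self.codebook.outcome] = out[self.codebook.outcome].astype(int)
        out.to_csv(path, index=False)

    def subset(self, indices: np.ndarray) -> "Dataset":
        return Dataset(self.frame.iloc[indices].reset_index(drop=True), self.codebook)


def load_dataset(
    path: str | Path,
    codebook: Codebook,
    exclusion_columns: Sequence[str] | None = None,
) -> Dataset:
    """Read a cohort CSV, deriving raw numeric fields into codebook levels.

    ``exclusion_columns`` optionally names boolean (0/1) columns; rows with a
    1 in any of them are dropped before validation (upstream exclusions such
    as death before delivery or transfer out).  No exclusion is applied by
    default.  Row numbers in error messages are 1-based data rows.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, na_filter=False)
    required = ["record_id", "stratum", *codebook.names, codebook.outcome]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    if exclusion_columns:
        absent = [c for c in exclusion_columns if c not in frame.columns]
        if absent:
            raise SchemaError(f"missing exclusion columns: {absent}")
        keep = np.ones(len(frame), dtype=bool)
        for c in exclusion_columns:
            keep &= frame[c].str.strip() != "1"
        frame = frame[keep].reset_index(drop=True)

    if frame["record_id"].duplicated().any():
        dup = frame["record_id"][frame["record_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate record_id {dup!r}")

    out = {"record_id": frame["record_id"], "stratum": frame["stratum"]}
    for name in codebook.names:
        raw = frame[name].tolist()
        out[name] = [codebook.coerce(name, val, row=i + 1) for i, val in enumerate(raw)]

    outcome_raw = frame[codebook.outcome].str.strip()
    bad = ~outcome_raw.isin(["0", "1"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise LevelError(
            f"row {row}, outcome {codebook.outcome!r}: "
            f"{outcome_raw.iloc[row - 1]!r} is not 0/1"
        )
    out[codebook.outcome] = (outcome_raw == "1").to_numpy()
    return Dataset(pd.DataFrame(out), codebook)


def match(pattern: Pattern, record: PatientRecord, codebook: Codebook | None = None) -> bool:
    """True iff every item of ``pattern`` holds exactly in ``record``."""
    if codebook is not None:
        pattern.validate(codebook)
    for item in pattern.items:
        if item.variable not in record.attributes:
            raise LevelError(f"record lacks variable {item.variable!r}")
        if record.attributes[item.variable] != item.level:
            return False
    return True


def split_three(dataset: Dataset, seed: int) -> tuple[Dataset, Dataset, Dataset]:
    """Random three-way partition into training / validation / test.

    Part sizes differ by at most one; when N is not divisible by 3 the
    earlier parts receive the extra records (N=89,518 gives
    29,840 / 29,839 / 29,839).  Simple random split, unstratified; records
    inside each part keep their original cohort order.  Deterministic for a
    given seed.
    """
    n = dataset.n
    if n < 3:
        raise SizeError(f"need at least 3 records to split, got {n}")
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    perm = np.random.default_rng(seed).permutation(n)
    parts = []
    start = 0
    for size in sizes:
        idx = np.sort(perm[start : start + size])
        parts.append(dataset.subset(idx))
        start += size
    return parts[0], parts[1], parts[2]
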