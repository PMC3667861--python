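"""Shared fixtures.

F1 is the canonical hand-checkable cohort used across the suite: 10 records,
two binary variables, deaths = records 1-4, X=1 for {1,2,5,6,7}, Y=1 for
{1,3,4,8} (1-based ids).  All expected counts quoted in tests were obtained
by manual enumeration of this table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riskpatterns.cohort import Codebook, Dataset, VariableDef


def make_f1() -> Dataset:
    x_ones = {1, 2, 5, 6, 7}
    y_ones = {1, 3, 4, 8}
    deaths = {1, 2, 3, 4}
    codebook = Codebook(
        variables=(
            VariableDef("X", ("0", "1")),
            VariableDef("Y", ("0", "1")),
        )
    )
    frame = pd.DataFrame(
        {
            "record_id": [f"p{i}" for i in range(1, 11)],
            "stratum": ["s1"] * 10,
            "X": ["1" if i in x_ones else "0" for i in range(1, 11)],
            "Y": ["1" if i in y_ones else "0" for i in range(1, 11)],
            "death": [i in deaths for i in range(1, 11)],
        }
    )
    return Dataset(frame, codebook)


@pytest.fixture
def f1() -> Dataset:
    return make_f1()


def random_dataset(
    rng: np.random.Generator, n_vars: int = 8, n_records: int = 200
) -> Dataset:
    """Small random cohorts for oracle-agreement property tests: binary and
    ternary variables with random prevalences, ~15% death rate so every
    measure is well populated."""
    variables = []
    columns = {}
    for j in range(n_vars):
        n_levels = 2 if j % 3 else 3
        levels = tuple(str(k) for k in range(n_levels))
        variables.append(VariableDef(f"v{j}", levels))
        probs = rng.dirichlet(np.ones(n_levels))
        columns[f"v{j}"] = rng.choice(levels, size=n_records, p=probs)
    codebook = Codebook(variables=tuple(variables))
    frame = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n_records)],
            "stratum": ["s"] * n_records,
            **columns,
            "death": rng.random(n_records) < 0.15,
        }
    )
    if not frame["death"].any():
        frame.loc[0, "death"] = True
    return Dataset(frame, codebook)
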