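"""Shared fixtures: a small hand-checkable point table and case builders."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from gpospom import (
    AgeBand,
    CaseRecord,
    ComorbidityGroup,
    PointTable,
    RiskMap,
    SurgeryGroup,
    synthetic_demo_risk_map,
    synthetic_demo_table,
)

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_table() -> PointTable:
    """3 age bands x 2 comorbidities x 2 surgeries; max attainable 8+4+2+9 = 23."""
    return PointTable(
        age_bands=(
            AgeBand(18, 59, 0),
            AgeBand(60, 74, 5),
            AgeBand(75, None, 8),
        ),
        comorbidities=(
            ComorbidityGroup("heart failure", ("I50",), 4),
            ComorbidityGroup("diabetes", ("E11",), 2),
        ),
        surgeries=(
            SurgeryGroup("hip replacement", ("5-82",), 6),
            SurgeryGroup("cardiac surgery", ("5-35",), 9),
        ),
        version="toy",
    )


@pytest.fixture(scope="session")
def demo_table() -> PointTable:
    return synthetic_demo_table()


@pytest.fixture(scope="session")
def demo_link() -> RiskMap:
    return synthetic_demo_risk_map()


def make_case(
    case_id: str = "c1",
    age: int | None = 50,
    sex: str = "female",
    icd: list[str] | None = None,
    ops: list[tuple[str, dt.date | None]] | None = None,
    discharge_reason: str | None = "01",
) -> CaseRecord:
    return CaseRecord(
        case_id=case_id,
        age=age,
        sex=sex,
        icd_codes=icd or [],
        procedures=ops or [],
        discharge_reason=discharge_reason,
    )


def random_toy_case(rng: np.random.Generator, table: PointTable, case_id: str) -> CaseRecord:
    """A random case against ``table``: random age, a random mix of matching
    and non-matching codes, possibly no index procedure."""
    icd_pool = [p for g in table.comorbidities for p in g.icd_prefixes] + ["Z999", "A00"]
    ops_pool = [p for g in table.surgeries for p in g.ops_prefixes] + ["1-999"]
    icd = list(rng.choice(icd_pool, size=rng.integers(0, 4), replace=True))
    n_ops = int(rng.integers(0, 3))
    ops = []
    for _ in range(n_ops):
        code = str(rng.choice(ops_pool))
        date = None if rng.random() < 0.5 else dt.date(2017, 1, int(rng.integers(1, 28)))
        ops.append((code, date))
    return CaseRecord(
        case_id=case_id,
        age=int(rng.integers(18, 100)),
        sex="female" if rng.random() < 0.5 else "male",
        icd_codes=icd,
        procedures=ops,
        discharge_reason="07" if rng.random() < 0.1 else "01",
    )
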