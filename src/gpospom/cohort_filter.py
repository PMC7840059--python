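"""Eligibility cascade: sequential attrition accounting for a case registry.

Exclusions are applied in a fixed order — (1) no index procedure relevant to
the score, (2) patient under the minimum age, (3) incomplete record — and
every input case is counted in exactly one bucket, so the flow-chart counts
always reconcile with the input total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .registry_io import CaseRecord
from .score_table import PointTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttritionReport:
    """Counts of the sequential exclusion steps; a partition of the input."""

    n_input: int
    n_no_index_procedure: int
    n_under_18: int
    n_incomplete: int
    n_included: int

    def __post_init__(self):
        parts = (self.n_no_index_procedure, self.n_under_18, self.n_incomplete, self.n_included)
        if any(c < 0 for c in (self.n_input, *parts)) or sum(parts) != self.n_input:
            raise ValueError(f"attrition counts do not partition the input: {self}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_no_index_procedure": self.n_no_index_procedure,
            "n_under_18": self.n_under_18,
            "n_incomplete": self.n_incomplete,
            "n_included": self.n_included,
        }


def has_index_procedure(case: CaseRecord, table: PointTable) -> bool:
    """True iff any procedure code matches any surgery-group prefix."""
    prefixes = tuple(p for g in table.surgeries for p in g.ops_prefixes)
    if not prefixes:
        return False
    return any(code.startswith(prefixes) for code, _ in case.procedures)


def is_complete(case: CaseRecord) -> bool:
    """All score variables attainable: age and discharge disposition present.

    An *empty* diagnosis list is complete — absence of coded comorbidity is
    informative (scores zero comorbidity points), not missing data.
    """
    return case.age is not None and case.discharge_reason is not None


def apply_eligibility(
    cases: Sequence[CaseRecord],
    table: PointTable,
    min_age: int = 18,
) -> tuple[list[CaseRecord], AttritionReport]:
    """Partition cases into included / excluded buckets, sequentially.

    A case failing several criteria is counted only in the first failing
    bucket.  A case whose age is missing cannot be asserted under-age and
    falls through to the incompleteness check.
    """
    prefixes = tuple(p for g in table.surgeries for p in g.ops_prefixes)
    included: list[CaseRecord] = []
    n_no_index = n_minor = n_incomplete = 0
    for case in cases:
        if not (prefixes and any(code.startswith(prefixes) for code, _ in case.procedures)):
            n_no_index += 1
        elif case.age is not None and case.age < min_age:
            n_minor += 1
        elif not is_complete(case):
            n_incomplete += 1
        else:
            included.append(case)
    report = AttritionReport(
        n_input=len(cases),
        n_no_index_procedure=n_no_index,
        n_under_18=n_minor,
        n_incomplete=n_incomplete,
        n_included=len(included),
    )
    log.info(
        "eligibility: %d input, %d without index procedure, %d under %d, "
        "%d incomplete, %d included",
        report.n_input, report.n_no_index_procedure, report.n_under_18,
        min_age, report.n_incomplete, report.n_included,
    )
    return included, report
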