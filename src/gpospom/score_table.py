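"""Point-table domain model for the POSPOM family of preoperative risk scores.

The POSPOM (Preoperative Score to Predict Postoperative Mortality, Le Manach
et al. 2016) is an additive integer score: one contribution from the patient's
age band, one from each of (typically 15) comorbidity groups defined by ICD-10
code prefixes, and one from the index-surgery category defined by procedure
code prefixes (OPS in the German adaptation).  This module holds the score
*definition* — the point table — together with its config format, validation,
and the score→probability risk map used for calibration analyses.

The published point values are deliberately not hard-coded: a table is loaded
from YAML/JSON supplied by the user (a template with the canonical group names
ships in ``gpospom/data``), so transcription from the original publication
remains the user's auditable step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

#: Sentinel for an open-ended upper age bound ("86 and older").
OPEN_END = None


class PointTableError(ValueError):
    """Raised when a point table or risk map fails structural validation."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid point table: " + "; ".join(self.violations))


def normalize_code(code: str) -> str:
    """Normalize an ICD-10 or OPS code: uppercase, strip dots and whitespace.

    ``"I50.1" -> "I501"``; hyphens (OPS chapter separators, ``"5-511"``) are
    kept.  Idempotent by construction.
    """
    return "".join(code.split()).replace(".", "").upper()


@dataclass(frozen=True)
class AgeBand:
    """One age stratum of the score, inclusive on both ends.

    ``upper_age`` is ``None`` for the open-ended top band.
    """

    lower_age: int
    upper_age: int | None
    points: int

    def contains(self, age: int) -> bool:
        if self.upper_age is None:
            return age >= self.lower_age
        return self.lower_age <= age <= self.upper_age


@dataclass(frozen=True)
class ComorbidityGroup:
    """A comorbidity defined by ICD-10 prefixes; scores at most once per case."""

    name: str
    icd_prefixes: tuple[str, ...]
    points: int

    def matches(self, codes: Iterable[str]) -> bool:
        return any(code.startswith(self.icd_prefixes) for code in codes) if self.icd_prefixes else False


@dataclass(frozen=True)
class SurgeryGroup:
    """An index-surgery category defined by OPS prefixes."""

    name: str
    ops_prefixes: tuple[str, ...]
    points: int

    def matches_code(self, code: str) -> bool:
        return bool(self.ops_prefixes) and code.startswith(self.ops_prefixes)


@dataclass(frozen=True)
class PointTable:
    """The full score definition: age bands, comorbidities, surgeries."""

    age_bands: tuple[AgeBand, ...]
    comorbidities: tuple[ComorbidityGroup, ...]
    surgeries: tuple[SurgeryGroup, ...]
    version: str = ""

    @property
    def max_attainable_score(self) -> int:
        """Upper bound on any case's score: max age + all comorbidities + max surgery."""
        max_age = max((b.points for b in self.age_bands), default=0)
        max_surg = max((g.points for g in self.surgeries), default=0)
        return max_age + sum(g.points for g in self.comorbidities) + max_surg

    def age_band_for(self, age: int) -> AgeBand:
        for band in self.age_bands:
            if band.contains(age):
                return band
        raise LookupError(f"no age band contains age {age}")


@dataclass(frozen=True)
class RiskMap:
    """Score → predicted in-hospital mortality probability.

    Two modes: ``table`` (an explicit per-score lookup, as published for the
    original derivation cohort) or ``logistic`` (inverse-logit of
    ``intercept + slope * score``).
    """

    mode: str  # "table" | "logistic"
    table: Mapping[int, float] | None = None
    intercept: float | None = None
    slope: float | None = None

    def __post_init__(self):
        if self.mode not in ("table", "logistic"):
            raise PointTableError([f"risk map mode must be 'table' or 'logistic', got {self.mode!r}"])
        if self.mode == "table":
            if not self.table:
                raise PointTableError(["table-mode risk map requires a non-empty score->probability table"])
            bad = [s for s, p in self.table.items() if not 0.0 <= p <= 1.0]
            if bad:
                raise PointTableError([f"risk map probabilities outside [0,1] at scores {sorted(bad)}"])
        else:
            if self.intercept is None or self.slope is None:
                raise PointTableError(["logistic-mode risk map requires intercept and slope"])


def predicted_risk(score: int, risk_map: RiskMap) -> float:
    """Predicted mortality probability for an integer score value.

    Table mode requires ``score`` to be a key; logistic mode evaluates the
    inverse-logit at any integer score.
    """
    if risk_map.mode == "table":
        assert risk_map.table is not None
        try:
            return float(risk_map.table[int(score)])
        except KeyError:
            raise KeyError(f"risk map defines no probability for score {score}") from None
    # logistic
    eta = risk_map.intercept + risk_map.slope * score
    # numerically safe inverse logit
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    e = math.exp(eta)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_point_table(table: PointTable, min_age: int = 18) -> list[str]:
    """Return a list of invariant violations (empty iff the table is valid).

    Checks: age bands non-overlapping and jointly covering all ages >= min_age
    with an open-ended top band; non-negative points everywhere; every group
    has at least one prefix; no two surgery groups can match the identical
    code (prefix ambiguity, detected as one prefix extending another across
    groups).
    """
    violations: list[str] = []

    if not table.age_bands:
        violations.append("age coverage gap: no age bands defined")
    else:
        bands = sorted(table.age_bands, key=lambda b: b.lower_age)
        if bands[0].lower_age > min_age:
            violations.append(
                f"age coverage gap: ages {min_age}..{bands[0].lower_age - 1} uncovered"
            )
        for prev, nxt in zip(bands, bands[1:]):
            if prev.upper_age is None:
                violations.append(
                    f"age band overlap: open-ended band [{prev.lower_age},∞) precedes [{nxt.lower_age},…]"
                )
            elif nxt.lower_age <= prev.upper_age:
                violations.append(
                    f"age band overlap: [{prev.lower_age},{prev.upper_age}] and [{nxt.lower_age},…]"
                )
            elif nxt.lower_age > prev.upper_age + 1:
                violations.append(
                    f"age coverage gap: ages {prev.upper_age + 1}..{nxt.lower_age - 1} uncovered"
                )
        if bands[-1].upper_age is not None:
            violations.append(
                f"age coverage gap: ages above {bands[-1].upper_age} uncovered (no open-ended band)"
            )
        for b in bands:
            if b.upper_age is not None and b.upper_age < b.lower_age:
                violations.append(f"age band [{b.lower_age},{b.upper_age}] is empty")
            if b.points < 0:
                violations.append(f"age band [{b.lower_age},{b.upper_age}] has negative points")

    for group in table.comorbidities:
        if not group.icd_prefixes:
            violations.append(f"comorbidity group {group.name!r} has no ICD prefixes")
        if group.points < 0:
            violations.append(f"comorbidity group {group.name!r} has negative points")
        for p in group.icd_prefixes:
            if p != normalize_code(p):
                violations.append(f"comorbidity group {group.name!r}: prefix {p!r} not normalized")

    seen_surgery_names: set[str] = set()
    for group in table.surgeries:
        if group.name in seen_surgery_names:
            violations.append(f"duplicate surgery group name {group.name!r}")
        seen_surgery_names.add(group.name)
        if not group.ops_prefixes:
            violations.append(f"surgery group {group.name!r} has no OPS prefixes")
        if group.points < 0:
            violations.append(f"surgery group {group.name!r} has negative points")
        for p in group.ops_prefixes:
            if p != normalize_code(p):
                violations.append(f"surgery group {group.name!r}: prefix {p!r} not normalized")

    # Ambiguity: two distinct groups could claim the identical full code iff
    # one group's prefix is a prefix of (or equal to) another group's prefix.
    for i, g1 in enumerate(table.surgeries):
        for g2 in table.surgeries[i + 1:]:
            for p1 in g1.ops_prefixes:
                for p2 in g2.ops_prefixes:
                    if p1.startswith(p2) or p2.startswith(p1):
                        violations.append(
                            f"surgery prefix ambiguity: {g1.name!r} prefix {p1!r} and "
                            f"{g2.name!r} prefix {p2!r} can match the same code"
                        )
    return violations


def validate_risk_map_covers(risk_map: RiskMap, table: PointTable) -> list[str]:
    """In table mode, every attainable score must have a probability."""
    if risk_map.mode != "table":
        return []
    assert risk_map.table is not None
    from .synthetic_cohort import attainable_scores  # cheap DP, avoids cycle at import

    missing = [s for s in attainable_scores(table) if s not in risk_map.table]
    if missing:
        return [f"risk map missing probabilities for attainable scores {missing}"]
    return []


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

def _parse_point_table(raw: Mapping) -> PointTable:
    try:
        age_bands = tuple(
            AgeBand(
                lower_age=int(b["lower_age"]),
                upper_age=None if b.get("upper_age") in (None, "open") else int(b["upper_age"]),
                points=int(b["points"]),
            )
            for b in raw["age_bands"]
        )
        comorbidities = tuple(
            ComorbidityGroup(
                name=str(g["name"]),
                icd_prefixes=tuple(normalize_code(p) for p in g["icd_prefixes"]),
                points=int(g["points"]),
            )
            for g in raw["comorbidities"]
        )
        surgeries = tuple(
            SurgeryGroup(
                name=str(g["name"]),
                ops_prefixes=tuple(normalize_code(p) for p in g["ops_prefixes"]),
                points=int(g["points"]),
            )
            for g in raw["surgeries"]
        )
    except (KeyError, TypeError) as exc:
        raise PointTableError([f"malformed point table structure: {exc!r}"]) from exc
    return PointTable(
        age_bands=age_bands,
        comorbidities=comorbidities,
        surgeries=surgeries,
        version=str(raw.get("version", "")),
    )


def load_point_table(path: str | Path, fmt: str | None = None) -> PointTable:
    """Load and validate a point table from a YAML or JSON file.

    ``fmt`` defaults to the file suffix.  Prefixes are normalized on load.
    Raises :class:`PointTableError` with the full violation list on invalid
    tables, or a parse error naming the line for syntactically broken files.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    text = path.read_text(encoding="utf-8")
    try:
        raw = json.loads(text) if fmt == "json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise PointTableError([f"cannot parse {path.name}: {exc}"]) from exc
    table = _parse_point_table(raw)
    violations = validate_point_table(table)
    if violations:
        raise PointTableError(violations)
    return table


def point_table_to_dict(table: PointTable) -> dict:
    """Serializable form; ``load`` of a dump round-trips to an equal table."""
    return {
        "version": table.version,
        "age_bands": [
            {"lower_age": b.lower_age, "upper_age": b.upper_age, "points": b.points}
            for b in table.age_bands
        ],
        "comorbidities": [
            {"name": g.name, "icd_prefixes": list(g.icd_prefixes), "points": g.points}
            for g in table.comorbidities
        ],
        "surgeries": [
            {"name": g.name, "ops_prefixes": list(g.ops_prefixes), "points": g.points}
            for g in table.surgeries
        ],
    }


def save_point_table(table: PointTable, path: str | Path) -> None:
    path = Path(path)
    d = point_table_to_dict(table)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


def load_risk_map(path: str | Path) -> RiskMap:
    """Load a risk map (keys ``mode``, ``table``, ``logistic``) from YAML/JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise PointTableError([f"cannot parse {path.name}: {exc}"]) from exc
    mode = raw.get("mode")
    if mode == "table":
        return RiskMap(mode="table", table={int(k): float(v) for k, v in raw["table"].items()})
    if mode == "logistic":
        logi = raw.get("logistic", {})
        return RiskMap(mode="logistic", intercept=float(logi["intercept"]), slope=float(logi["slope"]))
    raise PointTableError([f"risk map mode must be 'table' or 'logistic', got {mode!r}"])


def save_risk_map(risk_map: RiskMap, path: str | Path) -> None:
    path = Path(path)
    if risk_map.mode == "table":
        d = {"mode": "table", "table": {int(k): float(v) for k, v in sorted(risk_map.table.items())}}
    else:
        d = {"mode": "logistic", "logistic": {"intercept": risk_map.intercept, "slope": risk_map.slope}}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
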