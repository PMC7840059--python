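"""Accessors for the packaged config assets (demo table, template, schemas)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .score_table import PointTable, RiskMap, load_point_table, load_risk_map


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data asset."""
    return Path(str(resources.files("gpospom") / "data" / name))


def synthetic_demo_table() -> PointTable:
    """The synthetic demo point table (NOT the published score values)."""
    return load_point_table(data_path("synthetic_demo_table.yaml"))


def synthetic_demo_risk_map() -> RiskMap:
    """The synthetic demo logistic score→mortality link."""
    return load_risk_map(data_path("synthetic_demo_risk_map.yaml"))


def point_table_template_path() -> Path:
    """Template for transcribing the published point values."""
    return data_path("point_table_template.yaml")
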