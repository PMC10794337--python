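"""Canonical FeatureTable CSV schema shared by all pipeline stages."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from macromorph._geometry import DESCRIPTOR_COLUMNS

#: required leading columns; any number of ``<marker>_norm`` columns may follow
FEATURE_COLUMNS = ["cell_id", "donor_id", "class_id"] + DESCRIPTOR_COLUMNS

MORPHOLOGY_FEATURES = list(DESCRIPTOR_COLUMNS)


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Names of normalized-marker columns present in a feature table."""
    return [c for c in table.columns if c.endswith("_norm")]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical per-cell feature CSV (UTF-8, '.' decimal)."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing required columns: {missing}")
    cols = FEATURE_COLUMNS + marker_columns(table)
    table[cols].to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: not a feature table, missing columns {missing}")
    return table
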