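"""The 83-column per-gene feature schema.

Six feature groups with fixed sizes: population-genetic constraint (35),
nucleotide conservation (2), adult-tissue expression (19), developmental
brain expression (16), gene structure (4), chromosomal position (2) and
paralogy (5).  The concrete column names ship as an editable YAML config;
this module loads and validates it.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

#: required group -> expected number of columns
GROUP_SIZES = {
    "constraint": 35,
    "conservation": 2,
    "expression_adult": 19,
    "expression_developmental": 16,
    "structure": 4,
    "position": 2,
    "paralogue": 5,
}

N_FEATURES = sum(GROUP_SIZES.values())  # 83

#: features bounded to [0, 1] by construction
UNIT_INTERVAL_FEATURES = ("exon_score", "promoter_score", "tau", "tau_1", "tau_2")

#: features that must be non-negative
NONNEGATIVE_FEATURES = ("dist_centromere", "dist_telomere", "cds_length",
                        "exon_count", "transcript_length")


class SchemaError(ValueError):
    """Raised when a feature-schema config violates the group contract."""


_DEFAULT_SCHEMA_CACHE: dict[str, dict] = {}


def load_schema(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load and validate the feature schema (group -> ordered column names).

    Parameters
    ----------
    path
        Optional path to a YAML schema file; defaults to the packaged schema
        (cached after first load).
    """
    if path is None and "default" in _DEFAULT_SCHEMA_CACHE:
        return _DEFAULT_SCHEMA_CACHE["default"]
    if path is None:
        text = resources.files("xprio.data").joinpath("feature_schema.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if set(raw) != set(GROUP_SIZES):
        raise SchemaError(
            f"schema groups {sorted(raw)} != required {sorted(GROUP_SIZES)}")
    for group, names in raw.items():
        if len(names) != GROUP_SIZES[group]:
            raise SchemaError(
                f"group {group!r} has {len(names)} columns, expected {GROUP_SIZES[group]}")
    flat = [n for names in raw.values() for n in names]
    if len(set(flat)) != len(flat):
        dupes = sorted({n for n in flat if flat.count(n) > 1})
        raise SchemaError(f"duplicate feature names: {dupes}")
    if len(flat) != N_FEATURES:
        raise SchemaError(f"{len(flat)} features listed, expected {N_FEATURES}")
    if path is None:
        _DEFAULT_SCHEMA_CACHE["default"] = raw
    return raw


def feature_names(schema: dict[str, list[str]] | None = None) -> list[str]:
    """Flat, ordered list of all 83 feature names."""
    schema = schema if schema is not None else load_schema()
    return [n for names in schema.values() for n in names]


def feature_group(name: str, schema: dict[str, list[str]] | None = None) -> str:
    schema = schema if schema is not None else load_schema()
    for group, names in schema.items():
        if name in names:
            return group
    raise KeyError(name)
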