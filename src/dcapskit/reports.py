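"""Report assembly, serialization (TSV/JSON) and schema validation.

Reports are plain dicts with a stable, versioned schema so downstream
scripts can rely on field names.  Every configuration default in force is
echoed into the report header for provenance.  A machine-readable schema
ships with the package (``data/report.schema.json``); ``validate_report``
checks a report against it with a small built-in validator (required keys
and primitive types — not a full JSON-Schema engine).
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

__all__ = ["SCHEMA_VERSION", "load_schema", "validate_report", "to_json", "to_tsv"]

SCHEMA_VERSION = 1


def load_schema() -> dict:
    text = resources.files("dcapskit.data").joinpath("report.schema.json").read_text()
    return json.loads(text)


_TYPES = {
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "array": list,
    "object": dict,
}


def _check(obj: Any, schema: dict, path: str, errors: list[str]) -> None:
    t = schema.get("type")
    if t and not isinstance(obj, _TYPES[t]):
        errors.append(f"{path}: expected {t}, got {type(obj).__name__}")
        return
    if t == "object":
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{path}.{key}", errors)
    elif t == "array" and "items" in schema:
        for i, item in enumerate(obj):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict) -> list[str]:
    """Return a list of schema violations (empty when the report is valid)."""
    errors: list[str] = []
    _check(report, load_schema(), "$", errors)
    return errors


def to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"


def _flatten(value: Any) -> str:
    if isinstance(value, (list, tuple)):
        return ",".join(_flatten(v) for v in value) or "-"
    if isinstance(value, float):
        return f"{value:.2f}"
    if value is None or value == "":
        return "-"
    return str(value)


def to_tsv(report: dict) -> str:
    """Tab-separated rendering: ``# key=value`` provenance header, then one
    row per result."""
    lines = [f"# dcapskit report schema_version={report['schema_version']} mode={report['mode']}"]
    for key in sorted(report.get("config", {})):
        lines.append(f"# {key}={_flatten(report['config'][key])}")
    for w in report.get("warnings", []):
        lines.append(f"# warning: {w}")
    results = report.get("results", [])
    if not results:
        lines.append("# no assays found")
        return "\n".join(lines) + "\n"
    columns = list(results[0].keys())
    lines.append("\t".join(columns))
    for row in results:
        lines.append("\t".join(_flatten(row.get(c)) for c in columns))
    return "\n".join(lines) + "\n"
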