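"""Minimal JSON-schema-style validation for pipeline output files.

Schemas are plain dicts with "required" key -> type-name mappings; nested
objects use another dict.  ``validate`` raises ValueError on the first
violation.  This intentionally covers only what the pipeline writes.
"""

from __future__ import annotations

_TYPES = {"number": (int, float), "integer": int, "string": str,
          "boolean": bool, "array": list, "object": dict}

MANIFEST_SCHEMA = {
    "package": "string",
    "version": "string",
    "seed": "integer",
    "config_hash": "string",
    "stages": "array",
}

TIMING_SUMMARY_SCHEMA = {
    "n_samples": "integer",
    "n_early": "integer",
    "n_total": "integer",
    "binomial_p": "number",
}

META_RESULT_SCHEMA = {
    "pooled_or": "number",
    "ci_low": "number",
    "ci_high": "number",
    "q": "number",
    "q_p": "number",
}


def validate(obj: dict, schema: dict, path: str = "$") -> None:
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: expected object")
    for key, spec in schema.items():
        if key not in obj:
            raise ValueError(f"{path}.{key}: missing required key")
        val = obj[key]
        if isinstance(spec, dict):
            validate(val, spec, f"{path}.{key}")
        else:
            expected = _TYPES[spec]
            if isinstance(val, bool) and spec in ("number", "integer"):
                raise ValueError(f"{path}.{key}: expected {spec}, got boolean")
            if not isinstance(val, expected):
                raise ValueError(f"{path}.{key}: expected {spec}, got {type(val).__name__}")
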