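"""Lightweight shipped schemas for report files (required keys + types)."""
from __future__ import annotations

Number = (int, float)

SCHEMAS: dict[str, dict[str, type | tuple]] = {
    "cleaning_report": {"fraction_modified": Number, "n_windows": int, "n_flagged": int},
    "dipole_fit": {
        "location_mm": list,
        "moment": list,
        "residual_variance": Number,
        "dipolarity": Number,
        "within_brain": bool,
    },
    "cluster_report": {
        "members": list,
        "sessions_present": list,
        "reproducibility": Number,
        "mean_dipolarity": Number,
        "label": str,
    },
    "commonality_report": {"rows": list},
    "stat_report": {"subject_id": str, "scope": str, "results": list},
    "manifest": {
        "config_hash": str,
        "package_version": str,
        "stages": list,
        "seeds": dict,
    },
}


def validate_report(kind: str, obj: dict) -> None:
    """Raise ValueError if obj misses a required key or has a wrong type."""
    schema = SCHEMAS.get(kind)
    if schema is None:
        raise ValueError(f"unknown report kind {kind!r}")
    for key, typ in schema.items():
        if key not in obj:
            raise ValueError(f"{kind}: missing required key {key!r}")
        if not isinstance(obj[key], typ):
            raise ValueError(f"{kind}: key {key!r} has type {type(obj[key]).__name__}")
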