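"""CSV interchange schemas and validation diagnostics.

All tables are plain CSV with units embedded in column names (``_permil``,
``_cm2``, ``_per_L`` ...). :func:`validate_schema` returns row/column-level
diagnostics instead of raising, so the CLI can report every problem at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SchemaReport", "validate_schema", "SCHEMAS"]

_TREATMENTS = {"control", "F_2x", "F_6x", "B_F_6x"}

#: schema name -> {column -> spec}; spec keys: kind (numeric|label),
#: allowed (label vocabulary), lo/hi (plausible numeric range)
SCHEMAS: dict[str, dict[str, dict]] = {
    "fragments": {
        "fragment_id": {"kind": "label"},
        "colony": {"kind": "label"},
        "tank_id": {"kind": "label"},
        "treatment": {"kind": "label", "allowed": _TREATMENTS},
        "fraction": {"kind": "label", "allowed": {"host", "symbiont"}},
        "surface_area_cm2": {"kind": "numeric", "lo": 0.0, "hi": 1e4},
        "d13C_permil": {"kind": "numeric", "lo": -100.0, "hi": 100.0},
        "d15N_permil": {"kind": "numeric", "lo": -100.0, "hi": 100.0},
        "CN_molar": {"kind": "numeric", "lo": 0.0, "hi": 100.0},
    },
    "sources": {
        "source": {"kind": "label", "allowed": {"heterotrophic", "autotrophic"}},
        "replicate": {"kind": "numeric", "lo": 0, "hi": 1e6},
        "d13C_permil": {"kind": "numeric", "lo": -100.0, "hi": 100.0},
        "d15N_permil": {"kind": "numeric", "lo": -100.0, "hi": 100.0},
        "CN_molar": {"kind": "numeric", "lo": 0.0, "hi": 100.0},
    },
    "feeding_events": {
        "tank_id": {"kind": "label"},
        "treatment": {"kind": "label", "allowed": _TREATMENTS},
        "date_index": {"kind": "numeric", "lo": 0, "hi": 1e6},
        "density_initial_per_L": {"kind": "numeric", "lo": 0.0, "hi": 1e6},
        "density_final_per_L": {"kind": "numeric", "lo": 0.0, "hi": 1e6},
        "volume_L": {"kind": "numeric", "lo": 0.0, "hi": 1e6},
        "duration_h": {"kind": "numeric", "lo": 0.0, "hi": 1e3},
        "coral_surface_area_cm2": {"kind": "numeric", "lo": 0.0, "hi": 1e6},
    },
}


@dataclass
class SchemaReport:
    """Pass/fail plus human-readable problem strings naming file/column/row."""

    path: str
    schema: str
    ok: bool = True
    problems: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.ok = False
        self.problems.append(f"{self.path}: {msg}")


def validate_schema(path: str | Path, schema_name: str) -> SchemaReport:
    """Validate a CSV against a named schema.

    FA columns (``fa_*``) are checked as numeric relative abundances when
    present. Raises only for unreadable files or unknown schema names.
    """
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise OSError(f"file not found: {path}")
    report = SchemaReport(path=str(path), schema=schema_name)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - depends on broken input
        report.add(f"unreadable CSV ({exc})")
        return report

    spec = SCHEMAS[schema_name]
    for col, rules in spec.items():
        if col not in df.columns:
            report.add(f"missing column '{col}'")
            continue
        if rules["kind"] == "numeric":
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            for idx in df.index[bad][:5]:
                report.add(f"column '{col}' row {idx}: non-numeric value {df[col][idx]!r}")
            in_range = parsed.dropna()
            lo, hi = rules.get("lo", -np.inf), rules.get("hi", np.inf)
            out = in_range[(in_range < lo) | (in_range > hi)]
            for idx in out.index[:5]:
                report.add(
                    f"column '{col}' row {idx}: value {out[idx]} outside [{lo}, {hi}]"
                )
        elif "allowed" in rules:
            bad_vals = set(df[col].dropna().unique()) - rules["allowed"]
            if bad_vals:
                report.add(
                    f"column '{col}': unexpected label(s) {sorted(map(str, bad_vals))}"
                )
    for col in df.columns:
        if col.startswith("fa_"):
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            for idx in df.index[bad][:5]:
                report.add(f"column '{col}' row {idx}: non-numeric value {df[col][idx]!r}")
            if (parsed.dropna() < 0).any():
                report.add(f"column '{col}': negative relative abundance")
    return report
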