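"""End-to-end pipeline: feeding -> fatty acids -> isotopes -> report tables.

:func:`run_pipeline` validates the input CSVs, runs every stage, and writes
stage outputs plus a long-format ``report_summary.csv`` and a JSON run
manifest (config hash, seed, package versions). All randomness flows from
the single configured seed; report bytes are reproducible, timestamps live
only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fatty_acids, feeding, isotopes
from .errors import ComputationError, ValidationError
from .schemas import validate_schema

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("mixotracer")


@dataclass
class PipelineConfig:
    fragments_csv: str
    sources_csv: str
    events_csv: str | None = None
    out_dir: str = "mixotracer_out"
    alpha: float = 0.05
    delta13C_capture_threshold: float = isotopes.DEFAULT_CAPTURE_THRESHOLD
    nauplius_mass_ug: float = feeding.NAUPLIUS_MASS_UG
    epsilon_separation: float = isotopes.DEFAULT_EPSILON_PERMIL
    n_perm: int = 1999
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in (
            "alpha",
            "delta13C_capture_threshold",
            "nauplius_mass_ug",
            "epsilon_separation",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be positive")


@dataclass(frozen=True)
class _Source:
    """Mean endmember values pooled from replicate source measurements."""

    d13C: float
    d15N: float
    CN_molar: float


def _check_inputs(config: PipelineConfig) -> None:
    pairs = [(config.fragments_csv, "fragments"), (config.sources_csv, "sources")]
    if config.events_csv:
        pairs.append((config.events_csv, "feeding_events"))
    problems: list[str] = []
    for path, schema in pairs:
        report = validate_schema(path, schema)
        problems.extend(report.problems)
    if problems:
        raise ValidationError("schema validation failed:\n" + "\n".join(problems))


def _fa_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("fa_")]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of the in-memory stage outputs keyed by file stem.
    """
    config.validate()
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fragments = pd.read_csv(config.fragments_csv)
    sources = pd.read_csv(config.sources_csv)
    outputs: dict[str, pd.DataFrame] = {}
    warning_counts: dict[str, int] = {}

    def run_stage(name, fn):
        logger.info("stage %s", name)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                result = fn()
            except ValidationError:
                raise
            except Exception as exc:
                raise ComputationError(f"stage '{name}' failed: {exc}") from exc
        warning_counts[name] = len(caught)
        for w in caught:
            logger.warning("stage %s: %s", name, w.message)
        return result

    # ---- feeding ----------------------------------------------------------
    if config.events_csv:
        events = pd.read_csv(config.events_csv)
        captures = run_stage(
            "feeding/captures",
            lambda: feeding.capture_table(events, nauplius_mass_ug=config.nauplius_mass_ug),
        )
        outputs["capture_per_event"] = captures
        outputs["cumulative_per_tank"] = run_stage(
            "feeding/cumulative", lambda: feeding.cumulative_capture(captures)
        )
        outputs["feeding_curves"] = run_stage(
            "feeding/curves", lambda: feeding.fit_curves_by_treatment(captures)
        )

    # ---- fatty acids ------------------------------------------------------
    fa_cols = _fa_columns(fragments)
    het_reps = sources[sources["source"] == "heterotrophic"][fa_cols]
    aut_reps = sources[sources["source"] == "autotrophic"][fa_cols]
    het_reps = het_reps.rename(columns=lambda c: c[3:])
    aut_reps = aut_reps.rename(columns=lambda c: c[3:])
    outputs["biomarker_labels"] = run_stage(
        "fatty_acids/biomarkers",
        lambda: fatty_acids.classify_source_biomarkers(het_reps, aut_reps, alpha=config.alpha),
    )

    host = fragments[fragments["fraction"] == "host"].reset_index(drop=True)
    host_fa = host[fa_cols].rename(columns=lambda c: c[3:])
    design = host[["treatment", "colony", "tank_id"]]
    outputs["pattern_calls"] = run_stage(
        "fatty_acids/patterns",
        lambda: fatty_acids.classify_all_patterns(
            host_fa, design, alpha=config.alpha, n_perm=config.n_perm, seed=config.seed
        ),
    )

    # ---- isotopes ---------------------------------------------------------
    het_rows = sources[sources["source"] == "heterotrophic"]
    source_mean = _Source(
        d13C=float(het_rows["d13C_permil"].mean()),
        d15N=float(het_rows["d15N_permil"].mean()),
        CN_molar=float(het_rows["CN_molar"].mean()),
    )
    outputs["delta_offsets"] = run_stage(
        "isotopes/offsets", lambda: isotopes.delta_offset_table(fragments)
    )
    turnover = run_stage(
        "isotopes/turnover",
        lambda: isotopes.turnover_table(
            fragments, source_mean, epsilon=config.epsilon_separation
        ),
    )
    outputs["turnover"] = turnover

    pref_rows = []
    grouped = turnover.pivot_table(
        index=["treatment", "fraction"],
        columns="element",
        values="percent_turnover",
        aggfunc="mean",
    )
    for (treatment, fraction), row in grouped.iterrows():
        if treatment == "control" or pd.isna(row.get("N")) or pd.isna(row.get("C")):
            continue
        f_N = row["N"] / 100.0
        f_C = row["C"] / 100.0
        if f_N < 0 or f_C < 0:
            logger.warning(
                "negative mean turnover for %s/%s; preference factor skipped",
                treatment, fraction,
            )
            continue
        pf = isotopes.preference_factor(f_N, f_C, source_mean.CN_molar)
        pref_rows.append(
            {
                "treatment": treatment,
                "fraction": fraction,
                "f_N": f_N,
                "f_C": f_C,
                "CN_source": source_mean.CN_molar,
                "factor": pf.factor,
                "factor_rounded": pf.rounded,
                "infinite": pf.infinite,
            }
        )
    outputs["preference_factors"] = pd.DataFrame(pref_rows)

    # ---- summary ----------------------------------------------------------
    summary_rows = []
    stats = turnover.groupby(["treatment", "fraction", "element"])["percent_turnover"].agg(
        ["mean", "std", "size"]
    )
    for (treatment, fraction, element), row in stats.iterrows():
        summary_rows.append(
            {
                "section": "turnover",
                "group": f"{treatment}/{fraction}/{element}",
                "metric": "mean_percent",
                "value": row["mean"],
            }
        )
        summary_rows.append(
            {
                "section": "turnover",
                "group": f"{treatment}/{fraction}/{element}",
                "metric": "sd_percent",
                "value": row["std"],
            }
        )
    for r in pref_rows:
        summary_rows.append(
            {
                "section": "preference_factor",
                "group": f"{r['treatment']}/{r['fraction']}",
                "metric": "factor",
                "value": r["factor"],
            }
        )
    offsets = outputs["delta_offsets"]
    with_offset = offsets[offsets["delta13C_offset_permil"].notna()]
    if len(with_offset):
        summary_rows.append(
            {
                "section": "delta13C_capture",
                "group": "all",
                "metric": "percent_flagged",
                "value": 100.0 * with_offset["captures_heterotrophy"].mean(),
            }
        )
    for label, count in outputs["biomarker_labels"]["label"].value_counts().items():
        summary_rows.append(
            {"section": "biomarker_labels", "group": label, "metric": "count", "value": count}
        )
    for pattern, count in outputs["pattern_calls"]["pattern"].value_counts().items():
        summary_rows.append(
            {"section": "pattern_calls", "group": pattern, "metric": "count", "value": count}
        )
    outputs["report_summary"] = pd.DataFrame(summary_rows)

    for stem, df in outputs.items():
        df.to_csv(out / f"{stem}.csv", index=False)

    cfg_dict = asdict(config)
    manifest = {
        "package": "mixotracer",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "warning_counts": warning_counts,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest
    return outputs
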