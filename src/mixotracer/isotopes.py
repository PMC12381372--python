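"""Two-endmember stable-isotope mixing and derived heterotrophy statistics.

Implements host-minus-symbiont delta offsets, the strict ``< -2 permil``
carbon-offset heterotrophy flag, percent elemental turnover from a linear
two-source mixing model anchored at per-colony control means, and the
preferential nitrogen-incorporation factor ``(f_N / f_C) * source C:N``.

Zero trophic discrimination is assumed throughout: the unfed control tissue
defines 0% turnover and the prey endmember defines 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMixingError, ValidationError

__all__ = [
    "DEFAULT_CAPTURE_THRESHOLD",
    "DEFAULT_EPSILON_PERMIL",
    "PreferenceFactor",
    "delta_offset",
    "flag_heterotrophy_capture",
    "percent_turnover",
    "turnover_table",
    "preference_factor",
]

DEFAULT_CAPTURE_THRESHOLD = -2.0  # permil, host-minus-symbiont delta13C
DEFAULT_EPSILON_PERMIL = 0.5  # minimum endmember separation for mixing

_ELEMENT_COLUMNS = {"N": "d15N_permil", "C": "d13C_permil"}


def delta_offset(host_delta: float | None, symbiont_delta: float | None) -> float:
    """Host-minus-symbiont delta offset in permil (for either element).

    A missing fraction (e.g. no symbiont record for bleached fragments)
    yields ``nan`` rather than an exception.
    """
    if host_delta is None or symbiont_delta is None:
        return math.nan
    host_delta = float(host_delta)
    symbiont_delta = float(symbiont_delta)
    if math.isnan(host_delta) or math.isnan(symbiont_delta):
        return math.nan
    return host_delta - symbiont_delta


def flag_heterotrophy_capture(
    delta13C_offset: float, threshold: float = DEFAULT_CAPTURE_THRESHOLD
) -> bool:
    """True iff the host-symbiont d13C offset is strictly below ``threshold``.

    ``nan`` offsets (missing symbiont fraction) are never flagged.
    """
    if math.isnan(delta13C_offset):
        return False
    return delta13C_offset < threshold


def percent_turnover(
    delta_fed: float,
    control_mean: float,
    source_mean: float,
    epsilon: float = DEFAULT_EPSILON_PERMIL,
) -> float:
    """Percent of a tissue element replaced by heterotrophic material.

    Linear two-endmember mixing: the control mean maps to 0% and the prey
    source mean to 100%. Values outside [0, 100] are possible under
    measurement noise and are returned unchanged.

    Raises
    ------
    UndefinedMixingError
        If the endmembers are separated by less than ``epsilon`` permil.
    """
    separation = source_mean - control_mean
    if abs(separation) <= epsilon:
        raise UndefinedMixingError(
            f"endmember separation {separation:.3g} permil is below epsilon={epsilon}"
        )
    return 100.0 * (delta_fed - control_mean) / separation


def turnover_table(
    records: pd.DataFrame,
    source: "SourceEndmember | object",
    epsilon: float = DEFAULT_EPSILON_PERMIL,
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-fragment, per-element percent turnover against a prey endmember.

    ``records`` must carry columns ``fragment_id, colony, treatment, fraction,
    d13C_permil, d15N_permil``; ``source`` needs ``d13C`` and ``d15N``
    attributes (a :class:`~mixotracer.synthetic_data.SourceEndmember` fits).

    The 0%-turnover anchor is the mean delta of control fragments within the
    same colony and tissue fraction; colonies without control fragments fall
    back to the global control mean for that fraction (``fallback_used``
    True). Rows outside [0, 100] are flagged ``out_of_range`` but retained.
    """
    required = {"fragment_id", "colony", "treatment", "fraction"} | set(
        _ELEMENT_COLUMNS.values()
    )
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    controls = records[records["treatment"] == control_label]
    if controls.empty:
        raise ValidationError("no control fragments available for the 0% anchor")

    source_means = {"N": float(source.d15N), "C": float(source.d13C)}
    rows = []
    for element, col in _ELEMENT_COLUMNS.items():
        colony_means = controls.groupby(["colony", "fraction"])[col].mean()
        global_means = controls.groupby("fraction")[col].mean()
        for rec in records.itertuples(index=False):
            delta = getattr(rec, col)
            if pd.isna(delta):
                continue
            key = (rec.colony, rec.fraction)
            if key in colony_means.index and not pd.isna(colony_means[key]):
                control_mean = float(colony_means[key])
                fallback = False
            elif rec.fraction in global_means.index:
                control_mean = float(global_means[rec.fraction])
                fallback = True
            else:
                continue  # fraction absent from controls (e.g. bleached symbiont)
            turnover = percent_turnover(
                delta, control_mean, source_means[element], epsilon=epsilon
            )
            rows.append(
                {
                    "fragment_id": rec.fragment_id,
                    "colony": rec.colony,
                    "treatment": rec.treatment,
                    "fraction": rec.fraction,
                    "element": element,
                    "percent_turnover": turnover,
                    "control_mean_used": control_mean,
                    "source_mean_used": source_means[element],
                    "fallback_used": fallback,
                    "out_of_range": not 0.0 <= turnover <= 100.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PreferenceFactor:
    """Excess of heterotrophic N over C retained, relative to delivered C:N."""

    f_N: float
    f_C: float
    CN_source: float
    factor: float
    infinite: bool

    @property
    def rounded(self) -> int | None:
        """Nearest-integer rendering, ``None`` when the factor is infinite."""
        return None if self.infinite else round(self.factor)


def preference_factor(f_N: float, f_C: float, CN_source: float) -> PreferenceFactor:
    """Preferential nitrogen-incorporation factor ``(f_N / f_C) * CN_source``.

    ``f_N`` and ``f_C`` are incorporation fractions (a common rescaling of
    both leaves the factor unchanged). ``f_C == 0`` yields an
    infinite-preference result rather than an exception.
    """
    if CN_source <= 0:
        raise ValidationError("CN_source must be positive")
    if f_C < 0 or f_N < 0:
        raise ValidationError("incorporation fractions must be non-negative")
    if f_C == 0:
        return PreferenceFactor(f_N, f_C, CN_source, math.inf, True)
    return PreferenceFactor(f_N, f_C, CN_source, (f_N / f_C) * CN_source, False)


def delta_offset_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-fragment host-minus-symbiont offsets for both elements.

    Fragments lacking a symbiont record get ``nan`` offsets. Adds a
    ``captures_heterotrophy`` column from the strict d13C threshold rule.
    """
    wide = records.pivot_table(
        index=["fragment_id", "colony", "treatment"],
        columns="fraction",
        values=list(_ELEMENT_COLUMNS.values()),
        aggfunc="first",
    )
    out = []
    for (fragment_id, colony, treatment), row in wide.iterrows():
        d13 = delta_offset(
            row.get(("d13C_permil", "host"), math.nan),
            row.get(("d13C_permil", "symbiont"), math.nan),
        )
        d15 = delta_offset(
            row.get(("d15N_permil", "host"), math.nan),
            row.get(("d15N_permil", "symbiont"), math.nan),
        )
        out.append(
            {
                "fragment_id": fragment_id,
                "colony": colony,
                "treatment": treatment,
                "delta13C_offset_permil": d13,
                "delta15N_offset_permil": d15,
                "captures_heterotrophy": flag_heterotrophy_capture(d13),
            }
        )
    return pd.DataFrame(out)
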