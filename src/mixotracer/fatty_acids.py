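"""Fatty-acid biomarker classification and response-pattern typing.

Three stages: (1) convert per-FA masses to relative abundance (% of total);
(2) label each FA as a heterotrophic or autotrophic biomarker by a rank-sum
comparison of the two nutritional source groups; (3) type each FA's response
across the feeding gradient into one of four patterns using blocked
permutation contrasts (F_2x vs control, F_6x vs control, B_F_6x vs F_6x).

Labels use raw p < alpha, matching the source study's convention;
Benjamini-Hochberg adjusted p-values are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .errors import ValidationError

__all__ = [
    "FAProfile",
    "BiomarkerLabel",
    "PatternCall",
    "CONTRASTS",
    "relative_abundance",
    "min_max_normalize",
    "classify_source_biomarkers",
    "classify_response_pattern",
    "classify_all_patterns",
]

#: (name, reference treatment, alternative treatment); effect = alt - ref
CONTRASTS: tuple[tuple[str, str, str], ...] = (
    ("F_2x_vs_control", "control", "F_2x"),
    ("F_6x_vs_control", "control", "F_6x"),
    ("B_F_6x_vs_F_6x", "F_6x", "B_F_6x"),
)
_FEEDING_CONTRASTS = ("F_2x_vs_control", "F_6x_vs_control")
_BLEACHING_CONTRAST = "B_F_6x_vs_F_6x"


@dataclass(frozen=True)
class FAProfile:
    """One fragment's or source replicate's fatty-acid composition."""

    id: str
    fraction: str  # host | symbiont | source
    values: dict[str, float]  # FA name -> relative abundance (% of total)
    masses: dict[str, float] | None = None  # FA name -> ug per g dry tissue


@dataclass(frozen=True)
class BiomarkerLabel:
    fa: str
    label: str  # heterotrophic | autotrophic | non_distinguishing
    p_value: float
    direction: float  # sign of (heterotrophic - autotrophic) median difference


@dataclass(frozen=True)
class PatternCall:
    fa: str
    pattern: str  # positive_with_heterotrophy | negative_with_heterotrophy |
    #              bleaching_effect | no_effect
    ambiguous: bool
    contrast_stats: dict[str, dict[str, float]] = field(default_factory=dict)


def relative_abundance(masses: dict[str, float]) -> dict[str, float]:
    """Convert per-FA masses to percent of total; output sums to 100.

    Scale-invariant: multiplying all masses by a constant leaves the result
    unchanged.
    """
    if any(m < 0 for m in masses.values()):
        raise ValidationError("FA masses must be non-negative")
    total = sum(masses.values())
    if total <= 0:
        raise ValidationError("total FA mass must be positive")
    return {fa: 100.0 * m / total for fa, m in masses.items()}


def min_max_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise min-max scaling to [0, 1].

    Constant columns map to 0 with a warning (the heatmap convention leaves
    them undefined). Accepts and returns either a DataFrame or a 2-D array.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    arr = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError("expected a non-empty 2-D matrix")
    if arr.shape[0] < 2:
        raise ValidationError("min-max normalization needs at least 2 rows")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) mapped to 0", stacklevel=2
        )
    safe = np.where(constant, 1.0, span)
    out = (arr - lo) / safe
    out[:, constant] = 0.0
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _coerce_profiles(reps) -> pd.DataFrame:
    if isinstance(reps, pd.DataFrame):
        return reps
    return pd.DataFrame([p.values for p in reps])


def classify_source_biomarkers(
    hetero_reps, auto_reps, alpha: float = 0.05
) -> pd.DataFrame:
    """Label each FA by which nutritional source it distinguishes.

    ``hetero_reps`` / ``auto_reps`` are replicate profiles (DataFrame rows or
    a list of :class:`FAProfile`) of the prey and the control-symbiont source
    groups. Per FA, a two-sided rank-sum test compares the groups; FAs with
    ``p < alpha`` are labelled by the sign of the median difference
    (prey-higher -> ``heterotrophic``), others ``non_distinguishing``.
    """
    het = _coerce_profiles(hetero_reps)
    aut = _coerce_profiles(auto_reps)
    if len(het) < 3 or len(aut) < 3:
        raise ValidationError("need at least 3 replicates per source group")
    common = [fa for fa in het.columns if fa in aut.columns]
    if not common:
        raise ValidationError("source groups share no FA columns")

    rows = []
    for fa in common:
        x = het[fa].to_numpy(dtype=float)
        y = aut[fa].to_numpy(dtype=float)
        stat, p = stats_core.rank_sum_test(x, y)
        direction = float(np.sign(np.median(x) - np.median(y)))
        if p < alpha and direction != 0:
            label = "heterotrophic" if direction > 0 else "autotrophic"
        else:
            label = "non_distinguishing"
        rows.append(
            {
                "fa": fa,
                "label": label,
                "p_value": p,
                "direction": direction,
                "statistic": stat,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj_bh"] = stats_core.adjust_p(out["p_value"].to_numpy(), method="BH")
    return out


def plot_pattern_heatmap(
    values: pd.DataFrame,
    row_groups: pd.Series,
    pattern_calls: pd.DataFrame,
    path: str,
) -> None:
    """Optional convenience plot: min-max normalized FA heatmap (PNG).

    Rows are ordered by source group / treatment, columns by pattern class.
    Requires matplotlib (``pip install mixotracer[plot]``); untested output,
    not part of the analysis surface.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = pattern_calls.sort_values("pattern")["fa"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = min_max_normalize(values[order])
    row_order = np.argsort(row_groups.to_numpy(), kind="stable")
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(mat.to_numpy()[row_order], aspect="auto", cmap="coolwarm",
                   vmin=0, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="min-max normalized abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def classify_response_pattern(
    fa: str,
    values,
    design: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1999,
    seed: int = 0,
    block_col: str = "colony",
) -> PatternCall:
    """Type one FA's response across the feeding gradient.

    ``values`` are host-fraction relative abundances aligned with ``design``
    (columns ``treatment`` and ``block_col``). Treatments are assigned at the
    tank level, so contrasts block on colony by default: labels are permuted
    within colonies only.

    Decision rule: a significant feeding contrast (F_2x or F_6x vs control)
    wins and sets the sign; conflicting significant signs are resolved by the
    larger absolute effect and flagged ``ambiguous``. Otherwise a significant
    B_F_6x vs F_6x contrast gives ``bleaching_effect``; otherwise
    ``no_effect``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(design):
        raise ValidationError("values and design must be equal length")
    present = set(design["treatment"].unique())
    needed = {"control", "F_2x", "F_6x", "B_F_6x"}
    if not needed <= present:
        raise ValidationError(f"missing treatment(s): {sorted(needed - present)}")

    stats: dict[str, dict[str, float]] = {}
    for i, (name, ref, alt) in enumerate(CONTRASTS):
        mask = design["treatment"].isin([ref, alt]).to_numpy()
        res = stats_core.blocked_permutation_test(
            values[mask],
            design.loc[mask, "treatment"].to_numpy(),
            design.loc[mask, block_col].to_numpy(),
            n_perm=n_perm,
            seed=seed + i,
            group_order=(ref, alt),
        )
        stats[name] = {"effect": res.observed_effect, "p_value": res.p_value}

    feeding_sig = [
        name for name in _FEEDING_CONTRASTS if stats[name]["p_value"] < alpha
    ]
    ambiguous = False
    if feeding_sig:
        signs = {np.sign(stats[name]["effect"]) for name in feeding_sig}
        if len(signs) > 1:
            ambiguous = True
            top = max(feeding_sig, key=lambda nm: abs(stats[nm]["effect"]))
            sign = np.sign(stats[top]["effect"])
        else:
            sign = signs.pop()
        pattern = (
            "positive_with_heterotrophy" if sign > 0 else "negative_with_heterotrophy"
        )
    elif stats[_BLEACHING_CONTRAST]["p_value"] < alpha:
        pattern = "bleaching_effect"
    else:
        pattern = "no_effect"
    return PatternCall(fa=fa, pattern=pattern, ambiguous=ambiguous, contrast_stats=stats)


def classify_all_patterns(
    host_values: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1999,
    seed: int = 0,
    block_col: str = "colony",
) -> pd.DataFrame:
    """Run :func:`classify_response_pattern` over every FA column.

    Returns a tidy table with one row per FA, the pattern call and the three
    contrast effects/p-values.
    """
    rows = []
    for j, fa in enumerate(host_values.columns):
        call = classify_response_pattern(
            fa,
            host_values[fa].to_numpy(dtype=float),
            design,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed + 1000 * j,
            block_col=block_col,
        )
        row = {"fa": fa, "pattern": call.pattern, "ambiguous": call.ambiguous}
        for name, st in call.contrast_stats.items():
            row[f"effect_{name}"] = st["effect"]
            row[f"p_{name}"] = st["p_value"]
        rows.append(row)
    return pd.DataFrame(rows)
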