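"""Synthetic feeding-gradient experiments with known ground truth.

Emulates the statistical structure the downstream analyses assume: fragments
of 12 parent colonies distributed over 3 replicate tanks for each of four
treatments (unfed control, fed 2x/week, fed 6x/week, bleached + fed
6x/week), tissue isotope values generated by two-endmember mixing with
element-, treatment- and fraction-specific incorporation fractions, additive
Gaussian colony and tank effects, FA compositions on the simplex with four
configured response patterns, and tank-level feeding events drawn around
logarithmic rate-density curves.

Everything is driven by a single integer seed; identical seed + config gives
bit-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = [
    "FA_NAMES",
    "TREATMENTS",
    "SourceEndmember",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_source_profiles",
    "generate_experiment",
    "write_experiment",
]

TREATMENTS = ("control", "F_2x", "F_6x", "B_F_6x")

#: the 27 fatty acids tracked by default
FA_NAMES = (
    "14:0", "14:1", "15:0", "16:0", "16:1n7", "17:0", "18:0", "18:1n9",
    "18:1n7", "18:2n6", "18:3n6", "18:3n3", "18:4n3", "20:0", "20:1n9",
    "20:2n6", "20:3n6", "20:4n6", "20:4n3", "20:5n3", "22:0", "22:1n9",
    "22:4n6", "22:5n3", "22:6n3", "23:0", "24:0",
)

# FAs elevated in each generated source profile (the remaining three are
# non-distinguishing)
HET_ELEVATED = (
    "18:2n6", "18:3n3", "20:5n3", "18:1n9", "18:1n7", "18:0", "22:0",
    "20:4n6", "20:2n6", "22:4n6", "17:0", "15:0",
)
AUTO_ELEVATED = (
    "16:1n7", "18:3n6", "18:4n3", "20:1n9", "20:3n6", "22:1n9", "22:6n3",
    "23:0", "14:0", "14:1", "22:5n3", "20:4n3",
)

#: default true response-pattern assignment for host tissues
DEFAULT_FA_PATTERNS: dict[str, str] = {
    **{fa: "positive_with_heterotrophy" for fa in (
        "18:2n6", "18:3n3", "20:5n3", "22:4n6", "18:1n7", "20:2n6",
        "22:5n3", "20:4n6", "24:0")},
    **{fa: "negative_with_heterotrophy" for fa in (
        "18:3n6", "20:1n9", "20:3n6", "22:1n9", "23:0", "18:1n9",
        "14:1", "17:0", "15:0")},
    **{fa: "bleaching_effect" for fa in ("16:1n7", "18:4n3", "22:6n3", "18:0", "20:0")},
    **{fa: "no_effect" for fa in ("16:0", "14:0", "20:4n3", "22:0")},
}

# signed bleaching shifts sum to zero so renormalization stays neutral
_BLEACH_SIGN = {"16:1n7": -1.0, "18:4n3": -1.0, "22:6n3": -1.0, "18:0": 1.5, "20:0": 1.5}

_BASE_BUMPS = {"16:0": 18.0, "18:0": 6.0, "22:6n3": 8.0, "20:4n6": 5.0, "18:1n9": 5.0}


@dataclass(frozen=True)
class SourceEndmember:
    """One nutritional source: isotope and C:N values plus an FA profile."""

    name: str  # heterotrophic | autotrophic
    d13C: float  # permil vs PDB
    d15N: float  # permil vs air
    CN_molar: float
    fa_profile: dict[str, float]  # FA name -> % of total, sums to 100

    def __post_init__(self) -> None:
        if self.CN_molar <= 0:
            raise ConfigurationError("CN_molar: must be positive")
        vals = np.array(list(self.fa_profile.values()), dtype=float)
        if vals.size:
            if (vals < 0).any():
                raise ConfigurationError("fa_profile: abundances must be >= 0")
            if abs(vals.sum() - 100.0) > 1e-6:
                raise ConfigurationError(
                    f"fa_profile: must sum to 100, got {vals.sum():.8f}"
                )


def _default_incorporation_N() -> dict[str, dict[str, float]]:
    return {
        "control": {"host": 0.0, "symbiont": 0.0},
        "F_2x": {"host": 0.224, "symbiont": 0.19},
        "F_6x": {"host": 0.381, "symbiont": 0.31},
        "B_F_6x": {"host": 0.336},
    }


def _default_incorporation_C() -> dict[str, dict[str, float]]:
    return {
        "control": {"host": 0.0, "symbiont": 0.0},
        "F_2x": {"host": 0.095, "symbiont": 0.015},
        "F_6x": {"host": 0.095, "symbiont": 0.054},
        "B_F_6x": {"host": 0.095},
    }


def _default_feeding_curves() -> dict[str, tuple[float, float]]:
    return {"F_2x": (-275.7, 54.4), "F_6x": (-209.1, 41.0), "B_F_6x": (-177.1, 33.8)}


def _default_n_feedings() -> dict[str, int]:
    return {"F_2x": 6, "F_6x": 18, "B_F_6x": 18}


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic experiment."""

    n_colonies: int = 12
    n_tanks_per_treatment: int = 3
    n_fragments_per_tank: int = 10
    treatments: tuple[str, ...] = TREATMENTS
    endmembers: tuple[SourceEndmember, SourceEndmember] | None = None

    # incorporation fractions: treatment -> tissue fraction -> f in [0, 1]
    incorporation_N: dict[str, dict[str, float]] = field(
        default_factory=_default_incorporation_N
    )
    incorporation_C: dict[str, dict[str, float]] = field(
        default_factory=_default_incorporation_C
    )

    # FA generation
    fa_names: tuple[str, ...] = FA_NAMES
    fa_patterns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FA_PATTERNS))
    fa_effect_size: float = 2.0  # percentage points at full feeding level
    bleach_effect_size: float = 3.0
    sd_fa: float = 0.25
    source_separation: float = 3.0  # percentage points added to elevated FAs
    n_source_replicates: int = 4
    sd_source_fa: float = 0.15

    # isotopes
    host_symbiont_d15N_offset: float = 2.0  # permil
    sd_colony: float = 0.3
    sd_tank: float = 0.15
    sd_measurement_d15N: float = 0.4
    sd_measurement_d13C: float = 0.5
    sd_CN: float = 0.08

    # feeding events
    feeding_curve_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_feeding_curves
    )
    n_feedings: dict[str, int] = field(default_factory=_default_n_feedings)
    density_range: tuple[float, float] = (200.0, 1300.0)
    sd_rate: float = 6.0  # nauplii cm^-2 h^-1 around the curve
    tank_volume_L: float = 40.0
    feeding_duration_h: float = 2.0

    # fragment geometry
    surface_area_mean_cm2: float = 12.0
    surface_area_sd_cm2: float = 2.0

    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in ("n_colonies", "n_tanks_per_treatment", "n_fragments_per_tank"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name}: must be a positive count")
        if "control" not in self.treatments:
            raise ConfigurationError("treatments: must include 'control'")
        for attr in ("incorporation_N", "incorporation_C"):
            table = getattr(self, attr)
            for trt, fracs in table.items():
                for frac, f in fracs.items():
                    if not 0.0 <= f <= 1.0:
                        raise ConfigurationError(
                            f"{attr}[{trt}][{frac}]: fraction {f} outside [0, 1]"
                        )
            for frac, f in table.get("control", {}).items():
                if f != 0.0:
                    raise ConfigurationError(
                        f"{attr}[control][{frac}]: control incorporation must be 0"
                    )
        for name in (
            "sd_colony", "sd_tank", "sd_measurement_d15N", "sd_measurement_d13C",
            "sd_CN", "sd_fa", "sd_source_fa", "sd_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be non-negative")
        if self.source_separation < 0:
            raise ConfigurationError("source_separation: must be non-negative")
        lo, hi = self.density_range
        if not 0 < lo < hi:
            raise ConfigurationError("density_range: need 0 < low < high")
        unknown = set(self.fa_patterns) - set(self.fa_names)
        if unknown:
            raise ConfigurationError(f"fa_patterns: unknown FA(s) {sorted(unknown)}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = dataclasses.asdict(self)
        if self.endmembers is not None:
            d["endmembers"] = [dataclasses.asdict(e) for e in self.endmembers]
        return plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("endmembers"):
            d["endmembers"] = tuple(SourceEndmember(**e) for e in d["endmembers"])
        for key in ("treatments", "fa_names"):
            if key in d:
                d[key] = tuple(d[key])
        if "density_range" in d:
            d["density_range"] = tuple(d["density_range"])
        if "feeding_curve_params" in d:
            d["feeding_curve_params"] = {
                k: tuple(v) for k, v in d["feeding_curve_params"].items()
            }
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated experiment."""

    incorporation: pd.DataFrame  # fragment_id, fraction, element, f
    fa_patterns: dict[str, str]
    feeding_curves: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        """Single long-format table (the ``truth.csv`` layout)."""
        rows = [
            {
                "kind": "incorporation",
                "key": r.fragment_id,
                "subkey": f"{r.fraction}:{r.element}",
                "value": r.f,
            }
            for r in self.incorporation.itertuples(index=False)
        ]
        rows += [
            {"kind": "fa_pattern", "key": fa, "subkey": pattern, "value": np.nan}
            for fa, pattern in self.fa_patterns.items()
        ]
        for trt, (a, b) in self.feeding_curves.items():
            rows.append({"kind": "feeding_curve", "key": trt, "subkey": "a", "value": a})
            rows.append({"kind": "feeding_curve", "key": trt, "subkey": "b", "value": b})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# source profiles
# ---------------------------------------------------------------------------

def _normalize(values: np.ndarray) -> np.ndarray:
    return 100.0 * values / values.sum()


def generate_source_profiles(
    config: SimulationConfig,
) -> tuple[SourceEndmember, SourceEndmember]:
    """The two nutritional endmembers with separated FA profiles.

    Both profiles start from a shared base composition; a configured subset
    of FAs is elevated in each source by ``source_separation`` percentage
    points (before renormalization to 100%). A separation of 0 makes the
    profiles identical.
    """
    config.validate()
    if config.endmembers is not None:
        return config.endmembers
    het_set = [fa for fa in HET_ELEVATED if fa in config.fa_names]
    auto_set = [fa for fa in AUTO_ELEVATED if fa in config.fa_names]
    overlap = set(het_set) & set(auto_set)
    if overlap:
        raise ConfigurationError(f"elevated subsets overlap: {sorted(overlap)}")

    base = np.full(len(config.fa_names), 2.0)
    for fa, bump in _BASE_BUMPS.items():
        if fa in config.fa_names:
            base[config.fa_names.index(fa)] += bump

    het = base.copy()
    aut = base.copy()
    for fa in het_set:
        het[config.fa_names.index(fa)] += config.source_separation
    for fa in auto_set:
        aut[config.fa_names.index(fa)] += config.source_separation

    het_profile = dict(zip(config.fa_names, _normalize(het)))
    aut_profile = dict(zip(config.fa_names, _normalize(aut)))
    return (
        SourceEndmember("heterotrophic", -20.5, 9.8, 4.48, het_profile),
        SourceEndmember("autotrophic", -16.1, -1.5, 5.79, aut_profile),
    )


def _perturb_profile(profile: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    noisy = np.clip(profile + rng.normal(0.0, sd, profile.size) if sd > 0 else profile, 0.01, None)
    return _normalize(noisy)


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------

_PATTERN_LEVEL = {"control": 0.0, "F_2x": 0.5, "F_6x": 1.0, "B_F_6x": 1.0}


def _fa_delta(config: SimulationConfig, fa: str, treatment: str) -> float:
    pattern = config.fa_patterns.get(fa, "no_effect")
    level = _PATTERN_LEVEL.get(treatment, 0.0)
    if pattern == "positive_with_heterotrophy":
        return config.fa_effect_size * level
    if pattern == "negative_with_heterotrophy":
        return -config.fa_effect_size * level
    if pattern == "bleaching_effect" and treatment == "B_F_6x":
        return config.bleach_effect_size * _BLEACH_SIGN.get(fa, -1.0)
    return 0.0


def generate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic experiment.

    Returns ``(fragments, feeding_events, sources, truth)``. ``fragments``
    has one row per fragment x tissue fraction (bleached fragments carry no
    symbiont row); ``sources`` holds replicate endmember measurements;
    ``feeding_events`` covers the fed treatments only.

    Tissue deltas follow ``(1 - f) * baseline + f * source`` where the
    baseline includes the autotrophic endmember, the host d15N offset, and
    additive Gaussian colony and tank effects, and ``f`` is the configured
    element/treatment/fraction incorporation fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    het, aut = generate_source_profiles(config)

    colony_ids = [f"colony_{i + 1:02d}" for i in range(config.n_colonies)]
    colony_eff_N = rng.normal(0.0, config.sd_colony, config.n_colonies)
    colony_eff_C = rng.normal(0.0, config.sd_colony, config.n_colonies)

    fa_names = list(config.fa_names)
    aut_base = np.array([aut.fa_profile[fa] for fa in fa_names])
    het_base = np.array([het.fa_profile[fa] for fa in fa_names])
    # host tissue baseline: symbiont-derived profile blended with a flat
    # component so low-abundance FAs keep headroom for negative effects
    host_base = _normalize(0.5 * aut_base + 0.5 * np.full(len(fa_names), 100.0 / len(fa_names)))

    frag_rows = []
    truth_rows = []
    tank_records = []  # (tank_id, treatment, total surface area)
    frag_counter = 0
    for treatment in config.treatments:
        for t in range(config.n_tanks_per_treatment):
            tank_id = f"tank_{treatment}_{t + 1}"
            tank_eff_N = rng.normal(0.0, config.sd_tank)
            tank_eff_C = rng.normal(0.0, config.sd_tank)
            tank_sa = 0.0
            for _ in range(config.n_fragments_per_tank):
                colony_idx = frag_counter % config.n_colonies
                frag_counter += 1
                fragment_id = f"frag_{frag_counter:04d}"
                sa = max(
                    1.0,
                    rng.normal(config.surface_area_mean_cm2, config.surface_area_sd_cm2),
                )
                tank_sa += sa
                fractions = ("host",) if treatment == "B_F_6x" else ("host", "symbiont")
                for fraction in fractions:
                    f_N = config.incorporation_N.get(treatment, {}).get(fraction, 0.0)
                    f_C = config.incorporation_C.get(treatment, {}).get(fraction, 0.0)
                    base_15N = aut.d15N + colony_eff_N[colony_idx] + tank_eff_N
                    if fraction == "host":
                        base_15N += config.host_symbiont_d15N_offset
                    base_13C = aut.d13C + colony_eff_C[colony_idx] + tank_eff_C
                    d15N = (
                        (1 - f_N) * base_15N
                        + f_N * het.d15N
                        + rng.normal(0.0, config.sd_measurement_d15N)
                    )
                    d13C = (
                        (1 - f_C) * base_13C
                        + f_C * het.d13C
                        + rng.normal(0.0, config.sd_measurement_d13C)
                    )
                    cn = (
                        (1 - f_C) * aut.CN_molar
                        + f_C * het.CN_molar
                        + rng.normal(0.0, config.sd_CN)
                    )
                    if fraction == "host":
                        deltas = np.array(
                            [_fa_delta(config, fa, treatment) for fa in fa_names]
                        )
                        fa_vals = host_base + deltas
                    else:
                        fa_vals = aut_base.copy()
                    fa_vals = _perturb_profile(fa_vals, config.sd_fa, rng)
                    row = {
                        "fragment_id": fragment_id,
                        "colony": colony_ids[colony_idx],
                        "tank_id": tank_id,
                        "treatment": treatment,
                        "fraction": fraction,
                        "surface_area_cm2": round(sa, 6),
                        "d13C_permil": d13C,
                        "d15N_permil": d15N,
                        "CN_molar": cn,
                    }
                    row.update({f"fa_{fa}": v for fa, v in zip(fa_names, fa_vals)})
                    frag_rows.append(row)
                    truth_rows.append(
                        {
                            "fragment_id": fragment_id,
                            "fraction": fraction,
                            "element": "N",
                            "f": f_N,
                        }
                    )
                    truth_rows.append(
                        {
                            "fragment_id": fragment_id,
                            "fraction": fraction,
                            "element": "C",
                            "f": f_C,
                        }
                    )
            tank_records.append((tank_id, treatment, tank_sa))

    fragments = pd.DataFrame(frag_rows)

    # ---- feeding events ---------------------------------------------------
    event_rows = []
    lo, hi = config.density_range
    for tank_id, treatment, tank_sa in tank_records:
        params = config.feeding_curve_params.get(treatment)
        if params is None:
            continue  # unfed treatment
        a, b = params
        for day in range(config.n_feedings.get(treatment, 0)):
            density0 = rng.uniform(lo, hi)
            rate = a + b * np.log(density0) + rng.normal(0.0, config.sd_rate)
            rate = max(0.0, rate)
            consumed = rate * tank_sa * config.feeding_duration_h
            density1 = max(0.0, density0 - consumed / config.tank_volume_L)
            event_rows.append(
                {
                    "tank_id": tank_id,
                    "treatment": treatment,
                    "date_index": day,
                    "density_initial_per_L": density0,
                    "density_final_per_L": density1,
                    "volume_L": config.tank_volume_L,
                    "duration_h": config.feeding_duration_h,
                    "coral_surface_area_cm2": tank_sa,
                }
            )
    feeding_events = pd.DataFrame(event_rows)

    # ---- source replicate measurements ------------------------------------
    source_rows = []
    for src, base_profile in ((het, het_base), (aut, aut_base)):
        for r in range(config.n_source_replicates):
            profile = _perturb_profile(base_profile, config.sd_source_fa, rng)
            row = {
                "source": src.name,
                "replicate": r,
                "d13C_permil": src.d13C + rng.normal(0.0, config.sd_measurement_d13C),
                "d15N_permil": src.d15N + rng.normal(0.0, config.sd_measurement_d15N),
                "CN_molar": src.CN_molar + rng.normal(0.0, config.sd_CN),
            }
            row.update({f"fa_{fa}": v for fa, v in zip(fa_names, profile)})
            source_rows.append(row)
    sources = pd.DataFrame(source_rows)

    truth = SyntheticTruth(
        incorporation=pd.DataFrame(truth_rows),
        fa_patterns={fa: config.fa_patterns.get(fa, "no_effect") for fa in fa_names},
        feeding_curves=dict(config.feeding_curve_params),
    )
    return fragments, feeding_events, sources, truth


def write_experiment(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate an experiment and write the four CSVs plus a metadata file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fragments, events, sources, truth = generate_experiment(config)
    paths = {
        "fragments": out / "fragments.csv",
        "feeding_events": out / "feeding_events.csv",
        "sources": out / "sources.csv",
        "truth": out / "truth.csv",
    }
    fragments.to_csv(paths["fragments"], index=False)
    events.to_csv(paths["feeding_events"], index=False)
    sources.to_csv(paths["sources"], index=False)
    truth.to_frame().to_csv(paths["truth"], index=False)
    meta = {"seed": config.seed, "config": config.to_dict()}
    meta_path = out / "simulation_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    paths["metadata"] = meta_path
    return paths
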