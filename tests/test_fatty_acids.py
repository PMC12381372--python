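import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixotracer.errors import ValidationError
from mixotracer.fatty_acids import (
    classify_all_patterns,
    classify_response_pattern,
    classify_source_biomarkers,
    min_max_normalize,
    relative_abundance,
)


class TestRelativeAbundance:
    def test_worked_example(self):
        out = relative_abundance({"A": 2.0, "B": 3.0, "C": 5.0})
        assert out == pytest.approx({"A": 20.0, "B": 30.0, "C": 50.0})

    def test_single_fa(self):
        assert relative_abundance({"X": 0.123})["X"] == pytest.approx(100.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValidationError):
            relative_abundance({"A": 0.0, "B": 0.0})

    def test_negative_raises(self):
        with pytest.raises(ValidationError):
            relative_abundance({"A": -1.0, "B": 2.0})

    @given(
        masses=st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.floats(0.01, 1e4),
            min_size=1,
        ),
        scale=st.floats(0.001, 1e3),
    )
    @settings(max_examples=60, deadline=None)
    def test_sums_to_100_and_scale_invariant(self, masses, scale):
        out = relative_abundance(masses)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)
        scaled = relative_abundance({k: v * scale for k, v in masses.items()})
        for k in masses:
            assert scaled[k] == pytest.approx(out[k], rel=1e-9)


class TestMinMaxNormalize:
    def test_column_example(self):
        out = min_max_normalize(np.array([[1.0], [3.0], [5.0]]))
        assert out.ravel() == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = min_max_normalize(np.array([[2.0, 1.0], [2.0, 3.0], [2.0, 5.0]]))
        assert out[:, 0] == pytest.approx([0.0, 0.0, 0.0])

    def test_bounds_attained(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(8, 5))
        out = min_max_normalize(mat)
        assert out.min(axis=0) == pytest.approx(np.zeros(5))
        assert out.max(axis=0) == pytest.approx(np.ones(5))

    def test_dataframe_roundtrip(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [5.0, 3.0]}, index=["r1", "r2"])
        out = min_max_normalize(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == ["x", "y"]

    def test_single_row_raises(self):
        with pytest.raises(ValidationError):
            min_max_normalize(np.array([[1.0, 2.0]]))


class TestSourceBiomarkers:
    def _reps(self, values):
        return pd.DataFrame(values)

    def test_complete_separation_4v4(self):
        het = self._reps({"fa1": [5.0, 6, 7, 8], "fa2": [1.0, 2, 3, 4]})
        aut = self._reps({"fa1": [1.0, 2, 3, 4], "fa2": [5.0, 6, 7, 8]})
        out = classify_source_biomarkers(het, aut).set_index("fa")
        assert out.loc["fa1", "p_value"] == pytest.approx(2 / 70)
        assert out.loc["fa1", "label"] == "heterotrophic"
        assert out.loc["fa2", "label"] == "autotrophic"

    def test_identical_values_non_distinguishing(self):
        het = self._reps({"fa1": [2.0, 2.0, 2.0, 2.0]})
        aut = self._reps({"fa1": [2.0, 2.0, 2.0, 2.0]})
        out = classify_source_biomarkers(het, aut)
        assert out.loc[0, "label"] == "non_distinguishing"

    def test_3v3_separation_still_non_distinguishing(self):
        # exact two-sided p = 2/20 = 0.1 at n=3 regardless of separation
        het = self._reps({"fa1": [10.0, 11, 12]})
        aut = self._reps({"fa1": [1.0, 2, 3]})
        out = classify_source_biomarkers(het, aut)
        assert out.loc[0, "p_value"] == pytest.approx(0.1)
        assert out.loc[0, "label"] == "non_distinguishing"

    def test_label_symmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        het = pd.DataFrame(rng.normal(5, 1, size=(4, 3)), columns=list("abc"))
        aut = pd.DataFrame(rng.normal(3, 1, size=(5, 3)), columns=list("abc"))
        fwd = classify_source_biomarkers(het, aut).set_index("fa")
        rev = classify_source_biomarkers(aut, het).set_index("fa")
        swap = {"heterotrophic": "autotrophic", "autotrophic": "heterotrophic",
                "non_distinguishing": "non_distinguishing"}
        for fa in "abc":
            assert rev.loc[fa, "label"] == swap[fwd.loc[fa, "label"]]
            assert rev.loc[fa, "p_value"] == pytest.approx(fwd.loc[fa, "p_value"])

    def test_too_few_replicates_raises(self):
        het = self._reps({"fa1": [1.0, 2.0]})
        aut = self._reps({"fa1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            classify_source_biomarkers(het, aut)

    def test_generator_sources_mostly_distinguishing(self, default_experiment):
        # qualitative analogue of a strongly separated source pair:
        # the classifier should flag at least 20 of the 27 FAs
        _, _, sources, _ = default_experiment
        fa_cols = [c for c in sources.columns if c.startswith("fa_")]
        strip = lambda c: c[3:]  # noqa: E731
        het = sources[sources.source == "heterotrophic"][fa_cols].rename(columns=strip)
        aut = sources[sources.source == "autotrophic"][fa_cols].rename(columns=strip)
        out = classify_source_biomarkers(het, aut)
        n_distinguishing = (out.label != "non_distinguishing").sum()
        assert n_distinguishing >= 20


def _design(n_per=8, n_colonies=4):
    rows = []
    for trt in ("control", "F_2x", "F_6x", "B_F_6x"):
        for i in range(n_per):
            rows.append({"treatment": trt, "colony": f"c{i % n_colonies}"})
    return pd.DataFrame(rows)


def _values_for(design, means, seed=0):
    rng = np.random.default_rng(seed)
    return np.array(
        [means[t] + rng.normal(0, 0.2) for t in design["treatment"]]
    )


class TestResponsePattern:
    def test_monotone_increase_positive(self):
        design = _design()
        vals = _values_for(design, {"control": 5, "F_2x": 6, "F_6x": 7, "B_F_6x": 7})
        call = classify_response_pattern("fa", vals, design, seed=1)
        assert call.pattern == "positive_with_heterotrophy"
        assert not call.ambiguous

    def test_bleaching_shift_only(self):
        design = _design()
        vals = _values_for(design, {"control": 5, "F_2x": 5, "F_6x": 5, "B_F_6x": 2}, seed=1)
        call = classify_response_pattern("fa", vals, design, seed=1)
        assert call.pattern == "bleaching_effect"

    def test_decrease_negative(self):
        design = _design()
        vals = _values_for(design, {"control": 7, "F_2x": 6, "F_6x": 5, "B_F_6x": 5})
        call = classify_response_pattern("fa", vals, design, seed=1)
        assert call.pattern == "negative_with_heterotrophy"

    def test_missing_treatment_raises(self):
        design = _design()
        design = design[design.treatment != "F_2x"]
        with pytest.raises(ValidationError):
            classify_response_pattern(
                "fa", np.zeros(len(design)), design.reset_index(drop=True)
            )

    def test_conflicting_signs_flagged_ambiguous(self):
        # F_2x strongly above control, F_6x strongly below: both significant
        design = _design(n_per=10)
        vals = _values_for(design, {"control": 5, "F_2x": 8, "F_6x": 1, "B_F_6x": 1})
        call = classify_response_pattern("fa", vals, design, seed=1)
        assert call.ambiguous
        # |F_6x effect| = 4 > |F_2x effect| = 3 -> negative wins
        assert call.pattern == "negative_with_heterotrophy"

    def test_pure_noise_rarely_rejects(self):
        # oracle for the rule's joint type-I error: three correlated contrasts
        # at alpha 0.05 leave ~87% of pure-noise FAs labelled no_effect
        # (independent tests would give 0.95^3 ~ 86%; shared groups raise it)
        design = _design(n_per=8)
        rng = np.random.default_rng(42)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            vals = rng.normal(5.0, 1.0, len(design))
            call = classify_response_pattern("fa", vals, design, n_perm=499, seed=seed)
            hits += call.pattern == "no_effect"
        assert hits / n_seeds >= 0.80
        assert hits / n_seeds <= 0.97

    def test_pattern_recovery_on_generated_data(self, host_design):
        values, design = host_design
        calls = classify_all_patterns(values, design, n_perm=999, seed=0)
        from mixotracer.synthetic_data import DEFAULT_FA_PATTERNS

        correct = sum(
            DEFAULT_FA_PATTERNS[row.fa] == row.pattern
            for row in calls.itertuples(index=False)
        )
        assert correct / len(calls) >= 0.9
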