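"""Depth-profile assembly, replicate statistics and significance tiers."""

import numpy as np
import pytest

from memepr.features import measure_splittings
from memepr.observables import ObservableSet, observables_from_features
from memepr.profiles import (
    DepthProfile,
    ProfileError,
    ProfilePoint,
    build_profile,
    compare_profiles,
    render_profile_table,
)
from memepr.simulate import OrderedPowderParams, simulate_ordered_powder
from memepr.spectrum import Spectrum, SpectrumMeta


def stub_spectrum(label, membrane="PM", condition="control"):
    field = np.linspace(3300.0, 3400.0, 64)
    return Spectrum(
        field,
        np.sin(np.linspace(0, 6.28, 64)),
        SpectrumMeta(spin_label=label, membrane_class=membrane,
                     retinoid_condition=condition),
    )


def record(label, value, membrane="PM", condition="control", observable="two_A_zz"):
    obs = ObservableSet()
    setattr(obs, observable, value)
    return (stub_spectrum(label, membrane, condition), obs)


def profile_from_values(values_by_pos, condition="control", observable="two_A_zz"):
    records = [
        record(f"{pos}-PC", v, condition=condition, observable=observable)
        for pos, values in values_by_pos.items()
        for v in values
    ]
    return build_profile(records, observable)


class TestBuildProfile:
    def test_grouping_contract(self):
        profile = profile_from_values(
            {"5": [70.9, 71.1, 71.0], "10": [68.4, 68.6, 68.5], "16": [66.4, 66.6, 66.5]}
        )
        assert profile.positions == [5, 10, 16]
        for pos in (5, 10, 16):
            assert profile.points[pos].n_replicates == 3
        assert profile.points[5].mean == pytest.approx(71.0)

    def test_profile_means_recover_simulated_order_gradient(self):
        """Ordered simulations at S = 0.65/0.45/0.25 at labels 5/10/16 come back."""
        truth = {"5": 0.65, "10": 0.45, "16": 0.25}
        records = []
        for pos, s_true in truth.items():
            for rep in range(3):
                spec = simulate_ordered_powder(
                    OrderedPowderParams(S_target=s_true, seed=17 * rep + int(pos)),
                    meta=SpectrumMeta(spin_label=f"{pos}-PC", membrane_class="PM",
                                      retinoid_condition="control"),
                )
                obs = observables_from_features(
                    splitting_features=measure_splittings(spec, smoothing_window=1.0)
                )
                records.append((spec, obs))
        profile = build_profile(records, "S")
        for pos, s_true in truth.items():
            assert profile.points[int(pos)].mean == pytest.approx(s_true, abs=0.05)

    def test_single_replicate_has_undefined_sd(self):
        profile = profile_from_values({"5": [71.0]})
        assert profile.points[5].sd is None
        assert profile.points[5].n_replicates == 1

    def test_mean_is_permutation_invariant(self):
        a = profile_from_values({"5": [70.0, 71.0, 72.0]})
        b = profile_from_values({"5": [72.0, 70.0, 71.0]})
        assert a.points[5].mean == b.points[5].mean
        assert a.points[5].sd == b.points[5].sd

    def test_mixed_membrane_classes_rejected(self):
        records = [record("5-PC", 71.0), record("5-PC", 71.0, membrane="YDM")]
        with pytest.raises(ProfileError, match="mixed"):
            build_profile(records, "two_A_zz")

    def test_unknown_label_rejected(self):
        with pytest.raises(Exception, match="spin label"):
            build_profile([record("9-PC", 71.0)], "two_A_zz")

    def test_empty_input_rejected(self):
        with pytest.raises(ProfileError, match="no spectra"):
            build_profile([], "two_A_zz")


class TestCompareProfiles:
    def test_identical_profiles_never_flagged(self):
        values = {"5": [71.0, 71.2, 70.8, 71.1], "16": [66.3, 66.6, 66.5, 66.4]}
        control = profile_from_values(values)
        treated = profile_from_values(values, condition="atral")
        comparison = compare_profiles(control, treated)
        for pos, point in comparison.per_depth.items():
            assert point.delta == 0.0
            assert point.tier == "none"

    def test_injected_shift_flagged_only_at_shifted_depths(self):
        rng = np.random.default_rng(99)
        base = {"5": 71.0, "10": 68.5, "16": 66.5}
        shift = {"5": 1.5, "10": 1.5, "16": 0.0}
        control = profile_from_values(
            {p: rng.normal(mu, 0.2, 4) for p, mu in base.items()}
        )
        treated = profile_from_values(
            {p: rng.normal(mu + shift[p], 0.2, 4) for p, mu in base.items()},
            condition="atral",
        )
        comparison = compare_profiles(control, treated)
        assert comparison.per_depth[5].tier == "double_star"
        assert comparison.per_depth[10].tier == "double_star"
        assert comparison.per_depth[16].tier == "none"

    def test_inflated_variance_kills_significance(self):
        rng = np.random.default_rng(7)
        control = profile_from_values({"5": rng.normal(71.0, 4.0, 4)})
        treated = profile_from_values(
            {"5": rng.normal(72.5, 4.0, 4)}, condition="atral"
        )
        comparison = compare_profiles(control, treated)
        assert comparison.per_depth[5].tier == "none"

    def test_mismatched_positions_rejected(self):
        control = profile_from_values({"5": [71.0, 71.1]})
        treated = profile_from_values({"10": [68.5, 68.6]}, condition="atral")
        with pytest.raises(ProfileError, match="positions"):
            compare_profiles(control, treated)

    def test_insufficient_replicates_marked_not_failed(self):
        control = profile_from_values({"5": [71.0]})
        treated = profile_from_values({"5": [72.5]}, condition="atral")
        comparison = compare_profiles(control, treated)
        point = comparison.per_depth[5]
        assert point.tier == "insufficient_replicates"
        assert point.p_value is None
        assert point.delta == pytest.approx(1.5)

    def test_tier_thresholds_are_nested(self):
        """double_star implies the star threshold: p<0.02 ⇒ p<0.05."""
        rng = np.random.default_rng(3)
        control = profile_from_values({"5": rng.normal(71.0, 0.2, 4)})
        treated = profile_from_values(
            {"5": rng.normal(74.0, 0.2, 4)}, condition="atral"
        )
        point = compare_profiles(control, treated).per_depth[5]
        assert point.tier == "double_star"
        assert point.p_value < 0.02 < 0.05

    def test_holm_correction_is_more_conservative(self):
        rng = np.random.default_rng(11)
        base = {"5": 71.0, "10": 68.5, "16": 66.5}
        control = profile_from_values(
            {p: rng.normal(mu, 0.5, 4) for p, mu in base.items()}
        )
        treated = profile_from_values(
            {p: rng.normal(mu + 0.7, 0.5, 4) for p, mu in base.items()},
            condition="atral",
        )
        plain = compare_profiles(control, treated)
        holm = compare_profiles(control, treated, holm_correction=True)
        rank = {"none": 0, "star": 1, "double_star": 2}
        for pos in plain.per_depth:
            assert rank[holm.per_depth[pos].tier] <= rank[plain.per_depth[pos].tier]


class TestRenderTable:
    def test_row_count_matches_positions(self):
        control = profile_from_values({"5": [71.0, 71.1], "16": [66.5, 66.6]})
        treated = profile_from_values(
            {"5": [72.0, 72.1], "16": [66.5, 66.6]}, condition="atral"
        )
        comparison = compare_profiles(control, treated)
        table = render_profile_table(control, treated, comparison)
        data_rows = [
            r for r in table.splitlines() if r and not r.startswith(("#", "position"))
        ]
        assert len(data_rows) == 2

    def test_polarity_table_carries_orientation_note(self):
        control = profile_from_values({"5": [71.0, 71.1]})
        table = render_profile_table(control)
        assert "decrease in polarity" in table
        assert "carbon 5 of the stearoyl chain" in table

    def test_empty_profile_renders_header_only(self):
        empty = DepthProfile("PM", "control", "two_A_zz", {})
        table = render_profile_table(empty)
        assert "position" in table
        data_rows = [
            r for r in table.splitlines() if r and not r.startswith(("#", "position"))
        ]
        assert data_rows == []
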