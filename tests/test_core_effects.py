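"""Closed-form effects: frozen oracle values, identities, sign templates."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spamodel import (
    CorrelationSet,
    DirectionalEffects,
    EffectsBundle,
    SpamParams,
    change_effect,
    change_on_change_effect,
    classify_signs,
    effects_bundle,
    implied_correlations,
    lagged_effects,
    partial_beta,
)
from spamodel.core_effects import DegenerateInputError, MissingCorrelationError

from conftest import random_psd_correlation_set


def normal_equations_beta(r_xy, r_xz, r_yz):
    """Independent oracle: solve the 2-predictor normal equations directly."""
    gram = np.array([[1.0, r_xz], [r_xz, 1.0]])
    rhs = np.array([r_xy, r_yz])
    return np.linalg.solve(gram, rhs)[0]


class TestPartialBeta:
    @pytest.mark.parametrize(
        "r_xy, r_xz, r_yz, expected",
        [
            (0.379, 0.493, 0.568, 0.1307561519834177),  # frozen from the solver oracle
            (0.24, 0.40, 0.60, 0.0),                     # numerator vanishes
            (0.50, 0.00, 0.30, 0.50),                    # uncorrelated covariate
        ],
    )
    def test_frozen_examples(self, r_xy, r_xz, r_yz, expected):
        assert partial_beta(r_xy, r_xz, r_yz) == pytest.approx(expected, abs=1e-10)

    @given(
        r_xy=st.floats(-0.95, 0.95),
        r_xz=st.floats(-0.95, 0.95),
        r_yz=st.floats(-0.95, 0.95),
    )
    def test_matches_normal_equations(self, r_xy, r_xz, r_yz):
        assert partial_beta(r_xy, r_xz, r_yz) == pytest.approx(
            normal_equations_beta(r_xy, r_xz, r_yz), abs=1e-10
        )

    @given(r_xy=st.floats(-0.99, 0.99), r_yz=st.floats(-0.99, 0.99))
    def test_zero_predictor_correlation_identity(self, r_xy, r_yz):
        assert partial_beta(r_xy, 0.0, r_yz) == r_xy

    def test_perfect_predictor_correlation_raises(self):
        with pytest.raises(DegenerateInputError):
            partial_beta(0.3, 1.0, 0.2)


class TestLaggedEffects:
    def test_frozen_lon_sa(self, lon_sa):
        fwd, rev = lagged_effects(lon_sa, "xy")
        # frozen from the normal-equations oracle
        assert fwd == pytest.approx(0.1307561519834177, abs=1e-10)
        assert rev == pytest.approx(0.3243125838579380, abs=1e-10)

    def test_zero_cross_correlations_give_zero(self):
        cs = CorrelationSet(0.5, 0.0, 0.0, 0.2, 0.3, 0.5)
        assert lagged_effects(cs, "xy") == (0.0, 0.0)

    def test_symmetric_set_reduces_to_common_correlation(self):
        cs = CorrelationSet(0.5, 0.4, 0.4, 0.2, 0.3, 0.0)
        fwd, rev = lagged_effects(cs, "xy")
        assert fwd == pytest.approx(0.4 / (1 - 0.16))
        assert fwd == rev

    def test_missing_input_names_the_entry(self, lon_sa):
        incomplete = CorrelationSet(r_x1x2=0.5, r_x1y1=0.4, r_x2y1=0.3)
        with pytest.raises(MissingCorrelationError, match="r_x1y2"):
            lagged_effects(incomplete, "xy")


class TestChangeEffects:
    def test_frozen_lon_sa_both_directions(self, lon_sa):
        assert change_effect(lon_sa, "xy") == pytest.approx(-0.12264447262990151, abs=1e-10)
        assert change_effect(lon_sa, "yx") == pytest.approx(-0.15935954943134792, abs=1e-10)

    def test_equal_correlations_give_null_change(self):
        cs = CorrelationSet(0.5, 0.35, 0.35, 0.2, 0.4, 0.6)
        assert change_effect(cs, "xy") == 0.0

    def test_frozen_change_on_change(self, lon_sa):
        assert change_on_change_effect(lon_sa) == pytest.approx(
            0.38031497949358234, abs=1e-10
        )

    def test_change_on_change_zero_when_concurrent_equals_cross(self):
        cs = CorrelationSet(0.5, 0.3, 0.3, 0.3, 0.3, 0.6)
        assert change_on_change_effect(cs) == 0.0

    def test_change_on_change_symmetric_under_label_swap(self, rng):
        for _ in range(20):
            cs = random_psd_correlation_set(rng)
            assert change_on_change_effect(cs) == pytest.approx(
                change_on_change_effect(cs.swapped()), abs=1e-12
            )

    def test_unit_autocorrelation_raises(self):
        with pytest.raises(ValueError):
            CorrelationSet(0.5, 0.3, 0.3, 0.3, 0.3, 1.0)


class TestEffectsBundle:
    def test_frozen_lon_sa_bundle(self, lon_sa):
        bundle = effects_bundle(lon_sa)
        assert bundle.xy.beta_lag_fwd == pytest.approx(0.1307561519834177, abs=1e-10)
        assert bundle.xy.beta_lag_rev == pytest.approx(0.3243125838579380, abs=1e-10)
        assert bundle.xy.beta_change == pytest.approx(-0.12264447262990151, abs=1e-10)
        assert bundle.xy.beta_change_on_change == pytest.approx(0.38031497949358234, abs=1e-10)

    def test_change_on_change_identical_across_directions(self, rng):
        for _ in range(20):
            bundle = effects_bundle(random_psd_correlation_set(rng))
            assert bundle.xy.beta_change_on_change == pytest.approx(
                bundle.yx.beta_change_on_change, abs=1e-12
            )

    def test_zero_state_covariance_kills_change_effect(self):
        cs = implied_correlations(SpamParams(a=0.7, s=+1, b=0.8, c=0.6, d=0.0))
        bundle = effects_bundle(cs)
        assert bundle.xy.beta_change == pytest.approx(0.0, abs=1e-12)
        assert bundle.yx.beta_change == pytest.approx(0.0, abs=1e-12)
        assert bundle.xy.beta_change_on_change == pytest.approx(0.0, abs=1e-12)

    def test_missing_y2_leaves_reverse_direction_available(self):
        cs = CorrelationSet(r_x1x2=0.6, r_x1y1=0.4, r_x2y1=0.3)
        bundle = effects_bundle(cs)
        assert bundle.xy.beta_lag_fwd is None
        assert bundle.yx.beta_lag_fwd is not None
        assert bundle.xy.beta_change_on_change is None

    def test_strict_mode_raises_on_missing(self):
        cs = CorrelationSet(r_x1x2=0.6, r_x1y1=0.4, r_x2y1=0.3)
        with pytest.raises(MissingCorrelationError):
            effects_bundle(cs, strict=True)


def bundle_from(xy, yx=None):
    return EffectsBundle(
        xy=DirectionalEffects(*xy), yx=DirectionalEffects(*(yx or xy))
    )


class TestClassifySigns:
    @pytest.mark.parametrize(
        "effects, verdict",
        [
            ((+0.123, +0.354, -0.145, +0.366), "spurious-positive"),
            ((+0.3, -0.2, +0.25, +0.3), "true-increasing"),
            ((-0.3, +0.2, -0.25, -0.3), "true-decreasing"),
            ((-0.12, -0.35, +0.15, -0.37), "spurious-negative"),
            ((+0.01, +0.01, -0.01, +0.01), "inconclusive"),
            ((+0.3, +0.2, +0.25, +0.3), "inconclusive"),
        ],
    )
    def test_templates(self, effects, verdict):
        signs = classify_signs(bundle_from(effects), epsilon=0.02)
        assert signs["xy"].verdict == verdict

    def test_zero_band_counts_as_zero(self):
        signs = classify_signs(bundle_from((0.3, 0.3, 0.015, 0.015)), epsilon=0.02)
        assert signs["xy"].signs == (1, 1, 0, 0)
        assert signs["xy"].verdict == "spurious-positive"

    def test_missing_effects_are_inconclusive(self):
        bundle = bundle_from((0.3, None, 0.1, 0.1))
        assert classify_signs(bundle)["xy"].verdict == "inconclusive"

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            classify_signs(bundle_from((0.1, 0.1, 0.1, 0.1)), epsilon=-0.1)


class TestCorrelationSetIO:
    def test_json_round_trip(self, lon_sa):
        assert CorrelationSet.from_json(lon_sa.to_json()) == lon_sa

    def test_csv_round_trip(self, lon_sa):
        recovered = CorrelationSet.from_csv(lon_sa.to_csv())
        for field in ("r_x1x2", "r_x1y1", "r_x1y2", "r_x2y1", "r_x2y2", "r_y1y2"):
            assert getattr(recovered, field) == pytest.approx(getattr(lon_sa, field))

    def test_out_of_range_correlation_rejected_with_name(self):
        with pytest.raises(ValueError, match="r_x1y2"):
            CorrelationSet(0.5, 0.4, 1.2, 0.3, 0.2, 0.5)

    def test_asymmetric_matrix_rejected(self):
        m = np.eye(4)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationSet.from_matrix(m)

    def test_psd_check(self, lon_sa):
        assert lon_sa.is_positive_semidefinite()
        bad = CorrelationSet(0.9, -0.9, 0.9, 0.9, 0.9, 0.9)
        assert not bad.is_positive_semidefinite()
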