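"""Unit and property tests for the elementary model operations."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinamosaic import (
    ModelParams,
    Mode,
    Regime,
    classify_regime,
    column_defaults,
    default_probability,
    full_probability,
    mistake_correction,
    mistake_correction_column,
    mixture_probability,
    mode_column_default,
    update_X,
)


class TestThresholdSwitch:
    @pytest.mark.parametrize(
        "X, X0, P0, expected",
        [
            (2.0008, 5.0, 0.0001, 0.0001),  # below threshold: low branch
            (6.0, 5.0, 0.0001, 0.9999),  # above threshold: high branch
            (5.0, 5.0, 0.3, 0.3),  # boundary belongs to the low branch
        ],
    )
    def test_branches(self, X, X0, P0, expected):
        params = ModelParams.doli(X0=X0, P0_structured=P0)
        assert default_probability(X, params) == pytest.approx(expected)

    def test_nonfinite_X_rejected(self, doli_params):
        with pytest.raises(ValueError):
            default_probability(float("nan"), doli_params)


class TestXUpdate:
    @pytest.mark.parametrize(
        "p, beta, gamma, expected",
        [
            (0.9999, 8.0, 10.0, 2.0008),  # worked stripe-building step
            (0.0, 8.0, 10.0, 10.0),
            (1.0, 8.0, 10.0, 2.0),
        ],
    )
    def test_linear_update(self, p, beta, gamma, expected):
        params = ModelParams.doli(beta=beta, gamma=gamma)
        assert update_X(p, params) == pytest.approx(expected)

    def test_probability_range_enforced(self, doli_params):
        with pytest.raises(ValueError):
            update_X(1.5, doli_params)


class TestRegimeClassifier:
    @pytest.mark.parametrize(
        "beta, gamma, X0, P0, expected",
        [
            (8.0, 10.0, 5.0, 0.0001, Regime.alternating),  # Doli stripes
            (-8.0, 2.0, 5.0, 0.0001, Regime.fixed_high),  # uniform fly
            (8.0, 10.0, 5.0, 0.7, Regime.bistable),  # P0 > 0.5 overlap
            (8.0, 10.0, -1.0, 0.0001, Regime.invalid),  # negative threshold
            (1.0, 10.0, 5.0, 0.0001, Regime.fixed_high),  # both levels above X0
            (8.0, 4.0, 5.0, 0.0001, Regime.fixed_low),  # both levels below X0
        ],
    )
    def test_examples(self, beta, gamma, X0, P0, expected):
        params = ModelParams.doli(beta=beta, gamma=gamma, X0=X0, P0_structured=P0)
        assert classify_regime(params) is expected

    def test_fixed_regime_X_constant_after_first_step(self):
        # iterating the raw dynamics in a fixed regime pins X at
        # gamma - beta * (1 - P0) from the first update onward
        params = ModelParams.doli(beta=-8.0, gamma=2.0)
        x = params.X0 + 1.0
        expected = params.gamma - params.beta * (1.0 - params.P0_structured)
        for _ in range(10):
            x = update_X(default_probability(x, params), params)
            assert x == pytest.approx(expected)


class TestModeDefaults:
    def test_fixed_modes(self):
        params = ModelParams.from_mode(Mode.fg, alpha=1.0, epsilon=0.0,
                                       P0_structured=0.1)
        assert mode_column_default(Mode.fg, 7, params) == pytest.approx(0.9)
        assert mode_column_default(Mode.fr, 7, params) == pytest.approx(0.1)

    def test_fixed_red_with_inference_constraint_is_zero(self):
        params = ModelParams.from_mode(Mode.fr, alpha=1.0, epsilon=0.0,
                                       P0_structured=0.0)
        assert mode_column_default(Mode.fr, 3, params) == 0.0

    @pytest.mark.parametrize("P0", [0.0, 0.1])
    def test_alternating_modes_match_threshold_dynamics(self, P0):
        # oracle: iterate the threshold switch + X update and compare with
        # the closed-form alternating modes, both phases
        params = ModelParams.doli(P0_structured=P0)
        mode_params = ModelParams.from_mode(Mode.ag, alpha=1.0, epsilon=0.0,
                                            P0_structured=P0)
        x = params.X0 + 1.0  # above threshold: green start
        for j in range(20):
            p = default_probability(x, params)
            assert mode_column_default(Mode.ag, j, mode_params) == pytest.approx(p)
            assert mode_column_default(Mode.ar, j, mode_params) == pytest.approx(
                P0 if p == 1.0 - P0 else 1.0 - P0
            )
            x = update_X(p, params)

    def test_negative_column_rejected(self, doli_params):
        with pytest.raises(ValueError):
            mode_column_default(Mode.ag, -1, doli_params)


class TestMistakeCorrection:
    def test_no_mistakes_gives_zero(self, doli_params):
        prev = np.zeros(10, dtype=np.uint8)
        l = mistake_correction_column(prev, 0.9999, doli_params, prev_default=0.0001)
        assert np.all(l == 0.0)

    def test_zero_epsilon_gives_zero(self, doli_params):
        params = doli_params.with_(epsilon=0.0)
        prev = np.array([0, 1, 0, 0], dtype=np.uint8)
        assert np.all(mistake_correction_column(prev, 0.9999, params,
                                                prev_default=0.0001) == 0.0)

    def test_single_green_mistake_pulls_green_column_down(self, doli_params):
        # one green cell in a type-R column feeding a green-default column:
        # l = eps * exp(0) * (0 - p_j) = -0.95 * 0.9999
        prev = np.zeros(9, dtype=np.uint8)
        prev[4] = 1
        l = mistake_correction(prev, 0.9999, 4, doli_params, prev_default=0.0001)
        assert l == pytest.approx(-0.95 * 0.9999)

    def test_kernel_decays_with_squared_distance(self, doli_params):
        prev = np.zeros(9, dtype=np.uint8)
        prev[4] = 1
        l = mistake_correction_column(prev, 0.9999, doli_params, prev_default=0.0001)
        base = -0.95 * 0.9999
        assert l[5] == pytest.approx(base * np.exp(-1.0))
        assert l[6] == pytest.approx(base * np.exp(-4.0))

    def test_translation_invariance_and_symmetry(self, doli_params):
        prev = np.zeros(15, dtype=np.uint8)
        prev[7] = 1
        l = mistake_correction_column(prev, 0.9999, doli_params, prev_default=0.0001)
        # symmetric in |i - i'|
        assert l[7 - 3] == pytest.approx(l[7 + 3])
        # shifting the mistake shifts the correction identically
        prev2 = np.roll(prev, 2)
        l2 = mistake_correction_column(prev2, 0.9999, doli_params, prev_default=0.0001)
        assert np.allclose(l2[2:], l[:-2])

    def test_column_type_follows_default_not_majority(self, doli_params):
        # a normally-green column that drew mostly red keeps type G, so the
        # red cells are the mistakes
        prev = np.array([0, 0, 0, 1], dtype=np.uint8)
        l_typed = mistake_correction_column(prev, 0.0001, doli_params, prev_default=0.9999)
        assert np.all(l_typed[:3] > 0)  # pulled toward green near red mistakes
        l_majority = mistake_correction_column(prev, 0.0001, doli_params)
        assert l_majority[3] < 0  # majority fallback: the green cell is the mistake

    def test_empty_previous_column_rejected(self, doli_params):
        with pytest.raises(ValueError):
            mistake_correction_column(np.array([]), 0.5, doli_params)


class TestMixtureAndClipping:
    @pytest.mark.parametrize(
        "p, l, expected",
        [(0.9999, 0.0, 0.9999), (0.9999, -0.9499, 0.05), (0.9, 0.5, 1.0)],
    )
    def test_full_probability_clips(self, p, l, expected):
        assert full_probability(p, l) == pytest.approx(expected, abs=1e-12)

    def test_alpha_one_ignores_stochastic_component(self):
        params = ModelParams.doli(alpha=1.0, P0_droso=0.2)
        assert mixture_probability(0.9999, params) == pytest.approx(0.9999)

    def test_alpha_zero_is_pure_drosophila(self):
        params = ModelParams.drosophila(P0_droso=0.35)
        assert mixture_probability(0.123, params) == pytest.approx(0.65)

    def test_half_mixture_arithmetic(self):
        params = ModelParams.doli(alpha=0.5, P0_droso=0.35)
        assert mixture_probability(0.9999, params) == pytest.approx(0.82495)


class TestColumnDefaults:
    def test_doli_branch_alternates(self, doli_params):
        d = column_defaults(doli_params, 6)
        assert np.allclose(d.structured, [0.9999, 0.0001] * 3)
        assert d.x_trace is not None and d.x_trace.size == 6

    def test_uniform_branch_is_constant(self):
        params = ModelParams.doli(beta=-8.0, gamma=2.0)
        d = column_defaults(params, 5)
        assert np.allclose(d.structured, 0.99)
        assert d.x_trace is None

    def test_negative_threshold_rejected(self):
        params = ModelParams.doli(X0=-1.0)
        with pytest.raises(ValueError):
            column_defaults(params, 5)

    def test_structured_driver_required_when_alpha_positive(self):
        params = ModelParams(alpha=0.5, beta=None, gamma=None)
        with pytest.raises(ValueError):
            column_defaults(params, 5)


class TestParamValidation:
    def test_unit_interval_fields_checked(self):
        with pytest.raises(ValueError):
            ModelParams.doli(alpha=1.5)
        with pytest.raises(ValueError):
            ModelParams.doli(epsilon=-0.1)

    def test_gamma_strictly_positive(self):
        with pytest.raises(ValueError):
            ModelParams.doli(gamma=0.0)

    def test_mode_excludes_beta_gamma(self):
        with pytest.raises(ValueError):
            ModelParams(mode=Mode.ag, beta=8.0, gamma=10.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0, 1),
    epsilon=st.floats(0, 1),
    p0s=st.floats(0, 1),
    p0d=st.floats(0, 1),
    k=st.floats(0.1, 100),
    s=st.floats(0, 1),
    bits=st.lists(st.integers(0, 1), min_size=2, max_size=20),
    ctype=st.floats(0, 1),
)
def test_site_probability_always_in_unit_interval(alpha, epsilon, p0s, p0d, k, s,
                                                  bits, ctype):
    """The corrected-and-mixed site probability is a valid probability for
    every admissible parameter set and every realized previous column."""
    params = ModelParams(alpha=alpha, beta=None, gamma=None, P0_structured=p0s,
                         P0_droso=p0d, epsilon=epsilon, k=k, mode=Mode.ag)
    prev = np.array(bits, dtype=np.uint8)
    l = mistake_correction_column(prev, s, params, prev_default=ctype)
    P = mixture_probability(full_probability(s, l), params)
    assert np.all(P >= 0.0) and np.all(P <= 1.0)
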