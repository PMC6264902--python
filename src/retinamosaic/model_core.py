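"""Elementary operations of the colour-patterning model.

These are the pure building blocks the simulator and the likelihood share:
the threshold switch on the furrow factor X, the linear X update, the regime
classifier of the (beta, gamma, X0, P0) dynamics, the mode-based column
defaults used for inference, the mistake-propagation correction between
adjacent columns, and the alpha-mixture of structured and stochastic
components.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import Mode, ModelParams, Perturbation, Regime

__all__ = [
    "default_probability",
    "update_X",
    "classify_regime",
    "mode_column_default",
    "column_majority",
    "mistake_correction",
    "mistake_correction_column",
    "full_probability",
    "mixture_probability",
    "ColumnDefaults",
    "column_defaults",
]


def default_probability(X: float, params: ModelParams) -> float:
    """Column default green probability from the threshold switch on X.

    Returns ``P0_structured`` while X is at or below the threshold ``X0``
    (the boundary belongs to the lower branch) and ``1 - P0_structured``
    above it.
    """
    if not np.isfinite(X):
        raise ValueError(f"X must be finite, got {X!r}")
    if X <= params.X0:
        return params.P0_structured
    return 1.0 - params.P0_structured


def update_X(p_j: float, params: ModelParams) -> float:
    """Linear update of the furrow factor: ``X_{j+1} = gamma - beta * p_j``."""
    if not (0.0 <= p_j <= 1.0):
        raise ValueError(f"p_j must be a probability, got {p_j!r}")
    if params.beta is None or params.gamma is None:
        raise ValueError("update_X requires the (beta, gamma) parameterisation")
    return params.gamma - params.beta * p_j


def classify_regime(params: ModelParams) -> Regime:
    """Classify the long-run behaviour of the X dynamics.

    The two candidate fixed levels are ``X_A = gamma - beta*(1-P0)`` (reached
    after a green-default column) and ``X_B = gamma - beta*P0`` (after a red
    one).  A level is a self-consistent fixed point when it reproduces the
    default that generated it: X_A must stay above threshold, X_B at or below
    it.  Neither self-consistent means the dynamics hop between the levels
    (period-2 alternation, the Doli stripes); both self-consistent means the
    outcome is pinned by the initial condition.  In the latter case P0 > 0.5
    is reported as ``bistable`` (the overlap region of the phase diagram),
    while for P0 <= 0.5 — the uniform-fly situation arising for beta < 0 —
    the conventional above-threshold initial condition selects the green
    fixed point and the label is ``fixed_high``.

    Negative thresholds are physically inadmissible and labelled ``invalid``.
    """
    if params.X0 < 0:
        return Regime.invalid
    if params.beta is None or params.gamma is None:
        raise ValueError("classify_regime requires the (beta, gamma) parameterisation")
    P0 = params.P0_structured
    x_high = params.gamma - params.beta * (1.0 - P0)  # follows a green column
    x_low = params.gamma - params.beta * P0           # follows a red column
    green_fixed = x_high > params.X0
    red_fixed = x_low <= params.X0
    if green_fixed and red_fixed:
        if P0 > 0.5:
            return Regime.bistable
        return Regime.fixed_high
    if green_fixed:
        return Regime.fixed_high
    if red_fixed:
        return Regime.fixed_low
    return Regime.alternating


def mode_column_default(mode: Mode, j: int, params: ModelParams) -> float:
    """Structured-component green default of column ``j`` under a dynamic mode.

    Fixed-point modes hold their level for every column (``fg`` high green,
    ``fr`` low); alternating modes flip phase every column, with ``ag``
    green-high on even columns and ``ar`` the complementary phase.  During
    inference the fixed-point modes are used with ``P0_structured = 0``, so
    ``fr`` pins the structured component fully red and ``fg`` fully green.
    """
    if j < 0:
        raise ValueError(f"column index must be >= 0, got {j}")
    mode = Mode(mode)
    P0 = params.P0_structured
    if mode.is_fixed:
        return 1.0 - P0 if mode.starts_green else P0
    green_phase = (j % 2 == 0) == mode.starts_green
    return 1.0 - P0 if green_phase else P0


def column_majority(column: np.ndarray, default: Optional[float] = None) -> int:
    """Majority colour (1 = G column, 0 = R column) of a realized column.

    Exact ties are broken by the column's default green probability when
    given (``default >= 0.5`` labels it G), and default to G otherwise.
    """
    column = np.asarray(column)
    ones = int(column.sum())
    n = column.size
    if 2 * ones > n:
        return 1
    if 2 * ones < n:
        return 0
    if default is None:
        return 1
    return 1 if default >= 0.5 else 0


def mistake_correction_column(
    prev_column: np.ndarray,
    p_j: float,
    params: ModelParams,
    prev_default: Optional[float] = None,
) -> np.ndarray:
    """Mistake-propagation correction ``l_ij`` for every row of column ``j``.

    Mistakes are the elements of the realized previous column that disagree
    with that column's type: the type its default green probability
    ``prev_default`` dictates when given (a perturbed, normally-green column
    keeps type G even when half its draws came out red), or the realized
    majority otherwise.  Each mistake pulls nearby sites of the current
    column toward the opposite of its own colour, weighted by a kernel
    decaying exponentially in squared row distance::

        l_ij = epsilon * sum_{i' in mistakes} exp(-(i - i')**2 / k)
                        * ((1 - a_{i', j-1}) - p_j)

    where ``p_j`` is the current column's uncorrected structured-component
    green probability (the column default itself in a pure structured
    retina).  A previous column free of mistakes leaves the default
    untouched (zero vector).
    """
    prev_column = np.asarray(prev_column)
    if prev_column.size == 0:
        raise ValueError("previous column must be nonempty")
    n = prev_column.size
    if params.epsilon == 0.0:
        return np.zeros(n)
    if prev_default is None:
        ctype = column_majority(prev_column)
    else:
        ctype = 1 if prev_default >= 0.5 else 0
    mistakes = np.flatnonzero(prev_column != ctype)
    if mistakes.size == 0:
        return np.zeros(n)
    rows = np.arange(n)
    weights = np.exp(-((rows[:, None] - mistakes[None, :]) ** 2) / params.k)
    # all mistakes share one colour, so the target (1 - a_mistake) is the
    # previous column's type value
    return params.epsilon * weights.sum(axis=1) * (ctype - p_j)


def mistake_correction(
    prev_column: np.ndarray,
    p_j: float,
    i: int,
    params: ModelParams,
    prev_default: Optional[float] = None,
) -> float:
    """Correction ``l_ij`` at a single row ``i`` (see mistake_correction_column)."""
    prev_column = np.asarray(prev_column)
    if not (0 <= i < prev_column.size):
        raise ValueError(f"row index {i} outside previous column of size {prev_column.size}")
    return float(mistake_correction_column(prev_column, p_j, params, prev_default)[i])


def full_probability(p_j, l_ij):
    """Site probability ``P_ij = p_j + l_ij`` clipped into [0, 1]."""
    return np.clip(np.asarray(p_j, dtype=float) + l_ij, 0.0, 1.0)


def mixture_probability(p_structured, params: ModelParams):
    """Alpha-mixture of the structured component with the stochastic one.

    ``alpha * p_structured + (1 - alpha) * (1 - P0_droso)``; at alpha=1 the
    stochastic term vanishes, at alpha=0 only the Drosophila-like bias acts.
    """
    return params.alpha * np.asarray(p_structured, dtype=float) + (
        1.0 - params.alpha
    ) * params.droso_green


@dataclass(frozen=True)
class ColumnDefaults:
    """Per-column defaults of one model evaluation.

    ``p`` is the mixed (and possibly perturbed) green default actually used
    for drawing, ``structured`` the structured component feeding the mixture,
    and ``x_trace`` the X trajectory when the (beta, gamma) dynamics drive it.
    """

    p: np.ndarray
    structured: np.ndarray
    x_trace: Optional[np.ndarray]


def column_defaults(
    params: ModelParams,
    n_cols: int,
    x_init: Optional[float] = None,
    perturbation: Optional[Perturbation] = None,
) -> ColumnDefaults:
    """Compute every column's default green probability for one model.

    The structured component comes from the dynamic mode when given;
    otherwise from iterating the threshold switch and the linear X update
    (beta > 0, alternating/Doli branch) or from the constant uniform-fly
    probability ``P_ordered`` (beta < 0).  The defaults are deterministic in
    the parameters — they never depend on realized colours — which is what
    makes the likelihood factorise exactly over columns.
    """
    if n_cols < 1:
        raise ValueError(f"n_cols must be >= 1, got {n_cols}")
    if params.X0 < 0:
        raise ValueError("X0 < 0 is physically inadmissible")
    x_trace = None
    if params.mode is not None:
        structured = np.array(
            [mode_column_default(params.mode, j, params) for j in range(n_cols)]
        )
    elif params.beta is not None:
        if params.beta > 0:
            x = params.X0 + 1.0 if x_init is None else float(x_init)
            xs = np.empty(n_cols)
            structured = np.empty(n_cols)
            for j in range(n_cols):
                xs[j] = x
                structured[j] = default_probability(x, params)
                x = update_X(structured[j], params)
            x_trace = xs
        else:
            structured = np.full(n_cols, params.P_ordered)
    elif params.alpha == 0.0:
        # pure stochastic limit: the structured component carries zero weight
        structured = np.full(n_cols, 0.5)
    else:
        raise ValueError(
            "alpha > 0 requires a structured driver: set mode or (beta, gamma)"
        )
    p = mixture_probability(structured, params)
    if perturbation is not None:
        if not (0 <= perturbation.t < n_cols):
            raise ValueError(
                f"perturbation column {perturbation.t} outside pattern with {n_cols} columns"
            )
        p = p.copy()
        p[perturbation.t] = perturbation.P_per
    return ColumnDefaults(p=p, structured=structured, x_trace=x_trace)
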