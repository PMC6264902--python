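"""Parameter containers for the ommatidial colour-patterning model.

The model describes the binary colour choice (0 = red/pale, 1 = green/yellow)
of ommatidia laid down column by column behind the morphogenetic furrow.  A
furrow-borne factor X gates a threshold switch that sets each column's default
green probability; a mixing weight ``alpha`` interpolates between that
structured component and a fully stochastic, Drosophila-like component; and a
local correction term propagates mistakes from one column into the next.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

__all__ = ["Mode", "Regime", "ModelParams", "Perturbation"]


class Mode(str, Enum):
    """Discrete dynamic-mode variable used in place of (beta, gamma) for inference.

    The first letter selects the column dynamic (``f`` = fixed point,
    ``a`` = period-2 alternation), the second the initial condition
    (``r`` = green probability low / red start, ``g`` = high / green start).
    """

    fr = "fr"
    fg = "fg"
    ar = "ar"
    ag = "ag"

    @property
    def is_fixed(self) -> bool:
        return self in (Mode.fr, Mode.fg)

    @property
    def is_alternating(self) -> bool:
        return not self.is_fixed

    @property
    def starts_green(self) -> bool:
        return self in (Mode.fg, Mode.ag)


class Regime(str, Enum):
    """Qualitative behaviour of the X dynamics under the threshold switch."""

    fixed_high = "fixed_high"
    fixed_low = "fixed_low"
    alternating = "alternating"
    bistable = "bistable"
    invalid = "invalid"


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of one generative model.

    Parameters
    ----------
    alpha : float
        Mixing weight in [0, 1] of the structured (Doli / uniform-fly)
        component relative to the stochastic Drosophila-like component.
    beta, gamma : float, optional
        Constants of the linear X update ``X_{j+1} = gamma - beta * p_j``.
        ``beta > 0`` selects the alternating (Doli) branch of the mixture,
        ``beta < 0`` the uniform-fly branch.  ``gamma`` must be strictly
        positive.  Mutually exclusive with ``mode``.
    X0 : float
        Threshold on X of the column default switch.  Negative values are
        physically inadmissible; they are accepted here so that the regime
        classifier can label them, but simulation rejects them.
    P0_structured : float
        Default-probability constant of the structured component: columns
        default to green probability ``P0_structured`` below threshold and
        ``1 - P0_structured`` above it.
    P0_droso : float
        Pale/red bias constant of the stochastic component; the stochastic
        green probability is ``1 - P0_droso`` (0.35 reproduces the 35:65
        pale:yellow ratio of Drosophila).
    P_ordered : float
        Constant green probability of the hypothetical uniform fly used on
        the ``beta < 0`` branch (default 0.99).
    epsilon : float
        Local speckle correlation coefficient scaling the mistake-propagation
        correction between adjacent columns.
    k : float
        Spatial range of error propagation, in squared-row-distance units,
        strictly positive.
    mode : Mode, optional
        Inference-time parameterisation replacing (beta, gamma).  Exactly one
        of ``mode`` or the (beta, gamma) pair may drive the structured
        component.
    """

    alpha: float = 1.0
    beta: Optional[float] = 8.0
    gamma: Optional[float] = 10.0
    X0: float = 5.0
    P0_structured: float = 0.0001
    P0_droso: float = 0.35
    P_ordered: float = 0.99
    epsilon: float = 0.95
    k: float = 1.0
    mode: Optional[Mode] = None

    def __post_init__(self) -> None:
        _check_unit("alpha", self.alpha)
        _check_unit("P0_structured", self.P0_structured)
        _check_unit("P0_droso", self.P0_droso)
        _check_unit("P_ordered", self.P_ordered)
        _check_unit("epsilon", self.epsilon)
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k!r}")
        if not math.isfinite(self.X0):
            raise ValueError("X0 must be finite")
        if self.mode is not None:
            if self.beta is not None or self.gamma is not None:
                raise ValueError(
                    "mode and (beta, gamma) are mutually exclusive drivers of "
                    "the structured component; set beta=gamma=None with mode"
                )
            object.__setattr__(self, "mode", Mode(self.mode))
        else:
            if (self.beta is None) != (self.gamma is None):
                raise ValueError("beta and gamma must be given together")
            if self.gamma is not None and not self.gamma > 0:
                raise ValueError(f"gamma must be strictly positive, got {self.gamma!r}")

    @property
    def droso_green(self) -> float:
        """Green probability of the stochastic (Drosophila-like) component."""
        return 1.0 - self.P0_droso

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def doli(cls, **overrides) -> "ModelParams":
        """Parameters of a perfect ordered (Doli-like) retina: alternating
        columns via the worked constants beta=8, gamma=10, X0=5."""
        base = dict(alpha=1.0, beta=8.0, gamma=10.0, X0=5.0,
                    P0_structured=0.0001, epsilon=0.95, k=1.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def drosophila(cls, P0_droso: float = 0.35, **overrides) -> "ModelParams":
        """Fully stochastic retina (alpha=0) with the Drosophila 35:65 bias."""
        base = dict(alpha=0.0, beta=None, gamma=None, P0_droso=P0_droso, epsilon=0.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_mode(cls, mode: Mode, alpha: float, epsilon: float,
                  P0_structured: float, k: float = 1.0,
                  P0_droso: float = 0.5) -> "ModelParams":
        """Construct an inference-parameterised model (mode instead of beta/gamma)."""
        return cls(alpha=alpha, beta=None, gamma=None, epsilon=epsilon,
                   P0_structured=P0_structured, k=k, P0_droso=P0_droso,
                   mode=Mode(mode))


@dataclass(frozen=True)
class Perturbation:
    """Override of one column's default green probability during simulation.

    Models a developmental insult (e.g. thermal stress) hitting the furrow at
    column ``t``: that column is drawn with green probability ``P_per``
    instead of its model default.
    """

    t: int = 8
    P_per: float = 0.5

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"perturbation column must be >= 0, got {self.t}")
        _check_unit("P_per", self.P_per)
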