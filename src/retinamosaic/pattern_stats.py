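"""Summary statistics of retina patterns and the phase-diagram scan.

The central statistic is the mean horizontal correlation coefficient
<R^h>: the Pearson correlation over all horizontally adjacent site pairs
(a_ij, a_{i,j+1}).  Perfect alternating stripes give -1, fully random
mosaics give 0, and a constant (uniform-fly) retina has no defined
correlation, reported as NaN to keep it distinguishable from randomness.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams
from .pattern import RetinaPattern

__all__ = [
    "CorrelationStats",
    "PhaseDiagram",
    "column_labels_and_mistakes",
    "horizontal_correlation",
    "vertical_correlation",
    "pattern_statistics",
    "phase_diagram",
]


def _paired_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of pooled pairs; NaN when either side is constant."""
    x = x.astype(float).ravel()
    y = y.astype(float).ravel()
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def horizontal_correlation(pattern: RetinaPattern) -> float:
    """Lag-1 horizontal correlation <R^h> over adjacent-column site pairs."""
    if pattern.n_cols < 2:
        raise ValueError("horizontal correlation requires at least 2 columns")
    a = pattern.cells
    return _paired_pearson(a[:, :-1], a[:, 1:])


def vertical_correlation(pattern: RetinaPattern) -> float:
    """Lag-1 vertical correlation <R^v>, averaged over columns.

    Computed within each column (correlation of a_ij with a_{i+1,j}) and
    averaged across the columns where it is defined, so a striped retina
    whose columns are internally uniform reports NaN — no within-column
    structure — rather than a pooled-pairs artifact.
    """
    if pattern.n_rows < 2:
        raise ValueError("vertical correlation requires at least 2 rows")
    a = pattern.cells
    rs = [
        _paired_pearson(a[:-1, j], a[1:, j])
        for j in range(pattern.n_cols)
    ]
    rs = np.asarray(rs)
    if np.isnan(rs).all():
        return float("nan")
    return float(np.nanmean(rs))


def column_labels_and_mistakes(
    pattern: RetinaPattern,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label columns by majority colour and flag minority elements.

    Returns ``(labels, mistakes, ambiguous)``: per-column majority colour
    (1 = G column, 0 = R column), a boolean mistake mask (an element valued 1
    in an R column or 0 in a G column), and a per-column flag marking exact
    50/50 ties.  A tied column takes the label implied by the alternation
    phase of the nearest untied column (flip per intervening column); if
    every column is tied, labels default to G.
    """
    a = pattern.cells
    n, m = a.shape
    ones = a.sum(axis=0)
    labels = np.where(2 * ones > n, 1, 0).astype(np.int8)
    tied = 2 * ones == n
    if tied.any():
        untied = np.flatnonzero(~tied)
        for j in np.flatnonzero(tied):
            if untied.size == 0:
                labels[j] = 1
            else:
                jref = untied[np.argmin(np.abs(untied - j))]
                dist = abs(int(jref) - int(j))
                labels[j] = labels[jref] if dist % 2 == 0 else 1 - labels[jref]
    mistakes = a != labels[None, :]
    return labels, mistakes, tied


@dataclass(frozen=True)
class CorrelationStats:
    """Bundle of pattern summary statistics."""

    R_h: float
    R_v: float
    green_fraction: float
    mistakes_per_column: np.ndarray
    ambiguous_columns: np.ndarray

    def as_dict(self) -> dict:
        return {
            "R_h": self.R_h,
            "R_v": self.R_v,
            "green_fraction": self.green_fraction,
            "total_mistakes": int(self.mistakes_per_column.sum()),
            "n_ambiguous_columns": int(self.ambiguous_columns.sum()),
        }


def pattern_statistics(pattern: RetinaPattern) -> CorrelationStats:
    """Compute the full summary-statistic bundle for a pattern."""
    _, mistakes, tied = column_labels_and_mistakes(pattern)
    return CorrelationStats(
        R_h=horizontal_correlation(pattern) if pattern.n_cols >= 2 else float("nan"),
        R_v=vertical_correlation(pattern) if pattern.n_rows >= 2 else float("nan"),
        green_fraction=pattern.green_fraction,
        mistakes_per_column=mistakes.sum(axis=0),
        ambiguous_columns=tied,
    )


@dataclass(frozen=True)
class PhaseDiagram:
    """Mean <R^h> over a (branch, alpha, P0_droso) grid.

    ``values[b, i, j]`` is the mean horizontal correlation at
    ``alpha_grid[i]``, ``p0_droso_grid[j]`` on branch ``branches[b]``
    (``"doli"`` = beta > 0 alternating component, ``"uniform"`` = beta < 0
    uniform-fly component).  Cells whose replicates were all constant
    patterns are NaN.
    """

    values: np.ndarray
    alpha_grid: np.ndarray
    p0_droso_grid: np.ndarray
    branches: Tuple[str, ...]
    n_reps: int
    seed: Optional[int]


def phase_diagram(
    alpha_grid: Sequence[float],
    p0_droso_grid: Sequence[float],
    params_base: Optional[ModelParams] = None,
    n_reps: int = 5,
    size: Tuple[int, int] = (30, 50),
    seed: Optional[int] = None,
) -> PhaseDiagram:
    """Scan mean <R^h> over the signed-alpha x P0_droso plane.

    The right half of the published diagram (beta > 0) uses the alternating
    structured component; the left half (beta < 0) the constant uniform-fly
    component.  Both are simulated here as separate branch layers.
    """
    from .simulator import simulate

    alpha_grid = np.asarray(alpha_grid, dtype=float)
    p0_grid = np.asarray(p0_droso_grid, dtype=float)
    if alpha_grid.size == 0 or p0_grid.size == 0:
        raise ValueError("phase-diagram grids must be nonempty")
    if params_base is None:
        params_base = ModelParams.doli()
    rng = np.random.default_rng(seed)
    branches = ("doli", "uniform")
    values = np.full((2, alpha_grid.size, p0_grid.size), np.nan)
    beta = abs(params_base.beta) if params_base.beta else 8.0
    for b, branch in enumerate(branches):
        for i, alpha in enumerate(alpha_grid):
            for j, p0 in enumerate(p0_grid):
                params = params_base.with_(
                    alpha=float(alpha),
                    P0_droso=float(p0),
                    beta=beta if branch == "doli" else -beta,
                )
                rs = []
                for _ in range(n_reps):
                    res = simulate(params, size[0], size[1], seed=int(rng.integers(2**31)))
                    rs.append(horizontal_correlation(res.pattern))
                rs = np.asarray(rs)
                if not np.isnan(rs).all():
                    values[b, i, j] = np.nanmean(rs)
    return PhaseDiagram(
        values=values,
        alpha_grid=alpha_grid,
        p0_droso_grid=p0_grid,
        branches=branches,
        n_reps=n_reps,
        seed=seed,
    )
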