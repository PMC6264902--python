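"""Likelihood, grid-search maximum likelihood and parameter recovery.

The colour of every ommatidium is drawn from a Bernoulli probability that
depends only on the model parameters and the realized previous column, so
the likelihood of a whole pattern factorises exactly over columns and sites:

    log L = sum_ij [ a_ij log P_ij + (1 - a_ij) log(1 - P_ij) ]

with P_ij computed exactly as the simulator computes it.  No latent state
needs to be marginalised: the furrow factor X is a deterministic function of
the column defaults.

Inference follows the discretised grid-search scheme: the (beta, gamma) pair
is replaced by a four-valued dynamic-mode variable m in {fr, fg, ar, ag},
and alpha, epsilon and P0 take values on finite grids.  Fixed-point modes
pin P0 to 0, since alpha and P0 are fully interdependent there.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .model_core import (
    column_defaults,
    full_probability,
    mistake_correction_column,
    mixture_probability,
)
from .params import Mode, ModelParams
from .pattern import RetinaPattern

__all__ = [
    "ParameterGrid",
    "InferenceResult",
    "RecoveryReport",
    "RankCorrelationResult",
    "site_probabilities",
    "log_likelihood",
    "infer",
    "recovery_experiment",
    "spearman_permutation",
]

#: canonical (lexicographic) ordering of the dynamic modes
MODE_ORDER: Tuple[Mode, ...] = (Mode.fr, Mode.fg, Mode.ar, Mode.ag)


# ---------------------------------------------------------------------------
# parameter grid


@dataclass(frozen=True)
class ParameterGrid:
    """Finite discretised parameter space for grid-search ML.

    ``p0_droso`` is the (fixed, not searched) pale-bias constant of the
    stochastic component; 0.5 makes the stochastic component a fair coin so
    that mode/alpha/P0 remain identifiable.
    """

    modes: Tuple[Mode, ...] = MODE_ORDER
    alphas: Tuple[float, ...] = ()
    epsilons: Tuple[float, ...] = ()
    P0s: Tuple[float, ...] = ()
    ks: Tuple[float, ...] = (1.0,)
    p0_droso: float = 0.5

    def __post_init__(self) -> None:
        modes = tuple(m for m in MODE_ORDER if Mode(m) in {Mode(x) for x in self.modes})
        if not modes or not self.alphas or not self.epsilons or not self.ks:
            raise ValueError("parameter grid axes must be nonempty")
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "epsilons", tuple(float(e) for e in self.epsilons))
        object.__setattr__(self, "P0s", tuple(float(p) for p in self.P0s))
        object.__setattr__(self, "ks", tuple(float(k) for k in self.ks))
        for name in ("alphas", "epsilons", "P0s"):
            for v in getattr(self, name):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} values must lie in [0, 1], got {v}")
        for k in self.ks:
            if not k > 0:
                raise ValueError(f"k values must be > 0, got {k}")
        if self.modes_need_p0 and not self.P0s:
            raise ValueError("P0 axis must be nonempty when alternating modes are present")

    @property
    def modes_need_p0(self) -> bool:
        return any(Mode(m).is_alternating for m in self.modes)

    def p0_values(self, mode: Mode) -> Tuple[float, ...]:
        """Eligible P0 values for a mode: fixed-point modes pin P0 = 0."""
        return (0.0,) if Mode(mode).is_fixed else self.P0s

    def eligible_combinations(self) -> Iterator[Tuple[Mode, float, float, float, float]]:
        """Yield (mode, alpha, epsilon, P0, k) in canonical lexicographic order."""
        for mode in self.modes:
            for alpha in self.alphas:
                for eps in self.epsilons:
                    for P0 in self.p0_values(mode):
                        for k in self.ks:
                            yield mode, alpha, eps, P0, k

    def params_for(self, mode: Mode, alpha: float, epsilon: float,
                   P0: float, k: float) -> ModelParams:
        return ModelParams.from_mode(mode, alpha=alpha, epsilon=epsilon,
                                     P0_structured=P0, k=k, P0_droso=self.p0_droso)

    def __len__(self) -> int:
        n_alt = sum(1 for m in self.modes if Mode(m).is_alternating)
        n_fix = len(self.modes) - n_alt
        per = len(self.alphas) * len(self.epsilons) * len(self.ks)
        return per * (n_fix + n_alt * len(self.P0s))

    @classmethod
    def simulated(cls) -> "ParameterGrid":
        """Preset used for the simulated recovery study: alpha step 0.01,
        epsilon in {0, 0.1, ..., 0.5}, P0 in {0, 0.1}, k fixed at 1."""
        return cls(
            modes=MODE_ORDER,
            alphas=tuple(np.round(np.arange(0, 101) * 0.01, 2)),
            epsilons=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
            P0s=(0.0, 0.1),
            ks=(1.0,),
        )

    @classmethod
    def real_data(cls) -> "ParameterGrid":
        """Preset mirroring the finer grid used for photograph-derived data:
        alpha in {0.01..0.99}, P0 in {0.01,0.02,0.04,0.08,0.16}, epsilon in
        {0, 0.001, ..., 0.010}, k over perfect squares up to 625."""
        return cls(
            modes=MODE_ORDER,
            alphas=tuple(np.round(np.arange(1, 100) * 0.01, 2)),
            epsilons=tuple(np.round(np.arange(0, 11) * 0.001, 3)),
            P0s=(0.01, 0.02, 0.04, 0.08, 0.16),
            ks=tuple(float(i * i) for i in range(1, 26)),
        )


# ---------------------------------------------------------------------------
# likelihood


def site_probabilities(
    pattern: RetinaPattern, params: ModelParams, x_init: Optional[float] = None
) -> np.ndarray:
    """Per-site green probabilities P_ij conditioned on the realized pattern.

    This mirrors the simulator's generation path exactly: column defaults
    from the parameters, then the mistake correction from the realized
    previous column, clipped into [0, 1].
    """
    defaults = column_defaults(params, pattern.n_cols, x_init=x_init)
    structured = defaults.structured
    P = np.empty(pattern.cells.shape)
    P[:, 0] = defaults.p[0]
    for j in range(1, pattern.n_cols):
        l = mistake_correction_column(
            pattern.column(j - 1), structured[j], params,
            prev_default=structured[j - 1],
        )
        P[:, j] = mixture_probability(full_probability(structured[j], l), params)
    return P


def log_likelihood(
    pattern: RetinaPattern,
    params: ModelParams,
    floor: Optional[float] = None,
    x_init: Optional[float] = None,
) -> float:
    """Exact log-likelihood of a pattern; -inf when an observed cell has
    probability zero (unless a floor probability is given)."""
    P = site_probabilities(pattern, params, x_init=x_init)
    if floor is not None:
        P = np.clip(P, floor, 1.0 - floor)
    a = pattern.cells.astype(bool)
    with np.errstate(divide="ignore"):
        lp = np.log(P)
        l1p = np.log1p(-P)
    return float(np.where(a, lp, l1p).sum())


# ---------------------------------------------------------------------------
# fast grid evaluation

def _pattern_summary(A: np.ndarray, ks: Sequence[float]) -> dict:
    """Pattern precomputations reused across the whole grid.

    For every column: the count of 1s, plus — for each kernel range k — the
    summed kernel weights of the would-be mistakes under either column type
    (K_G: mistakes are the 0s of a type-G column; K_R: the 1s of a type-R
    column).
    """
    n, m = A.shape
    ones = A.sum(axis=0)
    rows = np.arange(n)
    d2 = (rows[:, None] - rows[None, :]) ** 2
    K_G, K_R = {}, {}
    for k in ks:
        W = np.exp(-d2 / k)
        K_G[k] = W @ (1 - A)  # (n, m)
        K_R[k] = W @ A
    return {"n": n, "m": m, "ones": ones, "K_G": K_G, "K_R": K_R}


def _structured_defaults(mode: Mode, P0: float, m: int) -> np.ndarray:
    """Structured-component defaults per column for a dynamic mode."""
    mode = Mode(mode)
    if mode.is_fixed:
        level = 1.0 - P0 if mode.starts_green else P0
        return np.full(m, level)
    phase = np.arange(m) % 2 == 0
    green = phase == mode.starts_green
    return np.where(green, 1.0 - P0, P0)


def _iid_contrib(ll: np.ndarray, pvec: np.ndarray, n1: int, n0: int) -> None:
    """Add an iid-column contribution in place, avoiding 0 * (-inf)."""
    with np.errstate(divide="ignore"):
        if n1 > 0:
            ll += n1 * np.log(pvec)
        if n0 > 0:
            ll += n0 * np.log1p(-pvec)


def _block_loglik(
    A: np.ndarray,
    summary: dict,
    structured: np.ndarray,
    eps: float,
    k: float,
    alphas: np.ndarray,
    g: float,
    floor: Optional[float],
) -> np.ndarray:
    """Log-likelihoods for all alpha values at fixed (mode, P0, epsilon, k).

    P_ij = alpha * clip(s_j + eps*K_ij*(T - s_j)) + (1-alpha) * g, where T
    is the previous column's type under its structured default: the whole
    corrected structured component is alpha-independent, so it is computed
    once per column and mixed across the entire alpha axis at once.
    """
    n, m = summary["n"], summary["m"]
    ones = summary["ones"]
    one_minus = 1.0 - alphas
    ll = np.zeros(alphas.size)
    pv = alphas * structured[0] + one_minus * g
    if floor is not None:
        pv = np.clip(pv, floor, 1 - floor)
    _iid_contrib(ll, pv, int(ones[0]), n - int(ones[0]))
    K_G = summary["K_G"][k]
    K_R = summary["K_R"][k]
    for j in range(1, m):
        prev = j - 1
        sj = structured[j]
        ctype = 1.0 if structured[prev] >= 0.5 else 0.0
        n_mistakes = n - int(ones[prev]) if ctype == 1.0 else int(ones[prev])
        if eps == 0.0 or n_mistakes == 0:
            # no mistakes in the previous column (or no coupling): iid column
            pv = alphas * sj + one_minus * g
            if floor is not None:
                pv = np.clip(pv, floor, 1 - floor)
            _iid_contrib(ll, pv, int(ones[j]), n - int(ones[j]))
            continue
        K = (K_G if ctype == 1.0 else K_R)[:, prev]
        C = np.clip(sj + eps * K * (ctype - sj), 0.0, 1.0)  # (n,)
        P = alphas[:, None] * C[None, :] + one_minus[:, None] * g  # (nA, n)
        if floor is not None:
            P = np.clip(P, floor, 1 - floor)
        with np.errstate(divide="ignore"):
            lp = np.log(P)
            l1p = np.log1p(-P)
        acol = A[:, j].astype(bool)
        ll += np.where(acol[None, :], lp, l1p).sum(axis=1)
    return ll


# ---------------------------------------------------------------------------
# grid-search maximum likelihood


@dataclass(frozen=True)
class InferenceResult:
    """Maximum-likelihood grid point with the full likelihood surface.

    ``surface`` holds one row per eligible grid point in canonical
    lexicographic order (mode, alpha, epsilon, P0, k); ``ties`` lists every
    grid point attaining the maximum (the reported ``best_params`` is the
    lexicographically first of them).
    """

    best_params: ModelParams
    log_likelihood: float
    surface: pd.DataFrame
    ties: pd.DataFrame

    @property
    def n_ties(self) -> int:
        return len(self.ties)


def infer(
    pattern: RetinaPattern,
    grid: Optional[ParameterGrid] = None,
    floor: Optional[float] = None,
) -> InferenceResult:
    """Exhaustive maximum-likelihood search over a discretised grid.

    Evaluates the exact column-factorised log-likelihood at every eligible
    grid point and returns the maximiser, breaking ties deterministically in
    favour of the lexicographically first point (mode order fr, fg, ar, ag,
    then ascending alpha, epsilon, P0, k).
    """
    if grid is None:
        grid = ParameterGrid.simulated()
    A = pattern.cells.astype(np.float64)
    summary = _pattern_summary(A, grid.ks)
    alphas = np.asarray(grid.alphas)
    g = 1.0 - grid.p0_droso
    blocks = {}
    for mode in grid.modes:
        for P0 in grid.p0_values(mode):
            structured = _structured_defaults(mode, P0, summary["m"])
            for eps in grid.epsilons:
                for k in grid.ks:
                    blocks[(mode, P0, eps, k)] = _block_loglik(
                        A, summary, structured, eps, k, alphas, g, floor
                    )
    alpha_index = {a: i for i, a in enumerate(grid.alphas)}
    rows = [
        (mode.value, alpha, eps, P0, k,
         float(blocks[(mode, P0, eps, k)][alpha_index[alpha]]))
        for mode, alpha, eps, P0, k in grid.eligible_combinations()
    ]
    surface = pd.DataFrame(
        rows, columns=["mode", "alpha", "epsilon", "P0", "k", "loglik"]
    )
    ll = surface["loglik"].to_numpy()
    best_idx = int(np.argmax(ll))  # first occurrence wins on exact ties
    best = surface.iloc[best_idx]
    ties = surface[ll == ll[best_idx]].reset_index(drop=True)
    best_params = grid.params_for(
        Mode(best["mode"]), best["alpha"], best["epsilon"], best["P0"], best["k"]
    )
    return InferenceResult(
        best_params=best_params,
        log_likelihood=float(best["loglik"]),
        surface=surface,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# recovery experiment


@dataclass(frozen=True)
class RecoveryReport:
    """Results of the simulate-then-infer parameter-recovery study."""

    records: pd.DataFrame
    n_realizations: int
    seed: Optional[int]
    size: Tuple[int, int]

    def alpha_curve(self, bin_width: float = 0.1) -> pd.DataFrame:
        """Per-true-alpha-bin means: inferred alpha, absolute errors of every
        parameter and the mode misidentification rate."""
        df = self.records
        edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
        bins = np.clip(np.digitize(df["true_alpha"], edges) - 1, 0, edges.size - 2)
        out = df.assign(_bin=bins).groupby("_bin").apply(
            lambda gdf: pd.Series(
                {
                    "n": len(gdf),
                    "mean_true_alpha": gdf["true_alpha"].mean(),
                    "mean_inferred_alpha": gdf["inf_alpha"].mean(),
                    "std_inferred_alpha": gdf["inf_alpha"].std(ddof=0),
                    "mae_alpha": (gdf["inf_alpha"] - gdf["true_alpha"]).abs().mean(),
                    "mae_epsilon": (gdf["inf_epsilon"] - gdf["true_epsilon"]).abs().mean(),
                    "mae_P0": (gdf["inf_P0"] - gdf["true_P0"]).abs().mean(),
                    "mode_error_rate": (gdf["inf_mode"] != gdf["true_mode"]).mean(),
                }
            ),
            include_groups=False,
        )
        out.index = edges[:-1][out.index.astype(int)] + bin_width / 2
        out.index.name = "alpha_bin_center"
        return out

    def epsilon_curve(self) -> pd.DataFrame:
        """Mean inferred epsilon per true epsilon value."""
        return (
            self.records.groupby("true_epsilon")["inf_epsilon"]
            .agg(["mean", "std", "count"])
            .rename(columns={"mean": "mean_inferred_epsilon"})
        )


def recovery_experiment(
    n_realizations: int,
    size: Tuple[int, int] = (30, 50),
    grid: Optional[ParameterGrid] = None,
    seed: Optional[int] = None,
) -> RecoveryReport:
    """Simulate-then-infer self-consistency study.

    For each realization, true parameters are drawn uniformly from the set
    of eligible grid combinations, one pattern of the given size is
    simulated, and grid-search ML is run on it.  Aggregated curves (mean
    inferred alpha vs true alpha, etc.) are exposed on the report.
    """
    from .simulator import simulate

    if n_realizations < 1:
        raise ValueError(f"n_realizations must be >= 1, got {n_realizations}")
    if grid is None:
        grid = ParameterGrid.simulated()
    combos = list(grid.eligible_combinations())
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_realizations):
        mode, alpha, eps, P0, k = combos[int(rng.integers(len(combos)))]
        true = grid.params_for(mode, alpha, eps, P0, k)
        res = simulate(true, size[0], size[1], seed=int(rng.integers(2**31)))
        fit = infer(res.pattern, grid)
        bp = fit.best_params
        records.append(
            {
                "true_mode": mode.value,
                "true_alpha": alpha,
                "true_epsilon": eps,
                "true_P0": P0,
                "true_k": k,
                "inf_mode": bp.mode.value,
                "inf_alpha": bp.alpha,
                "inf_epsilon": bp.epsilon,
                "inf_P0": bp.P0_structured,
                "inf_k": bp.k,
                "loglik": fit.log_likelihood,
                "n_ties": fit.n_ties,
            }
        )
    return RecoveryReport(
        records=pd.DataFrame(records),
        n_realizations=n_realizations,
        seed=seed,
        size=size,
    )


# ---------------------------------------------------------------------------
# rank correlation with permutation p-value


@dataclass(frozen=True)
class RankCorrelationResult:
    rho: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    method: str = "random"


def spearman_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: Optional[int] = 10000,
    seed: Optional[int] = None,
) -> RankCorrelationResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    The p-value is the fraction of permutations of ``y`` whose |rho| is at
    least the observed |rho|; the identity permutation is always included in
    the count, so p > 0.  With ``n_permutations=None`` all n! permutations
    are enumerated exactly (n <= 9 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation is undefined for a constant vector")
    rho = float(sp_stats.spearmanr(x, y).statistic)
    tol = 1e-12
    if n_permutations is None:
        if x.size > 9:
            raise ValueError("exact enumeration supported only for n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(range(x.size)):
            r = float(sp_stats.spearmanr(x, y[list(perm)]).statistic)
            count += abs(r) >= abs(rho) - tol
            total += 1
        return RankCorrelationResult(rho, count / total, total, None, method="exact")
    rng = np.random.default_rng(seed)
    count = 1  # the identity permutation
    for _ in range(n_permutations):
        r = float(sp_stats.spearmanr(x, rng.permutation(y)).statistic)
        count += abs(r) >= abs(rho) - tol
    return RankCorrelationResult(
        rho, count / (n_permutations + 1), n_permutations, seed, method="random"
    )
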