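"""Exhaustive design search over duration and allocation weights.

Candidate designs are pairs (pi, q): an allocation weight vector on the fixed
support points and a number of inspection periods q <= q_max (the first q
grid intervals).  For a two-arm trial with the default 0.01 weight step and
q_max = 12 this is the 12 x 99 = 1188-candidate grid.

The search is a plain enumeration: the per-period, per-group information
matrices are precomputed once in the full-duration parameter layout, so each
grid cell costs one small determinant.  Ties at 1e-10 tolerance are broken
deterministically: smallest q first, then the allocation closest to equal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as mdl
from .criteria import SelectionMatrix, efficiency_from_phi, phi_from_fim, selection_matrix
from .information import CostSpec, Design, _jacobian_from_lambda

__all__ = [
    "SearchGrid",
    "DesignProblem",
    "OptimizeResult",
    "ScenarioEvaluator",
    "multi_arm_grid",
    "optimize",
    "equal_allocation_optimum",
    "efficiency_surface",
]

log = logging.getLogger(__name__)

TIE_TOL = 1e-10


def multi_arm_grid(k: int, step: float = 0.01) -> tuple:
    """All weight vectors on the k-simplex with coordinates multiples of step.

    Coordinates of exactly 0 are excluded (each arm keeps at least one step of
    weight): single-group designs carry no information on treatment contrasts.
    """
    if k < 2:
        raise ValueError("need at least two groups")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("1/step must be an integer")
    grid = tuple(
        tuple(m * step for m in parts)
        for parts in _compositions(n, k)
    )
    if not grid:
        raise ValueError(f"step {step} too coarse for {k} groups (empty grid)")
    return grid


def _compositions(n: int, k: int):
    """Integer compositions of n into k positive parts, lexicographic."""
    if k == 1:
        if n >= 1:
            yield (n,)
        return
    for first in range(1, n - k + 2):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


@dataclass(frozen=True)
class SearchGrid:
    """Candidate durations and allocation weight vectors."""

    q_candidates: tuple
    weight_grid: tuple  # tuples of k weights, each summing to 1
    allocation_mode: str = "free"

    def __post_init__(self):
        if not self.q_candidates:
            raise ValueError("no candidate period counts")
        if not self.weight_grid:
            raise ValueError("no candidate weight vectors")

    @property
    def size(self) -> int:
        return len(self.q_candidates) * len(self.weight_grid)

    @classmethod
    def two_arm(cls, q_max: int, step: float = 0.01,
                allocation: str = "free") -> "SearchGrid":
        qs = tuple(range(1, q_max + 1))
        if allocation == "equal":
            return cls(qs, ((0.5, 0.5),), "equal")
        if allocation == "free":
            return cls(qs, multi_arm_grid(2, step), "free")
        raise ValueError(f"unknown allocation mode {allocation!r}")


@dataclass(frozen=True)
class DesignProblem:
    """A fully specified design scenario: model, nominal theta, costs, criterion."""

    spec: mdl.ModelSpec
    theta: np.ndarray
    costspec: CostSpec
    criterion: str = "treatment_effects"
    subset: tuple | None = None
    support: tuple = (0.0, 1.0)

    def selection(self, q: int) -> SelectionMatrix:
        return selection_matrix(self.criterion, self.spec, q, self.subset)


@dataclass
class OptimizeResult:
    design: Design
    phi: float
    v: int
    table: pd.DataFrame
    problem: DesignProblem = field(repr=False, default=None)


class ScenarioEvaluator:
    """Precomputed information and cost pieces for one scenario.

    Period information matrices are accumulated in the full q_max layout; for
    a saturated baseline the submatrix belonging to the first q periods (plus
    effects and structural zero) is extracted per candidate duration.
    """

    def __init__(self, problem: DesignProblem):
        self.problem = problem
        spec = problem.spec
        theta = np.asarray(problem.theta, dtype=float).ravel()
        cost = problem.costspec
        q_max = spec.q_max
        d = spec.theta_dim()
        self.q_max = q_max
        self.cum_fim = []   # per support point: (q_max, d, d) cumulative sums
        self.costs = []     # per support point: cost c(x_i, q) for q = 1..q_max
        # First duration at which a hazard underflows to zero: a saturated
        # model is exactly singular from there on (no information on that
        # period's own intercept), so those cells are reported as infeasible.
        self.degenerate_from = q_max + 1
        for i, x in enumerate(problem.support):
            lam = mdl.hazard_path(spec, x, theta)
            surv = np.cumprod(lam[:, spec.n_risks])
            surv_prev = np.concatenate([[1.0], surv[:-1]])
            wt = surv_prev * (1.0 - cost.rho) ** np.arange(q_max)
            cum = np.zeros((q_max, d, d))
            acc = np.zeros((d, d))
            for t in range(1, q_max + 1):
                if wt[t - 1] > 0.0 and t < self.degenerate_from:
                    X = mdl.design_matrix(spec, t, x)
                    try:
                        G = _jacobian_from_lambda(spec, lam[t - 1], X)
                    except FloatingPointError:
                        log.info(
                            "hazard underflow at support %s, period %d; "
                            "durations q >= %d are infeasible", x, t, t
                        )
                        self.degenerate_from = min(self.degenerate_from, t)
                    else:
                        M = G.T @ (G / lam[t - 1][:, None])
                        acc = acc + wt[t - 1] * 0.5 * (M + M.T)
                cum[t - 1] = acc
            self.cum_fim.append(cum)
            c1, c2 = cost.recruit(i), cost.measure(i)
            if cost.variant == "all_visits":
                cq = c1 + c2 * (np.arange(1, q_max + 1) + 1.0)
            else:
                # sum_{s=1}^{q} S(s-1|x)(1-rho)^{s-1} (+1 with intake charged)
                base = 1.0 if cost.baseline_measurement else 0.0
                cq = c1 + c2 * (base + np.cumsum(wt))
            self.costs.append(cq)
        self._idx = {}
        self._sel = {}

    def indices(self, q: int) -> np.ndarray:
        if q not in self._idx:
            spec = self.problem.spec
            if spec.baseline == "saturated":
                J = spec.n_risks
                self._idx[q] = np.concatenate(
                    [np.arange(q * J), np.arange(self.q_max * J, spec.theta_dim())]
                )
            else:
                self._idx[q] = np.arange(spec.theta_dim())
        return self._idx[q]

    def selection(self, q: int) -> SelectionMatrix:
        if q not in self._sel:
            self._sel[q] = self.problem.selection(q)
        return self._sel[q]

    def standardized_fim(self, weights, q: int) -> np.ndarray:
        idx = self.indices(q)
        M = sum(w * self.cum_fim[i][q - 1] for i, w in enumerate(weights))
        c = sum(w * self.costs[i][q - 1] for i, w in enumerate(weights))
        return M[np.ix_(idx, idx)] / c

    def phi(self, weights, q: int) -> tuple:
        sel = self.selection(q)
        if q >= self.degenerate_from:
            return np.inf, sel.v
        return phi_from_fim(self.standardized_fim(weights, q), sel.A), sel.v

    def evaluate_design(self, design: Design) -> tuple:
        """(phi, v) for an arbitrary design on this scenario's support."""
        if tuple(design.support) != tuple(self.problem.support):
            raise ValueError("design support differs from the scenario support")
        return self.phi(design.weights, design.q)


def optimize(problem: DesignProblem, grid: SearchGrid) -> OptimizeResult:
    """Exhaustive minimization of the D_A criterion over the candidate grid."""
    ev = ScenarioEvaluator(problem)
    k = len(problem.support)
    rows = []
    for cell, (q, w) in enumerate(
        itertools.product(grid.q_candidates, grid.weight_grid)
    ):
        phi, v = ev.phi(w, q)
        rows.append((q, *w, phi, v))
        if cell % 100 == 0:
            log.info("grid progress: %d/%d cells", cell, grid.size)
        log.debug("cell q=%d w=%s phi=%.10g", q, w, phi)
    cols = ["q"] + [f"w{i + 1}" for i in range(k)] + ["phi", "v"]
    table = pd.DataFrame(rows, columns=cols)
    if k == 2:
        table["pi"] = table["w2"]
    finite = table["phi"].to_numpy()
    if not np.any(np.isfinite(finite)):
        raise RuntimeError(
            "all candidate designs have singular information; "
            "the criterion is undefined on the whole grid"
        )
    best = _pick_best(table, k)
    v_best = int(best["v"])
    phi_best = float(best["phi"])
    table["re"] = [
        efficiency_from_phi(phi_best, v_best, p, int(vv))
        for p, vv in zip(table["phi"], table["v"])
    ]
    design = Design(
        support=problem.support,
        weights=tuple(best[f"w{i + 1}"] for i in range(k)),
        q=int(best["q"]),
    )
    return OptimizeResult(design, phi_best, v_best, table, problem)


def _pick_best(table: pd.DataFrame, k: int) -> pd.Series:
    # Rank on the per-parameter scale phi / v (log det^{1/v}) so D-criterion
    # values remain comparable when theta's dimension varies with q; for a
    # fixed-rank selection matrix this is a monotone relabelling of phi.
    phi = (table["phi"] / table["v"]).to_numpy()
    cand = table[phi <= np.nanmin(phi[np.isfinite(phi)]) + TIE_TOL]
    cand = cand[cand["q"] == cand["q"].min()]
    dist = sum((cand[f"w{i + 1}"] - 1.0 / k) ** 2 for i in range(k))
    return cand.loc[dist.idxmin()]


def equal_allocation_optimum(problem: DesignProblem,
                             q_candidates: tuple | None = None) -> OptimizeResult:
    """Best duration when subjects are split equally across the groups."""
    k = len(problem.support)
    qs = q_candidates or tuple(range(1, problem.spec.q_max + 1))
    grid = SearchGrid(tuple(qs), ((1.0 / k,) * k,), "equal")
    return optimize(problem, grid)


def efficiency_surface(problem: DesignProblem, grid: SearchGrid | None = None
                       ) -> pd.DataFrame:
    """Long-format (pi, q, RE) table of efficiencies relative to the optimum."""
    grid = grid or SearchGrid.two_arm(problem.spec.q_max)
    res = optimize(problem, grid)
    cols = ["pi", "q", "re"] if "pi" in res.table else ["q", "re"]
    return res.table[cols].reset_index(drop=True)
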