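"""Fisher information for the discrete-time competing-risks model.

Per person-period the outcome is multinomial with probabilities
``lambda(t|x)``, so the individual information in period t is the Gram form

    M_t(x) = (d lambda / d theta)' diag(lambda)^{-1} (d lambda / d theta),

with the hazard Jacobian obtained from the unified link,
``d lambda / d theta' = (C' D^{-1} L)^{-1} X_t``, ``D = diag(L lambda)``.
Group-level information weights each period by the expected fraction of the
group still at risk, ``S(t-1|x) (1-rho)^{t-1}`` (attrition rate rho), and the
cost-standardized information divides the design-weighted sum by the average
per-subject cost so designs with different durations compete on equal
expenditure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model as mdl

__all__ = [
    "Design",
    "CostSpec",
    "hazard_jacobian",
    "period_fim",
    "risk_set_weight",
    "group_fim",
    "cost_per_subject",
    "standardized_fim",
    "cost_weights",
    "derived_sample_size",
]

# Reciprocal-condition threshold below which a matrix is treated as singular.
RCOND_SINGULAR = 1e-12


@dataclass(frozen=True)
class Design:
    """Exact design: support points, allocation weights, duration, optional N."""

    support: tuple
    weights: tuple
    q: int
    N: float | None = None

    def __post_init__(self):
        w = tuple(float(v) for v in self.weights)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "support", tuple(self.support))
        if len(self.support) != len(w):
            raise ValueError("support and weights must have equal length")
        if len(set(self.support)) != len(self.support):
            raise ValueError("support points must be distinct")
        if any(v <= 0 for v in w):
            raise ValueError("allocation weights must be positive")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("allocation weights must sum to 1")
        if self.q < 1:
            raise ValueError("q must be >= 1")

    @property
    def k(self) -> int:
        return len(self.support)

    def group_sizes(self, N: int | None = None) -> tuple:
        """Integer group sizes by largest-remainder rounding of N * pi_i."""
        N = int(self.N if N is None else N)
        raw = np.array(self.weights) * N
        base = np.floor(raw).astype(int)
        short = N - int(base.sum())
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
        return tuple(int(n) for n in base)


@dataclass(frozen=True)
class CostSpec:
    """Study cost structure.

    ``c1`` is the per-group recruitment cost (scalar or one value per group),
    ``c2`` the per-measurement cost.  ``variant`` chooses between charging all
    scheduled measurements per subject (``all_visits``) and charging only
    measurements taken while the subject is still under observation
    (``until_event``: the expected measurement count sum_s S(s-1|x)(1-rho)^{s-1}
    over the implemented visits).  ``rho`` is the per-interval attrition
    probability.  ``baseline_measurement`` additionally charges the intake
    measurement at a_0; it is off by default, so ``all_visits`` charges q + 1
    visits while ``until_event`` charges the q post-baseline ones.
    """

    c1: object = 1.0
    c2: object = 1.0
    variant: str = "until_event"
    rho: float = 0.0
    c0: float = 0.0
    budget: float | None = None
    baseline_measurement: bool = False

    def __post_init__(self):
        if self.variant not in ("all_visits", "until_event"):
            raise ValueError(f"unknown cost variant {self.variant!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("attrition rate rho must lie in [0, 1)")
        for c in np.atleast_1d(self.c1):
            if c < 0:
                raise ValueError("recruitment costs must be nonnegative")
        for c in np.atleast_1d(self.c2):
            if c <= 0:
                raise ValueError("measurement costs must be positive")
        if self.c0 < 0:
            raise ValueError("setup cost must be nonnegative")

    @classmethod
    def from_cost_ratio(cls, f, variant: str = "until_event", rho: float = 0.0,
                        **kw) -> "CostSpec":
        """Costs from the recruitment/measurement ratio f = c1 / c2 (c2 = 1)."""
        f = tuple(np.atleast_1d(np.asarray(f, dtype=float)))
        c1 = f[0] if len(f) == 1 else f
        return cls(c1=c1, c2=1.0, variant=variant, rho=rho, **kw)

    def recruit(self, i: int) -> float:
        c = np.atleast_1d(self.c1)
        return float(c[i] if c.size > 1 else c[0])

    def measure(self, i: int) -> float:
        c = np.atleast_1d(self.c2)
        return float(c[i] if c.size > 1 else c[0])


def hazard_jacobian(spec: mdl.ModelSpec, t: int, x, theta, q: int | None = None
                    ) -> np.ndarray:
    """d lambda(t|x) / d theta', shape (J+1) x theta_dim(q).

    Columns sum to zero because the hazards sum to one identically.
    """
    lam = mdl.hazards(spec, t, x, theta, q)
    X = mdl.design_matrix(spec, t, x, q)
    return _jacobian_from_lambda(spec, lam, X)


def _jacobian_from_lambda(spec: mdl.ModelSpec, lam: np.ndarray, X: np.ndarray
                          ) -> np.ndarray:
    if np.any(lam <= 0.0):
        raise FloatingPointError(
            "a hazard component underflowed to 0; the period carries no "
            "information on its own coordinates and the FIM is singular"
        )
    L = mdl.contrast_L(spec.n_risks, spec.link)
    Ct = mdl.contrast_C(spec.n_risks)
    D = L @ lam
    B = Ct @ (L / D[:, None])
    try:
        return np.linalg.solve(B, X)
    except np.linalg.LinAlgError as err:  # pragma: no cover - interior hazards
        raise np.linalg.LinAlgError(
            f"singular link Jacobian (condition number {np.linalg.cond(B):.3e})"
        ) from err


def period_fim(spec: mdl.ModelSpec, t: int, x, theta, q: int | None = None
               ) -> np.ndarray:
    """Individual information M_t(x), symmetric PSD of rank <= J+1."""
    lam = mdl.hazards(spec, t, x, theta, q)
    X = mdl.design_matrix(spec, t, x, q)
    G = _jacobian_from_lambda(spec, lam, X)
    M = G.T @ (G / lam[:, None])
    return 0.5 * (M + M.T)


def risk_set_weight(spec: mdl.ModelSpec, t: int, x, theta, rho: float,
                    q: int | None = None) -> float:
    """Expected at-risk fraction entering period t: S(t-1|x) (1-rho)^{t-1}."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    return mdl.survival(spec, t - 1, x, theta, q) * (1.0 - rho) ** (t - 1)


def group_fim(spec: mdl.ModelSpec, x, theta, q: int, rho: float = 0.0) -> np.ndarray:
    """Per-subject information of a group observed for q periods.

    Sum over t of the risk-set weight times the period information; periods
    whose weight underflows to zero are skipped.
    """
    q = spec.check_q(q)
    lam = mdl.hazard_path(spec, x, theta, q)
    surv_prev = np.concatenate([[1.0], np.cumprod(lam[:, spec.n_risks])[:-1]])
    M = np.zeros((spec.theta_dim(q),) * 2)
    for t in range(1, q + 1):
        w = surv_prev[t - 1] * (1.0 - rho) ** (t - 1)
        if w == 0.0:
            continue
        X = mdl.design_matrix(spec, t, x, q)
        G = _jacobian_from_lambda(spec, lam[t - 1], X)
        M += w * (G.T @ (G / lam[t - 1][:, None]))
    return 0.5 * (M + M.T)


def cost_per_subject(spec: mdl.ModelSpec, x, q: int, theta, costspec: CostSpec,
                     group_index: int = 0) -> float:
    """Expected cost of one subject under condition x observed for q periods.

    ``all_visits``: c1 + c2 (q + 1).  ``until_event``: c1 + c2 sum_{s=1}^{q}
    S(s-1|x)(1-rho)^{s-1}, plus one extra c2 for the intake measurement when
    ``baseline_measurement`` is set.
    """
    c1 = costspec.recruit(group_index)
    c2 = costspec.measure(group_index)
    if costspec.variant == "all_visits":
        return c1 + c2 * (q + 1)
    q = spec.check_q(q)
    lam = mdl.hazard_path(spec, x, theta, q)
    surv = np.cumprod(lam[:, spec.n_risks])
    # S_i(a_s) = S(s-1|x)(1-rho)^{s-1}; the s = 1 term is always 1.
    terms = sum(
        surv[s - 2] * (1.0 - costspec.rho) ** (s - 1) if s >= 2 else 1.0
        for s in range(1, q + 1)
    )
    if costspec.baseline_measurement:
        terms += 1.0
    return c1 + c2 * terms


def cost_weights(spec: mdl.ModelSpec, design: Design, theta, costspec: CostSpec
                 ) -> np.ndarray:
    """Cost-inflated weights pi_i^c = pi_i c(x_i) / sum_j pi_j c(x_j)."""
    c = np.array(
        [
            cost_per_subject(spec, x, design.q, theta, costspec, i)
            for i, x in enumerate(design.support)
        ]
    )
    w = np.array(design.weights) * c
    return w / w.sum()


def standardized_fim(spec: mdl.ModelSpec, design: Design, theta,
                     costspec: CostSpec) -> np.ndarray:
    """Cost-standardized information sum_i pi_i M(x_i) / sum_j pi_j c(x_j)."""
    M = sum(
        w * group_fim(spec, x, theta, design.q, costspec.rho)
        for x, w in zip(design.support, design.weights)
    )
    c = sum(
        w * cost_per_subject(spec, x, design.q, theta, costspec, i)
        for i, (x, w) in enumerate(zip(design.support, design.weights))
    )
    return M / c


def derived_sample_size(budget: float, c0: float, spec: mdl.ModelSpec,
                        design: Design, theta, costspec: CostSpec) -> float:
    """Sample size implied by spending the budget: N = (C - c0) / sum pi_i c(x_i)."""
    if budget <= c0:
        raise ValueError("budget must exceed the setup cost")
    c = sum(
        w * cost_per_subject(spec, x, design.q, theta, costspec, i)
        for i, (x, w) in enumerate(zip(design.support, design.weights))
    )
    return (budget - c0) / c
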