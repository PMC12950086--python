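"""Discrete-time survival model with competing risks.

A subject alive at the start of interval t = 1..q experiences one of J
mutually exclusive event types, or survives the interval.  The J+1
conditional outcome probabilities (cause-specific hazards plus conditional
survival) are tied to covariates through one of two links:

* ``multinomial`` -- each cause's hazard relative to conditional survival is
  log-linear in a per-cause predictor ``eta_r = gamma_{0tr} + f_r(x)' gamma_r``;
* ``cumulative`` -- logits of the cumulative cause probabilities share a
  single effect vector and carry ordered intercepts.

Both links are special cases of the unified form ``C' log(L lambda) = X_t theta``
with link-specific stacking matrix L; that form is what the Fisher
information machinery differentiates.

The parameter vector ``theta`` stacks the baseline coefficients (time-major:
period 1 risks 1..J, period 2 risks 1..J, ...), then the treatment effects,
then a fixed structural zero which is the predictor of the reference
(survival) category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, softmax

__all__ = [
    "TimeGrid",
    "ModelSpec",
    "ParameterVector",
    "contrast_C",
    "contrast_L",
    "identity_map",
    "polynomial_basis",
    "design_matrix",
    "linear_predictors",
    "hazards",
    "hazard_path",
    "survival",
    "cif",
]

CovariateMap = Callable[[object, int], np.ndarray]
BasisFunction = Callable[[float], float]


def identity_map(x, t: int) -> np.ndarray:
    """Default covariate map: a scalar treatment indicator used as-is."""
    return np.atleast_1d(np.asarray(x, dtype=float))


def time_varying_effect_map(x, t: int) -> np.ndarray:
    """Covariate map (x, x*(t-1)) for linearly time-varying treatment effects."""
    x = float(np.asarray(x).reshape(()))
    return np.array([x, x * (t - 1)], dtype=float)


@dataclass(frozen=True)
class TimeGrid:
    """Ordered candidate inspection instants a_0 < a_1 < ... < a_{q_max}.

    Interval t (1-based) is [a_{t-1}, a_t); choosing a period count q < q_max
    truncates the visit list to the first q intervals.
    """

    instants: tuple

    def __post_init__(self):
        inst = tuple(float(a) for a in self.instants)
        object.__setattr__(self, "instants", inst)
        if len(inst) < 2:
            raise ValueError("a time grid needs at least a_0 and a_1")
        if any(b <= a for a, b in zip(inst, inst[1:])):
            raise ValueError("inspection instants must be strictly increasing")

    @property
    def q_max(self) -> int:
        return len(self.instants) - 1

    @classmethod
    def unit(cls, q_max: int, start: float = 0.0) -> "TimeGrid":
        """Equally spaced grid a_t = start + t, the default for monthly visits."""
        return cls(tuple(start + t for t in range(q_max + 1)))


def polynomial_basis(degree: int, time_scale: float = 1.0) -> tuple:
    """Basis functions (1, u, u^2, ...) with u = t / time_scale.

    Rescaling time keeps the polynomial well conditioned when the grid spans
    many periods.
    """

    def make(k: int) -> BasisFunction:
        return lambda t: (t / time_scale) ** k

    return tuple(make(k) for k in range(degree + 1))


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of the hazard model.

    Parameters
    ----------
    n_risks:
        Number of competing event types J.
    link:
        ``"multinomial"`` or ``"cumulative"``.
    time_grid:
        Candidate inspection instants.
    baseline:
        ``"saturated"`` (one intercept per period and risk) or ``"basis"``
        (per-risk basis expansion of the baseline coefficients).
    basis:
        Per-risk tuples of scalar basis functions of t; required when
        ``baseline == "basis"``.
    covariate_maps:
        Per-risk maps f_r(x, t) -> 1-d array.  For the cumulative link the
        effect vector is shared, so all maps must have equal dimension.
    effect_dims:
        Per-risk effect dimensions (cumulative link: all equal).
    """

    n_risks: int
    link: str
    time_grid: TimeGrid
    baseline: str = "saturated"
    basis: tuple | None = None
    covariate_maps: tuple | None = None
    effect_dims: tuple = field(default=None)

    def __post_init__(self):
        if self.n_risks < 1:
            raise ValueError("need at least one risk")
        if self.link not in ("multinomial", "cumulative"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.baseline not in ("saturated", "basis"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if self.baseline == "basis":
            if self.basis is None or len(self.basis) != self.n_risks:
                raise ValueError("basis baseline needs one basis tuple per risk")
        if self.covariate_maps is None:
            object.__setattr__(
                self, "covariate_maps", (identity_map,) * self.n_risks
            )
        elif len(self.covariate_maps) != self.n_risks:
            raise ValueError("need one covariate map per risk")
        if self.effect_dims is None:
            object.__setattr__(self, "effect_dims", (1,) * self.n_risks)
        elif len(self.effect_dims) != self.n_risks:
            raise ValueError("need one effect dimension per risk")
        if self.link == "cumulative" and len(set(self.effect_dims)) != 1:
            raise ValueError("cumulative link shares one effect vector")

    @property
    def q_max(self) -> int:
        return self.time_grid.q_max

    @property
    def p(self) -> int:
        """Total treatment-effect dimension."""
        if self.link == "multinomial":
            return int(sum(self.effect_dims))
        return int(self.effect_dims[0])

    def baseline_dim(self, q: int | None = None) -> int:
        if self.baseline == "saturated":
            q = self.q_max if q is None else int(q)
            return q * self.n_risks
        return sum(len(b) for b in self.basis)

    def theta_dim(self, q: int | None = None) -> int:
        return self.baseline_dim(q) + self.p + 1

    def baseline_index(self, t: int, r: int, q: int | None = None) -> int:
        """Column of the saturated intercept gamma_{0tr} (t, r 1-based)."""
        if self.baseline != "saturated":
            raise ValueError("baseline_index applies to the saturated layout")
        return (t - 1) * self.n_risks + (r - 1)

    def effect_slice(self, r: int, q: int | None = None) -> slice:
        """Columns of risk r's effect block (shared block for cumulative)."""
        off = self.baseline_dim(q)
        if self.link == "cumulative":
            return slice(off, off + self.p)
        start = off + int(sum(self.effect_dims[: r - 1]))
        return slice(start, start + self.effect_dims[r - 1])

    def covariate_values(self, x, t: int) -> list:
        vals = []
        for r in range(self.n_risks):
            f = np.atleast_1d(np.asarray(self.covariate_maps[r](x, t), dtype=float))
            if f.size != self.effect_dims[r]:
                raise ValueError(
                    f"covariate map for risk {r + 1} returned dimension "
                    f"{f.size}, expected {self.effect_dims[r]}"
                )
            vals.append(f)
        return vals

    def check_q(self, q: int | None) -> int:
        q = self.q_max if q is None else int(q)
        if not 1 <= q <= self.q_max:
            raise ValueError(f"period count q={q} outside 1..{self.q_max}")
        return q


@dataclass
class ParameterVector:
    """theta split into its blocks; the structural zero is implicit.

    ``baseline`` is time-major for the saturated layout (gamma_{011},
    gamma_{012}, ..., gamma_{0qJ}) or the stacked per-risk basis coefficients;
    ``effects`` stacks (gamma_1', ..., gamma_J') or the shared gamma.
    """

    baseline: np.ndarray
    effects: np.ndarray

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float).ravel()
        self.effects = np.asarray(self.effects, dtype=float).ravel()

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.baseline, self.effects, [0.0]])

    @classmethod
    def from_theta(cls, theta, spec: ModelSpec, q: int | None = None) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float).ravel()
        b = spec.baseline_dim(q)
        if theta.size != b + spec.p + 1:
            raise ValueError(
                f"theta has length {theta.size}, expected {b + spec.p + 1}"
            )
        if theta[-1] != 0.0:
            raise ValueError("last coordinate of theta (structural zero) must be 0")
        return cls(theta[:b], theta[b:-1])

    def validate_monotone(self, spec: ModelSpec, q: int | None = None) -> None:
        """Cumulative-link intercepts must satisfy gamma_{0tr} <= gamma_{0t,r+1}."""
        if spec.link != "cumulative" or spec.n_risks == 1:
            return
        if spec.baseline == "saturated":
            q = spec.check_q(q)
            table = self.baseline.reshape(q, spec.n_risks)
            ts = range(1, q + 1)
        else:
            ts = range(1, spec.q_max + 1)
            table = np.array(
                [_basis_intercepts(spec, self.baseline, t) for t in ts]
            )
        for t, row in zip(ts, table):
            bad = np.nonzero(np.diff(row) < 0)[0]
            if bad.size:
                r = int(bad[0]) + 1
                raise ValueError(
                    f"non-monotone cumulative intercepts at period t={t}: "
                    f"gamma_0{t}{r} > gamma_0{t}{r + 1}"
                )


def _basis_intercepts(spec: ModelSpec, baseline: np.ndarray, t: int) -> np.ndarray:
    out = np.empty(spec.n_risks)
    off = 0
    for r in range(spec.n_risks):
        m = len(spec.basis[r])
        phi = np.array([f(t) for f in spec.basis[r]])
        out[r] = phi @ baseline[off : off + m]
        off += m
    return out


# ---------------------------------------------------------------------------
# Unified-form contrast matrices
# ---------------------------------------------------------------------------

def contrast_C(n_risks: int) -> np.ndarray:
    """C' = [I_J, -I_J, 0; 0', 0', 1], shape (J+1) x (2J+1)."""
    J = n_risks
    Ct = np.zeros((J + 1, 2 * J + 1))
    Ct[:J, :J] = np.eye(J)
    Ct[:J, J : 2 * J] = -np.eye(J)
    Ct[J, 2 * J] = 1.0
    return Ct


def contrast_L(n_risks: int, link: str) -> np.ndarray:
    """Stacking matrix L, shape (2J+1) x (J+1); its last row is all ones."""
    J = n_risks
    L = np.zeros((2 * J + 1, J + 1))
    if link == "multinomial":
        L[:J, :J] = np.eye(J)
        L[J : 2 * J, J] = 1.0
    elif link == "cumulative":
        for r in range(J):
            L[r, : r + 1] = 1.0      # pi_r
            L[J + r, r + 1 :] = 1.0  # 1 - pi_r
    else:
        raise ValueError(f"unknown link {link!r}")
    L[2 * J, :] = 1.0
    return L


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def design_matrix(spec: ModelSpec, t: int, x, q: int | None = None) -> np.ndarray:
    """Design matrix X_t, shape (J+1) x theta_dim(q).

    Row r carries the baseline entries for risk r (an intercept indicator at
    column (t-1)J + r for the saturated layout, the basis values phi_r(t)
    otherwise) and the covariate values f_r(x, t) in the effect block; the
    reference row carries a single 1 in the structural-zero column.
    """
    q = spec.check_q(q)
    if not 1 <= t <= q:
        raise ValueError(f"period t={t} outside 1..{q}")
    J = spec.n_risks
    d = spec.theta_dim(q)
    X = np.zeros((J + 1, d))
    if spec.baseline == "saturated":
        for r in range(1, J + 1):
            X[r - 1, spec.baseline_index(t, r, q)] = 1.0
    else:
        off = 0
        for r in range(J):
            m = len(spec.basis[r])
            X[r, off : off + m] = [f(t) for f in spec.basis[r]]
            off += m
    fvals = spec.covariate_values(x, t)
    for r in range(1, J + 1):
        X[r - 1, spec.effect_slice(r, q)] = fvals[r - 1]
    X[J, d - 1] = 1.0
    return X


def linear_predictors(spec: ModelSpec, t: int, x, theta, q: int | None = None) -> np.ndarray:
    """eta(t|x) = X_t theta; the last component is identically 0."""
    theta = np.asarray(theta, dtype=float).ravel()
    X = design_matrix(spec, t, x, q)
    if theta.size != X.shape[1]:
        raise ValueError(
            f"theta has length {theta.size}, expected {X.shape[1]} for q={spec.check_q(q)}"
        )
    return X @ theta


def hazards(spec: ModelSpec, t: int, x, theta, q: int | None = None) -> np.ndarray:
    """Conditional outcome probabilities (lambda_1, ..., lambda_J, lambda_{J+1}).

    The last component is the conditional survival probability.  For the
    cumulative link the predictors must be non-decreasing in r; a violation
    (which would produce a negative hazard) is rejected with the offending
    period and risk named.
    """
    eta = linear_predictors(spec, t, x, theta, q)
    return hazards_from_eta(spec, eta, t=t)


def hazards_from_eta(spec: ModelSpec, eta: np.ndarray, t: int | None = None) -> np.ndarray:
    J = spec.n_risks
    if spec.link == "multinomial":
        return softmax(eta)
    cum = expit(eta[:J])
    lam = np.empty(J + 1)
    lam[0] = cum[0]
    lam[1:J] = np.diff(cum)
    lam[J] = 1.0 - cum[J - 1]
    if np.any(lam[:J] <= 0.0):
        r = int(np.nonzero(lam[:J] <= 0.0)[0][0]) + 1
        where = f"period t={t}, " if t is not None else ""
        raise ValueError(
            f"cumulative link yields non-positive hazard ({where}risk r={r}): "
            "intercepts are not monotone"
        )
    return lam


def hazard_path(spec: ModelSpec, x, theta, q: int | None = None) -> np.ndarray:
    """Hazard vectors for t = 1..q, stacked as a (q, J+1) array."""
    q = spec.check_q(q)
    return np.array([hazards(spec, t, x, theta, q) for t in range(1, q + 1)])


def survival(spec: ModelSpec, t: int, x, theta, q: int | None = None) -> float:
    """S(t|x) = P(T > t | x); S(0|x) = 1 by convention."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 1.0
    lam = hazard_path(spec, x, theta, spec.check_q(q))[:t]
    return float(np.prod(lam[:, spec.n_risks]))


def cif(spec: ModelSpec, t: int, x, theta, r: int, q: int | None = None) -> float:
    """Cumulative incidence F_r(t|x) = sum_s lambda_r(s|x) S(s-1|x)."""
    if not 1 <= r <= spec.n_risks:
        raise ValueError(f"risk index r={r} outside 1..{spec.n_risks}")
    if t == 0:
        return 0.0
    lam = hazard_path(spec, x, theta, spec.check_q(q))[:t]
    surv_prev = np.concatenate([[1.0], np.cumprod(lam[:-1, spec.n_risks])])
    return float(np.sum(lam[:, r - 1] * surv_prev))
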