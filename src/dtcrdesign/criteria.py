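"""Design criteria: D_A objectives, relative efficiency, CIF variance.

The working objective is

    Phi_DA(zeta | theta) = log | A' (M^c(zeta | theta))^{-1} A |,

minimized over candidate designs.  A = I gives D-optimality for the full
parameter vector; A selecting the treatment-effect coordinates gives the
Ds-criteria used for subset estimation.  A singular standardized information
makes the criterion undefined; during a search this is reported as +inf so
infeasible candidates lose to any feasible one without raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from . import model as mdl
from .information import CostSpec, Design, cost_per_subject, standardized_fim

__all__ = [
    "SelectionMatrix",
    "selection_matrix",
    "phi_DA",
    "phi_from_fim",
    "relative_efficiency",
    "efficiency_from_phi",
    "cif_variance",
]

log = logging.getLogger(__name__)

ROLES = ("full", "treatment_effects", "risk1_effects", "custom")


@dataclass(frozen=True)
class SelectionMatrix:
    """Selection matrix A (theta_dim x v) with its rank v and role label."""

    A: np.ndarray
    role: str

    @property
    def v(self) -> int:
        return self.A.shape[1]


def selection_matrix(role: str, spec: mdl.ModelSpec, q: int | None = None,
                     subset=None) -> SelectionMatrix:
    """Build the selection matrix for a criterion role.

    ``full`` -> identity (D-optimality); ``treatment_effects`` -> the p effect
    coordinates (Ds); ``risk1_effects`` -> risk 1's effect coordinates only;
    ``custom`` -> explicit 0-based indices within the effect block.
    """
    d = spec.theta_dim(q)
    if role == "full":
        return SelectionMatrix(np.eye(d), role)
    off = spec.baseline_dim(q)
    if role == "treatment_effects":
        idx = np.arange(off, off + spec.p)
    elif role == "risk1_effects":
        sl = spec.effect_slice(1, q)
        idx = np.arange(sl.start, sl.stop)
    elif role == "custom":
        if subset is None:
            raise ValueError("custom role needs explicit effect indices")
        idx = off + np.asarray(subset, dtype=int)
        if np.any(idx < off) or np.any(idx >= off + spec.p):
            raise ValueError("custom subset indices fall outside the effect block")
    else:
        raise ValueError(f"unknown selection role {role!r}; choose from {ROLES}")
    A = np.zeros((d, idx.size))
    A[idx, np.arange(idx.size)] = 1.0
    return SelectionMatrix(A, role)


def phi_from_fim(Mc: np.ndarray, A: np.ndarray | None = None) -> float:
    """log |A' Mc^{-1} A|; +inf when Mc (or the projected matrix) is singular."""
    Mc = np.asarray(Mc, dtype=float)
    try:
        cho = cho_factor(Mc, lower=True)
    except (LinAlgError, ValueError):
        log.warning("standardized information singular; criterion set to +inf")
        return np.inf
    if A is None or (A.shape[0] == A.shape[1] and np.array_equal(A, np.eye(A.shape[0]))):
        return float(-2.0 * np.sum(np.log(np.diag(cho[0]))))
    Y = cho_solve(cho, A)
    sign, ld = np.linalg.slogdet(A.T @ Y)
    if sign <= 0:
        log.warning("projected covariance not positive definite; criterion +inf")
        return np.inf
    return float(ld)


def phi_DA(design: Design, theta, A, costspec: CostSpec, spec: mdl.ModelSpec
           ) -> float:
    """D_A criterion of a design (lower is better)."""
    Amat = A.A if isinstance(A, SelectionMatrix) else np.asarray(A, dtype=float)
    Mc = standardized_fim(spec, design, theta, costspec)
    return phi_from_fim(Mc, Amat)


def efficiency_from_phi(phi_ref: float, v_ref: int, phi: float, v: int | None = None
                        ) -> float:
    """Efficiency of a design relative to a reference (usually the optimum).

    exp(phi_ref / v_ref - phi / v): the v-th-root determinant ratio with the
    reference in the numerator, so values are <= 1 when the reference is the
    grid optimum and the ranks agree.  With unequal ranks (D-criterion across
    saturated models of different duration) each criterion value is normalized
    by its own rank.
    """
    v = v_ref if v is None else v
    if not np.isfinite(phi):
        return 0.0
    return float(np.exp(phi_ref / v_ref - phi / v))


def relative_efficiency(design_a: Design, design_b: Design, theta, A,
                        costspec: CostSpec, spec: mdl.ModelSpec,
                        orientation: str = "a_over_b") -> float:
    """Relative efficiency |A'Mc(a)^{-1}A|^{1/v} / |A'Mc(b)^{-1}A|^{1/v}.

    With design_a the optimum, the value is the efficiency deficit of
    design_b: 0.5 means design_b must be replicated twice to match design_a.
    ``orientation="b_over_a"`` returns the reciprocal.
    """
    Amat = A.A if isinstance(A, SelectionMatrix) else np.asarray(A, dtype=float)
    v = Amat.shape[1]
    pa = phi_DA(design_a, theta, Amat, costspec, spec)
    pb = phi_DA(design_b, theta, Amat, costspec, spec)
    if not (np.isfinite(pa) and np.isfinite(pb)):
        raise ValueError("relative efficiency undefined: singular information")
    re = float(np.exp((pa - pb) / v))
    return re if orientation == "a_over_b" else 1.0 / re


def cif_variance(design: Design, theta, t: int, x, r: int, costspec: CostSpec,
                 spec: mdl.ModelSpec, cost_normalized: bool = True) -> float:
    """Delta-method variance of the plug-in CIF estimate F_r(t|x).

    The gradient of the CIF in theta is taken by central finite differences
    (the structural zero is never perturbed); the covariance is the inverse
    (cost-standardized) information.  With ``cost_normalized=False`` and a
    design carrying N, the per-trial information N sum_i pi_i M_i is used and
    the value approximates the sampling variance of the estimator.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    d = theta.size
    grad = np.zeros(d)
    for j in range(d - 1):  # structural zero excluded
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        grad[j] = (
            mdl.cif(spec, t, x, tp, r, design.q) - mdl.cif(spec, t, x, tm, r, design.q)
        ) / (2 * h)
    Mc = standardized_fim(spec, design, theta, costspec)
    if not cost_normalized:
        if design.N is None:
            raise ValueError("variance on the sampling scale needs design.N")
        c = sum(
            design.weights[i]
            * cost_per_subject(spec, xx, design.q, theta, costspec, i)
            for i, xx in enumerate(design.support)
        )
        Mc = Mc * c * design.N
    try:
        cho = cho_factor(Mc, lower=True)
    except (LinAlgError, ValueError) as err:
        raise ValueError("singular information: CIF variance undefined") from err
    return float(grad @ cho_solve(cho, grad))
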