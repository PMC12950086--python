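"""Two-arm sensitivity-study scenarios on a 12-month unit inspection grid.

Two multinomial-logit hazard models with J = 2 competing risks and a binary
treatment indicator x in {0, 1} are covered:

* constant treatment effects, eta_r(t|x) = gamma_{0tr} + gamma_{r1} x;
* linearly time-varying effects,
  eta_r(t|x) = gamma_{0tr} + gamma_{r1} x + gamma_{r2} x (t - 1).

Control-group baselines are calibrated from the Weibull mixture
(event fractions w_r, shapes tau_r, mixing proportion kappa).  The mixture
is parameterized on the study-duration scale: inspection instant a_t = t /
q_max, so w_r is the fraction of control subjects with a risk-r event by the
end of the full q_max-month horizon.  This spreads an increasing hazard
(tau_r > 1) over the whole horizon instead of exhausting it within the first
few months, which is what makes long durations competitive in those
scenarios.

The helpers here assemble a :class:`~dtcrdesign.search.DesignProblem` per
parameter setting and run the grid searches behind the published-style
summary tables (optimal duration for equal allocation; optimal (pi, q) with
the efficiency of the equal-allocation optimum for free allocation).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .calibration import WeibullCRSpec, calibrated_theta
from .information import CostSpec
from .model import ModelSpec, TimeGrid, time_varying_effect_map
from .search import (
    DesignProblem,
    SearchGrid,
    equal_allocation_optimum,
    optimize,
)
from .criteria import efficiency_from_phi

__all__ = [
    "constant_effect_spec",
    "time_varying_effect_spec",
    "weibull_problem",
    "equal_allocation_qstar",
    "free_allocation_optimum",
    "duration_table",
    "allocation_table",
]

#: Hazard-conversion denominator used for the headline tables; the printed
#: cause-specific form is the package default elsewhere.
DEFAULT_DENOMINATOR = "cause_specific"


def _study_grid(q_max: int) -> TimeGrid:
    """Inspection grid on the study-duration scale, a_t = t / q_max."""
    return TimeGrid(tuple(t / q_max for t in range(q_max + 1)))


def constant_effect_spec(q_max: int = 12, link: str = "multinomial") -> ModelSpec:
    """J = 2 saturated model with a scalar treatment effect per risk."""
    return ModelSpec(
        n_risks=2, link=link, time_grid=_study_grid(q_max), baseline="saturated"
    )


def time_varying_effect_spec(q_max: int = 12, link: str = "multinomial") -> ModelSpec:
    """J = 2 saturated model with per-risk effects (gamma_r1, gamma_r2 (t-1) x)."""
    return ModelSpec(
        n_risks=2,
        link=link,
        time_grid=_study_grid(q_max),
        baseline="saturated",
        covariate_maps=(time_varying_effect_map, time_varying_effect_map),
        effect_dims=(2, 2),
    )


def weibull_problem(
    w1: float,
    w2: float,
    tau1: float,
    tau2: float,
    effects,
    kappa: float = 0.5,
    f: float = 1.0,
    rho: float = 0.0,
    cost_variant: str = "until_event",
    criterion: str = "treatment_effects",
    q_max: int = 12,
    link: str = "multinomial",
    denominator: str = DEFAULT_DENOMINATOR,
    subset=None,
) -> DesignProblem:
    """Design problem for a Weibull-calibrated two-arm scenario.

    ``effects`` is a pair of per-risk effect vectors: scalars give the
    constant-effect model, pairs (gamma_r1, gamma_r2) the time-varying one.
    """
    eff = [np.atleast_1d(np.asarray(e, dtype=float)) for e in effects]
    if all(e.size == 1 for e in eff):
        spec = constant_effect_spec(q_max, link)
    elif all(e.size == 2 for e in eff):
        spec = time_varying_effect_spec(q_max, link)
    else:
        raise ValueError("effects must be per-risk vectors of dimension 1 or 2")
    wspec = WeibullCRSpec.from_first_period_fractions(w1, w2, tau1, tau2, kappa)
    theta = calibrated_theta(wspec, eff, spec, denominator)
    cost = CostSpec.from_cost_ratio(f, variant=cost_variant, rho=rho)
    return DesignProblem(
        spec=spec, theta=theta, costspec=cost, criterion=criterion, subset=subset
    )


def equal_allocation_qstar(problem: DesignProblem) -> tuple:
    """(q*, criterion value) for the equal-allocation search."""
    res = equal_allocation_optimum(problem)
    return res.design.q, res.phi


def free_allocation_optimum(problem: DesignProblem, step: float = 0.01) -> dict:
    """Free-allocation optimum plus the efficiency of the equal-split optimum.

    Returns pi* (experimental-group proportion), q*, the criterion value, and
    ``re_equal``: the relative efficiency of the best equal-allocation design
    against the unrestricted optimum.
    """
    grid = SearchGrid.two_arm(problem.spec.q_max, step=step)
    res = optimize(problem, grid)
    eq = equal_allocation_optimum(problem)
    re_eq = efficiency_from_phi(res.phi, res.v, eq.phi, eq.v)
    return {
        "pi": res.design.weights[1],
        "q": res.design.q,
        "phi": res.phi,
        "re_equal": re_eq,
        "result": res,
        "equal_result": eq,
    }


def duration_table(
    gamma_grid=((-2.5, -2.5), (-2.5, 2.5), (2.5, -2.5), (2.5, 2.5)),
    tau_values=(1 / 3, 3.0),
    w_values=(0.3, 0.5),
    kappa: float = 0.5,
    f: float = 1.0,
    rho: float = 0.0,
    denominator: str = DEFAULT_DENOMINATOR,
) -> pd.DataFrame:
    """Equal-allocation optimal durations q* over the (tau, w, gamma) panel.

    One row per (tau_1, tau_2, w_1, w_2) with tau_1 <= tau_2, one column per
    treatment-effect pair.
    """
    rows = []
    taus = [
        (t1, t2) for t1, t2 in itertools.product(tau_values, tau_values) if t1 <= t2
    ]
    for (tau1, tau2), (w1, w2) in itertools.product(
        taus, itertools.product(w_values, w_values)
    ):
        row = {"tau1": tau1, "tau2": tau2, "w1": w1, "w2": w2}
        for g in gamma_grid:
            prob = weibull_problem(
                w1, w2, tau1, tau2, g, kappa=kappa, f=f, rho=rho,
                denominator=denominator,
            )
            row[f"qstar{g}"] = equal_allocation_qstar(prob)[0]
        rows.append(row)
    return pd.DataFrame(rows)


def allocation_table(
    settings,
    gamma_grid=((-2.5, -2.5), (-2.5, 2.5), (2.5, -2.5), (2.5, 2.5)),
    kappa: float = 0.5,
    f: float = 1.0,
    rho: float = 0.0,
    denominator: str = DEFAULT_DENOMINATOR,
    criterion: str = "treatment_effects",
) -> pd.DataFrame:
    """Free-allocation optima (pi*, q*, RE of equal split) per scenario row.

    ``settings`` is an iterable of (tau1, tau2, w1, w2); for the time-varying
    model pass 2-vectors in ``gamma_grid``.
    """
    rows = []
    for tau1, tau2, w1, w2 in settings:
        row = {"tau1": tau1, "tau2": tau2, "w1": w1, "w2": w2}
        for g in gamma_grid:
            prob = weibull_problem(
                w1, w2, tau1, tau2, g, kappa=kappa, f=f, rho=rho,
                denominator=denominator, criterion=criterion,
            )
            opt = free_allocation_optimum(prob)
            row[f"pi{g}"] = opt["pi"]
            row[f"q{g}"] = opt["q"]
            row[f"re{g}"] = opt["re_equal"]
        rows.append(row)
    return pd.DataFrame(rows)
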