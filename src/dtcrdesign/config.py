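"""Scenario files: validated loading and report writing.

A single YAML scenario file drives every command.  Sections:

``model``
    link (multinomial | cumulative), J, q_max, baseline (saturated |
    polynomial), polynomial degree and time rescale for the polynomial case.
``weibull``
    w1, w2 (or lambda1, lambda2), tau1, tau2, kappa, denominator
    (cause_specific | overall), time_scale (study_duration | months).
``effects``
    per-risk coefficient lists, e.g. ``[[-2.5], [-2.5]]``; explicit baseline
    coefficients may be given instead of a Weibull section via ``baseline``.
``cost``
    variant (until_event | all_visits), f (scalar or per group), rho, c0,
    budget, baseline_measurement.
``criterion``
    role (D | Ds | Ds1 | Ds2 | c_cif) and, for the CIF variance criterion,
    cif: {t, x, r}.
``search``
    allocation (free | equal | fixed), weight_step, q_candidates, weights.

Unknown keys anywhere are rejected with the offending key path.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import WeibullCRSpec, calibrated_theta
from .information import CostSpec
from .model import ModelSpec, ParameterVector, TimeGrid, identity_map, time_varying_effect_map
from .search import DesignProblem, SearchGrid, multi_arm_grid

__all__ = ["Scenario", "load_scenario", "write_report"]

_SECTIONS = {"model", "weibull", "effects", "baseline", "cost", "criterion", "search"}
_KEYS = {
    "model": {"link", "J", "q_max", "baseline", "degree", "time_rescale",
              "time_varying_effects"},
    "weibull": {"w1", "w2", "lambda1", "lambda2", "tau1", "tau2", "kappa",
                "denominator", "time_scale"},
    "cost": {"variant", "f", "rho", "c0", "budget", "baseline_measurement"},
    "criterion": {"role", "cif", "subset"},
    "search": {"allocation", "weight_step", "q_candidates", "weights"},
}
_CRITERION_ROLES = {
    "D": "full", "Ds": "treatment_effects", "Ds1": "treatment_effects",
    "Ds2": "risk1_effects", "c_cif": "c_cif",
}


class ScenarioError(ValueError):
    pass


def _check_keys(section: str, data: dict) -> None:
    extra = set(data) - _KEYS[section]
    if extra:
        raise ScenarioError(
            f"unknown key(s) in section '{section}': {sorted(extra)}"
        )


@dataclass
class Scenario:
    """A validated scenario: model, nominal parameters, costs, criterion, grid."""

    spec: ModelSpec
    theta: np.ndarray
    costspec: CostSpec
    criterion: str
    cif_target: dict | None
    grid: SearchGrid
    raw: dict = field(repr=False, default_factory=dict)
    digest: str = ""

    def problem(self) -> DesignProblem:
        role = _CRITERION_ROLES[self.criterion]
        if role == "c_cif":
            raise ScenarioError(
                "the CIF-variance criterion is evaluated via "
                "dtcrdesign.criteria.cif_variance, not the grid search"
            )
        return DesignProblem(
            spec=self.spec, theta=self.theta, costspec=self.costspec,
            criterion=role,
        )

    def provenance(self, seed=None) -> str:
        lines = [
            f"# dtcrdesign {__version__}",
            f"# scenario sha256 {self.digest}",
        ]
        if seed is not None:
            lines.append(f"# seed {seed}")
        return "\n".join(lines)


def load_scenario(path) -> Scenario:
    """Load and validate a YAML scenario file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ScenarioError("scenario file must be a mapping")
    extra = set(data) - _SECTIONS
    if extra:
        raise ScenarioError(f"unknown section(s): {sorted(extra)}")
    return build_scenario(data, digest=hashlib.sha256(text.encode()).hexdigest()[:16])


def build_scenario(data: dict, digest: str = "") -> Scenario:
    m = dict(data.get("model") or {})
    _check_keys("model", m)
    link = m.get("link", "multinomial")
    J = int(m.get("J", 2))
    q_max = int(m.get("q_max", 12))
    baseline = m.get("baseline", "saturated")
    time_varying = bool(m.get("time_varying_effects", False))

    w = dict(data.get("weibull") or {})
    _check_keys("weibull", w)
    time_scale = w.get("time_scale", "study_duration")
    if time_scale == "study_duration":
        grid = TimeGrid(tuple(t / q_max for t in range(q_max + 1)))
    elif time_scale == "months":
        grid = TimeGrid.unit(q_max)
    else:
        raise ScenarioError(f"weibull.time_scale {time_scale!r} unknown")

    if time_varying:
        maps = (time_varying_effect_map,) * J
        dims = (2,) * J
    else:
        maps = (identity_map,) * J
        dims = (1,) * J

    if baseline == "saturated":
        spec = ModelSpec(n_risks=J, link=link, time_grid=grid,
                         baseline="saturated", covariate_maps=maps,
                         effect_dims=dims)
    elif baseline == "polynomial":
        degree = int(m.get("degree", 2))
        rescale = float(m.get("time_rescale", q_max))

        def make(k):
            return lambda t: (t / rescale) ** k

        basis = tuple(tuple(make(k) for k in range(degree + 1)) for _ in range(J))
        spec = ModelSpec(n_risks=J, link=link, time_grid=grid,
                         baseline="basis", basis=basis, covariate_maps=maps,
                         effect_dims=dims)
    else:
        raise ScenarioError(f"model.baseline {baseline!r} unknown")

    effects = data.get("effects")
    if effects is None:
        raise ScenarioError("an 'effects' section (per-risk lists) is required")
    eff = [np.atleast_1d(np.asarray(e, dtype=float)) for e in effects]

    if "weibull" in data and data["weibull"]:
        if J != 2 or baseline != "saturated":
            raise ScenarioError(
                "Weibull calibration applies to the J=2 saturated model"
            )
        if "w1" in w:
            wspec = WeibullCRSpec.from_first_period_fractions(
                float(w["w1"]), float(w["w2"]),
                float(w.get("tau1", 1.0)), float(w.get("tau2", 1.0)),
                float(w.get("kappa", 0.5)),
            )
        else:
            wspec = WeibullCRSpec(
                float(w["lambda1"]), float(w["lambda2"]),
                float(w.get("tau1", 1.0)), float(w.get("tau2", 1.0)),
                float(w.get("kappa", 0.5)),
            )
        theta = calibrated_theta(
            wspec, eff, spec, w.get("denominator", "cause_specific")
        )
    elif "baseline" in data:
        base = np.asarray(data["baseline"], dtype=float).ravel()
        pv = ParameterVector(base, np.concatenate(eff))
        pv.validate_monotone(spec)
        theta = pv.theta
    else:
        raise ScenarioError("provide either a 'weibull' or a 'baseline' section")

    c = dict(data.get("cost") or {})
    _check_keys("cost", c)
    costspec = CostSpec.from_cost_ratio(
        c.get("f", 1.0),
        variant=c.get("variant", "until_event"),
        rho=float(c.get("rho", 0.0)),
        c0=float(c.get("c0", 0.0)),
        budget=c.get("budget"),
        baseline_measurement=bool(c.get("baseline_measurement", False)),
    )

    cr = dict(data.get("criterion") or {})
    _check_keys("criterion", cr)
    role = cr.get("role", "Ds")
    if role not in _CRITERION_ROLES:
        raise ScenarioError(
            f"criterion.role {role!r} unknown; choose from {sorted(_CRITERION_ROLES)}"
        )

    s = dict(data.get("search") or {})
    _check_keys("search", s)
    qs = tuple(int(v) for v in (s.get("q_candidates") or range(1, q_max + 1)))
    allocation = s.get("allocation", "free")
    if allocation == "equal":
        weights = ((0.5, 0.5),)
    elif allocation == "fixed":
        weights = (tuple(float(v) for v in s["weights"]),)
    elif allocation == "free":
        weights = multi_arm_grid(2, float(s.get("weight_step", 0.01)))
    else:
        raise ScenarioError(f"search.allocation {allocation!r} unknown")
    grid_obj = SearchGrid(qs, weights, allocation)

    return Scenario(
        spec=spec, theta=theta, costspec=costspec, criterion=role,
        cif_target=cr.get("cif"), grid=grid_obj, raw=data, digest=digest,
    )


def write_report(result, out_dir, scenario: Scenario | None = None,
                 seed=None) -> list:
    """Write grid/surface CSVs and a plain-text optimum summary.

    Returns the list of files written.  Numbers are stored at full precision;
    the summary adds 2-decimal columns for comparison with published tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    header = scenario.provenance(seed) if scenario is not None else ""
    grid_path = out / "grid.csv"
    result.table.to_csv(grid_path, index=False)
    written.append(grid_path)
    if "pi" in result.table:
        surf = result.table[["pi", "q", "re"]]
        surf_path = out / "surface.csv"
        surf.to_csv(surf_path, index=False)
        written.append(surf_path)
    d = result.design
    lines = [header] if header else []
    lines += [
        f"criterion_value_phi: {result.phi!r}",
        f"criterion_rank_v: {result.v}",
        f"phi_per_parameter: {result.phi / result.v!r}",
        f"q_star: {d.q}",
        f"weights: {tuple(round(wi, 10) for wi in d.weights)}",
    ]
    if len(d.weights) == 2:
        lines.append(f"pi_star (experimental arm): {d.weights[1]:.2f}")
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
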