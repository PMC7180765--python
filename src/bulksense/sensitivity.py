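"""Measurement-error propagation through a probabilistic bulking sensor.

The sensitivity coefficient of a joint perturbation is the probability
ratio S = p(perturbed inputs) / p0(base inputs): S = 1 at zero
perturbation, S > 1 when the mis-measurement inflates the predicted
bulking risk.  One to three inputs are perturbed simultaneously over a
Cartesian grid of signed offsets — relative (sensor miscalibration as a
fraction of the reading, the default, -30%..+30% in 5% steps) or
absolute.  The controlling block tau can be perturbed as an aggregate,
standing in for any combination of operating-parameter errors producing
the same shift.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sensor import LogitBulkingSensor

__all__ = [
    "PerturbSpec",
    "SensitivityResult",
    "default_deltas",
    "sensitivity_grid",
    "tau_sensitivity",
    "export_curves",
]


def default_deltas() -> np.ndarray:
    """Relative error grid -30%..+30% in 5% steps."""
    return np.round(np.arange(-0.30, 0.301, 0.05), 10)


@dataclass(frozen=True)
class PerturbSpec:
    """Offsets for one input: signed deltas plus their interpretation."""

    deltas: tuple[float, ...]
    mode: str = "relative"  # relative | absolute

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError("mode must be 'relative' or 'absolute'")
        ds = tuple(float(d) for d in self.deltas)
        if 0.0 not in ds:  # the grid always contains the unperturbed point
            ds = tuple(sorted(ds + (0.0,)))
        object.__setattr__(self, "deltas", ds)


@dataclass
class SensitivityResult:
    """S values over the Cartesian delta grid of the perturbed inputs."""

    variables: tuple[str, ...]
    deltas: dict[str, np.ndarray]
    modes: dict[str, str]
    p0: float
    S: np.ndarray  # shape (len(d_1), ..., len(d_k))
    base_inputs: dict

    def slice_at_zero(self, variable: str) -> "SensitivityResult":
        """Marginal sub-grid with ``variable`` held at zero perturbation."""
        i = self.variables.index(variable)
        zero = int(np.flatnonzero(self.deltas[variable] == 0.0)[0])
        S = np.take(self.S, zero, axis=i)
        variables = tuple(v for v in self.variables if v != variable)
        return SensitivityResult(
            variables,
            {v: self.deltas[v] for v in variables},
            {v: self.modes[v] for v in variables},
            self.p0,
            S,
            self.base_inputs,
        )

    def at_zero(self) -> float:
        idx = tuple(
            int(np.flatnonzero(self.deltas[v] == 0.0)[0]) for v in self.variables
        )
        return float(self.S[idx])


def _coerce_spec(spec) -> PerturbSpec:
    if isinstance(spec, PerturbSpec):
        return spec
    if isinstance(spec, Mapping):
        return PerturbSpec(tuple(spec["deltas"]), spec.get("mode", "relative"))
    return PerturbSpec(tuple(spec))


def _perturbed_inputs(base: Mapping, variable: str, delta: float, mode: str) -> dict:
    out = dict(base)
    x = float(base[variable])
    out[variable] = x * (1.0 + delta) if mode == "relative" else x + delta
    return out


def sensitivity_grid(
    model: LogitBulkingSensor,
    base_inputs: Mapping[str, float],
    perturb_spec: Mapping[str, PerturbSpec | Mapping | Sequence[float]],
    joint: Sequence[str] | None = None,
) -> SensitivityResult:
    """Sensitivity surface for 1-3 simultaneously perturbed inputs.

    ``perturb_spec`` maps input name (or "tau" for the aggregate
    controlling block) to its delta grid; ``joint`` selects the subset
    to perturb (defaults to every key of the spec).  Inputs outside the
    joint subset stay at their base values.
    """
    joint = tuple(joint) if joint is not None else tuple(perturb_spec)
    if not 1 <= len(joint) <= 3:
        raise ValueError("joint perturbation covers 1 to 3 inputs")
    missing = [v for v in joint if v not in perturb_spec]
    if missing:
        raise ValueError(f"no perturbation spec for {missing}")
    specs = {v: _coerce_spec(perturb_spec[v]) for v in joint}
    for v in joint:
        if v != "tau" and v not in base_inputs:
            raise KeyError(f"base_inputs lacks {v!r}")
        if v == "tau" and specs[v].mode != "absolute":
            raise ValueError("tau perturbations must be absolute offsets")

    p0 = float(model.predict_proba(base_inputs))
    if p0 <= 0.0:
        raise ValueError("baseline probability is zero; sensitivity ratio undefined")

    grids = {v: np.asarray(specs[v].deltas, dtype=float) for v in joint}
    shape = tuple(len(grids[v]) for v in joint)
    S = np.empty(shape)
    for idx in itertools.product(*(range(n) for n in shape)):
        inputs = dict(base_inputs)
        tau_offset = 0.0
        for v, i in zip(joint, idx):
            d = grids[v][i]
            if v == "tau":
                tau_offset += d
            else:
                inputs = _perturbed_inputs(inputs, v, d, specs[v].mode)
        X = model.tau(inputs) + model.omega(inputs) + tau_offset
        S[idx] = float(model.probability(X)) / p0
    return SensitivityResult(
        joint, grids, {v: specs[v].mode for v in joint}, p0, S, dict(base_inputs)
    )


def tau_sensitivity(
    model: LogitBulkingSensor,
    base_inputs: Mapping[str, float],
    tau_deltas: Sequence[float],
    partner_variable: str,
    partner_deltas: Sequence[float],
    partner_mode: str = "relative",
) -> SensitivityResult:
    """Joint perturbation of the aggregate controlling block tau and one
    load-side variable.

    Any operating-parameter error combination producing the same tau
    shift yields the same S, so the tau axis summarizes e.g. simultaneous
    MLSS and DO sensor errors in one coordinate.
    """
    spec = {
        "tau": PerturbSpec(tuple(tau_deltas), "absolute"),
        partner_variable: PerturbSpec(tuple(partner_deltas), partner_mode),
    }
    return sensitivity_grid(model, base_inputs, spec, joint=("tau", partner_variable))


def export_curves(result: SensitivityResult) -> pd.DataFrame:
    """Long-format table: one row per grid point, delta columns plus S."""
    if result.S.size == 0:
        raise ValueError("empty sensitivity grid")
    rows = []
    shape = result.S.shape
    for idx in itertools.product(*(range(n) for n in shape)):
        row = {
            f"delta_{v}": float(result.deltas[v][i])
            for v, i in zip(result.variables, idx)
        }
        row["S"] = float(result.S[idx])
        rows.append(row)
    return pd.DataFrame(rows)
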