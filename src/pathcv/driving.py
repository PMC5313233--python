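"""Reaction-coordinate driving by successive restrained minimizations.

The reaction coordinate is the fixed linear combination of three
interatomic distances used for phosphoryl-transfer-like processes,

    RC = d1 − d2 − d3,

where d1 is the breaking-side distance and d2, d3 are the forming-side
distances.  Driving proceeds by minimizing

    E(x) + ½ k (RC(x) − target)²

for an ordered, strictly monotone schedule of RC targets, emitting the
optimized state, achieved RC and energy at every stage.  Each stage
starts from the previous optimized state, so at fine schedules the
procedure traces a continuous path from reactant to product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import SpecError
from .systems import ToySystemSpec, evaluate_potential

__all__ = [
    "ReactionCoordinateSpec",
    "DrivingSchedule",
    "DrivingResult",
    "rc_value",
    "drive_reaction",
]


@dataclass(frozen=True)
class ReactionCoordinateSpec:
    """RC = d1 − d2 − d3 over three particle pairs."""

    d1: Tuple[int, int]
    d2: Tuple[int, int]
    d3: Tuple[int, int]

    def __post_init__(self):
        pairs = [tuple(int(v) for v in p) for p in (self.d1, self.d2, self.d3)]
        for p in pairs:
            if p[0] == p[1]:
                raise SpecError(f"distance pair {p} uses the same particle twice")
        if len(set(pairs)) != 3:
            raise SpecError("the three RC distance pairs must be distinct")
        object.__setattr__(self, "d1", pairs[0])
        object.__setattr__(self, "d2", pairs[1])
        object.__setattr__(self, "d3", pairs[2])


@dataclass(frozen=True)
class DrivingSchedule:
    """Ordered RC targets plus restraint and minimizer settings."""

    targets: Tuple[float, ...]
    force_constant: float  # on RC, kcal/mol/Å²
    max_iterations: int = 500
    gradient_tolerance: float = 1e-6

    def __post_init__(self):
        t = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "targets", tuple(float(v) for v in t))
        if len(t) and not (np.all(np.diff(t) > 0) or np.all(np.diff(t) < 0)):
            raise SpecError("RC targets must be strictly monotone")
        if self.force_constant <= 0:
            raise SpecError("RC restraint constant must be > 0")


@dataclass
class DrivingResult:
    states: np.ndarray  # (n_stages + 1, ndof), includes the optimized start
    rc_targets: np.ndarray  # (n_stages,)
    rc_achieved: np.ndarray  # (n_stages + 1,)
    energies: np.ndarray  # (n_stages + 1,) potential only, kcal/mol
    failure_index: Optional[int] = None  # schedule index of first minimizer failure

    def to_frame(self) -> pd.DataFrame:
        targets = np.concatenate([[np.nan], self.rc_targets])
        return pd.DataFrame(
            {
                "stage": np.arange(len(self.states)),
                "target_rc": targets[: len(self.states)],
                "achieved_rc": self.rc_achieved,
                "energy": self.energies,
            }
        )


def rc_value(conformation, spec: ReactionCoordinateSpec, gradient: bool = False):
    """RC = d1 − d2 − d3 in Å, with the exact coordinate gradient on request.

    A coincident particle pair (zero distance) makes the gradient
    undefined; it is then flagged by raising :class:`SpecError` when the
    gradient is requested.
    """
    conf = np.asarray(conformation, dtype=float)
    if conf.ndim == 1:
        conf = conf.reshape(-1, 3)
    value = 0.0
    grad = np.zeros_like(conf)
    for sign, (i, j) in ((1.0, spec.d1), (-1.0, spec.d2), (-1.0, spec.d3)):
        rij = conf[i] - conf[j]
        r = float(np.linalg.norm(rij))
        value += sign * r
        if gradient:
            if r == 0.0:
                raise SpecError(
                    f"gradient undefined: particles {i} and {j} are coincident"
                )
            unit = rij / r
            grad[i] += sign * unit
            grad[j] -= sign * unit
    if gradient:
        return value, grad
    return value


def drive_reaction(spec: ToySystemSpec, rc_spec: ReactionCoordinateSpec,
                   schedule: DrivingSchedule, x0) -> DrivingResult:
    """Drive a system along RC through the target schedule.

    The initial state is first minimized without the RC restraint; each
    subsequent stage minimizes energy plus the RC restraint at its
    target using L-BFGS-B with the analytic gradient.  On minimizer
    failure the partial results are returned with ``failure_index`` set.
    """
    ndof = spec.ndof
    x = np.asarray(x0, dtype=float).ravel()
    if x.shape != (ndof,):
        raise SpecError(f"x0 must have {ndof} degrees of freedom")

    def objective(flat, target=None):
        conf = flat
        e, g = evaluate_potential(conf, spec)
        e = float(e)
        g = g.copy()
        if target is not None:
            rc, grc = rc_value(conf.reshape(-1, 3), rc_spec, gradient=True)
            dv = rc - target
            e += 0.5 * schedule.force_constant * dv * dv
            g += schedule.force_constant * dv * grc.ravel()
        return e, g

    opts = {"maxiter": schedule.max_iterations, "gtol": schedule.gradient_tolerance}
    res = minimize(objective, x, jac=True, method="L-BFGS-B", options=opts)
    states = [res.x.copy()]
    energies = [float(evaluate_potential(res.x, spec)[0])]
    rcs = [rc_value(res.x.reshape(-1, 3), rc_spec)]
    failure = None
    x = res.x
    for stage, target in enumerate(schedule.targets):
        res = minimize(objective, x, args=(target,), jac=True, method="L-BFGS-B",
                       options=opts)
        x = res.x
        states.append(x.copy())
        energies.append(float(evaluate_potential(x, spec)[0]))
        rcs.append(rc_value(x.reshape(-1, 3), rc_spec))
        if not res.success and "CONVERGENCE" not in str(res.message).upper():
            failure = stage
            break
    return DrivingResult(
        states=np.asarray(states),
        rc_targets=np.asarray(schedule.targets[: len(states) - 1]),
        rc_achieved=np.asarray(rcs),
        energies=np.asarray(energies),
        failure_index=failure,
    )
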