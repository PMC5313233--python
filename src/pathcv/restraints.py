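"""Harmonic and flat-bottom (half-harmonic) restraints with time ramps.

A restraint acts on a scalar quantity of a conformation — a single
degree of freedom, the distance of one particle to a fixed anchor point,
or an interatomic distance — and contributes

* ``harmonic``:          E = ½ k (v − v0)²
* ``upper-flat-bottom``: E = ½ k (v − v0)²  for v > v0, else 0
* ``lower-flat-bottom``: E = ½ k (v − v0)²  for v < v0, else 0

Force constants may ramp linearly in time (the protocol used to pull a
side chain into position before production sampling): k(t) interpolates
from ``k_start`` to ``k_end`` over ``duration`` ps and stays constant
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import SpecError

__all__ = ["RampSchedule", "Restraint", "restraint_energy", "apply_restraints"]

_KINDS = ("harmonic", "lower-flat-bottom", "upper-flat-bottom")


@dataclass(frozen=True)
class RampSchedule:
    """Linear ramp of a force constant: k_start → k_end over duration ps."""

    k_start: float
    k_end: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise SpecError("ramp duration must be strictly positive")
        if self.k_start < 0 or self.k_end < 0:
            raise SpecError("ramped force constants must be >= 0")

    def at(self, time: float) -> float:
        f = min(max(time / self.duration, 0.0), 1.0)
        return self.k_start + (self.k_end - self.k_start) * f


@dataclass(frozen=True)
class Restraint:
    """A restraint on a scalar structural quantity.

    ``target`` identifies the quantity:

    * ``("coord", dof)`` — a single flat-coordinate degree of freedom;
    * ``("point", particle, (x, y, z))`` — distance of a particle to a
      fixed anchor point (3D bead systems only);
    * ``("distance", i, j)`` — interatomic distance between particles.

    ``value`` is the equilibrium value (harmonic) or threshold
    (flat-bottom) in Å; ``force_constant`` is in kcal/mol/Å².
    """

    kind: str
    target: Tuple
    value: float
    force_constant: float
    ramp: Optional[RampSchedule] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SpecError(f"unknown restraint kind {self.kind!r}; expected one of {_KINDS}")
        if self.force_constant < 0:
            raise SpecError("restraint force constant must be >= 0")
        if not self.target or self.target[0] not in ("coord", "point", "distance"):
            raise SpecError(f"unknown restraint target {self.target!r}")

    def k_at(self, time: float) -> float:
        return self.ramp.at(time) if self.ramp is not None else self.force_constant


def restraint_energy(restraint: Restraint, value, time: float = 0.0):
    """Energy (kcal/mol) and dE/dvalue (kcal/mol/Å) at a scalar value.

    Flat-bottom restraints contribute exactly zero strictly inside their
    allowed region; the force is the exact derivative of the energy.
    """
    v = np.asarray(value, dtype=float)
    k = restraint.k_at(time)
    dv = v - restraint.value
    if restraint.kind == "upper-flat-bottom":
        dv = np.maximum(dv, 0.0)
    elif restraint.kind == "lower-flat-bottom":
        dv = np.minimum(dv, 0.0)
    energy = 0.5 * k * dv * dv
    force = k * dv
    return energy, force


def apply_restraints(x: np.ndarray, restraints, time: float = 0.0):
    """Total restraint energy and coordinate gradient for flat coordinates.

    ``x`` may be batched with trailing axis = degrees of freedom.
    Returns ``(energy, gradient)`` with gradient the derivative of the
    energy with respect to ``x`` (so the restraint force is its
    negative).
    """
    x = np.asarray(x, dtype=float)
    energy = np.zeros(x.shape[:-1])
    grad = np.zeros_like(x)
    d = x.shape[-1]
    for res in restraints:
        tgt = res.target
        if tgt[0] == "coord":
            dof = int(tgt[1])
            e, dEdv = restraint_energy(res, x[..., dof], time)
            energy += e
            grad[..., dof] += dEdv
        else:
            pos = x.reshape(x.shape[:-1] + (d // 3, 3))
            if tgt[0] == "point":
                i = int(tgt[1])
                anchor = np.asarray(tgt[2], dtype=float)
                rij = pos[..., i, :] - anchor
                r = np.sqrt(np.sum(rij * rij, axis=-1))
                e, dEdv = restraint_energy(res, r, time)
                energy += e
                with np.errstate(invalid="ignore", divide="ignore"):
                    unit = np.where(r[..., None] > 0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
                g = grad.reshape(pos.shape)
                g[..., i, :] += dEdv[..., None] * unit
            else:  # distance
                i, j = int(tgt[1]), int(tgt[2])
                rij = pos[..., i, :] - pos[..., j, :]
                r = np.sqrt(np.sum(rij * rij, axis=-1))
                e, dEdv = restraint_energy(res, r, time)
                energy += e
                with np.errstate(invalid="ignore", divide="ignore"):
                    unit = np.where(r[..., None] > 0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
                g = grad.reshape(pos.shape)
                g[..., i, :] += dEdv[..., None] * unit
                g[..., j, :] -= dEdv[..., None] * unit
    return energy, grad
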