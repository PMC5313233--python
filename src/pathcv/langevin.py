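"""Langevin dynamics with the BAOAB splitting.

The integrator advances positions with the B-A-O-A-B scheme (half kick,
half drift, Ornstein–Uhlenbeck velocity refresh, half drift, half kick),
which remains accurate at the large friction coefficients used for
thermostatted sampling and reduces exactly to velocity Verlet when both
the temperature and friction are zero, so the same code serves the
energy-conservation checks and the production sampler.

Forces combine the analytic potential gradient, restraint gradients, and
an optional caller-supplied extra force (used for moving CV restraints
in the string method and for the metadynamics bias).  All randomness
flows from a single seeded generator, making trajectories bit-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .restraints import apply_restraints
from .systems import ToySystemSpec, evaluate_potential
from .units import KB, KCAL_PER_AKMA

__all__ = ["LangevinIntegrator", "LangevinResult", "run_langevin"]


@dataclass
class LangevinResult:
    positions: np.ndarray  # (n_samples, *batch, ndof)
    velocities: np.ndarray  # final velocities (*batch, ndof), Å/ps
    final: np.ndarray  # final positions (*batch, ndof)
    energies: np.ndarray  # sampled potential energies (n_samples, *batch)


class LangevinIntegrator:
    """Stepwise BAOAB integrator over (optionally batched) replicas."""

    def __init__(self, spec: ToySystemSpec, restraints=(), seed=None, x0=None, extra_force=None):
        self.spec = spec
        self.restraints = tuple(restraints)
        self.extra_force = extra_force
        self.rng = np.random.default_rng(spec.seed if seed is None else seed)
        if x0 is None:
            x0 = np.zeros(spec.ndof)
        self.x = np.array(x0, dtype=float)
        if self.x.shape[-1] != spec.ndof:
            raise SpecError(
                f"initial state has {self.x.shape[-1]} dof, spec expects {spec.ndof}"
            )
        self.v = np.zeros_like(self.x)
        self.time = 0.0
        dt, gamma = spec.timestep, spec.friction
        self._c1 = np.exp(-gamma * dt)
        # velocity variance in (Å/ps)^2: kB T * 418.4 / m
        self._c2 = np.sqrt(max(KB * spec.temperature * KCAL_PER_AKMA / spec.mass, 0.0)
                           * (1.0 - self._c1**2))
        self._acc = self._acceleration(self.x, self.time)

    def _acceleration(self, x, t):
        _, g = evaluate_potential(x, self.spec)
        force = -g
        if self.restraints:
            _, gr = apply_restraints(x, self.restraints, t)
            force = force - gr
        if self.extra_force is not None:
            force = force + self.extra_force(x, t)
        return force * (KCAL_PER_AKMA / self.spec.mass)

    def potential_energy(self):
        e, _ = evaluate_potential(self.x, self.spec)
        if self.restraints:
            er, _ = apply_restraints(self.x, self.restraints, self.time)
            e = e + er
        return e

    def kinetic_energy(self):
        """Kinetic energy in kcal/mol."""
        return 0.5 * self.spec.mass * np.sum(self.v * self.v, axis=-1) / KCAL_PER_AKMA

    def step(self, n: int = 1):
        dt = self.spec.timestep
        half = 0.5 * dt
        for _ in range(n):
            self.v += half * self._acc
            self.x += half * self.v
            if self._c2 > 0.0:
                self.v = self._c1 * self.v + self._c2 * self.rng.standard_normal(self.v.shape)
            else:
                self.v *= self._c1
            self.x += half * self.v
            self.time += dt
            self._acc = self._acceleration(self.x, self.time)
            self.v += half * self._acc
        return self.x


def run_langevin(
    spec: ToySystemSpec,
    restraints=(),
    n_steps: int = 1000,
    seed=None,
    x0=None,
    sample_stride: int = 1,
    extra_force=None,
) -> LangevinResult:
    """Run Langevin dynamics and return sampled positions.

    Positions are recorded every ``sample_stride`` steps (after the
    step).  ``x0`` may be a single state or a batch of replicas; the
    trajectory is deterministic for a fixed seed.
    """
    if n_steps < 1:
        raise SpecError("n_steps must be >= 1")
    if sample_stride < 1:
        raise SpecError("sample_stride must be >= 1")
    integ = LangevinIntegrator(spec, restraints, seed=seed, x0=x0, extra_force=extra_force)
    n_samples = n_steps // sample_stride
    positions = np.empty((n_samples,) + integ.x.shape)
    energies = np.empty((n_samples,) + integ.x.shape[:-1])
    k = 0
    for i in range(n_steps):
        integ.step()
        if (i + 1) % sample_stride == 0:
            positions[k] = integ.x
            energies[k] = integ.potential_energy()
            k += 1
    return LangevinResult(positions=positions, velocities=integ.v.copy(),
                          final=integ.x.copy(), energies=energies)
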