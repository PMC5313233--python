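"""Finite-temperature string method in collective variables.

Each image of the string runs restrained dynamics with its CVs tethered
to target values z* by a harmonic restraint of force constant k.  The
mean force on each CV is estimated from the sampling window as

    ∂F/∂z_i = k ⟨z_i* − z_i⟩,

and the targets are evolved by overdamped steepest descent on the free
energy,

    z_i*(t + dt) = z_i*(t) − γ⁻¹ m⁻¹ (∂F/∂z_i) dt,

with friction γ (125 ps⁻¹ by default), effective mass m (the mass of a
carbon atom by default) and the package-wide conversion of
1 kcal/mol = 418.4 amu·Å²/ps² applied so the displacement comes out in
Å.  After every update the string is reparametrized to equal arc-length
spacing in CV space.  Convergence is monitored through the RMSD of the
targets from their initial values; once the trailing window of that
trace is flat within tolerance, a longer sampling pass at fixed targets
estimates the final mean forces, and the potential of mean force is
obtained by integrating

    F(α) = ∫₀^α Σ_i (∂F/∂z_i)(∂z_i/∂α) dα

with centered differences for ∂z_i/∂α (one-sided at the ends) and the
trapezoidal rule for the integral, anchored at F(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .cv import CVSet
from .errors import SpecError
from .langevin import LangevinIntegrator
from .systems import ToySystemSpec
from .units import KCAL_PER_AKMA
from .zts import Path, reparametrize

__all__ = [
    "StringState",
    "MeanForceEstimate",
    "ConvergenceTrace",
    "PMFProfile",
    "StringResult",
    "estimate_mean_force",
    "update_string",
    "reparametrize_string",
    "check_convergence",
    "integrate_pmf",
    "run_string_method",
]


@dataclass
class StringState:
    """Per-image CV targets plus the evolution parameters."""

    targets: np.ndarray  # (n_images, n_cv)
    force_constant: float = 1.0  # k, kcal/mol/Å²
    friction: float = 125.0  # γ, ps⁻¹
    mass: float = 12.011  # m, amu (carbon)
    dt: float = 0.02  # evolution time step, ps
    stride: int = 10  # MD steps per sampling window
    fixed_endpoints: bool = False

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.ndim != 2:
            raise SpecError("targets must have shape (n_images, n_cv)")
        if self.force_constant <= 0 or self.friction <= 0 or self.mass <= 0:
            raise SpecError("k, friction and mass must be strictly positive")
        if self.stride < 1:
            raise SpecError("stride must be >= 1")


@dataclass
class MeanForceEstimate:
    """Estimated ∂F/∂z per image and CV, with block-averaged errors."""

    values: np.ndarray  # (n_images, n_cv) or (n_cv,)
    n_samples: int
    stderr: Optional[np.ndarray] = None


@dataclass
class ConvergenceTrace:
    """RMSD of the string targets from their initial values per update."""

    rmsd: list = field(default_factory=lambda: [0.0])

    def append(self, value: float):
        if value < 0:
            raise SpecError("RMSD entries must be non-negative")
        self.rmsd.append(float(value))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rmsd)


@dataclass
class PMFProfile:
    """Free energy along the normalized string parameter, F(0) = 0."""

    alpha: np.ndarray
    free_energy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alpha, "free_energy": self.free_energy})

    @property
    def barrier(self) -> float:
        return float(np.max(self.free_energy))

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.free_energy))


@dataclass
class StringResult:
    state: StringState
    pmf: PMFProfile
    trace: ConvergenceTrace
    converged: bool
    mean_forces: MeanForceEstimate
    final_samples: Optional[np.ndarray] = None


def estimate_mean_force(samples, zstar, force_constant: float,
                        n_blocks: int = 5) -> MeanForceEstimate:
    """Mean-force estimate k⟨z* − z⟩ over a sampling window.

    ``samples`` has shape (n_samples, ..., n_cv); the standard error is
    computed by block averaging (5 blocks by default) to allow for the
    correlation of consecutive samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim < 2 or samples.shape[0] < 1:
        raise SpecError("need at least one sample of shape (n_samples, ..., n_cv)")
    zstar = np.asarray(zstar, dtype=float)
    n = samples.shape[0]
    values = force_constant * (zstar - samples.mean(axis=0))
    stderr = None
    if n >= n_blocks and n_blocks > 1:
        usable = n - n % n_blocks
        blocks = samples[:usable].reshape((n_blocks, usable // n_blocks) + samples.shape[1:])
        block_means = force_constant * (zstar - blocks.mean(axis=1))
        stderr = block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return MeanForceEstimate(values=values, n_samples=n, stderr=stderr)


def update_string(state: StringState, forces: MeanForceEstimate) -> StringState:
    """One overdamped evolution step of the targets (endpoints included
    unless the state pins them)."""
    f = np.asarray(forces.values, dtype=float)
    if f.shape != state.targets.shape:
        raise SpecError(
            f"mean-force shape {f.shape} does not match targets {state.targets.shape}"
        )
    step = state.dt * KCAL_PER_AKMA / (state.friction * state.mass)
    new = state.targets - step * f
    if state.fixed_endpoints:
        new[0] = state.targets[0]
        new[-1] = state.targets[-1]
    return replace(state, targets=new)


def reparametrize_string(state: StringState) -> StringState:
    """Equal arc-length redistribution of the targets in CV space."""
    path = reparametrize(Path(state.targets, fixed_endpoints=True))
    return replace(state, targets=path.images)


def check_convergence(trace: ConvergenceTrace, window: int, tolerance: float) -> bool:
    """True when the RMSD trace's trailing window spans <= tolerance."""
    if window < 2:
        raise SpecError("convergence window must be >= 2")
    values = trace.as_array()
    if len(values) < window:
        return False
    tail = values[-window:]
    return float(tail.max() - tail.min()) <= tolerance


def integrate_pmf(targets: np.ndarray, forces: np.ndarray) -> PMFProfile:
    """Thermodynamic integration of mean forces along the string.

    ∂z_i/∂α is taken by centered differences on the uniform α grid
    (one-sided at the ends) and F accumulates by the trapezoidal rule.
    """
    targets = np.asarray(targets, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if targets.ndim != 2 or len(targets) < 2:
        raise SpecError("PMF integration needs at least 2 images")
    if forces.shape != targets.shape:
        raise SpecError("forces must match the targets' shape")
    alpha = np.linspace(0.0, 1.0, len(targets))
    dz_dalpha = np.gradient(targets, alpha, axis=0)
    integrand = np.sum(forces * dz_dalpha, axis=1)
    free_energy = np.concatenate([[0.0], cumulative_trapezoid(integrand, alpha)])
    return PMFProfile(alpha=alpha, free_energy=free_energy)


def run_string_method(
    spec: ToySystemSpec,
    cvset: CVSet,
    initial_path: Path,
    state: StringState,
    seed: int,
    max_updates: int = 300,
    burn_in: Optional[int] = None,
    reparam_every: int = 1,
    conv_window: int = 50,
    conv_tolerance: float = 0.01,
    pmf_steps: int = 2000,
    pmf_burn_in: Optional[int] = None,
    average_window: int = 0,
) -> StringResult:
    """Full string-method loop: sample, estimate, evolve, reparametrize.

    ``initial_path`` supplies both the initial conformations (one
    replica per image) and, through ``cvset``, the initial targets.
    ``burn_in`` steps (10× the sampling stride by default) are discarded
    after every reparametrization before forces accumulate.  If the
    update cap is reached without convergence the best state is returned
    with ``converged=False``.

    With ``average_window`` > 0 the converged string is taken as the
    time average of the targets over the trailing window of updates
    (reparametrized once more), which suppresses the Monte Carlo wander
    of the instantaneous string; the final PMF pass then samples at the
    averaged targets.
    """
    if burn_in is None:
        burn_in = 10 * state.stride
    if pmf_burn_in is None:
        pmf_burn_in = 10 * burn_in
    x = initial_path.images.copy()  # (n_images, ndof) replicas
    targets = cvset.values(x)
    state = replace(state, targets=targets)
    current = {"targets": state.targets}

    def cv_restraint_force(xx, t):
        cvv = cvset.values_and_grads(xx)
        dz = cvv.values - current["targets"]
        return -state.force_constant * np.einsum("...c,...cd->...d", dz, cvv.gradients)

    integ = LangevinIntegrator(spec, seed=seed, x0=x, extra_force=cv_restraint_force)
    initial_targets = state.targets.copy()
    trace = ConvergenceTrace()
    converged = False
    history = []
    for update in range(max_updates):
        if burn_in:
            integ.step(burn_in)
        window = np.empty((state.stride,) + state.targets.shape)
        for s in range(state.stride):
            integ.step()
            window[s] = cvset.values(integ.x)
        forces = estimate_mean_force(window, state.targets, state.force_constant)
        state = update_string(state, forces)
        if reparam_every and (update + 1) % reparam_every == 0:
            state = reparametrize_string(state)
        current["targets"] = state.targets
        if average_window:
            history.append(state.targets.copy())
            history = history[-average_window:]
        rmsd = float(np.sqrt(np.mean((state.targets - initial_targets) ** 2)))
        trace.append(rmsd)
        if check_convergence(trace, conv_window, conv_tolerance):
            converged = True
            break

    if average_window and history:
        state = replace(state, targets=np.mean(history, axis=0))
        state = reparametrize_string(state)
        current["targets"] = state.targets

    # final PMF pass at fixed targets
    if pmf_burn_in:
        integ.step(pmf_burn_in)
    samples = np.empty((pmf_steps,) + state.targets.shape)
    for s in range(pmf_steps):
        integ.step()
        samples[s] = cvset.values(integ.x)
    mean_forces = estimate_mean_force(samples, state.targets, state.force_constant)
    pmf = integrate_pmf(state.targets, mean_forces.values)
    return StringResult(state=state, pmf=pmf, trace=trace, converged=converged,
                        mean_forces=mean_forces, final_samples=samples)


def write_string_tsv(path, state: StringState) -> None:
    n_images, n_cv = state.targets.shape
    df = pd.DataFrame(
        {
            "image": np.repeat(np.arange(n_images), n_cv),
            "cv": np.tile(np.arange(n_cv), n_images),
            "target": state.targets.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_string_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    n_images = df["image"].max() + 1
    n_cv = df["cv"].max() + 1
    return df["target"].to_numpy().reshape(n_images, n_cv)
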