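"""Analytic model systems used in place of all-atom molecular mechanics.

Five potential kinds are provided:

``harmonic``
    Isotropic (or per-degree-of-freedom) harmonic well.
``double-well-1d``
    Symmetric quartic double well with minima at ±a, barrier ``b`` at the
    origin, and an optional linear tilt that sets the energy offset
    between the two minima.
``double-well-2d``
    The 1D double well in x plus a harmonic confinement in y.
``mueller-brown``
    The standard four-Gaussian Müller–Brown surface in its literature
    parameterization (reduced units), multiplied by a configurable scale
    factor that maps reduced energy to kcal/mol.
``bead-chain``
    A coarse-grained chain of beads with harmonic bonds, optional global
    confinement, optional short-range Gaussian pair attractions, and an
    optional double-well "bond" between one designated bead pair (a pair
    that can rest at either a short or a long separation, emulating a
    contact that forms and breaks during a conformational transition).

All potentials are batched: coordinates may have any leading shape as
long as the trailing axis matches the system's degrees of freedom, and
gradients are exact analytic derivatives of the returned energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DimensionalityError, SpecError
from .units import KB

__all__ = [
    "ToySystemSpec",
    "TwoStateLoopSpec",
    "evaluate_potential",
    "generate_two_state_loop",
    "make_two_state_loop_spec",
    "mueller_brown_minima",
    "mueller_brown_saddles",
    "substrate_positioning_system",
    "double_well_free_energy_difference",
]

_KINDS = ("mueller-brown", "double-well-1d", "double-well-2d", "harmonic", "bead-chain")

# Literature Müller–Brown parameters (reduced units).
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


@dataclass(frozen=True)
class ToySystemSpec:
    """Definition of a model system plus its Langevin parameters.

    Parameters
    ----------
    kind:
        One of ``mueller-brown``, ``double-well-1d``, ``double-well-2d``,
        ``harmonic``, ``bead-chain``.
    params:
        Potential parameters; see the module docstring for each kind.
    temperature:
        Thermostat temperature in K (>= 0).
    friction:
        Langevin damping coefficient in ps⁻¹ (>= 0; zero disables the
        thermostat and yields energy-conserving dynamics).
    timestep:
        Integration time step in ps (> 0).
    mass:
        Particle mass in amu, uniform across degrees of freedom.
    seed:
        Mandatory seed for any stochastic use of this system.
    """

    kind: str
    params: dict = field(default_factory=dict)
    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 0.002
    mass: float = 12.011
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SpecError(f"unknown potential kind {self.kind!r}; expected one of {_KINDS}")
        if self.timestep <= 0:
            raise SpecError("time step must be strictly positive")
        if self.temperature < 0:
            raise SpecError("temperature must be >= 0")
        if self.friction < 0:
            raise SpecError("friction must be >= 0")
        if self.mass <= 0:
            raise SpecError("mass must be strictly positive")
        for key in ("stiffness", "bond_stiffness", "confinement"):
            if key in self.params and not _positive_ok(self.params[key], key == "confinement"):
                raise SpecError(f"{key} must be strictly positive")
        if self.kind == "bead-chain":
            n = int(self.params.get("n_beads", 0))
            if n < 3:
                raise SpecError("bead-chain requires at least 3 beads")
            if float(self.params.get("bond_stiffness", 1.0)) <= 0:
                raise SpecError("bond_stiffness must be strictly positive")

    @property
    def ndof(self) -> int:
        if self.kind == "double-well-1d":
            return 1
        if self.kind in ("double-well-2d", "mueller-brown"):
            return 2
        if self.kind == "harmonic":
            center = self.params.get("center")
            if center is not None:
                return len(np.atleast_1d(center))
            return int(self.params.get("ndim", 1))
        return 3 * int(self.params["n_beads"])

    @property
    def n_particles(self) -> int | None:
        """Number of 3D particles, or None for low-dimensional surfaces."""
        return int(self.params["n_beads"]) if self.kind == "bead-chain" else None

    def with_seed(self, seed: int) -> "ToySystemSpec":
        return replace(self, seed=int(seed))


def _positive_ok(value, allow_zero: bool) -> bool:
    v = np.asarray(value, dtype=float)
    return bool(np.all(v >= 0) if allow_zero else np.all(v > 0))


# ---------------------------------------------------------------------------
# potential evaluation


def evaluate_potential(state, spec: ToySystemSpec):
    """Energy (kcal/mol) and gradient (kcal/mol/Å) of ``state`` under ``spec``.

    ``state`` may carry arbitrary leading batch axes; the trailing axis
    must equal ``spec.ndof``.
    """
    x = np.asarray(state, dtype=float)
    if x.shape[-1:] != (spec.ndof,):
        raise DimensionalityError(
            f"state has {x.shape[-1] if x.ndim else 0} degrees of freedom, "
            f"spec {spec.kind!r} expects {spec.ndof}"
        )
    return _DISPATCH[spec.kind](x, spec.params)


def _harmonic(x, params):
    k = np.asarray(params.get("stiffness", 1.0), dtype=float)
    center = np.asarray(params.get("center", np.zeros(x.shape[-1])), dtype=float)
    dx = x - center
    energy = 0.5 * np.sum(k * dx * dx, axis=-1)
    grad = k * dx
    return energy, grad


def _dw1d_scalar(x, params):
    b = float(params.get("barrier", 3.0))
    a = float(params.get("half_width", 1.0))
    tilt = float(params.get("tilt", 0.0))
    u = (x / a) ** 2 - 1.0
    energy = b * u * u + tilt * x / (2.0 * a)
    grad = 4.0 * b * u * x / a**2 + tilt / (2.0 * a)
    return energy, grad


def _double_well_1d(x, params):
    e, g = _dw1d_scalar(x[..., 0], params)
    return e, g[..., None]


def _double_well_2d(x, params):
    e, gx = _dw1d_scalar(x[..., 0], params)
    ky = float(params.get("stiffness_y", 1.0))
    y = x[..., 1]
    energy = e + 0.5 * ky * y * y
    grad = np.stack([gx, ky * y], axis=-1)
    return energy, grad


def _mueller_brown(x, params):
    scale = float(params.get("scale", 1.0))
    dx = x[..., 0, None] - _MB_x0
    dy = x[..., 1, None] - _MB_y0
    expo = _MB_a * dx * dx + _MB_b * dx * dy + _MB_c * dy * dy
    terms = _MB_A * np.exp(expo)
    energy = scale * np.sum(terms, axis=-1)
    gx = scale * np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy), axis=-1)
    gy = scale * np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy), axis=-1)
    return energy, np.stack([gx, gy], axis=-1)


def _pair_vectors(pos, i, j):
    rij = pos[..., i, :] - pos[..., j, :]
    r = np.sqrt(np.sum(rij * rij, axis=-1))
    return rij, r


def _bead_chain(x, params):
    n = int(params["n_beads"])
    pos = x.reshape(x.shape[:-1] + (n, 3))
    energy = np.zeros(x.shape[:-1])
    grad = np.zeros_like(pos)

    kb = float(params.get("bond_stiffness", 10.0))
    l0 = float(params.get("bond_length", 3.8))
    for i in range(n - 1):
        rij, r = _pair_vectors(pos, i, i + 1)
        dr = r - l0
        energy += 0.5 * kb * dr * dr
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[..., None] > 0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
        f = kb * dr[..., None] * unit
        grad[..., i, :] += f
        grad[..., i + 1, :] -= f

    kc = float(params.get("confinement", 0.0))
    if kc:
        energy += 0.5 * kc * np.sum(pos * pos, axis=(-2, -1))
        grad += kc * pos

    # Short-range Gaussian attractions: -depth * exp(-(r - r_eq)^2 / (2 w^2))
    for (i, j, depth, width, r_eq) in params.get("attractions", ()):
        rij, r = _pair_vectors(pos, int(i), int(j))
        s = r - float(r_eq)
        w2 = float(width) ** 2
        e = -float(depth) * np.exp(-0.5 * s * s / w2)
        energy += e
        dedr = -e * s / w2
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[..., None] > 0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
        f = dedr[..., None] * unit
        grad[..., int(i), :] += f
        grad[..., int(j), :] -= f

    dw = params.get("dw_bond")
    if dw is not None:
        i, j = (int(v) for v in dw["pair"])
        r1, r2 = float(dw["r1"]), float(dw["r2"])
        h = float(dw["barrier"])
        m = 0.5 * (r1 + r2)
        c = 0.5 * (r2 - r1)
        rij, r = _pair_vectors(pos, i, j)
        u = (r - m) ** 2 - c * c
        energy += h * u * u / c**4
        dedr = 4.0 * h * u * (r - m) / c**4
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[..., None] > 0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
        f = dedr[..., None] * unit
        grad[..., i, :] += f
        grad[..., j, :] -= f

    return energy, grad.reshape(x.shape)


_DISPATCH = {
    "harmonic": _harmonic,
    "double-well-1d": _double_well_1d,
    "double-well-2d": _double_well_2d,
    "mueller-brown": _mueller_brown,
    "bead-chain": _bead_chain,
}


# ---------------------------------------------------------------------------
# Müller–Brown stationary points (Newton oracle)


def _mb_newton(spec: ToySystemSpec, x0, want_saddle: bool):
    """Newton iteration on the analytic gradient; Hessian by finite differences."""
    x = np.asarray(x0, dtype=float)
    h = 1e-6
    for _ in range(100):
        _, g = evaluate_potential(x, spec)
        if np.linalg.norm(g) < 1e-12:
            break
        hess = np.empty((2, 2))
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            _, gp = evaluate_potential(x + e, spec)
            _, gm = evaluate_potential(x - e, spec)
            hess[:, k] = (gp - gm) / (2 * h)
        hess = 0.5 * (hess + hess.T)
        x = x - np.linalg.solve(hess, g)
    eig = np.linalg.eigvalsh(hess)
    is_saddle = eig[0] < 0 < eig[1]
    if want_saddle != is_saddle:
        raise ConvergenceWarningError(x, eig)
    return x


class ConvergenceWarningError(RuntimeError):
    def __init__(self, x, eig):
        super().__init__(f"Newton iteration converged to wrong stationary type at {x} (eig {eig})")


def mueller_brown_minima(spec: ToySystemSpec | None = None) -> np.ndarray:
    """The three Müller–Brown minima, deepest first, located by Newton iteration."""
    spec = spec or ToySystemSpec("mueller-brown")
    guesses = [(-0.55, 1.45), (-0.05, 0.47), (0.62, 0.03)]
    pts = np.array([_mb_newton(spec, g, want_saddle=False) for g in guesses])
    energies = evaluate_potential(pts, spec)[0]
    return pts[np.argsort(energies)]


def mueller_brown_saddles(spec: ToySystemSpec | None = None) -> np.ndarray:
    """The two Müller–Brown saddle points, higher-energy first."""
    spec = spec or ToySystemSpec("mueller-brown")
    guesses = [(-0.82, 0.62), (0.21, 0.29)]
    pts = np.array([_mb_newton(spec, g, want_saddle=True) for g in guesses])
    energies = evaluate_potential(pts, spec)[0]
    return pts[np.argsort(energies)[::-1]]


# ---------------------------------------------------------------------------
# double-well reference free energies


def double_well_free_energy_difference(spec: ToySystemSpec, split: float = 0.0) -> float:
    """Analytic (quadrature) free-energy difference between the two basins
    of a 1D double well at the spec's temperature: F(x > split) − F(x < split)."""
    from scipy.integrate import quad

    if spec.kind != "double-well-1d":
        raise SpecError("free-energy oracle defined for double-well-1d only")
    beta = 1.0 / (KB * spec.temperature)
    a = float(spec.params.get("half_width", 1.0))

    def boltz(x):
        e, _ = _dw1d_scalar(np.asarray(x), spec.params)
        return math.exp(-beta * float(e))

    lo, hi = -8.0 * a, 8.0 * a
    z_left, _ = quad(boltz, lo, split, limit=200)
    z_right, _ = quad(boltz, split, hi, limit=200)
    return -math.log(z_right / z_left) / beta


# ---------------------------------------------------------------------------
# two-state bead-chain loop


@dataclass(frozen=True)
class TwoStateLoopSpec:
    """Synthetic two-state "activation loop" stand-in.

    Two reference conformers of a bead chain (an extended "inactive"
    state and a hairpin "active" state) define a set of planted bead
    pairs whose separations cross the contact radius between states.
    Sampling draws frames from the two basins with Boltzmann weights set
    by the basin depths and adds isotropic Gaussian displacement noise.
    """

    n_beads: int
    ref_inactive: np.ndarray  # (n_beads, 3) Å
    ref_active: np.ndarray  # (n_beads, 3) Å
    planted_pairs: tuple  # ((i, j), ...)
    basin_depths: tuple = (0.0, 0.0)  # kcal/mol, (inactive, active); deeper = more populated
    noise_amplitude: float = 0.3  # Å
    temperature: float = 300.0
    seed: int = 0
    contact_radius: float = 8.0
    ratio: float = 1.5
    exclude_neighbors: int = 2

    def __post_init__(self):
        object.__setattr__(self, "ref_inactive", np.asarray(self.ref_inactive, dtype=float))
        object.__setattr__(self, "ref_active", np.asarray(self.ref_active, dtype=float))
        if self.n_beads < 3:
            raise SpecError("two-state loop requires at least 3 beads")
        for ref, name in ((self.ref_inactive, "inactive"), (self.ref_active, "active")):
            if ref.shape != (self.n_beads, 3):
                raise SpecError(f"reference {name!r} must have shape ({self.n_beads}, 3)")
        if self.noise_amplitude < 0:
            raise SpecError("noise amplitude must be >= 0")
        for (i, j) in self.planted_pairs:
            di = float(np.linalg.norm(self.ref_inactive[i] - self.ref_inactive[j]))
            da = float(np.linalg.norm(self.ref_active[i] - self.ref_active[j]))
            lo, hi = sorted((di, da))
            if not (lo < self.contact_radius < hi):
                raise SpecError(
                    f"planted pair ({i}, {j}) does not cross {self.contact_radius} Å "
                    f"between references (distances {di:.2f}, {da:.2f})"
                )
            if hi < self.ratio * lo:
                raise SpecError(
                    f"planted pair ({i}, {j}) violates the ratio rule: "
                    f"{hi:.2f} < {self.ratio} × {lo:.2f}"
                )


def make_two_state_loop_spec(
    n_beads: int = 20,
    bond_length: float = 3.8,
    strand_gap: float = 4.6,
    noise_amplitude: float = 0.3,
    basin_depths: Sequence[float] = (0.0, 0.0),
    seed: int = 0,
) -> TwoStateLoopSpec:
    """Construct a two-state loop: extended strand vs β-hairpin.

    The inactive reference is a straight chain along x with consecutive
    beads ``bond_length`` apart; the active reference folds the chain
    into a hairpin of two antiparallel strands separated by
    ``strand_gap`` Å, bringing cross-strand bead pairs inside the 8 Å
    contact radius.  The planted pair set is computed by brute-force
    double loop over the two references using the selection rule
    (crossing the contact radius with a >= 1.5 distance ratio, bonded
    neighbors |i − j| <= 2 excluded).
    """
    if n_beads % 2:
        raise SpecError("hairpin construction requires an even bead count")
    half = n_beads // 2
    inactive = np.zeros((n_beads, 3))
    inactive[:, 0] = bond_length * np.arange(n_beads)
    active = np.zeros((n_beads, 3))
    active[:half, 0] = bond_length * np.arange(half)
    active[half:, 0] = bond_length * np.arange(half - 1, -1, -1)
    active[half:, 1] = strand_gap

    planted = []
    for i in range(n_beads):
        for j in range(i + 3, n_beads):
            di = float(np.linalg.norm(inactive[i] - inactive[j]))
            da = float(np.linalg.norm(active[i] - active[j]))
            lo, hi = sorted((di, da))
            if lo < 8.0 < hi and hi >= 1.5 * lo:
                planted.append((i, j))
    return TwoStateLoopSpec(
        n_beads=n_beads,
        ref_inactive=inactive,
        ref_active=active,
        planted_pairs=tuple(planted),
        basin_depths=tuple(float(d) for d in basin_depths),
        noise_amplitude=noise_amplitude,
        seed=seed,
    )


def generate_two_state_loop(spec: TwoStateLoopSpec, n_frames: int = 200):
    """Sample an ensemble from the two-basin loop model.

    Returns ``(references, frames, labels)`` where ``references`` is the
    ``(inactive, active)`` pair, ``frames`` has shape
    ``(n_frames, n_beads, 3)`` and ``labels`` records the generating
    basin (0 = inactive, 1 = active).  Basin occupancies follow
    Boltzmann weights ``exp(depth / kB T)`` of the basin depths.
    """
    rng = np.random.default_rng(spec.seed)
    beta = 1.0 / (KB * spec.temperature)
    w = np.exp(beta * (np.asarray(spec.basin_depths) - max(spec.basin_depths)))
    p_active = w[1] / (w[0] + w[1])
    labels = (rng.random(n_frames) < p_active).astype(int)
    refs = np.stack([spec.ref_inactive, spec.ref_active])
    frames = refs[labels]
    if spec.noise_amplitude > 0:
        frames = frames + spec.noise_amplitude * rng.standard_normal(frames.shape)
    else:
        frames = frames.copy()
    return (spec.ref_inactive.copy(), spec.ref_active.copy()), frames, labels


# ---------------------------------------------------------------------------
# substrate-positioning (guardian bead) scenario


def substrate_positioning_system(mode: str, seed: int = 0) -> tuple:
    """Toy analogue of the restrained substrate-stabilization comparison.

    A "substrate" bead sits in a weak harmonic trap at the origin inside
    a stiff channel (its y and z motion is strongly restrained, mimicking
    the active-site cleft).  A "guardian" bead (the Arg664 analogue) is
    strongly anchored at a mode-dependent distance and attracts the
    substrate through a short-range Gaussian well with a 4.5 Å
    equilibrium separation.  Modes:

    ``in``
        guardian anchored 4.5 Å away (active-site position); a
        half-harmonic keeps the guardian–substrate distance below 6 Å.
    ``intermediate``
        guardian anchored 8 Å away (secondary-site position, the
        Asp530-bound analogue) with a half-harmonic around that site.
    ``out``
        guardian anchored 25 Å away; a half-harmonic keeps the
        guardian–substrate distance above 10 Å.

    Returns ``(spec, restraints, substrate_index)`` ready for
    :func:`pathcv.langevin.run_langevin`.
    """
    from .restraints import Restraint

    anchors = {"in": 4.5, "intermediate": 8.0, "out": 25.0}
    if mode not in anchors:
        raise SpecError(f"unknown mode {mode!r}; expected one of {sorted(anchors)}")
    d = anchors[mode]
    spec = ToySystemSpec(
        kind="bead-chain",
        params={
            "n_beads": 3,
            "bond_length": 5.0,
            "bond_stiffness": 1e-3,  # chain topology only; restraints dominate
            "attractions": [(0, 2, 4.0, 1.0, 4.5)],  # substrate–guardian well
        },
        temperature=300.0,
        friction=2.0,
        timestep=0.004,
        seed=seed,
    )
    restraints = [
        # substrate: weak trap along the channel axis, stiff channel walls
        Restraint("harmonic", ("coord", 0), 0.0, 0.3),
        Restraint("harmonic", ("coord", 1), 0.0, 5.0),
        Restraint("harmonic", ("coord", 2), 0.0, 5.0),
        # linker bead parked out of the way
        Restraint("harmonic", ("point", 1, (0.0, -12.0, 0.0)), 0.0, 5.0),
        # guardian anchored at the mode position
        Restraint("harmonic", ("point", 2, (d, 0.0, 0.0)), 0.0, 5.0),
    ]
    if mode == "in":
        restraints.append(Restraint("upper-flat-bottom", ("distance", 0, 2), 6.0, 5.0))
    elif mode == "out":
        restraints.append(Restraint("lower-flat-bottom", ("distance", 0, 2), 10.0, 5.0))
    else:
        restraints.append(
            Restraint("upper-flat-bottom", ("point", 2, (d, 0.0, 0.0)), 6.0, 5.0)
        )
    return spec, restraints, 0
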