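"""Well-tempered, multiple-walker metadynamics over arbitrary CVs.

Gaussian bias hills are deposited every ``stride`` dynamics steps at the
walkers' current CV values.  In the well-tempered variant the deposited
height shrinks as bias accumulates,

    h = h0 · exp(−V_bias(center) / (kB ΔT)),

where ΔT is the bias temperature and V_bias(center) is evaluated by
direct summation over every previously deposited hill, so each logged
height is exactly reproducible from the log itself.  Multiple walkers
share one hills log: at every deposition time the walkers deposit in
walker-id order, each seeing all hills deposited strictly before it —
a deterministic round-robin stand-in for the asynchronous file sharing
used by production engines.

During dynamics the bias and its gradient are interpolated from a
regular grid (0.002 spacing by default) that is updated as hills are
added; the free-energy surface is reconstructed from the log as

    F = −(T + ΔT)/ΔT · V_bias,

shifted so its minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import SpecError
from .langevin import LangevinIntegrator
from .systems import ToySystemSpec
from .units import KB

__all__ = [
    "WTParams",
    "HillsLog",
    "BiasGrid",
    "FESurface",
    "deposit_hill",
    "bias_energy",
    "run_wt_metadynamics",
    "reconstruct_fes",
    "free_energy_difference",
    "write_hills",
    "read_hills",
]


@dataclass(frozen=True)
class WTParams:
    """Well-tempered metadynamics parameters."""

    height: float = 0.7  # initial hill height h0, kcal/mol
    sigma: float | tuple = 0.1  # hill width per CV (CV units)
    stride: int = 500  # deposition stride in MD steps
    bias_temperature: float = 4200.0  # ΔT, K
    temperature: float = 300.0  # system temperature T, K
    convention: str = "delta"  # "delta": value is ΔT; "total": value is T + ΔT

    def __post_init__(self):
        if self.height <= 0:
            raise SpecError("hill height must be > 0")
        if np.any(np.asarray(self.sigma) <= 0):
            raise SpecError("hill width must be > 0")
        if self.stride < 1:
            raise SpecError("deposition stride must be >= 1")
        if self.convention not in ("delta", "total"):
            raise SpecError("convention must be 'delta' or 'total'")
        if self.delta_t <= 0:
            raise SpecError("bias temperature must give ΔT > 0")

    @property
    def delta_t(self) -> float:
        if self.convention == "delta":
            return self.bias_temperature
        return self.bias_temperature - self.temperature

    @property
    def bias_factor(self) -> float:
        """(T + ΔT)/T, the well-tempered bias factor."""
        return (self.temperature + self.delta_t) / self.temperature

    def sigmas(self, n_cv: int) -> np.ndarray:
        s = np.asarray(self.sigma, dtype=float)
        return np.full(n_cv, float(s)) if s.ndim == 0 else s


@dataclass
class HillsLog:
    """Time-ordered Gaussian bias records shared across walkers."""

    times: list = field(default_factory=list)
    walkers: list = field(default_factory=list)
    centers: list = field(default_factory=list)
    sigmas: list = field(default_factory=list)
    heights: list = field(default_factory=list)

    def __len__(self):
        return len(self.times)

    def append(self, time: float, walker: int, center, sigma, height: float):
        if self.times:
            prior = [t for t, w in zip(self.times, self.walkers) if w == walker]
            if prior and time < prior[-1]:
                raise SpecError("hill times must be non-decreasing per walker")
        if height <= 0:
            raise SpecError("hill heights must be > 0")
        self.times.append(float(time))
        self.walkers.append(int(walker))
        self.centers.append(np.asarray(center, dtype=float))
        self.sigmas.append(np.asarray(sigma, dtype=float))
        self.heights.append(float(height))

    def arrays(self):
        return (
            np.asarray(self.times),
            np.asarray(self.walkers),
            np.asarray(self.centers),
            np.asarray(self.sigmas),
            np.asarray(self.heights),
        )

    def per_walker(self, walker: int) -> "HillsLog":
        log = HillsLog()
        for t, w, c, s, h in zip(self.times, self.walkers, self.centers,
                                 self.sigmas, self.heights):
            if w == walker:
                log.times.append(t)
                log.walkers.append(w)
                log.centers.append(c)
                log.sigmas.append(s)
                log.heights.append(h)
        return log

    @classmethod
    def merge(cls, logs: Sequence["HillsLog"]) -> "HillsLog":
        """Merge per-walker logs by (time, walker id) into a shared log."""
        records = []
        for log in logs:
            records.extend(zip(log.times, log.walkers, log.centers, log.sigmas, log.heights))
        records.sort(key=lambda r: (r[0], r[1]))
        merged = cls()
        for t, w, c, s, h in records:
            merged.times.append(t)
            merged.walkers.append(w)
            merged.centers.append(c)
            merged.sigmas.append(s)
            merged.heights.append(h)
        return merged


def _gaussian_sum(points: np.ndarray, centers, sigmas, heights, gradient: bool = False):
    """Direct summation of Gaussians at query points (..., n_cv)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(heights) == 0:
        v = np.zeros(points.shape[:-1])
        return (v, np.zeros_like(points)) if gradient else v
    centers = np.asarray(centers, dtype=float)  # (H, n_cv)
    sigmas = np.asarray(sigmas, dtype=float)
    heights = np.asarray(heights, dtype=float)
    diff = points[..., None, :] - centers  # (..., H, n_cv)
    expo = np.exp(-0.5 * np.sum((diff / sigmas) ** 2, axis=-1))  # (..., H)
    v = np.sum(heights * expo, axis=-1)
    if not gradient:
        return v
    g = -np.sum(
        (heights * expo)[..., None] * diff / sigmas**2,
        axis=-2,
    )
    return v, g


class BiasGrid:
    """Regular grid storing accumulated bias and its gradient.

    Hills whose centers fall outside the grid are clamped to the edge
    with a logged warning (counted in ``n_clamped``).
    """

    def __init__(self, mins, maxs, spacing: float | Sequence[float] = 0.002):
        self.mins = np.atleast_1d(np.asarray(mins, dtype=float))
        self.maxs = np.atleast_1d(np.asarray(maxs, dtype=float))
        spacing = np.asarray(spacing, dtype=float)
        self.spacing = (
            np.full(self.mins.shape, float(spacing)) if spacing.ndim == 0 else spacing
        )
        if np.any(self.spacing <= 0):
            raise SpecError("grid spacing must be > 0")
        if np.any(self.maxs <= self.mins):
            raise SpecError("grid maxs must exceed mins")
        self.n_cv = len(self.mins)
        self.axes = [
            np.arange(lo, hi + 0.5 * sp, sp)
            for lo, hi, sp in zip(self.mins, self.maxs, self.spacing)
        ]
        shape = tuple(len(ax) for ax in self.axes)
        self.values = np.zeros(shape)
        self.grads = np.zeros(shape + (self.n_cv,))
        self.n_clamped = 0
        self._mesh = np.stack(np.meshgrid(*self.axes, indexing="ij"), axis=-1)

    def add_hill(self, center, sigma, height: float):
        center = np.asarray(center, dtype=float)
        if np.any(center < self.mins) or np.any(center > self.maxs):
            self.n_clamped += 1
            center = np.clip(center, self.mins, self.maxs)
        v, g = _gaussian_sum(self._mesh, [center], [np.asarray(sigma)], [height],
                             gradient=True)
        self.values += v
        self.grads += g

    def interpolate(self, points, gradient: bool = False):
        """Multilinear interpolation of bias (and gradient) at query points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx_f = (np.clip(pts, self.mins, self.maxs) - self.mins) / self.spacing
        lo = np.minimum(idx_f.astype(int), [len(ax) - 2 for ax in self.axes])
        frac = idx_f - lo
        value = np.zeros(pts.shape[:-1])
        grad = np.zeros_like(pts) if gradient else None
        # multilinear: iterate over the 2^n corner offsets
        for corner in range(2**self.n_cv):
            offs = np.array([(corner >> k) & 1 for k in range(self.n_cv)])
            w = np.prod(np.where(offs, frac, 1.0 - frac), axis=-1)
            cidx = tuple((lo + offs)[..., k] for k in range(self.n_cv))
            value += w * self.values[cidx]
            if gradient:
                grad += w[..., None] * self.grads[cidx]
        return (value, grad) if gradient else value


@dataclass
class FESurface:
    """Gridded free-energy surface with min shifted to zero."""

    axes: list
    free_energy: np.ndarray

    def minimum_locations(self, n: int = 2):
        """Grid coordinates of the n deepest local values (simple ranking)."""
        flat = np.argsort(self.free_energy, axis=None)[:n]
        coords = np.unravel_index(flat, self.free_energy.shape)
        return np.stack(
            [self.axes[k][coords[k]] for k in range(len(self.axes))], axis=-1
        )


def deposit_hill(cv_values, hills: HillsLog, grid: Optional[BiasGrid],
                 params: WTParams, time: float, walker: int = 0) -> float:
    """Deposit one well-tempered hill; returns the deposited height.

    The prior bias at the center is evaluated by direct summation over
    the existing log, so logged heights satisfy the well-tempered decay
    law exactly.
    """
    center = np.atleast_1d(np.asarray(cv_values, dtype=float))
    if not np.all(np.isfinite(center)):
        raise SpecError("CV values must be finite")
    sig = params.sigmas(len(center))
    v_prior = float(np.squeeze(_gaussian_sum(center, hills.centers, hills.sigmas,
                                             hills.heights)))
    height = params.height * np.exp(-v_prior / (KB * params.delta_t))
    hills.append(time, walker, center, sig, height)
    if grid is not None:
        grid.add_hill(center, sig, height)
    return height


def bias_energy(cv_values, source, gradient: bool = False):
    """Bias potential (kcal/mol) from a HillsLog (direct sum) or BiasGrid."""
    if isinstance(source, BiasGrid):
        return source.interpolate(cv_values, gradient=gradient)
    return _gaussian_sum(cv_values, source.centers, source.sigmas, source.heights,
                         gradient=gradient)


def run_wt_metadynamics(
    spec: ToySystemSpec,
    cvset,
    params: WTParams,
    n_steps: int,
    n_walkers: int = 10,
    seed: Optional[int] = None,
    x0=None,
    grid: Optional[BiasGrid] = None,
    restraints=(),
    sample_stride: Optional[int] = None,
):
    """Run multi-walker well-tempered metadynamics.

    All walkers advance synchronously under the shared bias; every
    ``params.stride`` steps each walker deposits a hill, in walker-id
    order at the same deposition time.  Returns ``(hills, trajectories)``
    where trajectories record walker positions every ``sample_stride``
    steps (the deposition stride by default).
    """
    if n_steps < params.stride:
        raise SpecError("n_steps must be at least one deposition stride")
    if x0 is None:
        raise SpecError("metadynamics requires explicit initial walker states x0")
    n_cv = len(cvset)
    if grid is None:
        # auto-size from the initial walker CVs ± a generous margin
        z0 = np.atleast_2d(cvset.values(np.atleast_2d(x0)))
        sig = params.sigmas(n_cv)
        lo = z0.min(axis=0) - 30 * sig
        hi = z0.max(axis=0) + 30 * sig
        grid = BiasGrid(lo, hi, 0.002)
    sample_stride = sample_stride or params.stride
    hills = HillsLog()

    def bias_force(x, t):
        z, gz = _cv_values_grads(cvset, x)
        _, gv = grid.interpolate(z, gradient=True)
        return -np.einsum("...c,...cd->...d", gv, gz)

    integ = LangevinIntegrator(spec, restraints=restraints, seed=seed, x0=x0,
                               extra_force=bias_force)
    if integ.x.ndim != 2 or integ.x.shape[0] != n_walkers:
        raise SpecError(f"x0 must provide one state per walker ({n_walkers})")
    traj = []
    for step in range(1, n_steps + 1):
        integ.step()
        if not np.all(np.isfinite(integ.x)):
            raise SpecError(f"walker divergence: non-finite coordinates at step {step}")
        if step % params.stride == 0:
            t = step * spec.timestep
            z = cvset.values(integ.x)
            for w in range(n_walkers):
                deposit_hill(z[w], hills, grid, params, t, walker=w)
        if step % sample_stride == 0:
            traj.append(integ.x.copy())
    return hills, np.asarray(traj)


def _cv_values_grads(cvset, x):
    cvv = cvset.values_and_grads(x)
    return cvv.values, cvv.gradients


def reconstruct_fes(hills: HillsLog, params: WTParams, grid: BiasGrid) -> FESurface:
    """Free-energy surface F = −(T + ΔT)/ΔT · V_bias, shifted to min 0."""
    mesh = grid._mesh
    v = _gaussian_sum(mesh, hills.centers, hills.sigmas, hills.heights)
    scale = (params.temperature + params.delta_t) / params.delta_t
    f = -scale * v
    f -= f.min()
    return FESurface(axes=grid.axes, free_energy=f)


def free_energy_difference(fes: FESurface, split: float, cv_index: int = 0,
                           temperature: float = 300.0) -> float:
    """Basin free-energy difference F(cv > split) − F(cv < split) by
    Boltzmann integration of the surface at the given temperature."""
    ax = fes.axes[cv_index]
    w = np.exp(-fes.free_energy / (KB * temperature))
    mask_hi = ax > split
    axis_moved = np.moveaxis(w, cv_index, 0)
    z_hi = axis_moved[mask_hi].sum()
    z_lo = axis_moved[~mask_hi].sum()
    if z_hi <= 0 or z_lo <= 0:
        raise SpecError("empty basin in free-energy difference")
    return float(-KB * temperature * np.log(z_hi / z_lo))


# ---------------------------------------------------------------------------
# HILLS-convention text I/O


def write_hills(path, hills: HillsLog, params: WTParams) -> None:
    """Write the hills log in the de-facto HILLS column convention."""
    times, walkers, centers, sigmas, heights = hills.arrays()
    n_cv = centers.shape[1] if len(hills) else 0
    cols = ["time"] + [f"cv{k+1}" for k in range(n_cv)] + \
        [f"sigma_cv{k+1}" for k in range(n_cv)] + ["height", "biasf", "walker"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for r in range(len(hills)):
            row = [times[r], *centers[r], *sigmas[r], heights[r],
                   params.bias_factor, walkers[r]]
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_hills(path) -> HillsLog:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["#!", "FIELDS"]:
            raise SpecError(f"{path}: not a HILLS file (missing '#! FIELDS' header)")
        cols = header[2:]
        n_cv = sum(1 for c in cols if c.startswith("cv"))
        hills = HillsLog()
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            vals = [float(v) for v in line.split()]
            rec = dict(zip(cols, vals))
            center = [rec[f"cv{k+1}"] for k in range(n_cv)]
            sigma = [rec[f"sigma_cv{k+1}"] for k in range(n_cv)]
            hills.append(rec["time"], int(rec.get("walker", 0)), center, sigma,
                         rec["height"])
    return hills
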