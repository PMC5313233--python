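"""Zero-temperature string method: minimum energy paths on model surfaces.

A discretized path (string) of images is relaxed toward the minimum
energy path by alternating a fixed number of steepest-descent steps on
every image with reparametrization that redistributes the images at
equal arc-length spacing along the piecewise-linear path.  The image
count follows a doubling schedule (4 → 8 → … → 256 by default): after
each stage one midpoint is inserted in every interval and, when the
``middle_extra`` bookkeeping is enabled, two points are inserted in the
central interval so that the count doubles exactly.  A fixed number of
equally strided images (32 by default, starting at index 7) is then
extracted to seed the finite-temperature string method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConvergenceError, SpecError
from .systems import ToySystemSpec, evaluate_potential

__all__ = [
    "Path",
    "ZTSSchedule",
    "arc_lengths",
    "reparametrize",
    "resample_images",
    "double_images",
    "extract_strided",
    "zts_minimize",
]


@dataclass
class Path:
    """An ordered string of images in configuration (or CV) space."""

    images: np.ndarray  # (n_images, ndof)
    fixed_endpoints: bool = True

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 2 or len(self.images) < 2:
            raise SpecError("a path needs at least 2 images of shape (n, ndof)")

    def __len__(self):
        return len(self.images)

    @property
    def alpha(self) -> np.ndarray:
        """Normalized arc-length parameter per image, in [0, 1], strictly increasing."""
        s = arc_lengths(self.images)
        if s[-1] == 0:
            raise SpecError("zero-length path: all images identical")
        return s / s[-1]


def arc_lengths(images: np.ndarray) -> np.ndarray:
    """Cumulative polyline arc length per image (first entry 0)."""
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _interp_along(images: np.ndarray, t_out: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation along the polyline at normalized arc lengths."""
    s = arc_lengths(images)
    if s[-1] == 0:
        raise SpecError("zero-length path: all images identical")
    t = s / s[-1]
    # collapse duplicate parameter values (coincident neighbors) for interp
    out = np.empty((len(t_out), images.shape[1]))
    for d in range(images.shape[1]):
        out[:, d] = np.interp(t_out, t, images[:, d])
    return out


def reparametrize(path: Path) -> Path:
    """Redistribute images at equal arc-length spacing; endpoints unchanged."""
    if len(path) < 3:
        raise SpecError("reparametrization needs at least 3 images")
    n = len(path)
    new = _interp_along(path.images, np.linspace(0.0, 1.0, n))
    new[0] = path.images[0]
    new[-1] = path.images[-1]
    return replace(path, images=new)


def resample_images(path: Path, n_out: int) -> Path:
    """Resample the path polyline at ``n_out`` equally spaced arc lengths."""
    if n_out < 2:
        raise SpecError("resampling needs n_out >= 2")
    new = _interp_along(path.images, np.linspace(0.0, 1.0, n_out))
    new[0] = path.images[0]
    new[-1] = path.images[-1]
    return replace(path, images=new)


def double_images(path: Path, middle_extra: bool = True) -> Path:
    """Insert one midpoint per interval; with ``middle_extra``, two points
    (at 1/3 and 2/3) in the central interval, so an even count doubles exactly."""
    imgs = path.images
    n = len(imgs)
    mid_gap = (n - 1) // 2 if middle_extra and (n - 1) % 2 == 1 else None
    out = [imgs[0]]
    for g in range(n - 1):
        a, b = imgs[g], imgs[g + 1]
        if g == mid_gap:
            out.append(a + (b - a) / 3.0)
            out.append(a + 2.0 * (b - a) / 3.0)
        else:
            out.append(0.5 * (a + b))
        out.append(b)
    return replace(path, images=np.array(out))


def extract_strided(path: Path, count: int = 32, start: int = 7) -> Path:
    """Extract ``count`` equally strided images starting at ``start``.

    With a 256-image path, the defaults give indices 7, 15, …, 255.
    """
    n = len(path)
    if count < 2 or start < 0 or start >= n:
        raise SpecError("invalid extraction parameters")
    stride, rem = divmod(n - 1 - start, count - 1)
    if stride < 1 or rem != 0:
        raise SpecError(
            f"cannot extract {count} equally strided images from {n} starting at {start}"
        )
    idx = start + stride * np.arange(count)
    return replace(path, images=path.images[idx].copy())


@dataclass(frozen=True)
class ZTSSchedule:
    """Descent/doubling schedule of the zero-temperature string."""

    descent_steps: int = 20
    iterations: int = 100
    start_images: int = 4
    final_images: int = 256
    extract_count: int = 32
    extract_start: int = 7
    middle_extra: bool = True
    descent_step: float = 1e-4  # per-surface steepest-descent step size

    def __post_init__(self):
        if self.descent_steps < 1 or self.iterations < 1:
            raise SpecError("descent steps and iterations must be >= 1")
        n = self.start_images
        if n < 2 or self.final_images < n:
            raise SpecError("image counts must grow from start to final")
        while n < self.final_images:
            n *= 2
        if n != self.final_images:
            raise SpecError("final image count must be start count times a power of two")
        if self.extract_count > self.final_images:
            raise SpecError("extraction count must not exceed the final image count")
        if self.descent_step <= 0:
            raise SpecError("descent step must be > 0")


def zts_minimize(path: Path, spec: ToySystemSpec, schedule: ZTSSchedule) -> Path:
    """Relax a path to the minimum energy path under the doubling schedule.

    Each stage runs ``iterations`` iterations of (``descent_steps``
    steepest-descent steps on every movable image, then
    reparametrization); the image count then doubles until
    ``final_images`` is reached.  Raises :class:`ConvergenceError` if
    energies diverge.
    """
    cur = Path(path.images.copy(), fixed_endpoints=path.fixed_endpoints)
    if len(cur) < schedule.start_images:
        cur = resample_images(cur, schedule.start_images)
    while True:
        cur = _zts_stage(cur, spec, schedule)
        if len(cur) >= schedule.final_images:
            break
        cur = double_images(cur, middle_extra=schedule.middle_extra)
    return cur


def _zts_stage(path: Path, spec: ToySystemSpec, schedule: ZTSSchedule) -> Path:
    imgs = path.images
    lo = 1 if path.fixed_endpoints else 0
    hi = len(imgs) - 1 if path.fixed_endpoints else len(imgs)
    for _ in range(schedule.iterations):
        for _ in range(schedule.descent_steps):
            energy, grad = evaluate_potential(imgs[lo:hi], spec)
            if not np.all(np.isfinite(energy)) or np.max(np.abs(energy)) > 1e10:
                raise ConvergenceError(
                    "zero-temperature string diverged: non-finite or exploding "
                    f"image energy (max |E| = {np.max(np.abs(energy)):.3g})"
                )
            imgs[lo:hi] -= schedule.descent_step * grad
        path = reparametrize(Path(imgs, fixed_endpoints=path.fixed_endpoints))
        imgs = path.images
    return path


def max_image_energy(path: Path, spec: ToySystemSpec) -> float:
    e, _ = evaluate_potential(path.images, spec)
    return float(np.max(e))


def perpendicular_gradient_norms(path: Path, spec: ToySystemSpec) -> np.ndarray:
    """Norm of the potential gradient component perpendicular to the path
    tangent at each interior image — zero everywhere on an exact MEP."""
    imgs = path.images
    _, grad = evaluate_potential(imgs, spec)
    tang = np.gradient(imgs, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-300)
    proj = np.sum(grad * tang, axis=1, keepdims=True) * tang
    perp = grad - proj
    return np.linalg.norm(perp, axis=1)[1:-1]
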