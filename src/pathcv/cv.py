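"""Collective variables with analytic gradients.

Four CV kinds are supported: single Cartesian coordinates, interatomic
distances, center-of-mass distances between two particle groups, and
contact-map distances against a reference structure.

The contact-map CV sums a rational switching function over a fixed list
of particle pairs.  For a pair at separation r with reference separation
d0 and switching radius r0, the switching term is

    s(r) = (1 − x⁶) / (1 − x¹²) = 1 / (1 + x⁶),   x = (r − d0) / r0,

evaluated through the singularity-free right-hand form (the printed
ratio has a removable singularity at x = 1, where s = 1/2).  Two
aggregate variants exist:

* ``literal``: sqrt(Σ s(r_p)) — maximal (=√n) when the conformation
  matches the reference, i.e. a similarity score;
* ``squared-difference``: sqrt(Σ (s(r_p) − 1)²) — a true distance that
  vanishes at the reference.

Contact pairs are chosen by the selection rule: a candidate pair is kept
when its separations in the two endpoint conformations straddle the
switching radius (8 Å by default) and the larger separation is at least
1.5 times the smaller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DimensionalityError, SpecError

__all__ = [
    "ContactMapSpec",
    "CVSpec",
    "CVVector",
    "CVSet",
    "switching_term",
    "switching_term_derivative",
    "contact_map_value",
    "select_contacts",
    "evaluate_cvs",
    "write_contact_map",
    "read_contact_map",
]


def switching_term(r, d0, r0: float = 8.0):
    """Rational switching term s(r) = 1 / (1 + ((r − d0)/r0)⁶), in (0, 1]."""
    if r0 <= 0:
        raise SpecError("switching radius r0 must be > 0")
    x = (np.asarray(r, dtype=float) - d0) / r0
    return 1.0 / (1.0 + x**6)


def switching_term_derivative(r, d0, r0: float = 8.0):
    """ds/dr of the switching term."""
    x = (np.asarray(r, dtype=float) - d0) / r0
    s = 1.0 / (1.0 + x**6)
    return -6.0 * x**5 * s * s / r0


@dataclass(frozen=True)
class ContactMapSpec:
    """Contact pairs with per-pair reference distances for two states.

    ``pairs`` is a sequence of (i, j) particle index pairs; ``d0`` maps a
    reference-state name (``"inactive"``/``"active"`` by convention) to
    the per-pair reference distances in Å.
    """

    pairs: Tuple[Tuple[int, int], ...]
    d0: dict  # state name -> array of reference distances, len == len(pairs)
    r0: float = 8.0
    variant: str = "literal"  # or "squared-difference"

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple((int(i), int(j)) for i, j in self.pairs))
        object.__setattr__(
            self, "d0", {k: np.asarray(v, dtype=float) for k, v in self.d0.items()}
        )
        if self.r0 <= 0:
            raise SpecError("switching radius r0 must be > 0")
        if self.variant not in ("literal", "squared-difference"):
            raise SpecError(f"unknown contact-map variant {self.variant!r}")
        for state, v in self.d0.items():
            if v.shape != (len(self.pairs),):
                raise SpecError(
                    f"reference state {state!r} must provide one d0 per pair "
                    f"({len(self.pairs)} pairs, got {v.shape})"
                )

    @classmethod
    def from_references(cls, references: dict, pairs, r0: float = 8.0,
                        variant: str = "literal") -> "ContactMapSpec":
        """Build a spec by measuring d0 for each pair in each reference."""
        pairs = tuple((int(i), int(j)) for i, j in pairs)
        d0 = {}
        for state, conf in references.items():
            conf = np.asarray(conf, dtype=float)
            d0[state] = np.array([np.linalg.norm(conf[i] - conf[j]) for i, j in pairs])
        return cls(pairs=pairs, d0=d0, r0=r0, variant=variant)


def _pair_distances(conf: np.ndarray, pairs):
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    rij = conf[..., i, :] - conf[..., j, :]
    return i, j, rij, np.sqrt(np.sum(rij * rij, axis=-1))


def contact_map_value(conformation, spec: ContactMapSpec, reference: str,
                      gradient: bool = False, variant: Optional[str] = None):
    """Contact-map CV of a conformation relative to a named reference state.

    ``conformation`` has shape (..., n_particles, 3).  With
    ``gradient=True`` also returns d(value)/d(coordinates) of the same
    shape as the conformation.
    """
    if reference not in spec.d0:
        raise SpecError(
            f"unknown reference state {reference!r}; spec defines {sorted(spec.d0)}"
        )
    variant = variant or spec.variant
    conf = np.asarray(conformation, dtype=float)
    d0 = spec.d0[reference]
    i, j, rij, r = _pair_distances(conf, spec.pairs)
    s = switching_term(r, d0, spec.r0)
    if variant == "literal":
        total = np.sum(s, axis=-1)
        value = np.sqrt(total)
    else:
        diff = s - 1.0
        value = np.sqrt(np.sum(diff * diff, axis=-1))
    if not gradient:
        return value

    dsdr = switching_term_derivative(r, d0, spec.r0)
    if variant == "literal":
        denom = np.maximum(2.0 * value, 1e-300)
        dvds = np.ones_like(s) / denom[..., None]
    else:
        denom = np.maximum(value, 1e-300)
        dvds = (s - 1.0) / denom[..., None]
    coeff = dvds * dsdr  # dvalue/dr per pair
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
    grad = np.zeros_like(conf)
    np.add.at(grad, (..., i, slice(None)), coeff[..., None] * unit)
    np.add.at(grad, (..., j, slice(None)), -coeff[..., None] * unit)
    # at the exact reference the squared-difference value is 0 and the
    # derivative direction is undefined; report a zero (sub)gradient
    if variant == "squared-difference":
        grad = np.where(value[..., None, None] > 0, grad, 0.0)
    return value, grad


def select_contacts(conf_a, conf_b, candidates: Optional[Sequence] = None,
                    r0: float = 8.0, ratio: float = 1.5,
                    exclude_neighbors: int = 2):
    """Pairs whose separations straddle ``r0`` between two conformations.

    A pair qualifies when one conformation places it closer than ``r0``
    and the other farther, and the larger separation is at least
    ``ratio`` times the smaller.  When ``candidates`` is None all pairs
    (i, j), j > i are considered except near-neighbors along the chain
    (|i − j| <= ``exclude_neighbors``).  The result is sorted and
    symmetric in the two conformations.
    """
    a = np.asarray(conf_a, dtype=float)
    b = np.asarray(conf_b, dtype=float)
    if a.shape != b.shape:
        raise SpecError("conformations must share the same particle set")
    n = a.shape[0]
    if candidates is None:
        candidates = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if j - i > exclude_neighbors
        ]
    selected = []
    for i, j in candidates:
        da = float(np.linalg.norm(a[i] - a[j]))
        db = float(np.linalg.norm(b[i] - b[j]))
        lo, hi = sorted((da, db))
        if lo < r0 < hi and hi >= ratio * lo:
            selected.append((int(i), int(j)))
    return sorted(selected)


# ---------------------------------------------------------------------------
# generic CV specs


@dataclass(frozen=True)
class CVSpec:
    """One collective variable.

    kinds: ``cartesian-coordinate`` (indices = (dof,)),
    ``interatomic-distance`` (indices = (i, j)),
    ``com-distance`` (groups = (group_a, group_b)),
    ``contact-map-distance`` (contact spec + reference state name).
    """

    kind: str
    indices: Tuple[int, ...] = ()
    groups: Tuple[Tuple[int, ...], ...] = ()
    contact: Optional[ContactMapSpec] = None
    reference: Optional[str] = None

    def __post_init__(self):
        kinds = ("cartesian-coordinate", "interatomic-distance", "com-distance",
                 "contact-map-distance")
        if self.kind not in kinds:
            raise SpecError(f"unknown CV kind {self.kind!r}; expected one of {kinds}")
        if self.kind == "contact-map-distance":
            if self.contact is None or self.reference is None:
                raise SpecError("contact-map CV needs a ContactMapSpec and a reference state")


@dataclass
class CVVector:
    """Ordered CV values with optional per-CV coordinate gradients."""

    values: np.ndarray  # (..., n_cv)
    gradients: Optional[np.ndarray] = None  # (..., n_cv, ndof)


class CVSet:
    """A fixed, ordered list of CVs evaluated on flat coordinate arrays.

    ``ndof`` is the flat dimensionality of the target system; 3D kinds
    (distances, COM distances, contact maps) require ``ndof`` divisible
    by 3 and interpret coordinates as (n_particles, 3).
    """

    def __init__(self, specs: Sequence[CVSpec], ndof: int):
        self.specs = tuple(specs)
        self.ndof = int(ndof)
        n_part = self.ndof // 3
        for spec in self.specs:
            if spec.kind == "cartesian-coordinate":
                if not (0 <= spec.indices[0] < self.ndof):
                    raise SpecError(f"cartesian CV index {spec.indices[0]} out of range")
            elif spec.kind == "interatomic-distance":
                self._check_particles(spec.indices, n_part)
            elif spec.kind == "com-distance":
                for g in spec.groups:
                    self._check_particles(g, n_part)
            else:
                for i, j in spec.contact.pairs:
                    self._check_particles((i, j), n_part)

    @staticmethod
    def _check_particles(indices, n_part):
        for i in indices:
            if not (0 <= int(i) < n_part):
                raise SpecError(f"particle index {i} out of range (n={n_part})")

    def __len__(self):
        return len(self.specs)

    def values(self, x) -> np.ndarray:
        return self._evaluate(x, gradient=False)

    def values_and_grads(self, x):
        return self._evaluate(x, gradient=True)

    def _evaluate(self, x, gradient: bool):
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.ndof:
            raise DimensionalityError(
                f"coordinates have {x.shape[-1]} dof, CV set expects {self.ndof}"
            )
        batch = x.shape[:-1]
        vals = np.empty(batch + (len(self.specs),))
        grads = np.zeros(batch + (len(self.specs), self.ndof)) if gradient else None
        pos = x.reshape(batch + (self.ndof // 3, 3)) if self.ndof % 3 == 0 else None
        for c, spec in enumerate(self.specs):
            if spec.kind == "cartesian-coordinate":
                dof = int(spec.indices[0])
                vals[..., c] = x[..., dof]
                if gradient:
                    grads[..., c, dof] = 1.0
                continue
            if pos is None:
                raise DimensionalityError(
                    f"CV kind {spec.kind!r} needs 3D particles; ndof={self.ndof}"
                )
            if spec.kind == "interatomic-distance":
                i, j = (int(v) for v in spec.indices)
                rij = pos[..., i, :] - pos[..., j, :]
                r = np.sqrt(np.sum(rij * rij, axis=-1))
                vals[..., c] = r
                if gradient:
                    with np.errstate(invalid="ignore", divide="ignore"):
                        unit = np.where(r[..., None] > 0,
                                        rij / np.maximum(r, 1e-300)[..., None], 0.0)
                    g = np.zeros(batch + (self.ndof // 3, 3))
                    g[..., i, :] += unit
                    g[..., j, :] -= unit
                    grads[..., c, :] = g.reshape(batch + (self.ndof,))
            elif spec.kind == "com-distance":
                ga = np.asarray(spec.groups[0], dtype=int)
                gb = np.asarray(spec.groups[1], dtype=int)
                ca = np.mean(pos[..., ga, :], axis=-2)
                cb = np.mean(pos[..., gb, :], axis=-2)
                rij = ca - cb
                r = np.sqrt(np.sum(rij * rij, axis=-1))
                vals[..., c] = r
                if gradient:
                    with np.errstate(invalid="ignore", divide="ignore"):
                        unit = np.where(r[..., None] > 0,
                                        rij / np.maximum(r, 1e-300)[..., None], 0.0)
                    g = np.zeros(batch + (self.ndof // 3, 3))
                    for idx in ga:
                        g[..., int(idx), :] += unit / len(ga)
                    for idx in gb:
                        g[..., int(idx), :] -= unit / len(gb)
                    grads[..., c, :] = g.reshape(batch + (self.ndof,))
            else:  # contact-map-distance
                if gradient:
                    v, gconf = contact_map_value(pos, spec.contact, spec.reference,
                                                 gradient=True)
                    vals[..., c] = v
                    grads[..., c, :] = gconf.reshape(batch + (self.ndof,))
                else:
                    vals[..., c] = contact_map_value(pos, spec.contact, spec.reference)
        return CVVector(vals, grads) if gradient else vals


def evaluate_cvs(conformation, specs: Sequence[CVSpec], ndof: Optional[int] = None,
                 gradient: bool = False):
    """Evaluate an ordered list of CVs on a flat coordinate array."""
    x = np.asarray(conformation, dtype=float)
    cvset = CVSet(specs, x.shape[-1] if ndof is None else ndof)
    return cvset.values_and_grads(x) if gradient else CVVector(cvset.values(x))


# ---------------------------------------------------------------------------
# serialization


def write_contact_map(path, spec: ContactMapSpec) -> None:
    """Serialize a contact map as TSV: pair indices, per-state d0, r0."""
    states = sorted(spec.d0)
    data = {"i": [p[0] for p in spec.pairs], "j": [p[1] for p in spec.pairs]}
    for state in states:
        data[f"d0_{state}"] = spec.d0[state]
    df = pd.DataFrame(data)
    df["r0"] = spec.r0
    df["variant"] = spec.variant
    df.to_csv(path, sep="\t", index=False)


def read_contact_map(path) -> ContactMapSpec:
    df = pd.read_csv(path, sep="\t")
    pairs = list(zip(df["i"], df["j"]))
    d0 = {
        col[len("d0_"):]: df[col].to_numpy()
        for col in df.columns
        if col.startswith("d0_")
    }
    return ContactMapSpec(pairs=pairs, d0=d0, r0=float(df["r0"].iloc[0]),
                          variant=str(df["variant"].iloc[0]))
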