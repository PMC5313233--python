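"""Conformational-ensemble post-processing.

Provides pairwise RMSD (with optional least-squares superposition),
diameter-bounded agglomerative clustering, cluster networks, geometric
state classification, 2D CV-space density maps, nearest-cluster
distance statistics, and per-particle RMSF profiles.

Clustering uses complete-linkage agglomeration cut at a diameter
threshold (3.0 Å by default), which guarantees that no two members of a
cluster are farther apart than the threshold; the guarantee is
certified post hoc on every run by a direct pairwise check.  Cluster
networks connect clusters whose distance — closest member pair by
default, or representative-to-representative — is within a link
threshold (3.8 Å by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import SpecError

__all__ = [
    "ConformationPool",
    "ClusterSet",
    "GeometricCriterion",
    "LabelRule",
    "GeometricClassifierSpec",
    "DensityMap",
    "superpose",
    "pairwise_rmsd",
    "cluster_conformations",
    "build_network",
    "classify_cluster",
    "mean_nearest_neighbor_distance",
    "density_contours",
    "compute_rmsf",
]


@dataclass
class ConformationPool:
    """Frames of equal particle count, with optional CV values and labels."""

    frames: np.ndarray  # (n_frames, n_particles, 3)
    frame_ids: Optional[np.ndarray] = None
    source_ids: Optional[np.ndarray] = None
    cv_values: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            raise SpecError("frames must have shape (n_frames, n_particles, 3)")
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.frames))

    def __len__(self):
        return len(self.frames)

    def select(self, selection) -> np.ndarray:
        if selection is None:
            return self.frames
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise SpecError("empty atom selection")
        return self.frames[:, selection, :]


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition (Kabsch) of one frame onto another."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    c = mc.T @ rc
    u, s, vt = np.linalg.svd(c)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return mc @ (u @ vt) + reference.mean(axis=0)


def pairwise_rmsd(pool, selection=None, superpose_frames: bool = True) -> np.ndarray:
    """Symmetric all-pairs RMSD matrix in Å.

    With superposition, each pair is optimally aligned (translation +
    rotation, Kabsch) before the RMSD √(Σd²/n) is taken; without it, raw
    coordinates are compared.  Batched over pairs via stacked SVDs.
    """
    coords = pool.select(selection) if isinstance(pool, ConformationPool) \
        else np.asarray(pool, dtype=float)
    n, m, _ = coords.shape
    if n < 2:
        raise SpecError("pairwise RMSD needs at least 2 frames")
    if not superpose_frames:
        diff = coords[:, None] - coords[None, :]
        return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))
    centered = coords - coords.mean(axis=1, keepdims=True)
    sq = np.sum(centered**2, axis=(1, 2))
    ii, jj = np.triu_indices(n, k=1)
    c = np.einsum("pmi,pmj->pij", centered[ii], centered[jj])
    u, s, vt = np.linalg.svd(c)
    det = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", u, vt)))
    trace = s[:, 0] + s[:, 1] + det * s[:, 2]
    msd = np.maximum((sq[ii] + sq[jj] - 2.0 * trace) / m, 0.0)
    out = np.zeros((n, n))
    out[ii, jj] = out[jj, ii] = np.sqrt(msd)
    return out


@dataclass
class ClusterSet:
    """A diameter-bounded partition of a conformation pool."""

    labels: np.ndarray  # (n_frames,) cluster id per frame, 0-based
    representatives: np.ndarray  # medoid frame index per cluster
    threshold: float
    rmsd: np.ndarray  # cached pairwise RMSD matrix
    node_labels: dict = field(default_factory=dict)  # cluster id -> state label

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def diameter(self, cluster: int) -> float:
        m = self.members(cluster)
        return float(self.rmsd[np.ix_(m, m)].max()) if len(m) > 1 else 0.0

    def certify(self) -> None:
        """Direct post-hoc check of the diameter invariant on every cluster."""
        for c in range(self.n_clusters):
            diam = self.diameter(c)
            if diam > self.threshold + 1e-9:
                raise SpecError(
                    f"cluster {c} violates the diameter bound: {diam:.3f} Å "
                    f"> {self.threshold} Å"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.labels)),
                "cluster": self.labels,
                "label": [self.node_labels.get(c, "") for c in self.labels],
            }
        )


def cluster_conformations(pool, threshold: float = 3.0, selection=None,
                          superpose_frames: bool = True,
                          rmsd: Optional[np.ndarray] = None) -> ClusterSet:
    """Complete-linkage agglomerative clustering with a diameter bound.

    Merges always take the pair of clusters with the smallest
    complete-linkage distance; the hierarchy is cut so that no merge
    above the threshold is applied, which bounds every cluster's
    diameter by the threshold.  Clusters are renumbered by their
    smallest member frame id; representatives are medoids (ties to the
    lowest frame id).  The diameter invariant is certified on every call.
    """
    frames = pool.frames if isinstance(pool, ConformationPool) else np.asarray(pool)
    if len(frames) == 0:
        raise SpecError("cannot cluster an empty pool")
    if rmsd is None:
        rmsd = pairwise_rmsd(pool, selection=selection,
                             superpose_frames=superpose_frames)
    n = len(rmsd)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(rmsd, checks=False), method="complete")
        labels = fcluster(z, t=threshold, criterion="distance") - 1
    # renumber by smallest member frame id for permutation invariance
    order = {}
    for frame, lab in enumerate(labels):
        order.setdefault(lab, frame)
    remap = {
        old: new
        for new, old in enumerate(sorted(order, key=lambda lab: order[lab]))
    }
    labels = np.array([remap[lab] for lab in labels])
    reps = []
    for c in range(labels.max() + 1):
        m = np.flatnonzero(labels == c)
        sums = rmsd[np.ix_(m, m)].sum(axis=1)
        reps.append(int(m[np.argmin(sums)]))  # argmin ties -> first (lowest id)
    cs = ClusterSet(labels=labels, representatives=np.array(reps),
                    threshold=threshold, rmsd=rmsd)
    cs.certify()
    return cs


def cluster_distance(clusters: ClusterSet, a: int, b: int,
                     mode: str = "single") -> float:
    """Distance between two clusters: closest member pair (``single``) or
    representative-to-representative (``representative``)."""
    if mode == "single":
        ma, mb = clusters.members(a), clusters.members(b)
        return float(clusters.rmsd[np.ix_(ma, mb)].min())
    if mode == "representative":
        ra, rb = clusters.representatives[a], clusters.representatives[b]
        return float(clusters.rmsd[ra, rb])
    raise SpecError(f"unknown linkage mode {mode!r}")


def build_network(clusters: ClusterSet, link_threshold: float = 3.8,
                  mode: str = "single") -> nx.Graph:
    """Cluster network: an edge joins clusters within the link threshold."""
    g = nx.Graph()
    for c in range(clusters.n_clusters):
        g.add_node(c, representative=int(clusters.representatives[c]),
                   members=clusters.members(c).tolist(),
                   label=clusters.node_labels.get(c, ""))
    for a in range(clusters.n_clusters):
        for b in range(a + 1, clusters.n_clusters):
            d = cluster_distance(clusters, a, b, mode=mode)
            if d <= link_threshold:
                g.add_edge(a, b, distance=d)
    return g


# ---------------------------------------------------------------------------
# geometric classification


@dataclass(frozen=True)
class GeometricCriterion:
    """One distance criterion with strict-inequality semantics.

    ``distance``: ``("atom-atom", i, j)`` or ``("com-atom", group, j)``;
    ``op``: ``"lt"`` or ``"gt"``; ``aggregate``: ``("fraction", p)``
    (true when strictly more than fraction p of frames satisfy the
    inequality) or ``("mean",)`` (true when the mean distance satisfies
    it).
    """

    distance: Tuple
    threshold: float
    op: str = "lt"
    aggregate: Tuple = ("fraction", 0.5)

    def __post_init__(self):
        if self.threshold <= 0:
            raise SpecError("criterion thresholds must be > 0")
        if self.op not in ("lt", "gt"):
            raise SpecError("criterion op must be 'lt' or 'gt'")
        if self.aggregate[0] == "fraction":
            p = self.aggregate[1]
            if not (0.0 < p < 1.0):
                raise SpecError("fraction thresholds must lie in (0, 1)")
        elif self.aggregate[0] != "mean":
            raise SpecError(f"unknown aggregation {self.aggregate!r}")


@dataclass(frozen=True)
class LabelRule:
    label: str
    criteria: Tuple[GeometricCriterion, ...]


@dataclass(frozen=True)
class GeometricClassifierSpec:
    rules: Tuple[LabelRule, ...]
    default: str = "other"


def _criterion_distances(frames: np.ndarray, crit: GeometricCriterion) -> np.ndarray:
    kind = crit.distance[0]
    m = frames.shape[1]
    if kind == "atom-atom":
        i, j = int(crit.distance[1]), int(crit.distance[2])
        for idx in (i, j):
            if not (0 <= idx < m):
                raise SpecError(f"criterion names missing atom {idx}")
        return np.linalg.norm(frames[:, i] - frames[:, j], axis=-1)
    if kind == "com-atom":
        group = [int(v) for v in crit.distance[1]]
        j = int(crit.distance[2])
        for idx in (*group, j):
            if not (0 <= idx < m):
                raise SpecError(f"criterion names missing atom {idx}")
        com = frames[:, group].mean(axis=1)
        return np.linalg.norm(com - frames[:, j], axis=-1)
    raise SpecError(f"unknown distance definition {kind!r}")


def criterion_satisfied(frames: np.ndarray, crit: GeometricCriterion) -> bool:
    d = _criterion_distances(frames, crit)
    hit = d < crit.threshold if crit.op == "lt" else d > crit.threshold
    if crit.aggregate[0] == "fraction":
        return bool(np.mean(hit) > crit.aggregate[1])  # strictly "more than"
    mean = float(d.mean())
    return mean < crit.threshold if crit.op == "lt" else mean > crit.threshold


def classify_cluster(frames, spec: GeometricClassifierSpec) -> str:
    """Label a cluster's frames by the first rule whose criteria all hold."""
    frames = np.asarray(frames, dtype=float)
    for rule in spec.rules:
        if all(criterion_satisfied(frames, c) for c in rule.criteria):
            return rule.label
    return spec.default


def mean_nearest_neighbor_distance(clusters: ClusterSet, query: Sequence[int],
                                   reference: Sequence[int],
                                   mode: str = "representative") -> float:
    """Average over query clusters of the distance to the nearest
    reference cluster (a query also present in the reference set is
    excluded from its own comparisons)."""
    query = list(query)
    reference = list(reference)
    if not query or not reference:
        raise SpecError("query and reference sets must be non-empty")
    dists = []
    for q in query:
        refs = [r for r in reference if r != q]
        if not refs:
            raise SpecError(f"no reference clusters left for query {q} after self-exclusion")
        dists.append(min(cluster_distance(clusters, q, r, mode=mode) for r in refs))
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# density maps and RMSF


@dataclass
class DensityMap:
    """Normalized 2D histogram over two CVs with fixed contour interval."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # sums to 1
    contour_interval: float = 0.005

    @property
    def contour_levels(self) -> np.ndarray:
        top = self.density.max()
        if top < self.contour_interval:
            return np.array([])
        return np.arange(self.contour_interval, top + 1e-12, self.contour_interval)


def density_contours(cv_pairs, bins: int = 50, ranges=None,
                     contour_interval: float = 0.005) -> DensityMap:
    """Normalized 2D density of per-frame CV pairs."""
    pts = np.asarray(cv_pairs, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise SpecError("density needs at least one frame with two CV values")
    if ranges is not None:
        (x0, x1), (y0, y1) = ranges
        if not (x1 > x0 and y1 > y0):
            raise SpecError("degenerate density grid")
    h, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=ranges)
    if xe[-1] <= xe[0] or ye[-1] <= ye[0]:
        raise SpecError("degenerate density grid")
    return DensityMap(x_edges=xe, y_edges=ye, density=h / h.sum(),
                      contour_interval=contour_interval)


def substrate_positioning_rmsf(modes=("in", "intermediate", "out"), seed: int = 0,
                               n_steps: int = 120000, sample_stride: int = 10) -> dict:
    """Substrate RMSF under the three guardian-positioning protocols.

    Runs the restrained Langevin production simulation for each mode of
    :func:`pathcv.systems.substrate_positioning_system` and returns the
    substrate bead's RMSF per mode.  With a stabilizing guardian in the
    active site the substrate fluctuates least; with the guardian
    excluded it fluctuates most; the secondary-site protocol falls in
    between.
    """
    from .langevin import run_langevin
    from .systems import substrate_positioning_system

    anchors = {"in": 4.5, "intermediate": 8.0, "out": 25.0}
    out = {}
    for mode in modes:
        spec, restraints, substrate = substrate_positioning_system(mode, seed=seed)
        x0 = np.zeros(spec.ndof)
        x0[3 * 2] = anchors[mode]  # guardian starts at its anchor
        x0[3 * 1 + 1] = -12.0  # linker parked
        res = run_langevin(spec, restraints, n_steps=n_steps, seed=seed, x0=x0,
                           sample_stride=sample_stride)
        traj = res.positions.reshape(len(res.positions), -1, 3)
        out[mode] = float(compute_rmsf(traj, superpose_frames=False)[substrate])
    return out


def compute_rmsf(trajectory, selection=None, superpose_frames: bool = True) -> np.ndarray:
    """Per-particle root-mean-square fluctuation about the mean structure.

    With superposition each frame is rigid-body aligned to the running
    mean structure (two passes: align to the first frame, recompute the
    mean, re-align) before fluctuations are measured.
    """
    frames = trajectory.select(selection) if isinstance(trajectory, ConformationPool) \
        else np.asarray(trajectory, dtype=float)
    if selection is not None and not isinstance(trajectory, ConformationPool):
        frames = frames[:, np.asarray(selection, dtype=int), :]
    if frames.ndim != 3 or len(frames) < 2:
        raise SpecError("RMSF needs at least 2 frames")
    if superpose_frames:
        ref = frames[0]
        aligned = np.array([superpose(f, ref) for f in frames])
        mean = aligned.mean(axis=0)
        aligned = np.array([superpose(f, mean) for f in aligned])
    else:
        aligned = frames
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=-1), axis=0))
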