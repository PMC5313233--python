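"""Canonical benchmark computations with built-in analytic oracles.

Each function runs one of the package's methods on a model system under
fixed study conditions and returns both the method's result and the
corresponding independent reference (Newton-located saddle points,
Gaussian/Boltzmann closed forms, brute-force enumerations), so that the
test suite and the reproduction script measure the same quantities
without duplicating protocol code.  All functions are deterministic for
a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .cv import ContactMapSpec, CVSet, CVSpec, contact_map_value, select_contacts
from .ensemble import (
    build_network,
    cluster_conformations,
    compute_rmsf,
    substrate_positioning_rmsf,
)
from .langevin import run_langevin
from .metad import (
    BiasGrid,
    HillsLog,
    WTParams,
    bias_energy,
    free_energy_difference,
    reconstruct_fes,
    run_wt_metadynamics,
)
from .restraints import Restraint
from .stringmethod import StringState, estimate_mean_force, integrate_pmf, run_string_method
from .systems import (
    ToySystemSpec,
    double_well_free_energy_difference,
    generate_two_state_loop,
    make_two_state_loop_spec,
    mueller_brown_minima,
    mueller_brown_saddles,
)
from .units import KB
from .zts import Path, ZTSSchedule, extract_strided, zts_minimize

__all__ = [
    "min_distance_to_polyline",
    "string_method_benchmark",
    "mean_force_benchmark",
    "pmf_integration_check",
    "metadynamics_benchmark",
    "contact_map_checks",
    "clustering_benchmark",
    "rmsf_benchmark",
    "driving_benchmark",
]


def min_distance_to_polyline(images: np.ndarray, point: np.ndarray) -> float:
    """Distance from a point to the piecewise-linear path through images."""
    a = images[:-1]
    b = images[1:]
    ab = b - a
    t = np.clip(np.einsum("id,id->i", point - a, ab) / np.einsum("id,id->i", ab, ab),
                0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - point, axis=1)))


def string_method_benchmark(seed: int = 0, n_images: int = 32,
                            max_updates: int = 120) -> dict:
    """Full string-method pipeline on the Müller–Brown surface.

    The zero-temperature string relaxes a 4→256-image path between the
    two outer minima; 32 strided images seed the finite-temperature
    string in Cartesian CVs, which runs restrained Langevin sampling
    with Eq.-style mean-force evolution until the RMSD trace plateaus,
    then integrates the PMF.  Saddle points located independently by
    Newton iteration serve as the reference.
    """
    geometry = ToySystemSpec("mueller-brown")
    minima = mueller_brown_minima(geometry)
    saddles = mueller_brown_saddles(geometry)
    mep = zts_minimize(Path(np.array([minima[0], minima[1]])), geometry, ZTSSchedule())
    init = extract_strided(mep, count=n_images, start=7)

    sampling = ToySystemSpec("mueller-brown", {"scale": 0.1}, temperature=150.0,
                             friction=20.0, timestep=0.001)
    cvset = CVSet([CVSpec("cartesian-coordinate", (0,)),
                   CVSpec("cartesian-coordinate", (1,))], 2)
    state = StringState(targets=init.images.copy(), force_constant=400.0,
                        stride=60, dt=0.005, fixed_endpoints=True)
    result = run_string_method(sampling, cvset, Path(init.images.copy(), False),
                               state, seed=seed, max_updates=max_updates,
                               conv_window=40, conv_tolerance=0.02, pmf_steps=2000,
                               average_window=30)
    targets = result.state.targets
    dists = {
        "zts": [min_distance_to_polyline(mep.images, s) for s in saddles],
        "string": [min_distance_to_polyline(targets, s) for s in saddles],
    }
    nearest_to_high = int(np.argmin(np.linalg.norm(targets - saddles[0], axis=1)))
    return {
        "saddles": saddles,
        "mep": mep,
        "result": result,
        "saddle_distances": dists,
        "pmf_argmax": result.pmf.argmax,
        "image_nearest_high_saddle": nearest_to_high,
        "n_images": n_images,
    }


def mean_force_benchmark(seed: int = 0, n_samples: int = 10_000) -> dict:
    """Restrained sampling in an analytic harmonic well U = ½a(z−z0)².

    The mean-force estimator k⟨z*−z⟩ applied to the restrained Langevin
    trajectory is compared with the Gaussian closed form
    k·a·(z*−z0)/(a+k).
    """
    a, k, z0, zstar = 3.0, 2.0, -1.0, 1.5
    spec = ToySystemSpec("harmonic", {"stiffness": a, "center": [z0]},
                         temperature=300.0, friction=10.0, timestep=0.005)
    restraint = Restraint("harmonic", ("coord", 0), zstar, k)
    # sample every 10 steps: ~10 position-relaxation times apart, so the
    # block-averaged standard error is trustworthy
    res = run_langevin(spec, [restraint], n_steps=10 * n_samples, seed=seed,
                       x0=np.array([z0]), sample_stride=10)
    est = estimate_mean_force(res.positions, np.array([zstar]), k, n_blocks=10)
    closed = k * a * (zstar - z0) / (a + k)
    return {
        "estimate": float(est.values[0]),
        "closed_form": closed,
        "stderr": float(est.stderr[0]),
        "n_samples": int(est.n_samples),
    }


def pmf_integration_check(length: float = 7.0, g: float = 1.3,
                          n_images: int = 16) -> dict:
    """Constant tangential mean force on a straight string: F(1) = g·L
    exactly (the trapezoid rule is exact on constants)."""
    direction = np.array([3.0, 4.0]) / 5.0
    targets = np.linspace(0.0, length, n_images)[:, None] * direction
    forces = np.tile(g * direction, (n_images, 1))
    pmf = integrate_pmf(targets, forces)
    return {
        "f_end": float(pmf.free_energy[-1]),
        "expected": g * length,
        "error": abs(float(pmf.free_energy[-1]) - g * length),
        "n_images": n_images,
    }


def metadynamics_benchmark(seed: int = 0, n_steps: int = 100_000,
                           n_walkers: int = 10) -> dict:
    """Well-tempered multi-walker run on a tilted 1D double well.

    Returns the reconstructed inter-basin ΔF against the analytic
    Boltzmann integral, the largest deviation of any logged hill height
    from the well-tempered replay oracle, and whether merging the
    per-walker logs reproduces the shared log.
    """
    spec = ToySystemSpec("double-well-1d",
                         {"barrier": 2.5, "half_width": 1.0, "tilt": 1.2},
                         temperature=300.0, friction=2.0, timestep=0.002)
    cvset = CVSet([CVSpec("cartesian-coordinate", (0,))], 1)
    params = WTParams()
    grid = BiasGrid([-2.2], [2.2], 0.002)
    x0 = np.array([[-1.0] if w % 2 == 0 else [1.0] for w in range(n_walkers)])
    hills, _ = run_wt_metadynamics(spec, cvset, params, n_steps=n_steps,
                                   n_walkers=n_walkers, seed=seed, x0=x0, grid=grid)
    fes = reconstruct_fes(hills, params, grid)
    df = free_energy_difference(fes, 0.0, temperature=spec.temperature)
    df_true = double_well_free_energy_difference(spec, 0.0)

    replay = HillsLog()
    max_dev = 0.0
    for t, w, c, s, h in zip(hills.times, hills.walkers, hills.centers,
                             hills.sigmas, hills.heights):
        v = float(np.squeeze(bias_energy(c, replay))) if len(replay) else 0.0
        expected = params.height * np.exp(-v / (KB * params.delta_t))
        max_dev = max(max_dev, abs(h - expected))
        replay.append(t, w, c, s, h)

    merged = HillsLog.merge([hills.per_walker(w) for w in range(n_walkers)])
    union_ok = (merged.times == hills.times and merged.walkers == hills.walkers
                and merged.heights == hills.heights)
    return {
        "delta_f": float(df),
        "delta_f_analytic": float(df_true),
        "delta_f_error": abs(float(df) - float(df_true)),
        "replay_max_deviation": max_dev,
        "union_exact": bool(union_ok),
        "n_hills": len(hills),
    }


def contact_map_checks(seed: int = 0, n_frames: int = 200) -> dict:
    """Contact-map CV identities plus selection-rule recovery on the
    synthetic two-state loop."""
    from .cv import switching_term

    loop = make_two_state_loop_spec(n_beads=20, seed=seed)
    refs, frames, labels = generate_two_state_loop(loop, n_frames=n_frames)
    recovered = select_contacts(refs[0], refs[1])
    planted = sorted(loop.planted_pairs)
    cmap = ContactMapSpec.from_references(
        {"inactive": refs[0], "active": refs[1]}, recovered)
    literal = float(contact_map_value(refs[0], cmap, "inactive"))
    sqdiff = float(contact_map_value(refs[0], cmap, "inactive",
                                     variant="squared-difference"))
    inter = len(set(recovered) & set(planted))
    union = len(set(recovered) | set(planted))
    return {
        "n_pairs": len(recovered),
        "literal_at_reference": literal,
        "sqrt_n": float(np.sqrt(len(recovered))),
        "sqdiff_at_reference": sqdiff,
        "switching_at_x1": float(switching_term(8.0, 0.0, 8.0)),
        "selection_jaccard": inter / union if union else 1.0,
        "frames": frames,
        "labels": labels,
        "references": refs,
    }


def clustering_benchmark(seed: int = 0, n_frames: int = 150) -> dict:
    """Diameter-bounded clustering of the two-state loop ensemble plus an
    exhaustive member-pair check of the 3.8 Å network adjacency."""
    loop = make_two_state_loop_spec(n_beads=20, seed=seed)
    _, frames, labels = generate_two_state_loop(loop, n_frames=n_frames)
    clusters = cluster_conformations(frames, threshold=3.0)
    # partition accuracy against the planted basin labels
    correct = 0
    for c in range(clusters.n_clusters):
        members = clusters.members(c)
        majority = np.bincount(labels[members]).argmax()
        correct += int(np.sum(labels[members] == majority))
    graph = build_network(clusters, link_threshold=3.8, mode="single")
    mismatches = 0
    for a in range(clusters.n_clusters):
        for b in range(a + 1, clusters.n_clusters):
            ma, mb = clusters.members(a), clusters.members(b)
            d = float(clusters.rmsd[np.ix_(ma, mb)].min())
            if graph.has_edge(a, b) != (d <= 3.8):
                mismatches += 1
    max_diameter = max(clusters.diameter(c) for c in range(clusters.n_clusters))
    return {
        "n_clusters": clusters.n_clusters,
        "partition_accuracy": correct / n_frames,
        "max_diameter": max_diameter,
        "network_mismatches": mismatches,
        "n_frames": n_frames,
    }


def rmsf_benchmark(seed: int = 0, n_steps: int = 120_000) -> dict:
    """Equipartition check of the RMSF estimator plus the guardian-bead
    stabilization ordering (in < intermediate < out)."""
    k, temp = 1.0, 300.0
    spec = ToySystemSpec("bead-chain",
                         {"n_beads": 3, "bond_stiffness": 1e-6, "bond_length": 1.0},
                         temperature=temp, friction=3.0, timestep=0.004)
    restraints = [Restraint("harmonic", ("point", i, (4.0 * i, 0.0, 0.0)), 0.0, k)
                  for i in range(3)]
    x0 = np.zeros(9)
    x0[[0, 3, 6]] = [0.0, 4.0, 8.0]
    res = run_langevin(spec, restraints, n_steps=n_steps, seed=seed, x0=x0,
                       sample_stride=10)
    traj = res.positions.reshape(-1, 3, 3)[500:]
    rmsf = compute_rmsf(traj, superpose_frames=False)
    expected = float(np.sqrt(3 * KB * temp / k))
    modes = substrate_positioning_rmsf(seed=seed, n_steps=n_steps)
    return {
        "harmonic_rmsf": float(rmsf.mean()),
        "harmonic_expected": expected,
        "harmonic_ratio": float(rmsf.mean()) / expected,
        "modes": modes,
        "ordering_ok": modes["in"] < modes["intermediate"] < modes["out"],
        "n_steps": n_steps,
    }


def driving_benchmark(n_targets: int = 24) -> dict:
    """Double-well bead-chain driving: product-basin arrival, monotone RC,
    and forward-then-backward energy return."""
    from scipy.optimize import minimize

    from .driving import DrivingSchedule, ReactionCoordinateSpec, drive_reaction, rc_value
    from .systems import evaluate_potential

    spec = ToySystemSpec(
        "bead-chain",
        {"n_beads": 4, "bond_length": 3.8, "bond_stiffness": 20.0,
         "dw_bond": {"pair": (0, 3), "r1": 4.0, "r2": 10.0, "barrier": 3.0}},
    )
    rc = ReactionCoordinateSpec((0, 3), (0, 1), (2, 3))
    x0 = np.zeros((4, 3))
    x0[:, 0] = np.arange(4) * 3.8
    x0[3] = x0[0] + [4.0, 0.3, 0.0]
    targets = np.linspace(-3.6, 2.4, n_targets)
    fwd = drive_reaction(spec, rc, DrivingSchedule(tuple(targets), 20.0), x0.ravel())
    back = drive_reaction(spec, rc, DrivingSchedule(tuple(targets[::-1]), 20.0),
                          fwd.states[-1])
    # product minimum from an independent descent started on the product side
    xp = x0.copy().reshape(4, 3)
    xp[3] = xp[0] + [10.0, 0.3, 0.0]
    oracle = minimize(lambda x: evaluate_potential(x, spec)[0], xp.ravel(),
                      jac=lambda x: evaluate_potential(x, spec)[1], method="L-BFGS-B")
    return {
        "monotone_rc": bool(np.all(np.diff(fwd.rc_achieved[1:]) > 0)),
        "final_rc": float(rc_value(fwd.states[-1].reshape(4, 3), rc)),
        "final_energy": float(fwd.energies[-1]),
        "product_energy": float(oracle.fun),
        "product_gap": abs(float(fwd.energies[-1]) - float(oracle.fun)),
        "roundtrip_energy_error": abs(float(back.energies[-1]) - float(fwd.energies[0])),
        "barrier_height": float(np.max(fwd.energies) - fwd.energies[0]),
        "n_targets": n_targets,
    }
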