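"""Model potentials, restraints, Langevin sampling, two-state loop generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcv.errors import DimensionalityError, SpecError
from pathcv.langevin import LangevinIntegrator, run_langevin
from pathcv.restraints import RampSchedule, Restraint, apply_restraints, restraint_energy
from pathcv.systems import (
    ToySystemSpec,
    double_well_free_energy_difference,
    evaluate_potential,
    generate_two_state_loop,
    make_two_state_loop_spec,
    substrate_positioning_system,
)
from pathcv.units import KB, KCAL_PER_AKMA

SPECS = {
    "harmonic": ToySystemSpec("harmonic", {"stiffness": 2.0, "center": [0.5, -1.0, 2.0]}),
    "double-well-1d": ToySystemSpec("double-well-1d", {"barrier": 3.0, "tilt": 1.0}),
    "double-well-2d": ToySystemSpec("double-well-2d", {"barrier": 2.0, "stiffness_y": 4.0}),
    "mueller-brown": ToySystemSpec("mueller-brown", {"scale": 0.05}),
    "bead-chain": ToySystemSpec(
        "bead-chain",
        {
            "n_beads": 4,
            "bond_length": 3.8,
            "bond_stiffness": 10.0,
            "confinement": 0.1,
            "attractions": [(0, 3, 2.0, 1.5, 4.0)],
            "dw_bond": {"pair": (0, 2), "r1": 4.0, "r2": 9.0, "barrier": 2.0},
        },
    ),
}


@pytest.mark.parametrize("kind", sorted(SPECS))
def test_gradient_is_exact_derivative(kind, rng):
    """Analytic gradients agree with central finite differences."""
    spec = SPECS[kind]
    x = rng.normal(scale=1.5, size=spec.ndof)
    if kind == "bead-chain":  # keep beads apart so distances are regular
        x = x + 3.8 * np.arange(spec.ndof) % 11
    _, g = evaluate_potential(x, spec)
    h = 1e-6
    for d in range(spec.ndof):
        e = np.zeros(spec.ndof)
        e[d] = h
        ep, _ = evaluate_potential(x + e, spec)
        em, _ = evaluate_potential(x - e, spec)
        assert g[d] == pytest.approx((ep - em) / (2 * h), rel=1e-4, abs=1e-5)


def test_harmonic_minimum_is_zero():
    spec = SPECS["harmonic"]
    e, g = evaluate_potential(np.array([0.5, -1.0, 2.0]), spec)
    assert e == 0.0
    assert np.all(g == 0.0)


def test_mueller_brown_minimum_is_stationary(mb_spec, mb_minima):
    """Newton-located deepest minimum (≈ (−0.558, 1.442)) has a vanishing gradient."""
    assert mb_minima[0] == pytest.approx([-0.558, 1.442], abs=2e-3)
    _, g = evaluate_potential(mb_minima[0], mb_spec)
    assert np.linalg.norm(g) < 1e-6


def test_double_well_barrier_by_construction():
    spec = ToySystemSpec("double-well-1d", {"barrier": 3.0, "half_width": 1.0})
    e0, _ = evaluate_potential(np.array([0.0]), spec)
    e1, _ = evaluate_potential(np.array([1.0]), spec)
    assert e0 - e1 == pytest.approx(3.0, abs=1e-12)


def test_dimension_mismatch_rejected(mb_spec):
    with pytest.raises(DimensionalityError):
        evaluate_potential(np.zeros(3), mb_spec)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"kind": "nonsense"},
        {"kind": "harmonic", "timestep": 0.0},
        {"kind": "harmonic", "temperature": -1.0},
        {"kind": "bead-chain", "params": {"n_beads": 2}},
        {"kind": "bead-chain", "params": {"n_beads": 4, "bond_stiffness": 0.0}},
    ],
)
def test_invalid_system_specs_rejected(kwargs):
    with pytest.raises(SpecError):
        ToySystemSpec(**kwargs)


# ---------------------------------------------------------------------------
# restraints


@pytest.mark.parametrize(
    "value,expected",
    [(5.0, 0.0), (6.0, 0.0), (7.0, 2.5)],
)
def test_half_harmonic_energy(value, expected):
    """Half-harmonic beyond 6 Å with k=5 contributes ½·5·(v−6)² only outside."""
    res = Restraint("upper-flat-bottom", ("coord", 0), 6.0, 5.0)
    e, _ = restraint_energy(res, value)
    assert e == pytest.approx(expected, abs=1e-12)


def test_ramped_force_constant_midpoint():
    """A 0→10 kcal/mol/Å² ramp over 200 ps reads k=5 at 100 ps."""
    res = Restraint("harmonic", ("coord", 0), 0.0, 0.0,
                    ramp=RampSchedule(0.0, 10.0, 200.0))
    assert res.k_at(100.0) == pytest.approx(5.0)
    assert res.k_at(500.0) == pytest.approx(10.0)  # constant after the ramp


def test_negative_force_constant_rejected():
    with pytest.raises(SpecError):
        Restraint("harmonic", ("coord", 0), 0.0, -1.0)


@pytest.mark.parametrize(
    "restraint",
    [
        Restraint("harmonic", ("coord", 2), 1.0, 3.0),
        Restraint("harmonic", ("point", 1, (1.0, 2.0, 3.0)), 2.0, 4.0),
        Restraint("upper-flat-bottom", ("distance", 0, 2), 3.0, 5.0),
        Restraint("lower-flat-bottom", ("distance", 1, 2), 9.0, 2.0),
    ],
)
def test_restraint_forces_are_exact_derivatives(restraint, rng):
    x = rng.normal(scale=4.0, size=9)
    _, g = apply_restraints(x, [restraint])
    h = 1e-6
    for d in range(9):
        e = np.zeros(9)
        e[d] = h
        ep, _ = apply_restraints(x + e, [restraint])
        em, _ = apply_restraints(x - e, [restraint])
        fd = (ep - em) / (2 * h)
        assert g[d] == pytest.approx(float(fd), rel=1e-5, abs=1e-6)


# ---------------------------------------------------------------------------
# Langevin dynamics


def test_zero_temperature_descends_to_minimum():
    spec = ToySystemSpec("harmonic", {"stiffness": 1.0, "center": [0.0, 0.0]},
                         temperature=0.0, friction=5.0, timestep=0.01)
    res = run_langevin(spec, n_steps=4000, seed=0, x0=np.array([3.0, -2.0]),
                       sample_stride=400)
    energies = res.energies
    assert np.all(np.diff(energies) <= 1e-12)
    assert energies[-1] < 1e-6


def test_equipartition_position_variance():
    """Harmonic sampling reproduces var(x) = kB T / k within 5%."""
    k, temp = 2.0, 300.0
    spec = ToySystemSpec("harmonic", {"stiffness": k, "center": [0.0]},
                         temperature=temp, friction=5.0, timestep=0.005, seed=42)
    res = run_langevin(spec, n_steps=200_000, seed=42, x0=np.zeros(1), sample_stride=5)
    var = res.positions[2000:, 0].var()
    assert var == pytest.approx(KB * temp / k, rel=0.05)


def test_same_seed_bit_identical():
    spec = ToySystemSpec("double-well-1d", {"barrier": 2.0}, seed=9)
    a = run_langevin(spec, n_steps=500, seed=9, x0=np.array([1.0]))
    b = run_langevin(spec, n_steps=500, seed=9, x0=np.array([1.0]))
    assert np.array_equal(a.positions, b.positions)


def test_energy_conservation_without_thermostat():
    """γ=0, T=0 reduces BAOAB to velocity Verlet: drift < 1e-4 over 1e4 steps."""
    spec = ToySystemSpec("harmonic", {"stiffness": 1.0, "center": [0.0]},
                         temperature=0.0, friction=0.0, timestep=0.001)
    integ = LangevinIntegrator(spec, x0=np.array([1.0]))
    e0 = float(integ.potential_energy() + integ.kinetic_energy())
    drift = 0.0
    for _ in range(100):
        integ.step(100)
        e = float(integ.potential_energy() + integ.kinetic_energy())
        drift = max(drift, abs(e - e0))
    assert drift < 1e-4


def test_boltzmann_two_state_occupancy():
    """Tilted double-well occupancy matches exp(−ΔF/kBT) within 3 SE."""
    spec = ToySystemSpec("double-well-1d", {"barrier": 1.0, "tilt": 0.6},
                         temperature=300.0, friction=2.0, timestep=0.002, seed=7)
    res = run_langevin(spec, n_steps=400_000, seed=7, x0=np.array([-1.0]),
                       sample_stride=10)
    x = res.positions[2000:, 0]
    right = x > 0
    d_f = double_well_free_energy_difference(spec)
    expected = 1.0 / (1.0 + np.exp(d_f / (KB * 300.0)))
    # standard error of the occupancy from 20 blocks of the trajectory
    blocks = right[: len(right) // 20 * 20].reshape(20, -1).mean(axis=1)
    se = blocks.std(ddof=1) / np.sqrt(20)
    assert abs(right.mean() - expected) < 3 * se + 1e-9


def test_restraint_forces_enter_dynamics():
    """A stiff coordinate restraint shifts the sampled mean to its target."""
    spec = ToySystemSpec("harmonic", {"stiffness": 1.0, "center": [0.0]},
                         temperature=300.0, friction=5.0, timestep=0.005, seed=3)
    res = run_langevin(spec, [Restraint("harmonic", ("coord", 0), 2.0, 50.0)],
                       n_steps=50_000, seed=3, x0=np.array([2.0]), sample_stride=5)
    mean = res.positions[1000:, 0].mean()
    assert mean == pytest.approx(50.0 * 2.0 / 51.0, abs=0.05)


# ---------------------------------------------------------------------------
# two-state loop generator


def test_two_state_references_and_zero_noise(loop_spec):
    from dataclasses import replace

    spec = replace(loop_spec, noise_amplitude=0.0)
    refs, frames, labels = generate_two_state_loop(spec, n_frames=40)
    for frame, lab in zip(frames, labels):
        assert np.array_equal(frame, refs[lab])


def test_two_state_symmetric_occupancy(loop_spec):
    _, _, labels = generate_two_state_loop(loop_spec, n_frames=4000)
    p = labels.mean()
    assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 4000)


def test_two_state_depth_bias():
    spec = make_two_state_loop_spec(basin_depths=(0.0, 1.0), seed=5)
    _, _, labels = generate_two_state_loop(spec, n_frames=4000)
    expected = 1.0 / (1.0 + np.exp(-1.0 / (KB * 300.0)))
    assert labels.mean() == pytest.approx(expected, abs=0.05)


def test_planted_pairs_straddle_contact_radius(loop_spec):
    for i, j in loop_spec.planted_pairs:
        di = np.linalg.norm(loop_spec.ref_inactive[i] - loop_spec.ref_inactive[j])
        da = np.linalg.norm(loop_spec.ref_active[i] - loop_spec.ref_active[j])
        lo, hi = sorted((di, da))
        assert lo < 8.0 < hi and hi >= 1.5 * lo


def test_invalid_planted_pair_rejected(loop_spec):
    from pathcv.systems import TwoStateLoopSpec

    with pytest.raises(SpecError):
        TwoStateLoopSpec(
            n_beads=loop_spec.n_beads,
            ref_inactive=loop_spec.ref_inactive,
            ref_active=loop_spec.ref_active,
            planted_pairs=((0, 1),),  # bonded neighbors never cross 8 Å
        )


def test_substrate_positioning_modes_validate():
    for mode in ("in", "intermediate", "out"):
        spec, restraints, idx = substrate_positioning_system(mode)
        assert spec.ndof == 9 and idx == 0 and len(restraints) == 6
    with pytest.raises(SpecError):
        substrate_positioning_system("sideways")


# ---------------------------------------------------------------------------
# unit bookkeeping


def test_thermal_velocity_scale():
    """Velocity variance from the thermostat matches kB T·418.4/m."""
    spec = ToySystemSpec("harmonic", {"stiffness": 1e-9, "center": [0.0]},
                         temperature=300.0, friction=10.0, timestep=0.002, seed=12)
    integ = LangevinIntegrator(spec, x0=np.zeros(1))
    vs = []
    for _ in range(20_000):
        integ.step()
        vs.append(integ.v[0])
    target = KB * 300.0 * KCAL_PER_AKMA / spec.mass
    assert np.var(vs) == pytest.approx(target, rel=0.05)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(-3, 3), st.floats(0.1, 5))
def test_flat_bottom_zero_inside_allowed_region(value, k):
    upper = Restraint("upper-flat-bottom", ("coord", 0), 3.5, k)
    lower = Restraint("lower-flat-bottom", ("coord", 0), -3.5, k)
    assert restraint_energy(upper, value)[0] == 0.0
    assert restraint_energy(lower, value)[0] == 0.0
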