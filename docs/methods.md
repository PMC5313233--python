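# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `pathcv`, in the order the pipeline runs them.

## Units and integrator

All quantities use Å, ps, kcal/mol, amu and K, with
kB = 0.0019872041 kcal/mol/K and the conversion
1 kcal/mol = 418.4 amu·Å²/ps² applied wherever an energy gradient
updates a momentum (Langevin kicks, thermal velocities, the string
evolution step).  Dynamics uses the BAOAB splitting of Langevin
dynamics: half kick, half drift, exact Ornstein–Uhlenbeck velocity
refresh, half drift, half kick.  BAOAB stays accurate at the large
friction coefficients used for thermostatted sampling and reduces
exactly to velocity Verlet when friction and temperature are both zero,
which is how the energy-conservation test exercises the same code path
as production sampling.  Sampling is constant-volume; the package has
no barostat, so protocols that would equilibrate pressure in an
all-atom setting are represented by constant-volume Langevin runs.

All stochastic operations draw from one `numpy` generator seeded from a
mandatory config field, making every trajectory, hills log and output
file bit-reproducible.

## Model systems

* **Müller–Brown** uses the standard four-Gaussian literature
  parameterization in reduced units; a `scale` factor maps reduced
  energy to kcal/mol.  Its three minima and two saddles are located at
  run time by Newton iteration on the analytic gradient with an
  eigenvalue check — these serve as the independent reference for every
  path-method test, and are never taken from the path being tested.
* **Double wells** are quartic, `b((x/a)²−1)²`, with an optional linear
  tilt that sets the basin free-energy asymmetry; the exact inter-basin
  ΔF is computed by quadrature of the Boltzmann integral and acts as
  the metadynamics oracle.
* **Bead chains** have harmonic bonds, optional global confinement,
  optional short-range Gaussian pair attractions, and an optional
  double-well bond (a pair that rests at either a short or a long
  separation) used as the reaction-driving benchmark.

### The synthetic two-state loop

The stand-in for the two crystallographic endpoint structures is a
20-bead chain with a 3.8 Å bond length: the "inactive" reference is the
extended strand, the "active" reference a β-hairpin of two antiparallel
strands 4.6 Å apart.  Cross-strand bead pairs sit near 4–6 Å in the
hairpin and ≥ 11 Å in the strand, so the contact-selection rule (cross
8 Å between states, larger/smaller ratio ≥ 1.5, bonded neighbors
|i−j| ≤ 2 excluded) recovers a planted pair set computed independently
by a brute-force double loop at construction time.  Ensemble sampling
draws each frame's basin from Boltzmann weights of the two basin depths
(symmetric depths give 50/50 occupancy) and adds isotropic Gaussian
noise of amplitude 0.3 Å.  This generator reproduces the *topology* of
a two-state ensemble — two well-separated backbone clusters with
state-dependent contacts — but none of the continuous transition
pathway, solvent effects, or correlated loop motions of a real kinase;
tests passing on it certify the machinery (selection, CV evaluation,
clustering, classification), not biological realism.

## Zero-temperature string

The minimum energy path is found by the stated protocol: start from the
two endpoint structures plus two linear interpolants, run 100
iterations of (20 steepest-descent steps per image, then
reparametrization to equal arc-length spacing), then double the image
count — one midpoint per interval and two points in the central
interval, so the count doubles exactly — and repeat until 256 images;
32 strided images (7, 15, …, 255) seed the finite-temperature string.
The descent step is a per-surface constant (1e-4 on Müller–Brown in
reduced units).  Two properties of this discretization are worth
stating plainly:

* Reparametrization places images *on* the current polyline at equal
  arc spacing; chord distances between consecutive images are therefore
  equal only up to corner-cutting, and the polyline length can only
  shrink.  Tests assert exactly this.
* The pointwise gradient component perpendicular to the path does not
  vanish at convergence: plain descent alternated with reparametrization
  leaves images on chords of the curved MEP, and on Müller–Brown the
  floor is ≈1.4 reduced units at the sharpest bend (median 0.04).  The
  meaningful convergence statement — the one tested — is that the path
  passes within 0.05 of both Newton-located saddles (measured ≈3e-4).

## Finite-temperature string

Each image is an independent Langevin replica whose CVs are tethered to
targets z\* with force constant k; after each sampling window the mean
force k⟨z\*−z⟩ updates the targets by overdamped descent with
γ = 125 ps⁻¹ and m = 12.011 amu (defaults as stated for the kinase
protocol), followed by reparametrization in CV space.  Choices the
protocol leaves open, fixed here:

* **Evolution time step** defaults to (update stride × MD time step),
  the dimensionally consistent reading of "update every 10 steps".
* **Burn-in**: 10× the sampling stride is discarded after every
  reparametrization before forces accumulate, because the restrained
  distribution must re-equilibrate at the moved targets.
* **Error bars** on mean forces come from block averaging (5 blocks by
  default) since consecutive samples are correlated.
* **Convergence** is declared when the trailing window of the
  targets-vs-initial RMSD trace spans less than a tolerance; the
  benchmark uses window 40 and tolerance 0.02 Å, the plateau noise
  observed under the benchmark sampling parameters.
* **Endpoints** evolve freely by default (the evolution equation is
  written for all images); a pin flag is provided and the benchmark
  uses it (below).
* **Trailing-window averaging** (`average_window`): optionally the
  converged string is reported as the time average of the targets over
  the last N updates, reparametrized once — a standard
  variance-reduction estimator for a string fluctuating about its fixed
  point.  Off by default.

### Benchmark study conditions (Müller–Brown)

The defaults above are calibrated to a high-dimensional all-atom
system; a 2D toy at those settings (k = 1 kcal/mol/Å² on two Cartesian
CVs) barely feels its restraints.  The benchmark therefore runs the
surface at scale 0.1 kcal/mol per reduced unit and 150 K with k = 400
kcal/mol/Å², 60-step sampling windows, dt = 0.005 ps, pinned endpoints
and a 30-update trailing average.  Two of these choices correct
systematic effects seen at looser settings: at 300 K with k = 200 the
thermally smoothed string sits ~0.06–0.09 reduced units off the steep
higher saddle (a real finite-temperature/finite-restraint shift, not
noise), and with free endpoints the higher saddle projects almost
exactly halfway between two images, making "the image nearest the
saddle" ill-conditioned; pinning phases the saddle onto an image.  With
these conditions the string passes within ~0.01–0.02 of both saddles
and the PMF maximum lands on the saddle-crossing image for every seed
tried.

The PMF integrates Σᵢ (∂F/∂zᵢ)(∂zᵢ/∂α) with centered differences
(one-sided at the ends) and the trapezoidal rule, F(0) = 0; the final
mean forces come from a longer sampling pass (2000 windows) at fixed
targets.

## Well-tempered multiple-walker metadynamics

Hills of initial height 0.7 kcal/mol and width 0.1 (CV units) are
deposited every 500 steps with bias temperature ΔT = 4200 K — read as
ΔT, so the bias factor at 300 K is 15; a config switch reinterprets the
value as T+ΔT.  The deposited height is
h₀·exp(−V_prior/(kB ΔT)) where **V_prior is evaluated by direct
summation over the existing log**, so every logged height is exactly
reproducible from the log alone (the replay identity holds to floating
point, and is asserted in tests).  During dynamics the bias and its
gradient are interpolated multilinearly from a 0.002-spaced grid
updated at each deposition; hills falling outside the grid are clamped
to its edge and counted.

Walkers share one log and advance in lockstep; at each deposition time
they deposit in walker-id order, each seeing all earlier hills — a
deterministic round-robin replacement for the asynchronous file sharing
of production engines, chosen so multi-walker runs are bit-reproducible.
Merging the per-walker logs by (time, walker) reproduces the shared log
exactly.

The free-energy surface is F = −(T+ΔT)/ΔT·V_bias shifted to min 0, and
inter-basin ΔF values are Boltzmann integrals of that surface at the
system temperature.  The benchmark (tilted 1D double well, barrier 2.5,
tilt 1.2 kcal/mol, 10 walkers × 100 000 steps → 2000 hills) recovers
the analytic ΔF within ≈0.05–0.2 kcal/mol across seeds; the budget was
sized so the error stays well inside 0.3 kcal/mol, the tolerance used
in testing.

## Ensemble analysis

Pairwise RMSD uses least-squares (Kabsch) superposition per pair,
implemented as batched SVDs; `scipy`'s rotation alignment serves as an
independent cross-check in tests, not as the implementation.
Clustering is complete-linkage agglomeration cut at a 3.0 Å diameter:
the merge of smallest complete-linkage distance is always taken (ties
to the lowest index), which guarantees every cluster's maximum
intra-cluster RMSD stays under the cut; the guarantee is *certified*,
not assumed, by a direct pairwise check on every call.  Clusters are
renumbered by smallest member frame id so the partition is invariant
under frame permutation; representatives are medoids.  Network edges
default to single-linkage member-pair distance ≤ 3.8 Å (the "any pair
within 3.8 Å" reading), with a representative-to-representative mode;
the nearest-cluster statistic defaults to representative RMSD because
the quantity is reported in Å, not hops.  Density maps are normalized
2D histograms (no kernel smoothing) with contour levels at multiples of
0.005.  RMSF is √⟨|x−⟨x⟩|²⟩ per particle, after optional two-pass
superposition onto the mean structure.

### The substrate-positioning experiment

The restrained comparison of substrate stabilization is modeled with
three beads: a "substrate" in a weak trap (k = 0.3 kcal/mol/Å² along a
channel axis; 5 kcal/mol/Å² channel walls in y, z), a "guardian"
anchored at 4.5 Å (in), 8 Å (intermediate/secondary site) or 25 Å
(out), and a short-range Gaussian attraction between them (depth 4
kcal/mol, width 1.0 Å, equilibrium separation 4.5 Å), plus the
production half-harmonic restraints of the original protocol
(k = 5 kcal/mol/Å² beyond 6 Å for "in", below 10 Å for "out").
Parameters were chosen against the exact 1D Boltzmann marginal of this
model so the predicted substrate fluctuations separate cleanly
(σₓ ≈ 0.43 / 0.99 / 1.41 Å); a naive local-curvature analysis is
misleading here because the guardian's attractive well is strongly
anharmonic at intermediate distance.  The claim tested is direction
only — in < intermediate < out — matching the qualitative ordering of
the restrained comparison; no numeric fluctuation value is asserted.

## Reaction driving

RC = d₁ − d₂ − d₃ over three particle pairs, with analytic gradient
(undefined and flagged for coincident pairs).  Driving minimizes
E + ½k(RC − target)² per target with L-BFGS-B and the exact gradient,
24 evenly spaced targets by default, each stage starting from the
previous optimum; the initial state is first minimized without the RC
restraint.  The single-region minimizer replaces the alternating
QM/MM optimization scheme of the original protocol — there is no
electronic structure in scope.  The RC restraint constant is a required
input (the original value is unstated); the benchmark uses 20
kcal/mol/Å², stiff relative to the double-well bond so the achieved RC
tracks its targets without hysteresis, which is what makes
forward-then-backward driving return to the initial energy to ~1e-11
kcal/mol.

## Problem sizes

The shipped benchmarks and the bundled demo are sized for a single CPU:
the string benchmark runs 32 replicas × ~100 updates × 660 steps plus a
2000-window PMF pass (~10 s), metadynamics 10 walkers × 100 000 steps
(~8 s), the RMSF comparison 3 × 120 000 steps (~1 min), and the full
demo configuration completes in well under a minute.  These sizes were
chosen as the smallest at which the statistical checks sit comfortably
inside their tolerances across seeds.

## Known limitations

* No all-atom force field, solvent, electrostatics, constraints or
  barostat: the toy potentials probe the algorithms, not kinase
  energetics, and none of the kinase-specific quantities (cluster
  counts, barrier frame, contact counts) are reproduced.
* The zero-temperature string's pointwise perpendicular-gradient floor
  (above) is inherent to descent-plus-reparametrization at finite image
  count.
* The contact-map formula is implemented in both its printed
  (similarity) and squared-difference (distance) readings because the
  two disagree; the literal form is the default and plots/outputs label
  the variant in use.
* Flat 2D histograms under-resolve densities for small ensembles;
  there is deliberately no kernel smoothing.
* Metadynamics offers no reweighting estimators or adaptive hills;
  free-energy surfaces are read directly from the accumulated bias.
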