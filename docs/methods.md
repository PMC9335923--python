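# Methods

`nanopbpk` simulates the whole-body disposition of antibody-coated
nanoparticles (NPs) in a mouse with a family of physiologically based
pharmacokinetic (PBPK) models whose parameters are physical rather than
empirical: binding kinetics follow from particle size through diffusion
and multivalent-adhesion relations, and organ coupling follows from
measured blood flows and compartment volumes.

## Compartment structure and state variables

Every organ is split into three sub-compartments: free NP in the organ's
vascular space (`bl`), NP bound to endothelial ICAM-1 receptors (`EC`),
and NP internalized in tissue (`T`). First-order rate constants connect
them: binding `K_on` (bl → EC), unbinding `K_off` (EC → bl), transcytosis
`K_up` (EC → T), non-specific paracellular uptake `K_NS` (bl → T), and
degradation `K_deg` (every sub-compartment → a cumulative sink). Organs
are joined by venous and arterial compartments through blood flows `Q`
(L/min).

States are integrated as molar amounts `N` rather than concentrations.
All kinetic terms in the source equations have the form `K · C · V = K ·
N`, so on an amount basis the whole system is a linear autonomous ODE
`dN/dt = A N`, flows enter as `Q/V` washout rates, and the total-mass
audit is a sum — no volume bookkeeping can silently break it.
Concentrations are recovered on output as `N/V`.

Two lumped wirings are provided:

* **Model A** (17 ODEs): lung, heart, kidney, liver and spleen in
  parallel between artery and vein — a deliberately oversimplified
  circulatory map.
* **Model B** (23 ODEs): adds gut and a pooled 'other' compartment,
  routes the full cardiac output serially through vein → heart → lung →
  heart → artery, perfuses the heart itself through a coronary branch
  (artery → heart → vein), and drains spleen and gut through the liver
  (`Q_hep = Q_liver + Q_spleen + Q_gut`).

Both wirings are generated from their flow topology under strict
node-wise flow balance (inflow = outflow at every vascular node),
enforced at assembly time. This is the structural condition for exact
mass conservation; the per-compartment balance equations follow from it
mechanically.

The initial condition places the full dose as a bolus in the venous
compartment; the dose and every volume, flow and rate constant come from
a YAML/JSON parameter file with mandatory unit annotations.

## Degradation bookkeeping and the conservation audit

Degradation losses accumulate in one auxiliary state with
`d(deg)/dt = Σ K_deg,i N_i`. The augmented system then has total mass
(states + degraded) as an exact linear invariant: every column of the
augmented rate matrix sums to zero, which the builder asserts to 1e-9
relative. Because consistent ODE methods preserve linear invariants, the
audit `max |M(t) − M(0)|/M(0)` measures only roundoff and Newton
tolerance; with the defaults it sits near 1e-13 over 10^4 s for all
three models, far below the 1e-6 acceptance bound used in the tests. A
Riemann-sum variant of the degraded mass (left-endpoint quadrature of
the degradation flux on the output grid) is provided as an independent
fidelity check of the auxiliary state; the two agree to O(Δt).

## Vascular branching element

The branched model resolves each organ's vasculature into a symmetric
bifurcating element built from Murray's law `d_parent^k = d_1^k + d_2^k`
with `k = 3`, i.e. `d_child = d_parent · 2^(−1/k)` per split, starting at
the murine main-artery diameter `d_0 = 600 µm` and stopping at the first
generation at or below the red-blood-cell diameter (15 µm); the stopping
rule is inclusive because "reaches the bound" is otherwise ambiguous.
This yields G = 16 bifurcations; the venous half mirrors the arterial
half, giving 32 generations. Vessel length is `L = β·d` with `β = 3`;
branch count doubles per descending generation (`N = 2^n`). Element
surface area and volume are `2 Σ π d l N` and `2 Σ π (d/2)² l N` over the
descending half. A convenient identity of the `k = 3, L = 3d` element is
that every generation carries the same volume (`(3π/4) d_0³ 2^{-n} 2^n`),
so each of the 32 generations holds 1/32 of the element volume.

The element geometry is organ-independent; an organ differs only through
its element count `φ = V_bl / V_element` (fractional values allowed —
the murine fixture gives spleen ≈ 0.5 and 'other' ≈ 31).

## Branched model (457 ODEs)

The branched model keeps the model-B wiring but replaces each organ's
vascular compartment with a serial chain of 32 generation states, each
paired with an endothelial state, plus one whole-organ tissue state:
2 + 32·7 + 32·7 + 7 = 457 states. The full organ flow passes through
every generation (what splits at a bifurcation is per-branch flow
`Q/N^n`), so amount flux is conserved across generation boundaries.

Per-generation storage volumes are those of a **single** element, and
every vascular/endothelial rate constant is multiplied by `φ` — this is
the formulation the per-generation balance equations define, and it is
what produces the φ-dependent dynamics: effective washout is
`Q/V_element`, φ-fold faster than the lumped model where `φ > 1`, so
well-vascularized organs reach tissue earlier in the branched model while
the spleen (`φ < 1`) is the least accelerated. Tissue degradation is
*not* φ-scaled: the tissue compartment is the whole organ, not a tiled
element, and φ-scaling it would decouple branched and lumped tissue
kinetics entirely (for the 'other' compartment by a factor ≈ 31).

A volume-preserving variant (`volume_scaling="organ"`: per-generation
volumes `φ·V_gen`, unscaled rates) is kept behind a switch; collapsing
the tree to a single generation under that scaling reproduces model B
state-for-state and is used as an exact consistency check of the
assembly.

The endothelial-layer volume of one element (`V_EC/φ`) is allocated
across generations proportionally to generation surface area — the
receptor layer lives on the vessel wall, so area is the natural measure;
the split is not observable in the lumped outputs.

## Parameter derivations

* **Endothelial volume**: `V_EC = φ_EC · V_T · l_NC,b / D_EC` with
  endothelial volume fraction `φ_EC = 0.3`, cell diameter
  `D_EC = 5 µm` and receptor-layer height `l_NC,b = 50 nm` (the area
  `l_EC² = φ_EC V_T / D_EC` times the layer height; litres × m/m keeps
  the unit consistent without conversion).
* **Size-dependent kinetics**: the on-rate is diffusion-limited through
  the glycocalyx, `K_on = D/l²` with `l = 0.5 µm` and the Stokes–Einstein
  diffusivity `D = k_B T / (6π η r)` at `T = 310 K`, plasma viscosity
  `η = 1.2e-3 Pa·s` and `r` the particle radius; at 100 nm this gives
  `K_on ≈ 15 s⁻¹`. The off-rate uses the crowding-corrected equilibrium
  constant, `K_off = K_on / log₁₀(K_EC)`, with `log₁₀(K_EC)` linear in
  particle diameter (slope-point form anchored at 800 nm, per-organ
  anchors expressing receptor density). Base-10 log is the default and
  configurable; the relation errors out if it extrapolates to
  `log(K_EC) ≤ 0`, where the off-rate is undefined.
* **Blood volumes**: `V_vein = V_art = (V_total − Σ V_bl)/2` with the
  murine total blood volume `V_total = 2146 µL`.

## The murine fixture as the study condition

The shipped `murine.yaml` is a synthetic parameter set with
literature-plausible magnitudes for a ~25 g mouse: cardiac output
≈ 13 mL/min distributed over kidney, gut, liver (arterial), spleen,
coronary and 'other' branches; vascular volumes summing to ≈ 0.76 mL;
organ weights averaging male and female values. The free rate constants
(`K_up`, `K_NS`, `K_deg` per organ — the ones a local sensitivity
analysis would tune against data) were set against one explicit regime
criterion: the vascular + endothelial pool should hold less than ~10 % of
the dose by t = 300 s, i.e. a blood half-life of roughly two minutes.
That is the regime the method family targets — vascular and endothelial
profiles collapse quickly after the initial distribution spike, which is
also what makes the quasi-steady-state reduction sensible — and it
matches the minutes-scale clearance reported for 100 nm particles taken
up by the mononuclear phagocyte system. The resulting values are
`K_up ∈ [2e-3, 8e-3] s⁻¹`, `K_NS ∈ [5e-4, 4e-3] s⁻¹`,
`K_deg ∈ [2e-5, 2e-4] s⁻¹`, with lung given the largest non-specific
uptake.

What the fixture does *not* emulate: saturation of receptors or uptake
(the system is linear by construction), hematocrit/margination physics in
the branching network, shear- or generation-dependent binding (a constant
`K_on` per organ; the per-generation structure exposes the hook),
inter-animal variability, and any specific experimental dataset. Tests
passing on this fixture therefore demonstrate structural and numerical
correctness and the stated qualitative orderings — not agreement with any
particular in vivo measurement.

## Solvers and stiffness

With binding at ~15 s⁻¹ (and per-generation washout up to ~500 s⁻¹ in the
branched model) against degradation at ~1e-5 s⁻¹, the full systems are
stiff: |λ|max/|λ|min ≈ 1e6 (model B) to 3e7 (branched), computed from the
dense spectrum after discarding eigenvalues below 1e-12·|λ|max (the
conserved zero modes of a closed system — the ratio would otherwise be
infinite; the cutoff is far below any physical rate). The default
integrator is adaptive implicit (`BDF`, constant Jacobian supplied);
`Radau`, `LSODA` and explicit methods are available, and an exact
matrix-exponential propagator (`method="expm"`) steps `e^{AΔt}` on a
uniform grid — exact for these linear systems to machine precision, used
both as the cross-check oracle for the adaptive solvers and as the fast
path for sensitivity analysis (~1 ms per model-B solve). Fixed-step
compatibility (`dt`) maps to the propagator step or to `max_step`.
Default tolerances: `rtol = 1e-8`, `atol = 1e-14 · max|y0|`.

## Quasi-steady-state reduction

The QSSA declares all vascular and endothelial states algebraic: with
states partitioned into fast `N_ss` (bl + EC; 14 for model B, 448
branched) and slow `N_nss` (vein, artery, 7 tissues), setting
`dN_ss/dt = 0` gives `N_ss = −A_ss⁻¹ A_sn N_nss` and a 9-state reduced
system `M = A_nn − A_ns A_ss⁻¹ A_sn`. Because the system is linear the
elimination is exact at every instant — pre-reducing the matrix and
re-solving the algebraic block each step are the same operation; the
per-step route is retained where the training loop of the neural solver
interleaves it. The algebraic residual is audited at `1e-10` relative.
Degradation from the eliminated states is folded into the reduced
degradation functional via the same elimination.

The reduced system is integrated with an explicit nonstiff method
(`RK45`); its stiffness ratio drops to ~1e4 (vein washout ~0.3 s⁻¹ over
tissue decay ~2e-5 s⁻¹). The approximation error is the mass transiting
the eliminated pool during the distribution phase; with the fixture
regime the tissue-trajectory relative L2 distance between reduced and
full models over t ∈ [1e2, 1e4] s is ≈ 0.12 for both the lumped and the
branched systems, against a documented tolerance of 0.2. The error
shrinks as binding kinetics are scaled faster at fixed `K_on/K_off`
(timescale-separation limit), which the tests assert directionally.

## Sensitivity analysis

The 21 under-determined rates (`K_deg`, `K_up`, `K_NS` × 7 organs) are
explored by one-at-a-time sweeps and by variance-based global analysis.
Quantities of interest: maximum tissue amount over time and time-mean
endothelial-bound amount, per organ, as dose fractions. Sobol sampling
uses a scrambled Sobol' sequence in the Saltelli A/B/AB_i radial design
(`(d+2)·n_base` model solves; `n_base = 256` by default, seedable), the
Saltelli-2010 estimator for first-order and Jansen for total-order
indices. Ranges default to one decade either side of the fixture value,
log-uniform, since rate constants are scale parameters. Degenerate
ranges are reported as zero indices with a warning. The estimators are
validated against the closed-form variance shares of an additive linear
model and the S1≈0/ST≈1 signature of a pure product interaction.

## Neural solver

The physics-informed network maps scaled time `τ = t/t_max ∈ [0, 1]`
(`t_max = 1e3 s`) to the nine slow amounts, normalized by the injected
dose so a sigmoid output layer can represent them. Architecture: scalar
input, two tanh hidden layers (width 64), 9 sigmoid outputs. The loss is
the batch-mean squared ODE residual plus a weighted squared
initial-condition error; the residual compares a first-order finite
difference of the network against the reduced right-hand side, formed in
scaled-time units (the same equation as in physical time, rescaled to
keep the loss surface O(1)). The quasi-steady block is solved for the
current network output at every iteration, as in the reduction above.

Numerical choices that training proved load-bearing, all configurable:
finite-difference step equal to one collocation spacing (512 equally
spaced points), so no inter-node behaviour is invisible to the residual;
IC weight 10; Adam at lr 1e-3 decayed 10× over the run; and a
multi-scale first-layer initialization (unit timescales log-spread over
1–500 in scaled time) so the seconds-scale redistribution transient is
representable from the start — with small-weight initialization the
optimizer stalls on it. Training runs 30 000 epochs (~90 s CPU),
stopping early at loss ≤ 1e-8 or after an 8 000-epoch plateau with
best-so-far parameters restored. Against an `RK45` reference on the same
grid the trained solution's relative L2 error is 0.07–0.08 across seeds;
the residual error concentrates in the first seconds, where the true
vein/artery redistribution is faster than any collocation-resolvable
feature. The trainer refuses the full stiff system by type: its
sub-second binding transients are unrepresentable on the scaled-time
grid, and degraded mass is not tracked by the network solution.

## Steady-state %ID/g model

For observation times shorter than internalization, percent injected
dose per gram follows from association constants alone. The
implementation uses the dimensional reconstruction in which each
bracketed association term is divided by (cell diameter × injected
concentration):

    %ID/g = { κ_p + φ_EC K_EC L_EC,b / (D_EC C_out) } · L_cap/L_EC,b
          + { φ_M  K_M  L_M,b  / (D_M  C_out) } · L_cap/L_M,b

(the typeset source lost its fraction bars; this grouping is fixed once
and exposed for audit). The macrophage term uses the macrophage
concentration `φ_M` — the printed repetition of `φ_EC` there is treated
as a typo. In the `original` variant the non-specific coefficient enters
multiplicatively in the leading term; its ambiguous grouping is behind a
switch (`normalized` divides by `D_EC·C_out` like every other term;
`literal` keeps the printed product). Four membrane conditions (flat,
membrane, ± resident/active macrophages) times three antibody surface
densities (41, 100, 162; `K_EC` scales linearly with count in the
fixture) give the 5-organ condition table. The steady-state fixture
constants are synthetic, chosen once so %ID/g lands in the 1–100 range
typical of targeted NPs; the cross-check against the temporal model at
30 min is an order-of-magnitude consistency test (ratio within 10×), not
a calibration — the two fixtures parameterize different physical
quantities.

## Validation machinery

Experimental tables carry (organ, time, value, unit, source) rows in
%ID/g or %ID/t; conversion is `%ID/t = %ID/g × organ weight`. Model
curves (endothelial + tissue content as %ID/t) are linearly interpolated
at experimental times and scored by NRMSD — RMSD divided by the mean of
the experimental values (range and max normalizations available; the
source's normalization is unstated, and its printed NRMSD values are not
reproducible without the digitized experimental inputs, so they are not
asserted anywhere).

## Numerical edge cases

* Flow imbalance or a mass-closure residual above 1e-9 relative aborts
  assembly naming the node/column.
* `φ_EC = 0` yields a zero endothelial volume (degenerate but legal for
  the derivation chain alone; organ validation requires positive V_EC).
* A singular quasi-steady block (an organ state with no escape path)
  raises naming the offending state; the reduction also rejects initial
  conditions that place mass in an eliminated state.
* Ties in the tree termination (`d == d_min` exactly) terminate — the
  stopping rule is inclusive.
* The stiffness ratio excludes eigenvalues below 1e-12·|λ|max; an
  all-zero matrix is an error.

## Problem sizes used by the test suite

The suite integrates models A and B over the full 10^4 s horizon, the
branched model on a grid with dense early sampling (601 points over the
first 600 s), runs Sobol at `n_base = 64` in unit tests and 256 in the
acceptance checks, and trains the neural solver at full epoch budget for
the acceptance comparison and at reduced budgets elsewhere. These sizes
were chosen so the whole suite runs on one desktop-class CPU core in
minutes while keeping every estimator in its asymptotically valid range.

## Known limitations

Linearity throughout (no receptor or transporter saturation, no
dose-dependence); no margination or hematocrit physics in the branching
element (the per-generation structure is the hook for both); `K_on`
constant across generations; the 'other' compartment is a single
well-mixed pool; the fixture is a murine scenario only (the schema is
species-agnostic); and the neural solver is a demonstration of
PINN-on-reduced-system feasibility, not a production integrator — the
conventional nonstiff solver is both faster and more accurate for this
system size.
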