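# Methods

`windtree` couples a growth-cycle functional–structural plant model of the
GreenLab family to an incremental beam-mechanics solver, a wind-drag model,
a stress-based breakage rule, and a constrained bi-objective optimizer.
This note records the model, its numerical choices, and the design
decisions taken where the problem was genuinely open.

## Growth model

Time advances in growth cycles (one year for a temperate tree).  Each cycle
the tree:

1. **develops** — every living axis tip appends a growth unit (GU) of
   phytomers; lateral buds of physiological age (PA) p+1 appear on the new
   GU and expand the following cycle;
2. **produces** a biomass pool `Q(n)` from the previous cycle's blade area
   `A` through a saturating Beer-law form
   `Q = E_pot · S_p · (1 − exp(−k · A / S_p))`, where `S_p` is the ground
   area available to the crown; the first cycle runs on a seed reserve;
3. **allocates** the pool over competing sinks.  Primary sinks are the new
   blades and internode piths with per-PA sink strengths `P_b`, `P_i`.  The
   secondary (ring) demand follows the pipe model,
   `D_sec = S_layer · N_leaves(n−1)`, one sink unit per leaf borne in the
   previous cycle.  The ring pool `Q_sec = Q · D_sec / D` is then spread
   over standing internodes by the mixture rule

   `q_ring = [(1−λ)/D1 + λ·spa/D2] · l · P_r · Q_sec`,

   with `D1 = Σ l·P_r`, `D2 = Σ l·P_r·spa` over eligible internodes and
   `spa` the count of living leaves distal to the internode.  The rule
   conserves `Q_sec` exactly for every λ ∈ [0, 1].
4. **updates geometry** — pith length from the allometric rule
   `l = β q^((1+α)/2)`; ring area `s = q/(ρ·l)`; internode radius
   `r = sqrt((s_pith + Σ s_ring)/π)`.

Ring density follows a linear schedule in cambial ring index from 0.36 to
0.48 g·cm⁻³, saturating at the eighth ring (a constant override is
available).  Leaves live one cycle (deciduous default, configurable).

The **species preset** carries the published poplar parameter set
(P_m = 4, e = 0.023 g·cm⁻², the four-element sink and allometry vectors,
ρ_pith = 0.36, MOR = 45 MPa).  The production constants are not part of
that set; `E_pot = 5500 g·m⁻²` per cycle and `k = 0.8` were calibrated once
so that an eight-cycle wind-free run yields a tree of 15–20 m height and
stem biomass of order 10² kg, and were not revisited.  The default crown
architecture bears one lateral per GU (GU sizes 5, 4, 3, 2 for PA 1..4,
insertion 45°, phyllotaxy 137.5°): one lateral per *phytomer* multiplies
organ demand combinatorially (≈10⁴ sink units by cycle 8), which starves
trunk piths and makes trees of the calibrated magnitude unreachable.

## Biomechanics

Each internode is a straight multilayer beam element (pith + annual rings).
Composite section stiffness is `EI = Σ E_i π (r_out⁴ − r_in⁴)/4` (similarly
EA, and a torsional GJ with G/E = 1/16 for green wood).  A solve makes two
passes: an upward pass accumulates the internal load resultants from
distributed loads (self-weight increments, stem drag) and concentrated
loads (leaves, branch insertions), with moment arms on the *deformed*
geometry; a downward pass integrates small-deflection Euler–Bernoulli
transfer relations exactly for a linearly varying moment plus a uniform
segment load.  A single segment therefore reproduces `PL³/3EI`, `PL²/2EI`
and `qL⁴/8EI` to machine precision, and the branched solver is checked
against enumeration oracles.

**Incremental logic.**  Only this cycle's weight increment loads the
gravity stage; its converged deformation is committed into the rest pose
(rotating each internode's direction by its mid-segment rotation and
accumulating the internal load increments).  Because committed loads keep
acting while the structure moves, both the gravity and the wind stage add
the *geometric* moment increment of all previously balanced weight —
`Σ (t_i − t_s) × W_i` for displacement field `t` — recomputed from the
previous iterate (a Picard loop).  This is the mechanism by which a
swaying tree's gravity centre shifts and feeds back on bending; without it
slender stems neither sway realistically nor fail.  Wind deformation is
elastic and never committed: removing the wind restores the rest pose
identically, unless breakage changed the structure, in which case the
severed weight is applied as a one-time negative load and the spring-back
is committed.

The equilibrium loop iterates {solve, update geometry, recompute drag}
until the maximum displacement change falls below `tol = 1e-4 m` (default
cap 10 iterations).  Divergence — three consecutively growing updates — is
reported as an instability, not an exception.  Free-tip boundary residuals
(`|F| < 1e-3 N`, `|M| < 1e-3 N·m`) validate each solution.  A maturation
strain hook (per-segment pre-curvature) exists but is off by default;
reaction-wood behaviour is out of scope.

**Elastic modulus.**  `E_ref = 7 GPa` (green poplar order of magnitude),
uniform across layers by default; an optional flag scales layer modulus
with ring density.  E is the main fidelity knob of the mechanics.

## Wind

Open-terrain logarithmic profile `u(z) = u(h0) ln(z/z0)/ln(h0/z0)` with
h0 = 10 m and z0 = 0.06·h0, clamped to zero below z0 (the logarithm is
negative there; only the lowest internodes of young trees are affected).
Stem drag on an internode uses the frontal area `A = 2 l r |sin χ|` and
`F = ½ ρ_air C_d A u(z)²` (ρ_air = 1.226 kg·m⁻³, C_d = 0.25), applied as a
distributed load along the wind; drag is invariant under reversal of the
internode axis.  Heights and angles are re-evaluated on the deformed
geometry at every equilibrium iteration.

**Leaf drag.**  Leaves additionally contribute a concentrated drag
`F = ½ ρ_air C_d,leaf A_blade u(z)²` at their bearing node, with
`C_d,leaf = 0.2` reflecting reconfiguration (fluttering blades streamline;
bluff-body values overestimate their load).  This term is the package's
resolution of an open modelling question: with stem drag alone the wind
moment on a grown tree stays an order of magnitude below any breakage
threshold (trunk stress ~1–4 MPa at 13.5 m/s against a 45 MPa MOR), so
stem failure, critical wind speeds in the 10–30 m/s band, and
wind-dependent optima — the phenomena this model exists to study — cannot
occur at any realistic stiffness.  Setting `Cd_leaf = 0` restores the
stem-only reading.

## Safety

Peripheral longitudinal stress at an internode base is
`σ = 32 |M| / (π d³)` with `M` the resultant bending moment in the section
plane (committed state plus the current solve's increment) and `d` the
internode diameter.  Breakage is brittle: any internode with `σ > MOR`
fails; the most basal failing internode of an axis severs its whole distal
substructure (itself included), which leaves every weight aggregate and
stops regrowing from that tip.  Stress is checked at every wind iteration,
after the gravity commit, and after wind removal.  The critical wind speed
(CWS) of a configuration regrows the tree from seed under each candidate
wind (coarse scan + bisection to 0.1 m/s; a capped search returns an
explicit "unbroken" sentinel).  Trunk breakage is fatal for the
optimization constraint; branch breakage only prunes the crown.

## Optimization

Thigmomorphogenesis is modelled as constrained fitness maximization: find
`S_layer` maximizing `(H_tree, Q_stem)` subject to the trunk never breaking
over the horizon.  The NSGA-II implementation (real-coded, SBX η=15 at
probability 0.7, polynomial mutation η=20 at probability 0.4, binary
tournaments, fast non-dominated sort, crowding distance,
constraint-domination) is written in-package and validated against the
analytic Pareto front of min(x, 1−√x) — note that a 50-point population
can at best reach the hypervolume of the ideal 50-point discretization of
that front, which is the oracle the tests use.  `S_layer` is searched on a
log scale: it is a scale-like ratio spanning (0.1, 20] whose biologically
relevant optima lie in the lowest decade, which a small uniform-linear
population would barely sample.  The simulator is deterministic, so
fitness evaluations are cached and the optimizer seed is the only source
of randomness.  Strategy I is the front's heaviest tree, III the tallest,
II the member closest (Euclidean, objectives min-max standardized over the
front) to the front's mean objective vector; ties prefer smaller
`S_layer`.  The constraint is enforced per cycle (a broken trunk is fatal
whenever it happens), and λ is fixed at 0.1 rather than optimized — it
redistributes rings along the stem but barely moves the objectives.

## Problem sizes and study conditions

The shipped studies use the poplar preset at horizon 8 (≈460 internodes,
seconds per simulation).  The sensitivity sweeps run wind-free or per-wind
single simulations; the CWS study uses λ = 0.4 over S_layer ∈ {2,4,6,8}
with a 40 m/s search cap; the optimization study uses population 20,
15 generations, horizon 6, winds {0, 8, 12, 16} m/s.  Under these
conditions the wind-free optimum sits near S_layer ≈ 0.5–0.7 and the
feasibility floor rises from ≈0.25 at calm to ≈0.5 at 12 m/s, so the
optimal allocation shifts toward thicker stems — "stronger wind, smaller
tree" — as an emergent property.

## What the synthetic scenarios do and do not show

All inputs are generated by the package itself (there is no field data):
the poplar preset emulates a single open-grown tree with deterministic
architecture, steady uniform wind, and non-limiting light, water and
temperature.  Passing tests therefore demonstrate internal consistency,
agreement with beam-theory oracles and the printed worked cases, and the
emergence of the qualitative acclimation trends — not predictive accuracy
for real stands.  Known limitations: small-rotation beam kinematics are
pushed beyond their strict validity in near-failure states (large sways
are qualitatively, not quantitatively, resolved; severely drooping
configurations near the self-weight stability limit are possible without
rupture); no turbulence, gusts or dynamic resonance; no root anchorage
(stem rupture only); no light competition; committed internal loads are
stored in the world frame and are not re-rotated by later small permanent
rotations (second-order at the deformations committed per cycle).
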