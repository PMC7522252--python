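# Methods

## Model overview and assumptions

The simulator advances a discrete root architecture with a fixed step
ΔT (default 0.05 d) while the substrate water field evolves underneath
it. Each step: (1) scheduled axes emerge and lateral primordia past
their delay germinate; (2) every active tip samples the substrate at its
position, elongates and reorients; (3) the steady xylem network is
solved against the collar transpiration flux and its radial flows are
deposited on the mesh as the uptake sink; (4) the Richards solver
advances the water field over the same interval with its own adaptive
substepping. Units are cm, day and kPa throughout; z increases upward;
the growth plane is x–z with the origin at the bottom-left corner.

Assumptions worth keeping in mind: water flow only (no solutes or
temperature); the xylem network is steady within a step (no capacitance,
no rhizosphere resistance, no osmotic potentials); the domain is one
element thick and growth is strictly planar; obstacles are rigid,
immobile rectangles; roots neither decay nor respond to carbon
allocation.

## Soil water flow

The mixed-form Richards equation is discretised with node-centred finite
volumes on the structured mesh (equivalent to mass-lumped bilinear FEM):
five-point stencil, face conductivity the arithmetic mean of the nodal
conductivities, no-flux boundaries arising naturally. Nodal material
assignment uses the element whose lower-left corner is the node (clamped
at boundaries); at an obstacle interface this biases one row of nodes to
one material, which is immaterial at the mesh sizes used. The elemental
sink is lumped equally onto the four corner nodes, so the discrete
balance "storage change = −sink volume + boundary inflow" holds exactly.

Each implicit substep runs the modified Picard iteration (storage
expanded to first order around the previous iterate), solved sparsely,
with convergence at max|Δh| < 1e−6 cm and at most 50 iterations.
Failures halve the substep down to ΔT/64 before raising a diagnostic
error. Near saturation the moisture capacity vanishes and the linear
system approaches singularity; an iterate whose magnitude exceeds 1e8 cm
is treated as divergence and triggers the same substep halving. The pore
connectivity exponent is not part of the substrate parameter table and
defaults to the Mualem value l = 0.5 (configurable).

Two boundary regimes are supported, reflecting the two physical setups:
fully undrained with a hydrostatic initial condition (water table at the
bottom, the petri-dish scenario), and the same walls with the bottom row
of nodes held at h = 0 (the rhizobox scenario, where agar sits on a
maintained water table). The thin rhizobox slab (4.8 × 6.8 × 0.08 cm)
stores only ≈0.9 cm³ of drainable water while the collar withdraws
0.2 cm³/day, so multi-day obstacle runs are only physically sustainable
with the replenishing bottom boundary; the obstacle scenario enables it
by default.

## Xylem hydraulics

The root network is a resistor tree in the Doussan sense: one node at
the collar and one at each segment's distal end, axial conductance
K_x/l per segment and radial conductance 2πr·L_r·l lumped at the distal
node. K_x = 4.32e−2 cm³/day and L_r = 1.73e−4 cm/day per unit length,
uniform across orders; the root radius is not part of the parameter
table and defaults to 0.03 cm. Summing the nodal balances shows the
total radial uptake equals the collar flux identically, which the tests
assert to 1e−8 relative. Soil heads are sampled at segment midpoints by
bilinear interpolation; segment geometry is clipped against the element
grid once per segment (cached) so the sink assembly is a scatter-add.
Coupling is by sequential operator splitting with one outer pass per
architecture step.

## Growth rules

Elongation-versus-age tables are linearly interpolated and clamped: axes
decline from 2.0 to 0.5 cm/day over the first 3.5 days and stay constant
after; laterals elongate at a constant 0.5 cm/day. These magnitudes are
a realistic choice for wheat seminal roots on agar; the declining-axes /
constant-laterals shape is the observed pattern. Five axes emerge over
1.5 d at alternating insertion orientations (0°, ±30°, ±55° from
vertical).

The penetration resistance R is evaluated per element from the
element-mean head (with the product |ψ|·Se clamped at 1e−6 to keep the
logarithm finite at saturation) and the element material's bulk density
(substrate 1.2 g/cm³, obstacles 1.4 g/cm³). R at a tip is the value of
the containing element; ∇R is the central-difference gradient of the
element-centre field interpolated at the tip, zeroed below 1e−9 kPa/cm.
The direction rule normalises

    w_hist · rotate(d_old, δ_sample) + W_g·g + W_r·u,

with u the **unit** vector opposite ∇R — growing into stiffer substrate
would contradict the observed obstacle avoidance — and w_hist = 1
outside recovery. The random deviation δ_sample is uniform on [−δ, +δ]
and is drawn once per tip per step from the single run generator.
Newborn tips (axes and laterals alike) take their first step along their
scheduled emergence or insertion direction, so the branching angle is
encoded exactly in the stored geometry and can be measured back from any
RSML export.

Branching: a primordium at arc s_j = j·spacing initiates when the parent
tip passes the previous site s_{j−1} (the root's own germination for
j = 1) and germinates tip_delay days later, provided the tip has already
passed s_j itself. Under this rule the first lateral of an axis
germinates exactly tip_delay after the axis — the way the tip delay is
defined as a morphological trait — while consecutive laterals are
additionally staggered by the spacing traversal time, and a branch point
created at t always activates at t + tip_delay. Insertion sides
alternate (+, −, …) at ±32.55°; child order is capped at max_order
(default 3).

## Obstacles

Obstacles are inclined rectangles rasterised onto the mesh by the
element-centroid rule and assigned ρ_b = 1.4 g/cm³, K_s = 5 cm/day
(stiff, quasi-impermeable, but mild enough not to destabilise the flow
solver). Their influence on growth has two layers:

* the resistance gradient of the stiff region deflects approaching tips
  (full W_r weight, since u is a unit vector), and hard collision
  clamping guarantees no segment endpoint ever enters the polygon;
* the contact phase machine. Contact is declared when the tip is within
  a threshold of the obstacle boundary. Because the elemental R field
  smears the obstacle edge over one to two elements — tips ride that
  halo at a standoff of about an element — the default threshold is
  resolution-linked: max(root radius, 1.5 × the largest element edge),
  configurable. During contact W_g is forced to 1, δ is ignored, and a
  step that would enter the polygon is projected onto the nearest edge
  tangent (sense preserving forward motion, falling back to the gravity
  component for a dead-normal approach). The mean unit step direction
  d̄ is accumulated over the episode. On contact loss at t₁ the machine
  computes t₂ = t₁ + κ(t₁ − t₀) and the direction rule's history term
  becomes W_o(t)·d̄ on the first recovery step and W_o(t)·d_old after,
  with W_o falling linearly from W_oi (default 5) to 0. Re-contact
  cancels recovery and opens a new episode. W_r stays active during
  contact (it reinforces exclusion); a tip reaching the domain boundary
  is halted wherever it is in the cycle.

Laterals interact with obstacles exactly as axes do.

## Network indices and calibration

Foraging area is the convex-hull area of an axis group's node
coordinates (the hull is the natural formalisation of "explored area"
for a planar tracing); area and branching density are evaluated on the
first two axes, the ones that develop laterals. The architecture reduces
to a weighted undirected tree over seed, junctions and tips for node
connectivity and betweenness centrality; betweenness uses the standard
pair normalisation 2/((n−1)(n−2)) with edge weights as distances and is
averaged over nodes. The Steiner reference length is the Euclidean MST
over {seed} ∪ tips — the classical 2-approximation (2/√3 in the plane)
of the Steiner minimal tree; the exact Steiner tree is out of scope and
the approximation is labelled as such. β(t) is measured from the
instantaneous tip direction, folded into [0°, 90°] from horizontal.

Calibration follows the two-stage order of the original workflow: tip
delay against total length first (the only free parameter affecting it),
then (W_g, W_r, δ) against foraging area and branching density, then
(κ, W_oi) against episode durations and β trajectories. Index errors
are combined with equal weight after normalising each series by the RMS
of its target (the weighting is otherwise unconstrained); grid-search
ties resolve to the first point in grid order and are reported.
`grid_search_fit`/`fit_w_oi` take any `simulator(params, seed)`
callable; the shipped surrogates in `fixtures` emulate the branching
arithmetic and the direction-update kinematics without the soil solve,
which keeps a full sweep in milliseconds. κ is the least-squares
through-origin slope of recovery versus contact duration.

## Synthetic data generator

`fixtures.generate_fixture` emulates the statistical structure of the
experimental tracings: elongation-versus-age tables (declining axes,
constant laterals) with optional multiplicative Gaussian noise; contact
episodes with uniform contact durations and recovery = κ × contact (plus
noise); β(t) trajectories with a plateau at the obstacle inclination
followed by the W_o-driven recovery; and index time series from the
kinematic surrogate. It does **not** reproduce inter-replicate genetic
variability, root withering, image-digitisation error structure, or any
3D effect — so passing closed-loop recovery tests demonstrates the
calibration machinery is self-consistent, not that the trait values are
field-accurate.

## Numerical choices and problem sizes

Default meshes: 40 × 40 elements for the 10 × 10 cm petri scenario,
32 × 45 (0.15 cm elements) for the 4.8 × 6.8 cm rhizobox; the test suite
runs the same scenarios at 30 × 30 and the default rhizobox mesh, and the
acceptance script uses 40 × 40 for the petri runs. A six-day coupled run
takes a few seconds on one CPU. Determinism: all randomness flows from
one `numpy` generator seeded per run; with δ = 0 the obstacle scenario
is exactly reproducible regardless of seed. Degenerate inputs are
contracts, not accidents: empty axis schedules grow nothing, a zero
horizon returns the initial state, a singular xylem system (all radial
conductances zero) and cyclic parent links raise typed errors.

## Known limitations

* The pseudo-2D slab cannot capture out-of-plane root escape around
  obstacles.
* The unit-vector resistance term makes tips respond to the direction
  of ∇R but not its magnitude; faint ambient gradients steer as strongly
  as obstacle walls. The contact threshold choice compensates near
  obstacles.
* The contact standoff (and hence t₀, t₁) inherits an element-scale
  resolution dependence.
* Betweenness normalisation conventions differ across tools; ours is
  documented above and asserted in tests, but absolute values are only
  comparable within that convention.
* The elongation tables and axis schedule are package defaults standing
  in for figure-only experimental data; users with their own tracings
  should supply measured tables via the run configuration.
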