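# Methods

## Model

The package simulates a confluent epithelial monolayer as a collection of
cell-centre particles in the plane.  The tissue geometry is the Voronoi
tessellation of the cell centres, obtained through its dual Delaunay
triangulation: every Voronoi vertex (meeting point of three cells) is the
circumcenter of a Delaunay triangle.  The mechanical energy is the vertex
model,

    E = Σ_i K_i/2 (A_i − A0_i)²  +  Σ_i Γ_i/2 P_i²  +  Σ_i Σ_{e∈∂i} Λ_e l_e ,

with per-cell area modulus K_i, perimeter modulus Γ_i, native area A0_i, and
junction tension Λ_e looked up from the pair of cell types across each
junction (the reserved type `M` stands for the boundary).  Accumulating the
tension per cell side counts interior–interior junctions twice, which makes
the uniform-tension model identical to the preferred-perimeter form
Γ/2 (P − P0)² with P0 = −Λ/Γ up to the constant Λ²/(2Γ) per cell.  The
dimensionless shape factor p0 = P0/√A0 is the control parameter of the
solid–liquid transition; regular hexagons, pentagons, squares and triangles
have p0 = 3.722, 3.812, 4.000 and 4.559, and the fluidisation onset sits at
the pentagon value.

Forces on cell centres are the exact negative gradient of E.  The energy is
naturally a function of the Voronoi vertices; the chain rule runs through
the analytic Jacobian of each circumcenter with respect to its three
Delaunay sites (closed form obtained by differentiating the standard
determinant formula, computed in centroid-relative coordinates).  Because
each vertex depends on three sites, the force is local but *not* pairwise.
A harmonic soft core between Delaunay-adjacent cell centres,
E = k_core/2 (a − r)² for r < a, stabilises the dense and high-p0 regimes;
its range a = 1 is the unit of length, K = 1 the unit of energy density,
and γ/(K a²) the unit of time.

Dynamics is overdamped Euler–Maruyama:

    γ   dr_i/dt = f_a n_i + F_i + ν_i(t),      ⟨ν ν⟩ = 2D δ,
    γ_r dθ_i/dt = τ_i + ν_i^r(t),              ⟨ν^r ν^r⟩ = 2D_r δ,

with self-propulsion f_a along the polarity n_i = (cos θ_i, sin θ_i) and
free-cell speed v0 = f_a/γ.  The polarity decorrelation time is
τ_r = γ_r/(2 D_r); configuration files expose τ_r⁻¹ and map it to
D_r = τ_r⁻¹/2.  Torques come from three optional alignment mechanisms
(additive when combined): neighbour polarity (Vicsek-like,
τ = J_p Σ_j sin(θ_j − θ_i)), the normalised previous-step velocity
(τ = J_v sin(θ_v − θ_i); the zero-velocity limit is zero torque), and the
principal axis of the cell shape tensor built from coordinate differences
of consecutive polygon vertices (nematic coupling: the eigenvector sign is
chosen so n·p ≥ 0 each step, avoiding spurious π flips).

After every step the Delaunay property is restored by equiangulation: any
interior edge whose opposite angles sum to more than 180° is flipped (FIFO
queue seeded with the violated edges; a flip re-queues the four quadrilateral
edges).  A flip exchanges exactly one Voronoi junction and is the model's T1
event; flips whose four sites are all interior cells are logged as T1s.  The
duality makes the junction length shrink continuously to zero at the
cocircular configuration and reopen smoothly — no length cut-off is needed.
Cocircular ties (incircle determinant within 1e−12 of the natural scale) are
not flipped, preventing flip oscillation.

## Boundaries

The tissue edge is a line of ghost particles with fixed connectivity: each
ghost has exactly two neighbours, loops are simple polygons, and the loop
count never changes (no tissue splitting or hole formation).  Ghosts own no
cell but bound the rim cells' polygons, and feel the resulting vertex-model
forces plus a line tension ½λ(l − l0)² per edge and bending energy
½ζ(θ − π)² per site.  In `fixed` mode they are clamped; in `free` mode they
move under passive forces only — never activity or noise, so the boundary
cannot diffuse independently of the tissue.  Edges longer than l_max = 2 l0
are split at their midpoint and edges shorter than l_min = l0/2 contracted
(defaults chosen to keep the ghost spacing commensurate with the cell size);
proposals that would break simplicity are rejected.  A topology guard
verifies all invariants every step and aborts the run on violation.  The
run is flagged unstable when the boundary length exceeds 1.05× its running
minimum; the first such time is τ_inst.

## Population dynamics

Native areas compound as A0 ← (1 + η dt) A0 and ages advance by dt each
step.  Every `check_every` steps (default 25) each cell divides with
probability min(χ (A − A_c) Δt, 1) over the true elapsed interval Δt, so χ
is independent of the time step; A_c = 2.8 a².  Daughters are placed at
± daughter_offset/2 (default 0.25 a) along the mother's polarity, inherit
half her native area each (conserving target area through division, a
package choice), and restart at age zero.  Cells reaching max_age are
removed instantly (disabled by default).  Every division or death triggers
a full Delaunay rebuild.  η and χ have no canonical published values; the
defaults used in the test protocols (η = 0.05, χ = 0.1) were chosen so a
37-cell patch completes several doubling epochs within a desk-scale run.

## Observables

The self-intermediate scattering function F(q, t) = ⟨exp(i q·Δr)⟩ is
averaged over interior cells, 8 equally spaced q directions and ≥10 time
origins at q = 2π/a; τ_α is the first, linearly interpolated, crossing of
½ (reported as run_length × 10 with a censoring flag when it never
crosses).  Cells created or destroyed inside an averaging window are
excluded.  The per-cell stress is a virial built from scalar edge tensions
t_e = ∂E/∂l_e on the two edge networks: junction edges carry the perimeter
and tension derivatives, Delaunay edges the area-term derivative through
the exact kite decomposition A_i = Σ_e l_junction l_delaunay/4 of a Voronoi
cell; σ_i = (1/A_i) Σ t_e l_e ê⊗ê over cell i's own contributions, so the
area-weighted mean reproduces the global virial.  Pressure is −½ tr σ with
**compression positive** (tensile networks give negative pressure).  The
decomposition assumes the generic case where circumcenters straddle their
dual edges; strongly degenerate polygons can misattribute kite signs.  A
run is classified solid (no T1 and censored τ_α), unstable (finite τ_inst)
or liquid.

## Initial conditions

Packings mimic an evenly spaced, off-lattice confluent monolayer: soft
disks with radii uniform in 1 ± polydispersity (default 10%) are minimised
(L-BFGS on the overlap + wall energy) in a disk, annulus, rectangle strips
or cavity at packing fraction φ = 1, ghosts are strung on the rim at
spacing l0, and all coordinates are rescaled once so that the mean Voronoi
cell area equals A0 = π exactly.  `relax` drives any tissue to a local
energy minimum (L-BFGS followed by a gradient-only descent polish, since
line searches stall at the energy-difference rounding floor) — this is the
canonical "relaxed state" used before production runs.

## Numerical choices

dt defaults to 0.01 (0.005 for growth runs, 0.025 for slow solid-phase
scans), matching the stable range for these stiffnesses; a per-step
displacement above 0.5 a raises a step-size error.  The run loop treats
such an error during a production run as a transient (typically a fresh
division in a crowded region) and re-integrates that single step as 50
sub-steps at dt/50 before giving up.  Triangles are kept
in a canonical (rotation + lexicographic) order after every rebuild or flip
pass so that force accumulation order — and hence the trajectory — is
bit-reproducible for a given seed, including across snapshot restarts.  If
a flip cascade fails to converge or the cell complex cannot be walked (a
corrupted mesh after an extreme local move), the triangulation is rebuilt
from scratch; T1 bookkeeping for that single step is lost.  All randomness
flows through one seeded generator whose state is saved alongside each
trajectory.

## What the synthetic protocols do and do not show

The test suite validates the machinery on scaled-down versions of the
canonical experiments: a fluidisation scan at N = 100 (onset of T1 activity
at p0 ≈ 3.8), two-type sorting at N = 64 with noise D = 0.05 (the noise
amplitude has no canonical value; it was chosen strong enough to drive
junction exchanges at these tensions yet small against the junction energy
scale), growth of 37-cell patches, and an open-vs-fixed boundary comparison
at N = 80 asserting the direction of the effect (open boundaries
decorrelate faster).  Growth is checked two ways: freely expanding patches
(an ensemble of three seeds, since log N(t) of a ~40-cell patch carries
Poisson counting noise) show log-linear early growth, a centre-peaked
pressure profile and a bulk neighbour distribution with mode six; a
clamped-rim run with a reduced critical area A_c = 1.4 shows division
halting once crowding pushes cell areas below A_c.  (A fixed rim does not
pin the total Voronoi area — at p0 = 3.10 cells contract away from the
ghosts and settle near area 2.8, so the growth-study A_c = 2.8 produces no
divisions at all in this scaled-down geometry.)  These runs establish the
model's qualitative phase structure and exact force/stress consistency;
they do not reproduce hour-scale quantities such as relaxation times of
N = 1000 tissues or absolute grown-patch cell counts (the division
constant χ has no published value).  Real epithelia additionally feature curved junctions, cell-cell
friction, mechanosensitive division and death, and biochemical coupling,
none of which are modelled.

## Limitations

Planar, non-periodic geometry only; boundary topology is immutable; the
quasi-2D assumption ignores apical-basal structure; Euler–Maruyama is first
order, so very stiff parameter sets need small dt; the virial stress is
per-cell only (no coarse-grained continuum fields).
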