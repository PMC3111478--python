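# Methods

`cytosolkit` builds simplified models of the bacterial cytosol — a crowded
aqueous solution of metabolites, monatomic ions and (optionally) small
proteins — and analyses molecular trajectories of such systems for
structure, transport and electrostatics. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
validation does and does not demonstrate.

## Units and constants

Internal units are Å, ps, elementary charge e and kelvin. Reported
quantities are converted only at the output boundary: diffusion
coefficients in Å²/ps and in 10⁻⁵ cm²/s (1 Å²/ps = 10 × 10⁻⁵ cm²/s),
conductivity in S/m, dielectric constants dimensionless in units of the
vacuum permittivity ε₀. CODATA 2018 values of e, k_B, N_A and ε₀ live in
one constants table (`cytosolkit.constants`); every prefactor is derived
from them, never typed in twice.

Only orthorhombic periodic cells are supported (the model boxes are cubic);
triclinic input is rejected with an explicit error. Barostat volume
fluctuations are accommodated by storing a cell per frame and using the
mean cell volume in fluctuation and Helfand prefactors.

## Box construction

A composition table lists species with concentration c (mol/L), net charge
(e) and an effective packing radius (Å). For a box of volume V the count of
a species is round(c·N_A·V). Species whose expectation falls below 0.5
molecules are not automatically included; they form a rare-species pool.
Because the omitted tail is a real part of the total metabolite
concentration (~0.28 M in exponentially growing *E. coli* versus ~0.23 M
from the automatically included species), the builder tops the total up to
a target concentration by repeatedly drawing one rare species with
probability proportional to its concentration, until the implied total
first reaches the target.

Neutralization adds putrescine (28 mM, 2+), Mg²⁺ (40 mM) and K⁺ (290 mM).
Putrescine and Mg²⁺ counts come straight from their concentrations; K⁺ is
then adjusted by the minimal integer change that makes the box exactly
neutral. This is a documented policy choice: K⁺ is the most appropriate
slack variable because it is the dominant osmolyte and the most weakly
bound cation. A system whose metabolites are net positive cannot be
neutralized (there are no mobile anions in the model) and is an error.

Packing treats every molecule as a buffered sphere. Spheres are inserted
sequentially in descending radius order (large first — the insertion order
is otherwise free, and descending radius packs measurably better) by
trialling uniform random positions until one clears every placed sphere by
r_i + r_j + buffer (default buffer 1 Å, default 10⁵ trials per sphere).
The clash test uses the minimum-image convention so the configuration is
valid under periodicity; a `wall` mode that instead keeps spheres off the
box faces is available as a config switch. The initial configuration
therefore has no molecular contacts at all. Validity is verifiable by an
independent O(N²) minimum-image distance check (`verify_packing`), which
the tests run on every seeded build. When a species has an atomic
structure, its packing radius defaults to half its maximum interatomic
distance plus 2 Å; structures are dropped onto sphere centers unrotated
(rotational clash search is out of scope).

## Diffusion

Diffusion coefficients come from the Einstein relation: the slope of the
mean-squared displacement over lag time equals 2·N_dim·D in the diffusive
regime. MSD curves are averaged over all molecules of a species and over
replica time origins spaced 50 ps apart (a stride that is not a whole
number of 4 ps frames is rounded to the nearest frame count). Molecule
displacement uses the center of mass of unwrapped coordinates; an
atom-averaged mode is available behind a flag since the two differ for
flexible molecules. The default fit window is 100–2000 ps; a 1000–3000 ps
window is equally supported, as both appear in practice and the choice is
material only when the MSD bends at long lags.

Per-species standard errors are the spread over copies of the same
molecule: D is fitted per copy, the SE is the sample SD over √n, and
single-copy species report no SE. Lateral diffusion uses 2-D fits on the
xy, xz and yz coordinate planes, with their mean reported as the lateral
value. Sub-trajectory (windowed) re-fits support stationarity checks.

The velocity-autocorrelation route is deliberately not implemented (worse
convergence, requires stored velocities), and no finite-size (periodic
self-interaction) correction is applied to D.

## SASA and contact

SASA is computed by Shrake–Rupley point sampling: 960 deterministic
Fibonacci-lattice points per atom on the accessible sphere (van der Waals
radius + probe, probe 1.4 Å, Bondi element radii by default), a point
being accessible unless it falls inside the accessible sphere of an
occluding atom. The occluder context is an explicit selection, which is
the operation the contact analyses need: excluded (contact) area of a
molecule = SASA computed in isolation − SASA computed with every other
non-water molecule occluding. Water never occludes. The implementation's
contract is numerical agreement with closed forms: a single atom is exact
to rounding, and a two-sphere overlap matches the analytic spherical-cap
union within 0.1% at default resolution (the tests also cross-check a
multi-atom cluster against an independent Shrake–Rupley implementation).
Occlusion is minimum-image when a periodic cell is given.

A molecule is **in contact** in a frame iff its excluded area strictly
exceeds 0.48 Ų — the average excluded area observed when two hydrogen
bonds are present, adopted here as a fixed calibration constant (the
calibration itself is not re-derived; a value exactly at the threshold is
free). Maximal runs of contact frames are contact events; maximal runs of
non-contact frames are full-solvation events; the two tile the frame axis
exactly, and durations are run length × dt. Reported per molecule:
percent time in contact, average contact area, percent contact area
(average excluded / average isolated × 100), and mean/max event durations.

Per-residue protein contact profiles use the same subtraction with the
environment restricted to metabolites (not other protein copies), each
residue's excluded area reported as a percentage of its average isolated
SASA and ranked. The total-SASA trace sums non-water SASA per frame, with
a trailing running average (2 ns default window) and a percent-loss figure
comparing the initial running average against the final plateau.

Mg²⁺ coordination ("ionic bonds") is an invented operational criterion —
an O or N atom with partial charge ≤ −0.3 e within 3.0 Å of the Mg center
— standing in for a proper coordination analysis; it is a geometric count,
not an energetic statement.

## NIMS detection

Non-covalently interacting metabolite structures are connected components
of a per-frame contact graph over non-water molecules. Two edge criteria:
`sasa` mode (pairwise excluded SASA > 0.48 Ų, symmetrized as the mean of
the two directed excluded areas) and a cheap `distance` screen (any
interatomic minimum-image distance < 4.0 Å), whose graph is a superset of
the SASA graph at matched scales. Components are matched frame-to-frame by
maximal Jaccard overlap of their member sets (minimum 0.5; ties to the
older track; below the minimum a track dies and a new one is born), giving
birth/death frames and lifetimes. A track is protein-attached when it ever
contains a protein molecule and a bridge when a single frame's component
contains at least two proteins. All tracking thresholds are documented
choices — the phenomenon itself has no canonical quantitative definition.
π-stacking is flagged geometrically: ring-centroid distance ≤ 4.5 Å and
inter-plane angle ≤ 30° (plane normals from SVD).

## Dielectric constant and conductivity

For systems with net-charged molecules the molecular dipole depends on the
reference point, so the system dipole is decomposed into a rotational part
M_D = Σ_mol Σ_i q_i(r_i − r_com) (origin-independent per molecule) and a
translational part M_J tracking charge centers, accumulated from
charge-weighted center-of-mass displacements — i.e. the time-integrated
charge current, which avoids discontinuities from ions wandering across
images. Only net-charged molecules contribute to M_J increments.

The static dielectric constant is ε = 1 + ε_rot + ε_MJ with the cross term
omitted (almost no molecule carries both a net charge and a significant
internal dipole, so the cross term is negligible; reported contribution
columns are pure fluctuation terms and the vacuum 1 is added once):

* ε_rot = (⟨M_D²⟩ − ⟨M_D⟩²) / (3 ε₀ V k_B T), with a standard error from
  block averaging over 10 consecutive blocks;
* σ and ε_MJ from the Einstein–Helfand method: a linear regression of the
  replica-averaged MSD of M_J over a lag window gives
  σ = slope/(6 V k_B T) and ε_MJ = intercept/(3 ε₀ V k_B T), with σ's SE
  propagated from the regression slope SE. The conventional window is
  100–500 ps (100–300 ps for the smallest systems). The analysis needs
  densely stored frames; a window whose lower edge is below 10·dt is
  refused with an explanatory error. An all-neutral system returns σ = 0
  with a zero-variance warning rather than an error.

## Synthetic data: what it emulates, and what it does not

Every estimator is validated against generators with known ground truth:

* **Brownian gas** — independent particles with Gaussian increments of
  per-dimension variance 2·D·dt; retains the raw unwrapped path, so
  unwrapping is checked bit-for-bit against truth. Charged species make an
  ideal charge gas whose conductivity is exactly Nernst–Einstein
  σ = Σq²D/(V k_B T) — the oracle for the Helfand estimator.
* **Dipole gas** — N rigid dipoles of magnitude μ with orientations
  resampled uniformly per frame. This deliberately has no angular
  autocorrelation: the static ε_rot depends only on the stationary
  distribution (var(M_D) = N·μ²), so rotational Langevin dynamics would
  add cost without adding validity for the static estimator.
* **Cluster configurations and hand timelines** — constructed ground truth
  for component detection, tracking and event segmentation.

These generators contain no interparticle forces, no hydrodynamics, no
solvent and no real molecular geometry. Passing them shows the estimators
are unbiased and correctly unit-converted on their ideal inputs; it says
nothing about force-field adequacy, sampling convergence of real ~100 ns
trajectories, or the physical values of cytosolic ε, σ or D, which require
actual molecular-dynamics input.

## Problem sizes used in validation

The shipped validation runs use 100-molecule Brownian ensembles of 5·10⁴
frames (4 ps cadence) for diffusion, a 200-ion gas of 4–6·10⁴ frames
(0.5 ps cadence) for conductivity, 1000 dipoles over 10⁴ frames for
ε_rot, and 200-sphere packings. At these sizes the diffusion estimate is
within ~1% of truth, the Helfand σ within a few percent of Nernst–Einstein,
and ε_rot within ~1% of the stationary value — comfortably inside the 5%
and 10% acceptance bands the estimators are held to.

## Known limitations

* Sphere-proxy packing ignores molecular shape and orientation.
* The 0.48 Ų contact threshold is adopted, not re-calibrated; it encodes a
  hydrogen-bond-scale criterion and silently includes π-contacts.
* The unwrapping assumption (no particle moves half a box edge between
  stored frames) is not detectable from wrapped input alone; violating it
  with too-sparse sampling silently corrupts displacements.
* ε_MJ uses the fit-intercept convention; on short trajectories of strongly
  subdiffusive charge carriers the intercept is a biased estimate of the
  M_J variance.
* No finite-size corrections to D or σ.
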