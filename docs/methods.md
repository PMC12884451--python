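# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `quadhop`, and what the synthetic-data generators
do and do not emulate.

## System and conventions

The system is a four-indole tryptophan quadruplex at a protein–protein
interface: residues 124 and 122 on each of two chains (A and D). Site
labels are residue number + chain ("124A"); oxidized states append "+"
("124A+"). The six inter-site separations split into *sides*
(intramolecular 124A–122A, 122D–124D), *edges* (interfacial 124A–122D,
122A–124D) and *diagonals* (122D–122A short, 124A–124D long).

Every distance in the package is the **minimum over all cross pairs of
C/N side-chain heavy atoms** (CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3,
CH2), hydrogens and backbone (including CB) disregarded. A single
convention is used everywhere — structural maps, frame filters, water
assignment, cluster linkage — so numbers are comparable across modules.
Distances are computed at full precision; comparisons against printed
crystallographic values use 0.1 Å rounding (one printed decimal).

No periodic-boundary imaging is applied: the analysis region is a compact
interface and inputs are expected unwrapped. This is a documented
limitation for periodic trajectories.

## Classifiers

* **Re in/out conformer**: the dmp–indole shortest-distance distributions
  peak at 3–4 Å ("in") and 5–6 Å ("out"); the package cutoff is the
  midpoint, 4.5 Å, strict less-than, configurable.
* **Quadruplex shape**: a side is "short" below 4.0 Å (the same bound the
  frame-selection filter uses); rhombic iff both sides short, trapezoidal
  otherwise, with both-long frames labeled by the shorter/longer ordering
  and flagged `both_long`.
* **Multi-model PDB**: model index = frame index (0-based internally,
  1-based in files). Crystal altlocs: keep the highest-occupancy
  conformer; ties resolve to altloc 'A'.

## Hydration analysis

Waters are represented by their oxygen positions throughout (the analyses
in scope measure water-oxygen structure). *Exclusive* coordination
assigns each water to its single closest indole before counting — in
whole-indole mode (min over the 9 ring atoms) or NH mode (distance to
NE1); both are provided because the assignment rule behind published
coordination figures is ambiguous between them. Ties resolve to the fixed
site order 124A, 122A, 122D, 124D. Aggregate "quadruplex hydration"
sums per-site exclusive counts at r = 3.5 Å.

Density maps are computed on a regular lattice (default spacing 0.1 Å)
after least-squares (Kabsch) superposition of every frame onto the first
frame's quadruplex heavy atoms; the fit set is the four indoles because
the average quadruplex geometry is state-independent to good accuracy.
Voxel values are molecules/Å³ per frame. A Gaussian kernel of bandwidth
**0.4 Å** (default, configurable) is applied: with a few hundred frames
per state, raw 0.1 Å voxel counts are shot-noise dominated (a single
count in one voxel corresponds to ~2 molecules/Å³ at 500 frames), while a
0.4 Å kernel suppresses voxel noise to well below the isocontour
threshold yet still resolves 0.1–0.2 Å density displacements. The
difference map Δρ = ρ_final − ρ_initial is thresholded at ±2.5ρ₀
(ρ₀ = 0.0334 molecules/Å³, bulk water at 298 K; the isocontour factor,
mask radius 4 Å around NE1 and spacing are all exposed). Connected
regions use 26-neighbor voxel connectivity; regions smaller than 0.01 Å³
are discarded as residual shot noise. Both bandwidth and minimum region
volume were fixed from this noise analysis, not fitted to data.

Water-shift quantification: the frame-route estimator averages the
position of the water nearest the site's NE1 over each state block (after
superposition) and projects the displacement of that mean onto the unit
vector toward NE1 (positive = toward the site). This estimator is exact
for quasi-structural waters. The grid-route estimator (centroid of the
density peak nearest the site within a 1 Å window) is provided for
map-only inputs; the fixed window truncates the displaced distribution,
biasing the magnitude low by ~20 % at 0.15 Å shifts — it agrees in sign
and scale but the frame route is preferred when frames are available.

g(r) uses the standard shell-volume normalization to ρ₀.

## Hole-state analysis

Charge/spin series carry six fragments (four indoles, dmpA, Re(CO)₃);
per-frame sums must be constant within 10⁻³ (asserted on ingest).
*Localized* means the dominant indole's mean charge is ≥ 0.9 of the total
indole hole charge; the 0.9 fraction operationalizes a "≥90 % localized"
criterion stated without a formula, and is configurable.
*Delocalization episodes* are maximal intervals where a non-dominant
indole holds ≥ 0.2 e for ≥ 5 fs; the 0.2 e threshold is a package
convention (no quantitative definition of "partial delocalization"
exists for this system) and is echoed in all outputs. *Complete
transfers* are dominant-site changes persisting ≥ 50 fs (or to the end of
the series); an excursion undone by back-transfer within the window — the
characteristic ~30 fs back-transfer — is not counted. Durations come from
timestamps, so non-uniform cadence is supported.

## Energetics

Potentials are vacuum Coulomb sums ϕ = Σ q·K/r with K = 14.3996 V·Å/e, no
cutoff, no reaction field — appropriate for finite snapshot environments,
a documented limitation for periodic inputs. ϕ at an indole is the
unweighted mean over its 9 C/N atoms (the evaluation point behind
published indole potentials is not stated; NE1-only is a flag). Particles
closer than 0.5 Å to an evaluation atom raise an error, catching
environments that accidentally include the evaluated indole itself.
Δϕ = ϕ(oxidized) − ϕ(neutral) is positive when transfer toward the
neutral indole is favored. Units: potentials in V, energies in meV
(1 e·V = 1000 meV), conversions centralized in `quadhop.constants`.

Free energies use the **two-ensemble linear-response estimator** on
vertical gaps ΔE = E(product) − E(reactant):
ΔG = (⟨ΔE⟩_A + ⟨ΔE⟩_B)/2, λ = (⟨ΔE⟩_A − ⟨ΔE⟩_B)/2. The estimator behind
the published table is cited without a formula; the two-ensemble average
is the standard Marcus-picture choice consistent with how λ is used for
this system, and the estimator name is recorded in every result.
Uncertainties come from a block bootstrap (20 blocks, 200 resamples by
default). A non-positive λ estimate is flagged as inconsistent ensembles
(warning, not error).

The 4×4 step table is checked for antisymmetry and for 3-cycle closure;
the package **reports** residuals without judging them, because ensemble
tables assembled from separate trajectories per step carry genuine cycle
residuals (the bundled table's largest 3-cycle residual is −230 meV;
124A→122A→122D→124A closes at +91 meV).

## Hopping network

Marcus rates: k = (2π/ħ)·H_ab²·(4πλk_BT)^(−1/2)·exp(−(ΔG+λ)²/4λk_BT),
with λ = 800 meV and T = 298 K defaults (k_BT = 25.68 meV from CODATA
k_B; constants centralized). Feasibility presets: the default
`scheme2` thresholds are strict ΔG < +70 meV and H_ab > 0.2 meV; a
`loose` preset (ΔG ≤ +100 meV) is also shipped because both bounds
circulate for this system — neither is privileged beyond the default.

Couplings are directional (medians differ by direction), so exact
detailed balance holds only in symmetric-coupling mode, which replaces
each pair by the **geometric mean** of the two directional medians (rates
scale with H², so this gives the geometric-mean rate pair); asymmetric
mode reports its balance residual.

The master equation dp/dt = K·p is solved by matrix exponential (4-node
scale); the stationary state comes from the null space of K with a
10⁻¹² residual check. Because the bundled ΔG table is cycle-inconsistent,
its raw rate network is a *driven* system: the stationary state is not
Boltzmann of any potential, and its ordering among the minor states is an
artifact of which row dominates the exchange (the raw network puts the
least stationary population on 124A+, not on the thermodynamically least
stable state). For stationarity statements the package therefore offers
`cycle_consistent=True`, which projects the ΔG table onto its
least-squares node free-energy landscape (for the bundled table:
124A 0, 122A +66, 122D −239.75, 124D +92.75 meV relative to 124A; max
per-edge projection shift 80.25 meV, recorded in the network metadata)
before computing rates; feasibility flags always keep the raw values.
On that landscape the stationary distribution is exactly Boltzmann:
maximal at 122D+ and minimal at 124D+, the dead-end state.

The adiabaticity index κ = 2πH_ab²/(ħν_eff·(4πλk_BT)^(1/2)) with
(ν_eff)⁻¹ = 100 fs default is a Landau–Zener-type package convention
(no specific formula is fixed by the source discussion); κ ≥ 1 classifies
a step as adiabatic. For H_ab = 31 meV, λ = 800 meV, 298 K: κ ≈ 1.8.

## Cluster mining

Nodes are Trp residues of the first model (highest-occupancy altlocs);
edges link pairs with minimal indole C/N distance ≤ 10 Å (inclusive, per
"within"); clusters are connected components of size ≥ 2 by default,
smaller components reported as diagnostics. Whether published searches
used indole-minimum, Cβ–Cβ or centroid distances is not stated; the
default is the package-wide indole minimum, with centroid and NH metrics
exposed. Classification: intramolecular (one chain) vs interfacial;
interfacial + exactly two chains = dimer link. The tight-quadruplex test
requires all six pairwise minima strictly below 5 Å. Size histograms are
reported per cluster and per structure id. Biological-assembly expansion,
X-ray-only filtering and <90 % sequence-identity deduplication are the
caller's responsibility via a pre-filtered id list.

## Synthetic data

Generators are pure functions of (spec, seed); a single integer seed
feeds per-generator streams via
`SeedSequence(seed, spawn_key=(stream_id,))` with fixed stream ids.

* **Quadruplex**: the six target distances are embedded as four anchor
  points in 3D (classical MDS on the distance matrix; non-embeddable sets
  raise), and an idealized planar indole (regular pentagon + hexagon,
  bond length 1.39 Å, 9 heavy atoms, no CB or hydrogens) is placed at
  each anchor with its CD1 contact atom on the anchor and the ring
  extending outward from the centroid, so CD1–CD1 pairs realize the
  requested minima; the emitted structure is verified against the spec
  within 0.05 Å before being returned. The bundled
  `REFERENCE_QUAD_SPEC` uses the published crystal-interface diagonals
  (3.7 and 5.4 Å) with near-rhombic sides (3.5 Å) and short edges
  (3.9/4.0 Å); it is an idealized synthetic stand-in for the deposited
  interface, not its coordinates.
* **Trajectories**: rigid quadruplex, oxygen-only waters with fixed mean
  positions and per-frame Gaussian jitter (default σ = 0.05 Å). One
  *bridging* water sits between the NE1 groups of the hole-donor and
  hole-acceptor indoles, biased half the planted shift toward whichever
  indole currently holds the hole — mimicking the quasi-structural water
  that tracks the positive charge — so its mean moves by exactly the
  planted 0.1–0.2 Å toward the newly oxidized site on the state switch.
  Four shell waters sit 3.2 Å outside each NE1; further waters fill the
  quadruplex region randomly. Defaults (8 waters, 0.15 Å shift) represent
  the sterically restricted interfacial hydration: a handful of
  quasi-structural waters, largely disconnected from bulk.
* **Charge/spin series**: the hole (total indole charge 1.0 e) sits on
  the hot site; the residual indole charge is split 0.6/0.2/0.2 with the
  interfacial edge partner weighted highest, making hot/partner
  fluctuations anticorrelated by construction; dmpA (−0.4 e) and Re(CO)₃
  (+0.2 e) carry mutually anticorrelated fluctuations. Sums are exactly
  conserved per frame. Planted events move a charge fraction to a partner
  for a frame window; a fraction of 1.0 lasting to the series end is a
  complete transfer. Default cadence 0.5 fs.
* **Energy gaps**: Gaussian with means ΔG ± λ and variance 2λk_BT in both
  endpoint ensembles — the exact linear-response picture — so (ΔG, λ)
  recovery is well-posed.
* **Planted clusters**: Trp groups sharing one pairwise distance merge
  into a single simplex (n ≤ 4: all pairs exact) or chain (n > 4)
  arrangement; groups with different distances become separate,
  well-separated clusters. Decoys are isolated Trps ≥ 30 Å away.
  Cofactors are planted on the extreme cluster atom along a random
  outward direction so the minimal distance equals the request exactly.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: full protein scaffolds and force-field physics
(only the four indoles and waters are emitted), explicit hydrogens, bulk
solvent and exchange with it (the published system has ~38k waters; the
synthetic scale is a handful, which is deliberate — no analysis in scope
depends on system size), conformational transitions within a state block
(the quadruplex is rigid, so superposition is exact rather than
approximate), non-Gaussian gap distributions, and the broad, tailed
H_ab distributions behind the published medians. Recovery tolerances
(e.g. shift within 0.02 Å at 500 frames/state) therefore bound estimator
error, not MD sampling error.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at desk scale: 500 frames
per state for hydration (1,000-frame trajectories), 10⁴ gap samples per
ensemble for (ΔG, λ) recovery, 10³-frame charge series, 100 random
structures of 12 Trp for the mining oracle, and 10³ random Coulomb
configurations. These sizes make every stochastic check comfortably
resolvable (e.g. the ΔG standard error at 10⁴ samples is ≈1.4 meV against
a ±5 meV target) while keeping the full suite under a minute of compute.

## Known limitations

* No periodic imaging; no Ewald/reaction-field electrostatics.
* The grid-route shift estimator is biased low (~20 %) by its fixed
  window; use the frame route when frames are available.
* Episode counting is monotone in the partner threshold for unimodal
  planted events; pathological multimodal excursions could split.
* Ring-plane orientation metrics (T-stacking angles) are out of scope.
* `fetch_pdb` requires network access; nothing in the tests depends on it.
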