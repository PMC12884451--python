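# quadhop

Analysis toolkit for **hole hopping through tryptophan quadruplexes at
protein–protein interfaces**, built around the dimeric azurin construct
{Re126W124W122Cu<sup>I</sup>}<sub>2</sub> (crystal structure PDB 6MJS), in
which four tryptophan indoles — residues 124 and 122 of chains A and D —
form a quadruplex that carries electron holes both within and between the
two protein molecules.

The package is aimed at computational chemists and structural
bioinformaticians who have simulation outputs (trajectories, per-fragment
charge/spin series, energy-gap samples, point-charge snapshots) or printed
tables of step free energies ΔG and electronic couplings H<sub>ab</sub>,
and want the downstream analysis:

* **geometry** — shortest inter-indole distances (minimum over C/N heavy
  atoms, hydrogens disregarded), 2D structural maps, rhombic/trapezoidal
  shape and Re-chromophore in/out conformer classification, frame filters;
* **hydration** — exclusive water coordination numbers (each water
  assigned to its single closest indole), g(r) around the indole N–H, 3D
  water-oxygen density maps at 0.1 Å resolution and difference maps
  Δρ = ρ_final − ρ_initial with ±2.5ρ₀ isocontour regions, and
  quantification of the 0.1–0.2 Å quasi-structural water shifts that
  accompany a hole transfer;
* **holes** — hole-localization statistics (localized iff the dominant
  indole carries ≥ 90 % of the indole hole charge), delocalization
  episodes, complete-transfer detection, fluctuation anticorrelation;
* **energetics** — vacuum Coulomb potentials ϕ at indoles from tagged
  point-charge environments with component partitioning, Δϕ feasibility
  statistics, and linear-response free energies from two-ensemble energy
  gaps: ΔG = (⟨ΔE⟩_A + ⟨ΔE⟩_B)/2, λ = (⟨ΔE⟩_A − ⟨ΔE⟩_B)/2;
* **hopnet** — the 4-state hole-transfer network: feasibility thresholds
  (ΔG < +70 meV, H_ab > 0.2 meV), nonadiabatic Marcus rates
  k = (2π/ħ)·H_ab²·(4πλk_BT)^(−1/2)·exp(−(ΔG+λ)²/4λk_BT) with
  λ = 800 meV by default, master-equation populations and a Landau–Zener
  adiabaticity index;
* **mining** — PDB/mmCIF-wide tryptophan-cluster search: 10 Å linkage
  graph, connected components, intramolecular/interfacial/dimer
  classification, the all-six-pairs-below-5-Å tight-quadruplex test, and
  cofactor proximity;
* **synthetic** — generators for every input class with planted ground
  truth (quadruplex geometries, hydrated trajectories, charge/spin series,
  Gaussian energy-gap ensembles, planted cluster structures), so the whole
  pipeline is testable without downloads.

The published ΔG and H<sub>ab</sub> tables for the four oxidized
quadruplex states ship as delimited text under `quadhop/data/` with
loaders in `quadhop.datasets`.

## Worked example

Build the hopping network from the bundled tables, with symmetrized
couplings, and solve for the stationary hole populations:

```sh
$ quadhop hopnet --symmetric --out net.json
feasible edges: 7/12; sinks: ['122D+']; stationary max at 122D+ -> net.json
```

Seven of the twelve directed steps pass both feasibility thresholds; the
only state with no feasible outgoing step is 122D<sup>•+</sup>, so every
feasible hole-transfer pathway terminates there — the state from which
Cu<sup>I</sup> on chain D is subsequently oxidized. The stationary
populations written to `net.json`,

```
{'124A+': 4e-06, '122A+': 1e-05, '122D+': 0.999954, '124D+': 3.2e-05}
```

put essentially all stationary population on 122D<sup>•+</sup>, the most
stable oxidized state. The Marcus rate for the strongly downhill
interfacial step 124A<sup>•+</sup> → 122D (ΔG = −320 meV,
H_ab = 31 meV, λ = 800 meV, 298 K) is ~10<sup>12</sup> s<sup>−1</sup> on
the nonadiabatic expression — far above the observed nanosecond hopping,
consistent with transport being gated by rare structural/solvent
fluctuations rather than by the electronic factor (the adiabaticity index
for this step is κ ≈ 1.8, i.e. at least partly adiabatic).

The same analyses are available as library calls; e.g. the planted-truth
round trip for hydration:

```python
from quadhop import synthetic as syn, hydration as hyd

st = syn.gen_quadruplex(syn.REFERENCE_QUAD_SPEC)
traj = syn.gen_trajectory(st, syn.HydrationSpec(shift_magnitude=0.15, seed=1),
                          500, "122D+")
shift = hyd.measure_shift(traj.select_state("124A+"),
                          traj.select_state("122D+"), "122D")
print(f"{shift:.3f}")   # 0.150 — the planted bridging-water shift
```

## Notes

* Every inter-group distance in the package uses one convention: the
  minimum over cross pairs of C/N side-chain heavy atoms.
* The deposited 6MJS coordinates are not bundled; `quadhop.io.fetch_pdb`
  downloads structures when network access is available, and the
  geometry checks run on a synthetic idealized quadruplex built from the
  published distance targets (see `docs/methods.md`).
* See `docs/methods.md` for the model assumptions, parameter defaults,
  numerical choices, and known limitations.
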