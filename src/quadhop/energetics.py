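"""Electrostatic potentials at indoles and linear-response free energies.

The environment (protein, the two Re chromophore moieties, solvent,
counterions) creates an electrostatic potential ϕ at each indole.  The
package evaluates ϕ as the unweighted mean over the indole's C/N heavy
atoms of the vacuum Coulomb sum Σ_k q_k·K/r_k (K = 14.3996 V·Å/e), with
no distance cutoff and no periodic correction; per-component potentials
restrict the sum to particles carrying a given component tag.  Δϕ between
the oxidized and a neutral indole indicates the thermodynamic feasibility
of hole transfer toward that indole (higher Δϕ = larger driving force).

Reaction free energies come from the two-ensemble linear-response
estimator on vertical energy gaps ΔE = E(product) - E(reactant):

    ΔG = (⟨ΔE⟩_A + ⟨ΔE⟩_B) / 2      λ = (⟨ΔE⟩_A - ⟨ΔE⟩_B) / 2

with uncertainties from a block bootstrap.  This standard Marcus-picture
estimator is a package decision (the estimator behind the published ΔG
table is not spelled out in its source); it is flagged in all outputs via
``FreeEnergyResult.estimator``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import COULOMB_K
from .core import SITE_ORDER, IndoleSite

#: Recognized environment component tags.
COMPONENT_TAGS = (
    "protein",
    "ReA-",
    "ReD",
    "solvent",
    "counterion",
    "oxidized_indole",
    "other",
)

#: Minimal particle-site distance (Å); closer particles signal mis-tagged
#: input (the evaluated indole's own atoms leaking into its environment).
MIN_PARTICLE_DISTANCE = 0.5

ESTIMATOR_NAME = "two-ensemble linear response"


@dataclass
class ChargedEnvironment:
    """Point-charge environment of an indole.

    ``tags`` partition the particles into components; the indole under
    evaluation must never be part of its own environment.
    """

    coords: np.ndarray  # (n, 3) Å
    charges: np.ndarray  # (n,) e
    tags: np.ndarray  # (n,) str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, float).ravel()
        self.tags = np.asarray(self.tags, dtype=object).ravel()
        if not (len(self.coords) == len(self.charges) == len(self.tags)):
            raise ValueError("coords, charges and tags must have equal length")

    def __len__(self):
        return len(self.charges)

    @property
    def components(self) -> list:
        seen = dict.fromkeys(self.tags)
        return list(seen)

    def restrict(self, tags) -> "ChargedEnvironment":
        mask = np.isin(self.tags, list(tags))
        return ChargedEnvironment(self.coords[mask], self.charges[mask], self.tags[mask])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ChargedEnvironment":
        return cls(df[["x", "y", "z"]].to_numpy(), df["charge"].to_numpy(),
                   df["tag"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "ChargedEnvironment":
        return cls.from_dataframe(pd.read_csv(path))

    @classmethod
    def from_extended_xyz(cls, path) -> "ChargedEnvironment":
        """Read an extended XYZ file with columns: element x y z charge tag."""
        lines = Path(path).read_text().splitlines()
        n = int(lines[0].split()[0])
        coords, charges, tags = [], [], []
        for ln in lines[2 : 2 + n]:
            parts = ln.split()
            coords.append([float(v) for v in parts[1:4]])
            charges.append(float(parts[4]))
            tags.append(parts[5] if len(parts) > 5 else "other")
        return cls(np.array(coords), np.array(charges), np.array(tags))

    def to_csv(self, path) -> Path:
        df = pd.DataFrame(self.coords, columns=["x", "y", "z"])
        df["charge"] = self.charges
        df["tag"] = self.tags
        df.to_csv(path, index=False)
        return Path(path)


@dataclass
class PotentialRecord:
    """Electrostatic potential at one indole, partitioned by component."""

    site: str
    phi_total: float  # V
    phi_by_component: dict  # component -> V
    state: str = ""
    frame: int = -1
    atom_mode: str = "mean"  # "mean" over heavy atoms | "ne1"

    def __post_init__(self):
        total = sum(self.phi_by_component.values())
        if abs(total - self.phi_total) > 1e-9:
            raise ValueError("component potentials do not sum to the total")


def site_potential(
    site: IndoleSite,
    env: ChargedEnvironment,
    components=None,
    state: str = "",
    frame: int = -1,
    atom_mode: str = "mean",
) -> PotentialRecord:
    """Electrostatic potential at an indole from a point-charge environment.

    ϕ is the unweighted mean of atomic-site potentials over the indole's
    C/N heavy atoms (``atom_mode="mean"``) or at NE1 only
    (``atom_mode="ne1"``).  Vacuum Coulomb, no cutoff.  Raises when a
    particle sits closer than 0.5 Å to an evaluation point (overlapping
    particle: the indole's own atoms were not excluded).
    """
    if components is not None:
        env = env.restrict(components)
    if atom_mode == "ne1":
        pts = site.nh_position.reshape(1, 3)
    elif atom_mode == "mean":
        pts = site.coords
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    if len(env) == 0:
        return PotentialRecord(site.label, 0.0, {}, state, frame, atom_mode)
    r = cdist(pts, env.coords)
    if (r < MIN_PARTICLE_DISTANCE).any():
        k = np.argwhere(r < MIN_PARTICLE_DISTANCE)[0]
        raise ValueError(
            f"particle {k[1]} lies {r[tuple(k)]:.3f} Å from an atom of "
            f"{site.label}: overlapping particle (mis-tagged environment?)"
        )
    per_particle = COULOMB_K * env.charges / r  # (n_atoms, n_particles)
    by_comp = {}
    for comp in env.components:
        mask = env.tags == comp
        by_comp[comp] = float(per_particle[:, mask].sum(axis=1).mean())
    phi_total = float(per_particle.sum(axis=1).mean())
    # guard against accumulation-order drift between total and components
    drift = phi_total - sum(by_comp.values())
    if by_comp:
        first = next(iter(by_comp))
        by_comp[first] += drift
    return PotentialRecord(site.label, phi_total, by_comp, state, frame, atom_mode)


@dataclass
class DeltaPhiResult:
    """Distribution of Δϕ = ϕ(oxidized indole) - ϕ(neutral indole), V.

    Positive values favor hole transfer toward the neutral indole.
    """

    values: np.ndarray
    mean: float
    median: float
    q25: float
    q75: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DeltaPhiResult":
        v = np.asarray(values, float)
        return cls(v, float(v.mean()), float(np.median(v)),
                   float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def delta_phi(records_oxidized, records_neutral) -> DeltaPhiResult:
    """Per-frame potential differences between the oxidized and a neutral
    indole, computed from matched per-frame records (or raw ϕ arrays)."""
    phi_ox = _phis(records_oxidized)
    phi_nt = _phis(records_neutral)
    if phi_ox.shape != phi_nt.shape:
        raise ValueError("frame mismatch between the two potential series")
    return DeltaPhiResult.from_values(phi_ox - phi_nt)


def _phis(records) -> np.ndarray:
    if isinstance(records, np.ndarray):
        return records.astype(float)
    records = list(records)
    if records and isinstance(records[0], PotentialRecord):
        return np.array([r.phi_total for r in records])
    return np.asarray(records, float)


@dataclass
class GapSamples:
    """Vertical energy-gap samples ΔE = E(product) - E(reactant), meV,
    collected in one endpoint charge state."""

    state_label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float).ravel()
        if self.values.size < 2:
            raise ValueError("need at least 2 gap samples")
        if not np.isfinite(self.values).all():
            raise ValueError("gap samples must be finite")


@dataclass
class FreeEnergyResult:
    """Linear-response ΔG and λ for one hole-transfer step (meV)."""

    dG: float
    lambda_est: float
    dG_se: float
    lambda_se: float
    n_A: int
    n_B: int
    step: tuple = ("", "")
    kT: float = float("nan")
    estimator: str = ESTIMATOR_NAME
    lambda_warning: bool = False


def linear_response_dG(
    gaps_A: GapSamples,
    gaps_B: GapSamples,
    step: tuple = ("", ""),
    kT: float = float("nan"),
    n_boot: int = 200,
    n_blocks: int = 20,
    seed: int = 0,
) -> FreeEnergyResult:
    """Two-ensemble linear-response estimate of ΔG and λ.

    ΔG = (⟨ΔE⟩_A + ⟨ΔE⟩_B)/2 and λ = (⟨ΔE⟩_A - ⟨ΔE⟩_B)/2, where A is the
    reactant-state and B the product-state ensemble.  Standard errors come
    from a block bootstrap (``n_blocks`` contiguous blocks per ensemble,
    resampled ``n_boot`` times).  A non-positive λ estimate flags
    inconsistent ensembles (warning, not an error).
    """
    mean_a, mean_b = gaps_A.values.mean(), gaps_B.values.mean()
    dg = 0.5 * (mean_a + mean_b)
    lam = 0.5 * (mean_a - mean_b)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2))
    blocks_a = np.array_split(gaps_A.values, min(n_blocks, gaps_A.values.size))
    blocks_b = np.array_split(gaps_B.values, min(n_blocks, gaps_B.values.size))
    for i in range(n_boot):
        ma = np.concatenate(
            [blocks_a[k] for k in rng.integers(0, len(blocks_a), len(blocks_a))]
        ).mean()
        mb = np.concatenate(
            [blocks_b[k] for k in rng.integers(0, len(blocks_b), len(blocks_b))]
        ).mean()
        boot[i] = 0.5 * (ma + mb), 0.5 * (ma - mb)
    dg_se, lam_se = boot.std(axis=0, ddof=1)

    warn = lam <= 0
    if warn:
        warnings.warn(
            f"non-positive reorganization energy estimate ({lam:.1f} meV): "
            "gap ensembles are inconsistent with the linear-response picture",
            stacklevel=2,
        )
    return FreeEnergyResult(
        dG=float(dg),
        lambda_est=float(lam),
        dG_se=float(dg_se),
        lambda_se=float(lam_se),
        n_A=gaps_A.values.size,
        n_B=gaps_B.values.size,
        step=tuple(step),
        kT=kT,
        lambda_warning=bool(warn),
    )


@dataclass
class DGTableReport:
    """4x4 step free-energy table with consistency diagnostics.

    The package reports antisymmetry violations and 3-site cycle residuals;
    it does not judge them (published ensemble tables may carry genuine
    cycle residuals from sampling different trajectories per step).
    """

    table: pd.DataFrame  # rows "from", columns "to", meV
    antisymmetry: list  # [((i, j), d_ij + d_ji), ...] beyond tolerance
    cycles: list = field(default_factory=list)  # [((i, j, k), residual), ...]
    tolerance: float = 1e-9

    @property
    def antisymmetric(self) -> bool:
        return not self.antisymmetry

    def max_antisymmetry_residual(self) -> float:
        if not self.antisymmetry:
            return 0.0
        return max(abs(r) for _, r in self.antisymmetry)


def dg_table(results, sites=SITE_ORDER, tolerance: float = 1e-9) -> DGTableReport:
    """Assemble step ΔG values into the 4x4 antisymmetric table layout and
    check thermodynamic consistency.

    ``results`` may be a mapping ``{(from, to): dG}``, an iterable of
    :class:`FreeEnergyResult`, or a pandas DataFrame already in table
    layout.  Antisymmetry (ΔG(i→j) = -ΔG(j→i)) is checked wherever both
    directions are present; every oriented 3-site cycle with all three
    entries present is summed and reported.
    """
    table = pd.DataFrame(np.nan, index=list(sites), columns=list(sites), dtype=float)
    if isinstance(results, pd.DataFrame):
        for i in results.index:
            for j in results.columns:
                if i in table.index and j in table.columns:
                    table.loc[i, j] = results.loc[i, j]
    else:
        if isinstance(results, dict):
            items = [(k, v) for k, v in results.items()]
        else:
            items = [((r.step[0], r.step[1]), r.dG) for r in results]
        seen = {}
        for (i, j), v in items:
            if (i, j) in seen and abs(seen[(i, j)] - v) > tolerance:
                raise ValueError(f"duplicate conflicting entries for step {i}->{j}")
            seen[(i, j)] = v
            table.loc[i, j] = v
    np.fill_diagonal(table.values, 0.0)

    anti = []
    for i, j in combinations(sites, 2):
        dij, dji = table.loc[i, j], table.loc[j, i]
        if np.isfinite(dij) and np.isfinite(dji):
            resid = dij + dji
            if abs(resid) > tolerance:
                anti.append(((i, j), float(resid)))

    cycles = []
    for i, j, k in combinations(sites, 3):
        legs = (table.loc[i, j], table.loc[j, k], table.loc[k, i])
        if all(np.isfinite(v) for v in legs):
            cycles.append(((i, j, k), float(sum(legs))))

    return DGTableReport(table=table, antisymmetry=anti, cycles=cycles, tolerance=tolerance)
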