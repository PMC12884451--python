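"""Marcus hopping network over the four oxidized quadruplex states.

From a step free-energy table (ΔG, meV) and a directional electronic
coupling table (H_ab medians, meV) the module builds a directed 4-node
network, flags each edge as thermodynamically feasible (ΔG below a
threshold) and kinetically feasible (H_ab above a threshold), computes
nonadiabatic Marcus rates

    k = (2π/ħ) · H_ab² · (4πλk_BT)^(-1/2) · exp(-(ΔG+λ)² / 4λk_BT),

solves the master equation dp/dt = K·p for the state populations, and
evaluates a Landau-Zener-type adiabaticity parameter

    κ = 2π · H_ab² / (ħ · ν_eff · (4πλk_BT)^(1/2)),

classifying a step adiabatic when κ >= 1 (the specific κ convention is a
package decision; published discussions of adiabaticity in this system
argue from λ = 800 meV and (ν_eff)^-1 > 100 fs without fixing a formula).

Two feasibility presets are shipped: the default strict thresholds
ΔG < +70 meV and H_ab > 0.2 meV, and a looser ΔG <= +100 meV variant that
also circulates for this system; see :data:`FEASIBILITY_PRESETS`.

The coupling medians are direction-dependent, so exact detailed balance
holds only in symmetric-coupling mode (geometric mean of the two
directional medians); asymmetric mode reports its balance residual.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space

from .constants import (
    DEFAULT_LAMBDA_MEV,
    DEFAULT_TEMPERATURE,
    HBAR_MEV_FS,
    HBAR_MEV_S,
    kt_mev,
)
from .core import SITE_ORDER, site_of, state_of

#: Feasibility threshold presets: (dG_max meV with strict/loose flag, H_min meV).
FEASIBILITY_PRESETS = {
    "scheme2": {"dG_max": 70.0, "dG_strict": True, "H_min": 0.2, "H_strict": True},
    "loose": {"dG_max": 100.0, "dG_strict": False, "H_min": 0.2, "H_strict": True},
}

#: Default effective nuclear frequency period, fs.
NU_EFF_INV_FS = 100.0


def marcus_rate(h_ab, dg, lam: float = DEFAULT_LAMBDA_MEV,
                temperature: float = DEFAULT_TEMPERATURE):
    """Nonadiabatic Marcus rate in s^-1 (inputs in meV, temperature in K).

    Vectorized over ``h_ab`` and ``dg``.
    """
    if lam <= 0:
        raise ValueError("reorganization energy must be positive")
    kt = kt_mev(temperature)
    h_ab = np.asarray(h_ab, float)
    dg = np.asarray(dg, float)
    pref = (2.0 * np.pi / HBAR_MEV_S) * h_ab**2 / np.sqrt(4.0 * np.pi * lam * kt)
    k = pref * np.exp(-((dg + lam) ** 2) / (4.0 * lam * kt))
    return float(k) if k.ndim == 0 else k


def adiabaticity_index(h_ab: float, lam: float = DEFAULT_LAMBDA_MEV,
                       nu_eff_inv_fs: float = NU_EFF_INV_FS,
                       temperature: float = DEFAULT_TEMPERATURE):
    """Landau-Zener-type adiabaticity parameter κ and its classification.

    κ = 2π H_ab² / (ħ ν_eff (4πλk_BT)^{1/2}); the step is classified
    adiabatic when κ >= 1.  Returns ``(kappa, "adiabatic"|"nonadiabatic")``.
    """
    if lam <= 0 or nu_eff_inv_fs <= 0 or temperature <= 0:
        raise ValueError("lam, nu_eff_inv_fs and temperature must be positive")
    kt = kt_mev(temperature)
    nu_eff = 1.0 / nu_eff_inv_fs  # fs^-1
    kappa = 2.0 * np.pi * h_ab**2 / (HBAR_MEV_FS * nu_eff * np.sqrt(4.0 * np.pi * lam * kt))
    return float(kappa), ("adiabatic" if kappa >= 1.0 else "nonadiabatic")


@dataclass(frozen=True)
class HopEdge:
    from_state: str
    to_state: str
    dG: float  # meV
    h_ab: float  # meV (directional or symmetrized)
    rate: float  # s^-1
    feasible_thermo: bool
    feasible_kinetic: bool

    @property
    def feasible(self) -> bool:
        return self.feasible_thermo and self.feasible_kinetic


@dataclass
class HopNetwork:
    """Directed 4-node hole-transfer network with Marcus rates."""

    nodes: tuple
    edges: dict  # (from_state, to_state) -> HopEdge
    lam: float  # meV
    temperature: float  # K
    nu_eff_inv_fs: float = NU_EFF_INV_FS
    symmetric_coupling: bool = False
    preset: str = "scheme2"
    meta: dict = field(default_factory=dict)

    @property
    def kT(self) -> float:
        return kt_mev(self.temperature)

    def feasible_edges(self) -> list:
        return [e for e in self.edges.values() if e.feasible]

    def feasible_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.feasible_edges():
            g.add_edge(e.from_state, e.to_state, dG=e.dG, h_ab=e.h_ab, rate=e.rate)
        return g

    def feasible_sinks(self) -> list:
        """Nodes with no outgoing feasible edge (pathway termini)."""
        g = self.feasible_graph()
        return [n for n in g.nodes if g.out_degree(n) == 0]

    def all_paths_terminate_at(self, target: str) -> bool:
        """True iff the target is a feasible-path terminus reachable from
        every other node: it has no outgoing feasible edge and every node
        has a feasible directed path to it."""
        g = self.feasible_graph()
        if g.out_degree(target) != 0:
            return False
        return all(nx.has_path(g, n, target) for n in g.nodes if n != target)

    def rate_matrix(self) -> np.ndarray:
        """Column-conservative rate matrix K: K[j, i] = k(i→j),
        K[i, i] = -Σ_j k(i→j)."""
        n = len(self.nodes)
        idx = {s: i for i, s in enumerate(self.nodes)}
        K = np.zeros((n, n))
        for e in self.edges.values():
            K[idx[e.to_state], idx[e.from_state]] += e.rate
        K[np.diag_indices(n)] -= K.sum(axis=0)
        return K

    def detailed_balance_residual(self) -> float:
        """Max |log(k_ij/k_ji) + ΔG_ij/kT| over edge pairs (0 when exact)."""
        resid = 0.0
        for (i, j), e in self.edges.items():
            back = self.edges.get((j, i))
            if back is None or e.rate == 0 or back.rate == 0:
                continue
            resid = max(resid, abs(np.log(e.rate / back.rate) + e.dG / self.kT))
        return resid

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "from": e.from_state,
                "to": e.to_state,
                "dG_meV": e.dG,
                "H_ab_meV": e.h_ab,
                "rate_per_s": e.rate,
                "feasible_thermo": e.feasible_thermo,
                "feasible_kinetic": e.feasible_kinetic,
                "feasible": e.feasible,
            }
            for e in self.edges.values()
        ]
        return pd.DataFrame(rows)

    def to_dot(self) -> str:
        lines = ["digraph hopnet {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for e in self.edges.values():
            style = "solid" if e.feasible else "dotted"
            lines.append(
                f'  "{e.from_state}" -> "{e.to_state}" '
                f'[label="ΔG={e.dG:+.0f} meV, H={e.h_ab:g} meV", style={style}];'
            )
        lines.append("}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "lambda_meV": self.lam,
            "temperature_K": self.temperature,
            "kT_meV": self.kT,
            "nu_eff_inv_fs": self.nu_eff_inv_fs,
            "symmetric_coupling": self.symmetric_coupling,
            "preset": self.preset,
            "edges": self.to_dataframe().to_dict(orient="records"),
        }


def potential_from_dg(dg: pd.DataFrame, reference: str = "124A") -> pd.Series:
    """Least-squares node free energies from a step ΔG table (meV).

    Solves ``min Σ_(i,j) (G_j - G_i - ΔG_ij)²`` over all ordered pairs
    present in the table; for a complete antisymmetric table this reduces
    to the column means.  The result is the table's nearest
    cycle-consistent free-energy landscape; the projection residual per
    edge quantifies the table's thermodynamic inconsistency (ensemble
    tables sampled from different trajectories per step carry genuine
    cycle residuals).  Energies are reported relative to ``reference``.
    """
    dg = _normalize_labels(dg)
    sites = [s for s in SITE_ORDER if s in dg.index and s in dg.columns]
    rows, rhs = [], []
    idx = {s: k for k, s in enumerate(sites)}
    for i in sites:
        for j in sites:
            if i == j:
                continue
            v = dg.loc[i, j]
            if np.isfinite(v):
                row = np.zeros(len(sites))
                row[idx[j]] = 1.0
                row[idx[i]] = -1.0
                rows.append(row)
                rhs.append(float(v))
    # gauge fixing: pin the reference site to zero
    pin = np.zeros(len(sites))
    pin[idx[reference]] = 1.0
    rows.append(pin)
    rhs.append(0.0)
    g, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    g = g - g[idx[reference]]
    return pd.Series(g, index=sites)


def consistent_dg_table(dg: pd.DataFrame, reference: str = "124A") -> pd.DataFrame:
    """Cycle-consistent projection of a step ΔG table: ΔG_ij = G_j - G_i
    with G the least-squares node free energies."""
    g = potential_from_dg(dg, reference=reference)
    out = pd.DataFrame(
        g.values[None, :] - g.values[:, None], index=g.index, columns=g.index
    )
    return out


def symmetrize_couplings(hab: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean of the two directional couplings for each pair.

    Rates scale with H², so the geometric mean of the directional medians
    gives the geometric-mean rate pair and restores exact detailed balance
    under a shared λ and an antisymmetric ΔG table.
    """
    out = hab.copy().astype(float)
    for i in out.index:
        for j in out.columns:
            if i == j or j not in out.index or i not in out.columns:
                continue
            hij, hji = hab.loc[i, j], hab.loc[j, i]
            if np.isfinite(hij) and np.isfinite(hji):
                out.loc[i, j] = np.sqrt(hij * hji)
    return out


def _normalize_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Accept either site ("124A") or state ("124A+") labels on the axes."""
    df = df.copy()
    df.index = [site_of(str(i).strip()) for i in df.index]
    df.columns = [site_of(str(c).strip()) for c in df.columns]
    return df


def feasibility_graph(
    dg: pd.DataFrame,
    hab: pd.DataFrame,
    dG_max: float | None = None,
    H_min: float | None = None,
    lam: float = DEFAULT_LAMBDA_MEV,
    temperature: float = DEFAULT_TEMPERATURE,
    symmetric_coupling: bool = False,
    cycle_consistent: bool = False,
    preset: str = "scheme2",
    nu_eff_inv_fs: float = NU_EFF_INV_FS,
) -> HopNetwork:
    """Build the hop network from ΔG and coupling tables and flag edges.

    ``dg`` and ``hab`` are 4x4 tables (rows = from-site, columns =
    to-site), in meV, with site or state labels on the axes.  Feasibility:
    thermodynamic iff ΔG < dG_max (strict, Scheme-2 preset; <= in the loose
    preset), kinetic iff H_ab > H_min (strict).  Explicit ``dG_max`` /
    ``H_min`` override the preset values.  Every ordered pair of the four
    sites must be present in both tables.

    ``cycle_consistent=True`` replaces the raw step ΔG values (for the
    rates only; feasibility flags keep the raw values) by their
    least-squares cycle-consistent projection (see
    :func:`potential_from_dg`), so that the master-equation stationary
    state is the Boltzmann distribution over well-defined node free
    energies.  The maximum projection shift is recorded in ``meta``.
    """
    cfg = dict(FEASIBILITY_PRESETS[preset])
    if dG_max is not None:
        cfg["dG_max"] = dG_max
    if H_min is not None:
        cfg["H_min"] = H_min

    dg = _normalize_labels(dg)
    hab = _normalize_labels(hab)
    if symmetric_coupling:
        hab = symmetrize_couplings(hab)
    rate_dg = dg
    projection_shift = 0.0
    if cycle_consistent:
        rate_dg = consistent_dg_table(dg)
        diffs = (rate_dg - dg.loc[rate_dg.index, rate_dg.columns]).to_numpy()
        projection_shift = float(np.nanmax(np.abs(diffs)))

    edges = {}
    for i, j in permutations(SITE_ORDER, 2):
        try:
            dgv = float(dg.loc[i, j])
            hv = float(hab.loc[i, j])
        except KeyError as err:
            raise ValueError(f"missing pair {i}->{j} in input tables") from err
        if not (np.isfinite(dgv) and np.isfinite(hv)):
            raise ValueError(f"missing pair {i}->{j} in input tables")
        if hv < 0:
            raise ValueError(f"negative coupling for {i}->{j}")
        thermo = dgv < cfg["dG_max"] if cfg["dG_strict"] else dgv <= cfg["dG_max"]
        kinetic = hv > cfg["H_min"] if cfg["H_strict"] else hv >= cfg["H_min"]
        dg_rate = float(rate_dg.loc[i, j])
        edges[(state_of(i), state_of(j))] = HopEdge(
            from_state=state_of(i),
            to_state=state_of(j),
            dG=dg_rate,
            h_ab=hv,
            rate=marcus_rate(hv, dg_rate, lam, temperature),
            feasible_thermo=bool(thermo),
            feasible_kinetic=bool(kinetic),
        )
    return HopNetwork(
        nodes=tuple(state_of(s) for s in SITE_ORDER),
        edges=edges,
        lam=lam,
        temperature=temperature,
        nu_eff_inv_fs=nu_eff_inv_fs,
        symmetric_coupling=symmetric_coupling,
        preset=preset,
        meta={
            "dG_max": cfg["dG_max"],
            "H_min": cfg["H_min"],
            "cycle_consistent": cycle_consistent,
            "max_projection_shift_meV": projection_shift,
        },
    )


@dataclass
class MasterEquationResult:
    nodes: tuple
    times: np.ndarray  # s
    populations: np.ndarray  # (n_times, n_nodes)
    stationary: np.ndarray  # (n_nodes,)

    def population(self, state: str) -> np.ndarray:
        return self.populations[:, self.nodes.index(state)]

    def stationary_of(self, state: str) -> float:
        return float(self.stationary[self.nodes.index(state)])


def master_equation(network: HopNetwork, p0, t_grid) -> MasterEquationResult:
    """Solve dp/dt = K·p by matrix exponential and find the stationary
    distribution from the null space of K.

    ``p0`` maps node labels to initial populations (or is a vector in node
    order) and must be normalized; populations stay normalized to 1e-9
    along the whole trajectory (column conservation of K).
    """
    nodes = network.nodes
    if isinstance(p0, dict):
        vec = np.array([p0.get(n, 0.0) for n in nodes], float)
    else:
        vec = np.asarray(p0, float)
    if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
        raise ValueError("p0 must be a normalized distribution over the nodes")
    K = network.rate_matrix()
    t_grid = np.asarray(t_grid, float)
    scale = np.abs(K).max()
    pops = np.empty((t_grid.size, len(nodes)))
    for i, t in enumerate(t_grid):
        pops[i] = expm(K * t) @ vec if scale > 0 else vec

    if scale == 0:
        stationary = vec.copy()
    else:
        ns = null_space(K / scale, rcond=1e-10)
        if ns.shape[1] == 0:
            raise RuntimeError("rate matrix has no stationary state")
        # pick the null vector with a consistent sign and unit total
        best = None
        for k in range(ns.shape[1]):
            v = ns[:, k]
            v = v * np.sign(v.sum() if v.sum() != 0 else 1.0)
            if (v >= -1e-12).all():
                best = v
                break
        if best is None:
            best = np.abs(ns[:, 0])
        stationary = best / best.sum()
        resid = np.abs(K @ stationary).max()
        if resid > 1e-12 * max(scale, 1.0):
            raise RuntimeError(f"stationary-state residual too large: {resid:.2e}")
    return MasterEquationResult(nodes, t_grid, pops, stationary)


def boltzmann_from_dg(dg: pd.DataFrame, reference: str = "124A",
                      temperature: float = DEFAULT_TEMPERATURE) -> pd.Series:
    """Boltzmann populations implied by one row of the ΔG table.

    Node free energies are taken relative to ``reference`` using the
    reference row; exact only when the table is cycle-consistent.
    """
    dg = _normalize_labels(dg)
    kt = kt_mev(temperature)
    g = np.array([0.0 if s == reference else float(dg.loc[reference, s])
                  for s in SITE_ORDER])
    w = np.exp(-g / kt)
    return pd.Series(w / w.sum(), index=[state_of(s) for s in SITE_ORDER])


def read_table_csv(path) -> pd.DataFrame:
    """Read a ΔG or H_ab table from CSV (first column = from-site labels)."""
    df = pd.read_csv(path, index_col=0)
    return _normalize_labels(df.apply(pd.to_numeric, errors="coerce"))
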