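"""Synthetic inputs with planted ground truth.

Every generator here emulates one input class of the analysis pipeline:

* :func:`gen_quadruplex` -- an idealized four-indole quadruplex whose six
  shortest C/N inter-indole distances match a requested :class:`QuadSpec`;
* :func:`gen_trajectory` -- a two-block trajectory with quasi-structural
  waters, one of which (a bridging water between the initially oxidized
  indole and the hole-accepting indole) shifts by a planted amount toward
  the newly oxidized site when the charge state switches;
* :func:`gen_charge_series` -- per-fragment charge/spin time series that
  are >= 90 % localized on one indole, with anticorrelated fluctuations and
  optional planted delocalization/transfer events;
* :func:`gen_energy_gaps` -- Gaussian vertical energy-gap ensembles
  consistent with a planted (ΔG, λ) in the linear-response picture
  (variance 2 λ k_B T in both endpoint states);
* :func:`gen_planted_pdb` -- an mmCIF/PDB structure with planted
  tryptophan clusters, decoys and optional redox cofactors for the
  cluster miner.

Determinism: every generator is a pure function of (spec, seed).  A single
integer seed feeds per-generator streams split with
``numpy.random.SeedSequence(seed, spawn_key=(stream_id,))``; the stream ids
are fixed in :data:`STREAM_IDS`.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import io as qio
from .core import EDGE_PARTNER, SITE_ORDER, IndoleSite, Frame, Trajectory, site_of
from .geometry import classify_quad_shape, min_site_distance

STREAM_IDS = {
    "quadruplex": 1,
    "trajectory": 2,
    "charges": 3,
    "gaps": 4,
    "planted_pdb": 5,
    "random_trp": 6,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Per-generator random stream derived from one global integer seed."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(STREAM_IDS[stream],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Idealized indole geometry
# ---------------------------------------------------------------------------
# Planar indole built from a regular pentagon (side 1.39 Å) fused to a
# regular hexagon (side 1.39 Å) along the CD2-CE2 bond.  Local frame: CD1
# at the origin, the ring extending toward +x, ring plane z = 0.  Only the
# 9 C/N heavy atoms are emitted (CB and backbone excluded); the distance
# analysis needs nothing more than rigid planar rings.

_R5 = 1.39 / (2 * np.sin(np.pi / 5))
_A5 = 1.39 / (2 * np.tan(np.pi / 5))
_A6 = 1.39 * np.sqrt(3) / 2

_RAW_INDOLE = {
    "CD2": (0.0, -0.695, 0.0),
    "CE2": (0.0, 0.695, 0.0),
    "NE1": (-_A5 + _R5 * np.cos(np.radians(108)), _R5 * np.sin(np.radians(108)), 0.0),
    "CG": (-_A5 + _R5 * np.cos(np.radians(-108)), _R5 * np.sin(np.radians(-108)), 0.0),
    "CD1": (-_A5 - _R5, 0.0, 0.0),
    "CZ2": (_A6, 1.39, 0.0),
    "CE3": (_A6, -1.39, 0.0),
    "CH2": (2 * _A6, 0.695, 0.0),
    "CZ3": (2 * _A6, -0.695, 0.0),
}

IDEAL_INDOLE_NAMES = tuple(_RAW_INDOLE)
_CD1 = np.array(_RAW_INDOLE["CD1"])
#: Local-frame coordinates: CD1 (the contact atom) at the origin, all other
#: atoms at strictly positive x.
IDEAL_INDOLE = np.array([_RAW_INDOLE[n] for n in IDEAL_INDOLE_NAMES]) - _CD1


def _orient_indole(anchor, outward, secondary):
    """Place the ideal indole with CD1 at ``anchor``, ring extending along
    ``outward``; ``secondary`` fixes the in-plane y direction."""
    u = np.asarray(outward, float)
    u = u / np.linalg.norm(u)
    w = np.asarray(secondary, float)
    w = w - (w @ u) * u
    n = np.linalg.norm(w)
    if n < 1e-8:
        w = np.array([0.0, 0.0, 1.0]) - u[2] * u
        n = np.linalg.norm(w)
        if n < 1e-8:
            w = np.array([0.0, 1.0, 0.0]) - u[1] * u
            n = np.linalg.norm(w)
    w = w / n
    v = np.cross(u, w)
    R = np.column_stack([u, w, v])  # local (x, y, z) -> lab
    return IDEAL_INDOLE @ R.T + np.asarray(anchor, float)


# ---------------------------------------------------------------------------
# QuadSpec and gen_quadruplex
# ---------------------------------------------------------------------------

#: Vertex order of the quadruplex cycle used for distance embedding.
_QUAD_VERTICES = ("124A", "122A", "124D", "122D")


@dataclass(frozen=True)
class QuadSpec:
    """Target shortest-distance set of a four-indole quadruplex (Å).

    Sides are the intramolecular 124A-122A and 122D-124D separations,
    edges the interfacial 124A-122D and 122A-124D separations, and
    diagonals connect 122D-122A (short in the reference crystal, 3.7 Å)
    and 124A-124D (long, 5.4 Å).
    """

    side_AA: float = 3.5
    side_DD: float = 3.5
    edge_AD: float = 4.0  # 124A-122D
    edge_DA: float = 4.0  # 122A-124D
    diag_short: float = 3.7  # 122D-122A
    diag_long: float = 5.4  # 124A-124D

    def __post_init__(self):
        for name, value in self.distances().items():
            if value <= 2.0:
                raise ValueError(f"{name} = {value} Å: all lengths must exceed 2.0 Å")

    def distances(self) -> dict:
        return {
            "side_AA": self.side_AA,
            "side_DD": self.side_DD,
            "edge_AD": self.edge_AD,
            "edge_DA": self.edge_DA,
            "diag_short": self.diag_short,
            "diag_long": self.diag_long,
        }

    @property
    def shape_label(self) -> str:
        return classify_quad_shape(self.side_AA, self.side_DD).label

    def distance_matrix(self) -> np.ndarray:
        """4x4 target distance matrix in :data:`_QUAD_VERTICES` order."""
        d = np.zeros((4, 4))
        pairs = {
            ("124A", "122A"): self.side_AA,
            ("122D", "124D"): self.side_DD,
            ("124A", "122D"): self.edge_AD,
            ("122A", "124D"): self.edge_DA,
            ("122D", "122A"): self.diag_short,
            ("124A", "124D"): self.diag_long,
        }
        idx = {s: i for i, s in enumerate(_QUAD_VERTICES)}
        for (a, b), v in pairs.items():
            d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
        return d


#: Distance targets of the reference crystal interface (PDB 6MJS): the
#: printed diagonals are 3.7 Å (122D-122A) and 5.4 Å (124A-124D); sides and
#: edges are set to the near-rhombic, short-edge geometry the crystal
#: adopts.  This spec drives a synthetic idealized stand-in, not the
#: deposited coordinates.
REFERENCE_QUAD_SPEC = QuadSpec(
    side_AA=3.5,
    side_DD=3.5,
    edge_AD=3.9,
    edge_DA=4.0,
    diag_short=3.7,
    diag_long=5.4,
)


def _embed_distances(dist: np.ndarray) -> np.ndarray:
    """Embed a 4x4 distance matrix in 3D (classical MDS).

    Raises ValueError when the distance set is not realizable (Gram matrix
    not positive semi-definite, i.e. triangle/tetrahedron inequalities
    violated).
    """
    n = dist.shape[0]
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -1e-6 * max(vals.max(), 1.0):
        raise ValueError(
            "infeasible geometry: requested distance set is not embeddable "
            f"(Gram eigenvalues {vals})"
        )
    vals = np.clip(vals, 0.0, None)
    pts = vecs[:, ::-1][:, :3] * np.sqrt(vals[::-1][:3])
    return pts


def gen_quadruplex(spec: QuadSpec, seed: int = 0) -> gemmi.Structure:
    """Generate a PDB-writable structure of four Trp residues on chains A
    and D whose minimal C/N inter-indole distances match ``spec``.

    The four CD1 contact atoms realize the anchor geometry exactly; each
    ring extends outward from the quadruplex centroid so that CD1-CD1
    pairs stay the closest contacts.  The emitted structure is verified
    against the spec (0.05 Å) before being returned.

    ``seed`` is accepted for interface uniformity; the construction is
    deterministic in the spec alone, so any two seeds give identical
    topology and distances.
    """
    del seed  # deterministic construction
    anchors = _embed_distances(spec.distance_matrix())
    centroid = anchors.mean(axis=0)
    # secondary (in-plane) direction shared by all rings: the direction of
    # least anchor spread, so ring breadth points away from the neighbors
    spread = anchors - centroid
    _, _, vt = np.linalg.svd(spread, full_matrices=True)
    shared_w = vt[-1]

    sites = {}
    for i, label in enumerate(_QUAD_VERTICES):
        outward = anchors[i] - centroid
        if np.linalg.norm(outward) < 1e-8:
            outward = np.array([1.0, 0.0, 0.0])
        coords = _orient_indole(anchors[i], outward, shared_w)
        sites[label] = IndoleSite(label[-1], int(label[:-1]), IDEAL_INDOLE_NAMES, coords)

    _verify_quad(sites, spec)
    frame = Frame(0, 0.0, "GS", sites)
    st = qio.trajectory_to_structure(Trajectory([frame]), name="synthetic quadruplex")
    return st


def _verify_quad(sites: dict, spec: QuadSpec, tol: float = 0.05) -> None:
    targets = {
        ("124A", "122A"): spec.side_AA,
        ("122D", "124D"): spec.side_DD,
        ("124A", "122D"): spec.edge_AD,
        ("122A", "124D"): spec.edge_DA,
        ("122D", "122A"): spec.diag_short,
        ("124A", "124D"): spec.diag_long,
    }
    for (a, b), want in targets.items():
        got = min_site_distance(sites[a], sites[b])
        if abs(got - want) > tol:
            raise ValueError(
                f"infeasible geometry: emitted {a}-{b} distance {got:.3f} Å "
                f"misses target {want:.3f} Å by more than {tol} Å "
                "(ring packing incompatible with the requested distance set)"
            )


# ---------------------------------------------------------------------------
# Hydrated trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HydrationSpec:
    """Quasi-structural water layout and its response to a charge switch.

    ``shift_magnitude`` is the displacement (Å) of the bridging water's
    mean position toward the newly oxidized indole's NE1 upon the state
    switch; ``jitter_sigma`` is the per-frame isotropic Gaussian positional
    noise of every water.
    """

    n_waters: int = 8
    shift_magnitude: float = 0.15
    jitter_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")
        if self.n_waters < 1:
            raise ValueError("need at least the bridging water (n_waters >= 1)")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def gen_trajectory(
    structure,
    hyd: HydrationSpec,
    n_frames_per_state: int,
    switch_state: str,
    initial_state: str = "124A+",
    dt_ps: float = 0.4,
) -> Trajectory:
    """Two-block trajectory around a forced hole transfer.

    The first ``n_frames_per_state`` frames are tagged ``initial_state``,
    the rest ``switch_state``.  The quadruplex is rigid; waters jitter
    around fixed mean positions.  One bridging water sits between the NE1
    groups of the initially and newly oxidized indoles, biased half the
    planted shift toward whichever indole currently carries the hole, so
    its mean position moves by exactly ``hyd.shift_magnitude`` toward the
    newly oxidized site (and its NE1) across the switch.
    """
    if n_frames_per_state < 2:
        raise ValueError("n_frames_per_state must be >= 2")
    if isinstance(structure, gemmi.Structure):
        sites = qio.indole_sites(structure[0])
    else:
        sites = dict(structure)
    missing = [s for s in SITE_ORDER if s not in sites]
    if missing:
        raise ValueError(f"structure lacks indole sites {missing}")

    src = site_of(initial_state)
    dst = site_of(switch_state)
    if src == dst:
        raise ValueError("switch_state must differ from initial_state")
    rng = stream_rng(hyd.seed, "trajectory")

    nh = {s: sites[s].nh_position for s in SITE_ORDER}
    centroid = np.mean([sites[s].coords for s in SITE_ORDER], axis=(0, 1))
    mid = 0.5 * (nh[src] + nh[dst])
    u = nh[dst] - nh[src]
    u = u / np.linalg.norm(u)

    # mean water positions per block
    means_a, means_b = [], []
    means_a.append(mid - 0.5 * hyd.shift_magnitude * u)  # bridging water
    means_b.append(mid + 0.5 * hyd.shift_magnitude * u)
    shell = []
    for s in SITE_ORDER:
        out = nh[s] - centroid
        out = out / np.linalg.norm(out)
        shell.append(nh[s] + 3.2 * out)
    extra = []
    n_extra = hyd.n_waters - 1 - min(4, hyd.n_waters - 1)
    quad_atoms = np.vstack([sites[s].coords for s in SITE_ORDER])
    while len(extra) < n_extra:
        cand = centroid + rng.uniform(-4.5, 4.5, size=3)
        d_atoms = np.linalg.norm(quad_atoms - cand, axis=1).min()
        d_nh = min(np.linalg.norm(cand - nh[s]) for s in SITE_ORDER)
        d_means = min(
            (np.linalg.norm(cand - m) for m in means_a[1:] + shell + extra),
            default=np.inf,
        )
        if 2.6 <= d_atoms and d_nh >= 3.4 and d_means >= 2.4:
            extra.append(cand)
    fixed = (shell[: hyd.n_waters - 1] + extra)[: hyd.n_waters - 1]
    means_a.extend(fixed)
    means_b.extend(fixed)
    means_a, means_b = np.array(means_a), np.array(means_b)

    # the bridging water must be the nearest water to the newly oxidized
    # NE1 in the switched block, otherwise the planted shift is ill-defined
    d_bridge = np.linalg.norm(means_b[0] - nh[dst])
    d_others = np.linalg.norm(means_b[1:] - nh[dst], axis=1).min() if len(means_b) > 1 else np.inf
    if d_bridge >= d_others:
        raise ValueError(
            "bridging water is not the closest water to the target site; "
            "the requested geometry cannot plant a recoverable shift"
        )

    frames = []
    for block, (state, means) in enumerate(
        ((initial_state, means_a), (switch_state, means_b))
    ):
        for k in range(n_frames_per_state):
            idx = block * n_frames_per_state + k
            jitter = rng.normal(0.0, hyd.jitter_sigma, size=means.shape)
            frames.append(
                Frame(
                    frame_index=idx,
                    time=idx * dt_ps,
                    state=state,
                    sites=sites,
                    waters=means + jitter,
                )
            )
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# Charge/spin series
# ---------------------------------------------------------------------------

FRAGMENTS = ("124A", "122A", "122D", "124D", "dmpA", "ReCO3")

#: Mean charges of the non-indole fragments in every state: the dmpA
#: ligand carries ca. -0.4 e and Re(CO)3 ca. +0.2 e.
DMPA_CHARGE = -0.4
RECO3_CHARGE = 0.2


@dataclass(frozen=True)
class ChargeSeriesSpec:
    """Planted per-fragment charge/spin series.

    The hole (total indole charge 1.0 e) sits on ``hot_site`` with mean
    ``hot_mean``; the residual indole charge is split over the neutral
    indoles, weighted toward the interfacial edge partner, whose
    fluctuations therefore anticorrelate with the hot site by
    construction.  ``deloc_events`` plants delocalization episodes:
    tuples ``(start_frame, duration_frames, partner_site,
    transfer_fraction)``; a fraction of 1.0 lasting to the end of the
    series is a complete hole transfer.
    """

    hot_site: str = "124A"
    hot_mean: float = 0.9
    noise_sigma: float = 0.02
    deloc_events: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if site_of(self.hot_site) not in SITE_ORDER:
            raise ValueError(f"unknown hot site {self.hot_site!r}")
        if not 0.0 <= self.hot_mean <= 1.0:
            raise ValueError("hot_mean must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        events = sorted(self.deloc_events, key=lambda e: e[0])
        for (s1, d1, *_), (s2, *_rest) in zip(events, events[1:]):
            if s1 + d1 > s2:
                raise ValueError(f"overlapping delocalization events at frame {s2}")
        for start, duration, partner, frac in events:
            if site_of(partner) not in SITE_ORDER:
                raise ValueError(f"unknown partner site {partner!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("transfer_fraction must lie in [0, 1]")
            if start < 0 or duration < 1:
                raise ValueError("events need start >= 0 and duration >= 1")


def gen_charge_series(spec: ChargeSeriesSpec, n_frames: int, dt_fs: float = 0.5):
    """Generate a :class:`~quadhop.holes.ChargeSpinSeries` with planted truth.

    Per-frame fragment charges sum exactly to the planted total
    (1.0 + dmpA + Re(CO)3 charge); spins sum exactly to 1.
    """
    from .holes import ChargeSpinSeries

    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = stream_rng(spec.seed, "charges")
    hot = site_of(spec.hot_site)
    others = [s for s in SITE_ORDER if s != hot]
    partner = EDGE_PARTNER[hot]
    weights = {s: (0.6 if s == partner else 0.2) for s in others}

    delta = rng.normal(0.0, spec.noise_sigma, size=n_frames)
    eps = rng.normal(0.0, spec.noise_sigma / 2, size=n_frames)

    charge = np.zeros((n_frames, len(FRAGMENTS)))
    col = {f: i for i, f in enumerate(FRAGMENTS)}
    hot_q = spec.hot_mean + delta
    charge[:, col[hot]] = hot_q
    for s in others:
        charge[:, col[s]] = weights[s] * (1.0 - hot_q)
    charge[:, col["dmpA"]] = DMPA_CHARGE + eps
    charge[:, col["ReCO3"]] = RECO3_CHARGE - eps

    # spins: same localization pattern, total indole spin 0.95,
    # dmpA/Re(CO)3 small and mutually anticorrelated, total exactly 1
    spin = np.zeros_like(charge)
    hot_s = 0.95 * (hot_q / max(spec.hot_mean, 1e-9)) if spec.hot_mean else hot_q
    spin[:, col[hot]] = hot_s
    for s in others:
        spin[:, col[s]] = weights[s] * (0.95 - hot_s)
    spin[:, col["dmpA"]] = 0.04 + eps / 2
    spin[:, col["ReCO3"]] = 0.01 - eps / 2

    for start, duration, partner_site, frac in spec.deloc_events:
        partner_site = site_of(partner_site)
        end = min(start + duration, n_frames)
        for arr in (charge, spin):
            moved = frac * arr[start:end, col[hot]]
            arr[start:end, col[hot]] -= moved
            arr[start:end, col[partner_site]] += moved

    times = np.arange(n_frames) * dt_fs
    return ChargeSpinSeries(
        times=times, fragments=FRAGMENTS, charge=charge, spin=spin, method_tag="synthetic"
    )


# ---------------------------------------------------------------------------
# Energy gaps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapSpec:
    """Planted linear-response energy-gap ensembles.

    The vertical gap ΔE = E(product state) - E(reactant state) is Gaussian
    with mean ΔG + λ in the reactant ensemble (A), mean ΔG - λ in the
    product ensemble (B), and variance 2 λ k_B T in both.
    """

    dG_true: float = -320.0  # meV
    lambda_true: float = 800.0  # meV
    kT: float = 25.7  # meV
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.kT <= 0:
            raise ValueError("kT must be positive")


def gen_energy_gaps(spec: GapSpec):
    """Return ``(gaps_A, gaps_B)`` :class:`~quadhop.energetics.GapSamples`."""
    from .energetics import GapSamples

    rng = stream_rng(spec.seed, "gaps")
    sigma = np.sqrt(2.0 * spec.lambda_true * spec.kT)
    a = rng.normal(spec.dG_true + spec.lambda_true, sigma, size=spec.n_samples)
    b = rng.normal(spec.dG_true - spec.lambda_true, sigma, size=spec.n_samples)
    return GapSamples("reactant", a), GapSamples("product", b)


# ---------------------------------------------------------------------------
# Planted PDB structures for the cluster miner
# ---------------------------------------------------------------------------


def _simplex_anchors(n: int, d: float, rng: np.random.Generator) -> np.ndarray:
    """n points with controlled pairwise separations.

    For n <= 4 a regular simplex (all pairwise exactly d); for larger n a
    linear chain with spacing d (consecutive pairs at d, others farther).
    """
    if n == 1:
        return np.zeros((1, 3))
    if n <= 4:
        base = {
            2: np.array([[0, 0, 0], [1, 0, 0]], float),
            3: np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], float),
            4: np.array(
                [
                    [0, 0, 0],
                    [1, 0, 0],
                    [0.5, np.sqrt(3) / 2, 0],
                    [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
                ],
                float,
            ),
        }[n]
        return base * d
    return np.column_stack([np.arange(n) * d, np.zeros(n), np.zeros(n)])


def _place_trp_residues(model, placements, rng):
    """Append TRP residues to a gemmi model.

    ``placements`` is a list of (chain_id, residue_number, anchor, outward).
    """
    chains = {}
    for chain_id, resnum, anchor, outward in placements:
        w = rng.normal(size=3)
        coords = _orient_indole(anchor, outward, w)
        res = gemmi.Residue()
        res.name = "TRP"
        res.seqid = gemmi.SeqId(int(resnum), " ")
        for name, xyz in zip(IDEAL_INDOLE_NAMES, coords):
            res.add_atom(qio._make_atom(name, xyz, "N" if name == "NE1" else "C"))
        chains.setdefault(chain_id, []).append(res)
    for cname in sorted(chains):
        chain = gemmi.Chain(cname)
        for res in chains[cname]:
            chain.add_residue(res)
        model.add_chain(chain)


def gen_planted_pdb(
    cluster_layout,
    decoys: int = 0,
    seed: int = 0,
    cofactors=(),
) -> gemmi.Structure:
    """Structure with planted tryptophan clusters for the cluster miner.

    ``cluster_layout`` is a list of ``(chain_id, n_trp, pairwise_distance)``
    groups.  Groups sharing one pairwise distance are merged into a single
    spatial arrangement (all mutual separations equal to that distance for
    up to four tryptophans, a chain with that spacing beyond), which is how
    cross-chain/interfacial clusters are planted.  Groups with differing
    distances are placed as separate, well-separated clusters.

    ``decoys`` adds isolated tryptophans more than 30 Å from everything
    (singletons under any linkage cutoff <= 10 Å).  ``cofactors`` is a list
    of ``(residue_name, distance)`` pairs; each plants a single-atom
    HETATM cofactor whose minimal distance to the first cluster's indole
    atoms equals ``distance`` exactly.
    """
    rng = stream_rng(seed, "planted_pdb")
    layout = list(cluster_layout)
    if not layout and decoys == 0:
        raise ValueError("empty layout")
    for chain_id, n_trp, d in layout:
        if n_trp < 1 or d <= 2.0:
            raise ValueError(f"infeasible layout entry ({chain_id}, {n_trp}, {d})")

    distances = {d for _, _, d in layout}
    merged = []  # list of (members, distance) with members = [(chain, count)]
    if len(distances) <= 1 and layout:
        merged.append(([(c, n) for c, n, _ in layout], layout[0][2]))
    else:
        for chain_id, n_trp, d in layout:
            merged.append(([(chain_id, n_trp)], d))

    st = gemmi.Structure()
    st.name = "synthetic planted clusters"
    model = gemmi.Model(1)
    st.add_model(model)
    model = st[0]

    placements = []
    next_resnum = {}
    cluster_origin = np.zeros(3)
    first_cluster_atoms = None
    for members, d in merged:
        n_total = sum(n for _, n in members)
        anchors = _simplex_anchors(n_total, d, rng) + cluster_origin
        centroid = anchors.mean(axis=0)
        chain_seq = [c for c, n in members for _ in range(n)]
        for i, (chain_id, anchor) in enumerate(zip(chain_seq, anchors)):
            outward = anchor - centroid
            if np.linalg.norm(outward) < 1e-8:
                outward = rng.normal(size=3)
            resnum = next_resnum.get(chain_id, 10)
            next_resnum[chain_id] = resnum + 10
            placements.append((chain_id, resnum, anchor, outward))
        cluster_origin = cluster_origin + np.array([60.0, 0.0, 0.0])

    for k in range(decoys):
        anchor = np.array([-60.0 - 40.0 * k, 0.0, 0.0])
        resnum = next_resnum.get("X", 10)
        next_resnum["X"] = resnum + 10
        placements.append(("X", resnum, anchor, rng.normal(size=3)))

    _place_trp_residues(model, placements, rng)

    if cofactors:
        first_n = merged[0][0] if merged else []
        n_first = sum(n for _, n in first_n)
        cluster_atoms = []
        count = 0
        for chain in model:
            for res in chain:
                if res.name == "TRP" and count < n_first and chain.name != "X":
                    for atom in res:
                        cluster_atoms.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    count += 1
        cluster_atoms = np.asarray(cluster_atoms)
        hchain = gemmi.Chain("Z")
        for ci, (resname, dist) in enumerate(cofactors, start=1):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # anchor on the extreme atom along u so the planted distance is
            # exactly the minimum over all cluster atoms
            proj = cluster_atoms @ u
            a_star = cluster_atoms[np.argmax(proj)]
            pos = a_star + dist * u
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(900 + ci, " ")
            res.het_flag = "H"
            element = "Fe" if resname in ("FE", "FES", "SF4") else "C"
            res.add_atom(qio._make_atom("C1" if element == "C" else "FE", pos, element))
            hchain.add_residue(res)
        model.add_chain(hchain)

    st.setup_entities()
    return st


def gen_random_trp_structure(
    n_trp: int, seed: int = 0, box: float = 40.0, n_chains: int = 2, min_sep: float = 4.0
) -> gemmi.Structure:
    """Random tryptophan placements in a cubic box (for oracle tests).

    Anchors are uniform in ``[0, box]^3`` with a minimum mutual separation;
    ring orientations are random; chains are assigned round-robin.
    """
    rng = stream_rng(seed, "random_trp")
    anchors = []
    while len(anchors) < n_trp:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - a) >= min_sep for a in anchors):
            anchors.append(cand)
    st = gemmi.Structure()
    st.name = "synthetic random tryptophans"
    st.add_model(gemmi.Model(1))
    model = st[0]
    chain_names = [chr(ord("A") + i) for i in range(n_chains)]
    placements = []
    counters = {c: itertools.count(10, 10) for c in chain_names}
    for i, anchor in enumerate(anchors):
        chain_id = chain_names[i % n_chains]
        placements.append((chain_id, next(counters[chain_id]), anchor, rng.normal(size=3)))
    _place_trp_residues(model, placements, rng)
    st.setup_entities()
    return st
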