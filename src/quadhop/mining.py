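"""Tryptophan-cluster mining in protein structures.

A cluster is a connected component of the graph whose nodes are tryptophan
residues and whose edges link pairs within a distance cutoff (default
10 Å, inclusive), using the same minimal C/N indole-atom distance
convention as the rest of the package.  Clusters are classified
intramolecular (one chain) or interfacial (several chains); an interfacial
cluster spanning exactly two chains is a dimer link.  A size-4 cluster is
a "tight quadruplex" when all six pairwise minima are strictly below 5 Å.

Only the first model of the deposited asymmetric unit is scanned
(highest-occupancy altlocs); biological-assembly expansion and
sequence-identity deduplication are the caller's responsibility via a
pre-filtered id list.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import io as qio

#: Default linkage cutoff, Å ("within 10 Å" -> inclusive).
LINK_CUTOFF = 10.0

#: Default tight-quadruplex cutoff, Å ("below 5 Å" -> strict).
TIGHT_CUTOFF = 5.0

#: Recognized redox-cofactor residue names (flavins, porphyrins,
#: nonheme/cluster iron, nicotinamides).
COFACTOR_NAMES = ("FAD", "FMN", "HEM", "HEC", "FE", "FES", "SF4", "NAD", "NAI", "NAP")


@dataclass
class TrpCluster:
    structure_id: str
    members: list  # [(chain, residue_number), ...] sorted
    pairwise_min_distances: np.ndarray  # (size, size), Å
    classification: str = ""  # intramolecular | interfacial
    dimer_link: bool = False
    tight_quadruplex: bool = False

    def __post_init__(self):
        self.members = sorted(self.members)
        chains = self.span_chains
        self.classification = "intramolecular" if len(chains) == 1 else "interfacial"
        self.dimer_link = self.classification == "interfacial" and len(chains) == 2
        if self.size == 4:
            self.tight_quadruplex = tight_quadruplex_check(self)[0]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span_chains(self) -> set:
        return {c for c, _ in self.members}


def tight_quadruplex_check(cluster: TrpCluster, cutoff: float = TIGHT_CUTOFF):
    """All six pairwise minima strictly below ``cutoff``?

    Returns ``(bool, failing_pairs)`` where each failing pair is
    ``(member_i, member_j, distance)``.
    """
    if cluster.size != 4:
        raise ValueError(f"tight-quadruplex test needs size 4, got {cluster.size}")
    failing = []
    d = cluster.pairwise_min_distances
    for i, j in combinations(range(4), 2):
        if not d[i, j] < cutoff:
            failing.append((cluster.members[i], cluster.members[j], float(d[i, j])))
    return (not failing), failing


def _trp_sites(structure, metric: str):
    """(member, coords) list for every Trp with usable indole atoms."""
    if isinstance(structure, (str, Path)):
        structure = qio.read_structure(structure)
    model = structure[0]
    out = []
    sites = qio.indole_sites(model, min_atoms=1)
    for label in sorted(sites, key=lambda s: (sites[s].chain_id, sites[s].residue_number)):
        site = sites[label]
        if metric == "indole_min":
            coords = site.coords
        elif metric == "centroid":
            coords = site.coords.mean(axis=0, keepdims=True)
        elif metric == "nh":
            coords = site.nh_position.reshape(1, 3)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        out.append(((site.chain_id, site.residue_number), coords))
    return structure, out


def _pairwise_min(coords_list) -> np.ndarray:
    n = len(coords_list)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = cdist(coords_list[i], coords_list[j]).min()
    return d


@dataclass
class StructureScan:
    structure_id: str
    clusters: list  # TrpCluster, size >= min_size
    singletons: list = field(default_factory=list)  # diagnostics only
    n_trp: int = 0


def scan_structure(
    structure,
    structure_id: str = "",
    link_cutoff: float = LINK_CUTOFF,
    min_size: int = 2,
    metric: str = "indole_min",
) -> StructureScan:
    """Find all tryptophan clusters in one structure, with diagnostics.

    ``structure`` is a path (PDB/mmCIF) or a gemmi Structure.  Edges link
    Trp pairs with minimal indole C/N distance <= ``link_cutoff``
    (alternative metrics: "centroid", "nh").  Components of size >=
    ``min_size`` become clusters; smaller components are reported as
    singleton diagnostics.
    """
    try:
        structure, trps = _trp_sites(structure, metric)
    except (RuntimeError, ValueError, OSError) as err:
        raise ValueError(f"cannot parse structure {structure_id or structure}: {err}") from err
    if not structure_id:
        structure_id = structure.name or "structure"
    members = [m for m, _ in trps]
    coords = [c for _, c in trps]
    dmat = _pairwise_min(coords)

    g = nx.Graph()
    g.add_nodes_from(range(len(members)))
    for i, j in combinations(range(len(members)), 2):
        if dmat[i, j] <= link_cutoff:
            g.add_edge(i, j)

    clusters, singles = [], []
    for comp in nx.connected_components(g):
        idx = sorted(comp, key=lambda k: members[k])
        if len(idx) < min_size:
            singles.extend(members[k] for k in idx)
            continue
        clusters.append(
            TrpCluster(
                structure_id=structure_id,
                members=[members[k] for k in idx],
                pairwise_min_distances=dmat[np.ix_(idx, idx)],
            )
        )
    clusters.sort(key=lambda c: c.members)
    return StructureScan(structure_id, clusters, sorted(singles), len(members))


def find_clusters(structure, link_cutoff: float = LINK_CUTOFF, min_size: int = 2,
                  metric: str = "indole_min") -> list:
    """Clusters of size >= ``min_size`` in one structure (see
    :func:`scan_structure` for diagnostics)."""
    return scan_structure(structure, link_cutoff=link_cutoff, min_size=min_size,
                          metric=metric).clusters


@dataclass
class SizeDistribution:
    per_size: pd.DataFrame  # index size; columns n_clusters, n_structures
    quad_breakdown: dict  # intramolecular / interfacial / dimer counts
    n_structures: int


def size_distribution(scans) -> SizeDistribution:
    """Cluster-size histogram over a structure set.

    Counts are reported per cluster and per structure id (a structure with
    two disjoint size-4 clusters contributes twice to the per-cluster
    size-4 count and once to the per-structure count).  Size-4 clusters
    are additionally split by intramolecular/interfacial classification and
    the dimer flag.
    """
    scans = list(scans)
    rows = {}
    ids_by_size = {}
    quad = {"intramolecular": 0, "interfacial": 0, "dimer": 0}
    for scan in scans:
        for cl in scan.clusters:
            rows[cl.size] = rows.get(cl.size, 0) + 1
            ids_by_size.setdefault(cl.size, set()).add(scan.structure_id)
            if cl.size == 4:
                quad[cl.classification] += 1
                if cl.dimer_link:
                    quad["dimer"] += 1
    sizes = sorted(rows)
    per_size = pd.DataFrame(
        {
            "n_clusters": [rows[s] for s in sizes],
            "n_structures": [len(ids_by_size[s]) for s in sizes],
        },
        index=pd.Index(sizes, name="size"),
    )
    return SizeDistribution(per_size, quad, len(scans))


@dataclass(frozen=True)
class CofactorProximity:
    cofactor: tuple  # (residue_name, chain, residue_number)
    d_min: float  # Å, minimal heavy-atom distance to any cluster indole atom


def cofactor_proximity(structure, cluster: TrpCluster,
                       cofactor_names=COFACTOR_NAMES) -> list:
    """Minimal heavy-atom distances from recognized cofactors to a cluster.

    Returns an empty list when the structure carries no recognized
    cofactor het-groups.
    """
    if isinstance(structure, (str, Path)):
        structure = qio.read_structure(structure)
    model = structure[0]
    member_set = set(cluster.members)
    cluster_atoms = []
    for chain in model:
        for res in chain:
            if res.name == "TRP" and (chain.name, res.seqid.num) in member_set:
                for atom in res:
                    if atom.element.name != "H":
                        cluster_atoms.append([atom.pos.x, atom.pos.y, atom.pos.z])
    cluster_atoms = np.asarray(cluster_atoms)
    out = []
    for chain in model:
        for res in chain:
            if res.name not in cofactor_names:
                continue
            pts = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for a in res if a.element.name != "H"]
            )
            if pts.size == 0 or cluster_atoms.size == 0:
                continue
            d = float(cdist(pts, cluster_atoms).min())
            out.append(CofactorProximity((res.name, chain.name, res.seqid.num), d))
    out.sort(key=lambda c: c.d_min)
    return out


def clusters_to_dataframe(scans) -> pd.DataFrame:
    """Per-cluster long-format table for CSV export."""
    rows = []
    for scan in scans:
        for i, cl in enumerate(scan.clusters):
            rows.append(
                {
                    "structure_id": scan.structure_id,
                    "cluster": i,
                    "size": cl.size,
                    "members": ";".join(f"{c}{n}" for c, n in cl.members),
                    "classification": cl.classification,
                    "dimer_link": cl.dimer_link,
                    "tight_quadruplex": cl.tight_quadruplex if cl.size == 4 else False,
                    "max_pairwise_min": float(cl.pairwise_min_distances.max()),
                }
            )
    return pd.DataFrame(rows)
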