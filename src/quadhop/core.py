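"""Core domain types for the tryptophan-quadruplex analysis.

The quadruplex consists of four tryptophan indole side chains at a
protein-protein interface, two per chain: residues 124 and 122 of chain A
and residues 122 and 124 of chain D.  Sites are labeled by residue number
plus chain letter ("124A", "122A", "122D", "124D").  Oxidized (hole-carrying)
states append "+" ("124A+" denotes the state with the hole on 124A).

All inter-site distances follow one convention: the minimum over all
cross pairs of carbon/nitrogen heavy atoms of the indole group, hydrogens
disregarded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed site order used for tie-breaking and reporting.
SITE_ORDER = ("124A", "122A", "122D", "124D")

#: Oxidized-state label for each site.
STATE_OF_SITE = {s: s + "+" for s in SITE_ORDER}

#: Recognized trajectory state labels.
STATE_LABELS = ("GS", "MLCT", "124A+", "122A+", "122D+", "124D+")

#: Indole side-chain heavy atoms used for all distance measurements
#: (C and N only; CB and backbone excluded).
INDOLE_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

#: The six quadruplex pairs and their geometric kind.  Sides are the
#: intramolecular 124-122 contacts, edges the interfacial contacts, and
#: diagonals connect equivalent residues across the interface.
QUAD_PAIRS = (
    ("124A", "122A", "side"),
    ("122D", "124D", "side"),
    ("124A", "122D", "edge"),
    ("122A", "124D", "edge"),
    ("122D", "122A", "diagonal"),
    ("124A", "124D", "diagonal"),
)

#: Unordered pair -> kind lookup.
PAIR_KIND = {frozenset((a, b)): kind for a, b, kind in QUAD_PAIRS}

#: Interfacial edge partner of each site (the indole lying opposite
#: along the protein-protein interface).
EDGE_PARTNER = {"124A": "122D", "122D": "124A", "122A": "124D", "124D": "122A"}


def site_label(residue_number: int, chain_id: str) -> str:
    return f"{residue_number}{chain_id}"


def state_of(site: str) -> str:
    """Oxidized-state label for a site ("124A" -> "124A+")."""
    return site if site.endswith("+") else site + "+"


def site_of(state: str) -> str:
    """Site carrying the hole in an oxidized state ("124A+" -> "124A")."""
    return state[:-1] if state.endswith("+") else state


@dataclass
class IndoleSite:
    """One tryptophan side chain as a named set of C/N heavy atoms.

    Parameters
    ----------
    chain_id, residue_number
        Crystallographic identity of the residue.
    atom_names
        Names drawn from :data:`INDOLE_ATOMS`; NE1 must appear exactly once
        and at least five atoms must be present.
    coords
        (n_atoms, 3) array of positions in Å.
    """

    chain_id: str
    residue_number: int
    atom_names: tuple
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.atom_names = tuple(self.atom_names)
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom_names and coords length mismatch")
        bad = [n for n in self.atom_names if n not in INDOLE_ATOMS]
        if bad:
            raise ValueError(f"atoms outside the indole C/N set: {bad}")
        if len(self.atom_names) < 5:
            raise ValueError(
                f"site {self.label}: only {len(self.atom_names)} indole atoms "
                "present, need at least 5"
            )
        if self.atom_names.count("NE1") != 1:
            raise ValueError(f"site {self.label}: NE1 must be present exactly once")

    @property
    def label(self) -> str:
        return site_label(self.residue_number, self.chain_id)

    @property
    def nh_position(self) -> np.ndarray:
        """Position of the NE1 nitrogen (the indole N-H reference point)."""
        return self.coords[self.atom_names.index("NE1")]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "IndoleSite":
        return IndoleSite(
            self.chain_id,
            self.residue_number,
            self.atom_names,
            self.coords @ rotation.T + translation,
        )


@dataclass
class Frame:
    """One trajectory frame: the four indole sites, optional auxiliary atom
    groups (dmp ligands, Re(CO)3, SAL backbone segments) and water oxygens.

    ``state`` tags the redox state of the quadruplex the frame was sampled
    in and is constant within a declared trajectory block.
    """

    frame_index: int
    time: float  # ps
    state: str
    sites: dict  # label -> IndoleSite
    waters: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    groups: dict = field(default_factory=dict)  # name -> (n, 3) C/N coords

    def __post_init__(self):
        self.waters = np.asarray(self.waters, dtype=float).reshape(-1, 3)
        missing = [s for s in SITE_ORDER if s not in self.sites]
        if missing:
            raise ValueError(f"frame {self.frame_index}: missing indole sites {missing}")
        if self.state not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.state!r}")

    def quad_coords(self) -> np.ndarray:
        """Heavy-atom coordinates of the four indoles, fixed site order."""
        return np.vstack([self.sites[s].coords for s in SITE_ORDER])

    def nh_positions(self) -> dict:
        return {s: self.sites[s].nh_position for s in SITE_ORDER}


@dataclass
class Trajectory:
    """Ordered frames with per-block state tags."""

    frames: list

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def states(self) -> list:
        return [f.state for f in self.frames]

    def blocks(self) -> list:
        """Contiguous (state, frame list) blocks in order."""
        out = []
        for f in self.frames:
            if out and out[-1][0] == f.state:
                out[-1][1].append(f)
            else:
                out.append((f.state, [f]))
        return out

    def select_state(self, state: str) -> list:
        return [f for f in self.frames if f.state == state]
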