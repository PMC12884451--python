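"""Structure and trajectory I/O.

Single-frame structures (PDB or mmCIF) are handled through :mod:`gemmi`;
multi-frame trajectories are multi-model PDB files (model index = frame
index, 0-based internally, 1-based in the file) or plain XYZ streams.

Altloc convention for crystal input: keep the highest-occupancy conformer
of each atom; ties resolve to the altloc letter sorting first ('A').
"""
from __future__ import annotations

import json
import urllib.request
from pathlib import Path

import gemmi
import numpy as np

from .core import INDOLE_ATOMS, IndoleSite, Frame, Trajectory, site_label

WATER_NAMES = {"HOH", "WAT", "H2O", "TIP", "TIP3", "SPC", "SOL"}


def read_structure(path) -> gemmi.Structure:
    """Read a PDB or mmCIF file and resolve altlocs (highest occupancy)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    st.setup_entities()
    _strip_altlocs(st)
    return st


def _strip_altlocs(st: gemmi.Structure) -> None:
    for model in st:
        for chain in model:
            for res in chain:
                best = {}
                for atom in res:
                    key = atom.name
                    if key not in best:
                        best[key] = atom
                        continue
                    prev = best[key]
                    if (atom.occ, _altloc_rank(atom)) > (prev.occ, _altloc_rank(prev)):
                        best[key] = atom
                keep = set(id(a) for a in best.values())
                for i in range(len(res) - 1, -1, -1):
                    if id(res[i]) not in keep:
                        del res[i]
                for atom in res:
                    atom.altloc = "\0"


def _altloc_rank(atom) -> int:
    # blank altloc ranks highest; then reverse-alphabetical so that 'A'
    # wins ties when occupancies are equal
    alt = atom.altloc
    if alt in ("\0", "", " "):
        return 1000
    return -ord(alt)


def indole_sites(model: gemmi.Model, min_atoms: int = 5) -> dict:
    """Extract all tryptophan indole C/N sites from a gemmi model.

    Returns a dict keyed by site label ("124A"), skipping residues with
    fewer than ``min_atoms`` indole atoms resolved.
    """
    sites = {}
    for chain in model:
        for res in chain:
            if res.name != "TRP":
                continue
            names, coords = [], []
            for atom in res:
                if atom.name in INDOLE_ATOMS:
                    names.append(atom.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if len(names) < min_atoms or "NE1" not in names:
                continue
            site = IndoleSite(chain.name, res.seqid.num, tuple(names), np.array(coords))
            sites[site.label] = site
    return sites


def _is_cn(atom) -> bool:
    return atom.element.name in ("C", "N")


def model_to_frame(model: gemmi.Model, frame_index: int, time: float, state: str) -> Frame:
    """Convert one gemmi model into a :class:`Frame`.

    Non-tryptophan, non-water residues are collected into auxiliary atom
    groups keyed ``f"{resname}{chain}"`` (C/N atoms only, per the global
    distance convention).
    """
    sites = indole_sites(model)
    waters = []
    groups = {}
    for chain in model:
        for res in chain:
            if res.name == "TRP":
                continue
            if res.name in WATER_NAMES:
                for atom in res:
                    if atom.element.name == "O":
                        waters.append([atom.pos.x, atom.pos.y, atom.pos.z])
                continue
            key = f"{res.name}{chain.name}"
            for atom in res:
                if _is_cn(atom):
                    groups.setdefault(key, []).append([atom.pos.x, atom.pos.y, atom.pos.z])
    groups = {k: np.asarray(v) for k, v in groups.items()}
    return Frame(
        frame_index=frame_index,
        time=time,
        state=state,
        sites=sites,
        waters=np.asarray(waters).reshape(-1, 3),
        groups=groups,
    )


def _expand_states(states, n_frames: int) -> list:
    if states is None:
        return ["GS"] * n_frames
    if isinstance(states, str):
        return [states] * n_frames
    states = list(states)
    if states and isinstance(states[0], (tuple, list)):
        out = []
        for count, label in states:
            out.extend([label] * int(count))
        if len(out) != n_frames:
            raise ValueError(
                f"state blocks cover {len(out)} frames but trajectory has {n_frames}"
            )
        return out
    if len(states) != n_frames:
        raise ValueError("per-frame state list length mismatch")
    return states


def read_trajectory(path, states=None, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Parameters
    ----------
    states
        State tags: a single label, a per-frame list, a list of
        ``(n_frames, label)`` blocks, or None (tags every frame "GS").
        If a JSON manifest written by the synthetic generator sits next to
        the file (``<stem>.manifest.json``), it is used when ``states`` is
        None.
    dt_ps
        Frame cadence in ps (used when the file carries no time metadata).
    """
    path = Path(path)
    if states is None:
        manifest = path.with_suffix(".manifest.json")
        if manifest.exists():
            meta = json.loads(manifest.read_text())
            states = [tuple(b) for b in meta.get("state_blocks", [])] or None
            dt_ps = meta.get("dt_ps", dt_ps)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    labels = _expand_states(states, len(st))
    frames = [
        model_to_frame(model, i, i * dt_ps, labels[i]) for i, model in enumerate(st)
    ]
    return Trajectory(frames)


def trajectory_to_structure(traj: Trajectory, name: str = "synthetic") -> gemmi.Structure:
    """Build a multi-model gemmi structure from a trajectory.

    Waters become oxygen-only HOH pseudo-residues on chain W.
    """
    st = gemmi.Structure()
    st.name = name
    for f in traj:
        model = gemmi.Model(f.frame_index + 1)
        by_chain = {}
        for label in sorted(f.sites):
            site = f.sites[label]
            res = gemmi.Residue()
            res.name = "TRP"
            res.seqid = gemmi.SeqId(site.residue_number, " ")
            for atom_name, xyz in zip(site.atom_names, site.coords):
                res.add_atom(_make_atom(atom_name, xyz, "N" if atom_name == "NE1" else "C"))
            by_chain.setdefault(site.chain_id, []).append(res)
        for cname in sorted(by_chain):
            chain = gemmi.Chain(cname)
            for res in by_chain[cname]:
                chain.add_residue(res)
            model.add_chain(chain)
        if len(f.waters):
            wchain = gemmi.Chain("W")
            for wi, xyz in enumerate(f.waters, start=1):
                res = gemmi.Residue()
                res.name = "HOH"
                res.seqid = gemmi.SeqId(wi, " ")
                res.het_flag = "H"
                res.add_atom(_make_atom("O", xyz, "O"))
                wchain.add_residue(res)
            model.add_chain(wchain)
        st.add_model(model)
    st.setup_entities()
    return st


def _make_atom(name: str, xyz, element: str) -> gemmi.Atom:
    atom = gemmi.Atom()
    atom.name = name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*map(float, xyz))
    atom.occ = 1.0
    atom.b_iso = 0.0
    return atom


def write_structure(st: gemmi.Structure, path) -> Path:
    """Write a gemmi structure as PDB (.pdb/.ent) or mmCIF (.cif)."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.setup_entities()
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path


def write_trajectory(traj: Trajectory, path, manifest: dict | None = None) -> Path:
    """Write a trajectory as a multi-model PDB plus a JSON state manifest."""
    path = Path(path)
    st = trajectory_to_structure(traj)
    st.write_pdb(str(path))
    blocks = [[len(fr), state] for state, fr in traj.blocks()]
    meta = {"state_blocks": blocks}
    if len(traj) > 1:
        meta["dt_ps"] = traj[1].time - traj[0].time
    if manifest:
        meta.update(manifest)
    path.with_suffix(".manifest.json").write_text(json.dumps(meta, indent=1))
    return path


def write_xyz(path, frames) -> Path:
    """Write frames (or one frame) as a plain multi-frame XYZ stream.

    Atom labels are element symbols; site/water identity is not preserved,
    so XYZ is a lossy export format (coordinates only).
    """
    path = Path(path)
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for f in frames:
            rows = []
            for label in sorted(f.sites):
                site = f.sites[label]
                for name, xyz in zip(site.atom_names, site.coords):
                    rows.append(("N" if name == "NE1" else "C", xyz))
            for xyz in f.waters:
                rows.append(("O", xyz))
            fh.write(f"{len(rows)}\n")
            fh.write(f"frame {f.frame_index} state {f.state} time_ps {f.time}\n")
            for el, xyz in rows:
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    return path


def read_xyz(path) -> list:
    """Read a multi-frame XYZ stream into a list of (elements, coords)."""
    out = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        body = lines[i + 2 : i + 2 + n]
        elements = [ln.split()[0] for ln in body]
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in body])
        out.append((elements, coords))
        i += 2 + n
    return out


def fetch_pdb(pdb_id: str, directory=".", fmt: str = "cif") -> Path:
    """Download a structure from the RCSB (network required; optional helper)."""
    pdb_id = pdb_id.lower()
    suffix = "cif" if fmt == "cif" else "pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.{suffix}"
    dest = Path(directory) / f"{pdb_id}.{suffix}"
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())
    return dest
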