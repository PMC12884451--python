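"""Distance-based structural observables of the tryptophan quadruplex.

Every distance in this package is the minimum over all cross pairs of
C/N heavy atoms of the two groups (hydrogens and backbone disregarded).
Shape and conformer classifiers operate on these shortest distances:

* the Re chromophore is "in" when its dmp ligand sits close to the
  proximal tryptophan (distance distribution peaked at 3-4 Å) and "out"
  when far (5-6 Å); the package cutoff is the midpoint, 4.5 Å;
* the quadruplex is "rhombic" when both intramolecular sides
  (124A-122A and 122D-124D) are short (< 4 Å) and trapezoidal when only
  one of them is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import PAIR_KIND, QUAD_PAIRS, Frame, IndoleSite, Trajectory

#: dmp-indole distance (Å) separating "in" from "out" Re conformers
#: (midpoint of the 3-4 Å and 5-6 Å distribution peaks).
IN_OUT_CUTOFF = 4.5

#: Side length (Å) below which an intramolecular side counts as "short".
SHORT_SIDE_CUTOFF = 4.0


def _coords(obj) -> np.ndarray:
    if isinstance(obj, IndoleSite):
        return obj.coords
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr


def min_site_distance(a, b) -> float:
    """Shortest distance (Å) between two atom groups.

    Arguments may be :class:`IndoleSite` objects or plain (n, 3) coordinate
    arrays already restricted to C/N heavy atoms.  Symmetric in arguments.
    """
    A, B = _coords(a), _coords(b)
    for arr, obj in ((A, a), (B, b)):
        if arr.size == 0:
            label = getattr(obj, "label", "atom group")
            raise ValueError(f"empty atom set for {label}")
    return float(cdist(A, B).min())


@dataclass(frozen=True)
class DistanceRecord:
    pair: tuple  # ordered (site_a, site_b)
    d_min: float  # Å
    kind: str  # side | edge | diagonal | auxiliary


def distance_table(frame: Frame, aux_pairs=None) -> list:
    """All six quadruplex shortest distances for one frame, plus auxiliary
    group-site distances when the atom groups are present.

    ``aux_pairs`` is a list of (group_name, site_label) pairs; by default
    every group in the frame is measured against every site whose label it
    plausibly references is NOT guessed -- auxiliary distances are emitted
    for the conventional observables dmpA-124A, dmpA-122D, SALA-122A and
    SALD-122D whenever those groups exist.
    """
    records = []
    for a, b, kind in QUAD_PAIRS:
        d = min_site_distance(frame.sites[a], frame.sites[b])
        records.append(DistanceRecord((a, b), d, kind))
    if aux_pairs is None:
        aux_pairs = [
            ("dmpA", "124A"),
            ("dmpA", "122D"),
            ("SALA", "122A"),
            ("SALD", "122D"),
        ]
        aux_pairs = [(g, s) for g, s in aux_pairs if g in frame.groups]
    for group, site in aux_pairs:
        if group not in frame.groups:
            raise ValueError(f"frame {frame.frame_index}: atom group {group!r} absent")
        d = min_site_distance(frame.groups[group], frame.sites[site])
        records.append(DistanceRecord((group, site), d, "auxiliary"))
    return records


def distance_frame(traj: Trajectory, aux_pairs=None) -> pd.DataFrame:
    """Per-frame long-format distance table for a whole trajectory."""
    rows = []
    for f in traj:
        for rec in distance_table(f, aux_pairs=aux_pairs):
            rows.append(
                {
                    "frame": f.frame_index,
                    "time_ps": f.time,
                    "state": f.state,
                    "pair": "-".join(rec.pair),
                    "d_min": rec.d_min,
                    "kind": rec.kind,
                }
            )
    return pd.DataFrame(rows)


def classify_re_conformer(d_dmp_trp: float, cutoff: float = IN_OUT_CUTOFF) -> str:
    """Classify the Re chromophore rotamer from the dmp-indole shortest
    distance: "in" if d < cutoff (strict), else "out"."""
    if d_dmp_trp <= 0:
        raise ValueError("distance must be positive")
    return "in" if d_dmp_trp < cutoff else "out"


@dataclass(frozen=True)
class ShapeClass:
    label: str  # rhombic | trapezoid_shortlong | trapezoid_longshort
    both_long: bool = False

    def __str__(self):
        return self.label + ("(both_long)" if self.both_long else "")


def classify_quad_shape(
    side_AA: float, side_DD: float, short_cutoff: float = SHORT_SIDE_CUTOFF
) -> ShapeClass:
    """Classify the quadruplex shape from its two intramolecular sides.

    "Short" means strictly below ``short_cutoff``.  Rhombic iff both sides
    are short; trapezoid_shortlong iff 124A-122A is short and 122D-124D is
    not; trapezoid_longshort for the mirror case.  Frames with both sides
    long are labeled trapezoid by the shorter/longer ordering and flagged
    ``both_long``.
    """
    if side_AA <= 0 or side_DD <= 0:
        raise ValueError("side lengths must be positive")
    aa_short = side_AA < short_cutoff
    dd_short = side_DD < short_cutoff
    if aa_short and dd_short:
        return ShapeClass("rhombic")
    if aa_short:
        return ShapeClass("trapezoid_shortlong")
    if dd_short:
        return ShapeClass("trapezoid_longshort")
    label = "trapezoid_shortlong" if side_AA <= side_DD else "trapezoid_longshort"
    return ShapeClass(label, both_long=True)


@dataclass(frozen=True)
class DistancePredicate:
    """Frame filter on a shortest distance: ``d(a, b) OP threshold``.

    ``a`` and ``b`` name sites or auxiliary atom groups; ``op`` is one of
    "<", "<=", ">", ">=".
    """

    a: str
    b: str
    op: str
    threshold: float

    _OPS = {
        "<": np.less,
        "<=": np.less_equal,
        ">": np.greater,
        ">=": np.greater_equal,
    }

    def __post_init__(self):
        if self.op not in self._OPS:
            raise ValueError(f"unknown operator {self.op!r}")

    def _group(self, frame: Frame, name: str):
        if name in frame.sites:
            return frame.sites[name]
        if name in frame.groups:
            return frame.groups[name]
        raise ValueError(
            f"frame {frame.frame_index}: no site or atom group named {name!r}"
        )

    def __call__(self, frame: Frame) -> bool:
        d = min_site_distance(self._group(frame, self.a), self._group(frame, self.b))
        return bool(self._OPS[self.op](d, self.threshold))

    def describe(self) -> str:
        return f"d({self.a},{self.b}) {self.op} {self.threshold}"


def select_frames(traj, predicates) -> tuple:
    """Frames satisfying the conjunction of all predicates.

    Returns ``(selected_frames, report)`` where the report counts, per
    predicate, how many frames satisfied it individually.  An empty
    predicate set selects every frame.
    """
    frames = list(traj)
    per_pred = {}
    masks = []
    for pred in predicates:
        mask = np.array([pred(f) for f in frames], dtype=bool)
        masks.append(mask)
        per_pred[pred.describe()] = int(mask.sum())
    combined = np.logical_and.reduce(masks) if masks else np.ones(len(frames), bool)
    selected = [f for f, keep in zip(frames, combined) if keep]
    report = {
        "n_frames": len(frames),
        "n_selected": len(selected),
        "per_predicate": per_pred,
    }
    return selected, report


@dataclass
class Map2D:
    """2D histogram of paired distance series (a structural map)."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def modes(self, min_count: int = 1) -> list:
        """Bin-center coordinates of local maxima, highest count first."""
        from scipy.ndimage import maximum_filter

        c = self.counts
        local_max = (c == maximum_filter(c, size=3)) & (c >= min_count)
        xs = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        ys = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        peaks = [(c[i, j], xs[i], ys[j]) for i, j in zip(*np.nonzero(local_max))]
        peaks.sort(reverse=True)
        return [(x, y, int(n)) for n, x, y in peaks]


def structural_map_2d(x_distances, y_distances, bin_width: float = 0.1) -> Map2D:
    """2D structural map correlating two shortest-distance series.

    Bin edges are aligned to multiples of ``bin_width`` so that maps from
    different trajectories share a common grid.  Total counts equal the
    number of frames.
    """
    x = np.asarray(x_distances, float)
    y = np.asarray(y_distances, float)
    if x.shape != y.shape:
        raise ValueError("paired distance series must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    def edges(v):
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        return np.arange(lo, hi + 0.5 * bin_width, bin_width)

    counts, xe, ye = np.histogram2d(x, y, bins=(edges(x), edges(y)))
    return Map2D(counts, xe, ye)


def kabsch(moving: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (rotation + translation) mapping
    ``moving`` onto ``reference``.

    Returns ``(R, t)`` with ``aligned = moving @ R.T + t``.  Raises on
    rank-deficient (degenerate) point sets.
    """
    mov = np.asarray(moving, float)
    ref = np.asarray(reference, float)
    if mov.shape != ref.shape or mov.shape[0] < 3:
        raise ValueError("superposition needs two equal sets of >= 3 points")
    mc, rc = mov.mean(axis=0), ref.mean(axis=0)
    H = (mov - mc).T @ (ref - rc)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate superposition: rank-deficient point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    return R, t
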