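"""Bundled reference tables for the azurin-dimer tryptophan quadruplex.

The published per-step reaction free energies (MM/MD ensembles) and median
electronic couplings (QM/MM/MD diabatic-state analysis) for the four
oxidized states of the {Re126W124W122Cu}2 quadruplex, shipped as
delimited text.  The package consumes these tables as inputs; it does not
recompute them.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .hopnet import _normalize_labels


def _load(name: str) -> pd.DataFrame:
    with resources.files("quadhop.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return _normalize_labels(df.apply(pd.to_numeric, errors="coerce"))


def load_reference_dg() -> pd.DataFrame:
    """Step free energies ΔG (meV), rows = hole donor, columns = acceptor.

    Diagonal entries are zero; the table is antisymmetric.
    """
    return _load("reference_dg_mev.csv")


def load_reference_hab() -> pd.DataFrame:
    """Median electronic couplings H_ab (meV), directional.

    Includes the extra "ReA-" acceptor column where reported; same-site
    entries are missing (NaN).
    """
    return _load("reference_hab_mev.csv")
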