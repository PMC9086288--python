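"""Mass-weighted centres of mass from PDB files (demo convenience).

Wraps MDAnalysis so that real-structure geometry (e.g. a ligand and a
pocket from a deposited complex) can seed a volume specification.  Not
used by any simulation code path; purely a front-end helper.
"""

from __future__ import annotations

import numpy as np

from .errors import SelectionError

__all__ = ["read_structure_com"]


def read_structure_com(path, selection: str) -> np.ndarray:
    """Mass-weighted COM (Å) of an MDAnalysis ``selection`` in a PDB file.

    Atoms with unknown elements fall back to MDAnalysis mass guessing;
    an empty selection raises SelectionError.
    """
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass guessing chatter on minimal PDBs
        u = mda.Universe(str(path))
        group = u.select_atoms(selection)
    if len(group) == 0:
        raise SelectionError(f"selection {selection!r} matches no atoms in {path}")
    masses = np.asarray(group.masses, dtype=float)
    if not np.all(masses > 0):
        masses = np.ones(len(group))
    pos = np.asarray(group.positions, dtype=float)
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()
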