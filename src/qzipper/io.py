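"""Structure and trajectory I/O.

PDB files (Angstrom, CRYST1 box) are handled through biotite; multi-frame
DCD/XYZ trajectories through MDAnalysis.  Internally everything is nm.
"""
from __future__ import annotations

import string
from pathlib import Path

import numpy as np

from .core import Structure, Trajectory

# single-character chain alphabet (PDB column 22); cycled beyond 62 chains,
# in which case residue numbering still disambiguates chain breaks on read
_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_for(index: int) -> str:
    return _CHAIN_ALPHABET[index % len(_CHAIN_ALPHABET)]


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_pdb(structure: Structure, path) -> None:
    """Write a structure as PDB (Angstrom); the box goes to CRYST1."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    if not np.all(np.isfinite(structure.coords)):
        raise ValueError("refusing to write non-finite coordinates")
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32) * 10.0
    arr.atom_name = structure.atom_names.astype(str)
    arr.res_id = structure.resids
    arr.res_name = structure.resnames.astype(str)
    arr.chain_id = np.array(
        [chain_id_for(c) for c in structure.chain_index], dtype="U4"
    )
    arr.element = np.array([_element_of(s) for s in structure.atom_names], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    if structure.box is not None:
        arr.box = np.diag(structure.box * 10.0)
    f = PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def read_pdb(path) -> Structure:
    """Read a PDB file; a missing CRYST1 yields ``box=None``."""
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    box = None
    if arr.box is not None:
        diag = np.diagonal(arr.box)
        if np.all(diag > 0):
            box = diag * 0.1
    # chain boundaries: chain-letter change or residue number decrease
    n = arr.array_length()
    chain_index = np.zeros(n, dtype=int)
    cur = 0
    for i in range(1, n):
        if arr.chain_id[i] != arr.chain_id[i - 1] or arr.res_id[i] < arr.res_id[i - 1]:
            cur += 1
        chain_index[i] = cur
    return Structure(
        coords=arr.coord.astype(float) * 0.1,
        atom_names=arr.atom_name.astype(object),
        resids=arr.res_id.astype(int),
        chain_index=chain_index,
        resnames=arr.res_name.astype(object),
        box=box,
    )


def _mda_universe(topology: Structure, tmpdir=None):
    import tempfile

    import MDAnalysis as mda

    tmp = Path(tempfile.mkdtemp(dir=tmpdir)) / "top.pdb"
    write_pdb(topology, tmp)
    return mda.Universe(str(tmp))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to DCD or XYZ, chosen by file extension."""
    import MDAnalysis as mda

    path = Path(path)
    u = _mda_universe(traj.topology)
    with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.xyz[i] * 10.0
            if traj.topology.box is not None:
                u.dimensions = [*(traj.topology.box * 10.0), 90.0, 90.0, 90.0]
            w.write(u.atoms)


def read_trajectory(top_path, traj_path) -> Trajectory:
    """Read a DCD/XYZ trajectory against a PDB topology."""
    import MDAnalysis as mda

    topology = read_pdb(top_path)
    u = mda.Universe(str(top_path), str(traj_path))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory]) * 0.1
    return Trajectory(xyz=frames, topology=topology)
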