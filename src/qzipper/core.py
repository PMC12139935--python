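"""Shared containers: a lightweight multichain structure and trajectory.

Coordinates are stored in nm; PDB files are read and written in Angstrom
(the conversion lives in :mod:`qzipper.io`).  Chains are tracked with an
explicit integer ``chain_index`` per atom so analyses never have to parse
chain letters.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

NM_PER_ANG = 0.1


@dataclass
class Structure:
    """A single frame of one or more chains.

    Attributes
    ----------
    coords : (n_atoms, 3) float array, nm
    atom_names : (n_atoms,) str array (e.g. "CA", "CG")
    resids : (n_atoms,) int array, 1-based residue number within a chain
    chain_index : (n_atoms,) int array, 0-based chain label
    resnames : (n_atoms,) str array
    box : (3,) float array (nm) or None
    periodic : (3,) bool array — which box axes are treated as periodic
    """

    coords: np.ndarray
    atom_names: np.ndarray
    resids: np.ndarray
    chain_index: np.ndarray
    resnames: np.ndarray
    box: np.ndarray | None = None
    periodic: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=bool)
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.chain_index = np.asarray(self.chain_index, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        n = len(self.coords)
        for arr in (self.atom_names, self.resids, self.chain_index, self.resnames):
            if len(arr) != n:
                raise ValueError("inconsistent per-atom array lengths")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_chains(self) -> int:
        return int(self.chain_index.max()) + 1 if self.n_atoms else 0

    def chains(self) -> Iterator[np.ndarray]:
        """Yield index arrays, one per chain, in chain order."""
        for c in range(self.n_chains):
            yield np.nonzero(self.chain_index == c)[0]

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return replace(
            self,
            coords=self.coords[mask].copy(),
            atom_names=self.atom_names[mask].copy(),
            resids=self.resids[mask].copy(),
            chain_index=self.chain_index[mask].copy(),
            resnames=self.resnames[mask].copy(),
        )

    def atom_index(self, chain: int, resid: int, name: str) -> int:
        hit = np.nonzero(
            (self.chain_index == chain)
            & (self.resids == resid)
            & (self.atom_names == name)
        )[0]
        if hit.size != 1:
            raise KeyError(f"atom {name} of chain {chain} residue {resid}: {hit.size} matches")
        return int(hit[0])

    def residue_atoms(self, chain: int, resid: int) -> np.ndarray:
        return np.nonzero((self.chain_index == chain) & (self.resids == resid))[0]

    def with_coords(self, coords) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def copy(self) -> "Structure":
        return replace(self, coords=self.coords.copy())


@dataclass
class Trajectory:
    """Multiple frames sharing one topology (same atom metadata)."""

    xyz: np.ndarray  # (n_frames, n_atoms, 3) nm
    topology: Structure
    times: np.ndarray | None = None  # ps

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError("trajectory shape does not match topology")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.xyz[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)


def concatenate(structures: list[Structure]) -> Structure:
    """Merge structures, renumbering chains consecutively."""
    if not structures:
        raise ValueError("nothing to concatenate")
    offset = 0
    chains = []
    for s in structures:
        chains.append(s.chain_index + offset)
        offset += s.n_chains
    first = structures[0]
    return Structure(
        coords=np.concatenate([s.coords for s in structures]),
        atom_names=np.concatenate([s.atom_names for s in structures]),
        resids=np.concatenate([s.resids for s in structures]),
        chain_index=np.concatenate(chains),
        resnames=np.concatenate([s.resnames for s in structures]),
        box=first.box,
        periodic=first.periodic,
    )
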