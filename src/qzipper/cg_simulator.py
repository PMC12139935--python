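"""Implicit-solvent Langevin engine for multichain aggregation.

The engine is representation-agnostic: it integrates any set of beads
under harmonic bonds/angles, cosine dihedrals, explicit native 12-6
pairs (truncated and shifted at the global cutoff) and excluded-volume
repulsion between every other non-excluded pair.  The same machinery
minimizes heavy-atom fibril lattices (beads = atoms, restraint topology
from the built geometry) and runs 2-bead/residue aggregation boxes.

Langevin dynamics uses the BAOAB ("middle") splitting.  Units: nm, ps,
kJ/mol, amu, K.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels as K
from .core import Structure, Trajectory

KB = 0.00831446261815324  # kJ/mol/K
N_AVOGADRO = 6.02214076e23

__all__ = [
    "Topology",
    "SimConfig",
    "SystemState",
    "NonbondedTables",
    "SimulationResult",
    "box_side_from_concentration",
    "initialize_system",
    "energy_forces",
    "minimize",
    "run",
    "polyq_bead_topology",
    "restraint_topology",
    "compile_nonbonded",
    "excluded_volume_tables",
    "BONDED_DEFAULTS",
]


#: transferable bonded parameters for the 2-bead/residue polyQ mapping,
#: fit once against the builder's ideal strand and helix traces (r0 from
#: built geometry; soft angle/dihedral terms so contacts, not bonded
#: terms, select secondary structure)
BONDED_DEFAULTS = {
    "bond_bb_r0": 0.381,  # CA(i)-CA(i+1), nm
    "bond_sc_r0": 0.255,  # CA(i)-SC(i), nm
    "bond_k": 8000.0,  # kJ/mol/nm^2
    "angle_bb_theta0": 127.0,  # CA-CA-CA, deg
    "angle_bb_k": 20.0,  # kJ/mol/rad^2
    "angle_sc_theta0": 110.0,  # SC-CA-CA(next), deg
    "angle_sc_k": 20.0,
    "dihedral_bb_phi0": -170.0,  # CA pseudo-dihedral, deg (extended-biased, weak)
    "dihedral_bb_k": 0.5,  # kJ/mol
}


@dataclass
class Topology:
    """Bonded terms and bead bookkeeping for one simulation system."""

    masses: np.ndarray
    bonds: np.ndarray  # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray  # (na, 3) int
    angle_theta0: np.ndarray  # rad
    angle_k: np.ndarray
    dihedrals: np.ndarray  # (nd, 4) int
    dihedral_phi0: np.ndarray  # rad
    dihedral_k: np.ndarray
    chain_of: np.ndarray
    resid_of: np.ndarray
    bead_names: np.ndarray
    exclusion_graph_distance: int = 2
    #: optional harmonic positional restraints toward reference coords
    position_restraint_ref: np.ndarray | None = None
    position_restraint_k: float = 0.0

    def __post_init__(self):
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.dihedrals = np.asarray(self.dihedrals, dtype=np.int64).reshape(-1, 4)
        for b in self.bonds:
            if self.chain_of[b[0]] != self.chain_of[b[1]]:
                raise ValueError("bonds must connect beads within one chain")
        self._excl_keys = None

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def exclusion_keys(self) -> np.ndarray:
        """Sorted i*n+j keys of pairs excluded from nonbonded terms
        (bond-graph distance <= exclusion_graph_distance)."""
        if self._excl_keys is not None:
            return self._excl_keys
        n = self.n_beads
        neigh: dict[int, set[int]] = {i: set() for i in range(n)}
        for a, b in self.bonds:
            neigh[int(a)].add(int(b))
            neigh[int(b)].add(int(a))
        keys = set()
        for i in range(n):
            frontier = {i}
            seen = {i}
            for _ in range(self.exclusion_graph_distance):
                frontier = {x for f in frontier for x in neigh[f]} - seen
                seen |= frontier
            for j in seen:
                if j > i:
                    keys.add(i * n + j)
        self._excl_keys = np.array(sorted(keys), dtype=np.int64)
        return self._excl_keys


@dataclass
class NonbondedTables:
    """Compiled nonbonded interactions for the engine."""

    native_pairs: np.ndarray  # (m, 2) int
    native_eps: np.ndarray
    native_sigma: np.ndarray
    rep_sigma: float = 0.35
    rep_eps: float = 1.0
    cutoff: float = 1.45

    def __post_init__(self):
        self.native_pairs = np.asarray(self.native_pairs, dtype=np.int64).reshape(-1, 2)
        self.native_eps = np.asarray(self.native_eps, dtype=float)
        self.native_sigma = np.asarray(self.native_sigma, dtype=float)


@dataclass
class SimConfig:
    timestep: float = 0.01  # ps
    friction: float = 1.0  # 1/ps
    temperature: float = 300.0  # K
    cutoff: float = 1.45  # nm
    seed: int = 0
    skin: float = 0.3  # nm
    report_interval: int = 1000  # steps

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


@dataclass
class SystemState:
    positions: np.ndarray  # (n, 3) nm
    velocities: np.ndarray  # (n, 3) nm/ps
    box: np.ndarray  # (3,) nm
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))
    step: int = 0
    rng_state: dict | None = None
    minimized: bool = False
    converged: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in system state")

    def copy(self) -> "SystemState":
        return replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
        )


@dataclass
class SimulationResult:
    frames: np.ndarray  # (n_reports, n_beads, 3)
    times: np.ndarray  # ps
    temperatures: np.ndarray  # instantaneous kinetic T per report
    energies: dict  # term -> per-report array
    final_state: SystemState


def box_side_from_concentration(n_chains: int, concentration: float) -> float:
    """Cubic box side (nm) holding ``n_chains`` at ``concentration`` mol/L."""
    if n_chains < 1 or concentration <= 0:
        raise ValueError("need n_chains >= 1 and concentration > 0")
    volume_dm3 = n_chains / (N_AVOGADRO * concentration)
    return float(volume_dm3 ** (1.0 / 3.0) * 1e8)  # dm -> nm


# ----------------------------------------------------------------------
# topology builders


def polyq_bead_topology(
    n_chains: int,
    n_res: int,
    params: dict | None = None,
    mass_backbone: float = 57.0,
    mass_sidechain: float = 72.0,
) -> tuple[Topology, Structure]:
    """2-bead/residue polyQ topology (backbone bead at CA, side-chain
    bead at CG) with transferable bonded terms.

    Returns the topology and a matching bead Structure template (all
    coordinates zero) for trajectory bookkeeping.
    """
    p = dict(BONDED_DEFAULTS)
    if params:
        p.update(params)
    per = 2 * n_res
    n = n_chains * per
    masses = np.empty(n)
    chain_of = np.empty(n, dtype=np.int64)
    resid_of = np.empty(n, dtype=np.int64)
    names = np.empty(n, dtype=object)
    bonds, b_r0 = [], []
    angles, a_t0 = [], []
    dihedrals, d_p0 = [], []
    for c in range(n_chains):
        base = c * per
        for r in range(n_res):
            bb = base + 2 * r
            sc = bb + 1
            masses[bb], masses[sc] = mass_backbone, mass_sidechain
            chain_of[bb] = chain_of[sc] = c
            resid_of[bb] = resid_of[sc] = r + 1
            names[bb], names[sc] = "CA", "SC"
            bonds.append((bb, sc))
            b_r0.append(p["bond_sc_r0"])
            if r + 1 < n_res:
                bonds.append((bb, bb + 2))
                b_r0.append(p["bond_bb_r0"])
        for r in range(n_res - 2):
            bb = base + 2 * r
            angles.append((bb, bb + 2, bb + 4))
            a_t0.append(np.radians(p["angle_bb_theta0"]))
        for r in range(n_res - 1):
            sc = base + 2 * r + 1
            angles.append((sc, sc - 1, sc + 1))
            a_t0.append(np.radians(p["angle_sc_theta0"]))
        for r in range(n_res - 3):
            bb = base + 2 * r
            dihedrals.append((bb, bb + 2, bb + 4, bb + 6))
            d_p0.append(np.radians(p["dihedral_bb_phi0"]))
    topo = Topology(
        masses=masses,
        bonds=np.array(bonds) if bonds else np.empty((0, 2)),
        bond_r0=np.array(b_r0),
        bond_k=np.full(len(b_r0), p["bond_k"]),
        angles=np.array(angles) if angles else np.empty((0, 3)),
        angle_theta0=np.array(a_t0),
        angle_k=np.full(len(a_t0), p["angle_bb_k"]),
        dihedrals=np.array(dihedrals) if dihedrals else np.empty((0, 4)),
        dihedral_phi0=np.array(d_p0),
        dihedral_k=np.full(len(d_p0), p["dihedral_bb_k"]),
        chain_of=chain_of,
        resid_of=resid_of,
        bead_names=names,
    )
    template = Structure(
        coords=np.zeros((n, 3)),
        atom_names=names.copy(),
        resids=resid_of.copy(),
        chain_index=chain_of.copy(),
        resnames=np.array(["GLN"] * n, dtype=object),
    )
    return topo, template


def restraint_topology(
    structure: Structure,
    bond_k: float = 20000.0,
    angle_k: float = 300.0,
    dihedral_k: float = 40.0,
) -> Topology:
    """Restraint topology built from an existing heavy-atom structure.

    Bond lengths, angles and torsions are restrained at their *built*
    values, so only the excluded-volume term can drive motion during
    minimization — the engine-level realization of excluded-volume
    relaxation for all-atom lattices.
    """
    from .fibril_builder import _bond_pairs
    from .geometry import measure_angle, measure_dihedral

    coords = structure.coords
    bonds = np.array(_bond_pairs(structure), dtype=np.int64)
    bond_r0 = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)

    neigh: dict[int, list[int]] = {}
    for a, b in bonds:
        neigh.setdefault(int(a), []).append(int(b))
        neigh.setdefault(int(b), []).append(int(a))
    angles = []
    for j, partners in neigh.items():
        ps = sorted(partners)
        for x in range(len(ps)):
            for y in range(x + 1, len(ps)):
                angles.append((ps[x], j, ps[y]))
    angles = np.array(angles, dtype=np.int64)
    theta0 = np.array(
        [np.radians(measure_angle(coords[i], coords[j], coords[k])) for i, j, k in angles]
    )
    # torsions: one per central bond with both ends extendable
    dihedrals = []
    for a, b in bonds:
        a, b = int(a), int(b)
        exts_a = [x for x in neigh[a] if x != b]
        exts_b = [x for x in neigh[b] if x != a]
        if exts_a and exts_b:
            dihedrals.append((min(exts_a), a, b, min(exts_b)))
    dihedrals = np.array(dihedrals, dtype=np.int64)
    phi0 = np.array(
        [
            np.radians(measure_dihedral(coords[i], coords[j], coords[k], coords[l]))
            for i, j, k, l in dihedrals
        ]
    )
    return Topology(
        masses=np.full(structure.n_atoms, 14.0),
        bonds=bonds,
        bond_r0=bond_r0,
        bond_k=np.full(len(bonds), bond_k),
        angles=angles,
        angle_theta0=theta0,
        angle_k=np.full(len(angles), angle_k),
        dihedrals=dihedrals,
        dihedral_phi0=phi0,
        dihedral_k=np.full(len(dihedrals), dihedral_k),
        chain_of=structure.chain_index.astype(np.int64),
        resid_of=structure.resids.astype(np.int64),
        bead_names=structure.atom_names.copy(),
    )


def compile_nonbonded(potential, topology: Topology) -> NonbondedTables:
    """Project a residue-level MultiStatePotential onto bead pairs.

    Each native residue pair maps to the side-chain beads of the two
    residues (falling back to the backbone bead where no side-chain
    bead exists); intrachain records are replicated per chain,
    interchain records applied between every chain pair with the
    intermolecular epsilon equal to the intramolecular one.

    Energy-preserving resolution reduction: a single bead pair stands
    in for all the atomic contacts of the residue pair, so its well
    depth is epsilon times the recorded contact multiplicity (the mean
    number of site pairs within the contact cutoff in the source
    ensemble).  Without this factor a residue-level projection of an
    atomic-resolution contact model underestimates cohesion roughly
    tenfold.
    """
    n_chains = int(topology.chain_of.max()) + 1 if topology.n_beads else 0
    bead_of: dict[tuple, int] = {}
    for idx in range(topology.n_beads):
        key = (int(topology.chain_of[idx]), int(topology.resid_of[idx]))
        name = topology.bead_names[idx]
        if name == "SC" or key not in bead_of:
            bead_of[key] = idx

    pairs, eps, sig = [], [], []

    def eps_of(row):
        base = potential.epsilon
        if potential.epsilon_mode == "probability":
            base = base * float(row["probability"])
        try:
            mult = float(row["multiplicity"])
        except (KeyError, TypeError):
            mult = 1.0
        return base * max(mult, 1.0)

    for _, row in potential.pairs.iterrows():
        if row["class"] != "native":
            continue
        ri, rj = int(row["res_i"]), int(row["res_j"])
        e, s = eps_of(row), float(row["sigma_nm"])
        if e <= 0:
            continue
        if row["scope"] == "intra":
            for c in range(n_chains):
                if (c, ri) in bead_of and (c, rj) in bead_of:
                    pairs.append((bead_of[(c, ri)], bead_of[(c, rj)]))
                    eps.append(e)
                    sig.append(s)
        else:
            for a in range(n_chains):
                for b in range(a + 1, n_chains):
                    combos = {(bead_of.get((a, ri)), bead_of.get((b, rj))),
                              (bead_of.get((a, rj)), bead_of.get((b, ri)))}
                    for i, j in combos:
                        if i is None or j is None:
                            continue
                        pairs.append((i, j))
                        eps.append(e)
                        sig.append(s)
    return NonbondedTables(
        native_pairs=np.array(pairs, dtype=np.int64) if pairs else np.empty((0, 2), dtype=np.int64),
        native_eps=np.array(eps),
        native_sigma=np.array(sig),
        rep_sigma=potential.sigma_rep,
        rep_eps=potential.epsilon,
        cutoff=potential.cutoff,
    )


def excluded_volume_tables(sigma_rep: float = 0.30, rep_eps: float = 1.0,
                           cutoff: float = 1.45) -> NonbondedTables:
    """Purely repulsive nonbonded tables (no native pairs)."""
    return NonbondedTables(
        native_pairs=np.empty((0, 2), dtype=np.int64),
        native_eps=np.empty(0),
        native_sigma=np.empty(0),
        rep_sigma=sigma_rep,
        rep_eps=rep_eps,
        cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# initialization


def initialize_system(
    n_chains: int,
    concentration: float,
    monomer_conformer_pool: list,
    topology: Topology,
    seed: int,
    temperature: float = 300.0,
    min_distance: float = 0.4,
    max_attempts: int = 500,
) -> SystemState:
    """Place chains at random positions/orientations in a cubic box.

    Each chain's conformation is drawn from ``monomer_conformer_pool``
    (arrays of per-chain bead coordinates).  Placements are rejection
    sampled so no interchain bead pair comes below ``min_distance`` nm;
    velocities are Maxwell-Boltzmann at ``temperature``.
    """
    if not monomer_conformer_pool:
        raise ValueError("monomer conformer pool is empty")
    side = box_side_from_concentration(n_chains, concentration)
    box = np.array([side, side, side])
    rng = np.random.default_rng(seed)
    per_chain = topology.n_beads // n_chains
    placed: list[np.ndarray] = []
    all_pts: list[np.ndarray] = []
    for _ in range(n_chains):
        ok = False
        for _attempt in range(max_attempts):
            conf = monomer_conformer_pool[rng.integers(len(monomer_conformer_pool))]
            conf = np.asarray(conf, dtype=float)
            if conf.shape[0] != per_chain:
                raise ValueError("pool conformer bead count does not match topology")
            conf = conf - conf.mean(axis=0)
            # uniform random rotation via QR of a Gaussian matrix
            q, r = np.linalg.qr(rng.standard_normal((3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            pos = conf @ q.T + rng.uniform(0.0, side, size=3)
            if all_pts:
                tree = cKDTree(
                    np.concatenate(all_pts), boxsize=box
                )
                if tree.query(np.mod(pos, box), k=1)[0].min() < min_distance:
                    continue
            placed.append(pos)
            all_pts.append(np.mod(pos, box))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                "chain placement failed: packing too dense - use a larger box"
            )
    positions = np.concatenate(placed)
    sigma_v = np.sqrt(KB * temperature / topology.masses)[:, None]
    velocities = rng.standard_normal((topology.n_beads, 3)) * sigma_v
    return SystemState(
        positions=positions,
        velocities=velocities,
        box=box,
        periodic=np.ones(3, dtype=bool),
        rng_state=rng.bit_generator.state,
    )


# ----------------------------------------------------------------------
# energies and forces


def _pair_list(state: SystemState, topology: Topology, nonbonded: NonbondedTables, rlist: float):
    excl = topology.exclusion_keys()
    n = topology.n_beads
    native_keys = np.sort(
        np.minimum(nonbonded.native_pairs[:, 0], nonbonded.native_pairs[:, 1]) * n
        + np.maximum(nonbonded.native_pairs[:, 0], nonbonded.native_pairs[:, 1])
    ) if len(nonbonded.native_pairs) else np.empty(0, dtype=np.int64)
    all_excl = np.unique(np.concatenate([excl, native_keys])).astype(np.int64)
    return K.build_pair_list(
        state.positions, state.box, state.periodic, rlist, all_excl, n
    )


def energy_forces(
    state: SystemState,
    topology: Topology,
    nonbonded: NonbondedTables,
    pairs: np.ndarray | None = None,
    native_idx: np.ndarray | None = None,
):
    """Total energy (kJ/mol), per-term decomposition, and forces.

    Forces are exact negative gradients of the implemented energy;
    minimum-image convention applies on periodic axes.
    """
    pos = state.positions
    if np.any(~np.isfinite(pos)):
        raise FloatingPointError("non-finite positions")
    forces = np.zeros_like(pos)
    per = np.asarray(state.periodic, dtype=np.bool_)
    terms = {}
    if (
        topology.position_restraint_ref is not None
        and topology.position_restraint_k > 0
    ):
        dx = pos - topology.position_restraint_ref
        terms["posres"] = 0.5 * topology.position_restraint_k * float((dx ** 2).sum())
        forces -= topology.position_restraint_k * dx
    terms["bond"] = K.bond_energy_forces(
        pos, topology.bonds, topology.bond_r0, topology.bond_k, state.box, per, forces
    ) if len(topology.bonds) else 0.0
    terms["angle"] = K.angle_energy_forces(
        pos, topology.angles, topology.angle_theta0, topology.angle_k, state.box, per, forces
    ) if len(topology.angles) else 0.0
    terms["dihedral"] = K.dihedral_energy_forces(
        pos, topology.dihedrals, topology.dihedral_phi0, topology.dihedral_k, state.box, per, forces
    ) if len(topology.dihedrals) else 0.0
    if native_idx is not None:
        np_pairs = nonbonded.native_pairs[native_idx]
        np_eps = nonbonded.native_eps[native_idx]
        np_sig = nonbonded.native_sigma[native_idx]
    else:
        np_pairs = nonbonded.native_pairs
        np_eps = nonbonded.native_eps
        np_sig = nonbonded.native_sigma
    terms["native"] = K.native_energy_forces(
        pos,
        np_pairs,
        np_eps,
        np_sig,
        nonbonded.cutoff,
        state.box,
        per,
        forces,
    ) if len(np_pairs) else 0.0
    if pairs is None:
        pairs = _pair_list(state, topology, nonbonded, nonbonded.rep_sigma)
    terms["repulsive"] = K.repulsive_energy_forces(
        pos, pairs, nonbonded.rep_sigma, nonbonded.rep_eps, state.box, per, forces
    ) if len(pairs) else 0.0
    total = float(sum(terms.values()))
    return total, terms, forces


def minimize(
    state: SystemState,
    topology: Topology,
    nonbonded: NonbondedTables,
    fmax: float = 1000.0,
    max_steps: int = 2000,
    initial_step: float = 0.001,
) -> SystemState:
    """Steepest descent until max |force| < fmax kJ/mol/nm.

    Energy is non-increasing across accepted steps; returns the first
    converged state, or the lowest-energy state seen with
    ``converged=False`` after ``max_steps``.
    """
    st = state.copy()
    if not np.isfinite(fmax):
        st.minimized = True
        return st

    skin = 0.3
    rlist = nonbonded.rep_sigma + skin
    nlist = nonbonded.cutoff + skin
    per_flags = np.asarray(st.periodic, dtype=np.bool_)

    def rebuild(positions):
        probe = replace(st, positions=positions)
        pairs = _pair_list(probe, topology, nonbonded, rlist)
        if len(nonbonded.native_pairs):
            nidx = K.filter_active_pairs(
                positions, nonbonded.native_pairs, st.box, per_flags, nlist
            )
        else:
            nidx = None
        return pairs, nidx

    pairs, nidx = rebuild(st.positions)
    ref_pos = st.positions.copy()

    def evaluate(positions):
        nonlocal pairs, nidx, ref_pos
        if np.abs(positions - ref_pos).max() > skin / 2:
            pairs, nidx = rebuild(positions)
            ref_pos = positions.copy()
        return energy_forces(
            replace(st, positions=positions), topology, nonbonded, pairs, nidx
        )

    e, _, f = evaluate(st.positions)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite initial energy")
    best = st.positions.copy()
    best_e = e
    h = initial_step
    for it in range(max_steps):
        fnorm = np.abs(f).max()
        if fnorm < fmax:
            st.minimized = True
            st.converged = True
            return st
        step = h * f / max(fnorm, 1e-12)
        trial = st.positions + step
        e_t, _, f_t = evaluate(trial)
        if not np.isfinite(e_t):
            raise FloatingPointError(f"non-finite energy at minimization step {it}")
        if e_t <= e:
            st.positions = trial
            e, f = e_t, f_t
            h = min(h * 1.2, 0.05)
            if e < best_e:
                best_e, best = e, trial.copy()
        else:
            h *= 0.5
            if h < 1e-10:
                break
    st.positions = best
    st.minimized = True
    st.converged = bool(np.abs(evaluate(st.positions)[2]).max() < fmax)
    return st


def run(
    state: SystemState,
    topology: Topology,
    nonbonded: NonbondedTables,
    config: SimConfig,
    n_steps: int,
    z_wall: bool = False,
) -> SimulationResult:
    """BAOAB Langevin dynamics in the NVT ensemble.

    Frames, instantaneous kinetic temperature and energy terms are
    recorded every ``config.report_interval`` steps.  Identical seed and
    state give identical trajectories.  A persistent thermal blow-up
    (T > 10x target) aborts with diagnostics.
    """
    st = state.copy()
    rng = np.random.default_rng(config.seed)
    if st.rng_state is not None:
        pass  # placement RNG is independent of the dynamics RNG
    dt = config.timestep
    gamma = config.friction
    masses = topology.masses[:, None]
    kT = KB * config.temperature
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kT / masses)

    rlist = nonbonded.rep_sigma + config.skin
    nlist = nonbonded.cutoff + config.skin
    per_flags = np.asarray(st.periodic, dtype=np.bool_)
    pairs = _pair_list(st, topology, nonbonded, rlist)

    def native_active():
        if len(nonbonded.native_pairs) == 0:
            return None
        return K.filter_active_pairs(
            st.positions, nonbonded.native_pairs, st.box, per_flags, nlist
        )

    native_idx = native_active()
    ref_pos = st.positions.copy()

    if not st.minimized:
        import warnings

        warnings.warn("running dynamics from an unminimized state", stacklevel=2)

    frames, times, temps = [], [], []
    eterms: dict[str, list] = {}
    n_dof = 3 * topology.n_beads
    _, terms, forces = energy_forces(st, topology, nonbonded, pairs, native_idx)

    blowups = 0
    for step in range(n_steps):
        v = st.velocities
        v += 0.5 * dt * forces / masses  # B
        st.positions += 0.5 * dt * v  # A
        if gamma > 0:
            v *= c1
            v += c2 * sigma_v * rng.standard_normal(v.shape)  # O
        st.positions += 0.5 * dt * v  # A
        if z_wall and not st.periodic[2]:
            hi = st.box[2]
            over = st.positions[:, 2] > hi
            st.positions[over, 2] = 2 * hi - st.positions[over, 2]
            v[over, 2] *= -1
            under = st.positions[:, 2] < 0
            st.positions[under, 2] = -st.positions[under, 2]
            v[under, 2] *= -1
        disp = np.abs(st.positions - ref_pos).max()
        if disp > config.skin / 2:
            pairs = _pair_list(st, topology, nonbonded, rlist)
            native_idx = native_active()
            ref_pos = st.positions.copy()
        _, terms, forces = energy_forces(st, topology, nonbonded, pairs, native_idx)
        v += 0.5 * dt * forces / masses  # B
        st.step += 1

        if (step + 1) % config.report_interval == 0 or step == n_steps - 1:
            ke = 0.5 * float(np.sum(topology.masses[:, None] * v * v))
            t_inst = 2.0 * ke / (n_dof * KB)
            frames.append(st.positions.copy())
            times.append(st.step * dt)
            temps.append(t_inst)
            for k2, v2 in terms.items():
                eterms.setdefault(k2, []).append(float(v2))
            if gamma > 0 and t_inst > 10.0 * config.temperature:
                blowups += 1
                if blowups >= 3:
                    raise FloatingPointError(
                        f"thermal blow-up: T={t_inst:.0f} K at step {st.step} "
                        "(check timestep/topology)"
                    )
            else:
                blowups = 0
    return SimulationResult(
        frames=np.array(frames),
        times=np.array(times),
        temperatures=np.array(temps),
        energies={k2: np.array(v2) for k2, v2 in eterms.items()},
        final_state=st,
    )


def result_trajectory(result: SimulationResult, template: Structure, box=None) -> Trajectory:
    """Wrap raw simulation frames into a Trajectory for analysis."""
    top = template.copy()
    if box is not None:
        top.box = np.asarray(box, dtype=float)
        top.periodic = np.ones(3, dtype=bool)
    return Trajectory(xyz=result.frames, topology=top, times=result.times)
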