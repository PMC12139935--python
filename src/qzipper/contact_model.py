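"""Multi-state native-contact potentials.

Native contacts are learned separately from ensembles representing the
free-energy minima of an aggregating peptide — the soluble monomer, the
fibril (semi-infinite lattice), and optionally a dense multichain phase
for flanking-domain interactions — and merged into one pair potential:

* native pairs: 12-6 Lennard-Jones, truncated and shifted at the global
  cutoff, with a single reference interaction strength ``epsilon``
  shared by intra- and intermolecular contacts;
* all other pairs: excluded-volume repulsion;
* interchain pairs between flanking domains (N17/P5) and the polyQ core
  are forced repulsive regardless of what any source ensemble shows, so
  the flanking domains cannot frustrate fibril growth.

Distances in nm, energies in kJ/mol.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Structure, Trajectory

__all__ = [
    "DomainMask",
    "ContactMatrix",
    "MultiStatePotential",
    "EnsembleStats",
    "extract_contact_matrix",
    "merge_states",
    "pair_energy",
    "calibrate_epsilon",
    "q16_reference_potential",
    "h16_reference_potential",
    "shift_residues",
    "H16_DOMAIN_MASK",
    "Q16_DOMAIN_MASK",
]

SIXTH_ROOT_OF_TWO = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class DomainMask:
    """Named contiguous residue ranges covering a chain."""

    ranges: tuple  # ((name, first, last), ...) 1-based inclusive

    def __post_init__(self):
        prev_last = 0
        for name, first, last in self.ranges:
            if first != prev_last + 1:
                raise ValueError(f"domain {name} not contiguous with predecessor")
            if last < first:
                raise ValueError(f"domain {name} has negative extent")
            prev_last = last

    @property
    def n_residues(self) -> int:
        return self.ranges[-1][2]

    def domain_of(self, resid: int) -> str:
        for name, first, last in self.ranges:
            if first <= resid <= last:
                return name
        raise KeyError(f"residue {resid} outside mask")

    def residues(self, name: str) -> range:
        for nm, first, last in self.ranges:
            if nm == name:
                return range(first, last + 1)
        raise KeyError(name)

    @property
    def names(self):
        return tuple(r[0] for r in self.ranges)


#: Httex1-like H16 construct: N17 helix, 16 glutamines, 5 prolines
H16_DOMAIN_MASK = DomainMask((("N17", 1, 17), ("Q16", 18, 33), ("P5", 34, 38)))
#: bare polyQ tract
Q16_DOMAIN_MASK = DomainMask((("Q16", 1, 16),))


@dataclass
class ContactMatrix:
    """Residue-pair contact probabilities from one source ensemble."""

    entries: pd.DataFrame  # columns: scope, res_i, res_j, probability, mean_distance_nm
    source: str  # monomer | fibril | dense
    cutoff: float  # nm
    n_frames: int

    def __post_init__(self):
        need = {"scope", "res_i", "res_j", "probability", "mean_distance_nm"}
        if not need.issubset(self.entries.columns):
            raise ValueError(f"entries missing columns {need - set(self.entries.columns)}")
        p = self.entries["probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities outside [0, 1]")
        if (self.entries["mean_distance_nm"] <= 0).any():
            raise ValueError("non-positive contact distances")

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        df["source"] = self.source
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cutoff: float = 0.6, n_frames: int = 0) -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t")
        source = df["source"].iloc[0] if "source" in df and len(df) else "unknown"
        return cls(
            entries=df.drop(columns=["source"], errors="ignore"),
            source=str(source),
            cutoff=cutoff,
            n_frames=n_frames,
        )

    def lookup(self, scope: str) -> pd.DataFrame:
        return self.entries[self.entries["scope"] == scope]

    def as_dense(self, n_res: int, scope: str) -> np.ndarray:
        mat = np.zeros((n_res, n_res))
        sub = self.lookup(scope)
        i = sub["res_i"].to_numpy() - 1
        j = sub["res_j"].to_numpy() - 1
        mat[i, j] = sub["probability"].to_numpy()
        mat[j, i] = sub["probability"].to_numpy()
        return mat


@dataclass
class MultiStatePotential:
    """Merged pair potential over residue pairs.

    ``pairs`` rows: scope (intra|inter), res_i, res_j, class
    (native|repulsive), sigma_nm, source.  ``epsilon`` is the global
    native interaction strength; ``epsilon_mode`` selects the flat
    assignment (every native pair gets ``epsilon``) or the
    probability-weighted variant (``epsilon * p_ij``).
    """

    pairs: pd.DataFrame
    epsilon: float  # kJ/mol
    sigma_rep: float = 0.35  # nm
    cutoff: float = 1.45  # nm
    epsilon_mode: str = "flat"  # flat | probability
    domain_mask: DomainMask | None = None
    bonded_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.epsilon_mode not in ("flat", "probability"):
            raise ValueError("epsilon_mode must be 'flat' or 'probability'")

    def native_pairs(self, scope: str) -> pd.DataFrame:
        return self.pairs[(self.pairs["class"] == "native") & (self.pairs["scope"] == scope)]

    def epsilon_of(self, row) -> float:
        if self.epsilon_mode == "probability":
            return self.epsilon * float(row["probability"])
        return self.epsilon

    # -- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "epsilon": self.epsilon,
            "sigma_rep": self.sigma_rep,
            "cutoff": self.cutoff,
            "epsilon_mode": self.epsilon_mode,
            "bonded_params": self.bonded_params,
            "domain_mask": list(self.domain_mask.ranges) if self.domain_mask else None,
            "pairs": self.pairs.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MultiStatePotential":
        with open(path) as fh:
            payload = json.load(fh)
        mask = payload.get("domain_mask")
        return cls(
            pairs=pd.DataFrame(payload["pairs"]),
            epsilon=payload["epsilon"],
            sigma_rep=payload["sigma_rep"],
            cutoff=payload["cutoff"],
            epsilon_mode=payload.get("epsilon_mode", "flat"),
            domain_mask=DomainMask(tuple(tuple(r) for r in mask)) if mask else None,
            bonded_params=payload.get("bonded_params", {}),
        )


@dataclass
class EnsembleStats:
    """Reference observables for calibration."""

    rg_samples: np.ndarray  # nm
    contact_map: np.ndarray | None = None  # (n_res, n_res) intra probabilities
    ss_fractions: np.ndarray | None = None

    def __post_init__(self):
        self.rg_samples = np.asarray(self.rg_samples, dtype=float)
        if (self.rg_samples <= 0).any():
            raise ValueError("non-positive radius of gyration")


# ----------------------------------------------------------------------
# contact extraction


def _residue_sites(structure: Structure):
    """site index lists keyed by (chain, resid), in deterministic order."""
    keys = []
    sites = {}
    for idx in range(structure.n_atoms):
        key = (int(structure.chain_index[idx]), int(structure.resids[idx]))
        if key not in sites:
            sites[key] = []
            keys.append(key)
        sites[key].append(idx)
    return keys, sites


def contact_pairs_bruteforce(coords, cutoff):
    """All site pairs within cutoff — O(N^2) reference implementation."""
    n = len(coords)
    out = set()
    for i in range(n):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        for j in np.nonzero(d < cutoff)[0]:
            out.add((i, int(i + 1 + j)))
    return out


def contact_pairs_celllist(coords, cutoff):
    """All site pairs within cutoff via spatial binning (cell list)."""
    coords = np.asarray(coords)
    cells: dict[tuple, list[int]] = {}
    inv = 1.0 / cutoff
    keys = np.floor(coords * inv).astype(np.int64)
    for idx, key in enumerate(map(tuple, keys)):
        cells.setdefault(key, []).append(idx)
    out = set()
    for (cx, cy, cz), members in cells.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    other = cells.get((cx + dx, cy + dy, cz + dz))
                    if other is None:
                        continue
                    for i in members:
                        for j in other:
                            if j <= i:
                                continue
                            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                                out.add((i, j))
    return out


def extract_contact_matrix(
    trajectory: Trajectory,
    cutoff: float = 0.6,
    scope: str = "intra",
    min_probability: float = 0.05,
    min_sequence_separation: int = 2,
) -> ContactMatrix:
    """Residue-pair contact probabilities over a trajectory.

    A residue pair is in contact in a frame when any site of one is
    within ``cutoff`` of any site of the other.  The recorded mean
    distance is measured between the residues' *representative* sites
    (the side-chain bead, or the CG atom of a heavy-atom glutamine),
    i.e. the sites the simulator's bead projection will couple, so the
    derived pair minimum sits where the source geometry actually puts
    the beads.  Intrachain pairs closer in sequence than
    ``min_sequence_separation`` are ignored (trivially bonded).
    Interchain probabilities are averaged over all ordered chain pairs
    and symmetrized.  Pairs below ``min_probability`` are dropped.
    """
    if trajectory.n_frames < 1:
        raise ValueError("empty trajectory")
    if scope not in ("intra", "inter"):
        raise ValueError("scope must be 'intra' or 'inter'")
    top = trajectory.topology
    keys, sites = _residue_sites(top)
    n_chains = top.n_chains
    if scope == "inter" and n_chains < 2:
        raise ValueError("interchain extraction needs at least two chains")

    hits: dict[tuple, int] = {}
    dist_sums: dict[tuple, float] = {}
    mult_sums: dict[tuple, float] = {}
    site_of = np.empty(top.n_atoms, dtype=np.int64)
    for k, key in enumerate(keys):
        for idx in sites[key]:
            site_of[idx] = k
    # representative site per residue: side-chain bead / CG atom when
    # present, else the first site
    rep_site = {}
    for key in keys:
        rep = sites[key][0]
        for idx in sites[key]:
            if top.atom_names[idx] in ("SC", "CG"):
                rep = idx
                break
        rep_site[key] = rep

    for f in range(trajectory.n_frames):
        coords = trajectory.xyz[f]
        tree = cKDTree(coords)
        seen: dict[tuple, tuple] = {}
        for i, j in tree.query_pairs(cutoff):
            ki, kj = keys[site_of[i]], keys[site_of[j]]
            if ki == kj:
                continue
            same_chain = ki[0] == kj[0]
            if scope == "intra":
                if not same_chain or abs(ki[1] - kj[1]) < min_sequence_separation:
                    continue
            else:
                if same_chain:
                    continue
            ri, rj = min(ki[1], kj[1]), max(ki[1], kj[1])
            if scope == "inter":
                # track per chain pair so distances/multiplicities are
                # per contacting chain-pair instance
                pair = (min(ki[0], kj[0]), max(ki[0], kj[0]), ri, rj)
            else:
                pair = (ki[0], ri, rj)
            rep_d = float(
                np.linalg.norm(coords[rep_site[ki]] - coords[rep_site[kj]])
            )
            if pair not in seen:
                seen[pair] = (rep_d, 1)
            else:
                prev_d, cnt = seen[pair]
                seen[pair] = (min(prev_d, rep_d), cnt + 1)
        for pair, (d, mult) in seen.items():
            key = pair[-2:] if scope == "inter" else pair
            hits[key] = hits.get(key, 0) + 1
            dist_sums[key] = dist_sums.get(key, 0.0) + d
            mult_sums[key] = mult_sums.get(key, 0.0) + mult

    if scope == "intra":
        denom = trajectory.n_frames * n_chains
        # pool over chains: (chain, i, j) -> (i, j)
        pooled_hits: dict[tuple, int] = {}
        pooled_d: dict[tuple, float] = {}
        pooled_m: dict[tuple, float] = {}
        for (c, i, j), h in hits.items():
            pooled_hits[(i, j)] = pooled_hits.get((i, j), 0) + h
            pooled_d[(i, j)] = pooled_d.get((i, j), 0.0) + dist_sums[(c, i, j)]
            pooled_m[(i, j)] = pooled_m.get((i, j), 0.0) + mult_sums[(c, i, j)]
        hits, dist_sums, mult_sums = pooled_hits, pooled_d, pooled_m
    else:
        # each frame contributes per unordered chain pair at most once,
        # counted over ordered pairs then halved by symmetry
        denom = trajectory.n_frames * (n_chains * (n_chains - 1) // 2)

    rows = []
    for (i, j), h in sorted(hits.items()):
        p = h / denom
        if p < min_probability:
            continue
        rows.append(
            dict(
                scope=scope,
                res_i=i,
                res_j=j,
                probability=p,
                mean_distance_nm=dist_sums[(i, j)] / h,
                multiplicity=mult_sums[(i, j)] / h,
            )
        )
    entries = pd.DataFrame(
        rows,
        columns=[
            "scope", "res_i", "res_j", "probability", "mean_distance_nm",
            "multiplicity",
        ],
    )
    return ContactMatrix(
        entries=entries, source="unknown", cutoff=cutoff, n_frames=trajectory.n_frames
    )


# ----------------------------------------------------------------------
# state merging


def merge_states(
    monomer: ContactMatrix,
    fibril: ContactMatrix,
    dense: ContactMatrix | None,
    mask: DomainMask,
    epsilon: float = 0.4,
    sigma_rep: float = 0.35,
    cutoff: float = 1.45,
    epsilon_mode: str = "flat",
) -> MultiStatePotential:
    """Merge per-state contact matrices into one multi-state potential.

    Intramolecular contacts come from the monomer ensemble; polyQ-core
    interchain contacts from the fibril ensemble; flanking-domain
    interchain contacts from the dense phase (when given).  Conflicting
    claims resolve by precedence fibril > dense > monomer (logged in
    the ``conflicts`` attribute).  Every interchain pair coupling a
    flanking domain to the polyQ core is forced repulsive.
    """
    core = "Q16" if "Q16" in mask.names else mask.names[0]
    flanking = [n for n in mask.names if n != core]

    records: dict[tuple, dict] = {}
    conflicts = []

    def add(scope, res_i, res_j, prob, dist, source, mult):
        key = (scope, min(res_i, res_j), max(res_i, res_j))
        rec = dict(
            scope=scope, res_i=key[1], res_j=key[2], probability=prob,
            sigma_nm=dist / SIXTH_ROOT_OF_TWO, multiplicity=mult,
            source=source, **{"class": "native"},
        )
        if key in records:
            old = records[key]
            precedence = {"fibril": 2, "dense": 1, "monomer": 0}
            if precedence[source] > precedence[old["source"]]:
                conflicts.append((key, old["source"], source))
                records[key] = rec
            else:
                conflicts.append((key, source, old["source"]))
            return
        records[key] = rec

    n_res = mask.n_residues
    for cm, source in ((monomer, "monomer"), (fibril, "fibril"), (dense, "dense")):
        if cm is None:
            continue
        for _, row in cm.entries.iterrows():
            ri, rj = int(row["res_i"]), int(row["res_j"])
            if ri > n_res or rj > n_res:
                raise ValueError(f"residue pair ({ri},{rj}) outside domain mask")
            scope = str(row["scope"])
            if source == "monomer" and scope != "intra":
                continue
            if source == "fibril" and scope == "inter":
                # fibril state informs only the core's self-assembly
                if mask.domain_of(ri) != core or mask.domain_of(rj) != core:
                    continue
            if source == "dense" and scope == "inter":
                if mask.domain_of(ri) not in flanking or mask.domain_of(rj) not in flanking:
                    continue
            add(
                scope, ri, rj, float(row["probability"]),
                float(row["mean_distance_nm"]),
                source,
                float(row.get("multiplicity", 1.0)),
            )

    # excluded-volume contract: flanking x core interchain pairs repulsive
    dropped = 0
    for key in list(records):
        scope, ri, rj = key
        if scope != "inter":
            continue
        di, dj = mask.domain_of(ri), mask.domain_of(rj)
        if (di in flanking) != (dj in flanking):
            del records[key]
            dropped += 1
    for ri in range(1, n_res + 1):
        for rj in range(ri, n_res + 1):
            di, dj = mask.domain_of(ri), mask.domain_of(rj)
            if (di in flanking) != (dj in flanking):
                records[("inter", ri, rj)] = dict(
                    scope="inter", res_i=ri, res_j=rj, probability=0.0,
                    sigma_nm=sigma_rep, multiplicity=0.0, source="contract",
                    **{"class": "repulsive"},
                )

    pairs = pd.DataFrame(
        sorted(records.values(), key=lambda r: (r["scope"], r["res_i"], r["res_j"])),
        columns=[
            "scope", "res_i", "res_j", "class", "probability", "sigma_nm",
            "multiplicity", "source",
        ],
    )
    pot = MultiStatePotential(
        pairs=pairs,
        epsilon=epsilon,
        sigma_rep=sigma_rep,
        cutoff=cutoff,
        epsilon_mode=epsilon_mode,
        domain_mask=mask,
    )
    pot.conflicts = conflicts
    pot.n_forced_repulsive = dropped
    return pot


def shift_residues(cm: ContactMatrix, offset: int) -> ContactMatrix:
    """Renumber a contact matrix's residues by a constant offset (used
    to embed the polyQ-core fibril contacts into a flanked construct)."""
    entries = cm.entries.copy()
    entries["res_i"] = entries["res_i"] + offset
    entries["res_j"] = entries["res_j"] + offset
    return ContactMatrix(
        entries=entries, source=cm.source, cutoff=cm.cutoff, n_frames=cm.n_frames
    )


def _fibril_contact_matrix(seed: int = 0, cutoff: float = 0.6) -> ContactMatrix:
    """Contacts of the beta-arc A1 reference lattice (intra + inter)."""
    from .fibril_builder import ZipperSpec, build_lattice, build_tertiary_unit

    unit = build_tertiary_unit(ZipperSpec(unit_kind="BA"))
    # contact statistics tolerate slightly tighter packing than the
    # model-validation lattices require
    lattice = build_lattice(unit, "A1", 2, 4, clash_threshold=1.8)
    traj = Trajectory(
        xyz=lattice.structure.coords[None, :, :], topology=lattice.structure
    )
    intra = extract_contact_matrix(traj, cutoff, "intra", min_probability=0.0)
    inter = extract_contact_matrix(traj, cutoff, "inter", min_probability=0.0)
    entries = pd.concat([intra.entries, inter.entries], ignore_index=True)
    return ContactMatrix(entries=entries, source="fibril", cutoff=cutoff, n_frames=1)


def q16_reference_potential(
    seed: int = 0,
    epsilon: float = 0.4,
    n_coil_frames: int = 60,
    min_probability: float = 0.05,
) -> MultiStatePotential:
    """The shipped Q16 model: monomer contacts from a synthetic coil
    ensemble, fibril contacts from the built beta-arc A1 lattice,
    epsilon = 0.4 kJ/mol."""
    from .synthetic_data import generate_coil_ensemble

    coil = generate_coil_ensemble(16, n_coil_frames, seed=seed)
    monomer = extract_contact_matrix(coil, scope="intra", min_probability=min_probability)
    monomer.source = "monomer"
    fibril = _fibril_contact_matrix(seed)
    return merge_states(monomer, fibril, None, Q16_DOMAIN_MASK, epsilon=epsilon)


def h16_reference_potential(
    seed: int = 0,
    epsilon: float = 0.325,
    n_coil_frames: int = 40,
) -> MultiStatePotential:
    """The shipped H16 (N17-Q16-P5) model: flanking-domain interchain
    contacts from a synthetic dense phase, polyQ-core interchain
    contacts from the beta-arc fibril lattice (renumbered into the
    flanked construct), epsilon = 0.325 kJ/mol; flanking-core
    interchain pairs are excluded volume by construction."""
    from .synthetic_data import generate_coil_ensemble, generate_dense_phase

    coil = generate_coil_ensemble(
        H16_DOMAIN_MASK.n_residues, n_coil_frames, seed=seed
    )
    monomer = extract_contact_matrix(coil, scope="intra")
    monomer.source = "monomer"
    fibril = shift_residues(_fibril_contact_matrix(seed), 17)
    dense_traj = generate_dense_phase(seed=seed, mask=H16_DOMAIN_MASK)
    dense = extract_contact_matrix(dense_traj, scope="inter")
    dense.source = "dense"
    return merge_states(monomer, fibril, dense, H16_DOMAIN_MASK, epsilon=epsilon)


# ----------------------------------------------------------------------
# pair energies


def pair_energy(r: float, record, epsilon: float | None = None,
                sigma_rep: float = 0.35, cutoff: float = 1.45):
    """Energy (kJ/mol) and force magnitude (kJ/mol/nm) of one pair.

    ``record`` is a mapping with keys ``class`` and ``sigma_nm`` (and
    optionally ``epsilon``).  Native pairs: 12-6 LJ truncated and
    shifted at ``cutoff``; repulsive pairs: the r^-12 branch only,
    active below ``sigma_rep``.  The force magnitude is -dU/dr.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    cls = record["class"] if isinstance(record, dict) else record["class"]
    eps = epsilon if epsilon is not None else record.get("epsilon", 1.0)
    if cls == "native":
        sigma = record["sigma_nm"]
        if r >= cutoff:
            return 0.0, 0.0
        s6 = (sigma / r) ** 6
        sc6 = (sigma / cutoff) ** 6
        u = 4.0 * eps * (s6 * s6 - s6) - 4.0 * eps * (sc6 * sc6 - sc6)
        f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r
        return float(u), float(f)
    if cls == "repulsive":
        sig = record.get("sigma_nm", sigma_rep) or sigma_rep
        if r >= sig:
            return 0.0, 0.0
        s12 = (sig / r) ** 12
        u = eps * (s12 - 1.0)
        f = 12.0 * eps * s12 / r
        return float(u), float(f)
    raise ValueError(f"unknown pair class {cls!r}")


# ----------------------------------------------------------------------
# epsilon calibration


def trajectory_rg(xyz: np.ndarray, indices=None) -> np.ndarray:
    """Radius of gyration per frame (over backbone beads if given)."""
    sub = xyz if indices is None else xyz[:, indices]
    centred = sub - sub.mean(axis=1, keepdims=True)
    return np.sqrt((centred ** 2).sum(axis=2).mean(axis=1))


def calibrate_epsilon(
    potential_template: MultiStatePotential,
    reference: EnsembleStats,
    epsilon_grid,
    simulator_config=None,
    seed: int = 0,
    n_steps: int = 60000,
    contact_weight: float = 0.5,
    n_res: int = 16,
):
    """Grid search of the native-contact strength against a reference.

    For each grid value a single-chain simulation is run and scored as
    the 1-Wasserstein distance between radius-of-gyration distributions
    plus a weighted L1 contact-map difference; the argmin is returned
    together with the full score table.  Deterministic given ``seed``.
    """
    from scipy.stats import wasserstein_distance

    from .cg_simulator import (
        SimConfig,
        SystemState,
        compile_nonbonded,
        polyq_bead_topology,
        run,
        KB,
    )

    epsilon_grid = list(epsilon_grid)
    if not epsilon_grid:
        raise ValueError("empty epsilon grid")
    if len(reference.rg_samples) < 100:
        raise ValueError("need at least 100 reference Rg samples")
    config = simulator_config or SimConfig(seed=seed, friction=0.5, report_interval=200)

    rows = []
    best = None
    for k, eps in enumerate(epsilon_grid):
        try:
            traj, topo, template = simulate_single_chain(
                potential_template, eps, n_res, config, seed, n_steps
            )
            bb = np.nonzero(template.atom_names == "CA")[0]
            rg = trajectory_rg(traj.xyz, bb)
            burn = len(rg) // 5
            rg = rg[burn:]
            score = float(wasserstein_distance(reference.rg_samples, rg))
            if reference.contact_map is not None:
                cm = extract_contact_matrix(
                    Trajectory(xyz=traj.xyz[burn:], topology=template),
                    cutoff=0.8,
                    scope="intra",
                    min_probability=0.0,
                ).as_dense(n_res, "intra")
                score += contact_weight * float(
                    np.abs(cm - reference.contact_map).mean()
                )
            rows.append(dict(epsilon=eps, score=score, failed=False))
            if best is None or score < best[1]:
                best = (eps, score)
        except (FloatingPointError, RuntimeError) as err:
            rows.append(dict(epsilon=eps, score=np.nan, failed=True, error=str(err)))
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("all calibration simulations failed")
    return best[0], table


def simulate_single_chain(
    potential_template: MultiStatePotential,
    epsilon: float,
    n_res: int,
    config,
    seed: int,
    n_steps: int,
):
    """Run one chain under the template potential at a given epsilon."""
    from dataclasses import replace as dc_replace

    from .cg_simulator import (
        KB,
        SystemState,
        compile_nonbonded,
        minimize,
        polyq_bead_topology,
        result_trajectory,
        run,
    )

    topo, template = polyq_bead_topology(1, n_res)
    pot = dc_replace(potential_template, epsilon=epsilon)
    nb = compile_nonbonded(pot, topo)
    rng = np.random.default_rng(seed)
    # extended initial conformation with small jitter
    pos = np.zeros((topo.n_beads, 3))
    for r in range(n_res):
        pos[2 * r] = (0.36 * r, 0.0, 0.0)
        pos[2 * r + 1] = (0.36 * r, 0.25, 0.0)
    pos += rng.normal(scale=0.01, size=pos.shape)
    vel = rng.standard_normal((topo.n_beads, 3)) * np.sqrt(
        KB * config.temperature / topo.masses
    )[:, None]
    state = SystemState(
        positions=pos,
        velocities=vel,
        box=np.full(3, 50.0),
        periodic=np.zeros(3, dtype=bool),
    )
    state = minimize(state, topo, nb, fmax=1000.0, max_steps=500)
    result = run(state, topo, nb, config, n_steps)
    return result_trajectory(result, template), topo, template
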