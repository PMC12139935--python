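"""Trajectory statistics for aggregation runs.

Implements the standard observables of fibrillation studies: chain
clustering by backbone proximity (10 A Calpha cutoff), monomer and
largest-cluster fractions with the monomer-depletion half-time t1/2,
oligomer-order distributions windowed around t1/2, secondary-structure
assignment (hydrogen-bond based on heavy atoms, pseudo-dihedral based
on coarse-grained beads), end-to-end conformer classification, and
interchain contact maps.

Interface units follow field conventions: clustering and contact
cutoffs in Angstrom, coordinates internally in nm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import Structure, Trajectory
from .contact_model import extract_contact_matrix

__all__ = [
    "ClusterAssignment",
    "KineticsTrace",
    "OligomerDistribution",
    "SSProfile",
    "cluster_chains",
    "kinetics_trace",
    "oligomer_distribution",
    "assign_secondary_structure",
    "end_to_end_classify",
    "interchain_contact_map",
    "compute_t_half",
]

COIL, HELIX, STRAND = 0, 1, 2
_LABELS = {COIL: "coil", HELIX: "helix", STRAND: "strand"}


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-chain integer component labels
    frame_index: int
    cutoff: float  # Angstrom

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


@dataclass
class KineticsTrace:
    """Aggregation kinetics time series (times in model-time units)."""

    times: np.ndarray
    monomer_fraction: np.ndarray
    largest_cluster_fraction: np.ndarray
    n_chains: int
    beta_fraction: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.monomer_fraction = np.asarray(self.monomer_fraction, dtype=float)
        self.largest_cluster_fraction = np.asarray(
            self.largest_cluster_fraction, dtype=float
        )
        for arr in (self.monomer_fraction, self.largest_cluster_fraction):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("fractions must lie in [0, 1]")
        if (self.largest_cluster_fraction < 1.0 / self.n_chains - 1e-9).any():
            raise ValueError("largest-cluster fraction below 1/n_chains")

    @property
    def t_half(self) -> float | None:
        return compute_t_half(self.times, self.monomer_fraction)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            dict(
                time=self.times,
                monomer_fraction=self.monomer_fraction,
                largest_cluster_fraction=self.largest_cluster_fraction,
            )
        )
        if self.beta_fraction is not None:
            df["beta_fraction"] = self.beta_fraction
        df.to_csv(path, sep="\t", index=False)


@dataclass
class OligomerDistribution:
    """Percentage of chains residing in each oligomer order."""

    percentages: dict  # order -> percent of chains
    window: str  # before | after
    n_frames: int

    def __post_init__(self):
        total = sum(self.percentages.values())
        if self.percentages and abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")


@dataclass
class SSProfile:
    """Per-residue, per-frame secondary-structure labels."""

    labels: np.ndarray  # (n_frames, n_residues_total) ints
    residue_keys: list  # [(chain, resid), ...] column order
    mode: str  # heavy | bead

    @property
    def beta_fraction(self) -> np.ndarray:
        return (self.labels == STRAND).mean(axis=1)

    @property
    def helix_fraction(self) -> np.ndarray:
        return (self.labels == HELIX).mean(axis=1)

    def helicity_profile(self) -> dict:
        """Per-residue helix fraction over frames, keyed by resid
        (averaged over chains)."""
        out: dict[int, list] = {}
        frac = (self.labels == HELIX).mean(axis=0)
        for (chain, resid), f in zip(self.residue_keys, frac):
            out.setdefault(resid, []).append(f)
        return {r: float(np.mean(v)) for r, v in sorted(out.items())}

    def strand_profile(self) -> dict:
        out: dict[int, list] = {}
        frac = (self.labels == STRAND).mean(axis=0)
        for (chain, resid), f in zip(self.residue_keys, frac):
            out.setdefault(resid, []).append(f)
        return {r: float(np.mean(v)) for r, v in sorted(out.items())}


# ----------------------------------------------------------------------
# clustering


def _min_image(diff: np.ndarray, box, periodic) -> np.ndarray:
    if box is None:
        return diff
    for k in range(3):
        if periodic is None or periodic[k]:
            diff[..., k] -= box[k] * np.rint(diff[..., k] / box[k])
    return diff


def _backbone_coords(frame: Structure):
    """Per-chain backbone (CA or backbone-bead) coordinates."""
    coords = []
    for c, idx in enumerate(frame.chains()):
        names = frame.atom_names[idx]
        ca = idx[np.isin(names, ("CA",))]
        if len(ca) == 0:
            raise ValueError(f"chain {c} has no CA/backbone sites")
        coords.append(frame.coords[ca])
    return coords


def cluster_chains(frame: Structure, cutoff: float = 10.0) -> ClusterAssignment:
    """Connected components of the chain-contact graph.

    Two chains are adjacent when any Calpha-Calpha pair is within
    ``cutoff`` Angstrom (minimum image on periodic axes).
    """
    coords = _backbone_coords(frame)
    n = len(coords)
    cut = cutoff * 0.1  # nm
    rows, cols = [], []
    for a in range(n):
        for b in range(a + 1, n):
            diff = coords[a][:, None, :] - coords[b][None, :, :]
            diff = _min_image(diff, frame.box, frame.periodic)
            if (np.einsum("ijk,ijk->ij", diff, diff) < cut * cut).any():
                rows.append(a)
                cols.append(b)
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return ClusterAssignment(labels=labels, frame_index=-1, cutoff=cutoff)


def compute_t_half(times, monomer_fraction) -> float | None:
    """First time the monomer fraction reaches 1/2, linearly
    interpolated between the bracketing frames; None if never."""
    times = np.asarray(times, dtype=float)
    mf = np.asarray(monomer_fraction, dtype=float)
    below = np.nonzero(mf <= 0.5)[0]
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    f0, f1 = mf[i - 1], mf[i]
    if f0 == f1:
        return float(t1)
    return float(t0 + (f0 - 0.5) / (f0 - f1) * (t1 - t0))


def kinetics_trace(
    trajectory: Trajectory,
    cutoff: float = 10.0,
    ss_profile: SSProfile | None = None,
) -> KineticsTrace:
    """Monomer and largest-cluster fractions over a trajectory.

    The largest-cluster fraction is the chain count of the biggest
    cluster normalized by the total number of chains; the monomer
    fraction counts size-1 clusters.  Optionally carries a precomputed
    beta-fraction trace.
    """
    if trajectory.n_frames < 2:
        raise ValueError("kinetics need at least two frames")
    n_chains = trajectory.topology.n_chains
    times = (
        trajectory.times
        if trajectory.times is not None
        else np.arange(trajectory.n_frames, dtype=float)
    )
    mono, largest = [], []
    for f, frame in enumerate(trajectory):
        asg = cluster_chains(frame, cutoff)
        sizes = asg.sizes()
        mono.append((sizes == 1).sum() / n_chains)
        largest.append(sizes.max() / n_chains)
    return KineticsTrace(
        times=times,
        monomer_fraction=np.array(mono),
        largest_cluster_fraction=np.array(largest),
        n_chains=n_chains,
        beta_fraction=ss_profile.beta_fraction if ss_profile is not None else None,
    )


def oligomer_distribution(
    trajectory: Trajectory,
    trace: KineticsTrace,
    window: str = "after",
    horizon: float = 200.0,
    cutoff: float = 10.0,
) -> OligomerDistribution:
    """Percentage of chains per oligomer order, pooled over frames in
    [t_half, t_half + horizon] (after) or [0, t_half) (before)."""
    if window not in ("before", "after"):
        raise ValueError("window must be 'before' or 'after'")
    t_half = trace.t_half
    if t_half is None and window == "after":
        raise ValueError("t_half undefined: cannot window after it")
    times = (
        trajectory.times
        if trajectory.times is not None
        else np.arange(trajectory.n_frames, dtype=float)
    )
    if window == "after":
        sel = (times >= t_half) & (times <= t_half + horizon)
        if not sel.any():
            # boundary: use the first frame at/after t_half
            sel = np.zeros(len(times), dtype=bool)
            sel[np.searchsorted(times, t_half)] = True
    else:
        sel = times < (t_half if t_half is not None else np.inf)
    counts: dict[int, int] = {}
    total = 0
    for f in np.nonzero(sel)[0]:
        sizes = cluster_chains(trajectory.frame(int(f)), cutoff).sizes()
        for s in sizes:
            counts[int(s)] = counts.get(int(s), 0) + int(s)
            total += int(s)
    percentages = {k: 100.0 * v / total for k, v in sorted(counts.items())}
    return OligomerDistribution(
        percentages=percentages, window=window, n_frames=int(sel.sum())
    )


# ----------------------------------------------------------------------
# secondary structure


_KS_FACTOR = 27.888  # kcal*A/mol: 332 * 0.42 * 0.20
_KS_CUTOFF = -0.5  # kcal/mol


def _ks_hbond_matrix(frame: Structure):
    """Kabsch-Sander H-bond matrix over residues: hb[d, a] True when
    the amide of residue d donates to the carbonyl of residue a."""
    keys = []
    atoms = {}
    for c in range(frame.n_chains):
        resids = np.unique(frame.resids[frame.chain_index == c])
        for r in resids:
            entry = {}
            for nm in ("N", "CA", "C", "O"):
                try:
                    entry[nm] = frame.coords[frame.atom_index(c, int(r), nm)] * 10.0
                except KeyError:
                    pass
            if len(entry) == 4:
                keys.append((c, int(r)))
                atoms[(c, int(r))] = entry
    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    # amide H from the previous residue's carbonyl direction
    H = {}
    for c, r in keys:
        prev = (c, r - 1)
        if prev in atoms:
            co = atoms[prev]["C"] - atoms[prev]["O"]
            H[(c, r)] = atoms[(c, r)]["N"] + co / np.linalg.norm(co)
    hb = np.zeros((n, n), dtype=bool)
    for d in keys:
        if d not in H:
            continue
        nd, hd = atoms[d]["N"], H[d]
        for a in keys:
            if a == d:
                continue
            if a[0] == d[0] and abs(a[1] - d[1]) < 2:
                continue
            ca_, oa = atoms[a]["C"], atoms[a]["O"]
            r_on = np.linalg.norm(oa - nd)
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(ca_ - hd)
            r_oh = np.linalg.norm(oa - hd)
            r_cn = np.linalg.norm(ca_ - nd)
            if min(r_oh, r_cn) < 0.5:
                continue
            energy = _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _KS_CUTOFF:
                hb[index[d], index[a]] = True
    return keys, index, hb


def _assign_frame_heavy(frame: Structure):
    keys, index, hb = _ks_hbond_matrix(frame)
    n = len(keys)
    labels = np.zeros(n, dtype=np.int8)

    def has(d, a):
        return d in index and a in index and hb[index[d], index[a]]

    # helices: two consecutive i->i+4 turns mark residues i+1..i+4
    for (c, r) in keys:
        if has((c, r + 4), (c, r)) and has((c, r + 5), (c, r + 1)):
            for rr in (r + 1, r + 2, r + 3, r + 4, r + 5):
                if (c, rr) in index:
                    labels[index[(c, rr)]] = HELIX
    # bridges (parallel and antiparallel, Kabsch-Sander patterns)
    for i, ki in enumerate(keys):
        for j in range(i + 1, n):
            kj = keys[j]
            if ki[0] == kj[0] and abs(ki[1] - kj[1]) < 3:
                continue
            ci, ri = ki
            cj, rj = kj
            anti = (has(ki, kj) and has(kj, ki)) or (
                has((ci, ri - 1), (cj, rj + 1)) and has((cj, rj - 1), (ci, ri + 1))
            )
            para = (has((ci, ri - 1), kj) and has(kj, (ci, ri + 1))) or (
                has((cj, rj - 1), ki) and has(ki, (cj, rj + 1))
            )
            if anti or para:
                if labels[i] != HELIX:
                    labels[i] = STRAND
                if labels[j] != HELIX:
                    labels[j] = STRAND
    return keys, labels


#: pseudo-angle/dihedral windows (deg) for the bead-mode assignment,
#: centred on the builder's ideal strand and helix backbone traces
BEAD_SS_WINDOWS = {
    "strand_angle": (100.0, 160.0),
    "strand_dihedral_abs": (135.0, 180.0),
    "helix_angle": (75.0, 105.0),
    "helix_dihedral": (25.0, 75.0),
}


def _assign_frame_bead(frame: Structure):
    from .geometry import measure_angle, measure_dihedral

    w = BEAD_SS_WINDOWS
    keys = []
    labels = []
    for c in range(frame.n_chains):
        idx = np.nonzero((frame.chain_index == c) & (frame.atom_names == "CA"))[0]
        resids = frame.resids[idx]
        order = np.argsort(resids)
        idx = idx[order]
        ca = frame.coords[idx]
        n = len(ca)
        lab = np.zeros(n, dtype=np.int8)
        if n >= 4:
            ang = np.full(n, np.nan)
            dih = np.full(n, np.nan)
            for k in range(1, n - 1):
                ang[k] = measure_angle(ca[k - 1], ca[k], ca[k + 1])
            for k in range(1, n - 2):
                dih[k] = measure_dihedral(ca[k - 1], ca[k], ca[k + 1], ca[k + 2])
            # terminal residues inherit the nearest defined geometry
            ang[0], ang[n - 1] = ang[1], ang[n - 2]
            dih[0], dih[n - 2], dih[n - 1] = dih[1], dih[n - 3], dih[n - 3]
            for k in range(n):
                a = ang[k]
                d = dih[k]
                if np.isnan(a) or np.isnan(d):
                    continue
                if w["strand_angle"][0] <= a <= w["strand_angle"][1] and (
                    w["strand_dihedral_abs"][0] <= abs(d) <= w["strand_dihedral_abs"][1]
                ):
                    lab[k] = STRAND
                elif w["helix_angle"][0] <= a <= w["helix_angle"][1] and (
                    w["helix_dihedral"][0] <= d <= w["helix_dihedral"][1]
                ):
                    lab[k] = HELIX
        keys.extend((c, int(r)) for r in resids[order])
        labels.append(lab)
    return keys, np.concatenate(labels) if labels else np.empty(0, dtype=np.int8)


def assign_secondary_structure(obj) -> SSProfile:
    """Per-residue secondary-structure labels (strand/helix/coil).

    Structures carrying full backbone heavy atoms (N, CA, C, O) are
    scored with the Kabsch-Sander hydrogen-bond criterion; bead-level
    structures fall back to Calpha pseudo-angle/dihedral windows.
    Chains shorter than four residues come out all-coil.
    """
    frames = [obj] if isinstance(obj, Structure) else list(obj)
    first = frames[0]
    heavy = all(nm in set(first.atom_names) for nm in ("N", "C", "O"))
    keys_ref = None
    rows = []
    for frame in frames:
        keys, labels = (
            _assign_frame_heavy(frame) if heavy else _assign_frame_bead(frame)
        )
        if keys_ref is None:
            keys_ref = keys
        rows.append(labels)
    return SSProfile(
        labels=np.vstack(rows),
        residue_keys=keys_ref,
        mode="heavy" if heavy else "bead",
    )


# ----------------------------------------------------------------------
# conformer classification and contact maps


def end_to_end_classify(
    chain: Structure,
    domain_range: tuple,
    threshold: float = 3.5,
    chain_index: int = 0,
):
    """Classify a chain's domain as extended or compact.

    Distance between the first and last Calpha (or backbone bead) of
    ``domain_range`` (1-based inclusive); extended iff strictly greater
    than ``threshold`` nm.
    """
    first, last = domain_range
    try:
        a = chain.coords[chain.atom_index(chain_index, first, "CA")]
        b = chain.coords[chain.atom_index(chain_index, last, "CA")]
    except KeyError as err:
        raise ValueError(f"domain range {domain_range} outside chain") from err
    dist = float(np.linalg.norm(b - a))
    return ("extended" if dist > threshold else "compact"), dist


def interchain_contact_map(
    trajectory: Trajectory, cutoff: float = 6.0, n_res: int | None = None
) -> np.ndarray:
    """Symmetric residue-pair interchain contact-probability map
    (cutoff in Angstrom), averaged over chain pairs and frames."""
    if trajectory.topology.n_chains < 2:
        raise ValueError("interchain map needs at least two chains")
    cm = extract_contact_matrix(
        trajectory, cutoff=cutoff * 0.1, scope="inter", min_probability=0.0
    )
    if n_res is None:
        n_res = int(trajectory.topology.resids.max())
    return cm.as_dense(n_res, "inter")
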