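import numpy as np
import pytest

from qzipper.fibril_builder import (
    ZipperSpec,
    build_lattice,
    build_tertiary_unit,
)


@pytest.fixture(scope="session")
def ba_unit():
    return build_tertiary_unit(ZipperSpec(unit_kind="BA"))


@pytest.fixture(scope="session")
def bt_unit():
    return build_tertiary_unit(ZipperSpec(unit_kind="BT"))


@pytest.fixture(scope="session")
def ba_a1_lattice(ba_unit):
    return build_lattice(ba_unit, "A1", 2, 4)


@pytest.fixture(scope="session")
def q16_potential():
    from qzipper.contact_model import q16_reference_potential

    return q16_reference_potential(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def brute_force_components(coords_per_chain, cutoff_nm, box=None, periodic=None):
    """Independent O(n^2) connected-components oracle used across tests."""
    n = len(coords_per_chain)
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            hit = False
            for pa in coords_per_chain[a]:
                for pb in coords_per_chain[b]:
                    d = pa - pb
                    if box is not None:
                        for k in range(3):
                            if periodic is None or periodic[k]:
                                d[k] -= box[k] * round(d[k] / box[k])
                    if np.dot(d, d) < cutoff_nm * cutoff_nm:
                        hit = True
                        break
                if hit:
                    break
            adj[a, b] = adj[b, a] = hit
    labels = -np.ones(n, dtype=int)
    cur = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = cur
        while stack:
            u = stack.pop()
            for v in range(n):
                if adj[u, v] and labels[v] < 0:
                    labels[v] = cur
                    stack.append(v)
        cur += 1
    return labels


def same_partition(a, b) -> bool:
    """Label-permutation-invariant partition equality."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)
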