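"""Seeded random phasing instances and brute-force oracles for the tests."""

from __future__ import annotations

import itertools

import numpy as np

from matphase.extraction import HaplotypePair
from matphase.io import Fragment, ReadMatrix, build_read_matrix
from matphase.simulate import simulate_truth


def _connected(rm: ReadMatrix) -> bool:
    from matphase.blocks import filter_informative, partition

    blocks = partition(filter_informative(rm, 2))
    return len(blocks) == 1 and blocks[0].n_sites == rm.n_sites


def random_instance(seed: int, l: int = 16, n: int = 24, all_het: bool = True,
                    k_range=(3, 7)):
    """A noiseless instance: truth pair, read matrix, per-read parent flags.

    Reads draw scattered SNP subsets; the draw is conditioned on column
    degree >= 2 and single-block connectivity.  For mixed (non-all-het)
    truth the conditions additionally guarantee identifiability of the
    pair: every column is observed by both parents and the heterozygous
    sub-matrix is itself connected.
    """
    rng = np.random.default_rng(seed)
    while True:
        truth = simulate_truth(l, all_het, 0.5, rng)
        het = truth.hp != truth.hm
        if not all_het and not 4 <= het.sum() <= l - 2:
            continue
        for _ in range(300):
            frags, parents = [], []
            for i in range(n):
                k = int(rng.integers(*k_range))
                sites = np.sort(rng.choice(l, size=k, replace=False))
                is_p = bool(rng.random() < 0.5)
                parent = truth.hp if is_p else truth.hm
                frags.append(
                    Fragment(f"r{i}", tuple((int(j), int(parent[j])) for j in sites))
                )
                parents.append(is_p)
            parents = np.array(parents)
            rm = build_read_matrix(frags, l)
            if np.diff(rm.matrix.tocsc().indptr).min() < 2 or not _connected(rm):
                continue
            if not all_het:
                M = rm.densify() != 0
                if not (M[parents].any(0).all() and M[~parents].any(0).all()):
                    continue
                sub = ReadMatrix(rm.matrix[:, np.flatnonzero(het)])
                if not _connected(sub):
                    continue
            return truth, rm, parents


def tiny_noisy_instance(seed: int, l: int = 6, n: int = 8):
    """A connected instance small enough for exhaustive search, with at
    most one flipped cell."""
    rng = np.random.default_rng(seed)
    while True:
        truth = simulate_truth(l, False, 0.5, rng)
        for _ in range(300):
            frags = []
            for i in range(n):
                k = int(rng.integers(2, 5))
                sites = np.sort(rng.choice(l, size=k, replace=False))
                parent = truth.hp if rng.random() < 0.5 else truth.hm
                frags.append(
                    Fragment(f"r{i}", tuple((int(j), int(parent[j])) for j in sites))
                )
            rm = build_read_matrix(frags, l)
            if np.diff(rm.matrix.tocsc().indptr).min() < 2 or not _connected(rm):
                continue
            if rng.random() < 0.7:
                m = rm.matrix.copy()
                cell = int(rng.integers(m.nnz))
                m.data[cell] = -m.data[cell]
                rm = ReadMatrix(m)
            return truth, rm


def brute_force_minimizers(R_dense: np.ndarray):
    """All unordered haplotype pairs minimizing the observed-cell error.

    Exhaustive enumeration over all 2^l x 2^l sign-vector pairs, assigning
    each read to its better haplotype — the independent oracle for the
    rank-constrained objective on sign matrices.
    """
    n, l = R_dense.shape
    obs = R_dense != 0
    signs = np.array(list(itertools.product([-1.0, 1.0], repeat=l)))
    dists = np.array([((R_dense != s[None, :]) & obs).sum(axis=1) for s in signs])
    best = None
    argmins = []
    for i1 in range(len(signs)):
        d = np.minimum(dists[i1][None, :], dists[i1:]).sum(axis=1)
        j = int(np.argmin(d))
        cost = int(d[j])
        if best is None or cost < best:
            best = cost
            argmins = [(i1, i1 + j)]
            ties = np.flatnonzero(d == cost)
            argmins = [(i1, i1 + int(t)) for t in ties]
        elif cost == best:
            ties = np.flatnonzero(d == cost)
            argmins.extend((i1, i1 + int(t)) for t in ties)
    pairs = [HaplotypePair(signs[a], signs[b]) for a, b in argmins]
    return best, pairs
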