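"""Haplotype-block partitioning of the read matrix.

On real data reads do not all overlap, so the read–SNP graph splits into
connected components; each component is a *haplotype block* that must be
completed and phased on its own (a rank-2 model carries no information
between disconnected components, and the relative phase of two blocks is
undefined).  Reads observing fewer than two SNPs cannot link sites and are
excluded from connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import ReadMatrix

logger = logging.getLogger(__name__)


@dataclass
class Block:
    """A maximal read-connected set of SNP columns with its sub-matrix."""

    snp_indices: np.ndarray   # 0-based global column indices, ascending
    read_indices: np.ndarray  # 0-based global row indices, ascending
    read_matrix: ReadMatrix   # restricted to those rows/columns

    @property
    def n_sites(self) -> int:
        return len(self.snp_indices)

    @property
    def n_reads(self) -> int:
        return len(self.read_indices)


def filter_informative(read_matrix: ReadMatrix, min_snps_per_read: int = 2) -> ReadMatrix:
    """Drop reads observing fewer than ``min_snps_per_read`` sites."""
    if min_snps_per_read < 1:
        raise ValueError("min_snps_per_read must be >= 1")
    counts = np.diff(read_matrix.matrix.indptr)
    keep = counts >= min_snps_per_read
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "removed %d reads with < %d observed SNPs", n_removed, min_snps_per_read
        )
    if not n_removed:
        return read_matrix
    ids = read_matrix.read_ids
    return ReadMatrix(
        read_matrix.matrix[keep],
        None if ids is None else tuple(np.asarray(ids)[keep]),
    )


def partition(read_matrix: ReadMatrix) -> list[Block]:
    """Split into connected components of the bipartite read–SNP graph.

    Only reads with >= 2 observed sites create connectivity; sites covered by
    no such read belong to no block.  Blocks are sorted by first SNP index,
    and the result is invariant to read order.
    """
    n, l = read_matrix.n_reads, read_matrix.n_sites
    if read_matrix.n_observed == 0:
        return []
    pattern = read_matrix.matrix.copy()
    pattern.data = np.ones_like(pattern.data)
    counts = np.diff(pattern.indptr)
    linking = counts >= 2
    bip = sp.bmat(
        [[None, pattern[linking]], [pattern[linking].T, None]], format="csr"
    )
    n_link = int(linking.sum())
    if n_link == 0:
        return []
    _, labels = connected_components(bip, directed=False)
    read_labels = np.full(n, -1)
    read_labels[linking] = labels[:n_link]
    site_labels = labels[n_link:]
    covered = np.asarray(pattern[linking].sum(axis=0)).ravel() > 0

    # attach non-linking reads (single-SNP) to the block covering their site
    coo = read_matrix.matrix.tocoo()
    for i, j in zip(coo.row, coo.col):
        if read_labels[i] == -1 and covered[j]:
            read_labels[i] = site_labels[j]

    blocks = []
    for comp in np.unique(site_labels[covered]):
        sites = np.flatnonzero(covered & (site_labels == comp))
        reads = np.flatnonzero(read_labels == comp)
        sub = read_matrix.matrix[reads][:, sites]
        ids = read_matrix.read_ids
        sub_ids = None if ids is None else tuple(np.asarray(ids)[reads])
        blocks.append(Block(sites, reads, ReadMatrix(sub, sub_ids)))
    blocks.sort(key=lambda b: b.snp_indices[0])
    n_missing = l - sum(b.n_sites for b in blocks)
    if n_missing:
        logger.info("%d sites covered by no informative read (unphasable)", n_missing)
    return blocks


def missing_sites(blocks: list[Block], l: int) -> np.ndarray:
    """0-based indices of sites belonging to no block."""
    covered = np.zeros(l, dtype=bool)
    for b in blocks:
        covered[b.snp_indices] = True
    return np.flatnonzero(~covered)
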