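"""End-to-end assembly: filter → partition → complete → extract.

``MatrixPhaser`` is the scikit-learn-style front door: ``fit`` takes a read
matrix (or fragments), solves each haplotype block independently with the
chosen completion solver, and exposes full-length haplotypes plus per-block
diagnostics as fitted attributes.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .blocks import Block, filter_informative, missing_sites, partition
from .completion import as_read_matrix, make_completer
from .extraction import HaplotypePair, extract_pair
from .io import Fragment, ReadMatrix, build_read_matrix

logger = logging.getLogger(__name__)


class MatrixPhaser(BaseEstimator):
    """Diploid haplotype assembly by per-block low-rank matrix completion.

    Parameters
    ----------
    solver : {"svt", "nuc", "opt"}
        Completion solver (aliases "nuclear"/"optspace" accepted).
    rank : {1, 2}
        Model rank; forced to 1 when ``all_het`` is set.
    all_het : bool
        All-heterozygous mode: the second haplotype is the negative of the
        first by construction.
    min_snps_per_read : int
        Reads observing fewer sites are discarded before partitioning.
    zero_band : float
        Completed entries within ±zero_band quantize to missing.
    solver_params : dict, optional
        Extra keyword arguments for the completer.

    Attributes
    ----------
    haplotypes_ : HaplotypePair
        Full-length estimate; sites in no block (or quantized to the zero
        band) are missing.
    blocks_ : list of Block
    block_pairs_ : list of HaplotypePair  (full-length, one per block)
    diagnostics_ : list of dict, one per block
    n_sites_ : int
    """

    def __init__(self, solver: str = "optspace", rank: int = 2,
                 all_het: bool = False, min_snps_per_read: int = 2,
                 zero_band: float = 0.0, solver_params: dict | None = None):
        self.solver = solver
        self.rank = rank
        self.all_het = all_het
        self.min_snps_per_read = min_snps_per_read
        self.zero_band = zero_band
        self.solver_params = solver_params

    def fit(self, R, y=None) -> "MatrixPhaser":
        from .completion import SOLVERS

        if self.solver not in SOLVERS:
            raise ValueError(
                f"unknown solver {self.solver!r}; choose from svt, nuc, opt"
            )
        rm = self._coerce(R)
        rank = 1 if self.all_het else self.rank
        filtered = filter_informative(rm, self.min_snps_per_read)
        blocks = partition(filtered)
        l = rm.n_sites
        hp = np.zeros(l)
        hm = np.zeros(l)
        block_pairs: list[HaplotypePair] = []
        diagnostics: list[dict] = []
        params = dict(self.solver_params or {})
        for block in blocks:
            diag: dict = {
                "first_snp": int(block.snp_indices[0]) + 1,
                "n_sites": block.n_sites,
                "n_reads": block.n_reads,
            }
            try:
                completer = make_completer(self.solver, rank=rank, **params)
                H = completer.fit_transform(block.read_matrix)
                pair = extract_pair(H, rank=rank, zero_band=self.zero_band,
                                    read_matrix=block.read_matrix)
                for attr in ("n_iter_", "converged_", "feasibility_"):
                    if hasattr(completer, attr):
                        diag[attr.rstrip("_")] = getattr(completer, attr)
                if hasattr(completer, "diagnostics_"):
                    diag["final_objective"] = completer.diagnostics_["final_objective"]
                diag["status"] = "ok"
            except Exception as exc:  # a failed block stays unphased
                logger.warning(
                    "block at SNP %d failed (%s); left unphased",
                    block.snp_indices[0] + 1, exc,
                )
                diag["status"] = f"failed: {exc}"
                pair = None
            if pair is not None:
                hp[block.snp_indices] = pair.hp
                hm[block.snp_indices] = pair.hm
                full = HaplotypePair(np.zeros(l), np.zeros(l))
                full.hp[block.snp_indices] = pair.hp
                full.hm[block.snp_indices] = pair.hm
                block_pairs.append(full)
            else:
                block_pairs.append(HaplotypePair(np.zeros(l), np.zeros(l)))
            diagnostics.append(diag)
        self.haplotypes_ = HaplotypePair(hp, hm, ambiguous=True)
        self.blocks_ = blocks
        self.block_pairs_ = block_pairs
        self.diagnostics_ = diagnostics
        self.n_sites_ = l
        self.missing_sites_ = missing_sites(blocks, l)
        return self

    def fit_predict(self, R, y=None) -> HaplotypePair:
        return self.fit(R).haplotypes_

    @staticmethod
    def _coerce(R) -> ReadMatrix:
        if isinstance(R, (list, tuple)) and R and isinstance(R[0], Fragment):
            l = max(j for frag in R for j, _ in frag.sites) + 1
            return build_read_matrix(R, l)
        return as_read_matrix(R)


def assemble(R, solver: str = "optspace", **kwargs) -> HaplotypePair:
    """Functional wrapper: fit a :class:`MatrixPhaser` and return the pair."""
    return MatrixPhaser(solver=solver, **kwargs).fit_predict(R)
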