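"""Haplotype extraction from a completed matrix.

Every row of an ideal completed matrix equals one of the two haplotypes, so
two linearly independent rows suffice.  They are located via the pivot
columns of the reduced row echelon form of ``H^T`` (the first two pivots
index two independent rows of ``H``), and the selected rows are quantized
to signs.  Exact zeros in the completed matrix are reported as *missing*
rather than forced to a sign — an exactly-zero cell carries no phase
information and feeds the SNP-missing-rate accounting downstream.

The two haplotype labels are arbitrary: no assembler can tell maternal from
paternal, so results carry a label-ambiguity flag and all comparisons
downstream are label-swap invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HaplotypePair:
    """Two length-l vectors over {+1, -1, 0}; 0 marks a missing call."""

    hp: np.ndarray
    hm: np.ndarray
    ambiguous: bool = True

    def __post_init__(self):
        self.hp = np.asarray(self.hp, dtype=float)
        self.hm = np.asarray(self.hm, dtype=float)
        if self.hp.shape != self.hm.shape:
            raise ValueError("haplotype vectors must have equal length")

    @property
    def l(self) -> int:
        return len(self.hp)

    def swapped(self) -> "HaplotypePair":
        return HaplotypePair(self.hm.copy(), self.hp.copy(), self.ambiguous)

    def matches(self, other: "HaplotypePair") -> bool:
        """Equality as an unordered pair (labels may swap)."""
        direct = np.array_equal(self.hp, other.hp) and np.array_equal(self.hm, other.hm)
        crossed = np.array_equal(self.hp, other.hm) and np.array_equal(self.hm, other.hp)
        return direct or crossed


def quantize(H: np.ndarray, zero_band: float = 0.0) -> np.ndarray:
    """Map completed entries to signs; |entry| <= zero_band becomes 0 (missing)."""
    if zero_band < 0:
        raise ValueError("zero_band must be non-negative")
    H = np.asarray(H, dtype=float)
    out = np.zeros_like(H)
    out[H > zero_band] = 1.0
    out[H < -zero_band] = -1.0
    return out


def _rref_pivot_columns(A: np.ndarray, rel_tol: float, max_pivots: int) -> list[int]:
    """Pivot columns of the RREF of ``A`` by Gauss-Jordan with partial pivoting.

    Stops once ``max_pivots`` pivots are found (only the leading pivots are
    needed); the tolerance is relative to the largest absolute entry of A.
    """
    A = np.array(A, dtype=float)
    m, n = A.shape
    scale = np.max(np.abs(A)) if A.size else 0.0
    if scale == 0.0:
        return []
    tol = rel_tol * scale
    pivots: list[int] = []
    row = 0
    for col in range(n):
        if row >= m or len(pivots) >= max_pivots:
            break
        sub = np.abs(A[row:, col])
        p = int(np.argmax(sub))
        if sub[p] <= tol:
            continue
        if p:
            A[[row, row + p]] = A[[row + p, row]]
        A[row] /= A[row, col]
        others = np.arange(m) != row
        A[others] -= np.outer(A[others, col], A[row])
        pivots.append(col)
        row += 1
    return pivots


def select_pivot_rows(H: np.ndarray, rel_tol: float = 1e-6) -> tuple[int, int | None]:
    """Indices of two linearly independent rows of ``H``.

    Computed as the first two pivot columns of ``rref(H^T)``.  If H has
    numerical rank 1 the second index is ``None``.  An all-zero H is an
    error.
    """
    H = np.asarray(H, dtype=float)
    pivots = _rref_pivot_columns(H.T, rel_tol, max_pivots=2)
    if not pivots:
        raise ValueError("cannot select pivot rows of an all-zero matrix")
    if len(pivots) == 1:
        return pivots[0], None
    return pivots[0], pivots[1]


def cluster_rows(H: np.ndarray) -> np.ndarray:
    """Partition the rows of a (near) rank-2 completed matrix by parent.

    Rows are projected onto the top-2 left singular coordinates; of those
    two coordinate axes, the one whose signs split the rows most evenly is
    the heterozygous (parent-separating) direction — the other axis carries
    the shared homozygous content and has one common sign.  Returns a
    boolean label per row.
    """
    H = np.asarray(H, dtype=float)
    k = min(2, min(H.shape))
    U, s, _ = np.linalg.svd(H, full_matrices=False)
    coords = U[:, :k] * s[:k]
    best_dim = 0
    best_imbalance = np.inf
    for d in range(k):
        signs = np.sign(coords[:, d])
        if not signs.any():
            continue
        imbalance = abs(signs.sum()) / max(np.count_nonzero(signs), 1)
        if imbalance < best_imbalance:
            best_imbalance = imbalance
            best_dim = d
    return coords[:, best_dim] >= 0


def _cluster_vote(H: np.ndarray, mask: np.ndarray, zero_band: float,
                  R_dense: np.ndarray | None) -> np.ndarray:
    """Consensus haplotype of one row cluster.

    With observed data available the vote is the column sum of the
    cluster's raw observations (the majority decoder given assignments);
    columns the cluster never observes — and observation ties — fall back
    to the sign of the cluster's completed-value mean, which is where the
    rank model supplies the inferred cells.  Without observed data the
    completed-value mean is used throughout: determined cells carry
    consistent near-±1 values while undetermined cells largely cancel.
    """
    l = H.shape[1]
    if not mask.any():
        return np.zeros(l)
    h_soft = quantize(H[mask].mean(axis=0), zero_band)
    if R_dense is None:
        return h_soft
    votes = quantize(R_dense[mask].sum(axis=0))
    return np.where(votes != 0, votes, h_soft)


def consensus_pair(H: np.ndarray, labels: np.ndarray, zero_band: float = 0.0,
                   R_dense: np.ndarray | None = None) -> HaplotypePair:
    """Per-column consensus over each row cluster (see ``_cluster_vote``)."""
    labels = np.asarray(labels, dtype=bool)
    ha = _cluster_vote(H, labels, zero_band, R_dense)
    hb = _cluster_vote(H, ~labels, zero_band, R_dense)
    return HaplotypePair(ha, hb, ambiguous=True)


def _exhaustive_labels(H: np.ndarray, R_dense: np.ndarray,
                       zero_band: float) -> np.ndarray:
    """Best read bipartition by exhaustive search (rows <= 12).

    Every labeling (row 0 pinned: labels matter only up to swap) is scored
    by how well its two consensus haplotypes explain the observed entries;
    fully vectorized over the 2^(n-1) candidates.
    """
    n, l = H.shape
    m = 2 ** (n - 1)
    codes = np.arange(m)[:, None] >> np.arange(n - 1)[None, :]
    L = np.hstack([np.ones((m, 1)), codes & 1]).astype(float)  # m x n
    counts_a = L.sum(axis=1, keepdims=True)
    counts_b = n - counts_a
    with np.errstate(invalid="ignore", divide="ignore"):
        soft_a = quantize(np.where(counts_a > 0, (L @ H) / counts_a, 0.0), zero_band)
        soft_b = quantize(np.where(counts_b > 0, ((1 - L) @ H) / counts_b, 0.0), zero_band)
    votes_a = L @ R_dense
    votes_b = (1 - L) @ R_dense
    hp_all = np.where(votes_a != 0, np.sign(votes_a), soft_a)
    hm_all = np.where(votes_b != 0, np.sign(votes_b), soft_b)
    s1 = R_dense @ hp_all.T  # n x m
    s2 = R_dense @ hm_all.T
    scores = np.maximum(s1, s2).sum(axis=0)
    return L[int(np.argmax(scores))].astype(bool)


def refine_labels(R_dense: np.ndarray, H: np.ndarray, labels: np.ndarray,
                  zero_band: float = 0.0, n_iter: int = 8) -> np.ndarray:
    """Refine a row clustering by observed-data agreement (k-means style).

    Each round recomputes the two consensus haplotypes and reassigns every
    read to the one its *observed* entries agree with more (ties keep the
    current label).  Converges in a few rounds; the observed entries are
    immune to the undetermined-cell artifacts of the completed matrix.
    """
    labels = np.asarray(labels, dtype=bool).copy()
    for _ in range(n_iter):
        pair = consensus_pair(H, labels, zero_band, R_dense)
        score_a = R_dense @ pair.hp
        score_b = R_dense @ pair.hm
        new = np.where(score_a == score_b, labels, score_a > score_b)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def extract_pair(H: np.ndarray, rank: int = 2, zero_band: float = 0.0,
                 rel_tol: float = 1e-6, method: str = "consensus",
                 read_matrix=None) -> HaplotypePair:
    """Extract the haplotype pair from a completed matrix.

    ``method="pivot"`` quantizes ``H`` and takes the two pivot rows
    verbatim.  The default ``"consensus"`` clusters all rows by parent and
    takes per-column soft consensus values, which is robust when the
    rank-2 completion is not unique (reads observing only heterozygous
    sites leave their homozygous-column entries undetermined, so any
    single completed row can carry arbitrary values there); the first
    pivot row fixes which cluster is reported first.  When the observed
    ``read_matrix`` is supplied the clustering is additionally refined by
    observed-data agreement.

    With ``rank=1`` (all-heterozygous model) the two parent clusters carry
    the same information up to sign, so the consensus combines all rows
    with cluster-dependent orientation and the second haplotype is the
    elementwise negative of the first (missing stays missing); the same
    applies when only one pivot exists.
    """
    if method not in ("consensus", "pivot"):
        raise ValueError(f"unknown extraction method {method!r}")
    p0, p1 = select_pivot_rows(H, rel_tol)
    rank1 = rank == 1 or p1 is None
    if method == "pivot" or H.shape[0] < 2:
        Hq = quantize(H, zero_band)
        hp = Hq[p0].copy()
        hm = None if rank1 else Hq[p1].copy()
    else:
        labels = cluster_rows(H)
        R_dense = None
        if read_matrix is not None:
            from .completion import as_read_matrix

            R_dense = as_read_matrix(read_matrix).densify()
            n_rows = H.shape[0]
            if n_rows <= 12:
                # a block this small affords the exact assignment search
                # over every read bipartition
                labels = _exhaustive_labels(H, R_dense, zero_band)
            else:
                # refine from deterministic seedings (plus fixed-seed
                # restarts guarding against local minima) and keep the
                # fixed point whose consensus explains the data best
                seeds = [labels]
                if p1 is not None:
                    seeds.append(H @ H[p0] >= H @ H[p1])
                # observed read-read agreement: the most mutually
                # disagreeing pair of reads anchors the two parents
                sparse = as_read_matrix(read_matrix).matrix
                W = (sparse @ sparse.T).tocoo()
                if W.nnz:
                    k = int(np.argmin(W.data))
                    a, b = int(W.row[k]), int(W.col[k])
                    if a != b and W.data[k] < 0:
                        Wc = W.tocsc()
                        wa = np.asarray(Wc[:, a].todense()).ravel()
                        wb = np.asarray(Wc[:, b].todense()).ravel()
                        seeds.append(wa >= wb)
                restart_rng = np.random.default_rng(0)
                seeds.extend(restart_rng.random(n_rows) < 0.5 for _ in range(8))
                best_score = -np.inf
                for seed_labels in seeds:
                    cand = refine_labels(R_dense, H, seed_labels, zero_band)
                    pair_c = consensus_pair(H, cand, zero_band, R_dense)
                    score = float(
                        np.sum(np.maximum(R_dense @ pair_c.hp, R_dense @ pair_c.hm))
                    )
                    if score > best_score:
                        best_score = score
                        labels = cand
        if rank1:
            # orient every row by its cluster and pool: both clusters carry
            # the same haplotype up to a global sign
            signs = np.where(labels, 1.0, -1.0)
            pooled = quantize((signs[:, None] * H).mean(axis=0), zero_band)
            hp = pooled if labels[p0] else -pooled
            hm = None
        else:
            pair = consensus_pair(H, labels, zero_band, R_dense)
            hp, hm = (pair.hp, pair.hm) if labels[p0] else (pair.hm, pair.hp)
    if hm is None:
        hm = -hp
        hm[hp == 0] = 0.0
    return HaplotypePair(hp, hm, ambiguous=True)


def sign_completion(H: np.ndarray, pair: HaplotypePair | None = None,
                    zero_band: float = 0.0, read_matrix=None) -> np.ndarray:
    """The model-consistent quantized completion: one haplotype per row.

    Under the diploid model every row of the completed matrix is one of
    the two haplotypes; each row is therefore assigned to the extracted
    haplotype it agrees with best — by its observed entries when
    ``read_matrix`` is given (ties fall back to the completed row), else
    by its quantized completed entries — and the returned sign matrix
    stacks those assignments.  This is the quantized completed matrix the
    assembler reports (a raw entrywise sign of ``H`` is arbitrary at cells
    the rank-2 model does not determine).
    """
    if pair is None:
        pair = extract_pair(H, zero_band=zero_band, read_matrix=read_matrix)
    Hq = quantize(H, zero_band)
    soft = Hq @ (pair.hp - pair.hm)
    if read_matrix is not None:
        from .completion import as_read_matrix

        R_dense = as_read_matrix(read_matrix).densify()
        obs = R_dense @ (pair.hp - pair.hm)
        score = np.where(obs != 0, obs, soft)
    else:
        score = soft
    out = np.where((score >= 0)[:, None], pair.hp[None, :], pair.hm[None, :])
    return out
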