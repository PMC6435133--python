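"""Built-in worked example: ten reads over the ten SNPs of the β2AR gene.

A classic small phasing instance: ten bi-allelic SNP sites of the human
beta-2 adrenergic receptor gene, two known haplotypes, and ten error-free
aligned reads each observing a handful of sites.  It is small enough to
check every pipeline stage bit-exactly — the coded read matrix, the unique
rank-2 completion, and the extracted haplotype pair — and is used throughout
the test suite.

Genomic positions in the site map are synthetic placeholders (the example
only needs relative order); the alleles and haplotypes are the published
β2AR ones.
"""

from __future__ import annotations

import numpy as np

from .io import Fragment, ReadMatrix, SiteMap, build_read_matrix, encode_fragment

#: wild/rare alleles at the ten β2AR SNP sites (wild listed first)
B2AR_ALLELES = (
    ("G", "A"), ("C", "A"), ("G", "A"), ("C", "G"), ("T", "C"),
    ("T", "C"), ("T", "C"), ("G", "A"), ("C", "G"), ("G", "A"),
)

B2AR_SITE_MAP = SiteMap(
    chrom=("b2ar",) * 10,
    pos=tuple(101 + 100 * j for j in range(10)),  # synthetic spacing
    wild=tuple(w for w, _ in B2AR_ALLELES),
    rare=tuple(r for _, r in B2AR_ALLELES),
)

#: the two true haplotypes as nucleotides
B2AR_HM_SEQ = "ACGGCCCGGG"
B2AR_HP_SEQ = "GCACTTTACG"

#: and as ±1 codewords (wild → +1, rare → −1)
B2AR_HM = np.array([-1, 1, 1, -1, -1, -1, -1, 1, -1, 1], dtype=float)
B2AR_HP = np.array([1, 1, -1, 1, 1, 1, 1, -1, 1, 1], dtype=float)

#: the ten aligned reads as (0-based site, base) observations
B2AR_READS: tuple[tuple[tuple[int, str], ...], ...] = (
    ((0, "A"), (1, "C"), (2, "G")),
    ((2, "G"), (3, "G"), (4, "C"), (5, "C")),
    ((2, "G"), (3, "G"), (8, "G"), (9, "G")),
    ((0, "G"), (1, "C"), (2, "A"), (3, "C"), (4, "T"), (5, "T")),
    ((2, "A"), (5, "T"), (6, "T"), (7, "A"), (8, "C"), (9, "G")),
    ((0, "G"), (1, "C"), (4, "T"), (5, "T")),
    ((0, "A"), (1, "C"), (4, "C"), (9, "G")),
    ((0, "A"), (1, "C"), (4, "C"), (5, "C"), (6, "C")),
    ((0, "G"), (3, "C"), (6, "T"), (7, "A"), (8, "C")),
    ((2, "A"), (3, "C"), (8, "C"), (9, "G")),
)

#: which haplotype each read was drawn from ('m' or 'p')
B2AR_READ_PARENTS = ("m", "m", "m", "p", "p", "p", "m", "m", "p", "p")

#: the coded incomplete read matrix the reads stack into
B2AR_R = np.array(
    [
        [-1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, -1, -1, -1, 0, 0, 0, 0],
        [0, 0, 1, -1, 0, 0, 0, 0, -1, 1],
        [1, 1, -1, 1, 1, 1, 0, 0, 0, 0],
        [0, 0, -1, 0, 0, 1, 1, -1, 1, 1],
        [1, 1, 0, 0, 1, 1, 0, 0, 0, 0],
        [-1, 1, 0, 0, -1, 0, 0, 0, 0, 1],
        [-1, 1, 0, 0, -1, -1, -1, 0, 0, 0],
        [1, 0, 0, 1, 0, 0, 1, -1, 1, 0],
        [0, 0, -1, 1, 0, 0, 0, 0, 1, 1],
    ],
    dtype=float,
)

#: the completed rank-2 matrix: each row is the haplotype its read came from
B2AR_H = np.array([B2AR_HM if p == "m" else B2AR_HP for p in B2AR_READ_PARENTS])


def load_b2ar_fragments() -> list[Fragment]:
    """The ten example reads encoded against the β2AR site map."""
    frags = []
    for i, obs in enumerate(B2AR_READS):
        frag = encode_fragment(f"read{i + 1}", obs, B2AR_SITE_MAP)
        assert frag is not None
        frags.append(frag)
    return frags


def load_b2ar_read_matrix() -> ReadMatrix:
    """The example's coded incomplete read matrix (10 × 10)."""
    return build_read_matrix(load_b2ar_fragments(), l=10)
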