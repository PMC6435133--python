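"""Fragment I/O and ±1 encoding of SNP observations.

Sequencing reads that span several heterozygous SNPs are reduced to the
alleles they carry at those sites.  With the usual bi-allelic assumption each
site has a *wild* and a *rare* allele, coded ``+1`` and ``-1`` respectively;
a read then becomes a sparse row vector over the ``l`` SNP sites of the
region, and a set of reads stacks into the incomplete read matrix ``R`` whose
observed entries lie in ``{-1, +1}`` and whose unobserved entries are zero.

Conventions
-----------
* SNP indices are 1-based in all files and 0-based everywhere in memory.
* Fragment files use the HapCUT whitespace dialect (allele char ``'0'`` =
  wild = ``+1``, ``'1'`` = rare = ``-1``; quality strings are parsed but
  ignored, the completion model is unweighted).
* A triplet table is the trivial alternative: one ``read_id  snp_index
  coded_allele`` row per observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

MISSING_CHAR = "-"


class NonBiallelicError(ValueError):
    """An observed base matches neither allele of a bi-allelic site."""


class FragmentParseError(ValueError):
    """A fragment/triplet line could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SiteMap:
    """Per-SNP metadata: chromosome, position and the two alleles.

    Arrays are indexed 0-based; file representations are 1-based.
    """

    chrom: tuple[str, ...]
    pos: tuple[int, ...]
    wild: tuple[str, ...]
    rare: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chrom) == len(self.wild) == len(self.rare) == n):
            raise ValueError("site map columns have unequal lengths")
        for w, r in zip(self.wild, self.rare):
            if w not in _BASES or r not in _BASES:
                raise ValueError(f"alleles must be A/C/G/T, got {w}/{r}")
            if w == r:
                raise ValueError(f"wild and rare alleles coincide ({w})")

    def __len__(self) -> int:
        return len(self.pos)

    @classmethod
    def read(cls, stream: IO[str] | str) -> "SiteMap":
        """Read a TSV with columns ``index  chrom  pos  wild  rare``.

        Indices must be contiguous ``1..l``.
        """
        df = pd.read_csv(
            stream,
            sep=r"\s+",
            names=["index", "chrom", "pos", "wild", "rare"],
            dtype={"index": int, "chrom": str, "pos": int, "wild": str, "rare": str},
            comment="#",
        )
        df = df.sort_values("index")
        if not np.array_equal(df["index"].to_numpy(), np.arange(1, len(df) + 1)):
            raise ValueError("site indices must be contiguous 1..l")
        return cls(
            chrom=tuple(df["chrom"]),
            pos=tuple(df["pos"]),
            wild=tuple(df["wild"]),
            rare=tuple(df["rare"]),
        )

    def write(self, stream: IO[str]) -> None:
        for j in range(len(self)):
            stream.write(
                f"{j + 1}\t{self.chrom[j]}\t{self.pos[j]}\t{self.wild[j]}\t{self.rare[j]}\n"
            )


@dataclass(frozen=True)
class Fragment:
    """One read: an id plus ``(site, code)`` pairs, sites 0-based increasing."""

    read_id: str
    sites: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("fragment must cover at least one site")
        idx = [s for s, _ in self.sites]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("fragment sites must be strictly increasing")
        if any(c not in (-1, 1) for _, c in self.sites):
            raise ValueError("coded alleles must be +1 or -1")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class ReadMatrix:
    """The incomplete N × l read matrix with entries in {-1, 0, +1}.

    The sparsity pattern *is* the observed set Ω: stored values are ±1 and an
    absent (structurally zero) cell is unobserved.
    """

    matrix: sp.csr_matrix
    read_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix, dtype=np.float64)
        m.sum_duplicates()
        m.eliminate_zeros()
        if m.nnz and not np.all(np.isin(m.data, (-1.0, 1.0))):
            raise ValueError("read matrix entries must be -1 or +1")
        self.matrix = m
        if self.read_ids is not None and len(self.read_ids) != m.shape[0]:
            raise ValueError("read_ids length does not match row count")

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_observed(self) -> int:
        return self.matrix.nnz

    def omega(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column index arrays of the observed cells."""
        coo = self.matrix.tocoo()
        return coo.row, coo.col

    def densify(self) -> np.ndarray:
        """Dense copy with exact zeros at unobserved cells."""
        return np.asarray(self.matrix.todense())

    @classmethod
    def from_dense(
        cls, arr: np.ndarray, read_ids: Sequence[str] | None = None
    ) -> "ReadMatrix":
        return cls(sp.csr_matrix(np.asarray(arr, dtype=np.float64)),
                   None if read_ids is None else tuple(read_ids))


def encode_allele(base: str, wild: str, rare: str, *, on_mismatch: str = "error") -> int | None:
    """Code a nucleotide observation at a bi-allelic site: wild→+1, rare→-1.

    ``on_mismatch`` is ``"error"`` (raise :class:`NonBiallelicError`) or
    ``"drop"`` (return ``None`` so the caller discards the observation).
    """
    if base == wild:
        return 1
    if base == rare:
        return -1
    if on_mismatch == "drop":
        return None
    raise NonBiallelicError(
        f"non-biallelic observation: base {base!r} matches neither {wild!r} nor {rare!r}"
    )


def encode_fragment(
    read_id: str,
    observations: Iterable[tuple[int, str]],
    site_map: SiteMap,
    *,
    on_mismatch: str = "error",
) -> Fragment | None:
    """Encode ``(0-based site, base)`` observations into a :class:`Fragment`.

    Returns ``None`` if every observation was dropped.
    """
    pairs = []
    for j, base in observations:
        code = encode_allele(base, site_map.wild[j], site_map.rare[j], on_mismatch=on_mismatch)
        if code is not None:
            pairs.append((j, code))
    if not pairs:
        return None
    return Fragment(read_id, tuple(_majority_merge(pairs)))


def _majority_merge(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Resolve repeated observations of a site by majority vote; ties drop."""
    votes: dict[int, int] = {}
    for j, c in pairs:
        votes[j] = votes.get(j, 0) + c
    out = []
    for j in sorted(votes):
        if votes[j] > 0:
            out.append((j, 1))
        elif votes[j] < 0:
            out.append((j, -1))
        else:
            logger.warning("site %d dropped: conflicting duplicate observations tie", j + 1)
    return out


def _parse_hapcut_line(line: str, lineno: int) -> Fragment | None:
    tokens = line.split()
    try:
        n_seg = int(tokens[0])
    except (ValueError, IndexError):
        raise FragmentParseError("expected leading segment count", lineno)
    if len(tokens) < 2 + 2 * n_seg:
        raise FragmentParseError(
            f"expected {2 * n_seg} segment tokens after the read id", lineno
        )
    read_id = tokens[1]
    pairs: list[tuple[int, int]] = []
    for k in range(n_seg):
        try:
            start = int(tokens[2 + 2 * k])
        except ValueError:
            raise FragmentParseError(f"bad segment start {tokens[2 + 2 * k]!r}", lineno)
        alleles = tokens[3 + 2 * k]
        for off, ch in enumerate(alleles):
            if ch == "0":
                pairs.append((start - 1 + off, 1))
            elif ch == "1":
                pairs.append((start - 1 + off, -1))
            elif ch == MISSING_CHAR:
                continue
            else:
                raise FragmentParseError(f"bad allele character {ch!r}", lineno)
    # trailing token is the quality string; the model is unweighted so it is
    # accepted and ignored
    if not pairs:
        return None
    return Fragment(read_id, tuple(_majority_merge(pairs)))


def parse_fragments(stream: IO[str] | Iterable[str], dialect: str = "hapcut_fragment") -> list[Fragment]:
    """Parse a fragment stream in the ``hapcut_fragment`` or ``triplet_table`` dialect.

    Malformed lines raise :class:`FragmentParseError` with the line number;
    fragments left empty (all observations dropped) are skipped with a warning.
    """
    if dialect not in ("hapcut_fragment", "triplet_table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fragments: list[Fragment] = []
    n_skipped = 0
    if dialect == "hapcut_fragment":
        for lineno, line in enumerate(stream, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            frag = _parse_hapcut_line(line, lineno)
            if frag is None:
                n_skipped += 1
            else:
                fragments.append(frag)
    else:
        per_read: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        for lineno, line in enumerate(stream, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise FragmentParseError("expected read_id, snp_index, coded_allele", lineno)
            rid, idx_s, code_s = tokens
            try:
                idx = int(idx_s)
                code = int(float(code_s))
            except ValueError:
                raise FragmentParseError("non-numeric snp_index or code", lineno)
            if code not in (-1, 1):
                raise FragmentParseError(f"coded allele must be +1/-1, got {code}", lineno)
            if idx < 1:
                raise FragmentParseError(f"snp_index must be >= 1, got {idx}", lineno)
            if rid not in per_read:
                per_read[rid] = []
                order.append(rid)
            per_read[rid].append((idx - 1, code))
        for rid in order:
            merged = _majority_merge(per_read[rid])
            if merged:
                fragments.append(Fragment(rid, tuple(merged)))
            else:
                n_skipped += 1
    if n_skipped:
        logger.warning("%d empty fragments skipped", n_skipped)
    return fragments


def write_fragments(fragments: Iterable[Fragment], stream: IO[str]) -> None:
    """Write fragments in the HapCUT dialect (contiguous runs become segments)."""
    for frag in fragments:
        segments: list[tuple[int, str]] = []
        cur_start = None
        cur: list[str] = []
        prev = None
        for j, code in frag.sites:
            ch = "0" if code == 1 else "1"
            if prev is not None and j == prev + 1:
                cur.append(ch)
            else:
                if cur_start is not None:
                    segments.append((cur_start, "".join(cur)))
                cur_start, cur = j, [ch]
            prev = j
        segments.append((cur_start, "".join(cur)))  # type: ignore[arg-type]
        qual = "I" * frag.n_sites
        seg_str = " ".join(f"{s + 1} {a}" for s, a in segments)
        stream.write(f"{len(segments)} {frag.read_id} {seg_str} {qual}\n")


def build_read_matrix(fragments: Sequence[Fragment], l: int) -> ReadMatrix:
    """Stack fragments into the sparse N × l read matrix.

    Row ``i`` carries fragment ``i``'s codes at its covered columns and exact
    zeros elsewhere; conflicting duplicate observations of one cell are
    resolved by majority vote, with ties dropped from Ω.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i, frag in enumerate(fragments):
        for j, code in frag.sites:
            if j >= l:
                raise IndexError(
                    f"fragment {frag.read_id!r} covers site {j + 1} beyond l={l}"
                )
            rows.append(i)
            cols.append(j)
            vals.append(float(code))
    m = sp.coo_matrix((vals, (rows, cols)), shape=(len(fragments), l)).tocsr()
    # coincident duplicates were summed; clamp majorities to ±1, drop ties
    m.data = np.sign(m.data)
    m.eliminate_zeros()
    return ReadMatrix(m, tuple(f.read_id for f in fragments))


def decode_haplotype(hap: np.ndarray, site_map: SiteMap) -> str:
    """Decode a ±1/0 haplotype vector to nucleotides; 0 (missing) → ``'-'``."""
    hap = np.asarray(hap)
    if len(hap) != len(site_map):
        raise ValueError("haplotype length does not match site map")
    out = []
    for j, v in enumerate(hap):
        if v > 0:
            out.append(site_map.wild[j])
        elif v < 0:
            out.append(site_map.rare[j])
        else:
            out.append(MISSING_CHAR)
    return "".join(out)


def encode_haplotype(seq: str, site_map: SiteMap) -> np.ndarray:
    """Inverse of :func:`decode_haplotype`; ``'-'`` → 0 (missing)."""
    if len(seq) != len(site_map):
        raise ValueError("sequence length does not match site map")
    out = np.zeros(len(seq))
    for j, ch in enumerate(seq):
        if ch == MISSING_CHAR:
            continue
        out[j] = encode_allele(ch, site_map.wild[j], site_map.rare[j])
    return out


def _code_char(v: float) -> str:
    if v > 0:
        return "0"
    if v < 0:
        return "1"
    return MISSING_CHAR


def write_phased_blocks(blocks_with_pairs, site_map: SiteMap | None, stream: IO[str]) -> None:
    """Write phased blocks in a HapCUT-style text layout.

    ``blocks_with_pairs`` is an iterable of ``(block, pair)`` where ``block``
    exposes 0-based ``snp_indices`` and ``pair`` has full-length ``hp``/``hm``
    vectors.  Blocks are emitted in ascending order of their first SNP; site
    lines carry 1-based index, the two allele codes ('0' wild / '1' rare /
    '-' unphased), chromosome and position.
    """
    items = sorted(blocks_with_pairs, key=lambda bp: min(bp[0].snp_indices))
    for block, pair in items:
        idx = sorted(block.snp_indices)
        phased = sum(
            1 for j in idx if pair.hp[j] != 0 or pair.hm[j] != 0
        )
        first = idx[0] + 1
        span = idx[-1] - idx[0] + 1
        stream.write(f"BLOCK: offset: {first} len: {span} phased: {phased}\n")
        for j in idx:
            chrom = site_map.chrom[j] if site_map is not None else "."
            pos = site_map.pos[j] if site_map is not None else j + 1
            stream.write(
                f"{j + 1}\t{_code_char(pair.hp[j])}\t{_code_char(pair.hm[j])}\t{chrom}\t{pos}\n"
            )
        stream.write("********\n")


def read_phased_blocks(stream: IO[str], l: int):
    """Read a phased-block file back into ``(site_sets, hp, hm)``.

    Returns the list of per-block 0-based site index lists plus the two
    full-length haplotype vectors (0 = unphased / not in any block).
    """
    site_sets: list[list[int]] = []
    hp = np.zeros(l)
    hm = np.zeros(l)
    current: list[int] | None = None
    code = {"0": 1.0, "1": -1.0, MISSING_CHAR: 0.0}
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith("BLOCK:"):
            current = []
            site_sets.append(current)
        elif line.startswith("*"):
            current = None
        else:
            tokens = line.split()
            j = int(tokens[0]) - 1
            if j >= l:
                raise ValueError(f"site index {j + 1} beyond l={l}")
            hp[j] = code[tokens[1]]
            hm[j] = code[tokens[2]]
            if current is not None:
                current.append(j)
    return site_sets, hp, hm


def write_truth_table(hp: np.ndarray, hm: np.ndarray, stream: IO[str]) -> None:
    """Write a truth haplotype TSV: 1-based index, hp code, hm code."""
    for j, (a, b) in enumerate(zip(hp, hm)):
        stream.write(f"{j + 1}\t{int(a)}\t{int(b)}\n")


def read_truth_table(stream: IO[str]) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(stream, sep=r"\s+", names=["index", "hp", "hm"], comment="#")
    l = int(df["index"].max())
    hp = np.zeros(l)
    hm = np.zeros(l)
    hp[df["index"].to_numpy() - 1] = df["hp"].to_numpy()
    hm[df["index"].to_numpy() - 1] = df["hm"].to_numpy()
    return hp, hm
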