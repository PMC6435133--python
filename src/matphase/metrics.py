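"""Phasing evaluation: reconstruction rate, switch errors, SMR, block stats.

All metrics are label-swap invariant: the assembler cannot distinguish the
maternal from the paternal haplotype, so estimated labels are first
assigned to the truth labels by total-Hamming-distance minimization.

Definitions
-----------
reconstruction rate
    ``rr = 1 - min{HD(hm_est, hm), HD(hp_est, hp)} / l`` with the augmented
    Hamming distance HD that counts any non-identical pair of entries —
    a missing call differs from ±1 (and two missing calls are identical).
switch error rate (SWER)
    Walk the heterozygous truth sites where the estimate is phased and
    label each with the parent the estimate agrees with; every change of
    that label is a switch, and SWER = switches / l.
short vs long switches
    An isolated single-site flip produces two back-to-back switches and is
    classified as one *short* switch event; a flip sustained for >= 2 sites
    is a *long* switch event per boundary.
SNP missing rate (SMR)
    Fraction of the l sites at which neither estimated haplotype carries a
    call (sites outside every block included).
AN50
    Adjusted N50 of block spans: each block's span is weighted by the
    fraction of its alleles phased correctly; blocks are scanned in
    decreasing adjusted-span order and AN50 is the adjusted span at which
    the running sum first reaches half the total unadjusted span.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .extraction import HaplotypePair

__all__ = [
    "EvalReport",
    "hamming_distance",
    "align_labels",
    "reconstruction_rate",
    "count_switches",
    "classify_switches",
    "swer",
    "smr",
    "block_stats",
    "evaluate_pair",
]


@dataclass
class EvalReport:
    """Aggregate evaluation of one assembly against the truth."""

    rr: float
    switch_count: int
    swer: float
    short_switches: int
    long_switches: int
    smr: float
    mean_block_length: float | None = None
    an50: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Count positions where the vectors differ (missing != ±1; missing == missing)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return int(np.sum(a != b))


def align_labels(est: HaplotypePair, truth: HaplotypePair) -> HaplotypePair:
    """Assign estimate labels to truth labels by total-distance minimization."""
    direct = hamming_distance(est.hp, truth.hp) + hamming_distance(est.hm, truth.hm)
    crossed = hamming_distance(est.hm, truth.hp) + hamming_distance(est.hp, truth.hm)
    return est if direct <= crossed else est.swapped()


def reconstruction_rate(est: HaplotypePair, truth: HaplotypePair) -> float:
    """``1 - min{HD(hm_est, hm), HD(hp_est, hp)} / l`` after label alignment."""
    if est.l != truth.l:
        raise ValueError("estimate and truth lengths differ")
    est = align_labels(est, truth)
    hd = min(hamming_distance(est.hm, truth.hm), hamming_distance(est.hp, truth.hp))
    return 1.0 - hd / truth.l


def _origin_sequence(est: HaplotypePair, truth: HaplotypePair) -> tuple[np.ndarray, np.ndarray]:
    """Agreement labels over consecutive compared sites.

    Compared sites are those where truth is heterozygous (hp != hm, both
    called) and the estimate's first strand is phased.  The label is +1
    where the estimate matches truth's hp, -1 where it matches hm.
    """
    het = (truth.hp != truth.hm) & (truth.hp != 0) & (truth.hm != 0)
    phased = est.hp != 0
    sites = np.flatnonzero(het & phased)
    origins = np.where(est.hp[sites] == truth.hp[sites], 1, -1)
    return origins, sites


def count_switches(est: HaplotypePair, truth: HaplotypePair) -> tuple[int, list[int]]:
    """Number of parental-origin changes between consecutive compared sites.

    Returns the count and the 0-based site indices at which each switch
    completes (the right-hand site of the changing pair).
    """
    if est.l != truth.l:
        raise ValueError("estimate and truth lengths differ")
    origins, sites = _origin_sequence(est, truth)
    if len(origins) < 2:
        return 0, []
    changes = np.flatnonzero(origins[1:] != origins[:-1])
    return len(changes), [int(sites[c + 1]) for c in changes]


def classify_switches(est: HaplotypePair, truth: HaplotypePair) -> tuple[int, int]:
    """Split switch events into (short, long).

    An interior run of flipped origin of length 1 consumes its two boundary
    switches as one short event; every remaining switch boundary is a long
    event.  ``2*short + long`` equals the raw switch count.
    """
    origins, _ = _origin_sequence(est, truth)
    if len(origins) < 2:
        return 0, 0
    boundaries = np.flatnonzero(origins[1:] != origins[:-1])
    short = 0
    long_ = 0
    i = 0
    while i < len(boundaries):
        # back-to-back switches (a single-site run between them) pair into
        # one short event; anything else is a long event per boundary
        if i + 1 < len(boundaries) and boundaries[i + 1] == boundaries[i] + 1:
            short += 1
            i += 2
        else:
            long_ += 1
            i += 1
    return short, long_


def swer(est: HaplotypePair, truth: HaplotypePair) -> float:
    """Switch count divided by the haplotype length l."""
    count, _ = count_switches(est, truth)
    return count / truth.l


def smr(est: HaplotypePair, l: int | None = None) -> float:
    """Fraction of sites with no call on either estimated haplotype."""
    if l is None:
        l = est.l
    if l <= 0:
        raise ValueError("l must be positive")
    missing = int(np.sum((est.hp == 0) & (est.hm == 0)))
    return missing / l


def block_stats(spans_and_correctness) -> tuple[float | None, float | None]:
    """Mean block span and AN50 from ``(span, fraction_correct)`` pairs.

    Spans are in base pairs when a site map is available, otherwise in SNP
    counts (callers label which).  Returns ``(None, None)`` when there are
    no blocks.
    """
    items = [(float(s), float(f)) for s, f in spans_and_correctness]
    if not items:
        return None, None
    spans = [s for s, _ in items]
    mean_len = sum(spans) / len(spans)
    total = sum(spans)
    adjusted = sorted((s * f for s, f in items), reverse=True)
    running = 0.0
    an50 = adjusted[-1]
    for a in adjusted:
        running += a
        if running >= total / 2.0:
            an50 = a
            break
    return mean_len, an50


def block_spans(blocks, site_map=None) -> list[float]:
    """Block spans in bp (``last - first + 1`` by site-map position) or SNP count."""
    spans = []
    for b in blocks:
        idx = np.sort(np.asarray(b.snp_indices))
        if site_map is not None:
            spans.append(float(site_map.pos[idx[-1]] - site_map.pos[idx[0]] + 1))
        else:
            spans.append(float(len(idx)))
    return spans


def block_correct_fraction(block, est: HaplotypePair, truth: HaplotypePair) -> float:
    """Fraction of a block's sites phased correctly on the better-aligned strand."""
    idx = np.asarray(block.snp_indices)
    sub_est = HaplotypePair(est.hp[idx], est.hm[idx])
    sub_truth = HaplotypePair(truth.hp[idx], truth.hm[idx])
    return reconstruction_rate(sub_est, sub_truth)


def evaluate_pair(est: HaplotypePair, truth: HaplotypePair,
                  blocks=None, site_map=None) -> EvalReport:
    """Full evaluation of an estimated pair against the truth."""
    count, _ = count_switches(est, truth)
    short, long_ = classify_switches(est, truth)
    mean_len = an50 = None
    if blocks:
        spans = block_spans(blocks, site_map)
        fracs = [block_correct_fraction(b, est, truth) for b in blocks]
        mean_len, an50 = block_stats(zip(spans, fracs))
    return EvalReport(
        rr=reconstruction_rate(est, truth),
        switch_count=count,
        swer=count / truth.l,
        short_switches=short,
        long_switches=long_,
        smr=smr(est),
        mean_block_length=mean_len,
        an50=an50,
    )
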