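"""Flanking-haplotype sharing around a candidate recurrent CNV.

A CNV descended from a single ancestral mutation sits on a characteristic
haplotype. Each carrier chromosome still matches that ancestral background
over a segment flanking the CNV; recombination erodes the segment, so its
genetic length shrinks with the number of generations since the founder
event. This module measures, for each carrier haplotype, the maximal shared
flank on both sides of the CNV — the per-haplotype lengths ``l_i`` that feed
the Gamma-method age estimator in :mod:`foundercnv.dating`.

Procedure, per candidate rCNV:

1. take the nearest ``n`` SNPs (default 60) upstream and downstream of the
   CNV region from a phased panel (:func:`build_flank_window`);
2. form the consensus (modal) carrier haplotype over the window — the
   putative ancestral background (:func:`consensus_haplotype`);
3. walk outward from each CNV boundary along each carrier haplotype,
   extending while alleles match the consensus; a single mismatching SNP is
   "rescued" as a point mutation or genotyping error when the next
   ``rescue_k`` (default 5) SNPs outward all match (:func:`extend_shared`);
4. convert the two flank extents to a genetic length in Morgans on the local
   recombination map (:func:`shared_segment`).

A walk that reaches the window edge is censored: the true shared length is
only bounded below, and censored segments are excluded from dating by
default (widen the window instead). The terminus is the last matching SNP's
position, not the midpoint to the next SNP, which puts a small, explicit
downward bias on measured lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .formats import GeneticMap, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    chrom: str
    start_bp: int
    end_bp: int


@dataclass
class FlankWindow:
    """SNPs flanking a CNV region, all strictly outside [start, end].

    Positions are in genomic order; ``left_positions`` end just before the
    CNV start and ``right_positions`` begin just after the CNV end.
    """

    region: Region
    left_positions: np.ndarray
    right_positions: np.ndarray
    left_alleles: np.ndarray  # (n_haps, n_left), genomic order
    right_alleles: np.ndarray  # (n_haps, n_right), genomic order
    hap_ids: list[str]
    short_left: bool = False
    short_right: bool = False

    def hap_index(self, hap_id: str) -> int:
        return self.hap_ids.index(hap_id)


def build_flank_window(
    panel: HaplotypePanel, region: Region, n_snps: int = 60
) -> FlankWindow:
    """Select the nearest ``n_snps`` panel SNPs on each side of the region.

    SNPs inside [start_bp, end_bp] are excluded. Sides with fewer than
    ``n_snps`` available take all and set the corresponding short flag;
    a side with zero SNPs is an error.
    """
    if panel.chrom and panel.chrom != region.chrom:
        raise ValueError(f"panel chromosome {panel.chrom} != region {region.chrom}")
    pos = panel.positions
    left_idx = np.where(pos < region.start_bp)[0]
    right_idx = np.where(pos > region.end_bp)[0]
    if len(left_idx) == 0 or len(right_idx) == 0:
        raise ValueError("no flanking SNPs on one side of the region")
    short_left = len(left_idx) < n_snps
    short_right = len(right_idx) < n_snps
    left_idx = left_idx[-n_snps:]
    right_idx = right_idx[:n_snps]
    return FlankWindow(
        region=region,
        left_positions=pos[left_idx],
        right_positions=pos[right_idx],
        left_alleles=panel.alleles[:, left_idx],
        right_alleles=panel.alleles[:, right_idx],
        hap_ids=list(panel.hap_ids),
        short_left=short_left,
        short_right=short_right,
    )


def consensus_haplotype(
    window: FlankWindow, carrier_hap_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP modal allele among carrier haplotypes over both flanks.

    An exact 0/1 tie takes the allele of the lexicographically first carrier
    haplotype id, which makes the consensus deterministic.
    """
    if len(carrier_hap_ids) == 0:
        raise ValueError("empty carrier set")
    order = sorted(carrier_hap_ids)
    idx = [window.hap_index(h) for h in order]
    out = []
    for alleles in (window.left_alleles, window.right_alleles):
        sub = alleles[idx]
        ones = sub.sum(axis=0)
        half = sub.shape[0] / 2.0
        cons = np.where(ones > half, 1, 0).astype(np.int8)
        tie = ones == half
        cons[tie] = sub[0, tie]  # first-sorted haplotype id breaks ties
        out.append(cons)
    return out[0], out[1]


@dataclass(frozen=True)
class Extension:
    last_match: int  # outward index of last matching SNP; -1 = no extension
    n_rescued: int
    censored: bool  # the walk reached the window edge


def _walk(hap: np.ndarray, cons: np.ndarray, rescue_k: int | float) -> Extension:
    """Outward walk over aligned allele vectors (index 0 nearest the CNV).

    ``rescue_k=0`` disables rescue (stop at the first mismatch); an infinite
    ``rescue_k`` rescues a mismatch only when every remaining SNP matches.
    When fewer than ``rescue_k`` SNPs remain past a mismatch, all remaining
    must match (vacuously true at the window edge).
    """
    n = len(hap)
    last = -1
    rescued = 0
    i = 0
    while i < n:
        if hap[i] == cons[i]:
            last = i
            i += 1
            continue
        if rescue_k:
            stop = n if math.isinf(rescue_k) else min(i + 1 + int(rescue_k), n)
            if all(hap[j] == cons[j] for j in range(i + 1, stop)):
                rescued += 1
                i += 1
                continue
        break
    return Extension(last_match=last, n_rescued=rescued, censored=i == n)


def extend_shared(
    window: FlankWindow,
    hap_id: str,
    consensus: tuple[np.ndarray, np.ndarray],
    direction: Literal["left", "right"],
    rescue_k: int | float = 5,
) -> Extension:
    """Extend one carrier haplotype outward from the CNV boundary on one side."""
    hi = window.hap_index(hap_id)
    cons_left, cons_right = consensus
    if direction == "left":
        hap = window.left_alleles[hi][::-1]  # outward = decreasing position
        cons = cons_left[::-1]
    elif direction == "right":
        hap = window.right_alleles[hi]
        cons = cons_right
    else:
        raise ValueError("direction must be 'left' or 'right'")
    return _walk(hap, cons, rescue_k)


@dataclass
class SharedSegment:
    """One carrier haplotype's maximal shared flank around the CNV.

    ``genetic_length_morgans`` is the Gamma method's ``l_i``: the genetic
    distance from the left terminus to the CNV start plus the distance from
    the CNV end to the right terminus (the CNV interior itself carries no
    recombination information).
    """

    haplotype_id: str
    left_terminus_bp: int
    right_terminus_bp: int
    censored_left: bool
    censored_right: bool
    n_rescued: int
    length_bp: int
    genetic_length_morgans: float

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


def shared_segment(
    window: FlankWindow,
    hap_id: str,
    consensus: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    rescue_k: int | float = 5,
) -> SharedSegment:
    """Measure one carrier haplotype's shared segment on both sides.

    A side with no matching SNP at all keeps its terminus at the CNV
    boundary and contributes zero genetic length.
    """
    left = extend_shared(window, hap_id, consensus, "left", rescue_k)
    right = extend_shared(window, hap_id, consensus, "right", rescue_k)
    region = window.region
    if left.last_match >= 0:
        left_term = int(window.left_positions[::-1][left.last_match])
    else:
        left_term = region.start_bp
    if right.last_match >= 0:
        right_term = int(window.right_positions[right.last_match])
    else:
        right_term = region.end_bp
    chrom = region.chrom
    l_morgans = (
        gmap.cm_at(chrom, region.start_bp)
        - gmap.cm_at(chrom, left_term)
        + gmap.cm_at(chrom, right_term)
        - gmap.cm_at(chrom, region.end_bp)
    ) / 100.0
    return SharedSegment(
        haplotype_id=hap_id,
        left_terminus_bp=left_term,
        right_terminus_bp=right_term,
        censored_left=left.censored,
        censored_right=right.censored,
        n_rescued=left.n_rescued + right.n_rescued,
        length_bp=(region.start_bp - left_term) + (right_term - region.end_bp),
        genetic_length_morgans=float(l_morgans),
    )


def measure_sharing(
    panel: HaplotypePanel,
    region: Region,
    gmap: GeneticMap,
    carrier_hap_ids: Sequence[str],
    n_snps: int = 60,
    rescue_k: int | float = 5,
    mode: Literal["consensus", "pairwise"] = "consensus",
    reference: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[SharedSegment]:
    """Shared segments for every carrier haplotype of one candidate rCNV.

    ``mode="consensus"`` (default) measures each carrier against the modal
    carrier haplotype — the single ancestral background the characteristic-
    haplotype observation implies. ``mode="pairwise"`` instead takes, per
    haplotype and side, the longest extension against any other carrier.
    ``reference`` substitutes an explicit (left, right) allele-vector pair
    for the modal consensus — e.g. a known ancestral haplotype; note the
    modal consensus itself drifts toward the background majority at flank
    distances where most carriers have already recombined.
    """
    window = build_flank_window(panel, region, n_snps=n_snps)
    if reference is not None:
        return [
            shared_segment(window, h, reference, gmap, rescue_k=rescue_k)
            for h in carrier_hap_ids
        ]
    if mode == "consensus":
        cons = consensus_haplotype(window, carrier_hap_ids)
        return [
            shared_segment(window, h, cons, gmap, rescue_k=rescue_k)
            for h in carrier_hap_ids
        ]
    segments = []
    for h in carrier_hap_ids:
        best: SharedSegment | None = None
        for other in carrier_hap_ids:
            if other == h:
                continue
            oi = window.hap_index(other)
            cons = (window.left_alleles[oi], window.right_alleles[oi])
            seg = shared_segment(window, h, cons, gmap, rescue_k=rescue_k)
            if best is None or seg.genetic_length_morgans > best.genetic_length_morgans:
                best = seg
        if best is None:
            raise ValueError("pairwise mode needs at least two carrier haplotypes")
        segments.append(best)
    return segments


def exclude_relatives(
    hap_ids: Iterable[str], excluded_pairs: Iterable[tuple[str, str]]
) -> list[str]:
    """Drop haplotypes of related samples so no excluded pair remains.

    ``excluded_pairs`` lists related *sample* pairs (first/second degree,
    computed externally). Greedy: repeatedly remove the sample in the most
    remaining pairs (ties broken lexicographically); both haplotypes of a
    removed sample go. Order of retained ids is preserved.
    """
    hap_ids = list(hap_ids)
    samples = {HaplotypePanel.sample_of(h) for h in hap_ids}
    pairs = {
        frozenset(p)
        for p in excluded_pairs
        if p[0] != p[1] and p[0] in samples and p[1] in samples
    }
    dropped: set[str] = set()
    while pairs:
        degree: dict[str, int] = {}
        for p in pairs:
            for s in p:
                degree[s] = degree.get(s, 0) + 1
        top = max(degree.values())
        victim = min(s for s, d in degree.items() if d == top)
        dropped.add(victim)
        pairs = {p for p in pairs if victim not in p}
    return [h for h in hap_ids if HaplotypePanel.sample_of(h) not in dropped]
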