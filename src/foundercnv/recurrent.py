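"""Recurrent-CNV detection by shared breakpoints.

On one genotyping array, independent carriers of the same ancestral CNV are
called with probe-identical boundaries, so recurrence within a population is
detected by clustering same-state calls whose start and end boundaries agree
within ``bp_tolerance`` (default 0 bp, i.e. exact probe-boundary match;
single linkage so near-identical boundary jitter chains together when a
tolerance is allowed).

Across populations genotyped on different arrays the probe grids differ, so
the same ancestral event is matched by reciprocal interval overlap (default
0.8) rather than exact boundaries.

Recurrence by breakpoints is only the first stage of the definition: a
cluster is confirmed as identical-by-descent by the flanking-haplotype
analysis in :mod:`foundercnv.sharing`.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .formats import CNVCall


@dataclass
class RecurrentGroup:
    """A cluster of same-state CNV calls sharing breakpoints.

    The group region takes the modal start and modal end over member calls
    (ties resolved to the smallest coordinate). Carrier count is the number
    of distinct samples; carrier frequency (carriers / individuals in the
    population) is attached when the population size is known. Under an
    all-heterozygote assumption the allele frequency is carriers / 2N;
    when copy numbers indicate homozygotes those chromosomes are counted.
    """

    chrom: str
    start_bp: int
    end_bp: int
    state: str
    population: str
    members: list[CNVCall] = field(default_factory=list)
    carrier_frequency: float | None = None
    allele_frequency: float | None = None

    @property
    def carrier_samples(self) -> frozenset[str]:
        return frozenset(c.sample_id for c in self.members)

    @property
    def carrier_count(self) -> int:
        return len(self.carrier_samples)

    @property
    def recurrent(self) -> bool:
        return self.carrier_count >= 2

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def annotate_frequency(self, n_individuals: int) -> None:
        if n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        self.carrier_frequency = self.carrier_count / n_individuals
        n_chrom = 0
        for sid in self.carrier_samples:
            cns = [c.copy_number for c in self.members if c.sample_id == sid]
            cn = cns[0] if cns and cns[0] is not None else None
            homozygous = cn is not None and cn in (0, 4)
            n_chrom += 2 if homozygous else 1
        self.allele_frequency = n_chrom / (2 * n_individuals)


def _modal_min(values: Sequence[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, n in counts.items() if n == top)


def cluster_recurrent(
    calls: Sequence[CNVCall],
    bp_tolerance: int = 0,
    population: str = "",
    n_individuals: int | None = None,
) -> list[RecurrentGroup]:
    """Single-linkage clustering of same-chromosome, same-state calls whose
    start and end boundaries each differ by at most ``bp_tolerance``.

    Deterministic and permutation-invariant: calls are canonically sorted
    before linking and group regions use modal boundaries with smallest-
    coordinate tie-breaks. Output sorted by (chrom, start, end, state).
    """
    if bp_tolerance < 0:
        raise ValueError("bp_tolerance must be non-negative")
    by_key: dict[tuple[str, str], list[CNVCall]] = defaultdict(list)
    for c in calls:
        by_key[(c.chrom, c.state)].append(c)

    groups: list[RecurrentGroup] = []
    for (chrom, state), members in by_key.items():
        members = sorted(members, key=lambda c: (c.start_bp, c.end_bp, c.sample_id))
        # union-find over O(n^2) within-chromosome candidates; cohorts are small
        parent = list(range(len(members)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].start_bp - members[i].start_bp > bp_tolerance:
                    break  # sorted by start: no later j can link to i directly
                if abs(members[i].end_bp - members[j].end_bp) <= bp_tolerance:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        clusters: dict[int, list[CNVCall]] = defaultdict(list)
        for i, c in enumerate(members):
            clusters[find(i)].append(c)
        for cluster in clusters.values():
            g = RecurrentGroup(
                chrom=chrom,
                start_bp=_modal_min([c.start_bp for c in cluster]),
                end_bp=_modal_min([c.end_bp for c in cluster]),
                state=state,
                population=population,
                members=cluster,
            )
            if n_individuals is not None:
                g.annotate_frequency(n_individuals)
            groups.append(g)
    groups.sort(key=lambda g: (g.chrom, g.start_bp, g.end_bp, g.state))
    return groups


@dataclass(frozen=True)
class GroupMatch:
    group_a: RecurrentGroup
    group_b: RecurrentGroup
    reciprocal_overlap: float  # min of the two overlap fractions


def match_across_populations(
    groups_a: Sequence[RecurrentGroup],
    groups_b: Sequence[RecurrentGroup],
    min_reciprocal_overlap: float = 0.8,
) -> list[GroupMatch]:
    """One-to-one matching of recurrent groups between two populations by
    reciprocal overlap of their regions (state must agree), greedy by the
    greatest overlap fraction."""
    candidates = []
    for i, a in enumerate(groups_a):
        for j, b in enumerate(groups_b):
            if a.chrom != b.chrom or a.state != b.state:
                continue
            ov = min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1
            if ov <= 0:
                continue
            frac = min(ov / a.size_bp, ov / b.size_bp)
            if frac >= min_reciprocal_overlap:
                candidates.append((frac, a.start_bp, i, j, a, b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for frac, _, i, j, a, b in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(GroupMatch(a, b, frac))
    return matches


def select_testable(
    groups: Sequence[RecurrentGroup],
    min_carriers: int,
    min_frequency: float = 0.022,
) -> list[RecurrentGroup]:
    """Groups eligible for individual association testing: carrier count at
    least ``min_carriers`` and carrier frequency strictly above
    ``min_frequency`` (the >2.2% design rule at which an OR of 10 is
    detectable with 80% power at these cohort sizes)."""
    out = []
    for g in groups:
        if g.carrier_frequency is None:
            raise ValueError("carrier_frequency not annotated; pass n_individuals")
        if g.carrier_count >= min_carriers and g.carrier_frequency > min_frequency:
            out.append(g)
    return out
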