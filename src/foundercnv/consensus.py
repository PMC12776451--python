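"""Dual-caller consensus and retention filtering.

CNV calls from SNP-array data are noisy and caller-dependent, so a call is
trusted only when two independent callers report it for the same sample with
the same copy-number direction. "Detected by both" is operationalised as
reciprocal overlap of at least ``min_reciprocal_overlap`` (default 0.5); the
consensus interval is the *intersection* of the two callers' intervals,
which is conservative for downstream breakpoint clustering (union is
available via ``mode="union"``).

Retained calls must additionally span >= 10 probes, be >= 10 kb, and lie on
an autosome — the standard array-CNV retention rule.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .formats import CNVCall, is_autosome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusCNV(CNVCall):
    """A call confirmed by two callers; interval is their intersection."""

    source_callers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.source_callers and len(self.source_callers) != 2:
            raise ValueError("consensus requires exactly two source callers")


def _overlap_bp(a: CNVCall, b: CNVCall) -> int:
    return min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1


def intersect_callers(
    calls_a: Sequence[CNVCall],
    calls_b: Sequence[CNVCall],
    min_reciprocal_overlap: float = 0.5,
    mode: Literal["intersection", "union"] = "intersection",
) -> list[ConsensusCNV]:
    """Pair calls across two callers and emit consensus calls.

    Candidate pairs share sample, chromosome and state and each call covers
    at least ``min_reciprocal_overlap`` of the other. Pairing is greedy by
    descending overlap (ties broken by leftmost start), each input call used
    at most once. The consensus probe count is the smaller of the pair's
    (conservative for the 10-probe retention rule); copy number is kept only
    when the callers agree.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")

    by_key: dict[tuple, tuple[list, list]] = defaultdict(lambda: ([], []))
    for i, c in enumerate(calls_a):
        by_key[(c.sample_id, c.chrom, c.state)][0].append((i, c))
    for j, c in enumerate(calls_b):
        by_key[(c.sample_id, c.chrom, c.state)][1].append((j, c))

    out: list[ConsensusCNV] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for key in sorted(by_key):
        side_a, side_b = by_key[key]
        candidates = []
        for i, a in side_a:
            for j, b in side_b:
                ov = _overlap_bp(a, b)
                if ov <= 0:
                    continue
                if ov / a.size_bp >= min_reciprocal_overlap and ov / b.size_bp >= min_reciprocal_overlap:
                    candidates.append((ov, max(a.start_bp, b.start_bp), i, j, a, b))
        # greedy: biggest overlap first, leftmost intersection on ties
        candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        for ov, _, i, j, a, b in candidates:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            if mode == "intersection":
                start, end = max(a.start_bp, b.start_bp), min(a.end_bp, b.end_bp)
            else:
                start, end = min(a.start_bp, b.start_bp), max(a.end_bp, b.end_bp)
            cn = a.copy_number if a.copy_number == b.copy_number else None
            out.append(
                ConsensusCNV(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    start_bp=start,
                    end_bp=end,
                    state=a.state,
                    n_probes=min(a.n_probes, b.n_probes),
                    caller="consensus",
                    copy_number=cn,
                    source_callers=frozenset({a.caller or "A", b.caller or "B"}),
                )
            )
    n_unmatched = (len(calls_a) - len(used_a)) + (len(calls_b) - len(used_b))
    if n_unmatched:
        logger.info(
            "intersect_callers: %d consensus call(s); %d unmatched call(s) excluded",
            len(out),
            n_unmatched,
        )
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start_bp, c.end_bp))
    return out


def filter_calls(
    calls: Iterable[CNVCall],
    min_probes: int = 10,
    min_size_bp: int = 10_000,
    autosomes_only: bool = True,
) -> list[CNVCall]:
    """Apply the retention rule: >=10 adjacent probes, >=10 kb, autosomal.

    A call failing several rules increments each rule's rejection counter;
    counts are logged at INFO.
    """
    kept: list[CNVCall] = []
    rejected: Counter[str] = Counter()
    for c in calls:
        ok = True
        if c.n_probes < min_probes:
            rejected["min_probes"] += 1
            ok = False
        if c.size_bp < min_size_bp:
            rejected["min_size_bp"] += 1
            ok = False
        if autosomes_only and not is_autosome(c.chrom):
            rejected["non_autosomal"] += 1
            ok = False
        if ok:
            kept.append(c)
    if rejected:
        logger.info("filter_calls: rejections %s", dict(rejected))
    return kept


@dataclass
class CohortSummary:
    """Descriptive totals for one cohort's retained CNV events."""

    n_individuals: int
    n_events: int
    n_del: int
    n_dup: int
    frac_del: float
    frac_dup: float
    mean_size_kb: float
    events_per_person: float
    empty: bool = False

    def report_row(self) -> dict:
        """Display-rounded row: percentages to the nearest integer,
        per-person averages to one decimal."""
        return {
            "n_individuals": self.n_individuals,
            "n_events": self.n_events,
            "n_del": self.n_del,
            "n_dup": self.n_dup,
            "pct_del": round(100 * self.frac_del),
            "pct_dup": round(100 * self.frac_dup),
            "mean_size_kb": round(self.mean_size_kb),
            "events_per_person": round(self.events_per_person, 1),
        }


def cohort_summary(calls: Sequence[CNVCall], n_individuals: int) -> CohortSummary:
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    n = len(calls)
    n_del = sum(1 for c in calls if c.state == "DEL")
    n_dup = n - n_del
    if n == 0:
        return CohortSummary(n_individuals, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    return CohortSummary(
        n_individuals=n_individuals,
        n_events=n,
        n_del=n_del,
        n_dup=n_dup,
        frac_del=n_del / n,
        frac_dup=n_dup / n,
        mean_size_kb=sum(c.size_bp for c in calls) / n / 1000.0,
        events_per_person=n / n_individuals,
    )
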