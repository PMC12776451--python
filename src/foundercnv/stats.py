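"""Carrier association statistics, CNV burden, and power by simulation.

Association of a recurrent CNV with a binary phenotype is tested on the
carrier-by-case 2x2 table with the Pearson chi-square statistic (no
continuity correction) and summarised by the odds ratio with a Woolf
(log-normal) confidence interval:

    OR = a*d / (b*c),   CI = exp( ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) )

Zero cells receive the Haldane-Anscombe +0.5 correction (flagged). Multiple
testing across rCNVs is handled by Bonferroni or Benjamini-Hochberg.

Burden is per-individual: number of consensus CNV events and gene load —
the count of distinct genes overlapped by >= 1 bp by any of the sample's
CNVs — compared between phenotype classes with the Mann-Whitney test.

``power_by_simulation`` reproduces the design computation behind the
carrier-frequency threshold for testable rCNVs: given cohort size,
population prevalence, carrier frequency and carrier odds ratio, it solves
the non-carrier case probability so the population prevalence is matched,
simulates case/carrier tables, and reports the fraction of replicates whose
chi-square p falls below alpha.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .dating import mann_whitney
from .formats import CNVCall, GeneInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Table2x2:
    """Counts: a = carrier cases, b = carrier non-cases, c = non-carrier
    cases, d = non-carrier non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def carriers(self) -> int:
        return self.a + self.b

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def two_by_two(
    carrier_status: Mapping[str, int], phenotype: Mapping[str, int]
) -> Table2x2:
    """Cross-tabulate carrier status against a binary phenotype.

    Samples present in only one mapping are excluded with a logged count;
    fully disjoint sample sets are an error.
    """
    common = set(carrier_status) & set(phenotype)
    if not common:
        raise ValueError("carrier and phenotype sample sets are disjoint")
    n_dropped = len(set(carrier_status) | set(phenotype)) - len(common)
    if n_dropped:
        logger.info("two_by_two: excluded %d sample(s) missing a value", n_dropped)
    a = b = c = d = 0
    for s in common:
        if carrier_status[s]:
            if phenotype[s]:
                a += 1
            else:
                b += 1
        elif phenotype[s]:
            c += 1
        else:
            d += 1
    return Table2x2(a, b, c, d)


@dataclass
class OddsRatioCI:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool = False
    undefined: bool = False


def odds_ratio_ci(
    table: Table2x2,
    alpha: float = 0.05,
    method: Literal["woolf", "exact"] = "woolf",
) -> OddsRatioCI:
    """Odds ratio with a Woolf CI (default) or scipy's exact conditional CI.

    Any single zero cell triggers the Haldane-Anscombe +0.5 correction to
    all cells (flagged). Two zero cells in one row or column leave the OR
    undefined (flagged, NaN)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        return OddsRatioCI(float("nan"), float("nan"), float("nan"), undefined=True)
    if method == "exact":
        res = stats.contingency.odds_ratio(
            [[a, b], [c, d]], kind="conditional"
        )
        ci = res.confidence_interval(confidence_level=1 - alpha)
        return OddsRatioCI(float(res.statistic), float(ci.low), float(ci.high))
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = a * d / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return OddsRatioCI(
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - z * se)),
        ci_high=float(np.exp(np.log(orr) + z * se)),
        haldane_corrected=corrected,
    )


def chi_square_p(
    table: Table2x2, sided: Literal["two", "one"] = "two"
) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on the 2x2 table.

    Two-sided p from the 1-df chi-square law; the one-sided p halves it when
    the observed OR exceeds 1 and is its complement-half otherwise. A zero
    margin leaves the statistic undefined (NaN, NaN) with a warning.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        logger.warning("chi_square_p: zero margin, statistic undefined")
        return float("nan"), float("nan")
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected <= 5):
        logger.warning("chi_square_p: expected cell count <= 5; chi-square approximation weak")
    chi2, p_two, _, _ = stats.chi2_contingency(arr, correction=False)
    if sided == "two":
        return float(chi2), float(p_two)
    # direction from the (possibly corrected) observed OR
    orr = odds_ratio_ci(table).odds_ratio
    p_one = p_two / 2 if orr > 1 else 1 - p_two / 2
    return float(chi2), float(p_one)


def adjust_p(
    p_values: Sequence[float], method: Literal["bonferroni", "bh"]
) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni min(1, m*p) or the
    Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AssociationResult:
    label: str
    table: Table2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_two_sided: float
    p_one_sided: float
    p_bonferroni: float | None = None
    q_bh: float | None = None
    haldane_corrected: bool = False


def associate(
    label: str, carrier_status: Mapping[str, int], phenotype: Mapping[str, int],
    alpha: float = 0.05,
) -> AssociationResult:
    """One rCNV against one phenotype: table, OR + Woolf CI, chi-square."""
    table = two_by_two(carrier_status, phenotype)
    orr = odds_ratio_ci(table, alpha=alpha)
    chi2, p_two = chi_square_p(table, sided="two")
    _, p_one = chi_square_p(table, sided="one")
    return AssociationResult(
        label=label,
        table=table,
        odds_ratio=orr.odds_ratio,
        ci_low=orr.ci_low,
        ci_high=orr.ci_high,
        chi2=chi2,
        p_two_sided=p_two,
        p_one_sided=p_one,
        haldane_corrected=orr.haldane_corrected,
    )


def adjust_association_results(
    results: Sequence[AssociationResult], which: Literal["two", "one"] = "two"
) -> None:
    """Attach Bonferroni and BH adjustments across a family of tests."""
    ps = [r.p_two_sided if which == "two" else r.p_one_sided for r in results]
    bonf = adjust_p(ps, "bonferroni")
    bh = adjust_p(ps, "bh")
    for r, pb, qb in zip(results, bonf, bh):
        r.p_bonferroni = float(pb)
        r.q_bh = float(qb)


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------


@dataclass
class BurdenSummary:
    sample_id: str
    n_cnvs: int
    gene_load: int


def burden_metrics(
    calls: Iterable[CNVCall], genes: Sequence[GeneInterval],
    samples: Sequence[str] | None = None,
) -> dict[str, BurdenSummary]:
    """Per-sample CNV count and gene load.

    Gene load counts distinct genes overlapped by >= 1 bp by any of the
    sample's CNVs; partial overlap counts and a gene hit by two CNVs counts
    once. ``samples`` extends the output to individuals with zero calls.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        # interval tree is half-open; +1 makes the 1-based inclusive end interior
        trees[g.chrom].addi(g.start_bp, g.end_bp + 1, g.name)
    per_sample_calls: dict[str, list[CNVCall]] = defaultdict(list)
    for c in calls:
        per_sample_calls[c.sample_id].append(c)
    universe = list(samples) if samples is not None else sorted(per_sample_calls)
    out: dict[str, BurdenSummary] = {}
    for sid in universe:
        sample_calls = per_sample_calls.get(sid, [])
        hit: set[str] = set()
        for c in sample_calls:
            for iv in trees[c.chrom].overlap(c.start_bp, c.end_bp + 1):
                hit.add(iv.data)
        out[sid] = BurdenSummary(sid, n_cnvs=len(sample_calls), gene_load=len(hit))
    return out


def burden_test(
    burdens: Mapping[str, float], phenotype: Mapping[str, int]
) -> tuple[float, float]:
    """Mann-Whitney comparison of burden values between phenotype classes."""
    cases = [v for s, v in burdens.items() if phenotype.get(s) == 1]
    controls = [v for s, v in burdens.items() if phenotype.get(s) == 0]
    if not cases or not controls:
        raise ValueError("both phenotype classes must be non-empty")
    return mann_whitney(cases, controls)


# ---------------------------------------------------------------------------
# Power by simulation
# ---------------------------------------------------------------------------


def solve_noncarrier_rate(
    prevalence: float, carrier_freq: float, odds_ratio: float
) -> tuple[float, float]:
    """Solve (p_noncarrier, p_carrier) so the population prevalence equals
    ``prevalence`` when carriers' case odds are ``odds_ratio`` times
    non-carriers'. Raises if no probability pair achieves it."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if not 0 <= carrier_freq < 1:
        raise ValueError("carrier_freq must be in [0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")

    def p1_of(p0: float) -> float:
        o = odds_ratio * p0 / (1 - p0)
        return o / (1 + o)

    def gap(p0: float) -> float:
        return carrier_freq * p1_of(p0) + (1 - carrier_freq) * p0 - prevalence

    lo, hi = 1e-12, 1 - 1e-12
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("infeasible prevalence / carrier_freq / odds_ratio combination")
    p0 = optimize.brentq(gap, lo, hi, xtol=1e-14)
    return float(p0), float(p1_of(p0))


@dataclass
class PowerEstimate:
    power: float
    se: float  # binomial standard error over replicates
    reps: int
    alpha: float


def power_by_simulation(
    n: int,
    prevalence: float,
    carrier_freq: float,
    odds_ratio: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of the chi-square carrier test.

    Per replicate: carrier count ~ Binomial(n, carrier_freq); cases among
    carriers and non-carriers ~ Binomial at the solved class probabilities;
    significance at ``alpha`` by the two-sided Pearson chi-square without
    continuity correction. Replicates with a zero margin count as
    non-significant. Reproducible by ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    p0, p1 = solve_noncarrier_rate(prevalence, carrier_freq, odds_ratio)
    rng = np.random.default_rng(seed)
    nc = rng.binomial(n, carrier_freq, size=reps)
    a = rng.binomial(nc, p1)
    c = rng.binomial(n - nc, p0)
    b = nc - a
    d = n - nc - c
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    valid = denom > 0
    chi2 = np.zeros(reps)
    chi2[valid] = (
        n * (a[valid] * d[valid] - b[valid] * c[valid]).astype(float) ** 2
        / denom[valid]
    )
    pvals = np.ones(reps)
    pvals[valid] = stats.chi2.sf(chi2[valid], 1)
    power = float(np.mean(pvals < alpha))
    se = float(np.sqrt(power * (1 - power) / reps))
    return PowerEstimate(power=power, se=se, reps=reps, alpha=alpha)
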