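"""Synthetic data with the statistical structure the pipeline assumes.

The study's tribal genotypes are not publicly deposited, so every pipeline
stage is exercised on generated inputs with known ground truth. The
generator emulates:

* haplotype decay around a focal CNV — each carrier haplotype copies an
  ancestral background over a flank whose per-side *genetic* length is
  exponential with rate ``tau`` per Morgan (the generative counterpart of
  the Gamma method's independence assumption; no full coalescent);
* per-SNP mismatches on shared segments at rate ``epsilon``, covering both
  point mutation and the rare genotyping error without distinguishing them;
* two noisy caller outputs per true CNV (boundary jitter, dropout);
* binary phenotypes with a specified carrier odds ratio at a target
  population prevalence.

Defaults are the study's conditions: the 96-kb chr6 MHC-region deletion
with 60 carriers among 387 individuals, age 750 generations, 60 SNPs per
flank, epsilon 0.001 (duplicate-genotype reproducibility 0.999), AUD
prevalence 0.60 with carrier OR 3.18. The flank spans 700 kb at a uniform
1 cM/Mb, about five mean shared-lengths at tau=750, keeping censoring near
1%.

Every operation takes its randomness from a seeded generator; outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import CNVCall, GeneticMap, HaplotypePanel, PhenotypeTable, uniform_map
from .sharing import Region
from .stats import solve_noncarrier_rate


@dataclass
class SimConfig:
    """Generator parameters; see the module docstring for default rationale.

    ``map_profile`` is either a uniform rate in cM/Mb (float) or an explicit
    anchor list [(pos_bp, rate_cM_Mb, cumulative_cM), ...]. ``seed`` is any
    value numpy's default_rng accepts (an int or a tuple of ints).
    """

    seed: int | tuple
    tau_generations: float = 750.0
    n_carriers: int = 60
    n_noncarriers: int = 327
    n_snps_per_flank: int = 60
    region: Region = field(default_factory=lambda: Region("chr6", 31_355_318, 31_451_476))
    state: str = "DEL"
    flank_span_bp: int = 700_000
    map_profile: float | list[tuple[int, float, float]] = 1.0
    epsilon: float = 0.001
    background_freq_range: tuple[float, float] = (0.1, 0.9)
    caller_jitter_bp: int = 0
    caller_dropout_prob: float = 0.0
    #: genome-wide array probe spacing (bp) used for call probe counts;
    #: ~550k probes over 3 Gb on a HumanHap550-class array
    array_probe_spacing_bp: int = 5_500
    baseline_prevalence: float = 0.60
    carrier_odds_ratio: float = 3.18
    background_psych_prob: float = 0.2
    mark_breakpoints: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.tau_generations <= 0:
            raise ValueError("tau_generations must be positive")
        for name in ("epsilon", "caller_dropout_prob", "baseline_prevalence",
                     "background_psych_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_carriers < 1 or self.n_snps_per_flank < 1:
            raise ValueError("n_carriers and n_snps_per_flank must be >= 1")


def carrier_sample_ids(config: SimConfig) -> list[str]:
    return [f"CAR{i:04d}" for i in range(config.n_carriers)]


def noncarrier_sample_ids(config: SimConfig) -> list[str]:
    return [f"CTL{i:04d}" for i in range(config.n_noncarriers)]


@dataclass
class RegionSim:
    """A simulated locus: map, flank SNP grid, ancestral haplotype and the
    per-SNP background allele frequencies from which non-shared alleles are
    drawn."""

    config: SimConfig
    gmap: GeneticMap
    positions: np.ndarray  # flank SNPs only, ascending, none inside the CNV
    ancestral: np.ndarray  # 0/1 alleles over positions
    background_freqs: np.ndarray

    @property
    def left_mask(self) -> np.ndarray:
        return self.positions < self.config.region.start_bp


def simulate_region(config: SimConfig) -> RegionSim:
    """Lay out flank SNPs uniformly, build the map, draw the ancestral
    haplotype and per-SNP background allele frequencies."""
    rng = np.random.default_rng(config.seed)
    region = config.region
    n = config.n_snps_per_flank
    left = np.sort(
        rng.choice(np.arange(region.start_bp - config.flank_span_bp, region.start_bp),
                   size=n, replace=False)
    )
    right = np.sort(
        rng.choice(np.arange(region.end_bp + 1, region.end_bp + config.flank_span_bp + 1),
                   size=n, replace=False)
    )
    positions = np.concatenate([left, right]).astype(np.int64)
    if isinstance(config.map_profile, (int, float)):
        gmap = uniform_map(
            region.chrom,
            region.start_bp - config.flank_span_bp,
            region.end_bp + config.flank_span_bp,
            float(config.map_profile),
        )
    else:
        gmap = GeneticMap()
        anchors = sorted(config.map_profile)
        gmap.add_chromosome(
            region.chrom,
            [a[0] for a in anchors],
            [a[1] for a in anchors],
            [a[2] for a in anchors],
        )
    lo, hi = config.background_freq_range
    freqs = rng.uniform(lo, hi, size=len(positions))
    ancestral = (rng.random(len(positions)) < freqs).astype(np.int8)
    return RegionSim(config, gmap, positions, ancestral, freqs)


def simulate_shared_lengths(
    tau: float, n: int, rng: np.random.Generator, max_side_morgans: float = np.inf
) -> np.ndarray:
    """Two-sided shared lengths l_i = left + right, each side Exp(tau) in
    Morgans, truncated at ``max_side_morgans``. The continuous model behind
    the Gamma estimator, used directly for CI-coverage checks."""
    sides = rng.exponential(scale=1.0 / tau, size=(n, 2))
    return np.minimum(sides, max_side_morgans).sum(axis=1)


def simulate_carriers(
    config: SimConfig, region_sim: RegionSim
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Carrier and non-carrier haplotypes plus a per-carrier truth table.

    Each carrier's first haplotype carries the CNV: it copies the ancestral
    alleles over a shared segment whose per-side genetic length is drawn
    Exp(tau) (truncated at the window, setting the censor flag), with each
    within-segment SNP flipped independently at rate epsilon; outside the
    segment, alleles are background draws. The second haplotype and all
    non-carrier haplotypes are background draws.

    With ``mark_breakpoints=True`` the first SNP outside an uncensored
    segment is forced to mismatch the ancestral allele, removing chance
    sharing beyond the true recombination breakpoint; the default leaves
    chance sharing in, as in real data.

    The truth table records, per carrier haplotype: the drawn per-side
    genetic lengths, censor flags, and the discretised termini (outermost
    SNP inside the segment, or the CNV boundary when none is covered).
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed, 1))
    region = cfg.region
    pos = region_sim.positions
    chrom = region.chrom
    gmap = region_sim.gmap
    left_mask = region_sim.left_mask
    left_pos = pos[left_mask]
    right_pos = pos[~left_mask]
    n_left = len(left_pos)

    # genetic distance of every flank SNP from its CNV boundary (Morgans, >=0)
    d_left = np.asarray(gmap.morgans_at(chrom, region.start_bp)) - np.asarray(
        gmap.morgans_at(chrom, left_pos)
    )
    d_right = np.asarray(gmap.morgans_at(chrom, right_pos)) - np.asarray(
        gmap.morgans_at(chrom, region.end_bp)
    )
    window_left = float(d_left.max())
    window_right = float(d_right.max())

    hap_rows: list[np.ndarray] = []
    hap_ids: list[str] = []
    truth_rows = []

    def background_row() -> np.ndarray:
        return (rng.random(len(pos)) < region_sim.background_freqs).astype(np.int8)

    for sid in carrier_sample_ids(cfg):
        l_left = float(rng.exponential(1.0 / cfg.tau_generations))
        l_right = float(rng.exponential(1.0 / cfg.tau_generations))
        cens_left = l_left >= window_left
        cens_right = l_right >= window_right
        eff_left = min(l_left, window_left)
        eff_right = min(l_right, window_right)
        in_left = d_left <= eff_left
        in_right = d_right <= eff_right
        shared = np.concatenate([in_left, in_right])

        hap = background_row()
        hap[shared] = region_sim.ancestral[shared]
        if cfg.epsilon > 0:
            flip = shared & (rng.random(len(pos)) < cfg.epsilon)
            hap[flip] = 1 - hap[flip]
        if cfg.mark_breakpoints:
            # force a mismatch at the first off-segment SNP on each
            # uncensored side (nearest the CNV among off-segment SNPs)
            if not cens_left:
                out_idx = np.where(~in_left)[0]
                hap[out_idx[-1]] = 1 - region_sim.ancestral[out_idx[-1]]
            if not cens_right:
                out_idx = np.where(~in_right)[0]
                j = n_left + out_idx[0]
                hap[j] = 1 - region_sim.ancestral[j]

        hap_rows.append(hap)
        hap_ids.append(f"{sid}_h1")
        hap_rows.append(background_row())
        hap_ids.append(f"{sid}_h2")
        truth_rows.append(
            {
                "hap_id": f"{sid}_h1",
                "left_len_morgans": l_left,
                "right_len_morgans": l_right,
                "censored_left": cens_left,
                "censored_right": cens_right,
                "left_terminus_bp": int(left_pos[in_left][0]) if in_left.any() else region.start_bp,
                "right_terminus_bp": int(right_pos[in_right][-1]) if in_right.any() else region.end_bp,
            }
        )

    for sid in noncarrier_sample_ids(cfg):
        for k in (1, 2):
            hap_rows.append(background_row())
            hap_ids.append(f"{sid}_h{k}")

    panel = HaplotypePanel(chrom, pos, np.stack(hap_rows), hap_ids)
    return panel, pd.DataFrame(truth_rows)


def true_cnv_calls(config: SimConfig, n_probes: int | None = None) -> list[CNVCall]:
    """The ground-truth call set: one CNV over the region per carrier.

    Probe counts follow the array's genome-wide probe spacing, not the
    60-SNP analysis flank grid."""
    region = config.region
    if n_probes is None:
        n_probes = max(
            1, round((region.end_bp - region.start_bp + 1) / config.array_probe_spacing_bp)
        )
    return [
        CNVCall(sid, region.chrom, region.start_bp, region.end_bp, config.state,
                n_probes=n_probes, caller="truth")
        for sid in carrier_sample_ids(config)
    ]


def simulate_caller_tables(
    true_cnvs: Sequence[CNVCall], config: SimConfig
) -> tuple[list[CNVCall], list[CNVCall]]:
    """Two noisy caller outputs: per caller, each true CNV is dropped with
    ``caller_dropout_prob`` and its boundaries jittered uniformly within
    +/- ``caller_jitter_bp``; probe counts follow the array probe spacing."""
    rng = np.random.default_rng((config.seed, 2))
    tables: list[list[CNVCall]] = []
    for caller in ("callerA", "callerB"):
        rows: list[CNVCall] = []
        for c in true_cnvs:
            if rng.random() < config.caller_dropout_prob:
                continue
            j = config.caller_jitter_bp
            start = c.start_bp + (int(rng.integers(-j, j + 1)) if j else 0)
            end = c.end_bp + (int(rng.integers(-j, j + 1)) if j else 0)
            if end < start:
                start, end = end, start
            n_probes = (
                max(1, round((end - start + 1) / config.array_probe_spacing_bp))
                if j
                else c.n_probes
            )
            rows.append(replace(c, start_bp=start, end_bp=end, caller=caller,
                                n_probes=n_probes))
        tables.append(rows)
    return tables[0], tables[1]


def simulate_phenotypes(
    carrier_status: dict[str, int],
    baseline_prevalence: float,
    carrier_odds_ratio: float,
    seed: int | tuple,
    background_psych_prob: float = 0.0,
) -> PhenotypeTable:
    """Binary AUD phenotypes with the requested carrier odds ratio.

    The non-carrier case probability is solved so the population prevalence
    matches ``baseline_prevalence`` at the observed carrier fraction. An
    optional independent background psychiatric diagnosis ("OtherPsych") at
    ``background_psych_prob`` exercises the any-psych union.
    """
    rng = np.random.default_rng(seed)
    samples = list(carrier_status)
    freq = sum(bool(v) for v in carrier_status.values()) / len(samples)
    p0, p1 = solve_noncarrier_rate(baseline_prevalence, freq, carrier_odds_ratio)
    aud = {}
    diagnoses: dict[str, set] = {}
    for s in samples:
        p = p1 if carrier_status[s] else p0
        aud[s] = int(rng.random() < p)
        diagnoses[s] = set()
        if background_psych_prob and rng.random() < background_psych_prob:
            diagnoses[s].add("OtherPsych")
    return PhenotypeTable.from_mappings(aud, diagnoses)


def simulate_all(config: SimConfig):
    """Convenience bundle: region, panel+truth, caller tables, phenotypes."""
    region_sim = simulate_region(config)
    panel, truth = simulate_carriers(config, region_sim)
    calls_a, calls_b = simulate_caller_tables(true_cnv_calls(config), config)
    status = {sid: 1 for sid in carrier_sample_ids(config)}
    status.update({sid: 0 for sid in noncarrier_sample_ids(config)})
    phenotypes = simulate_phenotypes(
        status,
        config.baseline_prevalence,
        config.carrier_odds_ratio,
        seed=(config.seed, 3),
        background_psych_prob=config.background_psych_prob,
    )
    return region_sim, panel, truth, calls_a, calls_b, phenotypes
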