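"""End-to-end orchestration: consensus -> filter -> recurrent groups ->
haplotype sharing -> dating -> association / burden, from a single config.

The config is a flat YAML mapping; every analysis threshold used anywhere in
the run comes from it (defaults mirror the standard retention and design
rules: 10 probes, 10 kb, 60 flank SNPs, rescue depth 5, alpha 0.05, carrier
frequency > 0.022). The resolved config, per-stage counts, and the seed are
embedded in the output bundle's run log so a run is reproducible from its
outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import cohort_summary, filter_calls, intersect_callers
from .dating import EstimationError, estimate_tau
from .formats import (
    read_cnv_calls,
    read_genes_bed,
    read_genetic_map,
    read_haplotypes,
    read_phenotypes,
    write_cnv_calls,
)
from .recurrent import cluster_recurrent, match_across_populations, select_testable
from .sharing import Region, exclude_relatives, measure_sharing
from .stats import adjust_association_results, associate, burden_metrics, burden_test

logger = logging.getLogger(__name__)


@dataclass
class PopulationInputs:
    name: str
    calls_a: str
    calls_b: str
    n_individuals: int
    caller_a: str = "callerA"
    caller_b: str = "callerB"
    haplotypes: str | None = None  # phased VCF or matrix over the focal region
    phenotypes: str | None = None


@dataclass
class PipelineConfig:
    populations: list[PopulationInputs]
    genetic_map: str | None = None
    genes_bed: str | None = None
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    min_reciprocal_overlap: float = 0.5
    min_probes: int = 10
    min_size_bp: int = 10_000
    autosomes_only: bool = True
    bp_tolerance: int = 0
    cross_pop_overlap: float = 0.8
    n_flank_snps: int = 60
    rescue_k: int = 5
    weighting_mode: str = "per_haplotype"
    alpha: float = 0.05
    multiple_testing: str = "bh"
    min_carriers: int = 25
    min_frequency: float = 0.022
    years_per_generation: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pops = [PopulationInputs(**p) for p in raw.pop("populations")]
        raw["excluded_pairs"] = [tuple(p) for p in raw.get("excluded_pairs", [])]
        return cls(populations=pops, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_pairs"] = [list(p) for p in self.excluded_pairs]
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, writing one TSV per product plus run_log.json.

    Stages needing absent inputs (no haplotypes -> no dating; no phenotypes
    -> no association/burden) are skipped with a log entry. Returns the run
    log as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    gmap = read_genetic_map(config.genetic_map) if config.genetic_map else None
    genes = read_genes_bed(config.genes_bed) if config.genes_bed else None

    per_pop_groups = {}
    per_pop_consensus = {}
    summary_rows = []
    age_rows = []
    assoc_results = []
    burden_rows = []
    burden_tests = []

    for pop in config.populations:
        name = pop.name
        try:
            calls_a = read_cnv_calls(pop.calls_a, caller=pop.caller_a)
            calls_b = read_cnv_calls(pop.calls_b, caller=pop.caller_b)
        except Exception as exc:
            raise StageError(f"read_calls[{name}]", exc)
        try:
            consensus = intersect_callers(
                calls_a, calls_b, min_reciprocal_overlap=config.min_reciprocal_overlap
            )
            retained = filter_calls(
                consensus,
                min_probes=config.min_probes,
                min_size_bp=config.min_size_bp,
                autosomes_only=config.autosomes_only,
            )
        except Exception as exc:
            raise StageError(f"consensus[{name}]", exc)
        log["stages"][f"consensus[{name}]"] = {
            "calls_a": len(calls_a),
            "calls_b": len(calls_b),
            "consensus": len(consensus),
            "retained": len(retained),
        }
        if not retained:
            logger.warning("pipeline: no retained calls for %s", name)
        per_pop_consensus[name] = retained
        write_cnv_calls(retained, out / f"consensus_{name}.tsv")
        summary_rows.append(
            {"population": name, **cohort_summary(retained, pop.n_individuals).report_row()}
        )

        groups = cluster_recurrent(
            retained,
            bp_tolerance=config.bp_tolerance,
            population=name,
            n_individuals=pop.n_individuals,
        )
        per_pop_groups[name] = groups
        pd.DataFrame(
            [
                {
                    "population": name,
                    "chrom": g.chrom,
                    "start": g.start_bp,
                    "end": g.end_bp,
                    "size_mb": round(g.size_bp / 1e6, 2),
                    "state": g.state,
                    "carriers": g.carrier_count,
                    "carrier_frequency": g.carrier_frequency,
                    "carrier_frequency_2dp": int(g.carrier_frequency * 100) / 100,
                    "allele_frequency": g.allele_frequency,
                    "recurrent": g.recurrent,
                }
                for g in groups
            ]
        ).to_csv(out / f"rcnv_groups_{name}.tsv", sep="\t", index=False)
        log["stages"][f"detect_rcnv[{name}]"] = {
            "groups": len(groups),
            "recurrent": sum(g.recurrent for g in groups),
        }

        # --- haplotype sharing + dating on recurrent groups --------------
        if pop.haplotypes and gmap is not None:
            panel = read_haplotypes(pop.haplotypes)
            seg_rows = []
            for g in (g for g in groups if g.recurrent):
                if g.chrom != panel.chrom:
                    continue
                carrier_haps = [f"{s}_h1" for s in sorted(g.carrier_samples)
                                if f"{s}_h1" in panel.hap_ids]
                carrier_haps = exclude_relatives(carrier_haps, config.excluded_pairs)
                if not carrier_haps:
                    continue
                region = Region(g.chrom, g.start_bp, g.end_bp)
                try:
                    segments = measure_sharing(
                        panel, region, gmap, carrier_haps,
                        n_snps=config.n_flank_snps, rescue_k=config.rescue_k,
                    )
                except ValueError as exc:
                    logger.warning("sharing skipped for %s:%d-%d: %s",
                                   g.chrom, g.start_bp, g.end_bp, exc)
                    continue
                label = f"{g.chrom}:{g.start_bp}-{g.end_bp}_{g.state.lower()}"
                for s in segments:
                    seg_rows.append({
                        "population": name, "rcnv": label,
                        "haplotype_id": s.haplotype_id,
                        "left_terminus_bp": s.left_terminus_bp,
                        "right_terminus_bp": s.right_terminus_bp,
                        "censored_left": s.censored_left,
                        "censored_right": s.censored_right,
                        "n_rescued": s.n_rescued,
                        "length_bp": s.length_bp,
                        "genetic_length_morgans": s.genetic_length_morgans,
                    })
                try:
                    est = estimate_tau(
                        segments, weighting_mode=config.weighting_mode,
                        alpha=config.alpha,
                    )
                except EstimationError as exc:
                    logger.warning("dating skipped for %s: %s", label, exc)
                    continue
                row = {
                    "population": name, "rcnv": label,
                    "tau_generations": est.tau_generations,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "l_ave_morgans": est.l_ave_morgans,
                    "n_haplotypes": est.n_haplotypes,
                    "n_censored_excluded": est.n_censored_excluded,
                }
                if config.years_per_generation:
                    row["age_years"] = est.tau_generations * config.years_per_generation
                age_rows.append(row)
            pd.DataFrame(seg_rows).to_csv(
                out / f"shared_segments_{name}.tsv", sep="\t", index=False
            )
            log["stages"][f"share[{name}]"] = {"segments": len(seg_rows)}

        # --- association + burden ----------------------------------------
        if pop.phenotypes:
            phen = read_phenotypes(pop.phenotypes)
            testable = select_testable(
                groups, min_carriers=config.min_carriers,
                min_frequency=config.min_frequency,
            )
            pop_assoc = []
            for g in testable:
                label = f"{g.chrom}:{g.start_bp}-{g.end_bp}_{g.state.lower()}"
                status = {s: int(s in g.carrier_samples) for s in phen.samples}
                for phen_name, values in (
                    ("AUD", phen.aud_status()),
                    ("any_psych", phen.any_psych_status()),
                ):
                    r = associate(f"{name}:{label}:{phen_name}", status, values,
                                  alpha=config.alpha)
                    pop_assoc.append(r)
            if pop_assoc:
                adjust_association_results(pop_assoc)
                assoc_results.extend(pop_assoc)
            log["stages"][f"assoc[{name}]"] = {
                "testable_groups": len(testable), "tests": len(pop_assoc)
            }
            if genes is not None:
                burdens = burden_metrics(retained, genes, samples=phen.samples)
                for b in burdens.values():
                    burden_rows.append({
                        "population": name, "sample": b.sample_id,
                        "n_cnvs": b.n_cnvs, "gene_load": b.gene_load,
                    })
                for metric in ("n_cnvs", "gene_load"):
                    vals = {s: getattr(burdens[s], metric) for s in burdens}
                    for phen_name, values in (
                        ("AUD", phen.aud_status()),
                        ("any_psych", phen.any_psych_status()),
                    ):
                        try:
                            u, p = burden_test(vals, values)
                        except ValueError:
                            continue
                        burden_tests.append({
                            "population": name, "metric": metric,
                            "phenotype": phen_name, "U": u, "p": p,
                        })

    pd.DataFrame(summary_rows).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    if len(config.populations) >= 2:
        names = [p.name for p in config.populations]
        matches = match_across_populations(
            per_pop_groups[names[0]], per_pop_groups[names[1]],
            min_reciprocal_overlap=config.cross_pop_overlap,
        )
        pd.DataFrame(
            [
                {
                    "chrom": m.group_a.chrom, "state": m.group_a.state,
                    f"start_{names[0]}": m.group_a.start_bp,
                    f"end_{names[0]}": m.group_a.end_bp,
                    f"start_{names[1]}": m.group_b.start_bp,
                    f"end_{names[1]}": m.group_b.end_bp,
                    "reciprocal_overlap": m.reciprocal_overlap,
                }
                for m in matches
            ]
        ).to_csv(out / "cross_population_matches.tsv", sep="\t", index=False)
        log["stages"]["match"] = {"matched": len(matches)}
    if age_rows:
        pd.DataFrame(age_rows).to_csv(out / "rcnv_ages.tsv", sep="\t", index=False)
    if assoc_results:
        pd.DataFrame(
            [
                {
                    "test": r.label,
                    "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                    "OR": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "chi2": r.chi2, "p_two_sided": r.p_two_sided,
                    "p_one_sided": r.p_one_sided,
                    "p_bonferroni": r.p_bonferroni, "q_bh": r.q_bh,
                }
                for r in assoc_results
            ]
        ).to_csv(out / "association.tsv", sep="\t", index=False)
    if burden_rows:
        pd.DataFrame(burden_rows).to_csv(out / "burden.tsv", sep="\t", index=False)
        pd.DataFrame(burden_tests).to_csv(out / "burden_tests.tsv", sep="\t", index=False)

    log["config"] = config.to_dict()
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
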