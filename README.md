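# foundercnv

Recurrent copy-number variant (rCNV) analysis for founder populations.

Founder populations — population isolates with small effective breeding
size — can carry large, gene-deleting or gene-duplicating CNVs at common
frequencies, all descended from a single ancestral mutation. Such recurrent
CNVs are identifiable by shared breakpoints, confirmable by a shared
flanking haplotype, datable from how far that haplotype extends, and — when
common enough — testable for association with disease phenotypes such as
Alcohol Use Disorder. `foundercnv` implements that entire chain as a tested
Python library for statistical geneticists working with SNP-array CNV
calls:

1. **Consensus calling** — retain a CNV only when two independent callers
   report it (reciprocal overlap ≥ 0.5, intersected interval), then filter
   to calls with ≥ 10 probes, ≥ 10 kb, autosomal.
2. **Recurrence detection** — cluster same-state calls on shared
   breakpoints (exact probe boundaries within one array; reciprocal overlap
   ≥ 0.8 across arrays/populations); carrier counts and frequencies.
3. **Haplotype sharing** — for each carrier haplotype, the maximal flank
   around the CNV still matching the consensus carrier haplotype, extending
   through isolated mismatches when the next 5 SNPs match (the
   mutation/genotyping-error "rescue" rule); lengths in Morgans on a local
   recombination map.
4. **Coalescence dating** — the Gamma method under independence: per-side
   shared lengths are Exp(τ) per Morgan, so

   τ̂ = 2 / l̄,  with exact CI from 2 τ Σlᵢ ~ χ²(4n).

5. **Association and burden** — carrier 2×2 tables with OR and Woolf CI
   `exp(ln OR ± z √(1/a+1/b+1/c+1/d))`, Pearson χ², Bonferroni/BH
   adjustment; per-individual CNV count and gene load with Mann-Whitney
   tests; power-by-simulation for carrier-frequency design thresholds.
6. **Synthetic data** — a seeded generator producing phased haplotypes with
   exponentially decaying sharing around a focal CNV, noisy dual-caller
   tables, and phenotypes at a target carrier odds ratio, so every stage is
   testable with known ground truth.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

Simulate 60 carriers of a 96-kb deletion that arose 750 generations ago,
measure their shared flanking haplotypes, and date the variant
(`examples/03_haplotype_dating.py`):

```python
from foundercnv import SimConfig, estimate_tau, measure_sharing
from foundercnv.simulate import carrier_sample_ids, simulate_carriers, simulate_region

cfg = SimConfig(seed=23, tau_generations=750.0, n_carriers=60,
                n_noncarriers=0, epsilon=0.001)
region_sim = simulate_region(cfg)
panel, truth = simulate_carriers(cfg, region_sim)
segments = measure_sharing(panel, cfg.region, region_sim.gmap,
                           [f"{s}_h1" for s in carrier_sample_ids(cfg)],
                           n_snps=60, rescue_k=5)
est = estimate_tau(segments, alpha=0.05)
print(f"tau = {est.tau_generations:.0f} [{est.ci_low:.0f} - {est.ci_high:.0f}]")
```

Output:

```
60 carrier haplotypes; 0 censored at the window edge; 57 point mutations/genotyping errors rescued
mean shared length l_ave = 0.267 cM
estimated age tau = 748 generations [95% CI 620 - 888]
(simulated truth: 750 generations)
```

The mean shared flank of 0.267 cM corresponds to τ̂ = 2/0.00267 ≈ 748
generations — the 95% interval comfortably covers the simulated truth, and
the rescue rule absorbed the simulated genotyping errors instead of letting
them truncate the shared segments.

The association worked example (`examples/04_association_burden.py`) —
27 carriers of a chromosome-22 duplication among 387 individuals, 22 of
them AUD cases — prints:

```
OR = 3.18 [1.18 - 8.58], chi2 = 5.73, one-sided p = 0.008
```

an odds ratio of 3.18 whose Woolf interval excludes 1.

Each script in `examples/` is a short narrative of one capability:
consensus + cohort summary, recurrence detection, dating, association +
burden, and the power/design computation. A thin CLI wraps the same
functions (subcommands `simulate`, `consensus`, `summarize`, `detect-rcnv`,
`share`, `date`, `assoc`, `burden`, `power`; see `foundercnv --help`), and
`foundercnv run --config config.yaml --out-dir out/` executes the full
pipeline with a run log.

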