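"""Carrier association and CNV burden.

Reconstructs the worked association example — 27 carriers of a chr22
duplication among 387 individuals, 22 of them AUD cases out of 231 total —
and runs a synthetic burden comparison between cases and controls.
"""

from foundercnv.formats import GeneInterval
from foundercnv.simulate import SimConfig, simulate_caller_tables, simulate_phenotypes, true_cnv_calls
from foundercnv.stats import (
    adjust_p,
    associate,
    burden_metrics,
    burden_test,
)

# --- association worked example -------------------------------------------
carriers = {f"S{i}": int(i < 27) for i in range(387)}
aud = {f"S{i}": int(i < 22 or 27 <= i < 236) for i in range(387)}
res = associate("chr22dup:AUD", carriers, aud)
t = res.table
print(f"table: carriers {t.a}/{t.a + t.b} cases, non-carriers {t.c}/{t.c + t.d}")
print(f"OR = {res.odds_ratio:.2f} [{res.ci_low:.2f} - {res.ci_high:.2f}], "
      f"chi2 = {res.chi2:.2f}, one-sided p = {res.p_one_sided:.3f}")
print(f"BH q for p = 0.006 as the best of 13 tests: "
      f"{min(adjust_p([0.006] + [0.13] * 12, 'bh')):.3f}")

# --- burden on a synthetic cohort ----------------------------------------
cfg = SimConfig(seed=31, n_carriers=60, n_noncarriers=327)
calls, _ = simulate_caller_tables(true_cnv_calls(cfg), cfg)
genes = [GeneInterval("chr6", 31_360_000, 31_380_000, "GENE_A"),
         GeneInterval("chr6", 31_400_000, 31_410_000, "GENE_B")]
status = {c.sample_id: 1 for c in calls}
status.update({f"CTL{i:04d}": 0 for i in range(cfg.n_noncarriers)})
phen = simulate_phenotypes(status, 0.60, cfg.carrier_odds_ratio, seed=32)

burdens = burden_metrics(calls, genes, samples=list(status))
gene_load = {s: b.gene_load for s, b in burdens.items()}
u, p = burden_test(gene_load, phen.aud_status())
print(f"gene-load burden Mann-Whitney: U = {u:.0f}, p = {p:.3f}")
# With a single simulated locus, gene load is just carrier status times two
# genes, so the burden test inherits part of the carrier association; in a
# genome-wide setting burden aggregates many loci and is typically null.
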