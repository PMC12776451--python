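"""Dual-caller consensus and cohort descriptives.

Builds two noisy caller outputs for a simulated cohort, intersects them,
applies the retention rules (>=10 probes, >=10 kb, autosomal), and prints
the cohort summary. The per-person rate and deletion fraction are the
numbers a cohort-description table reports.
"""

from foundercnv.consensus import cohort_summary, filter_calls, intersect_callers
from foundercnv.simulate import SimConfig, simulate_caller_tables, true_cnv_calls

cfg = SimConfig(seed=11, n_carriers=60, n_noncarriers=327,
                caller_dropout_prob=0.05, caller_jitter_bp=2_000)
calls_a, calls_b = simulate_caller_tables(true_cnv_calls(cfg), cfg)

consensus = intersect_callers(calls_a, calls_b, min_reciprocal_overlap=0.5)
retained = filter_calls(consensus)

print(f"caller A: {len(calls_a)} calls, caller B: {len(calls_b)} calls")
print(f"consensus (both callers, reciprocal overlap >= 0.5): {len(consensus)}")
print(f"retained after probe/size/autosome filters: {len(retained)}")

summary = cohort_summary(retained, n_individuals=cfg.n_carriers + cfg.n_noncarriers)
row = summary.report_row()
print(f"events per person: {row['events_per_person']}  "
      f"(deletions {row['pct_del']}%, duplications {row['pct_dup']}%)")
# Each consensus call survives only if both callers reported it, so the
# retained count tracks (1 - dropout)^2 of the true events.
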