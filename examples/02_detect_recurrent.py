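"""Recurrent-CNV detection by shared breakpoints.

Clusters same-state calls with identical probe boundaries into recurrent
groups, annotates carrier frequencies, and matches a group across two
populations genotyped on different arrays (slightly different boundaries,
so matching uses reciprocal overlap instead of exact breakpoints).
"""

from foundercnv.formats import CNVCall
from foundercnv.recurrent import cluster_recurrent, match_across_populations, select_testable

# population 1: 60 carriers of one deletion, 3 carriers of another
pop1 = [CNVCall(f"P{i}", "chr6", 31_355_318, 31_451_476, "DEL", 17) for i in range(60)]
pop1 += [CNVCall(f"P{i}", "chr13", 84_102_440, 84_157_927, "DEL", 11) for i in range(3)]
groups1 = cluster_recurrent(pop1, population="POP1", n_individuals=387)

# population 2 calls the same chr6 deletion with a slightly different end
pop2 = [CNVCall(f"W{i}", "chr6", 31_355_318, 31_453_640, "DEL", 25) for i in range(93)]
groups2 = cluster_recurrent(pop2, population="POP2", n_individuals=350)

for g in groups1:
    print(f"POP1 {g.chrom}:{g.start_bp}-{g.end_bp} {g.state}: "
          f"{g.carrier_count} carriers (freq {g.carrier_frequency:.3f}), "
          f"recurrent={g.recurrent}")

matches = match_across_populations(groups1, groups2, min_reciprocal_overlap=0.8)
for m in matches:
    print(f"matched across populations at {m.group_a.chrom}: "
          f"reciprocal overlap {m.reciprocal_overlap:.3f}")

testable = select_testable(groups1, min_carriers=25, min_frequency=0.022)
print(f"groups testable for association (>=25 carriers, freq > 2.2%): {len(testable)}")
# The chr6 deletion matches across populations (overlap ~0.98) and is the
# only group common and testable; the chr13 group is recurrent but too rare.
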