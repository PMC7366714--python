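"""Simulate a small dRNA-seq dataset and call TSSs by TEX enrichment.

Builds a 30 kb synthetic genome with planted TSSs, simulates TEX+/TEX-
5'-end count tracks, and runs the enrichment-based TSS caller per
condition before consolidating across conditions.
"""

from drnamap import (PipelineParams, call_tss_candidates, merge_conditions,
                     normalize_per_million)
from drnamap.synthetic import SyntheticParams, generate_genome, simulate_coverage

sp = SyntheticParams(genome_length=30_000, n_plain_genes=3, n_utr5_genes=2,
                     n_utr3_genes=2, n_operons=2, n_antisense_hosts=2,
                     n_silent_genes=1, n_secondary=1, n_internal=1,
                     n_orphan=2, n_srna_intergenic=2, n_hc_intergenic=1,
                     n_decoys=2, n_standalone_terminators=1, rng_seed=7)
genome, genes, truth = generate_genome(sp)
cov = simulate_coverage(genome, truth, sp)
params = PipelineParams()

norm = normalize_per_million(cov)
per_condition = {c: call_tss_candidates(norm, params, c)
                 for c in sp.conditions}
records = merge_conditions(per_condition.values(), params, cov.length)

planted = {(t.position, t.strand) for t in truth.tss}
called = {(r.position, r.strand) for r in records}
hits = sum(1 for p in planted
           if any((p[0] + d, p[1]) in called for d in (-1, 0, 1)))

print(f"planted TSSs: {len(planted)}")
for c, cands in per_condition.items():
    print(f"  calls in {c}: {len(cands)}")
print(f"consolidated TSSs: {len(records)}")
print(f"recovered within +/-1 nt: {hits}/{len(planted)}")
print("Each consolidated record keeps the conditions it was detected in and")
print("the maximum step height / step factor / TEX+:TEX- enrichment across")
print("them; a recovered fraction near 1 means the enrichment gates separate")
print("genuine initiation peaks from background and processing sites.")
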