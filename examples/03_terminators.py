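"""Scan a genome for Rho-independent terminators and confirm them with
coverage drops.

The scanner looks for perfect inverted-repeat stems (Watson-Crick + G:U)
of 4-20 bp around 3-10 nt loops, scores them 3/2/1 per G:C / A:U / G:U
pair minus the loop length, and demands a U-tract just downstream.
"""

from drnamap import (PipelineParams, confirm_by_coverage,
                     scan_intrinsic_terminators)
from drnamap.synthetic import (SyntheticParams, dinucleotide_shuffle,
                               generate_genome, simulate_coverage)
from drnamap.model import GenomeSequence
import numpy as np

sp = SyntheticParams(genome_length=50_000, n_plain_genes=4, n_utr5_genes=2,
                     n_utr3_genes=3, n_operons=3, n_antisense_hosts=2,
                     n_silent_genes=1, n_secondary=1, n_internal=1,
                     n_orphan=1, n_srna_intergenic=3, n_hc_intergenic=2,
                     n_decoys=2, n_standalone_terminators=4, rng_seed=5)
genome, genes, truth = generate_genome(sp)
cov = simulate_coverage(genome, truth, sp)
params = PipelineParams()

calls = scan_intrinsic_terminators(genome, params)
calls = confirm_by_coverage(calls, cov, params)
recalled = sum(
    1 for t in truth.terminators
    if any(c.strand == t.strand and abs(c.stem5_start - t.stem5_start) <= 5
           for c in calls))
supported = sum(c.coverage_supported for c in calls)

rng = np.random.default_rng(0)
shuffled = GenomeSequence("shuf", dinucleotide_shuffle(genome.sequence, rng))
null = scan_intrinsic_terminators(shuffled, params)

print(f"planted canonical terminators: {len(truth.terminators)}")
print(f"scanner calls: {len(calls)} (recall {recalled}/{len(truth.terminators)})")
print(f"coverage-supported: {supported} "
      "(downstream/upstream mean ratio <= 0.5 over 50 nt windows)")
print(f"calls on a dinucleotide-shuffled genome: {len(null)} "
      f"per {len(shuffled.sequence)/1000:.0f} kb")
print("High recall with near-zero calls on shuffled sequence shows the")
print("hairpin score floor separates real terminator stems from chance")
print("inverted repeats of the same base composition.")
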