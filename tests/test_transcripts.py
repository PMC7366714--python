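import numpy as np
import pytest

from drnamap import transcripts as X
from drnamap.model import (FORWARD, REVERSE, GeneFeature, GenomeSequence,
                           PipelineParams, TerminatorRecord, TssRecord)


def ptss(pos, gene_id, strand=FORWARD, height=10.0):
    return TssRecord("chr", pos, strand, ("c1",), height, 2.0, 4.0,
                     categories=("primary",),
                     gene_associations=(f"primary:{gene_id}",))


def orphan(pos, strand=FORWARD):
    return TssRecord("chr", pos, strand, ("c1",), 10.0, 2.0, 4.0,
                     categories=("orphan",))


def gene(gid, start, end, strand=FORWARD):
    return GeneFeature(gid, "chr", start, end, strand)


class TestUtrInference:
    def test_lengths_and_flags(self, params):
        genes = [gene("g32", 1000, 2000), gene("g5", 3000, 4000),
                 gene("g120", 5000, 6000)]
        recs = [ptss(968, "g32"), ptss(2995, "g5"), ptss(4880, "g120")]
        utrs = {u.gene_id: u for u in X.infer_5utrs(recs, genes, params)}
        assert utrs["g32"].utr_length == 32
        assert not utrs["g32"].leaderless and not utrs["g32"].long_utr
        assert utrs["g5"].utr_length == 5 and utrs["g5"].leaderless
        assert utrs["g120"].utr_length == 120 and utrs["g120"].long_utr

    @pytest.mark.parametrize("length,leaderless,long_", [
        (9, True, False), (10, False, False),
        (100, False, False), (101, False, True),
    ])
    def test_strict_threshold_boundaries(self, params, length, leaderless, long_):
        genes = [gene("g", 1000, 2000)]
        recs = [ptss(1000 - length, "g")]
        u, = X.infer_5utrs(recs, genes, params)
        assert u.utr_length == length
        assert u.leaderless is leaderless and u.long_utr is long_
        assert not (u.leaderless and u.long_utr)

    def test_minus_strand_distance(self, params):
        genes = [gene("g", 1000, 2000, REVERSE)]
        recs = [ptss(2031, "g", REVERSE)]
        u, = X.infer_5utrs(recs, genes, params)
        assert u.utr_length == 32

    def test_genes_without_primary_tss_are_skipped(self, params):
        genes = [gene("g", 1000, 2000)]
        assert X.infer_5utrs([orphan(500)], genes, params) == []


class TestTranscriptAssembly:
    def _env(self, n, lo, hi, level=50):
        arr = np.zeros(n, dtype=np.int64)
        arr[lo:hi] = level
        return {FORWARD: arr, REVERSE: np.zeros(n, dtype=np.int64)}

    def test_ends_at_supported_terminator(self, params):
        term = TerminatorRecord("chr", FORWARD, 480, 489, 493, 502, 9, 4,
                                21.0, 8, coverage_supported=True)
        env = self._env(1000, 0, 520)
        t, = X.assemble_transcripts([orphan(0)], [term], env, [], params)
        assert t.end_kind == "terminator"
        assert t.end == 502 + params.u_tail_window
        assert t.length == 510

    def test_falloff_without_terminator(self, params):
        env = self._env(1000, 100, 400)
        t, = X.assemble_transcripts([orphan(100)], [], env, [], params)
        assert t.end_kind == "falloff"
        assert abs(t.end - 400) <= params.transcript_window

    def test_zero_downstream_coverage_flags_low_expression(self, params):
        env = self._env(1000, 0, 0)
        t, = X.assemble_transcripts([orphan(100)], [], env, [], params)
        assert t.low_expression and t.length == 1

    def test_unsupported_terminator_is_ignored(self, params):
        term = TerminatorRecord("chr", FORWARD, 200, 209, 213, 222, 9, 4,
                                21.0, 8, coverage_supported=False)
        env = self._env(1000, 0, 400)
        t, = X.assemble_transcripts([orphan(0)], [term], env, [], params)
        assert t.end_kind == "falloff"

    def test_three_gene_operon_containment(self, params):
        genes = [gene("g1", 50, 150), gene("g2", 170, 280), gene("g3", 300, 420)]
        env = self._env(1000, 20, 460)
        t, = X.assemble_transcripts([ptss(20, "g1")], [], env, genes, params)
        assert t.gene_ids == ("g1", "g2", "g3")

    def test_minus_strand_extension(self, params):
        n = 1000
        env = {REVERSE: np.zeros(n, dtype=np.int64),
               FORWARD: np.zeros(n, dtype=np.int64)}
        env[REVERSE][300:601] = 40
        t, = X.assemble_transcripts([orphan(600, REVERSE)], [], env, [], params)
        assert t.strand == REVERSE
        assert t.end == 601
        assert abs(t.start - 300) <= params.transcript_window


class TestOperons:
    def test_covered_gene_run_becomes_operon(self, params):
        genes = [gene("g1", 50, 150), gene("g2", 170, 280), gene("g3", 300, 420)]
        env = {FORWARD: np.full(1000, 50, dtype=np.int64),
               REVERSE: np.zeros(1000, dtype=np.int64)}
        ts = X.assemble_transcripts([ptss(20, "g1")], [], env, genes, params)
        ops = X.assemble_operons(ts, genes)
        assert [o.gene_ids for o in ops] == [("g1", "g2", "g3")]

    def test_internal_supported_terminator_splits_operons(self, params):
        genes = [gene("g1", 50, 150), gene("g2", 300, 420)]
        term = TerminatorRecord("chr", FORWARD, 160, 169, 173, 182, 9, 4,
                                21.0, 8, coverage_supported=True)
        env = {FORWARD: np.full(1000, 50, dtype=np.int64),
               REVERSE: np.zeros(1000, dtype=np.int64)}
        ts = X.assemble_transcripts([ptss(20, "g1"), ptss(260, "g2")],
                                    [term], env, genes, params)
        ops = X.assemble_operons(ts, genes)
        assert sorted(o.gene_ids for o in ops) == [("g1",), ("g2",)]

    def test_no_transcripts_no_operons(self):
        assert X.assemble_operons([], []) == []


class TestSorfScanner:
    def test_single_orf_with_stop(self, params):
        rng = np.random.default_rng(0)
        codons = "".join(rng.choice(["GCA", "CTG", "AAA", "CCC"], size=30))
        seq = "CC" + "ATG" + codons + "TAA" + "CC"
        genome = GenomeSequence("chr", seq)
        hits = X.find_sorfs([(0, len(seq), FORWARD)], genome, params)
        assert len(hits) == 1
        assert hits[0].n_codons == 31
        assert hits[0].start_codon == "ATG"

    def test_no_start_codon(self, params):
        genome = GenomeSequence("chr", "CCCCCCCCCCCCCCCCCCCC")
        assert X.find_sorfs([(0, 20, FORWARD)], genome, params) == []

    def test_below_minimum_length_rejected(self, params):
        seq = "ATG" + "GCA" * 8 + "TAA"
        genome = GenomeSequence("chr", seq + "C" * 10)
        assert X.find_sorfs([(0, len(seq), FORWARD)], genome, params) == []

    def test_minus_strand_coordinates(self, params):
        fwd = "ATG" + "GCA" * 12 + "TAA"
        from drnamap.model import revcomp
        seq = "CCCCC" + revcomp(fwd) + "CCCCC"
        genome = GenomeSequence("chr", seq)
        hits = X.find_sorfs([(0, len(seq), REVERSE)], genome, params)
        assert len(hits) == 1
        h = hits[0]
        assert genome.subseq(h.start, h.end, REVERSE) == fwd
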