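import numpy as np
import pytest

from drnamap import srna as S
from drnamap.model import (FORWARD, REVERSE, GeneFeature, GenomeSequence,
                           PipelineParams, PsRecord, SrnaCandidate,
                           SrnaRejection, TerminatorRecord, TssRecord)
from oracles import srna_predicate_violations


def tss(pos, strand=FORWARD):
    return TssRecord("chr", pos, strand, ("c1",), 10.0, 2.0, 4.0)


def ps(pos, strand=FORWARD):
    return PsRecord("chr", pos, strand, ("c1",), 10.0)


def term(stem5, strand=FORWARD):
    return TerminatorRecord("chr", strand, stem5, stem5 + 9, stem5 + 13,
                            stem5 + 22, 9, 4, 21.0, 8)


def make_ctx(n=2000, seq=None, genes=(), tss_records=(), ps_records=(),
             terminators=(), operons=(), transcripts=(), covered=(),
             level=50, fold_backend="reference"):
    rng = np.random.default_rng(0)
    if seq is None:
        seq = "".join(rng.choice(list("ACGT"), size=n))
    genome = GenomeSequence("chr", seq)
    env = {FORWARD: np.zeros(len(seq), dtype=np.int64),
           REVERSE: np.zeros(len(seq), dtype=np.int64)}
    for lo, hi, strand in covered:
        env[strand][lo:hi] = level
    return S.SrnaContext(genome=genome, genes=list(genes),
                         tss_records=list(tss_records),
                         processing_sites=list(ps_records),
                         terminators=list(terminators),
                         operons=list(operons), transcripts=list(transcripts),
                         envelope=env, fold_backend=fold_backend)


class TestSegmentation:
    def test_single_block(self, params):
        ctx = make_ctx(covered=[(50, 250, FORWARD)])
        segs = S.segment_transcribed_regions(ctx.envelope, [], params, "chr")
        fwd = [s for s in segs if s.strand == FORWARD]
        assert [(s.start, s.end) for s in fwd] == [(50, 250)]
        assert fwd[0].relation == "none"

    def test_below_floor_gives_no_segment(self, params):
        ctx = make_ctx(covered=[(50, 250, FORWARD)], level=3)
        assert S.segment_transcribed_regions(ctx.envelope, [], params, "chr") == []

    def test_zero_gap_splits_segments(self, params):
        ctx = make_ctx(covered=[(50, 150, FORWARD), (160, 260, FORWARD)])
        segs = S.segment_transcribed_regions(ctx.envelope, [], params, "chr")
        assert [(s.start, s.end) for s in segs] == [(50, 150), (160, 260)]


class TestDecisionTree:
    def test_folding_filter_boundary_is_strict(self, params):
        """A length-100 candidate at exactly -0.050 kcal/mol/nt is rejected
        (strict less-than); one infinitesimally below passes."""
        interval = (100, 200, FORWARD)
        kwargs = dict(covered=[(100, 200, FORWARD)],
                      tss_records=[tss(100)])
        ctx = make_ctx(fold_backend=lambda s: -5.0, **kwargs)
        res = S.classify_srna(interval, ctx, params)
        assert isinstance(res, SrnaRejection) and res.reason == "folding"
        ctx = make_ctx(fold_backend=lambda s: -5.1, **kwargs)
        res = S.classify_srna(interval, ctx, params)
        assert isinstance(res, SrnaCandidate)
        assert res.srna_class == "intergenic"
        assert res.norm_energy == pytest.approx(-0.051)

    def test_intergenic_acceptance(self, params):
        res = S.classify_srna((100, 245, FORWARD),
                              make_ctx(covered=[(100, 245, FORWARD)],
                                       tss_records=[tss(100)],
                                       fold_backend=lambda s: -10.15),
                              params)
        assert isinstance(res, SrnaCandidate)
        assert res.srna_class == "intergenic" and res.has_tss

    def test_unstructured_decoy_rejected_for_folding(self, params):
        res = S.classify_srna((100, 200, FORWARD),
                              make_ctx(covered=[(100, 200, FORWARD)],
                                       tss_records=[tss(100)],
                                       fold_backend=lambda s: -2.0),
                              params)
        assert isinstance(res, SrnaRejection) and res.reason == "folding"

    def test_length_gates(self, params):
        ctx = make_ctx(covered=[(100, 800, FORWARD)], tss_records=[tss(100)])
        res = S.classify_srna((100, 700, FORWARD), ctx, params)
        assert isinstance(res, SrnaRejection) and res.reason == "length"
        res = S.classify_srna((100, 120, FORWARD), ctx, params)
        assert isinstance(res, SrnaRejection) and res.reason == "length"

    def test_coverage_gate(self, params):
        ctx = make_ctx(covered=[(100, 200, FORWARD)], level=3,
                       tss_records=[tss(100)])
        res = S.classify_srna((100, 200, FORWARD), ctx, params)
        assert isinstance(res, SrnaRejection) and res.reason == "coverage"

    def test_cis_antisense_needs_antisense_overlap(self, params):
        gene = GeneFeature("g", "chr", 100, 600, REVERSE)
        ctx = make_ctx(genes=[gene], covered=[(200, 350, FORWARD)],
                       tss_records=[tss(200)], fold_backend=lambda s: -12.0)
        res = S.classify_srna((200, 350, FORWARD), ctx, params)
        assert isinstance(res, SrnaCandidate)
        assert res.srna_class == "cis_antisense"

    def test_utr5_derived_shares_primary_tss(self, params):
        gene = GeneFeature("g", "chr", 400, 900, FORWARD)
        primary = TssRecord("chr", 200, FORWARD, ("c1",), 10.0, 2.0, 4.0,
                            categories=("primary",),
                            gene_associations=("primary:g",))
        ctx = make_ctx(genes=[gene], covered=[(200, 900, FORWARD)],
                       tss_records=[primary], ps_records=[ps(330)])
        res = S.classify_srna((200, 330, FORWARD), ctx, params)
        assert isinstance(res, SrnaCandidate)
        assert res.srna_class == "utr5_derived"
        assert res.has_processing_3p

    def test_sense_overlap_rejected(self, params):
        gene = GeneFeature("g", "chr", 100, 600, FORWARD)
        ctx = make_ctx(genes=[gene], covered=[(200, 350, FORWARD)],
                       tss_records=[tss(200)], fold_backend=lambda s: -12.0)
        res = S.classify_srna((200, 350, FORWARD), ctx, params)
        assert isinstance(res, SrnaRejection) and res.reason == "overlaps_gene"


class TestHighConfidence:
    def _cand(self, cls, end=300, strand=FORWARD, cov=20.0):
        return SrnaCandidate("chr", 150, end, strand, cls, has_tss=True,
                             avg_coverage=cov, fold_energy=-20.0,
                             norm_energy=-0.13)

    def test_terminator_within_reach(self, params):
        # candidate 3' end 5 nt before the terminator tail edge
        t = term(283)  # three_prime_end = 305
        out = S.flag_high_confidence([self._cand("intergenic", end=300)],
                                     [t], params)
        assert out[0].high_confidence

    def test_no_terminator_within_reach(self, params):
        out = S.flag_high_confidence([self._cand("intergenic", end=300)],
                                     [term(600)], params)
        assert not out[0].high_confidence

    def test_class_gate_keeps_cis_antisense_unflagged(self, params):
        out = S.flag_high_confidence([self._cand("cis_antisense", end=300)],
                                     [term(283)], params)
        assert not out[0].high_confidence

    def test_subset_relation_on_full_run(self, default_run, params):
        result, _truth, _ = default_run
        hc = [s for s in result.srnas if s.high_confidence]
        assert hc  # the planted design includes high-confidence sRNAs
        assert all(s.srna_class == "intergenic" for s in hc)


class TestFullRunClassRecovery:
    def test_planted_classes_recovered(self, default_run):
        result, truth, _ = default_run
        real = truth.real_srnas
        correct = 0
        for p in real:
            for c in result.srnas:
                ov = min(c.end, p.end) - max(c.start, p.start)
                if (c.strand == p.strand and ov >= 0.5 * (p.end - p.start)
                        and c.srna_class == p.srna_class):
                    correct += 1
                    break
        assert correct / len(real) >= 0.9

    def test_no_accepted_candidate_violates_its_gates(self, default_run,
                                                      default_dataset, params):
        result, truth, _ = default_run
        sp, genome, genes, cov, _ = default_dataset
        ctx = S.SrnaContext(genome=genome, genes=genes,
                            tss_records=result.tss_records,
                            processing_sites=result.processing_sites,
                            terminators=result.terminators,
                            operons=result.operons,
                            transcripts=result.transcripts,
                            envelope=result.envelope)
        assert srna_predicate_violations(result.srnas, ctx, params) == []


class TestGcContent:
    def test_extremes_and_median(self):
        genome = GenomeSequence("chr", "GCGCATATGCAT")
        stats = S.gc_content_by_class({"a": [(0, 4)], "b": [(4, 8)]}, genome)
        assert stats["classes"]["a"]["mean"] == 1.0
        assert stats["classes"]["b"]["mean"] == 0.0
        three = S.gc_content_by_class(
            {"c": [(0, 4), (2, 6), (6, 10)]},
            GenomeSequence("chr", "GCGCATATGCAT"))
        med = three["classes"]["c"]["median"]
        assert 0.0 <= med <= 1.0

    def test_median_of_three(self):
        # GC fractions 0.30 / 0.35 / 0.40 -> median 0.35
        seq = ("GCG" + "A" * 7            # 0.30 over 10
               + "GCGCGCG" + "A" * 13     # 0.35 over 20
               + "GCGC" + "A" * 6)        # 0.40 over 10
        genome = GenomeSequence("chr", seq)
        stats = S.gc_content_by_class({"x": [(0, 10), (10, 30), (30, 40)]},
                                      genome)
        assert stats["classes"]["x"]["median"] == pytest.approx(0.35)

    def test_empty_class_absent(self):
        stats = S.gc_content_by_class({}, GenomeSequence("chr", "ACGT"))
        assert stats["classes"] == {}
        assert stats["genome_average"] == pytest.approx(0.5)


class TestDuplexScanner:
    def test_perfect_hexamer_seed(self, params):
        hits = S.predict_duplex("AGAUUA", "UAAUCU", params)
        assert hits
        best = hits[0]
        assert best.seed_len == 6
        assert best.score == pytest.approx(7.0)  # 1 G:C + 5 A:U

    def test_hexamer_substitution_destroys_seed(self, params):
        """The seed-disrupting target mutation strictly lowers the score and
        leaves no 6 bp contiguous seed."""
        wt = S.predict_duplex("AGAUUA", "UAAUCU", params)
        mut = S.predict_duplex("AGAUUA", "AUUAGA", params)
        wt_best = wt[0].score
        mut_best = max((h.score for h in mut), default=0.0)
        assert mut_best < wt_best
        assert all(h.seed_len < 6 for h in mut)

    def test_poly_a_cannot_pair(self, params):
        assert S.predict_duplex("AAAAAA", "AAAAAA", params) == []

    def test_symmetry_under_swap_and_revcomp(self, params):
        """Swapping the two RNAs and reverse-complementing both maps every
        Watson-Crick duplex onto itself; exact over wobble-free alphabets
        (a G:U pair would map to the unpairable A:C)."""
        from drnamap.model import revcomp

        rng = np.random.default_rng(9)
        p = PipelineParams(duplex_score_min=3.0)
        for _ in range(10):
            q = "".join(rng.choice(list("AU"), size=12))
            t = "".join(rng.choice(list("AU"), size=18))
            a = S.predict_duplex(q, t, p)
            q2 = revcomp(t.replace("U", "T")).replace("T", "U")
            t2 = revcomp(q.replace("U", "T")).replace("T", "U")
            b = S.predict_duplex(q2, t2, p)
            assert sorted((h.score, h.seed_len) for h in a) == \
                sorted((h.score, h.seed_len) for h in b)
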