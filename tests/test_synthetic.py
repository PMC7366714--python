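import numpy as np
import pytest

from drnamap.model import FORWARD, REVERSE, TEX_MINUS, TEX_PLUS
from drnamap import synthetic as syn
from conftest import small_synthetic_params


class TestGenerateGenome:
    def test_deterministic_under_fixed_seed(self):
        sp = small_synthetic_params(seed=5)
        g1, genes1, t1 = syn.generate_genome(sp)
        g2, genes2, t2 = syn.generate_genome(small_synthetic_params(seed=5))
        assert g1.sequence == g2.sequence
        assert genes1 == genes2
        assert t1.tss == t2.tss and t1.srnas == t2.srnas

    def test_truth_bookkeeping_counts(self, default_dataset):
        sp, genome, genes, cov, truth = default_dataset
        assert len(genes) == sp.n_genes == 60
        assert len(truth.tss) == 80
        by_class = {}
        for s in truth.srnas:
            by_class[s.srna_class] = by_class.get(s.srna_class, 0) + 1
        assert by_class == {"intergenic": 10, "cis_antisense": 10,
                            "utr5_derived": 10, "utr3_derived": 10,
                            "intra_operonic": 10, "decoy": 10}
        assert len(truth.terminators) == 50

    def test_genes_non_overlapping_same_strand(self, default_dataset):
        _, _, genes, _, _ = default_dataset
        by_strand = {}
        for g in genes:
            by_strand.setdefault(g.strand, []).append(g)
        for members in by_strand.values():
            members.sort(key=lambda g: g.start)
            for a, b in zip(members, members[1:]):
                assert a.end <= b.start

    def test_high_confidence_srnas_have_tss_and_terminator(self, default_dataset):
        _, _, _, _, truth = default_dataset
        tss_pos = {(t.position, t.strand) for t in truth.tss}
        hc = [s for s in truth.srnas if s.high_confidence]
        assert hc
        for s in hc:
            assert s.srna_class == "intergenic"
            p5 = s.start if s.strand == FORWARD else s.end - 1
            assert (p5, s.strand) in tss_pos
            edge = s.end if s.strand == FORWARD else s.start
            assert any(t.strand == s.strand
                       and abs((t.stem3_end if s.strand == FORWARD
                                else t.stem5_start) - edge) <= 20
                       for t in truth.terminators)

    def test_planted_category_geometry(self, default_dataset):
        sp, _, genes, _, truth = default_dataset
        for t in truth.tss:
            if t.category == "primary":
                ok = any(g.strand == t.strand and
                         0 <= (g.start - t.position if g.strand == FORWARD
                               else t.position - (g.end - 1)) < 300
                         for g in genes)
                assert ok
            elif t.category == "antisense":
                assert any(g.strand != t.strand
                           and g.start - 100 <= t.position < g.end + 100
                           for g in genes)
            elif t.category == "internal":
                assert any(g.strand == t.strand
                           and g.start <= t.position < g.end for g in genes)

    def test_srna_lengths_within_bounds(self, default_dataset):
        _, _, _, _, truth = default_dataset
        for s in truth.real_srnas:
            assert 30 <= s.end - s.start <= 500

    def test_unplaceable_configuration_raises(self):
        sp = small_synthetic_params()
        sp.genome_length = 10_000
        sp.n_operons = 20
        with pytest.raises(ValueError, match="cannot place"):
            syn.generate_genome(sp)

    def test_invalid_params_rejected(self):
        sp = small_synthetic_params()
        sp.tex_enrichment = 1.5  # below the enrichment gate: unsolvable
        with pytest.raises(ValueError):
            sp.validate()


class TestSimulateCoverage:
    def test_tex_enrichment_ratio_at_planted_tss(self, default_dataset):
        """Mean TEX+/TEX- 5'-count ratio at planted TSSs near the planted
        enrichment (5x) when averaged over all sites and replicates."""
        sp, genome, genes, cov, truth = default_dataset
        ratios = []
        for t in truth.tss:
            cond = t.conditions[0]
            tp = cov.fiveprime_mean(cond, TEX_PLUS, t.strand)[t.position]
            tm = cov.fiveprime_mean(cond, TEX_MINUS, t.strand)[t.position]
            if tm > 0:
                ratios.append(tp / tm)
        assert 4.0 <= np.mean(ratios) <= 6.0

    def test_processing_sites_not_tex_enriched(self, default_dataset):
        sp, genome, genes, cov, truth = default_dataset
        ratios = []
        for p in truth.processing_sites:
            cond = p.conditions[0]
            tp = cov.fiveprime_mean(cond, TEX_PLUS, p.strand)[p.position]
            tm = cov.fiveprime_mean(cond, TEX_MINUS, p.strand)[p.position]
            if tm > 0:
                ratios.append(tp / tm)
        assert np.mean(ratios) < 2.0  # below the enrichment gate

    def test_no_features_no_background_gives_all_zero(self):
        sp = small_synthetic_params()
        for name in ("n_plain_genes", "n_utr5_genes", "n_utr3_genes",
                     "n_operons", "n_antisense_hosts", "n_silent_genes",
                     "n_secondary", "n_internal", "n_orphan",
                     "n_srna_intergenic", "n_hc_intergenic", "n_decoys",
                     "n_standalone_terminators"):
            setattr(sp, name, 0)
        sp.background_5p_rate = 0.0
        sp.background_cov_rate = 0.0
        genome, genes, truth = syn.generate_genome(sp)
        cov = syn.simulate_coverage(genome, truth, sp)
        for arr in list(cov.fiveprime.values()) + list(cov.total.values()):
            assert not np.asarray(arr).any()

    def test_deterministic_given_seed(self):
        sp = small_synthetic_params(seed=7)
        g, genes, truth = syn.generate_genome(sp)
        c1 = syn.simulate_coverage(g, truth, sp)
        c2 = syn.simulate_coverage(g, truth, sp)
        for key in c1.fiveprime:
            np.testing.assert_array_equal(c1.fiveprime[key], c2.fiveprime[key])


class TestMirrorAndShuffle:
    def test_mirror_is_an_involution(self, small_dataset):
        sp, genome, genes, cov, truth = small_dataset
        g2, genes2, cov2, t2 = syn.mirror_dataset(genome, genes, cov, truth)
        g3, genes3, cov3, t3 = syn.mirror_dataset(g2, genes2, cov2, t2)
        assert g3.sequence == genome.sequence
        assert sorted(genes3, key=lambda g: g.gene_id) == \
            sorted(genes, key=lambda g: g.gene_id)
        assert t3.tss == truth.tss
        for key in cov.fiveprime:
            np.testing.assert_array_equal(cov3.fiveprime[key],
                                          cov.fiveprime[key])

    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=5000))

        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out

        shuf = syn.dinucleotide_shuffle(seq, rng)
        assert shuf != seq
        assert dinucs(shuf) == dinucs(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
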