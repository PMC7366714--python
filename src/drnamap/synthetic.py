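"""Synthetic dRNA-seq datasets with planted ground truth.

The generator emulates the statistical structure a TEX+/TEX- primary-
transcript-enrichment experiment produces over a bacterial genome:

* 5'-end count peaks at planted TSSs, negative-binomially distributed with
  TEX+/TEX- mean ratio ``tex_enrichment``;
* processing sites with 5'-end peaks in both libraries and the TEX+ side
  *depleted* (the exonuclease degrades 5'-monophosphate ends), i.e. no
  TEX enrichment;
* piecewise-constant total coverage over planted transcripts on top of
  sparse background, with negative-binomial per-position noise;
* planted two-box promoters, canonical hairpin+U8 intrinsic terminators,
  sRNAs of all five classes (with folded bodies that pass the energy
  filter) and unstructured A/C-alphabet decoy transcripts that cannot
  base-pair and therefore must fail it;
* three conditions emulating growth phases, each with replicate libraries,
  and per-feature expression masks so condition merging is exercised.

Default parameter values are the study conditions of the package's
validation design: 100 kb genome, 60 genes, 80 planted TSSs, 50 canonical
terminators, 10 sRNAs per class plus 10 decoys, 5x TEX enrichment, mean
peak 50 per million (500 raw reads at library size 1e7), dispersion 0.2,
three conditions with three replicates each.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import io as dio
from .model import (FORWARD, REVERSE, STRANDS, TEX_MINUS, TEX_PLUS,
                    CoverageSet, GeneFeature, GenomeSequence, revcomp)

CONDITIONS = ("early_exp", "mid_exp", "stationary")


# ---------------------------------------------------------------------------
# Parameters and truth registry


@dataclass
class SyntheticParams:
    genome_length: int = 100_000
    gc_content: float = 0.43

    # gene roles (total genes = plain + utr5 + utr3 + 2*operons + hosts + silent)
    n_plain_genes: int = 5
    n_utr5_genes: int = 10
    n_utr3_genes: int = 10
    n_operons: int = 10
    n_antisense_hosts: int = 10
    n_silent_genes: int = 5
    gene_len: Tuple[int, int] = (450, 750)

    # additional planted sites
    n_secondary: int = 5
    n_internal: int = 5
    n_orphan: int = 5
    n_srna_intergenic: int = 10
    n_hc_intergenic: int = 6
    n_decoys: int = 10
    n_standalone_terminators: int = 9

    # coverage model
    tex_enrichment: float = 5.0
    mean_5prime_peak: float = 500.0     # raw reads; 50 per million at 1e7
    ps_tex_ratio: float = 0.5           # TEX+ depletion at processing sites
    background_5p_rate: float = 0.02    # raw reads / nt
    background_cov_rate: float = 0.5
    nb_dispersion: float = 0.2
    srna_level: Tuple[float, float] = (50.0, 150.0)
    gene_level: Tuple[float, float] = (20.0, 60.0)
    utr5_boost: float = 3.0             # leader coverage factor for utr5 genes

    n_conditions: int = 3
    n_replicates: int = 3
    library_size: int = 10_000_000
    p_all_conditions: float = 0.45

    promoter_fraction_primary: float = 0.81
    promoter_fraction_secondary: float = 0.6
    promoter_fraction_orphan: float = 0.6
    initiator_probs: Tuple[float, float, float, float] = (0.45, 0.07, 0.41, 0.07)
    # order A, C, G, T

    rng_seed: int = 1

    def validate(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb for default counts")
        if self.tex_enrichment <= 2.0:
            raise ValueError("tex_enrichment must exceed the enrichment gate")
        if self.n_hc_intergenic > self.n_srna_intergenic:
            raise ValueError("n_hc_intergenic cannot exceed n_srna_intergenic")
        if not (1 <= self.n_conditions <= len(CONDITIONS)):
            raise ValueError(f"n_conditions must be in 1..{len(CONDITIONS)}")

    @property
    def n_genes(self) -> int:
        return (self.n_plain_genes + self.n_utr5_genes + self.n_utr3_genes
                + 2 * self.n_operons + self.n_antisense_hosts
                + self.n_silent_genes)

    @property
    def conditions(self) -> tuple:
        return CONDITIONS[: self.n_conditions]


@dataclass
class PlantedTss:
    position: int
    strand: str
    category: str
    conditions: tuple
    strength: float
    initiator: str
    has_promoter: bool


@dataclass
class PlantedPs:
    position: int
    strand: str
    conditions: tuple
    strength: float


@dataclass
class PlantedTerminator:
    strand: str
    stem5_start: int
    loop_start: int
    loop_end: int
    stem3_end: int


@dataclass
class PlantedSrna:
    start: int
    end: int
    strand: str
    srna_class: str          # one of the five classes, or "decoy"
    high_confidence: bool


@dataclass
class PlantedTranscript:
    start: int
    end: int
    strand: str
    level: float
    conditions: tuple
    seg_starts: tuple = ()
    seg_ends: tuple = ()
    seg_factors: tuple = ()


@dataclass
class PlantedUtr:
    gene_id: str
    utr_length: int


@dataclass
class PlantedPromoter:
    tss_position: int
    strand: str
    motif_name: str


@dataclass
class SyntheticTruth:
    genome_length: int
    conditions: tuple
    tss: List[PlantedTss] = field(default_factory=list)
    processing_sites: List[PlantedPs] = field(default_factory=list)
    terminators: List[PlantedTerminator] = field(default_factory=list)
    srnas: List[PlantedSrna] = field(default_factory=list)
    transcripts: List[PlantedTranscript] = field(default_factory=list)
    utrs: List[PlantedUtr] = field(default_factory=list)
    promoters: List[PlantedPromoter] = field(default_factory=list)

    @property
    def real_srnas(self) -> list:
        return [s for s in self.srnas if s.srna_class != "decoy"]

    @property
    def decoys(self) -> list:
        return [s for s in self.srnas if s.srna_class == "decoy"]


# ---------------------------------------------------------------------------
# Sequence helpers

_BASES = np.array(list("ACGT"))


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _ac_seq(rng, n: int) -> str:
    """A/C alphabet: no Watson-Crick or wobble pairs possible at all."""
    return "".join(np.array(list("AC"))[rng.choice(2, size=n, p=[0.6, 0.4])])


def _a_rich(rng, n: int) -> str:
    return "".join(np.array(list("AC"))[rng.choice(2, size=n, p=[0.8, 0.2])])


def _structured_body(rng, length: int) -> str:
    """A folded sRNA body: hairpins (8 bp stems, 5 G:C + 3 A:U pairs)
    joined by T-free linkers, so the energy filter passes and no spurious
    U-tract follows a stem."""
    hairpin_len = 8 + 4 + 8
    parts = ["".join(_a_rich(rng, 5))]
    used = 5
    while used + hairpin_len + 4 <= length:
        # 5 G/C bases and 3 A/T bases, shuffled
        bases = list("GCGCG") + list(rng.choice(list("AT"), size=3))
        order = rng.permutation(8)
        stem5 = "".join(np.array(bases)[order])
        loop = "ACAA"
        parts.append(stem5 + loop + revcomp(stem5))
        parts.append(_a_rich(rng, 4))
        used += hairpin_len + 4
    parts.append(_a_rich(rng, max(length - used, 0)))
    return "".join(parts)[:length]


def _terminator_seq(rng) -> Tuple[str, int, int, int, int]:
    """Canonical hairpin + U8 tail; returns (seq, stem5, loop_s, loop_e, stem3)
    offsets relative to the returned string (0-based half-open)."""
    bases = list("GCGCGCG") + list(rng.choice(list("AT"), size=2))
    stem5 = "".join(np.array(bases)[rng.permutation(9)])
    loop = "ACAA"
    seq = stem5 + loop + revcomp(stem5) + "T" * 8
    return seq, 0, 9, 13, 22


# ---------------------------------------------------------------------------
# Block construction


class _Block:
    """A contiguous oriented stretch of sequence plus its planted features,
    later written into the genome forward or reverse-complemented."""

    def __init__(self, kind: str):
        self.kind = kind
        self.seq: List[str] = []
        self.tss: List[tuple] = []          # (off, category, promoter_frac_key)
        self.ps: List[int] = []
        self.terms: List[tuple] = []        # (stem5, loop_s, loop_e, stem3) offsets
        self.genes: List[tuple] = []        # (start, end)
        self.srnas: List[tuple] = []        # (start, end, class, hc)
        self.transcripts: List[tuple] = []  # (start, end, role, [(s,e,factor)])
        self.utr: List[tuple] = []          # (gene_index_in_block, utr_len)

    def append(self, s: str) -> int:
        off = len(self.seq)
        self.seq.extend(s)
        return off

    def overwrite(self, off: int, s: str) -> None:
        if off < 0 or off + len(s) > len(self.seq):
            raise IndexError("overwrite outside block sequence")
        self.seq[off: off + len(s)] = list(s)

    def __len__(self) -> int:
        return len(self.seq)


def _plant_tss(block: _Block, rng, sp: SyntheticParams, off: int,
               category: str, promoter_key: str) -> None:
    initiator = "ACGT"[rng.choice(4, p=list(sp.initiator_probs))]
    block.overwrite(off, initiator)
    block.tss.append((off, category, promoter_key))


def _maybe_promoter(block: _Block, rng, sp: SyntheticParams, off: int,
                    fraction: float) -> bool:
    if rng.random() >= fraction or off < 35:
        return False
    nn = _random_seq(rng, 2, 0.5)
    box1 = "TA" + nn + "TTTG"                      # centers at -7
    spacer = "".join(np.array(list("ATC"))[
        rng.choice(3, size=20, p=[0.45, 0.45, 0.10])])
    block.overwrite(off - 34, "TTTG")              # box2, centers at -33
    block.overwrite(off - 30, spacer)
    block.overwrite(off - 10, box1)
    return True


def _gene_block(rng, sp: SyntheticParams, role: str) -> _Block:
    """plain / utr5 / utr3 / host / silent single-gene blocks."""
    b = _Block(role)
    gc = sp.gc_content
    b.append(_random_seq(rng, 80, gc))             # promoter + secondary margin
    tss_off = len(b)

    if role == "silent":
        g0 = b.append("ATG" + _random_seq(rng, int(rng.integers(*sp.gene_len)) - 3, gc))
        b.genes.append((g0, len(b)))
        return b

    if role == "host":
        g0 = b.append("ATG" + _random_seq(rng, int(rng.integers(*sp.gene_len)) - 3, gc))
        g1 = len(b)
        b.genes.append((g0, g1))
        # cis-antisense sRNA inside the gene body, on the opposite strand:
        # realized later because it needs the antisense orientation
        return b

    if role == "utr5":
        utr_len = int(rng.integers(150, 251))
        srna_len = int(rng.integers(60, min(utr_len - 30, 150) + 1))
    elif role == "plain":
        utr_len = -1  # set by caller via b._forced_utr
        srna_len = 0
    else:  # utr3
        utr_len = int(rng.integers(20, 61))
        srna_len = 0
    b._forced_utr = None  # type: ignore[attr-defined]
    b._role_meta = (utr_len, srna_len)  # type: ignore[attr-defined]
    return b


def _finish_gene_block(b: _Block, rng, sp: SyntheticParams, role: str,
                       utr_len: int, srna_len: int) -> None:
    gc = sp.gc_content
    tss_off = len(b)
    b.append(_random_seq(rng, utr_len, gc))
    _plant_tss(b, rng, sp, tss_off, "primary", "primary")
    if role == "utr5":
        ps_off = tss_off + srna_len
        b.ps.append(ps_off)
        b.srnas.append((tss_off, ps_off, "utr5_derived", False))
    g0 = b.append("ATG")
    glen = int(rng.integers(*sp.gene_len))
    b.append(_random_seq(rng, glen - 3, gc))
    g1 = len(b)
    b.genes.append((g0, g1))
    b.utr.append((0, utr_len))
    if role == "utr3":
        ps_off = g1 - 30
        b.ps.append(ps_off)
        ext = int(rng.integers(40, 121))
        b.append(_random_seq(rng, ext, gc))
    else:
        b.append(_random_seq(rng, 30, gc))
    tseq, s5, ls, le, s3 = _terminator_seq(rng)
    t0 = b.append(tseq)
    b.terms.append((t0 + s5, t0 + ls, t0 + le, t0 + s3))
    t_end = t0 + s3 + 8
    if role == "utr3":
        b.srnas.append((g1 - 30, t_end, "utr3_derived", False))
    if role == "utr5":
        segs = [(tss_off, tss_off + srna_len, sp.utr5_boost),
                (tss_off + srna_len, t_end, 1.0)]
    else:
        segs = [(tss_off, t_end, 1.0)]
    b.transcripts.append((tss_off, t_end, "gene", segs))


def _operon_block(rng, sp: SyntheticParams) -> _Block:
    b = _Block("operon")
    gc = sp.gc_content
    b.append(_random_seq(rng, 80, gc))
    tss_off = len(b)
    utr_len = int(rng.integers(20, 61))
    b.append(_random_seq(rng, utr_len, gc))
    _plant_tss(b, rng, sp, tss_off, "primary", "primary")
    g0 = b.append("ATG" + _random_seq(rng, int(rng.integers(*sp.gene_len)) - 3, gc))
    g1 = len(b)
    b.genes.append((g0, g1))
    # intra-operonic sRNA between the two genes, bounded by processing sites
    srna_len = int(rng.integers(60, 141))
    gap = srna_len + 20
    gap0 = b.append(_random_seq(rng, gap, gc))
    p5 = gap0 + 10
    p3 = p5 + srna_len
    b.ps.extend([p5, p3])
    b.srnas.append((p5, p3, "intra_operonic", False))
    g2 = b.append("ATG" + _random_seq(rng, int(rng.integers(*sp.gene_len)) - 3, gc))
    g3 = len(b)
    b.genes.append((g2, g3))
    b.append(_random_seq(rng, 30, gc))
    tseq, s5, ls, le, s3 = _terminator_seq(rng)
    t0 = b.append(tseq)
    b.terms.append((t0 + s5, t0 + ls, t0 + le, t0 + s3))
    t_end = t0 + s3 + 8
    b.transcripts.append((tss_off, t_end, "gene", [(tss_off, t_end, 1.0)]))
    b.utr.append((0, utr_len))
    return b


def _intergenic_srna_block(rng, sp: SyntheticParams, hc: bool) -> _Block:
    b = _Block("srna_intergenic")
    b.append(_random_seq(rng, 80, sp.gc_content))
    tss_off = len(b)
    body_len = int(rng.integers(80, 201))
    b.append(_structured_body(rng, body_len))
    _plant_tss(b, rng, sp, tss_off, "orphan", "orphan")
    if hc:
        tseq, s5, ls, le, s3 = _terminator_seq(rng)
        t0 = b.append(tseq)
        b.terms.append((t0 + s5, t0 + ls, t0 + le, t0 + s3))
        end = t0 + s3 + 8
    else:
        end = len(b)
    b.srnas.append((tss_off, end, "intergenic", hc))
    b.transcripts.append((tss_off, end, "srna", [(tss_off, end, 1.0)]))
    return b


def _decoy_block(rng, sp: SyntheticParams) -> _Block:
    b = _Block("decoy")
    b.append(_random_seq(rng, 80, sp.gc_content))
    tss_off = len(b)
    b.append(_ac_seq(rng, int(rng.integers(80, 121))))
    # A/C initiator keeps the decoy unpairable end to end
    b.tss.append((tss_off, "orphan", "orphan"))
    b.overwrite(tss_off, "AC"[int(rng.integers(2))])
    end = len(b)
    b.srnas.append((tss_off, end, "decoy", False))
    b.transcripts.append((tss_off, end, "srna", [(tss_off, end, 1.0)]))
    return b


def _orphan_block(rng, sp: SyntheticParams) -> _Block:
    b = _Block("orphan")
    b.append(_random_seq(rng, 80, sp.gc_content))
    tss_off = len(b)
    b.append(_random_seq(rng, int(rng.integers(100, 201)), sp.gc_content))
    _plant_tss(b, rng, sp, tss_off, "orphan", "orphan")
    end = len(b)
    b.transcripts.append((tss_off, end, "orphan", [(tss_off, end, 1.0)]))
    return b


def _standalone_term_block(rng, sp: SyntheticParams) -> _Block:
    b = _Block("terminator")
    b.append(_random_seq(rng, 20, sp.gc_content))
    tseq, s5, ls, le, s3 = _terminator_seq(rng)
    t0 = b.append(tseq)
    b.terms.append((t0 + s5, t0 + ls, t0 + le, t0 + s3))
    b.append(_random_seq(rng, 20, sp.gc_content))
    return b


# ---------------------------------------------------------------------------
# Assembly


def _condition_mask(rng, sp: SyntheticParams) -> tuple:
    conds = sp.conditions
    if len(conds) == 1 or rng.random() < sp.p_all_conditions:
        return tuple(conds)
    while True:
        mask = tuple(c for c in conds if rng.random() < 0.5)
        if mask and len(mask) < len(conds):
            return mask


def generate_genome(sp: SyntheticParams):
    """Build the genome, annotation, and planted-truth registry.

    Deterministic given ``sp.rng_seed``.  Returns
    ``(GenomeSequence, [GeneFeature], SyntheticTruth)``."""
    sp.validate()
    rng = np.random.default_rng(sp.rng_seed)

    blocks: List[_Block] = []
    for _ in range(sp.n_plain_genes):
        blocks.append(("plain", None))
    for _ in range(sp.n_utr5_genes):
        blocks.append(("utr5", None))
    for _ in range(sp.n_utr3_genes):
        blocks.append(("utr3", None))
    for _ in range(sp.n_operons):
        blocks.append(("operon", None))
    for _ in range(sp.n_antisense_hosts):
        blocks.append(("host", None))
    for _ in range(sp.n_silent_genes):
        blocks.append(("silent", None))
    for i in range(sp.n_srna_intergenic):
        blocks.append(("srna_intergenic", i < sp.n_hc_intergenic))
    for _ in range(sp.n_decoys):
        blocks.append(("decoy", None))
    for _ in range(sp.n_orphan):
        blocks.append(("orphan", None))
    for _ in range(sp.n_standalone_terminators):
        blocks.append(("terminator", None))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # UTR lengths for the plain genes include the leaderless/long boundary
    # values 9/10/100/101 so threshold behavior is exercised exactly.
    plain_utrs = [9, 10, 100, 101] + [32] * max(sp.n_plain_genes - 4, 0)
    plain_utrs = plain_utrs[: sp.n_plain_genes]
    plain_i = 0
    secondary_left = sp.n_secondary
    internal_left = sp.n_internal

    built: List[_Block] = []
    for kind, extra in blocks:
        if kind in ("plain", "utr5", "utr3", "host", "silent"):
            b = _gene_block(rng, sp, kind)
            if kind in ("plain", "utr5", "utr3"):
                utr_len, srna_len = b._role_meta  # type: ignore[attr-defined]
                if kind == "plain":
                    utr_len = plain_utrs[plain_i]
                    plain_i += 1
                _finish_gene_block(b, rng, sp, kind, utr_len, srna_len)
                if kind == "utr3" and secondary_left > 0:
                    # a weaker TSS in the same upstream window
                    # far enough upstream that the two promoter regions
                    # cannot overlap and corrupt each other
                    tss_off = b.tss[0][0]
                    delta = int(rng.integers(40, 46))
                    _plant_tss(b, rng, sp, tss_off - delta,
                               "secondary", "secondary")
                    secondary_left -= 1
                elif kind == "utr3" and internal_left > 0:
                    g0, g1 = b.genes[0]
                    _plant_tss(b, rng, sp, (g0 + g1) // 2, "internal", "orphan")
                    internal_left -= 1
        elif kind == "operon":
            b = _operon_block(rng, sp)
        elif kind == "srna_intergenic":
            b = _intergenic_srna_block(rng, sp, bool(extra))
        elif kind == "decoy":
            b = _decoy_block(rng, sp)
        elif kind == "orphan":
            b = _orphan_block(rng, sp)
        else:
            b = _standalone_term_block(rng, sp)
        built.append(b)

    # host blocks get their cis-antisense sRNA after placement (they live on
    # the strand opposite the block's)

    # ---- placement -------------------------------------------------------
    genome_arr = list(_random_seq(rng, sp.genome_length, sp.gc_content))
    truth = SyntheticTruth(genome_length=sp.genome_length,
                           conditions=sp.conditions)
    genes: List[GeneFeature] = []
    gene_n = 0
    pos = 500
    gene_kinds = {"plain", "utr5", "utr3", "operon", "host", "silent"}

    placements = []  # (block, lo, strand)
    for b in built:
        gap = int(rng.integers(420, 521)) if b.kind in gene_kinds \
            else int(rng.integers(150, 301))
        pos += gap
        lo = pos
        if lo + len(b) > sp.genome_length - 500:
            raise ValueError(
                f"cannot place planted features: genome_length {sp.genome_length}"
                f" too small for the requested counts"
            )
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        placements.append((b, lo, strand))
        pos = lo + len(b)

    for b, lo, strand in placements:
        n = len(b)

        def gpos(off: int) -> int:
            return lo + off if strand == FORWARD else lo + n - 1 - off

        def ginterval(a: int, z: int) -> tuple:
            if strand == FORWARD:
                return lo + a, lo + z
            return lo + n - z, lo + n - a

        # promoters must be written before the sequence is committed
        for off, category, pkey in b.tss:
            frac = {"primary": sp.promoter_fraction_primary,
                    "secondary": sp.promoter_fraction_secondary,
                    "orphan": sp.promoter_fraction_orphan}[pkey]
            planted = _maybe_promoter(b, rng, sp, off, frac)
            if planted:
                truth.promoters.append(PlantedPromoter(gpos(off), strand,
                                                       "sigmaABfr"))

        seq = "".join(b.seq)
        if strand == REVERSE:
            seq = revcomp(seq)
        genome_arr[lo: lo + n] = list(seq)

        block_mask = None
        for off, category, pkey in b.tss:
            mask = _condition_mask(rng, sp)
            if block_mask is None:
                block_mask = mask       # the block's first TSS drives its transcript
            strength = float(rng.uniform(0.5, 2.0))
            if category == "secondary":
                strength *= 0.3
            init = b.seq[off]
            truth.tss.append(PlantedTss(gpos(off), strand, category, mask,
                                        strength, init,
                                        any(p.tss_position == gpos(off)
                                            for p in truth.promoters)))
        if block_mask is None:
            block_mask = _condition_mask(rng, sp)
        for off in b.ps:
            truth.processing_sites.append(
                PlantedPs(gpos(off), strand, block_mask,
                          float(rng.uniform(0.5, 2.0))))
        for s5, ls, le, s3 in b.terms:
            a, z = ginterval(s5, s3)
            la, lz = ginterval(ls, le)
            truth.terminators.append(PlantedTerminator(strand, a, la, lz, z))
        for a, z, cls, hc in b.srnas:
            ga, gz = ginterval(a, z)
            truth.srnas.append(PlantedSrna(ga, gz, strand, cls, hc))
        for a, z, role, segs in b.transcripts:
            ga, gz = ginterval(a, z)
            if role == "gene":
                level = float(rng.uniform(*sp.gene_level))
            else:
                level = float(rng.uniform(*sp.srna_level))
            seg_g = [(*ginterval(sa, sz), f) for sa, sz, f in segs]
            seg_g.sort()
            truth.transcripts.append(PlantedTranscript(
                ga, gz, strand, level, block_mask,
                tuple(s for s, _, _ in seg_g),
                tuple(e for _, e, _ in seg_g),
                tuple(f for _, _, f in seg_g)))
        for gi, (a, z) in enumerate(b.genes):
            ga, gz = ginterval(a, z)
            gene_n += 1
            genes.append(GeneFeature(f"gene_{gene_n:04d}", "synth", ga, gz,
                                     strand))
        for gi, ulen in b.utr:
            gid = genes[len(genes) - len(b.genes) + gi].gene_id
            truth.utrs.append(PlantedUtr(gid, ulen))

        # cis-antisense sRNA inside host genes, on the opposite strand
        if b.kind == "host":
            g0, g1 = b.genes[0]
            ga, gz = ginterval(g0, g1)
            anti = FORWARD if strand == REVERSE else REVERSE
            body_len = int(rng.integers(80, min(gz - ga - 40, 200) + 1))
            # oriented coordinates on the antisense strand
            off0 = int(rng.integers(20, gz - ga - body_len - 20))
            if anti == FORWARD:
                a_start = ga + off0
                a_end = a_start + body_len
            else:
                a_end = gz - off0
                a_start = a_end - body_len
            body = _structured_body(rng, body_len)
            init = "ACGT"[rng.choice(4, p=list(sp.initiator_probs))]
            body = init + body[1:]
            if anti == FORWARD:
                genome_arr[a_start:a_end] = list(body)
                tss_pos = a_start
            else:
                genome_arr[a_start:a_end] = list(revcomp(body))
                tss_pos = a_end - 1
            mask = _condition_mask(rng, sp)
            truth.tss.append(PlantedTss(tss_pos, anti, "antisense", mask,
                                        float(rng.uniform(0.5, 2.0)), init,
                                        False))
            truth.srnas.append(PlantedSrna(a_start, a_end, anti,
                                           "cis_antisense", False))
            truth.transcripts.append(PlantedTranscript(
                a_start, a_end, anti,
                float(rng.uniform(*sp.srna_level)), mask,
                (a_start,), (a_end,), (1.0,)))

    genome = GenomeSequence("synth", "".join(genome_arr))
    genes.sort(key=lambda g: g.start)
    truth.tss.sort(key=lambda t: (t.position, t.strand))
    truth.processing_sites.sort(key=lambda p: (p.position, p.strand))
    truth.terminators.sort(key=lambda t: (t.stem5_start, t.strand))
    truth.srnas.sort(key=lambda s: (s.start, s.strand))
    truth.transcripts.sort(key=lambda t: (t.start, t.strand))
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Coverage simulation


def _nb(rng, mean, dispersion, size=None):
    """Negative binomial by (mean, dispersion); Poisson at dispersion -> 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-9:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_coverage(genome: GenomeSequence, truth: SyntheticTruth,
                      sp: SyntheticParams) -> CoverageSet:
    """TEX+/TEX- 5'-end and total coverage tracks for all conditions and
    replicates.  Deterministic given ``sp.rng_seed``."""
    rng = np.random.default_rng(sp.rng_seed + 7919)
    n = len(genome)
    cov = CoverageSet(replicon_id=genome.replicon_id, length=n)
    disp = sp.nb_dispersion

    for cond in sp.conditions:
        for rep in range(1, sp.n_replicates + 1):
            for lib in (TEX_PLUS, TEX_MINUS):
                cov.library_sizes[(cond, rep, lib)] = sp.library_size
            for strand in STRANDS:
                fp_plus = _nb(rng, np.full(n, sp.background_5p_rate), disp)
                fp_minus = _nb(rng, np.full(n, sp.background_5p_rate), disp)
                fp_plus = fp_plus.astype(np.int64)
                fp_minus = fp_minus.astype(np.int64)
                for t in truth.tss:
                    if t.strand != strand or cond not in t.conditions:
                        continue
                    m = sp.mean_5prime_peak * t.strength
                    fp_plus[t.position] += int(_nb(rng, m, disp))
                    fp_minus[t.position] += int(_nb(rng, m / sp.tex_enrichment,
                                                    disp))
                for p in truth.processing_sites:
                    if p.strand != strand or cond not in p.conditions:
                        continue
                    m = sp.mean_5prime_peak * p.strength
                    fp_minus[p.position] += int(_nb(rng, m, disp))
                    fp_plus[p.position] += int(_nb(rng, m * sp.ps_tex_ratio,
                                                   disp))
                cov.fiveprime[(cond, rep, TEX_PLUS, strand)] = fp_plus
                cov.fiveprime[(cond, rep, TEX_MINUS, strand)] = fp_minus

                total = _nb(rng, np.full(n, sp.background_cov_rate),
                            disp).astype(np.int64)
                for t in truth.transcripts:
                    if t.strand != strand or cond not in t.conditions:
                        continue
                    for s, e, f in zip(t.seg_starts, t.seg_ends, t.seg_factors):
                        total[s:e] += _nb(rng, np.full(e - s, t.level * f),
                                          disp).astype(np.int64)
                # TEX treatment leaves total mRNA coverage largely intact:
                # both libraries share the same total track.
                cov.total[(cond, rep, TEX_PLUS, strand)] = total
                cov.total[(cond, rep, TEX_MINUS, strand)] = total.copy()
    cov.validate()
    return cov


# ---------------------------------------------------------------------------
# Dataset writing / loading / mirroring

_TRUTH_FILES = {
    "tss": PlantedTss, "processing_sites": PlantedPs,
    "terminators": PlantedTerminator, "srnas": PlantedSrna,
    "transcripts": PlantedTranscript, "utrs": PlantedUtr,
    "promoters": PlantedPromoter,
}


def write_dataset(directory, genome: GenomeSequence, genes, cov: CoverageSet,
                  truth: SyntheticTruth, sp: SyntheticParams) -> None:
    """Write FASTA + GFF3 + per-track wiggle + manifest + truth TSVs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    dio.write_genome_fasta([genome], d / "genome.fa")
    dio.write_annotation_gff3(genes, d / "annotation.gff3")
    rows = []
    for kind, tracks in (("fiveprime", cov.fiveprime), ("total", cov.total)):
        for key in sorted(tracks):
            cond, rep, lib, strand = key
            sl = "fwd" if strand == FORWARD else "rev"
            libname = "texplus" if lib == TEX_PLUS else "texminus"
            fname = f"{kind}_{cond}_r{rep}_{libname}_{sl}.wig"
            dio.write_wiggle(tracks[key], d / fname, genome.replicon_id)
            rows.append({"file": fname, "condition": cond, "replicate": rep,
                         "library": lib, "strand": strand, "track_kind": kind,
                         "library_size": cov.library_sizes[key[:3]]})
    import pandas as pd
    pd.DataFrame(rows, columns=list(dio.MANIFEST_COLUMNS)).to_csv(
        d / "manifest.tsv", sep="\t", index=False)
    for name, cls in _TRUTH_FILES.items():
        dio.write_records_tsv(getattr(truth, name), d / f"truth_{name}.tsv")
    meta = {"genome_length": truth.genome_length,
            "conditions": list(truth.conditions),
            "params": dataclasses.asdict(sp)}
    (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_dataset(directory):
    """Read a written dataset back: (genome, genes, coverage, truth, params)."""
    d = Path(directory)
    genome = dio.read_genome(d / "genome.fa")[0]
    genes = dio.read_annotation(d / "annotation.gff3")
    cov = dio.read_coverage(d / "manifest.tsv", genomes=[genome])[genome.replicon_id]
    meta = json.loads((d / "meta.json").read_text())
    truth = SyntheticTruth(genome_length=meta["genome_length"],
                           conditions=tuple(meta["conditions"]))
    for name, cls in _TRUTH_FILES.items():
        setattr(truth, name, dio.read_records_tsv(d / f"truth_{name}.tsv", cls))
    p = meta["params"]
    for key in ("gene_len", "srna_level", "gene_level", "initiator_probs"):
        p[key] = tuple(p[key])
    sp = SyntheticParams(**p)
    return genome, genes, cov, truth, sp


def dinucleotide_shuffle(sequence: str, rng) -> str:
    """Dinucleotide-composition-preserving shuffle (Altschul-Erickson).

    Builds the dinucleotide multigraph, fixes a random spanning set of last
    edges into the final base so an Eulerian walk exists, shuffles the
    remaining edges, and replays the walk."""
    if len(sequence) < 3:
        return sequence
    from collections import defaultdict

    edges = defaultdict(list)
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]
    vertices = list(edges.keys())
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in last_edge:
            seen, u = set(), v
            while u != last:
                if u in seen or u not in last_edge:
                    ok = False
                    break
                seen.add(u)
                u = last_edge[u]
            if not ok:
                break
        if ok:
            break
    out_edges = {}
    for v in vertices:
        lst = list(edges[v])
        if v in last_edge:
            lst.remove(last_edge[v])
        lst = [lst[i] for i in rng.permutation(len(lst))]
        if v in last_edge:
            lst.append(last_edge[v])
        out_edges[v] = lst
    result = [sequence[0]]
    ptr = {v: 0 for v in vertices}
    v = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = out_edges[v][ptr[v]]
        ptr[v] += 1
        result.append(nxt)
        v = nxt
    return "".join(result)


def mirror_position(pos: int, length: int) -> int:
    return length - 1 - pos


def mirror_interval(start: int, end: int, length: int) -> tuple:
    return length - end, length - start


def mirror_dataset(genome: GenomeSequence, genes, cov: CoverageSet,
                   truth: SyntheticTruth):
    """Reverse-complement the whole dataset: genome, annotation, coverage
    arrays, and truth, with all strands swapped and coordinates mirrored."""
    from .model import other_strand

    n = len(genome)
    g2 = GenomeSequence(genome.replicon_id, revcomp(genome.sequence),
                        genome.circular)
    genes2 = sorted((GeneFeature(g.gene_id, g.replicon_id,
                                 *mirror_interval(g.start, g.end, n),
                                 other_strand(g.strand), g.feature_kind)
                     for g in genes), key=lambda g: g.start)
    cov2 = CoverageSet(replicon_id=cov.replicon_id, length=n,
                       library_sizes=dict(cov.library_sizes),
                       normalized=cov.normalized)
    for src, dst in ((cov.fiveprime, cov2.fiveprime), (cov.total, cov2.total)):
        for (cond, rep, lib, strand), arr in src.items():
            dst[(cond, rep, lib, other_strand(strand))] = np.asarray(arr)[::-1].copy()

    t2 = SyntheticTruth(genome_length=n, conditions=truth.conditions)
    for t in truth.tss:
        t2.tss.append(PlantedTss(mirror_position(t.position, n),
                                 other_strand(t.strand), t.category,
                                 t.conditions, t.strength, t.initiator,
                                 t.has_promoter))
    for p in truth.processing_sites:
        t2.processing_sites.append(PlantedPs(mirror_position(p.position, n),
                                             other_strand(p.strand),
                                             p.conditions, p.strength))
    for t in truth.terminators:
        a, z = mirror_interval(t.stem5_start, t.stem3_end, n)
        la, lz = mirror_interval(t.loop_start, t.loop_end, n)
        t2.terminators.append(PlantedTerminator(other_strand(t.strand),
                                                a, la, lz, z))
    for s in truth.srnas:
        a, z = mirror_interval(s.start, s.end, n)
        t2.srnas.append(PlantedSrna(a, z, other_strand(s.strand),
                                    s.srna_class, s.high_confidence))
    for t in truth.transcripts:
        a, z = mirror_interval(t.start, t.end, n)
        pairs = sorted(mirror_interval(s, e, n)
                       for s, e in zip(t.seg_starts, t.seg_ends))
        t2.transcripts.append(PlantedTranscript(
            a, z, other_strand(t.strand), t.level, t.conditions,
            tuple(s for s, _ in pairs), tuple(e for _, e in pairs),
            tuple(reversed(t.seg_factors))))
    t2.utrs = list(truth.utrs)
    for p in truth.promoters:
        t2.promoters.append(PlantedPromoter(mirror_position(p.tss_position, n),
                                            other_strand(p.strand),
                                            p.motif_name))
    t2.tss.sort(key=lambda x: (x.position, x.strand))
    t2.processing_sites.sort(key=lambda x: (x.position, x.strand))
    t2.terminators.sort(key=lambda x: (x.stem5_start, x.strand))
    t2.srnas.sort(key=lambda x: (x.start, x.strand))
    t2.transcripts.sort(key=lambda x: (x.start, x.strand))
    return g2, genes2, cov2, t2
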