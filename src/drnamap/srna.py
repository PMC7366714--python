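"""Five-class small-RNA discovery with quantitative filters.

Expressed segments (maximal per-strand runs of total coverage at or above
``min_avg_coverage``) and gene-anchored sub-intervals are classified by a
fixed-precedence decision tree after two universal gates (length 30-500 nt,
mean coverage >= 5):

1. **intergenic** — no gene overlap on either strand, outside operon
   spans, an (orphan) TSS at the 5' end, and a stable structure
   (folding energy normalized to length strictly below ``norm_energy_max``).
2. **cis_antisense** — antisense gene overlap plus the same TSS and
   structure gates.
3. **utr5_derived** — shares a gene's primary TSS and ends at a processing
   site or sharp coverage drop upstream of the CDS.
4. **utr3_derived** — a TSS or processing site within the 3' region of a
   gene (last ``utr3_region`` nt of the CDS or its 3' UTR) and a processing
   site or shared terminator at the 3' end.
5. **intra_operonic** — inside an operon between genes with a TSS or
   processing site at the 5' end and a drop or processing site at the 3' end.

A candidate whose 5' TSS is a gene's *primary* TSS is never routed to the
intergenic rule (leader-derived RNAs share their mRNA's TSS; trans-encoded
sRNAs have their own), which keeps rules 1 and 3 disjoint.

High-confidence flagging: intergenic candidates whose 3' end lies within
``term_dist`` nt of an intrinsic-terminator 3' edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import folding
from .model import (FORWARD, REVERSE, STRANDS, DuplexHit, GeneFeature,
                    GenomeSequence, OperonRecord, PipelineParams, PsRecord,
                    SrnaCandidate, SrnaRejection, TerminatorRecord,
                    TranscriptRecord, TssRecord)

# ---------------------------------------------------------------------------
# Context


@dataclass
class SrnaContext:
    """Everything the decision tree consults besides the candidate itself."""

    genome: GenomeSequence
    genes: Sequence[GeneFeature]
    tss_records: Sequence[TssRecord]
    processing_sites: Sequence[PsRecord]
    terminators: Sequence[TerminatorRecord]
    operons: Sequence[OperonRecord] = ()
    transcripts: Sequence[TranscriptRecord] = ()
    envelope: Dict[str, np.ndarray] = field(default_factory=dict)
    fold_backend: object = "reference"

    def __post_init__(self):
        self._primary_positions = {}
        for rec in self.tss_records:
            for asc in rec.gene_associations:
                label, _, gid = asc.partition(":")
                if label == "primary":
                    self._primary_positions.setdefault(
                        (rec.position, rec.strand), set()).add(gid)

    def primary_genes_at(self, position: int, strand: str, tol: int) -> set:
        out = set()
        for (pos, s), gids in self._primary_positions.items():
            if s == strand and abs(pos - position) <= tol:
                out |= gids
        return out


@dataclass
class Segment:
    """A maximal expressed run with its gene-overlap annotation."""

    replicon_id: str
    start: int
    end: int
    strand: str
    relation: str  # none | sense | antisense | utr | intra_operonic_gap

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Segmentation


def segment_transcribed_regions(envelope: Dict[str, np.ndarray],
                                genes: Sequence[GeneFeature],
                                params: PipelineParams,
                                replicon_id: str,
                                operons: Sequence[OperonRecord] = ()) -> List[Segment]:
    """Maximal runs of per-position coverage >= min_avg_coverage, per strand,
    annotated with their overlap relation to the annotation."""
    segments = []
    for strand in STRANDS:
        env = np.asarray(envelope[strand])
        mask = env >= params.min_avg_coverage
        diff = np.diff(mask.astype(np.int8), prepend=0, append=0)
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for lo, hi in zip(starts, ends):
            lo, hi = int(lo), int(hi)
            sense = any(g.strand == strand and g.start < hi and lo < g.end
                        for g in genes)
            anti = any(g.strand != strand and g.start < hi and lo < g.end
                       for g in genes)
            in_gap = any(o.strand == strand and o.start <= lo and hi <= o.end
                         for o in operons) and not sense
            if sense:
                relation = "sense"
            elif in_gap:
                relation = "intra_operonic_gap"
            elif anti:
                relation = "antisense"
            else:
                relation = "none"
            segments.append(Segment(replicon_id, lo, hi, strand, relation))
    return sorted(segments, key=lambda s: (s.start, s.strand))


# ---------------------------------------------------------------------------
# Helpers shared by derivation and classification


def _five_prime_edge(start: int, end: int, strand: str) -> int:
    return start if strand == FORWARD else end - 1


def _three_prime_edge(start: int, end: int, strand: str) -> int:
    return end - 1 if strand == FORWARD else start


def _sites_near(sites, position: int, strand: str, tol: int):
    return [s for s in sites
            if s.strand == strand and abs(s.position - position) <= tol]


def _mean_cov(env: np.ndarray, lo: int, hi: int) -> float:
    lo, hi = max(lo, 0), min(hi, env.shape[0])
    if hi <= lo:
        return 0.0
    return float(np.asarray(env[lo:hi], dtype=np.int64).sum()) / (hi - lo)


def coverage_drop_at(env: np.ndarray, position: int, strand: str,
                     params: PipelineParams) -> bool:
    """Sharp coverage drop: downstream/upstream window-mean ratio <= 0.5
    just 3' of ``position`` (the last covered base), strand-aware."""
    w = params.srna_drop_window
    if strand == FORWARD:
        up = _mean_cov(env, position + 1 - w, position + 1)
        dn = _mean_cov(env, position + 1, position + 1 + w)
    else:
        up = _mean_cov(env, position, position + w)
        dn = _mean_cov(env, position - w, position)
    if up < params.min_avg_coverage:
        return False
    return dn / up <= params.drop_ratio_max


def _terminator_near_3p(terminators, start: int, end: int, strand: str,
                        tol: int):
    edge = end if strand == FORWARD else start
    for t in terminators:
        if t.strand != strand:
            continue
        if abs(t.three_prime_end - edge) <= tol:
            return t
    return None


# ---------------------------------------------------------------------------
# Candidate derivation (geometry only; the decision tree re-checks gates)


def derive_candidates(segments: Sequence[Segment], ctx: SrnaContext,
                      params: PipelineParams) -> List[Tuple[int, int, str]]:
    """Candidate intervals for classification.

    Intergenic/antisense segments are candidates as-is.  Gene-anchored
    candidates (5'/3'-UTR-derived, intra-operonic) are carved out of sense
    segments using primary TSSs, processing sites, terminators and coverage
    drops."""
    cands = []
    seen = set()

    def add(start, end, strand):
        key = (start, end, strand)
        if end > start and key not in seen:
            seen.add(key)
            cands.append(key)

    for seg in segments:
        if seg.relation in ("none", "antisense", "intra_operonic_gap"):
            add(seg.start, seg.end, seg.strand)

    ps = ctx.processing_sites
    tol = params.tss_assoc_tol

    # 5' UTR-derived: from a gene's primary TSS to the processing site
    # nearest the CDS start (strictly before it).
    primary_by_gene = {}
    for rec in ctx.tss_records:
        for asc in rec.gene_associations:
            label, _, gid = asc.partition(":")
            if label == "primary":
                primary_by_gene[gid] = rec
    gene_by_id = {g.gene_id: g for g in ctx.genes}
    for gid, rec in sorted(primary_by_gene.items()):
        gene = gene_by_id[gid]
        if gene.strand == FORWARD:
            between = [s for s in ps if s.strand == FORWARD
                       and rec.position < s.position < gene.start]
            if between:
                cut = max(between, key=lambda s: s.position)
                add(rec.position, cut.position, FORWARD)
        else:
            between = [s for s in ps if s.strand == REVERSE
                       and gene.end - 1 < s.position < rec.position]
            if between:
                cut = min(between, key=lambda s: s.position)
                add(cut.position + 1, rec.position + 1, REVERSE)

    # 3' UTR-derived: from a TSS/PS in a gene's 3' region to the end of the
    # transcript containing the gene (terminator or falloff edge).
    tr_by_gene = {}
    for t in ctx.transcripts:
        for gid in t.gene_ids:
            cur = tr_by_gene.get(gid)
            if cur is None or t.length > cur.length:
                tr_by_gene[gid] = t
    sites_5p = list(ctx.tss_records) + list(ps)
    for gene in ctx.genes:
        t = tr_by_gene.get(gene.gene_id)
        if t is None:
            continue
        if gene.strand == FORWARD:
            lo, hi = gene.end - params.utr3_region, t.end
            for s in sites_5p:
                if s.strand == FORWARD and lo <= s.position < hi:
                    add(s.position, t.end, FORWARD)
        else:
            lo, hi = t.start, gene.start + params.utr3_region
            for s in sites_5p:
                if s.strand == REVERSE and lo <= s.position < hi:
                    add(t.start, s.position + 1, REVERSE)

    # intra-operonic: between genes inside an operon, 5' site to 3' site.
    for op in ctx.operons:
        members = sorted((gene_by_id[g] for g in op.gene_ids),
                         key=lambda g: g.start)
        for left, right in zip(members, members[1:]):
            gap_lo, gap_hi = left.end, right.start
            if gap_hi - gap_lo < params.srna_len_min:
                continue
            in_gap5 = [s for s in sites_5p if s.strand == op.strand
                       and gap_lo <= s.position < gap_hi]
            in_gap3 = [s for s in ps if s.strand == op.strand
                       and gap_lo <= s.position < gap_hi]
            if not in_gap5:
                continue
            if op.strand == FORWARD:
                p5 = min(s.position for s in in_gap5)
                ends = sorted(s.position for s in in_gap3 if s.position > p5)
                if ends:
                    add(p5, ends[-1], FORWARD)
            else:
                p5 = max(s.position for s in in_gap5)
                starts = sorted(s.position for s in in_gap3 if s.position < p5)
                if starts:
                    add(starts[0] + 1, p5 + 1, REVERSE)

    return sorted(cands)


# ---------------------------------------------------------------------------
# Decision tree


def classify_srna(interval: Tuple[int, int, str], ctx: SrnaContext,
                  params: PipelineParams) -> Union[SrnaCandidate, SrnaRejection]:
    """Apply the universal gates and the five-class decision tree to one
    candidate interval; returns an accepted candidate or a rejection with
    the first failed gate as its reason."""
    start, end, strand = interval
    length = end - start

    def reject(reason):
        return SrnaRejection(ctx.genome.replicon_id, start, end, strand, reason)

    if not (params.srna_len_min <= length <= params.srna_len_max):
        return reject("length")
    env = ctx.envelope[strand]
    avg_cov = _mean_cov(env, start, end)
    if avg_cov < params.min_avg_coverage:
        return reject("coverage")

    tol = params.tss_assoc_tol
    p5 = _five_prime_edge(start, end, strand)
    p3 = _three_prime_edge(start, end, strand)
    tss_at_5p = _sites_near(ctx.tss_records, p5, strand, tol)
    ps_at_5p = _sites_near(ctx.processing_sites, p5, strand, tol)
    ps_at_3p = _sites_near(ctx.processing_sites, p3, strand, tol)
    term = _terminator_near_3p(ctx.terminators, start, end, strand,
                               params.term_dist)
    drop3 = coverage_drop_at(env, p3, strand, params)

    sense_genes = [g for g in ctx.genes if g.strand == strand
                   and g.start < end and start < g.end]
    anti_genes = [g for g in ctx.genes if g.strand != strand
                  and g.start < end and start < g.end]
    in_operon = any(o.strand == strand and o.start <= start and end <= o.end
                    for o in ctx.operons)
    primary_gids = ctx.primary_genes_at(p5, strand, tol)
    has_own_tss = bool(tss_at_5p) and not primary_gids

    seq = ctx.genome.subseq(start, end, strand)
    energy = folding.fold_energy(seq, backend=ctx.fold_backend)
    norm = energy / length

    def accept(cls):
        return SrnaCandidate(
            replicon_id=ctx.genome.replicon_id, start=start, end=end,
            strand=strand, srna_class=cls,
            has_tss=bool(tss_at_5p), has_terminator=term is not None,
            has_processing_5p=bool(ps_at_5p), has_processing_3p=bool(ps_at_3p),
            avg_coverage=avg_cov, fold_energy=energy, norm_energy=norm,
        )

    # rule 1: intergenic
    if not sense_genes and not anti_genes and not in_operon:
        if has_own_tss:
            if norm < params.norm_energy_max:
                return accept("intergenic")
            return reject("folding")
        if not primary_gids and not ps_at_5p:
            return reject("no_tss")

    # rule 2: cis-antisense
    if anti_genes and not sense_genes:
        if tss_at_5p:
            if norm < params.norm_energy_max:
                return accept("cis_antisense")
            return reject("folding")
        if not ps_at_5p:
            return reject("no_tss")

    # rule 3: 5' UTR-derived — shares a gene's primary TSS, ends before its CDS
    for gid in sorted(primary_gids):
        gene = next(g for g in ctx.genes if g.gene_id == gid)
        if gene.strand != strand:
            continue
        before_cds = (p3 < gene.start if strand == FORWARD
                      else p3 > gene.end - 1)
        if before_cds and (ps_at_3p or drop3):
            return accept("utr5_derived")

    # rule 4: 3' UTR-derived — the candidate must share its 3' end (its
    # processing site or terminator) with the parental mRNA's transcript.
    if tss_at_5p or ps_at_5p:
        for gene in ctx.genes:
            if gene.strand != strand:
                continue
            if strand == FORWARD:
                in_3p_region = gene.end - params.utr3_region <= p5
                downstream_of_gene = p5 < gene.end + params.srna_len_max
                ordered = gene.start < p5
            else:
                in_3p_region = p5 < gene.start + params.utr3_region
                downstream_of_gene = p5 > gene.start - params.srna_len_max
                ordered = p5 < gene.end
            if not (in_3p_region and downstream_of_gene and ordered):
                continue
            shares_3p = False
            for t in ctx.transcripts:
                if gene.gene_id not in t.gene_ids or t.strand != strand:
                    continue
                t3 = _three_prime_edge(t.start, t.end, strand)
                if abs(t3 - p3) <= params.term_dist:
                    shares_3p = True
                    break
            if shares_3p and (ps_at_3p or term is not None):
                return accept("utr3_derived")

    # rule 5: intra-operonic
    if in_operon and not sense_genes and (tss_at_5p or ps_at_5p):
        if ps_at_3p or drop3:
            return accept("intra_operonic")

    if sense_genes:
        return reject("overlaps_gene")
    if not (tss_at_5p or ps_at_5p):
        return reject("no_tss")
    return reject("no_class")


def discover_srnas(ctx: SrnaContext, params: PipelineParams):
    """Segment, derive candidates, classify, and flag high confidence.

    Returns (accepted candidates, rejections)."""
    segments = segment_transcribed_regions(
        ctx.envelope, ctx.genes, params, ctx.genome.replicon_id, ctx.operons)
    intervals = derive_candidates(segments, ctx, params)
    accepted, rejected = [], []
    for interval in intervals:
        res = classify_srna(interval, ctx, params)
        if isinstance(res, SrnaCandidate):
            accepted.append(res)
        else:
            rejected.append(res)
    accepted = flag_high_confidence(accepted, ctx.terminators, params)
    return accepted, rejected


def flag_high_confidence(candidates: Sequence[SrnaCandidate],
                         terminators: Sequence[TerminatorRecord],
                         params: PipelineParams) -> List[SrnaCandidate]:
    """Intergenic candidates ending within term_dist of a terminator 3' edge
    (with the coverage gate already enforced by classification) are flagged."""
    out = []
    for c in candidates:
        hc = False
        if c.srna_class == "intergenic" and c.avg_coverage >= params.min_avg_coverage:
            t = _terminator_near_3p(terminators, c.start, c.end, c.strand,
                                    params.term_dist)
            hc = t is not None and c.has_tss
        out.append(SrnaCandidate(**{**c.__dict__, "high_confidence": hc}))
    return out


# ---------------------------------------------------------------------------
# GC statistics


def gc_content_by_class(features: Dict[str, Sequence[Tuple[int, int]]],
                        genome: GenomeSequence) -> dict:
    """Per-class GC summaries over feature intervals; N bases excluded.

    ``features`` maps a class name to a list of (start, end) intervals.
    Classes with no members are absent from the result."""
    out = {"genome_average": genome.gc_fraction()}
    classes = {}
    for name, intervals in features.items():
        vals = [genome.gc_fraction(s, e) for s, e in intervals]
        vals = [v for v in vals if v == v]  # drop NaN (all-N intervals)
        if not vals:
            continue
        arr = np.array(vals)
        classes[name] = {
            "n": len(vals),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "q25": float(np.percentile(arr, 25)),
            "q75": float(np.percentile(arr, 75)),
        }
    out["classes"] = classes
    return out


# ---------------------------------------------------------------------------
# Simplified duplex scanner

_RNA_PAIR = {("G", "C"): 2.0, ("C", "G"): 2.0,
             ("A", "U"): 1.0, ("U", "A"): 1.0,
             ("G", "U"): 0.5, ("U", "G"): 0.5}


def predict_duplex(srna_seq: str, target_seq: str,
                   params: PipelineParams) -> List[DuplexHit]:
    """Gapless antiparallel complementarity scan between an sRNA and a
    target window.

    For every antiparallel offset, terminal mismatches are trimmed, interior
    maximal mismatch runs cost an opening penalty of 2, and pairs score
    G:C 2, A:U 1, G:U 0.5.  A hit requires score >= duplex_score_min and a
    longest contiguous paired stretch (the seed) >= seed_min.  Intramolecular
    structure is ignored."""
    q = srna_seq.upper().replace("T", "U")
    t = target_seq.upper().replace("T", "U")
    for name, s in (("sRNA", q), ("target", t)):
        bad = set(s) - set("ACGUN")
        if bad:
            raise ValueError(f"non-RNA characters in {name}: {sorted(bad)}")
    lq, lt = len(q), len(t)
    hits = []
    for c in range(lq + lt - 1):
        i_lo = max(0, c - lt + 1)
        i_hi = min(lq - 1, c)
        paired = []
        for i in range(i_lo, i_hi + 1):
            j = c - i
            paired.append(_RNA_PAIR.get((q[i], t[j]), 0.0))
        # trim terminal mismatches
        a, b = 0, len(paired)
        while a < b and paired[a] == 0.0:
            a += 1
        while b > a and paired[b - 1] == 0.0:
            b -= 1
        if a == b:
            continue
        score = sum(paired[a:b])
        seed = run = 0
        openings = 0
        in_gap = False
        for v in paired[a:b]:
            if v > 0:
                run += 1
                seed = max(seed, run)
                in_gap = False
            else:
                run = 0
                if not in_gap:
                    openings += 1
                    in_gap = True
        score -= 2.0 * openings
        if score >= params.duplex_score_min and seed >= params.seed_min:
            qs, qe = i_lo + a, i_lo + b
            hits.append(DuplexHit(
                query_start=qs, query_end=qe,
                target_start=c - (qe - 1), target_end=c - qs + 1,
                pair_string="".join(
                    "|" if v >= 1.0 else (":" if v > 0 else ".")
                    for v in paired[a:b]),
                score=score, seed_len=seed,
            ))
    hits.sort(key=lambda h: (-h.score, h.query_start))
    return hits
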