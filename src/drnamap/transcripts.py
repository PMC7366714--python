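"""5' UTR, transcript, operon, and sORF inference.

Transcripts extend 3' from each primary/orphan TSS while a sliding
``transcript_window`` nt mean of total read coverage stays at or above
``min_avg_coverage``, ending either at the first coverage-supported
intrinsic terminator inside the extension (at the stem's 3' edge plus the
U-tail window) or at the coverage falloff point.  Operons are the maximal
same-strand gene runs contained in one transcript.  sORF scanning reports
open reading frames of 10-100 codons starting ATG/GTG/TTG inside supplied
regions (long 5' UTRs or intergenic transcripts).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import utr_distance
from .model import (FORWARD, REVERSE, GeneFeature, GenomeSequence,
                    OperonRecord, PipelineParams, SorfCandidate,
                    TerminatorRecord, TranscriptRecord, TssRecord, UtrRecord)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
SORF_MIN_CODONS = 10
SORF_MAX_CODONS = 100


def primary_tss_of_genes(records: Sequence[TssRecord]) -> Dict[str, TssRecord]:
    """gene_id -> its primary TSS record, from classified TSSs."""
    out = {}
    for rec in records:
        for asc in rec.gene_associations:
            label, _, gid = asc.partition(":")
            if label == "primary":
                out[gid] = rec
    return out


def infer_5utrs(records: Sequence[TssRecord], genes: Sequence[GeneFeature],
                params: PipelineParams) -> List[UtrRecord]:
    """One UTR record per gene with a primary TSS.

    ``leaderless`` is strict (< leaderless_max), ``long_utr`` is strict
    (> long_utr_min); the two are mutually exclusive."""
    by_gene = primary_tss_of_genes(records)
    out = []
    for gene in genes:
        tss = by_gene.get(gene.gene_id)
        if tss is None:
            continue
        length = utr_distance(tss.position, gene)
        out.append(UtrRecord(
            gene_id=gene.gene_id, replicon_id=gene.replicon_id,
            tss_position=tss.position, strand=gene.strand,
            utr_length=length,
            leaderless=length < params.leaderless_max,
            long_utr=length > params.long_utr_min,
        ))
    return sorted(out, key=lambda u: (u.tss_position, u.strand))


def utr_summary(utrs: Sequence[UtrRecord]) -> dict:
    if not utrs:
        return {"n": 0, "mean": float("nan"), "median": float("nan"),
                "mode": float("nan"), "leaderless_fraction": 0.0,
                "long_fraction": 0.0}
    lengths = np.array([u.utr_length for u in utrs])
    values, counts = np.unique(lengths, return_counts=True)
    return {
        "n": len(utrs),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "mode": int(values[np.argmax(counts)]),
        "leaderless_fraction": sum(u.leaderless for u in utrs) / len(utrs),
        "long_fraction": sum(u.long_utr for u in utrs) / len(utrs),
    }


def _falloff_point(cov_oriented: np.ndarray, start: int, window: int,
                   floor: float) -> int:
    """First oriented index >= start where the mean over the next ``window``
    nt (truncated at the array end) falls below ``floor``."""
    n = cov_oriented.shape[0]
    cum = np.concatenate(([0], np.cumsum(cov_oriented, dtype=np.int64)))
    j = start
    while j < n:
        hi = min(j + window, n)
        if float(cum[hi] - cum[j]) / (hi - j) < floor:
            return j
        j += 1
    return n


def assemble_transcripts(records: Sequence[TssRecord],
                         terminators: Sequence[TerminatorRecord],
                         coverage_envelope: Dict[str, np.ndarray],
                         genes: Sequence[GeneFeature],
                         params: PipelineParams) -> List[TranscriptRecord]:
    """Transcript boundaries from primary/orphan TSSs, terminators, coverage.

    ``coverage_envelope`` maps strand to a per-position total-coverage array
    (raw reads; typically the max over conditions of replicate means).
    """
    out = []
    term_by_strand: Dict[str, list] = {FORWARD: [], REVERSE: []}
    for t in terminators:
        if t.coverage_supported:
            term_by_strand[t.strand].append(t)
    for rec in records:
        cats = set(rec.categories)
        if not cats & {"primary", "orphan"}:
            continue
        strand = rec.strand
        env = coverage_envelope[strand]
        n = env.shape[0]
        oriented = env if strand == FORWARD else env[::-1]
        opos = rec.position if strand == FORWARD else n - 1 - rec.position
        fall = _falloff_point(oriented, opos, params.transcript_window,
                              params.min_avg_coverage)
        end_kind = "falloff"
        o_end = max(fall, opos + 1)
        low = fall <= opos
        # first coverage-supported terminator starting within the extension
        best = None
        for t in term_by_strand[strand]:
            t_start = (t.stem5_start if strand == FORWARD
                       else n - t.stem3_end)           # oriented start
            t_end = t_start + (t.stem3_end - t.stem5_start) + params.u_tail_window
            if opos < t_start and t_start <= o_end:
                if best is None or t_start < best[0]:
                    best = (t_start, min(t_end, n))
        if best is not None:
            o_end = best[1]
            end_kind = "terminator"
        if strand == FORWARD:
            start, end = rec.position, rec.position + (o_end - opos)
        else:
            start, end = rec.position + 1 - (o_end - opos), rec.position + 1
        contained = tuple(g.gene_id for g in sorted(genes, key=lambda g: g.start)
                          if g.strand == strand and start <= g.start and g.end <= end)
        out.append(TranscriptRecord(
            replicon_id=rec.replicon_id, start=start, end=end, strand=strand,
            tss_position=rec.position, end_kind=end_kind,
            gene_ids=contained, low_expression=low,
        ))
    return sorted(out, key=lambda t: (t.start, t.strand, t.end))


def assemble_operons(transcripts: Sequence[TranscriptRecord],
                     genes: Sequence[GeneFeature]) -> List[OperonRecord]:
    """Maximal same-strand gene runs covered by one transcript.

    Transcripts whose gene set is contained in another transcript's do not
    produce a separate operon; single covered genes become monocistrons."""
    gene_by_id = {g.gene_id: g for g in genes}
    runs = []
    for t in transcripts:
        if t.gene_ids:
            runs.append((t.replicon_id, t.strand, t.gene_ids))
    # drop runs strictly contained in a longer run on the same strand
    kept = []
    for rid, strand, ids in runs:
        ids_set = set(ids)
        contained = any(
            rid == rid2 and strand == s2 and ids_set < set(ids2)
            for rid2, s2, ids2 in runs
        )
        if not contained and (rid, strand, ids) not in kept:
            kept.append((rid, strand, ids))
    out = []
    for rid, strand, ids in kept:
        members = [gene_by_id[g] for g in ids]
        out.append(OperonRecord(
            replicon_id=rid, strand=strand,
            start=min(g.start for g in members),
            end=max(g.end for g in members),
            gene_ids=ids,
        ))
    return sorted(out, key=lambda o: (o.start, o.strand))


def find_sorfs(regions: Sequence[Tuple[int, int, str]], genome: GenomeSequence,
               params: Optional[PipelineParams] = None) -> List[SorfCandidate]:
    """Scan regions (start, end, strand) for small ORFs.

    An sORF begins with ATG/GTG/TTG, ends at the first in-frame stop inside
    the region, and spans 10-100 codons (start codon included, stop codon
    excluded from the count)."""
    out = []
    for start, end, strand in regions:
        seq = genome.subseq(start, end, strand)
        m = len(seq)
        for i in range(m - 2):
            if seq[i:i + 3] not in START_CODONS:
                continue
            for j in range(i + 3, m - 2, 3):
                if seq[j:j + 3] in STOP_CODONS:
                    n_codons = (j - i) // 3
                    if SORF_MIN_CODONS <= n_codons <= SORF_MAX_CODONS:
                        if strand == FORWARD:
                            g_start, g_end = start + i, start + j + 3
                        else:
                            g_start, g_end = end - (j + 3), end - i
                        out.append(SorfCandidate(
                            replicon_id=genome.replicon_id,
                            start=g_start, end=g_end, strand=strand,
                            start_codon=seq[i:i + 3], n_codons=n_codons,
                            frame=i % 3,
                        ))
                    break
    return sorted(out, key=lambda s: (s.start, s.strand, s.end))
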