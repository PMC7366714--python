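"""Rho-independent (intrinsic) terminator scanning and coverage confirmation.

The scanner finds hairpins — an inverted repeat forming a perfect stem
(Watson-Crick plus G:U wobble) of 4-20 bp around a 3-10 nt loop — scored as

    hairpin_score = 3 * (G:C) + 2 * (A:U) + 1 * (G:U) - loop_length

and requires at least ``u_tail_min`` T residues (template sense) in the
``u_tail_window`` nt immediately downstream of the stem.  Overlapping hits
collapse to the highest-scoring one.  The default score floor (19) is
calibrated on dinucleotide-composition-preserving shuffles of the
reference genome so that spurious hairpin+U-tract loci stay at or below
two per 100 kb across shuffle realizations, while canonical terminators
(>= 7 bp predominantly G:C stems, scoring >= 21) pass with margin.

Coverage confirmation compares mean total read coverage over fixed windows
downstream vs upstream of the hairpin (strand-aware): a terminator is
``coverage_supported`` when the downstream/upstream ratio drops to at most
``drop_ratio_max`` and the upstream side is expressed at all.

Record coordinates are genomic-forward: ``stem5_start < loop_start <
loop_end < stem3_end`` bound the (left stem, loop, right stem) interval;
for minus-strand records the reading-order 5' stem is the right one.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .model import (FORWARD, REVERSE, STRANDS, TEX_MINUS, CoverageSet,
                    GenomeSequence, PipelineParams, TerminatorRecord, revcomp)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# pair score table (transcript sense; T plays U): G:C=3, A:U=2, G:U=1
_PAIR_SCORE = np.zeros((5, 5), dtype=np.int64)
_PAIR_SCORE[2, 1] = _PAIR_SCORE[1, 2] = 3
_PAIR_SCORE[0, 3] = _PAIR_SCORE[3, 0] = 2
_PAIR_SCORE[2, 3] = _PAIR_SCORE[3, 2] = 1


def _encode_dna(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in seq], dtype=np.int8)


def _scan_oriented(enc: np.ndarray, params: PipelineParams) -> List[tuple]:
    """All qualifying (start, stem, loop, score, u_count) on one orientation."""
    n = enc.shape[0]
    is_t = (enc == 3).astype(np.int64)
    cum_t = np.concatenate(([0], np.cumsum(is_t)))
    hits = []
    for s in range(params.stem_len_min, params.stem_len_max + 1):
        for l in range(params.loop_len_min, params.loop_len_max + 1):
            span = 2 * s + l
            m = n - span + 1
            if m <= 0:
                continue
            total = np.zeros(m, dtype=np.int64)
            ok = np.ones(m, dtype=bool)
            for k in range(s):
                b1 = enc[k:k + m]
                b2 = enc[span - 1 - k: span - 1 - k + m]
                sc = _PAIR_SCORE[b1, b2]
                ok &= sc > 0
                total += sc
                if not ok.any():
                    break
            else:
                score = total - l
                ok &= score >= params.hairpin_score_min
                idx = np.nonzero(ok)[0]
                for i in idx:
                    tail_lo = i + span
                    tail_hi = min(tail_lo + params.u_tail_window, n)
                    u = int(cum_t[tail_hi] - cum_t[tail_lo])
                    if u >= params.u_tail_min:
                        hits.append((int(i), s, l, int(score[i]), u))
    return hits


def _resolve_overlaps(hits: List[tuple]) -> List[tuple]:
    """Greedy selection by descending score; drop hits overlapping a kept one."""
    hits = sorted(hits, key=lambda h: (-h[3], h[0], h[1], h[2]))
    kept = []
    occupied = []
    for h in hits:
        i, s, l, score, u = h
        lo, hi = i, i + 2 * s + l
        if any(lo < b and a < hi for a, b in occupied):
            continue
        kept.append(h)
        occupied.append((lo, hi))
    return kept


def scan_intrinsic_terminators(genome: GenomeSequence,
                               params: PipelineParams) -> List[TerminatorRecord]:
    """Scan both strands of a replicon for hairpin + U-tract terminators."""
    n = len(genome)
    records = []
    for strand in STRANDS:
        seq = genome.sequence if strand == FORWARD else revcomp(genome.sequence)
        enc = _encode_dna(seq)
        for i, s, l, score, u in _resolve_overlaps(_scan_oriented(enc, params)):
            span = 2 * s + l
            left = i if strand == FORWARD else n - i - span
            records.append(TerminatorRecord(
                replicon_id=genome.replicon_id, strand=strand,
                stem5_start=left, loop_start=left + s,
                loop_end=left + s + l, stem3_end=left + span,
                stem_length=s, loop_length=l,
                hairpin_score=float(score), u_tail_count=u,
            ))
    return sorted(records, key=lambda r: (r.stem5_start, r.strand))


def _pooled_total(cov: CoverageSet, strand: str) -> tuple:
    """(summed int array, number of tracks) over all untreated total tracks."""
    keys = [k for k in cov.total if k[2] == TEX_MINUS and k[3] == strand]
    if not keys:  # fall back to whatever total tracks exist on the strand
        keys = [k for k in cov.total if k[3] == strand]
    if not keys:
        raise KeyError(f"no total-coverage track on strand {strand!r}")
    acc = np.zeros(cov.length, dtype=np.int64)
    for k in keys:
        acc += np.asarray(cov.total[k], dtype=np.int64)
    return acc, len(keys)


def confirm_by_coverage(records: Sequence[TerminatorRecord], cov: CoverageSet,
                        params: PipelineParams) -> List[TerminatorRecord]:
    """Set drop_ratio / coverage_supported on each terminator record."""
    pooled = {strand: _pooled_total(cov, strand) for strand in STRANDS}
    n = cov.length
    w = params.drop_window
    out = []
    for rec in records:
        acc, ntracks = pooled[rec.strand]
        if rec.strand == FORWARD:
            up_lo, up_hi = rec.stem5_start - w, rec.stem5_start
            dn_lo, dn_hi = rec.stem3_end, rec.stem3_end + w
        else:
            up_lo, up_hi = rec.stem3_end, rec.stem3_end + w
            dn_lo, dn_hi = rec.stem5_start - w, rec.stem5_start
        truncated = up_lo < 0 or dn_lo < 0 or up_hi > n or dn_hi > n
        up_lo, dn_lo = max(up_lo, 0), max(dn_lo, 0)
        up_hi, dn_hi = min(up_hi, n), min(dn_hi, n)
        up_n, dn_n = up_hi - up_lo, dn_hi - dn_lo
        up_mean = float(acc[up_lo:up_hi].sum()) / (ntracks * up_n) if up_n else 0.0
        dn_mean = float(acc[dn_lo:dn_hi].sum()) / (ntracks * dn_n) if dn_n else 0.0
        if up_mean > 0:
            drop = dn_mean / up_mean
        else:
            drop = float("nan")
        supported = (up_mean >= params.min_avg_coverage
                     and up_mean > 0 and drop <= params.drop_ratio_max)
        rec2 = TerminatorRecord(**{**rec.__dict__,
                                   "drop_ratio": drop,
                                   "coverage_supported": bool(supported),
                                   "edge_truncated": truncated})
        out.append(rec2)
    return out
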