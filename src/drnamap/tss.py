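"""TSS and processing-site calling from TEX+/TEX- 5'-end count tracks.

A position is a TSS candidate in a condition when, on the replicate-averaged
per-million-normalized TEX+ 5'-end track,

* step factor   = TEX+(p) / max(TEX+(p-1), eps)  >= step_factor_min,
* step height   = TEX+(p)                        >= step_height_min,
* enrichment    = TEX+(p) / max(TEX-(p), eps)    >= enrichment_factor_min,

where p-1 is the strand-aware upstream neighbor.  Candidates within
``cluster_width`` nt on a strand are clustered to the highest-signal
position.  Processing sites are the complementary calls: a 5'-end step on
the untreated (TEX-) track without TEX enrichment.

All minus-strand work runs on reversed arrays through the plus-strand code
path, which makes every rule strand-mirror symmetric by construction.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .model import (FORWARD, REVERSE, STRANDS, TEX_MINUS, TEX_PLUS,
                    CoverageSet, GenomeSequence, PipelineParams,
                    ProcessingSite, PsRecord, TssCandidate, TssRecord,
                    revcomp)


def normalize_per_million(cov: CoverageSet) -> CoverageSet:
    """Scale every track by 1e6 / library_size.  Returns a new CoverageSet."""
    if cov.normalized:
        return cov
    out = CoverageSet(replicon_id=cov.replicon_id, length=cov.length,
                      library_sizes=dict(cov.library_sizes), normalized=True)
    for name, src, dst in (("fiveprime", cov.fiveprime, out.fiveprime),
                           ("total", cov.total, out.total)):
        for key, arr in src.items():
            lib_key = key[:3]
            size = cov.library_sizes.get(lib_key)
            if size is None or size <= 0:
                raise ValueError(f"missing or zero library size for {lib_key}")
            dst[key] = np.asarray(arr, dtype=float) * (1e6 / size)
    return out


def _oriented(arr: np.ndarray, strand: str) -> np.ndarray:
    return arr if strand == FORWARD else arr[::-1]


def _cluster_keep_max(positions: np.ndarray, heights: np.ndarray,
                      width: int) -> list:
    """Chain-cluster sorted oriented positions with gaps <= width; keep the
    highest-signal member of each cluster, ties to the 5'-most (smallest
    oriented index).  Returns list of indices into ``positions``."""
    keep = []
    start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or positions[i] - positions[i - 1] > width:
            block = slice(start, i)
            h = heights[block]
            keep.append(start + int(np.argmax(h)))  # argmax -> first max = 5'-most
            start = i
    return keep


def _call_sites(detect: np.ndarray, other: np.ndarray, params: PipelineParams,
                require_enriched: bool) -> list:
    """Shared rule evaluation on oriented arrays.

    ``detect`` is the track the 5'-end step is measured on (TEX+ for TSSs,
    TEX- for processing sites); ``other`` is its counterpart.  Returns
    [(oriented_pos, step_height, step_factor, enrichment_factor)].
    """
    eps = params.epsilon
    # the first oriented position has no upstream neighbor: no step there
    prev = np.concatenate((detect[:1], detect[:-1]))
    step_factor = detect / np.maximum(prev, eps)
    if require_enriched:
        texplus, texminus = detect, other
    else:
        texplus, texminus = other, detect
    enrichment = texplus / np.maximum(texminus, eps)
    mask = (detect >= params.step_height_min) & (step_factor >= params.step_factor_min)
    if require_enriched:
        mask &= enrichment >= params.enrichment_factor_min
    else:
        mask &= enrichment < params.enrichment_factor_min
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    keep = _cluster_keep_max(idx, detect[idx], params.cluster_width)
    return [(int(idx[k]), float(detect[idx[k]]), float(step_factor[idx[k]]),
             float(enrichment[idx[k]])) for k in keep]


def _condition_tracks(cov: CoverageSet, condition: str, strand: str):
    try:
        tp = cov.fiveprime_mean(condition, TEX_PLUS, strand)
        tm = cov.fiveprime_mean(condition, TEX_MINUS, strand)
    except KeyError as exc:
        raise KeyError(
            f"condition {condition!r}: missing 5'-end library ({exc})"
        ) from exc
    return tp, tm


def call_tss_candidates(cov: CoverageSet, params: PipelineParams,
                        condition: str) -> list:
    """TEX-enrichment TSS calls for one condition (replicates averaged)."""
    if not cov.normalized:
        raise ValueError("call_tss_candidates requires per-million-normalized tracks")
    out = []
    n = cov.length
    for strand in STRANDS:
        tp, tm = _condition_tracks(cov, condition, strand)
        hits = _call_sites(_oriented(tp, strand), _oriented(tm, strand),
                           params, require_enriched=True)
        for pos, h, sf, ef in hits:
            genomic = pos if strand == FORWARD else n - 1 - pos
            out.append(TssCandidate(cov.replicon_id, genomic, strand, condition,
                                    h, sf, ef))
    return sorted(out, key=lambda c: (c.position, c.strand))


def call_processing_sites(cov: CoverageSet, params: PipelineParams,
                          condition: str) -> list:
    """5'-end steps on the untreated track lacking TEX enrichment."""
    if not cov.normalized:
        raise ValueError("call_processing_sites requires normalized tracks")
    out = []
    n = cov.length
    for strand in STRANDS:
        tp, tm = _condition_tracks(cov, condition, strand)
        hits = _call_sites(_oriented(tm, strand), _oriented(tp, strand),
                           params, require_enriched=False)
        for pos, h, sf, ef in hits:
            genomic = pos if strand == FORWARD else n - 1 - pos
            out.append(ProcessingSite(cov.replicon_id, genomic, strand,
                                      condition, h, sf, ef))
    return sorted(out, key=lambda c: (c.position, c.strand))


def _merge_point_calls(candidates: Sequence, tolerance: int, length: int):
    """Cluster per-condition point calls across conditions, strand-aware.

    Yields (representative candidate, member list) with the representative at
    the highest step_height (tie: 5'-most on the strand)."""
    by_strand = {}
    for c in candidates:
        by_strand.setdefault((c.replicon_id, c.strand), []).append(c)
    for (replicon, strand), group in sorted(by_strand.items()):
        def okey(c):
            return c.position if strand == FORWARD else length - 1 - c.position
        group.sort(key=okey)
        block = []
        for c in group + [None]:
            if c is not None and (not block or okey(c) - okey(block[-1]) <= tolerance):
                block.append(c)
                continue
            if block:
                rep = max(block, key=lambda x: (x.step_height, okey(x) * -1))
                yield rep, list(block)
            block = [c] if c is not None else []


def merge_conditions(candidate_lists: Iterable, params: PipelineParams,
                     length: int) -> list:
    """Consolidate per-condition TSS candidates into TssRecords."""
    pool = [c for lst in candidate_lists for c in lst]
    records = []
    for rep, members in _merge_point_calls(pool, params.condition_merge_tolerance,
                                           length):
        records.append(TssRecord(
            replicon_id=rep.replicon_id,
            position=rep.position,
            strand=rep.strand,
            detected_in=tuple(sorted({m.condition for m in members})),
            step_height=max(m.step_height for m in members),
            step_factor=max(m.step_factor for m in members),
            enrichment_factor=max(m.enrichment_factor for m in members),
        ))
    return sorted(records, key=lambda r: (r.replicon_id, r.position, r.strand))


def merge_processing_sites(site_lists: Iterable, params: PipelineParams,
                           length: int) -> list:
    """Consolidate per-condition processing-site calls into PsRecords."""
    pool = [c for lst in site_lists for c in lst]
    records = []
    for rep, members in _merge_point_calls(pool, params.condition_merge_tolerance,
                                           length):
        records.append(PsRecord(
            replicon_id=rep.replicon_id,
            position=rep.position,
            strand=rep.strand,
            detected_in=tuple(sorted({m.condition for m in members})),
            step_height=max(m.step_height for m in members),
        ))
    return sorted(records, key=lambda r: (r.replicon_id, r.position, r.strand))


def initiating_nucleotide_stats(records: Sequence[TssRecord],
                                genome: GenomeSequence) -> dict:
    """Frequency of the +1 nucleotide, read strand-aware.  Sums to 1."""
    counts = {b: 0 for b in "ACGT"}
    n = 0
    for rec in records:
        base = genome.sequence[rec.position]
        if rec.strand == REVERSE:
            base = revcomp(base)
        if base in counts:
            counts[base] += 1
            n += 1
    if n == 0:
        return {b: 0.0 for b in "ACGT"}
    return {b: c / n for b, c in counts.items()}


def detection_matrix(records: Sequence[TssRecord], conditions: Sequence[str]):
    """Per-condition detection table: rows = TSSs, columns = conditions."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {"position": rec.position, "strand": rec.strand}
        for c in conditions:
            row[c] = c in rec.detected_in
        rows.append(row)
    return pd.DataFrame(rows)
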