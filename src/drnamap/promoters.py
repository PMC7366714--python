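"""Two-box promoter motif scanning upstream of TSSs.

The scan window is -50..+1 in promoter coordinates (+1 is the TSS itself,
-1 the base immediately upstream; there is no 0), extracted strand-aware.
A full hit places both IUPAC boxes at allowed center offsets within the
per-box mismatch budget with the inter-box spacer satisfying an optional
AT-fraction floor; the best placement (fewest total mismatches, then
most-upstream second box) is reported.  Box-only partial hits are reported
when the spec allows them.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from .model import (FORWARD, GenomeSequence, MotifHit, MotifSpec,
                    PipelineParams, TssRecord)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _mismatches(window: str, consensus: str, start_idx: int) -> Optional[int]:
    """Mismatch count of consensus placed at window[start_idx:]; None if the
    placement leaves the window."""
    if start_idx < 0 or start_idx + len(consensus) > len(window):
        return None
    mm = 0
    for off, c in enumerate(consensus):
        if window[start_idx + off] not in _IUPAC[c.upper()]:
            mm += 1
    return mm


def _at_fraction(s: str) -> float:
    if not s:
        return 1.0
    return sum(1 for c in s if c in "AT") / len(s)


def extract_promoter_window(genome: GenomeSequence, position: int, strand: str,
                            region=( -50, 1)) -> tuple:
    """(window sequence, index of promoter coordinate -50, truncated flag).

    The returned string runs 5'->3' toward the TSS with the TSS (+1) as its
    last character."""
    up, _down = -region[0], region[1]
    if strand == FORWARD:
        lo, hi = position - up, position + 1
        truncated = lo < 0
        lo = max(lo, 0)
        seq = genome.sequence[lo:hi]
    else:
        lo, hi = position, position + up + 1
        truncated = hi > len(genome)
        hi = min(hi, len(genome))
        from .model import revcomp
        seq = revcomp(genome.sequence[lo:hi])
    return seq, truncated


def _offset_to_index(offset: int, window_len: int) -> int:
    """Promoter coordinate -> index in the extracted window (last char = +1)."""
    # +1 maps to window_len - 1; -1 to window_len - 2; -k to window_len - 1 - k
    if offset >= 1:
        return window_len - 2 + offset
    return window_len - 1 + offset


def _box_placements(window: str, box: str, centers: Sequence[int],
                    budget: int) -> List[tuple]:
    """[(start_offset, mismatches)] for every allowed in-budget placement."""
    out = []
    half = (len(box) - 1) // 2
    for center in centers:
        start_offset = center - half
        idx = _offset_to_index(start_offset, len(window))
        mm = _mismatches(window, box, idx)
        if mm is not None and mm <= budget:
            out.append((start_offset, mm))
    return out


def scan_promoters(records: Sequence[TssRecord], genome: GenomeSequence,
                   specs: Sequence[MotifSpec],
                   params: PipelineParams) -> List[MotifHit]:
    hits = []
    for rec in records:
        window, truncated = extract_promoter_window(
            genome, rec.position, rec.strand, params.promoter_region)
        for spec in specs:
            p1 = _box_placements(window, spec.box1, spec.box1_centers,
                                 spec.max_mismatches)
            p2 = _box_placements(window, spec.box2, spec.box2_centers,
                                 spec.max_mismatches)
            best = None
            for off1, mm1 in p1:
                for off2, mm2 in p2:
                    if off2 + len(spec.box2) > off1:   # boxes must not overlap
                        continue
                    spacer_lo = _offset_to_index(off2, len(window)) + len(spec.box2)
                    spacer_hi = _offset_to_index(off1, len(window))
                    at = _at_fraction(window[spacer_lo:spacer_hi])
                    if spec.spacer_at_min is not None and at < spec.spacer_at_min:
                        continue
                    key = (mm1 + mm2, off2)   # fewest mismatches, most-upstream box2
                    if best is None or key < best[0]:
                        best = (key, off1, off2, mm1, mm2, at)
            if best is not None:
                _, off1, off2, mm1, mm2, at = best
                hits.append(MotifHit(rec.position, rec.strand, spec.name,
                                     off1, off2, mm1, mm2, at,
                                     partial=False, truncated=truncated))
            elif spec.allow_partial and p1:
                off1, mm1 = min(p1, key=lambda x: (x[1], x[0]))
                hits.append(MotifHit(rec.position, rec.strand, spec.name,
                                     off1, 0, mm1, -1, float("nan"),
                                     partial=True, truncated=truncated))
    return hits


def motif_frequency_by_category(hits: Sequence[MotifHit],
                                records: Sequence[TssRecord]) -> dict:
    """Fraction of TSSs in each category with at least one full hit of each
    motif; denominators are the category sizes.  Empty categories are
    reported with a note instead of a row."""
    full = {}
    for h in hits:
        if not h.partial:
            full.setdefault(h.motif_name, set()).add((h.tss_position, h.strand))
    by_cat: Dict[str, list] = {}
    for rec in records:
        for cat in rec.categories:
            by_cat.setdefault(cat, []).append((rec.position, rec.strand))
    table = {}
    notes = []
    from .classify import CATEGORIES
    for cat in CATEGORIES:
        members = by_cat.get(cat, [])
        if not members:
            notes.append(f"category {cat!r}: no TSSs, row omitted")
            continue
        row = {"n": len(members)}
        for motif, positions in sorted(full.items()):
            row[motif] = sum(1 for m in members if m in positions) / len(members)
        table[cat] = row
    return {"table": table, "notes": notes}
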