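"""Category assignment for consolidated TSSs relative to gene annotation.

Five multi-labels per TSS:

* ``primary``   — the strongest (highest step-height) TSS within the
  upstream window of a gene on its strand; one per gene at most.
* ``secondary`` — other TSSs within that window (never a TSS that is
  primary for some gene: primary and secondary are mutually exclusive
  at the TSS level).
* ``internal``  — sense TSS within a gene body.
* ``antisense`` — TSS on the opposite strand within the gene body extended
  by ``antisense_flank`` on both sides.
* ``orphan``    — carries none of the above.

The upstream window is strand-aware: a TSS at distance d from the gene's
first base, 0 <= d < window_upstream, is a window occupant; d = 0 (the
leaderless case, TSS at the start codon) counts as upstream.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Sequence, Tuple

from .model import (FORWARD, GeneFeature, PipelineParams, TssRecord)

CATEGORIES = ("primary", "secondary", "internal", "antisense", "orphan")


def utr_distance(position: int, gene: GeneFeature) -> int:
    """Strand-aware distance from a TSS position to the gene's first base;
    positive when the TSS lies upstream."""
    if gene.strand == FORWARD:
        return gene.start - position
    return position - (gene.end - 1)


def window_occupants(tss_positions: Sequence[Tuple[int, str]], gene: GeneFeature,
                     window: int) -> List[int]:
    """Indices of TSSs (position, strand) in the gene's upstream window."""
    out = []
    for i, (pos, strand) in enumerate(tss_positions):
        if strand != gene.strand:
            continue
        d = utr_distance(pos, gene)
        if 0 <= d < window:
            out.append(i)
    return out


def _assign_primaries(records: Sequence[TssRecord], genes: Sequence[GeneFeature],
                      params: PipelineParams) -> Dict[str, int]:
    """gene_id -> record index of its primary TSS.

    Each gene wants the highest step-height occupant of its window (ties:
    nearest to the gene start, then 5'-most, which on one strand collapses
    to the same position).  A TSS may be primary for at most one gene; when
    two genes contend for the same TSS, the nearer gene start wins and the
    other gene falls back to its best remaining occupant.
    """
    positions = [(r.position, r.strand) for r in records]
    prefs: Dict[str, List[int]] = {}
    for gene in genes:
        occ = window_occupants(positions, gene, params.window_upstream)
        if occ:
            occ.sort(key=lambda i: (-records[i].step_height,
                                    utr_distance(records[i].position, gene)))
            prefs[gene.gene_id] = occ
    gene_by_id = {g.gene_id: g for g in genes}
    taken: Dict[int, str] = {}       # record index -> gene_id
    assigned: Dict[str, int] = {}
    pending = sorted(prefs)
    while pending:
        proposals: Dict[int, List[str]] = {}
        still = []
        for gid in pending:
            cand = next((i for i in prefs[gid] if i not in taken), None)
            if cand is None:
                continue  # all its window TSSs claimed elsewhere: no primary
            proposals.setdefault(cand, []).append(gid)
        for idx, gids in proposals.items():
            winner = min(gids, key=lambda gid: (
                utr_distance(records[idx].position, gene_by_id[gid]), gid))
            taken[idx] = winner
            assigned[winner] = idx
            still.extend(g for g in gids if g != winner)
        if not proposals:
            break
        pending = sorted(still)
    return assigned


def classify_tss(records: Sequence[TssRecord], genes: Sequence[GeneFeature],
                 params: PipelineParams) -> List[TssRecord]:
    """Return new TssRecords with ``categories`` and ``gene_associations``."""
    positions = [(r.position, r.strand) for r in records]
    labels: List[set] = [set() for _ in records]
    assoc: List[set] = [set() for _ in records]

    primary_of = _assign_primaries(records, genes, params)
    primary_indices = set(primary_of.values())
    for gid, idx in primary_of.items():
        labels[idx].add("primary")
        assoc[idx].add(f"primary:{gid}")

    for gene in genes:
        for i in window_occupants(positions, gene, params.window_upstream):
            if i in primary_indices:
                continue  # primary somewhere: never also secondary
            labels[i].add("secondary")
            assoc[i].add(f"secondary:{gene.gene_id}")
        for i, (pos, strand) in enumerate(positions):
            if strand == gene.strand and gene.start <= pos < gene.end:
                labels[i].add("internal")
                assoc[i].add(f"internal:{gene.gene_id}")
            if strand != gene.strand and \
                    gene.start - params.antisense_flank <= pos < gene.end + params.antisense_flank:
                labels[i].add("antisense")
                assoc[i].add(f"antisense:{gene.gene_id}")

    out = []
    for rec, labs, asc in zip(records, labels, assoc):
        if not labs:
            labs = {"orphan"}
        out.append(replace(rec, categories=tuple(sorted(labs)),
                           gene_associations=tuple(sorted(asc))))
    return out


def category_summary(records: Sequence[TssRecord]) -> dict:
    """Counts and percentages per label plus the pairwise overlap matrix.

    Each TSS contributes once per distinct label; percentages are over the
    total number of TSSs (multi-labels make them sum past 100)."""
    counts = {c: 0 for c in CATEGORIES}
    overlap = {a: {b: 0 for b in CATEGORIES} for a in CATEGORIES}
    for rec in records:
        labs = set(rec.categories)
        for lab in labs:
            counts[lab] += 1
        for a in labs:
            for b in labs:
                if a != b:
                    overlap[a][b] += 1
    total = len(records)
    percentages = {c: (100.0 * counts[c] / total if total else 0.0)
                   for c in CATEGORIES}
    return {"total": total, "counts": counts, "percentages": percentages,
            "overlap": overlap}
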