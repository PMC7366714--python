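"""Independent reference implementations used as test oracles.

These deliberately re-derive results with plain, literal loops (no shared
code with the package's implementations beyond the data types) so that the
fast implementations can be checked against them.
"""

from __future__ import annotations

from drnamap.model import FORWARD, REVERSE, PipelineParams

# ---------------------------------------------------------------------------
# Folding: exhaustive enumeration of nested structures (n <= ~16)

_PAIRS = {("G", "C"): -3.0, ("C", "G"): -3.0,
          ("A", "U"): -2.0, ("U", "A"): -2.0,
          ("G", "U"): -1.0, ("U", "G"): -1.0}
_HAIRPIN = 4.0
_MIN_LOOP = 3


def fold_energy_bruteforce(sequence: str) -> float:
    """MFE by enumerating every nested structure explicitly."""
    seq = sequence.upper().replace("T", "U")
    best = [0.0]

    def energy(pairs):
        e = 0.0
        for (i, j) in pairs:
            e += _PAIRS[(seq[i], seq[j])]
            if not any(i < a and b < j for (a, b) in pairs if (a, b) != (i, j)):
                e += _HAIRPIN
        return e

    def rec(regions, pairs):
        # regions: list of independent index lists still to structure
        if not regions:
            best[0] = min(best[0], energy(pairs))
            return
        region = regions[0]
        rest = regions[1:]
        if not region:
            rec(rest, pairs)
            return
        i = region[0]
        rec([region[1:]] + rest, pairs)            # i unpaired
        for j in region[1:]:
            if (seq[i], seq[j]) in _PAIRS and j - i - 1 >= _MIN_LOOP:
                inside = [x for x in region[1:] if x < j]
                outside = [x for x in region[1:] if x > j]
                rec([inside, outside] + rest, pairs + [(i, j)])

    rec([list(range(len(seq)))], [])
    return best[0]


# ---------------------------------------------------------------------------
# TSS classification: literal rule evaluation

def classify_bruteforce(tss_list, genes, params: PipelineParams):
    """tss_list: [(position, strand, step_height)]; returns a list of label
    sets, evaluating every (TSS, gene, rule) combination literally."""
    n = len(tss_list)
    labels = [set() for _ in range(n)]

    def dist(pos, gene):
        if gene.strand == FORWARD:
            return gene.start - pos
        return pos - (gene.end - 1)

    # window occupancy per gene
    occupants = {}
    for g in genes:
        occ = []
        for i, (pos, strand, h) in enumerate(tss_list):
            if strand == g.strand and 0 <= dist(pos, g) < params.window_upstream:
                occ.append(i)
        if occ:
            occupants[g.gene_id] = occ
    gene_by_id = {g.gene_id: g for g in genes}

    # primary assignment: every gene wants its strongest occupant; a TSS is
    # primary for at most one gene; contested TSSs go to the nearer start and
    # the loser re-proposes among what remains.
    primary = {}
    claimed = {}
    remaining = dict(occupants)
    while True:
        wants = {}
        for gid, occ in remaining.items():
            free = [i for i in occ if i not in claimed]
            if not free:
                continue
            best = None
            for i in free:
                key = (-tss_list[i][2], dist(tss_list[i][0], gene_by_id[gid]))
                if best is None or key < best[0]:
                    best = (key, i)
            wants.setdefault(best[1], []).append(gid)
        if not wants:
            break
        for i, gids in wants.items():
            winner = None
            for gid in gids:
                key = (dist(tss_list[i][0], gene_by_id[gid]), gid)
                if winner is None or key < winner[0]:
                    winner = (key, gid)
            claimed[i] = winner[1]
            primary[winner[1]] = i
            del remaining[winner[1]]
    for gid, i in primary.items():
        labels[i].add("primary")

    primary_tss = set(primary.values())
    for g in genes:
        for i in occupants.get(g.gene_id, []):
            if i not in primary_tss:
                labels[i].add("secondary")
        for i, (pos, strand, h) in enumerate(tss_list):
            if strand == g.strand and g.start <= pos < g.end:
                labels[i].add("internal")
            if strand != g.strand and \
                    g.start - params.antisense_flank <= pos < g.end + params.antisense_flank:
                labels[i].add("antisense")
    for lab in labels:
        if not lab:
            lab.add("orphan")
    return labels


# ---------------------------------------------------------------------------
# sRNA gate predicates, re-verified literally per accepted candidate


def srna_predicate_violations(candidates, ctx, params: PipelineParams):
    """Check every accepted sRNA candidate against its own class gates,
    re-deriving each predicate directly from the context.  Returns a list of
    (candidate, message) violations."""
    import numpy as np

    from drnamap.folding import fold_energy

    problems = []
    for c in candidates:
        def bad(msg):
            problems.append((c, msg))

        length = c.end - c.start
        if not (params.srna_len_min <= length <= params.srna_len_max):
            bad("length outside 30-500")
        env = ctx.envelope[c.strand]
        cov = float(np.asarray(env[c.start:c.end]).sum()) / length
        if cov < params.min_avg_coverage:
            bad("mean coverage below floor")
        p5 = c.start if c.strand == FORWARD else c.end - 1
        p3 = c.end - 1 if c.strand == FORWARD else c.start
        tol = params.tss_assoc_tol
        has_tss = any(t.strand == c.strand and abs(t.position - p5) <= tol
                      for t in ctx.tss_records)
        has_ps5 = any(p.strand == c.strand and abs(p.position - p5) <= tol
                      for p in ctx.processing_sites)
        has_ps3 = any(p.strand == c.strand and abs(p.position - p3) <= tol
                      for p in ctx.processing_sites)
        sense = [g for g in ctx.genes if g.strand == c.strand
                 and g.start < c.end and c.start < g.end]
        anti = [g for g in ctx.genes if g.strand != c.strand
                and g.start < c.end and c.start < g.end]
        seq = ctx.genome.subseq(c.start, c.end, c.strand)
        norm = fold_energy(seq, backend=ctx.fold_backend) / length

        if c.srna_class in ("intergenic", "cis_antisense"):
            if not has_tss:
                bad("no TSS at 5' end")
            if not norm < params.norm_energy_max:
                bad("fails folding gate")
            if c.srna_class == "intergenic" and (sense or anti):
                bad("intergenic candidate overlaps a gene")
            if c.srna_class == "cis_antisense" and not anti:
                bad("cis-antisense without antisense overlap")
            if c.srna_class == "cis_antisense" and sense:
                bad("cis-antisense overlaps sense gene")
        elif c.srna_class in ("utr5_derived", "intra_operonic"):
            if not (has_tss or has_ps5):
                bad("no 5' site")
            w = params.srna_drop_window
            if c.strand == FORWARD:
                up = np.asarray(env[max(p3 + 1 - w, 0):p3 + 1]).mean()
                dn = np.asarray(env[p3 + 1:p3 + 1 + w]).mean()
            else:
                up = np.asarray(env[p3:p3 + w]).mean()
                dn = np.asarray(env[max(p3 - w, 0):p3]).mean()
            drop = (up >= params.min_avg_coverage
                    and dn <= params.drop_ratio_max * up)
            if not (has_ps3 or drop):
                bad("no 3' boundary evidence (processing site or drop)")
        elif c.srna_class == "utr3_derived":
            if not (has_tss or has_ps5):
                bad("no 5' site")
            edge = c.end if c.strand == FORWARD else c.start
            near_term = any(t.strand == c.strand
                            and abs(t.three_prime_end - edge) <= params.term_dist
                            for t in ctx.terminators)
            if not (has_ps3 or near_term):
                bad("no shared 3' end evidence")
        if c.high_confidence:
            if c.srna_class != "intergenic":
                bad("high-confidence outside intergenic class")
            edge = c.end if c.strand == FORWARD else c.start
            near = any(t.strand == c.strand
                       and abs(t.three_prime_end - edge) <= params.term_dist
                       for t in ctx.terminators)
            if not near:
                bad("high-confidence without nearby terminator")
            if not has_tss:
                bad("high-confidence without TSS")
            if cov < params.min_avg_coverage:
                bad("high-confidence below coverage floor")
    return problems


# ---------------------------------------------------------------------------
# Canonical, mirror-invariant views of pipeline outputs


def canonical_outputs(result, length: int, mirrored: bool) -> dict:
    """Map every output record to strand-mirror-canonical tuples so a run on
    the reverse-complemented dataset can be compared field-for-field with
    the original."""

    def pos(p):
        return length - 1 - p if mirrored else p

    def iv(a, b):
        return (length - b, length - a) if mirrored else (a, b)

    def flip(s):
        if not mirrored:
            return s
        return REVERSE if s == FORWARD else FORWARD

    def gene_order(ids):
        # gene lists are coordinate-ordered, so mirroring reverses them
        return tuple(reversed(ids)) if mirrored else tuple(ids)

    out = {}
    out["tss"] = sorted(
        (pos(r.position), flip(r.strand), r.detected_in, r.categories,
         r.gene_associations, r.step_height, r.step_factor,
         r.enrichment_factor)
        for r in result.tss_records)
    out["processing_sites"] = sorted(
        (pos(r.position), flip(r.strand), r.detected_in, r.step_height)
        for r in result.processing_sites)
    out["terminators"] = sorted(
        (*iv(r.stem5_start, r.stem3_end), flip(r.strand), r.stem_length,
         r.loop_length, r.hairpin_score, r.u_tail_count,
         r.coverage_supported)
        for r in result.terminators)
    out["utrs"] = sorted(
        (u.gene_id, u.utr_length, u.leaderless, u.long_utr)
        for u in result.utrs)
    out["transcripts"] = sorted(
        (*iv(t.start, t.end), flip(t.strand), t.end_kind,
         gene_order(t.gene_ids))
        for t in result.transcripts)
    out["operons"] = sorted(
        (*iv(o.start, o.end), flip(o.strand), gene_order(o.gene_ids))
        for o in result.operons)
    out["srnas"] = sorted(
        (*iv(s.start, s.end), flip(s.strand), s.srna_class, s.has_tss,
         s.has_terminator, s.high_confidence, s.fold_energy, s.avg_coverage)
        for s in result.srnas)
    out["motif_hits"] = sorted(
        (pos(h.tss_position), flip(h.strand), h.motif_name, h.box1_offset,
         h.box2_offset, h.mismatches1, h.mismatches2, h.partial)
        for h in result.motif_hits)
    return out
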