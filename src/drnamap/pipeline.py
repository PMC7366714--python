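"""End-to-end orchestration and the run summary report.

``run_pipeline`` wires the stages together on in-memory objects:
TSS/processing-site calling per condition, cross-condition consolidation,
category classification, terminator scanning and coverage confirmation,
5' UTR / transcript / operon inference, sORF scanning in long leaders,
five-class sRNA discovery, promoter-motif scanning, and expression
summaries.  ``summarize_run`` turns the result into a structured report,
including a planted-vs-recovered section when a synthetic truth registry
is supplied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import classify as C
from . import expression as E
from . import promoters as P
from . import srna as S
from . import terminators as T
from . import transcripts as X
from . import tss as D
from .model import (FORWARD, REVERSE, STRANDS, TEX_MINUS, CoverageSet,
                    GeneFeature, GenomeSequence, PipelineParams,
                    sigma_abfr_motif)


@dataclass
class PipelineResult:
    params: PipelineParams
    conditions: tuple
    tss_candidates: dict            # condition -> [TssCandidate]
    processing_candidates: dict     # condition -> [ProcessingSite]
    tss_records: list               # classified TssRecords
    processing_sites: list          # merged PsRecords
    category_summary: dict
    initiating_nucleotides: dict
    terminators: list
    utrs: list
    utr_summary: dict
    transcripts: list
    operons: list
    sorfs: list
    srnas: list
    srna_rejections: list
    gc_by_class: dict
    motif_hits: list
    motif_frequencies: dict
    expression: object              # rpkm DataFrame (condition means)
    envelope: dict                  # strand -> raw coverage envelope


def coverage_envelope(cov: CoverageSet) -> Dict[str, np.ndarray]:
    """Per-strand, per-position max over conditions of the replicate-mean
    untreated total coverage, kept on the raw-read scale."""
    return {s: cov.expression_envelope(s, TEX_MINUS) for s in STRANDS}


def run_pipeline(genome: GenomeSequence, genes: Sequence[GeneFeature],
                 cov: CoverageSet, params: Optional[PipelineParams] = None,
                 motifs=None, fold_backend="reference") -> PipelineResult:
    params = params or PipelineParams()
    params.validate()
    if motifs is None:
        motifs = [sigma_abfr_motif(params.max_mismatches, params.spacer_at_min)]
    conditions = tuple(cov.conditions)

    norm = D.normalize_per_million(cov)
    tss_candidates = {c: D.call_tss_candidates(norm, params, c)
                      for c in conditions}
    ps_candidates = {c: D.call_processing_sites(norm, params, c)
                     for c in conditions}
    records = D.merge_conditions(tss_candidates.values(), params, cov.length)
    ps_records = D.merge_processing_sites(ps_candidates.values(), params,
                                          cov.length)
    records = C.classify_tss(records, genes, params)
    cat_summary = C.category_summary(records)
    init_stats = D.initiating_nucleotide_stats(records, genome)

    terms = T.scan_intrinsic_terminators(genome, params)
    terms = T.confirm_by_coverage(terms, cov, params)

    env = coverage_envelope(cov)
    utrs = X.infer_5utrs(records, genes, params)
    transcripts = X.assemble_transcripts(records, terms, env, genes, params)
    operons = X.assemble_operons(transcripts, genes)
    long_utr_regions = []
    gene_by_id = {g.gene_id: g for g in genes}
    for u in utrs:
        if u.long_utr:
            g = gene_by_id[u.gene_id]
            if g.strand == FORWARD:
                long_utr_regions.append((u.tss_position, g.start, FORWARD))
            else:
                long_utr_regions.append((g.end, u.tss_position + 1, REVERSE))
    sorfs = X.find_sorfs(long_utr_regions, genome, params)

    ctx = S.SrnaContext(genome=genome, genes=genes, tss_records=records,
                        processing_sites=ps_records, terminators=terms,
                        operons=operons, transcripts=transcripts,
                        envelope=env, fold_backend=fold_backend)
    srnas, rejections = S.discover_srnas(ctx, params)

    gc_features: Dict[str, list] = {"CDS": [(g.start, g.end) for g in genes]}
    for s in srnas:
        gc_features.setdefault(s.srna_class, []).append((s.start, s.end))
    hc = [(s.start, s.end) for s in srnas if s.high_confidence]
    if hc:
        gc_features["intergenic_high_confidence"] = hc
    gc_stats = S.gc_content_by_class(gc_features, genome)

    hits = P.scan_promoters(records, genome, motifs, params)
    freqs = P.motif_frequency_by_category(hits, records)

    feats = {}
    for g in genes:
        feats[g.gene_id] = (g.start, g.end, g.strand)
    for i, s in enumerate(srnas, 1):
        feats[f"srna_{i:03d}"] = (s.start, s.end, s.strand)
    expr = E.expression_matrix(feats, cov) if cov.total else None

    return PipelineResult(
        params=params, conditions=conditions,
        tss_candidates=tss_candidates, processing_candidates=ps_candidates,
        tss_records=records, processing_sites=ps_records,
        category_summary=cat_summary, initiating_nucleotides=init_stats,
        terminators=terms, utrs=utrs, utr_summary=X.utr_summary(utrs),
        transcripts=transcripts, operons=operons, sorfs=sorfs,
        srnas=srnas, srna_rejections=rejections, gc_by_class=gc_stats,
        motif_hits=hits, motif_frequencies=freqs, expression=expr,
        envelope=env,
    )


# ---------------------------------------------------------------------------
# Recovery against a planted truth registry


def _match_points(planted, called, tol: int):
    called_set = {(p, s) for p, s in called}
    tp = 0
    for pos, strand in planted:
        if any((pos + d, strand) in called_set for d in range(-tol, tol + 1)):
            tp += 1
    planted_set = {(p, s) for p, s in planted}
    fp = 0
    for pos, strand in called:
        if not any((pos + d, strand) in planted_set for d in range(-tol, tol + 1)):
            fp += 1
    sens = tp / len(planted) if planted else float("nan")
    prec = (len(called) - fp) / len(called) if called else float("nan")
    return {"n_planted": len(planted), "n_called": len(called),
            "sensitivity": sens, "precision": prec}


def recovery_report(result: PipelineResult, truth, tol: int = 1) -> dict:
    """Sensitivity/precision per feature type against a SyntheticTruth."""
    out = {}
    out["tss"] = _match_points(
        [(t.position, t.strand) for t in truth.tss],
        [(r.position, r.strand) for r in result.tss_records], tol)
    out["processing_sites"] = _match_points(
        [(p.position, p.strand) for p in truth.processing_sites],
        [(r.position, r.strand) for r in result.processing_sites], tol)

    term_tol = 5
    calls = result.terminators
    rec = sum(
        1 for t in truth.terminators
        if any(c.strand == t.strand
               and abs(c.stem5_start - t.stem5_start) <= term_tol
               and abs(c.stem3_end - t.stem3_end) <= term_tol for c in calls)
    )
    out["terminators"] = {"n_planted": len(truth.terminators),
                          "n_called": len(calls),
                          "recall": rec / len(truth.terminators)
                          if truth.terminators else float("nan")}

    # sRNA class recovery: a planted sRNA is recovered when an accepted
    # candidate of the planted class overlaps it by >= 50% of its length.
    real = truth.real_srnas
    correct = 0
    for p in real:
        for c in result.srnas:
            if c.strand != p.strand:
                continue
            ov = min(c.end, p.end) - max(c.start, p.start)
            if ov >= 0.5 * (p.end - p.start) and c.srna_class == p.srna_class:
                correct += 1
                break
    decoys = truth.decoys
    rejected = 0
    for d in decoys:
        for r in result.srna_rejections:
            if r.strand == d.strand and r.reason == "folding":
                ov = min(r.end, d.end) - max(r.start, d.start)
                if ov >= 0.5 * (d.end - d.start):
                    rejected += 1
                    break
    out["srnas"] = {
        "n_planted": len(real),
        "class_accuracy": correct / len(real) if real else float("nan"),
        "n_decoys": len(decoys),
        "decoy_rejection": rejected / len(decoys) if decoys else float("nan"),
    }

    # UTR exactness over recovered primary TSSs
    planted_utr = {u.gene_id: u.utr_length for u in truth.utrs}
    exact = total = 0
    for u in result.utrs:
        if u.gene_id in planted_utr:
            total += 1
            if u.utr_length == planted_utr[u.gene_id]:
                exact += 1
    out["utrs"] = {"n_compared": total,
                   "exact_fraction": exact / total if total else float("nan")}

    # promoter recovery among primary TSSs
    planted_prom = {(p.tss_position, p.strand) for p in truth.promoters}
    primaries = [r for r in result.tss_records if "primary" in r.categories]
    with_hit = {(h.tss_position, h.strand) for h in result.motif_hits
                if not h.partial}
    if primaries:
        frac = sum(1 for r in primaries
                   if (r.position, r.strand) in with_hit) / len(primaries)
        planted_frac = sum(
            1 for t in truth.tss if t.category == "primary" and t.has_promoter
        ) / max(sum(1 for t in truth.tss if t.category == "primary"), 1)
        out["promoters"] = {"primary_with_motif": frac,
                            "planted_primary_fraction": planted_frac}
    return out


# ---------------------------------------------------------------------------
# Report rendering


def summarize_run(result: PipelineResult, truth=None) -> dict:
    """The pipeline-wide summary report as a nested plain-data dict."""
    report = {
        "conditions": list(result.conditions),
        "tss": {
            "total": result.category_summary["total"],
            "per_condition": {c: len(v) for c, v in
                              result.tss_candidates.items()},
            "detected_in_all": sum(
                1 for r in result.tss_records
                if set(result.conditions) <= set(r.detected_in)),
            "category_counts": result.category_summary["counts"],
            "category_percentages": result.category_summary["percentages"],
            "initiating_nucleotides": result.initiating_nucleotides,
        },
        "processing_sites": {"total": len(result.processing_sites)},
        "utr5": result.utr_summary,
        "transcripts": {
            "n": len(result.transcripts),
            "min_length": min((t.length for t in result.transcripts),
                              default=0),
            "max_length": max((t.length for t in result.transcripts),
                              default=0),
        },
        "operons": {"n": len(result.operons),
                    "polycistronic": sum(1 for o in result.operons
                                         if len(o.gene_ids) > 1)},
        "terminators": {
            "n": len(result.terminators),
            "coverage_supported": sum(1 for t in result.terminators
                                      if t.coverage_supported),
        },
        "sorfs": {"n": len(result.sorfs)},
        "srnas": {
            "total": len(result.srnas),
            "by_class": {cls: sum(1 for s in result.srnas
                                  if s.srna_class == cls)
                         for cls in ("intergenic", "cis_antisense",
                                     "utr5_derived", "utr3_derived",
                                     "intra_operonic")},
            "high_confidence": sum(1 for s in result.srnas
                                   if s.high_confidence),
            "rejections": len(result.srna_rejections),
        },
        "gc_by_class": result.gc_by_class,
        "motif_frequencies": result.motif_frequencies,
    }
    if truth is not None:
        report["recovery"] = recovery_report(result, truth)
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of the summary report."""
    lines = []

    def emit(obj, indent=0):
        pad = "  " * indent
        if isinstance(obj, dict):
            for k, v in obj.items():
                if isinstance(v, (dict, list)) and v and not _scalar_list(v):
                    lines.append(f"{pad}{k}:")
                    emit(v, indent + 1)
                else:
                    lines.append(f"{pad}{k}: {_fmt(v)}")
        elif isinstance(obj, list):
            for v in obj:
                lines.append(f"{pad}- {_fmt(v)}")

    def _scalar_list(v):
        return isinstance(v, list) and all(
            not isinstance(x, (dict, list)) for x in v)

    def _fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    emit(report)
    return "\n".join(lines) + "\n"


def write_report(result: PipelineResult, directory, truth=None) -> dict:
    """Write the full set of output tables and the summary report."""
    import json
    from pathlib import Path

    from . import io as dio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    dio.write_records_tsv(result.tss_records, d / "tss.tsv")
    dio.write_records_tsv(result.processing_sites, d / "processing_sites.tsv")
    dio.write_records_tsv(result.terminators, d / "terminators.tsv")
    dio.write_records_tsv(result.utrs, d / "utr5.tsv")
    dio.write_records_tsv(result.transcripts, d / "transcripts.tsv")
    dio.write_records_tsv(result.operons, d / "operons.tsv")
    dio.write_records_tsv(result.sorfs, d / "sorfs.tsv")
    dio.write_records_tsv(result.srnas, d / "srnas.tsv")
    dio.write_records_tsv(result.srna_rejections, d / "srna_rejections.tsv")
    dio.write_records_tsv(result.motif_hits, d / "motif_hits.tsv")
    for name, records in (("tss", result.tss_records),
                          ("terminators", result.terminators),
                          ("srnas", result.srnas)):
        dio.write_features_gff3(records, d / f"{name}.gff3")
    if result.expression is not None:
        result.expression.to_csv(d / "expression_rpkm.tsv", sep="\t")
    report = summarize_run(result, truth)
    (d / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (d / "report.txt").write_text(report_to_text(report))
    return report
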