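"""Readers and writers for FASTA, GFF3, wiggle/bedGraph tracks and TSV tables.

Coordinate conventions: everything internal is 0-based half-open; GFF3 is
written and read as 1-based inclusive; bedGraph is 0-based half-open;
variableStep/fixedStep wiggle is 1-based.  Minus-strand wiggle tracks in
either the negative-value or positive-value dialect are accepted and stored
as magnitudes.
"""

from __future__ import annotations

import dataclasses
import typing
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (FORWARD, REVERSE, CoverageSet, FormatError, GeneFeature,
                    GenomeSequence, OperonRecord, PsRecord, SorfCandidate,
                    SrnaCandidate, TerminatorRecord, TranscriptRecord,
                    TssRecord, UtrRecord)

# ---------------------------------------------------------------------------
# FASTA


def read_genome(path) -> list:
    """Read a FASTA file into a list of :class:`GenomeSequence`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_genome_fasta(genomes: Iterable[GenomeSequence], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.replicon_id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotation

_DEFAULT_KINDS = ("CDS", "rRNA", "tRNA")


def _parse_gff3_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _iter_gff3_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            yield lineno, cols


def read_annotation(path, kinds: Sequence[str] = _DEFAULT_KINDS) -> list:
    """Read gene features from GFF3 (1-based inclusive in the file) into
    internal 0-based half-open :class:`GeneFeature` objects."""
    import gffutils

    # gffutils silently tolerates end < start; validate the raw rows first
    # so a malformed file fails with a position-naming error.
    n_rows = 0
    for lineno, cols in _iter_gff3_rows(path):
        n_rows += 1
        if int(cols[4]) < int(cols[3]):
            raise FormatError(f"{path}:{lineno}: end {cols[4]} < start {cols[3]}")
    if n_rows == 0:
        return []

    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique")
    known = ("CDS", "rRNA", "tRNA")
    genes = []
    seen = set()
    auto = 0
    for feat in db.all_features(order_by=("seqid", "start")):
        if kinds is not None and feat.featuretype not in kinds:
            continue
        gene_id = (feat.attributes.get("ID", [None])[0]
                   or feat.attributes.get("locus_tag", [None])[0]
                   or feat.attributes.get("Name", [None])[0])
        if gene_id is None:
            auto += 1
            gene_id = f"feature_{auto}"
        if (feat.seqid, gene_id) in seen:
            raise FormatError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add((feat.seqid, gene_id))
        kind = feat.featuretype if feat.featuretype in known else "other"
        genes.append(GeneFeature(gene_id=gene_id, replicon_id=feat.seqid,
                                 start=feat.start - 1, end=feat.end,
                                 strand=feat.strand, feature_kind=kind))
    return genes


def write_annotation_gff3(genes: Iterable[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.replicon_id, "drnamap", g.feature_kind,
                str(g.start + 1), str(g.end), ".", g.strand, ".",
                f"ID={g.gene_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Coverage tracks (wiggle / bedGraph) and the track manifest

MANIFEST_COLUMNS = ("file", "condition", "replicate", "library", "strand",
                    "track_kind", "library_size")


def _parse_wiggle(path, lengths: Mapping[str, int]) -> dict:
    """Parse variableStep/fixedStep wiggle into dense per-replicon arrays."""
    arrays = {}
    mode = None
    chrom = None
    step = span = 1
    nxt = 0  # next 0-based position for fixedStep
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("variableStep") or line.startswith("fixedStep"):
                fields = dict(p.split("=", 1) for p in line.split()[1:])
                chrom = fields["chrom"]
                if chrom not in lengths:
                    raise FormatError(f"{path}:{lineno}: unknown replicon {chrom!r}")
                arrays.setdefault(chrom, np.zeros(lengths[chrom], dtype=float))
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    nxt = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before step declaration")
            parts = line.split()
            if mode == "variable":
                pos0 = int(parts[0]) - 1
                value = abs(float(parts[1]))
            else:
                pos0 = nxt
                nxt += step
                value = abs(float(parts[0]))
            if pos0 < 0 or pos0 + span > lengths[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: position {pos0 + 1} (span {span}) outside "
                    f"replicon {chrom!r} of length {lengths[chrom]}"
                )
            arrays[chrom][pos0:pos0 + span] = value
    return arrays


def _parse_bedgraph(path, lengths: Mapping[str, int]) -> dict:
    arrays = {}
    covered = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), abs(float(parts[3]))
            if chrom not in lengths:
                raise FormatError(f"{path}:{lineno}: unknown replicon {chrom!r}")
            if start < 0 or end > lengths[chrom] or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) outside replicon "
                    f"{chrom!r} of length {lengths[chrom]}"
                )
            arrays.setdefault(chrom, np.zeros(lengths[chrom], dtype=float))
            mask = covered.setdefault(chrom, np.zeros(lengths[chrom], dtype=bool))
            if mask[start:end].any():
                raise FormatError(f"{path}:{lineno}: overlapping bedGraph intervals")
            mask[start:end] = True
            arrays[chrom][start:end] = value
    return arrays


def read_track(path, lengths: Mapping[str, int]) -> dict:
    """Read a coverage track file, auto-detecting wiggle vs bedGraph."""
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("track", "#", "browser")):
                continue
            if s.startswith(("variableStep", "fixedStep")):
                return _parse_wiggle(path, lengths)
            return _parse_bedgraph(path, lengths)
    # empty file: all-zero everywhere
    return {c: np.zeros(n, dtype=float) for c, n in lengths.items()}


def write_wiggle(array: np.ndarray, path, replicon_id: str, *,
                 append: bool = False) -> None:
    """Write a dense array as variableStep wiggle (1-based, zeros omitted)."""
    mode = "a" if append else "w"
    arr = np.asarray(array)
    with open(path, mode) as fh:
        fh.write(f"variableStep chrom={replicon_id}\n")
        nz = np.nonzero(arr)[0]
        for i in nz:
            v = arr[i]
            fh.write(f"{i + 1} {int(v) if float(v).is_integer() else v}\n")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    df["replicate"] = df["replicate"].astype(int)
    df["library_size"] = df["library_size"].astype(int)
    return df


def read_coverage(manifest, base_dir=None, *, genomes=None, lengths=None) -> dict:
    """Read all coverage tracks named in a manifest.

    ``manifest`` is a path to a TSV with columns ``file condition replicate
    library strand track_kind library_size`` or an equivalent DataFrame.
    Returns ``{replicon_id: CoverageSet}`` with raw (unnormalized) tracks.
    """
    if lengths is None:
        if genomes is None:
            raise ValueError("need genomes or lengths")
        lengths = {g.replicon_id: len(g) for g in genomes}
    if not isinstance(manifest, pd.DataFrame):
        base_dir = base_dir or Path(manifest).parent
        manifest = read_manifest(manifest)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    out = {rid: CoverageSet(replicon_id=rid, length=n) for rid, n in lengths.items()}
    for row in manifest.itertuples(index=False):
        arrays = read_track(base_dir / row.file, lengths)
        key = (row.condition, int(row.replicate), row.library, row.strand)
        for rid, arr in arrays.items():
            cov = out[rid]
            target = cov.fiveprime if row.track_kind == "fiveprime" else cov.total
            if row.track_kind not in ("fiveprime", "total"):
                raise FormatError(f"unknown track_kind {row.track_kind!r}")
            target[key] = np.rint(arr).astype(np.int64)
            cov.library_sizes[(row.condition, int(row.replicate), row.library)] = \
                int(row.library_size)
    for cov in out.values():
        cov.validate()
    return out


# ---------------------------------------------------------------------------
# Generic record <-> GFF3 / TSV round-tripping

_GFF3_TYPES = {
    TssRecord: "TSS",
    PsRecord: "processing_site",
    TerminatorRecord: "terminator",
    UtrRecord: "five_prime_UTR",
    TranscriptRecord: "transcript",
    OperonRecord: "operon",
    SorfCandidate: "sORF",
    SrnaCandidate: "ncRNA",
}
_TYPE_TO_CLS = {v: k for k, v in _GFF3_TYPES.items()}


def _record_interval(rec) -> tuple:
    """(start, end) 0-based half-open for any record type."""
    if isinstance(rec, (TssRecord, PsRecord)):
        return rec.position, rec.position + 1
    if isinstance(rec, TerminatorRecord):
        return rec.stem5_start, rec.stem3_end
    if isinstance(rec, UtrRecord):
        if rec.strand == FORWARD:
            return rec.tss_position, rec.tss_position + max(rec.utr_length, 1)
        return rec.tss_position + 1 - max(rec.utr_length, 1), rec.tss_position + 1
    return rec.start, rec.end


def _field_to_str(value) -> str:
    if isinstance(value, tuple):
        return ",".join(_field_to_str(v) for v in value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _coerce(value: str, hint):
    origin = typing.get_origin(hint)
    if origin in (tuple, typing.Tuple) or hint is tuple:
        if value == "":
            return ()
        args = typing.get_args(hint)
        parts = value.split(",")
        if args and args[0] is not Ellipsis and args[0] is not str:
            return tuple(_coerce(p, args[0]) for p in parts)

        def auto(p):
            for conv in (int, float):
                try:
                    return conv(p)
                except ValueError:
                    continue
            return p
        if not args:
            return tuple(auto(p) for p in parts)
        return tuple(parts)
    if hint is int:
        return int(value)
    if hint is float:
        return float(value)
    if hint is bool:
        return value == "True"
    return value


def _record_hints(cls) -> dict:
    hints = typing.get_type_hints(cls)
    return {f.name: hints.get(f.name, str) for f in dataclasses.fields(cls)}


def record_to_gff3_row(rec, score: str = ".") -> str:
    start, end = _record_interval(rec)
    ftype = _GFF3_TYPES[type(rec)]
    skip = {"start", "end"}
    attrs = []
    for f in dataclasses.fields(rec):
        if f.name in skip:
            continue
        attrs.append(f"{f.name}={_field_to_str(getattr(rec, f.name))}")
    replicon = getattr(rec, "replicon_id")
    strand = getattr(rec, "strand", ".")
    return "\t".join([replicon, "drnamap", ftype, str(start + 1), str(end),
                      score, strand, ".", ";".join(attrs)])


def write_features_gff3(records: Iterable, path, lengths: Optional[Mapping[str, int]] = None) -> None:
    """Export result records as GFF3 (1-based inclusive), category/class and
    scores in the attribute column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            start, end = _record_interval(rec)
            if lengths is not None:
                n = lengths[rec.replicon_id]
                if start < 0 or end > n:
                    raise ValueError(
                        f"record interval [{start},{end}) outside replicon "
                        f"{rec.replicon_id!r} of length {n}"
                    )
            fh.write(record_to_gff3_row(rec) + "\n")


def read_features_gff3(path) -> list:
    """Read back a feature GFF3 written by :func:`write_features_gff3`."""
    records = []
    for lineno, cols in _iter_gff3_rows(path):
        seqid, _src, ftype, start, end, _score, strand, _phase, attr = cols
        cls = _TYPE_TO_CLS.get(ftype)
        if cls is None:
            continue
        attrs = _parse_gff3_attributes(attr)
        hints = _record_hints(cls)
        kwargs = {}
        for name, hint in hints.items():
            if name in attrs:
                kwargs[name] = _coerce(attrs[name], hint)
        if "start" in hints and "start" not in kwargs:
            kwargs["start"] = int(start) - 1
        if "end" in hints and "end" not in kwargs:
            kwargs["end"] = int(end)
        records.append(cls(**kwargs))
    return records


def records_to_frame(records: Sequence) -> pd.DataFrame:
    if not records:
        return pd.DataFrame()
    cls = type(records[0])
    cols = [f.name for f in dataclasses.fields(cls)]
    return pd.DataFrame(
        [{c: _field_to_str(getattr(r, c)) for c in cols} for r in records],
        columns=cols,
    )


def write_records_tsv(records: Sequence, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path, cls) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    hints = _record_hints(cls)
    out = []
    for row in df.itertuples(index=False):
        kwargs = {name: _coerce(getattr(row, name), hint)
                  for name, hint in hints.items() if hasattr(row, name)}
        out.append(cls(**kwargs))
    return out
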