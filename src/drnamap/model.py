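"""Domain types and coordinate conventions.

All internal coordinates are 0-based half-open intervals on the forward
(reference) strand, with the strand stored explicitly.  Point features
(TSSs, processing sites) store the genomic index of the +1 nucleotide,
i.e. the first transcribed base.  Exports to GFF3 are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional

import numpy as np

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

TEX_PLUS = "TEX+"
TEX_MINUS = "TEX-"
LIBRARIES = (TEX_PLUS, TEX_MINUS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def other_strand(strand: str) -> str:
    return REVERSE if strand == FORWARD else FORWARD


@dataclass(frozen=True)
class GenomeSequence:
    """A single replicon: uppercase A/C/G/T sequence (N tolerated)."""

    replicon_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"replicon {self.replicon_id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"replicon {self.replicon_id!r}: non-nucleotide character "
                f"{self.sequence[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = FORWARD) -> str:
        """Strand-aware subsequence; reverse-complemented on the - strand."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise ValueError(
                f"interval [{start},{end}) outside replicon "
                f"{self.replicon_id!r} of length {len(self.sequence)}"
            )
        s = self.sequence[start:end]
        return revcomp(s) if strand == REVERSE else s

    def gc_fraction(self, start: int = 0, end: Optional[int] = None) -> float:
        """(G+C)/(A+C+G+T) over the interval; N excluded from the denominator."""
        s = self.sequence[start: end if end is not None else len(self.sequence)]
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        return (s.count("G") + s.count("C")) / acgt


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    feature_kind: str = "CDS"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def tss_proximal_edge(self) -> int:
        """Genomic index of the first base of the gene in reading direction."""
        return self.start if self.strand == FORWARD else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Coverage container

TrackKey = tuple  # (condition, replicate, library, strand)


@dataclass
class CoverageSet:
    """Per-nucleotide 5'-end counts and total read coverage.

    Tracks are keyed by (condition, replicate, library, strand).  Raw tracks
    are integer arrays; after :func:`drnamap.tss.normalize_per_million` they
    are float arrays in reads-per-million units and ``normalized`` is set.
    """

    replicon_id: str
    length: int
    fiveprime: dict = field(default_factory=dict)
    total: dict = field(default_factory=dict)
    library_sizes: dict = field(default_factory=dict)  # (cond, rep, lib) -> int
    normalized: bool = False

    def validate(self) -> None:
        for name, tracks in (("fiveprime", self.fiveprime), ("total", self.total)):
            for key, arr in tracks.items():
                if len(arr) != self.length:
                    raise ValueError(
                        f"{name} track {key}: length {len(arr)} != replicon "
                        f"length {self.length}"
                    )
                if np.any(np.asarray(arr) < 0):
                    raise ValueError(f"{name} track {key}: negative counts")
        for key, size in self.library_sizes.items():
            if size <= 0:
                raise ValueError(f"library {key}: non-positive library size")

    @property
    def conditions(self) -> list:
        conds = {k[0] for k in self.fiveprime} | {k[0] for k in self.total}
        return sorted(conds)

    def replicates(self, condition: str) -> list:
        reps = {k[1] for k in self.fiveprime if k[0] == condition}
        reps |= {k[1] for k in self.total if k[0] == condition}
        return sorted(reps)

    def _mean_over_replicates(self, tracks: Mapping, condition: str,
                              library: str, strand: str) -> np.ndarray:
        keys = [k for k in tracks
                if k[0] == condition and k[2] == library and k[3] == strand]
        if not keys:
            raise KeyError(
                f"no track for condition={condition!r}, library={library!r}, "
                f"strand={strand!r}"
            )
        stack = np.stack([np.asarray(tracks[k], dtype=float) for k in sorted(keys)])
        return stack.mean(axis=0)

    def fiveprime_mean(self, condition: str, library: str, strand: str) -> np.ndarray:
        return self._mean_over_replicates(self.fiveprime, condition, library, strand)

    def total_mean(self, condition: str, library: str, strand: str) -> np.ndarray:
        return self._mean_over_replicates(self.total, condition, library, strand)

    def expression_envelope(self, strand: str, library: str = TEX_MINUS) -> np.ndarray:
        """Per-position max over conditions of the replicate-mean total coverage."""
        envs = [self.total_mean(c, library, strand) for c in self.conditions]
        return np.maximum.reduce(envs)


# ---------------------------------------------------------------------------
# Pipeline parameters


@dataclass
class PipelineParams:
    """All tunable thresholds of the pipeline, with field-standard defaults."""

    # TSS detection (TSSpredator-style defaults)
    window_upstream: int = 300
    antisense_flank: int = 100
    promoter_region: tuple = (-50, 1)
    enrichment_factor_min: float = 2.0
    step_factor_min: float = 2.0
    step_height_min: float = 0.3       # per-million-normalized 5' counts
    cluster_width: int = 3
    condition_merge_tolerance: int = 3
    epsilon: float = 0.1               # denominator floor, normalized counts

    # sRNA discovery
    srna_len_min: int = 30
    srna_len_max: int = 500
    norm_energy_max: float = -0.05     # kcal/mol per nt, strict less-than
    min_avg_coverage: float = 5.0      # raw reads
    tss_assoc_tol: int = 5             # nt, TSS/PS-to-candidate-end association
    term_dist: int = 20                # nt, 3' end to terminator for high confidence
    utr3_region: int = 50              # nt, "3' region" of a CDS
    srna_drop_window: int = 25         # nt, sharp-coverage-drop window

    # UTR flags
    leaderless_max: int = 10           # strict less-than
    long_utr_min: int = 100            # strict greater-than

    # terminator scanner
    stem_len_min: int = 4
    stem_len_max: int = 20
    loop_len_min: int = 3
    loop_len_max: int = 10
    hairpin_score_min: float = 19.0
    u_tail_min: int = 5
    u_tail_window: int = 8
    drop_window: int = 50
    drop_ratio_max: float = 0.5

    # transcript assembly
    transcript_window: int = 25

    # duplex scanner
    duplex_score_min: float = 6.0
    seed_min: int = 6

    # promoter scan
    max_mismatches: int = 1
    spacer_at_min: float = 0.6

    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("window_upstream", "antisense_flank", "cluster_width",
                     "condition_merge_tolerance", "stem_len_min", "stem_len_max",
                     "loop_len_min", "loop_len_max", "u_tail_window",
                     "drop_window", "transcript_window", "srna_drop_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.srna_len_min >= self.srna_len_max:
            raise ValueError("srna_len_min must be < srna_len_max")
        if self.enrichment_factor_min <= 1 or self.step_factor_min <= 1:
            raise ValueError("enrichment/step factors must be > 1")
        if self.stem_len_min > self.stem_len_max:
            raise ValueError("stem_len_min must be <= stem_len_max")
        if self.loop_len_min > self.loop_len_max:
            raise ValueError("loop_len_min must be <= loop_len_max")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


# ---------------------------------------------------------------------------
# Result records


@dataclass(frozen=True)
class TssCandidate:
    """A per-condition TSS call with its three detection statistics."""

    replicon_id: str
    position: int
    strand: str
    condition: str
    step_height: float
    step_factor: float
    enrichment_factor: float


@dataclass(frozen=True)
class ProcessingSite:
    """A 5'-end accumulation without TEX enrichment (RNA cleavage product)."""

    replicon_id: str
    position: int
    strand: str
    condition: str
    step_height: float
    step_factor: float
    enrichment_factor: float


@dataclass
class TssRecord:
    """A TSS consolidated across conditions, later carrying category labels."""

    replicon_id: str
    position: int
    strand: str
    detected_in: tuple          # sorted tuple of condition names
    step_height: float          # max across contributing candidates
    step_factor: float
    enrichment_factor: float
    categories: tuple = ()      # sorted tuple of labels
    gene_associations: tuple = ()  # sorted tuple of "label:gene_id" strings


@dataclass
class PsRecord:
    """A processing site consolidated across conditions."""

    replicon_id: str
    position: int
    strand: str
    detected_in: tuple
    step_height: float


@dataclass
class TerminatorRecord:
    replicon_id: str
    strand: str
    stem5_start: int
    loop_start: int
    loop_end: int
    stem3_end: int
    stem_length: int
    loop_length: int
    hairpin_score: float
    u_tail_count: int
    coverage_supported: bool = False
    drop_ratio: float = float("nan")
    edge_truncated: bool = False

    @property
    def start(self) -> int:
        return self.stem5_start

    @property
    def end(self) -> int:
        return self.stem3_end

    @property
    def three_prime_end(self) -> int:
        """Genomic index one past the terminator in reading direction."""
        return self.stem3_end if self.strand == FORWARD else self.stem5_start


@dataclass
class UtrRecord:
    gene_id: str
    replicon_id: str
    tss_position: int
    strand: str
    utr_length: int
    leaderless: bool
    long_utr: bool


@dataclass
class TranscriptRecord:
    replicon_id: str
    start: int
    end: int
    strand: str
    tss_position: int
    end_kind: str               # "terminator" | "falloff"
    gene_ids: tuple = ()
    low_expression: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OperonRecord:
    replicon_id: str
    strand: str
    start: int
    end: int
    gene_ids: tuple = ()


@dataclass
class SorfCandidate:
    replicon_id: str
    start: int
    end: int
    strand: str
    start_codon: str
    n_codons: int
    frame: int


SRNA_CLASSES = ("intergenic", "cis_antisense", "utr5_derived",
                "utr3_derived", "intra_operonic")


@dataclass
class SrnaCandidate:
    replicon_id: str
    start: int
    end: int
    strand: str
    srna_class: str
    has_tss: bool = False
    has_terminator: bool = False
    has_processing_5p: bool = False
    has_processing_3p: bool = False
    avg_coverage: float = 0.0
    fold_energy: float = 0.0
    norm_energy: float = 0.0
    high_confidence: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SrnaRejection:
    replicon_id: str
    start: int
    end: int
    strand: str
    reason: str


@dataclass(frozen=True)
class MotifSpec:
    """Two-box promoter motif with IUPAC consensus boxes at fixed center offsets.

    Offsets use promoter coordinates: -1 is the base immediately upstream of
    the TSS and +1 is the TSS itself (there is no position 0).  A box's
    center is its start offset plus ``(len(box) - 1) // 2``.
    """

    name: str
    box1: str
    box1_centers: tuple        # allowed center offsets, e.g. (-10 .. -4)
    box2: str
    box2_centers: tuple
    max_mismatches: int = 1
    spacer_at_min: Optional[float] = 0.6
    allow_partial: bool = False


@dataclass
class MotifHit:
    tss_position: int
    strand: str
    motif_name: str
    box1_offset: int           # promoter coordinate of box1 start
    box2_offset: int
    mismatches1: int
    mismatches2: int
    spacer_at_fraction: float
    partial: bool = False
    truncated: bool = False


@dataclass
class DuplexHit:
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    pair_string: str
    score: float
    seed_len: int


def sigma_abfr_motif(max_mismatches: int = 1, spacer_at_min: float = 0.6) -> MotifSpec:
    """The Bacteroidetes primary sigma-factor promoter: TAnnTTTG around -7
    plus TTTG around -33, separated by an AT-rich spacer."""
    return MotifSpec(
        name="sigmaABfr",
        box1="TANNTTTG", box1_centers=tuple(range(-10, -3)),
        box2="TTTG", box2_centers=tuple(range(-36, -29)),
        max_mismatches=max_mismatches,
        spacer_at_min=spacer_at_min,
        allow_partial=True,
    )


def record_fields(record_cls) -> list:
    return [f.name for f in fields(record_cls)]


__all__ = [name for name in dir() if not name.startswith("_")]
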