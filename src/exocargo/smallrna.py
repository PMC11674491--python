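"""Simplified small RNA-seq read processing and mature-miRNA quantification.

The chain mirrors a desk-scale miRNA quantification workflow: 3' adapter
trimming, read-level quality exclusion (mean Phred below Q25 drops the
read), a strict length filter (> 17 nt kept, i.e. >= 18), collapsing of
duplicate sequences, and assignment of collapsed reads to a mature-miRNA
reference by exact (or bounded-Hamming) substring matching. Reads matching
several references equally well are discarded as ambiguous and tallied.
Downstream: a consistency filter keeping miRNAs observed in every
replicate of a group, counts-per-million normalization, and ranking by
average normalized counts.

Deliberately out of scope: novel-miRNA discovery, precursor/hairpin
mapping, isomiR resolution and genome alignment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FastqRead",
    "CollapsedRead",
    "PreprocessParams",
    "QuantResult",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "trim_adapter",
    "quality_filter",
    "length_filter",
    "collapse_reads",
    "quantify",
    "process_sample",
    "build_count_matrix",
    "consistency_filter",
    "cpm_normalize",
    "rank_mirnas_top_k",
]

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33  # Phred+33 quality encoding


class FastqRead(NamedTuple):
    """A single sequencing read: identifier, bases, Phred+33 quality string."""

    id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class CollapsedRead:
    """A unique post-processing sequence with its occurrence multiplicity."""

    sequence: str
    multiplicity: int


@dataclass(frozen=True)
class PreprocessParams:
    """Read-preprocessing thresholds.

    adapter
        3' adapter sequence; trimming requires an exact match of an
        adapter prefix of at least 6 nt.
    min_quality
        Phred threshold (default 25); reads whose mean base quality falls
        below it are excluded (``quality_mode="mean"``), or whose minimum
        does (``"min"``).
    min_length_exclusive
        Reads must be strictly longer than this after trimming
        (default 17, i.e. >= 18 nt kept).
    max_mismatches_map
        Hamming mismatches tolerated when assigning reads to the mature
        reference (default 0).
    """

    adapter: str = "AGATCGGAAGAGCACACGTCT"
    min_quality: int = 25
    min_length_exclusive: int = 17
    max_mismatches_map: int = 0
    quality_mode: str = "mean"

    def __post_init__(self) -> None:
        if len(self.adapter) < 6:
            raise ValueError("adapter must be at least 6 nt")
        if self.min_quality < 0 or self.min_length_exclusive < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_mismatches_map < 0:
            raise ValueError("max_mismatches_map must be non-negative")
        if self.quality_mode not in ("mean", "min"):
            raise ValueError(f"unknown quality_mode {self.quality_mode!r}")


class QuantResult(NamedTuple):
    """Per-sample quantification outcome.

    counts
        miRNA id -> summed multiplicity of assigned reads.
    ambiguous
        Total multiplicity of reads matching >1 reference equally.
    unmatched
        Total multiplicity of reads matching no reference.
    """

    counts: dict[str, int]
    ambiguous: int
    unmatched: int


# ---------------------------------------------------------------------------
# FASTQ / FASTA IO (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[FastqRead]:
    """Read a Phred+33 FASTQ file into FastqRead records."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    """Write FastqRead records as a Phred+33 FASTQ file."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping."""
    ref = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ref:
            raise ValueError(f"duplicate reference identifier {rec.id!r}")
        ref[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not ref:
        raise ValueError(f"empty reference FASTA: {path}")
    return ref


# ---------------------------------------------------------------------------
# Read-level operations
# ---------------------------------------------------------------------------

def trim_adapter(read: FastqRead, adapter: str) -> FastqRead:
    """Truncate a read at its 3' adapter; qualities truncated in lockstep.

    The cut point is the leftmost occurrence, at or after position 1, of
    the longest adapter prefix of length >= 6 found in the read; longer
    prefixes are preferred over more-leftward shorter ones. Reads without
    any such match are returned unchanged.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    seq = read.sequence
    for plen in range(min(len(adapter), max(len(seq) - 1, 0)), 5, -1):
        pos = seq.find(adapter[:plen], 1)
        if pos != -1:
            return FastqRead(read.id, seq[:pos], read.quality[:pos])
    return read


def _phred(quality: str) -> np.ndarray:
    arr = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET
    if arr.size and (arr.min() < 0 or arr.max() > 93):
        raise ValueError("malformed Phred+33 quality string")
    return arr


def quality_filter(
    reads: Iterable[FastqRead], min_quality: int = 25, mode: str = "mean"
) -> list[FastqRead]:
    """Exclude reads whose mean (or minimum) base quality is below Q``min_quality``.

    Malformed quality strings drop the read; the count of such records is
    logged rather than raised, so one bad record cannot abort a sample.
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"unknown quality mode {mode!r}")
    kept, n_malformed = [], 0
    for r in reads:
        try:
            q = _phred(r.quality)
        except ValueError:
            n_malformed += 1
            continue
        if q.size == 0:
            continue
        stat = q.mean() if mode == "mean" else q.min()
        if stat >= min_quality:
            kept.append(r)
    if n_malformed:
        logger.warning("dropped %d reads with malformed quality strings", n_malformed)
    return kept


def length_filter(
    reads: Iterable[FastqRead], min_length_exclusive: int = 17
) -> list[FastqRead]:
    """Keep reads strictly longer than ``min_length_exclusive`` nt."""
    return [r for r in reads if len(r.sequence) > min_length_exclusive]


def collapse_reads(reads: Iterable[FastqRead]) -> list[CollapsedRead]:
    """Merge identical sequences; multiplicities sum to the input read count."""
    counts = Counter(r.sequence for r in reads)
    return [CollapsedRead(seq, n) for seq, n in sorted(counts.items())]


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def _matches(read_seq: str, ref_seq: str, max_mm: int) -> bool:
    """True if read_seq occurs within ref_seq (Hamming <= max_mm per window)."""
    if len(read_seq) > len(ref_seq):
        return False
    if max_mm == 0:
        return read_seq in ref_seq
    for start in range(len(ref_seq) - len(read_seq) + 1):
        window = ref_seq[start:start + len(read_seq)]
        if sum(a != b for a, b in zip(read_seq, window)) <= max_mm:
            return True
    return False


def quantify(
    collapsed: Sequence[CollapsedRead],
    reference: Mapping[str, str],
    max_mismatches: int = 0,
) -> QuantResult:
    """Assign collapsed reads to mature reference sequences.

    A read is assigned to the unique reference it equals or occurs within
    (Hamming distance <= ``max_mismatches`` per aligned window). Reads
    matching multiple references are discarded as ambiguous; counts
    accumulate collapse multiplicities.
    """
    if not reference:
        raise ValueError("empty mature reference")
    counts: dict[str, int] = {}
    ambiguous = unmatched = 0
    ref_items = sorted(reference.items())
    for cr in collapsed:
        hits = [mid for mid, seq in ref_items if _matches(cr.sequence, seq, max_mismatches)]
        if len(hits) == 1:
            counts[hits[0]] = counts.get(hits[0], 0) + cr.multiplicity
        elif len(hits) > 1:
            ambiguous += cr.multiplicity
        else:
            unmatched += cr.multiplicity
    return QuantResult(counts, ambiguous, unmatched)


def process_sample(
    reads: Iterable[FastqRead] | str | Path,
    reference: Mapping[str, str] | str | Path,
    params: PreprocessParams | None = None,
) -> QuantResult:
    """Full per-sample chain: trim, quality filter, length filter, collapse, quantify."""
    params = params or PreprocessParams()
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    trimmed = [trim_adapter(r, params.adapter) for r in reads]
    passed = quality_filter(trimmed, params.min_quality, params.quality_mode)
    passed = length_filter(passed, params.min_length_exclusive)
    collapsed = collapse_reads(passed)
    return quantify(collapsed, reference, params.max_mismatches_map)


# ---------------------------------------------------------------------------
# Count-matrix operations
# ---------------------------------------------------------------------------

def build_count_matrix(
    sample_counts: Mapping[str, Mapping[str, int]],
    mirnas: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble per-sample count dicts into a miRNA x sample integer matrix.

    Rows are miRNA identifiers, columns samples (insertion order). Absent
    (miRNA, sample) combinations are 0.
    """
    if mirnas is None:
        seen: dict[str, None] = {}
        for counts in sample_counts.values():
            for m in counts:
                seen[m] = None
        mirnas = sorted(seen)
    mat = pd.DataFrame(
        {s: [int(c.get(m, 0)) for m in mirnas] for s, c in sample_counts.items()},
        index=pd.Index(mirnas, name="mirna"),
        dtype=int,
    )
    if (mat.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return mat


def consistency_filter(matrix: pd.DataFrame, group: Sequence[str] | None = None) -> pd.DataFrame:
    """Keep miRNAs with a positive count in every sample of ``group``.

    ``group`` defaults to all columns — the all-replicates consistency
    rule. Raises on an empty group or on group members missing from the
    matrix.
    """
    cols = list(matrix.columns) if group is None else list(group)
    if not cols:
        raise ValueError("empty sample group")
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    keep = (matrix[cols] > 0).all(axis=1)
    return matrix.loc[keep]


def cpm_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million within each sample column."""
    sums = matrix.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero.index)}")
    return matrix / sums * 1e6


def rank_mirnas_top_k(normalized: pd.DataFrame, k: int = 20) -> list[str]:
    """Top-k miRNAs by row mean of normalized counts, descending.

    Ties break lexicographically by identifier.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    means = normalized.mean(axis=1)
    # stable sort: lexicographic index first, then descending mean
    order = means.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")
    return list(order.index[: min(k, len(order))])
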