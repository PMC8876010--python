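"""Read preprocessing: 3' adapter trimming, quality trimming, length filter.

The stages mirror the standard small-RNA workflow: remove the 3'
sequencing adapter (full internal occurrence or a 3'-terminal prefix of
it, allowing mismatches), clip low-quality 3' ends (< Q20 by default)
with the partial-sum rule, and discard inserts shorter than 18 nt.
Adapter matching is ungapped: small-RNA inserts are short and indel
errors are rare enough on Illumina chemistry that mismatch-only
semi-global matching recovers the insert.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


@dataclass
class ReadRecord:
    """One FASTQ read (Phred+33 qualities)."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_discarded_short: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_adapter_trimmed": self.n_adapter_trimmed,
            "n_discarded_short": self.n_discarded_short,
            "n_kept": self.n_kept,
        }


def _find_adapter(seq: str, adapter: str, max_error_rate: float, min_overlap: int) -> int | None:
    """Best-scoring ungapped occurrence of ``adapter`` in ``seq``.

    Considers every start offset; the match extends over
    min(len(adapter), len(seq) - start) bases, so a 3'-terminal prefix of
    the adapter also qualifies.  A candidate is valid when its mismatch
    count is at most floor(max_error_rate * matched_length) and the
    matched length is at least ``min_overlap``.  Among valid candidates
    the one with the most matching bases wins; ties go to fewer
    mismatches, then to the leftmost start.  Returns the start offset of
    the occurrence, or None.
    """
    n, m = len(seq), len(adapter)
    best: tuple[int, int, int] | None = None  # (-matches, mismatches, start)
    # fast path: leftmost exact full-length occurrence is always optimal
    # (no candidate can exceed len(adapter) matching bases)
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    for start in range(0, n - min_overlap + 1):
        length = min(m, n - start)
        budget = int(max_error_rate * length)
        mism = 0
        window = seq[start:start + length]
        for a, b in zip(window, adapter):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            cand = (-(length - mism), mism, start)
            if best is None or cand < best:
                best = cand
    return None if best is None else best[2]


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> ReadRecord:
    """Remove the best adapter occurrence and everything 3' of it."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    pos = _find_adapter(read.sequence, adapter, max_error_rate, min_overlap)
    if pos is None:
        return read
    return ReadRecord(read.id, read.sequence[:pos], read.quality[:pos])


def quality_trim(read: ReadRecord, q_threshold: int = 20) -> ReadRecord:
    """Clip the 3' end by the partial-sum (BWA/cutadapt) rule.

    Removes the suffix starting at the position that maximizes the
    running sum of (q_threshold - q) computed from the 3' end, provided
    that maximum is positive.
    """
    quals = read.quality
    s = 0
    best = 0
    cut = len(quals)
    for i in range(len(quals) - 1, -1, -1):
        s += q_threshold - (ord(quals[i]) - PHRED_OFFSET)
        if s > best:
            best = s
            cut = i
    if best <= 0:
        return read
    return ReadRecord(read.id, read.sequence[:cut], read.quality[:cut])


def filter_length(
    reads: Iterable[ReadRecord], min_len: int = 18
) -> tuple[list[ReadRecord], PreprocessStats]:
    stats = PreprocessStats()
    kept: list[ReadRecord] = []
    for read in reads:
        stats.n_input += 1
        if len(read.sequence) >= min_len:
            kept.append(read)
            stats.n_kept += 1
        else:
            stats.n_discarded_short += 1
    return kept, stats


def preprocess_read(
    read: ReadRecord,
    adapter: str,
    q_threshold: int = 20,
    max_error_rate: float = 0.1,
) -> ReadRecord:
    """Adapter trim then quality trim for a single read."""
    trimmed = trim_adapter(read, adapter, max_error_rate)
    return quality_trim(trimmed, q_threshold)


def preprocess_reads(
    reads: Iterable[ReadRecord],
    adapter: str,
    min_len: int = 18,
    q_threshold: int = 20,
    max_error_rate: float = 0.1,
) -> tuple[list[ReadRecord], PreprocessStats]:
    """Full preprocessing: adapter trim -> quality trim -> length filter."""
    stats = PreprocessStats()
    kept: list[ReadRecord] = []
    for read in reads:
        stats.n_input += 1
        out = trim_adapter(read, adapter, max_error_rate)
        if len(out.sequence) < len(read.sequence):
            stats.n_adapter_trimmed += 1
        out = quality_trim(out, q_threshold)
        if len(out.sequence) >= min_len:
            kept.append(out)
            stats.n_kept += 1
        else:
            stats.n_discarded_short += 1
    return kept, stats


# ---- FASTQ io -------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(title.split()[0], seq, qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
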