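"""Read preprocessing: quality trimming, 3' adapter clipping, length
filtering and collapsing to unique sequences.

The clipper is a deliberately simple exact matcher: a read is clipped at the
leftmost position where a prefix of the adapter (of at least ``min_overlap``
bases, possibly running off the read's 3' end) matches exactly. Error-tolerant
matching à la cutadapt is out of scope; with zero-mismatch downstream
classification, reads with adapter sequencing errors would not classify
anyway.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .references import normalize_seq

logger = logging.getLogger(__name__)

#: Illumina TruSeq small-RNA 3' adapter (the library kit implied by the
#: study design); overridable everywhere it is used.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

VALID_BASES = frozenset("ACGTN")


@dataclass
class ReadSet:
    """Collapsed reads: unique sequences with multiplicities.

    ``total_raw`` counts reads entering the stage that produced this set;
    ``total_kept`` equals the sum of retained counts, so the discard count at
    any stage is always ``total_raw - total_kept``.
    """

    records: list[tuple[str, int]]
    sample_id: str = ""
    total_raw: int = 0
    total_kept: int = 0

    def __post_init__(self) -> None:
        for seq, count in self.records:
            if count < 1:
                raise ValueError(f"non-positive count {count} for {seq}")
            if not set(seq) <= VALID_BASES:
                raise ValueError(f"invalid characters in read {seq!r}")
        kept = sum(c for _, c in self.records)
        if self.total_kept == 0:
            self.total_kept = kept
        elif self.total_kept != kept:
            raise ValueError("total_kept inconsistent with record counts")
        if self.total_raw == 0:
            self.total_raw = self.total_kept

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self) -> Counter:
        out: Counter = Counter()
        for seq, count in self.records:
            out[len(seq)] += count
        return out


def clip_adapter(seq: str, adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
                 min_overlap: int = 5, policy: str = "keep") -> str | None:
    """Clip the 3' adapter from one read.

    Returns the read prefix before the leftmost exact match of an adapter
    prefix of length >= ``min_overlap`` (anywhere in the read, including
    adapter prefixes running off the 3' end). With no match: the full read
    (``policy="keep"``) or None (``policy="discard_unclipped"``). An empty
    sequence yields None.
    """
    if not (1 <= min_overlap <= len(adapter)):
        raise ValueError("require adapter length >= min_overlap >= 1")
    if not seq:
        return None
    n = len(seq)
    for i in range(n - min_overlap + 1):
        k = min(len(adapter), n - i)
        if seq[i:i + k] == adapter[:k]:
            return seq[:i]
    if policy == "keep":
        return seq
    if policy == "discard_unclipped":
        return None
    raise ValueError(f"unknown unclipped-read policy {policy!r}")


def trim_quality(seq: str, quals: Sequence[int], cutoff: int = 20) -> str:
    """Trim trailing bases with Phred quality below ``cutoff``."""
    end = len(seq)
    while end > 0 and quals[end - 1] < cutoff:
        end -= 1
    return seq[:end]


def collapse_reads(raw: Iterable[str], sample_id: str = "") -> ReadSet:
    """Merge identical sequences; counts are multiplicities.

    Output order is deterministic (count-descending, then sequence), so the
    result is invariant to the input order.
    """
    counts = Counter(normalize_seq(s) for s in raw)
    records = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    return ReadSet(records=records, sample_id=sample_id,
                   total_raw=total, total_kept=total)


def length_filter(reads: ReadSet, min_len: int = 15) -> ReadSet:
    """Retain sequences of length >= ``min_len`` (reads shorter than 15 nt
    are too ambiguous to place by exact matching)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [(s, c) for s, c in reads.records if len(s) >= min_len]
    return ReadSet(records=kept, sample_id=reads.sample_id,
                   total_raw=reads.total_kept,
                   total_kept=sum(c for _, c in kept))


def drop_n_reads(reads: ReadSet) -> ReadSet:
    """Drop reads containing N — perfect matching cannot place them."""
    kept = [(s, c) for s, c in reads.records if "N" not in s]
    dropped = reads.total_kept - sum(c for _, c in kept)
    if dropped:
        logger.info("%s: dropped %d N-containing reads", reads.sample_id or "-", dropped)
    return ReadSet(records=kept, sample_id=reads.sample_id,
                   total_raw=reads.total_kept,
                   total_kept=sum(c for _, c in kept))


def _iter_input(path: str | Path) -> Iterator[tuple[str, Sequence[int] | None]]:
    path = str(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(path, fmt):
        quals = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
        yield str(rec.seq), quals


def preprocess_reads(path: str | Path,
                     adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
                     min_overlap: int = 5,
                     min_len: int = 15,
                     quality_cutoff: int = 20,
                     policy: str = "keep",
                     sample_id: str = "") -> ReadSet:
    """FASTQ/FASTA -> quality-trim -> clip adapter -> collapse -> length
    filter -> drop Ns. The standard entry point of the pipeline."""
    clipped: list[str] = []
    n_raw = 0
    for seq, quals in _iter_input(path):
        n_raw += 1
        seq = normalize_seq(seq)
        if quals is not None:
            seq = trim_quality(seq, quals, cutoff=quality_cutoff)
        out = clip_adapter(seq, adapter=adapter, min_overlap=min_overlap, policy=policy)
        if out:
            clipped.append(out)
    reads = collapse_reads(clipped, sample_id=sample_id)
    reads = length_filter(reads, min_len=min_len)
    reads = drop_n_reads(reads)
    reads.total_raw = n_raw  # whole-pipeline accounting: raw in, kept out
    return reads


# ---------------------------------------------------------------------------
# collapsed-FASTA round trip (headers ">seq{i}_x{count}")

def write_collapsed_fasta(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads.records, start=1):
            fh.write(f">seq{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path: str | Path, sample_id: str = "") -> ReadSet:
    records: list[tuple[str, int]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError):
            count = 1
        records.append((normalize_seq(rec.seq), count))
    total = sum(c for _, c in records)
    return ReadSet(records=records, sample_id=sample_id,
                   total_raw=total, total_kept=total)
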