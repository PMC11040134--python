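"""Raw-read processing: adapter/end trimming, contaminant removal, size selection.

Mirrors the preprocessing applied to the sequenced libraries: the NEXTflex
3' adapter is trimmed, 4 random bases are removed from each end of the
remaining insert, reads shorter than 23 nt are discarded, reads matching the
abundant rRNA/tRNA pool are filtered out, and RPF reads are restricted to
the 26-32 nt footprint window that the gel size selection targets.

Every read's fate is logged with a rule id so that the dispositions of a
run partition the input set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import TranscriptRecord, reverse_complement

# rule ids used in disposition logs
RULE_ADAPTER_SHORT = "adapter-discarded"   # too short after trimming
RULE_CONTAMINANT = "contaminant-removed"
RULE_SIZE = "size-rejected"
RULE_UNMAPPED = "unmapped"
RULE_ASSIGNED = "assigned"


@dataclass
class ReadSet:
    """Reads of one sample/assay: (read_id, sequence, optional quality)."""

    sample_id: str
    assay: str
    reads: list[tuple[str, str, str | None]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.sample_id}: duplicate read ids")
        if any(not r[1] for r in self.reads):
            raise ValueError(f"{self.sample_id}: empty read sequence")

    def __len__(self) -> int:
        return len(self.reads)


def read_fastq(path: str | Path, sample_id: str, assay: str) -> ReadSet:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            qual = fh.readline().strip()
            reads.append((header[1:].split()[0].strip(), seq, qual or None))
    return ReadSet(sample_id, assay, reads)


def _adapter_overlap(seq: str, adapter: str, min_overlap: int) -> int:
    """Longest k with seq[-k:] == adapter[:k]; 0 if none of length >= min_overlap.

    Longest match wins; for a fixed k the suffix position is unique, so
    longest-then-leftmost tie-breaking reduces to longest.
    """
    for k in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return k
    return 0


def trim_reads(
    reads: ReadSet,
    adapter: str,
    end_trim: int = 4,
    min_length: int = 23,
    min_overlap: int = 3,
) -> tuple[ReadSet, pd.DataFrame]:
    """Adapter-trim, end-trim, and length-filter a read set.

    The 3' adapter is located as the longest read suffix equal to an adapter
    prefix (at least ``min_overlap`` bases, the cutadapt convention) and cut;
    then ``end_trim`` bases are removed from each end; reads shorter than
    ``min_length`` are discarded. Returns the surviving reads plus a
    per-read disposition log (read_id, action, trimmed_length).
    """
    if set(adapter) - set("ACGT"):
        raise ValueError("adapter must be an ACGT string")
    if end_trim < 0 or min_length < 1:
        raise ValueError("end_trim must be >= 0 and min_length >= 1")

    kept: list[tuple[str, str, str | None]] = []
    log_rows = []
    for read_id, seq, qual in reads.reads:
        k = _adapter_overlap(seq, adapter, min_overlap)
        trimmed = seq[: len(seq) - k]
        trimmed = trimmed[end_trim: len(trimmed) - end_trim] if end_trim else trimmed
        if len(trimmed) < min_length:
            log_rows.append((read_id, RULE_ADAPTER_SHORT, len(trimmed)))
            continue
        tq = None
        if qual is not None:
            tq = qual[: len(seq) - k]
            tq = tq[end_trim: len(tq) - end_trim] if end_trim else tq
        kept.append((read_id, trimmed, tq))
        log_rows.append((read_id, "retained", len(trimmed)))
    out = ReadSet(reads.sample_id, reads.assay, kept)
    log = pd.DataFrame(log_rows, columns=["read_id", "action", "trimmed_length"])
    return out, log


def filter_contaminants(
    reads: ReadSet,
    contaminants: Sequence[TranscriptRecord],
    both_strands: bool = True,
) -> tuple[ReadSet, int]:
    """Remove reads that occur as exact substrings of any contaminant.

    An empty contaminant set is the identity. Both strands are searched by
    default (rRNA/tRNA fragments ligate in either orientation in practice).
    """
    if not contaminants:
        return reads, 0
    parts = [c.sequence for c in contaminants]
    if both_strands:
        parts += [reverse_complement(c.sequence) for c in contaminants]
    haystack = "#".join(parts)
    kept = [r for r in reads.reads if r[1] not in haystack]
    removed = len(reads) - len(kept)
    return ReadSet(reads.sample_id, reads.assay, kept), removed


def size_select(reads: ReadSet, min_len: int = 26, max_len: int = 32) -> ReadSet:
    """Keep RPF reads with min_len <= length <= max_len; mRNA reads bypass."""
    if min_len > max_len:
        raise ValueError("size_select: min_len > max_len")
    if reads.assay != "RPF":
        return reads
    kept = [r for r in reads.reads if min_len <= len(r[1]) <= max_len]
    return ReadSet(reads.sample_id, reads.assay, kept)
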