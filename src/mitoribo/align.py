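"""Transcript-space read assignment, EM multimapper resolution, counting.

The real libraries were quantified by aligning to the transcriptome with an
EM-based quantifier; synthetic reads are error-free, so a self-contained
exact-substring matcher (k-mer seeded, optional mismatch budget) plus an EM
over transcript abundances reproduces that role. SAM ingestion is the escape
hatch for externally aligned real data.

Coordinates are transcript-space, 0-based; coverage profiles count footprint
5' ends within the CDS.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import ConfigurationError, TranscriptRecord
from .reads import ReadSet

logger = logging.getLogger(__name__)

#: read_id -> list of (transcript_id, offset) compatibility entries
CompatMap = dict[str, list[tuple[str, int]]]


class KmerIndex:
    """Exact-substring matcher over a transcript set, seeded by k-mers."""

    def __init__(self, records: Sequence[TranscriptRecord], k: int = 12):
        if k < 1:
            raise ConfigurationError("k must be positive")
        self.k = k
        self.records = {r.transcript_id: r for r in records}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for r in records:
            seq = r.sequence
            for pos in range(len(seq) - k + 1):
                self._index[seq[pos: pos + k]].append((r.transcript_id, pos))

    def query(self, read: str, max_mismatch: int = 0) -> list[tuple[str, int]]:
        """All (transcript_id, offset) where the read matches with at most
        ``max_mismatch`` substitutions. Seeds at ``max_mismatch + 1``
        non-overlapping k-mers (pigeonhole: one seed must be exact)."""
        if len(read) < self.k:
            raise ConfigurationError(
                f"k={self.k} larger than read of length {len(read)}")
        n_seeds = max_mismatch + 1
        seed_starts = {min(i * self.k, len(read) - self.k) for i in range(n_seeds)}
        candidates: set[tuple[str, int]] = set()
        for s in seed_starts:
            for tid, pos in self._index.get(read[s: s + self.k], ()):
                candidates.add((tid, pos - s))
        hits = []
        for tid, offset in candidates:
            seq = self.records[tid].sequence
            if offset < 0 or offset + len(read) > len(seq):
                continue
            window = seq[offset: offset + len(read)]
            if max_mismatch == 0:
                if window == read:
                    hits.append((tid, offset))
            else:
                mm = sum(a != b for a, b in zip(window, read))
                if mm <= max_mismatch:
                    hits.append((tid, offset))
        return sorted(hits)


def assign_reads(
    reads: ReadSet,
    annotation: Sequence[TranscriptRecord] | KmerIndex,
    k: int = 12,
    max_mismatch: int = 0,
) -> tuple[CompatMap, list[str]]:
    """Map each read to every transcript containing it.

    Returns the compatibility map and the list of unmapped read ids.
    """
    index = annotation if isinstance(annotation, KmerIndex) else KmerIndex(annotation, k)
    compat: CompatMap = {}
    unmapped: list[str] = []
    for read_id, seq, _ in reads.reads:
        hits = index.query(seq, max_mismatch)
        if hits:
            compat[read_id] = hits
        else:
            unmapped.append(read_id)
    return compat, unmapped


def em_resolve_multimappers(
    compat: CompatMap,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[dict[str, list[tuple[str, float]]], pd.Series, list[float]]:
    """EM over transcript abundances with uniform initialization.

    Model: each read is drawn from transcript t with probability theta_t,
    uniformly within its compatible set. Iterates until the largest
    abundance change is below ``tol`` or ``max_iter`` is reached. Returns
    (per-read fractional weights, expected counts per transcript, the
    log-likelihood trace — non-decreasing by EM theory).
    """
    if not compat:
        raise ValueError("EM requires at least one mapped read")
    tids = sorted({tid for hits in compat.values() for tid, _ in hits})
    t_index = {t: i for i, t in enumerate(tids)}

    # collapse reads into equivalence classes by compatibility set
    classes: dict[tuple[int, ...], int] = defaultdict(int)
    read_class: dict[str, tuple[int, ...]] = {}
    for r, hits in compat.items():
        key = tuple(sorted({t_index[tid] for tid, _ in hits}))
        classes[key] += 1
        read_class[r] = key
    class_sets = [np.array(key, dtype=int) for key in classes]
    class_n = np.array(list(classes.values()), dtype=float)

    theta = np.full(len(tids), 1.0 / len(tids))
    n_reads = float(class_n.sum())
    ll_trace: list[float] = []
    for _ in range(max_iter):
        expected = np.zeros(len(tids))
        ll = 0.0
        for s, n in zip(class_sets, class_n):
            p = theta[s]
            tot = p.sum()
            ll += n * (np.log(tot) if tot > 0 else -np.inf)
            expected[s] += n * (p / tot if tot > 0 else 1.0 / len(s))
        ll_trace.append(float(ll))
        new_theta = expected / n_reads
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break

    class_weights = {}
    for key in classes:
        s = np.array(key, dtype=int)
        p = theta[s]
        tot = p.sum()
        class_weights[key] = p / tot if tot > 0 else np.full(len(s), 1.0 / len(s))

    weights: dict[str, list[tuple[str, float]]] = {}
    counts = np.zeros(len(tids))
    for r, key in read_class.items():
        w = class_weights[key]
        weights[r] = [(tids[j], float(w[i])) for i, j in enumerate(key)]
        counts[np.array(key, dtype=int)] += w
    return weights, pd.Series(counts, index=tids, name="expected_count"), ll_trace


@dataclass
class CoverageProfile:
    """Footprint 5'-end counts along one transcript's CDS."""

    transcript_id: str
    sample_id: str
    counts: np.ndarray  # length == CDS length; fractional after EM

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class CountMatrix:
    """Gene x sample counts for one assay, with per-sample library sizes."""

    counts: pd.DataFrame          # genes x samples, nonnegative reals
    library_size: pd.Series       # reads entering assignment, per sample
    assay: str

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    def cpm(self) -> pd.DataFrame:
        return self.counts / self.library_size * 1e6


def count_and_profile(
    weights_by_sample: Mapping[str, dict[str, list[tuple[str, float]]]],
    compat_by_sample: Mapping[str, CompatMap],
    annotation: Sequence[TranscriptRecord],
    library_sizes: Mapping[str, float],
) -> tuple[pd.DataFrame, dict[tuple[str, str], CoverageProfile]]:
    """Aggregate fractional weights into gene counts and coverage profiles.

    Gene counts sum the weights of all reads over that gene's transcripts
    (total assigned mass is conserved). Coverage adds each read's weight at
    its 5'-end position within the CDS; reads starting outside the CDS
    contribute to counts but not to the profile.
    """
    tid_to_gene = {r.transcript_id: r.gene_id for r in annotation}
    records = {r.transcript_id: r for r in annotation}
    gene_ids = sorted({r.gene_id for r in annotation if not r.is_contaminant})
    sample_ids = sorted(weights_by_sample)
    for s in sample_ids:
        if s not in library_sizes:
            raise ValueError(f"sample {s} absent from library sizes/design")

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mat = np.zeros((len(gene_ids), len(sample_ids)))
    profiles: dict[tuple[str, str], CoverageProfile] = {}
    for si, sample in enumerate(sample_ids):
        weights = weights_by_sample[sample]
        compat = compat_by_sample[sample]
        offsets = {r: dict(hits) for r, hits in compat.items()}
        cov: dict[str, np.ndarray] = {}
        for read_id, entries in weights.items():
            for tid, w in entries:
                gi = gene_pos.get(tid_to_gene[tid])
                if gi is not None:
                    mat[gi, si] += w
                rec = records[tid]
                pos = offsets[read_id][tid] - rec.cds_start
                if 0 <= pos < rec.cds_length:
                    if tid not in cov:
                        cov[tid] = np.zeros(rec.cds_length)
                    cov[tid][pos] += w
        for tid, arr in cov.items():
            profiles[(tid, sample)] = CoverageProfile(tid, sample, arr)
    counts = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    return counts, profiles


def write_bedgraph(profile: CoverageProfile, path: str | Path) -> None:
    """bedGraph of CDS coverage (transcript coordinates, 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={profile.transcript_id}.{profile.sample_id}\n")
        c = profile.counts
        start = 0
        for i in range(1, len(c) + 1):
            if i == len(c) or c[i] != c[start]:
                if c[start] != 0:
                    fh.write(f"{profile.transcript_id}\t{start}\t{i}\t{c[start]:g}\n")
                start = i


# ---------------------------------------------------------------------------
# SAM interchange

def export_sam(
    reads: ReadSet,
    compat: CompatMap,
    annotation: Sequence[TranscriptRecord],
    path: str | Path,
    mapq: int = 255,
) -> None:
    """Write the compatibility map as SAM against transcript references.

    The first hit of each read is primary, remaining hits are secondary;
    MAPQ defaults to 255 (unavailable) so round-trips keep every record.
    """
    refs = [r for r in annotation]
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": r.transcript_id, "LN": len(r.sequence)} for r in refs]}
    seq_by_id = {rid: s for rid, s, _ in reads.reads}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, hits in compat.items():
            seq = seq_by_id[read_id]
            for i, (tid, offset) in enumerate(hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = read_id
                a.query_sequence = seq
                a.reference_name = tid
                a.reference_start = offset
                a.mapping_quality = mapq
                a.cigarstring = f"{len(seq)}M"
                a.flag = 0 if i == 0 else 256  # secondary for extra hits
                out.write(a)


def ingest_alignments(
    path: str | Path,
    annotation: Sequence[TranscriptRecord],
    mapq_min: int = 5,
) -> CompatMap:
    """Read a SAM/BAM into a compatibility map, applying the MAPQ cutoff.

    Records with mapping quality below ``mapq_min`` are dropped; secondary
    and supplementary records are grouped with their primaries by read id.
    """
    known = {r.transcript_id for r in annotation}
    compat: CompatMap = defaultdict(list)
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for ref in fh.references:
            if ref not in known:
                raise ValueError(f"SAM reference {ref!r} absent from annotation")
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.mapping_quality < mapq_min:
                continue
            compat[rec.query_name].append((rec.reference_name, rec.reference_start))
    if not compat and n_unmapped:
        logger.warning("alignment file %s contained only unmapped records", path)
    return {r: sorted(set(hits)) for r, hits in compat.items()}
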