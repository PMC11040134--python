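"""Transcript annotation: records, gene classes, and the synthetic default set.

The default annotation emulates a mouse-like mitochondrial transcriptome:
the 13 mitochondrially encoded OXPHOS protein-coding genes, a configurable
panel of nuclear-encoded OXPHOS and mitochondria-associated genes, a
background of other nuclear transcripts, and the abundant rRNA/tRNA
contaminant pool that dominates unfiltered ribosome-profiling libraries.
Sequences are random but fixed by the seed; coordinates are transcript-space,
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MITOCHONDRIAL = "mitochondrial"
NUCLEAR = "nuclear"

GENE_CLASSES = (
    "mt-OXPHOS",
    "nu-OXPHOS",
    "mito-associated",
    "other",
    "contaminant-rRNA",
    "contaminant-tRNA",
)

#: The 13 protein-coding genes of the mammalian mitochondrial genome.
MT_OXPHOS_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Nd3", "mt-Nd4", "mt-Nd4l", "mt-Nd5", "mt-Nd6",
    "mt-Cytb", "mt-Co1", "mt-Co2", "mt-Co3", "mt-Atp6", "mt-Atp8",
)

#: Nuclear-encoded OXPHOS subunits used to name simulated nuclear transcripts.
NU_OXPHOS_GENES = (
    "Ndufv1", "Ndufa2", "Ndufa6", "Ndufb10", "Sdha", "Sdhb", "Sdhc", "Sdhd",
    "Cyc1", "Uqcrb", "Uqcrc1", "Uqcrfs1", "Cox5a", "Cox7a2l", "Cox7c",
    "Cox4i1", "Atp5o", "Atp5a1", "Atp5b", "Atp5c1",
)

#: Mitochondria-associated (MitoCarta-style) proteins outside OXPHOS.
MITO_ASSOCIATED_GENES = (
    "Mrpl12", "Ptcd3", "Cavin1", "Bsg", "Ece1", "Prxl2a", "Plpp3", "Pck2",
    "Nfs1", "Scp2", "Comt", "Tmlhe", "Mgst3", "Idh3a", "Slc25a24", "Clpp",
    "Me2", "Hspd1",
)

_BASES = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised for invalid generator/pipeline configuration."""


@dataclass
class TranscriptRecord:
    """A transcript with its sequence, CDS interval, and encoding class."""

    gene_id: str
    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int
    genome_of_origin: str  # mitochondrial | nuclear
    gene_class: str

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.transcript_id}: sequence has non-ACGT characters")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def is_contaminant(self) -> bool:
        return self.gene_class.startswith("contaminant")


@dataclass
class AnnotationConfig:
    """Counts, length ranges, and margins for the synthetic annotation.

    ``n_mt_oxphos`` defaults to the 13 mitochondrially encoded OXPHOS genes;
    larger values append synthetic ``mt-Gene``-style ids, smaller values take
    a prefix of the canonical names. Length ranges are inclusive.
    """

    n_mt_oxphos: int = 13
    n_nu_oxphos: int = 20
    n_mito_associated: int = 12
    n_other: int = 20
    n_rrna: int = 2
    n_trna: int = 22
    mito_length_range: tuple[int, int] = (300, 1400)
    nuclear_length_range: tuple[int, int] = (500, 2500)
    rrna_length_range: tuple[int, int] = (950, 1600)
    trna_length_range: tuple[int, int] = (68, 75)
    # UTR padding added on each side of the CDS (mito transcripts are
    # simulated essentially UTR-less, nuclear ones with short UTRs).
    mito_utr_margin: int = 0
    nuclear_utr_margin: int = 50

    def validate(self) -> None:
        for name in ("mito_length_range", "nuclear_length_range",
                     "rrna_length_range", "trna_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
        for name in ("n_mt_oxphos", "n_nu_oxphos", "n_mito_associated",
                     "n_other", "n_rrna", "n_trna"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.mito_utr_margin < 0 or self.nuclear_utr_margin < 0:
            raise ConfigurationError("UTR margins must be nonnegative")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _gene_names(canonical: Sequence[str], n: int, prefix: str) -> list[str]:
    names = list(canonical[:n])
    names += [f"{prefix}{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names


def _coding_record(rng: np.random.Generator, gene: str, length_range: tuple[int, int],
                   margin: int, genome: str, gene_class: str) -> TranscriptRecord:
    cds_len = int(rng.integers(length_range[0], length_range[1] + 1))
    cds_len -= cds_len % 3  # keep CDS a whole number of codons
    cds_len = max(cds_len, 30)
    seq = _random_sequence(rng, cds_len + 2 * margin)
    return TranscriptRecord(
        gene_id=gene,
        transcript_id=f"{gene}-201",
        sequence=seq,
        cds_start=margin,
        cds_end=margin + cds_len,
        genome_of_origin=genome,
        gene_class=gene_class,
    )


def build_default_annotation(
    config: AnnotationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TranscriptRecord]:
    """Generate the synthetic transcript annotation.

    Deterministic given the seed; gene ids are unique. Returns protein-coding
    transcripts for all classes plus contaminant rRNA/tRNA records (whose CDS
    interval is the whole sequence, by convention).
    """
    config = config or AnnotationConfig()
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    records: list[TranscriptRecord] = []
    for gene in _gene_names(MT_OXPHOS_GENES, config.n_mt_oxphos, "mt-Gene"):
        records.append(_coding_record(rng, gene, config.mito_length_range,
                                      config.mito_utr_margin, MITOCHONDRIAL, "mt-OXPHOS"))
    for gene in _gene_names(NU_OXPHOS_GENES, config.n_nu_oxphos, "NuOx"):
        records.append(_coding_record(rng, gene, config.nuclear_length_range,
                                      config.nuclear_utr_margin, NUCLEAR, "nu-OXPHOS"))
    for gene in _gene_names(MITO_ASSOCIATED_GENES, config.n_mito_associated, "MitoAssoc"):
        records.append(_coding_record(rng, gene, config.nuclear_length_range,
                                      config.nuclear_utr_margin, NUCLEAR, "mito-associated"))
    for gene in _gene_names((), config.n_other, "Gene"):
        records.append(_coding_record(rng, gene, config.nuclear_length_range,
                                      config.nuclear_utr_margin, NUCLEAR, "other"))
    for i in range(config.n_rrna):
        length = int(rng.integers(config.rrna_length_range[0], config.rrna_length_range[1] + 1))
        seq = _random_sequence(rng, length)
        name = f"rRNA-{'12S' if i == 0 else '16S' if i == 1 else str(i + 1)}"
        records.append(TranscriptRecord(name, f"{name}-201", seq, 0, length,
                                        MITOCHONDRIAL, "contaminant-rRNA"))
    for i in range(config.n_trna):
        length = int(rng.integers(config.trna_length_range[0], config.trna_length_range[1] + 1))
        seq = _random_sequence(rng, length)
        name = f"tRNA-{i + 1:02d}"
        records.append(TranscriptRecord(name, f"{name}-201", seq, 0, length,
                                        MITOCHONDRIAL, "contaminant-tRNA"))

    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate gene ids in generated annotation")
    return records


def coding_records(annotation: Iterable[TranscriptRecord]) -> list[TranscriptRecord]:
    return [r for r in annotation if not r.is_contaminant]


def contaminant_records(annotation: Iterable[TranscriptRecord]) -> list[TranscriptRecord]:
    return [r for r in annotation if r.is_contaminant]


# ---------------------------------------------------------------------------
# I/O: FASTA for sequences, BED (transcript coordinates) for CDS intervals.

def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.transcript_id, description=r.gene_id)
            for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_bed(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """BED6 + two extra columns (gene_class, genome_of_origin)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.cds_start}\t{r.cds_end}\t{r.gene_id}"
                     f"\t0\t+\t{r.gene_class}\t{r.genome_of_origin}\n")


def read_annotation(fasta_path: str | Path, bed_path: str | Path) -> list[TranscriptRecord]:
    """Reassemble TranscriptRecords from a FASTA + CDS BED pair."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            tid, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            gene_class = parts[6] if len(parts) > 6 else "other"
            genome = parts[7] if len(parts) > 7 else NUCLEAR
            if tid not in seqs:
                raise ValueError(f"BED transcript {tid} missing from FASTA")
            records.append(TranscriptRecord(gene, tid, seqs[tid], start, end,
                                            genome, gene_class))
    return records
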