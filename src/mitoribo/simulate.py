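"""Synthetic Ribo-seq/RNA-seq and TMT experiments with known ground truth.

The generator emulates the study design this package analyzes: three
genotypes (control, het, homo) of a striatal cell model, three paired
Ribo-seq (RPF) / RNA-seq replicates each, and a 16-plex TMT proteomics
experiment with five replicates per genotype and one unused channel.

Planted effects live in a :class:`TruthTable`: per-gene occupancy and mRNA
fold changes (het/control and homo/control), a positional skew parameter in
[-1, 1] tilting footprint starts toward the 3' (positive) or 5' (negative)
end of the CDS, and per-protein log2 abundance shifts. Counts are drawn from
a negative-binomial model (overdispersed, like real bulk libraries); reads
carry NEXTflex-style adapters (4 random bases flanking the insert, then the
3' adapter) so the trimming stage is exercised end to end.

Library-size convention: per-assay scale factors are computed from the
*baseline* composition, so sample totals drift with planted effects rather
than being renormalized to fixed depth. This keeps raw per-gene RPF/mRNA
ratios unbiased estimates of the planted occupancy fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ConfigurationError,
    TranscriptRecord,
    coding_records,
    contaminant_records,
)

GENOTYPES = ("control", "het", "homo")
ASSAYS = ("RPF", "mRNA")

#: 3' adapter of the NEXTflex small-RNA chemistry (trimmed with -a ... ).
NEXTFLEX_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.array(list("ACGT"))


class DesignError(ValueError):
    """Raised when a sample/plex design is inconsistent."""


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing sample: genotype x replicate x assay."""

    sample_id: str
    genotype: str
    replicate: int
    assay: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise DesignError(f"unknown genotype {self.genotype!r}")
        if self.assay not in ASSAYS:
            raise DesignError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise DesignError("replicate numbers are 1-based positive integers")


def paired_design(n_replicates: int = 3) -> list[SampleDesign]:
    """The default design: each genotype x replicate has an RPF and an mRNA sample."""
    design = []
    for genotype in GENOTYPES:
        for rep in range(1, n_replicates + 1):
            for assay in ASSAYS:
                design.append(SampleDesign(f"{genotype}_{rep}_{assay.lower()}",
                                           genotype, rep, assay))
    return design


def check_paired(design: Sequence[SampleDesign]) -> None:
    """Every RPF sample must have an mRNA partner (same genotype, replicate)."""
    keys = {(d.genotype, d.replicate, d.assay) for d in design}
    if len(keys) != len(design):
        raise DesignError("duplicate (genotype, replicate, assay) in design")
    for g, r, a in keys:
        if a == "RPF" and (g, r, "mRNA") not in keys:
            raise DesignError(f"RPF sample {g} rep {r} lacks an mRNA partner")


def design_frame(design: Sequence[SampleDesign]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in design])


def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    return [SampleDesign(r.sample_id, r.genotype, int(r.replicate), r.assay)
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Truth tables

@dataclass
class TruthTable:
    """Planted effects for genes (occupancy/mRNA FC, skew) and proteins."""

    genes: pd.DataFrame      # gene_id, occ_fc_het, occ_fc_homo, mrna_fc_het, mrna_fc_homo, skew
    proteins: pd.DataFrame   # protein_id, shift_het, shift_homo  (log2)

    def __post_init__(self) -> None:
        g = self.genes
        for col in ("occ_fc_het", "occ_fc_homo", "mrna_fc_het", "mrna_fc_homo"):
            if (g[col] <= 0).any():
                raise ValueError(f"{col}: fold changes must be positive")
        if (g["skew"].abs() > 1).any():
            raise ValueError("skew parameters must lie in [-1, 1]")

    @classmethod
    def null(cls, gene_ids: Iterable[str], protein_ids: Iterable[str] | None = None
             ) -> "TruthTable":
        gene_ids = list(gene_ids)
        genes = pd.DataFrame({
            "gene_id": gene_ids,
            "occ_fc_het": 1.0, "occ_fc_homo": 1.0,
            "mrna_fc_het": 1.0, "mrna_fc_homo": 1.0,
            "skew": 0.0,
        })
        pids = list(protein_ids) if protein_ids is not None else gene_ids
        proteins = pd.DataFrame({"protein_id": pids, "shift_het": 0.0, "shift_homo": 0.0})
        return cls(genes, proteins)

    def set_occupancy_fc(self, gene_ids: Iterable[str], het: float = 1.0,
                         homo: float = 1.0) -> "TruthTable":
        mask = self.genes["gene_id"].isin(list(gene_ids))
        self.genes.loc[mask, "occ_fc_het"] = het
        self.genes.loc[mask, "occ_fc_homo"] = homo
        return self

    def set_mrna_fc(self, gene_ids: Iterable[str], het: float = 1.0,
                    homo: float = 1.0) -> "TruthTable":
        mask = self.genes["gene_id"].isin(list(gene_ids))
        self.genes.loc[mask, "mrna_fc_het"] = het
        self.genes.loc[mask, "mrna_fc_homo"] = homo
        return self

    def set_skew(self, gene_ids: Iterable[str], skew: float) -> "TruthTable":
        mask = self.genes["gene_id"].isin(list(gene_ids))
        self.genes.loc[mask, "skew"] = skew
        return self

    def set_protein_shift(self, protein_ids: Iterable[str], het: float = 0.0,
                          homo: float = 0.0) -> "TruthTable":
        mask = self.proteins["protein_id"].isin(list(protein_ids))
        self.proteins.loc[mask, "shift_het"] = het
        self.proteins.loc[mask, "shift_homo"] = homo
        return self


# ---------------------------------------------------------------------------
# Ribo-seq / RNA-seq simulation

@dataclass
class RiboseqParams:
    """Study conditions for the sequencing simulation."""

    reads_per_sample: int = 50_000
    dispersion: float = 0.02          # NB: var = mu + dispersion * mu^2
    contaminant_fraction: float = 0.10
    base_expression_sigma: float = 1.0  # lognormal spread of baseline means
    rpf_length_range: tuple[int, int] = (26, 32)
    mrna_insert_range: tuple[int, int] = (28, 38)
    read_length: int = 50
    adapter: str = NEXTFLEX_ADAPTER
    umi_length: int = 4               # random bases ligated on each side
    dropout_genes: tuple[str, ...] = ()  # genes with per-replicate dropout
    dropout_prob: float = 0.0

    def validate(self) -> None:
        if self.rpf_length_range[0] > self.rpf_length_range[1]:
            raise ConfigurationError("rpf_length_range: min > max")
        if self.mrna_insert_range[0] > self.mrna_insert_range[1]:
            raise ConfigurationError("mrna_insert_range: min > max")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ConfigurationError("contaminant_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be nonnegative")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def _base_expression(genes: Sequence[TranscriptRecord], sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(0.0, sigma, size=len(genes)))


def _fc_columns(truth: TruthTable, gene_ids: Sequence[str], genotype: str,
                which: str) -> np.ndarray:
    if genotype == "control":
        return np.ones(len(gene_ids))
    tab = truth.genes.set_index("gene_id")
    return tab.loc[list(gene_ids), f"{which}_fc_{genotype}"].to_numpy(dtype=float)


def simulate_counts(
    annotation: Sequence[TranscriptRecord],
    design: Sequence[SampleDesign],
    truth: TruthTable,
    params: RiboseqParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-gene NB counts for every sample without generating reads.

    Returns (rpf_counts, mrna_counts, expected_means); count frames are
    genes x samples. This is the count-level core that the read simulator
    realizes into sequences; it is also usable directly for statistical
    calibration studies where read-level detail is irrelevant.
    """
    params = params or RiboseqParams()
    params.validate()
    check_paired(design)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = coding_records(annotation)
    gene_ids = [g.gene_id for g in genes]
    missing = set(gene_ids) - set(truth.genes["gene_id"])
    if missing:
        raise ValueError(f"truth table lacks genes: {sorted(missing)[:5]} ...")

    base = _base_expression(genes, params.base_expression_sigma, rng)
    scale = params.reads_per_sample * (1.0 - params.contaminant_fraction) / base.sum()

    rpf_cols, mrna_cols, mean_cols = {}, {}, {}
    for d in sorted(design, key=lambda d: d.sample_id):
        mrna_fc = _fc_columns(truth, gene_ids, d.genotype, "mrna")
        occ_fc = _fc_columns(truth, gene_ids, d.genotype, "occ")
        mu_mrna = base * mrna_fc * scale
        mu_rpf = mu_mrna * occ_fc
        mu = mu_rpf if d.assay == "RPF" else mu_mrna
        counts = _nb_draw(rng, mu, params.dispersion)
        if params.dropout_prob > 0 and params.dropout_genes:
            drop = np.isin(gene_ids, params.dropout_genes) & (
                rng.random(len(gene_ids)) < params.dropout_prob)
            counts = np.where(drop, 0, counts)
        (rpf_cols if d.assay == "RPF" else mrna_cols)[d.sample_id] = counts
        mean_cols[d.sample_id] = mu

    rpf = pd.DataFrame(rpf_cols, index=gene_ids)
    mrna = pd.DataFrame(mrna_cols, index=gene_ids)
    means = pd.DataFrame(mean_cols, index=gene_ids)
    return rpf, mrna, means


@dataclass
class SimulatedSample:
    """Reads plus exact per-read origin bookkeeping for one sample."""

    sample_id: str
    assay: str
    reads: list[tuple[str, str, str]]          # (read_id, sequence, quality)
    origins: pd.DataFrame                      # read_id, origin, start, insert_length


def _tilted_start_positions(rng: np.random.Generator, n: int, n_positions: int,
                            skew: float) -> np.ndarray:
    """Draw start indices from a linearly tilted density over [0, n_positions).

    Density at position i is proportional to 1 + skew * (2 i/(n-1) - 1):
    skew > 0 puts more mass toward the 3' end, skew < 0 toward the 5' end.
    """
    if n_positions == 1:
        return np.zeros(n, dtype=int)
    w = 1.0 + skew * (2.0 * np.arange(n_positions) / (n_positions - 1) - 1.0)
    w = np.clip(w, 0.0, None)
    return rng.choice(n_positions, size=n, p=w / w.sum())


def simulate_riboseq_experiment(
    annotation: Sequence[TranscriptRecord],
    design: Sequence[SampleDesign],
    truth: TruthTable,
    params: RiboseqParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SimulatedSample], pd.DataFrame, pd.DataFrame]:
    """Simulate adapter-carrying reads for every sample in the design.

    Returns (samples, rpf_true_counts, mrna_true_counts) where the count
    frames record the exact number of reads drawn per gene per sample
    (contaminant reads are booked separately in each sample's origin table).
    """
    params = params or RiboseqParams()
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = coding_records(annotation)
    contams = contaminant_records(annotation)
    if params.contaminant_fraction > 0 and not contams:
        raise ConfigurationError("contaminant_fraction > 0 but no contaminant records")
    skew_by_gene = dict(zip(truth.genes["gene_id"], truth.genes["skew"]))

    rpf_counts, mrna_counts, _ = simulate_counts(annotation, design, truth, params, rng)

    gene_by_id = {g.gene_id: g for g in genes}
    samples: list[SimulatedSample] = []
    for d in sorted(design, key=lambda d: d.sample_id):
        counts = (rpf_counts if d.assay == "RPF" else mrna_counts)[d.sample_id]
        inserts: list[str] = []
        origin_rows: list[tuple[str, int, int]] = []
        for gene, n in counts.items():
            if n == 0:
                continue
            rec = gene_by_id[gene]
            if d.assay == "RPF":
                lo, hi = params.rpf_length_range
                skew = skew_by_gene.get(gene, 0.0)
            else:
                lo, hi = params.mrna_insert_range
                skew = 0.0
            lengths = np.minimum(rng.integers(lo, hi + 1, size=int(n)), rec.cds_length)
            for length in np.unique(lengths):
                length = int(length)
                n_reads = int(np.sum(lengths == length))
                n_pos = rec.cds_length - length + 1
                starts = _tilted_start_positions(rng, n_reads, n_pos, skew)
                for start in starts:
                    start = int(start)
                    inserts.append(rec.sequence[rec.cds_start + start:
                                                rec.cds_start + start + length])
                    origin_rows.append((gene, start, length))
        # contaminant reads on top of the genic ones
        if params.contaminant_fraction > 0:
            n_genic = len(inserts)
            n_contam = int(round(n_genic * params.contaminant_fraction
                                 / (1.0 - params.contaminant_fraction)))
            picks = rng.integers(0, len(contams), size=n_contam)
            lo, hi = (params.rpf_length_range if d.assay == "RPF"
                      else params.mrna_insert_range)
            for c_idx in picks:
                rec = contams[int(c_idx)]
                length = int(min(rng.integers(lo, hi + 1), len(rec.sequence)))
                start = int(rng.integers(0, len(rec.sequence) - length + 1))
                inserts.append(rec.sequence[start: start + length])
                origin_rows.append((f"contaminant:{rec.gene_id}", start, length))

        # assemble raw reads: 4N + insert + 4N + adapter, truncated at read_length
        n_total = len(inserts)
        umis = _BASES[rng.integers(0, 4, size=(n_total, 2 * params.umi_length))]
        reads = []
        for i, insert in enumerate(inserts):
            u = "".join(umis[i])
            raw = (u[:params.umi_length] + insert + u[params.umi_length:]
                   + params.adapter)[: params.read_length]
            reads.append((f"{d.sample_id}.{i:07d}", raw, "I" * len(raw)))
        origins = pd.DataFrame(
            {"read_id": [r[0] for r in reads],
             "origin": [o[0] for o in origin_rows],
             "start": [o[1] for o in origin_rows],
             "insert_length": [o[2] for o in origin_rows]})
        samples.append(SimulatedSample(d.sample_id, d.assay, reads, origins))
    return samples, rpf_counts, mrna_counts


def write_fastq(sample: SimulatedSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in sample.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# TMT simulation

#: TMTpro 16-plex channel labels in mass order.
TMT16_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)

UNUSED = "unused"


def default_plex_design(n_replicates: int = 5) -> pd.DataFrame:
    """The study's 16-plex layout: interleaved homo/het, one unused channel,
    then the five controls."""
    if 2 * n_replicates + 1 + n_replicates > len(TMT16_CHANNELS):
        raise DesignError("more samples than channels in the 16-plex")
    rows = []
    idx = 0
    for rep in range(1, n_replicates + 1):
        rows.append((TMT16_CHANNELS[idx], "homo", rep)); idx += 1
        rows.append((TMT16_CHANNELS[idx], "het", rep)); idx += 1
    rows.append((TMT16_CHANNELS[idx], UNUSED, 0)); idx += 1
    for rep in range(1, n_replicates + 1):
        rows.append((TMT16_CHANNELS[idx], "control", rep)); idx += 1
    # remaining channels (if fewer replicates) stay unused
    for ch in TMT16_CHANNELS[idx:]:
        rows.append((ch, UNUSED, 0))
    return pd.DataFrame(rows, columns=["channel", "genotype", "replicate"])


def check_plex(plex: pd.DataFrame, n_channels: int = 16) -> None:
    if len(plex) > n_channels:
        raise DesignError(f"{len(plex)} channels assigned against a {n_channels}-plex")
    if plex["channel"].duplicated().any():
        raise DesignError("duplicate channel labels in plex design")


@dataclass
class TmtParams:
    """Study conditions for the TMT peptide-intensity simulation."""

    peptides_per_protein: tuple[int, int] = (1, 5)
    base_log2_abundance: float = 18.0
    protein_sigma: float = 2.0       # spread of protein baselines (log2)
    peptide_sigma: float = 1.0       # peptide ionization offsets (log2)
    channel_loading_sigma: float = 0.15  # per-channel loading imbalance (log2)
    noise_sigma: float = 0.10        # replicate/measurement noise (log2)
    impurity_spill: float = 0.02     # fraction spilling into each adjacent channel
    dropout_midpoint: float = 12.0   # log2 intensity of 50% detection
    dropout_scale: float = 1.0       # logistic width; <=0 disables dropout

    def validate(self) -> None:
        if self.peptides_per_protein[0] < 1:
            raise ConfigurationError("each protein needs at least one peptide")
        if self.peptides_per_protein[0] > self.peptides_per_protein[1]:
            raise ConfigurationError("peptides_per_protein: min > max")
        if not 0.0 <= self.impurity_spill < 0.5:
            raise ConfigurationError("impurity_spill must be in [0, 0.5)")


def impurity_matrix(n_channels: int, spill: float) -> pd.DataFrame:
    """Row i gives the observed channel composition of label i (adjacent spill)."""
    m = np.eye(n_channels) * (1.0 - 2.0 * spill)
    for i in range(n_channels):
        if i > 0:
            m[i, i - 1] = spill
        if i < n_channels - 1:
            m[i, i + 1] = spill
    # edge labels have only one neighbour; keep row sums <= 1
    m[0, 0] = 1.0 - spill
    m[-1, -1] = 1.0 - spill
    labels = list(TMT16_CHANNELS[:n_channels])
    return pd.DataFrame(m, index=labels, columns=labels)


def simulate_tmt_experiment(
    protein_ids: Sequence[str],
    truth: TruthTable,
    plex: pd.DataFrame | None = None,
    params: TmtParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide-level reporter-intensity table.

    Returns (peptides, plex, impurity): ``peptides`` has columns peptide_id,
    protein_id, then one intensity column per channel label (NaN = missing).
    Planted genotype shifts act on the log2 scale; dropout probability is a
    decreasing logistic function of log2 intensity (emulating the bias of
    data-dependent acquisition toward abundant peptides); reporter crosstalk
    mixes channels via the impurity matrix, which is returned for correction.
    """
    params = params or TmtParams()
    params.validate()
    plex = default_plex_design() if plex is None else plex
    check_plex(plex)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shift = truth.proteins.set_index("protein_id")
    missing = set(protein_ids) - set(shift.index)
    if missing:
        raise ValueError(f"truth table lacks proteins: {sorted(missing)[:5]} ...")

    channels = list(plex["channel"])
    genotype = dict(zip(plex["channel"], plex["genotype"]))
    loading = rng.normal(0.0, params.channel_loading_sigma, size=len(channels))

    protein_ids = list(protein_ids)
    n_prot = len(protein_ids)
    lo, hi = params.peptides_per_protein
    n_pep_per = rng.integers(lo, hi + 1, size=n_prot)
    prot_idx = np.repeat(np.arange(n_prot), n_pep_per)
    n_total = len(prot_idx)

    base_prot = params.base_log2_abundance + rng.normal(0.0, params.protein_sigma,
                                                        size=n_prot)
    pep_base = base_prot[prot_idx] + rng.normal(0.0, params.peptide_sigma,
                                                size=n_total)
    # planted genotype shifts per (protein, channel)
    shift_het = shift.loc[protein_ids, "shift_het"].to_numpy(dtype=float)
    shift_homo = shift.loc[protein_ids, "shift_homo"].to_numpy(dtype=float)
    delta = np.zeros((n_prot, len(channels)))
    for ci, ch in enumerate(channels):
        if genotype[ch] == "het":
            delta[:, ci] = shift_het
        elif genotype[ch] == "homo":
            delta[:, ci] = shift_homo

    log2 = (pep_base[:, None] + delta[prot_idx] + loading[None, :]
            + rng.normal(0.0, params.noise_sigma, size=(n_total, len(channels))))
    intensities = np.power(2.0, log2)

    pep_counter = np.concatenate([np.arange(1, n + 1) for n in n_pep_per]) \
        if n_total else np.array([], dtype=int)
    pep_meta = [(f"{protein_ids[pi]}.pep{c}", protein_ids[pi])
                for pi, c in zip(prot_idx, pep_counter)]

    # reporter-ion crosstalk: observed = M^T . true, per peptide
    imp = impurity_matrix(len(channels), params.impurity_spill)
    observed = intensities @ imp.to_numpy()  # (peptides x ch) . (ch x ch)

    # abundance-dependent dropout on the *observed* log2 intensity
    if params.dropout_scale > 0:
        with np.errstate(divide="ignore"):
            obs_log2 = np.log2(np.where(observed > 0, observed, np.nan))
        p_missing = 1.0 / (1.0 + np.exp((obs_log2 - params.dropout_midpoint)
                                        / params.dropout_scale))
        observed = np.where(rng.random(observed.shape) < p_missing, np.nan, observed)

    # unused channels carry only background: set to NaN
    unused_cols = [i for i, ch in enumerate(channels) if genotype[ch] == UNUSED]
    observed[:, unused_cols] = np.nan

    peptides = pd.DataFrame(observed, columns=channels)
    peptides.insert(0, "protein_id", [m[1] for m in pep_meta])
    peptides.insert(0, "peptide_id", [m[0] for m in pep_meta])
    imp = imp.copy()
    imp.index = channels
    imp.columns = channels
    return peptides, plex, imp
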