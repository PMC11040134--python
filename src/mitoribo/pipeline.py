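"""End-to-end orchestration: simulate -> process reads -> occupancy ->
proteomics -> integrate, plus format validation and the artifact manifest.

A run is fully determined by its configuration and seed: the manifest lists
every artifact with a SHA-256 content hash, and rerunning with the same
config/seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import align, annotation as anno, integrate, occupancy as occ, proteomics as prot
from .annotation import ConfigurationError, TranscriptRecord
from .config import RunConfig, dump_config
from .reads import (
    RULE_ADAPTER_SHORT, RULE_ASSIGNED, RULE_CONTAMINANT, RULE_SIZE, RULE_UNMAPPED,
    ReadSet, filter_contaminants, read_fastq, size_select, trim_reads,
)
from .simulate import (
    SampleDesign, TruthTable, default_plex_design, design_frame, paired_design,
    simulate_riboseq_experiment, simulate_tmt_experiment, write_fastq,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def default_truth(records: Sequence[TranscriptRecord]) -> TruthTable:
    """The default planted-effect scenario: mitochondrially encoded OXPHOS
    genes get raised occupancy (stronger in het) with mildly lowered mRNA —
    the stalling signature — plus 3' skew on a few of them; mito-associated
    proteins get allele-specific abundance shifts; nuclear OXPHOS stays flat."""
    genes = [r.gene_id for r in records if not r.is_contaminant]
    mt = [r.gene_id for r in records if r.gene_class == "mt-OXPHOS"]
    assoc = [r.gene_id for r in records if r.gene_class == "mito-associated"]
    truth = TruthTable.null(genes)
    truth.set_occupancy_fc(mt, het=3.0, homo=2.0)
    truth.set_mrna_fc(mt, het=0.8, homo=0.7)
    truth.set_skew([g for g in ("mt-Nd1", "mt-Nd3", "mt-Nd4l", "mt-Atp8") if g in genes], 0.6)
    truth.set_skew([g for g in ("mt-Nd2", "mt-Nd4", "mt-Nd6") if g in genes], -0.6)
    # protein level: raised occupancy does not translate into protein
    truth.set_protein_shift(mt, het=0.0, homo=-1.0)
    truth.set_protein_shift(assoc[: len(assoc) // 2], het=-1.0, homo=-1.0)
    truth.set_protein_shift(assoc[len(assoc) // 2:], het=1.0, homo=1.0)
    return truth


#: mt proteins typically missed by data-dependent acquisition in the TMT data
DEFAULT_UNDETECTED = ("mt-Nd3", "mt-Nd4", "mt-Nd4l", "mt-Co1", "mt-Co2",
                      "mt-Co3", "mt-Atp6", "mt-Atp8")


def detected_proteins(records: Sequence[TranscriptRecord],
                      undetected: Sequence[str] = DEFAULT_UNDETECTED) -> list[str]:
    return [r.gene_id for r in records
            if not r.is_contaminant and r.gene_id not in undetected]


def process_sample(
    raw: ReadSet,
    index: align.KmerIndex,
    contaminants: Sequence[TranscriptRecord],
    config: RunConfig,
) -> tuple[dict, align.CompatMap, dict[str, list[tuple[str, float]]], pd.DataFrame]:
    """Trim, filter, size-select, assign and EM-resolve one sample.

    Returns (stage counts, compatibility map, weights, disposition log).
    The dispositions partition the input reads across the five fates.
    """
    trimmed, trim_log = trim_reads(raw, config.trim.adapter, config.trim.end_trim,
                                   config.trim.min_length, config.trim.min_overlap)
    kept, removed = filter_contaminants(trimmed, list(contaminants))
    contaminant_ids = set(r[0] for r in trimmed.reads) - set(r[0] for r in kept.reads)
    sized = size_select(kept, config.size_select.min_len, config.size_select.max_len)
    size_rejected = set(r[0] for r in kept.reads) - set(r[0] for r in sized.reads)
    compat, unmapped = align.assign_reads(sized, index)
    if compat:
        weights, _, _ = align.em_resolve_multimappers(compat)
    else:
        weights = {}

    disposition = {}
    for rid, action, _ in trim_log.itertuples(index=False):
        if action != "retained":
            disposition[rid] = RULE_ADAPTER_SHORT
    for rid in contaminant_ids:
        disposition[rid] = RULE_CONTAMINANT
    for rid in size_rejected:
        disposition[rid] = RULE_SIZE
    for rid in unmapped:
        disposition[rid] = RULE_UNMAPPED
    for rid in compat:
        disposition[rid] = RULE_ASSIGNED
    log = pd.DataFrame({"read_id": list(disposition), "rule": list(disposition.values())})
    counts = log["rule"].value_counts().to_dict()
    counts["input"] = len(raw)
    return counts, compat, weights, log


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    artifacts: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, **kw) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        artifacts.append(path)
        return path

    dump_config(config, outdir / "config.resolved.yaml")
    artifacts.append(outdir / "config.resolved.yaml")

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        records = anno.build_default_annotation(config.annotation, rng)
        design = paired_design(config.n_replicates)
        truth = default_truth(records)
        samples, rpf_true, mrna_true = simulate_riboseq_experiment(
            records, design, truth, config.riboseq, rng)
        anno.write_fasta(records, outdir / "transcripts.fasta")
        anno.write_bed(records, outdir / "cds.bed")
        anno.write_fasta(anno.contaminant_records(records), outdir / "contaminants.fasta")
        artifacts += [outdir / "transcripts.fasta", outdir / "cds.bed",
                      outdir / "contaminants.fasta"]
        save_tsv(design_frame(design), "samples.tsv", index=False)
        save_tsv(truth.genes, "truth_genes.tsv", index=False)
        save_tsv(truth.proteins, "truth_proteins.tsv", index=False)
        save_tsv(rpf_true, "truth_rpf_counts.tsv", index_label="gene_id")
        save_tsv(mrna_true, "truth_mrna_counts.tsv", index_label="gene_id")
        fastq_dir = outdir / "fastq"
        fastq_dir.mkdir(exist_ok=True)
        origins = []
        for s in samples:
            write_fastq(s, fastq_dir / f"{s.sample_id}.fastq")
            artifacts.append(fastq_dir / f"{s.sample_id}.fastq")
            o = s.origins.copy()
            o.insert(0, "sample_id", s.sample_id)
            origins.append(o)
        save_tsv(pd.concat(origins, ignore_index=True), "truth_read_origins.tsv",
                 index=False)

        proteins = detected_proteins(records)
        peptides, plex, impurity = simulate_tmt_experiment(proteins, truth, None,
                                                           config.tmt, rng)
        save_tsv(peptides, "peptides.tsv", index=False)
        save_tsv(plex, "plex.tsv", index=False)
        impurity.to_csv(outdir / "impurity.csv")
        artifacts.append(outdir / "impurity.csv")
        mito = pd.DataFrame({"symbol": [r.gene_id for r in records
                                        if r.genome_of_origin == "mitochondrial"
                                        or r.gene_class == "mito-associated"]})
        save_tsv(mito, "mito_list.tsv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- process-reads ------------------------------------------------
    stage = "process-reads"
    try:
        coding = anno.coding_records(records)
        contaminants = anno.contaminant_records(records)
        index = align.KmerIndex(coding, config.kmer_size)
        weights_by_sample, compat_by_sample, lib_sizes = {}, {}, {}
        logs = []
        for s in samples:
            raw = ReadSet(s.sample_id, s.assay, s.reads)
            counts, compat, weights, log = process_sample(raw, index, contaminants, config)
            weights_by_sample[s.sample_id] = weights
            compat_by_sample[s.sample_id] = compat
            lib_sizes[s.sample_id] = counts["input"]
            log.insert(0, "sample_id", s.sample_id)
            logs.append(log)
        save_tsv(pd.concat(logs, ignore_index=True), "dispositions.tsv", index=False)

        rpf_ids = sorted(s.sample_id for s in samples if s.assay == "RPF")
        mrna_ids = sorted(s.sample_id for s in samples if s.assay == "mRNA")
        counts_all, profiles = align.count_and_profile(
            weights_by_sample, compat_by_sample, records, lib_sizes)
        rpf_cm = align.CountMatrix(counts_all[rpf_ids],
                                   pd.Series({k: float(lib_sizes[k]) for k in rpf_ids}),
                                   "RPF")
        mrna_cm = align.CountMatrix(counts_all[mrna_ids],
                                    pd.Series({k: float(lib_sizes[k]) for k in mrna_ids}),
                                    "mRNA")
        save_tsv(rpf_cm.counts, "rpf_counts.tsv", index_label="gene_id")
        save_tsv(mrna_cm.counts, "mrna_counts.tsv", index_label="gene_id")
        bg_dir = outdir / "coverage"
        bg_dir.mkdir(exist_ok=True)
        mt_tids = {r.transcript_id for r in records if r.gene_class == "mt-OXPHOS"}
        for (tid, sample), profile in sorted(profiles.items()):
            if tid in mt_tids:
                align.write_bedgraph(profile, bg_dir / f"{tid}.{sample}.bedgraph")
                artifacts.append(bg_dir / f"{tid}.{sample}.bedgraph")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- occupancy ----------------------------------------------------
    stage = "occupancy"
    try:
        occ_table = occ.compute_occupancy(rpf_cm, mrna_cm, design,
                                          config.stats.occupancy_mode)
        flat = occ_table.copy()
        flat.columns = [f"{g}_{r}" for g, r in occ_table.columns]
        save_tsv(flat, "occupancy.tsv", index_label="gene_id")
        stats_table = occ.occupancy_stats(occ_table,
                                          alpha=config.stats.occ_alpha,
                                          dunnett_method=config.stats.dunnett_method,
                                          mc_seed=config.seed)
        verdicts = occ.classify_occupancy_change(stats_table, config.stats.occ_alpha)
        save_tsv(stats_table.join(verdicts), "occupancy_stats.tsv",
                 index_label="gene_id")
        pol = occ.polarity_table(profiles)
        save_tsv(pol, "polarity.tsv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- proteomics ---------------------------------------------------
    stage = "proteomics"
    try:
        corrected = prot.correct_isotope_impurities(peptides, impurity)
        normalized = prot.normalize_channels(corrected)
        rolled = prot.rollup_proteins(normalized)
        pstats = prot.protein_statistics(rolled, plex,
                                         config.stats.fdr_alpha,
                                         config.stats.t_alpha,
                                         config.stats.ttest)
        pstats = prot.annotate_mito(pstats, mito["symbol"])
        pverdicts = prot.classify_protein_change(pstats)
        save_tsv(pstats.join(pverdicts), "protein_stats.tsv", index_label="protein_id")
        save_tsv(prot.dotplot_table(pstats[pstats["mito_flag"]]),
                 "dotplot_table.tsv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- integrate ----------------------------------------------------
    stage = "integrate"
    try:
        joined = integrate.join_omics(verdicts, pverdicts)
        dichotomy = integrate.classify_dichotomy(joined)
        save_tsv(dichotomy, "dichotomy.tsv", index=False)
        summary, text = integrate.stratify_report(dichotomy, records)
        save_tsv(summary, "dichotomy_summary.tsv", index=False)
        (outdir / "dichotomy_report.txt").write_text(text)
        artifacts.append(outdir / "dichotomy_report.txt")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    manifest = {"seed": config.seed,
                "artifacts": {str(p.relative_to(outdir)): _sha256(p)
                              for p in sorted(set(artifacts))}}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Format validation

def validate_formats(paths: dict[str, str]) -> list[dict[str, str]]:
    """Well-formedness checks for the pipeline's input files.

    ``paths`` maps kinds (annotation_fasta, cds_bed, samples_tsv, plex_tsv)
    to file paths; each violation is reported with file, line and rule id.
    """
    violations: list[dict[str, str]] = []

    def report(file: str, line: int, rule: str, message: str) -> None:
        violations.append({"file": file, "line": str(line), "rule": rule,
                           "message": message})

    seqs = {}
    if "annotation_fasta" in paths:
        path = paths["annotation_fasta"]
        try:
            from Bio import SeqIO
            for rec in SeqIO.parse(path, "fasta"):
                seqs[rec.id] = len(rec.seq)
                if set(str(rec.seq).upper()) - set("ACGTN"):
                    report(path, 0, "fasta-alphabet", f"{rec.id}: non-nucleotide characters")
            if not seqs:
                report(path, 0, "fasta-empty", "no records parsed")
        except (FileNotFoundError, ValueError) as e:
            report(path, 0, "fasta-parse", str(e))

    if "cds_bed" in paths:
        path = paths["cds_bed"]
        try:
            with open(path) as fh:
                for i, line in enumerate(fh, 1):
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) < 4:
                        report(path, i, "bed-columns", "fewer than 4 columns")
                        continue
                    try:
                        start, end = int(parts[1]), int(parts[2])
                    except ValueError:
                        report(path, i, "bed-coords", "non-integer coordinates")
                        continue
                    if not 0 <= start < end:
                        report(path, i, "bed-interval", f"invalid interval [{start},{end})")
                    if seqs and parts[0] in seqs and end > seqs[parts[0]]:
                        report(path, i, "bed-bounds",
                               f"CDS end {end} exceeds transcript length {seqs[parts[0]]}")
                    if seqs and parts[0] not in seqs:
                        report(path, i, "bed-reference", f"{parts[0]} not in FASTA")
        except FileNotFoundError as e:
            report(path, 0, "bed-missing", str(e))

    if "samples_tsv" in paths:
        path = paths["samples_tsv"]
        try:
            df = pd.read_csv(path, sep="\t")
            need = {"sample_id", "genotype", "replicate", "assay"}
            if not need.issubset(df.columns):
                report(path, 1, "design-columns", f"missing columns {need - set(df.columns)}")
            else:
                keys = set(zip(df.genotype, df.replicate, df.assay))
                for g, r, a in keys:
                    if a == "RPF" and (g, r, "mRNA") not in keys:
                        report(path, 0, "design-unpaired",
                               f"RPF sample {g} rep {r} lacks an mRNA partner")
        except (FileNotFoundError, pd.errors.ParserError) as e:
            report(path, 0, "design-parse", str(e))

    if "plex_tsv" in paths:
        path = paths["plex_tsv"]
        try:
            plex = pd.read_csv(path, sep="\t")
            if len(plex) > 16:
                report(path, 0, "plex-size", f"{len(plex)} channels against a 16-plex")
            if plex["channel"].duplicated().any():
                report(path, 0, "plex-duplicate", "duplicate channel labels")
        except (FileNotFoundError, pd.errors.ParserError, KeyError) as e:
            report(path, 0, "plex-parse", str(e))

    return violations
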