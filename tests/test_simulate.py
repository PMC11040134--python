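import io

import numpy as np
import pandas as pd
import pytest

from mitoribo.annotation import build_default_annotation
from mitoribo.simulate import (
    DesignError,
    RiboseqParams,
    SampleDesign,
    TmtParams,
    TruthTable,
    check_paired,
    default_plex_design,
    paired_design,
    simulate_counts,
    simulate_riboseq_experiment,
    simulate_tmt_experiment,
    write_fastq,
)


def _mean_columns(df, prefix):
    return df[[c for c in df.columns if c.startswith(prefix)]].mean(axis=1)


class TestRiboseqSimulation:
    def test_unpaired_rpf_sample_rejected(self):
        design = [SampleDesign("x", "control", 1, "RPF")]
        with pytest.raises(DesignError, match="mRNA partner"):
            check_paired(design)

    def test_null_config_reads_originate_within_cds(self, annotation, design, null_truth):
        params = RiboseqParams(reads_per_sample=800, contaminant_fraction=0.0)
        samples, _, _ = simulate_riboseq_experiment(annotation, design, null_truth,
                                                    params, seed=3)
        genes = {r.gene_id: r for r in annotation if not r.is_contaminant}
        for s in samples:
            assert not s.origins["origin"].str.startswith("contaminant").any()
            rec_len = s.origins["origin"].map(lambda g: genes[g].cds_length)
            assert ((s.origins["start"] >= 0)
                    & (s.origins["start"] + s.origins["insert_length"] <= rec_len)).all()

    def test_planted_occupancy_fc_recovered_at_depth(self, annotation, design, gene_ids):
        """Empirical RPF/mRNA ratio for a planted 3x gene converges to ~3x
        the control ratio at 50,000 reads/sample."""
        truth = TruthTable.null(gene_ids).set_occupancy_fc(["mt-Nd2"], het=3.0, homo=3.0)
        rpf, mrna, _ = simulate_counts(annotation, design, truth,
                                       RiboseqParams(reads_per_sample=50_000), seed=5)
        occ = rpf / mrna.to_numpy()
        est = (_mean_columns(occ, "het") / _mean_columns(occ, "control"))["mt-Nd2"]
        assert est == pytest.approx(3.0, rel=0.35)
        others = (_mean_columns(occ, "het") / _mean_columns(occ, "control")).drop("mt-Nd2")
        assert np.median(others) == pytest.approx(1.0, rel=0.2)

    def test_fixed_seed_reproduces_identical_fastq(self, annotation, design,
                                                   null_truth, tmp_path):
        params = RiboseqParams(reads_per_sample=300)
        out = []
        for run in range(2):
            samples, _, _ = simulate_riboseq_experiment(annotation, design, null_truth,
                                                        params, seed=9)
            buf = io.StringIO()
            for rid, seq, qual in samples[0].reads:
                buf.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_read_origins_cover_every_read(self, annotation, design, null_truth):
        samples, _, _ = simulate_riboseq_experiment(
            annotation, design, null_truth, RiboseqParams(reads_per_sample=500), seed=2)
        for s in samples:
            assert set(s.origins["read_id"]) == {r[0] for r in s.reads}

    def test_contaminant_fraction_planted(self, annotation, design, null_truth):
        params = RiboseqParams(reads_per_sample=4000, contaminant_fraction=0.1)
        samples, _, _ = simulate_riboseq_experiment(annotation, design, null_truth,
                                                    params, seed=8)
        s = samples[0]
        frac = s.origins["origin"].str.startswith("contaminant").mean()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_skew_tilts_starts_toward_3prime(self, annotation, design, gene_ids):
        truth = TruthTable.null(gene_ids).set_skew(["mt-Nd1"], 0.9)
        params = RiboseqParams(reads_per_sample=30_000, contaminant_fraction=0.0)
        samples, _, _ = simulate_riboseq_experiment(annotation, design, truth,
                                                    params, seed=4)
        rpf = next(s for s in samples if s.assay == "RPF")
        rec = next(r for r in annotation if r.gene_id == "mt-Nd1")
        sub = rpf.origins[rpf.origins["origin"] == "mt-Nd1"]
        rel = sub["start"] / (rec.cds_length - sub["insert_length"])
        assert rel.mean() > 0.55  # uniform would give ~0.5

    def test_truth_consistency_at_high_depth(self, annotation, design, gene_ids):
        """Empirical fold changes converge to the truth table within 10%
        at 10x the default depth."""
        truth = (TruthTable.null(gene_ids)
                 .set_occupancy_fc(["mt-Nd1", "mt-Nd5"], het=3.0, homo=2.0)
                 .set_mrna_fc(["mt-Co1"], het=0.5, homo=0.5))
        params = RiboseqParams(reads_per_sample=500_000)
        rpf, mrna, _ = simulate_counts(annotation, design, truth, params, seed=6)
        occ = rpf / mrna.to_numpy()
        est_fc = _mean_columns(occ, "het") / _mean_columns(occ, "control")
        assert est_fc["mt-Nd1"] == pytest.approx(3.0, rel=0.10)
        assert est_fc["mt-Nd5"] == pytest.approx(3.0, rel=0.10)
        mrna_fc = _mean_columns(mrna, "het") / _mean_columns(mrna, "control")
        assert mrna_fc["mt-Co1"] == pytest.approx(0.5, rel=0.10)


class TestTruthTable:
    def test_nonpositive_fold_change_rejected(self, gene_ids):
        genes = TruthTable.null(gene_ids).genes
        genes.loc[0, "occ_fc_het"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            TruthTable(genes, TruthTable.null(gene_ids).proteins)

    def test_skew_out_of_range_rejected(self, gene_ids):
        genes = TruthTable.null(gene_ids).genes
        genes.loc[0, "skew"] = 1.5
        with pytest.raises(ValueError, match="skew"):
            TruthTable(genes, TruthTable.null(gene_ids).proteins)


class TestTmtSimulation:
    def test_default_plex_has_15_occupied_one_unused(self):
        plex = default_plex_design()
        assert len(plex) == 16
        counts = plex["genotype"].value_counts()
        assert counts["unused"] == 1
        assert counts[["control", "het", "homo"]].tolist() == [5, 5, 5]

    def test_more_samples_than_channels_rejected(self):
        with pytest.raises(DesignError, match="channels"):
            default_plex_design(n_replicates=6)

    def test_zero_noise_zero_shift_channels_identical(self):
        params = TmtParams(noise_sigma=0.0, channel_loading_sigma=0.0,
                           impurity_spill=0.0, dropout_scale=0.0)
        pep, plex, _ = simulate_tmt_experiment(["P1"], TruthTable.null(["P1"]),
                                               params=params, seed=0)
        used = plex.loc[plex["genotype"] != "unused", "channel"]
        vals = pep[used].to_numpy()
        assert np.allclose(vals, vals[:, [0]])

    def test_planted_homo_shift_recovered_at_low_noise(self):
        params = TmtParams(noise_sigma=0.05, impurity_spill=0.0, dropout_scale=0.0,
                           channel_loading_sigma=0.0)
        truth = TruthTable.null(["X"]).set_protein_shift(["X"], homo=-1.0)
        pep, plex, _ = simulate_tmt_experiment(["X"], truth, params=params, seed=1)
        log2 = np.log2(pep[plex.loc[plex.genotype != "unused", "channel"]])
        homo = log2[plex.loc[plex.genotype == "homo", "channel"]].mean(axis=1)
        ctrl = log2[plex.loc[plex.genotype == "control", "channel"]].mean(axis=1)
        assert (homo - ctrl).mean() == pytest.approx(-1.0, abs=0.1)

    def test_every_protein_has_a_peptide_and_unused_channels_empty(self):
        pep, plex, _ = simulate_tmt_experiment(["A", "B", "C"],
                                               TruthTable.null(["A", "B", "C"]), seed=2)
        assert set(pep["protein_id"]) == {"A", "B", "C"}
        unused = plex.loc[plex["genotype"] == "unused", "channel"]
        assert pep[unused].isna().all().all()

    def test_dropout_prefers_low_abundance(self):
        params = TmtParams(dropout_midpoint=18.0, dropout_scale=1.5,
                           protein_sigma=3.0)
        ids = [f"P{i}" for i in range(60)]
        pep, plex, _ = simulate_tmt_experiment(ids, TruthTable.null(ids),
                                               params=params, seed=3)
        used = plex.loc[plex["genotype"] != "unused", "channel"]
        vals = pep[used]
        mean_int = np.log2(vals.mean(axis=1))
        missing = vals.isna().mean(axis=1)
        present = ~mean_int.isna()
        low = mean_int[present] < mean_int[present].median()
        assert missing[present][low].mean() > missing[present][~low].mean()
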