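import numpy as np
import pytest

from mitoribo.align import (
    CompatMap,
    KmerIndex,
    assign_reads,
    count_and_profile,
    em_resolve_multimappers,
    export_sam,
    ingest_alignments,
)
from mitoribo.annotation import ConfigurationError, TranscriptRecord
from mitoribo.reads import ReadSet


def _tr(gene, seq, cls="other", genome="nuclear"):
    return TranscriptRecord(gene, f"{gene}-201", seq, 0, len(seq), genome, cls)


def _rs(pairs, sample="s", assay="RPF"):
    return ReadSet(sample, assay, [(rid, seq, None) for rid, seq in pairs])


class TestAssignment:
    def test_unique_read_maps_with_correct_offset(self, annotation):
        rec = next(r for r in annotation if r.gene_id == "mt-Nd1")
        read = rec.sequence[rec.cds_start + 7: rec.cds_start + 7 + 28]
        compat, unmapped = assign_reads(_rs([("r0", read)]), annotation)
        assert unmapped == []
        assert compat["r0"] == [(rec.transcript_id, rec.cds_start + 7)]

    def test_shared_read_reports_both_paralogs(self):
        core = "ACGTGACCTTAGGCATCGATGCTAGCTT"
        a = _tr("A", "TTTTT" + core + "GGGGG")
        b = _tr("B", "CCCCC" + core + "AAAAA")
        compat, _ = assign_reads(_rs([("r0", core)]), [a, b])
        assert {t for t, _ in compat["r0"]} == {"A-201", "B-201"}

    def test_kmer_larger_than_read_rejected(self, annotation):
        with pytest.raises(ConfigurationError, match="larger"):
            assign_reads(_rs([("r0", "ACGTACGT")]), annotation, k=12)

    def test_matches_brute_force_substring_scan(self, annotation, rng):
        """Compatibility sets equal a quadratic scan over all transcripts."""
        coding = [r for r in annotation if not r.is_contaminant]
        reads = []
        for i in range(300):
            rec = coding[int(rng.integers(0, len(coding)))]
            length = int(rng.integers(20, 35))
            start = int(rng.integers(0, len(rec.sequence) - length + 1))
            reads.append((f"r{i}", rec.sequence[start: start + length]))
        compat, unmapped = assign_reads(_rs(reads), coding)
        for rid, seq in reads:
            expected = []
            for rec in coding:
                pos = rec.sequence.find(seq)
                while pos != -1:
                    expected.append((rec.transcript_id, pos))
                    pos = rec.sequence.find(seq, pos + 1)
            assert compat.get(rid, []) == sorted(expected)
        assert not unmapped


class TestEm:
    def test_unique_read_gets_weight_one(self):
        compat = {"r0": [("A", 0)]}
        weights, counts, _ = em_resolve_multimappers(compat)
        assert weights["r0"] == [("A", 1.0)]
        assert counts["A"] == 1.0

    def test_shared_read_converges_to_dominant_transcript(self):
        """Two unique reads on A, one shared A/B, none unique to B:
        the fixed point s = (2+s)/3 puts the shared read fully on A."""
        compat = {"u1": [("A", 0)], "u2": [("A", 5)], "s": [("A", 9), ("B", 0)]}
        weights, counts, ll = em_resolve_multimappers(compat)
        w = dict(weights["s"])
        assert w["A"] == pytest.approx(1.0, abs=1e-6)
        assert counts["A"] == pytest.approx(3.0, abs=1e-5)

    def test_symmetric_case_splits_half_half(self):
        compat = {"a": [("A", 0)], "b": [("B", 0)], "s": [("A", 3), ("B", 3)]}
        weights, _, _ = em_resolve_multimappers(compat)
        w = dict(weights["s"])
        assert w["A"] == pytest.approx(0.5, abs=1e-9)

    def test_loglikelihood_nondecreasing(self, rng):
        tids = [f"T{i}" for i in range(6)]
        compat = {}
        for i in range(150):
            k = int(rng.integers(1, 4))
            picks = rng.choice(6, size=k, replace=False)
            compat[f"r{i}"] = [(tids[j], 0) for j in picks]
        _, _, ll = em_resolve_multimappers(compat)
        assert all(b - a > -1e-9 for a, b in zip(ll, ll[1:]))

    def test_weights_sum_to_one_per_read(self, rng):
        compat = {f"r{i}": [(f"T{j}", 0) for j in
                            rng.choice(5, size=int(rng.integers(1, 4)), replace=False)]
                  for i in range(50)}
        weights, counts, _ = em_resolve_multimappers(compat)
        for w in weights.values():
            assert sum(x for _, x in w) == pytest.approx(1.0, abs=1e-9)
        assert counts.sum() == pytest.approx(len(compat), abs=1e-6)


class TestCounting:
    def test_unique_counts_and_conservation(self, annotation):
        coding = [r for r in annotation if not r.is_contaminant]
        rec = coding[0]
        reads = [(f"r{i}", rec.sequence[rec.cds_start + i: rec.cds_start + i + 26])
                 for i in range(7)]
        compat, _ = assign_reads(_rs(reads), coding)
        weights, _, _ = em_resolve_multimappers(compat)
        counts, profiles = count_and_profile({"s": weights}, {"s": compat},
                                             coding, {"s": 7})
        assert counts.loc[rec.gene_id, "s"] == pytest.approx(7.0)
        assert counts["s"].sum() == pytest.approx(7.0, abs=1e-6)
        prof = profiles[(rec.transcript_id, "s")]
        assert prof.total == pytest.approx(7.0)
        assert np.all(prof.counts[:7] == 1)

    def test_unknown_sample_rejected(self, annotation):
        with pytest.raises(ValueError, match="absent"):
            count_and_profile({"s": {}}, {"s": {}}, annotation, {"other": 1})


class TestSamInterchange:
    def test_mapq_boundary(self, annotation, tmp_path):
        coding = [r for r in annotation if not r.is_contaminant]
        rec = coding[0]
        read = rec.sequence[:30]
        rs = _rs([("keep", read), ("drop", read)])
        compat = {"keep": [(rec.transcript_id, 0)], "drop": [(rec.transcript_id, 0)]}
        path = tmp_path / "t.sam"
        export_sam(rs, {"keep": compat["keep"]}, coding, path, mapq=5)
        export_sam(_rs([("drop", read)]), {"drop": compat["drop"]},
                   coding, tmp_path / "low.sam", mapq=4)
        assert "keep" in ingest_alignments(path, coding)
        assert ingest_alignments(tmp_path / "low.sam", coding) == {}

    def test_round_trip_preserves_compatibility(self, annotation, rng, tmp_path):
        """Internal matcher -> SAM -> ingestion reproduces the same map."""
        coding = [r for r in annotation if not r.is_contaminant]
        reads = []
        for i in range(120):
            rec = coding[int(rng.integers(0, len(coding)))]
            length = int(rng.integers(24, 33))
            start = int(rng.integers(0, len(rec.sequence) - length + 1))
            reads.append((f"r{i}", rec.sequence[start: start + length]))
        rs = _rs(reads)
        compat, _ = assign_reads(rs, coding)
        path = tmp_path / "roundtrip.sam"
        export_sam(rs, compat, coding, path)
        back = ingest_alignments(path, coding, mapq_min=5)
        assert back == {r: sorted(h) for r, h in compat.items()}

    def test_unknown_reference_rejected(self, annotation, tmp_path):
        coding = [r for r in annotation if not r.is_contaminant]
        rec = coding[0]
        rs = _rs([("r0", rec.sequence[:30])])
        compat = {"r0": [(rec.transcript_id, 0)]}
        path = tmp_path / "bad.sam"
        export_sam(rs, compat, coding, path)
        with pytest.raises(ValueError, match="absent"):
            ingest_alignments(path, coding[1:])
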