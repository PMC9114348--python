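import numpy as np
import pytest

from lncpig import syndata
from lncpig.io_model import PIGMENTED


def _gc(s):
    return (s.count("G") + s.count("C")) / len(s)


class TestTranscriptome:
    def test_same_seed_identical_output(self):
        a, dba, ta = syndata.generate_transcriptome(20, 20, seed=42)
        b, dbb, tb = syndata.generate_transcriptome(20, 20, seed=42)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert [r.exons for r in a] == [r.exons for r in b]
        assert dba == dbb
        assert ta.coding_labels == tb.coding_labels

    def test_gc_separation_between_classes(self):
        """Coding minus noncoding mean GC > 2 percentage points (the
        generator's class calibration)."""
        recs, _, truth = syndata.generate_transcriptome(300, 300, seed=1)
        gc = {"coding": [], "noncoding": []}
        for r in recs:
            gc[truth.coding_labels[r.transcript_id]].append(_gc(r.sequence))
        assert np.mean(gc["coding"]) - np.mean(gc["noncoding"]) > 0.02

    def test_class_orderings_length_exons(self):
        recs, _, truth = syndata.generate_transcriptome(300, 300, seed=2)
        by = {"coding": [], "noncoding": []}
        for r in recs:
            by[truth.coding_labels[r.transcript_id]].append((r.length, r.n_exons))
        cod = np.array(by["coding"])
        non = np.array(by["noncoding"])
        assert cod[:, 0].mean() > non[:, 0].mean()  # length
        assert cod[:, 1].mean() > non[:, 1].mean()  # exons

    def test_no_noncoding_requested(self):
        _, _, truth = syndata.generate_transcriptome(10, 0, seed=0)
        assert "noncoding" not in set(truth.coding_labels.values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            syndata.generate_transcriptome(-1, 5, seed=0)

    def test_impossible_length_params_rejected(self):
        with pytest.raises(ValueError):
            syndata.generate_transcriptome(
                5, 5, seed=0, params=syndata.TranscriptomeParams(coding_length_mean=-10)
            )


class TestCounts:
    def test_poisson_limit(self):
        """dispersion -> 0 with large mean: sample variance ~= mean."""
        rng_truth = syndata.SyntheticTruth()
        rng = np.random.default_rng(0)
        draws = syndata._nb_draw(rng, np.full(10_000, 1000.0), 1e-8)
        assert abs(draws.var() / draws.mean() - 1.0) < 0.05

    def test_null_case_ratios_center_on_one(self):
        recs, _, truth = syndata.generate_transcriptome(40, 40, seed=3)
        cm = syndata.generate_counts(recs, truth, n_de=0, seed=3)
        pig = np.array([cm.group[s] == PIGMENTED for s in cm.sample_ids])
        ratios = (cm.array[:, pig].mean(axis=1) + 1) / (cm.array[:, ~pig].mean(axis=1) + 1)
        assert abs(np.median(np.log2(ratios))) < 0.3

    def test_seed_reproduces_matrix(self):
        recs, _, truth = syndata.generate_transcriptome(15, 15, seed=4)
        a = syndata.generate_counts(recs, truth, n_de=4, seed=9)
        recs2, _, truth2 = syndata.generate_transcriptome(15, 15, seed=4)
        b = syndata.generate_counts(recs2, truth2, n_de=4, seed=9)
        np.testing.assert_array_equal(a.array, b.array)

    def test_n_de_exceeding_features_rejected(self):
        recs, _, truth = syndata.generate_transcriptome(3, 3, seed=0)
        with pytest.raises(ValueError):
            syndata.generate_counts(recs, truth, n_de=100, seed=0)

    def test_noncoding_lower_expression(self):
        recs, _, truth = syndata.generate_transcriptome(150, 150, seed=5)
        cm = syndata.generate_counts(recs, truth, n_de=0, seed=5)
        is_cod = np.array(
            [truth.coding_labels[f] == "coding" for f in cm.feature_ids]
        )
        assert cm.array[is_cod].mean() > cm.array[~is_cod].mean()


@pytest.fixture(scope="module")
def study():
    recs, _, truth = syndata.generate_transcriptome(80, 80, seed=6)
    cm = syndata.generate_counts(recs, truth, n_de=40, seed=6)
    return recs, truth, cm


class TestPlanting:

    def test_cis_decoys_beyond_window(self, study):
        recs, truth, cm = study
        syndata.plant_cis_pairs(recs, truth, cm, n_pairs=4, seed=1)
        assert all(p["distance"] > 300_000 for p in truth.decoy_cis_pairs)
        assert all(p["distance"] <= 300_000 for p in truth.cis_pairs)
        loci = truth.gene_loci()
        by_tid = {t.transcript_id: t for t in recs}
        for p in truth.cis_pairs + truth.decoy_cis_pairs:
            lnc = loci[by_tid[p["lnc_id"]].gene_id]
            gene = loci[by_tid[p["gene_id"]].gene_id]
            assert gene.chrom == lnc.chrom
            gap = max(lnc.span[0], gene.span[0]) - min(lnc.span[1], gene.span[1])
            assert max(gap, 0) == p["distance"]

    def test_cis_window_zero_rejected(self, study):
        recs, truth, cm = study
        with pytest.raises(ValueError):
            syndata.plant_cis_pairs(recs, truth, cm, n_pairs=2, window=0, seed=0)

    def test_planted_cis_correlation(self, study):
        """Shared latent factor: empirical mean |r| of planted pairs well
        above background at n = 11 samples."""
        recs, truth, cm = study
        logc = np.log2(cm.array + 1.0)
        idx = {f: i for i, f in enumerate(cm.feature_ids)}
        rs = [
            abs(np.corrcoef(logc[idx[p["lnc_id"]]], logc[idx[p["gene_id"]]])[0, 1])
            for p in truth.cis_pairs
        ]
        assert np.mean(rs) >= 0.6

    def test_trans_same_seed_identical_sequences(self):
        out = []
        for _ in range(2):
            recs, _, truth = syndata.generate_transcriptome(60, 60, seed=8)
            cm = syndata.generate_counts(recs, truth, n_de=30, seed=8)
            syndata.plant_trans_pairs(recs, truth, cm, n_pairs=3, seed=2)
            out.append({r.transcript_id: r.sequence for r in recs})
        assert out[0] == out[1]

    def test_trans_seg_len_exceeding_lnc_rejected(self):
        recs, _, truth = syndata.generate_transcriptome(60, 60, seed=8)
        cm = syndata.generate_counts(recs, truth, n_de=30, seed=8)
        with pytest.raises(ValueError):
            syndata.plant_trans_pairs(recs, truth, cm, n_pairs=2, seg_len=10_000, seed=0)

    def test_trans_segment_is_reverse_complement(self):
        from lncpig.io_model import reverse_complement

        recs, _, truth = syndata.generate_transcriptome(60, 60, seed=9)
        cm = syndata.generate_counts(recs, truth, n_de=30, seed=9)
        syndata.plant_trans_pairs(recs, truth, cm, n_pairs=3, seg_len=20, seed=3)
        by_tid = {t.transcript_id: t for t in recs}
        for p in truth.trans_pairs:
            lnc = by_tid[p["lnc_id"]].sequence
            mrna = by_tid[p["gene_id"]].sequence
            seg = lnc[p["lnc_pos"] : p["lnc_pos"] + p["seg_len"]]
            assert seg == reverse_complement(
                mrna[p["mrna_pos"] : p["mrna_pos"] + p["seg_len"]]
            )


class TestQpcr:
    def _truth_with(self, lfc):
        t = syndata.SyntheticTruth()
        t.de_status["GENE"] = {"dir": "up", "log2fc": lfc, "base_mean": 100.0}
        return t

    def test_zero_noise_exact_ddct(self):
        truth = self._truth_with(2.0)
        ms = syndata.generate_qpcr(truth, ["GENE"], n_per_group=4, seed=0, noise_sd=0.0)
        from lncpig.downstream import qpcr_analysis

        (s,) = qpcr_analysis(ms)
        assert s.ddct == pytest.approx(-2.0, abs=1e-9)
        assert s.log2fc == pytest.approx(2.0, abs=1e-9)

    def test_empty_when_no_samples(self):
        truth = self._truth_with(1.0)
        assert syndata.generate_qpcr(truth, ["GENE"], n_per_group=0, seed=0) == []

    def test_duplicates_emitted(self):
        truth = self._truth_with(1.0)
        ms = syndata.generate_qpcr(truth, ["GENE"], n_per_group=3, seed=0, duplicates=2)
        assert len(ms) == 2 * 3 * 2  # groups x samples x duplicates
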