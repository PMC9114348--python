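import numpy as np
import pytest

from lncpig import targets
from lncpig.io_model import ExpressionMatrix, GeneLocus, reverse_complement
from .conftest import random_seq

PAIRS = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


def ndg_oracle(a, b, min_run=targets.DEFAULT_MIN_RUN):
    """Brute-force offset scan, independent reimplementation."""
    b_rev = b[::-1]
    n, m = len(a), len(b_rev)
    best = 0.0
    for s in range(-(m - 1), n):
        dg = 0.0
        run = []
        for i in range(max(s, 0), min(n, s + m)):
            e = PAIRS.get((a[i], b_rev[i - s]))
            if e is not None:
                run.append(e)
            else:
                if len(run) >= min_run:
                    dg += sum(run)
                run = []
        if len(run) >= min_run:
            dg += sum(run)
        best = min(best, dg)
    return best / min(n, m)


def _locus(gid, chrom, start, end, biotype="coding"):
    return GeneLocus(gene_id=gid, chrom=chrom, strand="+", span=(start, end), biotype=biotype)


class TestCisCandidates:
    def test_gap_of_250kb_is_candidate(self):
        lnc = _locus("L", "chr1", 500_000, 501_000, "lncRNA")
        gene = _locus("G", "chr1", 200_000, 250_000)
        (hit,) = targets.cis_candidates(lnc, [gene])
        assert hit == ("G", 250_000)

    def test_window_boundary_inclusive(self):
        lnc = _locus("L", "chr1", 1_000_000, 1_001_000, "lncRNA")
        inside = _locus("Gin", "chr1", 1_301_000, 1_302_000)
        outside = _locus("Gout", "chr1", 1_301_001, 1_302_000)
        assert targets.cis_candidates(lnc, [inside]) == [("Gin", 300_000)]
        assert targets.cis_candidates(lnc, [outside]) == []

    def test_overlap_distance_zero(self):
        lnc = _locus("L", "chr1", 100, 900, "lncRNA")
        gene = _locus("G", "chr1", 500, 2_000)
        assert targets.cis_candidates(lnc, [gene]) == [("G", 0)]

    def test_other_chromosome_ignored(self):
        lnc = _locus("L", "chr1", 100, 900, "lncRNA")
        gene = _locus("G", "chr2", 100, 900)
        assert targets.cis_candidates(lnc, [gene]) == []


class TestPearson:
    def test_perfect_positive(self):
        r, p = targets.pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = targets.pearson([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        r, p = targets.pearson([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and p == 1.0

    def test_p_matches_permutation_estimate(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=11)
        y = 0.7 * x + rng.normal(size=11)
        r_obs, p = targets.pearson(x, y)
        n_perm = 20_000
        perms = np.array([np.corrcoef(x, rng.permutation(y))[0, 1] for _ in range(n_perm)])
        p_perm = (np.abs(perms) >= abs(r_obs) - 1e-12).mean()
        assert p == pytest.approx(p_perm, abs=0.01)


class TestNdg:
    def test_poly_a_no_pairs(self):
        val, _ = targets.ndg("A" * 30, "A" * 30)
        assert val == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            targets.ndg("", "ACGT" * 10)

    def test_planted_20nt_complement_in_at_context(self):
        """A 20-nt exact reverse complement in pure-A context: twenty A:U
        pairs at -2 each give dG <= -40."""
        rng = np.random.default_rng(21)
        core = random_seq(rng, 20)
        mrna = "A" * 40 + core + "A" * 40
        lnc = "A" * 30 + reverse_complement(core) + "A" * 30
        val, _ = targets.ndg(lnc, mrna)
        assert val * min(len(lnc), len(mrna)) <= -40.0

    def test_symmetry(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(20, 60)))
            b = random_seq(rng, int(rng.integers(20, 60)))
            assert targets.ndg(a, b)[0] == pytest.approx(targets.ndg(b, a)[0])

    def test_monotone_in_segment_extension(self):
        """Extending the complementary segment never increases the raw
        duplex energy."""
        rng = np.random.default_rng(23)
        mrna = random_seq(rng, 120)
        prev = 0.0
        for seg_len in (20, 24, 28, 32):
            lnc = "A" * 25 + reverse_complement(mrna[40 : 40 + seg_len]) + "A" * 25
            val, _ = targets.ndg(lnc, mrna)
            dg = val * min(len(lnc), len(mrna))
            assert dg <= prev + 1e-9
            prev = dg

    def test_matches_exhaustive_offset_oracle(self):
        rng = np.random.default_rng(24)
        for _ in range(25):
            a = random_seq(rng, int(rng.integers(10, 50)))
            b = random_seq(rng, int(rng.integers(10, 50)))
            assert targets.ndg(a, b, min_run=4)[0] == pytest.approx(
                ndg_oracle(a, b, min_run=4)
            )


class TestLinkTargets:
    def _expr(self, ids, values):
        return ExpressionMatrix(feature_ids=ids, sample_ids=[f"s{i}" for i in range(11)], values=values)

    def test_planted_cis_pair_recovered_and_decoy_gated(self):
        rng = np.random.default_rng(25)
        shared = rng.normal(0, 1, 11)
        vals = np.vstack(
            [
                10 ** (shared + rng.normal(0, 0.1, 11)),
                10 ** (shared + rng.normal(0, 0.1, 11)),
                10 ** (shared + rng.normal(0, 0.1, 11)),
            ]
        )
        expr = self._expr(["L", "Gnear", "Gfar"], vals)
        loci = {
            "L": _locus("L", "chr1", 1_000_000, 1_002_000, "lncRNA"),
            "Gnear": _locus("Gnear", "chr1", 1_100_000, 1_110_000),
            "Gfar": _locus("Gfar", "chr1", 1_400_000, 1_410_000),
        }
        links = targets.link_targets(["L"], ["Gnear", "Gfar"], expr, loci=loci, mode="cis")
        assert [(L.gene_id, L.passed) for L in links] == [("Gnear", True)]
        assert links[0].distance == 98_000
        assert all(L.distance <= targets.DEFAULT_WINDOW for L in links)

    def test_trans_gate_requires_complementarity(self):
        rng = np.random.default_rng(26)
        shared = rng.normal(0, 1, 11)
        vals = np.vstack(
            [10 ** (shared + rng.normal(0, 0.05, 11)) for _ in range(3)]
        )
        expr = self._expr(["L", "Gcomp", "Grand"], vals)
        mrna = random_seq(rng, 400)
        lnc = random_seq(rng, 150) + reverse_complement(mrna[100:125]) + random_seq(rng, 150)
        seqs = {"L": lnc, "Gcomp": mrna, "Grand": random_seq(rng, 400)}
        links = targets.link_targets(
            ["L"], ["Gcomp", "Grand"], expr, sequences=seqs, mode="trans"
        )
        assert [(L.gene_id, L.passed) for L in links] == [("Gcomp", True)]
        assert links[0].ndg <= targets.DEFAULT_NDG_THRESHOLD

    def test_emitted_links_satisfy_own_invariants(self, small_study):
        import json
        import os

        import pandas as pd

        d = small_study["dir"]
        truth = small_study["truth"]
        from lncpig import seqfeat
        from lncpig.io_model import read_counts, read_gtf

        design = dict(pd.read_csv(os.path.join(d, "design.tsv"), sep="\t").values)
        cm = read_counts(os.path.join(d, "counts.tsv"), design)
        recs = read_gtf(os.path.join(d, "transcripts.gtf"))
        expr = seqfeat.fpkm(cm, {r.transcript_id: r.length for r in recs})
        loci = truth.gene_loci()
        tid_loci = {}
        for r in recs:
            L = loci[r.gene_id]
            tid_loci[r.transcript_id] = GeneLocus(
                gene_id=r.transcript_id, chrom=L.chrom, strand=L.strand,
                span=L.span, biotype=L.biotype,
            )
        de_lnc = [p["lnc_id"] for p in truth.cis_pairs + truth.decoy_cis_pairs]
        de_genes = [p["gene_id"] for p in truth.cis_pairs + truth.decoy_cis_pairs]
        links = targets.link_targets(de_lnc, de_genes, expr, loci=tid_loci, mode="cis")
        for L in links:
            assert L.distance <= targets.DEFAULT_WINDOW
            if L.passed:
                assert abs(L.r) >= 0.60 and L.r_p <= 0.05
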