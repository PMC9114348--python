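import numpy as np
import pytest

from lncpig.io_model import CountMatrix, TranscriptRecord, PIGMENTED, UNPIGMENTED


def make_transcript(
    tid="T1",
    exons=((0, 100), (200, 300)),
    class_code="u",
    chrom="chr1",
    strand="+",
    sequence=None,
    source="candidate",
):
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=f"G_{tid}",
        chrom=chrom,
        strand=strand,
        exons=[tuple(e) for e in exons],
        class_code=class_code,
        sequence=sequence,
        source=source,
    )


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def design_5v6():
    d = {f"P{i}": PIGMENTED for i in range(1, 6)}
    d.update({f"U{i}": UNPIGMENTED for i in range(1, 7)})
    return d


def make_counts(counts, design, ids=None):
    counts = np.asarray(counts)
    ids = ids or [f"f{i}" for i in range(counts.shape[0])]
    libs = {s: max(float(t), 1.0) for s, t in zip(design, counts.sum(axis=0))}
    return CountMatrix(
        feature_ids=ids,
        sample_ids=list(design),
        counts=counts,
        group=dict(design),
        library_sizes=libs,
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small simulated study shared by pipeline-level tests."""
    from lncpig import pipeline

    outdir = tmp_path_factory.mktemp("sim")
    cfg = pipeline.SimulateConfig(
        n_coding=60,
        n_noncoding=60,
        n_de=30,
        n_cis_pairs=3,
        n_trans_pairs=3,
        n_train_coding=120,
        n_train_noncoding=120,
    )
    truth = pipeline.simulate_study(str(outdir), seed=7, cfg=cfg)
    return {"dir": str(outdir), "truth": truth, "cfg": cfg}
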