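"""Synthetic transcriptome, count-matrix, qPCR and gene-set generator
with planted ground truth.

The generator emulates the structure of a pigmented-vs-unpigmented
eyelid-skin RNA-seq study at desk scale: coding transcripts carry a long
ORF sampled from a fixed synthetic codon-usage table (which induces
hexamer bias), noncoding transcripts are stop-codon-seeded, GC-poorer,
shorter, with fewer exons and lower expression; counts follow a negative
binomial (Var = mu + alpha mu^2) for a 5-vs-6 two-group design with
planted log2 fold changes; cis pairs are planted within a genomic window
with a shared latent expression factor, trans pairs by splicing a
reverse-complement segment of the target mRNA into the lncRNA.

All randomness flows through a single integer seed per operation
(numpy PCG64), so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .io_model import (
    CountMatrix,
    GeneLocus,
    GeneSet,
    QpcrMeasure,
    TranscriptRecord,
    PIGMENTED,
    UNPIGMENTED,
    reverse_complement,
)

__all__ = [
    "TranscriptomeParams",
    "SyntheticTruth",
    "generate_transcriptome",
    "generate_counts",
    "plant_cis_pairs",
    "plant_trans_pairs",
    "generate_qpcr",
    "generate_gene_sets",
    "default_design",
]

STOPS = ("TAA", "TAG", "TGA")

# class codes sampled for unannotated candidates, roughly matching the
# reported breakdown of novel isoform / overlap / intronic / intergenic /
# antisense classes
_CANDIDATE_CODES = ["j", "o", "i", "u", "x"]
_CANDIDATE_CODE_P = [0.515, 0.145, 0.123, 0.165, 0.052]


def _codon_table() -> tuple[list[str], np.ndarray]:
    with resources.files("lncpig.data").joinpath("codon_usage.json").open() as fh:
        tab = json.load(fh)
    codons = sorted(tab)
    p = np.array([tab[c] for c in codons])
    return codons, p / p.sum()


@dataclass
class TranscriptomeParams:
    """Per-class sequence and layout distributions.

    Lengths are lognormal around the class mean (coding transcripts
    longer), exon counts Poisson with a class floor, GC as stated.  The
    defaults reproduce the qualitative class orderings of the study's
    feature comparison (noncoding GC < coding GC, fewer exons, shorter,
    lower expression) at desk scale.
    """

    coding_length_mean: float = 900.0
    coding_length_sigma: float = 0.30
    noncoding_length_mean: float = 450.0
    noncoding_length_sigma: float = 0.35
    min_length: int = 150
    coding_gc: float = 0.52
    noncoding_gc: float = 0.469
    utr_gc: float = 0.50
    orf_fraction: float = 0.55
    coding_exons_mean: float = 12.3
    noncoding_exons_mean: float = 3.8
    stop_seed_interval: int = 24
    known_fraction: float = 0.15
    known_sub_rate: float = 0.03
    loci_per_chrom: int = 50
    gap_min_bp: int = 1_000
    gap_max_bp: int = 500_000
    intron_min_bp: int = 100
    intron_max_bp: int = 5_000


@dataclass
class SyntheticTruth:
    """Planted labels emitted alongside generated data."""

    coding_labels: dict[str, str] = field(default_factory=dict)
    de_status: dict[str, dict] = field(default_factory=dict)  # id -> {dir, log2fc}
    cis_pairs: list[dict] = field(default_factory=dict)
    trans_pairs: list[dict] = field(default_factory=dict)
    decoy_cis_pairs: list[dict] = field(default_factory=dict)
    known_ids: list[str] = field(default_factory=list)
    loci: dict[str, dict] = field(default_factory=dict)  # gene_id -> locus
    generator_config: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.cis_pairs, dict):
            self.cis_pairs = []
        if isinstance(self.trans_pairs, dict):
            self.trans_pairs = []
        if isinstance(self.decoy_cis_pairs, dict):
            self.decoy_cis_pairs = []

    def gene_loci(self) -> dict[str, GeneLocus]:
        return {
            g: GeneLocus(
                gene_id=g,
                chrom=d["chrom"],
                strand=d["strand"],
                span=(d["start"], d["end"]),
                biotype=d["biotype"],
            )
            for g, d in self.loci.items()
        }

    def to_json(self, path: str) -> None:
        def _plain(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not serializable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=_plain)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _noncoding_seq(rng: np.random.Generator, length: int, gc: float, interval: int) -> str:
    """ORF-poor sequence: random background with stop codons seeded at
    random frames every ~``interval`` nt."""
    seq = list(_random_seq(rng, length, gc))
    pos = int(rng.integers(0, max(interval // 2, 1)))
    while pos + 3 <= length:
        stop = STOPS[rng.integers(0, 3)]
        seq[pos : pos + 3] = stop
        pos += int(rng.integers(interval // 2, interval + interval // 2))
    return "".join(seq)


def _coding_seq(
    rng: np.random.Generator,
    length: int,
    params: TranscriptomeParams,
    codons: list[str],
    codon_p: np.ndarray,
) -> str:
    """5'UTR + ORF + 3'UTR; the ORF is ATG + codons drawn from the usage
    table + stop, occupying ~orf_fraction of the transcript."""
    orf_nt = int(length * params.orf_fraction)
    n_codons = max((orf_nt - 6) // 3, 10)
    orf = "ATG" + "".join(
        codons[i] for i in rng.choice(len(codons), size=n_codons, p=codon_p)
    ) + STOPS[rng.integers(0, 3)]
    rest = length - len(orf)
    if rest < 0:
        return orf[:length]
    utr5_len = rest // 2
    utr5 = _random_seq(rng, utr5_len, params.utr_gc)
    utr3 = _random_seq(rng, rest - utr5_len, params.utr_gc)
    # keep the planted ORF the longest: remove ATGs from the 5' UTR
    utr5 = utr5.replace("ATG", "ACG")
    return utr5 + orf + utr3


def _split_exons(
    rng: np.random.Generator, length: int, n_exons: int
) -> list[int]:
    """Split ``length`` nt into n_exons positive parts (Dirichlet-ish)."""
    n_exons = max(1, min(n_exons, length // 10))
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [length]])
    return list(np.diff(bounds).astype(int))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n_sub = int(round(rate * len(seq)))
    if n_sub == 0:
        return seq
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    for p in pos:
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[rng.integers(0, 3)]
    return "".join(out)


def generate_transcriptome(
    n_coding: int,
    n_noncoding: int,
    seed: int = 0,
    params: TranscriptomeParams | None = None,
) -> tuple[list[TranscriptRecord], dict[str, str], SyntheticTruth]:
    """Generate transcripts with recorded loci and planted class labels.

    Returns (records, known_db, truth): ``known_db`` holds lightly
    mutated copies of a subset of noncoding transcripts, standing in for
    an external known-lncRNA database.
    """
    params = params or TranscriptomeParams()
    if n_coding < 0 or n_noncoding < 0:
        raise ValueError("counts must be >= 0")
    if params.coding_length_mean <= 0 or params.noncoding_length_mean <= 0:
        raise ValueError("length means must be positive")
    rng = np.random.default_rng(seed)
    codons, codon_p = _codon_table()
    truth = SyntheticTruth(
        generator_config={
            "n_coding": n_coding,
            "n_noncoding": n_noncoding,
            "seed": seed,
            "params": asdict(params),
        }
    )
    specs = [("coding", i) for i in range(n_coding)] + [
        ("noncoding", i) for i in range(n_noncoding)
    ]
    rng.shuffle(specs)
    records: list[TranscriptRecord] = []
    known_db: dict[str, str] = {}
    cursor = 0
    chrom_i = 1
    for idx, (kind, _) in enumerate(specs):
        if idx % params.loci_per_chrom == 0 and idx > 0:
            chrom_i += 1
            cursor = 0
        chrom = f"chr{chrom_i}"
        gap = int(
            np.exp(
                rng.uniform(np.log(params.gap_min_bp), np.log(params.gap_max_bp))
            )
        )
        cursor += gap
        if kind == "coding":
            length = int(
                np.clip(
                    rng.lognormal(
                        np.log(params.coding_length_mean), params.coding_length_sigma
                    ),
                    params.min_length,
                    20_000,
                )
            )
            seq = _coding_seq(rng, length, params, codons, codon_p)
            n_ex = max(2, int(rng.poisson(params.coding_exons_mean)))
            tid = f"CODT_{idx:05d}"
            gid = f"CODG_{idx:05d}"
            class_code = "="
            source = "annotated_coding"
            biotype = "coding"
        else:
            length = int(
                np.clip(
                    rng.lognormal(
                        np.log(params.noncoding_length_mean),
                        params.noncoding_length_sigma,
                    ),
                    params.min_length,
                    20_000,
                )
            )
            seq = _noncoding_seq(rng, length, params.noncoding_gc, params.stop_seed_interval)
            n_ex = max(1, int(rng.poisson(params.noncoding_exons_mean)))
            tid = f"TCONS_{idx:05d}"
            gid = f"XLOC_{idx:05d}"
            class_code = _CANDIDATE_CODES[
                rng.choice(len(_CANDIDATE_CODES), p=_CANDIDATE_CODE_P)
            ]
            source = "candidate"
            biotype = "lncRNA"
        length = len(seq)
        exon_lens = _split_exons(rng, length, n_ex)
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(exon_lens) - 1:
                pos += int(
                    np.exp(
                        rng.uniform(
                            np.log(params.intron_min_bp), np.log(params.intron_max_bp)
                        )
                    )
                )
        strand = "+" if rng.random() < 0.5 else "-"
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            class_code=class_code,
            sequence=seq,
            source=source,
        )
        records.append(rec)
        cursor = exons[-1][1]
        truth.coding_labels[tid] = "coding" if kind == "coding" else "noncoding"
        truth.loci[gid] = {
            "chrom": chrom,
            "strand": strand,
            "start": exons[0][0],
            "end": exons[-1][1],
            "biotype": biotype,
        }
        if kind == "noncoding" and rng.random() < params.known_fraction:
            truth.known_ids.append(tid)
            known_db[f"KNOWN_{tid}"] = _mutate(rng, seq, params.known_sub_rate)
    return records, known_db, truth


def default_design(n_pigmented: int = 5, n_unpigmented: int = 6) -> dict[str, str]:
    design = {f"P{i+1}": PIGMENTED for i in range(n_pigmented)}
    design.update({f"U{i+1}": UNPIGMENTED for i in range(n_unpigmented)})
    return design


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if alpha <= 0:
        raise ValueError("dispersion must be > 0")
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_counts(
    features: list[TranscriptRecord],
    truth: SyntheticTruth,
    design: dict[str, str] | None = None,
    n_de: int = 40,
    lfc_range: tuple[float, float] = (1.5, 4.0),
    dispersion: float = 0.1,
    seed: int = 0,
    coding_mean: float = 150.0,
    noncoding_mean: float = 30.0,
    mean_sigma: float = 1.0,
) -> CountMatrix:
    """NB counts with planted DE.

    Base means are lognormal with class-specific centers (noncoding lower
    than coding); planted DE features get a group mean ratio of
    2^log2fc, split symmetrically, and their base mean is redrawn high
    enough to be detectable.  ``truth.de_status`` is filled for every
    feature (dir in {up, down, null}).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if n_de > len(features):
        raise ValueError("n_de exceeds number of features")
    design = design or default_design()
    rng = np.random.default_rng(seed)
    samples = sorted(design, key=lambda s: (design[s], s))
    pig = np.array([design[s] == PIGMENTED for s in samples])
    ids = [t.transcript_id for t in features]
    is_coding = np.array(
        [truth.coding_labels.get(t.transcript_id) == "coding" for t in features]
    )
    base = np.where(
        is_coding,
        rng.lognormal(np.log(coding_mean), mean_sigma, len(features)),
        rng.lognormal(np.log(noncoding_mean), mean_sigma, len(features)),
    )
    # plant DE half in coding, half in noncoding features
    n_de_cod = min(n_de // 2, int(is_coding.sum()))
    n_de_non = min(n_de - n_de_cod, int((~is_coding).sum()))
    de_idx = np.concatenate(
        [
            rng.choice(np.where(is_coding)[0], size=n_de_cod, replace=False),
            rng.choice(np.where(~is_coding)[0], size=n_de_non, replace=False),
        ]
    ).astype(int)
    lfc = np.zeros(len(features))
    if len(de_idx):
        mag = rng.uniform(lfc_range[0], lfc_range[1], size=len(de_idx))
        sign = np.where(rng.random(len(de_idx)) < 0.5, 1.0, -1.0)
        lfc[de_idx] = mag * sign
        base[de_idx] = rng.lognormal(np.log(150.0), 0.5, size=len(de_idx))
    mu = base[:, None] * np.power(2.0, np.where(pig[None, :], lfc[:, None] / 2, -lfc[:, None] / 2))
    counts = _nb_draw(rng, mu, dispersion)
    for i, tid in enumerate(ids):
        if lfc[i] > 0:
            d = "up"
        elif lfc[i] < 0:
            d = "down"
        else:
            d = "null"
        truth.de_status[tid] = {"dir": d, "log2fc": float(lfc[i]), "base_mean": float(base[i])}
    return CountMatrix(
        feature_ids=ids,
        sample_ids=samples,
        counts=counts,
        group={s: design[s] for s in samples},
    )


def _plantable_lnc(rec: TranscriptRecord | None) -> bool:
    """Pairs are planted on structurally well-formed lncRNAs (>= 2 exons,
    >= 200 nt) — the identification cascade excludes anything else by
    design, so planting there would create unrecoverable truth."""
    return rec is not None and rec.n_exons >= 2 and rec.length >= 200


def _correlate_pair(
    rng: np.random.Generator,
    counts: np.ndarray,
    i: int,
    j: int,
    pig: np.ndarray,
    truth: SyntheticTruth,
    ids: list[str],
    rho_sigma: float = 0.5,
    redraw_alpha: float = 0.02,
) -> None:
    """Redraw counts for features i and j with a shared per-sample latent
    lognormal factor so their expression correlates."""
    latent = np.exp(rng.normal(0.0, rho_sigma, counts.shape[1]) - rho_sigma**2 / 2)
    for f in (i, j):
        st = truth.de_status[ids[f]]
        base, lfc = st["base_mean"], st["log2fc"]
        mu = base * np.power(2.0, np.where(pig, lfc / 2, -lfc / 2)) * latent
        counts[f, :] = _nb_draw(rng, mu, redraw_alpha)


def plant_cis_pairs(
    records: list[TranscriptRecord],
    truth: SyntheticTruth,
    counts: CountMatrix,
    n_pairs: int = 8,
    window: int = 300_000,
    rho: float = 0.9,
    seed: int = 0,
) -> None:
    """Relocate coding gene loci next to DE lncRNAs (distance <= window)
    and correlate the pair's counts; an equal number of decoy pairs is
    placed just beyond the window, with the same planted correlation.

    Pairs are drawn from planted-DE features; both members keep their DE
    direction.  Mutates ``truth`` (cis_pairs/decoy_cis_pairs, loci) and
    ``counts`` in place.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    ids = list(counts.feature_ids)
    idx = {t: i for i, t in enumerate(ids)}
    by_tid = {t.transcript_id: t for t in records}
    de_lnc = [
        t
        for t in ids
        if truth.coding_labels.get(t) == "noncoding"
        and truth.de_status.get(t, {}).get("dir") != "null"
        and t not in {p["lnc_id"] for p in truth.trans_pairs}
        and _plantable_lnc(by_tid.get(t))
    ]
    de_cod = [
        t
        for t in ids
        if truth.coding_labels.get(t) == "coding"
        and truth.de_status.get(t, {}).get("dir") != "null"
    ]
    need = 2 * n_pairs
    if len(de_lnc) < need or len(de_cod) < need:
        raise ValueError("not enough planted-DE features to plant cis pairs")
    lncs = list(rng.choice(de_lnc, size=need, replace=False))
    genes = list(rng.choice(de_cod, size=need, replace=False))
    pig = np.array([counts.group[s] == PIGMENTED for s in counts.sample_ids])
    arr = counts.array
    # align DE directions within each pair so the group effect reinforces r
    for lnc_id, gene_id in zip(lncs, genes):
        st_l, st_g = truth.de_status[lnc_id], truth.de_status[gene_id]
        if (st_l["log2fc"] > 0) != (st_g["log2fc"] > 0):
            st_g["log2fc"] = -st_g["log2fc"]
            st_g["dir"] = "up" if st_g["log2fc"] > 0 else "down"
    for p in range(n_pairs):
        lnc_id, gene_id = lncs[p], genes[p]
        dist = int(rng.integers(10_000, window + 1))
        _relocate(truth, by_tid[lnc_id], by_tid[gene_id], dist)
        _correlate_pair(rng, arr, idx[lnc_id], idx[gene_id], pig, truth, ids)
        truth.cis_pairs.append({"lnc_id": lnc_id, "gene_id": gene_id, "distance": dist})
    for p in range(n_pairs, 2 * n_pairs):
        lnc_id, gene_id = lncs[p], genes[p]
        dist = int(rng.integers(window + 1, window + 200_000))
        _relocate(truth, by_tid[lnc_id], by_tid[gene_id], dist)
        _correlate_pair(rng, arr, idx[lnc_id], idx[gene_id], pig, truth, ids)
        truth.decoy_cis_pairs.append(
            {"lnc_id": lnc_id, "gene_id": gene_id, "distance": dist}
        )


def _relocate(
    truth: SyntheticTruth,
    lnc: TranscriptRecord,
    gene: TranscriptRecord,
    dist: int,
) -> None:
    """Move the gene's transcript (exons and recorded locus) to ``dist``
    bp downstream of the lncRNA locus on the lncRNA's chromosome."""
    lnc_locus = truth.loci[lnc.gene_id]
    start = lnc_locus["end"] + dist
    shift = start - gene.exons[0][0]
    gene.exons = [(s + shift, e + shift) for s, e in gene.exons]
    gene.chrom = lnc_locus["chrom"]
    old = truth.loci[gene.gene_id]
    truth.loci[gene.gene_id] = {
        "chrom": lnc_locus["chrom"],
        "strand": old["strand"],
        "start": gene.exons[0][0],
        "end": gene.exons[-1][1],
        "biotype": old["biotype"],
    }


def plant_trans_pairs(
    records: list[TranscriptRecord],
    truth: SyntheticTruth,
    counts: CountMatrix,
    n_pairs: int = 8,
    seg_len: int = 20,
    rho: float = 0.9,
    seed: int = 0,
) -> None:
    """Splice a reverse-complement ``seg_len``-nt segment of the target
    mRNA into each planted lncRNA (replacing an internal window of the
    same length) and correlate the pair's counts.  Mutates records
    (sequences), truth and counts in place."""
    rng = np.random.default_rng(seed)
    ids = list(counts.feature_ids)
    idx = {t: i for i, t in enumerate(ids)}
    by_tid = {t.transcript_id: t for t in records}
    used = {p["lnc_id"] for p in truth.cis_pairs} | {
        p["lnc_id"] for p in truth.decoy_cis_pairs
    }
    de_lnc = [
        t
        for t in ids
        if truth.coding_labels.get(t) == "noncoding"
        and truth.de_status.get(t, {}).get("dir") != "null"
        and t not in used
        and _plantable_lnc(by_tid.get(t))
    ]
    used_g = {p["gene_id"] for p in truth.cis_pairs} | {
        p["gene_id"] for p in truth.decoy_cis_pairs
    }
    de_cod = [
        t
        for t in ids
        if truth.coding_labels.get(t) == "coding"
        and truth.de_status.get(t, {}).get("dir") != "null"
        and t not in used_g
    ]
    if len(de_lnc) < n_pairs or len(de_cod) < n_pairs:
        raise ValueError("not enough planted-DE features to plant trans pairs")
    lncs = list(rng.choice(de_lnc, size=n_pairs, replace=False))
    genes = list(rng.choice(de_cod, size=n_pairs, replace=False))
    pig = np.array([counts.group[s] == PIGMENTED for s in counts.sample_ids])
    arr = counts.array
    for lnc_id, gene_id in zip(lncs, genes):
        lnc = by_tid[lnc_id]
        gene = by_tid[gene_id]
        if seg_len > len(lnc.sequence):
            raise ValueError(f"seg_len {seg_len} exceeds lncRNA length {len(lnc.sequence)}")
        st_l, st_g = truth.de_status[lnc_id], truth.de_status[gene_id]
        if (st_l["log2fc"] > 0) != (st_g["log2fc"] > 0):
            st_g["log2fc"] = -st_g["log2fc"]
            st_g["dir"] = "up" if st_g["log2fc"] > 0 else "down"
        m_pos = int(rng.integers(0, len(gene.sequence) - seg_len + 1))
        segment = reverse_complement(gene.sequence[m_pos : m_pos + seg_len])
        l_pos = int(rng.integers(0, len(lnc.sequence) - seg_len + 1))
        lnc.sequence = (
            lnc.sequence[:l_pos] + segment + lnc.sequence[l_pos + seg_len :]
        )
        _correlate_pair(rng, arr, idx[lnc_id], idx[gene_id], pig, truth, ids)
        truth.trans_pairs.append(
            {
                "lnc_id": lnc_id,
                "gene_id": gene_id,
                "lnc_pos": l_pos,
                "mrna_pos": m_pos,
                "seg_len": seg_len,
            }
        )


def generate_qpcr(
    truth: SyntheticTruth,
    genes: list[str],
    n_per_group: int = 5,
    seed: int = 0,
    noise_sd: float = 0.25,
    duplicates: int = 2,
) -> list[QpcrMeasure]:
    """Simulated qPCR wells for validation genes.

    Per sample: housekeeping Ct ~ N(20, 0.3); delta-Ct = gene baseline -
    planted log2FC (pigmented samples only) + N(0, noise_sd); each sample
    is emitted ``duplicates`` times with technical noise of the same SD
    scaled by 0.2.
    """
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasure] = []
    for gene in genes:
        lfc = truth.de_status.get(gene, {}).get("log2fc", 0.0)
        baseline = 6.0 + rng.normal(0, 0.5)
        for group, prefix in ((PIGMENTED, "P"), (UNPIGMENTED, "U")):
            for i in range(n_per_group):
                sample = f"{prefix}{i+1}"
                shift = -lfc if group == PIGMENTED else 0.0
                dct = baseline + shift + rng.normal(0, noise_sd)
                ct_house = 20.0 + rng.normal(0, 0.3)
                for _ in range(duplicates):
                    tech = rng.normal(0, 0.2 * noise_sd)
                    out.append(
                        QpcrMeasure(
                            sample_id=sample,
                            group=group,
                            gene_id=gene,
                            ct_target=ct_house + dct + tech,
                            ct_housekeeping=ct_house,
                        )
                    )
    return out


def generate_gene_sets(
    truth: SyntheticTruth,
    all_genes: list[str],
    n_random_sets: int = 10,
    seed: int = 0,
) -> list[GeneSet]:
    """Gene sets for the enrichment stage: one set enriched in planted
    target genes plus random sets of comparable size."""
    rng = np.random.default_rng(seed)
    target_genes = sorted(
        {p["gene_id"] for p in truth.cis_pairs} | {p["gene_id"] for p in truth.trans_pairs}
    )
    pool = sorted(set(all_genes))
    sets = []
    if target_genes:
        extra = [g for g in pool if g not in target_genes]
        pad = list(rng.choice(extra, size=min(5, len(extra)), replace=False))
        sets.append(
            GeneSet("PLANTED_TARGETS", "planted target genes", set(target_genes) | set(pad))
        )
    for i in range(n_random_sets):
        size = int(rng.integers(10, max(11, len(pool) // 5)))
        members = set(rng.choice(pool, size=min(size, len(pool)), replace=False))
        sets.append(GeneSet(f"RANDOM_{i:02d}", f"random set {i}", members))
    return sets
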