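"""End-to-end orchestration: simulate a synthetic study and/or run the
full analysis (identification cascade -> coding potential -> sequence
features -> differential expression -> cis/trans targets -> enrichment
-> qPCR validation) from one configuration, writing every stage table
plus a reproducibility manifest.

Re-running with the same config and seed reproduces byte-identical
outputs; the manifest records a hash of every written table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import codepot, diffexpr, downstream, lnc_filter, seqfeat, syndata, targets
from .io_model import (
    CountMatrix,
    GeneLocus,
    read_counts,
    read_fasta,
    read_gmt,
    read_gtf,
    read_qpcr,
    write_counts,
    write_fasta,
    write_gmt,
    write_gtf,
    write_results,
    PIGMENTED,
    UNPIGMENTED,
)

log = logging.getLogger("lncpig")

__all__ = ["RunConfig", "SimulateConfig", "simulate_study", "run_all"]


@dataclass
class SimulateConfig:
    """Study-scale defaults for the synthetic data generator: a 5-vs-6
    two-group design with planted DE, cis and trans structure."""

    n_coding: int = 150
    n_noncoding: int = 150
    n_de: int = 60
    n_cis_pairs: int = 6
    n_trans_pairs: int = 6
    trans_seg_len: int = 20
    dispersion: float = 0.1
    lfc_range: tuple = (1.5, 4.0)
    qpcr_noise_sd: float = 0.25
    n_train_coding: int = 300
    n_train_noncoding: int = 300


@dataclass
class RunConfig:
    """Paths and thresholds for a full analysis run.

    Threshold defaults are the study's printed values: class-code
    exclusion {=, e, p, c}; >= 2 exons; >= 200 bp; >= 10 reads in >= 5
    samples; known-match identity/coverage >= 0.90 with E <= 1e-6;
    consensus coding-potential gates (CPC2-like < 0.5, CPAT-like <= CV
    cutoff, PLEK-like < 0); strict DE padj <= 0.05 & |log2FC| >= 1.5;
    relaxed DE p <= 0.01 & |log2FC| >= 1; cis window 300 kb; correlation
    gate |r| >= 0.60, p <= 0.05.  The trans ndG threshold is in the
    package's integer-pair energy units (see docs/methods.md).
    """

    gtf: str = ""
    fasta: str = ""
    counts: str = ""
    known_db: str = ""
    gmt: str = ""
    qpcr: str = ""
    train_coding_fasta: str = ""
    train_noncoding_fasta: str = ""
    outdir: str = "lncpig_out"
    seed: int = 0
    min_exons: int = 2
    min_length: int = 200
    min_reads: int = 10
    min_samples: int = 5
    cv_folds: int = 10
    cpat_cutoff_override: float | None = None
    window: int = targets.DEFAULT_WINDOW
    ndg_threshold: float = targets.DEFAULT_NDG_THRESHOLD
    ndg_min_run: int = targets.DEFAULT_MIN_RUN
    max_fold_len: int = 250
    design: dict = field(default_factory=syndata.default_design)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_study(
    outdir: str, seed: int = 0, cfg: SimulateConfig | None = None
) -> syndata.SyntheticTruth:
    """Generate a complete synthetic study in ``outdir``: GTF, FASTA,
    counts TSV, known-lncRNA FASTA, training FASTAs, gene sets, a qPCR
    table and truth.json."""
    cfg = cfg or SimulateConfig()
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(8)]
    records, known_db, truth = syndata.generate_transcriptome(
        cfg.n_coding, cfg.n_noncoding, seed=seeds[0]
    )
    counts = syndata.generate_counts(
        records,
        truth,
        n_de=cfg.n_de,
        lfc_range=tuple(cfg.lfc_range),
        dispersion=cfg.dispersion,
        seed=seeds[1],
    )
    syndata.plant_cis_pairs(records, truth, counts, n_pairs=cfg.n_cis_pairs, seed=seeds[2])
    syndata.plant_trans_pairs(
        records, truth, counts, n_pairs=cfg.n_trans_pairs,
        seg_len=cfg.trans_seg_len, seed=seeds[3],
    )
    # qPCR validation genes: a planted-DE lncRNA trio and coding trio
    val_genes = [p["gene_id"] for p in truth.trans_pairs[:3]] + [
        p["lnc_id"] for p in truth.trans_pairs[:3]
    ]
    qpcr = syndata.generate_qpcr(
        truth, val_genes, n_per_group=5, seed=seeds[4], noise_sd=cfg.qpcr_noise_sd
    )
    gene_sets = syndata.generate_gene_sets(
        truth,
        [t.transcript_id for t in records if truth.coding_labels[t.transcript_id] == "coding"],
        seed=seeds[5],
    )
    train_rec, _, _ = syndata.generate_transcriptome(
        cfg.n_train_coding, cfg.n_train_noncoding, seed=seeds[6]
    )
    write_gtf(records, os.path.join(outdir, "transcripts.gtf"))
    write_fasta(
        {t.transcript_id: t.sequence for t in records},
        os.path.join(outdir, "transcripts.fa"),
    )
    write_counts(counts, os.path.join(outdir, "counts.tsv"))
    write_fasta(known_db, os.path.join(outdir, "known_lnc.fa"))
    write_fasta(
        {t.transcript_id: t.sequence for t in train_rec if t.source == "annotated_coding"},
        os.path.join(outdir, "train_coding.fa"),
    )
    write_fasta(
        {t.transcript_id: t.sequence for t in train_rec if t.source == "candidate"},
        os.path.join(outdir, "train_noncoding.fa"),
    )
    write_gmt(gene_sets, os.path.join(outdir, "gene_sets.gmt"))
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in qpcr],
            "group": [m.group for m in qpcr],
            "gene_id": [m.gene_id for m in qpcr],
            "ct_target": [round(m.ct_target, 6) for m in qpcr],
            "ct_housekeeping": [round(m.ct_housekeeping, 6) for m in qpcr],
        }
    ).to_csv(os.path.join(outdir, "qpcr.tsv"), sep="\t", index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
    with open(os.path.join(outdir, "design.tsv"), "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in sorted(counts.group.items()):
            fh.write(f"{s}\t{g}\n")
    return truth


def config_for_simulated(outdir: str, run_outdir: str, seed: int = 0) -> RunConfig:
    return RunConfig(
        gtf=os.path.join(outdir, "transcripts.gtf"),
        fasta=os.path.join(outdir, "transcripts.fa"),
        counts=os.path.join(outdir, "counts.tsv"),
        known_db=os.path.join(outdir, "known_lnc.fa"),
        gmt=os.path.join(outdir, "gene_sets.gmt"),
        qpcr=os.path.join(outdir, "qpcr.tsv"),
        train_coding_fasta=os.path.join(outdir, "train_coding.fa"),
        train_noncoding_fasta=os.path.join(outdir, "train_noncoding.fa"),
        outdir=run_outdir,
        seed=seed,
    )


def run_all(config: RunConfig) -> dict:
    """Run the full analysis.  Returns a manifest dict (also written to
    ``outdir/manifest.json``)."""
    for label in ("gtf", "fasta", "counts"):
        path = getattr(config, label)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"required input '{label}' missing: {path!r}")
    os.makedirs(config.outdir, exist_ok=True)
    stage_counts: dict[str, int] = {}

    records = read_gtf(config.gtf)
    seqs = read_fasta(config.fasta)
    for rec in records:
        rec.sequence = seqs.get(rec.transcript_id, rec.sequence)
    counts = read_counts(config.counts, config.design)
    known_db = read_fasta(config.known_db) if config.known_db else {}
    log.info("inputs: %d transcripts, %d known lncRNAs", len(records), len(known_db))
    stage_counts["input_transcripts"] = len(records)

    # 1. identification cascade
    cascade = lnc_filter.run_cascade(
        records,
        counts,
        known_db,
        min_exons=config.min_exons,
        min_length=config.min_length,
        min_reads=config.min_reads,
        min_samples=config.min_samples,
    )
    novel = cascade["novel_lnc_candidates"]
    known = cascade["known_lnc"]
    stage_counts["candidates_after_filters"] = len(novel) + len(known)
    stage_counts["known_lnc"] = len(known)
    for rep in cascade["reports"]:
        log.info("stage %s: %d -> %d", rep.stage, rep.n_in, rep.n_out)
    report_rows = [
        {"stage": r.stage, "n_in": r.n_in, "n_out": r.n_out, "removed_id": rid, "reason": reason}
        for r in cascade["reports"]
        for rid, reason in sorted(r.removed.items())
    ] or [{"stage": r.stage, "n_in": r.n_in, "n_out": r.n_out, "removed_id": "", "reason": ""} for r in cascade["reports"]]
    write_results(pd.DataFrame(report_rows), os.path.join(config.outdir, "filter_report.tsv"))
    write_results(
        pd.DataFrame(
            {
                "query_id": [m.query_id for m in cascade["match_results"]],
                "subject_id": [m.subject_id or "" for m in cascade["match_results"]],
                "identity": [m.identity for m in cascade["match_results"]],
                "coverage": [m.coverage for m in cascade["match_results"]],
                "evalue": [m.evalue for m in cascade["match_results"]],
                "verdict": [m.verdict for m in cascade["match_results"]],
            }
        ),
        os.path.join(config.outdir, "known_lnc.tsv"),
    )

    # 2. coding potential
    if config.train_coding_fasta and config.train_noncoding_fasta:
        train_cod = list(read_fasta(config.train_coding_fasta).values())
        train_non = list(read_fasta(config.train_noncoding_fasta).values())
    else:
        # fall back to in-run labels: annotated coding transcripts vs the
        # known-lncRNA database
        train_cod = [r.sequence for r in records if r.class_code in lnc_filter.DEFAULT_EXCLUDED_CODES and r.sequence]
        train_non = list(known_db.values())
    model = codepot.train_model(
        train_cod, train_non, folds=config.cv_folds, seed=config.seed
    )
    model.to_json(os.path.join(config.outdir, "codepot_model.json"))
    log.info("coding-potential cutoff (CV): %.4f", model.cpat_cutoff)
    score_rows = []
    lnc_ids = []
    for rec in novel + known:
        verdict, sc = codepot.classify_consensus(
            rec.sequence, model, cpat_cutoff=config.cpat_cutoff_override
        )
        score_rows.append(
            {
                "transcript_id": rec.transcript_id,
                "cpc2_like": sc["cpc2"],
                "cpat_like": sc["cpat"],
                "plek_like": sc["plek"],
                "verdict": verdict,
            }
        )
        if verdict == "noncoding":
            lnc_ids.append(rec.transcript_id)
    write_results(pd.DataFrame(score_rows), os.path.join(config.outdir, "codepot_scores.tsv"))
    known_ids = {r.transcript_id for r in known}
    novel_lnc = [r for r in novel if r.transcript_id in set(lnc_ids)]
    known_lnc = [r for r in known if r.transcript_id in set(lnc_ids)]
    stage_counts["putative_novel_lnc"] = len(novel_lnc)
    stage_counts["known_lnc_confirmed"] = len(known_lnc)
    write_fasta(
        {r.transcript_id: r.sequence for r in novel_lnc},
        os.path.join(config.outdir, "novel_candidates.fa"),
    )
    log.info("putative lncRNAs: %d novel, %d known", len(novel_lnc), len(known_lnc))

    # 3. expression + DE
    expressed_ids, _ = lnc_filter.filter_expression(
        counts, min_reads=config.min_reads, min_samples=config.min_samples
    )
    de_counts = counts.subset(expressed_ids)
    de = diffexpr.run_de(de_counts)
    write_results(de, os.path.join(config.outdir, "de_results.tsv"))
    lnc_set = {r.transcript_id for r in novel_lnc + known_lnc}
    coding_set = {
        r.transcript_id
        for r in records
        if r.class_code in lnc_filter.DEFAULT_EXCLUDED_CODES
    }
    strict = diffexpr.call_de(de, "strict")
    relaxed = diffexpr.call_de(de, "relaxed")
    de_lnc = [f for f in strict["up"] + strict["down"] if f in lnc_set]
    de_genes = [f for f in relaxed["up"] + relaxed["down"] if f in coding_set]
    stage_counts["de_lnc_strict"] = len(de_lnc)
    stage_counts["de_genes_relaxed"] = len(de_genes)
    log.info("DE: %d lncRNAs (strict), %d coding genes (relaxed)", len(de_lnc), len(de_genes))

    # 4. sequence features (Table-1-style comparison)
    lengths = {r.transcript_id: r.length for r in records}
    expr = seqfeat.fpkm(de_counts, {f: lengths[f] for f in de_counts.feature_ids})
    classes = {}
    for r in records:
        if r.transcript_id in known_ids and r.transcript_id in lnc_set:
            classes[r.transcript_id] = "known_lnc"
        elif r.transcript_id in lnc_set:
            classes[r.transcript_id] = "novel_lnc"
        elif r.transcript_id in coding_set:
            classes[r.transcript_id] = "coding"
    feat_records = [r for r in records if r.transcript_id in classes]
    ftable = seqfeat.feature_table(
        feat_records, expr=expr, classes=classes, max_fold_len=config.max_fold_len
    )
    write_results(ftable, os.path.join(config.outdir, "features.tsv"))
    comp = seqfeat.compare_classes(ftable)
    write_results(comp.summary, os.path.join(config.outdir, "summary.tsv"))

    # 5. targets
    spans: dict[str, list] = {}
    for r in records:
        s, e = r.span
        cur = spans.setdefault(r.gene_id, [r.chrom, r.strand, s, e, r.transcript_id])
        cur[2] = min(cur[2], s)
        cur[3] = max(cur[3], e)
    tid_loci = {}
    for r in records:
        c, st, s, e, _ = spans[r.gene_id]
        tid_loci[r.transcript_id] = GeneLocus(
            gene_id=r.transcript_id, chrom=c, strand=st, span=(s, e),
            biotype="lncRNA" if r.transcript_id in lnc_set else "coding",
        )
    cis_links = targets.link_targets(
        de_lnc, de_genes, expr, loci=tid_loci, mode="cis", window=config.window
    )
    seq_map = {r.transcript_id: r.sequence for r in records if r.sequence}
    trans_links = targets.link_targets(
        de_lnc,
        de_genes,
        expr,
        sequences=seq_map,
        mode="trans",
        ndg_threshold=config.ndg_threshold,
        min_run=config.ndg_min_run,
    )
    for name, links in (("targets_cis.tsv", cis_links), ("targets_trans.tsv", trans_links)):
        write_results(
            pd.DataFrame(
                {
                    "lnc_id": [L.lnc_id for L in links],
                    "gene_id": [L.gene_id for L in links],
                    "mode": [L.mode for L in links],
                    "distance": [L.distance if L.distance is not None else "" for L in links],
                    "ndg": [L.ndg if L.ndg is not None else "" for L in links],
                    "r": [L.r for L in links],
                    "r_p": [L.r_p for L in links],
                    "passed": [L.passed for L in links],
                }
            ),
            os.path.join(config.outdir, name),
        )
    cis_hits = [L for L in cis_links if L.passed]
    trans_hits = [L for L in trans_links if L.passed]
    stage_counts["cis_targets"] = len(cis_hits)
    stage_counts["trans_targets"] = len(trans_hits)
    log.info("targets: %d cis, %d trans", len(cis_hits), len(trans_hits))

    # 6. enrichment
    if config.gmt:
        gene_sets = read_gmt(config.gmt)
        study = sorted({L.gene_id for L in cis_hits + trans_hits})
        population = set(de_counts.feature_ids) & coding_set
        study = [g for g in study if g in population]
        enr = downstream.hypergeom_enrich(set(study), population, gene_sets)
        write_results(
            pd.DataFrame(
                {
                    "set_id": [e.set_id for e in enr],
                    "name": [e.name for e in enr],
                    "k": [e.k for e in enr],
                    "n": [e.n for e in enr],
                    "K": [e.K for e in enr],
                    "N": [e.N for e in enr],
                    "p": [e.p for e in enr],
                    "padj": [e.padj for e in enr],
                    "fold_enrichment": [e.fold_enrichment for e in enr],
                }
            ),
            os.path.join(config.outdir, "enrichment.tsv"),
        )
        stage_counts["enriched_sets_padj05"] = sum(e.padj <= 0.05 for e in enr)

    # 7. qPCR validation
    qpcr_skipped = True
    if config.qpcr and os.path.exists(config.qpcr):
        qpcr_skipped = False
        measures = read_qpcr(config.qpcr)
        summaries = downstream.qpcr_analysis(measures)
        write_results(
            pd.DataFrame(
                {
                    "gene_id": [s.gene_id for s in summaries],
                    "ddct": [s.ddct for s in summaries],
                    "log2fc": [s.log2fc for s in summaries],
                    "se": [s.se for s in summaries],
                    "t_p": [s.t_p for s in summaries],
                    "log2fc_low": [s.log2fc_low for s in summaries],
                    "log2fc_high": [s.log2fc_high for s in summaries],
                }
            ),
            os.path.join(config.outdir, "qpcr_summary.tsv"),
        )
        de_map = dict(zip(de["feature_id"], de["log2fc"]))
        conc = downstream.concordance_report(
            {g: de_map[g] for g in (s.gene_id for s in summaries) if g in de_map},
            {s.gene_id: s.log2fc for s in summaries},
        )
        write_results(conc, os.path.join(config.outdir, "concordance.tsv"))
        stage_counts["qpcr_genes"] = len(summaries)

    # manifest
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    tables = sorted(
        f for f in os.listdir(config.outdir)
        if f.endswith((".tsv", ".fa", ".json")) and f != "manifest.json"
    )
    manifest = {
        "lncpig_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_counts": stage_counts,
        "qpcr_skipped": qpcr_skipped,
        "tables": {f: _sha256(os.path.join(config.outdir, f)) for f in tables},
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
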