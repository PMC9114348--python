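"""Enrichment of target genes and qPCR validation statistics.

Enrichment: one-sided (over-representation) hypergeometric test per gene
set — equivalent to Fisher's exact test on the 2x2 table — with BH
adjustment across sets.  The universe defaults to the genes that entered
differential-expression testing.

qPCR: relative quantification against a housekeeping gene.  Per-sample
delta-Ct = Ct_target - Ct_housekeeping (technical duplicates averaged),
delta-delta-Ct = mean dCt(pigmented) - mean dCt(unpigmented), and
log2 fold change = -ddCt, with a Welch t-test between groups and a
range from ddCt +/- SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_model import GeneSet, QpcrMeasure, PIGMENTED, UNPIGMENTED

__all__ = [
    "EnrichmentResult",
    "QpcrSummary",
    "hypergeom_enrich",
    "qpcr_analysis",
    "concordance_report",
]


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    k: int  # study genes in set
    n: int  # study size
    K: int  # population genes in set
    N: int  # population size
    p: float
    padj: float
    fold_enrichment: float


def hypergeom_enrich(
    study: set,
    population: set,
    gene_sets: list[GeneSet],
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``study`` within each gene
    set, both intersected with ``population`` first; sets with no
    population member are skipped; BH across tested sets."""
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    N, n = len(population), len(study)
    rows = []
    for gs in gene_sets:
        members = gs.members & population
        K = len(members)
        if K == 0:
            continue
        k = len(study & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        if two_sided:
            p = min(1.0, 2 * min(p, float(stats.hypergeom.cdf(k, N, K, n))))
        fe = (k / n) / (K / N) if n else 0.0
        rows.append((gs, k, K, p, fe))
    padj = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentResult(
            set_id=gs.set_id,
            name=gs.name,
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            padj=float(q),
            fold_enrichment=fe,
        )
        for (gs, k, K, p, fe), q in zip(rows, padj)
    ]


@dataclass
class QpcrSummary:
    gene_id: str
    mean_dct_pigmented: float
    mean_dct_unpigmented: float
    ddct: float
    log2fc: float  # = -ddct
    se: float
    t_p: float
    log2fc_low: float  # from ddct + se
    log2fc_high: float  # from ddct - se


def qpcr_analysis(
    measures: list[QpcrMeasure],
    reference_group: str = UNPIGMENTED,
) -> list[QpcrSummary]:
    """Per-gene relative quantification with a Welch t-test on per-sample
    delta-Ct between groups (>= 2 samples per group required)."""
    df = pd.DataFrame(
        {
            "sample_id": m.sample_id,
            "group": m.group,
            "gene_id": m.gene_id,
            "dct": m.ct_target - m.ct_housekeeping,
        }
        for m in measures
    )
    if df.empty:
        return []
    out = []
    other = PIGMENTED if reference_group == UNPIGMENTED else UNPIGMENTED
    for gene_id, sub in df.groupby("gene_id", sort=True):
        per_sample = sub.groupby(["sample_id", "group"], sort=True)["dct"].mean().reset_index()
        a = per_sample.loc[per_sample["group"] == other, "dct"].to_numpy()
        b = per_sample.loc[per_sample["group"] == reference_group, "dct"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{gene_id}: each group needs >= 2 samples")
        ddct = float(a.mean() - b.mean())
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        if a.var(ddof=1) + b.var(ddof=1) == 0:
            t_p = 1.0 if ddct == 0 else 0.0
        else:
            _, t_p = stats.ttest_ind(a, b, equal_var=False)
        out.append(
            QpcrSummary(
                gene_id=str(gene_id),
                mean_dct_pigmented=float(a.mean() if other == PIGMENTED else b.mean()),
                mean_dct_unpigmented=float(b.mean() if other == PIGMENTED else a.mean()),
                ddct=ddct,
                log2fc=-ddct,
                se=se,
                t_p=float(t_p),
                log2fc_low=-(ddct + se),
                log2fc_high=-(ddct - se),
            )
        )
    return out


def concordance_report(
    de_log2fc: dict[str, float], qpcr_log2fc: dict[str, float]
) -> pd.DataFrame:
    """Join RNA-seq and qPCR log2 fold changes per validated gene and
    flag sign agreement."""
    genes = sorted(set(de_log2fc) & set(qpcr_log2fc))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "rnaseq_log2fc": [de_log2fc[g] for g in genes],
            "qpcr_log2fc": [qpcr_log2fc[g] for g in genes],
            "sign_agree": [
                bool(np.sign(de_log2fc[g]) == np.sign(qpcr_log2fc[g])) for g in genes
            ],
        }
    )
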