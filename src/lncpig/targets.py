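"""Cis and trans target prediction for differentially expressed lncRNAs.

Cis: protein-coding genes (relaxed DE set) whose locus lies within a
+/-300 kb window of a DE lncRNA locus, gated by expression correlation
(|Pearson r| >= 0.60, p <= 0.05, on log10 FPKM).

Trans: genes whose mRNA shows sequence complementarity to the lncRNA,
scored by an ungapped antiparallel hybridization scan.  For every offset
the duplex energy sums the pair energies (G:C -3, A:U -2, G:U -1) over
runs of at least ``min_run`` consecutive pairs (shorter runs are treated
as noise and contribute nothing).  The minimum over offsets, normalized
by the length of the shorter sequence, is the ndG statistic; candidates
must reach ndG <= ndg_threshold before the same correlation gate.

The energy scale is the package's integer pair model, not the
nearest-neighbor scale of thermodynamic folding tools, so the ndG
threshold is a calibrated quantity in these units.  The default
``min_run`` of 20 requires a perfect duplex core at the canonical
antisense-oligomer scale (~20 nt); at that setting the statistic is
essentially zero for shuffled sequences while any genuine >= 20-nt
complementary segment is always counted (see docs/methods.md for the
calibration; short-run noise swamps the statistic at small min_run).
Both the threshold and min_run are configuration knobs, and min_run = 1
disables the run filter entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernels import encode, hybrid_scan, pair_energy_matrix
from .io_model import ExpressionMatrix, GeneLocus

__all__ = [
    "TargetLink",
    "cis_candidates",
    "pearson",
    "ndg",
    "link_targets",
    "DEFAULT_WINDOW",
    "DEFAULT_NDG_THRESHOLD",
    "DEFAULT_MIN_RUN",
]

DEFAULT_WINDOW = 300_000
DEFAULT_NDG_THRESHOLD = -0.05
DEFAULT_MIN_RUN = 20
CORR_R = 0.60
CORR_P = 0.05
LOG10_PSEUDO = 1e-3


@dataclass
class TargetLink:
    lnc_id: str
    gene_id: str
    mode: str  # cis | trans
    r: float
    r_p: float
    passed: bool
    distance: int | None = None  # cis only; 0 when overlapping
    ndg: float | None = None  # trans only


def cis_candidates(
    lnc_locus: GeneLocus,
    gene_loci: list[GeneLocus],
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, int]]:
    """Genes whose span lies within ``window`` bp of the lncRNA span.

    Distance is the minimal endpoint gap between the two spans on the
    same chromosome (0 for overlap); the window boundary is inclusive.
    Strand is ignored for the neighborhood.
    """
    out = []
    ls, le = lnc_locus.span
    for g in gene_loci:
        if g.chrom != lnc_locus.chrom or g.gene_id == lnc_locus.gene_id:
            continue
        gs, ge = g.span
        d = max(0, max(ls, gs) - min(le, ge))
        if d <= window:
            out.append((g.gene_id, d))
    return sorted(out, key=lambda x: (x[1], x[0]))


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the usual t-based two-sided p.

    Zero-variance input is flagged undefined: returns (nan, 1.0) and can
    never pass the correlation gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


_DEFAULT_EMAT = pair_energy_matrix()


def ndg(
    lnc_seq: str,
    mrna_seq: str,
    pair_energy: dict[str, float] | None = None,
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[float, tuple[int, int]]:
    """Normalized duplex energy of the best ungapped antiparallel
    alignment of the two sequences.

    Returns (ndg, (lnc_start, lnc_end)) where the interval is the overlap
    of the best offset on the lncRNA; ndg = dG_min / min(len_lnc,
    len_mrna) and is always <= 0.
    """
    if not lnc_seq or not mrna_seq:
        raise ValueError("empty sequence")
    if pair_energy is None:
        emat = _DEFAULT_EMAT
    else:
        emat = pair_energy_matrix(
            gc=pair_energy.get("GC", -3.0),
            au=pair_energy.get("AU", -2.0),
            gu=pair_energy.get("GU", -1.0),
        )
    a = encode(lnc_seq)
    b_rev = encode(mrna_seq)[::-1].copy()
    dg_min, shift = hybrid_scan(a, b_rev, emat, min_run)
    n, m = len(a), len(b_rev)
    i0 = max(shift, 0)
    i1 = min(n, shift + m)
    return dg_min / min(n, m), (int(i0), int(i1))


def link_targets(
    de_lnc: list[str],
    de_genes: list[str],
    expr: ExpressionMatrix,
    loci: dict[str, GeneLocus] | None = None,
    sequences: dict[str, str] | None = None,
    mode: str = "cis",
    window: int = DEFAULT_WINDOW,
    ndg_threshold: float = DEFAULT_NDG_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    min_r: float = CORR_R,
    max_r_p: float = CORR_P,
) -> list[TargetLink]:
    """Link DE lncRNAs (strict set) to DE genes (relaxed set).

    cis needs ``loci`` (per lnc and gene); trans needs ``sequences``.
    Emitted links have passed the positional/energetic gate; ``passed``
    records the co-expression gate (|r| >= min_r and p <= max_r_p).
    Output is sorted by |r| descending.
    """
    expr_idx = {f: i for i, f in enumerate(expr.feature_ids)}
    vals = np.log10(np.asarray(expr.values) + LOG10_PSEUDO)
    links: list[TargetLink] = []
    for lnc in sorted(de_lnc):
        if lnc not in expr_idx:
            continue
        x = vals[expr_idx[lnc]]
        if mode == "cis":
            if loci is None:
                raise ValueError("cis mode requires loci")
            if lnc not in loci:
                continue
            gene_loci = [loci[g] for g in de_genes if g in loci]
            for gene_id, dist in cis_candidates(loci[lnc], gene_loci, window):
                if gene_id not in expr_idx:
                    continue
                r, p = pearson(x, vals[expr_idx[gene_id]])
                passed = (abs(r) >= min_r) and (p <= max_r_p) and r == r
                links.append(
                    TargetLink(lnc, gene_id, "cis", r, p, bool(passed), distance=dist)
                )
        elif mode == "trans":
            if sequences is None:
                raise ValueError("trans mode requires sequences")
            if lnc not in sequences:
                continue
            for gene_id in sorted(de_genes):
                if gene_id not in sequences or gene_id not in expr_idx:
                    continue
                e, _ = ndg(sequences[lnc], sequences[gene_id], min_run=min_run)
                if e > ndg_threshold:
                    continue
                r, p = pearson(x, vals[expr_idx[gene_id]])
                passed = (abs(r) >= min_r) and (p <= max_r_p) and r == r
                links.append(TargetLink(lnc, gene_id, "trans", r, p, bool(passed), ndg=e))
        else:
            raise ValueError("mode must be 'cis' or 'trans'")
    links.sort(key=lambda L: (-abs(L.r) if L.r == L.r else 0.0, L.lnc_id, L.gene_id))
    return links
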