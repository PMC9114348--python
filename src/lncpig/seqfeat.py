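"""Sequence characterization: GC content, FPKM, minimum folding energy
(ME) with its length normalization (MEN = ME / length * 100), and
rank-based group comparisons.

Folding uses a simplified nested-structure (Nussinov-style) model with
integer pair energies (G:C -3, A:U -2, G:U -1) and a minimum hairpin loop
of 3 unpaired bases.  This deliberately ignores stacking and loop
entropies, so absolute energies sit on a different scale from
nearest-neighbor folding programs; the per-100-nt normalization and the
between-class orderings are what the downstream comparisons use.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import encode, nussinov_fill, pair_energy_matrix
from .io_model import CountMatrix, ExpressionMatrix

__all__ = [
    "gc_content",
    "fpkm",
    "fold_me",
    "men",
    "wilcoxon_rank_sum",
    "compare_classes",
    "feature_table",
]

LOG10_PSEUDO = 1e-3  # display pseudocount for log10 FPKM


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator.  Returns NaN for
    empty or all-N input (flagged missing)."""
    s = seq.upper().replace("U", "T")
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    return gc / denom if denom else float("nan")


def fpkm(counts: CountMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """FPKM = count / (length/1000) / (library_size/1e6)."""
    lens = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    libs = np.array([counts.library_sizes[s] for s in counts.sample_ids], dtype=float)
    vals = counts.array / (lens[:, None] / 1e3) / (libs[None, :] / 1e6)
    return ExpressionMatrix(
        feature_ids=list(counts.feature_ids),
        sample_ids=list(counts.sample_ids),
        values=vals,
    )


# ---------------------------------------------------------------------------
# Folding

_DEFAULT_EMAT = pair_energy_matrix()


def fold_me(
    seq: str,
    energy: dict[str, float] | None = None,
    min_loop: int = 3,
) -> tuple[float, str]:
    """Minimum free energy over nested (pseudoknot-free) structures.

    ``energy`` maps pair classes {"GC", "AU", "GU"} to (negative) pair
    energies.  Hairpin loops must enclose at least ``min_loop`` unpaired
    bases; N never pairs.  Returns (energy <= 0, dot-bracket structure).
    Ties are broken toward fewer pairs, then by a deterministic traceback
    that prefers leaving the right end unpaired and pairing it with the
    leftmost partner otherwise.
    """
    if not seq:
        raise ValueError("empty sequence")
    if set(seq.upper().replace("U", "T")) - set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/U/N")
    if energy is None:
        emat = _DEFAULT_EMAT
    else:
        emat = pair_energy_matrix(
            gc=energy.get("GC", -3.0), au=energy.get("AU", -2.0), gu=energy.get("GU", -1.0)
        )
    if (emat > 0).any():
        raise ValueError("pair energies must be <= 0")
    enc = encode(seq)
    n = len(enc)
    if n < min_loop + 2:
        return 0.0, "." * n
    E, P = nussinov_fill(enc, emat, min_loop)
    structure = ["."] * n
    # iterative traceback mirroring the DP's (energy, pairs) ordering
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        if E[i, j] == E[i, j - 1] and P[i, j] == P[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if emat[enc[k], enc[j]] >= 0.0:
                continue
            left_e = E[i, k - 1] if k > i else 0.0
            left_p = P[i, k - 1] if k > i else 0
            mid_e = E[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
            mid_p = P[k + 1, j - 1] if k + 1 <= j - 1 else 0
            if (
                left_e + mid_e + emat[enc[k], enc[j]] == E[i, j]
                and left_p + mid_p + 1 == P[i, j]
            ):
                structure[k] = "("
                structure[j] = ")"
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                break
        else:  # pragma: no cover - DP consistency guard
            raise AssertionError("traceback failed")
    return float(E[0, n - 1]), "".join(structure)


def men(me: float, length: int) -> float:
    """Length-normalized folding energy: MEN = (ME / length) * 100."""
    if length <= 0:
        raise ValueError("length must be positive")
    return me / length * 100.0


def windowed_me(seq: str, max_fold_len: int = 250, **kwargs) -> tuple[float, int]:
    """ME of the central window of at most ``max_fold_len`` nt.

    Folding is cubic in length, so long transcripts are characterized by a
    representative central window; MEN should then be normalized by the
    folded length returned here.
    """
    if len(seq) <= max_fold_len:
        e, _ = fold_me(seq, **kwargs)
        return e, len(seq)
    start = (len(seq) - max_fold_len) // 2
    sub = seq[start : start + max_fold_len]
    e, _ = fold_me(sub, **kwargs)
    return e, max_fold_len


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)  # mid-ranks for ties
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Rank-sum test.  Exact permutation p (mid-ranks, enumeration over
    all group assignments of the observed data) when n_x+n_y <= 12; normal
    approximation with tie and continuity corrections otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _rank_sum_u(x, y)
    mean_u = nx * ny / 2.0
    if nx + ny <= 12:
        allv = np.concatenate([x, y])
        ranks = stats.rankdata(allv)
        total = 0
        hits = 0
        dev_obs = abs(u_obs - mean_u)
        for comb in itertools.combinations(range(nx + ny), nx):
            u = ranks[list(comb)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if alternative == "two-sided":
                hits += abs(u - mean_u) >= dev_obs - 1e-9
            elif alternative == "greater":
                hits += u >= u_obs - 1e-9
            else:
                hits += u <= u_obs + 1e-9
        return float(u_obs), hits / total
    # normal approximation
    allv = np.concatenate([x, y])
    n = nx + ny
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(u_obs), 1.0
    if alternative == "two-sided":
        z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
        p = 2 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_obs - mean_u - 0.5) / math.sqrt(var_u)
        p = stats.norm.sf(z)
    else:
        z = (u_obs - mean_u + 0.5) / math.sqrt(var_u)
        p = stats.norm.cdf(z)
    return float(u_obs), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Per-class summary with letter groups


@dataclass
class ClassComparison:
    summary: pd.DataFrame  # class x metric "mean ± SE" with letters
    pvalues: pd.DataFrame  # long table of pairwise Wilcoxon p per metric


METRICS = ["gc", "length", "exons", "log10_fpkm", "men"]


def feature_table(
    transcripts,
    expr: ExpressionMatrix | None = None,
    classes: dict[str, str] | None = None,
    max_fold_len: int = 250,
) -> pd.DataFrame:
    """Per-transcript feature table: GC, length, exon count, mean
    log10 FPKM, ME and MEN (ME normalized by the folded length)."""
    expr_map = {}
    if expr is not None:
        mean_fpkm = np.asarray(expr.values).mean(axis=1)
        expr_map = dict(zip(expr.feature_ids, mean_fpkm))
    rows = []
    for rec in transcripts:
        seq = rec.sequence or ""
        me_val, folded = windowed_me(seq, max_fold_len=max_fold_len) if seq else (0.0, 1)
        fp = expr_map.get(rec.transcript_id, float("nan"))
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "class": (classes or {}).get(rec.transcript_id, rec.source),
                "gc": gc_content(seq) if seq else float("nan"),
                "length": rec.length,
                "exons": rec.n_exons,
                "fpkm": fp,
                "log10_fpkm": math.log10(fp + LOG10_PSEUDO) if fp == fp else float("nan"),
                "me": me_val,
                "men": men(me_val, folded),
            }
        )
    return pd.DataFrame(rows)


def _letter_groups(class_names: list[str], means: dict[str, float], pmat: dict, alpha: float) -> dict[str, str]:
    """Compact letter display: classes sorted by mean; consecutive classes
    share a letter while every pairwise p within the group exceeds alpha."""
    ordered = sorted(class_names, key=lambda c: means[c])
    groups: list[list[str]] = []
    for c in ordered:
        placed = False
        for g in groups:
            if all(pmat[frozenset((c, o))] > alpha for o in g):
                g.append(c)
                placed = True
        if not placed:
            groups.append([c])
    letters = {c: "" for c in class_names}
    for i, g in enumerate(groups):
        for c in g:
            letters[c] += chr(ord("A") + i)
    return letters


def compare_classes(
    table: pd.DataFrame, alpha: float = 0.01, metrics: list[str] | None = None
) -> ClassComparison:
    """Per-metric class summary (mean ± SE, SE = SD/sqrt(n)) with pairwise
    rank-sum tests; classes whose pairwise p > alpha share a letter."""
    metrics = metrics or [m for m in METRICS if m in table.columns]
    classes = sorted(table["class"].unique())
    pairs = list(itertools.combinations(classes, 2))
    summary_rows = []
    p_rows = []
    for metric in metrics:
        vals = {
            c: table.loc[table["class"] == c, metric].dropna().to_numpy() for c in classes
        }
        means = {c: float(np.mean(v)) if len(v) else float("nan") for c, v in vals.items()}
        ses = {
            c: float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
            for c, v in vals.items()
        }
        pmat = {}
        for a, b in pairs:
            if len(vals[a]) and len(vals[b]):
                _, p = wilcoxon_rank_sum(vals[a], vals[b])
            else:
                p = float("nan")
            pmat[frozenset((a, b))] = p
            p_rows.append({"metric": metric, "class_a": a, "class_b": b, "p": p})
        letters = (
            _letter_groups(classes, means, pmat, alpha) if len(classes) > 1 else {c: "A" for c in classes}
        )
        for c in classes:
            summary_rows.append(
                {
                    "metric": metric,
                    "class": c,
                    "n": len(vals[c]),
                    "mean": means[c],
                    "se": ses[c],
                    "letter": letters[c],
                }
            )
    return ClassComparison(summary=pd.DataFrame(summary_rows), pvalues=pd.DataFrame(p_rows))
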