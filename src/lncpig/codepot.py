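"""Coding-potential assessment by a three-channel consensus.

A transcript is called noncoding only when three independent channels
agree, mirroring the common practice of intersecting CPC2-, CPAT- and
PLEK-style predictions:

* ``cpat_like`` — logistic regression on ORF length/coverage, Fickett
  TESTCODE score and in-frame hexamer usage bias, with a decision cutoff
  chosen by 10-fold cross-validation (Youden's J).
* ``cpc2_like`` — logistic regression on Fickett score and ORF
  length/coverage/integrity; fixed cutoff 0.5.
* ``plek_like`` — regularized linear (logistic) model on the normalized
  k-mer spectrum for k = 1..5; signed decision score, negative means
  noncoding.

The SVM of the original k-mer tool is deliberately replaced by a linear
model on the same features with the same sign convention; the decision
rule (score < 0 => noncoding) is unchanged.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureVector",
    "CodingPotentialModel",
    "longest_orf",
    "fickett_score",
    "hexamer_ratio",
    "build_hexamer_table",
    "kmer_spectrum",
    "train_channel",
    "predict_logistic",
    "select_cutoff",
    "train_model",
    "consensus_rule",
    "classify_consensus",
]

STOPS = ("TAA", "TAG", "TGA")

# ---------------------------------------------------------------------------
# ORF scanning


def longest_orf(seq: str) -> tuple[int, int, float, int]:
    """Longest open reading frame over the three forward frames.

    An ORF runs from ATG to the first in-frame stop codon (stop included);
    an ATG with no downstream in-frame stop is scored to the last complete
    codon with integrity -1 (open 3' end).  The longest span wins; ties go
    to the leftmost start.

    Returns ``(start, length, coverage, integrity)`` with coverage =
    length / len(seq) and integrity +1 (closed) or -1 (open or absent).
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    best = (0, -1, -1)  # (length, -start marker) handled explicitly below
    best_start, best_len, best_int = 0, 0, -1
    for frame in range(3):
        open_start = None
        i = frame
        while i + 3 <= n:
            codon = s[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            elif open_start is not None and codon in STOPS:
                length = i + 3 - open_start
                if length > best_len:
                    best_start, best_len, best_int = open_start, length, 1
                open_start = None
            i += 3
        if open_start is not None:
            # span to the last complete codon in this frame
            last = frame + ((n - frame) // 3) * 3
            length = last - open_start
            if length > best_len:
                best_start, best_len, best_int = open_start, length, -1
    coverage = best_len / n if n else 0.0
    return best_start, best_len, coverage, best_int


# ---------------------------------------------------------------------------
# Fickett TESTCODE score
#
# Lookup tables of the classic TESTCODE statistic: for each base, a
# position-asymmetry parameter (max/min+1 over the three codon positions)
# and a composition fraction are mapped through probability tables and
# combined with fixed weights.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.42, 0.29, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for i, p in enumerate(para):
        if value >= p:
            return probs[i]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic; case- and U/T-insensitive; N bases are
    ignored in the composition counts."""
    s = seq.upper().replace("U", "T")
    score = 0.0
    total = sum(s.count(b) for b in "ACGT")
    for base in "ACGT":
        counts = [s[i::3].count(base) for i in range(3)]
        pos_val = max(counts) / (min(counts) + 1.0)
        score += _lookup(pos_val, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        frac = s.count(base) / total if total else 0.0
        score += _lookup(frac, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias

_PSEUDO_FREQ = 1e-8


def build_hexamer_table(seqs: list[str]) -> dict[str, float]:
    """In-frame hexamer frequency table from training sequences; hexamers
    are taken in the frame of each sequence's longest ORF, step 3."""
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        s = seq.upper().replace("U", "T")
        start, length, _, _ = longest_orf(s)
        frame = start % 3
        for i in range(frame, len(s) - 5, 3):
            h = s[i : i + 6]
            if set(h) <= set("ACGT"):
                counts[h] = counts.get(h, 0) + 1
                total += 1
    if total == 0:
        return {}
    return {h: c / total for h, c in counts.items()}


def hexamer_ratio(
    seq: str,
    coding_freq_table: dict[str, float],
    noncoding_freq_table: dict[str, float],
) -> float:
    """Mean log-likelihood ratio log(f_coding/f_noncoding) over in-frame
    hexamers (frame of the longest ORF, step 3); 0 for sequences < 6 nt."""
    s = seq.upper().replace("U", "T")
    if len(s) < 6:
        return 0.0
    start, _, _, _ = longest_orf(s)
    frame = start % 3
    ratios = []
    for i in range(frame, len(s) - 5, 3):
        h = s[i : i + 6]
        fc = coding_freq_table.get(h, _PSEUDO_FREQ)
        fn = noncoding_freq_table.get(h, _PSEUDO_FREQ)
        ratios.append(math.log(fc / fn))
    return float(np.mean(ratios)) if ratios else 0.0


# ---------------------------------------------------------------------------
# k-mer spectrum (PLEK-like features)

_KMER_INDEX: dict[str, int] | None = None


def _kmer_index() -> dict[str, int]:
    global _KMER_INDEX
    if _KMER_INDEX is None:
        idx = {}
        for k in range(1, 6):
            for kmer in itertools.product("ACGT", repeat=k):
                idx["".join(kmer)] = len(idx)
        _KMER_INDEX = idx
    return _KMER_INDEX


def kmer_spectrum(seq: str) -> np.ndarray:
    """Concatenated normalized frequencies of all 1..5-mers (1364 values);
    each k-block sums to 1 (or 0 for sequences shorter than k)."""
    idx = _kmer_index()
    s = seq.upper().replace("U", "T")
    vec = np.zeros(len(idx), dtype=np.float64)
    offset = 0
    for k in range(1, 6):
        n_kmers = 4**k
        total = 0
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            j = idx.get(kmer)
            if j is not None:
                vec[j] += 1
                total += 1
        if total:
            vec[offset : offset + n_kmers] /= total
        offset += n_kmers
    return vec


@dataclass
class FeatureVector:
    """Per-transcript features feeding the three channels."""

    orf_length: int
    orf_coverage: float
    orf_integrity: int
    fickett: float
    hexamer_ratio: float
    kmer_spectrum: np.ndarray

    @classmethod
    def from_sequence(
        cls,
        seq: str,
        coding_hex: dict[str, float],
        noncoding_hex: dict[str, float],
    ) -> "FeatureVector":
        _, length, coverage, integrity = longest_orf(seq)
        return cls(
            orf_length=length,
            orf_coverage=coverage,
            orf_integrity=integrity,
            fickett=fickett_score(seq),
            hexamer_ratio=hexamer_ratio(seq, coding_hex, noncoding_hex),
            kmer_spectrum=kmer_spectrum(seq),
        )


# ---------------------------------------------------------------------------
# Logistic channel training (ridge IRLS)


def train_channel(
    features: np.ndarray,
    labels: np.ndarray,
    l2: float = 1e-3,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """L2-regularized logistic regression fit by iteratively reweighted
    least squares on standardized features.

    Deterministic given inputs (the seed is recorded for provenance only;
    IRLS has no random component).  The objective is the mean log-loss
    plus l2 * ||w||^2, so duplicating every observation leaves the fit
    unchanged.  Returns a dict with the standardized-scale weights,
    intercept, the standardization used, and convergence info.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features/labels shape mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if np.unique(y, axis=0).shape[0] > 2 or not set(classes) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n, p = Z.shape
    Zb = np.hstack([np.ones((n, 1)), Z])
    beta = np.zeros(p + 1)
    penalty = np.full(p + 1, l2 * n)  # per-observation penalty scaling
    penalty[0] = 0.0  # never penalize the intercept
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Zb @ beta, -30, 30)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(prob * (1 - prob), 1e-10)
        z = eta + (y - prob) / w
        A = Zb.T @ (Zb * w[:, None]) + np.diag(penalty)
        b = Zb.T @ (w * z)
        new_beta = np.linalg.solve(A, b)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    return {
        "intercept": float(beta[0]),
        "weights": beta[1:].tolist(),
        "feature_mean": mu.tolist(),
        "feature_sd": sd.tolist(),
        "l2": l2,
        "seed": seed,
        "converged": bool(converged),
    }


def predict_logistic(channel: dict, features: np.ndarray, decision: bool = False) -> np.ndarray:
    """Probability (or signed log-odds when ``decision``) from a trained
    channel."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    mu = np.asarray(channel["feature_mean"])
    sd = np.asarray(channel["feature_sd"])
    eta = channel["intercept"] + ((X - mu) / sd) @ np.asarray(channel["weights"])
    if decision:
        return eta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


# ---------------------------------------------------------------------------
# Cross-validated cutoff selection


def _best_cutoff_youden(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity+specificity for the rule
    'coding iff score > cutoff'.  Candidates are the unique scores; ties
    go to the smallest cutoff.  Returns (cutoff, sens, spec)."""
    cand = np.unique(scores)
    best = None
    for c in cand:
        sens = float(np.mean(scores[labels == 1] > c))
        spec = float(np.mean(scores[labels == 0] <= c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    assert best is not None
    return best[1], best[2], best[3]


def select_cutoff(
    scores: np.ndarray, labels: np.ndarray, folds: int = 10, seed: int = 0
) -> tuple[float, list[dict]]:
    """K-fold cross-validated decision cutoff.

    Samples are shuffled (seeded) and split into ``folds`` stratified
    parts (each class spread evenly across folds); for each fold the
    held-out scores provide the candidate cutoffs and the sensitivity/
    specificity used to maximize Youden's J.  The final cutoff is the
    mean of the per-fold winners.  Returns (cutoff, fold metadata).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    if folds < 1 or folds > n:
        raise ValueError("folds must be in [1, n]")
    rng = np.random.default_rng(seed)
    parts = [[] for _ in range(folds)]
    for cls in np.unique(labels):
        members = rng.permutation(np.where(labels == cls)[0])
        for i, idx in enumerate(members):
            parts[i % folds].append(idx)
    parts = [np.array(sorted(p), dtype=int) for p in parts]
    fold_info = []
    cutoffs = []
    for f, part in enumerate(parts):
        sc, lb = scores[part], labels[part]
        if len(np.unique(lb)) < 2:
            raise ValueError(f"fold {f} contains a single class; use fewer folds")
        c, sens, spec = _best_cutoff_youden(sc, lb)
        cutoffs.append(c)
        fold_info.append({"fold": f, "cutoff": c, "sensitivity": sens, "specificity": spec})
    return float(np.mean(cutoffs)), fold_info


# ---------------------------------------------------------------------------
# Full model


@dataclass
class CodingPotentialModel:
    """Trained three-channel model with the cross-validated CPAT-style
    cutoff and fixed CPC2-/PLEK-style cutoffs."""

    cpat_channel: dict
    cpc2_channel: dict
    plek_channel: dict
    coding_hexamers: dict[str, float]
    noncoding_hexamers: dict[str, float]
    cpat_cutoff: float
    cpc2_cutoff: float = 0.5
    plek_cutoff: float = 0.0
    metadata: dict = field(default_factory=dict)
    schema_version: int = 1

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "schema_version": self.schema_version,
                    "cpat_channel": self.cpat_channel,
                    "cpc2_channel": self.cpc2_channel,
                    "plek_channel": self.plek_channel,
                    "coding_hexamers": self.coding_hexamers,
                    "noncoding_hexamers": self.noncoding_hexamers,
                    "cpat_cutoff": self.cpat_cutoff,
                    "cpc2_cutoff": self.cpc2_cutoff,
                    "plek_cutoff": self.plek_cutoff,
                    "metadata": self.metadata,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "CodingPotentialModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        return cls(
            cpat_channel=d["cpat_channel"],
            cpc2_channel=d["cpc2_channel"],
            plek_channel=d["plek_channel"],
            coding_hexamers=d["coding_hexamers"],
            noncoding_hexamers=d["noncoding_hexamers"],
            cpat_cutoff=d["cpat_cutoff"],
            cpc2_cutoff=d["cpc2_cutoff"],
            plek_cutoff=d["plek_cutoff"],
            metadata=d.get("metadata", {}),
        )


def _cpat_features(fv: FeatureVector) -> np.ndarray:
    return np.array([fv.orf_length, fv.orf_coverage, fv.fickett, fv.hexamer_ratio])


def _cpc2_features(fv: FeatureVector) -> np.ndarray:
    return np.array([fv.fickett, fv.orf_length, fv.orf_coverage, fv.orf_integrity])


def train_model(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    folds: int = 10,
    seed: int = 0,
    l2: float = 1e-3,
) -> CodingPotentialModel:
    """Train all three channels plus the cross-validated cutoff.

    Hexamer tables are built from the training sequences themselves
    (coding vs noncoding), then every channel is fit on the pooled set.
    """
    coding_hex = build_hexamer_table(coding_seqs)
    noncoding_hex = build_hexamer_table(noncoding_seqs)
    fvs = [
        FeatureVector.from_sequence(s, coding_hex, noncoding_hex)
        for s in list(coding_seqs) + list(noncoding_seqs)
    ]
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    X_cpat = np.array([_cpat_features(f) for f in fvs])
    X_cpc2 = np.array([_cpc2_features(f) for f in fvs])
    X_plek = np.array([f.kmer_spectrum for f in fvs])
    cpat = train_channel(X_cpat, y, l2=l2, seed=seed)
    cpc2 = train_channel(X_cpc2, y, l2=l2, seed=seed)
    # heavier ridge on the 1364-dim k-mer spectrum
    plek = train_channel(X_plek, y, l2=max(l2, 1.0), seed=seed)
    cpat_scores = predict_logistic(cpat, X_cpat)
    cutoff, fold_info = select_cutoff(cpat_scores, y, folds=folds, seed=seed)
    return CodingPotentialModel(
        cpat_channel=cpat,
        cpc2_channel=cpc2,
        plek_channel=plek,
        coding_hexamers=coding_hex,
        noncoding_hexamers=noncoding_hex,
        cpat_cutoff=cutoff,
        metadata={
            "n_coding": len(coding_seqs),
            "n_noncoding": len(noncoding_seqs),
            "folds": folds,
            "seed": seed,
            "cv_folds": fold_info,
        },
    )


def channel_scores(seq: str, model: CodingPotentialModel) -> dict[str, float]:
    fv = FeatureVector.from_sequence(seq, model.coding_hexamers, model.noncoding_hexamers)
    return {
        "cpc2": float(predict_logistic(model.cpc2_channel, _cpc2_features(fv))[0]),
        "cpat": float(predict_logistic(model.cpat_channel, _cpat_features(fv))[0]),
        "plek": float(
            predict_logistic(model.plek_channel, fv.kmer_spectrum, decision=True)[0]
        ),
    }


def consensus_rule(
    cpc2: float,
    cpat: float,
    plek: float,
    cpat_cutoff: float,
    cpc2_cutoff: float = 0.5,
    plek_cutoff: float = 0.0,
) -> str:
    """The unanimity gate on channel scores: noncoding iff cpc2 < 0.5
    (strict), cpat <= cutoff (inclusive), and plek < 0 (strict)."""
    noncoding = cpc2 < cpc2_cutoff and cpat <= cpat_cutoff and plek < plek_cutoff
    return "noncoding" if noncoding else "coding_potential"


def classify_consensus(
    seq: str, model: CodingPotentialModel, cpat_cutoff: float | None = None
) -> tuple[str, dict[str, float]]:
    """Unanimity rule: noncoding iff the CPC2-like probability is < 0.5,
    the CPAT-like probability is <= the model cutoff, and the PLEK-like
    signed score is < 0.  ``cpat_cutoff`` overrides the trained cutoff
    (e.g. a published species default such as 0.36)."""
    sc = channel_scores(seq, model)
    cutoff = model.cpat_cutoff if cpat_cutoff is None else cpat_cutoff
    verdict = consensus_rule(
        sc["cpc2"], sc["cpat"], sc["plek"], cutoff, model.cpc2_cutoff, model.plek_cutoff
    )
    return verdict, sc
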