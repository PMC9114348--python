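"""Compiled inner loops shared by the folding, alignment and
hybridization modules.

Bases are encoded as int8: A=0, C=1, G=2, T/U=3, N=4.  N never pairs and
never matches.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.array([BASE_CODE[c] for c in seq.upper().replace("U", "T")], dtype=np.int8)


def pair_energy_matrix(gc: float = -3.0, au: float = -2.0, gu: float = -1.0) -> np.ndarray:
    """5x5 base-pair energy table; 0 means 'cannot pair'."""
    m = np.zeros((5, 5), dtype=np.float64)
    m[2, 1] = m[1, 2] = gc  # G:C
    m[0, 3] = m[3, 0] = au  # A:U
    m[2, 3] = m[3, 2] = gu  # G:U wobble
    return m


@njit(cache=False)
def nussinov_fill(seq, emat, min_loop):
    """Fill energy (E) and pair-count (P) tables for minimum-energy nested
    folding.  Optimality order is lexicographic on (energy, n_pairs), so
    among equal-energy structures the one with fewer pairs wins."""
    n = seq.shape[0]
    E = np.zeros((n, n), dtype=np.float64)
    P = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # option: j unpaired
            be = E[i, j - 1]
            bp = P[i, j - 1]
            # option: j pairs with k
            for k in range(i, j - min_loop):
                e_kj = emat[seq[k], seq[j]]
                if e_kj >= 0.0:
                    continue
                left_e = E[i, k - 1] if k > i else 0.0
                left_p = P[i, k - 1] if k > i else 0
                mid_e = E[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                mid_p = P[k + 1, j - 1] if k + 1 <= j - 1 else 0
                ce = left_e + mid_e + e_kj
                cp = left_p + mid_p + 1
                if ce < be or (ce == be and cp < bp):
                    be = ce
                    bp = cp
            E[i, j] = be
            P[i, j] = bp
    return E, P


@njit(cache=False)
def banded_sw(q, s, dlo, dhi, match, mismatch, gap_open, gap_ext):
    """Banded local alignment with affine gaps.

    Only cells with dlo <= j-i <= dhi are computed.  ``gap_open`` is the
    score of the first gap column, ``gap_ext`` of each further column
    (Biopython PairwiseAligner convention).  Returns (score, i_end, j_end)
    of the best cell (1-based DP indices) plus the H/trace matrices for a
    Python-side traceback.

    trace codes: 0 stop, 1 diagonal, 2 gap-in-query (left), 3 gap-in-subject (up).
    """
    n = q.shape[0]
    m = s.shape[0]
    NEG = -1.0e18
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    Eg = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    Fg = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    T = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        j0 = i + dlo
        j1 = i + dhi
        if j0 < 1:
            j0 = 1
        if j1 > m:
            j1 = m
        for j in range(j0, j1 + 1):
            in_band_left = (j - 1) - i >= dlo
            in_band_up = j - (i - 1) <= dhi
            # gap in query (consume subject base j)
            if in_band_left:
                open_sc = H[i, j - 1] + gap_open
                ext_sc = Eg[i, j - 1] + gap_ext
                Eg[i, j] = open_sc if open_sc >= ext_sc else ext_sc
            else:
                Eg[i, j] = NEG
            # gap in subject (consume query base i)
            if in_band_up:
                open_sc = H[i - 1, j] + gap_open
                ext_sc = Fg[i - 1, j] + gap_ext
                Fg[i, j] = open_sc if open_sc >= ext_sc else ext_sc
            else:
                Fg[i, j] = NEG
            if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0.0
            t = 0
            if diag > h:
                h = diag
                t = 1
            if Eg[i, j] > h:
                h = Eg[i, j]
                t = 2
            if Fg[i, j] > h:
                h = Fg[i, j]
                t = 3
            H[i, j] = h
            T[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, Eg, Fg, T


@njit(cache=False)
def hybrid_scan(a, b_rev, emat, min_run):
    """Minimum hybridization energy over all ungapped antiparallel offsets.

    ``b_rev`` must be the second sequence reversed (so that index walking
    is parallel).  For each shift, pair energies are summed over maximal
    runs of >= min_run consecutive complementary (WC or GU) positions;
    shorter runs contribute 0.  Returns (dG_min, best_shift) where shift s
    aligns a[i] with b_rev[i - s].
    """
    n = a.shape[0]
    m = b_rev.shape[0]
    best = 0.0
    best_shift = 0
    for s in range(-(m - 1), n):
        i0 = s if s > 0 else 0
        i1 = n if s + m > n else s + m
        dg = 0.0
        run_len = 0
        run_e = 0.0
        for i in range(i0, i1):
            e = emat[a[i], b_rev[i - s]]
            if e < 0.0:
                run_len += 1
                run_e += e
            else:
                if run_len >= min_run:
                    dg += run_e
                run_len = 0
                run_e = 0.0
        if run_len >= min_run:
            dg += run_e
        if dg < best:
            best = dg
            best_shift = s
    return best, best_shift
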