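"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a quantity by a route deliberately different
from the implementation under test: per-base boolean masks instead of
interval arithmetic, codon-by-codon walks instead of vectorised counting,
normal equations instead of library regression, and a linear-programming
formulation of the dip statistic instead of the GCM/LCM recursion.
"""

from __future__ import annotations


import numpy as np
from scipy.optimize import linprog

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


# ---------------------------------------------------------------------------
# sequence / interval oracles
# ---------------------------------------------------------------------------

def reverse_complement(seq):
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def coverage_mask(length, intervals):
    """Per-base boolean mask of [start, end) interval coverage."""
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return mask


def walk_positional_counts(cds_sequences):
    """GC and unambiguous-base counts per codon position, codon by codon.

    Returns ((gc1, gc2, gc3), (n1, n2, n3)) integer counts; positions with
    an ambiguous base are excluded from both numerator and denominator.
    """
    gc = [0, 0, 0]
    tot = [0, 0, 0]
    for seq in cds_sequences:
        assert len(seq) % 3 == 0
        s = seq.upper().replace("U", "T")
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            for k in range(3):
                base = codon[k]
                if base in "ACGT":
                    tot[k] += 1
                    if base in "GC":
                        gc[k] += 1
    return tuple(gc), tuple(tot)


def walk_codon_counts(cds_sequences):
    """Stride-3 3-mer counts, skipping codons with ambiguous bases."""
    counts = {}
    for seq in cds_sequences:
        s = seq.upper().replace("U", "T")
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if all(b in "ACGT" for b in codon):
                rna = codon.replace("T", "U")
                counts[rna] = counts.get(rna, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def midranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_by_hand(x, y):
    """Pearson correlation of midranks, written out explicitly."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def ols_normal_equations(x, y):
    """(slope, intercept) from the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1]), float(beta[0])


# ---------------------------------------------------------------------------
# dip oracle: direct minimisation over unimodal CDFs
# ---------------------------------------------------------------------------

def _min_band_halfwidth(x, left_pos, left_lohi, right_pos, right_lohi, big):
    """Smallest d admitting a unimodal CDF within the given bands.

    The left chain must be convex (entered at height 0 far to the left),
    the right chain concave (exiting at height 1 far to the right), both
    nondecreasing, with a jump allowed where they meet.  Bands are
    (lo_base - d, hi_base + d) boxes.  Solved as a linear program in the
    chain values and d.
    """
    nL, nR = len(left_pos), len(right_pos)
    nv = nL + nR + 1  # left values, right values, d
    i_d = nL + nR
    A, b = [], []

    def add(coefs, rhs):
        row = np.zeros(nv)
        for idx, c in coefs:
            row[idx] += c
        A.append(row)
        b.append(rhs)

    # boxes: v >= lo - d  and  v <= hi + d
    for i, (lo, hi) in enumerate(left_lohi):
        add([(i, -1.0), (i_d, -1.0)], -lo)
        add([(i, 1.0), (i_d, -1.0)], hi)
    for i, (lo, hi) in enumerate(right_lohi):
        add([(nL + i, -1.0), (i_d, -1.0)], -lo)
        add([(nL + i, 1.0), (i_d, -1.0)], hi)

    # monotone within chains and across the mode jump
    for i in range(nL - 1):
        add([(i, 1.0), (i + 1, -1.0)], 0.0)
    for i in range(nR - 1):
        add([(nL + i, 1.0), (nL + i + 1, -1.0)], 0.0)
    add([(nL - 1, 1.0), (nL, -1.0)], 0.0)  # G(mode-) <= G(mode)

    # convexity of the left chain, with a virtual entry point at height 0
    pos = [left_pos[0] - big] + list(left_pos)
    val = [None] + list(range(nL))  # None marks the constant-0 entry point
    for t in range(len(pos) - 2):
        p1, p2, p3 = pos[t], pos[t + 1], pos[t + 2]
        # (v2-v1)(p3-p2) <= (v3-v2)(p2-p1)
        coefs, rhs = [], 0.0
        for v, c in ((val[t], -(p3 - p2)), (val[t + 1], (p3 - p1)),
                     (val[t + 2], -(p2 - p1))):
            if v is None:
                rhs -= 0.0 * c
            else:
                coefs.append((v, c))
        add(coefs, rhs)

    # concavity of the right chain, with a virtual exit point at height 1
    pos = list(right_pos) + [right_pos[-1] + big]
    val = [nL + i for i in range(nR)] + [None]
    for t in range(len(pos) - 2):
        p1, p2, p3 = pos[t], pos[t + 1], pos[t + 2]
        # (v2-v1)(p3-p2) >= (v3-v2)(p2-p1)
        coefs, rhs = [], 0.0
        for v, c in ((val[t], (p3 - p2)), (val[t + 1], -(p3 - p1)),
                     (val[t + 2], (p2 - p1))):
            if v is None:
                rhs -= 1.0 * c
            else:
                coefs.append((v, c))
        add(coefs, rhs)

    cvec = np.zeros(nv)
    cvec[i_d] = 1.0
    bounds = [(0.0, 1.0)] * (nL + nR) + [(0.0, 1.0)]
    res = linprog(cvec, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    return res.fun if res.success else np.inf


def dip_by_lp(sample, gap_points=3):
    """Dip statistic by direct LP minimisation over unimodal CDFs.

    Works on the distinct sample coordinates: at a coordinate with
    cumulative count C and preceding cumulative count P, a continuous CDF
    within sup-distance d of the ECDF must take a value in
    [C/n - d, P/n + d]; at the mode the left limit (band around P/n) and
    the value (band around C/n) are decoupled by the allowed jump.  For
    every candidate mode (each coordinate, plus a few positions in every
    gap) the minimal feasible d is found by linear programming; the dip
    is the minimum over candidates.  Intended for small n only.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    xs, counts = np.unique(x, return_counts=True)
    m = xs.size
    C = np.cumsum(counts) / n       # F at each distinct coordinate
    P = C - counts / n              # F just left of it
    big = 1e6 * max(xs[-1] - xs[0], 1.0)
    best = np.inf

    # non-mode box at coordinate j (continuity): [C_j - d, P_j + d]
    box = [(C[j], P[j]) for j in range(m)]

    for k in range(m):
        # mode at xs[k]: left chain ends with G(mode-), right starts G(mode)
        left_pos = list(xs[: k + 1])
        left_lohi = box[:k] + [(P[k], P[k])]
        right_pos = list(xs[k:])
        right_lohi = [(C[k], C[k])] + box[k + 1:]
        best = min(best, _min_band_halfwidth(
            xs, left_pos, left_lohi, right_pos, right_lohi, big))

    for k in range(m - 1):
        gap = xs[k + 1] - xs[k]
        for frac in np.linspace(0.0, 1.0, gap_points + 2)[1:-1]:
            mode = xs[k] + frac * gap
            left_pos = list(xs[: k + 1]) + [mode]
            left_lohi = box[: k + 1] + [(C[k], C[k])]
            right_pos = [mode] + list(xs[k + 1:])
            right_lohi = [(C[k], C[k])] + box[k + 1:]
            best = min(best, _min_band_halfwidth(
                xs, left_pos, left_lohi, right_pos, right_lohi, big))

    return float(best)


# ---------------------------------------------------------------------------
# GFF/BED oracle on raw annotation text
# ---------------------------------------------------------------------------

def mask_from_gff3_text(text, seg_lengths):
    """Per-base CDS coverage masks built directly from raw GFF3 lines."""
    masks = {seg: np.zeros(ln, dtype=bool) for seg, ln in seg_lengths.items()}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[2] != "CDS":
            continue
        seg, start, end = parts[0], int(parts[3]), int(parts[4])
        masks[seg][start - 1:end] = True
    return masks


def mask_from_bed_text(text, seg_lengths):
    masks = {seg: np.zeros(ln, dtype=bool) for seg, ln in seg_lengths.items()}
    for line in text.splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        seg, start, end = parts[0], int(parts[1]), int(parts[2])
        masks[seg][start:end] = True
    return masks


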