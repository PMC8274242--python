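"""Statistical battery for compositional analyses.

This module provides the quantitative machinery used throughout the
pipeline: Spearman rank correlation, ordinary least-squares fits with
adjusted R^2, Hartigans' dip statistic with a Monte-Carlo unimodality
test, Gaussian kernel density estimation with mode detection, and the
per-codon virus-host correlation table.

The dip statistic is computed with the greatest-convex-minorant /
least-concave-majorant recursion of Hartigan & Hartigan (1985): the dip
is the maximum distance between the empirical CDF and the closest
unimodal CDF.  The null distribution for the test is obtained by
bootstrap from the uniform distribution, the least favourable unimodal
null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "CorrelationResult",
    "LinearFit",
    "DipResult",
    "DensityEstimate",
    "spearman_rho",
    "linear_fit",
    "dip_statistic",
    "dip_null_table",
    "dip_test",
    "nrd0_bandwidth",
    "kde_modes",
    "per_codon_correlation",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation: coefficient, sample size and p-value."""

    rho: float
    n: int
    p_value: float


@dataclass(frozen=True)
class LinearFit:
    """Simple OLS fit y ~ x with R^2 and adjusted R^2 (one predictor)."""

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    n: int


@dataclass(frozen=True)
class DipResult:
    """Hartigans' dip statistic with its Monte-Carlo p-value."""

    dip: float
    n: int
    p_value: float
    replicates: int
    seed: int


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian KDE on a 512-point grid, with the detected modes.

    ``modes`` holds the grid abscissae of strict local maxima of the
    gridded density, sorted ascending.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    modes: tuple


# ---------------------------------------------------------------------------
# correlation and regression
# ---------------------------------------------------------------------------

def spearman_rho(x, y, p_method="t"):
    """Spearman's rank correlation (midranks for ties).

    The coefficient is the Pearson correlation of the midrank-transformed
    samples; the p-value uses the t approximation, or exact permutation
    enumeration when ``p_method='exact'`` (only for n <= 10).

    Raises ``ValueError`` on unequal lengths, n < 2, non-finite values or
    zero rank variance in either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance: Spearman's rho is undefined")

    if p_method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        rx = _sps.rankdata(x)
        ry = _sps.rankdata(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        # permutation distribution of |rho| under independence
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / denom
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
            total += 1
        return CorrelationResult(rho=rho, n=n, p_value=hits / total)

    res = _sps.spearmanr(x, y)
    rho = float(res.statistic)
    p = float(res.pvalue) if n >= 3 else float("nan")
    return CorrelationResult(rho=rho, n=n, p_value=p)


def linear_fit(x, y):
    """Ordinary least squares fit of y on x with adjusted R^2.

    adj_r2 = 1 - (1 - r2) (n - 1) / (n - 2) for a single predictor.
    Requires n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations for a linear fit")
    if np.all(x == x[0]):
        raise ValueError("constant x: slope is undefined")
    res = _sps.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        adj_r2=adj,
        n=n,
    )


# ---------------------------------------------------------------------------
# Hartigans' dip
# ---------------------------------------------------------------------------

def _lower_hull(x, lo, hi):
    # Vertices (indices, lo..hi ascending) of the greatest convex minorant
    # of the points (x[i], i).  Collinear interior points are merged.
    hull = [lo]
    for j in range(lo + 1, hi + 1):
        while len(hull) >= 2:
            a = hull[-2]
            b = hull[-1]
            if (x[j] - x[b]) * (b - a) < (x[b] - x[a]) * (j - b):
                break
            hull.pop()
        hull.append(j)
    return hull


def _upper_hull(x, lo, hi):
    # Vertices of the least concave majorant of the points (x[i], i).
    hull = [lo]
    for j in range(lo + 1, hi + 1):
        while len(hull) >= 2:
            a = hull[-2]
            b = hull[-1]
            if (x[j] - x[b]) * (b - a) > (x[b] - x[a]) * (j - b):
                break
            hull.pop()
        hull.append(j)
    return hull


def dip_statistic(sample):
    """Hartigans' dip statistic D_n of a 1-D sample (n >= 4).

    Returns the maximum distance between the empirical CDF and the
    closest unimodal CDF; always in [1/(2n), 1/4].  Invariant under
    strictly increasing affine transforms of the sample.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic requires at least 4 observations")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in sample")
    x = x.tolist()

    low, high = 0, n - 1
    dip = 1.0  # in units of 2n

    while True:
        G = _lower_hull(x, low, high)  # GCM vertices, low -> high
        L = _upper_hull(x, low, high)  # LCM vertices, low -> high
        p, q = len(G), len(L)

        # --- largest distance between the two hull curves ----------------
        d = 0.0
        nl = 0        # position in G of the new lower modal bound
        nh = q - 1    # position in L of the new upper modal bound
        if p == 2 and q == 2:
            d = 1.0
        else:
            i_g, i_l = 1, 1
            while True:
                gx, lx = G[i_g], L[i_l]
                if gx > lx:
                    # LCM vertex lx between GCM vertices G[i_g-1], G[i_g]
                    a, b = G[i_g - 1], G[i_g]
                    if x[b] > x[a]:
                        interp = a + (x[lx] - x[a]) * (b - a) / (x[b] - x[a])
                    else:
                        interp = float(a)
                    dx = (lx + 1) - interp
                    i_l += 1
                    if dx >= d:
                        d = dx
                        nl = i_g - 1
                        nh = i_l - 1
                else:
                    # GCM vertex gx between LCM vertices L[i_l-1], L[i_l]
                    a, b = L[i_l - 1], L[i_l]
                    if x[b] > x[a]:
                        interp = a + (x[gx] - x[a]) * (b - a) / (x[b] - x[a])
                    else:
                        interp = float(b)
                    dx = interp - (gx - 1)
                    i_g += 1
                    if dx > d:
                        d = dx
                        nl = i_g - 1
                        nh = i_l
                if i_g > p - 1:
                    i_g = p - 1
                if i_l > q - 1:
                    i_l = q - 1
                if G[i_g] == L[i_l]:
                    break

        if d < dip:
            break

        new_low, new_high = G[nl], L[nh]

        # --- dip of the ECDF over the left tail against the GCM ----------
        dip_l = 0.0
        for t in range(nl):
            jb, je = G[t], G[t + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    tt = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if tt > max_t:
                        max_t = tt
            if max_t > dip_l:
                dip_l = max_t

        # --- dip of the ECDF over the right tail against the LCM ---------
        dip_u = 0.0
        for t in range(nh, q - 1):
            jb, je = L[t], L[t + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    tt = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if tt > max_t:
                        max_t = tt
            if max_t > dip_u:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)

        if low == new_low and high == new_high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_null_table(n, replicates=2000, seed=0):
    """Dip statistics of ``replicates`` uniform(0,1) samples of size n.

    The uniform is the least favourable unimodal null, so its dip
    distribution calibrates the test for any sample of the same size.
    """
    rng = np.random.default_rng(seed)
    return np.array(
        [dip_statistic(rng.random(n)) for _ in range(replicates)]
    )


def dip_test(sample, replicates=2000, seed=0, null_dips=None):
    """Monte-Carlo dip test of unimodality.

    p = (1 + #{dip(U_b) >= dip_obs}) / (replicates + 1) over uniform
    bootstrap samples U_b of the same size.  A precomputed ``null_dips``
    array (from :func:`dip_null_table`) may be supplied to amortise the
    null calibration across many tests of equal sample size.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    d = dip_statistic(sample)
    if null_dips is None:
        if replicates < 100:
            raise ValueError("need at least 100 bootstrap replicates")
        null_dips = dip_null_table(n, replicates=replicates, seed=seed)
    else:
        null_dips = np.asarray(null_dips, dtype=float)
        replicates = null_dips.size
    exceed = int(np.count_nonzero(null_dips >= d))
    p = (1.0 + exceed) / (replicates + 1.0)
    return DipResult(dip=d, n=n, p_value=p, replicates=replicates, seed=seed)


# ---------------------------------------------------------------------------
# kernel density estimation
# ---------------------------------------------------------------------------

def nrd0_bandwidth(values):
    """Silverman rule-of-thumb bandwidth 0.9 min(sd, IQR/1.349) n^(-1/5)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: bandwidth undefined")
    q75, q25 = np.percentile(x, [75.0, 25.0])
    scale = min(sd, (q75 - q25) / 1.349)
    if scale <= 0.0:
        scale = sd
    return 0.9 * scale * n ** (-0.2)


def kde_modes(values, bandwidth="nrd0"):
    """Gaussian KDE on a 512-point grid plus strict local maxima.

    The grid spans the data range extended by three bandwidths on each
    side.  ``bandwidth`` is either the string ``'nrd0'`` or a fixed
    positive kernel standard deviation.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.std(x) == 0.0:
        raise ValueError("zero variance: density estimate undefined")
    if isinstance(bandwidth, str):
        if bandwidth != "nrd0":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        h = nrd0_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0.0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - 3.0 * h, x.max() + 3.0 * h, 512)
    kde = _sps.gaussian_kde(x, bw_method=h / np.std(x, ddof=1))
    density = kde(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    # floating-point ripple in the far tails can fabricate strict maxima at
    # negligible density; require a mode to carry non-negligible mass
    interior &= density[1:-1] > 1e-4 * density.max()
    modes = tuple(grid[1:-1][interior])
    return DensityEstimate(grid=grid, density=density, bandwidth=h, modes=modes)


# ---------------------------------------------------------------------------
# per-codon virus-host correlation
# ---------------------------------------------------------------------------

def per_codon_correlation(pairs, normalization="fraction"):
    """Correlate virus vs host usage of each of the 64 codons across pairs.

    ``pairs`` is an iterable of VirusHostPair objects whose virus and host
    both carry codon tables.  For every codon the virus frequency is
    correlated (Spearman) with the host frequency across all pairs, and a
    linear fit provides the adjusted R^2.  Returns a DataFrame with
    columns (codon, rho, p_value, adj_r2, n) and a dict with the median
    rho and median adj_r2.  Codons with zero variance in either party are
    reported as NaN and excluded from the medians.
    """
    from .codon_usage import CODONS, normalize_codon_table

    usable = [
        p for p in pairs
        if p.virus_codon_table is not None and p.host.codon_table is not None
    ]
    if len(usable) < 3:
        raise ValueError("need at least 3 pairs with codon tables")

    virus = np.empty((len(usable), 64))
    host = np.empty((len(usable), 64))
    for i, p in enumerate(usable):
        vt = normalize_codon_table(p.virus_codon_table, normalization)
        ht = normalize_codon_table(p.host.codon_table, normalization)
        virus[i] = [vt.values[c] for c in CODONS]
        host[i] = [ht.values[c] for c in CODONS]

    rows = []
    for j, codon in enumerate(CODONS):
        hx, vy = host[:, j], virus[:, j]
        if np.all(hx == hx[0]) or np.all(vy == vy[0]):
            rows.append((codon, np.nan, np.nan, np.nan, len(usable)))
            continue
        corr = spearman_rho(hx, vy)
        fit = linear_fit(hx, vy)
        rows.append((codon, corr.rho, corr.p_value, fit.adj_r2, corr.n))
    table = pd.DataFrame(rows, columns=["codon", "rho", "p_value", "adj_r2", "n"])
    medians = {
        "rho": float(np.nanmedian(table["rho"].to_numpy())),
        "adj_r2": float(np.nanmedian(table["adj_r2"].to_numpy())),
    }
    return table, medians
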