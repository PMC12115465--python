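"""Independent naive reference implementations used as test oracles.

Every function here evaluates its defining double sum literally, with Python
loops and 1-based index ranges translated directly, deliberately sharing no
code with the package's vectorized implementations.  The wavelet reference is
a hand-written circular-convolution filter bank with the Daubechies-6
decomposition filters hardcoded as literals.
"""

import math

import numpy as np


def smd_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(m - 1):
        for y in range(n - 1):
            s += abs(a[x, y] - a[x + 1, y]) + abs(a[x, y] - a[x, y + 1])
    return s


def roberts_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(m - 1):
        for y in range(n - 1):
            s += (a[x + 1, y + 1] - a[x, y]) ** 2 + (a[x + 1, y] - a[x, y + 1]) ** 2
    return s


def tenengrad_ref(a):
    kx = [[1, 0, -1], [2, 0, -2], [1, 0, -1]]
    ky = [[1, 2, 1], [0, 0, 0], [-1, -2, -1]]
    m, n = a.shape
    s = 0.0
    for x in range(1, m - 1):
        for y in range(1, n - 1):
            gx = 0.0
            gy = 0.0
            for i in (-1, 0, 1):
                for j in (-1, 0, 1):
                    gx += kx[i + 1][j + 1] * a[x + i, y + j]
                    gy += ky[i + 1][j + 1] * a[x + i, y + j]
            s += gx * gx + gy * gy
    return s


def brenner_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(m - 2):
        for y in range(n):
            s += (a[x, y] - a[x + 2, y]) ** 2
    return s


def eog_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(m - 1):
        for y in range(n - 1):
            s += (a[x + 1, y] - a[x, y]) ** 2 + (a[x, y + 1] - a[x, y]) ** 2
    return s


def eol_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(1, m - 1):
        for y in range(1, n - 1):
            lap = (
                a[x + 1, y] + a[x - 1, y] + a[x, y + 1] + a[x, y - 1] - 4 * a[x, y]
            )
            s += lap * lap
    return s


def sml_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(1, m - 1):
        for y in range(1, n - 1):
            ml = abs(2 * a[x, y] - a[x - 1, y] - a[x + 1, y]) + abs(
                2 * a[x, y] - a[x, y - 1] - a[x, y + 1]
            )
            s += ml * ml
    return s


def variance_ref(a):
    m, n = a.shape
    mean = sum(a[x, y] for x in range(m) for y in range(n)) / (m * n)
    return sum((a[x, y] - mean) ** 2 for x in range(m) for y in range(n))


def vollath_ref(a):
    m, n = a.shape
    s = 0.0
    for x in range(m - 2):
        for y in range(n):
            s += a[x, y] * a[x + 1, y] - a[x, y] * a[x + 2, y]
    return s


def fft_ref(a):
    """Direct DFT summation over the centered grid u in [-M/2, M/2),
    v in [-N/2, N/2); unnormalized transform, P = |X|^2."""
    m, n = a.shape
    s = 0.0
    for u in range(-(m // 2), (m + 1) // 2):
        for v in range(-(n // 2), (n + 1) // 2):
            xu = 0.0 + 0.0j
            for x in range(m):
                for y in range(n):
                    xu += a[x, y] * np.exp(-2j * math.pi * (u * x / m + v * y / n))
            s += (u * u + v * v) * abs(xu) ** 2
    return s


def dct_ref(a):
    """Direct orthonormal 2-D DCT-II summation, weighted by u + v."""
    m, n = a.shape
    s = 0.0
    for u in range(m):
        for v in range(n):
            su = math.sqrt(1.0 / m) if u == 0 else math.sqrt(2.0 / m)
            sv = math.sqrt(1.0 / n) if v == 0 else math.sqrt(2.0 / n)
            c = 0.0
            for x in range(m):
                for y in range(n):
                    c += (
                        a[x, y]
                        * math.cos(math.pi * (2 * x + 1) * u / (2 * m))
                        * math.cos(math.pi * (2 * y + 1) * v / (2 * n))
                    )
            c *= su * sv
            s += (u + v) * c * c
    return s


# Daubechies-6 decomposition filters (12 taps, standard published values).
DB6_LO = np.array([
    -0.0010773010853084796, 0.004777257510945511, 0.0005538422011614961,
    -0.03158203931748603, 0.027522865530305727, 0.09750160558732304,
    -0.12976686756726194, -0.22626469396543983, 0.31525035170919763,
    0.7511339080210954, 0.49462389039845306, 0.11154074335010947,
])
DB6_HI = np.array([
    -0.11154074335010947, 0.49462389039845306, -0.7511339080210954,
    0.31525035170919763, 0.22626469396543983, -0.12976686756726194,
    -0.09750160558732304, 0.027522865530305727, 0.03158203931748603,
    0.0005538422011614961, -0.004777257510945511, -0.0010773010853084796,
])


def _dwt1d_periodic(x, filt):
    """One analysis channel under periodic extension: circular convolution
    with the filter, downsampled so coefficient k aligns as
    c[k] = sum_m f[m] * x[(2k - (L - 2) - m) mod n]."""
    n = len(x)
    L = len(filt)
    half = n // 2
    out = np.empty(half)
    for k in range(half):
        acc = 0.0
        for mm in range(L):
            acc += filt[mm] * x[(2 * k - (L - 2) - mm) % n]
        out[k] = acc
    return out


def dwt_detail_energy_ref(a):
    """Single-level DB6 detail energy under periodic extension: sum over the
    LH, HL and HH sub-images of squared deviations from each sub-image mean."""
    m, n = a.shape
    lo_cols = np.array([_dwt1d_periodic(a[:, y], DB6_LO) for y in range(n)]).T
    hi_cols = np.array([_dwt1d_periodic(a[:, y], DB6_HI) for y in range(n)]).T
    subbands = []
    for rows in (lo_cols, hi_cols):
        lo = np.array([_dwt1d_periodic(rows[x, :], DB6_LO) for x in range(rows.shape[0])])
        hi = np.array([_dwt1d_periodic(rows[x, :], DB6_HI) for x in range(rows.shape[0])])
        subbands.append((lo, hi))
    (ll, lh), (hl, hh) = subbands
    total = 0.0
    for sub in (lh, hl, hh):
        total += float(((sub - sub.mean()) ** 2).sum())
    return total


SPATIAL_STATISTICAL_REFS = {
    "SMD": smd_ref,
    "Roberts": roberts_ref,
    "Tenengrad": tenengrad_ref,
    "Brenner": brenner_ref,
    "EOG": eog_ref,
    "EOL": eol_ref,
    "SML": sml_ref,
    "Variance": variance_ref,
    "Vollath": vollath_ref,
}


def brute_force_segment(values, m, criterion="rss"):
    """Exhaustive enumeration of all steep/gradual window pairs via its own
    OLS (np.polyfit), replicating the pinned selection and tie rules.

    Returns (left_steep_window, left_gradual_window, klcp,
             right_steep_window, right_gradual_window, krcp).
    """
    f = np.asarray(values, dtype=float)
    n = f.size
    kmax = int(np.argmax(f)) + 1
    tol = 1e-9

    def ols(start):
        ks = np.arange(start, start + m, dtype=float)
        coef, residuals, *_ = np.polyfit(ks, f[start - 1 : start - 1 + m], 1, full=True)
        rss = float(residuals[0]) if residuals.size else 0.0
        return float(coef[0]), float(coef[1]), rss

    def pick(cands, key, prefer):
        # prefer: callable giving tie-break priority (higher wins)
        best = None
        for s in cands:
            item = (key(s), prefer(s), s)
            if best is None or item[0] < best[0] - tol * max(1, abs(item[0]), abs(best[0])):
                best = item
            elif abs(item[0] - best[0]) <= tol * max(1, abs(item[0]), abs(best[0])):
                if item[1] > best[1]:
                    best = item
        return best[2]

    out = []
    for side in ("left", "right"):
        if side == "left":
            starts = list(range(1, kmax - m + 2))
            steep_key = lambda s: -ols(s)[0]  # maximize slope
            steep_pref = lambda s: s  # nearest the peak = largest start
            grad_pref = lambda s: -s  # farthest = smallest start
        else:
            starts = list(range(kmax, n - m + 2))
            steep_key = lambda s: ols(s)[0]  # minimize slope (max descent)
            steep_pref = lambda s: -s  # nearest the peak = smallest start
            grad_pref = lambda s: s  # farthest = largest start
        s_steep = pick(starts, steep_key, steep_pref)
        disjoint = [s for s in starts if s + m - 1 < s_steep or s > s_steep + m - 1]
        if criterion == "rss":
            grad_key = lambda s: ols(s)[2]
        else:
            grad_key = lambda s: abs(ols(s)[0])
        s_grad = pick(disjoint, grad_key, grad_pref)
        a1, b1, _ = ols(s_steep)
        a2, b2, _ = ols(s_grad)
        kcp = (b2 - b1) / (a1 - a2)
        out.append(((s_steep, s_steep + m - 1), (s_grad, s_grad + m - 1), kcp))
    (lw, lg, klcp), (rw, rg, krcp) = out
    return lw, lg, klcp, rw, rg, krcp
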