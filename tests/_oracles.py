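"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration, independently of
the library implementation it is checked against.
"""

import itertools

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

#: same near-tie tolerance as the implementation's documented tie rule
OTSU_TIE_RTOL = 1e-10


def brute_otsu_thresholds(values: np.ndarray, n_thresholds: int, bins: int):
    """Exhaustive multi-level Otsu over all increasing bin tuples.

    Histograms ``values`` into ``bins`` uniform bins on [0, max], evaluates
    the between-class variance of every increasing boundary tuple by direct
    per-class summation, and returns the lowest tuple attaining the maximum
    (near-ties within OTSU_TIE_RTOL collapse to the lowest tuple).
    """
    vmax = float(values.max())
    bw = vmax / bins
    idx = np.minimum((values / bw).astype(int), bins - 1)
    counts = np.bincount(idx, minlength=bins).astype(float)
    centers = (np.arange(bins) + 0.5) * bw
    total = counts.sum()
    mu = float((counts * centers).sum() / total)

    tuples = list(itertools.combinations(range(1, bins), n_thresholds))
    objs = np.empty(len(tuples))
    for i, t in enumerate(tuples):
        bounds = (0,) + t + (bins,)
        obj = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            w = counts[a:b].sum()
            if w <= 0:
                continue
            m = (counts[a:b] * centers[a:b]).sum() / w
            obj += (w / total) * (m - mu) ** 2
        objs[i] = obj
    best = objs.max()
    tol = OTSU_TIE_RTOL * max(1.0, abs(best))
    return tuples[int(np.flatnonzero(objs >= best - tol)[0])]


def brute_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: >= 1 six-neighbour outside (grid edge = outside)."""
    padded = np.pad(mask, 1, constant_values=False)
    out = np.zeros_like(mask)
    for axis in range(3):
        for shift in (-1, 1):
            neighbour = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            out |= mask & ~neighbour
    return out


def brute_hd95(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs boundary-distance HD95 at anisotropic spacing."""
    pa = np.argwhere(brute_boundary(a)) * np.asarray(spacing)
    pb = np.argwhere(brute_boundary(b)) * np.asarray(spacing)
    d = cdist(pa, pb)
    return float(
        max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))
    )


def enum_wilcoxon_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        w1 = sum(r for s, r in zip(signs, ranks) if s > 0)
        if min(w1, total - w1) <= w_obs:
            count += 1
    return count / 2.0**n
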