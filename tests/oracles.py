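"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
exhaustive enumeration for local alignment and 2-clustering, plain loops for
the weighted score. They are deliberately slow and simple.
"""

from functools import lru_cache

import numpy as np


def brute_local_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Best local alignment score by enumerating every substring pair and
    recursively enumerating every global alignment of that pair."""

    @lru_cache(maxsize=None)
    def glob(sa: str, sb: str) -> int:
        if not sa and not sb:
            return 0
        opts = []
        if sa and sb:
            opts.append(glob(sa[1:], sb[1:]) + (match if sa[0] == sb[0] else mismatch))
        if sa:
            opts.append(glob(sa[1:], sb) + gap)
        if sb:
            opts.append(glob(sa, sb[1:]) + gap)
        return max(opts)

    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, glob(a[i1:i2], b[j1:j2]))
    return best


def brute_score(profile, weights, feature_mode="presence") -> float:
    """Plain-loop dot product over the profile's features."""
    total = 0.0
    for cid, count in profile.hit_counts.items():
        x = count if feature_mode == "count" else (1 if count > 0 else 0)
        total += weights.weights[cid] * x
    return total


def best_bipartition_sse(values) -> float:
    """Minimum within-cluster SSE over ALL 2-partitions (not only contiguous
    ones), vectorized over the 2^n - 2 non-trivial masks."""
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    masks = np.arange(1, 2**n - 1, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(np.float64)
    k = bits.sum(axis=1)
    s1 = bits @ x
    s_tot, sq_tot = x.sum(), (x**2).sum()
    sse = sq_tot - s1**2 / k - (s_tot - s1) ** 2 / (n - k)
    return float(sse.min())


def oracle_boundary(scores: dict, positive_refs) -> str | None:
    """Boundary strain by enumerating the N-1 contiguous splits with plain
    loops. Returns None when the references are split across clusters."""
    sids = sorted(scores, key=lambda s: scores[s])
    vals = [scores[s] for s in sids]
    best_sse, best_k = None, None
    for k in range(1, len(vals)):
        lo, hi = vals[:k], vals[k:]
        m_lo, m_hi = sum(lo) / len(lo), sum(hi) / len(hi)
        sse = sum((v - m_lo) ** 2 for v in lo) + sum((v - m_hi) ** 2 for v in hi)
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    low, high = set(sids[:best_k]), set(sids[best_k:])
    if all(r in high for r in positive_refs):
        cluster = high
    elif all(r in low for r in positive_refs):
        cluster = low
    else:
        return None
    return min(cluster, key=lambda s: (scores[s], s))
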