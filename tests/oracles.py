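"""Independent brute-force oracles used by the test suite.

Each oracle evaluates the defining formula of an operation directly
(exact rational arithmetic or naive enumeration) without sharing code
with the implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter
from fractions import Fraction

import numpy as np
from scipy import stats


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by explicit sort / scale / cummin / unsort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    adj = scaled[:]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    for i in range(m):
        out[order[i]] = min(adj[i], 1.0)
    return out


def fisher_upper_tail_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact hypergeometric upper tail by enumeration over the support."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n_total, col1)
    num = sum(
        math.comb(row1, k) * math.comb(n_total - row1, col1 - k)
        for k in range(a, min(row1, col1) + 1)
    )
    return Fraction(num, denom)


def moderated_t_oracle(
    ratios: np.ndarray, d0: float, s0_sq: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior variance and moderated t via exact rational arithmetic.

    ``ratios`` is one gene's replicate vector (NaN = missing); the
    prior (d0, s0_sq) is taken as given.  Returns (t_mod, dof).
    """
    obs = [Fraction(float(x)) for x in ratios if not np.isnan(x)]
    n = len(obs)
    beta = sum(obs, Fraction(0)) / n
    s_sq = sum((x - beta) ** 2 for x in obs) / (n - 1)
    s_sq = max(s_sq, Fraction(1, 10**8))
    df = n - 1
    if math.isinf(d0):
        s_tilde = Fraction(s0_sq)
        dof = math.inf
    else:
        d0_f = Fraction(d0)
        s0_f = Fraction(s0_sq)
        s_tilde = (d0_f * s0_f + df * s_sq) / (d0_f + df)
        dof = df + d0
    t = float(beta) / math.sqrt(float(s_tilde) / n)
    return t, dof


def moderated_p_oracle(ratios: np.ndarray, d0: float, s0_sq: float) -> float:
    t, dof = moderated_t_oracle(ratios, d0, s0_sq)
    if math.isinf(dof):
        return 2.0 * stats.norm.sf(abs(t))
    return 2.0 * stats.t.sf(abs(t), dof)


def window_entropy_oracle(seq: str, halfwidth: int) -> list[float]:
    """Per-position Shannon entropy by direct window counting."""
    out = []
    for i in range(len(seq)):
        window = seq[max(0, i - halfwidth) : i + halfwidth + 1]
        counts = Counter(window)
        n = len(window)
        out.append(-sum((v / n) * math.log2(v / n) for v in counts.values()))
    return out


def kmer_count_oracle(seq: str, k: int) -> dict[str, int]:
    """Sliding-window occurrence counts, skipping X/U windows."""
    seq = seq.rstrip("*").upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "X" in w or "U" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def venn_region_oracle(sets: dict[str, set]) -> dict[tuple, int]:
    """Region counts by classifying each element of the union."""
    union = set().union(*sets.values())
    regions: dict[tuple, int] = {}
    for x in union:
        key = tuple(sorted(label for label, s in sets.items() if x in s))
        regions[key] = regions.get(key, 0) + 1
    return regions
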