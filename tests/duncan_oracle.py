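"""Independent brute-force oracle for Duncan's multiple range test.

Works straight from the definition: a pair of ordered means is
non-significant iff *some* pair of means enclosing it (including itself)
has a range at or below its span's least significant range. No stepwise
sweep, no letter machinery — just exhaustive enumeration over enclosing
pairs, so it shares nothing with the implementation under test except the
studentized-range quantile function.
"""

import itertools
from functools import lru_cache

import numpy as np
from scipy.stats import studentized_range


@lru_cache(maxsize=None)
def _q(alpha: float, span: int, df: int) -> float:
    return float(studentized_range.ppf((1 - alpha) ** (span - 1), span, df))


def brute_force_decisions(summaries, alpha=0.05, n_h_mode="pair"):
    """Pairwise significance by exhaustive enclosing-pair evaluation.

    Returns ``{(label_i, label_j): significant}`` for all unordered pairs.
    """
    summ = sorted(summaries, key=lambda s: s.mean)
    k = len(summ)
    n = np.array([s.n for s in summ], dtype=float)
    sd = np.array([s.sd for s in summ], dtype=float)
    m = np.array([s.mean for s in summ], dtype=float)
    df = int(n.sum()) - k
    mse = float(np.sum((n - 1) * sd**2) / df)

    def lsr(a, b):
        span = b - a + 1
        if n_h_mode == "pair":
            nh = 2.0 / (1.0 / n[a] + 1.0 / n[b])
        else:
            nh = k / float(np.sum(1.0 / n))
        return _q(alpha, span, df) * np.sqrt(mse / nh)

    out = {}
    for i, j in itertools.combinations(range(k), 2):
        nonsig = any(
            (m[b] - m[a]) <= lsr(a, b)
            for a in range(i + 1)
            for b in range(j, k)
        )
        out[frozenset((summ[i].label, summ[j].label))] = not nonsig
    return out
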