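"""One-way ANOVA pooling, Duncan's multiple range test with compact letter
display, two-sample t-tests, Pearson correlation and knockout effect sizes.

Every procedure runs in two interchangeable modes: *raw* (lists/arrays of
observations per group) and *summary* (printed-table ``(label, n, mean, sd)``
records), since one-way ANOVA and all range tests depend on the data only
through those summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from haplomine.genomic_io import GroupSummary

__all__ = [
    "AnovaResult",
    "DuncanOutcome",
    "as_summaries",
    "duncan_mrt",
    "pearson",
    "percent_reduction",
    "pooled_anova",
    "two_sample_t",
]


def as_summaries(groups) -> list[GroupSummary]:
    """Normalize raw-sample mappings/lists into :class:`GroupSummary` records.

    Accepts a sequence of ``GroupSummary``, a mapping ``label -> values``, or
    a sequence of ``(label, values)`` pairs. Sample SD uses ddof=1 (0.0 when
    n == 1).
    """
    if isinstance(groups, Mapping):
        groups = list(groups.items())
    out: list[GroupSummary] = []
    for g in groups:
        if isinstance(g, GroupSummary):
            out.append(g)
            continue
        label, values = g
        x = np.asarray(values, dtype=float)
        if x.ndim != 1 or len(x) == 0:
            raise ValueError(f"group {label}: need a non-empty 1-D sample")
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        out.append(GroupSummary(label=str(label), n=len(x), mean=float(np.mean(x)), sd=sd))
    return out


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with the within-group variance pooled from group SDs."""

    mse: float
    df_error: int
    f: float
    p: float
    grand_mean: float
    k: int
    n_total: int


def pooled_anova(groups) -> AnovaResult:
    """One-way ANOVA from raw samples or printed summaries.

    ``MSE = sum((n_i - 1) * s_i^2) / sum(n_i - 1)`` with
    ``df_error = N - k``; the omnibus F compares the between-group mean
    square against MSE. Summary mode uses the given means/SDs exactly, so
    raw and summary mode agree to floating-point rounding.
    """
    summ = as_summaries(groups)
    if len(summ) < 2:
        raise ValueError(f"pooled_anova needs >= 2 groups, got {len(summ)}")
    n = np.array([s.n for s in summ], dtype=float)
    m = np.array([s.mean for s in summ], dtype=float)
    sd = np.array([s.sd for s in summ], dtype=float)
    df_error = int(n.sum()) - len(summ)
    if df_error < 1:
        raise ValueError("no error degrees of freedom (sum(n_i - 1) < 1)")
    mse = float(np.sum((n - 1) * sd**2) / df_error)
    if mse == 0.0:
        raise ValueError("all within-group variances are zero")
    grand = float(np.sum(n * m) / n.sum())
    ss_between = float(np.sum(n * (m - grand) ** 2))
    df_between = len(summ) - 1
    f = (ss_between / df_between) / mse
    p = float(sps.f.sf(f, df_between, df_error))
    return AnovaResult(
        mse=mse,
        df_error=df_error,
        f=float(f),
        p=p,
        grand_mean=grand,
        k=len(summ),
        n_total=int(n.sum()),
    )


@lru_cache(maxsize=16384)
def _q_crit(alpha_p: float, span: int, df: int) -> float:
    """Upper studentized-range quantile, cached: ppf is expensive in scipy."""
    return float(sps.studentized_range.ppf(1.0 - alpha_p, span, df))


def duncan_protection_level(alpha: float, span: int) -> float:
    """Duncan's span-dependent level ``1 - (1 - alpha)**(span - 1)``."""
    return 1.0 - (1.0 - alpha) ** (span - 1)


@dataclass(frozen=True)
class DuncanOutcome:
    """Result of Duncan's multiple range test as a compact letter display.

    Groups are ordered by descending mean. Two groups sharing any letter were
    declared non-significantly different at ``alpha``; groups sharing no
    letter differ significantly. By default letters run 'a', 'b', ... from
    the *smallest* mean upward (the orientation used in agronomy tables);
    ``duncan_mrt(..., letters_ascending=False)`` flips it.
    """

    groups: tuple[GroupSummary, ...]
    letters: tuple[str, ...]
    mse: float
    df_error: int
    alpha: float
    f: float
    p: float

    def letter_of(self, label: str) -> str:
        for g, let in zip(self.groups, self.letters):
            if g.label == label:
                return let
        raise KeyError(label)

    def share_letter(self, label_a: str, label_b: str) -> bool:
        return bool(set(self.letter_of(label_a)) & set(self.letter_of(label_b)))

    def any_disjoint_pair(self) -> bool:
        """True iff some pair of groups shares no letter (a significant pair)."""
        return any(
            not (set(a) & set(b)) for a, b in itertools.combinations(self.letters, 2)
        )

    def as_rows(self) -> list[dict]:
        return [
            {"label": g.label, "n": g.n, "mean": g.mean, "sd": g.sd, "letter": let}
            for g, let in zip(self.groups, self.letters)
        ]


def _least_significant_range(
    mse: float,
    df: int,
    alpha: float,
    span: int,
    n_lo: float,
    n_hi: float,
    harmonic_all: float | None,
) -> float:
    """Duncan-Kramer least significant range for a pair spanning ``span`` means."""
    nh = harmonic_all if harmonic_all is not None else 2.0 / (1.0 / n_lo + 1.0 / n_hi)
    q = _q_crit(duncan_protection_level(alpha, span), span, df)
    return q * math.sqrt(mse / nh)


def _significance_matrix(
    means: np.ndarray,
    ns: np.ndarray,
    mse: float,
    df: int,
    alpha: float,
    n_h_mode: str,
) -> np.ndarray:
    """Stepwise-protected pairwise decisions on means sorted ascending.

    Classic range-test sweep: spans are visited widest-first; a pair falling
    inside an interval already declared non-significant is non-significant
    without testing, otherwise its range is compared to R_span.
    """
    k = len(means)
    harmonic_all = (
        k / float(np.sum(1.0 / ns)) if n_h_mode == "all" else None
    )
    ns_mat = np.zeros((k, k), dtype=bool)  # ns_mat[i, j]: i..j declared non-sig
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            covered = any(
                ns_mat[a, b] for a in range(i + 1) for b in range(j, k) if (a, b) != (i, j)
            )
            if covered:
                ns_mat[i, j] = True
                continue
            r = _least_significant_range(
                mse, df, alpha, span, float(ns[i]), float(ns[j]), harmonic_all
            )
            ns_mat[i, j] = (means[j] - means[i]) <= r
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            sig[i, j] = sig[j, i] = not ns_mat[i, j]
    return sig


def _insert_absorb_letters(k: int, sig: np.ndarray) -> list[str]:
    """Compact letter display by insert-and-absorb over indices 0..k-1.

    Returns one letter-string per index; index order determines which group
    gets the earlier letter.
    """
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.append(col - {i})
                columns.append(col - {j})
            # absorb: drop columns that are subsets of another
            columns = [
                c
                for idx, c in enumerate(columns)
                if c and not any(c < d or (c == d and idx2 < idx)
                                 for idx2, d in enumerate(columns) if idx2 != idx)
            ]
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter, col in zip(itertools.chain(alphabet, itertools.count()), columns):
        if not isinstance(letter, str):
            raise ValueError("more letter groups than the alphabet supports")
        for i in col:
            letters[i] += letter
    return letters


def duncan_mrt(
    groups,
    alpha: float = 0.05,
    n_h_mode: str = "pair",
    letters_ascending: bool = True,
) -> DuncanOutcome:
    """Duncan's multiple range test with a compact letter display.

    For a pair of means spanning ``p`` ordered positions, the least
    significant range is ``R_p = q(1 - (1-alpha)**(p-1); p, df_error) *
    sqrt(MSE / n_h)`` where ``q`` is the upper studentized-range quantile
    and ``n_h`` the harmonic mean of the two compared group sizes
    (``n_h_mode="pair"``, the Kramer extension) or of all group sizes
    (``n_h_mode="all"``). Stepwise protection: a pair inside a span already
    declared non-significant is never called significant.

    ``letters_ascending=True`` (default) gives the smallest mean the letter
    'a', matching the usual agronomy-table orientation; groups in the result
    are nevertheless ordered by descending mean.
    """
    if n_h_mode not in ("pair", "all"):
        raise ValueError(f"unknown n_h_mode {n_h_mode!r}")
    summ = as_summaries(groups)
    if len(summ) == 0:
        raise ValueError("duncan_mrt needs >= 1 group")
    if len(summ) == 1:
        g = summ[0]
        return DuncanOutcome(
            groups=(g,),
            letters=("a",),
            mse=float("nan"),
            df_error=max(g.n - 1, 0),
            alpha=alpha,
            f=float("nan"),
            p=float("nan"),
        )
    anova = pooled_anova(summ)
    asc = sorted(range(len(summ)), key=lambda i: (summ[i].mean, i))
    means = np.array([summ[i].mean for i in asc])
    ns = np.array([summ[i].n for i in asc], dtype=float)
    sig = _significance_matrix(means, ns, anova.mse, anova.df_error, alpha, n_h_mode)
    if letters_ascending:
        letters_sorted = _insert_absorb_letters(len(summ), sig)
    else:
        rev = sig[::-1, ::-1]
        letters_sorted = _insert_absorb_letters(len(summ), rev)[::-1]
    # re-order result groups by descending mean
    desc = asc[::-1]
    letters_desc = letters_sorted[::-1]
    return DuncanOutcome(
        groups=tuple(summ[i] for i in desc),
        letters=tuple(letters_desc),
        mse=anova.mse,
        df_error=anova.df_error,
        alpha=alpha,
        f=anova.f,
        p=anova.p,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mode: str


def two_sample_t(s1, s2, mode: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test from group summaries (or raw samples).

    ``mode="welch"`` (default) uses the Welch-Satterthwaite df; ``"pooled"``
    assumes equal variances. Degenerate zero-variance input: equal means
    give ``p = 1`` by convention, unequal means give ``p = 0``.
    """
    if mode not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test mode {mode!r}")
    def _one(s, default_label):
        if isinstance(s, GroupSummary):
            return s
        if isinstance(s, tuple) and len(s) == 2 and isinstance(s[0], str):
            return as_summaries([s])[0]
        return as_summaries([(default_label, s)])[0]

    a, b = _one(s1, "a"), _one(s2, "b")
    if a.n < 2 or b.n < 2:
        raise ValueError("two_sample_t needs n >= 2 in each group")
    va, vb = a.sd**2, b.sd**2
    if va == 0.0 and vb == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0, mode=mode)
        return TTestResult(t=math.inf if a.mean > b.mean else -math.inf,
                           df=float(a.n + b.n - 2), p=0.0, mode=mode)
    if mode == "pooled":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        wa, wb = va / a.n, vb / b.n
        se = math.sqrt(wa + wb)
        df = (wa + wb) ** 2 / (wa**2 / (a.n - 1) + wb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, mode=mode)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def pearson(x, y) -> PearsonResult:
    """Pearson correlation over pairwise-complete observations.

    NaNs are treated as missing; a constant vector yields the undefined
    result ``(nan, nan)``. The two-sided p-value comes from the exact t
    transform (scipy's pearsonr).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"pearson needs >= 3 pairwise-complete pairs, got {n}")
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return PearsonResult(r=float("nan"), p=float("nan"), n=n)
    res = sps.pearsonr(xs, ys)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def percent_reduction(wt_mean: float, ko_means: Sequence[float]) -> float:
    """Mean per-line percent reduction ``100 * (wt - ko) / wt`` across KO lines.

    Per-line reductions are averaged (pooling the KO means first gives a
    different, not-reported number).
    """
    if wt_mean <= 0:
        raise ValueError("wild-type mean must be positive")
    ko = np.asarray(list(ko_means), dtype=float)
    if ko.size == 0:
        raise ValueError("need at least one knockout mean")
    return float(np.mean(100.0 * (wt_mean - ko) / wt_mean))
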