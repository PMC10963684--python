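"""Pairwise linkage disequilibrium and peak-anchored block delimitation.

LD is the squared Pearson correlation of allele codes across inbred
accessions, which on haploid-equivalent genotypes equals haplotype r².
Multiallelic sites are reduced to ref-vs-any-alt before computing r².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from haplomine.genomic_io import MISSING, GeneModel, VariantRecord

__all__ = ["LDMatrix", "ld_block", "ld_matrix", "r_squared", "region_report"]


def _binarize(g) -> np.ndarray:
    """Collapse allele codes to 0 (ref) / 1 (any alt) / NaN (missing)."""
    g = np.asarray(g, dtype=float)
    out = np.where(g == MISSING, np.nan, np.minimum(g, 1.0))
    out[~np.isfinite(g)] = np.nan
    return out


def r_squared(g_a, g_b) -> float:
    """Squared Pearson correlation of two genotype vectors.

    Computed over pairwise-complete accessions after ref-vs-alt collapsing.
    Returns NaN (undefined, *not* zero) when either vector is monomorphic
    over the complete pairs or fewer than two complete pairs exist.
    """
    a, b = _binarize(g_a), _binarize(g_b)
    if a.shape != b.shape:
        raise ValueError(f"genotype vectors differ in length: {a.shape} vs {b.shape}")
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        return float("nan")
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class LDMatrix:
    """Symmetric pairwise r² over ordered site positions (NaN = undefined)."""

    positions: tuple[int, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        if r2.shape != (len(self.positions), len(self.positions)):
            raise ValueError("r2 must be square over positions")
        object.__setattr__(self, "r2", r2)

    def index_of(self, pos: int) -> int:
        try:
            return self.positions.index(pos)
        except ValueError:
            raise KeyError(f"position {pos} not in LD matrix") from None


def ld_matrix(variants: Sequence[VariantRecord]) -> LDMatrix:
    """All-pairs r² for a list of variant records (sorted by position)."""
    recs = sorted(variants, key=lambda v: v.pos)
    k = len(recs)
    mat = np.full((k, k), np.nan)
    genos = [_binarize(v.genotypes) for v in recs]
    for i in range(k):
        mono = np.ptp(genos[i][np.isfinite(genos[i])]) == 0.0 if np.isfinite(genos[i]).any() else True
        mat[i, i] = np.nan if mono else 1.0
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = r_squared(genos[i], genos[j])
    return LDMatrix(positions=tuple(v.pos for v in recs), r2=mat)


def ld_block(ld: LDMatrix, peak: int, r2_min: float = 0.6) -> tuple[int, int]:
    """Maximal contiguous run of sites around ``peak`` with r² >= ``r2_min``.

    Every site in the returned run has r² to the peak at or above the
    threshold; the run always contains the peak. Returns the genomic
    interval (1-based, inclusive) spanned by the run's outermost sites.
    """
    pk = ld.index_of(peak)
    row = ld.r2[pk]
    if not np.isfinite(row[pk]):
        raise ValueError(f"peak site {peak} is monomorphic; LD to it is undefined")
    lo = pk
    while lo > 0 and np.isfinite(row[lo - 1]) and row[lo - 1] >= r2_min:
        lo -= 1
    hi = pk
    while hi < len(row) - 1 and np.isfinite(row[hi + 1]) and row[hi + 1] >= r2_min:
        hi += 1
    return (ld.positions[lo], ld.positions[hi])


@dataclass(frozen=True)
class RegionReport:
    interval: tuple[int, int]
    span_kb: float
    genes: tuple[GeneModel, ...]


def region_report(interval: tuple[int, int], genes: Sequence[GeneModel]) -> RegionReport:
    """Span (kb) of an inclusive interval plus the genes overlapping it by >= 1 bp."""
    lo, hi = interval
    overlapping = tuple(
        g for g in sorted(genes, key=lambda g: (g.chrom, g.start))
        if g.start <= hi and g.end >= lo
    )
    return RegionReport(
        interval=(lo, hi),
        span_kb=(hi - lo + 1) / 1000.0,
        genes=overlapping,
    )
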