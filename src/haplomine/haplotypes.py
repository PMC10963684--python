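"""Per-gene haplotype enumeration over promoter + CDS variants.

A gene-based haplotype is the joint allele signature an accession carries
across the gene's selected variant sites. Accessions missing a call at any
selected site are left unassigned rather than imputed. Haplotype ids are
frequency-ranked ("Hap1" = most common), with ties broken by first
occurrence in panel order; optionally the all-reference signature can be
pinned to a fixed label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from haplomine.genomic_io import MISSING, GeneModel, VariantRecord, promoter_interval

__all__ = [
    "GeneHaplotypes",
    "collect_gene_variants",
    "enumerate_haplotypes",
    "major_haplotypes",
]


def collect_gene_variants(
    variants: Sequence[VariantRecord],
    gene: GeneModel,
    regions: Iterable[str] = ("promoter", "cds"),
    promoter_len: int = 1000,
) -> list[VariantRecord]:
    """Select the variant sites of a gene, ordered by position.

    ``regions`` is any subset of {"promoter", "cds", "gene"}; the default
    promoter + CDS matches how candidate haplotypes are usually defined,
    while "gene" enables whole-gene-span mode. Intron-only variants are
    excluded under the default region set.
    """
    regions = {r.lower() for r in regions}
    unknown = regions - {"promoter", "cds", "gene"}
    if unknown:
        raise ValueError(f"unknown region selector(s): {sorted(unknown)}")
    intervals: list[tuple[int, int]] = []
    if "promoter" in regions:
        intervals.append(promoter_interval(gene, promoter_len))
    if "cds" in regions:
        intervals.extend(gene.cds_intervals)
    if "gene" in regions:
        intervals.append((gene.start, gene.end))
    picked = [
        v
        for v in variants
        if v.chrom == gene.chrom and any(lo <= v.pos <= hi for lo, hi in intervals)
    ]
    picked.sort(key=lambda v: v.pos)
    return picked


@dataclass
class GeneHaplotypes:
    """Haplotype assignment of a panel at one gene.

    ``signatures`` maps haplotype id -> allele-code tuple over ``sites``;
    ``assignments`` maps accession -> haplotype id (or None when any site is
    missing); ``counts`` is ordered by descending frequency, matching id
    rank. ``sum(counts) + unassigned == panel size`` always holds.
    """

    gene_id: str
    sites: tuple[VariantRecord, ...]
    accessions: tuple[str, ...]
    assignments: dict[str, str | None]
    signatures: dict[str, tuple[int, ...]]
    counts: dict[str, int]
    min_count: int | None = None  # set when filtered by major_haplotypes

    @property
    def unassigned(self) -> list[str]:
        return [a for a in self.accessions if self.assignments[a] is None]

    @property
    def n_haplotypes(self) -> int:
        return len(self.signatures)

    def accessions_of(self, hap_id: str) -> list[str]:
        return [a for a in self.accessions if self.assignments[a] == hap_id]

    def validate(self) -> None:
        sigs = list(self.signatures.values())
        if len(set(sigs)) != len(sigs):
            raise ValueError(f"{self.gene_id}: duplicate haplotype signatures")
        if sum(self.counts.values()) + len(self.unassigned) != len(self.accessions):
            raise ValueError(f"{self.gene_id}: counts + unassigned != panel size")


def enumerate_haplotypes(
    sites: Sequence[VariantRecord],
    accessions: Sequence[str],
    gene_id: str = "",
    reference_label: str | None = None,
) -> GeneHaplotypes:
    """Group accessions by their joint allele signature across ``sites``.

    Accessions with a complete (non-missing) code at every site receive the
    signature of their allele tuple; any missing code leaves the accession
    unassigned. Ids "Hap1", "Hap2", ... are assigned in descending-count
    order (ties by first occurrence in panel order). When
    ``reference_label`` is given and the all-reference signature is present
    in the panel, that signature is pinned to the requested label and the
    remaining ids fill the frequency ranks around it.
    """
    if len(sites) == 0:
        raise ValueError("enumerate_haplotypes requires at least one site")
    accessions = tuple(accessions)
    codes = np.stack([np.asarray(s.genotypes, dtype=np.int16) for s in sites], axis=1)
    if codes.shape[0] != len(accessions):
        raise ValueError(
            f"{len(accessions)} accessions but genotype vectors of length {codes.shape[0]}"
        )
    complete = ~(codes == MISSING).any(axis=1)
    sig_first: dict[tuple[int, ...], int] = {}
    sig_count: dict[tuple[int, ...], int] = {}
    sig_of_acc: list[tuple[int, ...] | None] = []
    for i in range(len(accessions)):
        if not complete[i]:
            sig_of_acc.append(None)
            continue
        sig = tuple(int(c) for c in codes[i])
        sig_of_acc.append(sig)
        sig_count[sig] = sig_count.get(sig, 0) + 1
        sig_first.setdefault(sig, i)
    ranked = sorted(sig_count, key=lambda s: (-sig_count[s], sig_first[s]))
    labels = [f"Hap{r + 1}" for r in range(len(ranked))]
    ref_sig = tuple(0 for _ in sites)
    if reference_label is not None and ref_sig in sig_count and reference_label in labels:
        # pin the reference signature to the requested rank label
        others = [s for s in ranked if s != ref_sig]
        id_of: dict[tuple[int, ...], str] = {ref_sig: reference_label}
        for lab in labels:
            if lab == reference_label:
                continue
            id_of[others.pop(0)] = lab
    else:
        id_of = dict(zip(ranked, labels))
    assignments = {
        acc: (id_of[sig] if sig is not None else None)
        for acc, sig in zip(accessions, sig_of_acc)
    }
    # counts/signatures in frequency-rank order of the underlying signature
    by_rank = sorted(id_of.items(), key=lambda kv: ranked.index(kv[0]))
    gh = GeneHaplotypes(
        gene_id=gene_id,
        sites=tuple(sites),
        accessions=accessions,
        assignments=assignments,
        signatures={lab: sig for sig, lab in by_rank},
        counts={lab: sig_count[sig] for sig, lab in by_rank},
    )
    gh.validate()
    return gh


def major_haplotypes(gh: GeneHaplotypes, min_count: int = 11) -> GeneHaplotypes:
    """Restrict to haplotypes carried by at least ``min_count`` accessions.

    The default 11 reads a "more than 10 accessions" rule strictly.
    Accessions of dropped haplotypes become unassigned; ids keep their
    original (unfiltered) frequency ranks.
    """
    keep = {h for h, c in gh.counts.items() if c >= min_count}
    assignments = {
        a: (h if h in keep else None) for a, h in gh.assignments.items()
    }
    out = GeneHaplotypes(
        gene_id=gh.gene_id,
        sites=gh.sites,
        accessions=gh.accessions,
        assignments=assignments,
        signatures={h: s for h, s in gh.signatures.items() if h in keep},
        counts={h: c for h, c in gh.counts.items() if h in keep},
        min_count=min_count,
    )
    out.validate()
    return out


def haplotype_report_rows(gh: GeneHaplotypes) -> list[dict]:
    """Flatten a GeneHaplotypes into TSV-ready rows."""
    return [
        {
            "gene_id": gh.gene_id,
            "hap_id": h,
            "count": gh.counts[h],
            "signature": "/".join(str(c) for c in gh.signatures[h]),
            "accessions": ",".join(gh.accessions_of(h)),
        }
        for h in gh.counts
    ]
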