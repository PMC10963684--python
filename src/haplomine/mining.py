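"""Region-wide candidate-gene mining.

For every gene in a region: select promoter + CDS variants, enumerate
haplotypes, keep the major ones, and test phenotype differences among them
in each environment. A gene is a candidate iff the differences are
significant in *every* environment, where per-environment significance is
an omnibus ANOVA p < alpha together with at least one pair of haplotypes
sharing no Duncan letter (the omnibus guard protects against letter
artifacts on tiny groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from haplomine.genomic_io import GeneModel, PhenotypeTable, VariantRecord
from haplomine.haplotypes import (
    GeneHaplotypes,
    collect_gene_variants,
    enumerate_haplotypes,
    major_haplotypes,
)
from haplomine.stats import DuncanOutcome, duncan_mrt, pooled_anova

logger = logging.getLogger(__name__)

__all__ = ["CandidateReport", "EnvironmentResult", "mine_candidates", "test_gene"]


@dataclass(frozen=True)
class EnvironmentResult:
    """Haplotype-vs-phenotype test of one gene in one environment."""

    gene_id: str
    environment: str
    n_haplotypes: int
    omnibus_p: float
    duncan: DuncanOutcome | None
    significant: bool
    untestable: bool = False
    reason: str = ""


def test_gene(
    gh: GeneHaplotypes,
    phen: PhenotypeTable,
    trait: str,
    environment: str,
    alpha: float = 0.05,
    n_h_mode: str = "pair",
) -> EnvironmentResult:
    """Test one gene's (major) haplotypes against a trait in one environment.

    Groups are the accessions of each haplotype that have a phenotype value
    for (trait, environment); accessions lacking a value are dropped from
    this environment only. Fewer than two populated haplotype groups (or no
    within-group variability) flags the result untestable rather than
    raising.
    """
    values = phen.values_for(trait, environment)
    groups = []
    for hap in gh.counts:
        obs = [values[a] for a in gh.accessions_of(hap) if a in values]
        if obs:
            groups.append((hap, obs))
    if len(groups) < 2:
        return EnvironmentResult(
            gene_id=gh.gene_id,
            environment=environment,
            n_haplotypes=len(groups),
            omnibus_p=float("nan"),
            duncan=None,
            significant=False,
            untestable=True,
            reason=f"{len(groups)} testable haplotype group(s); need >= 2",
        )
    try:
        anova = pooled_anova(groups)
        duncan = duncan_mrt(groups, alpha=alpha, n_h_mode=n_h_mode)
    except ValueError as exc:
        return EnvironmentResult(
            gene_id=gh.gene_id,
            environment=environment,
            n_haplotypes=len(groups),
            omnibus_p=float("nan"),
            duncan=None,
            significant=False,
            untestable=True,
            reason=str(exc),
        )
    significant = (anova.p < alpha) and duncan.any_disjoint_pair()
    return EnvironmentResult(
        gene_id=gh.gene_id,
        environment=environment,
        n_haplotypes=len(groups),
        omnibus_p=anova.p,
        duncan=duncan,
        significant=significant,
    )


@dataclass(frozen=True)
class CandidateReport:
    """All-environment decision for one gene."""

    gene_id: str
    results: tuple[EnvironmentResult, ...]
    is_candidate: bool
    reason: str

    @property
    def min_p(self) -> float:
        ps = [r.omnibus_p for r in self.results if not r.untestable]
        return min(ps) if ps else float("inf")


def mine_candidates(
    genes: Sequence[GeneModel],
    variants: Sequence[VariantRecord],
    accessions: Sequence[str],
    phen: PhenotypeTable,
    trait: str,
    environments: Iterable[str],
    alpha: float = 0.05,
    min_count: int = 11,
    regions: Iterable[str] = ("promoter", "cds"),
    promoter_len: int = 1000,
    bonferroni: bool = False,
) -> list[CandidateReport]:
    """Scan genes and call candidates significant in every environment.

    ``bonferroni=True`` divides alpha by the number of genes actually tested
    (off by default: the mining procedure this mirrors applies none).
    Reports are sorted by minimum omnibus p across environments; genes with
    no variant sites or fewer than two major haplotypes are reported as
    untestable, never silently skipped.
    """
    environments = list(environments)
    if not environments:
        raise ValueError("mine_candidates requires at least one environment")
    eff_alpha = alpha / max(len(genes), 1) if bonferroni else alpha
    reports: list[CandidateReport] = []
    for gene in genes:
        sites = collect_gene_variants(variants, gene, regions=regions, promoter_len=promoter_len)
        if not sites:
            results = tuple(
                EnvironmentResult(
                    gene_id=gene.gene_id,
                    environment=env,
                    n_haplotypes=0,
                    omnibus_p=float("nan"),
                    duncan=None,
                    significant=False,
                    untestable=True,
                    reason="no variant sites in the selected regions",
                )
                for env in environments
            )
            reports.append(
                CandidateReport(gene.gene_id, results, False, "no variant sites")
            )
            continue
        gh = major_haplotypes(
            enumerate_haplotypes(sites, accessions, gene_id=gene.gene_id),
            min_count=min_count,
        )
        logger.debug(
            "%s: %d sites, %d major haplotypes (of %d accessions)",
            gene.gene_id, len(sites), gh.n_haplotypes, len(accessions),
        )
        results = tuple(
            test_gene(gh, phen, trait, env, alpha=eff_alpha) for env in environments
        )
        if any(r.untestable for r in results):
            is_candidate = False
            reason = "untestable in at least one environment"
        elif all(r.significant for r in results):
            is_candidate = True
            reason = f"significant in all {len(environments)} environments"
        else:
            is_candidate = False
            n_sig = sum(r.significant for r in results)
            reason = f"significant in {n_sig}/{len(environments)} environments"
        reports.append(CandidateReport(gene.gene_id, results, is_candidate, reason))
    reports.sort(key=lambda r: (r.min_p, r.gene_id))
    return reports
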