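"""Two-gene haplotype-combination (pyramiding) analysis and dominance screen.

Accessions assigned at both genes are grouped into realized haplotype
combinations; Duncan letters across the combinations, read within and
across strata of each gene, yield a statistical dominance verdict: gene A
"dominates" when varying A moves the phenotype while varying B within any
fixed A stratum does not.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

from haplomine.genomic_io import PhenotypeTable
from haplomine.haplotypes import GeneHaplotypes
from haplomine.stats import DuncanOutcome, duncan_mrt

logger = logging.getLogger(__name__)

__all__ = ["ComboGroup", "ColumnVerdict", "DominanceReport", "combine_haplotypes", "dominance_screen"]

A_DOMINANT = "A-dominant"
B_DOMINANT = "B-dominant"
ADDITIVE = "additive"
NONE = "none"


@dataclass(frozen=True)
class ComboGroup:
    """One realized haplotype combination (hap at gene A, hap at gene B)."""

    hap_a: str
    hap_b: str
    accessions: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.hap_a}+{self.hap_b}"

    @property
    def n(self) -> int:
        return len(self.accessions)


def combine_haplotypes(
    gh_a: GeneHaplotypes,
    gh_b: GeneHaplotypes,
    min_count: int = 5,
) -> list[ComboGroup]:
    """Realized haplotype combinations over accessions assigned at both genes.

    Combinations with fewer than ``min_count`` members are dropped (the
    floor guards against degenerate one-member Duncan groups; there is no
    implicit major-haplotype-style cutoff here). Ordered by (hap_a, hap_b).
    """
    if set(gh_a.accessions) != set(gh_b.accessions):
        common = set(gh_a.accessions) & set(gh_b.accessions)
        if not common:
            logger.warning(
                "%s and %s share no accessions; no combinations possible",
                gh_a.gene_id, gh_b.gene_id,
            )
            return []
    cells: dict[tuple[str, str], list[str]] = {}
    for acc in gh_a.accessions:
        ha = gh_a.assignments.get(acc)
        hb = gh_b.assignments.get(acc)
        if ha is None or hb is None:
            continue
        cells.setdefault((ha, hb), []).append(acc)
    combos = [
        ComboGroup(hap_a=ha, hap_b=hb, accessions=tuple(accs))
        for (ha, hb), accs in cells.items()
        if len(accs) >= min_count
    ]
    combos.sort(key=lambda c: (c.hap_a, c.hap_b))
    return combos


@dataclass(frozen=True)
class ColumnVerdict:
    """Dominance evidence for one (trait, environment) column."""

    trait: str
    environment: str
    duncan: DuncanOutcome
    a_effect: bool  # some pair differing at gene A is significant
    b_effect: bool  # some pair differing at gene B is significant
    b_within_a: bool  # significant B contrast inside a fixed-A stratum
    a_within_b: bool  # significant A contrast inside a fixed-B stratum
    verdict: str


@dataclass(frozen=True)
class DominanceReport:
    columns: tuple[ColumnVerdict, ...]
    verdict: str


def _column_verdict(
    combos: Sequence[ComboGroup],
    duncan: DuncanOutcome,
    trait: str,
    environment: str,
) -> ColumnVerdict:
    sig = lambda x, y: not duncan.share_letter(x.label, y.label)
    a_effect = b_effect = b_within_a = a_within_b = False
    for x, y in itertools.combinations(combos, 2):
        if not sig(x, y):
            continue
        if x.hap_a != y.hap_a:
            a_effect = True
            if x.hap_b == y.hap_b:
                a_within_b = True
        if x.hap_b != y.hap_b:
            b_effect = True
            if x.hap_a == y.hap_a:
                b_within_a = True
    # attribution uses within-stratum contrasts (same hap at the other gene),
    # which keeps the verdict exactly symmetric under relabeling A <-> B
    if a_within_b and not b_within_a:
        verdict = A_DOMINANT
    elif b_within_a and not a_within_b:
        verdict = B_DOMINANT
    elif a_within_b and b_within_a:
        verdict = ADDITIVE
    else:
        verdict = NONE
    return ColumnVerdict(
        trait=trait,
        environment=environment,
        duncan=duncan,
        a_effect=a_effect,
        b_effect=b_effect,
        b_within_a=b_within_a,
        a_within_b=a_within_b,
        verdict=verdict,
    )


def dominance_screen(
    combos: Sequence[ComboGroup],
    phen: PhenotypeTable,
    columns: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    n_h_mode: str = "pair",
) -> DominanceReport:
    """Duncan letters across combinations, per (trait, environment) column.

    The overall verdict is the per-column verdict when all columns agree,
    "additive" when columns disagree only between a dominant call and
    additive, and "none" for fully inconsistent columns — dominance has to
    hold jointly across every column supplied.
    """
    if len(combos) < 2:
        raise ValueError("dominance_screen needs >= 2 combination groups")
    if not columns:
        raise ValueError("dominance_screen needs >= 1 (trait, environment) column")
    col_results: list[ColumnVerdict] = []
    for trait, env in columns:
        values = phen.values_for(trait, env)
        groups = []
        for combo in combos:
            obs = [values[a] for a in combo.accessions if a in values]
            if obs:
                groups.append((combo.label, obs))
        if len(groups) < 2:
            raise ValueError(f"no testable combination groups for {trait}/{env}")
        duncan = duncan_mrt(groups, alpha=alpha, n_h_mode=n_h_mode)
        present = {g[0] for g in groups}
        col_results.append(
            _column_verdict(
                [c for c in combos if c.label in present], duncan, trait, env
            )
        )
    # columns with no signal at all do not veto a dominance call; any pair of
    # columns pointing in different directions demotes the verdict to additive
    informative = {c.verdict for c in col_results} - {NONE}
    if not informative:
        overall = NONE
    elif len(informative) == 1:
        overall = informative.pop()
    else:
        overall = ADDITIVE
    return DominanceReport(columns=tuple(col_results), verdict=overall)


def transpose_combos(combos: Sequence[ComboGroup]) -> list[ComboGroup]:
    """Swap the roles of gene A and gene B (for symmetry checks)."""
    out = [ComboGroup(hap_a=c.hap_b, hap_b=c.hap_a, accessions=c.accessions) for c in combos]
    out.sort(key=lambda c: (c.hap_a, c.hap_b))
    return out
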