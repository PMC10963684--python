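"""Synthetic genotype-phenotype panels with planted haplotype effects.

The generator plants haplotype *labels* per accession and derives every
variant site of a gene from the label, so within-gene LD is total and the
haplotype is the causal unit. Phenotypes are
``grand mean + haplotype effect + environment offset + Normal(0, residual_sd)``;
a second trait shares the same haplotype effect scaled per trait, which
induces a positive genetic correlation between the two.

Random streams: genotype assignment (one child stream per gene) and
phenotype noise are drawn from separate children of one master seed, so
adding genes or traits never perturbs the other draws.
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from haplomine.genomic_io import (
    GeneModel,
    PhenotypeTable,
    VariantPanel,
    VariantRecord,
    classify_variant,
    promoter_interval,
    write_gff3,
    write_phenotypes,
    write_vcf,
)

__all__ = [
    "GeneSpec",
    "SimConfig",
    "SimulatedPanel",
    "default_config",
    "load_config",
    "make_null_gene",
    "simulate_panel",
    "write_fixtures",
]


@dataclass(frozen=True)
class GeneSpec:
    """Blueprint for one simulated gene and its haplotype architecture.

    ``hap_freqs`` must sum to 1; ``effects`` (cm, one per haplotype) shift
    the base trait and are scaled into the second trait. All-zero effects
    make a null gene. The first haplotype carries the all-reference
    signature.
    """

    gene_id: str
    chrom: str = "chr1"
    start: int = 10_000
    end: int = 14_000
    strand: str = "+"
    n_promoter_snps: int = 4
    n_promoter_indels: int = 0
    n_cds_snps: int = 2
    include_pav: bool = False
    hap_freqs: tuple[float, ...] = (0.6, 0.4)
    effects: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.hap_freqs) != len(self.effects):
            raise ValueError(f"{self.gene_id}: hap_freqs and effects lengths differ")
        if len(self.hap_freqs) < 1:
            raise ValueError(f"{self.gene_id}: need at least one haplotype")
        if any(f <= 0 for f in self.hap_freqs) or abs(sum(self.hap_freqs) - 1.0) > 1e-9:
            raise ValueError(
                f"{self.gene_id}: haplotype frequencies must be positive and sum to 1"
            )
        if self.n_sites < self.n_signature_bits:
            raise ValueError(
                f"{self.gene_id}: {self.n_sites} sites cannot encode "
                f"{len(self.hap_freqs)} distinct haplotypes"
            )

    @property
    def n_sites(self) -> int:
        return (
            self.n_promoter_snps
            + self.n_promoter_indels
            + self.n_cds_snps
            + (1 if self.include_pav else 0)
        )

    @property
    def n_signature_bits(self) -> int:
        return max(1, int(np.ceil(np.log2(len(self.hap_freqs))))) if len(self.hap_freqs) > 1 else 1

    def gene_model(self) -> GeneModel:
        span = self.end - self.start + 1
        # two exons: first ~40% and last ~40% of the span
        exon1 = (self.start, self.start + max(span * 2 // 5, 1))
        exon2 = (self.end - max(span * 2 // 5, 1), self.end)
        return GeneModel(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            start=self.start,
            end=self.end,
            cds_intervals=(exon1, exon2),
        )


# ~400 bp presence/absence deletion, echoing a frameshifting CDS structural variant
PAV_DELETION_LEN = 400

_BASES = np.array(list("ACGT"))


def _signature_matrix(n_haps: int, n_sites: int) -> np.ndarray:
    """Distinct 0/1 signatures, one row per haplotype; row 0 is all-reference."""
    bits = max(1, int(np.ceil(np.log2(n_haps)))) if n_haps > 1 else 1
    sig = np.zeros((n_haps, n_sites), dtype=np.int16)
    for h in range(n_haps):
        for j in range(n_sites):
            sig[h, j] = (h >> (j % bits)) & 1
    return sig


def _spread_positions(lo: int, hi: int, n: int) -> list[int]:
    if n == 0:
        return []
    return sorted({int(p) for p in np.linspace(lo, hi, num=n)})


def _gene_site_plan(spec: GeneSpec, model: GeneModel) -> list[tuple[int, str]]:
    """(position, kind) for every site of the gene; kinds: snp/indel/pav."""
    plo, phi = promoter_interval(model, 1000)
    n_prom = spec.n_promoter_snps + spec.n_promoter_indels
    prom_pos = _spread_positions(plo, phi - 10, n_prom)
    while len(prom_pos) < n_prom:  # linspace collisions on tiny promoters
        prom_pos.append(prom_pos[-1] + 1 if prom_pos else plo)
    plan = [(p, "snp") for p in prom_pos[: spec.n_promoter_snps]]
    plan += [(p, "indel") for p in prom_pos[spec.n_promoter_snps:]]
    cds1 = model.cds_intervals[0]
    n_cds = spec.n_cds_snps
    cds_pos = _spread_positions(cds1[0] + 1, cds1[1] - PAV_DELETION_LEN - 5, n_cds)
    while len(cds_pos) < n_cds:
        cds_pos.append((cds_pos[-1] if cds_pos else cds1[0]) + 1)
    plan += [(p, "snp") for p in cds_pos]
    if spec.include_pav:
        plan.append((cds1[1] - PAV_DELETION_LEN - 2, "pav"))
    plan.sort(key=lambda t: t[0])
    return plan


def _make_alleles(kind: str, rng: np.random.Generator) -> tuple[str, str]:
    if kind == "snp":
        ref, alt = rng.choice(4, size=2, replace=False)
        return str(_BASES[ref]), str(_BASES[alt])
    if kind == "indel":
        ins = "".join(rng.choice(_BASES, size=3))
        anchor = str(rng.choice(_BASES))
        return anchor + ins, anchor  # 3 bp deletion (<= 50 bp, an INDEL)
    if kind == "pav":
        anchor = str(rng.choice(_BASES))
        deleted = "".join(rng.choice(_BASES, size=PAV_DELETION_LEN))
        return anchor + deleted, anchor  # > 50 bp: a presence/absence variant
    raise ValueError(kind)


def _gene_variants(
    spec: GeneSpec,
    model: GeneModel,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    sig = _signature_matrix(len(spec.hap_freqs), spec.n_sites)
    plan = _gene_site_plan(spec, model)
    assert len(plan) == spec.n_sites
    records = []
    for j, (pos, kind) in enumerate(plan):
        ref, alt = _make_alleles(kind, rng)
        codes = sig[labels, j]
        records.append(
            VariantRecord(
                chrom=spec.chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                variant_class=classify_variant(ref, (alt,)),
                genotypes=codes,
            )
        )
    return records


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated panel; a fixed seed gives
    byte-identical fixture files."""

    genes: tuple[GeneSpec, ...]
    n_accessions: int = 343
    environments: tuple[tuple[str, float], ...] = (("GST", 10.0), ("GSF", 4.0), ("DST", 0.0))
    ph_locations: tuple[tuple[str, float], ...] = (("Guangzhou", 0.0), ("Yangjiang", 3.0))
    base_trait: str = "SL"
    second_trait: str = "PH"
    grand_mean: float = 120.0
    ph_grand_mean: float = 125.0
    residual_sd: float = 20.0
    ph_residual_sd: float = 20.0
    ph_effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.ph_residual_sd < 0:
            raise ValueError("residual SDs must be >= 0")
        if not self.genes:
            raise ValueError("need at least one gene")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "environments", tuple(map(tuple, self.environments)))
        object.__setattr__(self, "ph_locations", tuple(map(tuple, self.ph_locations)))


@dataclass
class SimulatedPanel:
    config: SimConfig
    accessions: tuple[str, ...]
    variants: VariantPanel
    genes: list[GeneModel]
    phenotypes: PhenotypeTable
    hap_labels: dict[str, np.ndarray]  # gene_id -> per-accession haplotype index


def _streams(cfg: SimConfig) -> tuple[list[np.random.Generator], np.random.Generator]:
    master = np.random.SeedSequence(cfg.seed)
    geno_root, noise_seed = master.spawn(2)
    gene_streams = [np.random.default_rng(s) for s in geno_root.spawn(len(cfg.genes))]
    return gene_streams, np.random.default_rng(noise_seed)


def simulate_panel(cfg: SimConfig) -> SimulatedPanel:
    """Draw a full panel: genotypes, gene models, and phenotype table.

    Haplotype labels are drawn per accession from each gene's frequencies;
    variant sites are constructed so allele signatures are in bijection with
    the labels. With ``residual_sd = 0`` every phenotype equals
    mean + effect + offset exactly.
    """
    accessions = tuple(f"ACC{i + 1:04d}" for i in range(cfg.n_accessions))
    gene_streams, noise_rng = _streams(cfg)
    variants = VariantPanel(samples=accessions)
    models: list[GeneModel] = []
    hap_labels: dict[str, np.ndarray] = {}
    genetic = np.zeros(cfg.n_accessions)
    for spec, rng in zip(cfg.genes, gene_streams):
        model = spec.gene_model()
        labels = rng.choice(len(spec.hap_freqs), size=cfg.n_accessions, p=spec.hap_freqs)
        variants.extend(_gene_variants(spec, model, labels, rng))
        models.append(model)
        hap_labels[spec.gene_id] = labels
        genetic = genetic + np.asarray(spec.effects, dtype=float)[labels]
    models.sort(key=lambda g: (g.chrom, g.start))
    variants.sort(key=lambda v: (v.chrom, v.pos))

    rows = []
    for env, offset in cfg.environments:
        noise = noise_rng.normal(0.0, cfg.residual_sd, size=cfg.n_accessions)
        vals = cfg.grand_mean + offset + genetic + noise
        rows += [
            (acc, cfg.base_trait, env, float(v)) for acc, v in zip(accessions, vals)
        ]
    for loc, offset in cfg.ph_locations:
        noise = noise_rng.normal(0.0, cfg.ph_residual_sd, size=cfg.n_accessions)
        vals = cfg.ph_grand_mean + offset + cfg.ph_effect_scale * genetic + noise
        rows += [
            (acc, cfg.second_trait, loc, float(v)) for acc, v in zip(accessions, vals)
        ]
    phen = PhenotypeTable(
        df=pd.DataFrame(rows, columns=list(PhenotypeTable.COLUMNS))
    )
    return SimulatedPanel(
        config=cfg,
        accessions=accessions,
        variants=variants,
        genes=models,
        phenotypes=phen,
        hap_labels=hap_labels,
    )


def make_null_gene(
    panel: SimulatedPanel,
    span: tuple[int, int],
    n_variants: int = 4,
    hap_freqs: Sequence[float] = (0.6, 0.4),
    seed: int | None = None,
    gene_id: str = "NULL",
) -> tuple[GeneModel, list[VariantRecord]]:
    """A gene with haplotype structure but no phenotype effect.

    Labels are drawn from a fresh stream (``seed``, independent of the
    panel's streams by construction), so the gene is independent of every
    phenotype and of any other null gene made with a different seed.
    """
    spec = GeneSpec(
        gene_id=gene_id,
        chrom=panel.genes[0].chrom if panel.genes else "chr1",
        start=span[0],
        end=span[1],
        n_promoter_snps=max(n_variants - 1, 1),
        n_cds_snps=min(n_variants - 1, 1),
        hap_freqs=tuple(hap_freqs),
        effects=tuple(0.0 for _ in hap_freqs),
    )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed if seed is not None else 0, spawn_key=(0xBEEF,))
    )
    model = spec.gene_model()
    if len(hap_freqs) == 1:
        labels = np.zeros(len(panel.accessions), dtype=np.int64)
    else:
        labels = rng.choice(len(hap_freqs), size=len(panel.accessions), p=list(hap_freqs))
    return model, _gene_variants(spec, model, labels, rng)


def default_config(
    seed: int = 0,
    n_genes: int = 10,
    causal_index: int = 4,
    effect_scale: float = 1.0,
    n_accessions: int = 343,
) -> SimConfig:
    """Ten-gene region with one planted causal gene.

    The causal gene has 4 haplotypes at frequencies proportional to
    (25, 91, 28, 46) with effects of printed-table magnitude
    (differences of ~29-45 cm against a ~20 cm residual SD); its variant
    architecture is 19 promoter SNPs + 1 promoter InDel + 2 CDS SNPs + 1
    ~400 bp CDS presence/absence deletion. ``effect_scale`` multiplies the
    causal effects (0 gives an all-null region).
    """
    if not (0 <= causal_index < n_genes):
        raise ValueError("causal_index out of range")
    counts = np.array([25.0, 91.0, 28.0, 46.0])
    freqs = tuple(counts / counts.sum())
    effects = tuple(effect_scale * e for e in (-28.9, 0.0, 16.1, 16.5))
    genes = []
    for i in range(n_genes):
        start = 38_340_000 + i * 20_000
        if i == causal_index:
            genes.append(
                GeneSpec(
                    gene_id=f"GENE{i + 1:02d}",
                    start=start,
                    end=start + 4_000,
                    n_promoter_snps=19,
                    n_promoter_indels=1,
                    n_cds_snps=2,
                    include_pav=True,
                    hap_freqs=freqs,
                    effects=effects,
                )
            )
        else:
            genes.append(
                GeneSpec(
                    gene_id=f"GENE{i + 1:02d}",
                    start=start,
                    end=start + 4_000,
                    n_promoter_snps=4,
                    n_cds_snps=2,
                    hap_freqs=(0.5, 0.3, 0.2),
                    effects=(0.0, 0.0, 0.0),
                )
            )
    return SimConfig(genes=tuple(genes), n_accessions=n_accessions, seed=seed)


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML config snapshot written by :func:`write_fixtures`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["genes"] = tuple(GeneSpec(**g) if isinstance(g, dict) else g for g in raw["genes"])
    for key in ("environments", "ph_locations"):
        if key in raw:
            raw[key] = tuple((str(n), float(o)) for n, o in raw[key])
    return SimConfig(**raw)


def _to_plain(obj):
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_fixtures(
    panel: SimulatedPanel, directory: str | Path, compress: bool = False
) -> dict[str, Path]:
    """Write VCF + GFF3 + phenotype CSV + YAML config snapshot.

    Re-reading the files reproduces the in-memory dataset exactly, and
    re-simulating from the config snapshot reproduces identical files.
    ``compress=True`` gzips the genomic files (readers accept both).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".gz" if compress else ""
    paths = {
        "vcf": write_vcf(panel.variants, directory / f"panel.vcf{ext}"),
        "gff3": write_gff3(panel.genes, directory / f"genes.gff3{ext}"),
        "phenotypes": write_phenotypes(panel.phenotypes, directory / "phenotypes.csv"),
    }
    cfg_path = directory / "sim_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(_to_plain(asdict(panel.config)), fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
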