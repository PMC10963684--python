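"""Readers/writers for VCF, GFF3 and phenotype tables, plus gene-region logic.

Coordinate convention: 1-based positions, inclusive intervals, everywhere in
this package (the BED emitted by the CLI is the sole, documented exception).
The panel is assumed inbred: homozygous diploid calls collapse to a single
allele code and heterozygous calls are treated as missing (counted and
logged, never silently dropped).
"""

from __future__ import annotations

import gzip
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele code for a missing (or heterozygous-collapsed) genotype.
MISSING: int = -1

#: Minimum REF/ALT length difference (bp) for a presence/absence variant.
PAV_MIN_LENGTH_DIFF: int = 50

SNP = "SNP"
INDEL = "INDEL"
PAV = "PAV"


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class Gff3ParseError(ValueError):
    """Raised when a GFF3 file violates the expectations documented here."""


def classify_variant(ref: str, alts: Sequence[str], svlen: int | None = None) -> str:
    """Classify a site as SNP, INDEL or PAV from its alleles.

    SNP iff every allele has length 1; PAV iff the largest REF/ALT length
    difference exceeds 50 bp; everything else is an INDEL. Symbolic ALTs
    (``<DEL>`` etc.) are accepted when ``svlen`` is given and classified PAV
    when ``abs(svlen) > 50``.
    """
    if not ref:
        raise ValueError("empty REF allele")
    alts = tuple(alts)
    if not alts or any(not a for a in alts):
        raise ValueError("empty ALT allele")
    if any(a.startswith("<") for a in alts):
        if svlen is None:
            raise ValueError(f"symbolic ALT {alts} requires an SVLEN")
        return PAV if abs(svlen) > PAV_MIN_LENGTH_DIFF else INDEL
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return SNP
    max_diff = max(abs(len(ref) - len(a)) for a in alts)
    return PAV if max_diff > PAV_MIN_LENGTH_DIFF else INDEL


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with collapsed per-accession allele codes.

    ``genotypes[i]`` is 0 for the reference allele, ``k >= 1`` for the k-th
    ALT, or :data:`MISSING` for the i-th accession of the panel.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    variant_class: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        g = np.asarray(self.genotypes, dtype=np.int16)
        object.__setattr__(self, "genotypes", g)
        n_alleles = 1 + len(self.alts)
        bad = (g != MISSING) & ((g < 0) | (g >= n_alleles))
        if bad.any():
            raise ValueError(
                f"{self.chrom}:{self.pos}: genotype codes {np.unique(g[bad])} "
                f"do not index the {n_alleles} defined alleles"
            )

    def __eq__(self, other: object) -> bool:  # array field needs custom eq
        if not isinstance(other, VariantRecord):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.pos == other.pos
            and self.ref == other.ref
            and self.alts == other.alts
            and self.variant_class == other.variant_class
            and np.array_equal(self.genotypes, other.genotypes)
        )


class VariantPanel(list):
    """A list of :class:`VariantRecord` that remembers the sample order."""

    def __init__(self, records: Iterable[VariantRecord] = (), samples: Sequence[str] = ()):
        super().__init__(records)
        self.samples: tuple[str, ...] = tuple(samples)
        self.n_het_collapsed: int = 0


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates with strand, TSS and CDS intervals (1-based, inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_intervals: tuple[tuple[int, int], ...] = ()
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        for lo, hi in self.cds_intervals:
            if lo < self.start or hi > self.end or lo > hi:
                raise ValueError(
                    f"gene {self.gene_id}: CDS interval ({lo}, {hi}) outside gene span"
                )
        if self.tss is None:
            object.__setattr__(self, "tss", self.start if self.strand == "+" else self.end)


def promoter_interval(gene: GeneModel, length: int = 1000) -> tuple[int, int]:
    """Upstream promoter interval of ``length`` bp, clipped at position 1.

    On the + strand this is ``[tss - length, tss - 1]``; on the - strand
    ``[tss + 1, tss + length]``.
    """
    if length < 1:
        raise ValueError("promoter length must be >= 1")
    if gene.strand == "+":
        return (max(1, gene.tss - length), gene.tss - 1)
    return (gene.tss + 1, gene.tss + length)


def _maybe_gunzip(path: str | Path) -> tuple[str, tempfile.TemporaryDirectory | None]:
    path = str(path)
    if not path.endswith(".gz"):
        return path, None
    tmp = tempfile.TemporaryDirectory()
    plain = str(Path(tmp.name) / Path(path).name[:-3])
    with gzip.open(path, "rb") as fin, open(plain, "wb") as fout:
        shutil.copyfileobj(fin, fout)
    return plain, tmp


def _parse_region(region) -> tuple[str, int, int]:
    if isinstance(region, str):
        chrom, _, span = region.partition(":")
        if span:
            lo, _, hi = span.partition("-")
            return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))
        return chrom, 1, np.iinfo(np.int64).max
    chrom, lo, hi = region
    return str(chrom), int(lo), int(hi)


def _collapse_diploid(gt: Sequence[int]) -> tuple[int, bool]:
    """Collapse one cyvcf2 genotype (allele indices + phase flag) to a code.

    Returns ``(code, was_het)``; heterozygous or partially missing calls
    become :data:`MISSING`.
    """
    alleles = [a for a in gt[:-1]]  # last element is the phase flag
    if not alleles:
        raise VcfParseError("sample call with zero ploidy")
    if any(a < 0 for a in alleles):
        return MISSING, False
    if len(set(alleles)) > 1:
        return MISSING, True
    return int(alleles[0]), False


def read_vcf(path: str | Path, region=None) -> VariantPanel:
    """Read a VCF into a :class:`VariantPanel`.

    Homozygous diploid calls collapse (``0/0 -> 0``, ``1/1 -> 1``);
    heterozygous calls map to missing because the panel is assumed inbred
    (the collapsed count is logged and stored on the panel). ``region`` is
    ``"chrom:start-end"`` or a ``(chrom, start, end)`` tuple, inclusive on
    both ends.
    """
    from cyvcf2 import VCF

    want = _parse_region(region) if region is not None else None
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2/htslib raise various types
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    panel = VariantPanel(samples=vcf.samples)
    n_het = 0
    lineno = 0
    try:
        for v in vcf:
            lineno += 1
            if want is not None and not (
                v.CHROM == want[0] and want[1] <= v.POS <= want[2]
            ):
                continue
            codes = np.empty(len(panel.samples), dtype=np.int16)
            for i, gt in enumerate(v.genotypes):
                code, was_het = _collapse_diploid(gt)
                codes[i] = code
                n_het += was_het
            svlen = v.INFO.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            panel.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=tuple(v.ALT),
                    variant_class=classify_variant(v.REF, v.ALT, svlen=svlen),
                    genotypes=codes,
                )
            )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: parse error near record {lineno}: {exc}") from exc
    finally:
        vcf.close()
    panel.n_het_collapsed = n_het
    if n_het:
        logger.info("%s: collapsed %d heterozygous calls to missing", path, n_het)
    return panel


def write_vcf(panel: VariantPanel, path: str | Path) -> Path:
    """Write a panel as a minimal VCF 4.2 (diploid-homozygous GT encoding).

    Gzip output when ``path`` ends in ``.gz``. Deterministic byte-for-byte
    for identical input.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(r.chrom for r in panel):
        maxpos = max(r.pos + len(r.ref) for r in panel if r.chrom == chrom)
        lines.append(f"##contig=<ID={chrom},length={maxpos + 1000}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples)
    )
    for rec in sorted(panel, key=lambda r: (r.chrom, r.pos)):
        gts = "\t".join(
            "./." if c == MISSING else f"{c}/{c}" for c in rec.genotypes
        )
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}\t.\tPASS\t.\tGT\t{gts}"
        )
    text = "\n".join(lines) + "\n"
    if path.suffix == ".gz":
        # mtime=0 keeps gzip output byte-identical across runs
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        path.write_text(text)
    return path


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + CDS features) from a GFF3 file.

    CDS intervals are collected from all descendants of each gene. The TSS
    defaults to the strand-appropriate gene boundary unless an mRNA child
    provides a transcript start. Genes are returned sorted by (chrom, start).
    """
    import gffutils

    plain, tmp = _maybe_gunzip(path)
    try:
        try:
            db = gffutils.create_db(
                plain,
                dbfn=":memory:",
                merge_strategy="create_unique",
                keep_order=True,
            )
        except Exception as exc:
            raise Gff3ParseError(f"{path}: cannot parse GFF3: {exc}") from exc
        genes: list[GeneModel] = []
        for feat in db.features_of_type("gene"):
            if feat.strand not in ("+", "-"):
                raise Gff3ParseError(f"{path}: gene {feat.id} has no strand")
            cds = sorted(
                (c.start, c.end) for c in db.children(feat, featuretype="CDS")
            )
            for lo, hi in cds:
                if lo < feat.start or hi > feat.end:
                    raise Gff3ParseError(
                        f"{path}: CDS ({lo}, {hi}) outside gene {feat.id} span"
                    )
            mrnas = list(db.children(feat, featuretype="mRNA", level=1))
            tss = None
            if mrnas:
                tss = (
                    min(m.start for m in mrnas)
                    if feat.strand == "+"
                    else max(m.end for m in mrnas)
                )
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=feat.start,
                    end=feat.end,
                    cds_intervals=tuple(cds),
                    tss=tss,
                )
            )
        genes.sort(key=lambda g: (g.chrom, g.start))
        return genes
    finally:
        if tmp is not None:
            tmp.cleanup()


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write gene models as GFF3 (gene + mRNA + CDS features)."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna_start = g.tss if g.strand == "+" else g.start
        mrna_end = g.tss if g.strand == "-" else g.end
        lines.append(
            f"{g.chrom}\t.\tmRNA\t{mrna_start}\t{mrna_end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.1;Parent={g.gene_id}"
        )
        for i, (lo, hi) in enumerate(g.cds_intervals, 1):
            lines.append(
                f"{g.chrom}\t.\tCDS\t{lo}\t{hi}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.1"
            )
    text = "\n".join(lines) + "\n"
    if path.suffix == ".gz":
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        path.write_text(text)
    return path


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one value per (accession, trait, environment).

    Replicate rows with the same key are averaged on ingestion; ``n_dropped``
    counts rows rejected for non-numeric values.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    COLUMNS = ("accession", "trait", "environment", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {', '.join(missing)}")
        if len(self.df) and not np.isfinite(self.df["value"].to_numpy(float)).all():
            raise ValueError("phenotype values must be finite")

    def values_for(self, trait: str, environment: str) -> dict[str, float]:
        """Map accession -> value for one trait in one environment."""
        sel = self.df[(self.df["trait"] == trait) & (self.df["environment"] == environment)]
        return dict(zip(sel["accession"], sel["value"].astype(float)))

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.df["environment"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.df.sort_values(list(self.COLUMNS[:3])).reset_index(drop=True)
        b = other.df.sort_values(list(self.COLUMNS[:3])).reset_index(drop=True)
        if not a[list(self.COLUMNS[:3])].equals(b[list(self.COLUMNS[:3])]):
            return False
        return np.allclose(a["value"], b["value"], rtol=0, atol=1e-9)


def read_phenotypes(path: str | Path, sep: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype file (columns accession/trait/environment/value).

    The delimiter is sniffed from the extension unless given. Non-numeric
    values are dropped (counted in ``n_dropped``); replicates are averaged.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if ".tsv" in path.suffixes or ".txt" in path.suffixes else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    missing = [c for c in PhenotypeTable.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    df = df[list(PhenotypeTable.COLUMNS)].copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_before = len(df)
    df = df.dropna(subset=["value"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d non-numeric phenotype rows", path, n_dropped)
    df = (
        df.groupby(["accession", "trait", "environment"], as_index=False, sort=True)["value"]
        .mean()
    )
    return PhenotypeTable(df=df, n_dropped=n_dropped)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.df.sort_values(["accession", "trait", "environment"])
    df.to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table style group summary: label, n, mean, SD (units of the trait)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label}: n must be >= 1")
        if self.sd < 0:
            raise ValueError(f"group {self.label}: sd must be >= 0")
        if self.sd > 0 and self.n < 2:
            raise ValueError(f"group {self.label}: sd requires n >= 2")


def read_group_summaries(path: str | Path, sep: str = ",") -> list[GroupSummary]:
    """Read a (label, n, mean, sd) CSV into :class:`GroupSummary` records."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("label", "n", "mean", "sd") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return [
        GroupSummary(label=str(r.label), n=int(r.n), mean=float(r.mean), sd=float(r.sd))
        for r in df.itertuples()
    ]
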