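# haplomine

Gene-based haplotype candidate mining for inbred diversity panels.

Given panel variants (VCF), gene models (GFF3) and a phenotype table, the
pipeline:

1. delimits the LD region around an association peak (pairwise r² of allele
   codes, peak-anchored contiguous block);
2. enumerates per-gene haplotypes from promoter (1 kb upstream of the TSS,
   configurable) + CDS variants — SNPs, InDels, and presence/absence
   variants (> 50 bp length difference);
3. keeps the major haplotypes (> 10 carriers, i.e. count ≥ 11 by default);
4. tests phenotype differences among them in every environment with a
   pooled one-way ANOVA and Duncan's multiple range test (compact letter
   display, Duncan–Kramer unequal-n handling); and
5. calls a gene a candidate iff the differences are significant in **all**
   environments.

Downstream helpers cover two-gene haplotype-combination (pyramiding)
screens with a dominance verdict, trait correlation, two-sample t-tests,
and knockout percent-reduction effect sizes. All statistics run both on raw
samples and on printed-table summaries (label, n, mean, SD), which is
enough for one-way ANOVA and every range test here.

A simulator (`haplomine.simulate`) generates panels with the same
statistical structure — planted haplotype effects, multiple environments,
a correlated second trait — so the whole pipeline is testable offline and
byte-reproducibly from a single seed.

Coordinates are 1-based with inclusive intervals throughout (VCF/GFF3
convention); the BED file written by `haplomine ld` is the one documented
exception. Heterozygous calls collapse to missing (the panel is assumed
inbred) with a logged count.

## CLI

```bash
# simulate a default 10-gene region (1 planted causal gene, 343 accessions)
haplomine simulate --seed 1 --out sim/

# LD block around a peak -> BED + per-site r2 TSV
haplomine ld --vcf sim/panel.vcf --peak chr1:38420000 --r2-min 0.6

# per-gene haplotype report
haplomine haplotypes --vcf sim/panel.vcf --gff3 sim/genes.gff3 --gene GENE05

# full candidate scan across three environments
haplomine mine --vcf sim/panel.vcf --gff3 sim/genes.gff3 \
    --pheno sim/phenotypes.csv --trait SL --envs GST,GSF,DST

# two-gene pyramiding screen with a dominance verdict
haplomine pyramid --vcf sim/panel.vcf --gff3 sim/genes.gff3 \
    --pheno sim/phenotypes.csv --genes GENE05,GENE01 \
    --columns SL:GST,SL:GSF,SL:DST

# Duncan letters straight from printed summaries (CSV: label,n,mean,sd)
haplomine duncan --summary groups.csv
```

## Layout

- `src/haplomine/genomic_io.py` — VCF/GFF3/phenotype readers + writers,
  variant classification (SNP/INDEL/PAV), promoter/CDS region logic
- `src/haplomine/ld.py` — pairwise r², peak-anchored LD block, region report
- `src/haplomine/haplotypes.py` — haplotype enumeration + major filter
- `src/haplomine/stats.py` — pooled ANOVA, Duncan MRT + compact letter
  display, t-tests, Pearson, percent reduction
- `src/haplomine/mining.py` — per-environment tests and the all-environment
  candidate decision
- `src/haplomine/pyramiding.py` — combination groups and dominance screen
- `src/haplomine/simulate.py` — seeded panel generator + fixture writer
- `src/haplomine/cli.py` — the `haplomine` command group
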