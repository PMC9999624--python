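# pseudohet

Detection and mapping of cryptic gene duplications in inbred lines from
spurious heterozygous SNP calls.

## The problem

Fully selfing (inbred) plant lines should be homozygous genome-wide, yet
short-read variant calling on such lines routinely reports heterozygous
genotypes. When a line carries a duplicate of a gene that the reference
genome lacks, reads from both copies pile up on the single reference locus
and every difference between the copies is miscalled as a heterozygous SNP
("pseudo-heterozygosity"). These artifacts corrupt genotype matrices and
propagate into downstream analyses — most notably bisulfite methylation
calls, where collapsed reads mix the methylation states of distinct copies.

`pseudohet` is for population geneticists and methylome analysts working
with inbred panels who want to (a) flag pseudo-SNPs, (b) locate the
unassembled duplicate copies, and (c) quantify the resulting
methylation-call artifacts.

## The method

For a pseudo-SNP *s*, code heterozygosity at *s* across the panel as a
binary phenotype, `y_i = 1` if accession *i* is het at *s*. Since the
carriers of the duplication are exactly the pseudo-heterozygous
accessions, the duplicate copy is mappable by a genome-wide association
scan of `y` against the het-filtered genotype matrix under a linear mixed
model

```
y = mu + x beta + g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)
```

with an IBS kinship K. The variance ratio delta = sigma_e^2/sigma_g^2 is
REML-fitted once under the null via eigendecomposition of K, and each SNP
is tested by generalized least squares in the rotated coordinates (the
EMMAX-style accelerated mixed model). Association signals are smoothed per
chromosome by a low-pass Fourier filter (keeping the lowest 5% of
components), local maxima become peaks, each peak is represented by its
strongest SNP within +-10 kb, and peaks are labelled **cis** (within 50 kb
of the focal pseudo-SNP — tagging the template) or **trans** (elsewhere —
tagging the duplicate copy), with final thresholds -log10 p >= 20 and
MAF >= 0.1. Predictions are confirmed in assembled genomes by local
alignment (70% identity, 70% query length, match within 20 kb of the
mapped peak), and methylation artifacts are quantified as the difference
in weighted methylation level, sum(c)/sum(t), between reference-collapsed
and own-genome mapping.

A bundled simulator (`pseudohet.popsim`) generates selfing populations
with founder-mosaic LD, planted trans/tandem duplications with diverged
copies, per-accession assemblies, bisulfite counts and junction read
pairs, so the entire pipeline is exercised against known ground truth.

## Worked example

```python
from pseudohet.pipeline import RunConfig, run_all

cfg = RunConfig(seed=11, n_accessions=150, chrom_lengths=(400_000, 400_000),
                n_genes_per_chrom=10, n_methyl_accessions=4,
                n_methyl_control_genes=5)
products = run_all(cfg, "example_run")
print(products["filter"][1])                      # pseudo-SNP filter funnel
print(products["recovery"].to_string(index=False))
```

prints

```
{'total_snps': 2046, 'het_snps': 49, 'freq_pass': 49, 'genic_pass': 49}
source_gene  mode insertion_chrom  insertion_pos  n_carriers  detected  label_correct  peak_distance_bp  confirmed
      g1_01 trans            chr2         270007          46      True           True                 0       True
```

Reading this: the simulated 150-accession panel contains 2,046 SNPs, of
which 49 carry heterozygous calls — all injected by the single planted
trans duplication of gene `g1_01`, whose extra copy sits at chr2:270,007
in its 46 carriers. All 49 pass the frequency (>= 5%) and genic filters.
The GWAS-plus-peak-calling stage detects the event (`detected`), labels it
trans (`label_correct`), and its top trans SNP lands 0 bp from the true
insertion point (`peak_distance_bp`); alignment against the carrier
assemblies confirms a non-syntenic copy near the predicted position
(`confirmed`). The same run writes TSVs for every stage (heterozygosity
summaries and tracts, scans, peaks, copy numbers, methylation discordance,
insertion presence) into `example_run/`.

The equivalent shell interface:

```bash
pseudohet run-all --config config.txt --out example_run   # key = value file
pseudohet hetscan --vcf example_run/sim.vcf --out hetscan_out
```

## Layout

| Module | Role |
| --- | --- |
| `io_formats` | VCF/GFF3/FASTA/TSV readers and writers, genotype matrix |
| `popsim` | synthetic selfing population + duplication ground truth |
| `hetscan` | het sharing, density, runs-of-heterozygosity caller |
| `pseudosnp` | pseudo-SNP filter, phenotypes, rare-variant enrichment |
| `mmgwas` | kinship, REML null fit, EMMAX-style scan |
| `peakcall` | FFT smoothing, peak detection, cis/trans classification |
| `dupconfirm` | seed-and-extend aligner, confirmation, copy number |
| `methylcmp` | weighted methylation levels, discordance tables |
| `pipeline`, `cli` | end-to-end orchestration and `pseudohet` subcommands |

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
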