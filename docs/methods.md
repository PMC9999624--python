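# Methods

## The problem

Accessions of a highly selfing plant species are expected to be homozygous
at essentially every position, yet standard short-read variant calling on
such lines produces large numbers of heterozygous SNP calls. Most of these
are artifacts of cryptic copy-number variation: when an accession carries a
duplicate of a gene that the reference genome lacks, reads from both copies
map onto the single reference locus, and every base difference between the
copies is called as a heterozygous genotype ("pseudo-heterozygosity", and
the sites are "pseudo-SNPs"). `pseudohet` implements the full detection and
mapping pipeline for this phenomenon and a synthetic-data generator to
exercise it end to end.

The chain of reasoning the pipeline encodes:

1. Genuine residual heterozygosity from recent outcrossing produces long,
   private heterozygous tracts. Pseudo-heterozygosity instead produces
   short tracts *shared* across the unrelated carriers of one duplication,
   and the spurious "het" alleles usually also segregate as ordinary
   homozygotes in the population. `hetscan` measures both signatures.
2. Because the duplicate copy is a segregating allele, its location can be
   mapped by genome-wide association: code heterozygosity at one pseudo-SNP
   as a 1/0 phenotype and scan the (het-excluded) genotype matrix with a
   linear mixed model. A significant association near the focal SNP (cis)
   tags the template; an association elsewhere (trans) tags the duplicate
   copy. `pseudosnp`, `mmgwas` and `peakcall` implement this.
3. Predicted locations are validated in assembled genomes by local
   alignment (`dupconfirm`), and the downstream consequence — spurious
   differential-methylation calls caused by read collapse — is quantified
   by `methylcmp`.

## The synthetic population (`popsim`)

Each accession is a recombinant mosaic of `n_founders` ancestral
haplotypes, homozygous everywhere. Mosaics are drawn independently per
accession: crossover count ~ Poisson(`recomb_rate` x length), founder
states sampled with the configurable `founder_weights`. Founder alleles at
each SNP are assigned by drawing a derived-allele count uniformly on
1..n_founders-1. Monomorphic sites are dropped, so every retained SNP
segregates. This deliberately replaces a coalescent model: the mapping
method needs controllable linkage disequilibrium and tag SNPs, not
realistic genealogies.

A `DuplicationEvent` copies a source gene to an insertion point. Carriers
are exactly the accessions whose mosaic at the insertion point equals the
event's `carrier_founder`; target carrier frequencies are reached through
the founder sampling weights. Two modes:

* **trans** — the copy descends from the `origin_founder` haplotype. For a
  carrier, any source-interval SNP where its own allele differs from the
  origin allele turns het immediately (pre-existing allelic variation),
  which also reproduces the empirical signature that both alleles of a
  pseudo-SNP are seen as homozygotes elsewhere in the population.
* **tandem** — the copy duplicates the carrier's own haplotype, so only
  copy divergence creates pseudo-SNPs; a fresh tandem copy injects
  nothing.

Divergence mutations (per-bp probability `divergence`, drawn once per
event) at positions without a pre-existing SNP create *new* sites that are
het in carriers and hom-ref elsewhere — expected injected het calls per
carrier from divergence alone is (SNP-free template length) x divergence.

Because a one-origin insertion is in complete linkage with its junction,
`plant_duplication` materialises a biallelic tag SNP at the insertion point
(the carrier-founder indicator). This is what makes the planted events
discoverable at single-tag resolution; without it, association strength
inside a founder block is distance-independent and the top SNP position
would be arbitrary within the block.

Emissions for downstream stages: per-accession assemblies (reference +
own alleles + inserted copies), per-cytosine bisulfite counts (CG and CHG
contexts, forward strand, Poisson depth, binomial methylation; for
carriers the reference-target counts pool both copies, emulating read
collapse), junction read-pair placements (carriers get spanning pairs,
non-carriers flank-only pairs), and 50 bp-window collapsed read depth
(doubled over duplicated genes in carriers).

What the generator does **not** model: read-level errors and mapping
quality, indels/inversions, CHH methylation, genotype-call noise (an
optional per-site false-negative rate, default 0, is the only imperfection
knob). Passing tests therefore demonstrate the pipeline's correctness and
calibration under clean mis-mapping signals, not its robustness to every
artifact of real short-read data.

## Heterozygosity runs (`hetscan`)

Per-SNP summaries count het calls, sharing and the both-alleles-homozygous
flag (het frequency uses non-missing calls by default; a flag switches to
the full accession count). Tracts of heterozygosity are called per
accession with a sliding window of `window_size = 10` consecutive SNPs; a
window is heterozygous when it has at most 1 homozygous and at most 1
missing call; a SNP is in-run when the heterozygous fraction of windows
overlapping it exceeds `threshold = 0.05` (strict). Maximal in-run
stretches are split at gaps > 1 Mb, trimmed to their first/last het call,
and kept if they contain >= 3 het SNPs, span >= 1 kb, and have >= 1 het
SNP per 100 kb. Tract sharing between accessions uses >= 50% reciprocal
overlap. The caller is verified against an exhaustive window-enumeration
oracle.

## Pseudo-SNP filter and phenotypes (`pseudosnp`)

Candidate pseudo-SNPs are het SNPs with population frequency >= 5%
(inclusive; denominator = all accessions) located inside annotated gene
bodies (CDS-only filtering is out of scope of the bundled annotation
model). The funnel counts at each stage are logged and written. The
phenotype of a pseudo-SNP is 1 where the accession is het, 0 otherwise
(missing -> 0 by default). Rare-variant enrichment in a given duplicated
gene set uses a one-sided exact binomial test of the observed
singleton/doubleton count against the fraction of genic SNP positions in
the set.

## Mixed-model scan (`mmgwas`)

Kinship is identity-by-state over homozygous co-typed calls (het calls are
excluded everywhere — in this application they are the measurement, not a
genotype). Per-pair denominators make the raw ratio matrix very slightly
indefinite; eigenvalue clipping at zero restores a valid covariance (the
perturbation is bounded by the clipped magnitude, ~1e-2 here). A VanRaden
centered-genotype kinship is available behind a flag.

The null model y = mu + g + e, g ~ N(0, sg2 K), e ~ N(0, se2 I) is fitted
once by REML: profile the restricted likelihood over log(delta), delta =
se2/sg2, on [-10, 10] with a 64-point grid scan plus bounded Brent
refinement (tolerance 1e-6) after eigendecomposition of K. A flat
criterion (K = I) is non-identifiable and returns heritability 0 by
convention. Every SNP is then tested by generalized least squares in the
rotated, whitened coordinates (the EMMAX approximation: delta is not
re-fitted per SNP; an exact per-SNP REML refit exists behind a flag for
cross-checking). Dosage coding is hom-ref 0 / hom-alt 1 with het and
missing mean-imputed per SNP; MAF is computed among homozygous calls;
binary phenotypes are treated as Gaussian. Two-sided t-tests use n-2
degrees of freedom; p-values below 1e-300 are reported as -log10 p = 300.
Raw scans are filtered at MAF >= 0.05 and -log10 p >= 4.

The scan is validated against a dense GLS oracle (full covariance solve)
to 1e-8 relative error, degenerates exactly to ordinary regression at
K = I, and is calibrated on permuted phenotypes. One practical note:
under strong founder structure the rejection fraction of a *single*
permuted phenotype is highly skewed (few effectively independent tests),
so calibration is assessed as the mean over permutations on a
weak-LD population.

## Peak calling (`peakcall`)

Filtered -log10 p values are gridded per chromosome onto 1 kb bins
(maximum per bin, empty bins 0), smoothed by keeping the lowest
ceil(0.05 x n) Fourier components, and strict local maxima above
`peak_floor = 4` become peaks (plateaus report their central bin). The
smoother is exactly linear; the non-negativity clip is applied at the
peak-calling step, not inside the transform, so linearity is preserved as
a testable invariant. Each peak is represented by its strongest SNP within
+-10 kb (ties -> smaller position; empty windows discard the peak) and
labelled cis when within 50 kb of the focal pseudo-SNP on the same
chromosome, else trans. Peaks of all pseudo-SNPs of a gene are pooled;
those passing the final thresholds (-log10 p >= 20, MAF >= 0.1) determine
the gene category cis_only / trans_only / both / none, which partitions
the gene set by construction.

## Assembly confirmation (`dupconfirm`)

The aligner is seed-and-extend: exact 15-mer seeds (both strands,
rolling-hash lookup), diagonal clustering, then banded affine-gap
Smith-Waterman extension (match +1, mismatch -2, gap open -5, gap extend
-2; a length-L gap costs open + (L-1) x extend; numba-compiled inner
loop). Percent identity counts matched bases over alignment columns
including gaps; fragments on the same target and strand within 1 kb whose
query intervals do not substantially overlap are chained before coverage
computation, so split hits count once while tandem copies count twice.
Matches require >= 70% identity and >= 70% query coverage. The aligner is
validated against full Smith-Waterman (Biopython's PairwiseAligner) on
small instances.

A predicted peak is mapped into an assembly by aligning the 10 kb
reference segment centered on it (segment anchoring; at simulator scale
this is equivalent to whole-genome synteny mapping) and confirmed when a
gene match center lies within 20 kb of the mapped position. Because the
syntenic source copy itself would trivially "confirm" any cis position,
a second verdict excludes matches near the mapped source locus; trans
predictions are judged by this non-syntenic confirmation. Copy number is
estimated both as the alignment match count (categories 0 / 1 / >1) and
as mean 50 bp-window collapsed depth over the gene divided by the
genome-wide median. Flank synteny extracts the 3 genes up- and downstream
and reports their matches (fragments >= 50% of input length). Insertion
presence requires >= 3 read pairs spanning the junction (left mate ending
strictly before it, right mate starting strictly after).

## Methylation artifacts (`methylcmp`)

The weighted methylation level of a unit (gene body by default, 200 bp
windows optionally) is sum(c_i)/sum(t_i) over cytosines with depth >= 3,
undefined when none qualify. A gene is differentially methylated between
mapping targets when the levels differ by more than 0.05 (CG) or 0.03
(CHG), strict inequality. The discordance table stratifies genes per
accession by copy number (0 / 1 / >1), excludes genes with an undefined
level in either target from the fractions, and uses the copy syntenic to
the reference position (the labelled source copy) for multi-copy genes,
falling back to the first copy with an ambiguity flag.

## Pipeline and reproducibility (`pipeline`, `cli`)

`run_all` executes simulate -> hetscan -> filter -> gwas -> peaks ->
confirm -> methyl -> read-pair presence and writes a per-event recovery
report (detected, label correct, peak-to-truth distance, confirmed). All
randomness derives from the single config seed through named per-module
generator streams, so runs are byte-identical; every stage writes TSVs
with commented headers and can be re-run from the previous stage's files
through the CLI subcommands. Identical phenotypes (pseudo-SNPs of one
event sharing a carrier set) are scanned once and cached. Stage failures
abort with the stage name and seed.

Problem sizes: the bundled study runs 300 accessions, 2 chromosomes x
1 Mb at 2.5 SNPs/kb (~5,000 SNPs), one planted trans duplication at
carrier frequency 0.3 and divergence 0.05 in a 1 kb gene; assembly
confirmation uses 2 carrier genomes per run and methylation analysis a
6-accession, ~13-gene universe at depth 30 — a desk-scale design chosen so
that every stage's statistical signal (tag-SNP association, 2x coverage,
pooled methylation shift) is unambiguous while a complete replicate set
runs in minutes.

## Known limitations

* The founder-mosaic model gives block-constant LD; fine-mapping behaviour
  inside a block is governed by the planted tag SNP, not by recombination
  gradients as in real data.
* Binary phenotypes are analysed with a Gaussian mixed model (as the
  method prescribes); no logistic mixed model is provided.
* The aligner's banded extension assumes copies diverge mainly by
  substitution (band +-32 around seed diagonals); very indel-rich copies
  would need a wider band.
* Tandem duplications with low divergence produce few pseudo-SNPs and
  carrier frequencies below the final MAF threshold stay undetectable —
  an inherent bias of the method, reproduced rather than corrected here.
* Methylation emission models cytosines on the forward strand only and
  CG/CHG contexts only.
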