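"""Pseudo-SNP filtering, binary phenotypes, and rare-variant enrichment.

The core set of candidate pseudo-SNPs is obtained by a frequency filter
(heterozygous in at least 5% of the population by default) combined with a
genic filter (position inside an annotated gene). Heterozygosity at one
retained SNP, coded 1/0 per accession, is the "phenotype" mapped by the
mixed-model association scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binomtest

from .io_formats import GeneAnnotation, GenotypeMatrix, HET

log = logging.getLogger(__name__)


def _gene_trees(annotation: list[GeneAnnotation],
                feature_class: str | None = "gene") -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        if feature_class is not None and g.feature_class != feature_class:
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1,
                                                       g.gene_id)
    return trees


def assign_genes(gm: GenotypeMatrix,
                 annotation: list[GeneAnnotation]) -> list[str | None]:
    """Containing gene id per SNP (first by start on overlap), or None."""
    trees = _gene_trees(annotation)
    out = []
    for chrom, pos in zip(gm.chrom, gm.pos):
        hits = trees[chrom][int(pos)] if chrom in trees else []
        if hits:
            out.append(sorted(hits, key=lambda iv: iv.begin)[0].data)
        else:
            out.append(None)
    return out


def filter_pseudo_snps(gm: GenotypeMatrix, annotation: list[GeneAnnotation],
                       freq_threshold: float = 0.05,
                       denominator: str = "all") -> tuple[pd.DataFrame, dict]:
    """Apply the frequency + genic filter funnel.

    Returns (pseudo_snps, funnel): pseudo_snps has columns snp_id, chrom,
    pos, het_count, het_frequency, gene_id; funnel counts the SNPs
    surviving each stage (total -> het -> frequency -> genic). The
    frequency threshold is inclusive (>=) and the default denominator is
    the full accession count ("population"); ``denominator="non_missing"``
    matches the hetscan convention instead.
    """
    c = gm.calls
    het_count = (c == HET).sum(axis=1)
    denom = (gm.n_accessions if denominator == "all"
             else np.maximum((c >= 0).sum(axis=1), 1))
    freq = het_count / denom
    gene_ids = np.array(assign_genes(gm, annotation), dtype=object)

    is_het = het_count >= 1
    freq_pass = is_het & (freq >= freq_threshold)
    genic_pass = freq_pass & (gene_ids != None)  # noqa: E711

    funnel = dict(total_snps=int(gm.n_snps),
                  het_snps=int(is_het.sum()),
                  freq_pass=int(freq_pass.sum()),
                  genic_pass=int(genic_pass.sum()))
    log.info("pseudo-SNP funnel: %s", funnel)

    ix = np.flatnonzero(genic_pass)
    out = pd.DataFrame(dict(
        snp_id=[gm.snp_ids[i] for i in ix], chrom=gm.chrom[ix],
        pos=gm.pos[ix], het_count=het_count[ix],
        het_frequency=freq[ix], gene_id=gene_ids[ix]))
    return out, funnel


def make_phenotype(gm: GenotypeMatrix, snp_id: str,
                   missing_as: int = 0) -> np.ndarray:
    """Binary phenotype: 1 iff the accession is het at the focal SNP.

    Missing calls are coded 0 by default; ``missing_as=-1`` marks them for
    exclusion by the caller.
    """
    chrom, pos = snp_id.rsplit(":", 1)
    j = gm.snp_index(chrom, int(pos))
    calls = gm.calls[j]
    y = (calls == HET).astype(np.int8)
    if missing_as != 0:
        y = np.where(calls < 0, missing_as, y).astype(np.int8)
    return y


def rare_enrichment(gm: GenotypeMatrix, duplicated_genes: set,
                    annotation: list[GeneAnnotation],
                    multiplicity: str = "singleton") -> dict:
    """Enrichment of rare (singleton/doubleton) het SNPs in duplicated genes.

    observed = fraction of rare genic het SNPs inside ``duplicated_genes``;
    expected = fraction of all genic SNP positions inside them; p-value
    from a one-sided exact binomial test (observed count vs expected
    fraction). Returns dict(observed, expected, n_rare, p_value,
    undefined).
    """
    target = {"singleton": 1, "doubleton": 2}[multiplicity]
    het_count = (gm.calls == HET).sum(axis=1)
    gene_ids = np.array(assign_genes(gm, annotation), dtype=object)
    genic = gene_ids != None  # noqa: E711
    in_dup = np.array([g in duplicated_genes if g is not None else False
                       for g in gene_ids])

    n_genic = int(genic.sum())
    expected = float(in_dup[genic].mean()) if n_genic else np.nan
    rare = genic & (het_count == target)
    n_rare = int(rare.sum())
    if n_rare == 0 or n_genic == 0:
        return dict(observed=np.nan, expected=expected, n_rare=n_rare,
                    p_value=np.nan, undefined=True)
    k = int((rare & in_dup).sum())
    p = binomtest(k, n_rare, expected, alternative="greater").pvalue
    return dict(observed=k / n_rare, expected=expected, n_rare=n_rare,
                p_value=float(p), undefined=False)
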