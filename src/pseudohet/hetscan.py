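"""Characterising heterozygosity in a nominally homozygous population.

In a selfing species every accession should be homozygous genome-wide, so
shared heterozygous calls are the first signature of cryptic duplications:
the same mis-mapped copy produces the same spurious het calls in every
carrier. This module computes per-SNP sharing statistics, the
both-alleles-homozygous check (pseudo-SNPs typically segregate as ordinary
homozygous alleles as well), genomic density profiles, and per-accession
runs (tracts) of heterozygosity with a sliding-window caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, HET, HOM_ALT, HOM_REF

log = logging.getLogger(__name__)


@dataclass
class TractParams:
    """Sliding-window run-of-heterozygosity parameters.

    window_size consecutive SNPs form a window; a window is heterozygous if
    it contains at most max_opp_window homozygous and max_miss_window
    missing calls. A SNP is in-run when the fraction of windows overlapping
    it that are heterozygous exceeds ``threshold`` (strict). Maximal in-run
    stretches are split at gaps > max_gap bp between consecutive SNPs,
    trimmed to their first/last het call, and kept when they contain at
    least min_snp het calls, span at least min_length bp, and have at least
    min_density het SNPs per kb.
    """

    window_size: int = 10
    threshold: float = 0.05
    min_density: float = 1 / 100  # SNPs per kb (>= 1 SNP / 100 kb)
    min_snp: int = 3
    max_gap: int = 1_000_000
    min_length: int = 1000
    max_opp_window: int = 1
    max_miss_window: int = 1

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


def summarize_het(gm: GenotypeMatrix,
                  denominator: str = "non_missing") -> pd.DataFrame:
    """Per-SNP heterozygosity summary.

    Columns: snp_id, chrom, pos, het_count, n_non_missing, het_frequency,
    both_alleles_homozygous, undefined (no non-missing call). The frequency
    denominator is the number of non-missing calls by default; ``"all"``
    uses the accession count.
    """
    c = gm.calls
    het = (c == HET).sum(axis=1)
    nonmiss = (c >= 0).sum(axis=1)
    denom = np.full(gm.n_snps, gm.n_accessions) if denominator == "all" else nonmiss
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(denom > 0, het / np.maximum(denom, 1), np.nan)
    both = ((c == HOM_REF).any(axis=1)) & ((c == HOM_ALT).any(axis=1))
    return pd.DataFrame(dict(
        snp_id=gm.snp_ids, chrom=gm.chrom, pos=gm.pos, het_count=het,
        n_non_missing=nonmiss, het_frequency=freq,
        both_alleles_homozygous=both, undefined=nonmiss == 0))


def het_density(gm: GenotypeMatrix, window_bp: int,
                min_shared: int = 2) -> pd.DataFrame:
    """Binned genome-wide counts of shared-het SNPs (het_count >= min_shared).

    Bin b covers positions (b*window_bp, (b+1)*window_bp]; bin counts sum
    to the total number of shared-het SNPs.
    """
    het = (gm.calls == HET).sum(axis=1)
    rows = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        pos = gm.pos[sl]
        shared = het[sl] >= min_shared
        if len(pos) == 0:
            continue
        nbins = int(np.ceil(pos.max() / window_bp))
        bins = np.minimum((pos - 1) // window_bp, nbins - 1)
        counts = np.bincount(bins[shared], minlength=nbins)
        rows.append(pd.DataFrame(dict(
            chrom=chrom, bin=np.arange(1, nbins + 1),
            start=np.arange(nbins) * window_bp + 1, count=counts)))
    if not rows:
        return pd.DataFrame(columns=["chrom", "bin", "start", "count"])
    return pd.concat(rows, ignore_index=True)


def _in_run_snps(calls: np.ndarray, params: TractParams) -> np.ndarray:
    """Boolean in-run flag per SNP from the sliding-window vote."""
    m = len(calls)
    w = params.window_size
    if m < w:
        return np.zeros(m, dtype=bool)
    hom = ((calls == HOM_REF) | (calls == HOM_ALT)).astype(int)
    miss = (calls < 0).astype(int)
    kern = np.ones(w, dtype=int)
    hom_w = np.convolve(hom, kern, mode="valid")
    miss_w = np.convolve(miss, kern, mode="valid")
    het_win = ((hom_w <= params.max_opp_window)
               & (miss_w <= params.max_miss_window)).astype(int)
    cum = np.concatenate([[0], np.cumsum(het_win)])
    idx = np.arange(m)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, m - w)
    n_win = hi - lo + 1
    n_het = cum[hi + 1] - cum[lo]
    return n_het / n_win > params.threshold


def detect_het_tracts(gm: GenotypeMatrix,
                      params: TractParams | None = None,
                      accessions=None) -> pd.DataFrame:
    """Per-accession runs of heterozygosity.

    Columns: accession, chrom, start, end, n_snps (het calls in the run),
    length_bp. Chromosomes with fewer SNPs than the window size yield no
    tracts (logged).
    """
    params = params or TractParams()
    if accessions is None:
        accessions = gm.accessions
    rows = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        pos = gm.pos[sl]
        if len(pos) < params.window_size:
            log.info("detect_het_tracts: %s has %d SNPs < window %d, skipped",
                     chrom, len(pos), params.window_size)
            continue
        for acc in accessions:
            a = gm.accessions.index(acc)
            calls = gm.calls[sl, a]
            in_run = _in_run_snps(calls, params)
            for s, e in _segments(in_run, pos, params.max_gap):
                tract = _trim_to_het(calls, pos, s, e, params)
                if tract is not None:
                    rows.append((acc, chrom) + tract)
    return pd.DataFrame(rows, columns=["accession", "chrom", "start", "end",
                                       "n_snps", "length_bp"])


def _segments(in_run: np.ndarray, pos: np.ndarray, max_gap: int):
    """Maximal stretches of consecutive in-run SNPs, split at large gaps."""
    idx = np.flatnonzero(in_run)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero((np.diff(idx) > 1)
                            | (np.diff(pos[idx]) > max_gap)) + 1
    for seg in np.split(idx, breaks):
        yield int(seg[0]), int(seg[-1])


def _trim_to_het(calls, pos, s, e, params):
    het_ix = np.flatnonzero(calls[s:e + 1] == HET) + s
    if len(het_ix) == 0:
        return None
    s, e = int(het_ix[0]), int(het_ix[-1])
    n_het = len(het_ix)
    length = int(pos[e] - pos[s] + 1)
    if n_het < params.min_snp or length < params.min_length:
        return None
    if n_het / (length / 1000) < params.min_density:
        return None
    return int(pos[s]), int(pos[e]), n_het, length


def tract_sharing(tracts: pd.DataFrame,
                  min_reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Per-tract carrier counts by reciprocal overlap across accessions.

    Two tracts from different accessions are shared when each covers at
    least ``min_reciprocal_overlap`` of the other. Adds a ``sharing``
    column (number of distinct accessions with a matching tract, the tract's
    own accession included).
    """
    out = tracts.copy().reset_index(drop=True)
    sharing = np.ones(len(out), dtype=int)
    for chrom, grp in out.groupby("chrom"):
        ix = grp.index.to_numpy()
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        acc = grp["accession"].to_numpy()
        for i in range(len(ix)):
            partners = {acc[i]}
            for j in range(len(ix)):
                if acc[j] == acc[i]:
                    continue
                ov = min(e[i], e[j]) - max(s[i], s[j]) + 1
                if ov <= 0:
                    continue
                if (ov >= min_reciprocal_overlap * (e[i] - s[i] + 1)
                        and ov >= min_reciprocal_overlap * (e[j] - s[j] + 1)):
                    partners.add(acc[j])
            sharing[ix[i]] = len(partners)
    out["sharing"] = sharing
    return out


def tract_length_summary(tracts: pd.DataFrame,
                         quantiles=(0.1, 0.25, 0.5, 0.75, 0.9)) -> pd.DataFrame:
    """Tract-length quantiles, the Fig-S2-style distribution summary."""
    if len(tracts) == 0:
        return pd.DataFrame(dict(quantile=list(quantiles),
                                 length_bp=[np.nan] * len(quantiles)))
    q = tracts["length_bp"].quantile(list(quantiles))
    return pd.DataFrame(dict(quantile=list(quantiles),
                             length_bp=q.to_numpy()))
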