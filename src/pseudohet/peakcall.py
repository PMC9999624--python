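"""Turning association scans into discrete duplication-location calls.

The -log10 p signal of one scan is gridded onto fixed-width bins per
chromosome (maximum value per bin, empty bins zero), smoothed by keeping
only the lowest Fourier components, and local maxima of the smoothed signal
become candidate peaks. Each peak is represented by its strongest SNP
within +-10 kb, classified *cis* (within 50 kb of the focal pseudo-SNP on
the same chromosome, i.e. tagging the template locus) or *trans* (tagging
the duplicate copy elsewhere), and peaks are pooled per gene into a
cis_only / trans_only / both / none category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PeakParams:
    pc_keep_comp: float = 0.05  # fraction of low-frequency components kept
    bin_bp: int = 1000
    peak_floor: float = 4.0  # on the smoothed -log10 p scale
    search_halfwidth: int = 10_000
    logp_final: float = 20.0
    maf_final: float = 0.1
    cis_radius: int = 50_000

    def __post_init__(self):
        if not 0 < self.pc_keep_comp <= 1:
            raise ValueError("pc_keep_comp must be in (0, 1]")
        if min(self.bin_bp, self.search_halfwidth, self.cis_radius) <= 0:
            raise ValueError("radii must be positive")


@dataclass
class PeakCall:
    pseudo_snp: str
    pseudo_chrom: str
    pseudo_pos: int
    peak_chrom: str
    peak_center: int  # bp
    top_snp: str
    top_pos: int
    minus_log10_p: float
    maf: float
    label: str  # {"cis", "trans"}


def fft_smooth(signal: np.ndarray, pc_keep_comp: float,
               clip: bool = False) -> np.ndarray:
    """Low-pass smooth: keep the ceil(pc*len) lowest Fourier components.

    Conjugate symmetry is preserved (real output). The operation is exactly
    linear; ``clip=True`` additionally floors the result at 0.
    """
    x = np.asarray(signal, dtype=np.float64)
    n = len(x)
    if n < 4:
        raise ValueError("signal length must be >= 4")
    n_keep = int(np.ceil(pc_keep_comp * n))
    F = np.fft.rfft(x)
    if n_keep < len(F):
        F[n_keep:] = 0
    out = np.fft.irfft(F, n=n)
    return np.clip(out, 0, None) if clip else out


def detect_peaks(smoothed: np.ndarray, peak_floor: float) -> list[int]:
    """Strict interior local maxima of height >= peak_floor.

    Plateaus (runs of equal values higher than both neighbours) report
    their central bin. Signal ends never count as peaks.
    """
    x = np.asarray(smoothed, dtype=np.float64)
    peaks = []
    i, n = 0, len(x)
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        interior = i > 0 and j < n - 1
        if (interior and x[i] >= peak_floor
                and x[i - 1] < x[i] and x[j + 1] < x[i]):
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def grid_signal(scan_df: pd.DataFrame, chrom: str, bin_bp: int,
                chrom_length: int | None = None) -> np.ndarray:
    """Maximum -log10 p per fixed-width bin for one chromosome."""
    sub = scan_df[scan_df["chrom"] == chrom]
    if chrom_length is None:
        chrom_length = int(sub["pos"].max()) if len(sub) else bin_bp
    n_bins = max(4, int(np.ceil(chrom_length / bin_bp)))
    sig = np.zeros(n_bins)
    if len(sub):
        bins = np.minimum((sub["pos"].to_numpy() - 1) // bin_bp, n_bins - 1)
        np.maximum.at(sig, bins, sub["minus_log10_p"].to_numpy())
    return sig


def top_snp_in_window(scan_df: pd.DataFrame, chrom: str, center_bp: int,
                      halfwidth: int = 10_000):
    """Row of the strongest SNP within +-halfwidth; ties -> smaller pos.

    Returns None when the window is empty (peak discarded upstream).
    """
    sub = scan_df[(scan_df["chrom"] == chrom)
                  & (scan_df["pos"] >= center_bp - halfwidth)
                  & (scan_df["pos"] <= center_bp + halfwidth)]
    if len(sub) == 0:
        return None
    best = sub["minus_log10_p"].max()
    ties = sub[sub["minus_log10_p"] == best]
    return ties.loc[ties["pos"].idxmin()]


def classify_peak(pseudo_chrom: str, pseudo_pos: int, top_chrom: str,
                  top_pos: int, cis_radius: int = 50_000) -> str:
    """cis iff same chromosome and distance <= cis_radius, else trans."""
    if top_chrom == pseudo_chrom and abs(top_pos - pseudo_pos) <= cis_radius:
        return "cis"
    return "trans"


def call_peaks(scan_df: pd.DataFrame, pseudo_snp: str, pseudo_chrom: str,
               pseudo_pos: int, params: PeakParams | None = None,
               chrom_lengths: dict | None = None) -> list[PeakCall]:
    """Full per-phenotype peak calling on a (pre-filtered) scan."""
    params = params or PeakParams()
    calls = []
    for chrom in scan_df["chrom"].unique():
        L = chrom_lengths.get(chrom) if chrom_lengths else None
        sig = grid_signal(scan_df, chrom, params.bin_bp, L)
        smoothed = fft_smooth(sig, params.pc_keep_comp, clip=True)
        for b in detect_peaks(smoothed, params.peak_floor):
            center = int(b * params.bin_bp + params.bin_bp // 2)
            top = top_snp_in_window(scan_df, chrom, center,
                                    params.search_halfwidth)
            if top is None:
                log.info("peak at %s:%d discarded: empty +-%d bp window",
                         chrom, center, params.search_halfwidth)
                continue
            label = classify_peak(pseudo_chrom, pseudo_pos, chrom,
                                  int(top["pos"]), params.cis_radius)
            calls.append(PeakCall(pseudo_snp, pseudo_chrom, pseudo_pos,
                                  chrom, center, str(top["snp_id"]),
                                  int(top["pos"]),
                                  float(top["minus_log10_p"]),
                                  float(top["maf"]), label))
    return calls


@dataclass
class GeneDuplicationCall:
    gene_id: str
    category: str  # {"cis_only", "trans_only", "both", "none"}
    peaks: list = field(default_factory=list)


def summarize_gene(gene_id: str, calls: list[PeakCall],
                   logp_final: float = 20.0,
                   maf_final: float = 0.1) -> GeneDuplicationCall:
    """Pool the peak calls of all pseudo-SNPs of one gene.

    Only peaks whose top SNP passes the final thresholds survive; the gene
    category follows from the surviving label set, so gene categories
    always partition the gene set.
    """
    surviving = [c for c in calls
                 if c.minus_log10_p >= logp_final and c.maf >= maf_final]
    labels = {c.label for c in surviving}
    if labels == {"cis"}:
        cat = "cis_only"
    elif labels == {"trans"}:
        cat = "trans_only"
    elif labels == {"cis", "trans"}:
        cat = "both"
    else:
        cat = "none"
    return GeneDuplicationCall(gene_id, cat, surviving)


def peaks_table(calls: list[PeakCall], gene_of: dict) -> pd.DataFrame:
    rows = [dict(pseudo_snp=c.pseudo_snp, gene=gene_of.get(c.pseudo_snp, ""),
                 peak_chrom=c.peak_chrom, center=c.peak_center,
                 top_snp=c.top_snp, top_pos=c.top_pos,
                 minus_log10_p=c.minus_log10_p, maf=c.maf, label=c.label)
            for c in calls]
    return pd.DataFrame(rows, columns=["pseudo_snp", "gene", "peak_chrom",
                                       "center", "top_snp", "top_pos",
                                       "minus_log10_p", "maf", "label"])
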