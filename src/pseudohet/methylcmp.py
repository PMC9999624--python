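"""Quantifying methylation-call artifacts caused by cryptic copy number.

When bisulfite reads of a duplicated gene are mapped to a reference genome
lacking the extra copy, reads from both copies collapse onto one locus and
the measured methylation level becomes a coverage-weighted mixture of the
copies' true levels. Comparing the weighted methylation level under
reference-collapsed mapping with the level obtained by mapping to the
accession's own genome quantifies the artifact, stratified by the gene's
copy number.

The weighted level of a unit (gene body or 200 bp window) is sum(c_i) /
sum(t_i) over its cytosines with depth >= 3; a gene is called
differentially methylated between mapping targets when the levels differ
by more than 0.05 (CG context) or 0.03 (CHG), strict inequality.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN_DEPTH = 3
DIFF_THRESHOLD = {"CG": 0.05, "CHG": 0.03}


def weighted_level(depth, methylated, min_depth: int = MIN_DEPTH) -> float:
    """Sum(c)/Sum(t) over cytosines with depth >= min_depth; NaN if none."""
    t = np.asarray(depth, dtype=np.float64)
    c = np.asarray(methylated, dtype=np.float64)
    if np.any(c > t) or np.any(c < 0):
        raise ValueError("need 0 <= methylated <= depth")
    keep = t >= min_depth
    denom = t[keep].sum()
    if denom == 0:
        return float("nan")
    return float(c[keep].sum() / denom)


def profile_levels(records: pd.DataFrame, unit: str = "gene",
                   window_bp: int = 200,
                   min_depth: int = MIN_DEPTH) -> pd.DataFrame:
    """Weighted levels per (unit, accession, context, mapping_target[, copy]).

    ``records`` holds per-cytosine rows (gene_id, chrom, pos, context,
    depth, methylated, mapping_target, accession, copy). ``unit="window"``
    groups by 200 bp windows instead of gene bodies.
    """
    df = records.copy()
    if unit == "window":
        df["unit"] = (df["gene_id"].astype(str) + ":w"
                      + ((df["pos"] - 1) // window_bp).astype(str))
    else:
        df["unit"] = df["gene_id"]
    keys = ["unit", "accession", "context", "mapping_target", "copy"]
    rows = []
    for key, grp in df.groupby(keys, dropna=False, sort=True):
        kept = grp[grp["depth"] >= min_depth]
        level = (kept["methylated"].sum() / kept["depth"].sum()
                 if kept["depth"].sum() > 0 else np.nan)
        rows.append(dict(zip(keys, key)) | dict(
            level=level, n_cytosines=int((grp["depth"] >= min_depth).sum())))
    return pd.DataFrame(rows)


def differential_call(level_ref: float, level_own: float,
                      context: str) -> str:
    """"differential" iff |ref - own| exceeds the context threshold (strict)."""
    thr = DIFF_THRESHOLD[context]
    if np.isnan(level_ref) or np.isnan(level_own):
        return "undefined"
    return "differential" if abs(level_ref - level_own) > thr else "concordant"


def discordance_table(profiles: pd.DataFrame, copy_numbers: pd.DataFrame,
                      gene_universe: list | None = None) -> pd.DataFrame:
    """Copy-number-stratified differential-methylation summary.

    ``profiles``: gene-level output of :func:`profile_levels` (both mapping
    targets). ``copy_numbers``: columns accession, gene_id, category in
    {"0", "1", ">1"}. For multi-copy genes the own-genome level uses the
    copy syntenic to the reference position ("source" copy) when labelled,
    else the record is flagged ambiguous and the first copy is used.

    Returns one row per (accession, context): gene counts per copy-number
    category and, within the 1-copy and multi-copy strata, the fraction of
    differential calls (genes with an undefined level in either target are
    excluded from the fractions).
    """
    cn = {(r.accession, r.gene_id): r.category
          for r in copy_numbers.itertuples()}
    ref = profiles[profiles["mapping_target"] == "reference"]
    own = profiles[profiles["mapping_target"] == "own_genome"]
    if gene_universe is None:
        gene_universe = sorted(profiles["unit"].unique())

    rows = []
    for (acc, ctx), ref_grp in ref.groupby(["accession", "context"]):
        ref_lv = {r.unit: r.level for r in ref_grp.itertuples()}
        own_grp = own[(own["accession"] == acc) & (own["context"] == ctx)]
        own_lv: dict[str, float] = {}
        ambiguous = set()
        for unit, g in own_grp.groupby("unit"):
            if len(g) == 1:
                own_lv[unit] = float(g["level"].iloc[0])
            elif (g["copy"] == "source").any():
                own_lv[unit] = float(g[g["copy"] == "source"]["level"].iloc[0])
            else:
                own_lv[unit] = float(g["level"].iloc[0])
                ambiguous.add(unit)
        counts = {"0": 0, "1": 0, ">1": 0}
        n_diff = {"1": 0, ">1": 0}
        n_called = {"1": 0, ">1": 0}
        for gene in gene_universe:
            cat = cn.get((acc, gene), "0" if gene not in own_lv else "1")
            counts[cat] += 1
            if cat == "0":
                continue
            call = differential_call(ref_lv.get(gene, np.nan),
                                     own_lv.get(gene, np.nan), ctx)
            if call == "undefined":
                continue
            n_called[cat] += 1
            n_diff[cat] += call == "differential"
        rows.append(dict(
            accession=acc, context=ctx, n_genes=len(gene_universe),
            copies_0=counts["0"], copies_1=counts["1"],
            copies_multi=counts[">1"],
            frac_differential_1=(n_diff["1"] / n_called["1"]
                                 if n_called["1"] else np.nan),
            frac_differential_multi=(n_diff[">1"] / n_called[">1"]
                                     if n_called[">1"] else np.nan),
            n_compared_1=n_called["1"], n_compared_multi=n_called[">1"],
            n_ambiguous=len(ambiguous)))
    return pd.DataFrame(rows)
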