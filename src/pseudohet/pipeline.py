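"""End-to-end orchestration: simulate -> detect -> map -> confirm -> methyl.

Every stage writes plain TSV outputs into the run directory and can be
re-run in isolation from the previous stage's files (the CLI wires this
up); all randomness flows from the single config seed through named
per-module generator streams, so a full run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dupconfirm, hetscan, methylcmp, mmgwas, peakcall, popsim, pseudosnp
from ._util import read_table, write_table
from .hetscan import TractParams
from .io_formats import write_fasta, write_gff, write_vcf
from .peakcall import PeakParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One flat block of every stage's tunable parameters."""

    seed: int
    # population
    n_accessions: int = 300
    chrom_lengths: tuple = (1_000_000, 1_000_000)
    snp_density: float = 0.0025
    n_founders: int = 8
    recomb_rate: float = 5e-6
    n_genes_per_chrom: int = 20
    gene_length: int = 1000
    missing_rate: float = 0.0
    # planted events
    n_trans_events: int = 1
    n_tandem_events: int = 0
    divergence: float = 0.05
    carrier_freq: float = 0.3
    het_fn_rate: float = 0.0
    # pseudo-SNP filter
    pseudo_freq_threshold: float = 0.05
    # mixed model + raw scan filter
    kinship_method: str = "ibs"
    maf_filter: float = 0.05
    logp_filter: float = 4.0
    # tract calling
    tract: TractParams = field(default_factory=TractParams)
    # peak calling
    peaks: PeakParams = field(default_factory=PeakParams)
    # confirmation
    n_confirm_accessions: int = 2
    confirm_radius: int = 20_000
    align_min_identity: float = 70.0
    align_min_cov: float = 0.70
    # methylation
    methyl_depth: float = 30.0
    n_methyl_accessions: int = 6
    n_methyl_control_genes: int = 10
    # read pairs
    n_read_pairs: int = 10
    insert_size: int = 400
    # stage switches
    run_confirm: bool = True
    run_methyl: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain ``key = value`` config file (seed is required)."""
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        if "seed" not in raw:
            raise ValueError("config must set seed")
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key}")
            kwargs[key] = _coerce(value, getattr(cls(seed=0), key))
        return cls(**kwargs)

    def sim_config(self) -> popsim.SimConfig:
        # founders 0..n_events-1 carry one event each at ~carrier_freq
        weights = None
        n_events = self.n_trans_events + self.n_tandem_events
        if self.n_founders > 1 and n_events:
            n_w = min(n_events, self.n_founders - 1,
                      int(0.9 / max(self.carrier_freq, 1e-9)))
            n_w = max(n_w, 1)
            rest = (1 - n_w * self.carrier_freq) / (self.n_founders - n_w)
            weights = (self.carrier_freq,) * n_w + (rest,) * (self.n_founders - n_w)
        return popsim.SimConfig(
            seed=self.seed, n_accessions=self.n_accessions,
            chrom_lengths=tuple(self.chrom_lengths),
            snp_density=self.snp_density, n_founders=self.n_founders,
            recomb_rate=self.recomb_rate, founder_weights=weights,
            n_genes_per_chrom=self.n_genes_per_chrom,
            gene_length=self.gene_length, missing_rate=self.missing_rate)


def _coerce(value: str, default):
    if isinstance(default, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    if isinstance(default, tuple):
        return tuple(int(v) for v in value.replace(",", " ").split())
    if dataclasses.is_dataclass(default):
        raise ValueError("nested parameter blocks are set programmatically")
    return value


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> popsim.Simulation:
    """Build the population, plant events, emit VCF/GFF/FASTA/truth files."""
    sim = popsim.simulate_population(cfg.sim_config())
    eligible = _genes_with_snps(sim)
    n_events = cfg.n_trans_events + cfg.n_tandem_events
    if n_events > len(eligible):
        raise ValueError("more events requested than genes with SNPs")
    step = max(1, len(eligible) // max(n_events, 1))
    chosen = [eligible[(i * step) % len(eligible)] for i in range(n_events)]
    for i, gene_id in enumerate(chosen):
        mode = "trans" if i < cfg.n_trans_events else "tandem"
        popsim.plant_duplication(
            sim, gene_id, mode=mode, divergence=cfg.divergence,
            carrier_founder=i % cfg.n_founders, origin_founder=(i + 1) % cfg.n_founders,
            het_fn_rate=cfg.het_fn_rate)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(sim.genotypes, outdir / "sim.vcf")
    write_gff(sim.annotation, outdir / "genes.gff3")
    write_fasta(sim.reference_fasta(), outdir / "reference.fa")
    write_table(sim.truth_table(), outdir / "truth_events.tsv")
    return sim


def _genes_with_snps(sim: popsim.Simulation) -> list[str]:
    gm = sim.genotypes
    out = []
    for g in sim.annotation:
        sl = gm.chrom_slice(g.chrom)
        n = int(((gm.pos[sl] >= g.start) & (gm.pos[sl] <= g.end)).sum())
        if n >= 1:
            out.append(g.gene_id)
    return out


def stage_hetscan(gm, cfg: RunConfig, outdir: Path) -> dict:
    summary = hetscan.summarize_het(gm)
    density = hetscan.het_density(gm, window_bp=100_000)
    tracts = hetscan.detect_het_tracts(gm, cfg.tract)
    shared = hetscan.tract_sharing(tracts) if len(tracts) else tracts.assign(sharing=[])
    write_table(summary, outdir / "het_summary.tsv")
    write_table(density, outdir / "density.tsv")
    write_table(shared, outdir / "tracts.tsv")
    return dict(summary=summary, density=density, tracts=shared)


def stage_filter(gm, annotation, cfg: RunConfig, outdir: Path):
    pseudo, funnel = pseudosnp.filter_pseudo_snps(
        gm, annotation, freq_threshold=cfg.pseudo_freq_threshold)
    write_table(pseudo, outdir / "pseudo_snps.tsv")
    write_table(pd.DataFrame([funnel]), outdir / "funnel_counts.tsv")
    return pseudo, funnel


def stage_gwas(gm, pseudo: pd.DataFrame, cfg: RunConfig, outdir: Path) -> dict:
    """One filtered association scan per pseudo-SNP phenotype.

    Identical phenotypes (pseudo-SNPs injected by the same event share one
    carrier set) are scanned once and the result reused.
    """
    scans: dict[str, pd.DataFrame] = {}
    if len(pseudo) == 0:
        return scans
    kin = mmgwas.compute_kinship(gm, method=cfg.kinship_method)
    cache: dict[bytes, pd.DataFrame] = {}
    scan_dir = outdir / "scans"
    scan_dir.mkdir(parents=True, exist_ok=True)
    for snp_id in pseudo["snp_id"]:
        y = pseudosnp.make_phenotype(gm, snp_id)
        key = y.tobytes()
        if key not in cache:
            vc = mmgwas.fit_null(y.astype(float), kin)
            raw = mmgwas.scan(y.astype(float), gm, kin, vc)
            cache[key] = mmgwas.filter_scan(raw, cfg.maf_filter, cfg.logp_filter)
        scans[snp_id] = cache[key]
        write_table(scans[snp_id],
                    scan_dir / f"scan_{snp_id.replace(':', '_')}.tsv")
    return scans


def stage_peaks(scans: dict, pseudo: pd.DataFrame, cfg: RunConfig,
                outdir: Path, chrom_lengths: dict | None = None):
    gene_of = dict(zip(pseudo["snp_id"], pseudo["gene_id"]))
    all_calls: list[peakcall.PeakCall] = []
    for row in pseudo.itertuples():
        scan_df = scans.get(row.snp_id)
        if scan_df is None or len(scan_df) == 0:
            continue
        all_calls.extend(peakcall.call_peaks(
            scan_df, row.snp_id, row.chrom, int(row.pos), cfg.peaks,
            chrom_lengths))
    by_gene: dict[str, list] = {}
    for c in all_calls:
        by_gene.setdefault(gene_of[c.pseudo_snp], []).append(c)
    gene_calls = {g: peakcall.summarize_gene(g, calls, cfg.peaks.logp_final,
                                             cfg.peaks.maf_final)
                  for g, calls in by_gene.items()}
    write_table(peakcall.peaks_table(all_calls, gene_of), outdir / "peaks.tsv")
    summary = pd.DataFrame(
        [dict(gene=g, category=gc.category, n_peaks=len(gc.peaks))
         for g, gc in sorted(gene_calls.items())],
        columns=["gene", "category", "n_peaks"])
    write_table(summary, outdir / "gene_summary.tsv")
    return all_calls, gene_calls


def stage_confirm(sim: popsim.Simulation, gene_calls: dict, cfg: RunConfig,
                  outdir: Path) -> pd.DataFrame:
    """Validate surviving peaks in carrier assemblies; copy-number table."""
    ref = sim.reference_fasta()
    rows, cn_rows = [], []
    for event in sim.events:
        gc = gene_calls.get(event.source_gene)
        if gc is None or not gc.peaks:
            continue
        best = max(gc.peaks, key=lambda p: p.minus_log10_p)
        gene = sim.gene(event.source_gene)
        gene_seq = ref[gene.chrom][gene.start - 1:gene.end]
        carriers = list(event.carriers)[:cfg.n_confirm_accessions]
        for acc in carriers:
            genome = popsim.emit_assembly(sim, acc)
            index = dupconfirm.build_genome_index(genome)
            conf = dupconfirm.confirm_prediction(
                gene_seq, best.peak_chrom, best.top_pos, ref, genome,
                radius=cfg.confirm_radius, source_chrom=gene.chrom,
                source_pos=(gene.start + gene.end) // 2,
                min_identity=cfg.align_min_identity,
                min_cov=cfg.align_min_cov, query_id=event.source_gene,
                index=index)
            rows.append(dict(
                gene=event.source_gene, accession=acc, mode=event.mode,
                peak_chrom=best.peak_chrom, peak_pos=best.top_pos,
                confirmed=conf.confirmed,
                confirmed_nonsyntenic=conf.confirmed_nonsyntenic,
                n_matches=len(conf.matches)))
            depth = popsim.emit_depth(sim, acc)
            est = dupconfirm.copy_number(
                event.source_gene, gene_seq, acc, genome, depth,
                (gene.chrom, gene.start, gene.end),
                cfg.align_min_identity, cfg.align_min_cov, index=index)
            cn_rows.append(dict(gene=event.source_gene, accession=acc,
                                n_matches=est.n_matches,
                                coverage_ratio=est.coverage_ratio,
                                category=est.category))
    conf_df = pd.DataFrame(rows, columns=["gene", "accession", "mode",
                                          "peak_chrom", "peak_pos",
                                          "confirmed", "confirmed_nonsyntenic",
                                          "n_matches"])
    cn_df = pd.DataFrame(cn_rows, columns=["gene", "accession", "n_matches",
                                           "coverage_ratio", "category"])
    write_table(conf_df, outdir / "confirmations.tsv")
    write_table(cn_df, outdir / "copy_number.tsv")
    return conf_df


def stage_methyl(sim: popsim.Simulation, cfg: RunConfig, outdir: Path):
    """Methylation artifact quantification on a tractable gene subset.

    The gene universe is every candidate duplicated gene plus a fixed
    number of single-copy control genes; accessions are the carriers of
    planted events first, topped up to ``n_methyl_accessions``.
    """
    dup_genes = [e.source_gene for e in sim.events]
    controls = [g.gene_id for g in sim.annotation if g.gene_id not in dup_genes]
    universe = dup_genes + controls[:cfg.n_methyl_control_genes]
    carriers = [a for e in sim.events for a in e.carriers]
    accs = list(dict.fromkeys(carriers))[:max(1, cfg.n_methyl_accessions // 2)]
    for a in sim.genotypes.accessions:
        if len(accs) >= cfg.n_methyl_accessions:
            break
        if a not in accs:
            accs.append(a)
    records = popsim.emit_methylation(sim, cfg.methyl_depth, accessions=accs,
                                      genes=universe)
    for target in ("reference", "own_genome"):
        write_table(records[records["mapping_target"] == target],
                    outdir / f"methylation_{target}.tsv")
    profiles = methylcmp.profile_levels(records)
    cn_rows = []
    carrier_of = {g: set() for g in universe}
    for e in sim.events:
        carrier_of[e.source_gene].update(e.carriers)
    for acc in accs:
        for g in universe:
            cat = ">1" if acc in carrier_of.get(g, ()) else "1"
            cn_rows.append(dict(accession=acc, gene_id=g, category=cat))
    cn = pd.DataFrame(cn_rows)
    table = methylcmp.discordance_table(profiles, cn, gene_universe=universe)
    write_table(profiles, outdir / "levels.tsv")
    write_table(table, outdir / "discordance_summary.tsv")
    return profiles, table


# ---------------------------------------------------------------------------
# run-all + recovery report
# ---------------------------------------------------------------------------

def recovery_report(sim: popsim.Simulation, gene_calls: dict,
                    conf_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per planted event: was it detected, where, and was it confirmed."""
    rows = []
    for e in sim.events:
        gc = gene_calls.get(e.source_gene)
        expected = "trans" if e.mode == "trans" else "cis"
        detected = gc is not None and gc.category != "none"
        label_ok = bool(gc and any(p.label == expected for p in gc.peaks))
        dist = np.nan
        if gc:
            cands = [p for p in gc.peaks if p.label == expected
                     and p.peak_chrom == e.insertion_chrom]
            if cands:
                dist = min(abs(p.top_pos - e.insertion_pos) for p in cands)
        confirmed = np.nan
        if conf_df is not None and len(conf_df):
            sub = conf_df[conf_df["gene"] == e.source_gene]
            if len(sub):
                col = ("confirmed_nonsyntenic" if e.mode == "trans"
                       else "confirmed")
                confirmed = bool(sub[col].any())
        rows.append(dict(source_gene=e.source_gene, mode=e.mode,
                         insertion_chrom=e.insertion_chrom,
                         insertion_pos=e.insertion_pos,
                         n_carriers=len(e.carriers), detected=detected,
                         label_correct=label_ok, peak_distance_bp=dist,
                         confirmed=confirmed))
    return pd.DataFrame(rows, columns=["source_gene", "mode",
                                       "insertion_chrom", "insertion_pos",
                                       "n_carriers", "detected",
                                       "label_correct", "peak_distance_bp",
                                       "confirmed"])


def run_all(cfg: RunConfig, outdir) -> dict:
    """Run every stage; returns the in-memory stage products."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        sim = stage_simulate(cfg, outdir)
    except Exception as err:
        raise RuntimeError(f"stage simulate failed (seed={cfg.seed})") from err
    gm = sim.genotypes
    chrom_lengths = dict(zip(cfg.sim_config().chrom_names, cfg.chrom_lengths))
    products = dict(sim=sim)
    for name, fn in [
            ("hetscan", lambda: stage_hetscan(gm, cfg, outdir)),
            ("filter", lambda: stage_filter(gm, sim.annotation, cfg, outdir)),
    ]:
        try:
            products[name] = fn()
        except Exception as err:
            raise RuntimeError(f"stage {name} failed (seed={cfg.seed})") from err
    pseudo = products["filter"][0]
    try:
        scans = stage_gwas(gm, pseudo, cfg, outdir)
        products["gwas"] = scans
    except Exception as err:
        raise RuntimeError(f"stage gwas failed (seed={cfg.seed})") from err
    try:
        all_calls, gene_calls = stage_peaks(scans, pseudo, cfg, outdir,
                                            chrom_lengths)
        products["peaks"] = (all_calls, gene_calls)
    except Exception as err:
        raise RuntimeError(f"stage peaks failed (seed={cfg.seed})") from err
    conf_df = None
    if cfg.run_confirm and cfg.n_confirm_accessions > 0:
        try:
            conf_df = stage_confirm(sim, gene_calls, cfg, outdir)
            products["confirm"] = conf_df
        except Exception as err:
            raise RuntimeError(f"stage confirm failed (seed={cfg.seed})") from err
    if cfg.run_methyl:
        try:
            products["methyl"] = stage_methyl(sim, cfg, outdir)
        except Exception as err:
            raise RuntimeError(f"stage methyl failed (seed={cfg.seed})") from err
    if sim.events:
        pairs = popsim.emit_read_pairs(sim, sim.events[0], cfg.n_read_pairs,
                                       cfg.insert_size)
        write_table(pairs, outdir / "read_pairs.tsv")
        presence = presence_table(pairs, pairs.attrs["junction"])
        write_table(presence, outdir / "presence.tsv")
        products["presence"] = presence
    report = recovery_report(sim, gene_calls, conf_df)
    write_table(report, outdir / "recovery_report.tsv")
    products["recovery"] = report
    return products


def presence_table(pairs: pd.DataFrame, junction: int) -> pd.DataFrame:
    rows = []
    for acc, grp in pairs.groupby("accession", sort=True):
        call, n = dupconfirm.insertion_present(grp, junction)
        rows.append(dict(accession=acc, call=call, n_spanning=n))
    return pd.DataFrame(rows, columns=["accession", "call", "n_spanning"])
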