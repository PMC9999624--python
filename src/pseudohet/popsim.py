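"""Forward simulator for a fully selfed population with cryptic duplications.

The model
---------
Each accession of a selfing species is a recombinant mosaic of ``n_founders``
ancestral haplotypes and is homozygous at every site: real residual
heterozygosity is absent by construction. A *duplication event* copies a gene
(its template haplotype) to a new location. Because a short-read reference
genome lacks the extra copy, reads from the copy pile up on the template
locus in carrier accessions and any base difference between copy and carrier
haplotype is called as a spurious heterozygous genotype (a *pseudo-SNP*).

Two event modes are simulated:

* ``trans`` -- a dispersed copy descending from one founder haplotype (the
  "origin" founder). Carriers whose own allele differs from the origin
  allele at a segregating site become pseudo-heterozygous immediately, and
  copy-specific divergence mutations add further pseudo-SNPs.
* ``tandem`` -- a local copy of the carrier's own haplotype. Only divergence
  mutations can create pseudo-SNPs, so a fresh tandem copy (divergence 0)
  injects nothing.

Divergence mutations falling where the population has no SNP create *new*
sites that are heterozygous in carriers and hom-ref everywhere else.

Carriers are exactly the accessions whose founder mosaic at the insertion
point equals ``carrier_founder``. Because the insertion arose once, it is in
complete LD with its junction; this is materialised as a biallelic tag SNP
at the insertion point (the carrier-founder indicator), which is what makes
the downstream GWAS well-posed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import stream_rng
from .io_formats import (GeneAnnotation, GenotypeMatrix, HET, HOM_ALT,
                         HOM_REF, MISSING)

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults give strong local LD (founder blocks of ~200 kb) at a SNP
    density of 2.5 SNPs/kb, the regime in which tag SNPs make planted
    duplications mappable by association.
    """

    seed: int
    n_accessions: int = 200
    chrom_lengths: tuple = (1_000_000, 1_000_000)
    snp_density: float = 0.0025  # SNPs per bp
    n_founders: int = 8
    recomb_rate: float = 5e-6  # crossovers per bp per mosaic draw
    founder_weights: tuple | None = None  # sampling weights of founders
    n_genes_per_chrom: int = 20
    gene_length: int = 1000
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_founders < 1:
            raise ValueError("counts must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        for L in self.chrom_lengths:
            if self.snp_density * L < 10:
                raise ValueError("need snp_density * length >= 10 per chromosome")
        if self.founder_weights is not None:
            w = np.asarray(self.founder_weights, float)
            if len(w) != self.n_founders or (w <= 0).any():
                raise ValueError("founder_weights must be positive, one per founder")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    def weights(self) -> np.ndarray:
        if self.founder_weights is None:
            w = np.ones(self.n_founders)
        else:
            w = np.asarray(self.founder_weights, float)
        return w / w.sum()


@dataclass
class DuplicationEvent:
    """Ground truth for one planted duplication."""

    source_gene: str
    chrom: str
    start: int
    end: int
    insertion_chrom: str
    insertion_pos: int
    mode: str  # {"trans", "tandem"}
    carrier_founder: int
    divergence: float
    carriers: tuple = ()
    origin_founder: int = 0
    # realised divergence mutations of the copy: absolute pos -> base (ACGT)
    div_mutations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("trans", "tandem"):
            raise ValueError(f"unknown mode {self.mode}")
        if self.mode == "tandem":
            d = min(abs(self.insertion_pos - self.start),
                    abs(self.insertion_pos - self.end))
            if self.insertion_chrom != self.chrom or d > 20_000:
                raise ValueError("tandem insertion must lie within 20 kb of source")


class Simulation:
    """Container for one simulated population and its planted truth.

    Attributes
    ----------
    genotypes : GenotypeMatrix
        Observed calls, including injected pseudo-heterozygosity.
    clean : GenotypeMatrix
        The true homozygous genotypes (no injection); substrate for
        per-accession assemblies.
    events : list[DuplicationEvent]
    annotation : list[GeneAnnotation]
    reference : dict[str, np.ndarray]
        Reference chromosome sequences as uint8 ASCII arrays.
    injected_by : np.ndarray
        (n_snps, n_accessions) int16; 0 = untouched, k = call injected by
        events[k-1].
    """

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.events: list[DuplicationEvent] = []
        self.annotation: list[GeneAnnotation] = []
        self.reference: dict[str, np.ndarray] = {}
        # mosaics: per chrom, per accession: (breakpoints, founder states)
        self._mosaic: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        self._founder_alleles: dict[str, np.ndarray] = {}  # (n_founders, m)

    # -- helpers -------------------------------------------------------
    def founder_at(self, acc_index: int, chrom: str, pos) -> np.ndarray:
        """Founder state of an accession's mosaic at bp position(s)."""
        bp, st = self._mosaic[chrom][acc_index]
        return st[np.searchsorted(bp, np.asarray(pos), side="right") - 1]

    def carrier_indicator(self, chrom: str, pos: int, founder: int) -> np.ndarray:
        return np.array([self.founder_at(i, chrom, pos) == founder
                         for i in range(self.cfg.n_accessions)], dtype=bool)

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.annotation:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def reference_fasta(self) -> dict[str, str]:
        return {c: a.tobytes().decode() for c, a in self.reference.items()}

    def truth_table(self) -> pd.DataFrame:
        rows = [dict(source_gene=e.source_gene, chrom=e.chrom, start=e.start,
                     end=e.end, insertion_chrom=e.insertion_chrom,
                     insertion_pos=e.insertion_pos, mode=e.mode,
                     carrier_founder=e.carrier_founder, divergence=e.divergence,
                     n_carriers=len(e.carriers),
                     carriers=",".join(e.carriers))
                for e in self.events]
        return pd.DataFrame(rows, columns=["source_gene", "chrom", "start",
                                           "end", "insertion_chrom",
                                           "insertion_pos", "mode",
                                           "carrier_founder", "divergence",
                                           "n_carriers", "carriers"])


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(cfg: SimConfig) -> Simulation:
    """Simulate the homozygous founder-mosaic population.

    Returns a :class:`Simulation` whose ``genotypes`` contain zero het
    calls; monomorphic sites are removed, so every retained SNP segregates.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    sim = Simulation(cfg)
    rng = stream_rng(cfg.seed, "popsim")
    weights = cfg.weights()

    chrom_arrays, acc_names = [], [f"acc{i:04d}" for i in range(cfg.n_accessions)]
    all_chrom, all_pos, all_ref, all_alt, all_calls = [], [], [], [], []

    for chrom, L in zip(cfg.chrom_names, cfg.chrom_lengths):
        seq = BASES[rng.integers(0, 4, size=L)]
        sim.reference[chrom] = seq

        m = max(10, int(round(cfg.snp_density * L)))
        pos = np.sort(rng.choice(L, size=min(m, L), replace=False)) + 1

        # founder allele matrix: per site, a uniform 1..n_founders-1 founders
        # carry the alternate allele (polymorphic among founders)
        mloc = len(pos)
        if cfg.n_founders > 1:
            k = rng.integers(1, cfg.n_founders, size=mloc)
            ranks = np.argsort(rng.random((mloc, cfg.n_founders)), axis=1)
            F = (np.argsort(ranks, axis=1) < k[:, None]).T  # (n_f, m)
        else:
            F = np.zeros((1, mloc), dtype=bool)
        sim._founder_alleles[chrom] = F

        # mosaics
        mosaics = []
        calls = np.zeros((mloc, cfg.n_accessions), dtype=np.int8)
        for a in range(cfg.n_accessions):
            n_x = rng.poisson(cfg.recomb_rate * L)
            bp = np.concatenate([[0], np.sort(rng.uniform(0, L, size=n_x))])
            st = rng.choice(cfg.n_founders, size=n_x + 1, p=weights)
            mosaics.append((bp, st))
            founders = st[np.searchsorted(bp, pos, side="right") - 1]
            calls[:, a] = np.where(F[founders, np.arange(mloc)], HOM_ALT, HOM_REF)
        sim._mosaic[chrom] = mosaics

        ref_base = seq[pos - 1]
        alt_base = BASES[(np.array([_CODE[b] for b in ref_base])
                          + rng.integers(1, 4, size=mloc)) % 4]
        all_chrom.extend([chrom] * mloc)
        all_pos.append(pos)
        all_ref.extend(chr(b) for b in ref_base)
        all_alt.extend(chr(b) for b in alt_base)
        all_calls.append(calls)

    calls = np.concatenate(all_calls) if all_calls else np.zeros((0, cfg.n_accessions), np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING

    gm = GenotypeMatrix(acc_names, all_chrom,
                        np.concatenate(all_pos) if all_pos else [],
                        all_ref, all_alt, calls)

    # drop monomorphic sites; allele frequencies then strictly in (0,1)
    valid = gm.calls >= 0
    alt_any = ((gm.calls == HOM_ALT) & valid).any(axis=1)
    ref_any = ((gm.calls == HOM_REF) & valid).any(axis=1)
    keep = np.flatnonzero(alt_any & ref_any)
    sim._snp_keep_per_chrom = None
    gm = gm.take_snps(keep)
    # keep founder-allele bookkeeping aligned with retained SNPs
    for chrom in cfg.chrom_names:
        sl = gm.chrom_slice(chrom)
        mask = np.isin(np.sort(np.asarray(all_pos[cfg.chrom_names.index(chrom)])),
                       gm.pos[sl])
        sim._founder_alleles[chrom] = sim._founder_alleles[chrom][:, mask]

    sim.genotypes = gm
    sim.clean = gm.copy()
    sim.injected_by = np.zeros(gm.calls.shape, dtype=np.int16)
    sim.annotation = _place_genes(cfg)
    return sim


def _place_genes(cfg: SimConfig) -> list[GeneAnnotation]:
    genes = []
    for ci, (chrom, L) in enumerate(zip(cfg.chrom_names, cfg.chrom_lengths)):
        n = cfg.n_genes_per_chrom
        for i in range(n):
            center = int(L * (i + 0.5) / n)
            start = max(1, center - cfg.gene_length // 2)
            end = min(L, start + cfg.gene_length - 1)
            genes.append(GeneAnnotation(f"g{ci + 1}_{i + 1:02d}", chrom, start, end))
    return genes


# ---------------------------------------------------------------------------
# duplications
# ---------------------------------------------------------------------------

def plant_duplication(sim: Simulation, source_gene: str, mode: str = "trans",
                      divergence: float = 0.05, carrier_founder: int | None = None,
                      insertion_chrom: str | None = None,
                      insertion_pos: int | None = None,
                      origin_founder: int = 0, het_fn_rate: float = 0.0,
                      add_tag_snp: bool = True) -> DuplicationEvent:
    """Plant one duplication and inject its pseudo-heterozygous calls.

    Mutates ``sim.genotypes`` in place (adds het calls, and new SNP rows for
    divergence mutations at previously invariant positions). Non-carriers
    are never modified. ``het_fn_rate`` is the per-(site, carrier)
    probability that mis-mapping fails to produce a het call (default 0).
    """
    cfg = sim.cfg
    rng = stream_rng(cfg.seed, f"plant:{source_gene}:{len(sim.events)}")
    gene = sim.gene(source_gene)
    gm = sim.genotypes

    if insertion_chrom is None or insertion_pos is None:
        if mode == "tandem":
            insertion_chrom = gene.chrom
            insertion_pos = min(cfg.chrom_lengths[cfg.chrom_names.index(gene.chrom)],
                                gene.end + 2000)
        else:
            others = [c for c in cfg.chrom_names if c != gene.chrom] or [gene.chrom]
            insertion_chrom = others[int(rng.integers(len(others)))]
            L = cfg.chrom_lengths[cfg.chrom_names.index(insertion_chrom)]
            insertion_pos = int(rng.integers(L // 10, 9 * L // 10))
    if carrier_founder is None:
        carrier_founder = 0

    event = DuplicationEvent(source_gene, gene.chrom, gene.start, gene.end,
                             insertion_chrom, int(insertion_pos), mode,
                             int(carrier_founder), float(divergence),
                             origin_founder=int(origin_founder))

    carrier_mask = sim.carrier_indicator(insertion_chrom, insertion_pos,
                                         carrier_founder)
    event.carriers = tuple(np.array(gm.accessions)[carrier_mask])
    if not carrier_mask.any():
        warnings.warn(f"duplication {source_gene}: no carriers, matrix unchanged")
        sim.events.append(event)
        return event

    sl = gm.chrom_slice(gene.chrom)
    in_gene = np.flatnonzero((gm.pos[sl] >= gene.start) & (gm.pos[sl] <= gene.end))
    if len(in_gene) == 0:
        raise ValueError(f"source gene {source_gene} contains no SNP")
    snp_idx = in_gene + sl.start

    # divergence mutations of the (single ancestral) copy
    glen = gene.end - gene.start + 1
    div_off = np.flatnonzero(rng.random(glen) < divergence)
    ref_seq = sim.reference[gene.chrom][gene.start - 1:gene.end]
    div_mut = {}
    for off in div_off:
        pos = gene.start + int(off)
        old = _copy_template_base(sim, event, pos)
        div_mut[pos] = chr(BASES[(_CODE[old] + int(rng.integers(1, 4))) % 4])
    event.div_mutations = div_mut

    ev_no = len(sim.events) + 1
    carriers_ix = np.flatnonzero(carrier_mask)

    # 1. existing SNPs inside the source interval
    for j in snp_idx:
        pos = int(gm.pos[j])
        for a in carriers_ix:
            own = gm.alt[j] if sim.clean.calls[j, a] == HOM_ALT else gm.ref[j]
            copy_base = _copy_base(sim, event, pos, acc_index=a)
            if copy_base != own and gm.calls[j, a] != MISSING:
                if het_fn_rate > 0 and rng.random() < het_fn_rate:
                    continue
                gm.calls[j, a] = HET
                sim.injected_by[j, a] = ev_no

    # 2. divergence mutations at previously invariant positions -> new sites
    existing = set(int(p) for p in gm.pos[snp_idx])
    new_rows = []
    for pos, mut in sorted(div_mut.items()):
        if pos in existing:
            continue
        ref_base = chr(ref_seq[pos - gene.start])
        calls = np.full(cfg.n_accessions, HOM_REF, dtype=np.int8)
        inj = np.zeros(cfg.n_accessions, dtype=np.int16)
        for a in carriers_ix:
            if het_fn_rate > 0 and rng.random() < het_fn_rate:
                continue
            calls[a] = HET
            inj[a] = ev_no
        new_rows.append((gene.chrom, pos, ref_base, mut, calls, inj, False))

    # 3. the junction tag SNP: carrier-founder indicator at the insertion
    if add_tag_snp:
        try:
            gm.snp_index(insertion_chrom, insertion_pos)
        except KeyError:
            ref_base = chr(sim.reference[insertion_chrom][insertion_pos - 1])
            alt_base = chr(BASES[(_CODE[ord(ref_base)] + 1) % 4])
            calls = np.where(carrier_mask, HOM_ALT, HOM_REF).astype(np.int8)
            new_rows.append((insertion_chrom, insertion_pos, ref_base,
                             alt_base, calls, np.zeros(cfg.n_accessions,
                                                       np.int16), True))

    if new_rows:
        _insert_rows(sim, new_rows)

    sim.events.append(event)
    return event


def _copy_template_base(sim, event, pos) -> int:
    """Pre-divergence template base (ASCII code) of a trans copy at pos."""
    gm = sim.genotypes
    ref = sim.reference[event.chrom][pos - 1]
    if event.mode == "tandem":
        return int(ref)
    try:
        j = gm.snp_index(event.chrom, pos)
    except KeyError:
        return int(ref)
    F = sim._founder_alleles[event.chrom]
    local = j - gm.chrom_slice(event.chrom).start
    if F[event.origin_founder, local]:
        return ord(gm.alt[j])
    return int(ref)


def _copy_base(sim, event, pos, acc_index=None) -> str:
    """Base carried by the duplicate copy at an absolute position.

    trans: origin-founder haplotype + divergence mutations (same for every
    carrier). tandem: the carrier's own haplotype + divergence mutations.
    """
    if pos in event.div_mutations:
        return event.div_mutations[pos]
    gm = sim.genotypes
    if event.mode == "tandem":
        try:
            j = gm.snp_index(event.chrom, pos)
        except KeyError:
            return chr(sim.reference[event.chrom][pos - 1])
        own_alt = sim.clean.calls[j, acc_index] == HOM_ALT
        return gm.alt[j] if own_alt else gm.ref[j]
    return chr(_copy_template_base(sim, event, pos))


def _insert_rows(sim, rows) -> None:
    """Insert new SNP rows keeping (chrom, pos) order and bookkeeping aligned."""
    gm = sim.genotypes
    for chrom, pos, ref, alt, calls, inj, is_real in rows:
        sl = gm.chrom_slice(chrom)
        if sl.stop == sl.start:
            at = gm.n_snps
        else:
            at = sl.start + int(np.searchsorted(gm.pos[sl.start:sl.stop], pos))
        gm.chrom = np.insert(gm.chrom, at, chrom)
        gm.pos = np.insert(gm.pos, at, pos)
        gm.ref = np.insert(gm.ref, at, ref)
        gm.alt = np.insert(gm.alt, at, alt)
        gm.calls = np.insert(gm.calls, at, calls, axis=0)
        sim.injected_by = np.insert(sim.injected_by, at, inj, axis=0)
        c = sim.clean
        clean_calls = calls if is_real else np.full_like(calls, HOM_REF)
        c.chrom = np.insert(c.chrom, at, chrom)
        c.pos = np.insert(c.pos, at, pos)
        c.ref = np.insert(c.ref, at, ref)
        c.alt = np.insert(c.alt, at, alt)
        c.calls = np.insert(c.calls, at, clean_calls, axis=0)
        F = sim._founder_alleles[chrom]
        local = at - gm.chrom_slice(chrom).start
        col = np.zeros((sim.cfg.n_founders, 1), dtype=bool)
        sim._founder_alleles[chrom] = np.concatenate(
            [F[:, :local], col, F[:, local:]], axis=1)
    gm.validate()


def choose_carrier_founder(sim: Simulation, chrom: str, pos: int,
                           target_freq: float) -> int:
    """Founder whose frequency at (chrom, pos) is closest to target_freq."""
    counts = np.bincount(
        [int(sim.founder_at(i, chrom, pos)) for i in range(sim.cfg.n_accessions)],
        minlength=sim.cfg.n_founders)
    freqs = counts / sim.cfg.n_accessions
    return int(np.argmin(np.abs(freqs - target_freq)))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def copy_sequence(sim: Simulation, event: DuplicationEvent,
                  accession: str | None = None) -> str:
    """Sequence of the duplicate copy carried at the insertion point."""
    acc_ix = None if accession is None else sim.genotypes.accessions.index(accession)
    return "".join(_copy_base(sim, event, p, acc_index=acc_ix)
                   for p in range(event.start, event.end + 1))


def emit_assembly(sim: Simulation, accession: str) -> dict[str, str]:
    """The accession's true genome: reference + own alleles (+ copies)."""
    gm = sim.clean
    a = gm.accessions.index(accession)
    out = {}
    for chrom, refarr in sim.reference.items():
        seq = refarr.copy()
        sl = gm.chrom_slice(chrom)
        alt_ix = np.flatnonzero(gm.calls[sl, a] == HOM_ALT) + sl.start
        for j in alt_ix:
            seq[gm.pos[j] - 1] = ord(gm.alt[j])
        parts, cursor = [], 0
        inserts = sorted((e for e in sim.events
                          if e.insertion_chrom == chrom and accession in e.carriers),
                         key=lambda e: e.insertion_pos)
        for e in inserts:
            cut = e.insertion_pos  # copy inserted after this base
            parts.append(seq[cursor:cut].tobytes().decode())
            parts.append(copy_sequence(sim, e, accession))
            cursor = cut
        parts.append(seq[cursor:].tobytes().decode())
        out[chrom] = "".join(parts)
    return out


def emit_assemblies(sim: Simulation, accessions=None):
    """Yield (accession, genome dict) pairs; defaults to all accessions."""
    for acc in (accessions or sim.genotypes.accessions):
        yield acc, emit_assembly(sim, acc)


# -- methylation ------------------------------------------------------------

def cytosine_positions(seq: str, context: str) -> list[int]:
    """0-based positions of CG / CHG cytosines on the forward strand."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i] != "C":
            continue
        if context == "CG" and seq[i + 1] == "G":
            out.append(i)
        elif context == "CHG" and seq[i + 1] in "ACT" and seq[i + 2] == "G":
            out.append(i)
    return out


def draw_methylation_truth(sim: Simulation, contexts=("CG", "CHG")) -> pd.DataFrame:
    """Per (gene, copy, context) true methylation level.

    Each copy is independently either methylated (level ~ U(0.6, 0.95)) or
    essentially unmethylated (level ~ U(0, 0.08)), emulating duplicates
    whose epigenetic state differs from their template.
    """
    rng = stream_rng(sim.cfg.seed, "methylation-truth")
    dup_genes = {e.source_gene for e in sim.events}
    rows = []
    for g in sim.annotation:
        copies = ["source"] + (["dup"] if g.gene_id in dup_genes else [])
        for copy in copies:
            for ctx in contexts:
                if rng.random() < 0.5:
                    level = rng.uniform(0.6, 0.95)
                else:
                    level = rng.uniform(0.0, 0.08)
                rows.append(dict(gene_id=g.gene_id, copy=copy, context=ctx,
                                 level=level))
    return pd.DataFrame(rows)


def emit_methylation(sim: Simulation, depth: float, accessions=None,
                     truth: pd.DataFrame | None = None,
                     contexts=("CG", "CHG"), genes=None) -> pd.DataFrame:
    """Per-cytosine counts under own-genome and reference-collapsed mapping.

    own_genome: one record per copy per cytosine, binomial at the copy's
    true level. reference: for carriers of a duplication the reads of both
    copies collapse onto the template gene -- depths and methylated counts
    are pooled, which is the mis-mapping artifact under study.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = stream_rng(sim.cfg.seed, "methylation-counts")
    if truth is None:
        truth = draw_methylation_truth(sim, contexts)
    if accessions is None:
        accessions = sim.genotypes.accessions
    level = {(r.gene_id, r.copy, r.context): r.level
             for r in truth.itertuples()}
    carrier_of = {g.gene_id: set() for g in sim.annotation}
    for e in sim.events:
        carrier_of[e.source_gene].update(e.carriers)

    rows = []
    for g in sim.annotation:
        if genes is not None and g.gene_id not in genes:
            continue
        seq = sim.reference[g.chrom][g.start - 1:g.end].tobytes().decode()
        for ctx in contexts:
            cpos = [g.start + i for i in cytosine_positions(seq, ctx)]
            for acc in accessions:
                copies = ["source"]
                if acc in carrier_of[g.gene_id]:
                    copies.append("dup")
                per_copy = {}
                for copy in copies:
                    lv = level[(g.gene_id, copy, ctx)]
                    t = rng.poisson(depth, size=len(cpos))
                    c = rng.binomial(t, lv)
                    per_copy[copy] = (t, c)
                    for p, ti, ci in zip(cpos, t, c):
                        rows.append((g.chrom, p, ctx, int(ti), int(ci),
                                     "own_genome", acc, copy, g.gene_id))
                t_sum = sum(t for t, _ in per_copy.values())
                c_sum = sum(c for _, c in per_copy.values())
                for p, ti, ci in zip(cpos, t_sum, c_sum):
                    rows.append((g.chrom, p, ctx, int(ti), int(ci),
                                 "reference", acc, "", g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "depth",
                                       "methylated", "mapping_target",
                                       "accession", "copy", "gene_id"])


# -- read pairs -------------------------------------------------------------

def emit_read_pairs(sim: Simulation, event: DuplicationEvent, n_pairs: int = 10,
                    insert_size: int = 400, read_len: int = 100,
                    region_halfwidth: int = 2000) -> pd.DataFrame:
    """Paired-read placements on the insertion-allele coordinate system.

    The junction sits at ``region_halfwidth`` (1-based local coordinates).
    Carriers receive ``n_pairs`` junction-spanning pairs (mate1 ends before
    the junction, mate2 starts after it). Non-carriers, whose genomes lack
    the insertion, receive flank-only pairs that never span the border.
    """
    rng = stream_rng(sim.cfg.seed, f"readpairs:{event.source_gene}")
    junction = region_halfwidth
    rows = []
    for acc in sim.genotypes.accessions:
        if acc in event.carriers:
            for _ in range(n_pairs):
                gap = max(2, insert_size - 2 * read_len)
                off = int(rng.integers(1, max(2, gap)))
                e1 = junction - off
                s2 = junction + (gap - off) + 1
                rows.append((acc, e1 - read_len + 1, e1, s2, s2 + read_len - 1))
        else:
            for i in range(n_pairs):
                side = -1 if i % 2 == 0 else 1
                base = junction + side * int(rng.integers(read_len + insert_size,
                                                          region_halfwidth - 1))
                if side == -1:  # whole pair left of the junction
                    s1 = base - insert_size
                    rows.append((acc, s1, s1 + read_len - 1,
                                 base - read_len + 1, base))
                else:  # whole pair right of the junction
                    rows.append((acc, base, base + read_len - 1,
                                 base + insert_size - read_len + 1,
                                 base + insert_size))
    df = pd.DataFrame(rows, columns=["accession", "mate1_start", "mate1_end",
                                     "mate2_start", "mate2_end"])
    df.attrs["junction"] = junction
    return df


# -- sequencing depth -------------------------------------------------------

def emit_depth(sim: Simulation, accession: str, mean_depth: float = 30.0,
               window: int = 50) -> pd.DataFrame:
    """Reference-collapsed per-window read depth (Poisson).

    Windows inside the source gene of a duplication carried by the
    accession receive doubled expected depth: reads of both copies map to
    the single reference locus.
    """
    rng = stream_rng(sim.cfg.seed, f"depth:{accession}")
    rows = []
    dup_intervals = [(e.chrom, e.start, e.end) for e in sim.events
                     if accession in e.carriers]
    for chrom, L in zip(sim.cfg.chrom_names, sim.cfg.chrom_lengths):
        starts = np.arange(1, L + 1, window)
        lam = np.full(len(starts), float(mean_depth))
        for (c, s, e) in dup_intervals:
            if c == chrom:
                hit = (starts + window - 1 >= s) & (starts <= e)
                lam[hit] *= 2.0
        depth = rng.poisson(lam)
        rows.append(pd.DataFrame(dict(chrom=chrom, start=starts,
                                      end=np.minimum(starts + window - 1, L),
                                      depth=depth)))
    return pd.concat(rows, ignore_index=True)
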