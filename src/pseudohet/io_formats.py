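"""Standard-format I/O: VCF genotype matrices, GFF3 annotation, FASTA.

Conventions used throughout the package:

* coordinates are 1-based inclusive everywhere (VCF/GFF convention);
* genotype calls are encoded ``0`` = hom-ref, ``1`` = het, ``2`` = hom-alt,
  ``-1`` = missing;
* heterozygosity is defined purely from the GT field (phased separators are
  accepted and treated as unphased);
* only biallelic single-nucleotide variants are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF
import gffutils

log = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
# cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
_CYVCF2_MAP = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)


@dataclass
class SnpRecord:
    """A single biallelic SNP with per-accession diploid calls."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    calls: np.ndarray  # int8 over accessions, values in {0,1,2,-1}

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele identical")
        if not set(np.unique(self.calls)) <= {-1, 0, 1, 2}:
            raise ValueError("calls must be in {-1,0,1,2}")

    @property
    def snp_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


class GenotypeMatrix:
    """Accessions x biallelic SNPs, stored column-wise as numpy arrays.

    SNPs are sorted by (chrom, pos): chromosomes form contiguous blocks and
    positions are strictly increasing within each chromosome.
    """

    def __init__(self, accessions, chrom, pos, ref, alt, calls):
        self.accessions = list(accessions)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, accessions, records: list[SnpRecord]) -> "GenotypeMatrix":
        if records:
            calls = np.stack([r.calls for r in records])
        else:
            calls = np.zeros((0, len(accessions)), dtype=np.int8)
        return cls(
            accessions,
            [r.chrom for r in records],
            [r.pos for r in records],
            [r.ref_allele for r in records],
            [r.alt_allele for r in records],
            calls,
        )

    @classmethod
    def empty(cls, accessions) -> "GenotypeMatrix":
        return cls.from_records(accessions, [])

    # -- basic interface ----------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def snp_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def snp(self, i: int) -> SnpRecord:
        return SnpRecord(self.chrom[i], int(self.pos[i]), self.ref[i],
                         self.alt[i], self.calls[i].copy())

    def snp_index(self, chrom: str, pos: int) -> int:
        idx = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if len(idx) != 1:
            raise KeyError(f"SNP {chrom}:{pos} not found")
        return int(idx[0])

    def chromosomes(self) -> list[str]:
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if len(idx) == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.accessions, self.chrom[index],
                              self.pos[index], self.ref[index],
                              self.alt[index], self.calls[index])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.accessions, self.chrom.copy(),
                              self.pos.copy(), self.ref.copy(),
                              self.alt.copy(), self.calls.copy())

    def validate(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n
                and self.calls.shape == (n, len(self.accessions))):
            raise ValueError("inconsistent array shapes")
        seen = set()
        for c in self.chromosomes():
            if c in seen:
                raise ValueError(f"chromosome block {c} not contiguous")
            seen.add(c)
            p = self.pos[self.chrom_slice(c)]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                bad = int(np.flatnonzero(np.diff(p) <= 0)[0])
                raise ValueError(
                    f"positions not strictly increasing on {c} near {p[bad + 1]}")

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.accessions == other.accessions
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.ref, other.ref)
                and np.array_equal(self.alt, other.alt)
                and np.array_equal(self.calls, other.calls))


@dataclass
class GeneAnnotation:
    """A gene-level feature interval (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    feature_class: str = "gene"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Load all biallelic SNP rows of a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP rows are skipped (count logged). Raises on
    unsorted positions and on non-diploid GT fields.
    """
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    chrom, pos, ref, alt, calls = [], [], [], [], []
    n_skipped = 0
    last = {}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.ploidy != 2:
            raise ValueError(f"non-diploid GT at {v.CHROM}:{v.POS}")
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(
                f"unsorted VCF: {v.CHROM}:{v.POS} after {v.CHROM}:{last[v.CHROM]}")
        last[v.CHROM] = v.POS
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        calls.append(_CYVCF2_MAP[np.asarray(v.gt_types)])
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP rows", n_skipped)
    calls_arr = (np.stack(calls) if calls
                 else np.zeros((0, len(accessions)), dtype=np.int8))
    gm = GenotypeMatrix(accessions, chrom, pos, ref, alt, calls_arr)
    gm.n_skipped = n_skipped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Emit a sorted VCF 4.2 that round-trips through :func:`read_vcf`."""
    gm.validate()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pseudohet\n")
        for c in gm.chromosomes():
            length = int(gm.pos[gm.chrom_slice(c)].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accessions) + "\n")
        for i in range(gm.n_snps):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_FEATURES = ("gene", "transposable_element")


def read_gff(path) -> list[GeneAnnotation]:
    """Parse gene-level features of a GFF3 file (1-based inclusive kept)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}: malformed GFF line {lineno}")
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for ftype in _GENE_FEATURES:
        for feat in db.features_of_type(ftype):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            out.append(GeneAnnotation(gene_id, feat.seqid, feat.start,
                                      feat.end, feat.strand or "+", ftype))
    out.sort(key=lambda g: (g.chrom, g.start))
    ids = [g.gene_id for g in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in annotation")
    return out


def write_gff(annotation: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tpseudohet\t{g.feature_class}\t{g.start}\t"
                     f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA to {id: uppercase sequence}; duplicate ids raise."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
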