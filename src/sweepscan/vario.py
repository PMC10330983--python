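"""Variant I/O, hard filtering, and functional annotation of SNPs.

The central container is :class:`VariantTable`, a biallelic-SNP genotype
matrix with per-site INFO metrics (QD, FS, MQ) and per-genotype qualities
(GQ), plus a sample -> population mapping.  Filtering follows the hard-filter
expression ``QD < 2.0 || FS > 60.0 || MQ < 40.0`` at the site level and
``GQ < 20`` at the genotype level, with strict inequalities: boundary values
pass.  Annotation classifies every site into exactly one of six genomic
classes and calls synonymous/nonsynonymous consequences for coding sites by
rebuilding the affected codon from the reference sequence.

Coordinates are 0-based half-open internally; VCF (1-based) and GFF3
(1-based closed) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

log = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: site classes in precedence order (first match wins)
SITE_CLASSES = ("exonic", "UTR", "intronic", "upstream", "downstream", "intergenic")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RefMismatchError(ValueError):
    """REF allele disagrees with the reference FASTA at a site."""


@dataclass
class VariantTable:
    """Biallelic SNP sites x diploid samples.

    Parameters
    ----------
    sites
        One row per site with columns ``chrom, pos, ref, alt, qd, fs, mq``;
        ``pos`` is 1-based as in VCF. Positions are strictly increasing
        within each chromosome.
    genotypes
        ``(n_sites, n_samples, 2)`` int8 array of allele indices
        (0 = REF, 1 = ALT, -1 = missing; both alleles of a genotype are
        missing together).
    samples
        Sample identifiers, column order of ``genotypes``.
    populations
        Mapping sample id -> population label.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str] = field(default_factory=dict)
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape[:1] != (len(self.sites),):
            raise ValueError("genotype rows != site rows")
        if self.genotypes.shape[1] != len(self.samples):
            raise ValueError("genotype columns != samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        """Column indices of samples, optionally restricted to one population."""
        if population is None:
            return np.arange(self.n_samples)
        idx = [i for i, s in enumerate(self.samples)
               if self.populations.get(s) == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.asarray(idx)

    def take_sites(self, mask_or_index) -> "VariantTable":
        """Subset sites by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ALT allele count, non-missing allele count) over a sample subset."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx, :]
        called = g >= 0
        return (g == 1).sum(axis=(1, 2)), called.sum(axis=(1, 2))

    def alt_dosage(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site x per-sample ALT dosage 0/1/2 (float, NaN where missing)."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx, :]
        dos = (g == 1).sum(axis=2).astype(float)
        dos[(g < 0).any(axis=2)] = np.nan
        return dos


@dataclass
class GeneModel:
    """Gene and CDS intervals on a reference, 0-based half-open.

    ``genes`` has columns ``gene_id, chrom, start, end, strand``; ``cds``
    maps gene id to a position-sorted list of ``(start, end, phase)``
    segments whose summed length is a multiple of 3.  ``flank`` (bp) defines
    the upstream/downstream annotation classes.
    """

    genes: pd.DataFrame
    cds: dict[str, list[tuple[int, int, int]]]
    flank: int = 1000

    def __post_init__(self) -> None:
        for gid, segs in self.cds.items():
            total = sum(e - s for s, e, _ in segs)
            if total % 3:
                raise ValueError(f"CDS length of {gid} not a multiple of 3")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])


def read_gff(path: str, flank: int = 1000) -> GeneModel:
    """Load gene/CDS features from a GFF3 file into a :class:`GeneModel`."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows, cds = [], {}
    for g in db.features_of_type("gene"):
        gid = g.id
        rows.append((gid, g.seqid, g.start - 1, g.end, g.strand))
        segs = []
        for c in db.children(g, featuretype="CDS", order_by="start"):
            phase = int(c.frame) if c.frame not in (None, ".") else 0
            segs.append((c.start - 1, c.end, phase))
        cds[gid] = segs
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneModel(genes=genes, cds=cds, flank=flank)


def read_vcf(path: str, pop_map: dict[str, str] | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF into a :class:`VariantTable`.

    Multi-allelic records and non-SNP records are excluded (counted in the
    log), matching a biallelic-SNP analysis.  ``pop_map`` maps sample id to
    population label; every mapped sample must be present in the VCF.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if pop_map:
        missing = set(pop_map) - set(samples)
        if missing:
            raise KeyError(f"samples in pop_map absent from VCF: {sorted(missing)}")
    rows, gts, gqs = [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1 \
                or rec.REF not in NUCLEOTIDES or rec.ALT[0] not in NUCLEOTIDES:
            n_skipped += 1
            continue
        info = rec.INFO
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                     info.get("QD", np.nan), info.get("FS", np.nan),
                     info.get("MQ", np.nan)))
        gt = np.asarray(rec.genotype.array())[:, :2]
        gts.append(gt)
        try:
            gq = rec.format("GQ")
            gq = np.full(len(samples), np.nan) if gq is None else gq[:, 0].astype(float)
        except KeyError:
            gq = np.full(len(samples), np.nan)
        gqs.append(gq)
    if n_skipped:
        log.info("read_vcf: excluded %d multi-allelic/non-SNP records", n_skipped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qd", "fs", "mq"])
    if rows:
        genotypes = np.stack(gts).astype(np.int8)
        genotypes[genotypes < 0] = -1
        # a half-called genotype is treated as fully missing
        half = (genotypes < 0).any(axis=2)
        genotypes[half] = -1
        gq = np.stack(gqs)
    else:
        genotypes = np.zeros((0, len(samples), 2), dtype=np.int8)
        gq = np.zeros((0, len(samples)))
    table = VariantTable(sites=sites, genotypes=genotypes, samples=samples,
                         populations=dict(pop_map or {}), gq=gq)
    table.n_skipped_multiallelic = n_skipped
    return table


@dataclass
class FilterReport:
    n_input_sites: int
    n_failed_sites: int
    n_genotypes_masked: int
    window_clause: str = "not implemented (cluster-window semantics unspecified)"


def apply_hard_filters(table: VariantTable,
                       qd_min: float = 2.0, fs_max: float = 60.0,
                       mq_min: float = 40.0, gq_min: float = 20.0,
                       ) -> tuple[VariantTable, FilterReport]:
    """Apply GATK-style hard filters.

    Sites failing ``QD < qd_min OR FS > fs_max OR MQ < mq_min`` are removed;
    genotypes with ``GQ < gq_min`` are set missing.  All inequalities are
    strict, so boundary values (QD=2.0, FS=60.0, MQ=40.0, GQ=20) are kept.
    A site with a missing INFO metric fails closed (removed).
    """
    qd = table.sites["qd"].to_numpy(float)
    fs = table.sites["fs"].to_numpy(float)
    mq = table.sites["mq"].to_numpy(float)
    bad = (qd < qd_min) | (fs > fs_max) | (mq < mq_min)
    bad |= np.isnan(qd) | np.isnan(fs) | np.isnan(mq)
    out = table.take_sites(~bad)
    n_masked = 0
    if out.gq is not None:
        mask = out.gq < gq_min  # NaN GQ compares False: genotype kept
        n_masked = int((mask & (out.genotypes[:, :, 0] >= 0)).sum())
        out.genotypes = out.genotypes.copy()
        out.genotypes[mask] = -1
    report = FilterReport(n_input_sites=table.n_sites,
                          n_failed_sites=int(bad.sum()),
                          n_genotypes_masked=n_masked)
    log.info("hard filters: %d/%d sites removed, %d genotypes masked",
             report.n_failed_sites, report.n_input_sites, n_masked)
    return out, report


def maf_filter(table: VariantTable, threshold: float = 0.05) -> VariantTable:
    """Remove sites with minor allele frequency strictly below ``threshold``.

    MAF is computed over non-missing alleles pooled across all samples; a
    site at exactly the threshold is retained.  Fully-missing sites are
    removed and logged.
    """
    alt, called = table.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = maf >= threshold
    n_all_missing = int((called == 0).sum())
    if n_all_missing:
        log.info("maf_filter: %d fully-missing sites removed", n_all_missing)
    keep &= called > 0
    return table.take_sites(keep)


def tstv_ratio(table: VariantTable) -> float:
    """Transition/transversion ratio over REF->ALT changes.

    Raises ``ZeroDivisionError`` if there are no transversions.
    """
    pairs = list(zip(table.sites["ref"], table.sites["alt"]))
    ts = sum(p in TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        raise ZeroDivisionError("ts/tv undefined: no transversions")
    return ts / tv


def _gene_intervals(genes: GeneModel):
    """Per-chromosome feature intervals in precedence order, precomputed."""
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in genes.genes.itertuples():
        d = by_chrom.setdefault(row.chrom, {c: [] for c in SITE_CLASSES[:-1]})
        segs = sorted(genes.cds.get(row.gene_id, []))
        for s, e, _ in segs:
            d["exonic"].append((s, e))
        if segs:
            cds_lo, cds_hi = segs[0][0], segs[-1][1]
            if row.start < cds_lo:
                d["UTR"].append((row.start, cds_lo))
            if cds_hi < row.end:
                d["UTR"].append((cds_hi, row.end))
            for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
                d["intronic"].append((e1, s2))
        else:
            d["intronic"].append((row.start, row.end))
        if row.strand == "-":
            up = (row.end, row.end + genes.flank)
            down = (max(0, row.start - genes.flank), row.start)
        else:
            up = (max(0, row.start - genes.flank), row.start)
            down = (row.end, row.end + genes.flank)
        d["upstream"].append(up)
        d["downstream"].append(down)
    return by_chrom


def classify_sites(table: VariantTable, genes: GeneModel) -> tuple[pd.Series, pd.Series]:
    """Assign each site exactly one genomic class.

    Precedence: exonic > UTR > intronic > upstream > downstream > intergenic.
    UTR here is the transcribed gene region 5' of the first or 3' of the last
    CDS base; introns lie between CDS segments.  Sites on chromosomes absent
    from the gene model are intergenic.  Returns (per-site class labels,
    class proportions).
    """
    feats = _gene_intervals(genes)
    labels = []
    for row in table.sites.itertuples():
        pos0 = row.pos - 1
        d = feats.get(row.chrom)
        label = "intergenic"
        if d is not None:
            for cls in SITE_CLASSES[:-1]:
                if any(s <= pos0 < e for s, e in d[cls]):
                    label = cls
                    break
        labels.append(label)
    labels = pd.Series(labels, name="site_class")
    props = labels.value_counts(normalize=True).reindex(SITE_CLASSES, fill_value=0.0)
    return labels, props


@dataclass
class NonsynSynSummary:
    n_nonsynonymous: int
    n_synonymous: int
    n_noncoding: int

    @property
    def ratio(self) -> float:
        """Nonsynonymous/synonymous count ratio."""
        return self.n_nonsynonymous / self.n_synonymous


def _codon_at(segs: list[tuple[int, int, int]], strand: str, pos0: int,
              seq: str, chrom_start: int):
    """Locate the codon covering genomic pos0 within a CDS.

    ``seq`` is the chromosome sequence slice starting at ``chrom_start``.
    Returns (codon string in coding orientation, index 0-2 of the variant
    base within it, genomic positions of the codon bases 5'->3' in coding
    orientation) or None if pos0 is not coding.
    """
    segs = sorted(segs)
    coords: list[int] = []
    for s, e, _ in segs:
        coords.extend(range(s, e))
    if strand == "-":
        coords = coords[::-1]
    try:
        cds_index = coords.index(pos0)
    except ValueError:
        return None
    codon_i = cds_index // 3
    codon_pos = [coords[codon_i * 3 + k] for k in range(3)]
    bases = []
    for p in codon_pos:
        b = seq[p - chrom_start].upper()
        bases.append(b.translate(_COMPLEMENT) if strand == "-" else b)
    return "".join(bases), cds_index % 3, codon_pos


def consequence(table: VariantTable, genes: GeneModel, fasta_path: str,
                ) -> tuple[pd.Series, NonsynSynSummary]:
    """Call synonymous/nonsynonymous/noncoding consequences per site.

    The codon containing each coding site is rebuilt from the reference
    FASTA (reverse-complemented on minus strand), the ALT allele substituted,
    and both codons translated with the standard genetic code.  A REF allele
    disagreeing with the FASTA raises :class:`RefMismatchError`.
    """
    fa = Fasta(str(fasta_path))
    calls = []
    genes_by_chrom: dict[str, list] = {}
    for row in genes.genes.itertuples():
        genes_by_chrom.setdefault(row.chrom, []).append(row)
    for row in table.sites.itertuples():
        pos0 = row.pos - 1
        if row.chrom in fa:
            ref_base = str(fa[row.chrom][pos0]).upper()
            if ref_base != row.ref:
                raise RefMismatchError(
                    f"REF {row.ref} != reference base {ref_base} at "
                    f"{row.chrom}:{row.pos}")
        call = "noncoding"
        for g in genes_by_chrom.get(row.chrom, []):
            segs = genes.cds.get(g.gene_id, [])
            if not segs or not any(s <= pos0 < e for s, e, _ in segs):
                continue
            lo = min(s for s, _, _ in segs)
            hi = max(e for _, e, _ in segs)
            seq = str(fa[row.chrom][lo:hi])
            located = _codon_at(segs, g.strand, pos0, seq, lo)
            if located is None:
                continue
            codon, offset, _ = located
            alt_base = row.alt if g.strand == "+" else row.alt.translate(_COMPLEMENT)
            mutant = codon[:offset] + alt_base + codon[offset + 1:]
            call = ("synonymous" if CODON_TABLE[codon] == CODON_TABLE[mutant]
                    else "nonsynonymous")
            break
        calls.append(call)
    calls = pd.Series(calls, name="consequence")
    summary = NonsynSynSummary(
        n_nonsynonymous=int((calls == "nonsynonymous").sum()),
        n_synonymous=int((calls == "synonymous").sum()),
        n_noncoding=int((calls == "noncoding").sum()),
    )
    return calls, summary


def write_vcf(table: VariantTable, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VariantTable as an uncompressed VCFv4.2 text file."""
    gq = getattr(table, "gq", None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom, ln in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, row in enumerate(table.sites.itertuples()):
            info = f"QD={row.qd:.2f};FS={row.fs:.2f};MQ={row.mq:.2f}"
            cells = []
            for j in range(table.n_samples):
                a, b = table.genotypes[i, j]
                gt = "./." if a < 0 else f"{a}/{b}"
                q = 99 if gq is None or np.isnan(gq[i, j]) else int(gq[i, j])
                cells.append(f"{gt}:{q}")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                     f"{info}\tGT:GQ\t" + "\t".join(cells) + "\n")
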