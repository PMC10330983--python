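"""Synthetic multi-population diploid SNP cohorts with implanted sweeps.

The generator emulates the data a genome-wide selective-sweep scan consumes:
several diverged populations of diploid genotypes with genome-wide
background differentiation, one or more sweep regions where the target
population has locally reduced diversity and elevated differentiation, and
an optional binary phenotype driven by causal SNPs inside a sweep region.

Model
-----
Ancestral allele frequencies follow a neutral-SFS-like law (derived-allele
count i drawn with probability proportional to 1/i over a nominal pool of
2N haplotypes).  Population frequencies diverge under the Balding-Nichols
construction: q_pop ~ Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and a
between-population variance giving an expected Hudson Fst of F.  Inside a
sweep interval the target population's frequency is displaced toward the
nearer boundary of {0, 1} so that expected heterozygosity is multiplied by
(1 - diversity_reduction).  Genotypes are binomial draws from the population
frequency.  All randomness flows through one seeded NumPy generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vario import NUCLEOTIDES, VariantTable, write_vcf

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SweepSpec:
    """One implanted sweep: target population, interval, intensity."""

    population: str
    chrom: str
    start: int
    end: int
    diversity_reduction: float

    def __post_init__(self):
        if not (0 <= self.diversity_reduction < 1):
            raise ValueError("diversity_reduction must lie in [0, 1)")
        if self.end <= self.start:
            raise ValueError("sweep interval is empty")


@dataclass(frozen=True)
class CausalSpec:
    """Phenotype driver: causal SNPs drawn from one sweep interval."""

    sweep_index: int = 0
    n_causal: int = 1
    penetrance: float = 1.0

    def __post_init__(self):
        if not (0.5 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must lie in [0.5, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_pops: int = 2
    samples_per_pop: int = 20
    chrom_lengths: tuple[int, ...] = (5_000_000,)
    n_sites: int = 5_000
    background_fst: float = 0.05
    sweep_specs: tuple[SweepSpec, ...] = ()
    causal_spec: CausalSpec | None = None
    seed: int = 0
    #: fraction of sites/genotypes drawn to fail each hard filter
    filter_fail_fraction: float = 0.02
    #: probability a REF->ALT change is a transition
    transition_prob: float = 0.7

    def __post_init__(self):
        if not (0 < self.background_fst < 1):
            raise ValueError("background_fst must lie in (0, 1)")
        lengths = dict(self.chrom_names_lengths())
        for sw in self.sweep_specs:
            if sw.chrom not in lengths or not (0 <= sw.start < sw.end <= lengths[sw.chrom]):
                raise ValueError(f"sweep interval outside chromosome: {sw}")
        if self.causal_spec is not None and not self.sweep_specs:
            raise ValueError("causal_spec requires at least one sweep")

    def chrom_names_lengths(self) -> list[tuple[str, int]]:
        return [(f"chr{i + 1}", ln) for i, ln in enumerate(self.chrom_lengths)]

    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    ancestral_freq: np.ndarray          # (n_sites,)
    pop_freq: np.ndarray                # (n_sites, n_pops)
    pop_names: list[str]
    sweeps: list[SweepSpec]
    causal_sites: list[int] = field(default_factory=list)   # row indices
    phenotypes: pd.DataFrame | None = None                  # sample_id, status


def _displace_toward_fixation(q: np.ndarray, reduction: float) -> np.ndarray:
    """Move frequencies toward the nearer of {0, 1} so 2q(1-q) shrinks by
    the factor (1 - reduction), staying on the same side of 1/2."""
    het = 2.0 * q * (1.0 - q) * (1.0 - reduction)
    root = 0.5 * (1.0 - np.sqrt(np.maximum(1.0 - 2.0 * het, 0.0)))
    return np.where(q <= 0.5, root, 1.0 - root)


def simulate_cohort(config: SimConfig) -> tuple[VariantTable, SimTruth]:
    """Draw a cohort under the Balding-Nichols-with-sweeps model.

    Deterministic given ``config.seed``; raises ``ValueError`` if any sweep
    interval contains zero sites.
    """
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names_lengths()
    total_len = sum(ln for _, ln in chroms)
    pops = config.pop_names()
    n_dip = config.samples_per_pop

    # site placement: uniform (sorted, unique) along chromosomes, count
    # proportional to length
    chrom_col, pos_col = [], []
    remaining = config.n_sites
    for k, (chrom, length) in enumerate(chroms):
        n = remaining if k == len(chroms) - 1 else int(round(config.n_sites * length / total_len))
        n = min(n, remaining)
        remaining -= n
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1  # 1-based
        chrom_col.extend([chrom] * n)
        pos_col.extend(pos.tolist())
    chrom_arr = np.asarray(chrom_col)
    pos_arr = np.asarray(pos_col, dtype=np.int64)
    n_sites = pos_arr.size

    # ancestral frequencies: derived count i in 1..2N-1 with P(i) ~ 1/i
    pool = 2 * config.n_pops * n_dip
    counts = np.arange(1, pool)
    w = 1.0 / counts
    anc = counts[rng.choice(counts.size, size=n_sites, p=w / w.sum())] / pool

    # Balding-Nichols population frequencies
    F = config.background_fst
    a = anc * (1 - F) / F
    b = (1 - anc) * (1 - F) / F
    pop_freq = np.column_stack([rng.beta(a, b) for _ in pops])

    # implant sweeps
    for sw in config.sweep_specs:
        j = pops.index(sw.population)
        in_sweep = (chrom_arr == sw.chrom) & (pos_arr - 1 >= sw.start) & (pos_arr - 1 < sw.end)
        if not in_sweep.any():
            raise ValueError(f"sweep interval contains zero sites: {sw}")
        pop_freq[in_sweep, j] = _displace_toward_fixation(
            pop_freq[in_sweep, j], sw.diversity_reduction)

    # diploid genotypes: per-sample ALT dosage ~ Binomial(2, q)
    genotypes = np.empty((n_sites, config.n_pops * n_dip, 2), dtype=np.int8)
    for j in range(config.n_pops):
        dos = rng.binomial(2, pop_freq[:, [j]], size=(n_sites, n_dip))
        cols = slice(j * n_dip, (j + 1) * n_dip)
        genotypes[:, cols, 0] = dos >= 1
        genotypes[:, cols, 1] = dos == 2

    # REF/ALT alleles with a transition bias
    ref = np.array([NUCLEOTIDES[i] for i in rng.integers(0, 4, n_sites)])
    is_ts = rng.random(n_sites) < config.transition_prob
    alt = np.empty(n_sites, dtype=ref.dtype)
    for i in range(n_sites):
        if is_ts[i]:
            alt[i] = _TRANSITION_OF[ref[i]]
        else:
            tv = [b for b in NUCLEOTIDES if b != ref[i] and b != _TRANSITION_OF[ref[i]]]
            alt[i] = tv[rng.integers(0, 2)]

    # QC annotations: a configurable fraction fails each hard filter
    f = config.filter_fail_fraction
    qd = np.where(rng.random(n_sites) < f, rng.uniform(0.1, 1.9, n_sites),
                  rng.uniform(10, 35, n_sites))
    fs = np.where(rng.random(n_sites) < f, rng.uniform(61, 200, n_sites),
                  rng.uniform(0, 30, n_sites))
    mq = np.where(rng.random(n_sites) < f, rng.uniform(5, 39, n_sites),
                  rng.uniform(45, 60, n_sites))
    gq = np.where(rng.random((n_sites, config.n_pops * n_dip)) < f,
                  rng.integers(2, 20, (n_sites, config.n_pops * n_dip)),
                  rng.integers(30, 99, (n_sites, config.n_pops * n_dip))).astype(float)

    samples = [f"{p}_s{i + 1}" for p in pops for i in range(n_dip)]
    sites = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "ref": ref,
                          "alt": alt, "qd": qd, "fs": fs, "mq": mq})
    table = VariantTable(sites=sites, genotypes=genotypes, samples=samples,
                         populations={s: s.rsplit("_", 1)[0] for s in samples},
                         gq=gq)
    truth = SimTruth(ancestral_freq=anc, pop_freq=pop_freq, pop_names=pops,
                     sweeps=list(config.sweep_specs))

    if config.causal_spec is not None:
        cs = config.causal_spec
        sw = config.sweep_specs[cs.sweep_index]
        in_sweep = np.flatnonzero(
            (chrom_arr == sw.chrom) & (pos_arr - 1 >= sw.start) & (pos_arr - 1 < sw.end))
        # causal variants emulate a breed-differentiated locus (the sweep's
        # focal variant): derived allele common in the swept population and
        # rare elsewhere, so carrier status separates cases from controls.
        # Rank sweep sites by that frequency differential and take the top.
        j = pops.index(sw.population)
        qs = pop_freq[in_sweep, j]
        others = np.delete(pop_freq[in_sweep], j, axis=1).max(axis=1)
        score = qs - others
        chosen = in_sweep[np.argsort(-score, kind="stable")[:cs.n_causal]]
        truth.causal_sites = sorted(int(i) for i in chosen)
        truth.phenotypes = simulate_phenotypes(table, truth, cs, rng)

    return table, truth


def simulate_phenotypes(table: VariantTable, truth: SimTruth, causal: CausalSpec,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw a binary phenotype from carrier status at the causal sites.

    A sample carrying at least one derived allele at any causal site is a
    case with probability ``penetrance``, otherwise with probability
    ``1 - penetrance``.
    """
    if not truth.causal_sites:
        raise ValueError("no causal sites in truth")
    g = table.genotypes[truth.causal_sites]
    carrier = (g == 1).any(axis=(0, 2))
    p_case = np.where(carrier, causal.penetrance, 1.0 - causal.penetrance)
    status = np.where(rng.random(table.n_samples) < p_case, "case", "control")
    return pd.DataFrame({"sample_id": table.samples, "status": status,
                         "carrier": carrier})


def _tile_genes(chrom_lengths: list[tuple[str, int]], spacing: int = 50_000,
                gene_len: int = 9_000) -> str:
    """GFF3 text with genes tiled along each chromosome.

    Each gene carries two CDS segments (summed length a multiple of 3) and
    flanking UTR-modelled transcript sequence; strands alternate.
    """
    lines = ["##gff-version 3"]
    n = 0
    for chrom, length in chrom_lengths:
        for start in range(10_000, length - gene_len, spacing):
            n += 1
            gid = f"gene{n:04d}"
            strand = "+" if n % 2 else "-"
            end = start + gene_len
            # layout within the gene: UTR | CDS1 | intron | CDS2 | UTR
            cds1 = (start + 1000, start + 1000 + 300)
            cds2 = (start + 5000, start + 5000 + 600)
            lines.append(f"{chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                         f"ID={gid};Name={gid}")
            lines.append(f"{chrom}\tsim\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                         f"ID={gid}.t1;Parent={gid}")
            phases = (0, 0)  # both segment lengths are multiples of 3
            lines.append(f"{chrom}\tsim\tCDS\t{cds1[0] + 1}\t{cds1[1]}\t.\t{strand}\t"
                         f"{phases[0]}\tID={gid}.c1;Parent={gid}.t1")
            lines.append(f"{chrom}\tsim\tCDS\t{cds2[0] + 1}\t{cds2[1]}\t.\t{strand}\t"
                         f"{phases[1]}\tID={gid}.c2;Parent={gid}.t1")
    return "\n".join(lines) + "\n"


def write_fixture(table: VariantTable, truth: SimTruth, out_dir: str | Path,
                  config: SimConfig) -> dict[str, Path]:
    """Write the cohort in standard formats for downstream stages.

    Emits ``cohort.vcf`` (QD/FS/MQ INFO, GQ FORMAT), ``genes.gff3`` tiled
    over the chromosomes, ``reference.fa`` consistent with the VCF REF
    alleles, ``populations.tsv``, ``phenotypes.tsv`` (if simulated), and
    ``truth.json``.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    chroms = config.chrom_names_lengths()

    paths["vcf"] = out / "cohort.vcf"
    write_vcf(table, paths["vcf"], contig_lengths=dict(chroms))

    # reference: deterministic filler sequence, REF alleles patched in
    rng = np.random.default_rng(config.seed + 101)
    records = []
    for chrom, length in chroms:
        seq = np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, length)]
        m = table.sites["chrom"] == chrom
        pos0 = table.sites.loc[m, "pos"].to_numpy() - 1
        seq[pos0] = table.sites.loc[m, "ref"].to_numpy().astype("S1")
        records.append(SeqRecord(Seq(seq.tobytes().decode()), id=chrom, description=""))
    paths["fasta"] = out / "reference.fa"
    SeqIO.write(records, paths["fasta"], "fasta")

    paths["gff"] = out / "genes.gff3"
    paths["gff"].write_text(_tile_genes(chroms))

    paths["pops"] = out / "populations.tsv"
    pd.DataFrame({"sample_id": table.samples,
                  "population": [table.populations[s] for s in table.samples]}
                 ).to_csv(paths["pops"], sep="\t", index=False)

    # gene sets: each tiled gene joins 1-3 of 20 synthetic pathways
    model_genes = [ln.split("ID=")[1].split(";")[0]
                   for ln in _tile_genes(chroms).splitlines()
                   if "\tgene\t" in ln]
    rng2 = np.random.default_rng(config.seed + 202)
    pathways: dict[str, list[str]] = {f"pathway{i + 1:02d}": [] for i in range(20)}
    names = list(pathways)
    for g in model_genes:
        for pid in rng2.choice(names, size=rng2.integers(1, 4), replace=False):
            pathways[pid].append(g)
    paths["gmt"] = out / "gene_sets.gmt"
    with open(paths["gmt"], "w") as fh:
        for pid, gs in pathways.items():
            if gs:
                fh.write(pid + "\tsynthetic\t" + "\t".join(gs) + "\n")

    if truth.phenotypes is not None:
        paths["pheno"] = out / "phenotypes.tsv"
        truth.phenotypes[["sample_id", "status"]].to_csv(
            paths["pheno"], sep="\t", index=False)

    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps({
        "pop_names": truth.pop_names,
        "sweeps": [vars(s) for s in truth.sweeps],
        "causal_sites": truth.causal_sites,
        "causal_positions": [
            [str(table.sites["chrom"][i]), int(table.sites["pos"][i])]
            for i in truth.causal_sites],
    }, indent=2))
    return paths
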