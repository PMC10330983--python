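"""Candidate-locus follow-up: per-SNP association, haplotypes, LD blocks.

Association uses the allelic 2x2 chi-square test (1 df, no continuity
correction), replaced by Fisher's exact test whenever an expected cell is
below 5, with Benjamini-Hochberg adjustment across tested SNPs; genotype
count tables are emitted alongside for transparency.  Haplotype frequencies
over small SNP sets (k <= 8) are estimated from unphased diploid genotypes
by EM over the multinomial haplotype-pair likelihood; pairwise D'/r^2 come
from the estimated two-locus haplotype frequencies, and an LD block is the
longest run of consecutive SNPs whose pairwise r^2 all clear a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .vario import VariantTable

EM_TOL = 1e-8
EM_MAX_ITER = 2000
ABSENT_FREQ = 1e-3  #: haplotypes below this frequency are reported absent


def snp_association(table: VariantTable, phenotypes: pd.DataFrame,
                    ) -> pd.DataFrame:
    """Allelic case-control association per SNP.

    ``phenotypes`` needs ``sample_id`` and ``status`` ('case'/'control')
    columns covering >= 2 cases and >= 2 controls.  For each polymorphic
    SNP the 2x2 ALT/REF x case/control allele-count table is tested with a
    1-df chi-square (Fisher's exact test when any expected count < 5);
    p-values are BH-adjusted across tested SNPs.  Monomorphic SNPs are
    skipped (``tested`` False).  Genotype counts per status are included.
    """
    status = dict(zip(phenotypes["sample_id"], phenotypes["status"]))
    case_idx = np.asarray([i for i, s in enumerate(table.samples)
                           if status.get(s) == "case"])
    ctrl_idx = np.asarray([i for i, s in enumerate(table.samples)
                           if status.get(s) == "control"])
    if case_idx.size < 2 or ctrl_idx.size < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    alt_ca, n_ca = table.allele_counts(case_idx)
    alt_co, n_co = table.allele_counts(ctrl_idx)
    dos = table.alt_dosage()
    rows = []
    for i in range(table.n_sites):
        a, b = int(alt_ca[i]), int(n_ca[i] - alt_ca[i])   # case ALT/REF
        c, d = int(alt_co[i]), int(n_co[i] - alt_co[i])   # control ALT/REF
        tot = a + b + c + d
        geno = {
            f"{grp}_{g}": int(np.nansum(dos[i, idx] == g))
            for grp, idx in (("case", case_idx), ("control", ctrl_idx))
            for g in (0, 1, 2)
        }
        row = {"chrom": table.sites["chrom"][i], "pos": int(table.sites["pos"][i]),
               "alt_case": a, "ref_case": b, "alt_control": c, "ref_control": d,
               **geno}
        if tot == 0 or (a + c) == 0 or (b + d) == 0:
            row.update(tested=False, test="none", chi2=np.nan, p=np.nan)
        else:
            obs = np.array([[a, b], [c, d]])
            expected = np.outer(obs.sum(1), obs.sum(0)) / tot
            if (expected < 5).any():
                _, p = sps.fisher_exact(obs)
                row.update(tested=True, test="fisher", chi2=np.nan, p=p)
            else:
                chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
                row.update(tested=True, test="chi2", chi2=chi2, p=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"],
                                             method="fdr_bh")[1]
    return out


@dataclass
class EMResult:
    """Converged haplotype-frequency estimate over k SNPs."""

    haplotypes: list[tuple[int, ...]]   # all 2^k allele configurations
    frequencies: np.ndarray
    log_likelihood: float
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    map_pairs: list[tuple[int, int]] = field(default_factory=list)

    def present(self, threshold: float = ABSENT_FREQ) -> dict[tuple[int, ...], float]:
        """Haplotypes whose estimated frequency exceeds ``threshold``."""
        return {h: float(f) for h, f in zip(self.haplotypes, self.frequencies)
                if f >= threshold}


def _compatible_pairs(geno: tuple[int, ...], k: int) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs consistent with an unphased genotype
    (ALT dosage 0/1/2 per SNP)."""
    hets = [i for i, g in enumerate(geno) if g == 1]
    base = 0
    for i, g in enumerate(geno):
        if g == 2:
            base |= 1 << i
    pairs = []
    if not hets:
        return [(base, base)]
    # fix the first het site's allele on haplotype 1 to avoid double counting
    first, rest = hets[0], hets[1:]
    for bits in product((0, 1), repeat=len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for site, b in zip(rest, bits):
            if b:
                h1 |= 1 << site
            else:
                h2 |= 1 << site
        pairs.append((min(h1, h2), max(h1, h2)))
    return pairs


def em_haplotypes(genotypes: np.ndarray, n_restarts: int = 5,
                  seed: int = 0, tol: float = EM_TOL) -> EMResult:
    """EM haplotype-frequency estimation from unphased diploid genotypes.

    ``genotypes`` is (n_samples, k) ALT dosage with NaN for missing; a SNP
    missing in every sample is dropped, and samples with any remaining
    missing call are excluded from the likelihood.  k must be <= 8 so the
    2^k haplotype space is enumerable.  The E-step distributes each
    ambiguous genotype over its compatible phase resolutions in proportion
    to current frequency products; the M-step re-estimates frequencies.
    Convergence: log-likelihood gain < ``tol``.  ``n_restarts`` random
    restarts are run and the best likelihood kept; the log-likelihood is
    asserted non-decreasing at every step.
    """
    g = np.asarray(genotypes, float)
    keep_snps = ~np.all(np.isnan(g), axis=0)
    g = g[:, keep_snps]
    k = g.shape[1]
    if k == 0:
        raise ValueError("no typed SNPs")
    if k > 8:
        raise ValueError("haplotype space too large (k > 8)")
    g = g[~np.isnan(g).any(axis=1)]
    if g.shape[0] == 0:
        raise ValueError("no fully-typed samples")
    n = g.shape[0]
    geno_counts: dict[tuple[int, ...], int] = {}
    for row in g.astype(int):
        geno_counts[tuple(row)] = geno_counts.get(tuple(row), 0) + 1
    pair_lists = {ge: _compatible_pairs(ge, k) for ge in geno_counts}
    m = 2 ** k
    rng = np.random.default_rng(seed)
    best: EMResult | None = None
    for restart in range(n_restarts):
        if restart == 0:
            f = np.full(m, 1.0 / m)
        else:
            f = rng.dirichlet(np.ones(m))
        prev_ll = -np.inf
        trace = []
        for it in range(1, EM_MAX_ITER + 1):
            counts = np.zeros(m)
            ll = 0.0
            for ge, cnt in geno_counts.items():
                pairs = pair_lists[ge]
                w = np.array([f[h1] * f[h2] * (1 if h1 == h2 else 2)
                              for h1, h2 in pairs])
                tot = w.sum()
                if tot <= 0:
                    w = np.full(len(pairs), 1.0 / len(pairs))
                    tot = 1.0
                    ll += cnt * np.log(1e-300)
                else:
                    w = w / tot
                    ll += cnt * np.log(tot)
                for (h1, h2), wi in zip(pairs, w):
                    counts[h1] += cnt * wi
                    counts[h2] += cnt * wi
            assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
            trace.append(ll)
            f = counts / (2 * n)
            if ll - prev_ll < tol and it > 1:
                break
            prev_ll = ll
        if best is None or ll > best.log_likelihood:
            haps = [tuple((h >> i) & 1 for i in range(k)) for h in range(m)]
            map_pairs = []
            for row in g.astype(int):
                pairs = pair_lists[tuple(row)]
                w = [f[h1] * f[h2] * (1 if h1 == h2 else 2) for h1, h2 in pairs]
                map_pairs.append(pairs[int(np.argmax(w))])
            best = EMResult(haplotypes=haps, frequencies=f, log_likelihood=ll,
                            n_iter=it, loglik_trace=trace, map_pairs=map_pairs)
    return best


def ld_stats(p_ab: float, p_a: float, p_b: float) -> tuple[float, float, float]:
    """D, D' and r^2 from haplotype frequency p_AB and allele frequencies.

    Alleles A and B are any chosen alleles at the two loci; both loci must
    be polymorphic (frequencies strictly inside (0, 1)).
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("LD undefined for a fixed SNP")
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return d, d_prime, r2


def ld_matrix(genotypes: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise D' and r^2 matrices via two-locus EM phase estimation.

    ``genotypes`` is (n_samples, k) ALT dosage.  Returns (d_prime, r2),
    NaN where a locus is fixed.
    """
    k = genotypes.shape[1]
    dp = np.full((k, k), np.nan)
    r2 = np.full((k, k), np.nan)
    np.fill_diagonal(dp, 1.0)
    np.fill_diagonal(r2, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            sub = genotypes[:, [i, j]]
            sub = sub[~np.isnan(sub).any(axis=1)]
            if sub.size == 0 or len(np.unique(sub[:, 0])) < 2 \
                    or len(np.unique(sub[:, 1])) < 2:
                continue
            em = em_haplotypes(sub, n_restarts=3, seed=seed)
            f = em.frequencies  # order: 00, 10, 01, 11 (bit 0 = first SNP)
            p_a = f[1] + f[3]
            p_b = f[2] + f[3]
            if 0 < p_a < 1 and 0 < p_b < 1:
                _, dp[i, j], r2[i, j] = ld_stats(f[3], p_a, p_b)
                dp[j, i], r2[j, i] = dp[i, j], r2[i, j]
    return dp, r2


@dataclass
class HaplotypeBlock:
    snp_indices: list[int]
    positions: list[int]
    start: int
    end: int
    em: EMResult | None = None
    r2: np.ndarray | None = None
    d_prime: np.ndarray | None = None


def define_block(positions, r2: np.ndarray, min_r2: float = 0.5,
                 ) -> HaplotypeBlock | None:
    """Longest run of consecutive SNPs with all pairwise r^2 >= min_r2.

    Ties break leftmost.  Returns None (no block) when no adjacent pair
    clears the threshold.
    """
    positions = list(positions)
    k = len(positions)
    best = None
    for i in range(k):
        j = i
        while j + 1 < k and all(
                np.isfinite(r2[a, j + 1]) and r2[a, j + 1] >= min_r2
                for a in range(i, j + 1)):
            j += 1
        if j > i and (best is None or (j - i) > (best[1] - best[0])):
            best = (i, j)
    if best is None:
        return None
    i, j = best
    return HaplotypeBlock(snp_indices=list(range(i, j + 1)),
                          positions=positions[i:j + 1],
                          start=positions[i], end=positions[j])


def analyse_block(table: VariantTable, snp_rows: list[int], min_r2: float = 0.5,
                  seed: int = 0) -> HaplotypeBlock | None:
    """LD-block + haplotype analysis over a set of SNP rows of a table.

    Computes the pairwise LD matrices, delimits the block, and runs the EM
    haplotype estimate over the block's SNPs.
    """
    dos = table.alt_dosage()[snp_rows].T  # samples x k
    positions = [int(table.sites["pos"][i]) for i in snp_rows]
    dp, r2 = ld_matrix(dos, seed=seed)
    block = define_block(positions, r2, min_r2=min_r2)
    if block is None:
        return None
    block.snp_indices = [snp_rows[i] for i in block.snp_indices]
    block.r2 = r2
    block.d_prime = dp
    block.em = em_haplotypes(dos[:, [positions.index(p) for p in block.positions]],
                             seed=seed)
    return block
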