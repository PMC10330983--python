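"""Windowed nucleotide diversity, Hudson-style Fst, and theta-pi ratios.

Statistics are computed from unphased diploid genotypes via allele counts,
which is algebraically identical to counting differing haplotype pairs:

* per-site pi = n0*n1 / C(n, 2) over the n non-missing alleles of a
  population (the plug-in pairwise-difference frequency; no extra n/(n-1)
  correction on top of pair counting),
* per-site between-population diversity d_xy = (n0A*n1B + n1A*n0B)/(nA*nB),
* Fst = (pi_between - pi_within)/pi_between with pi_within the unweighted
  mean of the two within-population values (Hudson 1992 convention).

Windowed values use a sliding grid (default 20-kb windows, 5-kb steps);
window Fst is the ratio of window-summed components (ratio of sums, not a
mean of per-site ratios), and the genome-wide "weighted" Fst is the ratio of
genome-summed components.  Windows where the denominator is zero are flagged
undefined (NaN) rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vario import VariantTable

WINDOW_SIZE = 20_000
WINDOW_STEP = 5_000


@dataclass
class WindowGrid:
    """Sliding windows per chromosome, 0-based half-open."""

    size: int = WINDOW_SIZE
    step: int = WINDOW_STEP
    windows: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 2) starts/ends

    def frame(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"chrom": c, "start": w[:, 0], "end": w[:, 1]})
                 for c, w in self.windows.items()]
        return (pd.concat(parts, ignore_index=True) if parts
                else pd.DataFrame(columns=["chrom", "start", "end"]))


def make_windows(chrom_lengths: dict[str, int], size: int = WINDOW_SIZE,
                 step: int = WINDOW_STEP) -> WindowGrid:
    """Build the sliding-window grid.

    Windows start at 0, step, 2*step, ... with start + size <= chromosome
    length; trailing partial windows are dropped.  A chromosome shorter than
    one window yields zero windows.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    grid = WindowGrid(size=size, step=step)
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(length - size + 1, 0), step, dtype=np.int64)
        grid.windows[chrom] = np.column_stack([starts, starts + size])
    return grid


def site_pi(alleles) -> float:
    """Pairwise-difference probability at one site from a haploid allele list.

    Equals the fraction of unordered allele pairs that differ.  Requires at
    least two non-missing alleles (entries < 0 are missing).
    """
    a = np.asarray(alleles)
    a = a[a >= 0]
    n = a.size
    if n < 2:
        raise ValueError("site_pi needs >= 2 non-missing alleles")
    n1 = int((a == 1).sum())
    return 2.0 * n1 * (n - n1) / (n * (n - 1))


def _site_components(table: VariantTable, pop_a: str, pop_b: str):
    """Per-site within/between diversity components for one comparison.

    Returns (pi_a, pi_b, pi_within, d_xy) arrays with NaN where a population
    has fewer than two called alleles at the site.
    """
    ia, ib = table.sample_indices(pop_a), table.sample_indices(pop_b)
    alt_a, n_a = table.allele_counts(ia)
    alt_b, n_b = table.allele_counts(ib)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_a = np.where(n_a >= 2, 2.0 * alt_a * (n_a - alt_a)
                        / np.maximum(n_a * (n_a - 1), 1), np.nan)
        pi_b = np.where(n_b >= 2, 2.0 * alt_b * (n_b - alt_b)
                        / np.maximum(n_b * (n_b - 1), 1), np.nan)
        d_xy = np.where((n_a >= 1) & (n_b >= 1),
                        (alt_a * (n_b - alt_b) + (n_a - alt_a) * alt_b)
                        / np.maximum(n_a * n_b, 1), np.nan)
    ok = ~np.isnan(pi_a) & ~np.isnan(pi_b) & ~np.isnan(d_xy)
    pi_within = np.where(ok, 0.5 * (pi_a + pi_b), np.nan)
    return pi_a, pi_b, pi_within, d_xy, ok


def _window_sums(positions: np.ndarray, values: np.ndarray, wins: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-site values over each [start, end) window; sites may fall in
    several overlapping windows.  positions are 0-based and sorted."""
    csum = np.concatenate([[0.0], np.cumsum(values)])
    ccnt = np.arange(positions.size + 1)
    lo = np.searchsorted(positions, wins[:, 0], side="left")
    hi = np.searchsorted(positions, wins[:, 1], side="left")
    return csum[hi] - csum[lo], ccnt[hi] - ccnt[lo]


def window_pi(table: VariantTable, grid: WindowGrid, population: str) -> pd.DataFrame:
    """Per-bp nucleotide diversity per window for one population.

    Sums per-site pi over SNPs in each window and divides by the window
    length; invariant positions contribute zero, and windows with no SNPs
    get pi = 0.
    """
    idx = table.sample_indices(population)
    alt, n = table.allele_counts(idx)
    with np.errstate(invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * alt * (n - alt) / np.maximum(n * (n - 1), 1), 0.0)
    out = []
    for chrom, wins in grid.windows.items():
        in_chrom = table.sites["chrom"].to_numpy() == chrom
        pos0 = table.sites.loc[in_chrom, "pos"].to_numpy() - 1
        sums, counts = _window_sums(pos0, pi[in_chrom], wins)
        out.append(pd.DataFrame({"chrom": chrom, "start": wins[:, 0],
                                 "end": wins[:, 1], "n_sites": counts,
                                 "pi": sums / grid.size}))
    return pd.concat(out, ignore_index=True)


def comparison_stats(table: VariantTable, grid: WindowGrid,
                     pop_a: str, pop_b: str) -> tuple[pd.DataFrame, float]:
    """Windowed pi, Fst and theta-pi ratio for one population comparison.

    Population A is the reference/control group (ratio numerator) and B the
    target/case group (denominator), so a sweep in B inflates the ratio.

    Returns a window table with columns ``chrom, start, end, n_sites, pi_a,
    pi_b, fst, ratio`` (per-bp pi; NaN marks undefined Fst/ratio) and the
    genome-wide weighted Fst (ratio of genome-summed components).
    """
    pi_a, pi_b, pi_w, d_xy, ok = _site_components(table, pop_a, pop_b)
    pos_all = table.sites["pos"].to_numpy() - 1
    chroms = table.sites["chrom"].to_numpy()
    rows = []
    for chrom, wins in grid.windows.items():
        m = (chroms == chrom) & ok
        pos0 = pos_all[m]
        s_pa, n_sites = _window_sums(pos0, pi_a[m], wins)
        s_pb, _ = _window_sums(pos0, pi_b[m], wins)
        s_w, _ = _window_sums(pos0, pi_w[m], wins)
        s_b, _ = _window_sums(pos0, d_xy[m], wins)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(s_b > 0, (s_b - s_w) / np.where(s_b > 0, s_b, 1), np.nan)
            ratio = np.where(s_pb > 0, s_pa / np.where(s_pb > 0, s_pb, 1), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": wins[:, 0], "end": wins[:, 1],
            "n_sites": n_sites, "pi_a": s_pa / grid.size, "pi_b": s_pb / grid.size,
            "fst": fst, "ratio": ratio}))
    stats = pd.concat(rows, ignore_index=True)
    tot_b = np.nansum(d_xy[ok])
    genome_fst = float((tot_b - np.nansum(pi_w[ok])) / tot_b) if tot_b > 0 else float("nan")
    return stats, genome_fst


def hudson_fst(table: VariantTable, grid: WindowGrid, pop_a: str, pop_b: str,
               ) -> tuple[pd.Series, float]:
    """Per-window Hudson Fst and the genome-wide weighted value."""
    stats, genome = comparison_stats(table, grid, pop_a, pop_b)
    return stats["fst"], genome


def theta_pi_ratio(pi_a: np.ndarray, pi_b: np.ndarray) -> np.ndarray:
    """Elementwise theta-pi ratio pi_A/pi_B; NaN where pi_B is zero."""
    pi_a = np.asarray(pi_a, float)
    pi_b = np.asarray(pi_b, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pi_b > 0, pi_a / np.where(pi_b > 0, pi_b, 1), np.nan)
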