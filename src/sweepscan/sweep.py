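"""Joint empirical-tail selection of sweep windows and region bookkeeping.

A window is called selected when its Fst lies in the right 5% tail of the
empirical distribution AND its theta-pi ratio lies in the requested tail
(left = diversity loss in the numerator population, right = loss in the
denominator population, or both).  Tail thresholds are nearest-rank
quantiles recomputed from the data at hand — printed thresholds from any
particular dataset are properties of that dataset, not constants of the
method.  Selected windows are merged into maximal regions (overlapping or
bookended windows coalesce), intersected with gene annotations, and
compared across case/control contrasts via a full Venn partition.

Intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .vario import GeneModel


@dataclass
class ComparisonResult:
    """Selection outcome for one case/control population contrast."""

    label: str
    fst_threshold: float
    ratio_threshold_left: float | None
    ratio_threshold_right: float | None
    selected: pd.DataFrame       # selected windows with a `tail` column
    regions: pd.DataFrame        # chrom, start, end, n_windows, peak_fst, peak_ratio, genes
    genes: set[str] = field(default_factory=set)


def empirical_tail_threshold(values, fraction: float, side: str) -> float:
    """Nearest-rank empirical tail threshold.

    The right tail selects the top ``ceil(fraction * N)`` values and reports
    the smallest of them; the left tail is symmetric.  Requires at least
    ``1/fraction`` finite values so the tail is neither empty nor the whole
    set.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 1.0 / fraction:
        raise ValueError(f"need >= {math.ceil(1 / fraction)} values for a "
                         f"{fraction:.0%} tail, got {n}")
    k = math.ceil(fraction * n)
    v.sort()
    if side == "right":
        return float(v[n - k])
    if side == "left":
        return float(v[k - 1])
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def select_windows(stats: pd.DataFrame, fraction: float = 0.05,
                   mode: str = "right") -> tuple[pd.DataFrame, dict]:
    """Joint Fst + theta-pi-ratio tail selection.

    ``stats`` must carry finite-or-NaN ``fst`` and ``ratio`` columns
    (NaN-flagged windows are excluded from the empirical distributions and
    never selected).  ``mode`` chooses the ratio tail: ``left``, ``right``
    or ``both``.  Returns the selected windows (with a ``tail`` column
    recording which ratio tail fired) and the thresholds used.
    """
    if mode not in ("left", "right", "both"):
        raise ValueError(f"invalid mode {mode!r}")
    fst = stats["fst"].to_numpy(float)
    ratio = stats["ratio"].to_numpy(float)
    fst_thr = empirical_tail_threshold(fst, fraction, "right")
    thresholds = {"fst": fst_thr, "ratio_left": None, "ratio_right": None}
    in_fst = np.isfinite(fst) & (fst >= fst_thr)
    tail = np.full(len(stats), "", dtype=object)
    picked = np.zeros(len(stats), bool)
    if mode in ("right", "both"):
        thr = empirical_tail_threshold(ratio, fraction, "right")
        thresholds["ratio_right"] = thr
        hit = in_fst & np.isfinite(ratio) & (ratio >= thr)
        tail[hit] = "right"
        picked |= hit
    if mode in ("left", "both"):
        thr = empirical_tail_threshold(ratio, fraction, "left")
        thresholds["ratio_left"] = thr
        hit = in_fst & np.isfinite(ratio) & (ratio <= thr)
        tail[hit] = np.where(tail[hit] == "right", "both", "left")
        picked |= hit
    out = stats.loc[picked].copy()
    out["tail"] = tail[picked]
    return out, thresholds


def merge_regions(selected: pd.DataFrame) -> pd.DataFrame:
    """Merge selected windows into maximal regions per chromosome.

    Windows overlapping by >= 1 bp or exactly bookended are coalesced.
    Returns ``chrom, start, end, n_windows, peak_fst, peak_ratio``.
    """
    rows = []
    for chrom, grp in selected.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for w in grp.itertuples():
            if cur is not None and w.start <= cur["end"]:
                cur["end"] = max(cur["end"], w.end)
                cur["n_windows"] += 1
                cur["peak_fst"] = max(cur["peak_fst"], w.fst)
                cur["peak_ratio"] = max(cur["peak_ratio"], w.ratio)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(w.start), "end": int(w.end),
                       "n_windows": 1, "peak_fst": w.fst, "peak_ratio": w.ratio}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                       "peak_fst", "peak_ratio"])


def regions_to_genes(regions: pd.DataFrame, genes: GeneModel,
                     ) -> tuple[pd.DataFrame, set[str]]:
    """Attach genes overlapping each region by >= 1 bp (half-open).

    Returns the region table with a ``genes`` column (comma-joined ids) and
    the deduplicated candidate gene set.
    """
    out = regions.copy()
    per_region: list[list[str]] = []
    all_genes: set[str] = set()
    for r in regions.itertuples():
        g = genes.genes
        hit = g[(g["chrom"] == r.chrom) & (g["start"] < r.end) & (g["end"] > r.start)]
        ids = sorted(hit["gene_id"])
        per_region.append(ids)
        all_genes.update(ids)
    out["genes"] = [",".join(ids) for ids in per_region]
    return out, all_genes


def _intersect_two(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ia = a[a["chrom"] == chrom].sort_values("start")
        ib = b[b["chrom"] == chrom].sort_values("start")
        for ra in ia.itertuples():
            for rb in ib.itertuples():
                s, e = max(ra.start, rb.start), min(ra.end, rb.end)
                if s < e:
                    rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _merge_plain(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cs, ce = None, None
        for r in grp.itertuples():
            if cs is not None and r.start <= ce:
                ce = max(ce, r.end)
            else:
                if cs is not None:
                    rows.append({"chrom": chrom, "start": cs, "end": ce})
                cs, ce = int(r.start), int(r.end)
        rows.append({"chrom": chrom, "start": cs, "end": ce})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def shared_regions(results: list[ComparisonResult],
                   ) -> tuple[pd.DataFrame, set[str], dict]:
    """Regions and genes shared by every comparison, plus Venn counts.

    A shared interval is genomic sequence covered by at least one merged
    region of *each* comparison, reported as maximal common intervals.
    Shared genes are the intersection of the candidate gene sets.  The Venn
    dictionary maps each non-empty label subset (ampersand-joined, sorted)
    to exclusive region-interval and gene counts.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 comparisons")
    shared = _merge_plain(results[0].regions[["chrom", "start", "end"]])
    for r in results[1:]:
        shared = _merge_plain(_intersect_two(shared, r.regions))
    shared_genes = set.intersection(*(r.genes for r in results))

    venn: dict[str, dict[str, int]] = {}
    labels = [r.label for r in results]
    for k in range(1, len(results) + 1):
        for combo in combinations(range(len(results)), k):
            inside = [results[i] for i in combo]
            outside = [results[i] for i in range(len(results)) if i not in combo]
            inter = _merge_plain(inside[0].regions[["chrom", "start", "end"]])
            for r in inside[1:]:
                inter = _merge_plain(_intersect_two(inter, r.regions))
            # exclusive region cover: subtract every outside comparison
            excl = inter
            for r in outside:
                excl = _subtract(excl, r.regions)
            g = set.intersection(*(r.genes for r in inside))
            for r in outside:
                g -= r.genes
            key = "&".join(labels[i] for i in combo)
            venn[key] = {"regions": len(excl), "genes": len(g)}
    return shared, shared_genes, venn


def _subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Interval difference a \\ b (both merged-interval tables)."""
    if a.empty or b.empty:
        return a
    rows = []
    for ra in a.itertuples():
        pieces = [(ra.start, ra.end)]
        for rb in b[b["chrom"] == ra.chrom].itertuples():
            nxt = []
            for s, e in pieces:
                if rb.end <= s or rb.start >= e:
                    nxt.append((s, e))
                else:
                    if s < rb.start:
                        nxt.append((s, rb.start))
                    if rb.end < e:
                        nxt.append((rb.end, e))
            pieces = nxt
        rows.extend({"chrom": ra.chrom, "start": s, "end": e} for s, e in pieces)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(regions: pd.DataFrame, path: str) -> None:
    """Write regions as 0-based half-open BED."""
    cols = regions[["chrom", "start", "end"]]
    cols.to_csv(path, sep="\t", header=False, index=False)
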