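"""Gene-set over-representation analysis with BH FDR control.

For each pathway the overlap k between the candidate gene list (size n)
and the pathway's genes (size K within a universe of size N) is scored
with the one-sided hypergeometric tail P(X >= k); p-values are
Benjamini-Hochberg adjusted across pathways and those with q <= 0.05
(inclusive) are flagged significant.  Only over-representation is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


@dataclass
class GeneSetCollection:
    """Pathway id -> gene set, plus the background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} is empty")
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"pathway {pid!r} has genes outside the universe: "
                    f"{sorted(extra)[:5]}")


def read_gmt(path: str, universe: set[str] | None = None) -> GeneSetCollection:
    """Load a GMT-style gene-set file (pathway, description, genes...).

    If no universe is given, the union of all pathway genes is used.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    else:
        sets = {pid: genes & universe for pid, genes in sets.items()}
        sets = {pid: genes for pid, genes in sets.items() if genes}
    return GeneSetCollection(sets=sets, universe=universe)


def ora(candidates: set[str], collection: GeneSetCollection,
        fdr: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Hypergeometric over-representation of candidates in each pathway.

    Candidates outside the universe are dropped with a warning; an empty
    candidate set is an error.  Returns a table sorted by p with columns
    ``pathway, n_pathway, n_overlap, overlap_genes, p, q, significant``.
    """
    outside = candidates - collection.universe
    if outside:
        log.warning("ora: %d candidate genes outside the universe dropped",
                    len(outside))
    cand = candidates & collection.universe
    if not cand:
        raise ValueError("empty candidate set (after universe restriction)")
    n_universe, n_cand = len(collection.universe), len(cand)
    rows = []
    for pid, genes in collection.sets.items():
        overlap = cand & genes
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, n_universe, len(genes), n_cand))
        rows.append({"pathway": pid, "n_pathway": len(genes), "n_overlap": k,
                     "overlap_genes": ",".join(sorted(overlap)), "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] <= fdr
    return out.sort_values("p", ignore_index=True)
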