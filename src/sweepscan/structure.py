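"""Population-structure summaries: allele-sharing distance, NJ tree, PCA.

The distance between two diploid samples is one minus the mean per-site
allele-sharing score (1 for identical genotypes, 0.5 for genotypes sharing
one allele, 0 for opposite homozygotes), averaged over sites typed in both.
The neighbor-joining tree follows the Saitou-Nei Q-matrix agglomeration
with lexicographic tie-breaking, so taxon input order never changes the
result; negative branch lengths are clamped to zero.  PCA uses
variance-standardized genotype scaling (each site centred at 2p and divided
by sqrt(2p(1-p)), the GRM convention of GCTA-style tools) followed by an
eigendecomposition of the sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vario import VariantTable
from .diversity import theta_pi_ratio  # noqa: F401  (re-export convenience)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have zero diagonal")


def pairwise_distance(table: VariantTable) -> DistanceMatrix:
    """Allele-sharing distance between all sample pairs.

    d(i, j) = 1 - mean over co-typed sites of the shared-allele score
    {0, 0.5, 1}; a pair with zero co-typed sites is an error naming the
    pair.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dos = table.alt_dosage()  # sites x samples, NaN = missing
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(dos[:, i]) & ~np.isnan(dos[:, j])
            if not both.any():
                raise ValueError(
                    f"samples {table.samples[i]!r} and {table.samples[j]!r} "
                    f"share no co-typed sites")
            score = 1.0 - np.abs(dos[both, i] - dos[both, j]) / 2.0
            d[i, j] = d[j, i] = 1.0 - score.mean()
    return DistanceMatrix(ids=list(table.samples), matrix=d)


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Saitou-Nei), returned as an unrooted newick.

    Taxa are processed in lexicographic id order and joins break ties on
    the smallest (row, column) pair, so permuting the input order yields an
    identical tree.  Negative branch lengths are clamped to 0.
    """
    order = np.argsort(np.asarray(dm.ids, dtype=object))
    ids = [dm.ids[i] for i in order]
    d = dm.matrix[np.ix_(order, order)].astype(float).copy()
    if len(ids) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    nodes = [_Node(name=i) for i in ids]
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first = smallest (i,j)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dn = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((n - 1, n - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dn[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        d = d2
    # terminal 3-taxon star: three-point formulas
    (a, b, c) = nodes
    la = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    lb = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    lc = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    root = _Node(children=[(a, la), (b, lb), (c, lc)])
    return root.newick() + ";"


def bootstrap_nj(table: VariantTable, n_replicates: int = 100,
                 seed: int = 0) -> list[str]:
    """NJ trees from site-resampled replicates (bootstrap over sites)."""
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_replicates):
        idx = np.sort(rng.integers(0, table.n_sites, table.n_sites))
        trees.append(nj_tree(pairwise_distance(table.take_sites(idx))))
    return trees


def pca(table: VariantTable, maf_threshold: float = 0.05,
        n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotype PCA with variance-standardized scaling.

    Applies the MAF filter first, codes genotypes as ALT dosage 0/1/2,
    centres each site at 2p and scales by sqrt(2p(1-p)), mean-imputes
    missing dosages (zero after centring), and eigendecomposes the sample
    covariance.  Components are ordered by eigenvalue; each component's
    sign is fixed so its largest-magnitude loading is positive.

    Returns (coordinates indexed by sample with columns PC1..PCk, explained
    variance fractions).
    """
    from .vario import maf_filter

    t = maf_filter(table, maf_threshold)
    if t.n_samples < 2 or t.n_sites == 0:
        raise ValueError("PCA needs >= 2 samples and >= 1 polymorphic site")
    dos = t.alt_dosage()
    alt, called = t.allele_counts()
    p = alt / called
    keep = (p > 0) & (p < 1)
    dos, p = dos[keep], p[keep]
    if dos.size == 0:
        raise ValueError("zero-variance input")
    z = (dos - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    z = np.nan_to_num(z, nan=0.0)
    m = z.shape[0]
    grm = z.T @ z / m
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, len(vals))
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] *= -1
    explained = np.maximum(vals, 0.0)
    explained = explained[:k] / explained.sum() if explained.sum() > 0 else explained[:k]
    frame = pd.DataFrame(coords, index=t.samples,
                         columns=[f"PC{i + 1}" for i in range(k)])
    frame.insert(0, "population",
                 [t.populations.get(s, "") for s in t.samples])
    return frame, explained
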