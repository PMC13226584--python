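"""Agreement between dissimilarity matrices: Mantel tests and summaries.

The Mantel test asks whether two distance matrices over the same samples are
correlated: the observed statistic is Pearson's (or Spearman's) r between the
condensed upper triangles, and the null distribution is built by jointly
permuting the rows and columns of one matrix.  The permutation p-value uses
the add-one convention p = (hits + 1) / (n_permutations + 1), so with 999
permutations the smallest attainable p is 0.001.

For the Spearman statistic, the matrix entries are rank-transformed once up
front: a joint row/column permutation preserves the multiset of condensed
entries, so the ranks of a permuted matrix equal the permuted ranks.  This
makes the Spearman permutation loop as cheap as the Pearson one; the
equivalence with naive per-permutation re-ranking is enforced by tests.

Also here: absolute-residual summaries between matrices, intra/inter-group
average dissimilarities, and UPGMA (average linkage) dendrograms in newick
form.  All matrix pairs are aligned by sample label, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .dissimilarity import DissimilarityMatrix
from .errors import DataError, UndefinedCorrelationError

__all__ = [
    "MantelResult",
    "condense",
    "correlation",
    "mantel",
    "residual_stats",
    "group_averages",
    "upgma_tree",
]

METHODS = ("pearson", "spearman")
ALTERNATIVES = ("two-sided", "greater", "less")


def condense(m: DissimilarityMatrix, atol: float = 1e-12) -> np.ndarray:
    """Upper-triangle entries, row-major; rejects asymmetric/non-hollow input."""
    v = m.values
    if not np.allclose(v, v.T, atol=atol, rtol=0):
        raise DataError("matrix is not symmetric within tolerance")
    if v.size and np.abs(np.diag(v)).max() > atol:
        raise DataError("matrix diagonal is not zero within tolerance")
    return m.condensed()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation of two equal-length vectors.

    Spearman is Pearson on midrank-transformed values (ties get average
    ranks).  Zero variance in either vector is an error, not NaN.
    """
    if method not in METHODS:
        raise DataError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DataError("correlation needs two equal-length vectors of length >= 3")
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    return _pearson(x, y)


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int
    alternative: str

    def __post_init__(self) -> None:
        if not (self.p_value >= 1.0 / (self.n_permutations + 1)):
            raise ValueError("p-value below permutation floor")


def mantel(
    m1: DissimilarityMatrix,
    m2: DissimilarityMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    alternative: str = "two-sided",
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test between two labelled dissimilarity matrices.

    ``m2`` is aligned to ``m1``'s labels before anything else, so row order
    on disk is irrelevant.  Rows/columns of the first matrix are jointly
    permuted ``n_permutations`` times; the returned statistic is exactly
    ``correlation(condense(m1), condense(m2), method)``.
    """
    if method not in METHODS:
        raise DataError(f"unknown correlation method {method!r}")
    if alternative not in ALTERNATIVES:
        raise DataError(f"unknown alternative {alternative!r}")
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    if sorted(map(str, m1.labels)) != sorted(map(str, m2.labels)):
        raise DataError("mantel: matrices have different sample labels")
    m2 = m2.reorder(m1.labels)
    n = m1.n
    if n < 3:
        raise DataError("mantel requires at least 3 samples")

    x = condense(m1)
    y = condense(m2)
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    observed = _pearson(x, y)

    # Permutation loop: centre/norm of the permuted x-vector are invariant
    # (the condensed multiset is preserved), so precompute both margins.
    X = squareform(x, checks=False)
    yc = y - y.mean()
    ny = np.sqrt(yc @ yc)
    xm = x.mean()
    nx = np.sqrt(((x - xm) ** 2).sum())
    iu = np.triu_indices(n, k=1)

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for i in range(n_permutations):
        p = rng.permutation(n)
        xp = X[np.ix_(p, p)][iu]
        perm_stats[i] = ((xp - xm) @ yc) / (nx * ny)

    if alternative == "two-sided":
        hits = int(np.sum(np.abs(perm_stats) >= abs(observed)))
    elif alternative == "greater":
        hits = int(np.sum(perm_stats >= observed))
    else:
        hits = int(np.sum(perm_stats <= observed))
    p_value = (hits + 1) / (n_permutations + 1)
    return MantelResult(observed, p_value, method, n_permutations, alternative)


def residual_stats(m1: DissimilarityMatrix, m2: DissimilarityMatrix,
                   ddof: int = 0) -> tuple[float, float]:
    """Mean and variance of absolute residuals between condensed matrices.

    Variance is the population variance (ddof=0) by default; symmetric in
    its arguments.
    """
    if sorted(map(str, m1.labels)) != sorted(map(str, m2.labels)):
        raise DataError("residual_stats: matrices have different sample labels")
    r = np.abs(condense(m1) - condense(m2.reorder(m1.labels)))
    return float(r.mean()), float(r.var(ddof=ddof))


def group_averages(m: DissimilarityMatrix, groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean dissimilarity within and between sample groups.

    One row per unordered group pair; (G, G) rows are intra-group averages
    over distinct sample pairs (NaN for singleton groups), (G, H) rows
    average all cross pairs.
    """
    missing = [l for l in m.labels if l not in groups]
    if missing:
        raise DataError(f"samples without a group label: {missing}")
    names = sorted({groups[l] for l in m.labels})
    members = {g: [i for i, l in enumerate(m.labels) if groups[l] == g] for g in names}
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                idx = members[ga]
                vals = [m.values[a, b] for ai, a in enumerate(idx) for b in idx[ai + 1:]]
            else:
                vals = [m.values[a, b] for a in members[ga] for b in members[gb]]
            rows.append((ga, gb, float(np.mean(vals)) if vals else float("nan"), len(vals)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_dissimilarity", "n_pairs"])


def upgma_tree(m: DissimilarityMatrix) -> str:
    """UPGMA (average linkage) dendrogram of a dissimilarity matrix, as newick.

    Agglomerates the closest pair at each step; cluster height is half the
    merge distance and branch lengths are ultrametric height differences.
    Ties are broken deterministically in favour of the pair containing the
    lexicographically smallest member label (then the smaller partner label),
    so the output is a pure function of the matrix.
    """
    n = m.n
    if n < 2:
        raise DataError("upgma_tree needs at least 2 samples")
    m.validate(atol=1e-9)

    labels = [str(l) for l in m.labels]
    nodes = [{"newick": labels[i], "min_label": labels[i], "height": 0.0, "size": 1}
             for i in range(n)]
    dist = {(i, j): float(m.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n

    def tiebreak(pair):
        i, j = pair
        a, b = sorted((nodes[i]["min_label"], nodes[j]["min_label"]))
        return (dist[pair], a, b)

    while len(active) > 1:
        best = min(((i, j) for ai, i in enumerate(active) for j in active[ai + 1:]),
                   key=tiebreak)
        i, j = best
        d = dist[best]
        height = d / 2.0
        bi = height - nodes[i]["height"]
        bj = height - nodes[j]["height"]
        # put the lexicographically smaller subtree first for a stable string
        (ci, bl1), (cj, bl2) = sorted(((i, bi), (j, bj)),
                                      key=lambda t: nodes[t[0]]["min_label"])
        merged = {
            "newick": f"({nodes[ci]['newick']}:{bl1:.10g},{nodes[cj]['newick']}:{bl2:.10g})",
            "min_label": min(nodes[i]["min_label"], nodes[j]["min_label"]),
            "height": height,
            "size": nodes[i]["size"] + nodes[j]["size"],
        }
        nodes.append(merged)
        for x in active:
            if x in (i, j):
                continue
            dxi = dist[tuple(sorted((x, i)))]
            dxj = dist[tuple(sorted((x, j)))]
            w = (nodes[i]["size"] * dxi + nodes[j]["size"] * dxj) / merged["size"]
            dist[(x, next_id) if x < next_id else (next_id, x)] = w
        active = [x for x in active if x not in (i, j)] + [next_id]
        next_id += 1

    return nodes[active[0]]["newick"] + ";"
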