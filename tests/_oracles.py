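"""Naive reference implementations used as independent oracles in tests.

Everything here is deliberately written the slow, obvious way (string
slicing, explicit loops, per-permutation re-ranking) and shares no code with
the package internals it checks.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def canonical_kmers(seq: str, k: int, canonical: bool = True) -> list[str]:
    """Window enumeration with string reverse-complement canonicalisation."""
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b not in "ACGT" for b in window):
            continue
        out.append(min(window, revcomp(window)) if canonical else window)
    return out


def count_kmers(reads, k: int, min_count: int = 1, canonical: bool = True) -> dict[str, int]:
    counts = Counter()
    for read in reads:
        counts.update(canonical_kmers(read, k, canonical))
    return {w: c for w, c in counts.items() if c >= min_count}


def bray_curtis(a: dict, b: dict) -> float:
    """Per-species loop over the union, straight from the definition."""
    species = set(a) | set(b)
    sum_min = sum(min(a.get(s, 0), b.get(s, 0)) for s in species)
    total = sum(a.values()) + sum(b.values())
    return 1.0 - 2.0 * sum_min / total

def jaccard_distance(a, b) -> float:
    sa = {s for s, v in dict(a).items() if v > 0} if isinstance(a, dict) else set(a)
    sb = {s for s, v in dict(b).items() if v > 0} if isinstance(b, dict) else set(b)
    return 1.0 - len(sa & sb) / len(sa | sb)


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def rank_average(x) -> np.ndarray:
    """Midranks computed by explicit tie-group averaging."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mantel_naive(values1: np.ndarray, values2: np.ndarray, method: str,
                 n_permutations: int, alternative: str, seed: int):
    """Mantel test with full per-permutation recomputation (incl. re-ranking).

    Draws permutations from the same generator protocol as the package
    (``default_rng(seed).permutation(n)`` per iteration) so outcomes are
    comparable draw for draw.
    """
    n = values1.shape[0]
    iu = np.triu_indices(n, 1)

    def stat(m):
        x, y = m[iu], values2[iu]
        if method == "spearman":
            x, y = rank_average(x), rank_average(y)
        return pearson(x, y)

    observed = stat(values1)
    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(n_permutations):
        p = rng.permutation(n)
        perms.append(stat(values1[np.ix_(p, p)]))
    perms = np.array(perms)
    if alternative == "two-sided":
        hits = int((np.abs(perms) >= abs(observed)).sum())
    elif alternative == "greater":
        hits = int((perms >= observed).sum())
    else:
        hits = int((perms <= observed).sum())
    return observed, (hits + 1) / (n_permutations + 1)


def group_means(values: np.ndarray, labels, groups) -> dict:
    """Brute-force double loop over all pairs, bucketed by group pair."""
    sums, counts = {}, {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((groups[labels[i]], groups[labels[j]])))
            sums[key] = sums.get(key, 0.0) + values[i, j]
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def random_ultrametric(rng: np.random.Generator, n_leaves: int):
    """A random ultrametric tree and its leaf distance matrix.

    Merges random cluster pairs at strictly increasing heights, so the
    topology is uniquely recoverable by average linkage.  Returns
    ``(labels, matrix, clades)`` where clades is the set of leaf-label
    frozensets of the internal nodes.
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    clusters = [{i} for i in range(n_leaves)]
    height = 0.0
    D = np.zeros((n_leaves, n_leaves))
    clades = set()
    while len(clusters) > 1:
        height += float(rng.uniform(0.05, 0.45))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                D[a, b] = D[b, a] = 2.0 * height
        merged = clusters[i] | clusters[j]
        clades.add(frozenset(labels[x] for x in merged))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    # normalise so entries stay in [0, 1]
    scale = D.max()
    return labels, D / (2.0 * scale), clades


def newick_clades(newick: str) -> set[frozenset]:
    """Internal-node leaf sets of a newick tree, via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    clades = set()
    for node in tree.preorder_node_iter():
        if node.is_internal():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            clades.add(leaves)
    return clades
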