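"""Bray-Curtis and Jaccard dissimilarities, abundance- and k-mer-based.

Both measures exist in two forms that share one algebraic skeleton:

* species-abundance form (the reference / ground-truth side), computed from
  per-sample species count vectors N_{X,i};
* k-mer form (the reference-free side), computed from the marginal and
  crossed terms of a pair of k-mer spectra.

Bray-Curtis:  BC(A,B) = 1 - 2 * sum_i min(N_A,i, N_B,i) / (N_A* + N_B*)
Jaccard distance:  d_J(A,B) = 1 - |S_A inter S_B| / |S_A union S_B|

where N_X* is the sample total and S_X the support (species or k-mers with
non-zero count).  Counts are used raw — Bray-Curtis is invariant to jointly
rescaling both samples but not to per-sample normalisation, which would turn
it into a Manhattan-type distance; an explicit ``normalize`` switch exists on
:func:`bc_from_profiles` and defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UndefinedDistanceError
from .kmer_engine import KmerSpectrum, PairStats, merge_stats

__all__ = [
    "AbundanceProfile",
    "DissimilarityMatrix",
    "bc_from_profiles",
    "bc_from_pair_stats",
    "jaccard_distance_from_profiles",
    "jaccard_distance_from_pair_stats",
    "build_matrix",
    "build_matrices",
    "METRICS",
]

METRICS = ("bray_curtis", "jaccard")


@dataclass
class AbundanceProfile:
    """Per-sample species abundance vector.

    ``counts`` maps species identifiers to non-negative counts; estimated
    (real-valued) abundances from classifier reports are accepted as well as
    integer truth counts — the dissimilarity formulas are count-agnostic.
    """

    sample_id: str
    counts: dict = field(repr=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise DataError(f"profile {self.sample_id}: negative abundance")

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    @property
    def support(self) -> frozenset:
        return frozenset(s for s, v in self.counts.items() if v > 0)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.sample_id)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species_id\tcount\n")
            for sp in sorted(self.counts, key=str):
                fh.write(f"{sp}\t{self.counts[sp]}\n")


def bc_from_profiles(a: AbundanceProfile, b: AbundanceProfile,
                     normalize: bool = False) -> float:
    """Species-level Bray-Curtis dissimilarity between two profiles.

    With ``normalize=True`` each profile is first scaled to relative
    abundances (non-default; changes the measure, see module docstring).
    """
    ta, tb = a.total, b.total
    if ta <= 0 or tb <= 0:
        raise UndefinedDistanceError(
            f"Bray-Curtis undefined for empty profile(s) {a.sample_id!r}/{b.sample_id!r}")
    sa = 1.0 / ta if normalize else 1.0
    sb = 1.0 / tb if normalize else 1.0
    shared = a.support & b.support
    sum_min = sum(min(a.counts[s] * sa, b.counts[s] * sb) for s in shared)
    return 1.0 - 2.0 * sum_min / (ta * sa + tb * sb)


def bc_from_pair_stats(s: PairStats) -> float:
    """k-mer Bray-Curtis from a pair's marginal and crossed terms."""
    denom = s.total_a + s.total_b
    if denom <= 0:
        raise UndefinedDistanceError("Bray-Curtis undefined: both spectra empty")
    return 1.0 - 2.0 * s.sum_min / denom


def jaccard_distance_from_profiles(a: AbundanceProfile, b: AbundanceProfile) -> float:
    """Presence-based Jaccard distance over species supports."""
    union = a.support | b.support
    if not union:
        raise UndefinedDistanceError(
            f"Jaccard undefined for empty supports {a.sample_id!r}/{b.sample_id!r}")
    return 1.0 - len(a.support & b.support) / len(union)


def jaccard_distance_from_pair_stats(s: PairStats) -> float:
    """k-mer Jaccard distance over spectrum supports (post min_count filter)."""
    if s.n_union <= 0:
        raise UndefinedDistanceError("Jaccard undefined: both spectra empty")
    return 1.0 - s.n_intersection / s.n_union


@dataclass
class DissimilarityMatrix:
    """Labelled symmetric hollow matrix of dissimilarities in [0, 1]."""

    labels: list
    values: np.ndarray
    metric_name: str = ""
    k: int | None = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError(f"matrix shape {self.values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise DataError("duplicate sample labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol, rtol=0):
            raise DataError(f"matrix {self.metric_name!r} is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > atol:
            raise DataError(f"matrix {self.metric_name!r} has a non-zero diagonal")
        if v.size and (v.min() < -atol or v.max() > 1 + atol):
            raise DataError(f"matrix {self.metric_name!r} has entries outside [0, 1]")

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (length n(n-1)/2)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence) -> "DissimilarityMatrix":
        """Return the matrix re-indexed to ``labels`` (alignment by label)."""
        missing = [l for l in labels if l not in self.labels]
        if missing or len(labels) != self.n:
            raise DataError(f"label mismatch: {missing or 'length differs'}")
        idx = [self.labels.index(l) for l in labels]
        return DissimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)],
                                   self.metric_name, self.k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        """Headered TSV with a '#metric'/'#k' metadata preamble."""
        with open(path, "w") as fh:
            fh.write(f"#metric\t{self.metric_name}\n")
            fh.write(f"#k\t{'' if self.k is None else self.k}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "DissimilarityMatrix":
        metric, k = "", None
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("\t")
                if key == "metric":
                    metric = value
                elif key == "k" and value:
                    k = int(value)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            try:
                df = pd.read_csv(fh, sep="\t", index_col=0)
            except Exception as exc:
                raise FormatError(f"{path}: cannot parse matrix TSV: {exc}") from exc
        if list(df.index) != list(df.columns):
            raise FormatError(f"{path}: row and column labels differ")
        m = cls([str(l) for l in df.index], df.to_numpy(dtype=float), metric, k)
        m.validate(atol=1e-9)
        return m

    def write_phylip(self, path) -> None:
        """PHYLIP square distance matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(str(label)[:10].ljust(10) + "  " +
                         "  ".join(f"{x:.6f}" for x in row) + "\n")


_PROFILE_METRICS = {
    "bray_curtis": bc_from_profiles,
    "jaccard": jaccard_distance_from_profiles,
}
_PAIRSTATS_METRICS = {
    "bray_curtis": bc_from_pair_stats,
    "jaccard": jaccard_distance_from_pair_stats,
}


def build_matrices(items: Sequence, metrics: Iterable[str]) -> dict[str, DissimilarityMatrix]:
    """Evaluate one or more dissimilarities over all pairs of samples.

    ``items`` is an ordered collection of :class:`AbundanceProfile` or
    :class:`KmerSpectrum`; each of the n(n-1)/2 pairs is evaluated once (for
    spectra, the pair statistics are computed once and shared across metrics).
    """
    metrics = list(metrics)
    unknown = [m for m in metrics if m not in METRICS]
    if unknown:
        raise DataError(f"unknown metric(s) {unknown}; choose from {METRICS}")
    items = list(items)
    if len(items) < 2:
        raise DataError("need at least 2 samples to build a matrix")
    labels = [it.sample_id for it in items]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate sample_ids in matrix input")

    spectra = isinstance(items[0], KmerSpectrum)
    k = None
    if spectra:
        ks = {it.k for it in items}
        if len(ks) != 1:
            raise DataError(f"inconsistent k across spectra: {sorted(ks)}")
        k = ks.pop()

    n = len(items)
    out = {m: np.zeros((n, n)) for m in metrics}
    for i in range(n):
        for j in range(i + 1, n):
            if spectra:
                stats = merge_stats(items[i], items[j])
            for m in metrics:
                try:
                    d = (_PAIRSTATS_METRICS[m](stats) if spectra
                         else _PROFILE_METRICS[m](items[i], items[j]))
                except UndefinedDistanceError as exc:
                    raise UndefinedDistanceError(
                        f"{m} undefined for pair ({labels[i]}, {labels[j]}): {exc}") from exc
                out[m][i, j] = out[m][j, i] = d
    return {m: DissimilarityMatrix(labels, out[m], m, k) for m in metrics}


def build_matrix(items: Sequence, metric: str) -> DissimilarityMatrix:
    """Single-metric convenience wrapper around :func:`build_matrices`."""
    return build_matrices(items, [metric])[metric]
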