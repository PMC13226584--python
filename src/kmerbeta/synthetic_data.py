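"""Synthetic metagenomic communities with read-level ground truth.

Emulates a small multi-environment study (e.g. four body sites with three
samples each): a global species pool of random genomes, per-environment
species subsets with a shared core, heavy-tailed (log-normal) per-sample
abundances, fixed-length single-end reads with uniform substitution errors,
and a read -> species truth table that replaces taxonomic read mapping.

Every stage draws from its own generator, seeded as a pure function of
``master_seed`` and the stage name (plus sample coordinates), so the whole
simulation is reproducible from one integer and adding samples never perturbs
existing ones.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dissimilarity import AbundanceProfile
from .errors import DataError, InvalidDesignError
from .kmer_engine import _CODE_BASE

__all__ = [
    "SpeciesGenome",
    "CommunityDesign",
    "TruthTable",
    "generate_genomes",
    "environment_supports",
    "sample_abundances",
    "simulate_reads",
    "simulate_community",
    "largest_remainder",
    "write_fastq",
    "write_fasta",
    "read_sequences",
]


def stage_rng(master_seed: int, *tokens) -> np.random.Generator:
    """Generator seeded purely by (master_seed, tokens) via a stable hash."""
    digest = hashlib.sha256("|".join(str(t) for t in tokens).encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                int.from_bytes(digest[:8], "little")]))


@dataclass(frozen=True)
class SpeciesGenome:
    """A species' reference sequence (uniform random stand-in for a real genome)."""

    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise DataError(f"genome {self.species_id}: sequence must be non-empty A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CommunityDesign:
    """Parameters of one synthetic multi-environment community.

    Defaults describe the study-scale scenario used throughout: 4 environments
    x 3 samples, a pool of 40 species (100 kb genomes), 12 species per
    environment of which a quarter come from a shared core, log-normal
    abundances (sigma=1), and 5x10^4 error-bearing 150 bp reads per sample at
    a 1% substitution rate.

    ``reads_per_sample_spread`` (default 1.0 = constant depth) draws each
    sample's depth log-uniformly from [reads/spread, reads*spread] to model
    heterogeneous sequencing effort.
    """

    n_environments: int = 4
    samples_per_environment: int = 3
    pool_size: int = 40
    species_per_environment: int = 12
    shared_fraction: float = 0.25
    abundance_sigma: float = 1.0
    reads_per_sample: int = 50_000
    read_length: int = 150
    substitution_rate: float = 0.01
    genome_length: int = 100_000
    master_seed: int = 0
    reads_per_sample_spread: float = 1.0

    def __post_init__(self) -> None:
        positive = ("n_environments", "samples_per_environment", "pool_size",
                    "species_per_environment", "reads_per_sample", "read_length",
                    "genome_length")
        for name in positive:
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be a positive integer")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise InvalidDesignError("shared_fraction must be in [0, 1]")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise InvalidDesignError("substitution_rate must be in [0, 1)")
        if self.abundance_sigma <= 0:
            raise InvalidDesignError("abundance_sigma must be positive")
        if self.reads_per_sample_spread < 1.0:
            raise InvalidDesignError("reads_per_sample_spread must be >= 1")
        if self.species_per_environment > self.pool_size:
            raise InvalidDesignError("species_per_environment exceeds pool_size")
        if self.read_length > self.genome_length:
            raise InvalidDesignError("read_length exceeds genome_length")
        needed = self.n_core + self.n_environments * (self.species_per_environment - self.n_core)
        if needed > self.pool_size:
            raise InvalidDesignError(
                f"pool_size={self.pool_size} too small: core + private supports need {needed} species")

    @property
    def n_core(self) -> int:
        """Number of core species shared by every environment."""
        return int(round(self.shared_fraction * self.species_per_environment))

    def sample_id(self, environment_index: int, sample_index: int) -> str:
        return f"E{environment_index + 1}S{sample_index + 1}"

    def environment_label(self, environment_index: int) -> str:
        return f"env{environment_index + 1}"

    def sample_coords(self) -> list[tuple[int, int]]:
        return [(e, s) for e in range(self.n_environments)
                for s in range(self.samples_per_environment)]

    def group_labels(self) -> dict[str, str]:
        """sample_id -> environment label, for intra/inter summaries."""
        return {self.sample_id(e, s): self.environment_label(e)
                for e, s in self.sample_coords()}

    def with_seed(self, master_seed: int) -> "CommunityDesign":
        return replace(self, master_seed=master_seed)


@dataclass
class TruthTable:
    """Read-level ground truth: one (read_id, sample_id, species_id) row per read."""

    records: list = field(default_factory=list)

    def extend(self, rows: Iterable[tuple[str, str, str]]) -> None:
        self.records.extend(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["read_id", "sample_id", "species_id"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["read_id", "sample_id", "species_id"]
        if list(df.columns) != expected:
            raise DataError(f"{path}: truth table must have columns {expected}")
        return cls(list(df.itertuples(index=False, name=None)))


def generate_genomes(design: CommunityDesign) -> dict[str, SpeciesGenome]:
    """The global species pool: i.i.d. uniform-base genomes, one per species."""
    rng = stage_rng(design.master_seed, "genomes")
    genomes: dict[str, SpeciesGenome] = {}
    for i in range(design.pool_size):
        species_id = f"sp{i + 1:03d}"
        bases = rng.integers(0, 4, size=design.genome_length, dtype=np.uint8)
        genomes[species_id] = SpeciesGenome(species_id, _CODE_BASE[bases].tobytes().decode("ascii"))
    return genomes


def environment_supports(design: CommunityDesign) -> list[list[str]]:
    """Species subset of each environment: shared core + disjoint private block.

    The pool is shuffled once (seeded by master_seed alone); the first
    ``n_core`` species form the core present in every environment, and each
    environment takes its own consecutive block of private species, so
    ``shared_fraction=0`` yields pairwise-disjoint supports.
    """
    rng = stage_rng(design.master_seed, "supports")
    order = rng.permutation(design.pool_size)
    ids = [f"sp{i + 1:03d}" for i in order]
    n_core = design.n_core
    n_private = design.species_per_environment - n_core
    core = ids[:n_core]
    supports = []
    for e in range(design.n_environments):
        start = n_core + e * n_private
        supports.append(sorted(core + ids[start:start + n_private]))
    return supports


def _sample_depth(design: CommunityDesign, environment_index: int, sample_index: int) -> int:
    if design.reads_per_sample_spread == 1.0:
        return design.reads_per_sample
    rng = stage_rng(design.master_seed, "depth",
                    design.sample_id(environment_index, sample_index))
    factor = design.reads_per_sample_spread ** rng.uniform(-1.0, 1.0)
    return max(1, int(round(design.reads_per_sample * factor)))


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerise non-negative weights to counts summing exactly to ``total``.

    Apportions floor(total * w / sum(w)) first, then hands the remaining units
    to the largest fractional parts (ties broken by lower index), so the
    result is deterministic and conserves the total exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise DataError("largest_remainder: weights sum to zero")
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(np.int64)
    short = total - int(counts.sum())
    if short > 0:
        order = np.lexsort((np.arange(weights.size), -(quota - counts)))
        counts[order[:short]] += 1
    return counts


def sample_abundances(design: CommunityDesign, environment_index: int,
                      sample_index: int) -> AbundanceProfile:
    """True abundance profile of one sample.

    Relative abundances are log-normal(0, sigma) over the environment's
    species support, then integerised by largest remainder so counts sum
    exactly to the sample's read depth.
    """
    if not (0 <= environment_index < design.n_environments):
        raise DataError(f"environment_index {environment_index} out of range")
    if not (0 <= sample_index < design.samples_per_environment):
        raise DataError(f"sample_index {sample_index} out of range")
    support = environment_supports(design)[environment_index]
    sample_id = design.sample_id(environment_index, sample_index)
    rng = stage_rng(design.master_seed, "abundances", sample_id)
    rel = rng.lognormal(mean=0.0, sigma=design.abundance_sigma, size=len(support))
    depth = _sample_depth(design, environment_index, sample_index)
    counts = largest_remainder(rel, depth)
    return AbundanceProfile(sample_id, {sp: int(c) for sp, c in zip(support, counts) if c > 0})


def simulate_reads(genomes: Mapping[str, SpeciesGenome], profile: AbundanceProfile,
                   design: CommunityDesign) -> tuple[list[tuple[str, str]], TruthTable]:
    """Error-bearing single-end reads for one sample, plus their truth rows.

    For each species i with truth count N_i, emits exactly N_i reads of
    ``read_length`` bp: uniform start, uniform strand (reverse reads are
    reverse-complemented), and each base substituted independently with
    probability ``substitution_rate`` to a uniformly chosen different base.
    """
    L = design.read_length
    for sp in profile.support:
        if sp not in genomes:
            raise DataError(f"species {sp} has no genome")
        if genomes[sp].length < L:
            raise DataError(f"genome {sp} shorter than read_length={L}")

    rng = stage_rng(design.master_seed, "reads", profile.sample_id)
    reads: list[tuple[str, str]] = []
    truth = TruthTable()
    serial = 0
    for sp in sorted(profile.support):
        n = int(profile.counts[sp])
        gseq = np.frombuffer(genomes[sp].sequence.encode("ascii"), dtype=np.uint8)
        gcodes = np.zeros(gseq.size, dtype=np.uint8)
        for b, c in zip(b"ACGT", range(4)):
            gcodes[gseq == b] = c
        starts = rng.integers(0, gseq.size - L + 1, size=n)
        mat = gcodes[starts[:, None] + np.arange(L)[None, :]]
        reverse = rng.random(n) < 0.5
        mat[reverse] = 3 - mat[reverse][:, ::-1]
        if design.substitution_rate > 0:
            hit = rng.random(mat.shape) < design.substitution_rate
            offsets = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
            mat = np.where(hit, (mat + offsets) % 4, mat)
        ascii_mat = _CODE_BASE[mat]
        for row in ascii_mat:
            read_id = f"{profile.sample_id}_r{serial:07d}"
            reads.append((read_id, row.tobytes().decode("ascii")))
            truth.records.append((read_id, profile.sample_id, sp))
            serial += 1
    return reads, truth


def simulate_community(design: CommunityDesign):
    """Full simulation: genomes, per-sample profiles, reads, and one truth table.

    Returns ``(genomes, profiles, reads, truth)`` where ``profiles`` and
    ``reads`` are dicts keyed by sample_id in design order.
    """
    genomes = generate_genomes(design)
    profiles: dict[str, AbundanceProfile] = {}
    reads: dict[str, list[tuple[str, str]]] = {}
    truth = TruthTable()
    for e, s in design.sample_coords():
        profile = sample_abundances(design, e, s)
        sample_reads, sample_truth = simulate_reads(genomes, profile, design)
        profiles[profile.sample_id] = profile
        reads[profile.sample_id] = sample_reads
        truth.extend(sample_truth.records)
    return genomes, profiles, reads, truth


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """4-line FASTQ records with a constant quality string; .gz supported."""
    with _open_text(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_fasta(path, genomes: Mapping[str, SpeciesGenome], width: int = 80) -> None:
    with _open_text(path, "w") as fh:
        for sp in sorted(genomes):
            fh.write(f">{sp}\n")
            seq = genomes[sp].sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_sequences(path) -> list[str]:
    """Sequences from a FASTA/FASTQ file (plain or gzipped), as strings."""
    from Bio import SeqIO

    path = str(path)
    fmt = "fastq" if path.removesuffix(".gz").endswith(("fastq", "fq")) else "fasta"
    with _open_text(path, "r") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
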