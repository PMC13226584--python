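"""End-to-end validation experiment orchestration.

One call runs the whole study: simulate a multi-environment community, count
canonical k-mers per sample (singletons excluded), build truth-side and
k-mer-side Bray-Curtis / Jaccard matrices for every requested k, and quantify
their agreement (Mantel Pearson/Spearman with permutations, absolute-residual
summaries, intra/inter-environment averages, UPGMA dendrograms).  Every
random draw is seeded from the single master seed, so two runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import correlation_stats as cs
from . import dissimilarity as dm
from . import synthetic_data as sd
from .errors import ConfigError, DataError, KmerBetaError
from .kmer_engine import count_sample

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "compare_external"]

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = (16, 21, 26, 31)


def stage_seed(master_seed: int, *tokens) -> int:
    """Deterministic sub-seed (< 2^31) for a named pipeline stage."""
    digest = hashlib.sha256(
        "|".join([str(int(master_seed) & 0x7FFFFFFF)] + [str(t) for t in tokens]).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one validation experiment."""

    community: sd.CommunityDesign = field(default_factory=sd.CommunityDesign)
    k_values: tuple = DEFAULT_K_VALUES
    min_count: int = 2
    metrics: tuple = dm.METRICS
    n_permutations: int = 999
    mantel_methods: tuple = ("pearson", "spearman")
    output_dir: str | None = None
    master_seed: int | None = None  # overrides community.master_seed when set
    write_reads: bool = True

    def __post_init__(self) -> None:
        if not self.k_values:
            raise ConfigError("k_values must be non-empty")
        for k in self.k_values:
            if not (1 <= k <= 31):
                raise ConfigError(f"k={k} outside [1, 31]")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        bad = [m for m in self.metrics if m not in dm.METRICS]
        if bad:
            raise ConfigError(f"unknown metric(s) {bad}")
        bad = [m for m in self.mantel_methods if m not in cs.METHODS]
        if bad:
            raise ConfigError(f"unknown mantel method(s) {bad}")
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")

    @property
    def design(self) -> sd.CommunityDesign:
        if self.master_seed is None:
            return self.community
        return self.community.with_seed(self.master_seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            community = sd.CommunityDesign(**raw.pop("community", {}))
            for key in ("k_values", "metrics", "mantel_methods"):
                if key in raw:
                    raw[key] = tuple(raw[key])
            return cls(community=community, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc


@dataclass
class ExperimentReport:
    """In-memory results of one experiment run."""

    config: ExperimentConfig
    truth_matrices: dict
    kmer_matrices: dict  # (metric, k) -> DissimilarityMatrix
    mantel_results: dict  # (metric, k, method) -> MantelResult
    residuals: dict  # (metric, k) -> (mean, variance)
    group_tables: dict  # matrix name -> DataFrame
    trees: dict  # matrix name -> newick string
    output_dir: Path | None = None

    def correlation_table(self, metric: str):
        """Per-k Mantel table: k, pearson_r, pearson_p, spearman_r, spearman_p."""
        import pandas as pd

        rows = []
        for k in self.config.k_values:
            row: dict = {"k": k}
            for method in self.config.mantel_methods:
                res = self.mantel_results[(metric, k, method)]
                row[f"{method}_r"] = res.statistic
                row[f"{method}_p"] = res.p_value
            rows.append(row)
        return pd.DataFrame(rows)

    def residual_table(self, metric: str):
        import pandas as pd

        return pd.DataFrame(
            [{"k": k, "mean": self.residuals[(metric, k)][0],
              "var": self.residuals[(metric, k)][1]} for k in self.config.k_values])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class _Stage:
    """Logs wall time per stage; marks the output dir FAILED on error."""

    def __init__(self, name: str, out: Path | None):
        self.name = name
        self.out = out

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            if self.out is not None:
                (self.out / "FAILED").write_text(f"stage: {self.name}\nerror: {exc}\n")
            logger.error("stage %s failed: %s", self.name, exc)
            if not isinstance(exc, KmerBetaError):
                raise KmerBetaError(f"stage {self.name} failed: {exc}") from exc
            return False
        logger.info("stage %s done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full simulate -> count -> distance -> correlate experiment."""
    design = config.design
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for sub in ("matrices", "reports", "trees"):
            (out / sub).mkdir(exist_ok=True)

    with _Stage("simulate", out):
        genomes, profiles, reads, truth = sd.simulate_community(design)
        logger.info("simulated %d samples, %d reads total",
                    len(profiles), sum(len(r) for r in reads.values()))
        if out is not None:
            sd.write_fasta(out / "genomes.fasta", genomes)
            truth.write_tsv(out / "truth.tsv")
            if config.write_reads:
                (out / "reads").mkdir(exist_ok=True)
                for sid, rs in reads.items():
                    sd.write_fastq(out / "reads" / f"{sid}.fastq", rs)

    sample_ids = list(profiles)
    groups = design.group_labels()

    with _Stage("truth-matrices", out):
        truth_matrices = dm.build_matrices([profiles[s] for s in sample_ids], config.metrics)
        truth_matrices = {m: dataclasses.replace(mat, metric_name=f"truth_{m}")
                          for m, mat in truth_matrices.items()}

    kmer_matrices: dict = {}
    with _Stage("kmer-matrices", out):
        for k in config.k_values:
            spectra = [count_sample((seq for _, seq in reads[s]), k,
                                    min_count=config.min_count, sample_id=s)
                       for s in sample_ids]
            for m, mat in dm.build_matrices(spectra, config.metrics).items():
                kmer_matrices[(m, k)] = dataclasses.replace(mat, metric_name=f"kmer_{m}")

    mantel_results: dict = {}
    residuals: dict = {}
    with _Stage("correlation", out):
        for m in config.metrics:
            for k in config.k_values:
                for method in config.mantel_methods:
                    mantel_results[(m, k, method)] = cs.mantel(
                        kmer_matrices[(m, k)], truth_matrices[m], method=method,
                        n_permutations=config.n_permutations,
                        seed=stage_seed(design.master_seed, "mantel", m, k, method))
                residuals[(m, k)] = cs.residual_stats(kmer_matrices[(m, k)], truth_matrices[m])

    group_tables: dict = {}
    trees: dict = {}
    with _Stage("summaries", out):
        named = {f"truth_{m}": mat for m, mat in truth_matrices.items()}
        named.update({f"kmer_{m}_k{k}": mat for (m, k), mat in kmer_matrices.items()})
        for name, mat in named.items():
            group_tables[name] = cs.group_averages(mat, groups)
            trees[name] = cs.upgma_tree(mat)

    report = ExperimentReport(config, truth_matrices, kmer_matrices, mantel_results,
                              residuals, group_tables, trees, out)

    if out is not None:
        with _Stage("write-outputs", out):
            _write_outputs(report, named, out, design)
    return report


def _write_outputs(report: ExperimentReport, named: Mapping, out: Path,
                   design: sd.CommunityDesign) -> None:
    for name, mat in named.items():
        mat.write_tsv(out / "matrices" / f"{name}.tsv")
        mat.write_phylip(out / "matrices" / f"{name}.phylip")
        (out / "trees" / f"{name}.nwk").write_text(report.trees[name] + "\n")
        report.group_tables[name].to_csv(out / "reports" / f"group_averages_{name}.tsv",
                                         sep="\t", index=False)
    for m in report.config.metrics:
        report.correlation_table(m).to_csv(out / "reports" / f"correlations_{m}.tsv",
                                           sep="\t", index=False, float_format="%.6g")
        report.residual_table(m).to_csv(out / "reports" / f"residuals_{m}.tsv",
                                        sep="\t", index=False, float_format="%.6g")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": {**dataclasses.asdict(report.config),
                   "community": dataclasses.asdict(design)},
        "master_seed": design.master_seed,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def compare_external(path_a, path_b, methods=("pearson", "spearman"),
                     n_permutations: int = 999, alternative: str = "two-sided",
                     seed: int = 0) -> dict:
    """Mantel + residual report for two dissimilarity matrices on disk.

    Accepts matrix TSVs from any source (this package, Simka-style exports,
    R distance objects written as labelled TSV); alignment is by label.
    """
    a = dm.DissimilarityMatrix.read_tsv(path_a)
    b = dm.DissimilarityMatrix.read_tsv(path_b)
    report: dict = {"labels": list(map(str, a.labels)), "n": a.n}
    for method in methods:
        res = cs.mantel(a, b, method=method, n_permutations=n_permutations,
                        alternative=alternative, seed=stage_seed(seed, "compare", method))
        report[method] = {"statistic": res.statistic, "p_value": res.p_value,
                          "n_permutations": res.n_permutations}
    mean, var = cs.residual_stats(a, b)
    report["residuals"] = {"mean": mean, "variance": var}
    return report
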