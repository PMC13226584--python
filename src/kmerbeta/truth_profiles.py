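"""Species-abundance profiles from ground truth or classifier reports.

Two sources produce the reference-side abundance vectors:

* a simulation truth table mapping every read to its source species (exact
  ground truth, as available for simulated communities);
* a Bracken-style species report estimated by a taxonomic classifier (the
  reference-based proxy used when no truth exists).

All profiles are species-level by default; species from reports are keyed by
taxonomy id rather than name to avoid name collisions across reports.
Unclassified reads simply do not appear in a report and therefore contribute
nothing to the profile.
"""

from __future__ import annotations

import logging

import pandas as pd

from .dissimilarity import AbundanceProfile
from .errors import DataError, FormatError
from .synthetic_data import TruthTable

__all__ = ["profiles_from_truth", "read_bracken_profile", "BRACKEN_COLUMNS"]

logger = logging.getLogger(__name__)

BRACKEN_COLUMNS = [
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
]


def profiles_from_truth(truth: TruthTable) -> dict[str, AbundanceProfile]:
    """Per-sample species counts from a read-level truth table.

    N_{X,i} is the number of truth rows assigning a read of sample X to
    species i, so each profile's total equals the sample's read count.
    """
    df = truth.to_frame()
    if df.empty:
        raise DataError("truth table is empty")
    if df.duplicated(subset=["read_id", "sample_id"]).any():
        dup = df[df.duplicated(subset=["read_id", "sample_id"])].iloc[0]
        raise DataError(f"malformed truth: duplicate read {dup.read_id!r} in sample {dup.sample_id!r}")
    profiles = {}
    for sample_id, sub in df.groupby("sample_id", sort=True):
        counts = sub["species_id"].value_counts().to_dict()
        profiles[str(sample_id)] = AbundanceProfile(str(sample_id), counts)
    return profiles


def read_bracken_profile(report_path, sample_id: str, rank_filter: str = "S") -> AbundanceProfile:
    """Abundance profile from a Bracken species report (tab-separated).

    Rows at taxonomic rank ``rank_filter`` (default 'S' = species) become
    counts keyed by taxonomy id, using the estimated read count column.
    Ranks other than species are accepted but logged, since species level is
    the intended resolution of the analysis.
    """
    try:
        df = pd.read_csv(report_path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{report_path}: cannot parse Bracken report: {exc}") from exc
    missing = [c for c in BRACKEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{report_path}: missing Bracken column(s) {missing}")
    bad = df["new_est_reads"] != df["kraken_assigned_reads"] + df["added_reads"]
    if bad.any():
        raise FormatError(
            f"{report_path}: inconsistent rows where new_est_reads != kraken_assigned_reads + added_reads")
    if rank_filter != "S":
        logger.warning("rank_filter=%r: profiles at non-species ranks are non-standard here", rank_filter)
    at_rank = df[df["taxonomy_lvl"] == rank_filter]
    if at_rank.empty:
        raise DataError(f"{report_path}: no rows at rank {rank_filter!r}; profile unusable")
    counts = {int(t): float(n) for t, n in zip(at_rank["taxonomy_id"], at_rank["new_est_reads"])}
    return AbundanceProfile(sample_id, counts)
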