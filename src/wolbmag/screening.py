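"""Positivity screening, prevalence and titer estimation.

A host sequencing sample is called Wolbachia-positive when the breadth of
coverage of at least one reference genome strictly exceeds a threshold
(default 50% at >=1x depth). Prevalence is the proportion of positive
samples per host species; hosts with too few samples are not reported, and
zero-prevalence hosts are reported only for large screens. The titer
approximates symbiont cells per host cell from read counts normalised by
the two genome lengths:

    titer = (wolbachia_reads / L_wolbachia) / (host_reads / L_host)

Host reads are approximated as total minus Wolbachia reads, which slightly
overestimates the host fraction when other contaminants are present; the
titer is therefore a lower bound in contaminated samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "TiterEstimate",
    "breadth_of_coverage",
    "call_positive",
    "prevalence",
    "estimate_titer",
    "titer_table",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for positivity calling and prevalence reporting.

    breadth_threshold
        Minimum breadth of coverage (exclusive) of at least one reference
        for a sample to be called positive.
    depth_floor
        Fold-coverage a position must reach to count as covered (1x).
    assembly_depth_min
        Mean depth (exclusive) required before a sample is assembled (4x).
    prevalence_min_samples
        Hosts with fewer screened samples are left out of prevalence
        reports.
    zero_prevalence_min_samples
        Hosts with zero positives appear only when at least this many
        samples were screened.
    """

    breadth_threshold: float = 0.5
    depth_floor: float = 1.0
    assembly_depth_min: float = 4.0
    prevalence_min_samples: int = 7
    zero_prevalence_min_samples: int = 50

    def __post_init__(self) -> None:
        if self.breadth_threshold <= 0 or self.depth_floor <= 0:
            raise ValueError("thresholds must be positive")
        if self.prevalence_min_samples < 1 or self.zero_prevalence_min_samples < 1:
            raise ValueError("sample-count minima must be positive")


@dataclass(frozen=True)
class TiterEstimate:
    wolbachia_reads: int
    host_reads: int
    wolbachia_genome_length: int
    host_genome_length: int
    titer: float

    def __post_init__(self) -> None:
        if self.titer < 0:
            raise ValueError("titer must be >= 0")


def breadth_of_coverage(
    depth_vector: Sequence[float] | np.ndarray, depth_floor: float = 1.0
) -> float:
    """Fraction of reference positions covered at >= depth_floor."""
    depths = np.asarray(depth_vector, dtype=float)
    if depths.size == 0:
        raise ValueError("depth vector is empty")
    return float(np.mean(depths >= depth_floor))


def call_positive(
    breadths: Mapping[str, float] | Sequence[float],
    config: ScreenConfig = ScreenConfig(),
) -> bool:
    """Positive iff any per-reference breadth strictly exceeds the threshold."""
    values = list(breadths.values()) if isinstance(breadths, Mapping) else list(breadths)
    return any(b > config.breadth_threshold for b in values)


def prevalence(
    sample_table: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> pd.DataFrame:
    """Per-host prevalence report from a table with ``host`` and ``positive``.

    Returns one row per host: host, n_samples, n_positive, prevalence,
    reported (bool) and, when unreported, the reason
    (``insufficient_samples`` or ``zero_positive_small_screen``).
    """
    if sample_table.empty:
        raise ValueError("sample table is empty")
    for col in ("host", "positive"):
        if col not in sample_table.columns:
            raise ValueError(f"sample table lacks column {col!r}")
    rows = []
    for host, grp in sample_table.groupby("host", sort=True):
        n = len(grp)
        pos = int(grp["positive"].astype(bool).sum())
        reported, reason = True, ""
        if n < config.prevalence_min_samples:
            reported, reason = False, "insufficient_samples"
        elif pos == 0 and n < config.zero_prevalence_min_samples:
            reported, reason = False, "zero_positive_small_screen"
        rows.append(
            {
                "host": host,
                "n_samples": n,
                "n_positive": pos,
                "prevalence": pos / n,
                "reported": reported,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def estimate_titer(
    wolbachia_reads: int,
    total_reads: int,
    wolbachia_genome_length: int,
    host_genome_length: int,
) -> TiterEstimate:
    """Length-normalised symbiont-to-host read-density ratio.

    ``host_reads`` is taken as ``total_reads - wolbachia_reads``.
    """
    if wolbachia_reads < 0:
        raise ValueError("wolbachia_reads must be >= 0")
    if wolbachia_genome_length <= 0 or host_genome_length <= 0:
        raise ValueError("genome lengths must be positive")
    host_reads = total_reads - wolbachia_reads
    if host_reads <= 0:
        raise ValueError("titer undefined: no host reads (total <= wolbachia)")
    titer = (wolbachia_reads / wolbachia_genome_length) / (
        host_reads / host_genome_length
    )
    return TiterEstimate(
        wolbachia_reads=int(wolbachia_reads),
        host_reads=int(host_reads),
        wolbachia_genome_length=int(wolbachia_genome_length),
        host_genome_length=int(host_genome_length),
        titer=titer,
    )


def titer_table(
    sample_table: pd.DataFrame,
    wolbachia_genome_length: int,
    host_genome_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-host titer summary over infected samples.

    ``sample_table`` needs columns host, total_reads, wolbachia_reads.
    Output columns: host, n_samples, n_positive, prevalence, mean_titer,
    sd_titer (positive = wolbachia_reads > 0 here; use :func:`prevalence`
    for threshold-based positivity reporting).
    """
    rows = []
    for host, grp in sample_table.groupby("host", sort=True):
        lh = host_genome_lengths[host]
        titers = [
            estimate_titer(int(w), int(t), wolbachia_genome_length, lh).titer
            for w, t in zip(grp["wolbachia_reads"], grp["total_reads"])
            if w > 0
        ]
        rows.append(
            {
                "host": host,
                "n_samples": len(grp),
                "n_positive": len(titers),
                "prevalence": len(titers) / len(grp),
                "mean_titer": float(np.mean(titers)) if titers else float("nan"),
                "sd_titer": float(np.std(titers, ddof=1))
                if len(titers) > 1
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
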