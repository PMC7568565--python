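"""Coinfection detection and MAG quality control.

The polymorphism test asks, position by position, whether the non-primary
base counts exceed what sequencing error alone explains. With depth n and
k = n - (count of the most frequent base), the p-value is the upper tail
P(X >= k) for X ~ Binomial(n, eps) with eps the per-base error rate
(default 0.01); positions with p < alpha (0.05) are polymorphic. k pools
all non-primary bases and no multiple-testing correction is applied across
positions — the test is a per-site screen, not an inference about any
single site.

A genome-wide polymorphic rate above 5% indicates more than one strain in
the sample (a chimeric assembly risk). Rates between 1% and 5% are
tolerated when the primary strain dominates the polymorphic positions
(mean primary-base fraction > 80%).

The quality gate combines four criteria: coverage >= 20x, core-gene
fraction >= 50% (genomes with 33-50% are kept for core-tree placement
only), total length within 750 kb - 1.7 Mb, and the chimera rule above.

Low-confidence region screening flags >=50 bp runs of unexpectedly high
coverage (>= 4x the median) and >=50 bp windows of elevated sequence
variation (variant sites carry a secondary base at >=5% of the coverage),
which can betray lateral gene transfer or collapsed repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import BASES, PileupColumn

__all__ = [
    "PolymorphismConfig",
    "QCConfig",
    "QCVerdict",
    "Region",
    "PolymorphismScan",
    "polymorphic_site_test",
    "scan_polymorphism",
    "qc_gate",
    "low_confidence_regions",
]


@dataclass(frozen=True)
class PolymorphismConfig:
    """Site test and chimera-rule parameters.

    error_rate
        Assumed per-base sequencing error under the single-strain null.
    alpha
        Per-site significance level.
    quality_floor
        Phred floor applied upstream when the pileup was built; recorded
        here for provenance, not applied again.
    chimera_rate / clean_rate
        Polymorphic-rate bounds: < clean_rate passes outright, above
        chimera_rate fails, the closed band in between passes only with
        sufficient dominance.
    dominance_threshold
        Minimum (exclusive) primary-strain dominance inside the band.
    """

    error_rate: float = 0.01
    alpha: float = 0.05
    quality_floor: int = 30
    chimera_rate: float = 0.05
    clean_rate: float = 0.01
    dominance_threshold: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.clean_rate < self.chimera_rate:
            raise ValueError("clean_rate must be below chimera_rate")


@dataclass(frozen=True)
class QCConfig:
    min_coverage: float = 20.0
    min_core_fraction_pass: float = 0.50
    min_core_fraction_tree: float = 1 / 3
    length_min: int = 750_000
    length_max: int = 1_700_000

    def __post_init__(self) -> None:
        if not self.length_min < self.length_max:
            raise ValueError("length_min must be below length_max")
        if self.min_core_fraction_tree > self.min_core_fraction_pass:
            raise ValueError("tree fraction must not exceed pass fraction")


@dataclass(frozen=True)
class QCVerdict:
    genome_id: str
    coverage: float
    core_fraction: float
    length: int
    polymorphic_rate: float
    dominance: float
    status: str  # pass | core-tree-only | fail
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status == "pass" and self.reasons:
            raise ValueError("a passing verdict cannot carry fail reasons")
        if not 0 <= self.polymorphic_rate <= 1:
            raise ValueError("polymorphic_rate must be in [0, 1]")


@dataclass(frozen=True)
class Region:
    """1-based inclusive span flagged by the low-confidence screen."""

    reference_id: str
    start: int
    end: int
    kind: str  # high-coverage | high-variation
    magnitude: float  # fold over the genome-wide baseline

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PolymorphismScan:
    polymorphic_rate: float
    dominance: float
    polymorphic_positions: tuple[int, ...]
    n_assessed: int
    assembly_length: int


def binomial_tail_pvalue(k: int, depth: int, error_rate: float) -> float:
    """P(X >= k) for X ~ Binomial(depth, error_rate): the probability that
    sequencing error alone produces at least k non-primary bases."""
    return float(stats.binom.sf(k - 1, depth, error_rate))


def polymorphic_site_test(
    column: PileupColumn, config: PolymorphismConfig = PolymorphismConfig()
) -> tuple[bool, float]:
    """Binomial upper-tail test of one pileup column.

    Returns (is_polymorphic, p_value) with p = P(X >= k),
    X ~ Binomial(depth, error_rate), k = depth - primary base count.
    """
    if column.depth < 1:
        raise ValueError("site test undefined at depth 0; skip the position")
    k = column.depth - column.primary_count()
    p_value = binomial_tail_pvalue(k, column.depth, config.error_rate)
    return p_value < config.alpha, p_value


def _counts_array(pileup: Sequence[PileupColumn]) -> tuple[np.ndarray, np.ndarray]:
    counts = np.array(
        [[c.counts.get(b, 0) for b in BASES] for c in pileup], dtype=np.int64
    )
    positions = np.array([c.position for c in pileup], dtype=np.int64)
    return counts, positions


def scan_polymorphism(
    pileup: Sequence[PileupColumn],
    config: PolymorphismConfig = PolymorphismConfig(),
    assembly_length: int | None = None,
    denominator: str = "assembly_length",
    dominance_stat: str = "mean",
) -> PolymorphismScan:
    """Apply the site test genome-wide and summarise.

    polymorphic_rate is the number of polymorphic positions over the
    assembly length (default) or over the positions actually assessed
    (``denominator='assessed'``). Positions with zero depth are never
    assessed. Dominance is the mean (or median) primary-base fraction over
    polymorphic positions, and 1.0 when there are none.
    """
    if denominator not in ("assembly_length", "assessed"):
        raise ValueError("denominator must be 'assembly_length' or 'assessed'")
    if dominance_stat not in ("mean", "median"):
        raise ValueError("dominance_stat must be 'mean' or 'median'")
    if assembly_length is None:
        assembly_length = len(pileup)
    if not pileup:
        return PolymorphismScan(0.0, 1.0, (), 0, assembly_length)

    counts, positions = _counts_array(pileup)
    depths = counts.sum(axis=1)
    assessed = depths > 0
    primary = counts.max(axis=1)
    k = depths - primary
    # vectorised upper tail; sf(-1) = 1 handles k = 0 exactly
    pvals = stats.binom.sf(k[assessed] - 1, depths[assessed], config.error_rate)
    poly_mask = np.zeros(len(pileup), dtype=bool)
    poly_mask[np.flatnonzero(assessed)] = pvals < config.alpha

    n_poly = int(poly_mask.sum())
    denom = assembly_length if denominator == "assembly_length" else int(assessed.sum())
    if denom <= 0:
        raise ValueError("no positions to assess")
    rate = n_poly / denom
    if n_poly == 0:
        dominance = 1.0
    else:
        fractions = primary[poly_mask] / depths[poly_mask]
        dominance = float(
            np.mean(fractions) if dominance_stat == "mean" else np.median(fractions)
        )
    return PolymorphismScan(
        polymorphic_rate=float(rate),
        dominance=dominance,
        polymorphic_positions=tuple(int(p) for p in positions[poly_mask]),
        n_assessed=int(assessed.sum()),
        assembly_length=assembly_length,
    )


def qc_gate(
    genome_id: str,
    coverage: float,
    core_fraction: float,
    length: int,
    polymorphic_rate: float,
    dominance: float,
    qc_config: QCConfig = QCConfig(),
    poly_config: PolymorphismConfig = PolymorphismConfig(),
) -> QCVerdict:
    """Four-criterion quality decision for one assembled genome.

    Reasons enumerate every violated criterion. A genome whose only
    shortfall is a core fraction in [tree, pass) is demoted to
    ``core-tree-only`` rather than failed.
    """
    reasons: list[str] = []
    if coverage < qc_config.min_coverage:
        reasons.append("coverage")
    if core_fraction < qc_config.min_core_fraction_pass:
        reasons.append("core_fraction")
    if not qc_config.length_min <= length <= qc_config.length_max:
        reasons.append("length")
    if polymorphic_rate > poly_config.chimera_rate:
        reasons.append("chimera")
    elif polymorphic_rate >= poly_config.clean_rate:
        if not dominance > poly_config.dominance_threshold:
            reasons.append("chimera")

    if not reasons:
        status = "pass"
    elif reasons == ["core_fraction"] and core_fraction >= qc_config.min_core_fraction_tree:
        status = "core-tree-only"
    else:
        status = "fail"
    return QCVerdict(
        genome_id=genome_id,
        coverage=coverage,
        core_fraction=core_fraction,
        length=int(length),
        polymorphic_rate=polymorphic_rate,
        dominance=dominance,
        status=status,
        reasons=tuple(reasons),
    )


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True runs of length >= min_len as 0-based [start, end]."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        if e - s >= min_len:
            out.append((int(s), int(e) - 1))
    return out


def low_confidence_regions(
    depth_vector: Sequence[float] | np.ndarray,
    variant_fraction_vector: Sequence[float] | np.ndarray,
    min_len: int = 50,
    cov_mult: float = 4.0,
    var_mult: float = 4.0,
    var_site_floor: float = 0.05,
    reference_id: str = "assembly",
    variation_mode: str = "density",
) -> list[Region]:
    """Flag high-coverage and high-variation spans of an assembly.

    High-coverage: maximal runs (>= min_len) of positions with depth >=
    cov_mult x the median depth.

    High-variation: spans where the local density of variant sites
    (secondary-base fraction >= var_site_floor) reaches var_mult x the
    genome-wide variant-site density, assessed in sliding windows of
    ``min_len`` positions; qualifying windows are merged. With
    ``variation_mode='mean'`` the window statistic is the mean secondary-
    base fraction compared against var_mult x its genome-wide mean instead.
    """
    depth = np.asarray(depth_vector, dtype=float)
    var = np.asarray(variant_fraction_vector, dtype=float)
    if depth.shape != var.shape:
        raise ValueError("depth and variant-fraction vectors differ in length")
    if variation_mode not in ("density", "mean"):
        raise ValueError("variation_mode must be 'density' or 'mean'")
    n = depth.size
    median = float(np.median(depth))
    if median <= 0:
        raise ValueError("median depth is zero: coverage baseline undefined")

    regions: list[Region] = []
    cov_mask = depth >= cov_mult * median
    for s, e in _runs(cov_mask, min_len):
        magnitude = float(np.mean(depth[s : e + 1]) / median)
        regions.append(Region(reference_id, s + 1, e + 1, "high-coverage", magnitude))

    if n >= min_len:
        if variation_mode == "density":
            signal = (var >= var_site_floor).astype(float)
        else:
            signal = var
        baseline = float(signal.mean())
        if baseline > 0:
            window = np.convolve(signal, np.ones(min_len), mode="valid") / min_len
            qualifying = window >= var_mult * baseline
            var_mask = np.zeros(n, dtype=bool)
            for i in np.flatnonzero(qualifying):
                var_mask[i : i + min_len] = True
            for s, e in _runs(var_mask, min_len):
                magnitude = float(np.mean(signal[s : e + 1]) / baseline)
                regions.append(
                    Region(reference_id, s + 1, e + 1, "high-variation", magnitude)
                )
    return regions
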