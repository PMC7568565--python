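"""Synthetic pipeline inputs with known ground truth.

Every generator plants a recoverable truth so each downstream stage can be
validated without any sequence archive download: a pangenome with a planted
universal core and planted CI genes, contig alignments constructed to sit
on the right side of the binning rule, single- and two-strain pileups with
a known biallelic site set, and per-host sample read-count tables with
planted prevalence and titer.

Randomness: each generator draws from its own stream derived from
``(seed, generator-tag)`` via numpy's SeedSequence, so adding or reordering
generators never perturbs another generator's output and identical seeds
reproduce identical outputs bit for bit.

Model choices (where the emulated study pipeline is silent):
* per-position depth is Poisson around the mean — the standard shotgun
  approximation;
* sequencing errors hit each read base independently and are distributed
  uniformly over the three other bases;
* the default pileup error rate is 0.001, the ceiling implied by the Q30
  base-quality filter applied when real pileups are built (Phred 30 means
  a 1e-3 error probability); pass ``error_rate=0.01`` to emulate raw
  unfiltered Illumina error;
* contig lengths are log-uniform so the log-scaled binning rule is
  exercised across its whole regime;
* accessory gene families belong to a single home supergroup (assigned
  round-robin) and are sampled only there — accessory content in real
  pangenomes is strongly lineage-restricted, and this keeps the planted
  core exactly recoverable (no accessory family can ever satisfy the
  every-supergroup core rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinningConfig, required_aligned_length
from .io import BASES, AlignmentRecord, GenePresenceMatrix, PileupColumn

__all__ = [
    "SimPangenomeConfig",
    "SimPileupConfig",
    "PangenomeTruth",
    "HostSpec",
    "gen_pangenome",
    "gen_pileup",
    "gen_contig_alignments",
    "gen_read_counts",
]

_SUPERGROUP_NAMES = ("A", "B", "C", "D", "F", "L")

# fixed per-generator tags for stream separation
_STREAM = {"pangenome": 1, "pileup": 2, "contigs": 3, "counts": 4}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[generator]]))


# ---------------------------------------------------------------------------
# Pangenome


@dataclass(frozen=True)
class SimPangenomeConfig:
    """Planted pangenome layout.

    Defaults emulate the study-scale pangenome shape scaled per supergroup:
    316 universal core families and accessory families totalling 6376,
    over five supergroups. ``genomes_per_supergroup`` may be a single
    count or one count per supergroup; ``accessory_presence_prob``
    likewise (per supergroup). ``lineage_sizes`` optionally replaces the
    genome count of selected supergroups by named lineages
    (e.g. ``{"A": {"wRi": 100, "wMel": 100, "wAu": 11}}``); genomes in
    lineages listed in ``ci_lineages`` carry every planted CI gene, all
    other genomes none.
    """

    n_supergroups: int = 5
    genomes_per_supergroup: int | Sequence[int] = 10
    n_core_families: int = 316
    n_accessory_families: int = 6060
    accessory_presence_prob: float | Sequence[float] = 0.3
    n_planted_ci_genes: int = 0
    seed: int = 0
    lineage_sizes: Mapping[str, Mapping[str, int]] | None = None
    ci_lineages: tuple[str, ...] = ("wRi", "wMel")

    def __post_init__(self) -> None:
        counts = (
            self.n_supergroups,
            self.n_core_families,
            self.n_accessory_families,
            self.n_planted_ci_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_supergroups == 0:
            raise ValueError("need at least one supergroup")
        for p in self._presence_probs():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability {p} outside [0, 1]")
        for g in self._genome_counts():
            if g < 0:
                raise ValueError("genome counts must be >= 0")

    def supergroup_names(self) -> list[str]:
        names = list(_SUPERGROUP_NAMES[: self.n_supergroups])
        names += [f"SG{i}" for i in range(len(names) + 1, self.n_supergroups + 1)]
        return names

    def _genome_counts(self) -> list[int]:
        if isinstance(self.genomes_per_supergroup, int):
            return [self.genomes_per_supergroup] * self.n_supergroups
        counts = list(self.genomes_per_supergroup)
        if len(counts) != self.n_supergroups:
            raise ValueError("one genome count per supergroup required")
        return counts

    def _presence_probs(self) -> list[float]:
        if isinstance(self.accessory_presence_prob, (int, float)):
            return [float(self.accessory_presence_prob)] * self.n_supergroups
        probs = [float(p) for p in self.accessory_presence_prob]
        if len(probs) != self.n_supergroups:
            raise ValueError("one presence probability per supergroup required")
        return probs


@dataclass(frozen=True)
class PangenomeTruth:
    core_families: tuple[str, ...]
    ci_families: tuple[str, ...]
    ci_genomes: tuple[str, ...] = ()


def gen_pangenome(
    config: SimPangenomeConfig = SimPangenomeConfig(),
) -> tuple[GenePresenceMatrix, PangenomeTruth]:
    """Binary pangenome with a planted universal core and planted CI genes."""
    rng = _rng(config.seed, "pangenome")
    names = config.supergroup_names()
    counts = config._genome_counts()
    probs = config._presence_probs()

    genome_ids: list[str] = []
    supergroup_of: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    sg_index: list[int] = []
    for i, (sg, n) in enumerate(zip(names, counts)):
        lineages = (
            dict(config.lineage_sizes[sg])
            if config.lineage_sizes and sg in config.lineage_sizes
            else {sg: n}
        )
        for lineage, n_lin in lineages.items():
            for j in range(n_lin):
                gid = f"{sg}.{lineage}.g{j:03d}"
                genome_ids.append(gid)
                supergroup_of[gid] = sg
                lineage_of[gid] = lineage
                sg_index.append(i)
    n_genomes = len(genome_ids)
    sg_index_arr = np.array(sg_index, dtype=int)

    core_ids = [f"core{i:04d}" for i in range(config.n_core_families)]
    ci_ids = [f"ci{i:03d}" for i in range(config.n_planted_ci_genes)]
    acc_ids = [f"acc{i:04d}" for i in range(config.n_accessory_families)]

    blocks = []
    if core_ids:
        blocks.append(np.ones((n_genomes, len(core_ids)), dtype=np.int8))
    ci_genomes: tuple[str, ...] = ()
    if ci_ids:
        is_ci = np.array(
            [lineage_of[g] in config.ci_lineages for g in genome_ids], dtype=np.int8
        )
        blocks.append(np.repeat(is_ci[:, None], len(ci_ids), axis=1))
        ci_genomes = tuple(g for g in genome_ids if lineage_of[g] in config.ci_lineages)
    if acc_ids:
        home = np.arange(len(acc_ids)) % config.n_supergroups
        acc = np.zeros((n_genomes, len(acc_ids)), dtype=np.int8)
        u = rng.random((n_genomes, len(acc_ids)))
        for sg_i in range(config.n_supergroups):
            rows = sg_index_arr == sg_i
            cols = home == sg_i
            acc[np.ix_(rows, cols)] = (u[np.ix_(rows, cols)] < probs[sg_i]).astype(
                np.int8
            )
        blocks.append(acc)

    family_ids = core_ids + ci_ids + acc_ids
    values = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((n_genomes, 0), dtype=np.int8)
    )
    matrix = GenePresenceMatrix(
        pd.DataFrame(values, index=genome_ids, columns=family_ids),
        supergroup_of,
        lineage_of,
    )
    return matrix, PangenomeTruth(tuple(core_ids), tuple(ci_ids), ci_genomes)


# ---------------------------------------------------------------------------
# Pileup


@dataclass(frozen=True)
class SimPileupConfig:
    """Single- or two-strain pileup layout.

    ``minor_fraction`` is the read fraction of the minor strain,
    ``divergence`` the probability a site differs between the two strains,
    ``error_rate`` the post-quality-filter per-base error (see module
    docstring for the 0.001 default).
    """

    genome_length: int = 100_000
    depth_mean: float = 100.0
    n_strains: int = 1
    minor_fraction: float = 0.0
    divergence: float = 0.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 0 or self.depth_mean < 0:
            raise ValueError("genome_length and depth_mean must be >= 0")
        if not 0.0 <= self.minor_fraction <= 0.5:
            raise ValueError("minor_fraction must be in [0, 0.5]")
        if not 0.0 <= self.divergence < 1.0 or not 0.0 <= self.error_rate < 1.0:
            raise ValueError("divergence and error_rate must be in [0, 1)")
        if self.n_strains not in (1, 2):
            raise ValueError("only 1 or 2 strains are supported")


def gen_pileup(
    config: SimPileupConfig = SimPileupConfig(), reference_id: str = "assembly"
) -> tuple[list[PileupColumn], set[int]]:
    """Pileup columns plus the set of true biallelic positions (1-based)."""
    rng = _rng(config.seed, "pileup")
    L = config.genome_length
    depths = rng.poisson(config.depth_mean, size=L)
    true_base = rng.integers(0, 4, size=L)

    if config.n_strains == 2:
        biallelic = rng.random(L) < config.divergence
        minor_base = (true_base + rng.integers(1, 4, size=L)) % 4
        minor_n = np.where(
            biallelic, rng.binomial(depths, config.minor_fraction), 0
        )
    else:
        biallelic = np.zeros(L, dtype=bool)
        minor_base = true_base
        minor_n = np.zeros(L, dtype=np.int64)
    primary_n = depths - minor_n

    counts = np.zeros((L, 4), dtype=np.int64)
    # 3 alternative bases for each true base, used to scatter errors
    others = np.array([[b for b in range(4) if b != a] for a in range(4)])
    third = np.full(3, 1 / 3)
    for source_base, source_n in ((true_base, primary_n), (minor_base, minor_n)):
        if config.error_rate > 0:
            errs = rng.binomial(source_n, config.error_rate)
            spread = rng.multinomial(errs, third)
        else:
            errs = np.zeros(L, dtype=np.int64)
            spread = np.zeros((L, 3), dtype=np.int64)
        np.add.at(counts, (np.arange(L), source_base), source_n - errs)
        np.add.at(counts, (np.arange(L)[:, None], others[source_base]), spread)

    base_names = np.array(BASES)
    columns = [
        PileupColumn(
            reference_id=reference_id,
            position=i + 1,
            counts={b: int(c) for b, c in zip(base_names, counts[i])},
            depth=int(depths[i]),
        )
        for i in range(L)
    ]
    truth = {int(i + 1) for i in np.flatnonzero(biallelic)}
    return columns, truth


# ---------------------------------------------------------------------------
# Contig alignments


def gen_contig_alignments(
    n_wolbachia: int,
    n_host: int,
    length_range: tuple[int, int] = (1000, 50_000),
    seed: int = 0,
    n_references: int = 3,
    config: BinningConfig = BinningConfig(),
) -> tuple[list[AlignmentRecord], dict[str, int], dict[str, str]]:
    """Separable mixed contig set for the binning rule.

    Wolbachia-truth contigs get one alignment with identity in (85, 99.5)
    spanning comfortably more than the rule requires; host-truth contigs
    get, with equal probability, no alignment, a full-length alignment at
    sub-threshold identity, or a high-identity alignment over about half
    the required span. The construction guarantees the binning stage
    recovers the truth partition exactly.
    """
    if n_wolbachia < 0 or n_host < 0:
        raise ValueError("contig counts must be >= 0")
    lo, hi = length_range
    if lo < config.min_contig_length or hi < lo:
        raise ValueError(
            f"length_range must satisfy {config.min_contig_length} <= lo <= hi"
        )
    rng = _rng(seed, "contigs")
    refs = [f"wRef{i+1}" for i in range(n_references)]

    records: list[AlignmentRecord] = []
    lengths: dict[str, int] = {}
    labels: dict[str, str] = {}

    def _length() -> int:
        return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))

    def _record(cid, ref, pid, qstart, qend, L_c):
        span = qend - qstart + 1
        return AlignmentRecord(
            query_id=cid,
            subject_id=ref,
            percent_identity=round(pid, 2),
            aligned_length=span,
            mismatches=int(round(span * (1 - pid / 100))),
            gap_opens=0,
            query_start=qstart,
            query_end=qend,
            subject_start=1,
            subject_end=span,
            e_value=1e-30,
            bit_score=round(2.0 * span, 1),
        )

    for i in range(n_wolbachia):
        cid = f"wolb_c{i:04d}"
        L_c = _length()
        lengths[cid] = L_c
        labels[cid] = "wolbachia"
        required = required_aligned_length(L_c, config)
        ref = refs[int(rng.integers(0, len(refs)))]
        pid = float(rng.uniform(85.0, 99.5))
        if required < L_c:
            qend = int(math.ceil((required + L_c) / 2))  # strictly > required
        else:
            qend = L_c  # full-length alignment for the 1000 bp limit case
        records.append(_record(cid, ref, pid, 1, qend, L_c))

    for i in range(n_host):
        cid = f"host_c{i:04d}"
        L_c = _length()
        lengths[cid] = L_c
        labels[cid] = "host"
        required = required_aligned_length(L_c, config)
        mode = int(rng.integers(0, 3))
        if mode == 0:
            continue  # no alignment at all
        ref = refs[int(rng.integers(0, len(refs)))]
        if mode == 1:  # identity below threshold, full span
            pid = float(rng.uniform(50.0, config.identity_threshold - 1.0))
            records.append(_record(cid, ref, pid, 1, L_c, L_c))
        else:  # good identity, clearly sub-threshold span
            pid = float(rng.uniform(85.0, 99.5))
            qend = max(1, int(required // 2))
            records.append(_record(cid, ref, pid, 1, qend, L_c))

    return records, lengths, labels


# ---------------------------------------------------------------------------
# Read-count tables


@dataclass(frozen=True)
class HostSpec:
    host_id: str
    n_samples: int
    prevalence: float
    titer: float
    genome_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.n_samples < 0 or self.titer < 0 or self.genome_length <= 0:
            raise ValueError("invalid host specification")


def gen_read_counts(
    hosts: Sequence[HostSpec | tuple],
    wolbachia_genome_length: int = 1_250_000,
    seed: int = 0,
    host_reads_mean: float = 1_000_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read counts with planted prevalence and titer.

    Infection is Bernoulli(prevalence) per sample; host reads are Poisson
    around ``host_reads_mean``; an infected sample's Wolbachia reads are
    Poisson around ``titer * host_reads * L_w / L_h`` (the titer formula
    inverted), uninfected samples get zero. Returns the sample table
    (sample, host, total_reads, wolbachia_reads) and a truth table
    (sample, host, infected, planted_prevalence, planted_titer).
    """
    specs = [h if isinstance(h, HostSpec) else HostSpec(*h) for h in hosts]
    rng = _rng(seed, "counts")
    rows = []
    truth_rows = []
    for spec in specs:
        infected = rng.random(spec.n_samples) < spec.prevalence
        host_reads = rng.poisson(host_reads_mean, size=spec.n_samples)
        expected_w = (
            spec.titer
            * host_reads
            * wolbachia_genome_length
            / spec.genome_length
        )
        w_reads = np.where(infected, rng.poisson(expected_w), 0)
        for j in range(spec.n_samples):
            sid = f"{spec.host_id}.s{j:04d}"
            rows.append(
                {
                    "sample": sid,
                    "host": spec.host_id,
                    "total_reads": int(host_reads[j] + w_reads[j]),
                    "wolbachia_reads": int(w_reads[j]),
                }
            )
            truth_rows.append(
                {
                    "sample": sid,
                    "host": spec.host_id,
                    "infected": bool(infected[j]),
                    "planted_prevalence": spec.prevalence,
                    "planted_titer": spec.titer,
                    "host_genome_length": spec.genome_length,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
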