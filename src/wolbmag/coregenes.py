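"""Supergroup-balanced core-genome construction and genome deduplication.

The core-gene set is built to be robust to the wildly uneven number of
assembled genomes per supergroup: each supergroup is summarised by (up to)
five representative genomes chosen by k-medoids (PAM) on Jaccard distances
between gene presence/absence profiles, and a family is core when every
supergroup has at least one representative carrying it. Core-gene calls in
individual genomes are then filtered on alignment quality (E-value,
identity, length window around the family's mean representative length),
families that are multi-copy in more than 10% of genomes are dropped, and
within retained families only single-hit calls are kept.

Near-identical genomes are collapsed with complete-linkage hierarchical
clustering on a pairwise distance matrix cut at a threshold (0.005 for
Mash-style dedup; 0 collapses exact duplicates), keeping one
representative per cluster.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import AlignmentRecord, GenePresenceMatrix

__all__ = [
    "CoreConfig",
    "CoreGeneCall",
    "DedupResult",
    "jaccard_distance",
    "jaccard_distance_matrix",
    "kmedoids",
    "select_representatives",
    "define_core",
    "filter_core_hits",
    "single_copy_filter",
    "dedup_genomes",
    "filter_rare_families",
]


@dataclass(frozen=True)
class CoreConfig:
    """Parameters of representative selection, core calling and filtering."""

    k_representatives: int = 5
    hit_evalue_max: float = 1e-10
    hit_identity_min: float = 66.0
    hit_len_min_frac: float = 0.50
    hit_len_max_frac: float = 1.25
    multi_hit_genome_frac: float = 0.10
    dedup_threshold: float = 0.005
    min_family_samples: int = 5
    exclude_supergroups: tuple[str, ...] = ("L",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hit_len_min_frac < 1 < self.hit_len_max_frac:
            raise ValueError("length window must satisfy 0 < min < 1 < max")
        if self.k_representatives < 1:
            raise ValueError("k_representatives must be >= 1")


def jaccard_distance(
    profile_a: Sequence[int] | np.ndarray, profile_b: Sequence[int] | np.ndarray
) -> float:
    """1 - |intersection| / |union| over the families present in either."""
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("Jaccard distance undefined for two empty profiles")
    inter = int(np.count_nonzero(a & b))
    return 1.0 - inter / union


def jaccard_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between the rows of a binary matrix.

    Pairs of all-zero profiles get distance 0 (they are indistinguishable),
    so downstream clustering remains well defined.
    """
    x = np.asarray(profiles, dtype=np.int64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    dist[union == 0] = 0.0
    np.fill_diagonal(dist, 0.0)
    return dist


_EXHAUSTIVE_LIMIT = 20_000  # medoid sets; C(18,5) is still under this


def _kmedoids_exhaustive(dist: np.ndarray, k: int) -> list[int]:
    """Globally optimal medoid set by enumeration (small instances only).

    Ties are broken toward the lexicographically smallest index tuple.
    """
    n = dist.shape[0]
    best_cost = math.inf
    best: tuple[int, ...] = ()
    for medoids in itertools.combinations(range(n), k):
        cost = float(dist[list(medoids)].min(axis=0).sum())
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    return list(best)


def _pam(dist: np.ndarray, k: int) -> list[int]:
    """Deterministic PAM: greedy BUILD then best-improvement SWAP.

    Ties are broken by the lowest index, so the result is reproducible
    regardless of input ordering randomness.
    """
    n = dist.shape[0]
    if n <= k:
        return list(range(n))
    # BUILD: start from the 1-medoid optimum, then greedily add the point
    # that most reduces the total distance to the nearest medoid.
    totals = dist.sum(axis=1)
    medoids = [int(np.argmin(totals))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))
        medoids.append(cand)
        nearest = np.minimum(nearest, dist[cand])

    def cost(meds: Sequence[int]) -> float:
        return float(dist[np.ix_(meds, range(n))].min(axis=0).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap: tuple[int, int] | None = None
        best_cost = current
        medoid_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoid_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_swap = (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            current = best_cost
            improved = True
    return sorted(medoids)


def kmedoids(
    profiles: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    dist: np.ndarray | None = None,
) -> list:
    """Medoid row labels (or indices) of a binary profile matrix.

    Minimises the total Jaccard distance of every genome to its nearest
    medoid. Small instances (at most ~20k candidate medoid sets) are
    solved exactly by enumeration; larger ones use PAM (greedy BUILD plus
    best-improvement SWAP), a local search that matches the exhaustive
    optimum in practice but does not guarantee it. Both routes are fully
    deterministic — the ``seed`` argument is accepted for interface
    stability but the procedure has no random component. With n <= k every
    row is its own medoid.
    """
    if isinstance(profiles, pd.DataFrame):
        labels = list(profiles.index)
        x = profiles.to_numpy()
    else:
        x = np.asarray(profiles)
        labels = list(range(x.shape[0]))
    n = x.shape[0]
    if n == 0:
        return []
    if dist is None:
        dist = jaccard_distance_matrix(x)
    if n <= k:
        idx = list(range(n))
    elif math.comb(n, k) <= _EXHAUSTIVE_LIMIT:
        idx = _kmedoids_exhaustive(dist, k)
    else:
        idx = _pam(dist, k)
    return [labels[i] for i in idx]


def select_representatives(
    matrix: GenePresenceMatrix, config: CoreConfig = CoreConfig()
) -> dict[str, list[str]]:
    """Per-supergroup medoid genomes (k=5); small supergroups contribute all.

    Every genome must carry a supergroup label.
    """
    unlabelled = [g for g in matrix.genome_ids if g not in matrix.supergroup_of]
    if unlabelled:
        raise ValueError(f"genomes without supergroup label: {unlabelled[:5]}")
    by_group: dict[str, list[str]] = {}
    for g in matrix.genome_ids:
        by_group.setdefault(matrix.supergroup_of[g], []).append(g)
    reps: dict[str, list[str]] = {}
    for sg in sorted(by_group):
        genomes = sorted(by_group[sg])
        if len(genomes) <= config.k_representatives:
            reps[sg] = genomes
        else:
            sub = matrix.values.loc[genomes]
            reps[sg] = sorted(kmedoids(sub, config.k_representatives, config.seed))
    return reps


def define_core(
    matrix: GenePresenceMatrix,
    representatives: Mapping[str, Sequence[str]],
    config: CoreConfig = CoreConfig(),
) -> list[str]:
    """Families present in >=1 representative of every (included) supergroup."""
    groups = [
        sg
        for sg, ids in representatives.items()
        if ids and sg not in config.exclude_supergroups
    ]
    if not groups:
        return []
    core_mask = np.ones(matrix.n_families, dtype=bool)
    for sg in groups:
        sub = matrix.values.loc[list(representatives[sg])]
        core_mask &= sub.to_numpy().any(axis=0)
    return [f for f, keep in zip(matrix.family_ids, core_mask) if keep]


@dataclass(frozen=True)
class CoreGeneCall:
    family_id: str
    status: str  # absent | single | multi
    targets: tuple[str, ...] = ()


def filter_core_hits(
    hits: Sequence[AlignmentRecord],
    mean_family_length: Mapping[str, float],
    family_of: Mapping[str, str] | Callable[[str], str],
    config: CoreConfig = CoreConfig(),
) -> dict[str, CoreGeneCall]:
    """Call core genes in one genome from representative-vs-genome hits.

    ``hits`` align representative gene sequences (queries) against the
    genome's genes (subjects); ``family_of`` maps each query id to its gene
    family. A hit is accepted iff E-value < 1e-10, identity > 66% and
    aligned length within [50%, 125%] of the family's mean representative
    gene length. Per family the distinct accepted subject sequences define
    the call: one -> single, several -> multi (flagged, resolved by
    :func:`single_copy_filter`).
    """
    get_family = family_of if callable(family_of) else family_of.__getitem__
    targets: dict[str, set[str]] = {}
    for h in hits:
        fam = get_family(h.query_id)
        if fam not in mean_family_length:
            raise ValueError(f"no mean length for family {fam!r}")
        mean_len = mean_family_length[fam]
        if (
            h.e_value < config.hit_evalue_max
            and h.percent_identity > config.hit_identity_min
            and config.hit_len_min_frac * mean_len
            <= h.aligned_length
            <= config.hit_len_max_frac * mean_len
        ):
            targets.setdefault(fam, set()).add(h.subject_id)
    calls: dict[str, CoreGeneCall] = {}
    for fam in mean_family_length:
        tg = tuple(sorted(targets.get(fam, ())))
        status = "absent" if not tg else ("single" if len(tg) == 1 else "multi")
        calls[fam] = CoreGeneCall(fam, status, tg)
    return calls


def single_copy_filter(
    calls: Mapping[str, Mapping[str, CoreGeneCall]],
    config: CoreConfig = CoreConfig(),
) -> tuple[list[str], dict[str, dict[str, CoreGeneCall]]]:
    """Drop families that are multi-copy in more than 10% of genomes.

    ``calls`` maps genome id -> family id -> call. Returns the retained
    family list and, per genome, only the single-hit calls within retained
    families.
    """
    genomes = list(calls)
    if not genomes:
        return [], {}
    families = sorted({f for per_genome in calls.values() for f in per_genome})
    retained: list[str] = []
    for fam in families:
        n_multi = sum(
            1
            for g in genomes
            if fam in calls[g] and calls[g][fam].status == "multi"
        )
        if n_multi / len(genomes) <= config.multi_hit_genome_frac:
            retained.append(fam)
    filtered: dict[str, dict[str, CoreGeneCall]] = {}
    for g in genomes:
        filtered[g] = {
            f: c
            for f, c in calls[g].items()
            if f in set(retained) and c.status == "single"
        }
    return retained, filtered


@dataclass(frozen=True)
class DedupResult:
    representatives: tuple[str, ...]
    representative_of: dict[str, str] = field(default_factory=dict)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for member, rep in self.representative_of.items():
            out.setdefault(rep, []).append(member)
        return {rep: sorted(members) for rep, members in out.items()}


def dedup_genomes(
    distances: pd.DataFrame,
    threshold: float = 0.005,
    tie_rule: Callable[[Sequence[str]], str] | None = None,
) -> DedupResult:
    """Collapse near-identical genomes by complete-linkage clustering.

    Clusters are cut so every merge happened at linkage distance <=
    ``threshold``; complete linkage guarantees the maximum intra-cluster
    pairwise distance does not exceed it. One representative per cluster is
    kept (default: lexicographically smallest id).
    """
    ids = list(distances.index)
    if list(distances.columns) != ids:
        raise ValueError("distance matrix index and columns must match")
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    pick = tie_rule if tie_rule is not None else min
    if len(ids) == 1:
        return DedupResult((ids[0],), {ids[0]: ids[0]})
    condensed = squareform(d, checks=False)
    labels = fcluster(linkage(condensed, method="complete"), t=threshold, criterion="distance")
    members: dict[int, list[str]] = {}
    for gid, lab in zip(ids, labels):
        members.setdefault(int(lab), []).append(gid)
    rep_of: dict[str, str] = {}
    reps: list[str] = []
    for lab in sorted(members, key=lambda l: min(members[l])):
        rep = pick(members[lab])
        reps.append(rep)
        for gid in members[lab]:
            rep_of[gid] = rep
    return DedupResult(tuple(reps), rep_of)


def filter_rare_families(
    matrix: GenePresenceMatrix, min_family_samples: int = 5
) -> GenePresenceMatrix:
    """Drop gene families present in fewer than ``min_family_samples`` genomes."""
    counts = matrix.presence_counts()
    keep = [f for f in matrix.family_ids if counts[f] >= min_family_samples]
    return matrix.restrict_families(keep)
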