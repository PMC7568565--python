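"""Lineage-specific gene gain/loss and cytoplasmic-incompatibility candidates.

Each gene family's presence/absence split between two genome groups forms
a 2x2 table tested with Fisher's exact test. Lineage-specific changes
compare a focal host lineage against every closely related lineage and
report a family only when the same direction (gain or loss) is significant
in all comparisons at the per-comparison alpha (0.05, uncorrected — the
comparisons are confirmatory replicates, not a family-wise sweep).

CI candidate genes are families enriched in BOTH CI-inducing lineages
(wRi-like and wMel) relative to the non-CI wAu-like genomes, at a
Bonferroni-corrected p < 1e-5 over all tested families. Genomes with
identical core profiles are collapsed first so clonal resequencing does
not inflate the counts. Finally, candidates that merely reflect gene
enrichment in the wAu-like lineage itself — visible as significant
wAu-vs-nematode-outgroup enrichment — are removed; the outgroup
comparison guards against mistaking a wAu-specific gain for a CI loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coregenes import dedup_genomes, filter_rare_families
from .io import GenePresenceMatrix

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "fisher_family_test",
    "lineage_specific_changes",
    "ci_candidates",
    "CIResult",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha_lineage: float = 0.05
    ci_p_threshold: float = 1e-5
    correction: str = "bonferroni"  # bonferroni | none
    test_sidedness: str = "greater"  # greater | two-sided

    def __post_init__(self) -> None:
        if not 0 < self.alpha_lineage < 1 or not 0 < self.ci_p_threshold < 1:
            raise ValueError("significance thresholds must be in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")
        if self.test_sidedness not in ("greater", "two-sided"):
            raise ValueError("test_sidedness must be 'greater' or 'two-sided'")


@dataclass(frozen=True)
class EnrichmentResult:
    family_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (present, absent) x (A, B)
    p_raw: float
    p_corrected: float
    direction: str  # gain-in-A | loss-in-A
    significant: bool

    def __post_init__(self) -> None:
        if self.p_corrected < self.p_raw - 1e-15:
            raise ValueError("corrected p cannot be below raw p")


def _correct(p: np.ndarray | float, n_tests: int, method: str):
    if method == "bonferroni":
        return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)
    return np.asarray(p, dtype=float)


def _greater_pvalues(
    present_a: np.ndarray, size_a: int, present_b: np.ndarray, size_b: int
) -> np.ndarray:
    """One-sided Fisher p-values (enrichment in A) via the hypergeometric tail.

    Conditioning on the table margins, the count present in A is
    hypergeometric; P(X >= a) is the one-sided 'greater' Fisher p-value.
    Vectorised over families.
    """
    total = size_a + size_b
    k = present_a + present_b
    return stats.hypergeom.sf(present_a - 1, total, k, size_a)


def fisher_family_test(
    presence_in_A: int,
    size_A: int,
    presence_in_B: int,
    size_B: int,
    config: EnrichmentConfig = EnrichmentConfig(),
    family_id: str = "",
    n_tests: int = 1,
) -> EnrichmentResult:
    """Exact test of one family's 2x2 presence table.

    With sidedness 'greater' the p-value tests enrichment in group A;
    'two-sided' uses scipy's exact two-sided Fisher test. The direction is
    read from the sign of the presence-rate difference regardless of
    sidedness.
    """
    if size_A <= 0 or size_B <= 0:
        raise ValueError("group sizes must be positive")
    if not 0 <= presence_in_A <= size_A or not 0 <= presence_in_B <= size_B:
        raise ValueError("presence counts must lie within group sizes")
    table = ((presence_in_A, size_A - presence_in_A), (presence_in_B, size_B - presence_in_B))
    if config.test_sidedness == "greater":
        p_raw = float(
            _greater_pvalues(
                np.array([presence_in_A]), size_A, np.array([presence_in_B]), size_B
            )[0]
        )
    else:
        p_raw = float(stats.fisher_exact(table, alternative="two-sided")[1])
    p_corr = float(_correct(p_raw, n_tests, config.correction))
    direction = (
        "gain-in-A"
        if presence_in_A / size_A >= presence_in_B / size_B
        else "loss-in-A"
    )
    return EnrichmentResult(
        family_id=family_id,
        table=table,
        p_raw=p_raw,
        p_corrected=p_corr,
        direction=direction,
        significant=p_corr < config.alpha_lineage,
    )


def _group_counts(matrix: GenePresenceMatrix, ids: Sequence[str]) -> np.ndarray:
    return matrix.values.loc[list(ids)].to_numpy().sum(axis=0)


def lineage_specific_changes(
    matrix: GenePresenceMatrix,
    focal_lineage: Sequence[str],
    related_lineages: Sequence[Sequence[str]],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Families gained or lost in the focal lineage vs every related lineage.

    ``focal_lineage`` and each entry of ``related_lineages`` are genome id
    lists; lineages must be disjoint. A family is reported only when the
    exact test is significant at ``alpha_lineage`` (raw p, one comparison
    per related lineage) with the same direction in every comparison.
    Output columns: family, direction (gain/loss), max_p (largest raw
    p-value across comparisons).
    """
    if not related_lineages:
        raise ValueError("need at least one related lineage")
    groups = [list(focal_lineage)] + [list(r) for r in related_lineages]
    seen: set[str] = set()
    for grp in groups:
        if not grp:
            raise ValueError("empty lineage")
        overlap = seen & set(grp)
        if overlap:
            raise ValueError(f"lineages overlap: {sorted(overlap)[:5]}")
        seen |= set(grp)

    fa = _group_counts(matrix, focal_lineage)
    na = len(focal_lineage)
    gained = np.ones(matrix.n_families, dtype=bool)
    lost = np.ones(matrix.n_families, dtype=bool)
    p_gain_max = np.zeros(matrix.n_families)
    p_loss_max = np.zeros(matrix.n_families)
    for rel in related_lineages:
        fb = _group_counts(matrix, rel)
        nb = len(rel)
        p_gain = _greater_pvalues(fa, na, fb, nb)
        p_loss = _greater_pvalues(fb, nb, fa, na)
        gained &= p_gain < config.alpha_lineage
        lost &= p_loss < config.alpha_lineage
        p_gain_max = np.maximum(p_gain_max, p_gain)
        p_loss_max = np.maximum(p_loss_max, p_loss)
    rows = []
    for i, fam in enumerate(matrix.family_ids):
        if gained[i]:
            rows.append({"family": fam, "direction": "gain", "max_p": float(p_gain_max[i])})
        elif lost[i]:
            rows.append({"family": fam, "direction": "loss", "max_p": float(p_loss_max[i])})
    return pd.DataFrame(rows, columns=["family", "direction", "max_p"])


@dataclass(frozen=True)
class CIResult:
    candidates: tuple[str, ...]
    table: pd.DataFrame
    n_tests: int
    n_genomes_after_dedup: int


def ci_candidates(
    matrix: GenePresenceMatrix,
    wAu_ids: Sequence[str],
    wRi_ids: Sequence[str],
    wMel_ids: Sequence[str],
    nematode_lineages: Sequence[Sequence[str]] = (),
    core_profiles_for_dedup: pd.DataFrame | None = None,
    config: EnrichmentConfig = EnrichmentConfig(),
    min_family_samples: int = 5,
) -> CIResult:
    """Gene families enriched in both CI lineages over the non-CI wAu group.

    Procedure: (1) collapse genomes with identical core profiles when a
    core-distance matrix is supplied (complete-linkage cut at 0);
    (2) drop families present in fewer than ``min_family_samples`` genomes
    and Bonferroni-correct over the families that remain; (3) a family is
    a candidate iff enriched (one-sided) in wRi-like vs wAu AND in wMel vs
    wAu, both at corrected p < ci_p_threshold; (4) candidates whose
    wAu-vs-nematode comparison shows significant wAu enrichment are
    removed (outgroup correction against spurious CI "loss" calls).
    """
    groups = {"wAu": list(wAu_ids), "wRi": list(wRi_ids), "wMel": list(wMel_ids)}
    seen: set[str] = set()
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"group {name} is empty")
        if seen & set(ids):
            raise ValueError("CI comparison groups must be disjoint")
        seen |= set(ids)

    if core_profiles_for_dedup is not None:
        dedup = dedup_genomes(core_profiles_for_dedup, threshold=0.0)
        kept = set(dedup.representatives)
        for name in groups:
            groups[name] = [g for g in groups[name] if g in kept]
            if not groups[name]:
                raise ValueError(f"group {name} empty after deduplication")
        nematode_lineages = [
            [g for g in lin if g in kept] for lin in nematode_lineages
        ]
    n_after = sum(len(v) for v in groups.values())

    filtered = filter_rare_families(matrix, min_family_samples)
    n_tests = filtered.n_families
    if n_tests == 0:
        return CIResult((), pd.DataFrame(), 0, n_after)

    au = _group_counts(filtered, groups["wAu"])
    n_au = len(groups["wAu"])
    table = pd.DataFrame(index=filtered.family_ids)
    enriched = np.ones(n_tests, dtype=bool)
    for name in ("wRi", "wMel"):
        ci = _group_counts(filtered, groups[name])
        n_ci = len(groups[name])
        p = _greater_pvalues(ci, n_ci, au, n_au)
        p_corr = _correct(p, n_tests, config.correction)
        table[f"{name}_present"] = ci
        table[f"p_{name}_vs_wAu"] = p
        table[f"p_corr_{name}_vs_wAu"] = p_corr
        enriched &= p_corr < config.ci_p_threshold
    table["wAu_present"] = au
    table["candidate"] = enriched

    # outgroup correction: a "CI enrichment" that is really a wAu-specific
    # gain shows up as wAu enrichment against the nematode outgroups
    rejected = np.zeros(n_tests, dtype=bool)
    for lin in nematode_lineages:
        lin = list(lin)
        if not lin:
            continue
        nem = _group_counts(filtered, lin)
        p = _greater_pvalues(au, n_au, nem, len(lin))
        p_corr = _correct(p, n_tests, config.correction)
        rejected |= p_corr < config.ci_p_threshold
    table["outgroup_rejected"] = rejected
    final = enriched & ~rejected
    table["candidate"] = final

    candidates = tuple(f for f, keep in zip(filtered.family_ids, final) if keep)
    return CIResult(candidates, table, n_tests, n_after)
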