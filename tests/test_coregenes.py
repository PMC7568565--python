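import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import complete_linkage_bruteforce, kmedoids_bruteforce
from wolbmag.coregenes import (
    CoreConfig,
    dedup_genomes,
    define_core,
    filter_core_hits,
    filter_rare_families,
    jaccard_distance,
    jaccard_distance_matrix,
    kmedoids,
    select_representatives,
    single_copy_filter,
)
from wolbmag.io import AlignmentRecord, GenePresenceMatrix
from wolbmag.simulate import SimPangenomeConfig, gen_pangenome


class TestJaccard:
    def test_identical_profiles(self):
        assert jaccard_distance([1, 1, 0], [1, 1, 0]) == 0.0

    def test_disjoint_profiles(self):
        assert jaccard_distance([1, 0, 0], [0, 1, 1]) == 1.0

    def test_worked_example(self):
        assert jaccard_distance([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(2 / 3)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_distance([0, 0], [0, 0])

    @given(
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
    )
    def test_matrix_matches_pairwise(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if not any(a) or not any(b):
            return
        m = jaccard_distance_matrix(np.array([a, b]))
        assert m[0, 1] == pytest.approx(jaccard_distance(a, b))
        assert m[0, 0] == 0.0


class TestKMedoids:
    def test_n_equals_k_identity(self, rng):
        x = rng.integers(0, 2, size=(4, 10))
        x[:, 0] = 1
        assert kmedoids(x, 4) == [0, 1, 2, 3]

    def test_identical_profiles_zero_cost(self):
        x = np.ones((6, 5), dtype=int)
        meds = kmedoids(x, 2)
        assert len(meds) == 2

    def test_two_tight_groups(self):
        x = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [1, 1, 1, 1, 0, 0],
                [1, 1, 1, 0, 1, 0],
                [0, 0, 0, 1, 1, 1],
                [0, 0, 1, 1, 1, 1],
                [1, 0, 0, 1, 1, 1],
            ]
        )
        dist = jaccard_distance_matrix(x)
        best_cost, best_sets = kmedoids_bruteforce(dist, 2)
        meds = kmedoids(x, 2)
        cost = float(dist[meds].min(axis=0).sum())
        assert cost == pytest.approx(best_cost)
        assert tuple(meds) in best_sets

    @pytest.mark.parametrize("n,k,seed", [(5, 2, 0), (7, 3, 1), (8, 2, 2), (8, 4, 3)])
    def test_matches_exhaustive_optimum_small_n(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, size=(n, 12))
        x[:, 0] = 1  # no all-zero profiles
        dist = jaccard_distance_matrix(x)
        best_cost, _ = kmedoids_bruteforce(dist, k)
        meds = kmedoids(x, k)
        cost = float(dist[meds].min(axis=0).sum())
        assert cost == pytest.approx(best_cost, abs=1e-9)

    def test_dataframe_returns_labels(self):
        df = pd.DataFrame(np.eye(3, dtype=int), index=["x", "y", "z"])
        assert kmedoids(df, 3) == ["x", "y", "z"]


class TestRepresentatives:
    def test_five_supergroups_yield_25(self):
        matrix, _ = gen_pangenome(SimPangenomeConfig(seed=3))
        reps = select_representatives(matrix)
        assert sum(len(v) for v in reps.values()) == 25
        for sg, ids in reps.items():
            assert all(matrix.supergroup_of[g] == sg for g in ids)

    def test_small_supergroup_contributes_all(self):
        matrix, _ = gen_pangenome(
            SimPangenomeConfig(genomes_per_supergroup=[3, 10, 10, 10, 10], seed=1)
        )
        reps = select_representatives(matrix)
        assert len(reps["A"]) == 3

    def test_single_supergroup(self):
        matrix, _ = gen_pangenome(
            SimPangenomeConfig(n_supergroups=1, genomes_per_supergroup=8, seed=2)
        )
        reps = select_representatives(matrix)
        assert len(reps["A"]) == 5

    def test_unlabelled_genome_rejected(self, tiny_matrix):
        del tiny_matrix.supergroup_of["A.g0"]
        with pytest.raises(ValueError, match="supergroup"):
            select_representatives(tiny_matrix)


class TestDefineCore:
    def test_one_representative_per_supergroup_suffices(self, tiny_matrix):
        reps = {"A": ["A.g0"], "B": ["B.g0"]}
        core = define_core(tiny_matrix, reps)
        # fam3 present in A.g0 but absent in B.g0 -> not core
        assert core == ["fam1", "fam2"]

    def test_absence_from_one_supergroup_excludes(self, tiny_matrix):
        reps = {"A": ["A.g1"], "B": ["B.g0", "B.g1"]}
        assert "fam3" not in define_core(tiny_matrix, reps)

    def test_all_ones_matrix_all_core(self):
        values = pd.DataFrame(np.ones((4, 3), dtype=int),
                              index=list("abcd"), columns=["f1", "f2", "f3"])
        m = GenePresenceMatrix(values, {g: "A" if g < "c" else "B" for g in "abcd"})
        core = define_core(m, {"A": ["a"], "B": ["c"]})
        assert core == ["f1", "f2", "f3"]

    def test_monotone_adding_presence_never_removes_core(self, tiny_matrix):
        reps = {"A": ["A.g0", "A.g1"], "B": ["B.g0", "B.g1"]}
        before = set(define_core(tiny_matrix, reps))
        richer = tiny_matrix.values.copy()
        richer.loc["B.g0", "fam3"] = 1
        m2 = GenePresenceMatrix(richer, tiny_matrix.supergroup_of, tiny_matrix.lineage_of)
        after = set(define_core(m2, reps))
        assert before <= after

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_core_recovered_exactly(self, seed):
        matrix, truth = gen_pangenome(SimPangenomeConfig(seed=seed))
        reps = select_representatives(matrix)
        assert set(define_core(matrix, reps)) == set(truth.core_families)


def _hit(fam="f1", target="geneX", pid=90.0, length=100, evalue=1e-20):
    return AlignmentRecord(f"{fam}|rep1", target, pid, length, 0, 0,
                           1, length, 1, length, evalue, 200.0)


class TestCoreHitFilter:
    MEANS = {"f1": 100.0}

    def _family_of(self, qid):
        return qid.split("|")[0]

    def test_low_identity_rejected(self):
        calls = filter_core_hits([_hit(pid=60.0)], self.MEANS, self._family_of)
        assert calls["f1"].status == "absent"

    def test_overlong_alignment_rejected(self):
        calls = filter_core_hits([_hit(length=130)], self.MEANS, self._family_of)
        assert calls["f1"].status == "absent"

    def test_combined_thresholds_accept(self):
        calls = filter_core_hits(
            [_hit(pid=80.0, length=100, evalue=1e-11)], self.MEANS, self._family_of
        )
        assert calls["f1"].status == "single"

    def test_evalue_boundary_strict(self):
        calls = filter_core_hits([_hit(evalue=1e-10)], self.MEANS, self._family_of)
        assert calls["f1"].status == "absent"

    def test_length_window_boundaries_closed(self):
        ok_lo = filter_core_hits([_hit(length=50)], self.MEANS, self._family_of)
        ok_hi = filter_core_hits([_hit(length=125)], self.MEANS, self._family_of)
        assert ok_lo["f1"].status == "single"
        assert ok_hi["f1"].status == "single"

    def test_two_targets_flagged_multi(self):
        calls = filter_core_hits(
            [_hit(target="geneX"), _hit(target="geneY")], self.MEANS, self._family_of
        )
        assert calls["f1"].status == "multi"
        assert calls["f1"].targets == ("geneX", "geneY")


class TestSingleCopyFilter:
    def _calls(self, multi_genomes: int, total: int = 100):
        from wolbmag.coregenes import CoreGeneCall

        calls = {}
        for i in range(total):
            status = "multi" if i < multi_genomes else "single"
            calls[f"g{i:03d}"] = {
                "f1": CoreGeneCall("f1", status, ("x", "y") if status == "multi" else ("x",))
            }
        return calls

    def test_eleven_percent_multi_excluded(self):
        retained, _ = single_copy_filter(self._calls(11))
        assert retained == []

    def test_exactly_ten_percent_retained(self):
        retained, filtered = single_copy_filter(self._calls(10))
        assert retained == ["f1"]
        # multi-hit genome calls are dropped even in retained families
        assert "f1" not in filtered["g000"]
        assert "f1" in filtered["g099"]

    def test_never_multi_retained(self):
        retained, _ = single_copy_filter(self._calls(0))
        assert retained == ["f1"]


class TestDedup:
    def _dm(self, ids, entries):
        n = len(ids)
        d = np.zeros((n, n))
        for (i, j), v in entries.items():
            d[i, j] = d[j, i] = v
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_close_pair_collapses(self):
        dm = self._dm(["a", "b"], {(0, 1): 0.004})
        assert dedup_genomes(dm).representatives == ("a",)

    def test_identical_genomes_single_representative(self):
        dm = self._dm(["a", "b", "c"], {})
        res = dedup_genomes(dm)
        assert res.representatives == ("a",)
        assert res.representative_of == {"a": "a", "b": "a", "c": "a"}

    def test_complete_linkage_blocks_chain(self):
        dm = self._dm(
            ["a", "b", "c"], {(0, 1): 0.004, (1, 2): 0.004, (0, 2): 0.006}
        )
        res = dedup_genomes(dm)
        assert set(res.clusters().get("a", [])) == {"a", "b"}
        assert res.representatives == ("a", "c")

    def test_asymmetric_matrix_rejected(self):
        dm = self._dm(["a", "b"], {(0, 1): 0.1})
        dm.iloc[0, 1] = 0.2
        with pytest.raises(ValueError, match="symmetric"):
            dedup_genomes(dm)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_agglomeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pts = rng.random((n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"g{i}" for i in range(n)]
        dm = pd.DataFrame(d, index=ids, columns=ids)
        threshold = float(rng.uniform(0.1, 0.8))
        res = dedup_genomes(dm, threshold=threshold)
        expected = complete_linkage_bruteforce(d, threshold)
        got = {frozenset(v) for v in res.clusters().values()}
        want = {frozenset(f"g{i}" for i in c) for c in expected}
        assert got == want

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_and_diameter_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 12
        pts = rng.random((n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"g{i}" for i in range(n)]
        res = dedup_genomes(pd.DataFrame(d, index=ids, columns=ids), threshold=0.3)
        members = [g for c in res.clusters().values() for g in c]
        assert len(members) == n and set(members) == set(ids)  # exact partition
        for cluster in res.clusters().values():
            idx = [ids.index(g) for g in cluster]
            for i in idx:
                for j in idx:
                    assert d[i, j] <= 0.3 + 1e-12


class TestRareFamilies:
    def test_threshold_at_five(self, rng):
        values = pd.DataFrame(0, index=[f"g{i}" for i in range(10)],
                              columns=["rare", "kept"])
        values.iloc[:4, 0] = 1
        values.iloc[:5, 1] = 1
        m = GenePresenceMatrix(values)
        out = filter_rare_families(m)
        assert out.family_ids == ["kept"]

    def test_empty_matrix(self):
        m = GenePresenceMatrix(pd.DataFrame(index=["g1"], columns=[], dtype="int8"))
        assert filter_rare_families(m).family_ids == []

    def test_universal_families_unchanged(self, tiny_matrix):
        out = filter_rare_families(tiny_matrix, min_family_samples=1)
        assert out.family_ids == tiny_matrix.family_ids


def test_core_config_validation():
    with pytest.raises(ValueError):
        CoreConfig(hit_len_min_frac=1.2)
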