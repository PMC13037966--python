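"""Interaction filtering, cluster expansion, hypergeometric ORA, BH control."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import phenocoex.annotation as anno


def write_interactions(tmp_path, rows, name="string.tsv"):
    path = tmp_path / name
    lines = ["protein1\tprotein2\tcombined_score"]
    lines += [f"{a}\t{b}\t{s}" for a, b, s in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadInteractions:
    def test_strict_score_boundary(self, tmp_path):
        path = write_interactions(
            tmp_path, [("a", "b", 950), ("a", "c", 951), ("b", "d", 1000)]
        )
        table = anno.load_interactions(path)
        assert table.partners("a") == {"c"}  # 950 dropped, strict >
        assert table.n_edges == 2

    def test_symmetric_closure(self, tmp_path):
        table = anno.load_interactions(write_interactions(tmp_path, [("a", "b", 990)]))
        assert table.partners("b") == {"a"}

    def test_malformed_score_names_line(self, tmp_path):
        path = write_interactions(tmp_path, [("a", "b", 990), ("c", "d", "high")])
        with pytest.raises(anno.InteractionFormatError, match="line 3"):
            anno.load_interactions(path)

    def test_id_map_translation(self, tmp_path):
        path = write_interactions(tmp_path, [("P1", "P2", 990)])
        table = anno.load_interactions(path, id_map={"P1": "G1", "P2": "G2"})
        assert table.partners("G1") == {"G2"}


class TestExpandCluster:
    def _table(self, rows):
        neighbors = {}
        for a, b in rows:
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)
        return anno.InteractionTable(neighbors=neighbors)

    def test_first_neighbors_minus_members(self):
        table = self._table([("a", "x"), ("b", "y")])
        assert anno.expand_cluster({"a", "b"}, table) == {"x", "y"}

    def test_internal_edges_contribute_nothing(self):
        table = self._table([("a", "b")])
        assert anno.expand_cluster({"a", "b"}, table) == set()

    def test_empty_table(self):
        assert anno.expand_cluster({"a"}, anno.InteractionTable({})) == set()


class TestGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tfirst set\tg1\tg2\tg3\nS2\tsecond\tg2\tg4\n")
        coll = anno.read_gmt(path, source="GO-BP-like")
        assert coll.sets == {"S1": frozenset({"g1", "g2", "g3"}), "S2": frozenset({"g2", "g4"})}
        assert coll.descriptions["S2"] == "second"
        assert coll.all_genes == frozenset({"g1", "g2", "g3", "g4"})

    def test_duplicate_name_is_error(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tx\tg1\nS1\ty\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            anno.read_gmt(path)

    def test_empty_set_is_error(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("S1\tx\t\n")
        with pytest.raises(ValueError):
            anno.read_gmt(path)


def enumeration_p(N, K, n, k):
    """Independent oracle: exhaustive scan of all C(N, n) draws."""
    universe = list(range(N))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g < K) >= k:
            hits += 1
    return hits / total


class TestOra:
    def _collection(self, sets):
        return anno.GeneSetCollection(
            sets={k: frozenset(v) for k, v in sets.items()},
            descriptions={k: k for k in sets},
        )

    def test_hand_computed_tail(self):
        # N=10, K=4, n=3, k=3 -> C(4,3)/C(10,3) = 4/120
        universe = [f"g{i}" for i in range(10)]
        coll = self._collection({"T": universe[:4]})
        res = anno.ora(universe[:3], coll, universe)
        assert res.loc[0, "p"] == pytest.approx(4 / 120, abs=1e-12)
        assert res.loc[0, ["k", "K", "n", "N"]].tolist() == [3, 4, 3, 10]

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        coll = self._collection({"T": universe[:3]})
        res = anno.ora(universe[5:], coll, universe)
        assert res.loc[0, "k"] == 0
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(10):
            N = int(rng.integers(4, 12))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            coll = self._collection({"T": universe[:K]})
            query = universe[:n] if rng.random() < 0.5 else universe[-n:]
            res = anno.ora(query, coll, universe)
            k = len(set(universe[:K]) & set(query))
            assert res.loc[0, "p"] == pytest.approx(enumeration_p(N, K, n, k), abs=1e-10)

    def test_query_outside_universe_dropped(self):
        universe = ["g1", "g2", "g3", "g4"]
        coll = self._collection({"T": ["g1", "g2"]})
        res = anno.ora(["g1", "nope"], coll, universe)
        assert res.loc[0, "n"] == 1

    def test_empty_query_empty_result(self):
        coll = self._collection({"T": ["g1"]})
        assert anno.ora(["zz"], coll, ["g1", "g2"]).empty

    def test_bh_matches_reference_step_up(self, rng):
        """q values equal the hand-written BH step-up (sorted p*m/rank with a
        cumulative minimum from the largest p down)."""
        universe = [f"g{i}" for i in range(40)]
        sets = {
            f"S{j}": rng.choice(universe, size=int(rng.integers(3, 12)), replace=False)
            for j in range(15)
        }
        coll = self._collection(sets)
        res = anno.ora(universe[:9], coll, universe)
        p = res["p"].to_numpy()
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q_ref = np.empty(m)
        q_ref[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(res["q"].to_numpy(), q_ref, atol=1e-12)
        assert (res["q"].to_numpy() >= res["p"].to_numpy() - 1e-12).all()


class TestGroupingsAndIntersection:
    def _setup(self, tmp_path):
        universe = [f"g{i}" for i in range(30)]
        coll = anno.GeneSetCollection(
            sets={
                "SA": frozenset(universe[:6]),
                "SB": frozenset(universe[6:12]),
                "SC": frozenset(universe[12:20]),
            },
            descriptions={},
        )
        table = anno.load_interactions(
            write_interactions(tmp_path, [("g0", "g6", 990), ("g1", "g7", 990)])
        )
        return universe, coll, table

    def test_identical_inputs_fully_overlap(self, tmp_path):
        universe, coll, table = self._setup(tmp_path)
        clusters = [["g0", "g1", "g2"], ["g3", "g4"]]
        runs = anno.run_groupings(clusters, clusters, table, coll, universe)
        for g in anno.GROUPINGS:
            pd.testing.assert_frame_equal(
                runs["results"][("DS1", g)], runs["results"][("DS2", g)]
            )
        assert all(
            runs["overlap"]["ds1_ds2_shared"][g]
            == int((runs["results"][("DS1", g)]["q"] < 0.05).sum())
            for g in anno.GROUPINGS
        )

    def test_venn_regions_partition_union(self, tmp_path):
        universe, coll, table = self._setup(tmp_path)
        runs = anno.run_groupings(
            [["g0", "g1", "g2", "g3"]], [["g12", "g13", "g14"]], table, coll, universe
        )
        for scen in ("DS1", "DS2"):
            ov = runs["overlap"][scen]
            regions = sum(
                ov[key]
                for key in (
                    "cluster_only", "interactors_only", "combined_only",
                    "cluster_and_interactors", "cluster_and_combined",
                    "interactors_and_combined", "all_three",
                )
            )
            assert regions == ov["union"]

    def test_intersection_thresholds(self):
        res1 = pd.DataFrame(
            {"term": ["T1", "T2"], "description": ["", ""],
             "k": 1, "K": 1, "n": 1, "N": 2, "p": [1e-7, 1e-3], "q": [1e-6, 1e-3]}
        )
        res2 = pd.DataFrame(
            {"term": ["T1", "T3"], "description": ["", ""],
             "k": 1, "K": 1, "n": 1, "N": 2, "p": [1e-7, 1e-3], "q": [1e-6, 1e-3]}
        )
        strict = anno.intersect_terms(res1, res2, fdr=1e-5)
        assert strict["term"].tolist() == ["T1"]
        loose = anno.intersect_terms(res1, res2, fdr=0.05)
        assert set(strict["term"]) <= set(loose["term"])
        disjoint = anno.intersect_terms(
            res1[res1["term"] == "T2"], res2[res2["term"] == "T3"], fdr=0.05
        )
        assert disjoint.empty
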