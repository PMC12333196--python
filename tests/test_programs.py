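from itertools import combinations, permutations

import numpy as np
import pytest

from lsgi import (
    ProgramSignature,
    annotate_meta_program,
    cluster_meta_programs,
    delta_shannon,
    enrichment_table,
    hypergeom_enrichment,
    meta_signature,
    program_overlap,
    shannon_entropy,
    specificity_score,
)


def sig(pid, genes, category=("T", "S")):
    return ProgramSignature(program_id=pid, genes=list(genes), category=category)


def make_genes(prefix, n):
    return [f"{prefix}{i:02d}" for i in range(n)]


class TestOverlapAndSignatures:
    def test_overlap_counts(self):
        core = make_genes("c", 30)
        a = sig("A", core + make_genes("a", 20))
        b = sig("B", core + make_genes("b", 20))
        assert program_overlap(a, a) == 50
        assert program_overlap(a, b) == 30
        assert program_overlap(a, sig("C", make_genes("z", 50))) == 0

    def test_meta_signature_of_identical_members(self):
        genes = make_genes("g", 50)
        merged = meta_signature([sig("A", genes), sig("B", genes)])
        assert merged == genes

    def test_shared_genes_outrank_private_genes(self):
        shared = make_genes("s", 30)
        merged = meta_signature(
            [sig("A", shared + make_genes("a", 20)),
             sig("B", shared + make_genes("b", 20))]
        )
        assert merged[:30] == shared

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(0)
        pool = make_genes("g", 80)
        members = [
            sig(f"P{i}", list(rng.choice(pool, size=50, replace=False)))
            for i in range(3)
        ]
        merged = meta_signature(members)
        # oracle: explicit (count desc, mean rank asc, name) sort
        stats = {}
        for m in members:
            for rank, gene in enumerate(m.genes, start=1):
                cnt, tot = stats.get(gene, (0, 0.0))
                stats[gene] = (cnt + 1, tot + rank)
        expected = sorted(
            stats, key=lambda g: (-stats[g][0], stats[g][1] / stats[g][0], g)
        )[:50]
        assert merged == expected

    def test_fewer_than_50_distinct_genes_warns(self):
        genes = make_genes("g", 30)
        with pytest.warns(UserWarning, match="distinct"):
            merged = meta_signature([sig("A", genes), sig("B", genes)])
        assert merged == genes


class TestMetaProgramClustering:
    def test_lone_pair_stays_unclustered(self):
        shared = make_genes("s", 25)
        sigs = [
            sig("P1", shared + make_genes("a", 25)),
            sig("P2", shared + make_genes("b", 25)),
        ]
        metas, unclustered = cluster_meta_programs(sigs)
        assert metas == []
        assert unclustered == ["P1", "P2"]

    def test_founder_with_two_partners_forms_cluster(self):
        core = make_genes("c", 30)
        sigs = [
            sig("P1", core + make_genes("a", 20)),
            sig("P2", core + make_genes("b", 20)),
            sig("P3", core + make_genes("d", 20)),
            sig("P4", make_genes("z", 50)),
        ]
        metas, unclustered = cluster_meta_programs(sigs)
        assert len(metas) == 1
        assert sorted(metas[0].members) == ["P1", "P2", "P3"]
        assert unclustered == ["P4"]
        # core genes, present in all three members, head the signature
        assert set(core) <= set(metas[0].signature)

    def test_members_disjoint_across_meta_programs(self):
        core1, core2 = make_genes("x", 30), make_genes("y", 30)
        sigs = [
            sig(f"A{i}", core1 + make_genes(f"a{i}", 20)) for i in range(3)
        ] + [
            sig(f"B{i}", core2 + make_genes(f"b{i}", 20)) for i in range(3)
        ]
        metas, unclustered = cluster_meta_programs(sigs)
        assert len(metas) == 2
        all_members = [m for mp in metas for m in mp.members]
        assert len(all_members) == len(set(all_members)) == 6
        assert unclustered == []

    def test_growth_threshold_respected(self):
        # P4 overlaps the core trio by only 10 genes: never merged
        core = make_genes("c", 30)
        sigs = [
            sig("P1", core + make_genes("a", 20)),
            sig("P2", core + make_genes("b", 20)),
            sig("P3", core + make_genes("d", 20)),
            sig("P4", core[:10] + make_genes("z", 40)),
        ]
        metas, unclustered = cluster_meta_programs(sigs)
        assert unclustered == ["P4"]

    def test_deterministic_under_input_order(self):
        core = make_genes("c", 30)
        sigs = [
            sig("P1", core + make_genes("a", 20)),
            sig("P2", core + make_genes("b", 20)),
            sig("P3", core + make_genes("d", 20)),
        ]
        m1, _ = cluster_meta_programs(sigs)
        m2, _ = cluster_meta_programs(sigs[::-1])
        assert [m.members for m in m1] == [m.members for m in m2]


class TestEntropy:
    def test_degenerate_and_uniform(self):
        assert shannon_entropy([1.0]) == 0.0
        assert shannon_entropy([0.25] * 4) == pytest.approx(np.log(4))

    def test_term_by_term_value(self):
        p = np.array([0.5, 0.25, 0.25])
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert shannon_entropy(p) == pytest.approx(expected)
        assert shannon_entropy(p) == pytest.approx(1.0397, abs=1e-4)

    def test_negative_fraction_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])

    def test_entropy_bounded_by_log_c(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(c))
            h = shannon_entropy(p)
            assert -1e-12 <= h <= np.log(c) + 1e-12


class TestDeltaShannon:
    def test_single_category_pool_gives_zero_delta(self):
        labels = {f"P{i}": "only" for i in range(5)}
        res = delta_shannon(["P0", "P1"], labels, seed=0)
        assert res.real_entropy == 0.0 and res.delta == 0.0

    def test_meta_program_equal_to_pool_gives_zero_delta(self):
        labels = {"P1": "a", "P2": "a", "P3": "b", "P4": "c"}
        res = delta_shannon(list(labels), labels, n_shuffles=25, seed=0)
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_permutation_oracle(self):
        # pool: 4 programs of category a, 2 of b; MP = the four a-programs
        labels = {"P1": "a", "P2": "a", "P3": "a", "P4": "a",
                  "P5": "b", "P6": "b"}
        members = ["P1", "P2", "P3", "P4"]
        pool = list(labels.values())
        ents = []
        for perm in permutations(pool):
            counts = np.unique(perm[:4], return_counts=True)[1]
            ents.append(shannon_entropy(counts / 4))
        exact_mean, exact_sd = np.mean(ents), np.std(ents)
        n = 10_000
        res = delta_shannon(members, labels, n_shuffles=n, seed=7)
        assert res.real_entropy == 0.0
        se = exact_sd / np.sqrt(n)
        assert abs(res.shuffled_mean - exact_mean) < 3 * se
        assert res.delta == pytest.approx(res.shuffled_mean)

    def test_sign_flip(self):
        labels = {"P1": "a", "P2": "a", "P3": "b", "P4": "b"}
        a = delta_shannon(["P1", "P2"], labels, seed=3)
        b = delta_shannon(["P1", "P2"], labels, seed=3, flip_sign=True)
        assert a.delta == pytest.approx(-b.delta)

    def test_unlabeled_member_errors(self):
        with pytest.raises(ValueError, match="unlabeled"):
            delta_shannon(["PX"], {"P1": "a"})


class TestHypergeometricEnrichment:
    UNIVERSE = make_genes("u", 10)

    def test_worked_example_10_gene_universe(self):
        gene_sets = {"S": self.UNIVERSE[:5]}
        query = self.UNIVERSE[:3]
        table = hypergeom_enrichment(query, gene_sets, self.UNIVERSE)
        assert table["p"].iloc[0] == pytest.approx(10 / 120)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        gene_sets = {
            "S1": list(rng.choice(self.UNIVERSE, 5, replace=False)),
            "S2": list(rng.choice(self.UNIVERSE, 7, replace=False)),
        }
        query = list(rng.choice(self.UNIVERSE, 4, replace=False))
        table = hypergeom_enrichment(query, gene_sets, self.UNIVERSE)
        for name, genes in gene_sets.items():
            observed = len(set(genes) & set(query))
            # oracle: enumerate all possible queries of the same size
            total, at_least = 0, 0
            for combo in combinations(self.UNIVERSE, len(query)):
                total += 1
                if len(set(combo) & set(genes)) >= observed:
                    at_least += 1
            expected = at_least / total
            got = float(table.loc[table["gene_set"] == name, "p"].iloc[0])
            assert got == pytest.approx(expected)

    def test_query_equals_universe_certain_event(self):
        gene_sets = {"S": self.UNIVERSE[:4]}
        table = hypergeom_enrichment(self.UNIVERSE, gene_sets, self.UNIVERSE)
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert table["overlap"].iloc[0] == 4

    def test_bh_adjustment_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(5)
        gene_sets = {
            f"S{i}": list(rng.choice(self.UNIVERSE, rng.integers(2, 8),
                                     replace=False))
            for i in range(8)
        }
        table = hypergeom_enrichment(self.UNIVERSE[:4], gene_sets, self.UNIVERSE)
        assert (table["adj_p"] >= table["p"] - 1e-15).all()
        srt = table.sort_values("p")
        assert (np.diff(srt["adj_p"]) >= -1e-15).all()

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment([], {"S": ["u00"]}, self.UNIVERSE)


class TestSpecificityAndAnnotation:
    def test_two_program_difference(self):
        e = np.array([[3.0, 1.0]])
        np.testing.assert_allclose(specificity_score(e), [[2.0, -2.0]])

    def test_constant_row_zero(self):
        e = np.full((2, 4), 1.7)
        np.testing.assert_allclose(specificity_score(e), 0.0)

    def test_row_arithmetic(self):
        e = np.array([[3.0, 1.0, 2.0]])
        np.testing.assert_allclose(
            specificity_score(e), [[1.5, -1.5, 0.0]]
        )

    def test_single_program_errors(self):
        with pytest.raises(ValueError):
            specificity_score(np.array([[1.0]]))

    def test_annotation_two_step_reduction(self):
        universe = make_genes("u", 40)
        # set X is unique to MP1's genes; set Y is shared by both queries
        queries = {"MP1": universe[:10], "MP2": universe[10:20]}
        gene_sets = {
            "X": universe[:10],
            "Y": universe[:20],
            "Z": universe[30:],
        }
        table = enrichment_table(queries, gene_sets, universe)
        top = annotate_meta_program(table, "MP1", top_by_specificity=2)
        assert list(top["gene_set"])[0] == "X"
        assert (top["specificity"].diff().dropna() <= 1e-12).all()

    def test_uniformly_enriched_set_ranks_below_unique_set(self):
        universe = make_genes("u", 30)
        queries = {"MP1": universe[:10], "MP2": universe[:10]}
        gene_sets = {"shared": universe[:10]}
        table = enrichment_table(queries, gene_sets, universe)
        np.testing.assert_allclose(table["specificity"], 0.0, atol=1e-12)
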