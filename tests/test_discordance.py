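import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from scipy import stats

from digs.discordance import (
    AADMatrix,
    aad_matrix,
    delta_pvalues,
    delta_statistics,
    fit_exponential_robust,
    hellinger_fit,
    noise_corrected_discordance,
    quartet_distance,
    simulate_discordance_dataset,
    single_linkage_subsets,
)
from digs.io import GenomeSet, read_newick
from digs.simulate import BaseGenomeConfig, evolve_aa, make_base_genome


def random_binary_tree(labels, rng: random.Random) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(list(labels))
    return dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1, rng=rng)


def quartet_topology_by_path_disjointness(tree, quad):
    """Independent oracle: split ab|cd holds iff paths a-b and c-d share no node."""
    nodes = {t.taxon.label: t for t in tree.leaf_node_iter()}

    def ancestors(x):
        out = []
        n = nodes[x]
        while n is not None:
            out.append(n)
            n = n.parent_node
        return out

    def path_nodes(x, y):
        ax, ay = ancestors(x), ancestors(y)
        set_y = set(ay)
        mrca = next(n for n in ax if n in set_y)
        out = set()
        for n in ax:
            out.add(n)
            if n is mrca:
                break
        for n in ay:
            if n is mrca:
                break
            out.add(n)
        return out

    a, b, c, d = quad
    splits = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    resolved = [i for i, ((x, y), (u, v)) in enumerate(splits)
                if not (path_nodes(x, y) & path_nodes(u, v))]
    return resolved[0] if len(resolved) == 1 else -1


class TestQuartetDistance:
    def test_identical_trees_distance_zero(self):
        rng = random.Random(1)
        t = random_binary_tree([f"g{i}" for i in range(10)], rng)
        t2 = read_newick(t.as_string(schema="newick"))
        assert quartet_distance(t, t2) == 0.0

    def test_conflicting_four_leaf_trees_distance_one(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert quartet_distance(t1, t2) == 1.0

    def test_fewer_than_four_shared_leaves_errors(self):
        t1 = read_newick("((A:1,B:1):1,C:1);")
        t2 = read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError):
            quartet_distance(t1, t2)

    def test_matches_path_disjointness_oracle_on_random_trees(self):
        rng = random.Random(7)
        labels = [f"g{i}" for i in range(10)]
        mismatches = 0
        for rep in range(25):
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            expected_diff = 0
            for quad in itertools.combinations(labels, 4):
                q1 = quartet_topology_by_path_disjointness(t1, quad)
                q2 = quartet_topology_by_path_disjointness(t2, quad)
                if q1 != q2 or (q1 < 0) != (q2 < 0):
                    expected_diff += 1
            expected = expected_diff / 210
            assert quartet_distance(t1, t2) == pytest.approx(expected)

    def test_metric_properties_on_random_triples(self):
        rng = random.Random(9)
        labels = [f"g{i}" for i in range(8)]
        trees = [random_binary_tree(labels, rng) for _ in range(3)]
        d01 = quartet_distance(trees[0], trees[1])
        d10 = quartet_distance(trees[1], trees[0])
        assert d01 == d10
        d02 = quartet_distance(trees[0], trees[2])
        d12 = quartet_distance(trees[1], trees[2])
        assert d02 <= d01 + d12 + 1e-12


class TestExponentialFit:
    def test_constant_ln2_gives_unit_rate(self):
        assert fit_exponential_robust([math.log(2)] * 7) == pytest.approx(1.0)

    @pytest.mark.parametrize("rate", [0.5, 1.0, 2.0, 5.0])
    def test_rate_recovery_within_5pct(self, rate):
        rng = np.random.default_rng(int(rate * 10))
        draws = rng.exponential(1.0 / rate, size=10_000)
        assert fit_exponential_robust(draws) == pytest.approx(rate, rel=0.05)

    def test_all_zero_deltas_undefined(self):
        assert math.isnan(fit_exponential_robust([0.0, 0.0, 0.0]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fit_exponential_robust([])


class TestHellingerFit:
    def test_exponential_sample_ranked_first(self):
        rng = np.random.default_rng(0)
        ranking = hellinger_fit(rng.exponential(1.0, size=10_000))
        assert ranking[0][0] == "exponential"

    def test_lognormal_sample_not_exponential(self):
        rng = np.random.default_rng(1)
        ranking = hellinger_fit(rng.lognormal(0.0, 1.0, size=10_000))
        assert ranking[0][0] != "exponential"

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            hellinger_fit([1.0] * 100)


def _chain_aad(ids, step=0.05):
    n = len(ids)
    v = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * step
    return AADMatrix(genome_ids=list(ids), values=v.astype(float))


class TestDeltaStatistics:
    def test_concordant_tree_gives_zero_deltas(self):
        # caterpillar tree ranks genomes exactly like the chain AAD
        newick = "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"
        tree = read_newick(newick)
        aad = _chain_aad(["A", "B", "C", "D", "E"])
        records = delta_statistics(tree, aad, k=1)
        by_query = {r.query: r for r in records}
        assert by_query["A"].deltas == [0.0]  # N1 = B = M
        assert all(d >= 0 for r in records for d in r.deltas)

    def test_multiple_copies_processed_independently(self):
        tree = read_newick("(((Q|1:1,A:1):1,(Q|2:1,B:1):1):1,C:3);")
        aad = _chain_aad(["Q", "A", "B", "C"])
        records = delta_statistics(tree, aad, k=2)
        q_records = [r for r in records if r.query == "Q"]
        assert len(q_records) == 2
        assert {r.query_leaf for r in q_records} == {"Q|1", "Q|2"}

    def test_survival_pvalues_and_bh(self):
        from digs.discordance import DiscordanceRecord

        recs = [DiscordanceRecord("g", "Q", "Q", "M", ["N"], [0.1], [d])
                for d in [0.0, math.log(2), 10 * math.log(2)]]
        out = delta_pvalues(recs)
        # lambda = ln2 / median(deltas) = 1
        assert out[0].p_values[0] == pytest.approx(1.0)
        assert out[1].p_values[0] == pytest.approx(0.5)
        assert out[2].p_values[0] == pytest.approx(2.0 ** -10, rel=1e-9)
        for r in out:
            assert r.q_values[0] >= r.p_values[0] - 1e-15

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert list(np.round(q, 10)) == [0.03, 0.03, 0.03]

    def test_cdf_tail_compatibility_flag(self):
        from digs.discordance import DiscordanceRecord

        recs = [DiscordanceRecord("g", "Q", "Q", "M", ["N"], [0.1], [d])
                for d in [0.5, 1.0, 2.0]]
        out = delta_pvalues(recs, tail="cdf")
        assert out[0].p_values[0] < out[2].p_values[0]  # lower tail now

    def test_pvalues_uniform_under_exponential_null(self):
        from digs.discordance import DiscordanceRecord

        rng = np.random.default_rng(5)
        deltas = rng.exponential(0.03, size=400)
        recs = [DiscordanceRecord("g", "Q", "Q", "M", ["N"], [0.1], [d])
                for d in deltas]
        out = delta_pvalues(recs)
        pvals = [r.p_values[0] for r in out]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAADMatrix:
    def test_identical_genomes_zero_aad(self):
        base = make_base_genome(BaseGenomeConfig(n_genes=40, seed=2), "x")
        twin = make_base_genome(BaseGenomeConfig(n_genes=40, seed=2), "y")
        gset = GenomeSet({"x": base, "y": twin})
        m = aad_matrix(gset)
        assert m.get("x", "y") == pytest.approx(0.0, abs=1e-12)

    def test_recovers_simulated_aa_divergence(self):
        base = make_base_genome(BaseGenomeConfig(n_genes=60, seed=3), "base")
        ev = evolve_aa(base, 0.1, seed=4)
        gset = GenomeSet({"A": base, "B": ev.genome})
        m = aad_matrix(gset)
        assert m.get("A", "B") == pytest.approx(ev.true_divergence, rel=0.10)

    def test_missing_pair_excluded_from_nearest(self):
        v = np.array([[0.0, np.nan, 0.3],
                      [np.nan, 0.0, 0.1],
                      [0.3, 0.1, 0.0]])
        m = AADMatrix(["A", "B", "C"], v)
        assert m.nearest("A") == "C"  # B is missing


class TestSubsets:
    def test_singleton_threshold_samples_freely(self):
        rng = np.random.default_rng(0)
        n = 15
        v = rng.uniform(0.2, 0.4, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        aad = AADMatrix([f"g{i}" for i in range(n)], v)
        subsets, skipped = single_linkage_subsets(
            aad, thresholds=[0.01], subsets_per_threshold=5, seed=1)
        assert len(subsets) == 5
        assert all(len(set(s.genome_ids)) == 10 for s in subsets)

    def test_two_cluster_matrix_cannot_build_size_10(self):
        v = np.array([
            [0.0, 0.01, 0.5, 0.5],
            [0.01, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 0.01],
            [0.5, 0.5, 0.01, 0.0],
        ])
        aad = AADMatrix(["a", "b", "c", "d"], v)
        with pytest.raises(ValueError):
            single_linkage_subsets(aad, thresholds=[0.1], seed=0)

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(2)
        n = 20
        v = rng.uniform(0.05, 0.4, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        aad = AADMatrix([f"g{i}" for i in range(n)], v)
        s1, _ = single_linkage_subsets(aad, thresholds=[0.01, 0.02],
                                       subsets_per_threshold=3, seed=5)
        s2, _ = single_linkage_subsets(aad, thresholds=[0.01, 0.02],
                                       subsets_per_threshold=3, seed=5)
        assert [s.genome_ids for s in s1] == [s.genome_ids for s in s2]


class TestNoiseCorrectedDiscordance:
    def test_identical_trees_fully_cancel(self):
        rng = random.Random(3)
        labels = [f"g{i}" for i in range(12)]
        t = random_binary_tree(labels, rng)
        clone = lambda: read_newick(t.as_string(schema="newick"))
        qs = noise_corrected_discordance(clone(), [clone(), clone()], clone(),
                                         labels[:10])
        assert qs.q_s == 0.0 and qs.corrected == 0.0

    def test_maximal_conflict_with_clean_bootstraps(self):
        gene = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        species = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        boot = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        qs = noise_corrected_discordance(gene, [boot], species, ["A", "B", "C", "D"])
        assert qs.corrected == 1.0

    def test_noise_cancellation_construction(self):
        # species tree == gene tree, noisy bootstraps: corrected ~ 0, q_noise > 0
        rng = random.Random(4)
        labels = [f"g{i}" for i in range(10)]
        t = random_binary_tree(labels, rng)
        species = read_newick(t.as_string(schema="newick"))
        boots = [random_binary_tree(labels, rng) for _ in range(3)]
        qs = noise_corrected_discordance(t, boots, species, labels)
        assert qs.q_s == 0.0
        assert qs.q_noise > 0.0
        assert qs.corrected <= 0.0

    def test_missing_subset_leaf_reported(self):
        gene = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        species = read_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="D"):
            noise_corrected_discordance(gene, [], species, ["A", "B", "C", "D"])


class TestPlantedTransferPipeline:
    def test_planted_transfer_detected_concordant_not(self):
        species, gene_trees, aad, planted = simulate_discordance_dataset(
            n_genomes=32, n_genes=40, n_transfers=1, seed=11)
        records = []
        for gid, tree in gene_trees.items():
            records.extend(delta_statistics(tree, aad, gene_id=gid))
        records = delta_pvalues(records)
        (gid, query, donor) = planted[0]
        planted_q = [min(r.q_values) for r in records
                     if r.gene_id == gid and r.query == query]
        assert planted_q and min(planted_q) < 0.001
        concordant_q = [q for r in records for q in r.q_values
                        if r.gene_id != gid]
        assert min(concordant_q) > 0.001
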