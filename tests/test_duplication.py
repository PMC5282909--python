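import itertools

import networkx as nx
import numpy as np
import pytest

from polyfam import duplication as dup
from polyfam.models import DatingConfig, SyntenyPair, ValidationError
from conftest import make_genes


def brute_force_clusters(family, index, window_bp=100_000, max_intervening=5):
    """Independent oracle: all-pairs rule check + connected components."""
    models = [index[g] for g in family if dup.is_placed(index[g].chrom)]
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in models)
    for a, b in itertools.combinations(models, 2):
        if (
            a.chrom == b.chrom
            and abs(a.rank - b.rank) - 1 <= max_intervening
            and abs(a.start - b.start) <= window_bp
        ):
            graph.add_edge(a.gene_id, b.gene_id)
    return sorted(
        tuple(sorted(c)) for c in nx.connected_components(graph) if len(c) >= 2
    )


def cluster_sets(clusters):
    return sorted(tuple(sorted(c.members)) for c in clusters)


class TestTandemRule:
    def test_adjacent_pair_within_window_clusters(self, toy_genome):
        index = {g.gene_id: g for g in toy_genome}
        (c,) = dup.find_tandem_clusters(["g1", "g2"], index)
        assert c.members == ("g1", "g2")

    def test_six_intervening_genes_break_the_link(self):
        # g0 and g7: 6 intervening genes, only 20 kb apart
        genes = make_genes(
            [("g0", "Chr01", 1)]
            + [(f"m{i}", "Chr01", 1 + 2500 * i) for i in range(1, 7)]
            + [("g7", "Chr01", 20_001)]
        )
        index = {g.gene_id: g for g in genes}
        assert dup.find_tandem_clusters(["g0", "g7"], index) == []

    def test_exactly_five_intervening_is_inclusive(self):
        genes = make_genes(
            [("g0", "Chr01", 1)]
            + [(f"m{i}", "Chr01", 1 + 2500 * i) for i in range(1, 6)]
            + [("g6", "Chr01", 20_001)]
        )
        index = {g.gene_id: g for g in genes}
        (c,) = dup.find_tandem_clusters(["g0", "g6"], index)
        assert set(c.members) == {"g0", "g6"}

    @pytest.mark.parametrize("distance,n_clusters", [(100_000, 1), (100_001, 0)])
    def test_window_boundary_inclusive_at_100kb(self, distance, n_clusters):
        genes = make_genes([("g1", "Chr01", 1), ("g2", "Chr01", 1 + distance)])
        index = {g.gene_id: g for g in genes}
        assert len(dup.find_tandem_clusters(["g1", "g2"], index)) == n_clusters

    def test_chain_clusters_transitively(self):
        # g1-g2 and g2-g3 each pass both thresholds; g1-g3 is exactly 100 kb
        genes = make_genes(
            [("g1", "Chr01", 1), ("g2", "Chr01", 50_001), ("g3", "Chr01", 100_001)]
        )
        index = {g.gene_id: g for g in genes}
        (c,) = dup.find_tandem_clusters(["g1", "g2", "g3"], index)
        assert c.members == ("g1", "g2", "g3")
        assert c.span_bp == 100_000

    def test_missing_family_gene_is_error_naming_it(self, toy_genome):
        index = {g.gene_id: g for g in toy_genome}
        with pytest.raises(ValidationError, match="ghost"):
            dup.find_tandem_clusters(["ghost"], index)

    def test_scaffold_genes_excluded(self):
        genes = make_genes(
            [("s1", "scaffold_12", 1), ("s2", "scaffold_12", 100), ("g1", "Chr01", 1)]
        )
        index = {g.gene_id: g for g in genes}
        assert dup.find_tandem_clusters(["s1", "s2", "g1"], index) == []

    def test_matches_brute_force_on_random_toy_genomes(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 51))
            chroms = rng.choice(["Chr01", "Chr02"], size=n)
            starts = rng.choice(np.arange(1, 2_000_000, 7919), size=n, replace=False)
            genes = make_genes(
                [(f"g{i}", c, int(s)) for i, (c, s) in enumerate(zip(chroms, starts))]
            )
            index = {g.gene_id: g for g in genes}
            family = [g.gene_id for g in genes if rng.random() < 0.4]
            got = cluster_sets(dup.find_tandem_clusters(family, index))
            assert got == brute_force_clusters(family, index)

    def test_cluster_invariants(self, rng):
        genes = make_genes(
            [(f"g{i}", "Chr01", 1 + int(s)) for i, s in enumerate(np.cumsum(rng.integers(2_000, 60_000, 40)))]
        )
        index = {g.gene_id: g for g in genes}
        family = [g.gene_id for g in genes if rng.random() < 0.5]
        clusters = dup.find_tandem_clusters(family, index)
        seen = set()
        for c in clusters:
            assert not (set(c.members) & seen)  # pairwise disjoint
            seen |= set(c.members)
            assert set(c.members) <= set(family)
            members = [index[m] for m in c.members]
            for a, b in zip(members, members[1:]):
                assert dup.tandem_linked(a, b)  # adjacent members satisfy the rule


class TestKsPeaks:
    def test_point_mass_gives_single_mode(self):
        assert dup.detect_ks_peaks([0.6] * 500) == [0.6]

    def test_two_component_mixture_recovers_both_modes(self):
        rng = np.random.default_rng(99)
        comp = rng.random(1000) < 0.5
        ks = np.where(comp, rng.normal(0.65, 0.12, 1000), rng.normal(1.9, 0.12, 1000))
        ks = np.abs(ks)
        modes = dup.detect_ks_peaks(ks)
        top_two = sorted(modes[:2])
        assert abs(top_two[0] - 0.65) < 0.1
        assert abs(top_two[1] - 1.9) < 0.1
        # fine-binned histogram argmax oracle on the same draws
        for lo, hi, mode in [(0.0, 1.3, top_two[0]), (1.3, 2.6, top_two[1])]:
            counts, edges = np.histogram(ks[(ks >= lo) & (ks < hi)], bins=26, range=(lo, hi))
            oracle = edges[np.argmax(counts)] + (edges[1] - edges[0]) / 2
            assert abs(mode - oracle) < 0.1

    def test_fewer_than_ten_values_is_error(self):
        with pytest.raises(ValidationError, match="histogram"):
            dup.detect_ks_peaks([0.5] * 9)

    def test_bandwidth_halving_never_decreases_mode_count(self):
        rng = np.random.default_rng(3)
        ks = np.abs(np.concatenate([rng.normal(0.6, 0.1, 300), rng.normal(1.8, 0.15, 200)]))
        for bw in (0.32, 0.16, 0.08, 0.04):
            assert len(dup.detect_ks_peaks(ks, bandwidth=bw)) <= len(
                dup.detect_ks_peaks(ks, bandwidth=bw / 2)
            )


class TestEventAssignment:
    @pytest.mark.parametrize(
        "ks,event",
        [
            (0.7, "recent_wgd"),
            (2.0, "ancient_hexaploidy"),
            (1.3, "unassigned"),
            (0.45, "recent_wgd"),  # window edges inclusive
            (1.08, "recent_wgd"),
            (1.50, "ancient_hexaploidy"),
            (2.45, "ancient_hexaploidy"),
            (3.0, "unassigned"),
        ],
    )
    def test_window_rules(self, ks, event):
        assert dup.assign_event(SyntenyPair("a", "b", "blk", ks)) == event

    def test_events_partition_all_pairs(self, rng):
        pairs = [
            SyntenyPair(f"a{i}", f"b{i}", "blk", float(ks))
            for i, ks in enumerate(rng.uniform(0, 3, 200))
        ]
        labelled = dup.assign_events(pairs)
        counts = {e: sum(1 for p in labelled if p.event == e) for e in
                  ("recent_wgd", "ancient_hexaploidy", "unassigned")}
        assert sum(counts.values()) == len(pairs)


class TestKsToTime:
    def test_zero_ks_is_zero_time(self):
        assert dup.ks_to_time(0.0) == 0.0

    def test_default_rate_maps_recent_peak_to_sixty_mya(self):
        assert dup.ks_to_time(0.648, 5.4e-9) == pytest.approx(60.0)

    def test_linear_in_ks(self):
        assert dup.ks_to_time(1.2) == pytest.approx(2 * dup.ks_to_time(0.6))

    def test_negative_inputs_are_errors(self):
        with pytest.raises(ValidationError):
            dup.ks_to_time(-0.1)
        with pytest.raises(ValidationError):
            dup.ks_to_time(0.5, 0.0)


class TestPairCounts:
    def test_direct_tally(self):
        pairs = [
            SyntenyPair("d1", "d2", "b", 0.5),
            SyntenyPair("d3", "d4", "b", 0.5),
            SyntenyPair("r1", "r2", "b", 0.5),
        ]
        subfam = {"d1": "DREB", "d2": "DREB", "d3": "DREB", "d4": "DREB", "r1": "RAV", "r2": "RAV"}
        table = dup.count_pairs_by_subfamily(pairs, subfam)["total"]
        assert dict(table) == {"DREB": 2, "RAV": 1}
        assert sum(table.values()) == 3

    def test_empty_pairs_give_empty_table(self):
        assert dict(dup.count_pairs_by_subfamily([], {})["total"]) == {}

    def test_mixed_pair_counts_as_mixed(self):
        pairs = [SyntenyPair("d1", "e1", "b", 0.5)]
        table = dup.count_pairs_by_subfamily(pairs, {"d1": "DREB", "e1": "ERF"})["total"]
        assert dict(table) == {"mixed": 1}
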