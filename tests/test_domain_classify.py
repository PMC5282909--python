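import numpy as np
import pytest

from polyfam import domain_classify as dc
from polyfam.models import AMINO_ACIDS, DomainHit, FamilyAssignment, GeneModel, ProteinRecord, ValidationError


@pytest.fixture(scope="module")
def profiles():
    return dc.default_profiles()


@pytest.fixture(scope="module")
def ap2_profile(profiles):
    return next(p for p in profiles if p.name == "AP2")


def hit(domain="AP2", start=1, end=60, aligned=None, score=100.0, pid="p"):
    return DomainHit(pid, domain, start, end, score, aligned)


class TestScanDomains:
    def test_consensus_in_polyg_flanks_found_at_embedded_coordinates(self, profiles):
        seq = "G" * 30 + dc.AP2_CONSENSUS_ERF + "G" * 40
        hits = dc.scan_domains(ProteinRecord("p", "p", seq), profiles)
        assert len(hits) == 1
        h = hits[0]
        assert (h.domain, h.start, h.end) == ("AP2", 31, 30 + dc.AP2_PROFILE_LENGTH)
        assert h.aligned == dc.AP2_CONSENSUS_ERF

    def test_two_separated_copies_give_two_hits(self, profiles):
        seq = "G" * 10 + dc.AP2_CONSENSUS_DREB + "G" * 50 + dc.AP2_CONSENSUS_ERF + "G" * 10
        hits = dc.scan_domains(ProteinRecord("p", "p", seq), profiles)
        assert [h.domain for h in hits] == ["AP2", "AP2"]
        assert hits[0].end < hits[1].start

    def test_random_sequence_has_no_hits(self, profiles):
        rng = np.random.default_rng(42)
        seq = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, 200)])
        assert dc.scan_domains(ProteinRecord("p", "p", seq), profiles) == []

    def test_sequence_shorter_than_profiles_is_empty_not_error(self, profiles):
        assert dc.scan_domains(ProteinRecord("p", "p", "MKV"), profiles) == []

    def test_threshold_above_random_window_scores(self, ap2_profile):
        # 10^4 random windows all score strictly below the calibrated threshold
        rng = np.random.default_rng(7)
        L = ap2_profile.length
        draws = rng.integers(0, 20, size=(10_000, L))
        scores = ap2_profile.matrix[np.arange(L), draws].sum(axis=1)
        assert scores.max() < ap2_profile.score_threshold


class TestClassifySubfamily:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            (["AP2", "AP2"], "AP2"),
            (["AP2", "B3"], "RAV"),
            (["AP2"], "DREB_or_ERF"),
            ([], "outsider"),
            (["AP2", "AP2", "AP2"], "outsider"),
            (["AP2", "AP2", "B3"], "outsider"),
            (["B3"], "outsider"),
        ],
    )
    def test_architecture_rules(self, domains, expected):
        lengths = {"AP2": 60, "B3": 50}
        hits = [hit(d, 1 + 100 * i, 100 * i + lengths[d]) for i, d in enumerate(domains)]
        assert dc.classify_subfamily(hits, lengths) == expected

    def test_incomplete_ap2_not_counted(self):
        # covers only 30 of 60 profile columns: below the 90% completeness bar
        partial = hit("AP2", 1, 30)
        assert dc.classify_subfamily([partial], {"AP2": 60}) == "outsider"


class TestSplitDrebErf:
    def base(self, res14, res19):
        s = list(dc.AP2_CONSENSUS_ERF)
        s[13], s[18] = res14, res19
        return "".join(s)

    @pytest.mark.parametrize(
        "res14,res19,expected",
        [
            ("V", "E", "DREB"),
            ("A", "D", "ERF"),
            ("V", "L", "DREB"),  # V14 decides even with a non-E residue at 19
            ("A", "E", "ERF"),
            ("G", "D", "ambiguous"),
        ],
    )
    def test_diagnostic_residues(self, res14, res19, expected):
        assert dc.split_dreb_erf(self.base(res14, res19)) == expected

    def test_wrong_length_is_error(self):
        with pytest.raises(ValidationError):
            dc.split_dreb_erf("VA")

    @pytest.mark.parametrize("res19", "ACDEFGHIKLMNPQRSTVWY")
    def test_never_erf_for_v14_nor_dreb_for_a14(self, res19):
        assert dc.split_dreb_erf(self.base("V", res19)) != "ERF"
        assert dc.split_dreb_erf(self.base("A", res19)) != "DREB"


@pytest.fixture(scope="module")
def exemplars():
    return dc.default_exemplars()


class TestAssignGroup:

    def test_exemplar_maps_to_its_own_group(self, exemplars):
        for subfam in ("DREB", "ERF"):
            for group, seqs in exemplars[subfam].items():
                assert dc.assign_group(seqs[0], exemplars[subfam]) == group

    def test_tie_breaks_to_lexicographically_smallest(self):
        toy = {"Z9": ("ACDEF" * 12,), "B2": ("ACDEF" * 12,)}
        assert dc.assign_group("ACDEF" * 12, toy) == "B2"

    def test_two_substitutions_keep_original_group(self, exemplars, rng):
        # brute-force oracle: highest mean positional identity over groups
        for subfam in ("DREB", "ERF"):
            for group, seqs in exemplars[subfam].items():
                query = list(seqs[0])
                for i in rng.choice(len(query), size=2, replace=False):
                    query[i] = "W" if query[i] != "W" else "Y"
                query = "".join(query)
                oracle = max(
                    sorted(exemplars[subfam]),
                    key=lambda g: np.mean(
                        [
                            sum(a == b for a, b in zip(query, s)) / len(s)
                            for s in exemplars[subfam][g]
                        ]
                    ),
                )
                assert oracle == group
                assert dc.assign_group(query, exemplars[subfam]) == group

    def test_permutation_invariant_in_exemplar_order(self, exemplars):
        groups = exemplars["ERF"]
        query = groups["B3"][1]
        reversed_groups = {g: tuple(reversed(s)) for g, s in reversed(list(groups.items()))}
        assert dc.assign_group(query, groups) == dc.assign_group(query, reversed_groups)

    def test_empty_exemplars_is_error(self):
        with pytest.raises(ValidationError):
            dc.assign_group("ACDEF", {})

    def test_similarity_floor_flags_unallocatable(self, exemplars):
        far_query = "G" * dc.AP2_PROFILE_LENGTH
        assert dc.assign_group(far_query, exemplars["ERF"], similarity_floor=1e6) == "none"


class TestNameGenes:
    @staticmethod
    def model(gid, chrom, start):
        return GeneModel(gid, chrom, start, start + 500, "+", ((start, start + 500),))

    def test_chromosome_order_gives_ordinals(self):
        assignments = [FamilyAssignment("gB", "DREB"), FamilyAssignment("gA", "DREB")]
        models = {"gA": self.model("gA", "Chr01", 10_000), "gB": self.model("gB", "Chr01", 50_000)}
        named = {a.gene_id: a.name for a in dc.name_genes(assignments, models, "Gr")}
        assert named == {"gA": "GrDREB1", "gB": "GrDREB2"}

    def test_single_rav_gets_ordinal_one(self):
        named = dc.name_genes(
            [FamilyAssignment("g1", "RAV")], {"g1": self.model("g1", "Chr02", 5)}, "Gr"
        )
        assert named[0].name == "GrRAV1"

    def test_natural_chromosome_sort(self):
        # Chr02 precedes Chr10 (numeric, not lexicographic)
        assignments = [FamilyAssignment("x", "ERF"), FamilyAssignment("y", "ERF")]
        models = {"x": self.model("x", "Chr10", 10), "y": self.model("y", "Chr02", 10)}
        named = {a.gene_id: a.name for a in dc.name_genes(assignments, models, "Gr")}
        assert named == {"y": "GrERF1", "x": "GrERF2"}

    def test_subgenome_suffixes_avoid_collision(self):
        assignments = [FamilyAssignment("a1", "DREB"), FamilyAssignment("d1", "DREB")]
        models = {"a1": self.model("a1", "A01", 100), "d1": self.model("d1", "D01", 100)}
        names = {a.name for a in dc.name_genes(assignments, models, "Gh", subgenome_tag=True)}
        assert names == {"GhDREB1A", "GhDREB1D"}

    def test_unlocated_gene_named_last_with_warning(self):
        assignments = [FamilyAssignment("lost", "ERF"), FamilyAssignment("ok", "ERF")]
        models = {"ok": self.model("ok", "Chr01", 100)}
        with pytest.warns(UserWarning, match="lost"):
            named = {a.gene_id: a.name for a in dc.name_genes(assignments, models, "Gr")}
        assert named == {"ok": "GrERF1", "lost": "GrERF2"}
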