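"""Complementation stages: association, dedup, filters, placement, gap fill."""

from fractions import Fraction as F

import pytest

from fluxsense.complement import (
    CatalogReaction,
    HomologyHit,
    ReactionCandidate,
    associate_reactions,
    compartmentalize,
    complement_network,
    dedupe_against_base,
    filter_known_reactants,
    gap_fill,
)
from fluxsense.netcore import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    find_dead_ends,
    write_network,
)
from fluxsense.synthdata import NetworkBlueprint, generate_homology_inputs, generate_network

GLYCERATE_KINASE_EC = "2.7.1.31"

CATALOG = [
    CatalogReaction("R00001", GLYCERATE_KINASE_EC, "glyc + atp -> pg3 + adp",
                    "glyoxylate and dicarboxylate metabolism"),
    CatalogReaction("R00002", GLYCERATE_KINASE_EC, "glyc + gtp -> pg3 + gdp",
                    "glyoxylate and dicarboxylate metabolism"),
    CatalogReaction("R00003", "1.1.1.1", "etoh + nad -> acald + nadh",
                    "glycolysis/gluconeogenesis"),
]


@pytest.fixture
def base_net():
    mets = [Metabolite(f"{n}[c]", "c") for n in ("glyc", "atp", "pg3", "adp")] + [
        Metabolite("glyc[h]", "h"), Metabolite("atp[h]", "h"),
        Metabolite("pg3[h]", "h"), Metabolite("adp[h]", "h"),
    ]
    rxns = [
        Reaction("EX_glyc", {"glyc[c]": F(1)}, lb=0, ub=10),
        Reaction("T_atp", {"atp[c]": F(1), "adp[c]": F(-1)}, lb=-10, ub=10),
        Reaction("sink", {"pg3[c]": F(-1)}, lb=0, ub=10),
    ]
    return MetabolicNetwork(["c", "h"], mets, rxns, "sink")


class TestAssociate:
    def test_two_reactions_under_one_ec(self):
        hits = [HomologyHit("GLYK", GLYCERATE_KINASE_EC, evalue=1e-50)]
        cands, unmatched = associate_reactions(hits, CATALOG)
        assert [c.catalog_id for c in cands] == ["R00001", "R00002"]
        assert unmatched == []

    def test_duplicate_hits_collapse(self):
        hits = [
            HomologyHit("GLYK", GLYCERATE_KINASE_EC, evalue=1e-50),
            HomologyHit("GLYK2", GLYCERATE_KINASE_EC, evalue=1e-40),
        ]
        cands, _ = associate_reactions(hits, CATALOG)
        assert len(cands) == 2  # one per catalog reaction, not per hit

    def test_empty_hits_give_empty_candidates(self):
        cands, unmatched = associate_reactions([], CATALOG)
        assert cands == [] and unmatched == []

    def test_unmatched_ec_recorded_not_raised(self):
        hits = [HomologyHit("X", "9.9.9.9", evalue=1e-50)]
        cands, unmatched = associate_reactions(hits, CATALOG)
        assert cands == [] and unmatched == ["9.9.9.9"]

    def test_evalue_cutoff_applies(self):
        hits = [HomologyHit("weak", GLYCERATE_KINASE_EC, evalue=0.5)]
        cands, _ = associate_reactions(hits, CATALOG)
        assert cands == []

    def test_pathway_blacklist(self):
        cat = [CatalogReaction("R1", "1.1.1.1", "a -> b", "penicillin biosynthesis")]
        hits = [HomologyHit("p", "1.1.1.1", evalue=1e-50)]
        cands, _ = associate_reactions(
            hits, cat, pathway_blacklist=frozenset({"penicillin biosynthesis"})
        )
        assert cands == []

    def test_malformed_ec_rejected(self):
        with pytest.raises(ValueError):
            HomologyHit("p", "not-an-ec")


class TestDedupe:
    def _cand(self, equation: str) -> ReactionCandidate:
        cat = CatalogReaction("C1", "1.1.1.1", equation)
        return ReactionCandidate("C1", cat.ec, cat.stoich)

    def test_identical_reaction_removed(self, base_net):
        out = dedupe_against_base([self._cand("adp -> atp")], base_net)
        # T_atp is adp -> atp compartment-stripped
        assert out == []

    def test_reverse_of_reversible_removed(self, base_net):
        # independent orientation check: T_atp is reversible, so its
        # reverse also counts as existing
        cand = self._cand("atp -> adp")
        fwd = {"adp": F(-1), "atp": F(1)}
        assert cand.stoich == {k: -v for k, v in fwd.items()}
        assert dedupe_against_base([cand], base_net) == []

    def test_reverse_of_irreversible_kept(self, base_net):
        # base "sink" consumes pg3 irreversibly; a producer of pg3 is new
        out = dedupe_against_base([self._cand("-> pg3")], base_net)
        assert len(out) == 1

    def test_coefficient_difference_kept(self, base_net):
        out = dedupe_against_base([self._cand("2 adp -> 2 atp")], base_net)
        assert len(out) == 1


class TestReactantFilter:
    def _cand(self, equation: str) -> ReactionCandidate:
        cat = CatalogReaction("C1", "1.1.1.1", equation)
        return ReactionCandidate("C1", cat.ec, cat.stoich)

    def test_all_known_passes(self, base_net):
        out = filter_known_reactants([self._cand("glyc + atp -> pg3 + adp")], base_net)
        assert len(out) == 1

    def test_one_novel_fails_naming_it(self, base_net):
        cand = self._cand("glyc + ctp -> pg3")
        assert filter_known_reactants([cand], base_net) == []
        assert "ctp" in cand.verdicts["reactant_filter"]

    def test_all_novel_fails(self, base_net):
        assert filter_known_reactants([self._cand("foo -> bar")], base_net) == []

    def test_generic_species_blacklisted(self, base_net):
        cand = self._cand("glyc -> an_alcohol")
        assert filter_known_reactants([cand], base_net) == []
        assert "generic" in cand.verdicts["reactant_filter"]


class TestCompartmentalize:
    def _cand(self, equation: str) -> ReactionCandidate:
        cat = CatalogReaction("C1", "1.1.1.1", equation)
        return ReactionCandidate("C1", cat.ec, cat.stoich)

    def test_two_compartments_two_placements(self, base_net):
        out = compartmentalize([self._cand("glyc + atp -> pg3 + adp")], base_net)
        assert sorted(r.id for r in out) == ["C1__c", "C1__h"]
        assert all("[c]" in m or "[h]" in m for r in out for m in r.stoich)

    def test_single_compartment_species(self):
        mets = [Metabolite("a[m]", "m"), Metabolite("b[m]", "m")]
        net = MetabolicNetwork(
            ["m"], mets, [Reaction("x", {"a[m]": F(1)})], "x"
        )
        out = compartmentalize([self._cand("a -> b")], net)
        assert [r.id for r in out] == ["C1__m"]

    def test_no_common_compartment_dropped(self):
        mets = [Metabolite("a[m]", "m"), Metabolite("b[h]", "h")]
        net = MetabolicNetwork(["m", "h"], mets, [Reaction("x", {"a[m]": F(1)})], "x")
        cand = self._cand("a -> b")
        assert compartmentalize([cand], net) == []
        assert cand.verdicts["compartmentalize"] == "fail: no viable compartment"

    def test_single_placement_prefers_cytosol(self, base_net):
        out = compartmentalize(
            [self._cand("glyc + atp -> pg3 + adp")], base_net, single_placement=True
        )
        assert [r.id for r in out] == ["C1__c"]


class TestGapFill:
    def test_catalog_consumer_preferred_over_sink(self):
        # orphan product B has a one-reaction catalog consumer: that path
        # (length 1 on the bipartite graph) must win over the sink fallback
        mets = [Metabolite(f"{n}[c]", "c") for n in "ABC"]
        rxns = [
            Reaction("in_a", {"A[c]": F(1)}, lb=0, ub=10),
            Reaction("ab", {"A[c]": F(-1), "B[c]": F(1)}),
            Reaction("out_c", {"C[c]": F(-1)}),
            Reaction("in_c", {"C[c]": F(1)}),
        ]
        net = MetabolicNetwork(["c"], mets, rxns, "out_c")
        catalog = [CatalogReaction("RBC", "1.1.1.1", "B -> C")]
        filled, report = gap_fill(net, catalog)
        assert "RBC__gf_c" in filled.reactions
        assert not any(r.startswith("SK_") for r in report.added_reactions)
        assert find_dead_ends(filled) == []

    def test_sink_fallback_when_no_consumer(self):
        mets = [Metabolite("A[c]", "c"), Metabolite("B[c]", "c")]
        rxns = [
            Reaction("in_a", {"A[c]": F(1)}, lb=0, ub=10),
            Reaction("ab", {"A[c]": F(-1), "B[c]": F(1)}),
        ]
        net = MetabolicNetwork(["c"], mets, rxns, "ab")
        filled, report = gap_fill(net, [])
        assert "SK_B[c]" in filled.reactions
        assert find_dead_ends(filled) == []

    def test_no_dead_ends_is_noop(self, chain_network):
        filled, report = gap_fill(chain_network, CATALOG)
        assert report.added_reactions == []
        assert filled == chain_network

    def test_tie_broken_lexicographically(self):
        mets = [Metabolite(f"{n}[c]", "c") for n in "ABC"]
        rxns = [
            Reaction("in_a", {"A[c]": F(1)}, lb=0, ub=10),
            Reaction("ab", {"A[c]": F(-1), "B[c]": F(1)}),
            Reaction("out_c", {"C[c]": F(-1)}),
            Reaction("in_c", {"C[c]": F(1)}),
        ]
        net = MetabolicNetwork(["c"], mets, rxns, "out_c")
        catalog = [
            CatalogReaction("R_ZZ", "1.1.1.1", "B -> C"),
            CatalogReaction("R_AA", "1.1.1.2", "B -> C"),
        ]
        _, report = gap_fill(net, catalog)
        assert report.added_reactions == ["R_AA__gf_c"]


class TestFullPipeline:
    def test_manifest_bookkeeping(self):
        net, truth = generate_network(NetworkBlueprint(seed=2))
        catalog, hits, manifest = generate_homology_inputs(net, truth, seed=2)
        ext, report, _ = complement_network(net, hits, catalog)
        assert report.counts == manifest["expected_counts"]
        assert report.unmatched_ecs == manifest["unmatched_ecs"]
        for rid in manifest["planned_gap_reactions"] + manifest["planned_sinks"]:
            assert rid in ext.reactions

    def test_counts_non_increasing_through_filters(self):
        net, truth = generate_network(NetworkBlueprint(seed=6))
        catalog, hits, _ = generate_homology_inputs(net, truth, seed=6)
        _, report, _ = complement_network(net, hits, catalog)
        c = report.counts
        assert c["associated"] >= c["deduplicated"] >= c["reactant_filtered"]

    def test_no_dead_ends_among_added_species(self):
        net, truth = generate_network(NetworkBlueprint(seed=8))
        catalog, hits, _ = generate_homology_inputs(net, truth, seed=8)
        ext, report, _ = complement_network(net, hits, catalog)
        added_species = set()
        for rid in report.added_reactions:
            added_species |= set(ext.reactions[rid].stoich)
        assert [m for m in find_dead_ends(ext) if m in added_species] == []

    def test_added_reactions_traceable(self):
        net, truth = generate_network(NetworkBlueprint(seed=2))
        catalog, hits, _ = generate_homology_inputs(net, truth, seed=2)
        ext, report, _ = complement_network(net, hits, catalog)
        catalog_ids = {c.catalog_id for c in catalog}
        for rid in report.added_reactions:
            root = rid.split("__")[0]
            assert root in catalog_ids or rid.startswith("SK_")

    def test_rerun_byte_identical(self, tmp_path):
        net, truth = generate_network(NetworkBlueprint(seed=2))
        catalog, hits, _ = generate_homology_inputs(net, truth, seed=2)
        paths = []
        for i in (1, 2):
            ext, _, _ = complement_network(net, hits, catalog)
            p = tmp_path / f"run{i}.tsv"
            write_network(ext, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
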