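"""Ortholog detection and reaction transfer."""

import pytest

from lactoflux import (
    MetabolicModel,
    Metabolite,
    OrthologPair,
    ProteinSet,
    Reaction,
    ValidationError,
    add_non_gene_reactions,
    kmer_bbh,
    make_toy_genomes,
    transfer_reactions,
)
from lactoflux.reconstruction import (
    copy_subsystems,
    evaluate_gene_rule,
    gene_rule_ids,
    parse_gene_rule,
)

from _oracles import brute_force_bbh


# --- gene rules ------------------------------------------------------------

@pytest.mark.parametrize(
    "rule,active,expected",
    [
        ("gA", {"gA"}, True),
        ("gA", set(), False),
        ("gA and gB", {"gA"}, False),
        ("gA or gB", {"gA"}, True),
        ("(gA or gB) and gC", {"gB", "gC"}, True),
        ("(gA or gB) and gC", {"gB"}, False),
        ("gA AND (gB OR gC)", {"gA", "gC"}, True),
    ],
)
def test_gene_rule_evaluation(rule, active, expected):
    assert evaluate_gene_rule(rule, active) is expected


def test_gene_rule_ids_and_malformed_rules():
    assert gene_rule_ids("(gA or gB) and gC") == {"gA", "gB", "gC"}
    for bad in ("gA and", "and gA", "(gA", "gA or or gB"):
        with pytest.raises(ValueError):
            parse_gene_rule(bad)


# --- kmer BBH --------------------------------------------------------------

def test_identical_sequences_pair_with_score_one():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    pairs = kmer_bbh(ProteinSet({"q1": seq}), ProteinSet({"r1": seq}), k=5,
                     min_score=0.3)
    assert [(p.query_gene, p.reference_gene, p.score) for p in pairs] == [
        ("q1", "r1", 1.0)
    ]


def test_disjoint_kmer_sets_give_no_pair():
    pairs = kmer_bbh(
        ProteinSet({"q1": "AAAAAAAAAA"}), ProteinSet({"r1": "WWWWWWWWWW"}),
        k=5, min_score=0.1,
    )
    assert pairs == []


def test_bbh_matches_brute_force_oracle_on_mutated_copies():
    query, reference, _truth = make_toy_genomes(seed=1, n_genes=5,
                                                mutation_rate=0.1)
    pairs = kmer_bbh(query, reference, k=5, min_score=0.3)
    oracle = brute_force_bbh(query.entries, reference.entries, k=5,
                             min_score=0.3)
    assert [(p.query_gene, p.reference_gene) for p in pairs] == [
        (q, r) for q, r, _ in oracle
    ]
    for p, (_, _, score) in zip(pairs, oracle):
        assert p.score == pytest.approx(score)


def test_bbh_symmetry_roles_swap():
    query, reference, _ = make_toy_genomes(seed=4, n_genes=6, mutation_rate=0.2)
    forward = kmer_bbh(query, reference, k=5, min_score=0.2)
    backward = kmer_bbh(reference, query, k=5, min_score=0.2)
    assert {(p.query_gene, p.reference_gene) for p in forward} == {
        (p.reference_gene, p.query_gene) for p in backward
    }


def test_empty_sequence_rejected():
    with pytest.raises(ValidationError):
        ProteinSet({"q1": ""})


# --- reaction transfer -----------------------------------------------------

def _reference():
    model = MetabolicModel(
        id="ref", compartments={"c", "e"},
        metabolites=[
            Metabolite(id="s_e", compartment="e"),
            Metabolite(id="s_c", compartment="c"),
            Metabolite(id="p_c", compartment="c"),
        ],
        genes={"gA", "gB"},
    )
    model.reactions = [
        Reaction(id="EX_s_e", stoichiometry={"s_e": -1.0}, kind="exchange"),
        Reaction(id="T_s", stoichiometry={"s_e": -1.0, "s_c": 1.0},
                 kind="transport"),  # non-gene transport
        Reaction(id="R_single", stoichiometry={"s_c": -1.0, "p_c": 1.0},
                 gene_rule="gA"),
        Reaction(id="R_and", stoichiometry={"s_c": -1.0, "p_c": 1.0},
                 gene_rule="gA and gB", subsystem="cell wall"),
        Reaction(id="R_or", stoichiometry={"s_c": -1.0, "p_c": 1.0},
                 gene_rule="gA or gB", subsystem="fatty acids"),
        Reaction(id="BIO", stoichiometry={"p_c": -1.0}, kind="biomass"),
    ]
    model.objective_reaction_id = "BIO"
    return model


def test_partial_map_keeps_or_drops_by_truth_table():
    ref = _reference()
    draft = transfer_reactions(ref, [OrthologPair("qA", "gA", 1.0)], "query")
    kept = set(draft.reaction_map)
    assert "R_single" in kept and "R_or" in kept
    assert "R_and" not in kept
    assert "BIO" in kept  # biomass always carried
    # rules rewritten to query gene ids
    assert draft.reaction_map["R_single"].gene_rule == "qA"
    assert draft.reaction_map["R_or"].gene_rule == "qA"
    assert draft.genes == {"qA"}


def test_empty_map_leaves_only_biomass():
    draft = transfer_reactions(_reference(), [], "query")
    assert set(draft.reaction_map) == {"BIO"}


def test_self_transfer_plus_non_gene_reproduces_reference():
    ref = _reference()
    identity = [OrthologPair(g, g, 1.0) for g in sorted(ref.genes)]
    draft = add_non_gene_reactions(transfer_reactions(ref, identity, ref.id), ref)
    assert set(draft.reaction_map) == set(ref.reaction_map)
    for rid, rxn in ref.reaction_map.items():
        assert draft.reaction_map[rid].stoichiometry == rxn.stoichiometry
        assert draft.reaction_map[rid].gene_rule == rxn.gene_rule


def test_transfer_monotone_in_ortholog_pairs():
    ref = _reference()
    kept_small = set(
        transfer_reactions(ref, [OrthologPair("qA", "gA", 1.0)], "q").reaction_map
    )
    kept_large = set(
        transfer_reactions(
            ref,
            [OrthologPair("qA", "gA", 1.0), OrthologPair("qB", "gB", 0.9)],
            "q",
        ).reaction_map
    )
    assert kept_small <= kept_large


def test_unknown_reference_gene_rejected():
    with pytest.raises(ValidationError):
        transfer_reactions(_reference(), [OrthologPair("q", "gZ", 1.0)], "q")


def test_add_non_gene_is_idempotent_and_counts_conserved():
    ref = _reference()
    draft = transfer_reactions(ref, [], "q")
    non_gene = [r for r in ref.reactions
                if not r.gene_rule and r.kind != "biomass"]
    once = add_non_gene_reactions(draft, ref)
    assert len(once.reactions) == len(draft.reactions) + len(non_gene)
    twice = add_non_gene_reactions(once, ref)
    assert set(twice.reaction_map) == set(once.reaction_map)


def test_every_reference_exchange_lands_in_draft(milk_trio):
    st = milk_trio[0]
    draft = add_non_gene_reactions(transfer_reactions(st, [], "draft"), st)
    for rxn in st.exchange_reactions():
        assert rxn.id in draft.reaction_map


def test_copy_subsystems_selects_exactly_named_sets():
    ref = _reference()
    draft = transfer_reactions(ref, [], "q")
    copied = copy_subsystems(draft, ref, ["cell wall"])
    assert "R_and" in copied.reaction_map
    assert "R_or" not in copied.reaction_map
    assert copied.reaction_map["R_and"].gene_rule == "gA and gB"
    assert {"gA", "gB"} <= copied.genes
    # empty list is a no-op
    assert set(copy_subsystems(draft, ref, []).reaction_map) == \
        set(draft.reaction_map)
    with pytest.raises(ValidationError):
        copy_subsystems(draft, ref, ["no such subsystem"])


def test_copy_then_transfer_order_independent():
    ref = _reference()
    pairs = [OrthologPair("qA", "gA", 1.0)]
    a = copy_subsystems(transfer_reactions(ref, pairs, "q"), ref, ["cell wall"])
    b = add_non_gene_reactions(a, ref)
    c = copy_subsystems(
        add_non_gene_reactions(transfer_reactions(ref, pairs, "q"), ref),
        ref, ["cell wall"],
    )
    assert set(b.reaction_map) == set(c.reaction_map)
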