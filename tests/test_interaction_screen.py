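"""Transport-knockout screen: essentiality, OR-groups, report table."""

import io

import pytest

from lactoflux import (
    GeneratorConfig,
    auto_groups,
    build_community,
    interaction_table,
    make_toy_pair,
    run_screen,
    screen_groups,
    screen_interactions,
)
from lactoflux.fba_core import GROWTH_EPSILON, knockout, solve_fba
from lactoflux.interaction_screen import ScreenError, read_interaction_table
from lactoflux.model_io import ValidationError

from conftest import make_chain


@pytest.fixture(scope="module")
def milk_screen(milk_community):
    report, groups = run_screen(milk_community)
    return report, groups


def _record(report, metabolite):
    return next(r for r in report.records if r.metabolite == metabolite)


def test_folate_and_peptides_are_essential_donations(milk_screen):
    report, _ = milk_screen
    for met in ("folate", "peptides"):
        record = _record(report, met)
        assert record.essential
        assert record.donor == "ST_C106"
        assert record.recipient == "LR_yoba2012"
        assert record.growth_after_knockout < GROWTH_EPSILON


def test_galactose_individually_dispensable(milk_screen):
    report, _ = milk_screen
    record = _record(report, "galactose")
    assert not record.essential
    assert record.growth_after_knockout >= GROWTH_EPSILON


def test_or_groups_found_exactly(milk_screen):
    _, groups = milk_screen
    assert set(groups) == {
        frozenset({"xanthine", "guanine"}),
        frozenset({"galactose", "succinate", "glycerol"}),
    }


def test_group_knockouts_joint_but_not_single(milk_community):
    growth = screen_groups(
        milk_community,
        [{"xanthine", "guanine"}, {"xanthine"}, {"guanine"},
         {"galactose", "succinate", "glycerol"}, {"galactose"}],
    )
    assert growth[frozenset({"xanthine", "guanine"})] < GROWTH_EPSILON
    assert growth[frozenset({"xanthine"})] >= GROWTH_EPSILON
    assert growth[frozenset({"guanine"})] >= GROWTH_EPSILON
    assert growth[frozenset({"galactose", "succinate", "glycerol"})] < GROWTH_EPSILON
    assert growth[frozenset({"galactose"})] >= GROWTH_EPSILON
    assert screen_groups(milk_community, [set()])[frozenset()] == pytest.approx(
        screen_interactions(milk_community).baseline_growth, abs=1e-6
    )


def test_screen_soundness_by_independent_resolve(milk_community, milk_screen):
    report, _ = milk_screen
    for record in report.records:
        targets = milk_community.transport_reactions_of(
            record.recipient, record.metabolite
        )
        mu = solve_fba(knockout(milk_community.system, targets)).objective_value
        assert record.essential == (mu < GROWTH_EPSILON)


def test_secretion_uptake_export_balance(milk_community):
    from lactoflux.fba_core import solve_pfba

    pfba = solve_pfba(milk_community.system)
    system = milk_community.system
    for record in screen_interactions(milk_community).records:
        base = record.metabolite
        row = system.row_index[f"{base}_e"]
        secretion = sum(
            system.S[row, system.col_index[cid]] * pfba.fluxes[cid]
            for cid in milk_community.transport_reactions_of(record.donor, base)
        )
        uptake = -sum(
            system.S[row, system.col_index[cid]] * pfba.fluxes[cid]
            for cid in milk_community.transport_reactions_of(record.recipient, base)
        )
        export = pfba.fluxes[milk_community.exchange_cols[base]]
        assert secretion == pytest.approx(uptake + export, abs=1e-6)


def test_knockout_of_nonshared_transport_leaves_records_unchanged(milk_community):
    import dataclasses

    baseline = screen_interactions(milk_community)
    # glucose is transported only by the LR member and absent from milk;
    # knocking its transporter out must not perturb the shared-metabolite
    # record set or its verdicts
    assert "glucose" not in milk_community.shared_metabolites
    ko_system = knockout(milk_community.system, ["B__GLCt"])
    hobbled = dataclasses.replace(milk_community, system=ko_system)
    after = screen_interactions(hobbled)
    assert [(r.metabolite, r.donor, r.essential) for r in after.records] == \
        [(r.metabolite, r.donor, r.essential) for r in baseline.records]


def test_no_shared_metabolites_yields_empty_report(sub_medium):
    community = build_community(make_chain("memberA"), make_chain("memberB"),
                                sub_medium)
    report = screen_interactions(community)
    assert report.records == []
    assert report.baseline_growth == pytest.approx(5.0, abs=1e-6)


def test_infeasible_baseline_is_a_precondition_error(sub_medium):
    a = make_chain("memberA")
    b = make_chain("memberB")
    b.reaction_map["BIO"].upper_bound = 0.0
    community = build_community(a, b, sub_medium)
    with pytest.raises(ScreenError):
        screen_interactions(community)


def test_screen_groups_rejects_unknown_metabolite(milk_community):
    with pytest.raises(ValidationError):
        screen_groups(milk_community, [{"unobtainium"}])


def test_auto_groups_empty_when_everything_essential():
    model_a, model_b, medium, _ = make_toy_pair(
        GeneratorConfig(seed=5, n_redundant_paths=0, noise_reactions=0)
    )
    community = build_community(model_a, model_b, medium)
    report = screen_interactions(community)
    groups = auto_groups(community, report)
    assert groups == []


def test_donor_side_knockout_mode(milk_community):
    report, _ = run_screen(milk_community, discover_groups=False,
                           knockout_side="donor")
    # folate has a single donor-side efflux; knocking it out starves LR too
    folate = next(r for r in report.records if r.metabolite == "folate")
    assert folate.essential


def test_interaction_table_layout_and_round_trip(milk_screen):
    report, _ = milk_screen
    table = interaction_table(report)
    frame = read_interaction_table(io.StringIO(table))
    assert list(frame.columns) == [
        "compound", "provides", "consumes", "essential", "robust", "flux",
        "group",
    ]
    assert set(frame["provides"]) == {"ST_C106"}
    assert set(frame["consumes"]) == {"LR_yoba2012"}
    # essential rows come first
    flags = list(frame["essential"])
    assert flags == sorted(flags, key=lambda f: f != "yes")
    # all six narrated compounds appear
    assert set(frame["compound"]) == {
        "Folic acid", "Galactose", "Glycerol", "Peptides", "Succinate",
        "Xanthine/Guanine",
    }


def test_empty_report_gives_header_only_table(sub_medium):
    community = build_community(make_chain("memberA"), make_chain("memberB"),
                                sub_medium)
    report = screen_interactions(community)
    table = interaction_table(report)
    assert table.splitlines() == [
        "compound\tprovides\tconsumes\tessential\trobust\tflux\tgroup"
    ]
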