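"""Model/medium I/O: round-trips, kind inference, validation completeness."""

import json

import pytest

from lactoflux import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
    fixture_path,
    make_milk_fixture,
    read_medium,
    read_model,
    write_medium,
    write_model,
)
from lactoflux.model_io import FormatError, infer_kind, models_equal, validate_model
from lactoflux.synthetic_data import MILK_COMPONENTS


def test_minimal_json_model_reads_with_inferred_exchange(tmp_path):
    payload = {
        "id": "mini",
        "compartments": ["e"],
        "metabolites": [{"id": "x_e", "compartment": "e"}],
        "reactions": [
            {"id": "EX_x_e", "stoichiometry": {"x_e": -1}, "lower_bound": -5,
             "upper_bound": 1000}
        ],
        "genes": [],
        "objective": None,
    }
    path = tmp_path / "mini.json"
    path.write_text(json.dumps(payload))
    model = read_model(path)
    assert len(model.metabolites) == 1
    assert len(model.reactions) == 1
    assert model.reactions[0].kind == "exchange"


@pytest.mark.parametrize("dialect", ["json", "sbml"])
def test_round_trip_identity_both_dialects(milk_trio, tmp_path, dialect):
    for model in milk_trio[:2]:
        path = tmp_path / f"{model.id}.{dialect}"
        write_model(model, path, dialect=dialect)
        again = read_model(path, dialect=dialect)
        assert models_equal(model, again)
        # idempotent: write the re-read model and read once more
        path2 = tmp_path / f"{model.id}_2.{dialect}"
        write_model(again, path2, dialect=dialect)
        assert models_equal(again, read_model(path2, dialect=dialect))


def test_round_trip_preserves_unicode_name(tmp_path):
    model = MetabolicModel(
        id="uni", compartments={"e"},
        metabolites=[Metabolite(id="x_e", name="β-galactosidase substrate",
                                compartment="e")],
        reactions=[Reaction(id="EX_x_e", stoichiometry={"x_e": -1.0},
                            lower_bound=0.0, kind="exchange")],
    )
    for dialect in ("json", "sbml"):
        path = tmp_path / f"uni.{dialect}"
        write_model(model, path, dialect=dialect)
        assert read_model(path, dialect=dialect).metabolites[0].name == \
            "β-galactosidase substrate"


def test_packaged_fixture_has_biomass_objective_and_key_reactions():
    model = read_model(fixture_path("ST.json"))
    assert model.reaction_map[model.objective_reaction_id].kind == "biomass"
    # lactose transporter and casein protease are present
    assert "LACt" in model.reaction_map
    assert model.reaction_map["LACt"].kind == "transport"
    assert "lactose_e" in model.reaction_map["LACt"].stoichiometry
    prot = model.reaction_map["PROT"]
    assert "stPrtS" in (prot.gene_rule or "")


def test_packaged_fixture_matches_generator(milk_trio):
    st, lr, _ = milk_trio
    assert models_equal(st, read_model(fixture_path("ST.json")))
    assert models_equal(lr, read_model(fixture_path("LR.json")))


def test_sbml_output_passes_libsbml_consistency_check(milk_trio, tmp_path):
    import libsbml

    st = milk_trio[0]
    path = tmp_path / "st.xml"
    write_model(st, path, dialect="sbml")
    doc = libsbml.readSBMLFromFile(str(path))
    doc.checkConsistency()
    assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0


def test_independent_toolbox_reproduces_fba_from_our_sbml(milk_trio, tmp_path):
    """cobra (used strictly as an oracle) reads our SBML output and its FBA
    optimum matches this package's on the same medium."""
    import cobra

    from lactoflux import build_system, solve_fba

    st, _, milk = milk_trio
    path = tmp_path / "st.xml"
    write_model(st, path, dialect="sbml")
    oracle_model = cobra.io.read_sbml_model(str(path))
    for exchange in oracle_model.exchanges:
        base = exchange.id[3:-2]  # EX_<base>_e
        exchange.lower_bound = -milk.uptake_bounds.get(base, 0.0)
    mu_oracle = oracle_model.slim_optimize()
    mu_ours = solve_fba(build_system(st, milk)).objective_value
    assert abs(mu_oracle - mu_ours) <= 1e-6


def test_validation_reports_one_diagnostic_per_violation():
    model = MetabolicModel(
        id="bad", compartments={"c"},
        metabolites=[
            Metabolite(id="a_c", compartment="c"),
            Metabolite(id="a_c", compartment="c"),      # duplicate id
            Metabolite(id="b_x", compartment="x"),      # undeclared compartment
        ],
        reactions=[
            Reaction(id="R1", stoichiometry={"missing": 1.0},  # unresolved met
                     lower_bound=5.0, upper_bound=-5.0),       # lb > ub
        ],
        objective_reaction_id="nope",                          # unresolved obj
    )
    diags = validate_model(model, collect=True)
    assert len(diags) == 5
    with pytest.raises(ValidationError) as err:
        validate_model(model)
    assert len(err.value.diagnostics) == 5


def test_exchange_and_transport_invariants_checked():
    model = MetabolicModel(
        id="kinds", compartments={"c", "e"},
        metabolites=[Metabolite(id="x_e", compartment="e"),
                     Metabolite(id="x_c", compartment="c")],
        reactions=[
            Reaction(id="EXBAD", stoichiometry={"x_e": -1.0, "x_c": 1.0},
                     kind="exchange"),
            Reaction(id="TBAD", stoichiometry={"x_c": -1.0}, kind="transport"),
        ],
    )
    diags = validate_model(model, collect=True)
    assert any("exchange" in d for d in diags)
    assert any("transport" in d for d in diags)


def test_kind_inference_rules():
    model = MetabolicModel(
        id="infer", compartments={"c", "e"},
        metabolites=[Metabolite(id="x_e", compartment="e"),
                     Metabolite(id="x_c", compartment="c"),
                     Metabolite(id="y_c", compartment="c")],
        objective_reaction_id="BIO",
    )
    ex = Reaction(id="EX_x_e", stoichiometry={"x_e": -1.0})
    tr = Reaction(id="T", stoichiometry={"x_e": -1.0, "x_c": 1.0})
    internal = Reaction(id="I", stoichiometry={"x_c": -1.0, "y_c": 1.0})
    bio = Reaction(id="BIO", stoichiometry={"y_c": -1.0})
    assert infer_kind(ex, model) == "exchange"
    assert infer_kind(tr, model) == "transport"
    assert infer_kind(internal, model) == "internal"
    assert infer_kind(bio, model) == "biomass"


def test_parse_error_carries_context(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text("{not json")
    with pytest.raises(FormatError) as err:
        read_model(path)
    assert "line" in str(err.value)


# --- medium TSV ------------------------------------------------------------

def test_packaged_milk_medium_has_the_ten_components():
    medium = read_medium(fixture_path("milk.tsv"))
    assert set(medium.uptake_bounds) == set(MILK_COMPONENTS)
    assert len(medium.uptake_bounds) == 10


def test_medium_empty_table_and_zero_bound(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("metabolite\tmax_uptake\n")
    assert read_medium(path).uptake_bounds == {}
    path2 = tmp_path / "closed.tsv"
    path2.write_text("metabolite\tmax_uptake\nlactose\t0\n")
    assert read_medium(path2).uptake_bounds == {"lactose": 0.0}


def test_medium_rejects_duplicates_and_negative_bounds(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("metabolite\tmax_uptake\nlactose\t1\nlactose\t2\n")
    with pytest.raises(ValidationError):
        read_medium(path)
    path2 = tmp_path / "neg.tsv"
    path2.write_text("metabolite\tmax_uptake\nlactose\t-1\n")
    with pytest.raises(ValidationError):
        read_medium(path2)
    with pytest.raises(ValidationError):
        Medium(uptake_bounds={"x": -0.5})


def test_medium_round_trip(tmp_path, milk_trio):
    medium = milk_trio[2]
    path = tmp_path / "milk.tsv"
    write_medium(medium, path)
    assert read_medium(path).uptake_bounds == medium.uptake_bounds
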