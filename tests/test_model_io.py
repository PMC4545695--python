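"""Model container invariants, SBML/TSV round trips, protection-spec parsing."""

import numpy as np
import pytest

from netreduce import (
    MetabolicModel,
    ModelError,
    Scenario,
    add_biomass_tracker,
    build_protection_spec,
    fba,
    read_protection_spec,
    read_sbml,
    read_tsv_model,
    write_sbml,
    write_tsv_model,
)
from netreduce.io import parse_constraint


# ---------------------------------------------------------------------------
# container invariants


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(metabolite_ids=["A", "A"]), "duplicate metabolite"),
        (dict(reaction_ids=["R1", "R1"]), "duplicate reaction"),
        (dict(lower_bounds=np.array([15.0, 0.0])), "lower bound exceeds"),
        (dict(S=np.array([[1.0, 0.0], [0.0, 0.0]])), "all-zero stoichiometry"),
        (dict(objective=np.array([0.0])), "length"),
    ],
)
def test_invalid_models_rejected(kwargs, match):
    base = dict(
        metabolite_ids=["A", "B"],
        reaction_ids=["R1", "R2"],
        S=np.array([[1.0, -1.0], [0.0, 1.0]]),
        lower_bounds=np.array([0.0, 0.0]),
        upper_bounds=np.array([10.0, 10.0]),
        objective=np.array([0.0, 1.0]),
    )
    base.update(kwargs)
    with pytest.raises(ModelError, match=match):
        MetabolicModel(**base)


def test_external_species_are_not_rows(chain_model):
    assert chain_model.S.shape == (2, 3)
    assert "X_ext" in chain_model.external_species
    assert "X_ext" not in chain_model.metabolite_ids


# ---------------------------------------------------------------------------
# SBML


def test_sbml_round_trip(tmp_path, worked_example):
    model, _, _ = worked_example
    path = tmp_path / "m.xml"
    write_sbml(model, path)
    back = read_sbml(path)
    assert back.metabolite_ids == model.metabolite_ids
    assert back.reaction_ids == model.reaction_ids
    assert back.external_species == model.external_species
    np.testing.assert_allclose(back.S, model.S, atol=1e-12)
    np.testing.assert_allclose(back.S_ext, model.S_ext, atol=1e-12)
    np.testing.assert_allclose(back.lower_bounds, model.lower_bounds)
    np.testing.assert_allclose(back.upper_bounds, model.upper_bounds)
    np.testing.assert_allclose(back.objective, model.objective)


def test_sbml_toy_dimensions(tmp_path, chain_model):
    # 2 internal metabolites + 2 boundary species, 3 reactions
    path = tmp_path / "chain.xml"
    write_sbml(chain_model, path)
    back = read_sbml(path)
    assert (back.n_metabolites, back.n_reactions) == (2, 3)
    assert set(back.external_species) == {"X_ext", "Y_ext"}


def test_sbml_missing_bounds_is_error(tmp_path, chain_model):
    path = tmp_path / "chain.xml"
    write_sbml(chain_model, path)
    text = path.read_text()
    text = text.replace('fbc:lowerFluxBound="bnd_0" ', "", 1)
    bad = tmp_path / "bad.xml"
    bad.write_text(text)
    with pytest.raises(ModelError, match="no flux bounds"):
        read_sbml(bad)


def test_sbml_parse_failure_names_file(tmp_path):
    bad = tmp_path / "broken.xml"
    bad.write_text("<sbml><model><unclosed></model>")
    with pytest.raises(ModelError, match="broken.xml"):
        read_sbml(bad)


def test_sbml_cobra_cross_check(tmp_path, worked_example):
    """Our SBML output is readable by cobrapy with identical FBA optimum."""
    import cobra.io

    model, _, _ = worked_example
    path = tmp_path / "m.xml"
    write_sbml(model, path)
    cm = cobra.io.read_sbml_model(str(path))
    cm.solver = "glpk"
    # cobra replaces boundary species by exchange reactions of its own and
    # clips the conventional "R_" id prefix
    clipped = {r[2:] if r.startswith("R_") else r for r in model.reaction_ids}
    own = [r for r in cm.reactions if r.id in clipped]
    assert len(own) == model.n_reactions
    # substrate-uptake cap so the optimum is finite
    cm.reactions.get_by_id("P_supply").upper_bound = 10.0
    sol = cm.optimize()
    ours = model.copy()
    ours.upper_bounds[ours.reaction_index("R_P_supply")] = 10.0
    res = fba(ours)
    assert res.status == "optimal"
    assert sol.objective_value == pytest.approx(res.objective_value, rel=1e-6)


# ---------------------------------------------------------------------------
# TSV


def test_tsv_round_trip(tmp_path, worked_example):
    model, _, _ = worked_example
    sp, bp = tmp_path / "stoich.tsv", tmp_path / "bounds.tsv"
    write_tsv_model(model, sp, bp)
    back = read_tsv_model(sp, bp)
    assert set(back.reaction_ids) == set(model.reaction_ids)
    assert set(back.metabolite_ids) == set(model.metabolite_ids)
    for rid in model.reaction_ids:
        assert back.reaction_stoichiometry(rid) == model.reaction_stoichiometry(rid)
        jb, jm = back.reaction_index(rid), model.reaction_index(rid)
        assert back.lower_bounds[jb] == model.lower_bounds[jm]
        assert back.upper_bounds[jb] == model.upper_bounds[jm]
        assert back.objective[jb] == model.objective[jm]


def test_tsv_minimal_model(tmp_path):
    (tmp_path / "s.tsv").write_text("A\tR1\t-1\nB\tR1\t1\n")
    (tmp_path / "b.tsv").write_text("R1\t0\t10\t1\n")
    m = read_tsv_model(tmp_path / "s.tsv", tmp_path / "b.tsv")
    assert (m.n_metabolites, m.n_reactions) == (2, 1)


@pytest.mark.parametrize(
    "stoich, bounds, match",
    [
        ("", "R1\t0\t10\t0\n", "empty stoichiometry"),
        ("A\tR1\t1\nA\tR1\t2\n", "R1\t0\t10\t0\n", "duplicate"),
        ("A\tR1\t1\n", "R1\t0\t10\t0\nR2\t0\t10\t0\n", "unknown reactions"),
        ("A\tR1\tabc\n", "R1\t0\t10\t0\n", "not numeric"),
        ("A\tR1\t1\n", "", "no bounds"),
    ],
)
def test_tsv_errors(tmp_path, stoich, bounds, match):
    (tmp_path / "s.tsv").write_text(stoich)
    (tmp_path / "b.tsv").write_text(bounds)
    with pytest.raises(ModelError, match=match):
        read_tsv_model(tmp_path / "s.tsv", tmp_path / "b.tsv")


# ---------------------------------------------------------------------------
# constraint parsing and protection specs


@pytest.mark.parametrize(
    "text, coefs, rel, const",
    [
        ("R1 <= 10", {"R1": 1.0}, "<=", 10.0),
        ("-mu <= -0.999", {"mu": -1.0}, "<=", -0.999),
        ("2*R1 - 3 * R2 >= 4", {"R1": 2.0, "R2": -3.0}, ">=", 4.0),
        ("R1 + 1 <= R2 + 3", {"R1": 1.0, "R2": -1.0}, "<=", 2.0),
        ("0.5 R1 = 1e-2", {"R1": 0.5}, "=", 0.01),
    ],
)
def test_parse_constraint(text, coefs, rel, const):
    got_coefs, got_rel, got_const, fbamax = parse_constraint(text)
    assert {k: v for k, v in got_coefs.items() if v} == coefs
    assert got_rel == rel
    assert got_const == pytest.approx(const)
    assert fbamax == []


def test_parse_constraint_fbamax_term():
    coefs, rel, const, fbamax = parse_constraint("-mu <= -0.999 * FBA_MAX(mu)")
    assert coefs == {"mu": -1.0}
    assert fbamax == [(-0.999, "mu")]
    assert const == 0.0


def test_parse_constraint_requires_single_relation():
    with pytest.raises(ModelError, match="exactly one relation"):
        parse_constraint("R1 <= 2 <= R2")


def test_scenario_normalisation_idempotent(chain_model):
    """Equalities become <= pairs; constraint order does not matter."""
    s1 = Scenario("a")
    s1.add({"R_ex": 1.0}, "==", 5.0)
    s2 = Scenario("b")
    s2.add({"R_ex": 1.0}, "<=", 5.0)
    s2.add({"R_ex": -1.0}, "<=", -5.0)
    r1 = fba(chain_model, scenario=s1)
    r2 = fba(chain_model, scenario=s2)
    assert r1.objective_value == pytest.approx(5.0)
    assert r2.objective_value == pytest.approx(r1.objective_value)
    s1.constraints.reverse()
    assert fba(chain_model, scenario=s1).objective_value == pytest.approx(5.0)


def test_read_protection_spec_resolves_fba_max(tmp_path, chain_model):
    path = tmp_path / "spec.yaml"
    path.write_text(
        "protected_reactions: [R_up, R_ex]\n"
        "enforce_protected_feasibility: true\n"
        "dof_min: 1\n"
        "n_min: 1\n"
        "scenarios:\n"
        "  - name: max_export\n"
        "    constraints:\n"
        "      - '-R_ex <= -0.999 * FBA_MAX(R_ex)'\n"
    )
    spec = read_protection_spec(path, chain_model)
    assert len(spec.scenarios) == 1
    assert spec.fba_max_resolutions["max_export:FBA_MAX(R_ex)"] == pytest.approx(10.0)
    # resolved constraint: -R_ex <= -9.99
    (con,) = spec.scenarios[0].constraints
    assert dict(con.coefs) == {"R_ex": -1.0}
    assert con.rhs == pytest.approx(-9.99)


def test_empty_protection_spec_is_valid(chain_model):
    spec = build_protection_spec({}, chain_model)
    assert spec.protected_reactions == set()
    assert spec.scenarios == []


def test_protection_spec_boundary_values(chain_model):
    assert build_protection_spec({"dof_min": 0}, chain_model).dof_min == 0
    with pytest.raises(ModelError, match="n_min"):
        build_protection_spec({"n_min": 0}, chain_model)
    with pytest.raises(ModelError, match="dof_min"):
        build_protection_spec({"dof_min": -1}, chain_model)


def test_protection_spec_unknown_ids_rejected(chain_model):
    with pytest.raises(ModelError, match="not in model"):
        build_protection_spec({"protected_reactions": ["nope"]}, chain_model)
    with pytest.raises(ModelError, match="unknown reactions"):
        build_protection_spec(
            {"scenarios": [{"name": "s", "constraints": ["ghost <= 1"]}]},
            chain_model,
        )


# ---------------------------------------------------------------------------
# biomass tracker transform


def test_add_biomass_tracker(chain_model):
    tracked = add_biomass_tracker(chain_model, "R_ex")
    assert "biomass" in tracked.metabolite_ids
    assert "EX_biomass" in tracked.reaction_ids
    # export flux equals the tracked reaction's flux, optimum unchanged
    res = fba(tracked, {"EX_biomass": 1.0})
    assert res.objective_value == pytest.approx(10.0)
    with pytest.raises(ModelError, match="already exists"):
        add_biomass_tracker(tracked, "R_ex")
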