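"""Subset detection, lumping, condensed biomass reporting, loss-freeness."""

import numpy as np
import pytest

from _cases import make_random_case
from _oracles import cobra_subset_partner

from netreduce import (
    MetabolicModel,
    ProtectionSpec,
    bsr_diff,
    build_toy,
    compress,
    condensed_bsr_report,
    count_efms,
    detect_subsets,
    dof,
    fba,
    prune,
)


def _bsr_coefs(report):
    return dict(zip(report["metabolite"], report["coefficient"]))


# ---------------------------------------------------------------------------
# subset detection


def test_chain_forms_one_subset_absorbing_the_bsr(worked_example):
    model, spec, _ = worked_example
    pruned = prune(model, spec, seed=0).model
    smap = detect_subsets(pruned, spec)
    multi = [s for s in smap.subsets if len(s.members) > 1]
    assert len(multi) == 1
    (s,) = multi
    assert set(s.member_ids) == {"R_D", "R_F", "R_A", "BSR"}
    assert s.representative == "BSR" and s.lumped_id == "BSR"
    ratios = dict(s.members)
    assert ratios == {"BSR": 1.0, "R_D": 2.0, "R_F": 2.0, "R_A": 2.0}


def test_branch_point_reactions_are_not_one_subset(diamond):
    model, _, _ = diamond
    smap = detect_subsets(model)
    for s in smap.subsets:
        members = set(s.member_ids)
        # each parallel branch lumps internally, never across the branch point
        assert not ({"P1a", "P2a"} <= members)
        assert not ({"P1b", "P2b"} <= members)


def test_two_protected_reactions_never_merge(worked_example):
    model, spec, _ = worked_example
    pruned = prune(model, spec, seed=0).model
    spec_all = ProtectionSpec(
        protected_reactions=set(pruned.reaction_ids),
        scenarios=spec.scenarios,
    )
    smap = detect_subsets(pruned, spec_all)
    assert all(len(s.members) == 1 for s in smap.subsets)
    comp = compress(pruned, spec_all)
    assert comp.model.reaction_ids == pruned.reaction_ids


def test_subset_ratios_match_fva_fixing_oracle():
    """Kernel-detected ratios agree with fixing r_i and watching r_j collapse."""
    checked = 0
    for seed in range(10):
        model, spec, _, _ = make_random_case(seed + 1300)
        smap = detect_subsets(model)
        for s in smap.subsets:
            if len(s.members) < 2:
                continue
            ratios = dict(s.members)
            rep = s.representative
            for rid, rho in s.members:
                if rid == rep:
                    continue
                oracle_rho = cobra_subset_partner(model, rep, rid)
                assert oracle_rho is not None, (seed, rep, rid)
                assert oracle_rho == pytest.approx(rho, rel=1e-5, abs=1e-7)
                checked += 1
    assert checked > 0  # the batch must actually exercise the oracle


def test_irreversible_pair_with_opposite_ratio_is_not_lumped():
    # A is made by R1 and consumed by R2; a hypothetical proportional pair
    # with negative ratio between irreversible reactions must not survive:
    # R1: -> A, R2: -> A (parallel producers), R3: A -> ; kernel rows of
    # R1/R2 are NOT proportional here, but R1/R3 pairs across the merge are.
    m = MetabolicModel(
        metabolite_ids=["A"],
        reaction_ids=["R1", "R2", "R3"],
        S=np.array([[1.0, 1.0, -1.0]]),
        lower_bounds=np.zeros(3),
        upper_bounds=np.full(3, 10.0),
        objective=np.zeros(3),
        external_species=["X_ext", "Y_ext", "Z_ext"],
        S_ext=np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]]),
    )
    smap = detect_subsets(m)
    assert all(len(s.members) == 1 for s in smap.subsets)


# ---------------------------------------------------------------------------
# compression


def test_worked_example_condensed_bsr(worked_example):
    model, spec, expected = worked_example
    pruned = prune(model, spec, seed=0).model
    comp = compress(pruned, spec)
    report = condensed_bsr_report(comp, "BSR")
    assert _bsr_coefs(report) == expected["condensed_bsr"]
    assert set(comp.eliminated_metabolites) == expected["eliminated_metabolites"]
    for mid in ("A", "D", "F"):
        assert mid not in comp.model.metabolite_ids


def test_model_without_subsets_is_unchanged():
    # one branch metabolite feeding two alternative sinks: nothing lumps
    m = MetabolicModel(
        metabolite_ids=["A"],
        reaction_ids=["R_in", "R1", "R2"],
        S=np.array([[1.0, -1.0, -1.0]]),
        lower_bounds=np.zeros(3),
        upper_bounds=np.full(3, 10.0),
        objective=np.zeros(3),
        external_species=["S_ext", "X_ext", "Y_ext"],
        S_ext=np.array([[-1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]),
    )
    comp = compress(m)
    assert comp.model.reaction_ids == m.reaction_ids
    np.testing.assert_array_equal(comp.subset_map.T, np.eye(3))
    np.testing.assert_array_equal(comp.model.S, m.S)


def test_trace_element_appears_in_condensed_bsr():
    model, spec, expected = build_toy("trace_element")
    pruned = prune(model, spec, seed=0).model
    comp = compress(pruned, spec)
    coefs = _bsr_coefs(condensed_bsr_report(comp, "BSR"))
    assert coefs == expected["condensed_bsr"]
    assert coefs["TE_ext"] == pytest.approx(-0.1)
    assert "TE" in comp.eliminated_metabolites


def test_protected_metabolite_row_is_never_deleted(worked_example):
    model, spec, _ = worked_example
    pruned = prune(model, spec, seed=0).model
    spec2 = ProtectionSpec(
        protected_metabolites={"D"},
        protected_reactions=spec.protected_reactions,
        scenarios=spec.scenarios,
    )
    comp = compress(pruned, spec2)
    assert "D" in comp.model.metabolite_ids  # kept despite an all-zero row


def test_lumped_bounds_are_tightest_scaled_member_bounds():
    # chain with ratio 2 between members: 2 A -> B ; B -> out
    m = MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["R_in", "R1", "R2"],
        S=np.array([[1.0, -2.0, 0.0], [0.0, 1.0, -1.0]]),
        lower_bounds=np.array([0.0, 0.0, 0.0]),
        upper_bounds=np.array([100.0, 7.0, 5.0]),
        objective=np.zeros(3),
        external_species=["S_ext", "P_ext"],
        S_ext=np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
    )
    comp = compress(m)
    (s,) = [x for x in comp.subset_map.subsets if len(x.members) > 1]
    # the whole chain is proportional: v_in = 2 v_1 = 2 v_2
    assert set(s.member_ids) == {"R_in", "R1", "R2"}
    assert dict(s.members)["R_in"] == pytest.approx(2.0)
    j = comp.model.reaction_index(s.lumped_id)
    # representative flux limited by min(100/2, 7, 5)
    assert comp.model.upper_bounds[j] == pytest.approx(5.0)


def test_compression_transform_is_exact(worked_example):
    model, spec, _ = worked_example
    pruned = prune(model, spec, seed=0).model
    comp = compress(pruned, spec)
    T = comp.subset_map.T
    S_full = pruned.S @ T
    rows = [pruned.metabolite_ids.index(mid) for mid in comp.model.metabolite_ids]
    np.testing.assert_allclose(comp.model.S, S_full[rows, :], atol=1e-10)
    dropped = [
        i for i, mid in enumerate(pruned.metabolite_ids)
        if mid in comp.eliminated_metabolites
    ]
    np.testing.assert_allclose(S_full[dropped, :], 0, atol=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_compression_is_loss_free(seed):
    """dof preserved exactly; FBA optima preserved to 1e-6 relative;
    expanded compressed fluxes are steady states of the input model."""
    model, spec, target, _ = make_random_case(seed + 2100)
    pruned = prune(model, spec, seed=seed).model
    comp = compress(pruned, spec)
    assert dof(comp.model) == dof(pruned)
    a = fba(pruned, {target: 1.0})
    b = fba(comp.model, {target: 1.0})  # target is protected: id survives
    assert b.status == a.status == "optimal"
    assert b.objective_value == pytest.approx(
        a.objective_value, rel=1e-6, abs=1e-6
    )
    v = comp.expand_flux(b.fluxes)
    assert np.allclose(pruned.S @ v, 0, atol=1e-6)
    assert np.all(v >= pruned.lower_bounds - 1e-6)
    assert np.all(v <= pruned.upper_bounds + 1e-6)


@pytest.mark.parametrize("toy", ["worked_example", "trace_element"])
def test_compression_preserves_elementary_mode_count(toy):
    model, spec, _ = build_toy(toy)
    pruned = prune(model, spec, seed=0).model
    comp = compress(pruned, spec)
    assert count_efms(comp.model) == count_efms(pruned)


# ---------------------------------------------------------------------------
# reports


def test_bsr_report_untouched_model_is_verbatim(worked_example):
    model, _, _ = worked_example
    coefs = _bsr_coefs(condensed_bsr_report(model, "BSR"))
    assert coefs == {"A": -2.0, "Biomass_ext": 1.0}


def test_bsr_diff_aligns_on_metabolite_union(worked_example):
    model, spec, _ = worked_example
    comp = compress(prune(model, spec, seed=0).model, spec)
    diff = bsr_diff(model, "BSR", comp, "BSR", names=("full", "compressed"))
    table = diff.set_index("metabolite")
    assert np.isnan(table.loc["A", "compressed"])  # absent after lumping
    assert np.isnan(table.loc["P", "full"])  # only in the condensed BSR
    assert table.loc["P", "compressed"] == pytest.approx(-4.0)
    assert table.loc["Biomass_ext", "full"] == pytest.approx(1.0)
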