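"""Model validation and reactant/product diffing."""
import pytest

from rulesim import bngl, fixtures
from rulesim.core import (AddBond, AmbiguousRuleError, ChangeState,
                          DeleteBond, DeleteMolecule, apply_transformations,
                          derive_transformations, union_graphs,
                          validate_model)
from rulesim.matching import connected_components, is_isomorphic

WELL_FORMED = """
begin parameters
  kf 1.0
  kr 0.5
end parameters
begin molecule types
  A(b)
  B(a)
end molecule types
begin seed species
  A(b) 10
end seed species
begin observables
  Molecules freeA A(b)
end observables
begin reaction rules
  bind: A(b) + B(a) <-> A(b!1).B(a!1) kf, kr
end reaction rules
"""


def test_well_formed_model_has_no_diagnostics():
    assert validate_model(bngl.parse_model(WELL_FORMED)) == []


@pytest.mark.parametrize("mutation, fragment", [
    # rule referencing an undeclared component
    ("A(x) + B(a) -> A(x!1).B(a!1) kf", "A.x"),
    # undeclared rate parameter
    ("A(b) + B(a) -> A(b!1).B(a!1) nosuch", "nosuch"),
    # undeclared state label
    ("A(b~Q) -> A(b) kf", "b~Q"),
])
def test_broken_rules_produce_error_diagnostics(mutation, fragment):
    text = WELL_FORMED.replace(
        "bind: A(b) + B(a) <-> A(b!1).B(a!1) kf, kr", mutation)
    diags = validate_model(bngl.parse_model(text))
    assert any(d.severity == "error" and fragment in d.message for d in diags)


def test_incomplete_seed_species_rejected():
    text = WELL_FORMED.replace("A(b) 10", "A() 10")
    diags = validate_model(bngl.parse_model(text))
    assert any("all components" in d.message for d in diags)


def test_negative_copy_number_rejected():
    model = bngl.parse_model(WELL_FORMED)
    model.seed_species[0] = (model.seed_species[0][0], -3)
    assert any("nonnegative" in d.message for d in validate_model(model))


def test_double_bond_on_one_component_rejected():
    # two bonds landing on the same component violates the <=1-bond invariant
    with pytest.raises(bngl.BnglSyntaxError):
        bngl.parse_pattern("A(b!1!2).B(a!1).B(a!2)")
    # a bond label with a single endpoint is structurally invalid too
    with pytest.raises(bngl.BnglSyntaxError):
        bngl.parse_pattern("A(b!1).B(a!2)")


class TestDeriveTransformations:
    def test_binding_diff(self):
        tfs = derive_transformations([bngl.parse_pattern("A(b)"),
                                      bngl.parse_pattern("B(a)")],
                                     [bngl.parse_pattern("A(b!1).B(a!1)")])
        assert tfs == [AddBond((0, 0), (1, 0))]

    def test_state_change_diff(self):
        tfs = derive_transformations([bngl.parse_pattern("R(y~U)")],
                                     [bngl.parse_pattern("R(y~P)")])
        assert tfs == [ChangeState((0, 0), "P")]

    def test_degradation_diff_breaks_bond_first(self):
        tfs = derive_transformations([bngl.parse_pattern("L(r!1).R(l!1)")],
                                     [bngl.parse_pattern("R(l)")])
        assert tfs == [DeleteBond((0, 0), (1, 0)), DeleteMolecule(0)]
        # re-applying the diff reproduces the product side
        union, _ = union_graphs([bngl.parse_pattern("L(r!1).R(l!1)")])
        result = apply_transformations(union, tfs)
        assert is_isomorphic(result, bngl.parse_pattern("R(l)"))

    def test_interchangeable_molecules_with_different_fates_are_ambiguous(self):
        with pytest.raises(AmbiguousRuleError):
            derive_transformations(
                [bngl.parse_pattern("A(s~U)"), bngl.parse_pattern("A(s~U)")],
                [bngl.parse_pattern("A(s~P)"), bngl.parse_pattern("A(s~U)")])

    def test_symmetric_dimerization_is_not_ambiguous(self):
        tfs = derive_transformations(
            [bngl.parse_pattern("A(b)"), bngl.parse_pattern("A(b)")],
            [bngl.parse_pattern("A(b!1).A(b!1)")])
        assert len(tfs) == 1 and isinstance(tfs[0], AddBond)


@pytest.mark.parametrize("builder", [
    lambda: fixtures.build_toy("binding"),
    lambda: fixtures.build_toy("dimerization"),
    lambda: fixtures.build_toy("multisite_phospho"),
    lambda: fixtures.build_toy("chain"),
    lambda: fixtures.build_toy("cooperative"),
    lambda: fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=1)),
    lambda: fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=2)),
])
def test_diff_roundtrip_on_every_fixture_rule(builder):
    """Applying each rule's transformations to its reactants reproduces its
    written product side up to isomorphism."""
    model = builder()
    assert validate_model(model) == []
    for rule in model.rules:
        derived = rule.derived_products()
        written = rule.products
        assert len(derived) == len(written), rule.name
        unmatched = list(written)
        for d in derived:
            hit = next((w for w in unmatched
                        if is_isomorphic(d, w)), None)
            assert hit is not None, rule.name
            unmatched.remove(hit)
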