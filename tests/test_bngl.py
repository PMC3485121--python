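"""Dialect reader/writer: round trips, wildcards, negative corpus."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rulesim import bngl, fixtures
from rulesim.core import BOUND_ANY, UNSPEC_BOND
from rulesim.matching import canonical_label

from conftest import random_species

MINIMAL = """
begin molecule types
  A(b)
end molecule types
begin seed species
  A(b) 100
end seed species
"""


def test_minimal_two_block_model():
    m = bngl.parse_model(MINIMAL)
    assert len(m.molecule_types) == 1
    assert m.seed_species[0][1] == 100


def test_reversible_rule_splits_into_linked_pair():
    m = fixtures.build_toy("binding")
    fwd = m.rule_by_name("bind_fwd")
    rev = m.rule_by_name("bind_rev")
    assert fwd.reversible_partner == "bind_rev"
    assert rev.reversible_partner == "bind_fwd"
    assert fwd.rate_param == "kon" and rev.rate_param == "koff"


@pytest.mark.parametrize("text, expect", [
    ("A(b!1).B(a!1)", (2, 1)),
    ("R(y~P!+)", (1, 0)),
    ("R(y)", (1, 0)),
])
def test_parse_pattern_shapes(text, expect):
    g = bngl.parse_pattern(text)
    n_bonds = sum(1 for ends in g.bond_map().values() if len(ends) == 2)
    assert (len(g.molecules), n_bonds) == expect


def test_pattern_wildcard_semantics():
    g = bngl.parse_pattern("R(y~P!+,z!?,w)")
    y, z, w = g.molecules[0].comps
    assert y.state == "P" and y.bond == BOUND_ANY
    assert z.bond == UNSPEC_BOND
    assert w.bond is None          # bare mention = unbound
    assert w.state is None


def test_state_wildcard_tilde_question():
    g = bngl.parse_pattern("R(y~?)")
    assert g.molecules[0].comps[0].state is None


@pytest.mark.parametrize("name", fixtures.TOY_NAMES)
def test_roundtrip_toys(name):
    model = fixtures.build_toy(name)
    text = bngl.write_model(model)
    again = bngl.write_model(bngl.parse_model(text))
    assert again == text


@pytest.mark.parametrize("tier", [1, 2])
def test_roundtrip_erbb(tier):
    model = fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=tier))
    text = bngl.write_model(model)
    m2 = bngl.parse_model(text)
    assert bngl.write_model(m2) == text
    assert len(m2.rules) == len(model.rules)
    assert len(m2.observables) == len(model.observables)


@pytest.mark.parametrize("seed", range(12))
def test_roundtrip_random_models(seed):
    model = fixtures.random_model(seed=seed)
    text = bngl.write_model(model)
    assert bngl.write_model(bngl.parse_model(text)) == text


def test_write_is_deterministic():
    a = bngl.write_model(fixtures.build_erbb_mini())
    b = bngl.write_model(fixtures.build_erbb_mini())
    assert a == b


def test_wildcard_observable_preserved_verbatim():
    model = fixtures.build_toy("multisite_phospho")
    text = bngl.write_model(model)
    assert "R(s1~P!?)" in text


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_species_text_roundtrip_property(seed):
    """Any concrete species serializes to text that parses back to an
    isomorphic graph with a stable serialization."""
    rng = np.random.default_rng(seed)
    g = random_species(rng, int(rng.integers(1, 6)))
    text = bngl.format_pattern(g)
    again = bngl.parse_pattern(text)
    assert bngl.format_pattern(again) == text
    assert canonical_label(again) == canonical_label(g)


NEGATIVE_CORPUS = [
    "begin molecule types\n  A(b\nend molecule types",       # unclosed paren
    "begin molecule types\n  A(b)\nend molecule types\n"
    "begin seed species\n  A(b!1) 5\nend seed species",       # dangling !1
    "begin parameters\n  k 1\nend parameters\n"
    "begin parameters\n  q 2\nend parameters",                # duplicate block
    "begin nonsense\nend nonsense",                           # unknown block
    "A(b) 100",                                               # outside block
    "begin parameters\n  k\nend parameters",                  # missing value
    "begin molecule types\n  A(b)",                           # unterminated
    "begin molecule types\n  A(b)\nend molecule types\n"
    "begin reaction rules\n  A(b) -> A(b!1) 1.0 junk\n"
    "end reaction rules",                                     # trailing text
    "begin molecule types\n  A(b)\nend molecule types\n"
    "begin reaction rules\n  A(b) <-> A(b) 1.0\n"
    "end reaction rules",                                     # one rate for <->
]


@pytest.mark.parametrize("text", NEGATIVE_CORPUS)
def test_negative_corpus_rejected(text):
    with pytest.raises(bngl.BnglSyntaxError):
        bngl.parse_model(text)


def test_syntax_error_carries_source_position():
    try:
        bngl.parse_model("begin parameters\n  k\nend parameters")
    except bngl.BnglSyntaxError as exc:
        assert exc.span.line == 2
    else:  # pragma: no cover
        pytest.fail("expected syntax error")
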