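"""Model container, GPR parsing, splitting and biomass quality control."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmkit import (
    MetabolicModel,
    Metabolite,
    Reaction,
    biomass_molar_mass,
    molar_mass,
    normalize_macromolecule,
    parse_gpr,
    read_model,
    split_isozymes,
    split_reversible,
    write_model,
)
from ecmkit.exceptions import (
    AmbiguousBiomassError,
    FormulaError,
    GPRSyntaxError,
    ModelIntegrityError,
    NormalizationError,
    UnsupportedGPRError,
)
from ecmkit.gpr import And, Gene, Or

from .conftest import cobra_fba_optimum, make_chain_model


# ---------------------------------------------------------------------------
# GPR parsing
# ---------------------------------------------------------------------------

class TestParseGPR:
    def test_four_gene_complex(self):
        # the ribose ABC transporter style rule: one 4-subunit complex
        gpr = parse_gpr("BSU35930 and BSU35940 and BSU35950 and BSU35960")
        assert isinstance(gpr.root, And)
        assert len(gpr.root.children) == 4
        assert gpr.genes == {"BSU35930", "BSU35940", "BSU35950", "BSU35960"}

    def test_isozyme_pair(self):
        gpr = parse_gpr("BSU31360 or BSU31370")
        assert isinstance(gpr.root, Or)
        assert [c.name for c in gpr.root.children] == ["BSU31360", "BSU31370"]

    def test_empty_expression(self):
        assert parse_gpr("").is_empty
        assert parse_gpr("   ").to_string() == ""

    @pytest.mark.parametrize(
        "text,reference",
        [
            ("a and b or c", "((a and b) or c)"),
            ("a or b and c", "(a or (b and c))"),
            ("(a or b) and (a or b)", "((a or b) and (a or b))"),
            ("a and (b or c) or d", "((a and (b or c)) or d)"),
        ],
    )
    def test_precedence_by_truth_table(self, text, reference):
        """'and' binds tighter than 'or': exhaustive truth-table comparison
        against the explicitly parenthesized reference parse."""
        got, want = parse_gpr(text), parse_gpr(reference)
        genes = sorted(got.genes)
        for bits in itertools.product([False, True], repeat=len(genes)):
            active = {g for g, b in zip(genes, bits) if b}
            assert got.evaluate(active) == want.evaluate(active)

    def test_truth_table_matches_cobra(self):
        """Independent cross-check against cobrapy's GPR evaluator."""
        from cobra.core.gene import GPR as CobraGPR

        text = "a and b or c and (d or e)"
        mine = parse_gpr(text)
        theirs = CobraGPR.from_string(text)
        genes = sorted(mine.genes)
        for bits in itertools.product([False, True], repeat=len(genes)):
            active = {g for g, b in zip(genes, bits) if b}
            knockouts = set(genes) - active
            assert mine.evaluate(active) == theirs.eval(knockouts)

    @pytest.mark.parametrize("bad", ["(a and b", "a and", "or a", "a b", "a and ()"])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(GPRSyntaxError):
            parse_gpr(bad)

    @given(
        st.recursive(
            st.sampled_from(["gA", "gB", "gC", "gD"]).map(Gene),
            lambda children: st.tuples(
                st.sampled_from([And, Or]),
                st.lists(children, min_size=2, max_size=3),
            ).map(lambda t: t[0](tuple(t[1]))),
            max_leaves=8,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_is_semantically_lossless(self, node):
        """to_string -> parse preserves the truth table (flattening may
        reassociate same-operator chains)."""
        from ecmkit.gpr import GPR

        original = GPR(node)
        reparsed = parse_gpr(original.to_string())
        genes = sorted(original.genes)
        for bits in itertools.product([False, True], repeat=len(genes)):
            active = {g for g, b in zip(genes, bits) if b}
            assert original.evaluate(active) == reparsed.evaluate(active)

    def test_text_form_round_trips_losslessly(self):
        for text in ["a and b", "a or b or c", "(a and b) or (c and d)"]:
            assert parse_gpr(parse_gpr(text).to_string()).to_string() == \
                parse_gpr(text).to_string()


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

class TestMolarMass:
    def test_hydrogen(self):
        assert molar_mass("H") == pytest.approx(1.008)

    def test_glucose_hand_sum(self):
        # 6 x 12.01 + 12 x 1.008 + 6 x 16.00
        assert molar_mass("C6H12O6") == pytest.approx(180.156, abs=1e-9)

    def test_empty_formula_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty formula"):
            assert molar_mass("") == 0.0

    def test_unknown_element(self):
        with pytest.raises(FormulaError):
            molar_mass("Zq3")


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

class TestSplitReversible:
    def test_reversible_becomes_pair(self):
        model = make_chain_model("g1", reversible_transport=True)
        split, mapping = split_reversible(model)
        assert mapping["T"] == ["T", "T_reverse"]
        fwd, rev = split.reaction("T"), split.reaction("T_reverse")
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 1000.0)
        assert (rev.lower_bound, rev.upper_bound) == (0.0, 1000.0)
        assert rev.stoichiometry == {"a_e": 1.0, "a_c": -1.0}
        assert all(r.lower_bound >= 0 for r in split.reactions)

    def test_irreversible_model_is_fixed_point(self):
        model = make_chain_model("g1")
        split, mapping = split_reversible(model)
        assert split.reaction_ids == ["EX_a_e", "EX_a_e_reverse", "T", "DM_a_c"]
        assert mapping["T"] == ["T"]

    def test_fba_optimum_invariant(self, toy):
        before = cobra_fba_optimum(toy.model)
        split, _ = split_reversible(toy.model)
        after = cobra_fba_optimum(split)
        assert after == pytest.approx(before, abs=1e-6)


class TestSplitIsozymes:
    def test_or_pair_splits_with_num_suffix(self, chain_model):
        split, _ = split_reversible(chain_model)
        split, mapping = split_isozymes(split)
        assert mapping["T"] == ["T_num1", "T_num2"]
        assert split.reaction("T_num1").gpr.to_string() == "g1"
        assert split.reaction("T_num2").gpr.to_string() == "g2"
        assert split.reaction("T_num1").stoichiometry == \
            split.reaction("T_num2").stoichiometry

    def test_single_gene_untouched(self):
        model, _ = split_reversible(make_chain_model("g1"))
        split, mapping = split_isozymes(model)
        assert mapping["T"] == ["T"]

    def test_or_of_and_complexes_supported(self):
        model, _ = split_reversible(make_chain_model("(g1 and g2) or g3"))
        split, _ = split_isozymes(model)
        assert split.reaction("T_num1").gpr.to_string() == "g1 and g2"
        assert split.reaction("T_num2").gpr.to_string() == "g3"

    def test_or_below_and_rejected(self):
        model, _ = split_reversible(make_chain_model("g1 and (g2 or g3)"))
        with pytest.raises(UnsupportedGPRError):
            split_isozymes(model)

    def test_requires_irreversible_input(self):
        model = make_chain_model("g1 or g2", reversible_transport=True)
        with pytest.raises(ModelIntegrityError):
            split_isozymes(model)

    def test_fba_optimum_invariant_after_both_splits(self, toy):
        split, _ = split_reversible(toy.model)
        split, _ = split_isozymes(split)
        assert all(r.lower_bound >= 0 for r in split.reactions)
        assert not any(
            isinstance(r.gpr.root, Or) for r in split.reactions
        )
        assert cobra_fba_optimum(split) == pytest.approx(
            cobra_fba_optimum(toy.model), abs=1e-6
        )


# ---------------------------------------------------------------------------
# Biomass quality control
# ---------------------------------------------------------------------------

def biomass_fixture(extra_products=None, precursor_mass_g_per_mmol=1.0):
    """A synthesis reaction whose implied species mass is constructed exactly."""
    glc_mw = molar_mass("C6H12O6")
    coef = precursor_mass_g_per_mmol * 1000.0 / glc_mw
    stoich = {"glc_c": -coef, "bm_c": 1.0}
    mets = [
        Metabolite("glc_c", formula="C6H12O6"),
        Metabolite("bm_c", formula=""),
        Metabolite("h_c", formula="H", charge=1),
        Metabolite("h2o_c", formula="H2O"),
    ]
    for met_id, c in (extra_products or {}).items():
        stoich[met_id] = c
    model = MetabolicModel(
        metabolites=mets,
        reactions=[
            Reaction("BM", stoich, 0.0, 1000.0),
            Reaction("USE_BM", {"bm_c": -0.5}, 0.0, 1000.0),
        ],
        objective_reaction_id="BM",
        biomass_reaction_id="BM",
    )
    model.validate()
    return model


class TestBiomassMolarMass:
    def test_constructed_one_gram_per_mmol(self):
        model = biomass_fixture()
        mass, _ = biomass_molar_mass(model, "BM")
        assert mass == pytest.approx(1.0, abs=1e-12)

    def test_proton_restoration_scenario(self):
        """A biomass equation at 1.025 g/mmol loses 105 protons' worth of
        mass once the missing H+ (coefficient 105) is restored to the
        product side: 1.025 - 105 * 1.008/1000 = 0.92 g/mmol."""
        model = biomass_fixture(precursor_mass_g_per_mmol=1.025)
        mass, _ = biomass_molar_mass(model, "BM")
        assert mass == pytest.approx(1.025, abs=1e-12)
        corrected = biomass_fixture(
            extra_products={"h_c": 105.0}, precursor_mass_g_per_mmol=1.025
        )
        mass_corrected, _ = biomass_molar_mass(corrected, "BM")
        assert round(mass_corrected, 2) == 0.92

    def test_affine_in_single_coefficient(self):
        """Removing a product of molar mass m increases the implied species
        mass by m/1000 per unit coefficient."""
        base = biomass_fixture(extra_products={"h2o_c": 2.0})
        fewer = biomass_fixture(extra_products={"h2o_c": 1.0})
        m_base, _ = biomass_molar_mass(base, "BM")
        m_fewer, _ = biomass_molar_mass(fewer, "BM")
        assert m_fewer - m_base == pytest.approx(molar_mass("H2O") / 1000.0, abs=1e-12)

    def test_two_formula_less_products_ambiguous(self):
        model = biomass_fixture()
        model.metabolites.append(Metabolite("bm2_c", formula=""))
        model.reaction("BM").stoichiometry["bm2_c"] = 1.0
        model.reindex()
        with pytest.raises(AmbiguousBiomassError):
            biomass_molar_mass(model, "BM")

    def test_imbalance_report(self):
        model = biomass_fixture(extra_products={"h_c": 105.0})
        _, imbalance = biomass_molar_mass(model, "BM")
        # 105 protons appear from nowhere on the product side
        coef = model.reaction("BM").stoichiometry["glc_c"]
        assert imbalance["H"] == pytest.approx(105.0 + coef * 12, abs=1e-9)
        assert imbalance["C"] == pytest.approx(coef * 6, abs=1e-9)


class TestNormalizeMacromolecule:
    def test_normalizes_to_one_gram_per_mmol(self):
        model = biomass_fixture(precursor_mass_g_per_mmol=0.86)
        normalized, factor = normalize_macromolecule(model, "BM")
        assert factor == pytest.approx(0.86, abs=1e-12)
        mass, _ = biomass_molar_mass(normalized, "BM")
        assert mass == pytest.approx(1.0, abs=1e-9)
        # downstream consumers scale by the old mass so mass flow is conserved
        assert normalized.reaction("USE_BM").stoichiometry["bm_c"] == \
            pytest.approx(-0.5 * 0.86, abs=1e-12)

    def test_already_normalized_factor_one(self):
        model = biomass_fixture()
        normalized, factor = normalize_macromolecule(model, "BM")
        assert factor == pytest.approx(1.0, abs=1e-12)
        for met, coef in model.reaction("BM").stoichiometry.items():
            assert normalized.reaction("BM").stoichiometry[met] == \
                pytest.approx(coef, rel=1e-12)

    def test_idempotent(self):
        model = biomass_fixture(precursor_mass_g_per_mmol=0.86)
        once, _ = normalize_macromolecule(model, "BM")
        twice, factor = normalize_macromolecule(once, "BM")
        assert factor == pytest.approx(1.0, abs=1e-9)
        for rxn_id in ("BM", "USE_BM"):
            for met, coef in once.reaction(rxn_id).stoichiometry.items():
                assert twice.reaction(rxn_id).stoichiometry[met] == \
                    pytest.approx(coef, abs=1e-9)

    def test_nonpositive_mass_rejected(self):
        model = biomass_fixture(
            precursor_mass_g_per_mmol=0.01, extra_products={"h2o_c": 5.0}
        )
        with pytest.raises(NormalizationError):
            normalize_macromolecule(model, "BM")


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def assert_models_equal(a: MetabolicModel, b: MetabolicModel, tol=1e-9):
    """Field-by-field equality up to element order and bound tolerance."""
    assert {m.id for m in a.metabolites} == {m.id for m in b.metabolites}
    for ma in a.metabolites:
        mb = b.metabolite(ma.id)
        assert (ma.formula, ma.compartment, ma.charge) == \
            (mb.formula, mb.compartment, mb.charge)
    assert set(a.reaction_ids) == set(b.reaction_ids)
    for ra in a.reactions:
        rb = b.reaction(ra.id)
        assert ra.stoichiometry.keys() == rb.stoichiometry.keys()
        for met in ra.stoichiometry:
            assert ra.stoichiometry[met] == pytest.approx(rb.stoichiometry[met], abs=tol)
        assert ra.lower_bound == pytest.approx(rb.lower_bound, abs=tol)
        assert ra.upper_bound == pytest.approx(rb.upper_bound, abs=tol)
        assert ra.gpr.to_string() == rb.gpr.to_string()
    assert sorted(a.genes) == sorted(b.genes)
    assert a.objective_reaction_id == b.objective_reaction_id


class TestModelIO:
    def test_json_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.json"
        write_model(toy.model, path)
        assert_models_equal(read_model(path), toy.model)

    def test_sbml_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy.model, path)
        loaded = read_model(path)
        assert_models_equal(loaded, toy.model)

    def test_empty_model_round_trip(self, tmp_path):
        empty = MetabolicModel(metabolites=[], reactions=[])
        path = tmp_path / "empty.json"
        write_model(empty, path)
        assert read_model(path).reactions == []

    def test_undeclared_metabolite_is_integrity_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"metabolites": [], "reactions": '
            '[{"id": "R1", "metabolites": {"ghost_c": -1.0}}], "genes": []}'
        )
        with pytest.raises(ModelIntegrityError, match="ghost_c"):
            read_model(path)

    def test_ec_model_json_carries_enzyme_annotations(self, toy_ecm, tmp_path):
        import json

        from ecmkit import read_ec_model, write_ec_model

        path = tmp_path / "ec.json"
        write_ec_model(toy_ecm, path)
        doc = json.loads(path.read_text())
        by_id = {r["id"]: r for r in doc["reactions"]}
        assert by_id["GLY"]["kcat_per_s"] == pytest.approx(toy_ecm.kcat["GLY"])
        assert by_id["GLY"]["enzyme_mw_kda"] == pytest.approx(toy_ecm.mw["GLY"])
        loaded = read_ec_model(path)
        assert loaded.kcat == pytest.approx(toy_ecm.kcat)
        assert loaded.mw == pytest.approx(toy_ecm.mw)
        assert loaded.enzyme_budget == pytest.approx(toy_ecm.enzyme_budget)
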