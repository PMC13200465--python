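"""Sequence-to-SMILES translation and formula round-trip validation.

RDKit serves as the independent oracle: every emitted SMILES must parse and
yield the same molecular formula as the engine's element bookkeeping.
"""

import pytest
from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from lignoforge.chem_core import Formula, exact_mass, parse_formula
from lignoforge.nomenclature import parse_sequence
from lignoforge.smiles import (
    TranslationError,
    _allocate_ring_indices,
    decompose_backbone,
    formula_from_smiles,
    snippet_coverage_report,
    translate_sequence_to_smiles,
    validate_formula_roundtrip,
)


def rdkit_formula(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"RDKit rejected {smiles!r}"
    return CalcMolFormula(mol)


class TestDecompose:
    def test_beta_o4_dimer_classes(self, demo_registry):
        seq = parse_sequence("GUpeol[b-O-4]GUpeol")
        first, second = decompose_backbone(seq, demo_registry)
        assert first.chain_role == "bO4" and first.ring_sites == ()
        assert second.chain_role == "free"
        assert dict(second.ring_sites).keys() == {"O4"}

    def test_monomer_class(self, demo_registry):
        (cls,) = decompose_backbone(parse_sequence("GUpeol"), demo_registry)
        assert cls.chain_role == "free" and not cls.incoming

    def test_trimer_middle_residue_has_both_ends(self, demo_registry):
        seq = parse_sequence("GUpeol[b-O-4]GUpeol[b-O-4]GUpeol")
        middle = decompose_backbone(seq, demo_registry)[1]
        assert middle.chain_role == "bO4"  # outgoing β donor
        assert dict(middle.ring_sites).keys() == {"O4"}  # incoming acceptor

    def test_c5_link_on_sinapyl_rejected(self, demo_registry):
        seq = parse_sequence("GUpeol[5-5]SYpeol")
        with pytest.raises(TranslationError, match="methoxyl"):
            decompose_backbone(seq, demo_registry)

    def test_double_chain_use_rejected(self, demo_registry):
        seq = parse_sequence("GUpeol[b-b]GUpeol[b-b]GUpeol")
        with pytest.raises(TranslationError, match="two side-chain"):
            decompose_backbone(seq, demo_registry)


class TestTranslation:
    def test_vanillin_monomer(self, demo_registry):
        result = translate_sequence_to_smiles("GUmeal", demo_registry)
        assert rdkit_formula(result.smiles) == "C8H8O3"

    def test_divanillin(self, demo_registry):
        result = translate_sequence_to_smiles("GUmeal[5-5]GUmeal", demo_registry)
        formula = formula_from_smiles(result.smiles)
        assert formula.hill() == "C16H14O6"
        assert rdkit_formula(result.smiles) == "C16H14O6"
        assert exact_mass(formula) == pytest.approx(302.07904, abs=1e-4)

    @pytest.mark.parametrize("name,expected", [
        ("GUpeol[b-O-4]GUpeol", "C20H24O7"),   # guaiacylglycerol-β-coniferyl ether
        ("GUpeol[b-b]GUpeol", "C20H22O6"),     # pinoresinol
        ("GUpeol[b-5]GUpeol", "C20H22O6"),     # dehydrodiconiferyl alcohol
        ("GUpeol[b-1]GUpeol", "C17H20O6"),     # 1,2-diarylpropane-1,3-diol
        ("GUpeol[a-O-4]GUpeol", "C20H24O7"),
        ("GUpeol[5-O-4]GUpeol", "C20H22O6"),
    ])
    def test_model_dimer_formulas(self, demo_registry, name, expected):
        result = translate_sequence_to_smiles(name, demo_registry)
        assert rdkit_formula(result.smiles) == expected

    def test_deterministic(self, demo_registry):
        a = translate_sequence_to_smiles("GUpeol[b-b]SYpeol", demo_registry)
        b = translate_sequence_to_smiles("GUpeol[b-b]SYpeol", demo_registry)
        assert a.smiles == b.smiles

    def test_missing_snippet_key_names_class(self, demo_registry):
        # resinol formation requires the γ-alcohol; aldehyde residues have no snippet
        with pytest.raises(TranslationError, match="bb_left"):
            translate_sequence_to_smiles("GUpeal[b-b]GUpeal", demo_registry)

    def test_coverage_report_flags_untranslatable_classes(self, demo_registry):
        missing = snippet_coverage_report(demo_registry)
        assert any("GUpeal" in m and "bb_left" in m for m in missing)
        alcohols = demo_registry.subset(["HYpeol", "GUpeol", "SYpeol"])
        assert snippet_coverage_report(alcohols) == []

    def test_full_library_round_trip_against_rdkit(self, demo_registry,
                                                   conventional_library_deg3):
        """Central correctness property: 100% formula round-trip on the
        exhaustive H/G/S seven-linkage library up to trimers."""
        checked = 0
        for d in conventional_library_deg3.degrees:
            for row in conventional_library_deg3.frame(d).itertuples(index=False):
                result = translate_sequence_to_smiles(row.name, demo_registry)
                expected = Formula({el: int(getattr(row, el)) for el in "CHNOS"})
                ok, issues = validate_formula_roundtrip(expected, result)
                assert ok, f"{row.name}: {issues}"
                assert rdkit_formula(result.smiles) == expected.hill(), row.name
                checked += 1
        assert checked == conventional_library_deg3.size


class TestRingIndices:
    def test_indices_reused_after_closure(self):
        # L2 opens only after L1 closed, so digit 1 is recycled
        out, _ = _allocate_ring_indices("{L1}{L1}{L2}{L2}")
        assert out == "1111"
        # concurrent bonds get distinct digits
        out, _ = _allocate_ring_indices("{L1}{L2}{L2}{L1}")
        assert out == "1221"

    def test_percent_notation_beyond_nine_concurrent(self):
        opens = "".join(f"{{L{i}}}" for i in range(1, 12))
        closes = "".join(f"{{L{i}}}" for i in range(11, 0, -1))
        out, _ = _allocate_ring_indices(opens + closes)
        assert "%10" in out and "%11" in out

    def test_unclosed_index_rejected(self):
        with pytest.raises(TranslationError, match="unclosed"):
            _allocate_ring_indices("{L1}")

    def test_no_doubly_used_index_in_real_output(self, demo_registry):
        result = translate_sequence_to_smiles(
            "GUpeol[b-b]GUpeol", demo_registry
        )
        # formula extraction re-walks every ring bond; it raises on dangling indices
        formula_from_smiles(result.smiles)


class TestFormulaFromSmiles:
    @pytest.mark.parametrize("smiles,expected", [
        ("C", "CH4"),
        ("c1ccccc1", "C6H6"),
        ("C=O", "CH2O"),
        ("CC(=O)O", "C2H4O2"),
        ("c1ccccc1O", "C6H6O"),
        ("C1CC1.C1CC1", "C6H12"),  # dot components with reused indices
        ("C1.C1", "C2H6"),         # cross-component ring-closure bond
    ])
    def test_known_molecules(self, smiles, expected):
        assert formula_from_smiles(smiles).hill() == parse_formula(expected).hill()

    def test_agrees_with_rdkit_on_emitted_output(self, demo_registry):
        result = translate_sequence_to_smiles(
            "SYpeol[b-O-4]GUpeol[b-5]HYpeol", demo_registry
        )
        assert formula_from_smiles(result.smiles).hill() == rdkit_formula(result.smiles)

    def test_brackets_rejected(self):
        with pytest.raises(TranslationError, match="unparsable"):
            formula_from_smiles("[Na+]")


class TestRoundTripValidator:
    def test_consistent_record_passes(self, demo_registry):
        result = translate_sequence_to_smiles("GUpeol", demo_registry)
        ok, issues = validate_formula_roundtrip(parse_formula("C10H12O3"), result)
        assert ok and issues == []

    def test_corrupted_formula_fails_naming_element(self, demo_registry):
        result = translate_sequence_to_smiles("GUpeol", demo_registry)
        ok, issues = validate_formula_roundtrip(parse_formula("C10H13O3"), result)
        assert not ok
        assert any(issue.startswith("H:") for issue in issues)
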