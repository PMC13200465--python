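"""Combinatorial engine: gating, cross products, mirror dedup, growth."""

import itertools

import pandas as pd
import pytest

from lignoforge.chem_core import SignedFormulaDelta, parse_formula
from lignoforge.engine import (
    EngineError,
    LinkageRule,
    MemoryGuardError,
    apply_linkage,
    audit_formula_conservation,
    grow_library,
    qc_linkage_rules,
    remove_mirror_duplicates,
    enumerate_formula_states,
)
from lignoforge.nomenclature import (
    LinkageToken,
    SequenceStructure,
    canonical_identifier,
    reverse_sequence,
)
from lignoforge.registry import ResidueTable

from conftest import make_toy_residue, make_toy_table, permissive_rule


def monomer_frame(table):
    from lignoforge.engine import _monomer_frame

    return _monomer_frame(table)


def rule_by_name(rules, name):
    return next(r for r in rules if r.name == name)


def brute_force_classes(residues: ResidueTable, rules, max_degree: int) -> dict[int, int]:
    """Independent oracle: enumerate sequences recursively at the sequence
    level (flags tracked per the rule semantics), then count reversal-
    equivalence classes per degree via unordered {forward, mirror} name pairs.
    """
    start = [
        (SequenceStructure((r.symbol,), ()), dict(r.flags()), True) for r in residues
    ]
    per_degree = {1: start}
    for degree in range(1, max_degree):
        nxt = []
        for seq, flags, alive in per_degree[degree]:
            if not alive:
                continue
            for rule in rules:
                for direction in rule.directions:
                    end_req = rule.left_requires if direction == "forward" else rule.right_requires
                    mono_req = rule.right_requires if direction == "forward" else rule.left_requires
                    consumed = rule.right_consumes if direction == "forward" else rule.left_consumes
                    if not all(flags[f] for f in end_req):
                        continue
                    token = rule.token if direction == "forward" else rule.token.reversed()
                    for mono in residues:
                        if not all(mono.flags()[f] for f in mono_req):
                            continue
                        new_seq = SequenceStructure(
                            seq.residues + (mono.symbol,), seq.tokens + (token,)
                        )
                        new_flags = {
                            f: (False if f in consumed else v)
                            for f, v in mono.flags().items()
                        }
                        nxt.append((new_seq, new_flags, not rule.terminator))
        per_degree[degree + 1] = nxt
    return {
        d: len({
            frozenset({s.serialize(), reverse_sequence(s).serialize()})
            for s, _, _ in seqs
        })
        for d, seqs in per_degree.items()
    }


class TestApplyLinkage:
    def test_cross_product_count(self):
        table = make_toy_table("AAAA", "BBBB", "CCCC")
        monomers = make_toy_table("DDDD", "EEEE")
        out = apply_linkage(monomer_frame(table), monomers, permissive_rule())
        assert len(out) == 3 * 2

    def test_sinapyl_filtered_from_5_5(self, monolignols, seven_rules):
        rule = rule_by_name(seven_rules, "5-5")
        out = apply_linkage(monomer_frame(monolignols), monolignols, rule)
        # S is blocked on both sides: only H and G participate
        assert len(out) == 4
        assert not out["name"].str.contains("SYpeol").any()

    def test_beta_o4_product_state(self, monolignols, seven_rules):
        rule = rule_by_name(seven_rules, "b-O-4")
        g = monolignols.subset(["GUpeol"])
        s = monolignols.subset(["SYpeol"])
        out = apply_linkage(monomer_frame(g), s, rule, "forward")
        assert list(out["name"]) == ["GUpeol[b-O-4]SYpeol"]
        row = out.iloc[0]
        # formula = sum + O
        assert (row["C"], row["H"], row["O"]) == (21, 26, 8)
        # endgroup = sinapyl flags minus consumed phenol4
        assert bool(row["vinyl_available"]) is True
        assert bool(row["phenol4_available"]) is False
        assert bool(row["ring5_open"]) is False
        assert bool(row["alive"]) is True

    def test_direction_must_be_permitted(self, seven_rules):
        rule = rule_by_name(seven_rules, "b-1")
        with pytest.raises(EngineError, match="direction"):
            apply_linkage(monomer_frame(make_toy_table("AAAA")),
                          make_toy_table("BBBB"), rule, "reverse")

    def test_negative_delta_caught(self):
        table = ResidueTable({"TINY": make_toy_residue("TINY", formula="CH4")})
        bad = permissive_rule(delta={"C": -3, "H": -4})
        with pytest.raises(EngineError, match="negative"):
            apply_linkage(monomer_frame(table), table, bad)

    def test_runtime_linear_in_output_rows(self):
        """Cost per product row stays flat as the cross product grows."""
        import time

        rule = permissive_rule()
        sizes = (2_000, 8_000)
        per_row = []
        for n in sizes:
            table = make_toy_table(*[f"A{chr(65 + i // 26)}{chr(65 + i % 26)}A" for i in range(20)])
            base = monomer_frame(table)
            frame = pd.concat([base] * (n // len(base)), ignore_index=True)
            best = float("inf")
            for _ in range(3):
                t0 = time.perf_counter()
                out = apply_linkage(frame, table, rule)
                best = min(best, time.perf_counter() - t0)
            per_row.append(best / len(out))
        # allow generous noise, but reject quadratic behaviour (ratio ~4)
        assert per_row[1] < per_row[0] * 2.5


class TestMirrorDedup:
    def test_mirror_pair_collapses_to_one(self):
        aab = "HYpeol[b-O-4]HYpeol[b-O-4]GUpeol"
        from lignoforge.nomenclature import parse_sequence

        baa = reverse_sequence(parse_sequence(aab)).serialize()
        frame = pd.DataFrame({
            "name": [aab, baa], "rname": [baa, aab],
            "degree": [3, 3], "C": [1, 1], "H": [1, 1], "N": [0, 0],
            "O": [0, 0], "S": [0, 0],
        })
        out = remove_mirror_duplicates(frame)
        assert len(out) == 1
        assert out.iloc[0]["name"] == min(aab, baa)

    def test_palindrome_untouched_and_idempotent(self):
        frame = pd.DataFrame({
            "name": ["GUmeal[5-5]GUmeal"], "rname": ["GUmeal[5-5]GUmeal"],
            "degree": [2], "C": [16], "H": [14], "N": [0], "O": [6], "S": [0],
        })
        once = remove_mirror_duplicates(frame)
        twice = remove_mirror_duplicates(once)
        assert len(once) == 1
        pd.testing.assert_frame_equal(once, twice)


class TestGrowLibrary:
    def test_closed_form_single_symmetric_linkage(self):
        """(M^k + M^ceil(k/2)) / 2 unique sequences for M residues, one
        always-compatible symmetric linkage."""
        table = make_toy_table("AAAA", "BBBB")
        lib = grow_library(table, [permissive_rule()], 3)
        assert len(lib.frame(2)) == 3
        assert len(lib.frame(3)) == 6

    @pytest.mark.parametrize("n_rules", [1, 2])
    def test_dedup_matches_brute_force_oracle(self, n_rules):
        table = make_toy_table("AAAA", "BBBB")
        rules = [
            permissive_rule("sym", "5", "5", symmetric=True),
            permissive_rule("asym", "b", "4", bridge="O", symmetric=False),
        ][:n_rules]
        lib = grow_library(table, rules, 4)
        oracle = brute_force_classes(table, rules, 4)
        for d in lib.degrees:
            assert len(lib.frame(d)) == oracle[d], f"degree {d}"

    def test_conventional_library_matches_brute_force(self, monolignols, seven_rules,
                                                      conventional_library_deg3):
        oracle = brute_force_classes(monolignols, seven_rules, 3)
        for d in (1, 2, 3):
            assert len(conventional_library_deg3.frame(d)) == oracle[d]

    def test_max_degree_bounds_library(self, monolignols, seven_rules):
        lib = grow_library(monolignols, seven_rules, 2)
        assert lib.degrees == (1, 2)

    def test_formula_conservation_by_name_reparse(self, monolignols, seven_rules,
                                                  conventional_library_deg3):
        for d in conventional_library_deg3.degrees:
            mismatches = audit_formula_conservation(
                conventional_library_deg3.frame(d), monolignols, seven_rules
            )
            assert mismatches == []

    def test_monotone_gating(self, monolignols, seven_rules):
        """Removing a residue or a rule never adds oligomers."""
        full = grow_library(monolignols, seven_rules, 3)
        no_s = grow_library(monolignols.subset(["HYpeol", "GUpeol"]), seven_rules, 3)
        fewer_rules = grow_library(
            monolignols, [r for r in seven_rules if r.name != "b-O-4"], 3
        )
        for d in (2, 3):
            full_ids = set(full.frame(d)["canonical_id"])
            assert set(no_s.frame(d)["canonical_id"]) <= full_ids
            assert set(fewer_rules.frame(d)["canonical_id"]) <= full_ids

    def test_empty_registry_and_bad_degree_rejected(self, monolignols):
        with pytest.raises(EngineError):
            grow_library(ResidueTable({}), [permissive_rule()], 3)
        with pytest.raises(EngineError):
            grow_library(monolignols, [permissive_rule()], 1)

    def test_memory_guard(self):
        table = make_toy_table("AAAA", "BBBB", "CCCC")
        with pytest.raises(MemoryGuardError):
            grow_library(table, [permissive_rule()], 6, row_cap=50)

    def test_terminator_caps_growth(self, monolignols, seven_rules):
        b1 = [rule_by_name(seven_rules, "b-1")]
        lib = grow_library(monolignols, b1, 4)
        assert len(lib.frame(2)) > 0
        assert len(lib.frame(3)) == 0  # dead endgroups cannot extend


class TestStateEnumeration:
    def test_states_cover_library_formulas(self, monolignols, seven_rules,
                                           conventional_library_deg3):
        levels = enumerate_formula_states(monolignols, seven_rules, 3)
        for d in (1, 2, 3):
            lib_formulas = {
                tuple(int(r[el]) for el in "CHNOS")
                for _, r in conventional_library_deg3.frame(d).iterrows()
            }
            state_formulas = {s[:5] for s in levels[d]}
            assert lib_formulas == state_formulas


class TestRuleQc:
    def test_default_rules_clean(self, monolignols, seven_rules):
        report = qc_linkage_rules(seven_rules, monolignols)
        assert not report.errors

    def test_negative_delta_flagged(self):
        table = ResidueTable({"TINY": make_toy_residue("TINY", formula="CH4")})
        report = qc_linkage_rules([permissive_rule(delta={"C": -3, "H": -4})], table)
        assert report.errors

    def test_unknown_vertex_rejected_at_construction(self):
        with pytest.raises(Exception, match="unknown vertex"):
            permissive_rule(left="7", right="7")

    def test_symmetric_vertex_mismatch_rejected(self):
        with pytest.raises(EngineError, match="mismatched"):
            LinkageRule(
                name="bad", token=LinkageToken("b", "", "5"), symmetric=True,
                directions=("forward",), left_requires=(), right_requires=(),
                left_consumes=(), right_consumes=(), delta=SignedFormulaDelta({}),
            )
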