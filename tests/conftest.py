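"""Shared fixtures: demo registries, rule sets, small grown libraries.

Heavier artifacts (the conventional H/G/S library to degree 3) are grown
once per session; toy residues/rules are built per test via the helpers.
"""

import pytest
from hypothesis import settings

from lignoforge.chem_core import SignedFormulaDelta, parse_formula
from lignoforge.engine import LinkageRule, default_linkage_rules, grow_library
from lignoforge.nomenclature import LinkageToken
from lignoforge.registry import ResidueRecord, ResidueTable, default_residue_table
from lignoforge.fixtures import conventional_monolignols

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_registry() -> ResidueTable:
    return default_residue_table()


@pytest.fixture(scope="session")
def monolignols() -> ResidueTable:
    return conventional_monolignols()


@pytest.fixture(scope="session")
def seven_rules():
    return default_linkage_rules()


@pytest.fixture(scope="session")
def conventional_library_deg3(monolignols, seven_rules):
    """Exhaustive H/G/S seven-linkage library up to trimers."""
    return grow_library(monolignols, seven_rules, 3)


def make_toy_residue(symbol: str, formula: str = "C9H10O2", **flag_overrides) -> ResidueRecord:
    flags = dict(vinyl_available=True, phenol4_available=True,
                 ring5_open=True, sidechain_intact=True)
    flags.update(flag_overrides)
    return ResidueRecord(
        symbol=symbol, name=f"toy {symbol}", formula=parse_formula(formula),
        tags=("toy",), ring_pattern="HY", sidechain_class="pe",
        substituent_class="ol", **flags,
    )


def make_toy_table(*symbols: str) -> ResidueTable:
    return ResidueTable({s: make_toy_residue(s) for s in symbols})


def permissive_rule(name: str = "xx", left: str = "5", right: str = "5",
                    bridge: str = "", symmetric: bool = True,
                    delta: dict | None = None) -> LinkageRule:
    """A linkage with no prerequisites and no consumed moieties."""
    directions = ("forward",) if symmetric else ("forward", "reverse")
    return LinkageRule(
        name=name, token=LinkageToken(left, bridge, right), symmetric=symmetric,
        directions=directions, left_requires=(), right_requires=(),
        left_consumes=(), right_consumes=(),
        delta=SignedFormulaDelta(delta or {}),
    )
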