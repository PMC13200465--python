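"""Dictionary-based translation of sequence names directly into SMILES.

No molecular-graph intermediate is built. The linkage vertices in a sequence
name pin down both the inter- and intra-residue connectivity, so a sequence
decomposes — much like a peptide — into a backbone of generalized residues
(what each residue's side chain and ring look like given the linkages
touching them) plus substituent information (methoxylation pattern,
side-chain substituent). Each backbone class maps to a static SMILES snippet
with placeholder slots; translation is lookup + substitution.

Emission strategy: every residue becomes its own dot-separated SMILES
component, and all inter-residue bonds (including the three bonds of a
resinol and the two of a phenylcoumaran) are written as shared ring-closure
indices across components. This keeps each snippet independently balanced
and makes ring-index bookkeeping a single linear pass: indices are allocated
sequentially, freed on closure, and switch to ``%nn`` notation when more
than nine are concurrently open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .chem_core import Formula
from .nomenclature import SequenceStructure, parse_sequence
from .registry import RING_PATTERNS, ResidueTable

__all__ = [
    "BackboneClass",
    "TranslationResult",
    "TranslationError",
    "decompose_backbone",
    "translate_sequence_to_smiles",
    "validate_formula_roundtrip",
    "formula_from_smiles",
    "snippet_coverage_report",
]


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneClass:
    """Connectivity state of one residue given its adjacent linkage tokens.

    ``chain_role`` names how the side chain participates (``free``, ``bO4``,
    ``aO4``, ``bb_left``/``bb_right``, ``b5``, ``b1``) or is ``None`` when
    the side chain was displaced (β-1 acceptor). ``ring_sites`` maps used
    ring positions (``O4``, ``C5``, ``C1``) to inter-residue bond ids.
    """

    chain_role: Optional[str]
    chain_bonds: tuple[tuple[str, int], ...]
    ring_sites: tuple[tuple[str, int], ...]
    sidechain_class: str
    substituent_class: str
    ring_pattern: str

    @property
    def incoming(self) -> bool:
        return bool(self.chain_bonds) or bool(self.ring_sites)


@dataclass
class TranslationResult:
    smiles: str
    fragments: list[str] = field(default_factory=list)
    ring_log: list[tuple[int, str]] = field(default_factory=list)


_SNIPPETS: dict[tuple[str, str, str], str] | None = None
_SUBSTITUENTS: dict[str, str] | None = None


def _load_tables():
    global _SNIPPETS, _SUBSTITUENTS
    if _SNIPPETS is None:
        with resources.files("lignoforge.data").joinpath("chain_snippets.csv").open() as fh:
            frame = pd.read_csv(fh)
        _SNIPPETS = {
            (r.role, r.chain_class, r.substituent): r.template
            for r in frame.itertuples()
        }
        with resources.files("lignoforge.data").joinpath("substituents.csv").open() as fh:
            sub = pd.read_csv(fh)
        _SUBSTITUENTS = dict(zip(sub["class"], sub["smiles"]))
    return _SNIPPETS, _SUBSTITUENTS


def _lookup_snippet(role: str, chain_class: str, substituent: str) -> str:
    snippets, _ = _load_tables()
    for key in ((role, chain_class, substituent), (role, chain_class, "*")):
        if key in snippets:
            return snippets[key]
    raise TranslationError(
        f"no SMILES snippet for backbone class (role={role!r}, "
        f"chain={chain_class!r}, substituent={substituent!r}); "
        "extend chain_snippets.csv to translate it"
    )


# how each linkage token consumes vertices: (chain vertex, ring sites used)
def _classify_token(tok) -> str:
    pair = frozenset((tok.left, tok.right))
    if tok.bridge == "O":
        if pair == frozenset(("b", "4")):
            return "bO4"
        if pair == frozenset(("a", "4")):
            return "aO4"
        if pair == frozenset(("5", "4")):
            return "5O4"
        raise TranslationError(f"unsupported ether token {tok}")
    if pair == frozenset(("b",)):
        return "bb"
    if pair == frozenset(("b", "5")):
        return "b5"
    if pair == frozenset(("5",)):
        return "55"
    if pair == frozenset(("b", "1")):
        return "b1"
    raise TranslationError(f"unsupported linkage token {tok}")


def decompose_backbone(
    seq: SequenceStructure, table: ResidueTable
) -> list[BackboneClass]:
    """One BackboneClass per residue, derived from its adjacent tokens."""
    chain_roles: list[Optional[str]] = ["free"] * seq.degree
    chain_bonds: list[dict[str, int]] = [{} for _ in range(seq.degree)]
    ring_sites: list[dict[str, int]] = [{} for _ in range(seq.degree)]
    next_bond = 0

    def take_bond() -> int:
        nonlocal next_bond
        next_bond += 1
        return next_bond

    def set_chain(i: int, role: str, bonds: dict[str, int]) -> None:
        if chain_roles[i] != "free":
            raise TranslationError(
                f"residue {seq.residues[i]} (position {i}) has two side-chain "
                "linkages — upstream gating failure"
            )
        chain_roles[i] = role
        chain_bonds[i].update(bonds)

    def set_site(i: int, site: str, bond: int) -> None:
        if site in ring_sites[i]:
            raise TranslationError(
                f"ring site {site} used twice on residue {seq.residues[i]} "
                f"(position {i}) — upstream gating failure"
            )
        rec = table[seq.residues[i]]
        if site == "C5" and 5 in RING_PATTERNS.get(rec.ring_pattern, ()):
            raise TranslationError(
                f"C5 linkage on {rec.symbol}: position 5 carries a methoxyl"
            )
        ring_sites[i][site] = bond

    for t, tok in enumerate(seq.tokens):
        kind = _classify_token(tok)
        li, ri = t, t + 1
        # which residue holds the chain vertex
        if kind in ("bO4", "aO4", "b1", "b5"):
            chain_vertex = "b" if kind != "aO4" else "a"
            chain_on_left = tok.left == chain_vertex
            ci, oi = (li, ri) if chain_on_left else (ri, li)
        if kind in ("bO4", "aO4"):
            b = take_bond()
            set_chain(ci, kind, {"b1": b})
            set_site(oi, "O4", b)
        elif kind == "bb":
            b1, b2, b3 = take_bond(), take_bond(), take_bond()
            set_chain(li, "bb_left", {"b1": b1, "b2": b2, "b3": b3})
            set_chain(ri, "bb_right", {"b1": b1, "b2": b2, "b3": b3})
        elif kind == "b5":
            b1, b2 = take_bond(), take_bond()
            set_chain(ci, "b5", {"b1": b1, "b2": b2})
            set_site(oi, "C5", b1)
            set_site(oi, "O4", b2)
        elif kind == "55":
            b = take_bond()
            set_site(li, "C5", b)
            set_site(ri, "C5", b)
        elif kind == "5O4":
            b = take_bond()
            five, four = (li, ri) if tok.left == "5" else (ri, li)
            set_site(five, "C5", b)
            set_site(four, "O4", b)
        elif kind == "b1":
            b = take_bond()
            set_chain(ci, "b1", {"b1": b})
            set_site(oi, "C1", b)
            chain_roles[oi] = None  # side chain displaced

    classes = []
    for i, symbol in enumerate(seq.residues):
        rec = table[symbol]
        classes.append(BackboneClass(
            chain_role=chain_roles[i],
            chain_bonds=tuple(sorted(chain_bonds[i].items())),
            ring_sites=tuple(sorted(ring_sites[i].items())),
            sidechain_class=rec.sidechain_class,
            substituent_class=rec.substituent_class,
            ring_pattern=rec.ring_pattern,
        ))
    return classes


def _ring_text(pattern: str, sites: dict[str, int], standalone_ar: Optional[int]) -> str:
    """Aromatic-ring SMILES walked C1→C6 with link-site slots filled.

    All demo patterns are 4-hydroxyphenyl rings with 0–2 methoxyls; the O4
    oxygen doubles as the ether/coumaran attachment when a bond id is bound
    to it. ``standalone_ar`` carries the aromatic closure bond id for
    chain-less (β-1 displaced) residues whose C1 bears a cross-link.
    """
    if pattern not in RING_PATTERNS:
        raise TranslationError(f"unknown ring pattern {pattern!r}")
    ome = RING_PATTERNS[pattern]
    c3 = "c(OC)" if 3 in ome else "c"
    o4 = f"c(O{{L{sites['O4']}}})" if "O4" in sites else "c(O)"
    if "C5" in sites:
        c5 = f"c{{L{sites['C5']}}}"
    else:
        c5 = "c(OC)" if 5 in ome else "c"
    ar = f"{{L{standalone_ar}}}" if standalone_ar is not None else "{ar}"
    c1 = f"c{ar}{{L{sites['C1']}}}" if "C1" in sites else f"c{ar}"
    return f"{c1}c{c3}{o4}{c5}c{ar}"


def _fragment_for(cls: BackboneClass, take_bond) -> str:
    _, substituents = _load_tables()
    sites = dict(cls.ring_sites)
    if cls.chain_role is None:
        # displaced side chain: the fragment is the bare ring, linked at C1
        if "C1" not in sites:
            raise TranslationError("chain-less residue without a C1 link")
        return _ring_text(cls.ring_pattern, sites, standalone_ar=take_bond())
    template = _lookup_snippet(cls.chain_role, cls.sidechain_class, cls.substituent_class)
    ring = _ring_text(cls.ring_pattern, sites, standalone_ar=None)
    ring = ring.replace("{ar}", f"{{L{take_bond()}}}")
    text = template.replace("{R}", ring)
    if "{T}" in text:
        try:
            text = text.replace("{T}", substituents[cls.substituent_class])
        except KeyError:
            raise TranslationError(
                f"unknown side-chain substituent class {cls.substituent_class!r}"
            ) from None
    for slot, bond in cls.chain_bonds:
        text = text.replace(f"{{{slot}}}", f"{{L{bond}}}")
    leftover = re.search(r"\{b\d\}", text)
    if leftover:
        raise TranslationError(
            f"template for role {cls.chain_role!r} has unfilled slot {leftover.group(0)}"
        )
    return text


_LABEL_RE = re.compile(r"\{L(\d+)\}")


def _allocate_ring_indices(text: str) -> tuple[str, list[tuple[int, str]]]:
    """Replace bond-label tokens with SMILES ring-closure indices.

    Digits 1–9 are recycled as soon as a pair closes; ``%nn`` indices are
    used while more than nine bonds are concurrently open.
    """
    open_labels: dict[int, str] = {}
    in_use: set[int] = set()
    log: list[tuple[int, str]] = []

    def digit_text(n: int) -> str:
        return str(n) if n <= 9 else f"%{n}"

    def substitute(m: re.Match) -> str:
        label = int(m.group(1))
        if label in open_labels:
            digit = open_labels.pop(label)
            in_use.discard(int(digit.lstrip("%")))
            return digit
        n = 1
        while n in in_use:
            n += 1
        in_use.add(n)
        open_labels[label] = digit_text(n)
        log.append((label, digit_text(n)))
        return digit_text(n)

    out = _LABEL_RE.sub(substitute, text)
    if open_labels:
        raise TranslationError(f"unclosed ring indices for labels {sorted(open_labels)}")
    return out, log


def translate_sequence_to_smiles(
    seq: SequenceStructure | str, table: ResidueTable
) -> TranslationResult:
    """Translate a sequence name into a SMILES string.

    Deterministic: the same sequence always yields the same text. Emits
    constitution only (no stereodescriptors), matching the engine's
    constitutional-isomer semantics.
    """
    if isinstance(seq, str):
        seq = parse_sequence(seq, table)
    classes = decompose_backbone(seq, table)
    counter = [1000]  # residue-internal labels; disjoint from inter-residue ids

    def take_bond() -> int:
        counter[0] += 1
        return counter[0]

    fragments = [_fragment_for(cls, take_bond) for cls in classes]
    raw = ".".join(fragments)
    smiles, log = _allocate_ring_indices(raw)
    if smiles.count("(") != smiles.count(")"):
        raise TranslationError(f"unbalanced parentheses in emitted SMILES: {smiles}")
    return TranslationResult(smiles=smiles, fragments=fragments, ring_log=log)


_VALENCE = {"C": 4, "O": 2, "N": 3, "S": 2}
_SMILES_TOKEN = re.compile(r"%\d\d|\d|[CONS]|[cons]|[=#().\-]")


def formula_from_smiles(smiles: str) -> Formula:
    """Element counts of an organic-subset SMILES, implicit hydrogens included.

    Supports the constructs this package emits: bare C/O/N/S atoms (aromatic
    lowercase), single/double/triple bonds, branches, ring closures (digit and
    ``%nn``) and dot-separated components. Aromatic carbon contributes one
    fewer implicit hydrogen, the usual organic-subset convention; brackets,
    charges and other elements are rejected.
    """
    pos = 0
    atoms: list[tuple[str, bool]] = []  # (element, aromatic)
    bond_sum: list[float] = []
    prev: Optional[int] = None
    pending = 1.0
    stack: list[Optional[int]] = []
    rings: dict[str, tuple[int, float]] = {}

    def close_bond(i: int, j: int, order: float) -> None:
        bond_sum[i] += order
        bond_sum[j] += order

    while pos < len(smiles):
        m = _SMILES_TOKEN.match(smiles, pos)
        if not m:
            raise TranslationError(f"unparsable SMILES at position {pos}: {smiles!r}")
        tok = m.group(0)
        pos = m.end()
        if tok in "=#-":
            pending = {"-": 1.0, "=": 2.0, "#": 3.0}[tok]
        elif tok == "(":
            stack.append(prev)
        elif tok == ")":
            prev = stack.pop()
        elif tok == ".":
            prev = None
            pending = 1.0
        elif tok.isdigit() or tok.startswith("%"):
            if prev is None:
                raise TranslationError("ring closure before any atom")
            if tok in rings:
                j, order = rings.pop(tok)
                close_bond(prev, j, max(order, pending))
            else:
                rings[tok] = (prev, pending)
            pending = 1.0
        else:
            aromatic = tok.islower()
            element = tok.upper()
            atoms.append((element, aromatic))
            bond_sum.append(0.0)
            idx = len(atoms) - 1
            if prev is not None:
                close_bond(prev, idx, pending)
            prev = idx
            pending = 1.0
    if rings:
        raise TranslationError(f"unclosed ring indices {sorted(rings)} in {smiles!r}")

    counts: dict[str, int] = {}
    hydrogens = 0
    for (element, aromatic), bonds in zip(atoms, bond_sum):
        counts[element] = counts.get(element, 0) + 1
        valence = _VALENCE[element] - (1 if aromatic and element == "C" else 0)
        hydrogens += max(0, int(round(valence - bonds)))
    if hydrogens:
        counts["H"] = counts.get("H", 0) + hydrogens
    return Formula(counts)


def validate_formula_roundtrip(
    expected: Formula, result: TranslationResult
) -> tuple[bool, list[str]]:
    """Compare the emitted SMILES' element counts against the tracked formula.

    Returns (pass, itemized mismatches).
    """
    derived = formula_from_smiles(result.smiles)
    issues = []
    for el in sorted(set(dict(expected.counts)) | set(dict(derived.counts))):
        if expected[el] != derived[el]:
            issues.append(f"{el}: formula has {expected[el]}, SMILES yields {derived[el]}")
    return (not issues, issues)


def snippet_coverage_report(table: ResidueTable) -> list[str]:
    """List backbone classes a registry can reach that the snippet tables lack.

    A residue can reach a donor role only if its flags permit the
    corresponding linkage, so e.g. β-β snippets are only demanded for
    vinyl-bearing residues.
    """
    missing = []
    for rec in table:
        roles = ["free"]
        if rec.vinyl_available:
            roles += ["bO4", "aO4", "bb_left", "bb_right", "b5", "b1"]
        for role in roles:
            try:
                _lookup_snippet(role, rec.sidechain_class, rec.substituent_class)
            except TranslationError:
                missing.append(
                    f"{rec.symbol}: no snippet for role {role} "
                    f"(chain {rec.sidechain_class}, substituent {rec.substituent_class})"
                )
    return missing
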