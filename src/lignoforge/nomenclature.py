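"""Sequence names: residue symbols joined by vertex-to-vertex linkage tokens.

A linear oligomer is written as residue symbols alternating with bracketed
linkage tokens, e.g. ``GUmeal[5-5]GUmeal`` (divanillin) or
``GUpeol[b-O-4]SYpeol``. Tokens name the connecting atom vertices (α, β, γ,
1, 4, 5); ``O`` marks an ether bridge. Because a linear sequence read
backwards (with each token's vertices swapped) denotes the same molecule,
every sequence has a mirror twin; the canonical identifier — the
alphabetically sorted pair of forward and reversed serializations — is
invariant under reversal and drives duplicate removal in the engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .registry import ResidueTable, parse_residue_symbol, RegistryError

__all__ = [
    "LinkageToken",
    "SequenceStructure",
    "parse_sequence",
    "reverse_sequence",
    "canonical_identifier",
    "NomenclatureError",
]

VERTEX_LABELS = ("a", "b", "g", "1", "4", "5")
_UNICODE_ALIASES = {"α": "a", "β": "b", "γ": "g"}
_PRETTY = {"a": "α", "b": "β", "g": "γ"}

# Reserved separator for canonical identifiers; cannot occur in names.
ID_SEPARATOR = "|"


class NomenclatureError(ValueError):
    pass


@dataclass(frozen=True)
class LinkageToken:
    """One inter-residue linkage: left vertex, bridge (direct or ether O), right vertex."""

    left: str
    bridge: str  # "" for a direct bond, "O" for an ether
    right: str

    def __post_init__(self):
        for v in (self.left, self.right):
            if v not in VERTEX_LABELS:
                raise NomenclatureError(
                    f"unknown vertex {v!r}; expected one of {VERTEX_LABELS}"
                )
        if self.bridge not in ("", "O"):
            raise NomenclatureError(f"unknown bridge {self.bridge!r}")

    def reversed(self) -> "LinkageToken":
        return LinkageToken(self.right, self.bridge, self.left)

    def serialize(self, pretty: bool = False) -> str:
        l, r = self.left, self.right
        if pretty:
            l, r = _PRETTY.get(l, l), _PRETTY.get(r, r)
        mid = f"-{self.bridge}-" if self.bridge else "-"
        return f"[{l}{mid}{r}]"

    def __str__(self) -> str:
        return self.serialize()


_TOKEN_RE = re.compile(r"\[([^\[\]]*)\]")
_TOKEN_BODY = re.compile(r"^([a-z1-9αβγ])-(?:(O)-)?([a-z1-9αβγ])$")
_SYMBOL_RE = re.compile(r"(?:[A-Z]{2}[a-z]{4}|[A-Z]{4})")


def _parse_token_body(body: str) -> LinkageToken:
    m = _TOKEN_BODY.match(body)
    if not m:
        raise NomenclatureError(f"malformed linkage token [{body}]")
    left = _UNICODE_ALIASES.get(m.group(1), m.group(1))
    right = _UNICODE_ALIASES.get(m.group(3), m.group(3))
    return LinkageToken(left, m.group(2) or "", right)


@dataclass(frozen=True)
class SequenceStructure:
    """Ordered residues and the tokens between them; degree = len(residues)."""

    residues: tuple[str, ...]
    tokens: tuple[LinkageToken, ...]

    def __post_init__(self):
        if not self.residues:
            raise NomenclatureError("empty sequence")
        if len(self.residues) != len(self.tokens) + 1:
            raise NomenclatureError(
                f"{len(self.residues)} residues require {len(self.residues) - 1} "
                f"linkage tokens, got {len(self.tokens)}"
            )

    @property
    def degree(self) -> int:
        return len(self.residues)

    def serialize(self, pretty: bool = False) -> str:
        parts = [self.residues[0]]
        for tok, res in zip(self.tokens, self.residues[1:]):
            parts.append(tok.serialize(pretty=pretty))
            parts.append(res)
        return "".join(parts)

    def __str__(self) -> str:
        return self.serialize()


def parse_sequence(text: str, table: Optional[ResidueTable] = None) -> SequenceStructure:
    """Parse a sequence name; validates symbols against ``table`` when given."""
    text = text.strip()
    if not text:
        raise NomenclatureError("empty sequence name")
    residues: list[str] = []
    tokens: list[LinkageToken] = []
    pos = 0
    expect_residue = True
    while pos < len(text):
        if expect_residue:
            m = _SYMBOL_RE.match(text, pos)
            if not m:
                raise NomenclatureError(
                    f"expected a residue symbol at position {pos} in {text!r}"
                )
            symbol = m.group(0)
            parse_residue_symbol(symbol)  # grammar check
            if table is not None and symbol not in table:
                raise RegistryError(f"unknown residue symbol {symbol!r} in {text!r}")
            residues.append(symbol)
            pos = m.end()
        else:
            m = _TOKEN_RE.match(text, pos)
            if not m:
                raise NomenclatureError(
                    f"expected a linkage token at position {pos} in {text!r}"
                )
            tokens.append(_parse_token_body(m.group(1)))
            pos = m.end()
        expect_residue = not expect_residue
    if expect_residue:
        raise NomenclatureError(f"dangling linkage at end of {text!r}")
    return SequenceStructure(tuple(residues), tuple(tokens))


def reverse_sequence(seq: SequenceStructure) -> SequenceStructure:
    """Mirror a sequence: residues reversed, token order reversed, vertices swapped."""
    return SequenceStructure(
        tuple(reversed(seq.residues)),
        tuple(tok.reversed() for tok in reversed(seq.tokens)),
    )


def canonical_identifier(seq: SequenceStructure) -> str:
    """Reversal-invariant identifier: the sorted (forward, mirror) pair.

    A sequence and its mirror serialize to the same sorted pair, so mirror
    duplicates converge on one identifier while distinct molecules never do.
    """
    fwd = seq.serialize()
    rev = reverse_sequence(seq).serialize()
    first, second = sorted((fwd, rev))
    return f"{first}{ID_SEPARATOR}{second}"


def canonical_id_from_names(forward: str, reverse: str) -> str:
    """Identifier from pre-serialized forward/mirror names (vectorized engine path)."""
    first, second = sorted((forward, reverse))
    return f"{first}{ID_SEPARATOR}{second}"
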