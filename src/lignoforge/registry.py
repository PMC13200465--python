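"""Monomer-residue registry: six-letter nomenclature, reactivity flags, QC.

Phenylpropanoid residues carry a descriptive six-letter symbol built from
three two-letter mnemonics — substituted benzene ring, side chain, and
side-chain substituent (e.g. ``GUmeal`` = guaiacol + methylene + aldehyde,
the vanillin residue). Non-phenylpropanoid residues (tricin and friends) use
an arbitrary four-capital code. The registry is a plain CSV so users can add
residues without touching code; QC functions catch the usual mistakes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .chem_core import Formula, default_mass_table, rdbe

__all__ = [
    "ResidueRecord",
    "ResidueTable",
    "QCReport",
    "QCEntry",
    "load_residue_table",
    "default_residue_table",
    "parse_residue_symbol",
    "qc_residue_table",
    "FLAG_NAMES",
]

PHENYLPROPANOID_SYMBOL = re.compile(r"^[A-Z]{2}[a-z]{4}$")
NON_PHENYLPROPANOID_SYMBOL = re.compile(r"^[A-Z]{4}$")

FLAG_NAMES = (
    "vinyl_available",
    "phenol4_available",
    "ring5_open",
    "sidechain_intact",
)

_REQUIRED_COLUMNS = [
    "symbol", "name", "C", "H", "N", "O", "S",
    "vinyl_available", "phenol4_available", "ring5_open", "sidechain_intact",
    "tags", "ring_pattern", "sidechain_class", "substituent_class",
]

# Ring substitution patterns the SMILES layer understands: methoxyl positions
# on the 4-hydroxyphenyl ring.
RING_PATTERNS = {"HY": (), "GU": (3,), "SY": (3, 5)}


class RegistryError(ValueError):
    """Raised when a residue table cannot be loaded cleanly."""


@dataclass(frozen=True)
class ResidueRecord:
    symbol: str
    name: str
    formula: Formula
    vinyl_available: bool
    phenol4_available: bool
    ring5_open: bool
    sidechain_intact: bool
    tags: tuple[str, ...]
    ring_pattern: str
    sidechain_class: str
    substituent_class: str
    alive: bool = True

    def flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in FLAG_NAMES}


@dataclass
class ResidueTable:
    """Residue records keyed by their unique symbol."""

    records: dict[str, ResidueRecord] = field(default_factory=dict)

    def __getitem__(self, symbol: str) -> ResidueRecord:
        try:
            return self.records[symbol]
        except KeyError:
            raise RegistryError(f"unknown residue symbol {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.records

    def __iter__(self):
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.records)

    def subset(self, symbols: Iterable[str]) -> "ResidueTable":
        return ResidueTable({s: self[s] for s in symbols})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            d = r.formula.as_dict()
            rows.append({
                "symbol": r.symbol, "name": r.name,
                **{el: d.get(el, 0) for el in ("C", "H", "N", "O", "S")},
                **r.flags(),
                "tags": ";".join(r.tags),
                "ring_pattern": r.ring_pattern,
                "sidechain_class": r.sidechain_class,
                "substituent_class": r.substituent_class,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class QCEntry:
    severity: str  # "error" | "warning"
    reference: str
    message: str


@dataclass
class QCReport:
    entries: list[QCEntry] = field(default_factory=list)

    def add(self, severity: str, reference: str, message: str) -> None:
        self.entries.append(QCEntry(severity, reference, message))

    @property
    def errors(self) -> list[QCEntry]:
        return [e for e in self.entries if e.severity == "error"]

    @property
    def warnings(self) -> list[QCEntry]:
        return [e for e in self.entries if e.severity == "warning"]

    def __bool__(self) -> bool:
        # truthy report == violations present
        return bool(self.entries)

    def __str__(self) -> str:
        if not self.entries:
            return "QC clean"
        return "\n".join(f"[{e.severity}] {e.reference}: {e.message}" for e in self.entries)


def parse_residue_symbol(symbol: str):
    """Split a residue symbol into its moiety codes.

    Returns ``(ring, sidechain, substituent)`` for six-letter phenylpropanoid
    codes, or the string ``"non-phenylpropanoid"`` for four-capital codes.
    """
    if PHENYLPROPANOID_SYMBOL.match(symbol):
        return symbol[0:2], symbol[2:4], symbol[4:6]
    if NON_PHENYLPROPANOID_SYMBOL.match(symbol):
        return "non-phenylpropanoid"
    raise RegistryError(
        f"malformed residue symbol {symbol!r}: expected 2 uppercase + 4 "
        "lowercase (phenylpropanoid) or 4 uppercase letters"
    )


def _parse_bool(value, where: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise RegistryError(f"{where}: cannot parse boolean {value!r}")


def load_residue_table(path: str | Path | pd.DataFrame) -> ResidueTable:
    """Load and validate a residue CSV; collects all row errors before raising."""
    frame = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryError(f"residue table missing columns: {missing}")

    problems: list[str] = []
    records: dict[str, ResidueRecord] = {}
    for i, row in frame.iterrows():
        where = f"row {i} ({row['symbol']})"
        try:
            symbol = str(row["symbol"]).strip()
            parse_residue_symbol(symbol)
            counts = {}
            for el in ("C", "H", "N", "O", "S"):
                n = int(row[el])
                if n < 0:
                    raise RegistryError(f"{where}, column {el}: negative atom count {n}")
                counts[el] = n
            formula = Formula(counts)
            if not formula.counts:
                raise RegistryError(f"{where}: empty formula")
            if symbol in records:
                raise RegistryError(f"{where}: duplicate symbol {symbol!r}")
            records[symbol] = ResidueRecord(
                symbol=symbol,
                name=str(row["name"]),
                formula=formula,
                vinyl_available=_parse_bool(row["vinyl_available"], where),
                phenol4_available=_parse_bool(row["phenol4_available"], where),
                ring5_open=_parse_bool(row["ring5_open"], where),
                sidechain_intact=_parse_bool(row["sidechain_intact"], where),
                tags=tuple(t for t in str(row["tags"]).split(";") if t and t != "nan"),
                ring_pattern=str(row["ring_pattern"]).strip(),
                sidechain_class=str(row["sidechain_class"]).strip(),
                substituent_class=str(row["substituent_class"]).strip(),
            )
        except (RegistryError, ValueError) as exc:
            problems.append(str(exc) if str(exc).startswith("row") else f"{where}: {exc}")
    if problems:
        raise RegistryError("residue table failed to load:\n" + "\n".join(problems))
    return ResidueTable(records)


def default_residue_table() -> ResidueTable:
    """The packaged demo registry (H/G/S monolignols + oxidized variants + vanillin)."""
    with resources.files("lignoforge.data").joinpath("residues.csv").open() as fh:
        return load_residue_table(pd.read_csv(fh, dtype=str))


def qc_residue_table(table: ResidueTable) -> QCReport:
    """Consistency checks on a loaded registry.

    Violations are report entries, never exceptions: an empty report means
    the table passed.
    """
    report = QCReport()
    mass_table = default_mass_table()
    for rec in table:
        ref = rec.symbol
        parsed = parse_residue_symbol(rec.symbol)
        is_phenylpropanoid = parsed != "non-phenylpropanoid"
        # S-type rings carry a 5-OMe, which blocks C5 coupling.
        if "S" in rec.tags and rec.ring5_open:
            report.add("error", ref, "S-tagged residue must have ring5_open=false (5-OMe blocks C5)")
        if rec.ring_pattern == "SY" and rec.ring5_open:
            report.add("error", ref, "SY ring pattern with ring5_open=true")
        if is_phenylpropanoid:
            value = rdbe(rec.formula, mass_table)
            if value < 4:
                report.add(
                    "warning", ref,
                    f"aromatic residue with RDBE {value} < 4: formula {rec.formula.hill()} "
                    "cannot hold a benzene ring",
                )
            if rec.ring_pattern not in RING_PATTERNS:
                report.add("error", ref, f"unknown ring pattern {rec.ring_pattern!r}")
            if parsed[0] != rec.ring_pattern:
                report.add("warning", ref, "symbol ring code disagrees with ring_pattern column")
        if not rec.sidechain_class:
            report.add("error", ref, "missing sidechain_class (needed for SMILES translation)")
        if rec.sidechain_class == "me" and rec.vinyl_available:
            report.add("error", ref, "one-carbon side chain cannot offer a conjugated vinyl")
    return report
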