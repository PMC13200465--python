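"""Molecular-formula arithmetic and mass-spectrometry metrics.

Everything downstream (the combinatorial engine, chemical-space plots,
suspect lists) works on element-count vectors rather than molecular graphs:
a linkage is fully described by which atoms it adds or removes, so formula
bookkeeping plus a fixed monoisotopic-mass table is enough to compute exact
masses, ring-double-bond equivalents (RDBE) and Kendrick mass defects (KMD)
for every oligomer in a library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Formula",
    "SignedFormulaDelta",
    "ElementMassTable",
    "KmdBase",
    "parse_formula",
    "formula_combine",
    "exact_mass",
    "rdbe",
    "kendrick_mass_defect",
    "atomic_ratio",
    "default_mass_table",
    "default_kmd_bases",
]

# Elements tracked explicitly by the engine's vectorized tables. Others are
# accepted by Formula but cannot appear in linkage CSVs.
TRACKED_ELEMENTS = ("C", "H", "N", "O", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for negative counts or unknown elements."""


def _clean(counts: Mapping[str, int]) -> dict[str, int]:
    return {el: int(n) for el, n in counts.items() if int(n) != 0}


@dataclass(frozen=True)
class Formula:
    """Element -> non-negative count; absent element means zero.

    Instances are immutable; arithmetic goes through :func:`formula_combine`
    or the ``+`` operator (which uses an empty delta).
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if int(n) < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
        object.__setattr__(
            self, "counts", tuple(sorted(_clean(items).items()))
        )

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        return formula_combine(self, other, SignedFormulaDelta({}))

    def hill(self) -> str:
        """Hill-order string (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                parts.append(el + (str(n) if n != 1 else ""))
        for el in sorted(d):
            n = d[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


@dataclass(frozen=True)
class SignedFormulaDelta:
    """Signed element-count correction term for a linkage reaction.

    Applying a delta may never drive any element below zero; the engine treats
    that as a mis-specified correction term rather than clamping.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        object.__setattr__(
            self, "counts", tuple(sorted(_clean(dict(counts)).items()))
        )

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


def parse_formula(text: str) -> Formula:
    """Parse a plain molecular-formula string like ``C10H12O3``."""
    text = text.strip()
    if not text:
        return Formula({})
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + (
            int(m.group(2)) if m.group(2) else 1
        )
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return Formula(counts)


def formula_combine(a: Formula, b: Formula, delta: SignedFormulaDelta) -> Formula:
    """Element-wise ``a + b + delta``, rejecting any negative result."""
    out: dict[str, int] = dict(a.counts)
    for el, n in b.counts:
        out[el] = out.get(el, 0) + n
    for el, n in delta.counts:
        out[el] = out.get(el, 0) + n
        if out[el] < 0:
            raise FormulaError(
                f"correction term drives element {el} to {out[el]} "
                f"(a={a.hill() or '∅'}, b={b.hill() or '∅'})"
            )
    return Formula(out)


class ElementMassTable:
    """Monoisotopic masses, nominal (integer) masses and standard valences.

    The packaged table pins C to exactly 12 so results are bit-stable across
    platforms; it is user-replaceable for exotic elements.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"element", "monoisotopic_mass", "nominal_mass", "valence"}
        missing = required - set(frame.columns)
        if missing:
            raise FormulaError(f"element table missing columns: {sorted(missing)}")
        if (frame["monoisotopic_mass"] <= 0).any():
            raise FormulaError("element masses must be positive")
        frame = frame.set_index("element")
        if "C" not in frame.index or frame.loc["C", "monoisotopic_mass"] != 12.0:
            raise FormulaError("carbon must be present with mass exactly 12.0")
        self._mono = frame["monoisotopic_mass"].to_dict()
        self._nominal = frame["nominal_mass"].astype(int).to_dict()
        self._valence = frame["valence"].astype(int).to_dict()

    def monoisotopic(self, element: str) -> float:
        try:
            return self._mono[element]
        except KeyError:
            raise FormulaError(f"unknown element {element!r}") from None

    def nominal(self, element: str) -> int:
        self.monoisotopic(element)
        return self._nominal[element]

    def valence(self, element: str) -> int:
        self.monoisotopic(element)
        return self._valence[element]

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._mono)


_DEFAULT_TABLE: ElementMassTable | None = None


def default_mass_table() -> ElementMassTable:
    """The packaged element table (CODATA/IUPAC monoisotopic masses)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.files("lignoforge.data").joinpath("elements.csv").open() as fh:
            _DEFAULT_TABLE = ElementMassTable(pd.read_csv(fh))
    return _DEFAULT_TABLE


def exact_mass(f: Formula, table: ElementMassTable | None = None) -> float:
    """Monoisotopic (exact) mass in Da."""
    table = table or default_mass_table()
    return sum(n * table.monoisotopic(el) for el, n in f.counts)


def exact_mass_signed(delta: SignedFormulaDelta, table: ElementMassTable | None = None) -> float:
    """Signed mass shift of a correction term (useful for audits)."""
    table = table or default_mass_table()
    return sum(n * table.monoisotopic(el) for el, n in delta.counts)


def rdbe(f: Formula, table: ElementMassTable | None = None) -> float:
    """Ring-plus-double-bond equivalents, 1 + Σ n_i (v_i - 2) / 2.

    With standard valences (C=4, H=1, N=3, O=2, S=2) divalent O and S drop
    out, matching conventional CHO usage in lignin work; half-integer values
    signal radicals and are returned as-is.
    """
    table = table or default_mass_table()
    val = sum(n * (table.valence(el) - 2) for el, n in f.counts)
    out = 1.0 + val / 2.0
    return int(out) if out == int(out) else out


@dataclass(frozen=True)
class KmdBase:
    """A Kendrick base fragment: its formula, exact mass, and nominal mass."""

    name: str
    formula: Formula
    exact: float
    nominal: int

    @classmethod
    def from_formula(
        cls, name: str, formula: Formula | str, table: ElementMassTable | None = None
    ) -> "KmdBase":
        table = table or default_mass_table()
        if isinstance(formula, str):
            formula = parse_formula(formula)
        exact = exact_mass(formula, table)
        nominal = sum(n * table.nominal(el) for el, n in formula.counts)
        return cls(name=name, formula=formula, exact=exact, nominal=nominal)


# The seven recurring lignin fragments used as Kendrick bases. One of them is
# conventionally dropped (usage varies); all are provided and user-selectable.
KMD_FRAGMENTS = ("CO", "CHO", "CH2O", "CH3O", "CO2", "CHO2", "C5H5O")


def default_kmd_bases(names: Iterable[str] = KMD_FRAGMENTS) -> list[KmdBase]:
    return [KmdBase.from_formula(n, n) for n in names]


def kendrick_mass_defect(mass: float, base: KmdBase, rounding: str = "even") -> float:
    """Kendrick mass defect of ``mass`` rescaled so ``base`` has integer mass.

    KM = mass * nominal(base) / exact(base); KMD = round(KM) - KM. The
    rounding convention is configurable: ``"even"`` (banker's rounding,
    default), ``"floor"`` or ``"ceil"``.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    km = mass * base.nominal / base.exact
    if rounding == "even":
        anchor = round(km)
    elif rounding == "floor":
        import math

        anchor = math.floor(km)
    elif rounding == "ceil":
        import math

        anchor = math.ceil(km)
    else:
        raise ValueError(f"unknown rounding convention {rounding!r}")
    return anchor - km


def atomic_ratio(f: Formula, numerator: str, denominator: str) -> float:
    """Atom-count ratio, e.g. O/C for Van Krevelen-style plots."""
    den = f[denominator]
    if den == 0:
        raise ZeroDivisionError(
            f"denominator element {denominator} absent from {f.hill() or '∅'}"
        )
    return f[numerator] / den
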