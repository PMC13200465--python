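"""Boolean-gated combinatorial growth of linear lignin oligomer libraries.

The generator works on tables, not molecules. An n-mer table (sequences of
degree n, each carrying its molecular formula and the boolean reactivity
state of its endgroup) is crossed against a monomer table under a linkage
rule: rows failing the rule's per-direction prerequisites are filtered out,
the survivors form the full cross product, formulas are added together with
the rule's correction term, and the incoming monomer's flags (minus the
moieties the reaction consumes) become the new endgroup state. Asymmetric
linkages run in both orientations; the resulting mirror twins are kept as
substrates (AAB and BAA grow into different (n+1)-mers) and collapsed only
in the per-degree output view, via the reversal-invariant canonical
identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    Formula,
    SignedFormulaDelta,
    TRACKED_ELEMENTS,
    default_mass_table,
    parse_formula,
)
from .nomenclature import (
    ID_SEPARATOR,
    LinkageToken,
    parse_sequence,
)
from .registry import FLAG_NAMES, QCReport, ResidueTable

__all__ = [
    "LinkageRule",
    "OligomerRecord",
    "Library",
    "load_linkage_table",
    "default_linkage_rules",
    "apply_linkage",
    "remove_mirror_duplicates",
    "grow_library",
    "qc_linkage_rules",
    "enumerate_formula_states",
    "audit_formula_conservation",
]

logger = logging.getLogger("lignoforge.engine")

_ELEMENT_COLS = list(TRACKED_ELEMENTS)
_FLAG_COLS = list(FLAG_NAMES)
_SUBSTRATE_COLS = ["name", "rname", "degree", *_ELEMENT_COLS, *_FLAG_COLS, "alive"]

DEFAULT_ROW_CAP = 50_000_000  # practical in-memory limit on substrate rows


class EngineError(RuntimeError):
    pass


class MemoryGuardError(EngineError):
    """Raised when a growth step would exceed the configured row cap."""


@dataclass(frozen=True)
class LinkageRule:
    """One linkage type and everything needed to apply it.

    ``left_requires``/``right_requires`` are flag names that must all be true
    on the residue playing that vertex; ``*_consumes`` are cleared on the new
    endgroup. In the forward direction the n-mer endgroup plays the left
    vertex and the monomer the right; the reverse direction swaps the roles
    (and the emitted token orientation). ``terminator`` marks the new
    endgroup dead (alive=false), capping the linkage at one per oligomer.
    """

    name: str
    token: LinkageToken
    symmetric: bool
    directions: tuple[str, ...]  # subset of ("forward", "reverse")
    left_requires: tuple[str, ...]
    right_requires: tuple[str, ...]
    left_consumes: tuple[str, ...]
    right_consumes: tuple[str, ...]
    delta: SignedFormulaDelta
    terminator: bool = False

    def __post_init__(self):
        if self.symmetric:
            if self.token.left != self.token.right:
                raise EngineError(
                    f"symmetric rule {self.name} has mismatched vertices "
                    f"{self.token.left}/{self.token.right}"
                )
            if self.directions != ("forward",):
                raise EngineError(
                    f"symmetric rule {self.name} must run in the forward direction only"
                )
        for flag in (*self.left_requires, *self.right_requires,
                     *self.left_consumes, *self.right_consumes):
            if flag not in FLAG_NAMES:
                raise EngineError(f"rule {self.name}: unknown flag name {flag!r}")


@dataclass(frozen=True)
class OligomerRecord:
    """One library entry, materialized from a table row."""

    name: str
    canonical_id: str
    degree: int
    formula: Formula
    endgroup_flags: dict
    exact_mass: float
    rdbe: float


@dataclass
class Library:
    """Per-degree deduplicated tables plus growth provenance.

    ``frames[d]`` holds the unique oligomers of degree d (one row per
    canonical identifier); ``substrate_counts[d]`` is the pre-dedup row count
    actually used as growth substrate, which is what memory costs scale with.
    """

    frames: dict[int, pd.DataFrame]
    config: dict
    substrate_counts: dict[int, int] = field(default_factory=dict)

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(sorted(self.frames))

    @property
    def size(self) -> int:
        return sum(len(f) for f in self.frames.values())

    def frame(self, degree: int) -> pd.DataFrame:
        return self.frames[degree]

    def all_records(self) -> pd.DataFrame:
        return pd.concat(
            [self.frames[d] for d in self.degrees], ignore_index=True
        )

    def records(self, degree: int):
        for row in self.frames[degree].itertuples(index=False):
            yield OligomerRecord(
                name=row.name,
                canonical_id=row.canonical_id,
                degree=int(row.degree),
                formula=Formula({el: int(getattr(row, el)) for el in _ELEMENT_COLS}),
                endgroup_flags={f: bool(getattr(row, f)) for f in _FLAG_COLS},
                exact_mass=float(row.exact_mass),
                rdbe=float(row.rdbe),
            )

    def export(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for d in self.degrees:
            path = directory / f"library_degree_{d}.csv"
            self.frames[d].to_csv(path, index=False)
            written.append(path)
        return written


def _parse_flag_list(text) -> tuple[str, ...]:
    text = "" if text is None or (isinstance(text, float) and np.isnan(text)) else str(text)
    text = text.strip()
    if not text or text.lower() == "nan":
        return ()
    return tuple(t.strip() for t in text.split(";") if t.strip())


def load_linkage_table(path: str | Path | pd.DataFrame) -> list[LinkageRule]:
    """Load linkage rules from CSV (see linkages.csv for the column layout)."""
    frame = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, dtype=str)
    rules = []
    for _, row in frame.iterrows():
        symmetric = str(row["symmetric"]).strip().lower() in ("true", "1")
        directions_text = str(row["directions"]).strip().lower()
        if directions_text == "both":
            directions: tuple[str, ...] = ("forward", "reverse")
        elif directions_text in ("forward", "reverse"):
            directions = (directions_text,)
        else:
            raise EngineError(f"rule {row['name']}: bad directions {directions_text!r}")
        bridge = "" if pd.isna(row["bridge"]) or str(row["bridge"]).strip() in ("", "nan") else str(row["bridge"]).strip()
        delta = SignedFormulaDelta({
            el: int(row[f"delta{el}"]) for el in _ELEMENT_COLS if f"delta{el}" in frame.columns
        })
        rules.append(LinkageRule(
            name=str(row["name"]).strip(),
            token=LinkageToken(str(row["left_vertex"]).strip(), bridge,
                               str(row["right_vertex"]).strip()),
            symmetric=symmetric,
            directions=directions,
            left_requires=_parse_flag_list(row["endgroup_requires"]),
            right_requires=_parse_flag_list(row["monomer_requires"]),
            left_consumes=_parse_flag_list(row["endgroup_consumes"]),
            right_consumes=_parse_flag_list(row["monomer_consumes"]),
            delta=delta,
            terminator=str(row["terminator"]).strip().lower() in ("true", "1"),
        ))
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise EngineError("duplicate rule names in linkage table")
    return rules


def default_linkage_rules() -> list[LinkageRule]:
    """The seven conventional linkages (β-O-4, α-O-4, β-β, β-5, 5-5, 5-O-4, β-1)."""
    from importlib import resources

    with resources.files("lignoforge.data").joinpath("linkages.csv").open() as fh:
        return load_linkage_table(pd.read_csv(fh, dtype=str))


def _monomer_frame(monomers: ResidueTable) -> pd.DataFrame:
    rows = []
    for rec in monomers:
        d = rec.formula.as_dict()
        rows.append({
            "name": rec.symbol,
            "rname": rec.symbol,
            "degree": 1,
            **{el: d.get(el, 0) for el in _ELEMENT_COLS},
            **rec.flags(),
            "alive": rec.alive,
        })
    return pd.DataFrame(rows, columns=_SUBSTRATE_COLS)


def _require_mask(frame: pd.DataFrame, flags: Sequence[str]) -> pd.Series:
    mask = pd.Series(True, index=frame.index)
    for flag in flags:
        mask &= frame[flag].astype(bool)
    return mask


def apply_linkage(
    nmers: pd.DataFrame,
    monomers: ResidueTable | pd.DataFrame,
    rule: LinkageRule,
    direction: str = "forward",
    row_cap: int = DEFAULT_ROW_CAP,
) -> pd.DataFrame:
    """Extend every eligible n-mer by every eligible monomer under one rule.

    Returns the (n+1)-mer substrate table; runtime and memory are linear in
    the number of product rows.
    """
    if direction not in rule.directions:
        raise EngineError(f"rule {rule.name} does not permit direction {direction!r}")
    if direction == "forward":
        end_req, mono_req = rule.left_requires, rule.right_requires
        consumed = rule.right_consumes
        token = rule.token
    else:
        end_req, mono_req = rule.right_requires, rule.left_requires
        consumed = rule.left_consumes
        token = rule.token.reversed()

    mono = monomers if isinstance(monomers, pd.DataFrame) else _monomer_frame(monomers)
    left = nmers[nmers["alive"].astype(bool) & _require_mask(nmers, end_req)]
    right = mono[mono["alive"].astype(bool) & _require_mask(mono, mono_req)]
    n_products = len(left) * len(right)
    if n_products == 0:
        return pd.DataFrame(columns=_SUBSTRATE_COLS)
    if n_products > row_cap:
        raise MemoryGuardError(
            f"rule {rule.name} ({direction}) would produce {n_products} rows "
            f"(cap {row_cap})"
        )

    tok = token.serialize()
    rtok = token.reversed().serialize()
    nl, nr = len(left), len(right)
    li = np.repeat(np.arange(nl), nr)
    ri = np.tile(np.arange(nr), nl)

    out = pd.DataFrame({
        "name": left["name"].to_numpy()[li] + tok + right["name"].to_numpy()[ri],
        "rname": right["name"].to_numpy()[ri] + rtok + left["rname"].to_numpy()[li],
        "degree": left["degree"].to_numpy()[li] + 1,
    })
    for el in _ELEMENT_COLS:
        out[el] = (
            left[el].to_numpy()[li] + right[el].to_numpy()[ri] + rule.delta[el]
        )
        if (out[el] < 0).any():
            bad = out.loc[out[el] < 0, "name"].iloc[0]
            raise EngineError(
                f"rule {rule.name}: correction term drives {el} negative for {bad}"
            )
    for flag in _FLAG_COLS:
        vals = right[flag].to_numpy()[ri]
        out[flag] = False if flag in consumed else vals
    out["alive"] = not rule.terminator
    return out[_SUBSTRATE_COLS]


def _with_ids(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    fwd = frame["name"].to_numpy()
    rev = frame["rname"].to_numpy()
    lo = np.minimum(fwd, rev)
    hi = np.maximum(fwd, rev)
    frame["canonical_id"] = lo + ID_SEPARATOR + hi
    return frame


def remove_mirror_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one row per canonical identifier.

    The survivor is the row whose forward name is the lexicographic minimum
    of its mirror pair; palindromes are untouched and the operation is
    idempotent.
    """
    if "canonical_id" not in frame.columns:
        frame = _with_ids(frame)
    out = frame.sort_values("name", kind="mergesort")
    out = out.drop_duplicates("canonical_id", keep="first")
    return out.sort_values("name", kind="mergesort").reset_index(drop=True)


def _finalize_view(frame: pd.DataFrame) -> pd.DataFrame:
    """Dedup a substrate table and attach formula string, mass and RDBE."""
    table = default_mass_table()
    cols = ["name", "canonical_id", "degree", "formula", "exact_mass", "rdbe",
            *_ELEMENT_COLS, *_FLAG_COLS, "alive"]
    if not len(frame):
        return pd.DataFrame(columns=cols)
    out = remove_mirror_duplicates(_with_ids(frame))
    mass = np.zeros(len(out))
    val = np.zeros(len(out))
    for el in _ELEMENT_COLS:
        mass += out[el].to_numpy(dtype=float) * table.monoisotopic(el)
        val += out[el].to_numpy(dtype=float) * (table.valence(el) - 2)
    # vectorized Hill-order formula strings (C, H, then alphabetical)
    formula = np.full(len(out), "", dtype=object)
    for el in ("C", "H", "N", "O", "S"):
        n = out[el].to_numpy()
        part = np.where(n == 0, "", np.where(n == 1, el, el + n.astype(str).astype(object)))
        formula = formula + part
    out["formula"] = formula
    out["exact_mass"] = mass
    out["rdbe"] = 1.0 + val / 2.0
    return out[cols]


def grow_library(
    residues: ResidueTable,
    rules: Iterable[LinkageRule],
    max_degree: int,
    row_cap: int = DEFAULT_ROW_CAP,
) -> Library:
    """Grow the exhaustive library of unique linear oligomers up to ``max_degree``.

    Starts from the selected residues as 1-mers and applies every rule in
    every allowed direction per degree. Substrate tables retain mirror
    orientations (they seed different extensions); each degree's output view
    is deduplicated once that degree is no longer needed as a substrate.
    """
    rules = list(rules)
    if len(residues) == 0:
        raise EngineError("empty residue selection")
    if max_degree < 2:
        raise EngineError("max_degree must be at least 2")

    substrate = _monomer_frame(residues)
    monomers = substrate
    views: dict[int, pd.DataFrame] = {}
    substrate_counts = {1: len(substrate)}
    for degree in range(1, max_degree):
        pieces = []
        for rule in rules:
            for direction in rule.directions:
                piece = apply_linkage(substrate, monomers, rule, direction, row_cap=row_cap)
                if len(piece):
                    pieces.append(piece)
                logger.debug(
                    "degree %d -> %d: rule %s (%s) produced %d rows",
                    degree, degree + 1, rule.name, direction, len(piece),
                )
        nxt = (
            pd.concat(pieces, ignore_index=True)
            if pieces else pd.DataFrame(columns=_SUBSTRATE_COLS)
        )
        if len(nxt) > row_cap:
            raise MemoryGuardError(
                f"degree {degree + 1} substrate would hold {len(nxt)} rows (cap {row_cap})"
            )
        # degree's view is finalized only now that degree+1 substrates exist
        views[degree] = _finalize_view(substrate)
        substrate_counts[degree + 1] = len(nxt)
        logger.info(
            "degree %d: %d unique oligomers (%d substrate rows); degree %d substrates: %d",
            degree, len(views[degree]), len(substrate), degree + 1, len(nxt),
        )
        substrate = nxt
    views[max_degree] = _finalize_view(substrate)
    logger.info("degree %d: %d unique oligomers (%d substrate rows)",
                max_degree, len(views[max_degree]), len(substrate))

    return Library(
        frames=views,
        config={
            "residues": list(residues.symbols),
            "rules": [r.name for r in rules],
            "max_degree": max_degree,
            "row_cap": row_cap,
        },
        substrate_counts=substrate_counts,
    )


def qc_linkage_rules(rules: Iterable[LinkageRule], residues: ResidueTable) -> QCReport:
    """Static checks on a rule set against a registry; violations as report entries."""
    report = QCReport()
    recs = list(residues)
    for rule in rules:
        ref = rule.name
        # delta must keep every registry pair non-negative
        for a in recs:
            for b in recs:
                combined = {el: a.formula[el] + b.formula[el] + rule.delta[el]
                            for el in _ELEMENT_COLS}
                bad = [el for el, n in combined.items() if n < 0]
                if bad:
                    report.add(
                        "error", ref,
                        f"correction term drives {','.join(bad)} negative for "
                        f"{a.symbol}+{b.symbol}",
                    )
        if rule.symmetric and rule.token.left != rule.token.right:
            report.add("error", ref, "symmetric rule with mismatched vertices")
        if rule.terminator and "reverse" in rule.directions:
            report.add("warning", ref, "terminator rule running in reverse direction")
    return report


def enumerate_formula_states(
    residues: ResidueTable,
    rules: Iterable[LinkageRule],
    max_degree: int,
) -> dict[int, set[tuple]]:
    """Per-degree reachable (formula, endgroup-flag, alive) states.

    Extension eligibility depends only on the endgroup state, so the set of
    formulas reachable at each degree — and hence every formula-level summary
    such as RDBE extrema — is identical to the full library's, at a state
    count that stays tiny. States are tuples
    ``(C, H, N, O, S, *flags, alive)``.
    """
    rules = list(rules)
    mono_states = []
    for rec in residues:
        d = rec.formula.as_dict()
        mono_states.append((
            *(d.get(el, 0) for el in _ELEMENT_COLS),
            *(rec.flags()[f] for f in _FLAG_COLS),
            rec.alive,
        ))
    n_el = len(_ELEMENT_COLS)
    flag_index = {f: n_el + i for i, f in enumerate(_FLAG_COLS)}

    def eligible(state, required):
        return state[-1] and all(state[flag_index[f]] for f in required)

    def mono_eligible(state, required):
        return all(state[flag_index[f]] for f in required)

    levels: dict[int, set[tuple]] = {1: set(mono_states)}
    for degree in range(1, max_degree):
        nxt: set[tuple] = set()
        for state in levels[degree]:
            for rule in rules:
                for direction in rule.directions:
                    end_req = rule.left_requires if direction == "forward" else rule.right_requires
                    mono_req = rule.right_requires if direction == "forward" else rule.left_requires
                    consumed = rule.right_consumes if direction == "forward" else rule.left_consumes
                    if not eligible(state, end_req):
                        continue
                    for mono in mono_states:
                        if not mono_eligible(mono, mono_req):
                            continue
                        counts = tuple(
                            state[i] + mono[i] + rule.delta[_ELEMENT_COLS[i]]
                            for i in range(n_el)
                        )
                        if any(c < 0 for c in counts):
                            raise EngineError(
                                f"rule {rule.name}: negative formula in state enumeration"
                            )
                        flags = tuple(
                            False if _FLAG_COLS[i] in consumed else mono[n_el + i]
                            for i in range(len(_FLAG_COLS))
                        )
                        nxt.add((*counts, *flags, not rule.terminator))
        levels[degree + 1] = nxt
    return levels


def _token_delta_map(rules: Iterable[LinkageRule]) -> dict[str, SignedFormulaDelta]:
    mapping: dict[str, SignedFormulaDelta] = {}
    for rule in rules:
        for tok in (rule.token, rule.token.reversed()):
            key = tok.serialize()
            if key in mapping and mapping[key].counts != rule.delta.counts:
                raise EngineError(f"ambiguous token {key}: conflicting deltas")
            mapping[key] = rule.delta
    return mapping


def audit_formula_conservation(
    frame: pd.DataFrame,
    residues: ResidueTable,
    rules: Iterable[LinkageRule],
) -> list[str]:
    """Re-parse every name and recompute its formula from scratch.

    Returns the names whose tracked formula disagrees with Σ residue formulas
    + Σ linkage correction terms — empty on a healthy library.
    """
    deltas = _token_delta_map(rules)
    mismatches = []
    for row in frame.itertuples(index=False):
        seq = parse_sequence(row.name, residues)
        expected = {el: 0 for el in _ELEMENT_COLS}
        for symbol in seq.residues:
            for el, n in residues[symbol].formula.counts:
                expected[el] += n
        for tok in seq.tokens:
            delta = deltas[tok.serialize()]
            for el in _ELEMENT_COLS:
                expected[el] += delta[el]
        actual = {el: int(getattr(row, el)) for el in _ELEMENT_COLS}
        if any(expected[el] != actual[el] for el in _ELEMENT_COLS):
            mismatches.append(row.name)
    return mismatches
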