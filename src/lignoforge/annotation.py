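"""HRMS suspect lists from libraries, feature matching, isomer statistics.

A grown library collapses into a compact suspect list — one row per unique
exact neutral mass — because lignin oligomers are massively isomeric: many
constitutions share one formula. Feature m/z values (after adduct
arithmetic) are matched against the list within a ppm or mDa tolerance, and
the isomer count behind each matched mass drives the annotation-confidence
sublevel: a level-3 (tentative candidate) match with one library isomer is a
different claim than one with two thousand.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import Library

__all__ = [
    "load_adduct_table",
    "build_suspect_list",
    "match_features",
    "isomer_statistics",
    "assign_confidence_sublevel",
    "DEFAULT_SUBLEVEL_BINS",
]

# isomer-count bins -> Schymanski level-3 sublevels; deliberately per-study
# configuration, these are the package defaults.
DEFAULT_SUBLEVEL_BINS: tuple[tuple[int, str], ...] = ((1, "3a"), (20, "3b"))
DEFAULT_SUBLEVEL_OVERFLOW = "3c"

MAX_EXAMPLE_NAMES = 3


class AnnotationError(ValueError):
    pass


def load_adduct_table(path: str | Path | None = None) -> pd.DataFrame:
    """Adduct definitions: label, charge, mass shift (Da).

    Neutral mass is recovered as ``m/z * |charge| - mass_shift``; the
    packaged table ships [M+H]+, [M+Na]+ and [M-H]-.
    """
    if path is None:
        with resources.files("lignoforge.data").joinpath("adducts.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    required = {"label", "charge", "mass_shift"}
    if required - set(frame.columns):
        raise AnnotationError(f"adduct table needs columns {sorted(required)}")
    return frame


def build_suspect_list(
    library: Library | pd.DataFrame, mass_decimals: int = 4
) -> pd.DataFrame:
    """Group library records by rounded exact mass into unique suspect entries.

    Returns a frame ordered by mass with columns ``mass`` (the rounded key),
    ``isomer_count``, ``degrees`` (semicolon-joined) and ``examples`` (up to
    three sequence names). Isomer counts partition the library: they sum to
    its size.
    """
    frame = library.all_records() if isinstance(library, Library) else library
    if not len(frame):
        raise AnnotationError("empty library")
    key = frame["exact_mass"].round(mass_decimals)
    grouped = frame.assign(mass=key).groupby("mass", sort=True)
    out = grouped.agg(
        isomer_count=("name", "size"),
        degrees=("degree", lambda s: ";".join(str(d) for d in sorted(set(s)))),
        examples=("name", lambda s: ";".join(sorted(s)[:MAX_EXAMPLE_NAMES])),
    ).reset_index()
    return out


def match_features(
    features: pd.DataFrame,
    suspects: pd.DataFrame,
    tolerance: float = 3.0,
    unit: str = "ppm",
    adducts: pd.DataFrame | None = None,
    default_adduct: str = "[M+H]+",
    sublevel_bins=DEFAULT_SUBLEVEL_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match feature m/z values against a suspect list.

    Every suspect within tolerance is reported per feature, nearest first,
    with mass errors in both ppm and mDa and a confidence sublevel from the
    suspect's isomer count. Returns ``(matches, unmatched_features)``.
    ``tolerance`` is interpreted in ``unit`` ("ppm" or "mda").
    """
    if tolerance <= 0:
        raise AnnotationError("tolerance must be positive")
    if unit not in ("ppm", "mda"):
        raise AnnotationError(f"unknown tolerance unit {unit!r}")
    if "mz" not in features.columns:
        raise AnnotationError("feature table needs an 'mz' column")
    if (features["mz"] <= 0).any():
        raise AnnotationError("non-positive m/z in feature table")
    adducts = load_adduct_table() if adducts is None else adducts
    shift = adducts.set_index("label")["mass_shift"].to_dict()
    charge = adducts.set_index("label")["charge"].to_dict()

    feats = features.reset_index(drop=True).copy()
    if "adduct" not in feats.columns:
        feats["adduct"] = default_adduct
    feats["adduct"] = feats["adduct"].fillna(default_adduct)
    unknown = set(feats["adduct"]) - set(shift)
    if unknown:
        raise AnnotationError(f"unknown adducts {sorted(unknown)}")
    z = feats["adduct"].map(charge).abs().to_numpy()
    feats["neutral_mass"] = feats["mz"].to_numpy() * z - feats["adduct"].map(shift).to_numpy()

    suspect_mass = suspects["mass"].to_numpy()
    order = np.argsort(suspect_mass)
    sm = suspect_mass[order]

    rows = []
    matched_idx = set()
    for i, row in feats.iterrows():
        m = row["neutral_mass"]
        tol_da = m * tolerance * 1e-6 if unit == "ppm" else tolerance * 1e-3
        lo = np.searchsorted(sm, m - tol_da, side="left")
        hi = np.searchsorted(sm, m + tol_da, side="right")
        for j in order[lo:hi]:
            s = suspects.iloc[j]
            err_da = m - s["mass"]
            count = int(s["isomer_count"])
            rows.append({
                "feature_index": i,
                "mz": row["mz"],
                "adduct": row["adduct"],
                "neutral_mass": m,
                "suspect_mass": s["mass"],
                "error_mda": err_da * 1e3,
                "error_ppm": err_da / s["mass"] * 1e6,
                "isomer_count": count,
                "degrees": s["degrees"],
                "sublevel": assign_confidence_sublevel(count, sublevel_bins),
            })
            matched_idx.add(i)
    matches = pd.DataFrame(rows, columns=[
        "feature_index", "mz", "adduct", "neutral_mass", "suspect_mass",
        "error_mda", "error_ppm", "isomer_count", "degrees", "sublevel",
    ])
    if len(matches):
        matches = (
            matches.assign(_abs=matches["error_ppm"].abs())
            .sort_values(["feature_index", "_abs"], kind="mergesort")
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
    unmatched = feats.loc[~feats.index.isin(matched_idx)].reset_index(drop=True)
    return matches, unmatched


def isomer_statistics(
    library: Library | pd.DataFrame, mass_decimals: int = 4
) -> pd.DataFrame:
    """Per-degree mean, SD and relative SD (%) of isomers per unique mass.

    SD is the sample standard deviation (ddof=1; 0 for a single mass).
    """
    frame = library.all_records() if isinstance(library, Library) else library
    if not len(frame):
        raise AnnotationError("empty library")
    key = frame["exact_mass"].round(mass_decimals)
    counts = (
        frame.assign(mass=key)
        .groupby(["degree", "mass"], sort=True)
        .size()
        .rename("isomers")
        .reset_index()
    )
    rows = []
    for degree, grp in counts.groupby("degree"):
        values = grp["isomers"].to_numpy(dtype=float)
        mean = values.mean()
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        rows.append({
            "degree": int(degree),
            "unique_masses": len(values),
            "mean_isomers": mean,
            "sd_isomers": sd,
            "rsd_percent": 100.0 * sd / mean if mean else float("nan"),
        })
    return pd.DataFrame(rows)


def assign_confidence_sublevel(
    isomer_count: int,
    bins: Mapping[int, str] | tuple[tuple[int, str], ...] = DEFAULT_SUBLEVEL_BINS,
    overflow: str = DEFAULT_SUBLEVEL_OVERFLOW,
) -> str:
    """Confidence sublevel from an isomer count via configured upper bounds.

    Defaults: 1 candidate -> "3a", 2-20 -> "3b", >20 -> "3c".
    """
    if isomer_count < 1:
        raise AnnotationError(f"isomer count must be >= 1, got {isomer_count}")
    items = sorted(dict(bins).items()) if isinstance(bins, Mapping) else sorted(bins)
    for upper, label in items:
        if isomer_count <= upper:
            return label
    return overflow
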