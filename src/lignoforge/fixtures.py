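"""Demo inputs and synthetic data so every workflow runs without downloads.

The packaged registry stands in for the (much larger) residue databases used
in practice: the three canonical monolignol residues, their aldehyde and acid
side-chain variants, and the vanillin residue, together with the seven
conventional linkage rules. The synthetic feature generator emulates a
positive-mode HRMS feature table drawn from a library — Gaussian ppm mass
noise around [M+H]+ ions plus decoy masses placed well outside any sensible
tolerance.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Library

__all__ = [
    "make_demo_inputs",
    "conventional_monolignols",
    "generate_synthetic_features",
]

_PACKAGED = ("residues.csv", "linkages.csv", "adducts.csv",
             "chain_snippets.csv", "substituents.csv", "elements.csv")

# the highly conventional H/G/S selection used in the worked examples
CONVENTIONAL_RESIDUES = ("HYpeol", "GUpeol", "SYpeol")


def conventional_monolignols():
    """The H/G/S monolignol subset of the demo registry."""
    from .registry import default_residue_table

    return default_residue_table().subset(CONVENTIONAL_RESIDUES)


def make_demo_inputs(directory: str | Path) -> list[Path]:
    """Write the packaged demo CSVs into ``directory`` (deterministic bytes)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _PACKAGED:
        text = resources.files("lignoforge.data").joinpath(name).read_text()
        path = directory / name
        path.write_text(text)
        written.append(path)
    return written


def generate_synthetic_features(
    library: Library | pd.DataFrame,
    n: int,
    noise_ppm: float = 1.0,
    n_decoys: int = 0,
    seed: int = 0,
    adduct: str = "[M+H]+",
    decoy_offset_da: float = 0.05,
    replace: bool = False,
) -> pd.DataFrame:
    """Sample a reproducible synthetic feature table from a library.

    ``n`` library masses are drawn (without replacement unless ``replace``),
    converted to m/z under ``adduct``, and perturbed with Gaussian mass noise
    of ``noise_ppm`` ppm (1 ppm is a typical well-calibrated TOF figure).
    ``n_decoys`` extra features are offset by at least ``decoy_offset_da``
    (default 0.05 Da, > 10x any ppm-scale tolerance at lignin masses) so they
    must never match. The ``is_decoy`` column carries ground truth.
    """
    from .annotation import load_adduct_table

    frame = library.all_records() if isinstance(library, Library) else library
    masses = frame["exact_mass"].to_numpy()
    unique = np.unique(masses)
    if n > len(unique) and not replace:
        raise ValueError(
            f"cannot draw {n} distinct masses from {len(unique)} without replacement"
        )
    rng = np.random.default_rng(seed)
    adducts = load_adduct_table()
    row = adducts.loc[adducts["label"] == adduct]
    if not len(row):
        raise ValueError(f"unknown adduct {adduct!r}")
    shift = float(row["mass_shift"].iloc[0])
    z = abs(int(row["charge"].iloc[0]))

    drawn = rng.choice(unique, size=n, replace=replace)
    mz = (drawn + shift) / z
    mz = mz * (1.0 + rng.normal(0.0, noise_ppm * 1e-6, size=n))
    records = [
        {"mz": float(v), "adduct": adduct, "intensity": float(i), "is_decoy": False}
        for v, i in zip(mz, rng.lognormal(10.0, 1.0, size=n))
    ]
    if n_decoys:
        base = rng.choice(unique, size=n_decoys, replace=True)
        signs = rng.choice([-1.0, 1.0], size=n_decoys)
        offsets = signs * (decoy_offset_da + rng.uniform(0.0, 0.02, size=n_decoys))
        dmz = (base + offsets + shift) / z
        records += [
            {"mz": float(v), "adduct": adduct, "intensity": float(i), "is_decoy": True}
            for v, i in zip(dmz, rng.lognormal(9.0, 1.0, size=n_decoys))
        ]
    return pd.DataFrame(records)
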