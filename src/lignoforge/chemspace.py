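"""Chemical-space metrics over libraries: RDBE/DP tables, KMD-PCA, ellipses.

Exhaustive libraries have hard chemical-space boundaries, which makes them
useful for validating degree-of-polymerisation (DP) classifiers: the
per-degree RDBE extrema say exactly which RDBE values are ambiguous between
degrees, and 95% confidence ellipses in KMD-PCA or RDBE-vs-O/C coordinates
visualize where degrees start to overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem_core import KmdBase, kendrick_mass_defect
from .engine import Library, enumerate_formula_states, LinkageRule
from .registry import ResidueTable

__all__ = [
    "DpRangeTable",
    "EllipseParams",
    "dp_rdbe_table",
    "dp_rdbe_table_from_states",
    "kmd_pca_scores",
    "group_ellipse",
    "ellipses_overlap",
    "classify_dp_by_rdbe",
    "rdbe_oc_table",
]


@dataclass(frozen=True)
class DpRangeTable:
    """Per-degree RDBE extrema and record counts."""

    rows: tuple[tuple[int, float, float, int], ...]  # (degree, min, max, count)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["degree", "rdbe_min", "rdbe_max", "count"])

    def range_for(self, degree: int) -> tuple[float, float]:
        for d, lo, hi, _ in self.rows:
            if d == degree:
                return lo, hi
        raise KeyError(f"degree {degree} not in table")

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(r[0] for r in self.rows)


def dp_rdbe_table(library: Library) -> DpRangeTable:
    """Exact per-degree RDBE extrema and counts from a grown library."""
    rows = []
    for d in library.degrees:
        frame = library.frame(d)
        if not len(frame):
            continue
        rdbe = frame["rdbe"]
        rows.append((d, float(rdbe.min()), float(rdbe.max()), int(len(frame))))
    return DpRangeTable(tuple(rows))


def dp_rdbe_table_from_states(
    residues: ResidueTable,
    rules: Iterable[LinkageRule],
    max_degree: int,
) -> DpRangeTable:
    """RDBE extrema from the reachable (formula, endgroup-state) sets.

    Equivalent to :func:`dp_rdbe_table` on the full library — growth
    eligibility depends only on the endgroup state, so the same formulas are
    reachable — but runs in seconds regardless of library size. Counts are
    state counts, not oligomer counts.
    """
    from .chem_core import TRACKED_ELEMENTS, default_mass_table

    table = default_mass_table()
    levels = enumerate_formula_states(residues, rules, max_degree)
    rows = []
    for d in sorted(levels):
        states = levels[d]
        if not states:
            continue
        values = []
        for state in states:
            val = sum(
                state[i] * (table.valence(el) - 2)
                for i, el in enumerate(TRACKED_ELEMENTS)
            )
            values.append(1.0 + val / 2.0)
        rows.append((d, min(values), max(values), len(states)))
    return DpRangeTable(tuple(rows))


def kmd_pca_scores(
    library: Library | pd.DataFrame,
    bases: Sequence[KmdBase],
    standardize: bool = True,
    rounding: str = "even",
):
    """PCA of the per-record KMD matrix (records x Kendrick bases).

    Columns are mean-centered and (by default) scaled to unit variance before
    the eigendecomposition; zero-variance columns are dropped with a warning
    in the returned metadata. Returns ``(scores, loadings, explained_ratio,
    kept_bases)``.
    """
    if len(bases) < 2:
        raise ValueError("need at least 2 Kendrick bases")
    frame = library.all_records() if isinstance(library, Library) else library
    if len(frame) < 3:
        raise ValueError("need at least 3 records")
    masses = frame["exact_mass"].to_numpy()
    kmd = np.column_stack([
        [kendrick_mass_defect(m, base, rounding=rounding) for m in masses]
        for base in bases
    ])
    std = kmd.std(axis=0, ddof=1)
    keep = std > 1e-12
    kept = [b for b, k in zip(bases, keep) if k]
    if len(kept) < 2:
        raise ValueError("fewer than 2 Kendrick bases with non-zero variance")
    x = kmd[:, keep] - kmd[:, keep].mean(axis=0)
    if standardize:
        x = x / std[keep]
    # deterministic full eigendecomposition of the covariance
    cov = np.cov(x, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = x @ eigvec
    explained = eigval / eigval.sum()
    return scores, eigvec, explained, kept


@dataclass(frozen=True)
class EllipseParams:
    """Confidence ellipse of a bivariate sample under a normal model."""

    center: tuple[float, float]
    covariance: tuple[tuple[float, float], tuple[float, float]]
    level: float
    radius_sq: float  # chi-square quantile, 2 degrees of freedom
    degenerate: bool = False

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(points) - np.asarray(self.center)
        inv = np.linalg.inv(np.asarray(self.covariance))
        return np.einsum("ij,jk,ik->i", diff, inv, diff)

    def boundary(self, n: int = 720) -> np.ndarray:
        """Dense angular sampling of the ellipse boundary."""
        cov = np.asarray(self.covariance)
        eigval, eigvec = np.linalg.eigh(cov)
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        axes = np.sqrt(np.maximum(eigval, 0.0) * self.radius_sq)
        return np.asarray(self.center) + (circle * axes) @ eigvec.T


def group_ellipse(points: np.ndarray, level: float = 0.95) -> EllipseParams:
    """Confidence ellipse: sample mean, sample covariance, chi2(level, df=2) radius."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(points) < 3:
        raise ValueError("need at least 3 points for a covariance ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12) < 2)
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        covariance=((float(cov[0, 0]), float(cov[0, 1])),
                    (float(cov[1, 0]), float(cov[1, 1]))),
        level=level,
        radius_sq=float(stats.chi2.ppf(level, df=2)),
        degenerate=degenerate,
    )


def ellipses_overlap(e1: EllipseParams, e2: EllipseParams, n: int = 720,
                     tol: float = 1e-9) -> bool:
    """True iff the two ellipses' interiors or boundaries intersect.

    Decided by containment checks plus dense angular sampling of each
    boundary against the other's Mahalanobis form.
    """
    for e in (e1, e2):
        if e.degenerate:
            raise ValueError("cannot test overlap with a degenerate ellipse")
    c1 = np.asarray(e1.center)[None, :]
    c2 = np.asarray(e2.center)[None, :]
    if e2.mahalanobis_sq(c1)[0] <= e2.radius_sq + tol:
        return True
    if e1.mahalanobis_sq(c2)[0] <= e1.radius_sq + tol:
        return True
    if (e2.mahalanobis_sq(e1.boundary(n)) <= e2.radius_sq + tol).any():
        return True
    if (e1.mahalanobis_sq(e2.boundary(n)) <= e1.radius_sq + tol).any():
        return True
    return False


def classify_dp_by_rdbe(rdbe_value: float, ranges: DpRangeTable) -> set[int]:
    """All degrees whose [min, max] RDBE window contains the value."""
    return {
        d for d, lo, hi, _ in ranges.rows if lo <= rdbe_value <= hi
    }


def rdbe_oc_table(library: Library) -> pd.DataFrame:
    """Per-record (rdbe, o_c_ratio, degree) scatter export for plotting."""
    frame = library.all_records()
    if (frame["C"] == 0).any():
        raise ValueError("records without carbon cannot have an O/C ratio")
    return pd.DataFrame({
        "name": frame["name"],
        "degree": frame["degree"],
        "rdbe": frame["rdbe"],
        "o_c_ratio": frame["O"] / frame["C"],
    })


def plot_rdbe_oc(library: Library, path, level: float = 0.95):  # pragma: no cover
    """RDBE vs O/C scatter with per-degree confidence ellipses (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = rdbe_oc_table(library)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for d, grp in table.groupby("degree"):
        pts = grp[["o_c_ratio", "rdbe"]].to_numpy()
        ax.scatter(pts[:, 0], pts[:, 1], s=6, label=f"DP {d}")
        if len(pts) >= 3:
            ell = group_ellipse(pts, level=level)
            if not ell.degenerate:
                b = ell.boundary(360)
                ax.plot(b[:, 0], b[:, 1], lw=1)
    ax.set_xlabel("O/C atom ratio")
    ax.set_ylabel("RDBE")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
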