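"""Molecule × molecule similarity matrices from z-scored descriptor tables.

The similarity matrix ``Mcorr`` holds the pairwise correlation between the
*molecules'* scaled descriptor vectors — i.e. correlations between rows of
the scaled table, not between descriptors. Pearson is the default and the
method used downstream for clustering; Kendall and Spearman are available
for comparison. Secondary summaries derived from the matrix: pairs above a
similarity threshold, and per-molecule boxplot-style correlation profiles
with 1.5·IQR outlier detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import ScaledTable

_METHODS = ("pearson", "kendall", "spearman")


class SimilarityError(ValueError):
    """Raised on invalid inputs to similarity computations."""


@dataclass
class SimilarityMatrix:
    """Square molecule × molecule correlation matrix with provenance tags."""

    values: pd.DataFrame  # square, index == columns == molecule ids
    method: str
    source_block: str = "BOTH"

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)

    def to_long_csv(self, path: str | Path) -> None:
        """Write the upper triangle as long-format rows (id_i, id_j, rho)."""
        rows = []
        ids = self.ids
        arr = self.values.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], arr[i, j]))
        pd.DataFrame(rows, columns=["id_i", "id_j", "rho"]).to_csv(path, index=False)


@dataclass
class CorrelationProfile:
    """Five-number boxplot summary of one molecule's correlation row."""

    molecule: str
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[tuple[str, float]]  # (partner id, rho) outside the fences

    def to_dict(self) -> dict:
        return {
            "molecule": self.molecule,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": [{"partner": p, "rho": r} for p, r in self.outliers],
        }


def pearson_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two molecules' descriptor vectors.

    Raises on length mismatch, length < 2, or a zero-variance vector (the
    coefficient is undefined there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SimilarityError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise SimilarityError("need at least 2 descriptors")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise SimilarityError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def similarity_matrix(
    scaled: ScaledTable, method: str = "pearson", source_block: str | None = None
) -> SimilarityMatrix:
    """Build Mcorr: pairwise molecule correlations over descriptors.

    The scaled table is transposed so that molecules become columns, then the
    chosen rank or product-moment correlation is taken between those columns.

    Raises if any molecule has a constant descriptor vector (its correlation
    with anything is undefined).
    """
    if method not in _METHODS:
        raise SimilarityError(f"unknown method {method!r}; expected one of {_METHODS}")
    if scaled.n_molecules < 2 or scaled.n_descriptors < 2:
        raise SimilarityError("need at least 2 molecules and 2 descriptors")
    spans = scaled.data.max(axis=1) - scaled.data.min(axis=1)
    flat = spans[spans == 0].index.tolist()
    if flat:
        raise SimilarityError(f"molecules with constant descriptor vector: {flat}")
    mat = scaled.data.T.corr(method=method)
    mat = (mat + mat.T) / 2.0  # enforce exact symmetry against float noise
    np.fill_diagonal(mat.values, 1.0)
    block = source_block
    if block is None:
        tags = set(scaled.blocks)
        block = tags.pop() if len(tags) == 1 else "BOTH"
    return SimilarityMatrix(values=mat, method=method, source_block=block)


def threshold_pairs(
    m: SimilarityMatrix, tau: float
) -> list[tuple[str, str, float]]:
    """All unordered off-diagonal pairs with similarity ≥ tau, sorted by descending rho."""
    if not -1.0 <= tau <= 1.0:
        raise SimilarityError(f"tau must be in [-1, 1], got {tau}")
    ids = m.ids
    arr = m.values.to_numpy()
    pairs = [
        (ids[i], ids[j], float(arr[i, j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if arr[i, j] >= tau
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs


def correlation_profile(
    m: SimilarityMatrix, include_diagonal: bool = False
) -> list[CorrelationProfile]:
    """Boxplot-style summary of each molecule's correlation row.

    Quartiles use linear interpolation; outliers are values outside
    [Q1 − 1.5·IQR, Q3 + 1.5·IQR], and the whiskers are the most extreme
    values inside those fences. With ``include_diagonal`` the molecule's
    self-correlation of 1.0 participates — this is how reference molecules
    whose row is otherwise weakly correlated show up as lone upper outliers.
    """
    if m.n < 5:
        raise SimilarityError("need at least 5 molecules for meaningful quartiles")
    ids = m.ids
    arr = m.values.to_numpy()
    profiles = []
    for i, mol in enumerate(ids):
        partners = list(ids)
        row = arr[i].copy()
        if not include_diagonal:
            row = np.delete(row, i)
            partners = partners[:i] + partners[i + 1:]
        q1, med, q3 = np.percentile(row, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = row[(row >= lo_fence) & (row <= hi_fence)]
        outliers = [
            (partners[j], float(row[j]))
            for j in range(len(row))
            if row[j] < lo_fence or row[j] > hi_fence
        ]
        profiles.append(
            CorrelationProfile(
                molecule=mol,
                median=float(med), q1=float(q1), q3=float(q3),
                whisker_low=float(inside.min()), whisker_high=float(inside.max()),
                outliers=outliers,
            )
        )
    return profiles


def profiles_to_json(profiles: list[CorrelationProfile], path: str | Path) -> None:
    Path(path).write_text(json.dumps([p.to_dict() for p in profiles], indent=2))
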