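"""Molecule × descriptor tables: reading, validation, block selection, z-scaling.

The central container is :class:`DescriptorTable`, a validated rectangular
table of molecules (rows) by numeric descriptors (columns). Each descriptor
carries a *block* tag — ``ADMET`` for pharmacokinetic/safety descriptors,
``ES`` for electronic-structure descriptors (orbital energies, charges,
volume, ...), or ``OTHER`` — and each molecule may carry an optional class
label (e.g. "cannabinoid", "classical AChEI").

Because descriptor blocks mix wildly different units (kcal/mol, eV, g/mol,
unitless counts), every downstream analysis operates on the z-scored table
produced by :func:`scale`, which records the per-descriptor mean and standard
deviation so the transformation is invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

VALID_BLOCKS = ("ADMET", "ES", "OTHER")


class DescriptorTableError(ValueError):
    """Raised when a descriptor table violates its invariants."""


@dataclass
class DescriptorTable:
    """Validated molecules × descriptors table.

    Parameters
    ----------
    data:
        DataFrame with molecule ids as index and descriptor names as columns;
        all entries numeric, no missing values.
    blocks:
        Per-descriptor block tag, aligned with ``data.columns``; values in
        ``{"ADMET", "ES", "OTHER"}``.
    class_labels:
        Optional per-molecule category, aligned with ``data.index``.
    """

    data: pd.DataFrame
    blocks: pd.Series
    class_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DescriptorTableError(f"duplicate molecule ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise DescriptorTableError(f"duplicate descriptor names: {dupes}")
        if self.data.isna().any().any():
            loc = [(idx[i], cols[j]) for i, j in np.argwhere(self.data.isna().to_numpy())]
            raise DescriptorTableError(f"missing values at (molecule, descriptor): {loc}")
        non_numeric = [c for c in cols if not pd.api.types.is_numeric_dtype(self.data[c])]
        if non_numeric:
            raise DescriptorTableError(f"non-numeric descriptor columns: {non_numeric}")
        self.blocks = pd.Series(self.blocks, dtype=object)
        if not self.blocks.index.equals(cols):
            self.blocks = self.blocks.reindex(cols)
        if self.blocks.isna().any():
            missing = self.blocks.index[self.blocks.isna()].tolist()
            raise DescriptorTableError(f"descriptors without a block tag: {missing}")
        bad_tags = sorted(set(self.blocks) - set(VALID_BLOCKS))
        if bad_tags:
            raise DescriptorTableError(
                f"invalid block tags {bad_tags}; expected one of {VALID_BLOCKS}"
            )
        if self.class_labels is not None:
            self.class_labels = pd.Series(self.class_labels, dtype=object)
            if not self.class_labels.index.equals(idx):
                self.class_labels = self.class_labels.reindex(idx)
            if self.class_labels.isna().any():
                missing = self.class_labels.index[self.class_labels.isna()].tolist()
                raise DescriptorTableError(f"molecules without class label: {missing}")

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_molecules(self) -> int:
        return self.data.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    def select_descriptors(self, names: Iterable[str]) -> "DescriptorTable":
        """Column-subset the table, preserving original column order."""
        names = list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise DescriptorTableError(f"unknown descriptors: {missing}")
        keep = [c for c in self.data.columns if c in set(names)]
        if not keep:
            raise DescriptorTableError("empty descriptor selection")
        return DescriptorTable(
            data=self.data[keep].copy(),
            blocks=self.blocks[keep].copy(),
            class_labels=None if self.class_labels is None else self.class_labels.copy(),
        )

    def to_csv(self, path: str | Path, id_column: str = "id", class_column: str = "class") -> None:
        """Write the table as CSV; class labels, if present, become a trailing column."""
        out = self.data.copy()
        out.index.name = id_column
        if self.class_labels is not None:
            out[class_column] = self.class_labels
        out.to_csv(path)


@dataclass
class ScaledTable(DescriptorTable):
    """A z-scored :class:`DescriptorTable` carrying the scaling statistics.

    ``mu`` and ``sigma`` are the per-descriptor mean and standard deviation of
    the raw table, so ``values * sigma + mu`` reconstructs the raw values.
    """

    mu: pd.Series = field(default_factory=pd.Series)
    sigma: pd.Series = field(default_factory=pd.Series)

    def unscale(self) -> DescriptorTable:
        """Invert the z-scaling, recovering the raw table."""
        raw = self.data * self.sigma + self.mu
        return DescriptorTable(raw, self.blocks.copy(),
                               None if self.class_labels is None else self.class_labels.copy())

    def write(self, path: str | Path, id_column: str = "id") -> None:
        """Write the scaled values as CSV plus a sidecar JSON of (mu, sigma)."""
        path = Path(path)
        self.to_csv(path, id_column=id_column)
        sidecar = {
            name: {"mu": float(self.mu[name]), "sigma": float(self.sigma[name])}
            for name in self.descriptor_names
        }
        path.with_suffix(path.suffix + ".stats.json").write_text(
            json.dumps(sidecar, indent=2)
        )


def load_block_map(path: str | Path) -> dict[str, str]:
    """Load a descriptor → block mapping from a YAML file.

    The file maps descriptor names (or name prefixes, see
    :func:`read_descriptor_table`) to ``ADMET`` or ``ES``.
    """
    mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, dict):
        raise DescriptorTableError(f"block map {path} must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _resolve_block(name: str, block_map: Mapping[str, str]) -> str:
    """Exact match first, then longest matching prefix, else OTHER."""
    if name in block_map:
        return block_map[name]
    best = ""
    tag = "OTHER"
    for key, value in block_map.items():
        if name.startswith(key) and len(key) > len(best):
            best, tag = key, value
    return tag


def read_descriptor_table(
    path: str | Path,
    id_column: str = "id",
    class_column: str | None = None,
    block_map: Mapping[str, str] | None = None,
) -> DescriptorTable:
    """Read a descriptor table from CSV and validate it.

    Parameters
    ----------
    path:
        CSV file, UTF-8, with a header row. ``id_column`` holds molecule ids;
        every other column except ``class_column`` must be numeric.
    block_map:
        Mapping of descriptor names or name-prefixes to block tags; unmapped
        descriptors default to ``OTHER``.

    Raises
    ------
    DescriptorTableError
        On duplicate ids, non-numeric descriptor cells (named by row and
        column), or missing values. No imputation is ever performed.
    """
    df = pd.read_csv(path, dtype=str).astype(object)
    if id_column not in df.columns:
        raise DescriptorTableError(f"id column {id_column!r} not found in {path}")
    ids = df[id_column]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise DescriptorTableError(f"duplicate molecule ids: {dupes}")
    df = df.set_index(id_column)
    class_labels = None
    if class_column is not None:
        if class_column not in df.columns:
            raise DescriptorTableError(f"class column {class_column!r} not found in {path}")
        class_labels = df[class_column].astype(object)
        df = df.drop(columns=[class_column])

    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            mol = bad.index[bad][0]
            raise DescriptorTableError(
                f"non-numeric value {df.loc[mol, col]!r} at molecule {mol!r}, "
                f"descriptor {col!r}"
            )
        if coerced.isna().any():
            mol = coerced.index[coerced.isna()][0]
            raise DescriptorTableError(
                f"missing value at molecule {mol!r}, descriptor {col!r}"
            )
        numeric[col] = coerced.astype(float)

    block_map = dict(block_map or {})
    blocks = pd.Series(
        {c: _resolve_block(c, block_map) for c in numeric.columns},
        index=numeric.columns, dtype=object,
    )
    return DescriptorTable(numeric, blocks, class_labels)


def select_block(table: DescriptorTable, which: str) -> DescriptorTable:
    """Subset a table to one descriptor block.

    ``which`` is ``"ADMET"``, ``"ES"``, or ``"BOTH"`` (the union, in original
    column order). Raises if the selection is empty.
    """
    which = which.upper()
    if which == "BOTH":
        wanted = {"ADMET", "ES"}
    elif which in ("ADMET", "ES"):
        wanted = {which}
    else:
        raise DescriptorTableError(f"unknown block selection {which!r}")
    keep = [c for c in table.data.columns if table.blocks[c] in wanted]
    if not keep:
        raise DescriptorTableError(f"no descriptors tagged {sorted(wanted)}")
    return DescriptorTable(
        table.data[keep].copy(), table.blocks[keep].copy(),
        None if table.class_labels is None else table.class_labels.copy(),
    )


def scale(table: DescriptorTable, ddof: int = 0, drop_constant: bool = False) -> ScaledTable:
    """Z-score every descriptor column: z = (x − μ) / σ.

    σ uses the population denominator (``ddof=0``) by default, matching the
    common standard-scaler convention; pass ``ddof=1`` for the sample variant.
    Binary descriptors are scaled exactly like continuous ones.

    Zero-variance columns are a hard error unless ``drop_constant`` is set,
    in which case they are silently removed before scaling.
    """
    mu = table.data.mean(axis=0)
    sigma = table.data.std(axis=0, ddof=ddof)
    constant = sigma[sigma == 0].index.tolist()
    data = table.data
    blocks = table.blocks
    if constant:
        if not drop_constant:
            raise DescriptorTableError(
                f"zero-variance descriptors (drop them or pass drop_constant=True): "
                f"{constant}"
            )
        keep = [c for c in data.columns if c not in set(constant)]
        if not keep:
            raise DescriptorTableError("all descriptors are constant")
        data = data[keep]
        blocks = blocks[keep]
        mu = mu[keep]
        sigma = sigma[keep]
    z = (data - mu) / sigma
    return ScaledTable(
        data=z, blocks=blocks.copy(),
        class_labels=None if table.class_labels is None else table.class_labels.copy(),
        mu=mu.astype(float), sigma=sigma.astype(float),
    )


def descriptor_ranges(table: DescriptorTable) -> pd.DataFrame:
    """Per-descriptor spread report: min, max, range, and the molecules attaining them.

    Useful for quick spread summaries such as the energy window of a given
    orbital across a molecule panel.
    """
    data = table.data
    report = pd.DataFrame(
        {
            "min": data.min(axis=0),
            "max": data.max(axis=0),
            "argmin": data.idxmin(axis=0),
            "argmax": data.idxmax(axis=0),
        }
    )
    report["range"] = report["max"] - report["min"]
    return report[["min", "argmin", "max", "argmax", "range"]]
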