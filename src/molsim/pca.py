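"""PCA on scaled descriptor tables: k selection, loadings, descriptor retention.

Three uses of principal components in the descriptor-analysis pipeline:

* **k selection** — the number of components that together explain "almost
  all" of the variance (default threshold 0.95) doubles as the number of
  clusters for K-means, exploiting the close relationship between the PCA
  reconstruction objective and the K-means within-cluster variance.
* **loadings analysis** — per-component maxima of |loading| name the
  descriptors that dominate each axis of variation.
* **descriptor reduction** — keep only descriptors whose maximum |loading|
  over the leading components passes a cutoff, and re-analyze the reduced
  table.

Loadings columns have a sign indeterminacy; each column is flipped so its
largest-magnitude entry is positive, making outputs reproducible. Comparisons
against published loading tables should be made on absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .descriptors import DescriptorTable, ScaledTable


class PCAError(ValueError):
    """Raised on invalid PCA inputs or retention rules."""


@dataclass
class PCAResult:
    """Full PCA decomposition of a scaled descriptor table.

    ``loadings`` is descriptors × components with orthonormal columns;
    ``scores`` is molecules × components (the centered data projected onto
    the loadings). ``source`` keeps the fitted table for downstream
    descriptor-reduction steps.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    source: ScaledTable

    @property
    def component_count(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class RetentionRule:
    """Keep descriptors whose max |loading| over the first ``n_components``
    principal components is at least ``cutoff``."""

    n_components: int = 5
    cutoff: float = 0.45


def fit_pca(scaled: ScaledTable) -> PCAResult:
    """Full PCA (min(N−1, d) components) with a deterministic sign convention."""
    n, d = scaled.data.shape
    if n < 2 or d < 2:
        raise PCAError("need at least 2 molecules and 2 descriptors")
    col_span = scaled.data.max(axis=0) - scaled.data.min(axis=0)
    constant = col_span[col_span == 0].index.tolist()
    if constant:
        raise PCAError(f"constant descriptor columns: {constant}")
    n_comp = min(n - 1, d)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(scaled.data.to_numpy())
    loadings = model.components_.T  # descriptors × components, unit-norm columns
    # sign convention: largest-|entry| of each column made positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=scaled.data.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=scaled.data.index, columns=comp_names),
        source=scaled,
    )


def k_from_variance(pca: PCAResult, threshold: float = 0.95) -> int:
    """Smallest number of leading components whose cumulative explained
    variance reaches ``threshold`` — used as the cluster count k."""
    if not 0 < threshold <= 1:
        raise PCAError(f"threshold must be in (0, 1], got {threshold}")
    cumulative = np.cumsum(pca.explained_variance_ratio)
    hit = np.nonzero(cumulative >= threshold - 1e-12)[0]
    if len(hit) == 0:
        return pca.component_count
    return int(hit[0]) + 1


def top_loadings(
    pca: PCAResult, n_components: int, tie_tol: float = 5e-3
) -> list[tuple[list[str], float]]:
    """Per-component descriptor(s) attaining the maximum |loading|.

    Returns, for each of the first ``n_components`` components, the list of
    descriptors within ``tie_tol`` of the maximum magnitude (ties are
    reported jointly) and that magnitude.
    """
    if n_components > pca.component_count:
        raise PCAError(
            f"n_components={n_components} exceeds component count {pca.component_count}"
        )
    out = []
    for j in range(n_components):
        col = pca.loadings.iloc[:, j].abs()
        top = float(col.max())
        winners = col.index[col >= top - tie_tol].tolist()
        out.append((winners, top))
    return out


def reduce_descriptors(pca: PCAResult, rule: RetentionRule | None = None) -> tuple[list[str], DescriptorTable]:
    """Apply a loadings-based retention rule and emit the reduced raw table.

    A descriptor is retained when its maximum |loading| over the first
    ``rule.n_components`` components meets ``rule.cutoff``. The returned
    table holds the retained columns of the *raw* (unscaled) source so it can
    be rescaled and re-analyzed from scratch.
    """
    rule = rule or RetentionRule()
    n_comp = min(rule.n_components, pca.component_count)
    maxima = pca.loadings.iloc[:, :n_comp].abs().max(axis=1)
    retained = maxima.index[maxima >= rule.cutoff].tolist()
    if not retained:
        raise PCAError(
            f"no descriptor reaches |loading| {rule.cutoff} over the first "
            f"{n_comp} components; lower the cutoff"
        )
    raw = pca.source.unscale()
    return retained, raw.select_descriptors(retained)


def scatter_scores(
    pca: PCAResult, n_components: int, labels: np.ndarray | list | None = None
) -> pd.DataFrame:
    """Score table for scatter-matrix plotting: first ``n_components`` score
    columns per molecule, with an optional cluster-label column attached."""
    if n_components > pca.component_count:
        raise PCAError(
            f"n_components={n_components} exceeds component count {pca.component_count}"
        )
    out = pca.scores.iloc[:, :n_components].copy()
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != len(out):
            raise PCAError(f"{len(labels)} labels for {len(out)} molecules")
        out["cluster"] = labels
    return out
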