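"""Synthetic descriptor tables with known class structure.

The generator emulates the shape of a small drug-discovery descriptor panel:
a few dozen molecules drawn from a handful of classes, described by two
blocks of descriptors on very different unit scales — an ADMET-like block
(molecular weight, counts, scores: magnitudes of tens to hundreds) and an
electronic-structure-like block (orbital energies in eV: magnitudes of a few
units) — plus optional binary descriptors such as a blood–brain-barrier
flag. The scale mismatch is deliberate: analyses that skip z-scaling give
visibly wrong answers on these fixtures.

Class structure is Gaussian: each class has a center, and the minimum
pairwise distance between class centers is ``separation`` in units of the
within-class standard deviation (which is 1 before block scaling). At
separation 0 all classes coincide and are statistically indistinguishable,
including the binary columns, whose per-class rates are derived from the
same centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable


@dataclass(frozen=True)
class BlobSpec:
    """Shape and difficulty of a synthetic descriptor panel.

    Defaults mirror a 30-molecule, 5-class panel with ten ADMET-like and
    fourteen electronic-structure-like descriptors and one binary flag, with
    ADMET-like columns inflated by a factor of 50 to mimic g/mol- and
    score-scale units against eV-scale electronic descriptors.
    """

    n_classes: int = 5
    members_per_class: int = 6
    n_admet: int = 10
    n_es: int = 14
    separation: float = 6.0
    admet_scale: float = 50.0
    es_scale: float = 1.0
    n_binary: int = 1
    layout: str = "simplex"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_classes, self.members_per_class, self.n_admet, self.n_es)
        if any(c <= 0 for c in counts):
            raise ValueError("n_classes, members_per_class, n_admet, n_es must be positive")
        if self.n_binary < 0 or self.separation < 0:
            raise ValueError("n_binary and separation must be nonnegative")
        if self.n_binary > self.n_admet:
            raise ValueError("n_binary cannot exceed n_admet (binary columns live in the ADMET block)")
        if self.layout not in ("simplex", "random"):
            raise ValueError(f"layout must be 'simplex' or 'random', got {self.layout!r}")


def _class_centers(
    rng: np.random.Generator, n_classes: int, dim: int, separation: float, layout: str
) -> np.ndarray:
    """Class centers with minimum pairwise distance exactly ``separation``.

    ``simplex`` places the classes at the vertices of a regular simplex
    (every pair equally far apart) embedded at a random orientation, so no
    pair of classes is privileged; ``random`` draws isotropic Gaussian
    directions and rescales them so the *closest* pair sits at
    ``separation``. Both return all-zero centers at separation 0.
    """
    if n_classes == 1 or separation == 0:
        return np.zeros((n_classes, dim))
    if layout == "simplex":
        if dim < n_classes - 1:
            raise ValueError(
                f"simplex layout of {n_classes} classes needs >= {n_classes - 1} descriptors"
            )
        corners = np.zeros((n_classes, dim))
        corners[:, :n_classes] = np.eye(n_classes) - 1.0 / n_classes
        q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        return (corners @ q.T) * (separation / np.sqrt(2.0))
    centers = rng.normal(size=(n_classes, dim))
    dmin = np.inf
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            dmin = min(dmin, float(np.linalg.norm(centers[i] - centers[j])))
    if dmin == 0:  # astronomically unlikely; resample deterministically
        return _class_centers(rng, n_classes, dim, separation, layout)
    return centers * (separation / dmin)


def make_blob_table(spec: BlobSpec) -> DescriptorTable:
    """Generate a labeled descriptor table from a :class:`BlobSpec`.

    Continuous descriptors are class-conditional Gaussians with unit
    within-class standard deviation before block scaling. Binary descriptors
    are obtained by thresholding a latent Gaussian centered on the class
    center, so their per-class rates converge to 0.5 everywhere as
    ``separation`` → 0. Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_cont = spec.n_admet - spec.n_binary + spec.n_es
    dim = n_cont + spec.n_binary
    centers = _class_centers(rng, spec.n_classes, dim, spec.separation, spec.layout)
    n = spec.n_classes * spec.members_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.members_per_class)
    latent = centers[labels] + rng.normal(size=(n, dim))

    cont = latent[:, :n_cont]
    binary = (latent[:, n_cont:] > 0).astype(float)

    n_admet_cont = spec.n_admet - spec.n_binary
    admet_cont = cont[:, :n_admet_cont] * spec.admet_scale
    es_cont = cont[:, n_admet_cont:] * spec.es_scale

    columns: dict[str, np.ndarray] = {}
    blocks: dict[str, str] = {}
    for j in range(n_admet_cont):
        name = f"ADMET{j + 1}"
        columns[name] = admet_cont[:, j]
        blocks[name] = "ADMET"
    for j in range(spec.n_binary):
        name = f"ADMET_bin{j + 1}"
        columns[name] = binary[:, j]
        blocks[name] = "ADMET"
    for j in range(spec.n_es):
        name = f"ES{j + 1}"
        columns[name] = es_cont[:, j]
        blocks[name] = "ES"

    ids = [f"M{i + 1:03d}" for i in range(n)]
    data = pd.DataFrame(columns, index=ids)
    return DescriptorTable(
        data=data,
        blocks=pd.Series(blocks, index=data.columns, dtype=object),
        class_labels=pd.Series([f"class{c}" for c in labels], index=ids, dtype=object),
    )


def make_correlated_pair(
    n_descriptors: int, target_rho: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two descriptor vectors whose sample correlation converges to
    ``target_rho`` as the number of descriptors grows.

    Standard bivariate-normal construction: b = ρ·a + √(1−ρ²)·ε with a, ε
    independent standard normals, so corr(a, b) = ρ exactly in population.
    """
    if not -1 < target_rho < 1:
        raise ValueError(f"target_rho must be in (-1, 1), got {target_rho}")
    if n_descriptors < 10:
        raise ValueError("need at least 10 descriptors")
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n_descriptors)
    noise = rng.normal(size=n_descriptors)
    b = target_rho * a + np.sqrt(1 - target_rho ** 2) * noise
    return a, b
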