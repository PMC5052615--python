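"""Community ecology: alpha diversity, Bray-Curtis and PCoA ordination."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import AbundanceMatrix

__all__ = ["shannon_index", "richness", "bray_curtis", "pcoa", "PCoAResult"]


def shannon_index(profile, base: float | None = None) -> float:
    """Shannon diversity H = -sum(p ln p) over the renormalised profile.

    Natural log by default; pass ``base`` (e.g. 2) for other units.
    """
    p = np.asarray(profile, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero profile has no diversity")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base is not None else h


def richness(profile, detection_min: float = 0.0) -> int:
    """Number of features detected strictly above ``detection_min``."""
    p = np.asarray(profile, dtype=float)
    return int((p > detection_min).sum())


def bray_curtis(abund: AbundanceMatrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples, in [0, 1]."""
    x = abund.values.to_numpy(dtype=float).T  # samples x features
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [abund.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=abund.sample_ids, columns=abund.sample_ids)


class PCoAResult:
    """Coordinates, eigenvalues and variance fractions from classical scaling."""

    def __init__(self, coordinates: pd.DataFrame, eigenvalues: np.ndarray,
                 proportion_explained: np.ndarray):
        self.coordinates = coordinates
        self.eigenvalues = eigenvalues
        self.proportion_explained = proportion_explained


def pcoa(dist: pd.DataFrame, n_axes: int = 2) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centres -1/2 J D^2 J, eigendecomposes, and returns
    coordinates eigenvector * sqrt(eigenvalue) for positive eigenvalues
    in descending order.  Negative eigenvalues (non-Euclidean input) are
    reported but excluded from the axes, with no correction applied.
    The sign of each axis is fixed so its largest-magnitude coordinate
    is positive.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    n_pos = int(pos.sum())
    if n_pos < n_axes:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s) available (requested {n_axes})",
            stacklevel=2,
        )
    n_take = min(n_axes, n_pos)
    coords = evecs[:, :n_take] * np.sqrt(evals[:n_take])
    for a in range(n_take):  # sign convention: largest |loading| positive
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    pos_evals = evals[pos]
    prop = pos_evals / pos_evals.sum() if n_pos else np.array([])
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PCo{a + 1}" for a in range(n_take)]
        ),
        eigenvalues=evals,
        proportion_explained=prop[:n_take] if n_pos else prop,
    )
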