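"""Backbone graph construction from mean functional connectivity.

All subjects share one binary graph: the element-wise mean of the *training*
FC matrices is thresholded at a cutoff tau (an entry becomes an edge iff its
mean correlation strictly exceeds tau).  tau is chosen at the elbow of the
edge-retention curve — the fraction of positive connections surviving each
candidate cutoff — operationalised as the grid point of maximum
perpendicular distance to the chord joining the curve's endpoints (the
"kneedle" criterion), after normalising both axes to [0, 1].

The thresholded adjacency A is augmented with self-loops (A~ = I + A) and
symmetrically normalised, S = D~^(-1/2) A~ D~^(-1/2), the propagation
operator of first-order spectral graph convolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import FCMatrix

logger = logging.getLogger(__name__)

__all__ = ["MeanMatrix", "RetentionCurve", "BackboneGraph", "mean_matrix",
           "retention_curve", "select_elbow", "binarize",
           "normalized_adjacency", "build_backbone"]


@dataclass
class MeanMatrix:
    """Element-wise mean of training FC matrices, diagonal zeroed."""

    values: np.ndarray
    n_subjects_averaged: int


@dataclass
class RetentionCurve:
    """Fraction of positive connections retained at each candidate cutoff."""

    thresholds: np.ndarray
    retained_fraction: np.ndarray


@dataclass
class BackboneGraph:
    """Binary shared adjacency plus its self-looped symmetric normalisation."""

    adjacency: np.ndarray          # A, binary, zero diagonal
    tau: float
    self_loop_adjacency: np.ndarray  # A~ = I + A
    degree: np.ndarray             # D~ diagonal entries
    normalized: np.ndarray         # S = D~^(-1/2) A~ D~^(-1/2)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def mean_matrix(training: list[FCMatrix]) -> MeanMatrix:
    """Element-wise arithmetic mean of the training matrices; diagonal -> 0."""
    if not training:
        raise ValueError("cannot average an empty list of matrices")
    n = training[0].n_regions
    for fc in training:
        if fc.n_regions != n:
            raise ValueError("matrices of differing size in mean_matrix")
    mean = np.mean([fc.values for fc in training], axis=0)
    mean = 0.5 * (mean + mean.T)
    np.fill_diagonal(mean, 0.0)
    return MeanMatrix(values=mean, n_subjects_averaged=len(training))


def retention_curve(m: MeanMatrix, grid: np.ndarray) -> RetentionCurve:
    """Fraction of positive off-diagonal connections with value > tau.

    The denominator counts only positive connections: negative correlations
    are never edges, so they do not contribute to the percentage.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("threshold grid must be a 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly ascending")
    iu = np.triu_indices(m.values.shape[0], k=1)
    vals = m.values[iu]
    n_positive = int(np.sum(vals > 0))
    if n_positive == 0:
        raise ValueError("mean matrix has no positive connections")
    retained = np.array([np.sum(vals > t) / n_positive for t in grid])
    return RetentionCurve(thresholds=grid, retained_fraction=retained)


def select_elbow(curve: RetentionCurve) -> float:
    """Cutoff at the elbow: maximum perpendicular distance to the endpoint chord.

    Both axes are first mapped to [0, 1] so the choice is unit-independent.
    Ties break toward the smaller threshold; a flat or perfectly linear
    curve (max distance < 1e-9) returns the smallest grid threshold with a
    warning.
    """
    t, r = curve.thresholds, curve.retained_fraction
    if t.size < 3:
        raise ValueError("need at least 3 grid points to locate an elbow")
    x = (t - t[0]) / (t[-1] - t[0])
    span = r[0] - r[-1]
    if abs(span) < 1e-12:
        warnings.warn("retention curve is flat; returning the smallest threshold")
        return float(t[0])
    y = (r - r[-1]) / span
    # distance from (x_i, y_i) to the chord through (0, y_0) and (1, y_last)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist = dist / np.hypot(y1 - y0, x1 - x0)
    if dist.max() < 1e-9:
        warnings.warn("retention curve is linear; returning the smallest threshold")
        return float(t[0])
    return float(t[int(np.argmax(dist))])


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """S = D~^(-1/2) (I + A) D~^(-1/2) for a binary symmetric adjacency."""
    a_tilde = adjacency + np.eye(adjacency.shape[0])
    deg = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a_tilde * np.outer(inv_sqrt, inv_sqrt)


def binarize(m: MeanMatrix, tau: float) -> BackboneGraph:
    """Threshold the mean matrix at tau (strict >) into a backbone graph."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    a = (m.values > tau).astype(np.float64)
    np.fill_diagonal(a, 0.0)
    a = np.maximum(a, a.T)  # mean matrix is symmetric; keep A exactly so
    if a.sum() == 0:
        warnings.warn(f"tau={tau} removes every edge; graph is self-loops only")
    a_tilde = a + np.eye(a.shape[0])
    deg = a_tilde.sum(axis=1)
    s = normalized_adjacency(a)
    return BackboneGraph(adjacency=a, tau=float(tau), self_loop_adjacency=a_tilde,
                         degree=deg, normalized=s)


def build_backbone(training: list[FCMatrix], grid: np.ndarray | None = None,
                   tau: float | None = None) -> tuple[BackboneGraph, RetentionCurve | None]:
    """Convenience pipeline: mean -> retention curve -> elbow -> binarize.

    Pass an explicit ``tau`` to override the elbow criterion (e.g. to
    reproduce a published cutoff such as 0.15 or 0.2).
    """
    m = mean_matrix(training)
    curve = None
    if tau is None:
        if grid is None:
            hi = float(m.values.max())
            if hi <= 0:
                raise ValueError("mean matrix has no positive entries")
            grid = np.linspace(0.0, 0.95 * hi, 40)
        curve = retention_curve(m, grid)
        tau = select_elbow(curve)
    elif grid is not None:
        curve = retention_curve(m, grid)
    graph = binarize(m, tau)
    logger.info("backbone graph: tau=%.4g, %d edges", tau, int(graph.adjacency.sum() / 2))
    return graph, curve
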