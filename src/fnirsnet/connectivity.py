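"""Functional-connectivity matrices and thresholded binary graphs.

Per subject: Pearson correlation between all HbO channel pairs, removal of
the three midline channels (leaving a 50x50 matrix), Fisher r-to-z with
negative correlations rectified to zero, and a sweep of binary graphs over
the eleven thresholds 0.40..0.90 (step 0.05) on the r scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .montage import ChannelAtlas, ValidationError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ConnectivityMatrix",
    "BinaryGraph",
    "EdgeProfile",
    "correlation_matrix",
    "drop_midline",
    "fisher_z_rectify",
    "build_connectivity",
    "threshold_graph",
    "edge_profile",
    "group_mean_matrix",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.40, 0.90, 11), 2))

_R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-pair association matrix in r and rectified-z form."""

    nodes: tuple[int, ...]  # channel indices (1-based), midline removed
    r: np.ndarray  # Pearson r, unit diagonal
    z: np.ndarray  # Fisher z of r, negatives -> 0, zero diagonal

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.nodes)
        if self.r.shape != (n, n) or self.z.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.r.shape} does not match {n} nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class BinaryGraph:
    """Undirected binary graph from thresholding a connectivity matrix."""

    nodes: tuple[int, ...]
    adjacency: np.ndarray  # bool, symmetric, zero diagonal
    threshold: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency shape does not match node list")
        if self.adjacency.diagonal().any():
            raise ValidationError("self-loops are not allowed")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValidationError("adjacency must be symmetric")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency.astype(int))
        return nx.relabel_nodes(g, dict(enumerate(self.nodes)))


@dataclass
class EdgeProfile:
    """Edge counts over the threshold sweep and their mean."""

    thresholds: tuple[float, ...]
    counts: tuple[int, ...]

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))


def correlation_matrix(hbo: np.ndarray, min_samples: int = 3) -> np.ndarray:
    """Pearson r between all channel pairs of an HbO array (channels x time).

    Channels with zero variance produce NaN rows/columns and a warning;
    downstream construction zeroes them out.
    """
    hbo = np.asarray(hbo, dtype=float)
    if hbo.ndim != 2:
        raise ValidationError("expected a (channels, samples) array")
    if hbo.shape[1] < min_samples:
        raise ValidationError(f"need >= {min_samples} samples, got {hbo.shape[1]}")
    sd = hbo.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(
            f"zero-variance channels (1-based): {list(dead + 1)}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(hbo)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if dead.size:
        r[dead, :] = np.nan
        r[:, dead] = np.nan
        np.fill_diagonal(r, 1.0)
    return r


def fisher_z_rectify(r_matrix: np.ndarray) -> np.ndarray:
    """Fisher z = arctanh(r) with negatives set to zero.

    Negative correlations are rectified to 0 (their physiological meaning is
    ambiguous); off-diagonal r = 1 (duplicate channels) is clamped just below
    1 with a warning; the diagonal is set to 0 (self-pairs are not edges).
    NaN entries (zero-variance channels) map to 0.
    """
    r = np.array(r_matrix, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1 + 1e-12):
        raise ValidationError("|r| > 1 in correlation matrix")
    off = ~np.eye(len(r), dtype=bool)
    if np.any(r[off & finite] >= _R_CLAMP):
        warnings.warn("off-diagonal r ~ 1 clamped before Fisher transform",
                      stacklevel=2)
    r = np.clip(r, -1.0, _R_CLAMP)
    z = np.where(r > 0, np.arctanh(np.clip(r, 0.0, _R_CLAMP)), 0.0)
    z = np.where(np.isfinite(r), z, 0.0)
    np.fill_diagonal(z, 0.0)
    return z


def drop_midline(r_matrix: np.ndarray, atlas: ChannelAtlas) -> ConnectivityMatrix:
    """Remove the midline channels and build the 50-node connectivity matrix.

    Node order (ascending channel index) is preserved.  Zero-variance
    channels (NaN rows) are zeroed with their identity reported via warning.
    """
    r = np.asarray(r_matrix, dtype=float)
    n_in = r.shape[0]
    if r.shape != (n_in, n_in):
        raise ValidationError("correlation matrix must be square")
    if n_in != len(atlas.mapping):
        raise ValidationError(
            f"matrix has {n_in} channels but atlas describes {len(atlas.mapping)}")
    keep_ids = atlas.lateral_channels
    keep = np.array([c - 1 for c in keep_ids], dtype=int)
    sub = r[np.ix_(keep, keep)]
    dead = np.flatnonzero(np.isnan(sub).any(axis=1))
    if dead.size:
        warnings.warn(
            f"channels zeroed (no variance): {[keep_ids[i] for i in dead]}",
            stacklevel=2)
    z = fisher_z_rectify(sub)
    sub = np.where(np.isfinite(sub), sub, 0.0)
    np.fill_diagonal(sub, 1.0)
    if dead.size:
        sub[dead, :] = 0.0
        sub[:, dead] = 0.0
        z[dead, :] = 0.0
        z[:, dead] = 0.0
        np.fill_diagonal(sub, 1.0)
    return ConnectivityMatrix(nodes=keep_ids, r=sub, z=z)


def build_connectivity(hbo: np.ndarray, atlas: ChannelAtlas) -> ConnectivityMatrix:
    """Correlation -> midline removal -> Fisher z rectification."""
    return drop_midline(correlation_matrix(hbo), atlas)


def threshold_graph(
    matrix: ConnectivityMatrix,
    tau: float,
    scale: str = "r",
) -> BinaryGraph:
    """Binarize: edge iff connection strength strictly exceeds ``tau``.

    Thresholds are interpreted on the r scale by default (``scale="z"``
    switches to the rectified Fisher-z values).
    """
    if not 0 <= tau < 1 and scale == "r":
        raise ValidationError(f"threshold {tau} outside [0, 1)")
    values = matrix.r if scale == "r" else matrix.z
    adj = values > tau
    np.fill_diagonal(adj, False)
    return BinaryGraph(nodes=matrix.nodes, adjacency=adj, threshold=float(tau))


def edge_profile(
    matrix: ConnectivityMatrix,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    scale: str = "r",
) -> EdgeProfile:
    """Edge counts across the threshold sweep plus their mean."""
    taus = tuple(float(t) for t in thresholds)
    if list(taus) != sorted(taus):
        raise ValidationError("thresholds must be sorted ascending")
    counts = tuple(threshold_graph(matrix, t, scale).n_edges for t in taus)
    return EdgeProfile(thresholds=taus, counts=counts)


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Elementwise mean of the rectified z matrices of one group."""
    if not matrices:
        raise ValidationError("empty group")
    nodes = matrices[0].nodes
    for m in matrices[1:]:
        if m.nodes != nodes:
            raise ValidationError("matrices have mismatched node sets")
    return np.mean([m.z for m in matrices], axis=0)
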