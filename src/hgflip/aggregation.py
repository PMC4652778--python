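"""Nucleoside self-association analysis: cluster statistics and the equal-K model.

Two molecules belong to the same aggregate when their centers of mass lie
within a cutoff (3.5 Angstrom by default); aggregates are the connected
components of that contact graph under the minimum-image convention.  The
osmotic coefficient of a frame is

    phi = m_N / m_T = sum_i [A_i] / sum_i i * [A_i]

i.e. the number of clusters over the number of molecules (the molal unit
cancels in the ratio).  Under the equal-K model (one association constant
for every oligomerization step) phi and the total molality obey

    (1 - phi) / phi^2 = K_A * m_T

which is fit as a least-squares slope through the origin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

DEFAULT_CUTOFF = 3.5  # Angstrom, center-of-mass contact criterion


@dataclass
class ComFrame:
    """Molecular center-of-mass coordinates, optionally in a periodic box."""

    positions: np.ndarray
    box: np.ndarray = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1 or self.positions.shape[1] != 3:
            raise ValueError("positions must be a non-empty (N, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")

    @property
    def n(self):
        return self.positions.shape[0]


@dataclass
class ClusterSizeDistribution:
    """Counts of i-mers in one frame: counts[i] clusters of size i."""

    counts: dict
    n_molecules: int

    def __post_init__(self):
        self.counts = {int(i): int(c) for i, c in self.counts.items() if c > 0}
        total = sum(i * c for i, c in self.counts.items())
        if total != self.n_molecules:
            raise ValueError(
                f"cluster sizes sum to {total}, expected {self.n_molecules}")

    @property
    def n_clusters(self):
        return sum(self.counts.values())


@dataclass
class OsmoticPoint:
    """One (total molality, osmotic coefficient) observation."""

    m_T: float
    phi: float

    def __post_init__(self):
        if not self.m_T > 0:
            raise ValueError("m_T must be > 0")
        if not 0 < self.phi <= 1:
            raise ValueError("phi must lie in (0, 1]")


@dataclass
class EqualKFit:
    K_A: float      # molal^-1
    residual: float

    def __post_init__(self):
        if self.K_A < 0:
            raise ValueError("K_A must be >= 0")


def cluster_sizes(frame, cutoff=DEFAULT_CUTOFF):
    """Cluster-size distribution of one frame.

    An edge joins two molecules whose (minimum-image) center distance is
    <= cutoff; clusters are connected components of that graph.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = frame.n
    if frame.box is not None:
        pos = np.mod(frame.positions, frame.box)
        tree = cKDTree(pos, boxsize=frame.box)
    else:
        tree = cKDTree(frame.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = Counter(Counter(labels).values())
    return ClusterSizeDistribution(dict(sizes), n)


def osmotic_coefficient(dist):
    """phi = clusters / molecules; averaged when given a sequence of frames."""
    if isinstance(dist, ClusterSizeDistribution):
        return dist.n_clusters / dist.n_molecules
    dists = list(dist)
    if not dists:
        raise ValueError("need at least one cluster-size distribution")
    return float(np.mean([d.n_clusters / d.n_molecules for d in dists]))


class UndefinedTransformError(ZeroDivisionError):
    pass


def fit_equal_k(points):
    """Least-squares equal-K association constant from (m_T, phi) points.

    Fits y = (1 - phi) / phi^2 against m_T as a slope through the origin.
    The residual is the RMS of y - K_A * m_T.
    """
    points = list(points)
    if not points:
        raise ValueError("need at least one osmotic point")
    m = np.array([p.m_T for p in points])
    phi = np.array([p.phi for p in points])
    if np.any(phi == 0):
        raise UndefinedTransformError("phi = 0 makes (1 - phi)/phi^2 undefined")
    y = (1.0 - phi) / phi ** 2
    k = float(np.dot(y, m) / np.dot(m, m))
    k = max(k, 0.0)
    residual = float(np.sqrt(np.mean((y - k * m) ** 2)))
    return EqualKFit(K_A=k, residual=residual)


def predict_phi(K_A, m_T):
    """Osmotic coefficient implied by the equal-K model.

    Solves (1 - phi)/phi^2 = K_A * m_T for phi in (0, 1]:
    phi = (-1 + sqrt(1 + 4 K_A m_T)) / (2 K_A m_T); phi = 1 when K_A = 0.
    """
    K_A = np.asarray(K_A, dtype=float)
    m_T = np.asarray(m_T, dtype=float)
    if np.any(K_A < 0):
        raise ValueError("K_A must be >= 0")
    if np.any(m_T <= 0):
        raise ValueError("m_T must be > 0")
    km = K_A * m_T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(km > 0, (np.sqrt(1.0 + 4.0 * km) - 1.0) / (2.0 * km), 1.0)
    if phi.ndim == 0:
        return float(phi)
    return phi
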