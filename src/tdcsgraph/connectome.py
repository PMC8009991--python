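"""Fisher-z connectivity matrices and density-thresholded weighted graphs.

Pairwise Pearson correlations between region time series are
variance-stabilized with Fisher's r-to-z transform, then proportionally
thresholded: at density d the round(d * N(N-1)/2) strongest edges are kept
with their z values as weights, so every sample's graph has the same node
and edge count.  The sweep spans densities 0.17..0.46 in steps of 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from tdcsgraph.sample_prep import SampleTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedGraph",
    "correlation_to_z",
    "threshold_by_density",
    "density_sweep",
    "density_grid",
    "edge_count_for_density",
]

# |r| is capped just below 1 before atanh so degenerate (collinear) region
# pairs yield a large finite weight instead of poisoning the matrix.
_R_CAP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity over regions, zero diagonal."""

    z: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite")
        if np.any(np.diag(z) != 0):
            raise ValueError("z diagonal must be exactly 0")
        self.z = z
        if not self.region_labels:
            self.region_labels = [f"ROI{i + 1:03d}" for i in range(z.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class ThresholdedGraph:
    """Undirected weighted graph at a fixed edge density.

    ``weights`` is a symmetric N x N matrix, 0 where no edge; all retained
    weights are strictly positive.  ``connected`` flags whether the graph is
    a single component (disconnection is a recorded warning, not an error).
    """

    weights: np.ndarray
    density: float
    connected: bool = True

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return [(int(a), int(b), float(self.weights[a, b])) for a, b in zip(i, j)]


def correlation_to_z(
    ts: SampleTimeSeries | np.ndarray, region_labels: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Pearson correlations between all region pairs, Fisher r-to-z.

    z_ij = atanh(r_ij) for i != j; the diagonal is 0.  Correlations with
    |r| = 1 (identical regions up to positive scaling) are capped at
    1 - 1e-7 with a warning rather than producing infinities.
    """
    if isinstance(ts, SampleTimeSeries):
        data = ts.data
    else:
        data = np.asarray(ts, dtype=float)
    if data.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    stds = data.std(axis=1)
    dead = np.nonzero(stds == 0)[0]
    if dead.size:
        labels = list(region_labels) if region_labels else None
        names = [labels[i] if labels else f"region {i}" for i in dead]
        raise ValueError(f"zero-variance region(s): {', '.join(names)}")
    r = np.corrcoef(data)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlation(s) of magnitude 1 capped before Fisher transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -_R_CAP, _R_CAP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, region_labels=list(region_labels or []))


def edge_count_for_density(n_nodes: int, density: float) -> int:
    """round(d * N(N-1)/2) with round-half-away-from-zero."""
    target = density * n_nodes * (n_nodes - 1) / 2.0
    return int(np.floor(target + 0.5))


def threshold_by_density(
    c: ConnectivityMatrix, density: float, check_connected: bool = True
) -> ThresholdedGraph:
    """Keep the k = round(d * N(N-1)/2) strongest-z edges as weights.

    Ties at the cut weight are resolved by keeping the lexicographically
    smallest (i, j) pairs, so the edge count is exact and platform-stable.
    Raises if any retained weight would be non-positive (the density is too
    high for this matrix once negative connections are discarded).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = c.n_regions
    k = edge_count_for_density(n, density)
    iu, ju = np.triu_indices(n, k=1)
    zvals = c.z[iu, ju]
    # Primary key: descending z; then ascending i, then j for ties.
    order = np.lexsort((ju, iu, -zvals))
    keep = order[:k]
    kept_z = zvals[keep]
    if np.any(kept_z <= 0):
        raise ValueError(
            f"density {density} retains non-positive weights; negative "
            "connections must be discarded - lower the density for this matrix"
        )
    weights = np.zeros((n, n))
    weights[iu[keep], ju[keep]] = kept_z
    weights += weights.T
    connected = True
    if check_connected:
        n_comp, _ = connected_components(
            csr_matrix(weights), directed=False, return_labels=True
        )
        connected = n_comp == 1
    return ThresholdedGraph(weights=weights, density=density, connected=connected)


def density_grid(
    d_min: float = 0.17, d_max: float = 0.46, step: float = 0.01
) -> list[float]:
    """Exact decimal density grid (integer hundredths, no float drift)."""
    lo = round(d_min * 100)
    hi = round(d_max * 100)
    st = round(step * 100)
    if st <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("d_min must not exceed d_max")
    return [h / 100.0 for h in range(lo, hi + 1, st)]


def density_sweep(
    c: ConnectivityMatrix,
    d_min: float = 0.17,
    d_max: float = 0.46,
    step: float = 0.01,
) -> list[ThresholdedGraph]:
    """Threshold one connectivity matrix at every density on the grid.

    The defaults give 30 graphs (0.17..0.46 step 0.01).  Because edges are
    ranked once by weight, edge sets are nested along the sweep.  Each graph
    carries a connectivity flag; a disconnected graph is a warning condition
    recorded on the graph, not an error.
    """
    return [threshold_by_density(c, d) for d in density_grid(d_min, d_max, step)]
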