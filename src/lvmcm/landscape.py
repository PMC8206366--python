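"""Spatial structure of the metacommunity: patch coordinates, Gabriel graph, dispersal.

Patches are scattered uniformly over a square arena of side sqrt(N), so the mean
patch density is one per unit area regardless of N and typical inter-patch
distances do not change as the landscape grows.  Patches are linked through a
Gabriel graph — a planar spatial network in which two patches are neighbours iff
the disk having them as diameter contains no third patch — which on uniform
points links each patch to about four close neighbours.  Dispersal between
neighbours follows a negative-exponential kernel with length scale ``ell``,
normalised so that the fraction ``e`` of biomass leaving a patch per unit time
is divided among its neighbours and nothing is lost in transit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree, distance_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

__all__ = [
    "Landscape",
    "sample_patches",
    "gabriel_graph",
    "build_dispersal",
    "build_landscape",
]

#: default emigration rate (fraction of biomass leaving a patch per unit time)
DEFAULT_EMIGRATION = 0.01
#: default dispersal length (arena length units)
DEFAULT_DISPERSAL_LENGTH = 0.5


@dataclass
class Landscape:
    """A spatial network of habitat patches with a dispersal operator.

    Attributes
    ----------
    N : int
        Number of patches.
    coords : ndarray, shape (N, 2)
        Patch coordinates in the arena ``[0, sqrt(N)]^2``.
    dist : ndarray, shape (N, N)
        Pairwise Euclidean distances.
    adjacency : ndarray of bool, shape (N, N)
        Symmetric Gabriel-graph adjacency, zero diagonal.
    D : scipy.sparse.csr_matrix, shape (N, N)
        Dispersal operator.  ``D[x, x] = -e``; ``D[y, x] > 0`` only for
        Gabriel neighbours; every row sums to zero, so the dispersal term
        alone conserves total biomass.  The dynamics use the product ``B @ D``.
    e : float
        Emigration rate per unit time.
    ell : float
        Dispersal length of the exponential kernel.
    """

    N: int
    coords: np.ndarray
    dist: np.ndarray
    adjacency: np.ndarray
    D: sparse.csr_matrix
    e: float = DEFAULT_EMIGRATION
    ell: float = DEFAULT_DISPERSAL_LENGTH

    @property
    def closed(self) -> bool:
        """True when the landscape is a single patch with no neighbours."""
        return self.N == 1

    def degree(self) -> np.ndarray:
        """Gabriel degree of every patch."""
        return self.adjacency.sum(axis=1)

    def neighbours(self, x: int) -> np.ndarray:
        """Indices of the Gabriel neighbours of patch ``x``."""
        return np.flatnonzero(self.adjacency[x])

    # -- serialisation -----------------------------------------------------

    def to_csv(self, directory: str | Path) -> None:
        """Write coordinates, edge list and sparse dispersal triplets as CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            {"patch_id": np.arange(self.N), "x": self.coords[:, 0], "y": self.coords[:, 1]}
        ).to_csv(directory / "patches.csv", index=False)
        xs, ys = np.nonzero(np.triu(self.adjacency, k=1))
        pd.DataFrame(
            {"x": xs, "y": ys, "distance": self.dist[xs, ys]}
        ).to_csv(directory / "edges.csv", index=False)
        coo = self.D.tocoo()
        pd.DataFrame(
            {"row": coo.row, "col": coo.col, "value": coo.data}
        ).to_csv(directory / "dispersal.csv", index=False)
        pd.DataFrame({"e": [self.e], "ell": [self.ell]}).to_csv(
            directory / "dispersal_params.csv", index=False
        )

    @classmethod
    def from_csv(cls, directory: str | Path) -> "Landscape":
        """Read a landscape previously written by :meth:`to_csv`."""
        directory = Path(directory)
        import pandas as pd

        patches = pd.read_csv(directory / "patches.csv")
        coords = patches[["x", "y"]].to_numpy(float)
        N = len(coords)
        dist = distance_matrix(coords, coords)
        adjacency = np.zeros((N, N), dtype=bool)
        edges = pd.read_csv(directory / "edges.csv")
        adjacency[edges["x"], edges["y"]] = True
        adjacency |= adjacency.T
        trip = pd.read_csv(directory / "dispersal.csv")
        D = sparse.csr_matrix(
            (trip["value"], (trip["row"], trip["col"])), shape=(N, N)
        )
        params = pd.read_csv(directory / "dispersal_params.csv")
        return cls(
            N=N,
            coords=coords,
            dist=dist,
            adjacency=adjacency,
            D=D,
            e=float(params["e"][0]),
            ell=float(params["ell"][0]),
        )


def sample_patches(N: int, seed: int | np.random.Generator) -> np.ndarray:
    """Sample ``N`` patch coordinates uniformly on the square ``[0, sqrt(N)]^2``.

    The arena area equals ``N``, so the expected patch density is one per unit
    area for every ``N`` and inter-patch distances stay fixed on average as the
    metacommunity grows.
    """
    if N < 1:
        raise ValueError(f"need at least one patch, got N={N}")
    rng = np.random.default_rng(seed)
    side = np.sqrt(N)
    return rng.uniform(0.0, side, size=(N, 2))


def gabriel_graph(coords: np.ndarray) -> np.ndarray:
    """Build the Gabriel-graph adjacency of a planar point set.

    An edge {x, y} is present iff no third point z satisfies
    ``d(x,z)^2 + d(y,z)^2 <= d(x,y)^2``, i.e. no point lies in the *closed*
    disk having xy as diameter.  The closed-disk rule drops edges whose
    blocking point sits exactly on the circle, which keeps the graph planar in
    degenerate symmetric configurations (e.g. the corners of a square lose
    both diagonals); on points in general position the tie has probability
    zero.  The Gabriel graph contains the Euclidean minimum spanning tree, so
    it is connected.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 1:
        raise ValueError("need at least one point")
    adjacency = np.zeros((n, n), dtype=bool)
    if n == 1:
        return adjacency
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("duplicate coordinates are not allowed")

    if n <= 3:
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        # Gabriel edges are a subset of the Delaunay triangulation.
        from scipy.spatial import Delaunay

        tri = Delaunay(coords)
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((simplex[a], simplex[b]))
                    pairs.add((i, j))
        candidates = sorted(pairs)

    tree = cKDTree(coords)
    for i, j in candidates:
        mid = 0.5 * (coords[i] + coords[j])
        r2 = 0.25 * np.sum((coords[i] - coords[j]) ** 2)
        # slightly inflated query radius, then exact closed-disk test
        nearby = tree.query_ball_point(mid, np.sqrt(r2) * (1 + 1e-9) + 1e-12)
        blocked = False
        for k in nearby:
            if k == i or k == j:
                continue
            if np.sum((coords[k] - mid) ** 2) <= r2:
                blocked = True
                break
        if not blocked:
            adjacency[i, j] = adjacency[j, i] = True
    return adjacency


def build_dispersal(
    dist: np.ndarray,
    adjacency: np.ndarray,
    e: float = DEFAULT_EMIGRATION,
    ell: float = DEFAULT_DISPERSAL_LENGTH,
) -> sparse.csr_matrix:
    """Assemble the sparse dispersal operator ``D``.

    ``D[y, y] = -e`` (emigration) and, for every Gabriel neighbour x of y,
    ``D[y, x] = e * exp(-d_xy / ell) / k_y`` with
    ``k_y = sum_{z in N(y)} exp(-d_yz / ell)``: the biomass leaving patch y is
    split among its neighbours in proportion to the exponential kernel, so each
    row sums to zero exactly and dispersal conserves biomass.  The dynamics
    apply D from the right, ``(B @ D)[i, x] = sum_y B[i, y] D[y, x]``.

    A single isolated patch (N = 1) yields ``D = [[-e]]``; the emigration term
    is retained but there is nowhere to immigrate from, i.e. a closed patch.
    """
    if not (0 < e < 1):
        raise ValueError(f"emigration rate must lie in (0, 1), got {e}")
    if ell <= 0:
        raise ValueError(f"dispersal length must be positive, got {ell}")
    n = len(dist)
    rows, cols, vals = [], [], []
    for y in range(n):
        neigh = np.flatnonzero(adjacency[y])
        rows.append(y)
        cols.append(y)
        vals.append(-e)
        if neigh.size == 0:
            continue
        weights = np.exp(-dist[y, neigh] / ell)
        k_y = weights.sum()
        for x, w in zip(neigh, weights):
            rows.append(y)
            cols.append(x)
            vals.append(e * w / k_y)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_landscape(
    N: int,
    seed: int | np.random.Generator,
    e: float = DEFAULT_EMIGRATION,
    ell: float = DEFAULT_DISPERSAL_LENGTH,
) -> Landscape:
    """Sample coordinates, build the Gabriel graph and the dispersal operator."""
    coords = sample_patches(N, seed)
    dist = distance_matrix(coords, coords)
    adjacency = gabriel_graph(coords)
    D = build_dispersal(dist, adjacency, e=e, ell=ell)
    return Landscape(N=N, coords=coords, dist=dist, adjacency=adjacency, D=D, e=e, ell=ell)


def contains_mst(landscape: Landscape) -> bool:
    """Check that the Gabriel graph contains the Euclidean minimum spanning tree."""
    mst = minimum_spanning_tree(landscape.dist).tocoo()
    for i, j in zip(mst.row, mst.col):
        if not landscape.adjacency[i, j]:
            return False
    return True
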