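"""Compositional turnover statistics.

Everything downstream of a stored biomass time series: Bray-Curtis
dissimilarity matrices between snapshots, compositional cluster counts from
complete-linkage hierarchical clustering, the temporal-turnover detector,
temporal occupancy, richness series, neighbourhood richness, the
species-time-area relation (STAR) and spatial/temporal beta diversities.

Presence/absence statistics use a detection threshold of 1e-4 biomass units.
Bray-Curtis matrices are computed on raw biomasses: the index is
abundance-based and the detection threshold applies only to presence-derived
statistics (richness, occupancy, STAR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import pdist, squareform

from .dynamics import CommunityTimeseries, DETECTION_THRESHOLD
from .landscape import Landscape

__all__ = [
    "bray_curtis",
    "temporal_dissimilarity",
    "count_clusters",
    "detect_turnover",
    "presence_tensor",
    "temporal_occupancy",
    "richness_timeseries",
    "neighbourhood_richness",
    "star",
    "beta_diversities",
    "abundance_structure",
    "OccupancyResult",
    "STARResult",
]

#: mean temporal Bray-Curtis above which a patch counts as turning over
TURNOVER_THRESHOLD = 1e-2
#: dendrogram cut height for compositional cluster counting
CLUSTER_CUT = 0.25


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``sum |u - v| / sum (u + v)``.

    A semimetric on non-negative abundance vectors, bounded by 1 (attained on
    disjoint supports) and invariant under joint rescaling.  Undefined when
    both vectors are all-zero.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    total = (u + v).sum()
    if total == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / total)


def _bc_matrix(columns: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis between the columns of an abundance matrix."""
    X = columns.T  # observations as rows
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("all-zero snapshot: Bray-Curtis undefined")
    return squareform(pdist(X, metric="braycurtis"))


def temporal_dissimilarity(
    timeseries: CommunityTimeseries, patch: int = 0, subsample_stride: int = 10
) -> np.ndarray:
    """Pairwise temporal Bray-Curtis matrix of one patch's composition.

    Raw biomasses are compared between time samples, thinned by
    ``subsample_stride`` (a 1e4-sample series gives a 1e3 x 1e3 matrix at the
    default stride).
    """
    if timeseries.t_max < 2:
        raise ValueError("need at least two samples")
    cols = timeseries.patch(patch)[:, ::subsample_stride]
    return _bc_matrix(cols)


def count_clusters(D: np.ndarray, cut: float = CLUSTER_CUT) -> int:
    """Number of compositional clusters at a complete-linkage dendrogram cut.

    Complete linkage merges two clusters only when *every* cross pair is
    within the merge height, so a cut at 0.25 groups snapshots that are all
    mutually less than 25% dissimilar — an estimate of the number of distinct
    community states visited.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if n < 2:
        return 1 if n == 1 else 0
    Z = complete(squareform(D, checks=False))
    labels = fcluster(Z, t=cut, criterion="distance")
    return int(labels.max())


def detect_turnover(
    timeseries: CommunityTimeseries,
    patch: int = 0,
    subsample_stride: int = 10,
    threshold: float = TURNOVER_THRESHOLD,
) -> tuple[bool, float]:
    """Flag autonomous turnover in one patch.

    Returns ``(turning_over, mean_bc)`` where ``mean_bc`` is the mean
    off-diagonal temporal Bray-Curtis; a patch at a fixed point scores ~0.
    """
    D = temporal_dissimilarity(timeseries, patch, subsample_stride)
    n = D.shape[0]
    mean_bc = float(D.sum() / (n * (n - 1)))
    return mean_bc > threshold, mean_bc


# ---------------------------------------------------------------------------
# presence-based statistics
# ---------------------------------------------------------------------------


def presence_tensor(
    timeseries: CommunityTimeseries, threshold: float = DETECTION_THRESHOLD
) -> np.ndarray:
    """Boolean tensor ``P[i, x, t]``: biomass above the detection threshold."""
    return timeseries.tensor > threshold


@dataclass
class OccupancyResult:
    """Temporal occupancy of every population that was present at least once."""

    occupancy: np.ndarray  # values in (0, 1]
    species: np.ndarray  # species index of each value
    patch: np.ndarray  # patch index of each value

    def histogram(self, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.occupancy, bins=bins, range=(0.0, 1.0))


def temporal_occupancy(P: np.ndarray) -> OccupancyResult:
    """Fraction of samples in which each population is present.

    ``TO[i, x] = (1 / t_max) * sum_t P[i, x, t]``, reported only for
    populations present at least once.  In turning-over communities the
    pooled distribution is characteristically bimodal: most populations are
    either near-core (occupancy ~1) or transient (occupancy ~0).
    """
    t_max = P.shape[2]
    if t_max < 1:
        raise ValueError("need at least one sample")
    to = P.sum(axis=2) / t_max
    i, x = np.nonzero(to > 0)
    return OccupancyResult(occupancy=to[i, x], species=i, patch=x)


def is_bimodal(occupancy: np.ndarray, bins: int = 10) -> bool:
    """Strict decile test for a bimodal occupancy distribution.

    True when both extreme deciles contain more populations than every
    interior decile — the signature of a community split into near-core
    (occupancy ~ 1) and transient (occupancy ~ 0) populations.  At small
    population counts the high mode can leak into adjacent deciles; see
    :func:`has_occupancy_dip` for a test robust to that.
    """
    hist, _ = np.histogram(occupancy, bins=bins, range=(0.0, 1.0))
    interior = hist[1:-1].max() if bins > 2 else 0
    return bool(hist[0] > interior and hist[-1] > interior)


def has_occupancy_dip(occupancy: np.ndarray, bins: int = 10) -> bool:
    """Dip test for bimodality: mid-range deciles below both extremes.

    True when every bin in the central 0.3-0.7 occupancy range holds fewer
    populations than each of the two extreme deciles, and both extremes are
    occupied — i.e. the distribution has modes near 0 and 1 with an interior
    minimum.
    """
    hist, edges = np.histogram(occupancy, bins=bins, range=(0.0, 1.0))
    centres = 0.5 * (edges[:-1] + edges[1:])
    mid = hist[(centres > 0.3) & (centres < 0.7)]
    if hist[0] == 0 or hist[-1] == 0 or len(mid) == 0:
        return False
    return bool(mid.max() < hist[0] and mid.max() < hist[-1])


def richness_timeseries(P: np.ndarray) -> np.ndarray:
    """Per-patch species richness at every sample: shape (N, T)."""
    return P.sum(axis=0)


def neighbourhood_richness(
    P_or_B: np.ndarray,
    landscape: Landscape,
    threshold: float = DETECTION_THRESHOLD,
) -> np.ndarray:
    """Distinct species in each patch plus its Gabriel neighbours.

    Accepts a biomass/presence matrix (S, N) or tensor (S, N, T); tensors are
    pooled over time before the union.  Isolated patches reduce to local
    richness.
    """
    arr = np.asarray(P_or_B)
    if arr.ndim == 3:
        present = (arr > threshold).any(axis=2) if arr.dtype != bool else arr.any(axis=2)
    else:
        present = arr > threshold if arr.dtype != bool else arr
    counts = np.zeros(landscape.N, dtype=int)
    for x in range(landscape.N):
        patches = np.concatenate([[x], landscape.neighbours(x)])
        counts[x] = int(present[:, patches].any(axis=1).sum())
    return counts


# ---------------------------------------------------------------------------
# species-time-area relation
# ---------------------------------------------------------------------------


@dataclass
class STARResult:
    """Mean observed richness over sliding space-time windows, with exponents.

    ``table[a, b]`` is the mean richness in windows of ``area_windows[a]``
    patches and ``time_windows[b]`` samples.  ``z[b]`` is the species-area
    exponent conditioned on the b-th time window, ``w[a]`` the species-time
    exponent conditioned on the a-th area window; both are the maximum
    successive slope of the curve on log10-log10 axes.
    """

    area_windows: np.ndarray
    time_windows: np.ndarray
    table: np.ndarray  # (len(area_windows), len(time_windows))
    z: np.ndarray  # per time window
    w: np.ndarray  # per area window

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.table, index=self.area_windows, columns=self.time_windows
        ).rename_axis(index="delta_A", columns="delta_T")


def _max_loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum slope between successive points on double-log axes."""
    lx, ly = np.log10(x), np.log10(y)
    slopes = np.diff(ly) / np.diff(lx)
    return float(np.max(slopes)) if len(slopes) else np.nan


def star(
    P: np.ndarray,
    coords: np.ndarray,
    area_windows=None,
    time_windows=None,
) -> STARResult:
    """Species-time-area relation by the sliding-window approach.

    For every focal patch the spatial window of size ``dA`` is the patch plus
    its ``dA - 1`` nearest patches (Euclidean distance, ties broken by patch
    index); for every start ``t`` the temporal window covers samples
    ``[t, t + dT)``.  Observed richness is the number of species present at
    least once anywhere in the window, averaged over all focal patches and
    starts.  Exponents z (area) and w (time) are the maximum successive
    log-log slopes of the mean-richness curves.
    """
    S, N, T = P.shape
    if area_windows is None:
        area_windows = [a for a in 2 ** np.arange(0, 9) if a <= N]
    if time_windows is None:
        time_windows = [dt for dt in (1, 5, 10, 50, 100, 500, 1000) if dt <= T]
    area_windows = np.asarray(sorted(area_windows), dtype=int)
    time_windows = np.asarray(sorted(time_windows), dtype=int)
    if area_windows.max() > N:
        raise ValueError("spatial window exceeds the number of patches")
    if time_windows.max() > T:
        raise ValueError("temporal window exceeds the series length")

    coords = np.asarray(coords, float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    # stable argsort breaks distance ties by patch index
    order = np.argsort(d, axis=1, kind="stable")

    table = np.zeros((len(area_windows), len(time_windows)))
    for a_i, dA in enumerate(area_windows):
        # per focal patch: presence pooled over its window patches -> (S, N, T)
        pooled = np.zeros((S, N, T), dtype=bool)
        for x in range(N):
            pooled[:, x, :] = P[:, order[x, :dA], :].any(axis=1)
        cs = np.concatenate(
            [np.zeros((S, N, 1), dtype=np.int32),
             np.cumsum(pooled, axis=2, dtype=np.int32)], axis=2
        )
        for t_i, dT in enumerate(time_windows):
            # sliding "any" over dT samples via cumulative sums
            window_any = (cs[:, :, dT:] - cs[:, :, :-dT]) > 0  # (S, N, T-dT+1)
            richness = window_any.sum(axis=0)  # (N, starts)
            table[a_i, t_i] = richness.mean()

    z = np.array(
        [_max_loglog_slope(area_windows, table[:, b]) for b in range(len(time_windows))]
    )
    w = np.array(
        [_max_loglog_slope(time_windows, table[a, :]) for a in range(len(area_windows))]
    )
    return STARResult(
        area_windows=area_windows, time_windows=time_windows, table=table, z=z, w=w
    )


# ---------------------------------------------------------------------------
# beta diversities and community structure
# ---------------------------------------------------------------------------


def beta_diversities(
    snapshot: np.ndarray | None = None,
    timeseries: CommunityTimeseries | None = None,
    subsample_stride: int = 10,
) -> tuple[float, float]:
    """Spatial and temporal turnover as mean Bray-Curtis dissimilarities.

    ``beta_s`` is the mean pairwise inter-patch Bray-Curtis of a biomass
    snapshot (S, N); ``beta_t`` is the mean over patches of the mean
    off-diagonal temporal Bray-Curtis.  Either input may be omitted, in which
    case the corresponding value is NaN.  With a timeseries but no snapshot,
    beta_s is computed from the final sample.
    """
    beta_s = beta_t = np.nan
    if snapshot is None and timeseries is not None:
        snapshot = timeseries.tensor[:, :, -1]
    if snapshot is not None:
        snapshot = np.asarray(snapshot, float)
        N = snapshot.shape[1]
        if N >= 2 and snapshot.sum() > 0:
            nonempty = snapshot[:, snapshot.sum(axis=0) > 0]
            if nonempty.shape[1] >= 2:
                Dm = _bc_matrix(nonempty)
                n = Dm.shape[0]
                beta_s = float(Dm.sum() / (n * (n - 1)))
            else:
                beta_s = 0.0
        elif N >= 2:
            beta_s = np.nan
        else:
            beta_s = 0.0
    if timeseries is not None:
        vals = []
        for x in range(timeseries.tensor.shape[1]):
            _, mean_bc = detect_turnover(timeseries, x, subsample_stride)
            vals.append(mean_bc)
        beta_t = float(np.mean(vals))
    return beta_s, beta_t


def abundance_structure(
    timeseries: CommunityTimeseries, patch: int, times: np.ndarray
) -> tuple[list[np.ndarray], float]:
    """Rank-abundance vectors at chosen times, with a distribution distance.

    Returns the descending-sorted abundance vectors at each requested sample
    index and the maximum two-sample Kolmogorov-Smirnov statistic between the
    log-abundance distributions of any pair of them (populations above the
    detection threshold only) — small values mean the macroscopic community
    structure is time-invariant even when identities reshuffle.
    """
    from scipy.stats import ks_2samp

    vectors = [np.sort(timeseries.patch(patch)[:, t])[::-1] for t in times]
    dists = []
    for a in range(len(vectors)):
        for b in range(a + 1, len(vectors)):
            va = vectors[a][vectors[a] > DETECTION_THRESHOLD]
            vb = vectors[b][vectors[b] > DETECTION_THRESHOLD]
            if len(va) and len(vb):
                dists.append(ks_2samp(np.log(va), np.log(vb)).statistic)
    return vectors, (float(max(dists)) if dists else 0.0)
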