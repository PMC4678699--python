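"""ST-ISODATA clustering core.

ISODATA is a k-means-like unsupervised segmentation algorithm whose cluster
count adapts to the data: at each iteration voxels are reassigned to the
nearest centroid (Mahalanobis distance), clusters that fall below a minimum
size (phi_N) are discarded, clusters whose internal dispersion (D_intra)
exceeds phi_S are split, and cluster pairs closer than phi_C (D_inter) are
merged. The live cluster count is confined to the open range
(0.5*K, 2*K + 1) around the configured anchor K.

Dispersion parameters are conventionally derived from the data itself:
phi_C as the Mahalanobis distance between the contralateral white-matter and
grey-matter mean feature vectors, and phi_S as the pooled standard deviation
of white-matter feature values. All Mahalanobis computations share a single
global diagonal covariance estimated from every analysis-mask row (close to
the identity when features are z-scored), regularized by adding
1e-6 x mean(diagonal); this keeps centroid-to-centroid distances symmetric
and well-defined.

Initialization is semi-randomized: the first centroid is a uniformly random
data row; each further centroid is the row at which the cumulative summed
distance to the previously chosen centroids first exceeds a uniform random
fraction of the total — rows far from the existing centroids are picked with
proportionally higher probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

#: Ridge added to the covariance diagonal, as a fraction of its mean.
COV_REGULARIZATION = 1e-6

#: Denominator guard in the relative centroid-displacement convergence error.
CONVERGENCE_EPS = 1e-12

#: Child-centroid offset along the max-variance axis, in sd units.
SPLIT_GAMMA = 0.5


@dataclass
class IsodataParams:
    """Tunable ISODATA parameters.

    phi_n: minimum voxels per cluster; phi_c: minimum inter-cluster distance;
    phi_s: maximum intra-cluster dispersion; k_init: initial cluster guess;
    k_anchor: anchor K of the allowed cluster-count range (0.5K, 2K+1);
    max_iter: iteration cap I; eps_r: convergence error threshold;
    max_merges: merges allowed per iteration (L).
    """

    phi_n: int = 100
    phi_c: float | None = None
    phi_s: float | None = None
    k_init: int = 6
    k_anchor: int = 8
    max_iter: int = 100
    eps_r: float = 1e-4
    max_merges: int = 1

    def __post_init__(self) -> None:
        if self.phi_n < 1:
            raise ValueError("phi_n must be >= 1")
        if self.k_init < 1 or self.k_anchor < 1:
            raise ValueError("k_init and k_anchor must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.eps_r <= 0:
            raise ValueError("eps_r must be positive")
        if self.max_merges < 1:
            raise ValueError("max_merges must be >= 1")
        for name in ("phi_c", "phi_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def min_clusters(self) -> int:
        """Smallest integer strictly greater than 0.5*K."""
        return int(np.floor(0.5 * self.k_anchor)) + 1

    @property
    def max_clusters(self) -> int:
        """Largest integer strictly less than 2*K + 1."""
        return 2 * self.k_anchor


@dataclass
class ClusterModel:
    """Result of an ISODATA run.

    Centroids live in the (possibly z-scored) feature space; ``assignments``
    gives a cluster index per feature row. ``covariance`` is the global
    diagonal used for every Mahalanobis distance. ``feature_index`` and the
    standardization columns are copied from the feature matrix so centroids
    can be mapped back to relative units without it.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    covariance: np.ndarray
    voxel_index: np.ndarray
    feature_index: tuple
    grid_shape: tuple
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    iteration_log: list = field(default_factory=list)
    seed: int | None = None
    params: IsodataParams | None = None
    converged: bool = False
    n_iterations: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)

    def centroids_relative(self) -> np.ndarray:
        """Centroids mapped back to relative (rADC/rFA/rT2) units."""
        if self.column_means is None:
            return self.centroids.copy()
        return self.centroids * self.column_sds + self.column_means

    def labels_volume(self, offset: int = 1, fill: int = 0) -> np.ndarray:
        """Scatter assignments onto the 3D grid (cluster ids offset by 1)."""
        out = np.full(self.grid_shape, fill, dtype=np.int32)
        x, y, z = self.voxel_index.T
        out[x, y, z] = self.assignments + offset
        return out


def global_covariance(features: FeatureMatrix) -> np.ndarray:
    """Regularized global diagonal covariance of all feature rows."""
    var = features.data.var(axis=0)
    return var + COV_REGULARIZATION * float(var.mean())


def mahalanobis(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Mahalanobis distance sqrt((x-mu)^T cov^-1 (x-mu)).

    ``cov`` may be a 1-D diagonal or a full symmetric positive-definite
    matrix.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape:
        raise ValueError("x and mu dimensions differ")
    d = x - mu
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 1:
        if np.any(cov <= 0):
            raise np.linalg.LinAlgError("singular diagonal covariance")
        q = float(np.sum(d * d / cov))
    else:
        try:
            sol = np.linalg.solve(cov, d)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular covariance") from exc
        q = float(d @ sol)
    return float(np.sqrt(max(q, 0.0)))


def _whiten(X: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Scale coordinates so Euclidean distance equals Mahalanobis distance."""
    return X / np.sqrt(cov)


def derive_dispersion_params(
    features: FeatureMatrix, wm_roi: np.ndarray, gm_roi: np.ndarray
) -> tuple:
    """Data-derived (phi_c, phi_s) from contralateral WM and GM ROIs.

    phi_c is the Mahalanobis distance between the WM and GM mean feature
    vectors under the global covariance; phi_s is the population standard
    deviation of all WM feature values pooled over rows and columns.
    """
    wm_rows = features.rows_for_mask(wm_roi)
    gm_rows = features.rows_for_mask(gm_roi)
    if len(wm_rows) < 2 or len(gm_rows) < 2:
        raise ValueError("WM and GM reference ROIs must each cover >= 2 voxels")
    cov = global_covariance(features)
    wm_mean = features.data[wm_rows].mean(axis=0)
    gm_mean = features.data[gm_rows].mean(axis=0)
    phi_c = mahalanobis(wm_mean, gm_mean, cov)
    phi_s = float(features.data[wm_rows].std())
    return phi_c, phi_s


def initialize_centroids(
    features: FeatureMatrix, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Semi-randomized distance-proportional centroid seeding.

    The first centroid is a uniformly random row. For each subsequent
    centroid, every row's summed distance to the already chosen centroids is
    accumulated and the row where the running sum first exceeds
    u x (grand total), u ~ Uniform(0, 1), becomes the next centroid.
    Distances here are Euclidean in the feature space as given; the global
    covariance is deliberately not applied, because it absorbs the
    between-cluster spread and would flatten the very contrast the
    distance-proportional seeding relies on.
    """
    X = features.data
    n = len(X)
    if k > n:
        raise ValueError(f"cannot initialize {k} centroids from {n} rows")
    Xw = X

    chosen = [int(rng.integers(n))]
    available = np.ones(n, dtype=bool)
    available[chosen[0]] = False
    summed = np.zeros(n)
    for _ in range(1, k):
        summed += np.linalg.norm(Xw - Xw[chosen[-1]], axis=1)
        weights = np.where(available, summed, 0.0)
        total = float(weights.sum())
        if total <= 0:
            raise ValueError(
                f"cannot initialize {k} centroids: fewer than {k} distinct rows"
            )
        u = float(rng.uniform())
        cut = int(np.searchsorted(np.cumsum(weights), u * total, side="right"))
        cut = min(cut, n - 1)
        chosen.append(cut)
        available[cut] = False
    return X[chosen].copy()


def assign_voxels(
    X: np.ndarray, centroids: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Assign each row to its Mahalanobis-nearest centroid (ties: lowest id)."""
    if len(centroids) < 1:
        raise ValueError("need at least one centroid")
    Xw = _whiten(np.asarray(X, dtype=float), cov)
    Cw = _whiten(np.asarray(centroids, dtype=float), cov)
    return np.argmin(cdist(Xw, Cw), axis=1)


def _recompute_centroids(
    X: np.ndarray, assignments: np.ndarray, n_clusters: int
) -> tuple:
    """Means per live (non-empty) cluster; empty clusters are dropped and
    assignments renumbered."""
    sizes = np.bincount(assignments, minlength=n_clusters)
    live = np.nonzero(sizes > 0)[0]
    remap = -np.ones(n_clusters, dtype=int)
    remap[live] = np.arange(len(live))
    assignments = remap[assignments]
    centroids = np.stack([X[assignments == j].mean(axis=0) for j in range(len(live))])
    return centroids, assignments


def intra_cluster_distances(
    X: np.ndarray, centroids: np.ndarray, assignments: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """D_intra per cluster: mean Mahalanobis distance of members to centroid."""
    Xw = _whiten(X, cov)
    Cw = _whiten(centroids, cov)
    out = np.zeros(len(centroids))
    for j in range(len(centroids)):
        members = assignments == j
        if members.any():
            out[j] = float(np.linalg.norm(Xw[members] - Cw[j], axis=1).mean())
    return out


def inter_cluster_distances(centroids: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """D_inter matrix: Mahalanobis distance between every centroid pair."""
    Cw = _whiten(centroids, cov)
    return cdist(Cw, Cw)


def discard_small_clusters(
    X: np.ndarray,
    centroids: np.ndarray,
    assignments: np.ndarray,
    cov: np.ndarray,
    phi_n: int,
    events: list | None = None,
) -> tuple:
    """Drop clusters below phi_n voxels, reassigning their rows.

    Rows of a discarded cluster move to the nearest surviving centroid, and
    surviving centroids are recomputed. Raises if every cluster is below
    phi_n (degenerate configuration).
    """
    sizes = np.bincount(assignments, minlength=len(centroids))
    keep = sizes >= phi_n
    if keep.all():
        return centroids, assignments
    if not keep.any():
        raise ValueError(
            f"all {len(centroids)} clusters are smaller than phi_n={phi_n}"
        )
    if events is not None:
        events.append(
            {"event": "discard", "clusters": np.nonzero(~keep)[0].tolist(),
             "sizes": sizes[~keep].tolist()}
        )
    surviving = centroids[keep]
    orphan = ~keep[assignments]
    remap = -np.ones(len(centroids), dtype=int)
    remap[keep] = np.arange(int(keep.sum()))
    assignments = remap[assignments]
    if orphan.any():
        assignments[orphan] = assign_voxels(X[orphan], surviving, cov)
    centroids, assignments = _recompute_centroids(X, assignments, len(surviving))
    return centroids, assignments


def split_cluster(
    X: np.ndarray,
    centroids: np.ndarray,
    assignments: np.ndarray,
    cov: np.ndarray,
    cluster_id: int,
    phi_n: int,
    phi_c: float = 0.0,
    events: list | None = None,
) -> tuple:
    """Split one cluster along its axis of largest per-column sd.

    Children start at mu +/- SPLIT_GAMMA * sd_max * e_max and the cluster's
    rows are divided between them by distance. The split is skipped (with a
    log entry) if either child would fall below phi_n, or if the children's
    final centroids would sit closer than phi_c — such a pair fails the
    inter-cluster separation criterion and would be merged straight back,
    so performing the split would only make the loop thrash.
    """
    members = np.nonzero(assignments == cluster_id)[0]
    rows = X[members]
    sds = rows.std(axis=0)
    axis = int(np.argmax(sds))
    offset = np.zeros(X.shape[1])
    offset[axis] = SPLIT_GAMMA * sds[axis]
    mu = centroids[cluster_id]
    children = np.stack([mu - offset, mu + offset])
    side = assign_voxels(rows, children, cov)
    if min((side == 0).sum(), (side == 1).sum()) < phi_n:
        if events is not None:
            events.append(
                {"event": "split_skipped", "cluster": int(cluster_id),
                 "reason": "child below phi_n"}
            )
        return centroids, assignments, False
    child0 = rows[side == 0].mean(axis=0)
    child1 = rows[side == 1].mean(axis=0)
    if phi_c > 0 and mahalanobis(child0, child1, cov) < phi_c:
        if events is not None:
            events.append(
                {"event": "split_skipped", "cluster": int(cluster_id),
                 "reason": "children closer than phi_c"}
            )
        return centroids, assignments, False
    new_id = len(centroids)
    assignments = assignments.copy()
    assignments[members[side == 1]] = new_id
    centroids = np.vstack([centroids, children[1]])
    centroids[cluster_id] = child0
    centroids[new_id] = child1
    if events is not None:
        events.append({"event": "split", "cluster": int(cluster_id)})
    return centroids, assignments, True


def merge_clusters(
    X: np.ndarray,
    centroids: np.ndarray,
    assignments: np.ndarray,
    cov: np.ndarray,
    phi_c: float,
    max_merges: int,
    min_clusters: int,
    events: list | None = None,
) -> tuple:
    """Merge the closest centroid pairs with D_inter < phi_c.

    At most ``max_merges`` merges per call; merging stops if it would push
    the live cluster count below the lower bound of the allowed range. The
    merged centroid is the size-weighted mean of the pair.
    """
    merged_any = False
    for _ in range(max_merges):
        if len(centroids) <= min_clusters:
            break
        dists = inter_cluster_distances(centroids, cov)
        np.fill_diagonal(dists, np.inf)
        i, j = np.unravel_index(np.argmin(dists), dists.shape)
        if dists[i, j] >= phi_c:
            break
        i, j = int(min(i, j)), int(max(i, j))
        sizes = np.bincount(assignments, minlength=len(centroids))
        w = sizes[i] + sizes[j]
        centroids[i] = (sizes[i] * centroids[i] + sizes[j] * centroids[j]) / max(w, 1)
        assignments = np.where(assignments == j, i, assignments)
        keep = np.arange(len(centroids)) != j
        remap = -np.ones(len(centroids), dtype=int)
        remap[keep] = np.arange(len(centroids) - 1)
        assignments = remap[assignments]
        centroids = centroids[keep]
        merged_any = True
        if events is not None:
            events.append({"event": "merge", "clusters": [i, j]})
    return centroids, assignments, merged_any


def _convergence_error(
    old: np.ndarray, new: np.ndarray
) -> float:
    """Max relative centroid displacement; infinite if the count changed."""
    if old.shape != new.shape:
        return float("inf")
    num = np.linalg.norm(new - old, axis=1)
    den = np.linalg.norm(old, axis=1) + CONVERGENCE_EPS
    return float((num / den).max())


def run_isodata(
    features: FeatureMatrix, params: IsodataParams, seed: int = 0
) -> ClusterModel:
    """Run the full ISODATA loop on a feature matrix.

    Per iteration: assign rows to nearest centroids, recompute centroids,
    discard undersized clusters, then either split the worst over-dispersed
    cluster (odd iterations, or whenever the count has fallen to the lower
    bound) or merge under-separated pairs (even iterations). The loop stops
    when the maximum relative centroid displacement across an iteration falls
    below eps_r, or after max_iter iterations (non-convergence is logged,
    not an error).
    """
    if params.phi_c is None or params.phi_s is None:
        raise ValueError(
            "phi_c and phi_s must be set (use derive_dispersion_params)"
        )
    X = features.data
    if len(X) < params.phi_n:
        raise ValueError(
            f"{len(X)} rows cannot support clusters of phi_n={params.phi_n}"
        )
    rng = np.random.default_rng(seed)
    cov = global_covariance(features)
    centroids = initialize_centroids(features, params.k_init, rng)

    iteration_log = []
    assignments = None
    converged = False
    n_iter = 0
    seen_states: dict = {}
    prev_state = None
    for it in range(1, params.max_iter + 1):
        n_iter = it
        events: list = []
        prev_centroids = centroids.copy()

        assignments = assign_voxels(X, centroids, cov)
        centroids, assignments = _recompute_centroids(X, assignments, len(centroids))

        if params.phi_n > 1:
            centroids, assignments = discard_small_clusters(
                X, centroids, assignments, cov, params.phi_n, events
            )

        d_intra = intra_cluster_distances(X, centroids, assignments, cov)
        d_inter = inter_cluster_distances(centroids, cov)

        below_min = len(centroids) < params.min_clusters
        if below_min or it % 2 == 1:
            # Split the worst offender (largest D_intra above phi_s), if the
            # upper bound leaves room. When discarding has pushed the count
            # below the allowed range, splitting is forced regardless of
            # parity and of phi_s to restore the count.
            if below_min:
                eligible = np.arange(len(centroids))
            else:
                eligible = np.nonzero(d_intra > params.phi_s)[0]
            if len(eligible) and len(centroids) < params.max_clusters:
                worst = int(eligible[np.argmax(d_intra[eligible])])
                centroids, assignments, _ = split_cluster(
                    X, centroids, assignments, cov, worst, params.phi_n,
                    events=events,
                )
            elif len(eligible):
                events.append({"event": "split_skipped", "reason": "at upper bound"})
        if not below_min and it % 2 == 0 and len(centroids) >= 2:
            centroids, assignments, _ = merge_clusters(
                X, centroids, assignments, cov, params.phi_c,
                params.max_merges, params.min_clusters, events,
            )

        centroids, assignments = _recompute_centroids(X, assignments, len(centroids))
        err = _convergence_error(prev_centroids, centroids)
        iteration_log.append(
            {
                "iteration": it,
                "n_clusters": int(len(centroids)),
                "sizes": np.bincount(assignments, minlength=len(centroids)).tolist(),
                "d_intra": np.round(d_intra, 6).tolist(),
                "d_inter_min": float(np.min(d_inter[np.triu_indices(len(d_inter), 1)]))
                if len(d_inter) > 1
                else None,
                "events": events,
                "convergence_error": err if np.isfinite(err) else None,
            }
        )
        if err < params.eps_r:
            converged = True
            break

        # The split and merge rules can undo each other indefinitely (a
        # split cluster whose children sit closer than phi_c is merged back
        # next iteration). Detect the resulting limit cycle by hashing the
        # partition: on recurrence, stop at the cycle state with the fewest
        # clusters — there every surviving pair separation is maximal.
        state_key = (len(centroids), assignments.tobytes())
        if state_key in seen_states:
            if prev_state is not None and len(prev_state[0]) < len(centroids):
                centroids, assignments = prev_state
                events.append({"event": "cycle_stop", "kept": "previous state"})
            else:
                events.append({"event": "cycle_stop", "kept": "current state"})
            iteration_log[-1]["events"] = events
            converged = True
            break
        seen_states[state_key] = it
        prev_state = (centroids.copy(), assignments.copy())

    if not converged:
        logger.info("ISODATA reached max_iter=%d without converging", params.max_iter)

    return ClusterModel(
        centroids=centroids,
        assignments=assignments,
        covariance=cov,
        voxel_index=features.voxel_index,
        feature_index=features.feature_index,
        grid_shape=features.shape,
        column_means=None
        if features.column_means is None
        else features.column_means.copy(),
        column_sds=None if features.column_sds is None else features.column_sds.copy(),
        iteration_log=iteration_log,
        seed=seed,
        params=params,
        converged=converged,
        n_iterations=n_iter,
    )
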