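"""Automated image deconvolution from per-well excision ratios.

The pipeline turns 96 bounded excision fractions into a binary image:

1. *Outlier curation* — Local Outlier Factor on the 1-D ratio values;
   detected outliers are reassigned to the nearest inlier value. This
   removes small low-density clusters and sharpens cluster edges before
   clustering.
2. *Clustering* — one of: exact 1-D k-means (optimal contiguous partition
   by dynamic programming), DBSCAN, OPTICS, or a univariate Gaussian
   mixture fitted by EM.
3. *Full ON/OFF assessment* — the plate is called all-ones when every
   cluster mean exceeds the calibrated cutoff, all-zeros when every mean
   falls below it.
4. *Cluster grouping* — for mixed plates, clusters collapse to binary
   states: the blue channel maps the lowest-mean cluster to OFF and the
   rest to ON; the red channel maps the two lowest-mean clusters to OFF
   (its raw ratio distribution sits higher overall).

An oracle threshold (exhaustive scan against a known ground truth) is
provided for benchmarking the unsupervised pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .grid import N_WELLS, BitGrid, accuracy as grid_accuracy, error_mask
from .readout import RatioTable

# Default LOF neighborhood sizes, tuned per color channel.
LOF_NEIGHBORS = {"blue": 20, "red": 10}


# ---------------------------------------------------------------------------
# Local Outlier Factor, from first principles (1-D)
# ---------------------------------------------------------------------------

def lof_scores(values: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Local Outlier Factor of each value among the given 1-D values.

    For each point: its k nearest neighbors (ties broken by index order),
    k-distance, reachability distance ``max(kdist(q), d(p, q))``, local
    reachability density (LRD, inverse mean reachability — infinite for
    points whose neighborhood collapses onto duplicates), and
    LOF = mean over neighbors of ``LRD(q) / LRD(p)`` with the conventions
    inf/inf = 1, finite/inf = 0. LOF ~ 1 marks inliers.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if n_neighbors >= n:
        raise ValueError("need at least n_neighbors + 1 points")
    d = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(d, np.inf)  # a point is not its own neighbor
    order = np.argsort(d, axis=1, kind="stable")
    neigh = order[:, :n_neighbors]  # (n, k) neighbor indices
    kdist = np.take_along_axis(d, neigh[:, -1:], axis=1)[:, 0]
    # reachability distance from each point to each of its neighbors
    reach = np.maximum(kdist[neigh], np.take_along_axis(d, neigh, axis=1))
    mean_reach = reach.mean(axis=1)
    with np.errstate(divide="ignore"):
        lrd = np.where(mean_reach > 0, 1.0 / np.where(mean_reach > 0, mean_reach, 1), np.inf)
    # LOF with explicit inf conventions
    scores = np.empty(n)
    for i in range(n):
        nb = lrd[neigh[i]]
        if np.isinf(lrd[i]):
            ratios = np.where(np.isinf(nb), 1.0, 0.0)
        else:
            ratios = nb / lrd[i]
        scores[i] = ratios.mean()
    return scores


@dataclass
class OutlierResult:
    """LOF labels (+1 inlier / -1 outlier), scores, and curated values."""

    labels: np.ndarray
    scores: np.ndarray
    curated: np.ndarray | None = None

    @property
    def n_outliers(self) -> int:
        return int((self.labels == -1).sum())


def lof_detect(
    values: np.ndarray,
    n_neighbors: int = 20,
    contamination: float = 0.05,
    threshold: float = 2.5,
) -> OutlierResult:
    """Flag low-density outliers among 1-D ratio values.

    A point is an outlier when its LOF exceeds both the absolute
    ``threshold`` and the strict (1 - contamination) score quantile. The
    default threshold of 2.5 sits well above the LOF values that finite
    uniform backgrounds produce at their edges (up to about 2 in 1-D)
    while genuinely detached points score far higher; the quantile term
    caps the flagged fraction at roughly ``contamination`` and leaves
    duplicate-saturated data (where every score ties) untouched.
    """
    x = np.asarray(values, dtype=float)
    if x.size <= n_neighbors:
        warnings.warn(
            f"lof_detect: only {x.size} values for n_neighbors={n_neighbors}; "
            "treating all as inliers",
            stacklevel=2,
        )
        return OutlierResult(
            labels=np.ones(x.size, dtype=int), scores=np.ones(x.size)
        )
    scores = lof_scores(x, n_neighbors)
    cut = np.quantile(scores, 1.0 - contamination)
    outlier = (scores > threshold) & (scores > cut)
    labels = np.where(outlier, -1, 1)
    return OutlierResult(labels=labels, scores=scores)


def reassign_outliers(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Replace each outlier's value with the nearest inlier value
    (absolute difference; ties resolve to the lower value). Idempotent;
    identity when there are no inliers (with a warning)."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    inliers = x[labels == 1]
    if inliers.size == 0:
        warnings.warn("reassign_outliers: no inliers; returning values unchanged",
                      stacklevel=2)
        return x.copy()
    out = x.copy()
    pool = np.sort(inliers)
    for i in np.nonzero(labels == -1)[0]:
        diffs = np.abs(pool - x[i])
        # argmin on sorted pool returns the lowest value among ties
        out[i] = pool[int(np.argmin(diffs))]
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """A fitted 1-D clustering: means sorted ascending (M0 < M1 < ...),
    labels remapped so label i belongs to mean M_i."""

    method: str
    k: int
    means: np.ndarray
    labels: np.ndarray
    settings: dict = field(default_factory=dict)
    weights: np.ndarray | None = None  # gmm only
    variances: np.ndarray | None = None  # gmm only
    log_likelihood: float | None = None  # gmm only
    seed: int | None = None


def _sorted_model(
    method: str,
    raw_labels: np.ndarray,
    values: np.ndarray,
    settings: dict,
    seed: int | None = None,
    weights: np.ndarray | None = None,
    variances: np.ndarray | None = None,
    log_likelihood: float | None = None,
) -> ClusterModel:
    """Normalize arbitrary cluster labels: drop empty clusters, compute
    means from members, sort ascending, remap labels accordingly."""
    uniq = np.unique(raw_labels)
    means = np.array([values[raw_labels == u].mean() for u in uniq])
    order = np.argsort(means, kind="stable")
    remap = {int(uniq[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(u)] for u in raw_labels])
    kw = {}
    if weights is not None:
        kw["weights"] = weights[uniq.astype(int)][order]
    if variances is not None:
        kw["variances"] = variances[uniq.astype(int)][order]
    return ClusterModel(
        method=method,
        k=len(uniq),
        means=means[order],
        labels=labels,
        settings=settings,
        seed=seed,
        log_likelihood=log_likelihood,
        **kw,
    )


def kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means: the globally optimal partition minimizing
    within-cluster sum of squares is contiguous in sorted order and found
    by dynamic programming. Returns labels (0..k-1 by ascending value).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs**2)))

    def sse(i: int, j: int) -> float:  # cost of segment xs[i:j]
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    NEG = np.inf
    cost = np.full((k + 1, n + 1), NEG)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                if cost[c - 1, i] == np.inf:
                    continue
                v = cost[c - 1, i] + sse(i, j)
                if v < best - 1e-15:
                    best, arg = v, i
            cost[c, j] = best
            cut[c, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = cut[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def fit_gmm_1d(
    values: np.ndarray,
    n_components: int = 3,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = 1e-6,
    allow_reduce: bool = False,
) -> ClusterModel:
    """Univariate Gaussian mixture fitted by EM.

    Initialized from the exact 1-D k-means partition (deterministic), with
    a variance floor against degenerate components. The log-likelihood is
    non-decreasing across iterations; labels are maximum-responsibility
    components, and components are reported sorted by mean.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    n_distinct = np.unique(x).size
    if n_distinct < n_components:
        if not allow_reduce:
            raise ValueError(
                f"need >= {n_components} distinct values, got {n_distinct}"
            )
        warnings.warn(
            f"fit_gmm_1d: reducing n_components {n_components} -> {n_distinct} "
            "(too few distinct values)",
            stacklevel=2,
        )
        n_components = n_distinct
    k = n_components
    init = kmeans_1d(x, k)
    means = np.array([x[init == c].mean() for c in range(k)])
    variances = np.array(
        [max(x[init == c].var(), var_floor) for c in range(k)]
    )
    weights = np.array([(init == c).mean() for c in range(k)])
    ll_prev = -np.inf
    ll = ll_prev
    history: list[float] = []
    for _ in range(max_iter):
        # E step (log domain)
        log_pdf = (
            -0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        log_joint = np.log(weights)[None, :] + log_pdf
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        history.append(ll)
        resp = np.exp(log_joint - log_norm[:, None])
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        weights = nk / n
    # final E step so labels/likelihood reflect the returned parameters
    log_pdf = (
        -0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    log_joint = np.log(weights)[None, :] + log_pdf
    log_norm = logsumexp(log_joint, axis=1)
    ll = float(log_norm.sum())
    resp = np.exp(log_joint - log_norm[:, None])
    raw_labels = np.argmax(resp, axis=1)
    # a component can lose all its points; _sorted_model drops empties
    return _sorted_model(
        "gmm",
        raw_labels,
        x,
        settings={
            "n_components": k,
            "tol": tol,
            "max_iter": max_iter,
            "ll_history": history,
        },
        seed=seed,
        weights=weights,
        variances=variances,
        log_likelihood=ll,
    )


def cluster_1d(
    values: np.ndarray,
    method: str = "gmm",
    k: int = 3,
    eps: float = 0.2,
    min_samples: int = 5,
    xi: float = 0.05,
    seed: int | None = 0,
) -> ClusterModel:
    """Cluster 1-D ratio values with one of the four supported methods.

    k-means and the Gaussian mixture are this package's own exact-DP /
    EM implementations; DBSCAN and OPTICS come from scikit-learn. Noise
    points from the density methods are reassigned to the cluster of the
    nearest clustered value; if everything is noise, a single cluster is
    returned with a warning. Requested k is clamped to the number of
    distinct values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values to cluster")
    n_distinct = np.unique(x).size
    if method in ("kmeans", "gmm") and k > n_distinct:
        warnings.warn(
            f"cluster_1d: clamping k {k} -> {n_distinct} (distinct values)",
            stacklevel=2,
        )
        k = n_distinct
    if method == "kmeans":
        raw = kmeans_1d(x, k)
        return _sorted_model("kmeans", raw, x, settings={"k": k}, seed=seed)
    if method == "gmm":
        model = fit_gmm_1d(x, n_components=k, seed=seed, allow_reduce=True)
        return model
    if method in ("dbscan", "optics"):
        from sklearn.cluster import DBSCAN, OPTICS

        X = x.reshape(-1, 1)
        if method == "dbscan":
            raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
            settings = {"eps": eps, "min_samples": min_samples}
        else:
            ms = min(min_samples, max(2, x.size - 1))
            raw = OPTICS(min_samples=ms, xi=xi).fit_predict(X)
            settings = {"min_samples": ms, "xi": xi}
        raw = _absorb_noise(x, raw)
        return _sorted_model(method, raw, x, settings=settings, seed=seed)
    raise ValueError(f"unknown clustering method: {method!r}")


def _absorb_noise(x: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Attach density-method noise points (-1) to the cluster of the
    nearest clustered value; all-noise collapses to one cluster."""
    raw = raw.copy()
    noise = raw == -1
    if not noise.any():
        return raw
    if noise.all():
        warnings.warn(
            "cluster_1d: all points labelled noise; falling back to a "
            "single cluster",
            stacklevel=3,
        )
        return np.zeros_like(raw)
    clustered_idx = np.nonzero(~noise)[0]
    for i in np.nonzero(noise)[0]:
        j = clustered_idx[np.argmin(np.abs(x[clustered_idx] - x[i]))]
        raw[i] = raw[j]
    return raw


# ---------------------------------------------------------------------------
# Full ON/OFF, grouping, composition
# ---------------------------------------------------------------------------

class Mode(Enum):
    MIXED = "mixed"
    ALL_ON = "all_on"
    ALL_OFF = "all_off"


def full_on_off_check(model: ClusterModel, cutoff: float = 0.5) -> Mode:
    """Plate-level call: ALL_ON when even the lowest cluster mean exceeds
    the cutoff, ALL_OFF when even the highest falls below it."""
    if model.means.min() > cutoff:
        return Mode.ALL_ON
    if model.means.max() < cutoff:
        return Mode.ALL_OFF
    return Mode.MIXED


def calibrate_cutoff(models: list[ClusterModel]) -> float:
    """Cutoff calibration from a collection of fitted plates: midpoint
    between the grand mean of the lowest-cluster means and the grand mean
    of the highest-cluster means."""
    if not models:
        raise ValueError("need at least one fitted model to calibrate")
    lows = [m.means.min() for m in models]
    highs = [m.means.max() for m in models]
    return float((np.mean(lows) + np.mean(highs)) / 2.0)


def group_clusters(model: ClusterModel, channel: str = "blue") -> np.ndarray:
    """Collapse a mixed plate's clusters to binary states.

    Blue: the lowest-mean cluster is OFF, everything else ON. Red: the two
    lowest-mean clusters are OFF (with only two clusters, just the
    lowest), the rest ON.
    """
    if model.k < 2:
        raise ValueError("group_clusters needs >= 2 clusters on a mixed plate")
    if channel == "red" and model.k >= 3:
        n_off = 2
    else:
        n_off = 1
    return (model.labels >= n_off).astype(np.uint8)


@dataclass
class DeconvolutionConfig:
    """Knobs of the automated deconvolution pipeline."""

    method: str = "gmm"
    k: int = 3
    eps: float = 0.2
    min_samples: int = 5
    xi: float = 0.05
    n_neighbors: int | None = None  # None -> per-channel default (20/10)
    contamination: float = 0.05
    lof_threshold: float = 2.5
    cutoff: float = 0.5
    seed: int = 0


@dataclass
class DeconvolutionResult:
    """Binary image plus full provenance of how it was called."""

    grid: BitGrid
    mode: Mode
    channel: str
    model: ClusterModel | None
    outliers: OutlierResult | None
    missing: np.ndarray  # bool per well
    values: np.ndarray  # raw ratio values (NaN = missing)
    curated: np.ndarray  # post-reassignment values used for clustering
    accuracy: float | None = None
    errors: np.ndarray | None = None  # 8x12 bool mask

    @property
    def states(self) -> np.ndarray:
        return self.grid.flat()

    def report(self) -> dict:
        from .grid import all_wells

        wells = []
        for w in all_wells():
            i = w.index
            wells.append(
                {
                    "well": w.well_id,
                    "value": None if np.isnan(self.values[i]) else float(self.values[i]),
                    "curated": None if np.isnan(self.curated[i]) else float(self.curated[i]),
                    "missing": bool(self.missing[i]),
                    "outlier": bool(
                        self.outliers is not None
                        and not self.missing[i]
                        and self._outlier_flag(i)
                    ),
                    "state": int(self.grid.flat()[i]),
                }
            )
        rep = {
            "mode": self.mode.value,
            "channel": self.channel,
            "method": self.model.method if self.model else None,
            "settings": self.model.settings if self.model else None,
            "cluster_means": (
                [float(m) for m in self.model.means] if self.model else None
            ),
            "n_missing": int(self.missing.sum()),
            "wells": wells,
        }
        if self.accuracy is not None:
            rep["accuracy"] = self.accuracy
            rep["error_wells"] = [
                w["well"]
                for w, bad in zip(wells, self.errors.reshape(-1))
                if bad
            ]
        return rep

    def _outlier_flag(self, well_index: int) -> bool:
        observed = np.nonzero(~self.missing)[0]
        pos = np.searchsorted(observed, well_index)
        if pos >= observed.size or observed[pos] != well_index:
            return False
        return bool(self.outliers.labels[pos] == -1)


def deconvolute(
    ratios: RatioTable,
    config: DeconvolutionConfig | None = None,
    truth: BitGrid | None = None,
) -> DeconvolutionResult:
    """Run the full automated pipeline on one channel's ratio table:
    LOF curation -> clustering -> full ON/OFF check -> cluster grouping.

    MISSING wells (zero coverage) are excluded from curation and
    clustering and called 0 ("no reads, no evidence of exposure") on mixed
    plates; plate-level ALL_ON/ALL_OFF calls cover every well.
    """
    cfg = config or DeconvolutionConfig()
    values = np.asarray(ratios.values, dtype=float)
    missing = np.isnan(values)
    observed_idx = np.nonzero(~missing)[0]
    curated_full = values.copy()

    if observed_idx.size == 0:
        warnings.warn("deconvolute: every well is MISSING; calling all-OFF",
                      stacklevel=2)
        grid = BitGrid.zeros()
        acc = grid_accuracy(grid, truth) if truth is not None else None
        errs = error_mask(grid, truth) if truth is not None else None
        return DeconvolutionResult(
            grid=grid, mode=Mode.ALL_OFF, channel=ratios.channel, model=None,
            outliers=None, missing=missing, values=values,
            curated=curated_full, accuracy=acc, errors=errs,
        )
    if missing.any():
        warnings.warn(
            f"deconvolute: {int(missing.sum())} MISSING wells imputed as 0 "
            "at the output boundary",
            stacklevel=2,
        )

    obs = values[observed_idx]
    n_neighbors = (
        cfg.n_neighbors
        if cfg.n_neighbors is not None
        else LOF_NEIGHBORS.get(ratios.channel, 20)
    )
    outres = lof_detect(
        obs,
        n_neighbors=n_neighbors,
        contamination=cfg.contamination,
        threshold=cfg.lof_threshold,
    )
    curated = reassign_outliers(obs, outres.labels)
    outres.curated = curated
    curated_full[observed_idx] = curated

    model = cluster_1d(
        curated,
        method=cfg.method,
        k=cfg.k,
        eps=cfg.eps,
        min_samples=cfg.min_samples,
        xi=cfg.xi,
        seed=cfg.seed,
    )
    mode = full_on_off_check(model, cutoff=cfg.cutoff)
    flat = np.zeros(N_WELLS, dtype=np.uint8)
    if mode is Mode.ALL_ON:
        flat[:] = 1
    elif mode is Mode.MIXED:
        flat[observed_idx] = group_clusters(model, channel=ratios.channel)
    grid = BitGrid.from_flat(flat)

    acc = grid_accuracy(grid, truth) if truth is not None else None
    errs = error_mask(grid, truth) if truth is not None else None
    return DeconvolutionResult(
        grid=grid,
        mode=mode,
        channel=ratios.channel,
        model=model,
        outliers=outres,
        missing=missing,
        values=values,
        curated=curated_full,
        accuracy=acc,
        errors=errs,
    )


def oracle_threshold(
    ratios: RatioTable | np.ndarray, truth: BitGrid
) -> tuple[float, float]:
    """Best fixed threshold given foreknowledge of the encoded image.

    Exhaustively scans every midpoint between adjacent distinct ratio
    values (plus one below the minimum and one above the maximum) and
    returns the (lowest) threshold maximizing well-call accuracy. MISSING
    wells count as value 0.
    """
    values = ratios.values if isinstance(ratios, RatioTable) else np.asarray(ratios)
    values = np.where(np.isnan(values), 0.0, values.astype(float))
    t_flat = truth.flat()
    distinct = np.unique(values)
    candidates = [distinct[0] - 1.0]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(distinct[-1] + 1.0)
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = float(((values > t).astype(np.uint8) == t_flat).mean())
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    return best_t, best_acc
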