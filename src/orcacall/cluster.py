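"""Call categorisation: feature assembly, k-means, group summaries.

Calls are grouped by k-means on their measured feature vectors,
minimising the total within-cluster sum of squared Euclidean distances.
Features are z-scored first — without standardization the kHz-scale
frequency parameters would dominate the count-valued ones. The clustered
feature set is the nine measured parameters plus the harmonic flag (0/1),
the sideband spacing (0 where absent) and a pulsed-class indicator.

The k-means core (k-means++ seeding, Lloyd iterations, best-of-restarts)
is implemented here so that its tie-breaking and seeding semantics are
fully specified and row-order invariant; scikit-learn's implementation
serves as an independent cross-check in the test suite, not as the
engine. The number of groups can be fixed (nine, the published repertoire
size) or selected by maximizing the mean silhouette over a range of k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .io_formats import PARAMETER_NAMES
from .synth import PULSED_CLASSES

FEATURE_COLUMNS = PARAMETER_NAMES + ("has_harmonics", "sideband_spacing", "pulsed")


@dataclass
class FeatureMatrix:
    """Standardized call-feature matrix plus the transform that made it."""

    X: np.ndarray  # rows x retained columns, z-scored
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    raw: pd.DataFrame  # all FEATURE_COLUMNS, original units
    labels: pd.Series | None = None  # true group labels when synthetic

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # standardized units
    assignments: np.ndarray
    within_ss: float
    n_iter: int
    seed: int
    within_ss_history: list[float] = field(default_factory=list)


@dataclass
class GroupSummary:
    """Range table for one discovered group, in original units."""

    label: str
    n: int
    ranges: dict[str, tuple[float, float]]
    sideband_range: tuple[float, float] | None = None


def _as_raw_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        rows = []
        for m in measurements:
            row = {name: getattr(m, name) for name in PARAMETER_NAMES}
            row["has_harmonics"] = m.has_harmonics
            row["sideband_spacing"] = m.sideband_spacing
            row["call_class"] = m.call_class
            rows.append(row)
        df = pd.DataFrame(rows)
    df["has_harmonics"] = df["has_harmonics"].astype(float)
    df["sideband_spacing"] = df["sideband_spacing"].astype(float).fillna(0.0)
    df["pulsed"] = df["call_class"].isin(PULSED_CLASSES).astype(float)
    return df


def build_feature_matrix(measurements) -> FeatureMatrix:
    """Assemble and z-score the feature matrix.

    Accepts measured calls or a synthetic feature-vector table. Columns
    that are constant across all calls carry no clustering information
    and are dropped with a warning.
    """
    df = _as_raw_frame(measurements)
    if len(df) < 2:
        raise ValueError("need at least two calls to standardize features")
    values = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(FEATURE_COLUMNS, keep) if not k]
        warnings.warn(f"constant feature columns dropped: {dropped}", stacklevel=2)
    X = (values[:, keep] - means[keep]) / sds[keep]
    labels = df["group"] if "group" in df.columns else None
    return FeatureMatrix(
        X=X,
        columns=[c for c, k in zip(FEATURE_COLUMNS, keep) if k],
        means=means[keep],
        sds=sds[keep],
        raw=df,
        labels=labels,
    )


def _as_array(matrix) -> np.ndarray:
    return matrix.X if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread the initial centroids apart."""
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centroids)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centroids)


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    k = centroids.shape[0]
    assign = np.full(X.shape[0], -1)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        new_assign = np.argmin(d2, axis=1)  # ties -> lowest centroid index
        for c in range(k):  # repair empty clusters with the worst-fit point
            if not np.any(new_assign == c):
                worst = int(np.argmax(d2[np.arange(X.shape[0]), new_assign]))
                new_assign[worst] = c
        centroids = np.vstack([X[new_assign == c].mean(axis=0) for c in range(k)])
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        wss = float(d2[np.arange(X.shape[0]), new_assign].sum())
        history.append(wss)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return centroids, assign, history[-1], it, history


def kmeans(
    matrix: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
) -> ClusterModel:
    """Best-of-restarts k-means with k-means++ seeding.

    Rows are put into a canonical (lexicographic) order before any seeded
    draw, so the result does not depend on input row order; assignments
    are returned in the caller's order. Within-cluster sum of squares is
    non-increasing over Lloyd iterations within every restart.
    """
    X = _as_array(matrix)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k={k} must be in [1, n_rows={X.shape[0]}]")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    order = np.lexsort(X.T[::-1])
    Xs = X[order]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        init = _plusplus_init(Xs, k, rng)
        centroids, assign, wss, n_iter, history = _lloyd(Xs, init, max_iter)
        if any(b > a + 1e-9 for a, b in zip(history, history[1:])):
            raise AssertionError("within-cluster SS increased during Lloyd iteration")
        if best is None or wss < best[2] - 1e-12:
            best = (centroids, assign, wss, n_iter, history)
    centroids, assign_sorted, wss, n_iter, history = best
    assignments = np.empty_like(assign_sorted)
    assignments[order] = assign_sorted
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        within_ss=wss,
        n_iter=n_iter,
        seed=seed,
        within_ss_history=history,
    )


def select_k(
    matrix: FeatureMatrix | np.ndarray,
    k_range: tuple[int, int] = (2, 15),
    seed: int = 0,
    restarts: int = 10,
) -> int:
    """Pick k by maximizing the mean silhouette; ties go to the smaller k."""
    X = _as_array(matrix)
    lo, hi = k_range
    if not 2 <= lo <= hi <= X.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_rows - 1]")
    best_k, best_score = lo, -np.inf
    for k in range(lo, hi + 1):
        model = kmeans(X, k, seed=seed, restarts=restarts)
        if len(np.unique(model.assignments)) < 2:
            continue
        score = silhouette_score(X, model.assignments)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


def summarize_groups(measurements, assignments: np.ndarray) -> list[GroupSummary]:
    """Per-group parameter ranges in original units, Tables-1-and-2 style.

    Groups are ordered by size descending, then label; sideband ranges
    cover only the calls where a spacing was measured.
    """
    df = _as_raw_frame(measurements)
    assignments = np.asarray(assignments)
    if len(df) != assignments.size:
        raise ValueError("assignments must cover every measurement")
    has_sb = None
    if not isinstance(measurements, pd.DataFrame):
        has_sb = np.array([m.sideband_spacing is not None for m in measurements])
    elif "sideband_spacing" in measurements.columns:
        has_sb = measurements["sideband_spacing"].notna().to_numpy()
    summaries = []
    for g in np.unique(assignments):
        sub = df[assignments == g]
        ranges = {
            name: (float(sub[name].min()), float(sub[name].max()))
            for name in PARAMETER_NAMES
        }
        sb_range = None
        if has_sb is not None:
            sb = df.loc[(assignments == g) & has_sb, "sideband_spacing"]
            if len(sb):
                sb_range = (float(sb.min()), float(sb.max()))
        summaries.append(
            GroupSummary(label=str(g), n=len(sub), ranges=ranges, sideband_range=sb_range)
        )
    summaries.sort(key=lambda s: (-s.n, s.label))
    return summaries


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Flatten group summaries to a lo/hi-column table for CSV export."""
    rows = []
    for s in summaries:
        row = {"group": s.label, "n": s.n}
        for name, (lo, hi) in s.ranges.items():
            row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
        if s.sideband_range is not None:
            row["sideband_lo"], row["sideband_hi"] = s.sideband_range
        rows.append(row)
    return pd.DataFrame(rows)
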