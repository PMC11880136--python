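"""k-means clustering of oscillator-robustness features.

Cells are grouped by their five-feature robustness vectors.  Features are
z-scored first (they mix counts, minutes, and dimensionless correlation
measures), then clustered with Lloyd's algorithm: iterations are capped at a
fixed number of *epochs* with early stopping once the assignment no longer
changes, and the best of several random restarts (by within-cluster sum of
squares, "inertia") is kept.  The number of groups is chosen by the elbow
method: the k at which the inertia-versus-k curve bends most sharply, i.e.
the maximal second difference of the curve.

The hand-written Lloyd loop is deliberate: the epoch cap, early stop,
restart policy, and a per-iteration check that inertia never increases are
part of this module's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .oscillation import FEATURE_NAMES, CorrectedTrace, FeatureVector

__all__ = [
    "ClusterResult",
    "standardize",
    "kmeans_cluster",
    "select_k_elbow",
    "summarize_groups",
    "features_to_matrix",
]

DEFAULT_EPOCHS = 50
DEFAULT_RESTARTS = 10
DEFAULT_K_MAX = 6


@dataclass
class ClusterResult:
    """Partition of cells in standardized feature space."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    inertia_curve: np.ndarray | None = None  # inertia for k = 1..k_max
    second_differences: np.ndarray | None = None  # elbow rationale, k = 2..k_max-1
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def summary(self) -> str:
        lines = [f"k-means: k={self.k}, inertia={self.inertia:.3f}"]
        for g in range(self.k):
            n = int((self.assignments == g).sum())
            lines.append(f"  group {g}: n={n}, centroid={np.round(self.centroids[g], 3)}")
        if self.inertia_curve is not None:
            lines.append(f"  inertia curve (k=1..{len(self.inertia_curve)}): "
                         f"{np.round(self.inertia_curve, 2)}")
        if self.second_differences is not None:
            lines.append(f"  second differences (k=2..): {np.round(self.second_differences, 2)}")
        return "\n".join(lines)


def features_to_matrix(features: list[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n_cells, 5) matrix."""
    return np.vstack([f.as_array() for f in features])


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Z-score each feature column (sample sd).

    Constant columns carry no clustering information and would divide by
    zero; they are dropped with a warning.  Returns the standardized matrix
    and the indices of the retained columns.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    sd = x.std(axis=0, ddof=1)
    keep = [int(j) for j in np.flatnonzero(sd > 0)]
    dropped = [j for j in range(x.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping constant feature column(s) {dropped}")
    if not keep:
        raise ValueError("all feature columns are constant")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return z, keep


def _lloyd(
    x: np.ndarray, k: int, epochs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n = len(x)
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    prev_inertia = np.inf
    for _ in range(epochs):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        new_assign = d2.argmin(1)
        inertia = float(d2[np.arange(n), new_assign].sum())
        assert inertia <= prev_inertia + 1e-8, "Lloyd iteration increased inertia"
        prev_inertia = inertia
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for g in range(k):
            members = x[assign == g]
            if len(members):
                centroids[g] = members.mean(0)
            else:  # re-seed an empty cluster at the worst-fit point
                centroids[g] = x[int(d2.min(1).argmax())]
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    assign = d2.argmin(1)
    inertia = float(d2[np.arange(n), assign].sum())
    return assign, centroids, inertia


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    epochs: int = DEFAULT_EPOCHS,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ClusterResult:
    """Lloyd k-means, best of ``restarts`` random initialisations."""
    x = np.asarray(matrix, dtype=float)
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if k < 1 or epochs < 1:
        raise ValueError("k and epochs must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        assign, cent, inertia = _lloyd(x, k, epochs, rng)
        if best is None or inertia < best[2]:
            best = (assign, cent, inertia)
    assert best is not None
    return ClusterResult(k=k, assignments=best[0], centroids=best[1], inertia=best[2])


def select_k_elbow(
    matrix: np.ndarray,
    k_max: int = DEFAULT_K_MAX,
    epochs: int = DEFAULT_EPOCHS,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ClusterResult:
    """Choose k by the elbow of the inertia curve.

    Fits k = 1..k_max and selects the k in 2..k_max-1 that maximises the
    second difference ``(I[k-1] - I[k]) - (I[k] - I[k+1])`` — the sharpest
    bend of the curve; ties break to the smallest k.  The inertia curve and
    second differences are attached to the result so the choice can be
    inspected or overridden.
    """
    x = np.asarray(matrix, dtype=float)
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    if len(x) < k_max:
        raise ValueError(f"need at least k_max={k_max} cells, got {len(x)}")
    results = [
        kmeans_cluster(x, k, epochs=epochs, restarts=restarts, seed=seed)
        for k in range(1, k_max + 1)
    ]
    inertia = np.array([r.inertia for r in results])
    d2 = (inertia[:-2] - inertia[1:-1]) - (inertia[1:-1] - inertia[2:])  # k = 2..k_max-1
    k_sel = int(np.argmax(d2)) + 2  # argmax returns the first (smallest-k) maximum
    chosen = results[k_sel - 1]
    chosen.inertia_curve = inertia
    chosen.second_differences = d2
    return chosen


def summarize_groups(
    result: ClusterResult,
    features: list[FeatureVector],
    aligned: list[CorrectedTrace] | None = None,
) -> dict:
    """Per-group feature means, sizes, mean aligned waveforms, and pairwise
    two-sample t-tests of each feature between groups."""
    fm = features_to_matrix(features)
    n = len(fm)
    if n != len(result.assignments):
        raise ValueError("assignments do not cover the feature set")
    groups = {}
    for g in range(result.k):
        members = np.flatnonzero(result.assignments == g)
        entry: dict = {
            "count": int(len(members)),
            "fraction": float(len(members) / n),
        }
        if len(members):
            entry["feature_mean"] = {
                name: float(fm[members, j].mean()) for j, name in enumerate(FEATURE_NAMES)
            }
            entry["feature_sd"] = {
                name: float(fm[members, j].std(ddof=1)) if len(members) > 1 else 0.0
                for j, name in enumerate(FEATURE_NAMES)
            }
        groups[g] = entry

    if aligned is not None:
        id_to_group = {f.cell_id: int(g) for f, g in zip(features, result.assignments)}
        for g in range(result.k):
            traces = [c for c in aligned if id_to_group.get(c.cell_id) == g]
            if not traces:
                continue
            # common pseudo-time grid across the group's aligned traces
            dt = traces[0].dt
            lo = min(c.t[0] for c in traces)
            hi = max(c.t[-1] for c in traces)
            grid = np.arange(round(lo / dt), round(hi / dt) + 1) * dt
            acc = np.full((len(traces), len(grid)), np.nan)
            for i, c in enumerate(traces):
                start = int(round((c.t[0] - lo) / dt))
                acc[i, start : start + len(c.t)] = c.smoothed
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_wave = np.nanmean(acc, axis=0)
            groups[g]["pseudo_time"] = grid.tolist()
            groups[g]["mean_waveform"] = mean_wave.tolist()

    tests = {}
    for a in range(result.k):
        for b in range(a + 1, result.k):
            ia = np.flatnonzero(result.assignments == a)
            ib = np.flatnonzero(result.assignments == b)
            if len(ia) < 2 or len(ib) < 2:
                continue
            tests[f"{a}_vs_{b}"] = {
                name: float(stats.ttest_ind(fm[ia, j], fm[ib, j]).pvalue)
                for j, name in enumerate(FEATURE_NAMES)
            }
    return {"k": result.k, "groups": groups, "t_tests": tests}
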