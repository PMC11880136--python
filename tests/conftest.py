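"""Shared fixtures and independent brute-force oracles.

The oracles are deliberately naive O(n²) double loops, kept separate from the
library's vectorised/tree-based code paths so they can certify them.
"""

from __future__ import annotations

import numpy as np
import pytest

from deltaosc import Window, gen_cell_field, label_positives


# ---------------------------------------------------------------- oracles


def oracle_nn_distances(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    out = np.empty(len(pts))
    for i in range(len(pts)):
        best = np.inf
        for j in range(len(pts)):
            if i == j:
                continue
            d = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
            best = min(best, d)
        out[i] = best
    return out


def oracle_k_function(
    points: np.ndarray, window: Window, radii: np.ndarray, edge_correction: str = "translation"
) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = np.zeros(len(radii))
    for ri, r in enumerate(radii):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(pts[i, 0] - pts[j, 0])
                dy = abs(pts[i, 1] - pts[j, 1])
                if np.sqrt(dx * dx + dy * dy) <= r:
                    if edge_correction == "translation":
                        total += window.area / ((window.width - dx) * (window.height - dy))
                    else:
                        total += 1.0
        out[ri] = window.area / (n * (n - 1)) * total
    return out


def oracle_autocorrelation(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    n = len(x)
    xbar = x.mean()
    denom = sum((v - xbar) ** 2 for v in x)
    out = np.empty(n - 1)
    for k in range(1, n):
        num = sum((x[t] - xbar) * (x[t + k] - xbar) for t in range(n - k))
        out[k - 1] = num / denom
    return out


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def unit_window() -> Window:
    return Window(0.0, 100.0, 0.0, 100.0)


@pytest.fixture(scope="session")
def csr_field(unit_window) -> np.ndarray:
    return gen_cell_field(200, unit_window, process="poisson", seed=11)


@pytest.fixture(scope="session")
def labelled_cells(csr_field):
    return label_positives(csr_field, 40, mode="random", seed=12)


@pytest.fixture(scope="session")
def grid_points() -> np.ndarray:
    """10 x 10 unit-spacing grid."""
    i, j = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
    return np.column_stack([i.ravel(), j.ravel()]).astype(float)
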