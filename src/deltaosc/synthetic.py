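"""Synthetic microscopy data with known ground truth.

Three generators mirror the three kinds of measurements the analysis consumes:

* **cell fields** — point patterns of nucleus positions in a rectangular
  window, either completely spatially random (homogeneous Poisson, conditioned
  on the count) or epithelium-like (jittered square lattice), with positive
  labels planted at random, maximally clustered, or maximally regular;
* **ISH-like images** — a bright background with a smooth linear gradient,
  dark circular stain blobs, and additive Gaussian noise, plus the ground
  truth blob mask;
* **reporter traces** — two-channel fluorescence time series (signal reporter
  over a constitutive volume marker) with sinusoidal oscillation, linear
  photobleaching drift, and white measurement noise.

``gen_population("mixed_default", ...)`` draws a mixture of robust, noisy, and
non-oscillatory cells whose planted three-group structure downstream feature
extraction and clustering should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import CellTable, PlacementError, Window
from .oscillation import Trace

__all__ = [
    "SyntheticTraceParams",
    "SyntheticImageParams",
    "MIXED_DEFAULT_CLASSES",
    "MIXED_DEFAULT_PROPORTIONS",
    "gen_cell_field",
    "label_positives",
    "gen_trace",
    "gen_population",
    "gen_ish_image",
]


@dataclass(frozen=True)
class SyntheticTraceParams:
    """Parameters of one synthetic two-channel reporter trace.

    The reporter channel follows
    ``baseline + drift_slope*t + amplitude*sin(2*pi*t/period + phase) + N(0, noise_sd^2)``;
    the volume marker is ``gfp_mean + N(0, gfp_noise_sd^2)`` truncated at a
    small positive floor so the ratio is always defined.  Times are minutes.
    """

    n_timepoints: int = 60
    dt: float = 5.0
    period: float = 60.0
    amplitude: float = 25.0
    phase: float = 0.0
    baseline: float = 100.0
    drift_slope: float = -0.15
    noise_sd: float = 2.0
    gfp_mean: float = 100.0
    gfp_noise_sd: float = 2.0
    class_label: str = "robust"

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.amplitude < 0 or self.noise_sd < 0 or self.gfp_noise_sd < 0:
            raise ValueError("amplitude and noise levels must be >= 0")
        if self.gfp_mean <= 0:
            raise ValueError("gfp_mean must be > 0")
        if self.period <= 0:
            raise ValueError("period must be > 0")


@dataclass(frozen=True)
class SyntheticImageParams:
    """Parameters of a synthetic chromogenic-stain image (dark blobs on a
    bright, gently sloping background)."""

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0
    n_blobs: int = 40
    blob_radius: float = 3.0
    blob_depth: float = 120.0
    background: float = 200.0
    background_gradient_range: float = 40.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.blob_radius <= 0:
            raise ValueError("blob_radius must be > 0")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        if min(self.shape) < 4:
            raise ValueError("image too small")


def gen_cell_field(
    n: int,
    window: Window,
    process: str = "poisson",
    seed: int = 0,
) -> np.ndarray:
    """Generate ``n`` cell positions (µm) inside ``window``.

    ``process="poisson"`` draws i.i.d. uniform positions (a binomial point
    process — CSR conditioned on the count).  ``process="jittered_grid"``
    places cells on a square lattice with i.i.d. uniform jitter of at most a
    quarter of the lattice spacing, mimicking regular epithelial packing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if process == "poisson":
        x = rng.uniform(window.x_min, window.x_max, n)
        y = rng.uniform(window.y_min, window.y_max, n)
        return np.column_stack([x, y])
    if process == "jittered_grid":
        m = math.ceil(math.sqrt(n))
        sx = window.width / m
        sy = window.height / m
        ix, iy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        cx = window.x_min + (ix.ravel() + 0.5) * sx
        cy = window.y_min + (iy.ravel() + 0.5) * sy
        jitter = rng.uniform(-0.25, 0.25, size=(m * m, 2))
        pts = np.column_stack([cx + jitter[:, 0] * sx, cy + jitter[:, 1] * sy])
        keep = rng.choice(m * m, size=n, replace=False)
        keep.sort()
        return pts[keep]
    raise ValueError(f"unknown process {process!r}")


def _farthest_point_subset(points: np.ndarray, k: int) -> np.ndarray:
    """Greedy farthest-point sampling, seeded with the most distant pair.

    Maximises (greedily) the minimum pairwise distance of the selected subset;
    on a regular grid with k=4 this picks the four corners.
    """
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    if k == 1:
        return np.array([0])
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [min(i, j), max(i, j)]
    mind2 = np.minimum(d2[chosen[0]], d2[chosen[1]])
    while len(chosen) < k:
        mind2[chosen] = -1.0
        nxt = int(np.argmax(mind2))
        chosen.append(nxt)
        mind2 = np.minimum(mind2, d2[nxt])
    return np.array(chosen)


def label_positives(
    field: np.ndarray,
    n_pos: int,
    mode: str = "random",
    seed: int = 0,
) -> CellTable:
    """Plant ``n_pos`` positive labels on a cell field.

    ``random`` samples uniformly without replacement (the null model used for
    the simulation envelopes); ``max_cluster`` takes a random focal cell plus
    its ``n_pos - 1`` nearest neighbours (maximally clustered control);
    ``max_regular`` uses greedy farthest-point sampling (maximally regular
    control).
    """
    field = np.asarray(field, dtype=float)
    n = len(field)
    if not 1 <= n_pos <= n:
        raise ValueError(f"n_pos must be in [1, {n}], got {n_pos}")
    rng = np.random.default_rng(seed)
    if mode == "random":
        idx = rng.choice(n, size=n_pos, replace=False)
    elif mode == "max_cluster":
        focal = int(rng.integers(n))
        d2 = ((field - field[focal]) ** 2).sum(1)
        idx = np.argsort(d2, kind="stable")[:n_pos]
    elif mode == "max_regular":
        idx = _farthest_point_subset(field, n_pos)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    positive = np.zeros(n, dtype=int)
    positive[idx] = 1
    return CellTable.from_arrays(field, positive=positive)


def gen_trace(params: SyntheticTraceParams, seed: int = 0) -> Trace:
    """Draw one two-channel trace from its generating model."""
    rng = np.random.default_rng(seed)
    t = np.arange(params.n_timepoints) * params.dt
    mcherry = (
        params.baseline
        + params.drift_slope * t
        + params.amplitude * np.sin(2 * np.pi * t / params.period + params.phase)
        + rng.normal(0.0, params.noise_sd, params.n_timepoints)
    )
    gfp = params.gfp_mean + rng.normal(0.0, params.gfp_noise_sd, params.n_timepoints)
    gfp = np.maximum(gfp, 0.01 * params.gfp_mean)  # floor keeps the ratio defined
    return Trace(cell_id=params.class_label, t=t, mcherry=mcherry, gfp=gfp)


# Class templates for the mixed population.  Drift and measurement noise model
# photobleaching and confocal intensity noise common to all cells; the classes
# differ in oscillation amplitude, period, and biological noise.
MIXED_DEFAULT_CLASSES: dict[str, SyntheticTraceParams] = {
    "robust": SyntheticTraceParams(amplitude=25.0, noise_sd=2.0, period=60.0, class_label="robust"),
    "noisy": SyntheticTraceParams(amplitude=15.0, noise_sd=8.0, period=40.0, class_label="noisy"),
    "flat": SyntheticTraceParams(amplitude=0.0, noise_sd=2.0, period=60.0, class_label="flat"),
}

#: Fractions of robust / noisy / flat cells in the mixed_default preset.
MIXED_DEFAULT_PROPORTIONS: dict[str, float] = {
    "robust": 1 / 3,
    "noisy": 1 / 2,
    "flat": 1 / 6,
}


def gen_population(
    preset: str,
    n_cells: int,
    seed: int = 0,
) -> tuple[list[Trace], list[str]]:
    """Draw a population of traces with per-cell ground-truth class labels.

    The only preset, ``mixed_default``, mixes robust oscillators (high
    amplitude, low noise, 60-min period), noisy oscillators (moderate
    amplitude, high noise, 40-min period), and non-oscillatory cells, in
    proportions 1/3 : 1/2 : 1/6.  Each cell gets a uniform random phase.
    """
    if preset != "mixed_default":
        raise ValueError(f"unknown preset {preset!r}")
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    rng = np.random.default_rng(seed)
    names = list(MIXED_DEFAULT_CLASSES)
    # largest-remainder apportionment of the class counts
    quotas = np.array([MIXED_DEFAULT_PROPORTIONS[c] * n_cells for c in names])
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts)):
        if counts.sum() >= n_cells:
            break
        counts[i] += 1
    counts[np.argmax(counts)] += n_cells - counts.sum()
    labels = [c for c, k in zip(names, counts) for _ in range(k)]
    traces = []
    for i, cls in enumerate(labels):
        p = replace(
            MIXED_DEFAULT_CLASSES[cls],
            phase=float(rng.uniform(0.0, 2 * np.pi)),
        )
        sub = int(rng.integers(2**31 - 1))
        tr = gen_trace(p, seed=sub)
        traces.append(Trace(cell_id=f"cell{i:03d}", t=tr.t, mcherry=tr.mcherry, gfp=tr.gfp))
    return traces, labels


def gen_ish_image(
    params: SyntheticImageParams,
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate an ISH-like image and its ground-truth positive mask.

    The image is ``background`` with a linear left-to-right gradient spanning
    ``background_gradient_range``, ``n_blobs`` non-overlapping dark disks of
    depth ``blob_depth``, and additive Gaussian noise.  The mask marks blob
    pixels.  Raises :class:`PlacementError` if the blobs cannot be placed
    without overlap within the retry budget.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    r_px = params.blob_radius / params.pixel_size
    yy, xx = np.mgrid[0:h, 0:w]
    img = params.background + params.background_gradient_range * (xx / max(w - 1, 1) - 0.5)
    mask = np.zeros((h, w), dtype=bool)

    centers: list[tuple[float, float]] = []
    tries = 0
    margin = r_px + 1
    while len(centers) < params.n_blobs:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(centers)}/{params.n_blobs} blobs in {max_tries} tries"
            )
        tries += 1
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        if all((cy - py) ** 2 + (cx - px) ** 2 > (2 * r_px) ** 2 for py, px in centers):
            centers.append((cy, cx))
    for cy, cx in centers:
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        img[disk] -= params.blob_depth
        mask |= disk
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return img, mask
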