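"""Synthetic tumor cross-sections with known ground truth.

Generates the geometry-and-labels content of a segmented histology export:
strand-like stromal regions (thick random walks, mimicking ECM deposition
strands), uniformly placed tumor-cell centroids outside stroma and
necrosis, and marker-positivity labels with an optional exponential
distance-dependent bias toward stroma.  No image appearance is rendered —
only what the spatial analysis consumes.

The marker model: exactly ``K = round(f * N)`` cells are flagged positive,
drawn without replacement with weights ``w_i = exp(-d_i / lambda)`` where
``d_i`` is the cell's distance to the nearest stroma pixel.  With
``lambda = inf`` the weights are uniform, which is *exactly* one digital-
avatar draw — the generator embeds the analysis null as a special case,
so unbiased tissue is unbiased by construction, not by approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from . import io as tissue_io
from .io import StromaGeometry, TissueSample
from .metrics import distance_map

_WALK_TURN_SD = 0.25  # radians per unit step; sets strand tortuosity


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic tumor cross-section.

    ``bias_length`` is the exponential length scale lambda of the
    marker-positivity bias, in microns; ``math.inf`` means no bias
    (labels exchangeable among cells).
    """

    width: int = 256
    height: int = 256
    pixel_size: float = 1.0
    n_stroma_seeds: int = 6
    stroma_thickness: int = 8
    target_stroma_fraction: float = 0.15
    n_cells: int = 2000
    positive_fraction: float = 0.1
    bias_length: float = math.inf
    necrosis_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_stroma_seeds < 0 or self.n_cells < 0:
            raise ValueError("counts must be >= 0")
        if self.stroma_thickness < 1:
            raise ValueError("stroma_thickness must be >= 1 pixel")
        if not 0 <= self.target_stroma_fraction < 1:
            raise ValueError("target_stroma_fraction must be in [0, 1)")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not self.bias_length > 0:
            raise ValueError("bias_length must be > 0 (inf for no bias)")
        if not 0 <= self.necrosis_fraction < 1:
            raise ValueError("necrosis_fraction must be in [0, 1)")
        if self.target_stroma_fraction + self.necrosis_fraction >= 1:
            raise ValueError(
                "target_stroma_fraction + necrosis_fraction must be < 1"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded at generation time (never re-derived)."""

    config: SyntheticConfig
    realized_stroma_fraction: float
    realized_necrosis_fraction: float
    n_positive: int


def _fold(values: np.ndarray, upper: float) -> np.ndarray:
    """Reflect a free coordinate into [0, upper] (mirror boundary)."""
    if upper <= 0:
        return np.zeros_like(values)
    return np.abs(np.mod(values, 2 * upper) - upper)


def generate_stroma(config: SyntheticConfig) -> StromaGeometry:
    """Grow strand-like stroma by persistent random walks.

    ``n_stroma_seeds`` walkers take unit steps with normally distributed
    turning angles; visited pixels dilated to ``stroma_thickness`` form the
    stroma mask.  Walking stops when the realized area fraction is within
    +-20% (relative) of ``target_stroma_fraction``; exceeding the step cap
    first is an error naming realized vs target.
    """
    h, w = config.height, config.width
    target = config.target_stroma_fraction
    if config.n_stroma_seeds == 0 or target == 0:
        if target > 0:
            raise ValueError(
                f"unreachable stroma fraction: realized 0.0, target {target} "
                "(no stroma seeds)"
            )
        return StromaGeometry(np.zeros((h, w), dtype=bool))

    rng = np.random.default_rng(config.seed)
    n = config.n_stroma_seeds
    radius = config.stroma_thickness // 2
    footprint = disk(radius) if radius > 0 else None

    target_px = target * h * w
    est_steps = max(1, int(target_px / config.stroma_thickness / n))
    chunk = max(16, est_steps // 10)
    max_steps = max(2000, 60 * est_steps)

    pos = np.column_stack(
        [rng.uniform(0, h - 1, n), rng.uniform(0, w - 1, n)]
    )  # (y, x), free (unfolded) coordinates
    ang = rng.uniform(0, 2 * np.pi, n)
    path = np.zeros((h, w), dtype=bool)
    steps_done = 0
    while True:
        turns = rng.normal(0.0, _WALK_TURN_SD, (n, chunk))
        angs = ang[:, None] + np.cumsum(turns, axis=1)
        ys = pos[:, 0, None] + np.cumsum(np.sin(angs), axis=1)
        xs = pos[:, 1, None] + np.cumsum(np.cos(angs), axis=1)
        ii = np.rint(_fold(ys, h - 1)).astype(np.intp)
        jj = np.rint(_fold(xs, w - 1)).astype(np.intp)
        path[ii.ravel(), jj.ravel()] = True
        pos = np.column_stack([ys[:, -1], xs[:, -1]])
        ang = angs[:, -1]
        steps_done += chunk

        mask = binary_dilation(path, structure=footprint) if footprint is not None else path
        frac = mask.mean()
        if frac >= 0.99 * target:
            if frac > 1.2 * target:
                raise ValueError(
                    f"stroma fraction overshot: realized {frac:.4f}, target {target}"
                )
            return StromaGeometry(mask)
        if steps_done >= max_steps:
            raise ValueError(
                f"unreachable stroma fraction: realized {frac:.4f}, "
                f"target {target} after {steps_done} steps"
            )


def place_cells(
    stroma: StromaGeometry | np.ndarray,
    exclusion: np.ndarray | None,
    n_cells: int,
    seed_or_rng,
) -> np.ndarray:
    """Sample cell centroids uniformly over admissible (non-stroma,
    non-excluded) pixels, with one uniform jitter inside the chosen pixel
    so coordinates are continuous.  Returns an (n_cells, 2) array of
    (x, y)."""
    raster = stroma.raster if isinstance(stroma, StromaGeometry) else np.asarray(stroma, bool)
    admissible = ~raster
    if exclusion is not None:
        admissible &= ~np.asarray(exclusion, bool)
    if n_cells == 0:
        return np.empty((0, 2), dtype=float)
    flat = np.flatnonzero(admissible)
    if flat.size == 0:
        raise ValueError("no admissible pixels to place cells on")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    pick = rng.choice(flat, size=n_cells, replace=True)
    ii, jj = np.divmod(pick, raster.shape[1])
    x = jj + rng.random(n_cells)
    y = ii + rng.random(n_cells)
    return np.column_stack([x, y])


def assign_marker(distances, f: float, bias_length: float, seed_or_rng) -> np.ndarray:
    """Flag exactly ``K = round(f * N)`` cells positive, drawn without
    replacement with weights ``exp(-d_i / bias_length)``.

    Uses the Efraimidis-Spirakis exponential-key scheme in log space, so
    arbitrarily strong biases (tiny ``bias_length``) stay numerically
    stable.  ``bias_length = inf`` gives uniform weights, i.e. exactly the
    digital-avatar null labeling.
    """
    d = np.asarray(distances, dtype=float)
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    if not bias_length > 0:
        raise ValueError("bias_length must be > 0")
    n = d.size
    k = int(round(f * n))
    flags = np.zeros(n, dtype=bool)
    if k == 0:
        return flags
    if k >= n:
        return np.ones(n, dtype=bool)
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        # smallest keys win: log(-log u) - log w = log(-log u) + d / lambda
        keys = np.log(-np.log(u))
    if np.isfinite(bias_length):
        keys = keys + d / bias_length
    flags[np.argpartition(keys, k - 1)[:k]] = True
    return flags


def _necrosis_mask(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """One random ellipse of area ~ necrosis_fraction of the grid."""
    h, w = config.height, config.width
    mask = np.zeros((h, w), dtype=bool)
    if config.necrosis_fraction == 0:
        return mask
    area = config.necrosis_fraction * h * w
    ratio = rng.uniform(0.5, 1.0)
    a = math.sqrt(area / (math.pi * ratio))
    b = a * ratio
    cy = rng.uniform(0, h)
    cx = rng.uniform(0, w)
    rot = rng.uniform(0, math.pi)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
    mask[rr, cc] = True
    return mask


def generate_dataset(config: SyntheticConfig) -> tuple[TissueSample, SyntheticTruth]:
    """Generate one complete synthetic sample and its ground-truth record.

    Composes stroma growth, necrosis placement, cell placement and marker
    assignment on independent child streams of ``config.seed``, then
    assembles a validated :class:`TissueSample` (round-trippable through
    the sample-bundle writers).
    """
    stroma = generate_stroma(config)
    children = np.random.SeedSequence(config.seed).spawn(3)
    necrosis = _necrosis_mask(config, np.random.default_rng(children[0]))

    xy = place_cells(stroma, necrosis, config.n_cells, np.random.default_rng(children[1]))
    effective_stroma = stroma.raster & ~necrosis
    dmap = distance_map(effective_stroma, config.pixel_size)
    d = dmap[xy[:, 1].astype(np.intp), xy[:, 0].astype(np.intp)]
    marker = assign_marker(
        d, config.positive_fraction, config.bias_length, np.random.default_rng(children[2])
    )

    cells = pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "cell_class": "tumor", "marker": marker}
    )
    sample = tissue_io.assemble_sample(
        cells,
        stroma,
        necrosis,
        pixel_size=config.pixel_size,
        sample_id=f"synthetic-{config.seed}",
    )
    truth = SyntheticTruth(
        config=config,
        realized_stroma_fraction=stroma.area_fraction,
        realized_necrosis_fraction=float(necrosis.mean()),
        n_positive=int(marker.sum()),
    )
    return sample, truth
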