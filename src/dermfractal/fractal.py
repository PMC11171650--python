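"""Box-counting (Minkowski–Bouligand) fractal dimension estimation.

For a binary mask, ``N(eps)`` is the number of cells of an ``eps``-pixel grid
that contain at least one foreground pixel.  The fractal dimension ``D_b`` is
the least-squares slope of ``log N(eps)`` against ``log(1/eps)`` over a finite
schedule of box sizes; on a raster the ``eps -> 0`` limit is unreachable, so
the smallest default box is 2 px to avoid pixel-noise saturation.

``D_b`` depends on the box schedule, so the schedule and the (eps, N) series
are always retained on the result for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError
from .imaging import BinaryMask, DEFAULT_SIDE, binarize, load_image, remove_background


@dataclass
class BoxCountSeries:
    """The (eps, N(eps)) pairs feeding the log-log regression."""

    epsilons: np.ndarray  # strictly increasing box sides, px
    counts: np.ndarray  # N(eps), non-increasing
    mask_side: int

    def __post_init__(self) -> None:
        self.epsilons = np.asarray(self.epsilons, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.epsilons.size != self.counts.size:
            raise ValueError("epsilons and counts must align")
        if np.any(np.diff(self.epsilons) <= 0):
            raise ValueError("epsilons must be strictly increasing")
        if self.epsilons.size and (
            self.epsilons[0] < 1 or self.epsilons[-1] > self.mask_side
        ):
            raise ValueError("epsilons must lie in [1, mask_side]")


@dataclass
class FractalEstimate:
    """Fitted box-counting dimension with its regression diagnostics.

    Attributes
    ----------
    db : float
        Slope of log N(eps) vs log(1/eps) — the box-counting dimension.
    intercept : float
        Regression intercept (same axes).
    r_squared : float
        Coefficient of determination of the log-log fit, in [0, 1].
    series : BoxCountSeries
        The counts the fit was computed from.
    meta : dict
        Run parameters recorded by the pipeline (thresholds, schedule, ...).
    """

    db: float
    intercept: float
    r_squared: float
    series: BoxCountSeries
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Box-counting fractal dimension fit",
            "----------------------------------",
            f"D_b        : {self.db:.6f}",
            f"intercept  : {self.intercept:.6f}",
            f"R^2        : {self.r_squared:.6f}",
            f"n scales   : {self.series.epsilons.size}",
            "  eps   N(eps)",
        ]
        for e, n in zip(self.series.epsilons, self.series.counts):
            lines.append(f"  {e:>4d}  {n}")
        return "\n".join(lines)


@dataclass
class FdConfig:
    """End-to-end pipeline configuration for per-image FD estimation."""

    target_side: int = DEFAULT_SIDE
    binarize_method: str = "otsu"
    fixed_threshold: int | None = None
    invert: bool = False
    fill_holes: bool = True
    min_component_px: int = 1
    scheme: str = "dyadic"
    custom_schedule: list[int] | None = None
    margin_only: bool = False
    grid_offset: tuple[int, int] = (0, 0)


def count_boxes(
    mask: BinaryMask, epsilon: int, grid_offset: tuple[int, int] = (0, 0)
) -> int:
    """Number of eps-grid cells containing at least one foreground pixel.

    The grid is anchored at ``grid_offset`` (row, col); partial cells at the
    right/bottom edges count as cells.
    """
    side = max(mask.height, mask.width)
    if not 1 <= epsilon <= side:
        raise ValueError(f"epsilon {epsilon} outside [1, {side}]")
    if mask.foreground_count == 0:
        raise EmptyMaskError("cannot count boxes of an empty mask")
    rows, cols = np.nonzero(mask.pixels)
    cell_r = (rows + grid_offset[0]) // epsilon
    cell_c = (cols + grid_offset[1]) // epsilon
    # one box id per occupied cell; stride covers any offset magnitude
    stride = int(cell_c.max()) + 1
    return int(np.unique(cell_r * stride + cell_c).size)


def box_schedule(
    mask_side: int, scheme: str = "dyadic", custom: list[int] | None = None
) -> list[int]:
    """Build a strictly increasing schedule of box sides.

    dyadic: powers of two in [2, mask_side/2]; ternary: powers of three in
    [3, mask_side/3]; custom: caller-supplied, validated.
    """
    if mask_side < 2:
        raise ValueError("mask_side must be >= 2")
    if scheme == "dyadic":
        out, e = [], 2
        while e <= mask_side // 2:
            out.append(e)
            e *= 2
        return out
    if scheme == "ternary":
        out, e = [], 3
        while e <= mask_side // 3:
            out.append(e)
            e *= 3
        return out
    if scheme == "custom":
        if not custom:
            raise ValueError("custom schedule is empty")
        sched = [int(e) for e in custom]
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("custom schedule must be strictly increasing")
        if sched[0] < 1 or sched[-1] > mask_side:
            raise ValueError("custom schedule outside [1, mask_side]")
        return sched
    raise ValueError(f"unknown schedule scheme {scheme!r}")


def estimate_fd(
    mask: BinaryMask,
    schedule: list[int],
    grid_offset: tuple[int, int] = (0, 0),
) -> FractalEstimate:
    """Least-squares slope of log N(eps) vs log(1/eps) over ``schedule``.

    A degenerate regression (all counts equal) yields db = 0 with R^2 = 1
    rather than an error.
    """
    if len(schedule) < 2:
        raise ValueError("schedule needs >= 2 box sizes for a slope")
    eps = np.asarray(sorted(schedule), dtype=int)
    counts = np.array([count_boxes(mask, int(e), grid_offset) for e in eps])
    series = BoxCountSeries(eps, counts, mask_side=max(mask.height, mask.width))
    y = np.log(counts.astype(float))
    if np.all(counts == counts[0]):
        return FractalEstimate(0.0, float(y[0]), 1.0, series)
    x = -np.log(eps.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return FractalEstimate(float(slope), float(intercept), r2, series)


def margin_mask(mask: BinaryMask) -> BinaryMask:
    """Inner morphological gradient: foreground pixels on the lesion margin."""
    eroded = ndimage.binary_erosion(mask.pixels)
    return BinaryMask(mask.pixels & ~eroded, meta=dict(mask.meta))


def estimate_fd_image(path: str | Path, config: FdConfig | None = None) -> FractalEstimate:
    """Full per-image pipeline: load -> binarize -> clean -> box-count fit.

    All intermediate parameters (threshold, schedule, modes) are recorded in
    the estimate's ``meta``.  Errors from any stage carry the image id.
    """
    cfg = config or FdConfig()
    img = load_image(path, target_side=cfg.target_side)
    try:
        mask = binarize(
            img,
            method=cfg.binarize_method,
            fixed_threshold=cfg.fixed_threshold,
            invert=cfg.invert,
        )
        mask = remove_background(
            mask, min_component_px=cfg.min_component_px, fill_holes=cfg.fill_holes
        )
        counted = margin_mask(mask) if cfg.margin_only else mask
        schedule = box_schedule(
            max(counted.height, counted.width), cfg.scheme, cfg.custom_schedule
        )
        est = estimate_fd(counted, schedule, grid_offset=cfg.grid_offset)
    except Exception as exc:
        exc.args = (f"{img.source_id}: {exc}",)
        raise
    est.meta = {
        "image_id": img.source_id,
        "threshold": mask.meta.get("threshold"),
        "binarize_method": cfg.binarize_method,
        "invert": cfg.invert,
        "fill_holes": cfg.fill_holes,
        "margin_only": cfg.margin_only,
        "schedule": list(schedule),
        "target_side": cfg.target_side,
    }
    return est
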