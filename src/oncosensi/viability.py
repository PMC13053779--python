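"""Viable-cell area quantification from green-fluorescence plate scans.

Viability is the count of pixels whose calcein-AM green intensity exceeds
a fixed threshold (default 20 on the 0-255 scale, strict inequality),
summed per 8-pillar strip or per pillar.  Growth rate is the day-5 to
day-1 ratio of viable area, in percent; per-dose viability is the treated
area as a percentage of the unirradiated control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate import PlateLayout


@dataclass(frozen=True)
class QuantConfig:
    intensity_threshold: float = 20.0
    strip_size: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_threshold < 255:
            raise ValueError("threshold must lie within the 8-bit dynamic range")
        if 384 % self.strip_size != 0:
            raise ValueError("strip_size must divide 384")


def _as_8bit(image: np.ndarray) -> np.ndarray:
    """Rescale 16-bit scans onto the 0-255 scale the threshold is defined on."""
    img = np.asarray(image)
    if img.dtype == np.uint16:
        return img.astype(float) * (255.0 / 65535.0)
    return img.astype(float)


def quantify_green_area(
    image: np.ndarray,
    layout: PlateLayout,
    config: QuantConfig = QuantConfig(),
) -> pd.DataFrame:
    """Above-threshold pixel count per 8-pillar strip.

    Returns a DataFrame with columns ``strip_index, area_px``, one row per
    strip, strips enumerated row-major.
    """
    img = _as_8bit(image)
    if img.shape != layout.image_shape:
        raise ValueError(
            f"image shape {img.shape} does not match layout {layout.image_shape}"
        )
    if layout.strip_size != config.strip_size:
        layout = PlateLayout(
            n_rows=layout.n_rows, n_cols=layout.n_cols,
            image_shape=layout.image_shape, strip_size=config.strip_size,
        )
    per_pillar = pillar_areas(img, layout, config)
    strip_of = np.array([
        layout.strip_index(r, c)
        for r in range(layout.n_rows) for c in range(layout.n_cols)
    ])
    areas = np.bincount(strip_of, weights=per_pillar.ravel(), minlength=layout.n_strips)
    return pd.DataFrame({
        "strip_index": np.arange(layout.n_strips),
        "area_px": areas.astype(int),
    })


def pillar_areas(
    image: np.ndarray,
    layout: PlateLayout,
    config: QuantConfig = QuantConfig(),
) -> np.ndarray:
    """Above-threshold pixel count per pillar, as an (n_rows, n_cols) array."""
    img = _as_8bit(image)
    if img.shape != layout.image_shape:
        raise ValueError("image shape does not match layout")
    above = img > config.intensity_threshold
    labels = layout.pillar_map()
    counts = np.bincount(labels.ravel(), weights=above.ravel(),
                         minlength=layout.n_rows * layout.n_cols)
    return counts.reshape(layout.n_rows, layout.n_cols).astype(int)


def growth_rate(area_day5: float, area_day1: float, convention: str = "ratio") -> float:
    """Percent growth of viable area between day 1 and day 5.

    ``convention="ratio"`` (default) returns 100 * A5/A1; values below 100
    then read as day-5 area at a fraction of day 1.  ``"increase"`` returns
    the percent change 100 * (A5 - A1)/A1.
    """
    if area_day1 <= 0:
        raise ValueError("day-1 area must be positive")
    if convention == "ratio":
        return 100.0 * area_day5 / area_day1
    if convention == "increase":
        return 100.0 * (area_day5 - area_day1) / area_day1
    raise ValueError(f"unknown growth convention {convention!r}")


def normalize_viability(treated_area: float, control_area: float) -> float:
    """Treated viable area as percent of the unirradiated control.

    Clamped below at 0; deliberately not clamped above 100, since organoids
    may keep growing under low dose.
    """
    if control_area <= 0:
        raise ValueError("control area must be positive")
    return max(0.0, 100.0 * treated_area / control_area)
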