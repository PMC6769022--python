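"""Quantification of two in-vitro readouts.

* Differential scanning fluorimetry (DSF): the melting temperature Tm is
  the temperature at which the min–max-normalized fluorescence trace first
  crosses 0.5 going upward, linearly interpolated between the bracketing
  grid points.

* Bead-aggregation images: the grayscale image is thresholded (fixed value
  or Otsu), connected components are labeled under 8-connectivity, blobs
  smaller than ``min_size`` pixels are discarded, and the per-particle
  areas and their mean are reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "MeltCurve",
    "AggregateStats",
    "NoTransitionError",
    "read_melt_curve",
    "melting_temperature",
    "quantify_aggregates",
    "aggregate_series",
]


class NoTransitionError(ValueError):
    """The melt trace never crosses its normalized midpoint upward."""


@dataclasses.dataclass
class MeltCurve:
    """A fluorescence-vs-temperature trace (temperatures strictly increasing)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape or self.temperatures.ndim != 1:
            raise ValueError("temperature and fluorescence must be equal-length 1-D")
        if len(self.temperatures) < 3:
            raise ValueError("melt curve needs at least 3 points")
        if not np.all(np.isfinite(self.temperatures)) or not np.all(
            np.isfinite(self.fluorescence)
        ):
            raise ValueError("melt curve contains non-finite values")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclasses.dataclass
class AggregateStats:
    particle_count: int
    areas: np.ndarray  # pixels, one entry per particle
    mean_area: float
    empty: bool  # True when no particle survived thresholding/size filter
    threshold_used: float


def read_melt_curve(path: str) -> MeltCurve:
    """Read a CSV with columns temperature,fluorescence (well id optional)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        t, f = cols["temperature"], cols["fluorescence"]
    except KeyError as exc:
        raise ValueError(f"{path}: need 'temperature' and 'fluorescence' columns") from exc
    return MeltCurve(df[t].to_numpy(), df[f].to_numpy())


def melting_temperature(curve: MeltCurve) -> float:
    """Tm = temperature of the first upward 0.5-crossing of the normalized trace.

    Normalization is min–max over the full trace, which makes the result
    invariant under any positive affine rescaling of the fluorescence.
    """
    f = curve.fluorescence
    lo, hi = float(f.min()), float(f.max())
    if hi <= lo:
        raise NoTransitionError("flat fluorescence trace")
    norm = (f - lo) / (hi - lo)
    t = curve.temperatures
    if norm[0] >= 0.5:
        raise NoTransitionError("trace starts at or above its midpoint")
    for i in range(len(norm) - 1):
        if norm[i] < 0.5 <= norm[i + 1]:
            frac = (0.5 - norm[i]) / (norm[i + 1] - norm[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise NoTransitionError("no upward crossing of normalized fluorescence 0.5")


def quantify_aggregates(
    image: np.ndarray,
    threshold: float | None = None,
    min_size: int = 1,
) -> AggregateStats:
    """Count and size bright particles in a grayscale image.

    ``threshold=None`` selects Otsu's threshold from the intensity
    histogram.  Pixels strictly above the threshold form the foreground;
    components are 8-connected; components smaller than ``min_size`` pixels
    are discarded.  A blank mask yields count 0 / mean 0 with ``empty``
    set.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise ValueError("image must be a non-empty 2-D array")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if threshold is None:
        if np.ptp(img) == 0:
            return AggregateStats(0, np.array([], dtype=int), 0.0, True, float(img.flat[0]))
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    if not mask.any():
        return AggregateStats(0, np.array([], dtype=int), 0.0, True, float(threshold))
    labels = label(mask, connectivity=2)
    areas = np.array(
        [p.area for p in regionprops(labels) if p.area >= min_size], dtype=int
    )
    if len(areas) == 0:
        return AggregateStats(0, areas, 0.0, True, float(threshold))
    return AggregateStats(len(areas), areas, float(areas.mean()), False, float(threshold))


def aggregate_series(
    images: list[np.ndarray],
    threshold: float | None = None,
    min_size: int = 1,
) -> tuple[float, float]:
    """Mean of per-image mean particle areas and its standard error.

    Replicate images (e.g. time points T0/T60 or post-rocking R1/R2) are
    treated independently; SEM uses n−1 in the variance (0 when n < 2).
    """
    means = np.array(
        [quantify_aggregates(im, threshold, min_size).mean_area for im in images]
    )
    if len(means) == 0:
        raise ValueError("no images given")
    sem = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0
    return float(means.mean()), sem
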