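"""Manders overlap analysis between two channels of a section.

Implements the intensity-weighted Manders coefficients:

    M1 = sum of channel-A intensity on pixels where both channels are
         above their thresholds, divided by the total channel-A intensity
         above A's threshold;
    M2 = the same with the channel roles swapped.

Thresholds gate the masks only; intensities are summed as they are, with
no background subtraction.  The directional prose often used to describe
M1/M2 ("the overlap of signal A over signal B") maps onto this formula as
"the proportion of A's suprathreshold signal that lies within B's
suprathreshold mask".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import threshold_channel

__all__ = ["ColocResult", "auto_threshold_pair", "manders", "scatter_data"]


@dataclass
class ColocResult:
    """Manders coefficients with the thresholds that produced them.

    ``m1``/``m2`` are NaN when the corresponding channel has no
    suprathreshold signal at all.  ``scatter`` is an optional (n, 2)
    paired-intensity sample for plotting.
    """

    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    scatter: np.ndarray | None = None


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel rasters must share a shape")
    return a, b


def auto_threshold_pair(
    raster_a: np.ndarray, raster_b: np.ndarray
) -> tuple[float, float]:
    """Per-channel automatic (Otsu) thresholds.

    A constant channel has no Otsu threshold; 0 is returned for it with a
    warning (so a constant-zero channel contributes an empty mask).
    """
    a, b = _check_pair(raster_a, raster_b)
    out = []
    for r in (a, b):
        if r.max() == r.min():
            warnings.warn(
                "constant channel: auto threshold undefined, using 0", stacklevel=2
            )
            out.append(0.0)
        else:
            _, t = threshold_channel(r, "otsu")
            out.append(t)
    return out[0], out[1]


def manders(
    raster_a: np.ndarray,
    raster_b: np.ndarray,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> ColocResult:
    """Intensity-weighted Manders coefficients of two equal-shape rasters.

    When thresholds are not supplied they are determined automatically
    with :func:`auto_threshold_pair`.
    """
    a, b = _check_pair(raster_a, raster_b)
    if threshold_a is None or threshold_b is None:
        ta, tb = auto_threshold_pair(a, b)
        threshold_a = ta if threshold_a is None else threshold_a
        threshold_b = tb if threshold_b is None else threshold_b
    if threshold_a < 0 or threshold_b < 0:
        raise ValueError("thresholds must be >= 0")
    mask_a = a > threshold_a
    mask_b = b > threshold_b

    total_a = a[mask_a].sum()
    total_b = b[mask_b].sum()
    m1 = float(a[mask_a & mask_b].sum() / total_a) if total_a > 0 else float("nan")
    m2 = float(b[mask_a & mask_b].sum() / total_b) if total_b > 0 else float("nan")
    return ColocResult(
        m1=m1, m2=m2, threshold_a=float(threshold_a), threshold_b=float(threshold_b)
    )


def scatter_data(
    raster_a: np.ndarray,
    raster_b: np.ndarray,
    max_points: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Paired pixel intensities, uniformly subsampled to ``max_points``.

    Returns an (n, 2) array of (A, B) intensities.  The subsample is
    drawn without replacement with a seeded generator, so it is
    reproducible; when the image has at most ``max_points`` pixels, all
    pixels are returned in raster order.
    """
    a, b = _check_pair(raster_a, raster_b)
    pairs = np.column_stack([a.ravel(), b.ravel()])
    if len(pairs) <= max_points:
        return pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=max_points, replace=False)
    return pairs[np.sort(idx)]
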