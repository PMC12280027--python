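"""Per-section morphometric metrics.

Every quantity is derived from the compartment masks, the nucleus table,
and (optionally) a marker channel such as GLP-1, PRLR, or 5-HT2B:

* areas in um^2 (pixel count x pixel_size^2) per compartment,
* fractional areas as % of the tissue (default) or exocrine area,
* mean area per islet (total compartment area / islet count),
* islet density in islets per mm^2 of tissue,
* islet diameters as maximum Feret diameter (longest axis) in um,
* estimated cell sizes (compartment area / nuclei count) in um^2,
* nuclei counts per compartment as % of total islet nuclei,
* the percentage of islets containing any alpha-positive area,
* marker-positive area and integrated marker intensity (AU/mm^2)
  per compartment.

Quantities that are undefined for a section (e.g. mean islet area with
zero islets) are reported as NaN, never as zero.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .nuclei import NucleusSet
from .segmentation import CompartmentSet, preprocess_channel, threshold_channel

__all__ = [
    "fractional_area",
    "mean_area_per_islet",
    "islet_density",
    "max_feret_diameter",
    "islet_diameters",
    "estimated_cell_size",
    "normalized_nuclei_count",
    "alpha_positive_islet_fraction",
    "marker_metrics",
    "section_metrics",
]


def _area(mask: np.ndarray, pixel_size: float) -> float:
    return float(np.count_nonzero(mask)) * pixel_size**2


def fractional_area(area: float, denominator_area: float) -> float:
    """Compartment area as a percentage of a reference area."""
    if denominator_area <= 0:
        raise ValueError("reference area must be > 0")
    return 100.0 * area / denominator_area


def mean_area_per_islet(total_area: float, islet_count: int) -> float:
    """Total compartment area divided by islet count; NaN for 0 islets."""
    if islet_count < 0:
        raise ValueError("islet_count must be >= 0")
    return float("nan") if islet_count == 0 else total_area / islet_count


def islet_density(islet_count: int, tissue_area_um2: float) -> float:
    """Islets per mm^2 of tissue."""
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be > 0")
    return islet_count / (tissue_area_um2 / 1e6)


def max_feret_diameter(coords: np.ndarray, pixel_size: float = 1.0) -> float:
    """Maximum pairwise distance between pixel centres, in um.

    ``coords`` is an (n, 2) array of pixel (row, col) indices.  The
    maximum is attained on the convex hull, so the hull is taken first
    and the brute-force pairwise maximum computed over its vertices; a
    single pixel has diameter 0 by convention.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if len(coords) <= 1:
        return 0.0
    pts = coords
    if len(coords) > 3:
        try:
            pts = coords[ConvexHull(coords).vertices]
        except QhullError:  # collinear points
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max()) * pixel_size


def islet_diameters(whole_islet: np.ndarray, pixel_size: float) -> np.ndarray:
    """Maximum Feret diameter of every labelled islet, in label order."""
    whole_islet = np.asarray(whole_islet)
    n = int(whole_islet.max())
    out = np.empty(n)
    slices = ndi.find_objects(whole_islet)
    for k in range(1, n + 1):
        sl = slices[k - 1]
        coords = np.argwhere(whole_islet[sl] == k)
        out[k - 1] = max_feret_diameter(coords, pixel_size)
    return out


def estimated_cell_size(compartment_area: float, nuclei_count: int) -> float:
    """Compartment area divided by its nuclei count; NaN for 0 nuclei."""
    if nuclei_count < 0:
        raise ValueError("nuclei_count must be >= 0")
    return float("nan") if nuclei_count == 0 else compartment_area / nuclei_count


def normalized_nuclei_count(count: int, total_islet_nuclei: int) -> float:
    """Compartment nuclei as a percentage of all islet nuclei; NaN if none."""
    if count > total_islet_nuclei:
        raise ValueError("compartment count exceeds total islet nuclei")
    if total_islet_nuclei == 0:
        return float("nan")
    return 100.0 * count / total_islet_nuclei


def alpha_positive_islet_fraction(
    compartments: CompartmentSet, min_alpha_area: float = 0.0
) -> float:
    """Percentage of islets whose alpha-positive area reaches ``min_alpha_area``.

    Alpha-positive area of an islet is its ``alpha_only | bihormonal``
    area in um^2; with the default ``min_alpha_area = 0`` any alpha pixel
    qualifies.  NaN when the section has no islets.
    """
    if min_alpha_area < 0:
        raise ValueError("min_alpha_area must be >= 0")
    n = compartments.islet_count
    if n == 0:
        return float("nan")
    alpha_pos = compartments.alpha_only | compartments.bihormonal
    px_area = compartments.pixel_size**2
    counts = np.bincount(
        compartments.whole_islet[alpha_pos].ravel(), minlength=n + 1
    )[1 : n + 1]
    if min_alpha_area == 0:
        positive = counts > 0
    else:
        positive = counts * px_area >= min_alpha_area
    return 100.0 * positive.sum() / n


def marker_metrics(
    marker_raster: np.ndarray,
    compartments: CompartmentSet,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    mean_radius: int = 1,
    fractional_mode: str = "tissue",
) -> dict[str, float]:
    """Marker-positive area and intensity per compartment.

    The marker channel is mean-filtered and thresholded to give the
    marker-positive mask.  For each compartment c the metrics are

    * ``marker_area_in_<c>_um2``: marker-positive area inside c,
    * ``marker_pct_of_<c>_area``: that area as % of c's area,
    * ``marker_intensity_<c>_au_per_mm2``: integrated raw marker
      intensity over all of c, divided by c's area in mm^2.

    Plus the whole-section quantities ``marker_area_um2``,
    ``marker_fractional_area_pct`` and ``marker_mean_area_per_islet_um2``.
    """
    marker_raster = np.asarray(marker_raster, dtype=np.float64)
    if marker_raster.shape != compartments.whole_islet.shape:
        raise ValueError("marker raster and compartments are on different grids")
    pre = preprocess_channel(marker_raster, closing_radius=0, mean_radius=mean_radius)
    mask, t = threshold_channel(
        pre,
        "fixed" if threshold_value is not None else threshold_method,
        threshold_value,
    )
    px = compartments.pixel_size
    regions = {
        "islet": compartments.islet_footprint,
        "alpha": compartments.alpha_only,
        "beta": compartments.beta_only,
        "bihormonal": compartments.bihormonal,
    }
    out: dict[str, float] = {"marker_threshold": t}
    marker_area = _area(mask, px)
    out["marker_area_um2"] = marker_area
    reference = (
        compartments.tissue if fractional_mode == "tissue" else compartments.exocrine
    )
    ref_area = _area(reference, px)
    out["marker_fractional_area_pct"] = (
        fractional_area(marker_area, ref_area) if ref_area > 0 else float("nan")
    )
    out["marker_mean_area_per_islet_um2"] = mean_area_per_islet(
        _area(mask & compartments.islet_footprint, px), compartments.islet_count
    )
    for name, region in regions.items():
        region_area = _area(region, px)
        inside = _area(mask & region, px)
        out[f"marker_area_in_{name}_um2"] = inside
        out[f"marker_pct_of_{name}_area"] = (
            100.0 * inside / region_area if region_area > 0 else float("nan")
        )
        out[f"marker_intensity_{name}_au_per_mm2"] = (
            float(marker_raster[region].sum()) / (region_area / 1e6)
            if region_area > 0
            else float("nan")
        )
    return out


def section_metrics(
    compartments: CompartmentSet,
    nuclei: NucleusSet | None = None,
    marker_raster: np.ndarray | None = None,
    fractional_mode: str = "tissue",
    marker_threshold_method: str = "otsu",
    marker_threshold_value: float | None = None,
) -> dict[str, float]:
    """All per-section metrics as one flat dict with unit-suffixed keys.

    ``fractional_mode`` selects the denominator of fractional areas:
    ``"tissue"`` (whole thresholded section, the default) or
    ``"exocrine"`` (tissue minus islets).  ``nuclei`` must already carry
    compartment assignments; nucleus-derived metrics are NaN when it is
    omitted.  Marker metrics are included when ``marker_raster`` is given.
    """
    if fractional_mode not in ("tissue", "exocrine"):
        raise ValueError(f"unknown fractional_mode {fractional_mode!r}")
    px = compartments.pixel_size
    areas = {
        "islet": _area(compartments.islet_footprint, px),
        "alpha": _area(compartments.alpha_only, px),
        "beta": _area(compartments.beta_only, px),
        "bihormonal": _area(compartments.bihormonal, px),
    }
    tissue_area = _area(compartments.tissue, px)
    reference_area = (
        tissue_area if fractional_mode == "tissue" else _area(compartments.exocrine, px)
    )
    n_islets = compartments.islet_count

    m: dict[str, float] = {}
    for c, area in areas.items():
        m[f"{c}_area_um2"] = area
        m[f"{c}_fractional_area_pct"] = (
            fractional_area(area, reference_area) if reference_area > 0 else float("nan")
        )
        m[f"{c}_mean_area_per_islet_um2"] = mean_area_per_islet(area, n_islets)
    for c in ("alpha", "beta", "bihormonal"):
        m[f"{c}_proportion_of_islet_pct"] = (
            100.0 * areas[c] / areas["islet"] if areas["islet"] > 0 else float("nan")
        )
    m["tissue_area_um2"] = tissue_area
    m["exocrine_area_um2"] = _area(compartments.exocrine, px)
    m["islet_count"] = float(n_islets)
    m["islet_density_per_mm2"] = (
        islet_density(n_islets, tissue_area) if tissue_area > 0 else float("nan")
    )
    diameters = islet_diameters(compartments.whole_islet, px)
    m["islet_diameter_mean_um"] = (
        float(diameters.mean()) if diameters.size else float("nan")
    )
    m["alpha_positive_islet_fraction_pct"] = alpha_positive_islet_fraction(compartments)

    for c in ("alpha", "beta"):
        m[f"estimated_cell_size_{c}_um2"] = float("nan")
        m[f"normalized_nuclei_count_{c}_pct"] = float("nan")
    m["islet_nuclei_count"] = float("nan")
    if nuclei is not None and "compartment" in nuclei.table.columns:
        counts = nuclei.counts_by_compartment()
        islet_total = counts["alpha"] + counts["beta"] + counts["bihormonal"]
        islet_total += counts["islet-other"]
        m["islet_nuclei_count"] = float(islet_total)
        for c in ("alpha", "beta"):
            m[f"estimated_cell_size_{c}_um2"] = estimated_cell_size(
                areas[c], counts[c]
            )
            m[f"normalized_nuclei_count_{c}_pct"] = normalized_nuclei_count(
                counts[c], islet_total
            )

    if marker_raster is not None:
        m.update(
            marker_metrics(
                marker_raster,
                compartments,
                threshold_method=marker_threshold_method,
                threshold_value=marker_threshold_value,
                fractional_mode=fractional_mode,
            )
        )
    if not all(
        math.isnan(v) or v >= 0 for k, v in m.items() if k != "marker_threshold"
    ):
        raise AssertionError("negative metric computed; masks are inconsistent")
    return m
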