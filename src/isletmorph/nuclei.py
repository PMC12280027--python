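"""Nucleus segmentation, size filtering, and compartment assignment.

Nuclei are segmented from the DAPI channel by thresholding followed by a
distance-transform watershed (seeds at h-maxima of the smoothed distance
map), which splits touching nuclei.  Objects larger than a maximum
equivalent diameter (default 10 um) are discarded as artefacts, and each
retained nucleus is assigned to the compartment containing its centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .segmentation import CompartmentSet, threshold_channel

__all__ = ["NucleusSet", "segment_nuclei", "filter_nuclei", "assign_nuclei"]

COMPARTMENT_NAMES = ("alpha", "beta", "bihormonal", "islet-other", "exocrine")

_COLUMNS = ["label", "centroid_row", "centroid_col", "area_um2", "eq_diameter_um"]


@dataclass
class NucleusSet:
    """Labelled nucleus map plus a per-nucleus table.

    ``table`` columns: ``label``, ``centroid_row``, ``centroid_col``
    (pixels), ``area_um2``, ``eq_diameter_um`` (``2 * sqrt(area / pi)``),
    and, after :func:`assign_nuclei`, ``compartment``.
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size: float

    def __len__(self) -> int:
        return len(self.table)

    def counts_by_compartment(self) -> dict[str, int]:
        if "compartment" not in self.table.columns:
            raise ValueError("nuclei not yet assigned; run assign_nuclei first")
        counts = self.table["compartment"].value_counts().to_dict()
        return {name: int(counts.get(name, 0)) for name in COMPARTMENT_NAMES}


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in _COLUMNS}).astype(
        {"label": int}
    )


def segment_nuclei(
    raster: np.ndarray,
    pixel_size: float,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    smooth_sigma: float = 0.5,
    h: float = 1.0,
) -> NucleusSet:
    """Distance-transform watershed segmentation of the nuclei channel.

    Foreground is obtained by thresholding, the Euclidean distance
    transform is Gaussian-smoothed (``smooth_sigma`` px), and watershed
    seeds are its h-maxima with height ``h`` px.  A blank channel yields
    an empty :class:`NucleusSet` rather than an error.
    """
    raster = np.asarray(raster)
    if raster.max() == raster.min():
        return NucleusSet(
            labels=np.zeros(raster.shape, dtype=np.int32),
            table=_empty_table(),
            pixel_size=pixel_size,
        )
    mask, _ = threshold_channel(
        raster,
        "fixed" if threshold_value is not None else threshold_method,
        threshold_value,
    )
    if not mask.any():
        return NucleusSet(
            labels=np.zeros(raster.shape, dtype=np.int32),
            table=_empty_table(),
            pixel_size=pixel_size,
        )
    distance = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(distance, smooth_sigma) if smooth_sigma > 0 else distance
    seeds, _ = ndi.label(h_maxima(smoothed, h))
    labels = watershed(-smoothed, seeds, mask=mask).astype(np.int32)

    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    table = pd.DataFrame(
        {
            "label": props["label"].astype(int),
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
            "area_um2": props["area"] * pixel_size**2,
        }
    )
    table["eq_diameter_um"] = 2.0 * np.sqrt(table["area_um2"] / np.pi)
    return NucleusSet(labels=labels, table=table, pixel_size=pixel_size)


def filter_nuclei(nuclei: NucleusSet, max_diameter: float = 10.0) -> NucleusSet:
    """Remove objects with equivalent diameter strictly above ``max_diameter`` um."""
    if max_diameter <= 0:
        raise ValueError("max_diameter must be > 0")
    keep = nuclei.table["eq_diameter_um"] <= max_diameter
    table = nuclei.table.loc[keep].reset_index(drop=True)
    kept_labels = set(table["label"].tolist())
    labels = np.where(np.isin(nuclei.labels, list(kept_labels)), nuclei.labels, 0)
    return replace(nuclei, labels=labels.astype(np.int32), table=table)


def assign_nuclei(nuclei: NucleusSet, compartments: CompartmentSet) -> NucleusSet:
    """Assign each nucleus to the compartment containing its centroid.

    Assignment is by centroid membership (rounded to the nearest pixel):
    ``alpha`` / ``beta`` / ``bihormonal`` for the islet cell territories,
    ``islet-other`` for islet pixels outside all three (possible only if
    masks were edited by hand), ``exocrine`` otherwise.  Centroids falling
    outside the tissue footprint are assigned ``exocrine`` with a warning.
    """
    if nuclei.labels.shape != compartments.whole_islet.shape:
        raise ValueError("nuclei and compartments are on different grids")
    table = nuclei.table.copy()
    if table.empty:
        table["compartment"] = pd.Series(dtype=object)
        return replace(nuclei, table=table)

    rows = np.clip(
        np.rint(table["centroid_row"]).astype(int), 0, nuclei.labels.shape[0] - 1
    )
    cols = np.clip(
        np.rint(table["centroid_col"]).astype(int), 0, nuclei.labels.shape[1] - 1
    )
    compartment = np.full(len(table), "exocrine", dtype=object)
    fp = compartments.islet_footprint
    compartment[fp[rows, cols]] = "islet-other"
    compartment[compartments.alpha_only[rows, cols]] = "alpha"
    compartment[compartments.beta_only[rows, cols]] = "beta"
    compartment[compartments.bihormonal[rows, cols]] = "bihormonal"

    outside = ~compartments.tissue[rows, cols]
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} nucleus centroid(s) outside the tissue footprint; "
            "assigned 'exocrine'",
            stacklevel=2,
        )
    table["compartment"] = compartment
    return replace(nuclei, table=table)
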