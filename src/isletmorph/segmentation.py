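"""Segmentation of multichannel pancreas sections into islet compartments.

The operator sequence mirrors a standard immunofluorescence morphometry
workflow: the glucagon and insulin channels are closed (to bridge small
gaps between stained cells) and mean-filtered (to suppress noise), then
thresholded.  The two hormone masks are combined into whole-islet objects,
small objects are discarded as non-specific staining, and each retained
islet is partitioned into three mutually exclusive cell compartments:

* ``alpha_only``   -- glucagon-positive, insulin-negative pixels,
* ``beta_only``    -- insulin-positive, glucagon-negative pixels,
* ``bihormonal``   -- pixels positive for both hormones.

Exocrine tissue is everything inside the thresholded tissue footprint that
is not part of a retained islet.

All masks live on the image pixel grid (row-major, origin top-left); areas
are ``pixel count * pixel_size**2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = [
    "MultiChannelSection",
    "CompartmentSet",
    "preprocess_channel",
    "threshold_channel",
    "segment_tissue",
    "assemble_islets",
    "compartmentalize",
    "derive_exocrine",
    "segment_section",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultiChannelSection:
    """A calibrated 2-D image stack with named channels.

    Parameters
    ----------
    channels
        Mapping from channel name (``"nuclei"``, ``"glucagon"``,
        ``"insulin"``, optionally ``"marker"``) to a 2-D float array of
        non-negative intensities.  All channels must share one shape.
    pixel_size
        Physical size of a pixel edge in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a section needs at least one channel")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {np.asarray(r).shape for r in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        self.channels = {
            name: np.asarray(r, dtype=np.float32) for name, r in self.channels.items()
        }
        for name, r in self.channels.items():
            if r.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if r.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class CompartmentSet:
    """Labelled whole-islet map plus binary compartment masks.

    ``whole_islet`` labels islet pixels 1..K (0 = background); its nonzero
    footprint equals ``alpha_only | beta_only | bihormonal`` exactly.
    ``exocrine`` is ``tissue`` minus the islet footprint.
    """

    whole_islet: np.ndarray
    alpha_only: np.ndarray
    beta_only: np.ndarray
    bihormonal: np.ndarray
    tissue: np.ndarray
    exocrine: np.ndarray
    pixel_size: float
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def islet_footprint(self) -> np.ndarray:
        return self.whole_islet > 0

    @property
    def islet_count(self) -> int:
        return int(self.whole_islet.max())

    def check_partition(self) -> bool:
        """True iff alpha-only/beta-only/bihormonal tile the islet footprint."""
        fp = self.islet_footprint
        disjoint = not (
            np.any(self.alpha_only & self.beta_only)
            or np.any(self.alpha_only & self.bihormonal)
            or np.any(self.beta_only & self.bihormonal)
        )
        union = self.alpha_only | self.beta_only | self.bihormonal
        return disjoint and bool(np.array_equal(union, fp))


# ---------------------------------------------------------------------------
# Channel preprocessing and thresholding
# ---------------------------------------------------------------------------

def preprocess_channel(
    raster: np.ndarray,
    closing_radius: int = 2,
    mean_radius: int = 1,
) -> np.ndarray:
    """Grayscale closing then mean filter, both with disc elements.

    Radii are in pixels; a radius of 0 disables the corresponding step.
    Closing fills dark gaps narrower than the disc, which bridges the
    small unstained spaces between adjacent hormone-positive cells.
    """
    raster = np.asarray(raster, dtype=np.float32)
    for r, name in ((closing_radius, "closing_radius"), (mean_radius, "mean_radius")):
        if r < 0:
            raise ValueError(f"{name} must be >= 0, got {r}")
        if 2 * r + 1 > min(raster.shape):
            raise ValueError(f"{name}={r} px exceeds image size {raster.shape}")
    out = raster
    if closing_radius > 0:
        out = ndi.grey_closing(out, footprint=disk(closing_radius))
    if mean_radius > 0:
        footprint = disk(mean_radius).astype(np.float32)
        footprint /= footprint.sum()
        out = ndi.convolve(out, footprint, mode="reflect")
    return out


def threshold_channel(
    raster: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
) -> tuple[np.ndarray, float]:
    """Binarise a channel; returns ``(mask, threshold_used)``.

    ``method="otsu"`` picks the threshold maximising between-class
    variance; ``method="fixed"`` uses ``value``.  The mask is strictly
    ``raster > threshold``.  A constant raster has no Otsu threshold: an
    empty mask is returned with a warning.
    """
    raster = np.asarray(raster)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        t = float(value)
    elif method == "otsu":
        if raster.max() == raster.min():
            warnings.warn(
                "constant raster: Otsu threshold is undefined, returning empty mask",
                stacklevel=2,
            )
            return np.zeros(raster.shape, dtype=bool), float(raster.max())
        t = float(threshold_otsu(raster))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return raster > t, t


def segment_tissue(section: MultiChannelSection) -> np.ndarray:
    """Tissue footprint from an all-channel sum projection.

    The summed projection of a slide image is trimodal — glass, tissue
    autofluorescence, bright staining — so a two-class Otsu threshold can
    land in a tissue/stain valley and discard dim exocrine tissue.  The
    projection is log-compressed (which stabilises the bright class, whose
    raw-intensity spread otherwise dominates the histogram) and split into
    three classes with multi-Otsu; tissue is everything above the lowest
    threshold, i.e. the glass/tissue boundary.  Holes are filled so dark
    regions enclosed by tissue stay in the footprint.
    """
    projection = np.sum(
        [section.channels[c] for c in section.channels], axis=0, dtype=np.float64
    )
    if projection.max() == projection.min():
        return np.zeros(projection.shape, dtype=bool)
    log_proj = np.log1p(projection)
    try:
        t = float(threshold_multiotsu(log_proj, classes=3)[0])
    except ValueError:  # fewer than 3 distinct values
        t = float(threshold_otsu(log_proj))
    return ndi.binary_fill_holes(log_proj > t)


# ---------------------------------------------------------------------------
# Islet assembly and compartmentalisation
# ---------------------------------------------------------------------------

def assemble_islets(
    alpha_mask: np.ndarray,
    beta_mask: np.ndarray,
    min_area: float = 1000.0,
    pixel_size: float = 0.65,
    closing_radius: int = 2,
) -> np.ndarray:
    """Combine hormone masks into a labelled whole-islet map.

    The union of the two masks is binary-closed (disc of
    ``closing_radius`` px) so that hormone blobs separated by sub-cellular
    gaps join into one islet, then 8-connected components are labelled.
    Labels are kept only on hormone-positive pixels (the closing decides
    connectivity, it does not add islet area), and components whose
    hormone-positive area is below ``min_area`` (square micrometres,
    strict ``<``) are removed as non-specific staining.  Surviving islets
    are relabelled 1..K.
    """
    alpha_mask = np.asarray(alpha_mask, dtype=bool)
    beta_mask = np.asarray(beta_mask, dtype=bool)
    if alpha_mask.shape != beta_mask.shape:
        raise ValueError("alpha and beta masks must share a shape")
    union = alpha_mask | beta_mask
    if not union.any():
        return np.zeros(union.shape, dtype=np.int32)
    closed = union
    if closing_radius > 0:
        closed = ndi.binary_closing(
            union, structure=disk(closing_radius), border_value=0
        ) | union
    labels = cc_label(closed, connectivity=2)
    labels = np.where(union, labels, 0)

    px_area = pixel_size**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts * px_area >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[labels]


def compartmentalize(
    whole_islet: np.ndarray,
    alpha_mask: np.ndarray,
    beta_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the islet footprint into alpha-only/beta-only/bihormonal masks.

    Returns ``(alpha_only, beta_only, bihormonal)``.  Within the islet
    footprint, bihormonal pixels are positive in both hormone channels and
    the three masks tile the footprint exactly.
    """
    fp = np.asarray(whole_islet) > 0
    alpha_mask = np.asarray(alpha_mask, dtype=bool)
    beta_mask = np.asarray(beta_mask, dtype=bool)
    bihormonal = fp & alpha_mask & beta_mask
    alpha_only = fp & alpha_mask & ~beta_mask
    beta_only = fp & beta_mask & ~alpha_mask
    return alpha_only, beta_only, bihormonal


def derive_exocrine(tissue: np.ndarray, whole_islet: np.ndarray) -> np.ndarray:
    """Exocrine tissue = tissue footprint minus the islet footprint."""
    return np.asarray(tissue, dtype=bool) & ~(np.asarray(whole_islet) > 0)


# ---------------------------------------------------------------------------
# End-to-end section segmentation
# ---------------------------------------------------------------------------

def segment_section(
    section: MultiChannelSection,
    closing_radius: int = 2,
    mean_radius: int = 1,
    threshold_method: str = "otsu",
    fixed_thresholds: dict[str, float] | None = None,
    min_islet_area: float = 1000.0,
) -> CompartmentSet:
    """Run the full segmentation sequence on one section.

    Glucagon and insulin channels are preprocessed and thresholded
    (per-section thresholds; fixed values per channel may be supplied via
    ``fixed_thresholds``), islets are assembled and size-filtered, the
    retained islets are compartmentalised, and the tissue/exocrine masks
    are derived.  The thresholds actually applied are recorded on the
    returned :class:`CompartmentSet`.
    """
    fixed_thresholds = fixed_thresholds or {}
    thresholds: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    for name in ("glucagon", "insulin"):
        pre = preprocess_channel(section.channel(name), closing_radius, mean_radius)
        if name in fixed_thresholds:
            mask, t = threshold_channel(pre, "fixed", fixed_thresholds[name])
        else:
            mask, t = threshold_channel(pre, threshold_method)
        masks[name], thresholds[name] = mask, t

    whole_islet = assemble_islets(
        masks["glucagon"],
        masks["insulin"],
        min_area=min_islet_area,
        pixel_size=section.pixel_size,
        closing_radius=closing_radius,
    )
    alpha_only, beta_only, bihormonal = compartmentalize(
        whole_islet, masks["glucagon"], masks["insulin"]
    )
    # tissue must contain every hormone-positive pixel by construction
    tissue = segment_tissue(section) | masks["glucagon"] | masks["insulin"]
    exocrine = derive_exocrine(tissue, whole_islet)
    return CompartmentSet(
        whole_islet=whole_islet,
        alpha_only=alpha_only,
        beta_only=beta_only,
        bihormonal=bihormonal,
        tissue=tissue,
        exocrine=exocrine,
        pixel_size=section.pixel_size,
        thresholds=thresholds,
    )
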