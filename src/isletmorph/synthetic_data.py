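"""Synthetic sections, cohorts, and protein matrices with known ground truth.

The section generator emulates a whole-slide immunofluorescence image of
pancreas: lobulated islets (unions of overlapping discs) scattered over an
exocrine background, each islet split into contiguous angular territories of alpha (glucagon+),
beta (insulin+), and bihormonal (glucagon+/insulin+) signal around a
compact hormone-negative core that stands in for non-endocrine islet
tissue; bihormonal wedges sit between the alpha and beta territories.  Nuclei are small discs on a jittered
grid across the whole tissue, spaced so that no two nuclei touch.  A
marker channel (e.g. GLP-1) labels a deterministic central portion of each
alpha territory.  Every ground-truth quantity is measured directly from
the rendered noise-free masks, so truth and image can never disagree.

The cohort generator draws a "pregnant" and a "control" group from the
same section parameters; pregnancy effect multipliers act on islet size
(area multiplier applied to the squared radius) and on the per-compartment
area shares, and a mean-preserving log-normal donor factor with a given
coefficient of variation models biological between-donor variability.
With all multipliers at 1 the two groups are exchangeable.

The matrix generator draws log-normal protein intensities (normal on the
log2 scale), shifts a chosen set of spiked proteins by a fixed log2 effect
in one group, and censors values completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .proteomics_diff import ProteinMatrix
from .segmentation import MultiChannelSection

__all__ = [
    "SectionParams",
    "GroundTruth",
    "CohortParams",
    "MatrixParams",
    "SectionRecord",
    "generate_section",
    "generate_cohort",
    "generate_protein_matrix",
]

# Default pregnancy multipliers: whole-islet, alpha-cell, beta-cell and
# bihormonal-cell area fold changes observed in third-trimester donors,
# plus marker (GLP-1) positive-fraction and intensity folds.
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "islet_area": 1.9,
    "alpha_area": 4.3,
    "beta_area": 1.9,
    "bihormonal_area": 5.4,
    "marker_area": 2.39,
    "marker_intensity": 1.33,
}

class PackingError(ValueError):
    """Raised when the requested islets cannot be placed on the canvas."""


@dataclass(frozen=True)
class SectionParams:
    """Parameters of one synthetic section.

    Defaults are calibrated so that a control section has ~1.6% of its
    tissue area occupied by islets with a mean islet area near 6250 um^2,
    the alpha/beta/bihormonal shares of islet area near 6%/88%/6%,
    and a marker-positive fraction of the alpha territory near 22%.
    """

    width: int = 560
    height: int = 560
    pixel_size: float = 2.0  # um per pixel
    n_islets: int = 3
    islet_radius_range: tuple[float, float] = (52.0, 57.0)  # um
    alpha_fraction: float = 0.05  # shares of the islet blob area
    beta_fraction: float = 0.70
    bihormonal_fraction: float = 0.05
    nuclei_density: float = 5.0  # nuclei per 1000 um^2 of tissue
    nucleus_radius: float = 4.0  # um
    marker_positive_fraction_of_alpha: float = 0.22
    signal_level: float = 200.0
    background_level: float = 40.0
    marker_intensity_scale: float = 1.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.width < 16 or self.height < 16:
            raise ValueError("canvas too small")
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        lo, hi = self.islet_radius_range
        if not (0 < lo <= hi):
            raise ValueError("islet_radius_range must satisfy 0 < lo <= hi")
        fr = (self.alpha_fraction, self.beta_fraction, self.bihormonal_fraction)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("compartment fractions must lie in [0, 1]")
        if sum(fr) > 1 + 1e-9:
            raise ValueError("compartment fractions must sum to <= 1")
        if not 0 <= self.marker_positive_fraction_of_alpha <= 1:
            raise ValueError("marker_positive_fraction_of_alpha must lie in [0, 1]")
        if self.nuclei_density < 0 or self.nucleus_radius <= 0:
            raise ValueError("nuclei_density >= 0 and nucleus_radius > 0 required")
        if self.nuclei_density > 0:
            pitch_um = math.sqrt(1000.0 / self.nuclei_density)
            if pitch_um < 2.5 * self.nucleus_radius:
                raise ValueError(
                    f"nuclei_density {self.nuclei_density}/1000um^2 is too high "
                    f"for nucleus_radius {self.nucleus_radius} um (grid pitch "
                    f"{pitch_um:.1f} um < minimum separation "
                    f"{2.5 * self.nucleus_radius:.1f} um)"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.background_level < self.signal_level:
            raise ValueError("need 0 <= background_level < signal_level")


@dataclass
class GroundTruth:
    """Noise-free truth for one generated section.

    ``masks`` holds boolean masks for alpha / beta / bihormonal / islet /
    tissue / exocrine / marker on the image grid; ``areas`` their pixel
    counts times ``pixel_size**2`` (um^2).  ``islet_labels`` labels each
    islet 1..K in placement order.  ``nuclei_centres`` maps compartment
    name to an (n, 2) float array of (row, col) nucleus centres.
    """

    masks: dict[str, np.ndarray]
    areas: dict[str, float]
    islet_labels: np.ndarray
    islet_count: int
    nuclei_centres: dict[str, np.ndarray]
    pixel_size: float

    def nuclei_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.nuclei_centres.items()}


class SectionRecord(NamedTuple):
    """One donor of a synthetic cohort."""

    section: MultiChannelSection
    truth: GroundTruth
    group: str
    donor_id: str


@dataclass(frozen=True)
class CohortParams:
    """Two-group cohort design.

    ``multipliers`` are "pregnant"-group fold changes of per-metric
    areas relative to control; compartment multipliers left unspecified
    follow the islet-area multiplier (pure size scaling preserves islet
    composition).  ``cv`` is the between-donor coefficient of variation,
    realised as one mean-preserving log-normal size factor per donor
    (marker fraction and intensity draw their own factors).
    """

    n_per_group: int = 7
    multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("effect multipliers must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass(frozen=True)
class MatrixParams:
    """Synthetic log2 protein-intensity matrix design."""

    n_proteins: int = 1000
    n_samples_per_group: int = 6
    baseline_log2_mean: float = 24.0
    baseline_log2_sd: float = 2.0
    within_sd: float = 0.3
    n_true_effects: int = 0
    effect_size: float = 2.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_samples_per_group < 2:
            raise ValueError("need >= 1 protein and >= 2 samples per group")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.n_true_effects <= self.n_proteins:
            raise ValueError("n_true_effects must lie in [0, n_proteins]")
        if self.within_sd <= 0 or self.baseline_log2_sd < 0:
            raise ValueError("within_sd > 0 and baseline_log2_sd >= 0 required")


# ---------------------------------------------------------------------------
# Section rendering
# ---------------------------------------------------------------------------

def _disc_mask(shape: tuple[int, int], centre: tuple[float, float], radius: float
               ) -> tuple[slice, slice, np.ndarray]:
    """Boolean disc on a bounding-box patch; returns (row slice, col slice, patch)."""
    r0, c0 = centre
    rmin = max(int(math.floor(r0 - radius)), 0)
    rmax = min(int(math.ceil(r0 + radius)) + 1, shape[0])
    cmin = max(int(math.floor(c0 - radius)), 0)
    cmax = min(int(math.ceil(c0 + radius)) + 1, shape[1])
    rr, cc = np.ogrid[rmin:rmax, cmin:cmax]
    patch = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return slice(rmin, rmax), slice(cmin, cmax), patch


def _place_islet_centres(
    params: SectionParams, radii_px: np.ndarray, margin: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample islet centres with centre distance >= 2 (r_i + r_j)."""
    centres: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        extent = 1.3 * r
        lo_r, hi_r = margin + extent, params.height - margin - extent
        lo_c, hi_c = margin + extent, params.width - margin - extent
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PackingError(
                f"islet of radius {r * params.pixel_size:.0f} um does not fit "
                f"on a {params.width}x{params.height} px canvas"
            )
        for _ in range(1000):
            cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            ok = all(
                math.hypot(cand[0] - cr, cand[1] - cc)
                >= 2.0 * (r + radii_px[j])
                for j, (cr, cc) in enumerate(centres)
            )
            if ok:
                centres.append(cand)
                break
        else:
            raise PackingError(
                f"could not place islet {i + 1} of {params.n_islets}: "
                "too many islets for the canvas"
            )
    return np.asarray(centres).reshape(-1, 2)


def _islet_blob(
    radius_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Lobulated blob on a local square patch: a central disc plus four
    overlapping satellite discs.  The patch centre is the blob centre."""
    size = 2 * int(math.ceil(1.45 * radius_px)) + 1
    blob = np.zeros((size, size), dtype=bool)
    centre = (size // 2, size // 2)
    rs, cs, patch = _disc_mask(blob.shape, centre, 0.8 * radius_px)
    blob[rs, cs] |= patch
    angles = rng.uniform(0, 2 * math.pi, size=4) + np.arange(4) * (math.pi / 2)
    for ang in angles:
        sat_r = 0.55 * radius_px * rng.uniform(0.85, 1.15)
        sat_c = (
            centre[0] + 0.5 * radius_px * math.sin(ang),
            centre[1] + 0.5 * radius_px * math.cos(ang),
        )
        rs, cs, patch = _disc_mask(blob.shape, sat_c, sat_r)
        blob[rs, cs] |= patch
    return blob


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items to len(weights) bins."""
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        counts[np.argsort(quota - counts)[::-1][:rem]] += 1
    return counts


def _split_territories(
    blob: np.ndarray,
    fractions: tuple[float, float, float],
    marker_fraction: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Tile a blob into a hormone-negative core plus angular cell territories.

    The innermost pixels (by boundary distance) form a compact
    hormone-negative core standing in for non-endocrine islet tissue; the
    remaining shell is split into contiguous angular sectors ordered
    ``bihormonal | alpha | bihormonal | beta`` around a random start
    angle.  The bihormonal wedges buffer alpha from beta, so the two
    single-hormone territories never touch: thresholded glucagon and
    insulin masks can then only intersect where the rendered truth is
    genuinely bihormonal.  Sector sizes follow the requested area
    fractions exactly (largest-remainder apportionment of pixels).  The
    marker region is the central ``marker_fraction`` of the alpha sector.
    """
    coords = np.argwhere(blob)
    n_px = len(coords)
    out = {
        k: np.zeros(blob.shape, dtype=bool)
        for k in ("alpha", "beta", "bihormonal", "marker")
    }
    a, b, h = fractions
    if n_px == 0 or a + b + h == 0:
        return out

    # compact hormone-negative core: innermost pixels by boundary distance
    n_keep = int(round((a + b + h) * n_px))
    if n_keep < n_px:
        edt = ndi.distance_transform_edt(blob)
        depth = edt[coords[:, 0], coords[:, 1]]
        order = np.lexsort((coords[:, 1], coords[:, 0], depth))  # deterministic ties
        coords = coords[order][:n_keep]  # keep the outer shell
    if len(coords) == 0:
        return out

    centre = coords.mean(axis=0)
    theta = np.arctan2(coords[:, 0] - centre[0], coords[:, 1] - centre[1])
    key = np.mod(theta - rng.uniform(0, 2 * math.pi), 2 * math.pi)
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0], key))]

    n_a, n_b, n_h = _apportion(len(coords), np.array([a, b, h], dtype=float))
    blocks = [
        ("bihormonal", n_h // 2),
        ("alpha", n_a),
        ("bihormonal", n_h - n_h // 2),
        ("beta", n_b),
    ]
    pos = 0
    for name, cnt in blocks:
        sel = coords[pos : pos + cnt]
        out[name][sel[:, 0], sel[:, 1]] = True
        pos += cnt

    k = int(round(marker_fraction * n_a))
    if k > 0:
        start = n_h // 2 + (n_a - k) // 2
        sel = coords[start : start + k]
        out["marker"][sel[:, 0], sel[:, 1]] = True
    return out


def _nucleus_centres(
    tissue: np.ndarray, params: SectionParams, rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid nucleus centres: target density with a hard minimum
    spacing of 2.5 nucleus radii, so rendered nuclei never touch."""
    if params.nuclei_density == 0:
        return np.empty((0, 2))
    pitch_um = math.sqrt(1000.0 / params.nuclei_density)
    min_sep_um = 2.5 * params.nucleus_radius
    if pitch_um < min_sep_um:
        raise ValueError(
            f"nuclei_density {params.nuclei_density}/1000um^2 is too high for "
            f"nucleus_radius {params.nucleus_radius} um (pitch {pitch_um:.1f} < "
            f"min separation {min_sep_um:.1f} um)"
        )
    pitch = pitch_um / params.pixel_size
    jitter = (pitch - min_sep_um / params.pixel_size) / 2.0
    rows = np.arange(pitch / 2, tissue.shape[0], pitch)
    cols = np.arange(pitch / 2, tissue.shape[1], pitch)
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
    grid = grid + rng.uniform(-jitter, jitter, size=grid.shape)
    idx = np.clip(np.rint(grid).astype(int), 0, np.array(tissue.shape) - 1)
    inside = tissue[idx[:, 0], idx[:, 1]]
    return grid[inside]


def generate_section(params: SectionParams) -> tuple[MultiChannelSection, GroundTruth]:
    """Render one synthetic section and its ground truth.

    Returns a four-channel section (``nuclei``, ``glucagon``, ``insulin``,
    ``marker``) and the matching :class:`GroundTruth`.  The same params
    and seed always produce bit-identical output.  Raises
    :class:`PackingError` when the islets cannot be placed at the required
    spacing (at least two islet radii of clearance between islets).
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    px = params.pixel_size

    margin = max(4, int(round(0.015 * min(shape))))
    tissue = np.zeros(shape, dtype=bool)
    tissue[margin:-margin, margin:-margin] = True

    lo, hi = params.islet_radius_range
    radii_px = rng.uniform(lo, hi, size=params.n_islets) / px
    centres = _place_islet_centres(params, radii_px, margin, rng)

    masks = {
        k: np.zeros(shape, dtype=bool)
        for k in ("alpha", "beta", "bihormonal", "marker")
    }
    islet_labels = np.zeros(shape, dtype=np.int32)
    fractions = (
        params.alpha_fraction,
        params.beta_fraction,
        params.bihormonal_fraction,
    )
    for k in range(params.n_islets):
        blob = _islet_blob(radii_px[k], rng)
        top = int(round(centres[k][0])) - blob.shape[0] // 2
        left = int(round(centres[k][1])) - blob.shape[1] // 2
        window = (
            slice(max(top, 0), min(top + blob.shape[0], shape[0])),
            slice(max(left, 0), min(left + blob.shape[1], shape[1])),
        )
        blob = blob[
            window[0].start - top : window[0].stop - top,
            window[1].start - left : window[1].stop - left,
        ]
        blob = blob & tissue[window]
        terr = _split_territories(
            blob,
            fractions,
            params.marker_positive_fraction_of_alpha,
            rng,
        )
        for name in masks:
            masks[name][window] |= terr[name]
        islet_px = terr["alpha"] | terr["beta"] | terr["bihormonal"]
        islet_labels[window][islet_px] = k + 1

    masks["islet"] = islet_labels > 0
    masks["tissue"] = tissue
    masks["exocrine"] = tissue & ~masks["islet"]

    nuclei_xy = _nucleus_centres(tissue, params, rng)
    nucleus_r_px = params.nucleus_radius / px
    nuclei_mask = np.zeros(shape, dtype=bool)
    if len(nuclei_xy):
        # stamp all nucleus discs at once, one candidate offset at a time
        base = np.floor(nuclei_xy).astype(int)
        reach = int(math.ceil(nucleus_r_px))
        for dr in range(-reach, reach + 2):
            for dc in range(-reach, reach + 2):
                rr, cc = base[:, 0] + dr, base[:, 1] + dc
                hit = (rr - nuclei_xy[:, 0]) ** 2 + (
                    cc - nuclei_xy[:, 1]
                ) ** 2 <= nucleus_r_px**2
                hit &= (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
                nuclei_mask[rr[hit], cc[hit]] = True

    # assign true nuclei to compartments by their (rounded) centre pixel
    centres_px = np.clip(np.rint(nuclei_xy).astype(int), 0, np.array(shape) - 1) \
        if len(nuclei_xy) else np.empty((0, 2), dtype=int)
    nuclei_centres: dict[str, np.ndarray] = {}
    taken = np.zeros(len(nuclei_xy), dtype=bool)
    for name in ("alpha", "beta", "bihormonal"):
        if len(nuclei_xy):
            sel = masks[name][centres_px[:, 0], centres_px[:, 1]] & ~taken
        else:
            sel = np.zeros(0, dtype=bool)
        nuclei_centres[name] = nuclei_xy[sel]
        taken |= sel
    nuclei_centres["exocrine"] = nuclei_xy[~taken]

    # The nuclei channel carries tissue autofluorescence above the bare
    # glass (so a projection threshold can recover the tissue footprint);
    # the quenched hormone/marker channels have a uniform background.
    bg, sig = params.background_level, params.signal_level
    autofluor = np.where(tissue, bg, 0.0).astype(np.float32)
    flat_bg = np.full(shape, bg, dtype=np.float32)
    channels = {
        "nuclei": np.where(nuclei_mask, sig, autofluor).astype(np.float32),
        "glucagon": np.where(
            masks["alpha"] | masks["bihormonal"], sig, flat_bg
        ).astype(np.float32),
        "insulin": np.where(
            masks["beta"] | masks["bihormonal"], sig, flat_bg
        ).astype(np.float32),
        "marker": np.where(
            masks["marker"], sig * params.marker_intensity_scale, flat_bg
        ).astype(np.float32),
    }
    if params.noise_sd > 0:
        # one shared low-frequency autofluorescence field plus white noise;
        # the field is synthesised on a coarse grid and upsampled (it only
        # has power at scales of ~5% of the image, so nothing is lost)
        coarse = (shape[0] // 8 + 2, shape[1] // 8 + 2)
        field = ndi.gaussian_filter(
            rng.normal(0.0, 1.0, size=coarse), sigma=0.05 * min(shape) / 8.0
        )
        field = ndi.zoom(field, 8.0, order=1)[: shape[0], : shape[1]]
        field *= 0.5 * params.noise_sd / max(field.std(), 1e-12)
        field *= tissue  # autofluorescence comes from the tissue, not glass
        for name in channels:
            noisy = (
                channels[name]
                + field
                + rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)
            )
            channels[name] = np.clip(noisy, 0.0, None).astype(np.float32)

    areas = {k: float(m.sum()) * px**2 for k, m in masks.items()}
    truth = GroundTruth(
        masks=masks,
        areas=areas,
        islet_labels=islet_labels,
        islet_count=params.n_islets,
        nuclei_centres=nuclei_centres,
        pixel_size=px,
    )
    return MultiChannelSection(channels=channels, pixel_size=px), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _donor_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-preserving log-normal factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def _donor_params(
    base: SectionParams,
    multipliers: dict[str, float],
    cv: float,
    seed: int,
    rng: np.random.Generator,
) -> SectionParams:
    # compartment folds default to the islet fold: a bare islet-area
    # multiplier scales the whole islet without changing its composition
    m_islet = multipliers.get("islet_area", 1.0)
    m = {
        **{k: m_islet for k in ("alpha_area", "beta_area", "bihormonal_area")},
        **{k: 1.0 for k in ("marker_area", "marker_intensity")},
        **multipliers,
    }
    # one log-normal size factor per donor: every area metric then has
    # between-donor coefficient of variation = cv, not a compounded one
    size_factor = _donor_factor(rng, cv)
    radius_scale = math.sqrt(m_islet * size_factor)
    # compartment shares move by their area fold relative to the islet fold
    a = base.alpha_fraction * m["alpha_area"] / m_islet
    b = base.beta_fraction * m["beta_area"] / m_islet
    h = base.bihormonal_fraction * m["bihormonal_area"] / m_islet
    total = a + b + h
    if total > 0.98:
        a, b, h = (f * 0.98 / total for f in (a, b, h))
    marker_frac = min(
        0.95,
        base.marker_positive_fraction_of_alpha
        * m["marker_area"]
        * _donor_factor(rng, cv),
    )
    marker_scale = base.marker_intensity_scale * m["marker_intensity"] * _donor_factor(
        rng, cv
    )
    lo, hi = base.islet_radius_range
    return SectionParams(
        width=base.width,
        height=base.height,
        pixel_size=base.pixel_size,
        n_islets=base.n_islets,
        islet_radius_range=(lo * radius_scale, hi * radius_scale),
        alpha_fraction=a,
        beta_fraction=b,
        bihormonal_fraction=h,
        nuclei_density=base.nuclei_density,
        nucleus_radius=base.nucleus_radius,
        marker_positive_fraction_of_alpha=marker_frac,
        signal_level=base.signal_level,
        background_level=base.background_level,
        marker_intensity_scale=marker_scale,
        noise_sd=base.noise_sd,
        seed=seed,
    )


def generate_cohort(
    cohort: CohortParams, base: SectionParams | None = None
) -> list[SectionRecord]:
    """Generate a two-group cohort of synthetic sections.

    Control donors use ``base`` (default :class:`SectionParams`); pregnant
    donors use base parameters scaled by the cohort multipliers.  Each
    donor has its own RNG stream derived from ``(cohort seed, group,
    donor index)``, so individual donors are reproducible in isolation.
    """
    base = base or SectionParams()
    records: list[SectionRecord] = []
    for g_idx, group in enumerate(("control", "pregnant")):
        multipliers = (
            {k: 1.0 for k in DEFAULT_MULTIPLIERS}
            if group == "control"
            else cohort.multipliers
        )
        for d_idx in range(cohort.n_per_group):
            ss = np.random.SeedSequence([cohort.seed, g_idx, d_idx])
            donor_rng = np.random.default_rng(ss)
            section_seed = int(ss.generate_state(1)[0] % (2**31))
            params = _donor_params(
                base, multipliers, cohort.cv, section_seed, donor_rng
            )
            section, truth = generate_section(params)
            records.append(
                SectionRecord(section, truth, group, f"{group}_{d_idx + 1}")
            )
    return records


# ---------------------------------------------------------------------------
# Protein matrices
# ---------------------------------------------------------------------------

def generate_protein_matrix(
    params: MatrixParams,
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Log2 protein matrix with spiked effects and random missingness.

    Returns the :class:`ProteinMatrix` (groups ``pregnant_islet`` vs
    ``control_islet``) and a truth table with one row per protein
    (``spiked`` flag and the true log2 effect, positive in the pregnant
    group).  The first ``n_true_effects`` proteins are the spiked ones.
    """
    rng = np.random.default_rng(params.seed)
    n, k = params.n_proteins, params.n_samples_per_group
    proteins = [f"P{i + 1:05d}" for i in range(n)]
    samples = [f"preg_{j + 1}" for j in range(k)] + [f"ctrl_{j + 1}" for j in range(k)]
    groups = pd.Series(
        ["pregnant_islet"] * k + ["control_islet"] * k, index=samples
    )
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n)
    values = baseline[:, None] + rng.normal(0.0, params.within_sd, size=(n, 2 * k))
    spiked = np.zeros(n, dtype=bool)
    spiked[: params.n_true_effects] = True
    values[spiked, :k] += params.effect_size
    if params.missing_rate > 0:
        values = np.where(
            rng.random(values.shape) < params.missing_rate, np.nan, values
        )
    data = pd.DataFrame(values, index=proteins, columns=samples)
    truth = pd.DataFrame(
        {
            "spiked": spiked,
            "log2_effect": np.where(spiked, params.effect_size, 0.0),
        },
        index=proteins,
    )
    return ProteinMatrix(data=data, groups=groups), truth
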