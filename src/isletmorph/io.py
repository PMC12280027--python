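"""File formats, run configuration, and pipeline orchestration.

Sections travel as multi-page TIFF (one page per channel) with a JSON
sidecar carrying the channel names and the pixel calibration; masks are
written as 16-bit label TIFF; tables as UTF-8 CSV with unit-suffixed
column names; configuration as YAML.  ``run_full_pipeline`` chains
segmentation, nucleus counting, morphometry, and group statistics over a
cohort of sections and emits a JSON run report recording every parameter
and threshold actually applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .group_stats import cohort_report
from .morphometry import section_metrics
from .nuclei import assign_nuclei, filter_nuclei, segment_nuclei
from .segmentation import CompartmentSet, MultiChannelSection, segment_section

__all__ = [
    "RunConfig",
    "read_section",
    "write_section",
    "write_mask",
    "analyze_section",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_METRICS = [
    "islet_fractional_area_pct",
    "alpha_fractional_area_pct",
    "beta_fractional_area_pct",
    "bihormonal_fractional_area_pct",
    "islet_mean_area_per_islet_um2",
    "alpha_mean_area_per_islet_um2",
    "beta_mean_area_per_islet_um2",
    "bihormonal_mean_area_per_islet_um2",
    "alpha_proportion_of_islet_pct",
    "beta_proportion_of_islet_pct",
    "bihormonal_proportion_of_islet_pct",
    "islet_density_per_mm2",
    "islet_diameter_mean_um",
    "alpha_positive_islet_fraction_pct",
    "estimated_cell_size_alpha_um2",
    "estimated_cell_size_beta_um2",
    "normalized_nuclei_count_alpha_pct",
    "normalized_nuclei_count_beta_pct",
]


@dataclass
class RunConfig:
    """All tunable parameters of a morphometry run.

    Round-trips losslessly through YAML (``to_yaml`` / ``from_yaml``).
    ``pixel_size`` must be supplied for real images (there is no safe
    universal default for slide scanners; 0.65 um/px is typical of a 10x
    scan and is the shipped reference value).
    """

    pixel_size: float = 0.65  # um per pixel
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"nuclei": 0, "glucagon": 1, "insulin": 2}
    )
    threshold_method: str = "otsu"
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    closing_radius: int = 2  # px
    mean_radius: int = 1  # px
    min_islet_area: float = 1000.0  # um^2
    nucleus_max_diameter: float = 10.0  # um
    fractional_area_mode: str = "tissue"  # or "exocrine"
    stats_policy: str = "auto"
    s0: float = 0.01
    n_permutations: int = 250
    fdr_threshold: float = 0.05
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Section I/O
# ---------------------------------------------------------------------------

def write_section(section: MultiChannelSection, path: str | Path) -> Path:
    """Write a section as multi-page TIFF plus a JSON sidecar.

    The sidecar (``<path>.json``) records channel order and pixel size; it
    is what :func:`read_section` uses to reconstruct the channel map.
    """
    path = Path(path)
    names = list(section.channels)
    stack = np.stack([section.channels[n] for n in names])
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    sidecar = {
        "channels": {name: i for i, name in enumerate(names)},
        "pixel_size_um": section.pixel_size,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_section(
    path: str | Path,
    sidecar: str | Path | None = None,
    channel_map: dict[str, int] | None = None,
    pixel_size: float | None = None,
) -> MultiChannelSection:
    """Read a TIFF stack into a :class:`MultiChannelSection`.

    The channel map and pixel size come from the JSON sidecar (written by
    :func:`write_section`, or hand-authored) or from the explicit
    arguments, which take precedence.  A missing pixel size is a hard
    error: areas in um^2 cannot be derived without a calibration.
    """
    path = Path(path)
    if sidecar is None:
        candidate = path.with_suffix(path.suffix + ".json")
        sidecar = candidate if candidate.exists() else None
    meta = json.loads(Path(sidecar).read_text()) if sidecar else {}
    channel_map = channel_map or meta.get("channels")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if channel_map is None:
        raise ValueError("no channel map: supply a sidecar or channel_map")
    if pixel_size is None:
        raise ValueError(
            "no pixel size: supply pixel_size or a sidecar with pixel_size_um"
        )
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    n_pages = stack.shape[0]
    bad = {name: idx for name, idx in channel_map.items() if not 0 <= idx < n_pages}
    if bad:
        raise ValueError(
            f"channel map refers to pages {bad} but the file has {n_pages} page(s)"
        )
    channels = {name: stack[idx] for name, idx in channel_map.items()}
    return MultiChannelSection(channels=channels, pixel_size=float(pixel_size))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary or label mask as 16-bit TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint16)
    elif arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    else:
        arr = arr.astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def analyze_section(
    section: MultiChannelSection,
    config: RunConfig | None = None,
    include_nuclei: bool = True,
) -> tuple[dict[str, float], CompartmentSet]:
    """Segment one section and compute its metrics.

    Returns ``(metrics, compartments)``.  Nucleus counting can be skipped
    (``include_nuclei=False``) when only area metrics are needed, e.g. in
    large simulation studies.  Marker metrics are computed whenever the
    section has a ``marker`` channel.
    """
    config = config or RunConfig()
    compartments = segment_section(
        section,
        closing_radius=config.closing_radius,
        mean_radius=config.mean_radius,
        threshold_method=config.threshold_method,
        fixed_thresholds=config.fixed_thresholds,
        min_islet_area=config.min_islet_area,
    )
    nuclei = None
    if include_nuclei and "nuclei" in section.channels:
        nuclei = segment_nuclei(section.channel("nuclei"), section.pixel_size)
        nuclei = filter_nuclei(nuclei, config.nucleus_max_diameter)
        nuclei = assign_nuclei(nuclei, compartments)
    marker = section.channels.get("marker")
    metrics = section_metrics(
        compartments,
        nuclei=nuclei,
        marker_raster=marker,
        fractional_mode=config.fractional_area_mode,
    )
    metrics.update({f"threshold_{k}": v for k, v in compartments.thresholds.items()})
    return metrics, compartments


def run_full_pipeline(
    sections: list[tuple[MultiChannelSection, str, str]],
    config: RunConfig | None = None,
    metrics: list[str] | None = None,
    output_dir: str | Path | None = None,
    include_nuclei: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the whole morphometry pipeline over a cohort.

    ``sections`` is a list of ``(section, group_label, donor_id)``.
    Returns ``(metrics_table, comparisons, report)``; when ``output_dir``
    is given, also writes ``metrics.csv``, ``comparisons.csv`` and
    ``report.json`` there.  Any stage failure is re-raised annotated with
    the stage and donor id.
    """
    config = config or RunConfig()
    wanted = metrics if metrics is not None else DEFAULT_METRICS
    rows = []
    thresholds_applied: dict[str, dict[str, float]] = {}
    for section, group, donor_id in sections:
        try:
            m, comps = analyze_section(section, config, include_nuclei=include_nuclei)
        except Exception as exc:  # annotate, do not swallow
            raise RuntimeError(
                f"pipeline stage 'analyze_section' failed for donor "
                f"{donor_id!r}: {exc}"
            ) from exc
        thresholds_applied[donor_id] = comps.thresholds
        logger.info("donor %s thresholds: %s", donor_id, comps.thresholds)
        rows.append({"donor_id": donor_id, "group": group, **m})
    table = pd.DataFrame(rows)

    present = [m for m in wanted if m in table.columns]
    groups = sorted(table["group"].unique())
    comparisons = pd.DataFrame()
    per_group_n = table["group"].value_counts()
    if len(groups) == 2 and per_group_n.min() >= 2:
        usable = [m for m in present if table[m].notna().groupby(table["group"]).sum().min() >= 2]
        comparisons = cohort_report(
            table, usable, group_col="group",
            groups=(groups[1], groups[0]) if "pregnant" in groups else tuple(groups),
            policy=config.stats_policy,
        )
    report = {
        "version": __version__,
        "config": asdict(config),
        "n_sections": len(sections),
        "groups": {g: int(n) for g, n in per_group_n.items()},
        "thresholds": thresholds_applied,
        "metrics": present,
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        if not comparisons.empty:
            comparisons.to_csv(out / "comparisons.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return table, comparisons, report
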