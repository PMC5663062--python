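"""Cultivar pattern library: bundled references, band discovery, pattern map.

Ships the 26-cultivar chrysanthemum reference library (characteristic peak
positions and max-normalized intensities per cultivar) and the compound
reference-band table used for tentative assignment, both as versioned JSON
data files. Provides cross-cultivar common-band discovery (contiguous runs
of pooled peak positions, e.g. the universal 731-734 cm^-1 band shared by
all 26 cultivars) and the color-block pattern map in which each cultivar is
one row and normalized intensity sweeps the hue from violet (near 0) to red
(1).
"""

from __future__ import annotations

import colorsys
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import (
    AssignmentEntry,
    AssignmentTable,
    PeakPattern,
    SpectralLibrary,
    ValidationError,
    load_library,
)

__all__ = [
    "BandCluster",
    "build_library",
    "find_common_bands",
    "render_pattern_map",
    "reference_library",
    "reference_assignments",
    "pattern_hue",
    "pattern_rgb",
]

_DATA = importlib.resources.files(__package__) / "data"

VIOLET_HUE_DEG = 270.0  # hue sweeps 270 (violet) -> 0 (red) as value goes 0 -> 1


@dataclass
class BandCluster:
    """A contiguous run of peak positions pooled across cultivars."""

    lower: float
    upper: float
    members: dict[str, float]  # cultivar -> position (at most one per cultivar)
    support: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError(f"cluster bounds out of order: {self.lower}, {self.upper}")
        if self.support < 1:
            raise ValidationError("cluster support must be at least 1")


def reference_library() -> SpectralLibrary:
    """The bundled 26-cultivar peak-pattern library."""
    with importlib.resources.as_file(_DATA / "chrysanthemum_library.json") as path:
        return load_library(path)


def reference_assignments() -> AssignmentTable:
    """The bundled compound reference-band table (3 cm^-1 point tolerance)."""
    doc = json.loads((_DATA / "band_assignments.json").read_text())
    entries = [
        AssignmentEntry(
            compound=rec["compound"],
            compound_class=rec["compound_class"],
            reference=tuple(rec["reference"]) if isinstance(rec["reference"], list)
            else rec["reference"],
            vibration=rec.get("vibration", ""),
        )
        for rec in doc["entries"]
    ]
    return AssignmentTable(entries=entries, tolerance=doc.get("tolerance", 3.0))


def build_library(patterns: Sequence[PeakPattern], name: str) -> SpectralLibrary:
    """Collect validated patterns into a named library."""
    mapping: dict[str, PeakPattern] = {}
    for pattern in patterns:
        if pattern.cultivar in mapping:
            raise ValidationError(f"duplicate cultivar name: {pattern.cultivar!r}")
        mapping[pattern.cultivar] = pattern
    return SpectralLibrary(name=name, patterns=mapping)


def find_common_bands(
    library: SpectralLibrary, gap_threshold: float = 8.0
) -> list[BandCluster]:
    """Partition the pooled peak positions into contiguous bands.

    All peak positions of all cultivars are pooled and sorted; a new cluster
    starts wherever consecutive positions differ by more than
    ``gap_threshold`` cm^-1. Support counts distinct cultivars; a cultivar
    with several peaks in one run contributes its first.
    """
    if len(library) == 0:
        raise ValidationError("cannot cluster an empty library")
    pooled = sorted(
        (peak.position, pattern.cultivar)
        for pattern in library
        for peak in pattern.peaks
    )
    clusters: list[BandCluster] = []
    run: list[tuple[float, str]] = []

    def close_run() -> None:
        members: dict[str, float] = {}
        for pos, cultivar in run:
            members.setdefault(cultivar, pos)
        clusters.append(
            BandCluster(
                lower=run[0][0],
                upper=run[-1][0],
                members=members,
                support=len(members),
            )
        )

    for item in pooled:
        if run and item[0] - run[-1][0] > gap_threshold:
            close_run()
            run = []
        run.append(item)
    if run:
        close_run()
    return clusters


def pattern_hue(value: float) -> float:
    """Hue angle in degrees for a normalized intensity: 270 (violet) down to 0 (red)."""
    if not 0 <= value <= 1:
        raise ValidationError(f"normalized intensity must lie in [0, 1], got {value}")
    return VIOLET_HUE_DEG * (1.0 - value)


def pattern_rgb(value: float) -> tuple[float, float, float]:
    """RGB color (full saturation and value) encoding a normalized intensity."""
    return colorsys.hsv_to_rgb(pattern_hue(value) / 360.0, 1.0, 1.0)


def pattern_map_image(
    library: SpectralLibrary, block_halfwidth: float = 2.0
) -> tuple[np.ndarray, list[str]]:
    """RGBA raster of the pattern map: one row per cultivar, 400-1800 cm^-1.

    Returns the (rows, 1401, 4) image array and the row labels (library
    order). The background is neutral light gray; each peak is a colored
    block of ``2*block_halfwidth + 1`` cm^-1.
    """
    cultivars = [p.cultivar for p in library]
    grid = np.arange(400, 1801)
    image = np.full((len(cultivars), len(grid), 4), (0.93, 0.93, 0.93, 1.0))
    for row, pattern in enumerate(library):
        for peak in pattern.peaks:
            lo = np.searchsorted(grid, peak.position - block_halfwidth, side="left")
            hi = np.searchsorted(grid, peak.position + block_halfwidth, side="right")
            image[row, lo:hi, :3] = pattern_rgb(peak.normalized_intensity)
    return image, cultivars


def render_pattern_map(library: SpectralLibrary, output: str | Path) -> Path:
    """Render the color-block pattern map to an image file (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colors as mcolors

    if len(library) == 0:
        raise ValidationError("cannot render an empty library")
    image, cultivars = pattern_map_image(library)
    fig, (ax, cax) = plt.subplots(
        1, 2, figsize=(10, 0.32 * len(cultivars) + 1.2),
        gridspec_kw={"width_ratios": [40, 1]},
    )
    ax.imshow(image, aspect="auto", interpolation="nearest",
              extent=(400, 1800, len(cultivars) - 0.5, -0.5))
    ax.set_yticks(range(len(cultivars)), cultivars, fontsize=7)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_title(library.name or "Characteristic peak distribution patterns")
    ramp = mcolors.ListedColormap([pattern_rgb(v) for v in np.linspace(0, 1, 256)])
    fig.colorbar(
        plt.cm.ScalarMappable(norm=mcolors.Normalize(0, 1), cmap=ramp),
        cax=cax, label="normalized intensity",
    )
    fig.tight_layout()
    output = Path(output)
    fig.savefig(output, dpi=150)
    plt.close(fig)
    return output
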