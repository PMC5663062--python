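"""Core domain types and file I/O for SERS peak-pattern chemotaxonomy.

The unit of processing is a :class:`RamanSpectrum`: intensities in arbitrary
units (a.u.) on a fixed wavenumber grid, by default 400-1800 cm^-1 at 1 cm^-1
(the scan range and resolution of the measurements the pipeline models).
Spectra travel through the pipeline in 6-replicate :class:`ReplicateSet`
bundles, are reduced to :class:`PeakPattern` fingerprints (position +
max-normalized intensity per characteristic peak), and the patterns of all
cultivars are collected in a :class:`SpectralLibrary`.

File formats are deliberately plain: two-column text for spectra (with ``#``
comment headers carrying metadata) and versioned JSON for libraries, plus a
flat CSV export for spreadsheets.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "WavenumberGrid",
    "RamanSpectrum",
    "ReplicateSet",
    "Peak",
    "PeakPattern",
    "SpectralLibrary",
    "AssignmentEntry",
    "AssignmentTable",
    "ValidationError",
    "SpectrumParseError",
    "CoverageError",
    "read_spectrum",
    "write_spectrum",
    "save_library",
    "load_library",
    "export_library_csv",
    "DEFAULT_GRID",
]

LIBRARY_SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """A domain invariant was violated."""


class SpectrumParseError(ValueError):
    """A spectrum file contained a malformed row."""


class CoverageError(ValueError):
    """A spectrum file does not cover the requested wavenumber grid."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform Raman-shift axis, in cm^-1."""

    start: float = 400.0
    stop: float = 1800.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValidationError(f"grid start must be < stop, got [{self.start}, {self.stop}]")
        if not self.step > 0:
            raise ValidationError(f"grid step must be positive, got {self.step}")

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self))

    def scaled(self) -> np.ndarray:
        """Axis rescaled to [-1, 1], the domain used for polynomial fits."""
        x = self.wavenumbers
        return 2.0 * (x - self.start) / (self.stop - self.start) - 1.0


DEFAULT_GRID = WavenumberGrid()


@dataclass
class RamanSpectrum:
    """Intensities (a.u.) on a :class:`WavenumberGrid`.

    ``metadata`` records provenance only (e.g. excitation_nm=785, power_mW=3.3);
    no computation depends on it.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    label: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) != len(self.grid):
            raise ValidationError(
                f"expected {len(self.grid)} intensity values, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.wavenumbers

    def with_intensities(self, values: np.ndarray, label: str | None = None) -> "RamanSpectrum":
        return RamanSpectrum(
            grid=self.grid,
            intensities=values,
            label=self.label if label is None else label,
            metadata=dict(self.metadata),
        )


@dataclass
class ReplicateSet:
    """Parallel spectra of one sample, measured at different spots (default 6)."""

    sample_name: str
    spectra: Sequence[RamanSpectrum]

    def __post_init__(self) -> None:
        if len(self.spectra) < 1:
            raise ValidationError("replicate set needs at least one spectrum")
        grid = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid != grid:
                raise ValidationError("all replicates must share one wavenumber grid")

    @property
    def grid(self) -> WavenumberGrid:
        return self.spectra[0].grid

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[RamanSpectrum]:
        return iter(self.spectra)


@dataclass
class Peak:
    """One characteristic peak.

    ``height`` is the baseline-corrected apex intensity, ``width`` the full
    width at half maximum. Library records transcribed from published tables
    carry only position and normalized intensity; height and width are
    populated for peaks this pipeline detects itself.
    """

    position: float
    normalized_intensity: float | None = None
    height: float | None = None
    width: float | None = None

    def __post_init__(self) -> None:
        if self.height is not None and not self.height > 0:
            raise ValidationError(f"peak height must be positive, got {self.height}")
        if self.width is not None and not self.width > 0:
            raise ValidationError(f"peak width must be positive, got {self.width}")
        if self.normalized_intensity is not None and not 0 < self.normalized_intensity <= 1:
            raise ValidationError(
                f"normalized intensity must lie in (0, 1], got {self.normalized_intensity}"
            )


@dataclass
class PeakPattern:
    """A cultivar's characteristic-peak distribution pattern."""

    cultivar: str
    peaks: Sequence[Peak]

    def __post_init__(self) -> None:
        self.peaks = list(self.peaks)
        positions = [p.position for p in self.peaks]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError(f"{self.cultivar}: peak positions must be strictly increasing")
        if self.peaks:
            values = [p.normalized_intensity for p in self.peaks]
            if any(v is None for v in values):
                raise ValidationError(f"{self.cultivar}: pattern peaks need normalized intensities")
            if not math.isclose(max(values), 1.0, rel_tol=0, abs_tol=1e-12):
                raise ValidationError(
                    f"{self.cultivar}: max normalized intensity must be 1, got {max(values)}"
                )

    @property
    def positions(self) -> list[float]:
        return [p.position for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.normalized_intensity for p in self.peaks]

    def strongest_position(self) -> float:
        """Position of the peak with normalized intensity 1."""
        if not self.peaks:
            raise ValidationError(f"{self.cultivar}: empty pattern has no strongest peak")
        return max(self.peaks, key=lambda p: p.normalized_intensity).position

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SpectralLibrary:
    """Named collection of cultivar peak patterns."""

    name: str
    patterns: Mapping[str, PeakPattern]
    created: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        self.patterns = dict(self.patterns)
        for cultivar, pattern in self.patterns.items():
            if not cultivar:
                raise ValidationError("cultivar names must be non-empty")
            if pattern.cultivar != cultivar:
                raise ValidationError(
                    f"pattern labelled {pattern.cultivar!r} filed under {cultivar!r}"
                )
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[PeakPattern]:
        return iter(self.patterns.values())

    def __getitem__(self, cultivar: str) -> PeakPattern:
        return self.patterns[cultivar]


@dataclass
class AssignmentEntry:
    """One compound reference band with its vibration-mode label.

    ``reference`` is either a single position or an inclusive (lower, upper)
    interval, in cm^-1.
    """

    compound: str
    compound_class: str
    reference: float | tuple[float, float]
    vibration: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.reference, (list, tuple)):
            lo, hi = self.reference
            if lo > hi:
                raise ValidationError(f"{self.compound}: interval bounds out of order ({lo}, {hi})")
            self.reference = (float(lo), float(hi))
            bounds = self.reference
        else:
            self.reference = float(self.reference)
            bounds = (self.reference, self.reference)
        if not (100 <= bounds[0] and bounds[1] <= 4000):
            raise ValidationError(f"{self.compound}: reference outside 100-4000 cm^-1")

    @property
    def is_interval(self) -> bool:
        return isinstance(self.reference, tuple)


@dataclass
class AssignmentTable:
    """Compound reference bands used for tentative peak assignment.

    ``tolerance`` is the half-window (cm^-1) applied around point references;
    interval references match by containment only.
    """

    entries: Sequence[AssignmentEntry]
    tolerance: float = 3.0

    def __post_init__(self) -> None:
        self.entries = list(self.entries)
        if self.tolerance < 0:
            raise ValidationError(f"tolerance must be non-negative, got {self.tolerance}")


# ---------------------------------------------------------------------------
# spectrum I/O


def read_spectrum(
    path: str | Path,
    *,
    grid: WavenumberGrid = DEFAULT_GRID,
    label: str = "",
) -> RamanSpectrum:
    """Read a two-column (wavenumber, intensity) text file.

    Whitespace- and comma-delimited files are both accepted; lines starting
    with ``#`` are comments (``# key: value`` lines are collected as
    metadata). If the file's axis differs from ``grid`` the intensities are
    linearly interpolated onto it; the native axis bounds are preserved in
    metadata.
    """
    path = Path(path)
    wavenumbers: list[float] = []
    values: list[float] = []
    metadata: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = val.strip()
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {len(fields)}: {line!r}"
                )
            try:
                wavenumbers.append(float(fields[0]))
                values.append(float(fields[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if not wavenumbers:
        raise SpectrumParseError(f"{path}: no data rows")

    wn = np.asarray(wavenumbers)
    iv = np.asarray(values)
    order = np.argsort(wn)
    wn, iv = wn[order], iv[order]
    if wn[0] > grid.start or wn[-1] < grid.stop:
        raise CoverageError(
            f"{path}: data cover {wn[0]:g}-{wn[-1]:g} cm^-1 but grid needs "
            f"{grid.start:g}-{grid.stop:g} cm^-1"
        )
    target = grid.wavenumbers
    if len(wn) == len(target) and np.allclose(wn, target, atol=1e-9):
        resampled = iv
    else:
        resampled = np.interp(target, wn, iv)
        metadata.setdefault("native_axis", f"{wn[0]:g}..{wn[-1]:g} ({len(wn)} points)")
    return RamanSpectrum(grid=grid, intensities=resampled,
                         label=label or metadata.get("label", path.stem), metadata=metadata)


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column text with ``#`` metadata headers."""
    path = Path(path)
    lines = []
    if spectrum.label:
        lines.append(f"# label: {spectrum.label}")
    for key, val in spectrum.metadata.items():
        lines.append(f"# {key}: {val}")
    for wn, value in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{wn:.6g} {value:.8g}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# library I/O


def _pattern_to_json(pattern: PeakPattern) -> dict:
    peaks = []
    for p in pattern.peaks:
        rec: dict[str, float] = {
            "position": p.position,
            "normalized_intensity": p.normalized_intensity,
        }
        if p.height is not None:
            rec["height"] = p.height
        if p.width is not None:
            rec["width"] = p.width
        peaks.append(rec)
    return {"cultivar": pattern.cultivar, "peaks": peaks}


def _pattern_from_json(rec: dict) -> PeakPattern:
    peaks = [
        Peak(
            position=p["position"],
            normalized_intensity=p["normalized_intensity"],
            height=p.get("height"),
            width=p.get("width"),
        )
        for p in rec["peaks"]
    ]
    return PeakPattern(cultivar=rec["cultivar"], peaks=peaks)


def save_library(library: SpectralLibrary, path: str | Path) -> Path:
    """Write a library as versioned JSON (see :func:`load_library`)."""
    path = Path(path)
    doc = {
        "schema_version": LIBRARY_SCHEMA_VERSION,
        "name": library.name,
        "created": library.created,
        "notes": library.notes,
        "patterns": [_pattern_to_json(p) for p in library],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")
    return path


def load_library(path: str | Path) -> SpectralLibrary:
    """Load a library JSON file, validating names and intensities."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != LIBRARY_SCHEMA_VERSION:
        raise ValidationError(f"unsupported library schema version: {version!r}")
    patterns: dict[str, PeakPattern] = {}
    for rec in doc["patterns"]:
        pattern = _pattern_from_json(rec)
        if pattern.cultivar in patterns:
            raise ValidationError(f"duplicate cultivar name: {pattern.cultivar!r}")
        patterns[pattern.cultivar] = pattern
    return SpectralLibrary(
        name=doc.get("name", ""),
        patterns=patterns,
        created=doc.get("created", ""),
        notes=doc.get("notes", ""),
    )


def export_library_csv(library: SpectralLibrary, path: str | Path) -> Path:
    """Flat CSV export: one row per peak (cultivar, position, normalized_intensity)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cultivar", "position", "normalized_intensity"])
        for pattern in library:
            for peak in pattern.peaks:
                writer.writerow([pattern.cultivar, peak.position, peak.normalized_intensity])
    return path
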