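"""Synthetic SERS spectrum generator.

Emulates what a baseline-uncorrected instrument trace looks like for a known
cultivar: sharp peaks (Gaussian or Lorentzian) at the pattern's positions,
scaled so normalized intensity 1 maps to ``base_amplitude`` a.u., riding on a
smooth fifth-order polynomial fluorescence background, plus additive Gaussian
noise. Replicates model spot-to-spot focusing differences as a single
multiplicative amplitude jitter per replicate, the way parallel measurements
of one homogenate differ mainly in overall signal level.

All randomness is drawn from a generator seeded by (seed, replicate_index),
so a replicate set is bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import (
    DEFAULT_GRID,
    PeakPattern,
    RamanSpectrum,
    ReplicateSet,
    ValidationError,
    WavenumberGrid,
)

__all__ = [
    "SyntheticConfig",
    "generate_background",
    "generate_spectrum",
    "generate_replicate_set",
]

BACKGROUND_ORDER = 5  # the polynomial degree the baseline correction assumes


@dataclass
class SyntheticConfig:
    """Generator settings.

    base_amplitude : a.u. assigned to normalized intensity 1 (default 4000,
        comfortably above the 400 a.u. characteristic-peak height filter).
    peak_fwhm : full width at half maximum of every generated peak, cm^-1.
        Must stay under the 100 cm^-1 width filter.
    background_coefficients : 6 coefficients of a fifth-order polynomial,
        evaluated on the wavenumber axis rescaled to [-1, 1].
    noise_sd : additive Gaussian noise, a.u.
    replicate_jitter : s.d. of the fractional amplitude variation applied to
        each replicate's peak sum.
    """

    peak_shape: str = "gaussian"
    base_amplitude: float = 4000.0
    peak_fwhm: float = 12.0
    background_coefficients: Sequence[float] = (0.0,) * (BACKGROUND_ORDER + 1)
    noise_sd: float = 20.0
    replicate_count: int = 6
    replicate_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_shape not in ("gaussian", "lorentzian"):
            raise ValidationError(f"unknown peak shape: {self.peak_shape!r}")
        if not self.base_amplitude > 400:
            raise ValidationError("base_amplitude must exceed the 400 a.u. peak-height filter")
        if not 0 < self.peak_fwhm < 100:
            raise ValidationError("peak_fwhm must lie in (0, 100) cm^-1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be at least 1")
        self.background_coefficients = tuple(float(c) for c in self.background_coefficients)
        if len(self.background_coefficients) != BACKGROUND_ORDER + 1:
            raise ValidationError(
                f"need {BACKGROUND_ORDER + 1} background coefficients, "
                f"got {len(self.background_coefficients)}"
            )

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load settings from a JSON file; omitted fields keep their defaults."""
        import json
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)


def generate_background(
    grid: WavenumberGrid, coefficients: Sequence[float]
) -> RamanSpectrum:
    """Fifth-order polynomial fluorescence background, clipped at zero.

    Coefficients are in ascending order (c0 + c1*x + ... + c5*x^5) on the
    wavenumber axis rescaled to [-1, 1] over the grid.
    """
    coefficients = tuple(float(c) for c in coefficients)
    if len(coefficients) != BACKGROUND_ORDER + 1:
        raise ValidationError(
            f"need {BACKGROUND_ORDER + 1} coefficients, got {len(coefficients)}"
        )
    x = grid.scaled()
    values = np.polynomial.polynomial.polyval(x, coefficients)
    return RamanSpectrum(grid=grid, intensities=np.clip(values, 0.0, None),
                         label="background")


def _lineshape(x: np.ndarray, center: float, fwhm: float, kind: str) -> np.ndarray:
    """Unit-apex peak profile."""
    if kind == "gaussian":
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((x - center) / sigma) ** 2)
    half = fwhm / 2.0
    return half**2 / ((x - center) ** 2 + half**2)


def peak_sum(
    pattern: PeakPattern, grid: WavenumberGrid, amplitude: float,
    fwhm: float, shape: str = "gaussian",
) -> np.ndarray:
    """Noise-free analytic sum of the pattern's peaks (the generator's signal term)."""
    x = grid.wavenumbers
    total = np.zeros(len(grid))
    for peak in pattern.peaks:
        total += peak.normalized_intensity * amplitude * _lineshape(
            x, peak.position, fwhm, shape
        )
    return total


def generate_spectrum(
    pattern: PeakPattern,
    config: SyntheticConfig,
    replicate_index: int = 0,
    grid: WavenumberGrid = DEFAULT_GRID,
) -> RamanSpectrum:
    """One synthetic replicate: background + jittered peak sum + noise."""
    if not pattern.peaks:
        raise ValidationError(
            "pattern has no peaks; use generate_background for a peak-free trace"
        )
    rng = np.random.default_rng([config.seed, replicate_index])
    jitter = rng.normal(0.0, config.replicate_jitter) if config.replicate_jitter > 0 else 0.0
    signal = peak_sum(pattern, grid, config.base_amplitude, config.peak_fwhm,
                      config.peak_shape) * (1.0 + jitter)
    background = generate_background(grid, config.background_coefficients).intensities
    noise = rng.normal(0.0, config.noise_sd, len(grid)) if config.noise_sd > 0 else 0.0
    return RamanSpectrum(
        grid=grid,
        intensities=background + signal + noise,
        label=f"{pattern.cultivar} [replicate {replicate_index}]",
        metadata={
            "cultivar": pattern.cultivar,
            "replicate": str(replicate_index),
            "seed": str(config.seed),
            "synthetic": "true",
        },
    )


def generate_replicate_set(
    pattern: PeakPattern,
    config: SyntheticConfig,
    grid: WavenumberGrid = DEFAULT_GRID,
) -> ReplicateSet:
    """``replicate_count`` parallel synthetic spectra of one cultivar."""
    spectra = [
        generate_spectrum(pattern, config, replicate_index=i, grid=grid)
        for i in range(config.replicate_count)
    ]
    return ReplicateSet(sample_name=pattern.cultivar, spectra=spectra)
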