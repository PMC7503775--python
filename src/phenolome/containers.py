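"""Core in-memory containers shared across the pipeline.

A :class:`Chromatogram` is a single UV trace (intensity vs. retention
time) for one sample at one detection wavelength; a
:class:`ChromatogramSet` bundles the traces of a whole experiment with
its design table.  Peak locations are represented as half-open,
0-based index intervals on the (aligned) retention-time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "ChromatogramSet",
    "PeakInterval",
    "CommonPeak",
]


@dataclass
class Chromatogram:
    """One sample's intensity trace on a retention-time grid.

    Parameters
    ----------
    rt : ndarray
        Retention times in minutes, strictly increasing.
    intensity : ndarray
        Detector response in absorbance units (AU), same length as ``rt``.
    wavelength : int
        Detection wavelength in nm (280 or 330 in the reference design).
    sample_id : str
        Unique sample token, matching the design table.
    sample_mass : float
        Extracted leaf sample mass in mg; must be positive.
    """

    rt: np.ndarray
    intensity: np.ndarray
    wavelength: int
    sample_id: str
    sample_mass: float

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("rt and intensity must be 1-D")
        if self.rt.shape != self.intensity.shape:
            raise ValueError(
                f"rt and intensity lengths differ "
                f"({self.rt.size} vs {self.intensity.size})"
            )
        if self.rt.size >= 2 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")
        if not (self.sample_mass > 0):
            raise ValueError(f"sample_mass must be > 0, got {self.sample_mass}")

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        """Return a copy carrying a new intensity vector."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    @property
    def n_points(self) -> int:
        return self.rt.size

    @property
    def grid_step(self) -> float:
        return float(self.rt[1] - self.rt[0])


@dataclass
class ChromatogramSet:
    """All chromatograms of an experiment plus the design table."""

    chromatograms: list[Chromatogram]
    design: pd.DataFrame

    def __iter__(self) -> Iterator[Chromatogram]:
        return iter(self.chromatograms)

    def __len__(self) -> int:
        return len(self.chromatograms)

    @property
    def wavelengths(self) -> list[int]:
        return sorted({c.wavelength for c in self.chromatograms})

    def by_wavelength(self, wavelength: int) -> list[Chromatogram]:
        return [c for c in self.chromatograms if c.wavelength == wavelength]

    def get(self, sample_id: str, wavelength: int) -> Chromatogram:
        for c in self.chromatograms:
            if c.sample_id == sample_id and c.wavelength == wavelength:
                return c
        raise KeyError(f"no chromatogram for sample {sample_id!r} at {wavelength} nm")


@dataclass(frozen=True, order=True)
class PeakInterval:
    """Half-open index interval [start_idx, end_idx) with an apex inside."""

    start_idx: int
    end_idx: int
    apex_idx: int

    def __post_init__(self) -> None:
        if not (self.start_idx < self.end_idx):
            raise ValueError(f"empty interval [{self.start_idx}, {self.end_idx})")
        if not (self.start_idx <= self.apex_idx < self.end_idx):
            raise ValueError("apex outside interval")

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    def overlaps(self, other: "PeakInterval") -> bool:
        return self.start_idx < other.end_idx and other.start_idx < self.end_idx


@dataclass(frozen=True)
class CommonPeak:
    """Cross-sample union of overlapping individual peak intervals."""

    interval: PeakInterval
    support: int
    peak_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
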