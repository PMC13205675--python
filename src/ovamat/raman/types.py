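"""Containers for Raman spectra, hyperspectral maps and NMF factors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from ovamat.errors import ParameterError

__all__ = ["RamanSpectrum", "HyperspectralMap", "ComponentSet"]


def _check_axis(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ParameterError("wavenumber axis must be 1-D with >= 2 channels")
    if not np.isfinite(w).all():
        raise ParameterError("wavenumber axis contains non-finite values")
    if not (np.diff(w) > 0).all():
        raise ParameterError("wavenumber axis must be strictly increasing")
    return w


@dataclass
class RamanSpectrum:
    """One spectrum: strictly ascending wavenumbers (cm^-1) and intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _check_axis(self.wavenumbers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavenumbers.shape:
            raise ParameterError("wavenumbers and intensities length mismatch")
        if not np.isfinite(self.intensities).all():
            raise ParameterError("intensities contain NaN/Inf")

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class HyperspectralMap:
    """A spatial grid of Raman spectra.

    ``A`` is the n-channels × m-pixels spectral matrix.  Pixel order is
    row-major over (y, x): pixel index p maps to y = p // nx, x = p % nx —
    i.e. y is the outer loop, x the inner.
    """

    wavenumbers: np.ndarray
    A: np.ndarray
    grid: Tuple[int, int]  # (nx, ny)
    x_step: float = 1.0  # µm
    y_step: float = 1.0  # µm

    def __post_init__(self) -> None:
        self.wavenumbers = _check_axis(self.wavenumbers)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ParameterError("A must be 2-D (channels x pixels)")
        n, m = self.A.shape
        if n != self.wavenumbers.size:
            raise ParameterError("A row count must match the wavenumber axis")
        nx, ny = self.grid
        if nx < 1 or ny < 1 or nx * ny != m:
            raise ParameterError(
                f"grid {self.grid} inconsistent with {m} pixels"
            )
        if not np.isfinite(self.A).all():
            raise ParameterError("spectral matrix contains NaN/Inf")

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.A.shape[1]

    def pixel_image(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-pixel vector to the (ny, nx) image, row-major."""
        nx, ny = self.grid
        return np.asarray(values).reshape(ny, nx)

    def spectrum_at(self, ix: int, iy: int) -> RamanSpectrum:
        nx, ny = self.grid
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise ParameterError(f"pixel ({ix}, {iy}) outside grid {self.grid}")
        return RamanSpectrum(self.wavenumbers, self.A[:, iy * nx + ix].copy())


@dataclass
class ComponentSet:
    """NMF factors of a hyperspectral map: A ≈ W · S.

    ``W`` (n × k) holds pure-component spectra with unit-area columns
    (trapezoid rule over the wavenumber axis); ``S`` (k × m) the matching
    concentration profiles.  ``objective_trace`` records the squared
    Frobenius reconstruction error per iteration of the best restart.
    """

    wavenumbers: np.ndarray
    W: np.ndarray
    S: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    restarts_used: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.wavenumbers = _check_axis(self.wavenumbers)
        self.W = np.asarray(self.W, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.W.ndim != 2 or self.S.ndim != 2:
            raise ParameterError("W and S must be 2-D")
        if self.W.shape[0] != self.wavenumbers.size:
            raise ParameterError("W rows must match the wavenumber axis")
        if self.W.shape[1] != self.S.shape[0]:
            raise ParameterError("inner dimensions of W and S disagree")
        if (self.W < 0).any() or (self.S < 0).any():
            raise ParameterError("NMF factors must be non-negative")
        self.objective_trace = np.asarray(self.objective_trace, dtype=float)

    @property
    def k(self) -> int:
        return self.W.shape[1]
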