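"""AFM force-map analysis: surface roughness (Sa) and stiffness-map summaries.

An AFM force-mapping session yields a height map (topography) and a Young's
modulus map on the same grid — here a 50 × 50 µm square sampled every 5 µm by
default.  The module computes the surface-roughness statistic

    Sa_rms      = sqrt( (1/N) * sum_i (Z_i - Z_avg)^2 )
    Sa_mean_abs = (1/N) * sum_i |Z_i - Z_avg|

where ``Z_i`` is the height at the i-th grid point, ``Z_avg`` the mean height
and ``N`` the number of (unmasked) points.  The rms reading is the default
because a plain mean of squared deviations would carry squared length units;
the ISO mean-absolute variant is available explicitly.  NaN entries are
treated as masked and excluded from ``N``.

Young's-modulus maps are consumed as data (the instrument's contact-model fit
is upstream of this package); only masked-aware summaries are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ovamat.errors import ParameterError

__all__ = [
    "HeightMap",
    "StiffnessMap",
    "RoughnessResult",
    "compute_sa",
    "sa_properties_check",
    "modulus_summary",
    "extract_profile",
    "grid_from_spec",
]


@dataclass
class HeightMap:
    """A rectangular grid of surface heights.

    Parameters
    ----------
    Z : ndarray, shape (rows, cols)
        Heights; NaN marks masked points.
    pixel_spacing : float
        Grid step in µm.
    units : str
        Length unit of ``Z`` (default nm).
    """

    Z: np.ndarray
    pixel_spacing: float = 5.0
    units: str = "nm"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.size < 1:
            raise ParameterError("height map must be a non-empty 2-D grid")
        if np.isinf(self.Z).any():
            raise ParameterError("height map contains infinite values")
        if self.pixel_spacing <= 0:
            raise ParameterError("pixel_spacing must be positive")


@dataclass
class StiffnessMap:
    """A rectangular grid of Young's modulus values in kPa (NaN = masked)."""

    E: np.ndarray
    pixel_spacing: float = 5.0

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2 or self.E.size < 1:
            raise ParameterError("stiffness map must be a non-empty 2-D grid")
        if np.isinf(self.E).any():
            raise ParameterError("stiffness map contains infinite values")
        finite = self.E[np.isfinite(self.E)]
        if finite.size and finite.min() < 0:
            raise ParameterError("Young's modulus values must be >= 0")


@dataclass
class RoughnessResult:
    """Surface roughness of one height map."""

    sa: float
    n_points: int
    z_avg: float
    formula_variant: str
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sa < 0:
            raise ParameterError("sa must be non-negative")


def compute_sa(hmap: HeightMap, variant: str = "rms") -> RoughnessResult:
    """Compute the areal roughness Sa of a height map.

    Parameters
    ----------
    hmap : HeightMap
    variant : {"rms", "mean_abs"}
        ``"rms"`` — root-mean-square deviation from the mean height
        (default); ``"mean_abs"`` — mean absolute deviation (ISO Sa).

    Returns
    -------
    RoughnessResult
        With ``n_points`` counting only unmasked (non-NaN) entries.
    """
    if variant not in ("rms", "mean_abs"):
        raise ParameterError(f"unknown Sa variant {variant!r}")
    z = hmap.Z
    valid = np.isfinite(z)
    n = int(valid.sum())
    if n == 0:
        raise ParameterError("height map is empty or fully masked")
    zv = z[valid]
    z_avg = float(zv.mean())
    dev = zv - z_avg
    if variant == "rms":
        sa = float(np.sqrt(np.mean(dev**2)))
    else:
        sa = float(np.mean(np.abs(dev)))
    return RoughnessResult(
        sa=sa,
        n_points=n,
        z_avg=z_avg,
        formula_variant=variant,
        masked_fraction=1.0 - n / z.size,
    )


def sa_properties_check(
    hmap: HeightMap, c: float, d: float, rtol: float = 1e-9
) -> dict:
    """Assert translation invariance and absolute homogeneity of Sa.

    Checks Sa(Z + d) == Sa(Z) and Sa(c*Z) == |c|*Sa(Z) for both variants and
    returns a report dict; raises ``AssertionError`` on violation.
    """
    report: dict = {"c": c, "d": d, "checks": {}}
    for variant in ("rms", "mean_abs"):
        base = compute_sa(hmap, variant).sa
        shifted = compute_sa(
            HeightMap(hmap.Z + d, hmap.pixel_spacing, hmap.units), variant
        ).sa
        scaled = compute_sa(
            HeightMap(c * hmap.Z, hmap.pixel_spacing, hmap.units), variant
        ).sa
        atol = rtol * max(base, 1.0)
        assert abs(shifted - base) <= atol, (
            f"Sa ({variant}) not translation invariant: {shifted} vs {base}"
        )
        assert abs(scaled - abs(c) * base) <= atol * max(abs(c), 1.0), (
            f"Sa ({variant}) not |c|-homogeneous: {scaled} vs {abs(c) * base}"
        )
        report["checks"][variant] = {
            "sa": base,
            "translation_ok": True,
            "homogeneity_ok": True,
        }
    return report


def modulus_summary(smap: StiffnessMap, bin_edges=None) -> dict:
    """Masked-aware location/dispersion summary of a Young's-modulus map.

    Returns mean, median, sd, quartiles and a histogram (counts, edges) in
    kPa.  ``bin_edges`` defaults to 20 equal-width bins over the data range.
    """
    e = smap.E[np.isfinite(smap.E)]
    if e.size == 0:
        raise ParameterError("stiffness map is empty or fully masked")
    if bin_edges is None:
        lo, hi = float(e.min()), float(e.max())
        if lo == hi:
            hi = lo + 1.0
        bin_edges = np.linspace(lo, hi, 21)
    counts, edges = np.histogram(e, bins=np.asarray(bin_edges, dtype=float))
    q1, med, q3 = np.percentile(e, [25, 50, 75])
    return {
        "n": int(e.size),
        "mean_kpa": float(e.mean()),
        "median_kpa": float(med),
        "sd_kpa": float(e.std(ddof=1)) if e.size > 1 else 0.0,
        "q1_kpa": float(q1),
        "q3_kpa": float(q3),
        "min_kpa": float(e.min()),
        "max_kpa": float(e.max()),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
        "masked_fraction": 1.0 - e.size / smap.E.size,
    }


def extract_profile(hmap: HeightMap, axis: str, index: int):
    """Extract one row or column as a 1-D profile with physical coordinates.

    Parameters
    ----------
    axis : {"row", "col"}
    index : int
        Row/column index into the grid.

    Returns
    -------
    (positions_um, heights) : tuple of ndarray
    """
    if axis not in ("row", "col"):
        raise ParameterError("axis must be 'row' or 'col'")
    rows, cols = hmap.Z.shape
    if axis == "row":
        if not 0 <= index < rows:
            raise ParameterError(f"row index {index} out of range [0, {rows})")
        heights = hmap.Z[index, :]
        n = cols
    else:
        if not 0 <= index < cols:
            raise ParameterError(f"col index {index} out of range [0, {cols})")
        heights = hmap.Z[:, index]
        n = rows
    positions = np.arange(n) * hmap.pixel_spacing
    return positions, heights.copy()


def grid_from_spec(extent_um: float = 50.0, step_um: float = 5.0) -> dict:
    """Expected number of sample points per axis for an AFM scan grid.

    Endpoints inclusive: points sit at 0, step, 2·step, …, extent, hence
    ``floor(extent/step) + 1`` per axis.  A step larger than the extent
    degenerates to a single point (warned).
    """
    if extent_um <= 0 or step_um <= 0:
        raise ParameterError("extent and step must be positive")
    n = int(np.floor(extent_um / step_um)) + 1
    if step_um > extent_um:
        warnings.warn(
            "step exceeds extent: grid degenerates to a single point",
            stacklevel=2,
        )
    return {
        "points_per_axis": n,
        "extent_um": extent_um,
        "step_um": step_um,
        "convention": "endpoints inclusive",
    }
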