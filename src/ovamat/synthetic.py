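"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is deterministic for a fixed seed (one seeded
``numpy.random.Generator`` per call, never global state) and returns the
latent truth that downstream recovery tests need:

* :func:`gen_raman_cube` — mixtures of smooth pure-component spectra (sums of
  Gaussian peaks) on smooth spatial abundance fields, plus a polynomial
  baseline, Gaussian noise and sparse single-channel cosmic spikes; returns
  the noiseless factors and the exact spike locations.
* :func:`gen_height_map` — correlated Gaussian random surface rescaled so its
  rms Sa equals the requested target exactly.
* :func:`gen_follicle_cohort` — follicle records whose morphology fields are
  consistent with their true stage labels.
* :func:`gen_omics_table` — paired mRNA/protein log2 fold changes drawn from
  a bivariate normal with a specified correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from ovamat.afm import HeightMap, compute_sa
from ovamat.errors import ParameterError
from ovamat.follicle import FollicleRecord
from ovamat.raman.types import ComponentSet, HyperspectralMap

__all__ = [
    "RamanPhantomSpec",
    "SurfacePhantomSpec",
    "CohortSpec",
    "OmicsTableSpec",
    "FollicleCohort",
    "gen_raman_cube",
    "gen_height_map",
    "gen_follicle_cohort",
    "gen_omics_table",
    "default_raman_phantom",
]


def _require_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.isfinite(arr).all():
        raise ParameterError(f"{name} contains non-finite values")


# ---------------------------------------------------------------------------
# Raman phantom
# ---------------------------------------------------------------------------

@dataclass
class RamanPhantomSpec:
    """Recipe for a synthetic hyperspectral Raman cube.

    ``peak_tables[c]`` lists (center cm⁻¹, width cm⁻¹, height a.u.) Gaussian
    peaks of component c.  ``abundance_fields`` are per-component (ny, nx)
    weight maps; when None, smooth blob fields are generated from the seed.
    ``baseline_coeffs`` are polynomial coefficients (ascending powers of the
    axis rescaled to [0, 1]) shared by all pixels, optionally modulated by a
    per-pixel scale in [0.8, 1.2].  ``spike_magnitude`` defaults to
    20 × ``noise_sd`` so that flagging is unambiguous.
    """

    n_components: int
    peak_tables: List[List[Tuple[float, float, float]]]
    wavenumber_axis: np.ndarray
    grid_shape: Tuple[int, int]  # (nx, ny)
    abundance_fields: Optional[List[np.ndarray]] = None
    baseline_coeffs: Sequence[float] = ()
    noise_sd: float = 0.0
    spike_rate: float = 0.0
    spike_magnitude: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavenumber_axis = np.asarray(self.wavenumber_axis, dtype=float)
        _require_finite("wavenumber_axis", self.wavenumber_axis)
        if not (np.diff(self.wavenumber_axis) > 0).all():
            raise ParameterError("wavenumber axis must be strictly increasing")
        if self.n_components < 1 or len(self.peak_tables) != self.n_components:
            raise ParameterError(
                "peak_tables must list one table per component"
            )
        for table in self.peak_tables:
            for center, width, height in table:
                _require_finite("peak parameters", [center, width, height])
                if width <= 0 or height < 0:
                    raise ParameterError(
                        "peak widths must be > 0 and heights >= 0"
                    )
        nx, ny = self.grid_shape
        if nx < 1 or ny < 1:
            raise ParameterError("grid_shape must be positive")
        if self.abundance_fields is not None:
            if len(self.abundance_fields) != self.n_components:
                raise ParameterError("one abundance field per component")
            for f in self.abundance_fields:
                f = np.asarray(f, dtype=float)
                _require_finite("abundance field", f)
                if f.shape != (ny, nx):
                    raise ParameterError(
                        f"abundance fields must have shape {(ny, nx)}"
                    )
                if (f < 0).any():
                    raise ParameterError("abundances must be >= 0")
        _require_finite("baseline_coeffs", list(self.baseline_coeffs))
        _require_finite("noise_sd", self.noise_sd)
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ParameterError("spike_rate must lie in [0, 1]")
        if self.spike_magnitude is not None:
            _require_finite("spike_magnitude", self.spike_magnitude)


def _gaussian_spectrum(axis: np.ndarray, table) -> np.ndarray:
    y = np.zeros_like(axis)
    for center, width, height in table:
        y += height * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return y


def _blob_fields(rng, n_components, nx, ny) -> List[np.ndarray]:
    """Smooth, spatially separated blob fields with a common floor.

    Blob centers are spread around an ellipse so each component dominates a
    distinct region and has near-pure pixels there (cell-body vs matrix
    contrast) — the spatial separability that makes the factorization
    identifiable; a small floor keeps every component weakly present
    everywhere.
    """
    yy, xx = np.mgrid[0:ny, 0:nx]
    fields = []
    for c in range(n_components):
        angle = 2 * np.pi * c / n_components + rng.uniform(-0.2, 0.2)
        cx = nx / 2 + 0.32 * nx * np.cos(angle)
        cy = ny / 2 + 0.32 * ny * np.sin(angle)
        sx = nx * rng.uniform(0.12, 0.18)
        sy = ny * rng.uniform(0.12, 0.18)
        blob = np.exp(
            -0.5 * (((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2)
        )
        fields.append(0.04 + blob)
    return fields


def gen_raman_cube(
    spec: RamanPhantomSpec,
) -> Tuple[HyperspectralMap, ComponentSet, np.ndarray]:
    """Synthesize a hyperspectral cube plus its ground truth.

    cube = Σ_c abundance_c ⊗ spectrum_c + baseline + N(0, noise_sd²)
           + spikes

    Returns the noisy map, the noiseless truth factors (W columns
    area-normalized with the scale absorbed into S, so W·S is exactly the
    noiseless mixed signal) and the exact boolean spike mask
    (channels × pixels).
    """
    axis = spec.wavenumber_axis
    nx, ny = spec.grid_shape
    n, m = axis.size, nx * ny
    rng = np.random.default_rng(spec.seed)

    W = np.column_stack(
        [_gaussian_spectrum(axis, t) for t in spec.peak_tables]
    )
    if spec.abundance_fields is not None:
        fields = [np.asarray(f, dtype=float) for f in spec.abundance_fields]
    else:
        fields = _blob_fields(rng, spec.n_components, nx, ny)
    S = np.vstack([f.reshape(-1) for f in fields])

    signal = W @ S
    cube = signal.copy()

    if len(spec.baseline_coeffs):
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        base = np.polynomial.polynomial.polyval(
            t, np.asarray(spec.baseline_coeffs, dtype=float)
        )
        # focus drift varies smoothly across a scan: blur the per-pixel
        # baseline scale so neighboring pixels share similar baselines
        pixel_scale = rng.uniform(0.8, 1.2, size=(ny, nx))
        pixel_scale = ndimage.gaussian_filter(
            pixel_scale, sigma=3.0, mode="nearest"
        ).reshape(-1)
        cube = cube + base[:, None] * pixel_scale[None, :]

    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, size=(n, m))

    spike_mask = np.zeros((n, m), dtype=bool)
    if spec.spike_rate > 0:
        spike_mask = rng.random((n, m)) < spec.spike_rate
        magnitude = (
            spec.spike_magnitude
            if spec.spike_magnitude is not None
            else 20.0 * spec.noise_sd
        )
        jitter = rng.uniform(1.0, 1.5, size=(n, m))
        cube = cube + spike_mask * magnitude * jitter

    hmap = HyperspectralMap(axis, cube, spec.grid_shape)

    # unit-area truth columns, scale absorbed into S: W_t @ S_t == signal
    areas = np.trapezoid(W, axis, axis=0)
    scale = np.where(areas > 0, areas, 1.0)
    truth = ComponentSet(
        wavenumbers=axis,
        W=W / scale,
        S=S * scale[:, None],
        objective_trace=np.array([0.0]),
        restarts_used=0,
        seed=spec.seed,
    )
    return hmap, truth, spike_mask


def default_raman_phantom(
    grid_shape: Tuple[int, int] = (50, 40),
    n_channels: int = 801,
    noise_frac: float = 0.01,
    spike_rate: float = 0.001,
    seed: int = 0,
) -> RamanPhantomSpec:
    """Standard 3-component test phantom on the 400–2000 cm⁻¹ window.

    Components emulate collagen-like, glycosaminoglycan-like and
    cell-body-like spectra with well-separated characteristic peaks; noise
    is ``noise_frac`` of the peak noiseless signal, and a broad decaying
    polynomial emulates tissue autofluorescence.
    """
    axis = np.linspace(400.0, 2000.0, n_channels)
    peak_tables = [
        # collagen-like
        [(855, 12, 1.0), (938, 12, 0.8), (1246, 14, 0.9),
         (1450, 12, 0.7), (1668, 14, 1.0)],
        # GAG-like
        [(898, 12, 0.7), (1063, 12, 1.0), (1126, 12, 0.6), (1375, 14, 0.8)],
        # cell-body-like (protein/nucleic acid)
        [(1004, 6, 1.0), (1095, 10, 0.4), (1340, 16, 0.6), (1580, 12, 0.5)],
    ]
    probe = RamanPhantomSpec(
        n_components=3,
        peak_tables=peak_tables,
        wavenumber_axis=axis,
        grid_shape=grid_shape,
        seed=seed,
    )
    _, truth, _ = gen_raman_cube(probe)
    peak_signal = float((truth.W @ truth.S).max())
    noise_sd = noise_frac * peak_signal
    return RamanPhantomSpec(
        n_components=3,
        peak_tables=peak_tables,
        wavenumber_axis=axis,
        grid_shape=grid_shape,
        baseline_coeffs=(
            0.5 * peak_signal, -0.6 * peak_signal, 0.25 * peak_signal
        ),
        noise_sd=noise_sd,
        spike_rate=spike_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# AFM surface phantom
# ---------------------------------------------------------------------------

@dataclass
class SurfacePhantomSpec:
    """Recipe for a correlated random surface with exact target roughness."""

    grid_shape: Tuple[int, int] = (100, 100)  # (rows, cols)
    pixel_spacing: float = 5.0  # µm
    target_sa: float = 10.0  # same length units as the output map
    correlation_length: float = 10.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ParameterError("grid_shape must be positive")
        _require_finite("target_sa", self.target_sa)
        if self.target_sa < 0:
            raise ParameterError("target_sa must be >= 0")
        if self.pixel_spacing <= 0 or self.correlation_length <= 0:
            raise ParameterError(
                "pixel_spacing and correlation_length must be positive"
            )


def gen_height_map(spec: SurfacePhantomSpec) -> HeightMap:
    """Correlated Gaussian surface rescaled to the exact target Sa (rms).

    White noise is smoothed with a Gaussian kernel of width
    ``correlation_length / pixel_spacing`` pixels, centered, and rescaled so
    the rms Sa of the returned map equals ``target_sa`` by construction.
    ``target_sa = 0`` yields a constant (flat) surface.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    if spec.target_sa == 0:
        return HeightMap(np.zeros((rows, cols)), spec.pixel_spacing)
    z = rng.standard_normal((rows, cols))
    sigma = spec.correlation_length / spec.pixel_spacing
    z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    z -= z.mean()
    rms = np.sqrt(np.mean(z**2))
    if rms == 0:  # pathological: a constant field cannot be rescaled
        raise ParameterError(
            "degenerate surface (zero variance); reduce correlation_length"
        )
    z *= spec.target_sa / rms
    hm = HeightMap(z, spec.pixel_spacing)
    # tighten against float error: one exact correction pass
    hm.Z *= spec.target_sa / compute_sa(hm, "rms").sa
    return hm


# ---------------------------------------------------------------------------
# Follicle cohort
# ---------------------------------------------------------------------------

#: Morphology fields implied by each true stage.
_STAGE_MORPHOLOGY = {
    "primordial": dict(
        granulosa_shape="flattened", layers=(1, 1), antrum=False
    ),
    "primary": dict(
        granulosa_shape="mixed_cuboidal_squamous", layers=(1, 1), antrum=False
    ),
    "secondary": dict(granulosa_shape="cuboidal", layers=(2, 5), antrum=False),
    "antral": dict(granulosa_shape="cuboidal", layers=(4, 8), antrum=True),
}

#: Default per-stage follicle diameter (mean, sd) in µm for 4-week mouse
#: ovaries: primordial ~tens of µm, antral up to several hundred µm.
DEFAULT_DIAMETERS = {
    "primordial": (20.0, 4.0),
    "primary": (65.0, 15.0),
    "secondary": (150.0, 40.0),
    "antral": (320.0, 70.0),
}


@dataclass
class CohortSpec:
    """Recipe for a synthetic follicle cohort."""

    stage_proportions: Dict[str, float] = field(
        default_factory=lambda: {
            "primordial": 0.55,
            "primary": 0.20,
            "secondary": 0.15,
            "antral": 0.10,
        }
    )
    diameter_distributions: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETERS)
    )
    n_follicles: int = 100
    atresia_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.stage_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"stage proportions sum to {total}, expected 1"
            )
        for stage in self.stage_proportions:
            if stage not in _STAGE_MORPHOLOGY:
                raise ParameterError(f"unknown stage {stage!r}")
            if self.stage_proportions[stage] < 0:
                raise ParameterError("proportions must be >= 0")
        if self.n_follicles < 0:
            raise ParameterError("n_follicles must be >= 0")
        if not 0.0 <= self.atresia_rate <= 1.0:
            raise ParameterError("atresia_rate must lie in [0, 1]")


@dataclass
class FollicleCohort:
    """Generated records plus their latent true stage labels."""

    records: List[FollicleRecord]
    true_stages: List[str]

    def __len__(self) -> int:
        return len(self.records)


def _positive_normal(rng, mean, sd) -> float:
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d > 0:
            return float(d)
    raise ParameterError(
        f"diameter distribution ({mean}, {sd}) almost never positive"
    )


def gen_follicle_cohort(spec: CohortSpec) -> FollicleCohort:
    """Sample a cohort whose morphology matches its true stage labels.

    Every record is classifiable back to its true stage by
    :func:`ovamat.follicle.classify_follicle` by construction; health flags
    are Bernoulli(1 − atresia_rate).
    """
    rng = np.random.default_rng(spec.seed)
    stages = sorted(spec.stage_proportions)
    probs = np.array([spec.stage_proportions[s] for s in stages])
    probs = probs / probs.sum()
    draws = rng.choice(len(stages), size=spec.n_follicles, p=probs)

    records: List[FollicleRecord] = []
    labels: List[str] = []
    for i, si in enumerate(draws):
        stage = stages[si]
        morph = _STAGE_MORPHOLOGY[stage]
        lo, hi = morph["layers"]
        mean, sd = spec.diameter_distributions[stage]
        records.append(
            FollicleRecord(
                id=f"f{i:05d}",
                nucleus_visible=True,
                granulosa_layers=int(rng.integers(lo, hi + 1)),
                granulosa_shape=morph["granulosa_shape"],
                antrum_present=morph["antrum"],
                healthy=bool(rng.random() >= spec.atresia_rate),
                follicle_diameter=_positive_normal(rng, mean, sd),
            )
        )
        labels.append(stage)
    return FollicleCohort(records, labels)


# ---------------------------------------------------------------------------
# Paired omics table
# ---------------------------------------------------------------------------

@dataclass
class OmicsTableSpec:
    """Recipe for a paired mRNA/protein fold-change table."""

    n_genes: int = 1000
    log2fc_correlation: float = 0.5
    fraction_significant: float = 0.3
    matrisome_fraction: float = 0.1
    effect_sd: float = 1.5  # sd of log2 fold changes on both axes
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite("log2fc_correlation", self.log2fc_correlation)
        if not -1.0 <= self.log2fc_correlation <= 1.0:
            raise ParameterError("correlation must lie in [-1, 1]")
        for name in ("fraction_significant", "matrisome_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.effect_sd <= 0:
            raise ParameterError("effect_sd must be > 0")


def gen_omics_table(spec: OmicsTableSpec) -> pd.DataFrame:
    """Paired fold changes from a bivariate normal at correlation ρ.

    A ``fraction_significant`` subset of genes receives p-values below 0.05
    on both axes (uniform on [0, 0.05)); the rest get p ≥ 0.05.  Columns:
    identifier, log2fc_mrna, p_mrna, log2fc_protein, p_protein, matrisome.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    rho = spec.log2fc_correlation
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = spec.effect_sd * z1
    y = spec.effect_sd * (rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2)

    sig = rng.random(n) < spec.fraction_significant
    p_mrna = np.where(sig, rng.uniform(0, 0.05, n), rng.uniform(0.05, 1, n))
    p_protein = np.where(
        sig, rng.uniform(0, 0.05, n), rng.uniform(0.05, 1, n)
    )
    return pd.DataFrame(
        {
            "identifier": [f"gene{i:05d}" for i in range(n)],
            "log2fc_mrna": x,
            "p_mrna": p_mrna,
            "log2fc_protein": y,
            "p_protein": p_protein,
            "matrisome": rng.random(n) < spec.matrisome_fraction,
        }
    )
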