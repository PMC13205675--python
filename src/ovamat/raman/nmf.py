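"""Non-negative matrix factorization of hyperspectral maps.

The preprocessed spectral matrix A (n channels × m pixels) is factorized as
A ≈ W·S with W ≥ 0 holding k pure-component spectra and S ≥ 0 the matching
per-pixel concentration profiles, by minimizing the squared Frobenius
reconstruction error ‖A − W·S‖²_F with multiplicative updates (Lee–Seung).
Multiplicative updates never increase the objective, so the recorded
objective trace is non-increasing up to floating-point slack.

NMF is determined only up to permutation and per-component scaling; the
indeterminacy is resolved by rescaling each W column to unit trapezoid area
over the wavenumber axis (inverse scale absorbed into S) and sorting
components by total abundance, descending.  The solver restarts from several
seeded random initializations and keeps the best objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ovamat.errors import ParameterError
from ovamat.raman.types import ComponentSet, HyperspectralMap

__all__ = [
    "nmf_decompose",
    "scree_over_k",
    "abundance_maps",
    "RamanUnmixingModel",
    "RamanUnmixingResults",
]

_EPS = 1e-12


def _multiplicative_nmf(
    A: np.ndarray,
    W0: np.ndarray,
    S0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """Run Lee–Seung updates from a given init; returns (W, S, trace)."""
    W, S = W0.copy(), S0.copy()
    trace = []
    prev = None
    for _ in range(max_iter):
        W *= (A @ S.T) / (W @ (S @ S.T) + _EPS)
        S *= (W.T @ A) / ((W.T @ W) @ S + _EPS)
        obj = float(np.linalg.norm(A - W @ S) ** 2)
        trace.append(obj)
        if prev is not None and prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj
    return W, S, np.asarray(trace)


def _random_init(rng: np.random.Generator, n, m, k, scale):
    # uniform in (0, scale]: avoid exact zeros, which multiplicative
    # updates can never leave
    W0 = scale * (1.0 - rng.random((n, k)))
    S0 = scale * (1.0 - rng.random((k, m)))
    return W0, S0


def _finalize(wavenumbers, W, S, trace, restarts, seed) -> ComponentSet:
    W = np.clip(W, 0.0, None)
    S = np.clip(S, 0.0, None)
    areas = np.trapezoid(W, wavenumbers, axis=0)
    scale = np.where(areas > 0, areas, 1.0)
    W = W / scale
    S = S * scale[:, None]
    order = np.argsort(-S.sum(axis=1), kind="stable")
    return ComponentSet(
        wavenumbers=wavenumbers,
        W=W[:, order],
        S=S[order, :],
        objective_trace=trace,
        restarts_used=restarts,
        seed=seed,
    )


def nmf_decompose(
    hmap: HyperspectralMap,
    k: int,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: Optional[int] = None,
    warm_start: Optional[ComponentSet] = None,
) -> ComponentSet:
    """Factorize a (preprocessed, non-negative) map into k components.

    Parameters
    ----------
    k : int
        Number of components (user-chosen; see :func:`scree_over_k`).
    n_restarts : int
        Seeded random initializations; the best final objective wins.
    tol : float
        Relative objective-change stopping criterion.
    warm_start : ComponentSet, optional
        Additional initialization built from a previous solution (used by
        the scree diagnostic to guarantee monotone objectives in k).

    Raises
    ------
    ParameterError
        If ``A`` has negative entries (naming the first offending
        pixel/channel) or ``k < 1``.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    A = hmap.A
    if (A < 0).any():
        ch, px = np.argwhere(A < 0)[0]
        raise ParameterError(
            f"A has a negative entry at channel {ch}, pixel {px}; "
            "run preprocessing first"
        )
    n, m = A.shape
    scale = float(A.max()) or 1.0
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_restarts)

    best = None
    for child in children:
        rng = np.random.default_rng(child)
        W0, S0 = _random_init(rng, n, m, k, scale)
        W, S, trace = _multiplicative_nmf(A, W0, S0, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, S, trace)
    if warm_start is not None and warm_start.k <= k:
        rng = np.random.default_rng(seq.spawn(1)[0])
        W0 = np.full((n, k), _EPS)
        S0 = np.full((k, m), _EPS)
        kw = warm_start.k
        W0[:, :kw] = np.clip(warm_start.W, _EPS, None)
        S0[:kw, :] = np.clip(warm_start.S, _EPS, None)
        if k > kw:
            W0[:, kw:], S0[kw:, :] = _random_init(
                rng, n, m, k - kw, 1e-6 * scale
            )
        W, S, trace = _multiplicative_nmf(A, W0, S0, max_iter, tol)
        if trace[-1] < best[2][-1]:
            best = (W, S, trace)
    W, S, trace = best
    return _finalize(hmap.wavenumbers, W, S, trace, n_restarts, seed)


def scree_over_k(
    hmap: HyperspectralMap,
    k_range: Sequence[int],
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: Optional[int] = None,
):
    """Best objective per candidate k, for user selection of k.

    Each k warm-starts from the previous best solution in addition to its
    random restarts, so the reported best objective is non-increasing in k.
    Returns a list of dicts ``{"k": k, "objective": best}``.
    """
    rows = []
    prev: Optional[ComponentSet] = None
    for k in sorted(k_range):
        cs = nmf_decompose(
            hmap, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=seed, warm_start=prev,
        )
        rows.append({"k": int(k), "objective": float(cs.objective_trace[-1])})
        prev = cs
    return rows


def abundance_maps(cs: ComponentSet, grid) -> np.ndarray:
    """Reshape each concentration profile to its (ny, nx) image.

    Pixel order is row-major over (y, x) — y outer, x inner — matching
    :class:`~ovamat.raman.types.HyperspectralMap`.
    """
    nx, ny = grid
    if cs.S.shape[1] != nx * ny:
        raise ParameterError(
            f"grid {grid} inconsistent with {cs.S.shape[1]} pixels"
        )
    return cs.S.reshape(cs.k, ny, nx)


class RamanUnmixingModel:
    """Spectral-unmixing model for one hyperspectral map.

    Statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`RamanUnmixingResults`.

    Parameters
    ----------
    hmap : HyperspectralMap
        Raw or preprocessed map.
    preprocess : PreprocessConfig or None
        When given, the preprocessing chain runs at fit time; when None the
        map is assumed preprocessed (must be non-negative).
    """

    def __init__(self, hmap: HyperspectralMap, preprocess=None):
        self.raw = hmap
        self.preprocess_config = preprocess
        self._pre = None
        self._pre_info = None

    @property
    def endog(self) -> HyperspectralMap:
        """The map actually factorized (preprocessed when configured)."""
        if self.preprocess_config is None:
            return self.raw
        if self._pre is None:
            from ovamat.raman.preprocess import preprocess_map

            self._pre, self._pre_info = preprocess_map(
                self.raw, self.preprocess_config, return_info=True
            )
        return self._pre

    def fit(
        self,
        k: int,
        n_restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-6,
        seed: Optional[int] = None,
    ) -> "RamanUnmixingResults":
        cs = nmf_decompose(
            self.endog, k, n_restarts=n_restarts, max_iter=max_iter,
            tol=tol, seed=seed,
        )
        return RamanUnmixingResults(self, cs)

    def scree(self, k_range, **kwargs):
        return scree_over_k(self.endog, k_range, **kwargs)


@dataclass
class RamanUnmixingResults:
    """Fitted unmixing: factors, diagnostics, maps and summary."""

    model: RamanUnmixingModel
    components: ComponentSet

    @property
    def W(self) -> np.ndarray:
        return self.components.W

    @property
    def S(self) -> np.ndarray:
        return self.components.S

    @property
    def k(self) -> int:
        return self.components.k

    @property
    def objective(self) -> float:
        return float(self.components.objective_trace[-1])

    @property
    def relative_error(self) -> float:
        """‖A − WS‖_F / ‖A‖_F on the factorized map."""
        A = self.model.endog.A
        return float(np.linalg.norm(A - self.W @ self.S) / np.linalg.norm(A))

    def abundance_maps(self) -> np.ndarray:
        return abundance_maps(self.components, self.model.endog.grid)

    def annotate(self, component_index, reference_peaks, **kwargs):
        from ovamat.raman.annotate import annotate_component

        return annotate_component(
            self.components, component_index, reference_peaks, **kwargs
        )

    def summary(self) -> str:
        cs = self.components
        grid = self.model.endog.grid
        lines = [
            "Raman NMF unmixing results",
            "=" * 42,
            f"components (k)      : {cs.k}",
            f"channels x pixels   : {cs.W.shape[0]} x {cs.S.shape[1]}"
            f"  (grid {grid[0]} x {grid[1]})",
            f"restarts            : {cs.restarts_used}"
            f"   seed: {cs.seed}",
            f"iterations (best)   : {cs.objective_trace.size}",
            f"final objective     : {self.objective:.6g}",
            f"relative error      : {self.relative_error:.4f}",
            "-" * 42,
            "component  total abundance  peak (cm^-1)",
        ]
        w = cs.wavenumbers
        for i in range(cs.k):
            tot = cs.S[i].sum()
            peak = w[int(np.argmax(cs.W[:, i]))]
            lines.append(f"{i:>9d}  {tot:>15.4g}  {peak:>12.1f}")
        return "\n".join(lines)

    def plot_abundances(self, path=None):
        """Render one abundance image per component (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        maps = self.abundance_maps()
        fig, axes = plt.subplots(1, self.k, figsize=(4 * self.k, 3.5))
        axes = np.atleast_1d(axes)
        for i, ax in enumerate(axes):
            im = ax.imshow(maps[i], origin="lower", cmap="viridis")
            ax.set_title(f"component {i}")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig
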