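"""FTIR hyperspectral pre-processing.

The chain mirrors the standard workflow for infrared microspectroscopy of
tissue sections: (1) separate tissue from background by thresholding the
per-pixel mean absorbance, (2) denoise each spectrum with a second-order
Savitzky-Golay filter, (3) remove Mie scattering distortion with an
iterative extended multiplicative signal correction whose interferent
subspace is spanned by principal components of van de Hulst extinction
curves (ME-EMSC), and (4) reject pixels whose correction residual (RMSE)
exceeds a cap or that failed to converge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "HyperspectralCube",
    "SGConfig",
    "MEEMSCConfig",
    "CorrectionResult",
    "build_tissue_mask",
    "sg_denoise",
    "vanhulst_extinction",
    "build_mie_subspace",
    "me_emsc_correct",
    "correct_cube",
    "quality_filter",
]


@dataclass
class HyperspectralCube:
    """An FTIR image: one absorbance spectrum per pixel.

    Attributes
    ----------
    wavenumbers : (n,) array, strictly increasing, cm^-1
    absorbance : (rows, cols, n) array, a.u.
    pixel_step : float, pixel pitch in micrometres
    mask : optional (rows, cols) boolean array, True on tissue
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    pixel_step: float = 6.5
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be a strictly increasing 1-D array")
        if self.absorbance.ndim != 3:
            raise ValueError("absorbance must be rows x cols x wavenumbers")
        if self.absorbance.shape[-1] != self.wavenumbers.size:
            raise ValueError("spectral dimension does not match wavenumber axis")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.absorbance.shape[:2]:
                raise ValueError("mask shape does not match spatial dimensions")
        if self.pixel_step <= 0:
            raise ValueError("pixel_step must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorbance.shape[:2]


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay smoothing settings (polynomial order 2, 21-sample
    window by default, i.e. 84 cm^-1 at 4 cm^-1 spacing)."""

    poly_order: int = 2
    window_length: int = 21

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if self.window_length <= self.poly_order:
            raise ValueError("window_length must exceed poly_order")


@dataclass
class MEEMSCConfig:
    """Settings of the iterative Mie-extinction EMSC.

    The interferent subspace is built from van de Hulst extinction
    curves evaluated on a grid of refractive indices ``n_grid`` and
    sphere diameters ``d_grid`` (micrometres), compressed by SVD to the
    smallest basis explaining ``explained_variance_target`` of the
    curve-set variance.  Iteration stops when the RMS difference
    between successive corrected spectra falls below ``rmse_stop`` or
    after ``max_iterations``.  ``weight_region`` restricts the least
    squares fit to an analysis window (uniform weight inside, zero
    outside); an explicit per-channel ``weights`` vector overrides it.
    ``reference_spectrum=None`` selects the built-in collagen-like
    spectrum evaluated on the working axis.
    """

    reference_spectrum: np.ndarray | None = None
    explained_variance_target: float = 0.9999
    max_iterations: int = 45
    rmse_stop: float = 0.05
    n_grid: tuple[float, float, int] = (1.1, 1.4, 10)
    d_grid: tuple[float, float, int] = (2.0, 7.1, 10)
    weight_region: tuple[float, float] = (1000.0, 4000.0)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.explained_variance_target < 1:
            raise ValueError("explained_variance_target must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rmse_stop <= 0:
            raise ValueError("rmse_stop must be positive")

    def resolve_reference(self, axis: np.ndarray) -> np.ndarray:
        if self.reference_spectrum is not None:
            ref = np.asarray(self.reference_spectrum, dtype=float)
            if ref.shape != axis.shape:
                raise ValueError("reference spectrum is not on the working axis")
            return ref
        from .spectra import collagen_like_peaks, build_spectrum

        return build_spectrum(collagen_like_peaks(), axis=axis)

    def resolve_weights(self, axis: np.ndarray) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != axis.shape:
                raise ValueError("weights vector is not on the working axis")
            return w
        lo, hi = self.weight_region
        return ((axis >= lo) & (axis <= hi)).astype(float)


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of ME-EMSC on a single spectrum."""

    corrected: np.ndarray
    rmse: float
    n_iterations: int
    converged: bool
    coefficients: np.ndarray  # [constant, linear, reference, loadings...]

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


# ---------------------------------------------------------------------------
# masking and denoising
# ---------------------------------------------------------------------------


def build_tissue_mask(
    cube: HyperspectralCube, threshold: float | str = "otsu"
) -> np.ndarray:
    """Tissue/background mask from per-pixel mean absorbance.

    A pixel is tissue iff its mean absorbance over the axis exceeds the
    threshold.  ``threshold="otsu"`` (default) splits the mean-intensity
    histogram automatically; a float is used directly.  A degenerate
    (flat) image yields an empty mask with a warning.
    """
    mean_img = cube.absorbance.mean(axis=-1)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold strategy {threshold!r}")
        if np.ptp(mean_img) < 1e-12:
            warnings.warn("flat mean-intensity image: returning empty tissue mask")
            return np.zeros(cube.shape, dtype=bool)
        thr = threshold_otsu(mean_img)
    else:
        thr = float(threshold)
    mask = mean_img > thr
    if not mask.any():
        warnings.warn("tissue mask is empty")
    return mask


def sg_denoise(spectrum: np.ndarray, config: SGConfig = SGConfig()) -> np.ndarray:
    """Savitzky-Golay smoothing along the last (spectral) axis.

    Edges are handled by evaluating the polynomial fitted to the
    terminal window (``mode="interp"``), so output length equals input
    length and polynomials up to ``poly_order`` pass through unchanged.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] < config.window_length:
        raise ValueError(
            f"spectrum length {spectrum.shape[-1]} is shorter than the "
            f"smoothing window {config.window_length}"
        )
    return savgol_filter(
        spectrum, config.window_length, config.poly_order, axis=-1, mode="interp"
    )


# ---------------------------------------------------------------------------
# Mie extinction model
# ---------------------------------------------------------------------------


def vanhulst_extinction(
    wavenumbers: np.ndarray, n: float, d: float
) -> np.ndarray:
    """van de Hulst extinction efficiency of a homogeneous sphere.

    ``Q_ext(rho) = 2 - (4 / rho) sin(rho) + (4 / rho^2)(1 - cos(rho))``
    with phase shift ``rho = 4 pi d (n - 1) nu`` (``d`` in micrometres
    converted to cm, ``nu`` in cm^-1).  The curve tends to 0 as
    ``rho -> 0`` and oscillates about 2 for large ``rho``.
    """
    if n <= 1:
        raise ValueError("refractive index n must exceed 1")
    if d <= 0:
        raise ValueError("sphere diameter d must be positive")
    nu = np.asarray(wavenumbers, dtype=float)
    rho = 4.0 * np.pi * (d * 1e-4) * (n - 1.0) * nu
    out = np.empty_like(rho)
    small = np.abs(rho) < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        r = rho[~small]
        out[~small] = 2.0 - (4.0 / r) * np.sin(r) + (4.0 / r**2) * (1.0 - np.cos(r))
    # second-order series: Q -> rho^2 / 2 as rho -> 0
    out[small] = 0.5 * rho[small] ** 2
    return out


def build_mie_subspace(
    config: MEEMSCConfig, axis: np.ndarray
) -> np.ndarray:
    """Orthonormal loading vectors spanning the Mie extinction curve set.

    Extinction curves are computed for every ``(n, d)`` grid point and
    compressed by (uncentred) singular value decomposition; the smallest
    number of right singular vectors whose cumulative explained variance
    reaches the configured target is returned, one loading per row.
    """
    n_lo, n_hi, n_num = config.n_grid
    d_lo, d_hi, d_num = config.d_grid
    ns = np.linspace(n_lo, n_hi, int(n_num))
    ds = np.linspace(d_lo, d_hi, int(d_num))
    if ns.size == 0 or ds.size == 0:
        raise ValueError("Mie parameter grids must be non-empty")
    curves = np.array([vanhulst_extinction(axis, n, d) for n in ns for d in ds])
    if curves.shape[0] == 1 or np.allclose(curves, curves[0]):
        v = curves[0]
        return (v / np.linalg.norm(v))[None, :]
    _, s, vt = np.linalg.svd(curves, full_matrices=False)
    explained = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(explained, config.explained_variance_target) + 1)
    return vt[:k]


# ---------------------------------------------------------------------------
# ME-EMSC
# ---------------------------------------------------------------------------


def _fit_emsc(
    spectrum: np.ndarray,
    reference: np.ndarray,
    loadings: np.ndarray,
    axis_scaled: np.ndarray,
    w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares of spectrum on [1, nu, reference, loadings]."""
    design = np.column_stack([np.ones_like(axis_scaled), axis_scaled, reference, loadings.T])
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], spectrum * sw, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("singular EMSC design matrix")
    return coef, design


def me_emsc_correct(
    spectrum: np.ndarray,
    config: MEEMSCConfig,
    axis: np.ndarray,
    loadings: np.ndarray | None = None,
) -> CorrectionResult:
    """Iterative Mie-extinction EMSC correction of one spectrum.

    Each iteration fits ``spectrum = a + b nu + c reference + sum g_i
    loading_i`` by weighted least squares and forms ``corrected =
    (spectrum - a - b nu - sum g_i loading_i) / c``; the corrected
    spectrum becomes the next reference.  Iteration stops when the RMS
    change between successive corrected spectra (over the weighted
    channels) drops below ``rmse_stop``, or at ``max_iterations`` with
    ``converged=False``.  A non-positive reference weight ``c`` also
    flags non-convergence.  The reported ``rmse`` is the weighted-region
    RMS residual of the first fit — the one against the configured
    reference — used downstream for pixel rejection: once the reference
    has been replaced by the pixel's own corrected spectrum, later fits
    are exact by construction and carry no quality information.

    ``loadings`` may be passed in to reuse a precomputed Mie subspace
    across many pixels (it depends only on the parameter grids).
    """
    axis = np.asarray(axis, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != axis.shape:
        raise ValueError("spectrum and axis lengths differ")
    reference = config.resolve_reference(axis)
    weights = config.resolve_weights(axis)
    if loadings is None:
        loadings = build_mie_subspace(config, axis)
    axis_scaled = (axis - axis[0]) / (axis[-1] - axis[0])
    w_idx = weights > 0
    n_w = int(w_idx.sum())

    prev_corrected = reference
    corrected = spectrum
    coef = np.zeros(3 + loadings.shape[0])
    rmse_fit = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        coef, design = _fit_emsc(spectrum, reference, loadings, axis_scaled, weights)
        model = design @ coef
        if n_iter == 1:
            rmse_fit = float(
                np.sqrt(np.sum(weights * (spectrum - model) ** 2) / n_w)
            )
        c = coef[2]
        if c <= 0:
            converged = False
            corrected = prev_corrected
            break
        interference = coef[0] + coef[1] * axis_scaled + loadings.T @ coef[3:]
        corrected = (spectrum - interference) / c
        delta = float(
            np.sqrt(np.mean((corrected[w_idx] - prev_corrected[w_idx]) ** 2))
        )
        prev_corrected = corrected
        if delta < config.rmse_stop:
            converged = True
            break
        reference = corrected
    return CorrectionResult(
        corrected=corrected,
        rmse=rmse_fit,
        n_iterations=n_iter,
        converged=converged,
        coefficients=coef,
    )


def correct_cube(
    cube: HyperspectralCube,
    config: MEEMSCConfig,
    mask: np.ndarray | None = None,
) -> tuple[HyperspectralCube, pd.DataFrame]:
    """Apply ME-EMSC to every masked pixel of a cube.

    Returns a new cube (non-tissue spectra untouched) and a per-pixel
    diagnostics table with columns row, col, rmse, n_iterations,
    converged.
    """
    mask = cube.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask is None:
        raise ValueError("no tissue mask available")
    loadings = build_mie_subspace(config, cube.wavenumbers)
    out = cube.absorbance.copy()
    records = []
    for r, c in zip(*np.nonzero(mask)):
        res = me_emsc_correct(
            cube.absorbance[r, c], config, cube.wavenumbers, loadings=loadings
        )
        out[r, c] = res.corrected
        records.append((r, c, res.rmse, res.n_iterations, res.converged))
    diag = pd.DataFrame(
        records, columns=["row", "col", "rmse", "n_iterations", "converged"]
    )
    corrected = HyperspectralCube(
        wavenumbers=cube.wavenumbers,
        absorbance=out,
        pixel_step=cube.pixel_step,
        mask=mask.copy(),
    )
    return corrected, diag


def quality_filter(
    diagnostics: pd.DataFrame,
    mask: np.ndarray,
    rmse_cap: float = 0.05,
) -> np.ndarray:
    """Drop pixels whose correction RMSE exceeds ``rmse_cap`` or that
    failed to converge; returns the updated tissue mask."""
    new_mask = np.asarray(mask, dtype=bool).copy()
    bad = diagnostics[(diagnostics["rmse"] > rmse_cap) | (~diagnostics["converged"])]
    new_mask[bad["row"].to_numpy(), bad["col"].to_numpy()] = False
    logger.info(
        "quality filter removed %d of %d tissue pixels (rmse cap %.3g)",
        len(bad),
        int(np.asarray(mask, bool).sum()),
        rmse_cap,
    )
    return new_mask
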