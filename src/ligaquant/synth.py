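"""Synthetic FTIR and qPLM phantoms with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes — tissue/background spectral contrast, collagen and
proteoglycan absorption bands, Mie scattering baseline distortion, and
spatially periodic fiber-orientation waves (crimp) — so that every
pipeline stage can be validated by parameter recovery without any real
tissue data.  All randomness flows from an explicit seed; identical
specs produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .ftir_preprocess import HyperspectralCube, vanhulst_extinction
from .qplm_crimp import OrientationImage
from .spectra import (
    SpectralPeak,
    build_spectrum,
    collagen_like_peaks,
    default_group_peaks,
    wavenumber_axis,
)

__all__ = [
    "MieDistortionParams",
    "PhantomSpecFTIR",
    "PhantomSpecQPLM",
    "FtirGroundTruth",
    "QplmGroundTruth",
    "apply_mie_distortion",
    "generate_ftir_phantom",
    "generate_qplm_phantom",
    "study_design",
]


# ---------------------------------------------------------------------------
# FTIR phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MieDistortionParams:
    """Forward Mie-scattering distortion: a convex mixture of the pure
    spectrum and a scaled van de Hulst extinction curve.

    ``distorted = (1 - w) * spectrum + w * scale * Q_ext(nu; n, d)``
    """

    n: float = 1.3
    d: float = 5.0  # micrometres
    mixing_weight: float = 0.3
    scale: float = 1.0  # absorbance units per unit extinction efficiency

    def __post_init__(self) -> None:
        if self.n <= 1:
            raise ValueError("refractive index n must exceed 1")
        if self.d <= 0:
            raise ValueError("sphere diameter d must be positive")
        if not 0 <= self.mixing_weight <= 1:
            raise ValueError("mixing_weight must lie in [0, 1]")


def apply_mie_distortion(
    spectrum: np.ndarray, params: MieDistortionParams, axis: np.ndarray
) -> np.ndarray:
    """Deterministically blend a spectrum with a Mie extinction curve."""
    q = vanhulst_extinction(axis, params.n, params.d)
    w = params.mixing_weight
    return (1.0 - w) * np.asarray(spectrum, float) + w * params.scale * q


@dataclass(frozen=True)
class FtirGroundTruth:
    """Configured truth stored with every FTIR phantom: the per-band
    true mean areas (a.u. * cm^-1), the tissue mask, and the per-pixel
    multiplicative jitter field."""

    band_areas: Mapping[str, float]
    mask: np.ndarray
    jitter: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_areas", MappingProxyType(dict(self.band_areas)))
        self.mask.flags.writeable = False
        self.jitter.flags.writeable = False


def _default_peaks_by_group() -> dict[str, list[SpectralPeak]]:
    return default_group_peaks()


@dataclass
class PhantomSpecFTIR:
    """Recipe for a synthetic FTIR cube.

    The default grid is a 64 x 64 desk-scale image (the instrument-scale
    ~230 x 200 raster is available by configuration), pixel pitch 6.5
    micrometres, axis 715-4000 cm^-1 at 4 cm^-1.  ``tissue_shape`` may
    be ``"ellipse"`` (centred, semi-axes 0.38 of the grid), ``"rect"``
    (centred half-size rectangle) or ``"all"``.  Per-pixel areas are the
    group truth times a multiplicative lognormal jitter of relative sd
    ``area_jitter_sd``.
    """

    grid: tuple[int, int] = (64, 64)
    pixel_step: float = 6.5
    axis: np.ndarray = field(default_factory=wavenumber_axis)
    tissue_shape: str = "ellipse"
    peaks_by_group: dict[str, list[SpectralPeak]] = field(
        default_factory=_default_peaks_by_group
    )
    baseline: tuple[float, ...] = ()
    noise_sd: float = 0.005
    area_jitter_sd: float = 0.05
    mie: MieDistortionParams | None = field(default_factory=MieDistortionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid[0] <= 0 or self.grid[1] <= 0:
            raise ValueError("grid must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.area_jitter_sd < 0:
            raise ValueError("area_jitter_sd must be >= 0")


def _tissue_mask(shape: str, grid: tuple[int, int]) -> np.ndarray:
    rows, cols = grid
    if shape == "all":
        return np.ones(grid, dtype=bool)
    if shape == "rect":
        m = np.zeros(grid, dtype=bool)
        m[rows // 4 : rows - rows // 4, cols // 4 : cols - cols // 4] = True
        return m
    if shape == "ellipse":
        r = (np.arange(rows) - (rows - 1) / 2) / (0.38 * rows)
        c = (np.arange(cols) - (cols - 1) / 2) / (0.38 * cols)
        return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0
    raise ValueError(f"unknown tissue_shape {shape!r}")


def generate_ftir_phantom(
    spec: PhantomSpecFTIR, group: str = "control"
) -> tuple[HyperspectralCube, FtirGroundTruth]:
    """Generate one sample's FTIR cube for an experimental group.

    Background pixels carry noise only; tissue pixels carry the group
    spectrum scaled by per-pixel lognormal jitter, then the Mie
    distortion, then i.i.d. Gaussian noise.  Ground truth records the
    configured per-band mean areas, the tissue mask and the jitter
    field.
    """
    if group not in spec.peaks_by_group:
        raise KeyError(
            f"unknown group {group!r}; phantom defines {sorted(spec.peaks_by_group)}"
        )
    rng = np.random.default_rng(spec.seed)
    peaks = spec.peaks_by_group[group]
    axis = np.asarray(spec.axis, float)
    pure = build_spectrum(peaks, spec.baseline, axis)
    mask = _tissue_mask(spec.tissue_shape, spec.grid)

    if spec.area_jitter_sd > 0:
        sigma = np.sqrt(np.log(1.0 + spec.area_jitter_sd**2))
        jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=spec.grid)
    else:
        jitter = np.ones(spec.grid)
    jitter = np.where(mask, jitter, 0.0)

    cube = jitter[..., None] * pure[None, None, :]
    if spec.mie is not None and spec.mie.mixing_weight > 0:
        q = vanhulst_extinction(axis, spec.mie.n, spec.mie.d)
        w = spec.mie.mixing_weight
        cube = np.where(
            mask[..., None], (1.0 - w) * cube + w * spec.mie.scale * q, cube
        )
    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, size=cube.shape)

    band_areas: dict[str, float] = {}
    for p in peaks:
        if p.name.startswith("carb"):
            band_areas["carbohydrate"] = band_areas.get("carbohydrate", 0.0) + p.area
        elif p.name:
            band_areas[p.name] = p.area
    truth = FtirGroundTruth(band_areas=band_areas, mask=mask.copy(), jitter=jitter)
    return (
        HyperspectralCube(
            wavenumbers=axis, absorbance=cube, pixel_step=spec.pixel_step, mask=mask.copy()
        ),
        truth,
    )


# ---------------------------------------------------------------------------
# qPLM phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QplmGroundTruth:
    crimp_angle_true: float
    crimp_length_true: float
    mean_fiber_angle_true: float
    out_of_plane_mask: np.ndarray

    def __post_init__(self) -> None:
        self.out_of_plane_mask.flags.writeable = False


@dataclass
class PhantomSpecQPLM:
    """Recipe for a synthetic orientation (slow-axis azimuth) image.

    The azimuth at pixel ``(row, col)`` is ``fiber_tilt`` plus a signed
    waveform along the column (longitudinal) direction whose limb angle
    is ``crimp_angle_true`` (degrees) and spatial period is
    ``crimp_length_true`` (micrometres), plus wrapped Gaussian noise.
    The triangular fiber waveform produces a square-wave angle signal
    alternating between +theta and -theta; the sinusoidal variant
    produces ``theta * sin(2 pi x / L)``.  The retardance channel is
    high everywhere except a low-retardance block of rows covering
    ``out_of_plane_fraction`` of the image area.
    """

    grid: tuple[int, int] = (640, 640)
    pixel_size: float = 1.0
    crimp_angle_true: float = 15.0
    crimp_length_true: float = 100.0
    fiber_tilt: float = 0.0
    waveform: str = "triangular"
    orientation_noise_sd: float = 2.0
    out_of_plane_fraction: float = 0.0
    phase: float = 0.25  # fraction of a period; 0.25 starts mid-limb
    retardance_high: float = 1.0
    retardance_low: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crimp_angle_true < 90:
            raise ValueError("crimp_angle_true must lie in [0, 90)")
        if self.crimp_length_true <= 0:
            raise ValueError("crimp_length_true must be positive")
        if self.crimp_length_true < 4 * self.pixel_size:
            raise ValueError(
                "crimp_length_true below 4 pixels: period is unresolvable"
            )
        if not 0 <= self.out_of_plane_fraction <= 1:
            raise ValueError("out_of_plane_fraction must lie in [0, 1]")
        if self.waveform not in ("triangular", "sinusoidal"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.orientation_noise_sd < 0:
            raise ValueError("orientation_noise_sd must be >= 0")


def _wave(spec: PhantomSpecQPLM, x_um: np.ndarray) -> np.ndarray:
    frac = (x_um / spec.crimp_length_true + spec.phase) % 1.0
    if spec.waveform == "triangular":
        return np.where(frac < 0.5, spec.crimp_angle_true, -spec.crimp_angle_true)
    return spec.crimp_angle_true * np.sin(2 * np.pi * frac)


def generate_qplm_phantom(
    spec: PhantomSpecQPLM,
) -> tuple[OrientationImage, QplmGroundTruth]:
    """Generate one orientation image plus its ground truth.

    The stored ``mean_fiber_angle_true`` is the mean of the noiseless
    azimuth field folded into [0, 90] degrees about the longitudinal
    axis — exactly what the orientation analysis should recover.
    """
    rows, cols = spec.grid
    x_um = np.arange(cols) * spec.pixel_size
    clean = spec.fiber_tilt + _wave(spec, x_um)
    azimuth = np.broadcast_to(clean, (rows, cols)).copy()

    folded = np.abs(azimuth) % 180.0
    folded = np.where(folded > 90.0, 180.0 - folded, folded)
    mean_true = float(folded.mean())

    if spec.orientation_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        azimuth = azimuth + rng.normal(0.0, spec.orientation_noise_sd, size=azimuth.shape)
    # azimuth is defined modulo 180; wrap into [-90, 90)
    azimuth = (azimuth + 90.0) % 180.0 - 90.0

    retardance = np.full(spec.grid, spec.retardance_high)
    n_low = int(round(spec.out_of_plane_fraction * rows))
    oop = np.zeros(spec.grid, dtype=bool)
    if n_low > 0:
        oop[:n_low, :] = True
        retardance[oop] = spec.retardance_low

    image = OrientationImage(
        azimuth=azimuth,
        retardance=retardance,
        pixel_size=spec.pixel_size,
        longitudinal_axis_angle=0.0,
    )
    truth = QplmGroundTruth(
        crimp_angle_true=spec.crimp_angle_true,
        crimp_length_true=spec.crimp_length_true,
        mean_fiber_angle_true=mean_true,
        out_of_plane_mask=oop,
    )
    return image, truth


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


def study_design(
    n_aclt_animals: int = 6,
    n_control_animals: int = 4,
    missing: tuple[tuple[str, str, str], ...] = (("A03", "ACLT", "LCL"),),
) -> "pd.DataFrame":
    """Sample metadata table for the emulated study design.

    Each operated animal contributes both knees (one surgically
    destabilised, one contralateral), each knee both collateral
    ligaments; control animals contribute both knees.  ``missing`` lists
    (animal, group, ligament) samples lost to histology, which with the
    defaults yields 11 LCL + 12 MCL operated-study ligaments and 16
    control ligaments.
    """
    import pandas as pd

    rows = []
    for i in range(n_aclt_animals):
        animal = f"A{i + 1:02d}"
        operated = "L" if i % 2 == 0 else "R"
        for knee in ("L", "R"):
            group = "ACLT" if knee == operated else "contralateral"
            for ligament in ("LCL", "MCL"):
                if (animal, group, ligament) in missing:
                    continue
                rows.append((animal, knee, ligament, group))
    for i in range(n_control_animals):
        animal = f"C{i + 1:02d}"
        for knee in ("L", "R"):
            for ligament in ("LCL", "MCL"):
                rows.append((animal, knee, ligament, "control"))
    df = pd.DataFrame(rows, columns=["animal_id", "knee", "ligament", "group"])
    df.insert(
        0,
        "sample_id",
        [
            f"{a}-{k}-{lig}"
            for a, k, lig in zip(df["animal_id"], df["knee"], df["ligament"])
        ],
    )
    return df
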