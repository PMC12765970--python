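"""Collagen fiber orientation and crimp morphometry from qPLM images.

Pixel values of a quantitative polarized light microscopy image are the
slow-axis azimuth, i.e. the local collagen fiber direction (defined
modulo 180 degrees).  Orientation analysis folds angles into [0, 90]
about the ligament's longitudinal axis; crimp analysis extracts a signed
1-D orientation profile along the longitudinal axis within rectangular
ROIs, partitions it into ascending/descending limbs at zero crossings,
and reports the crimp angle theta = (phi_upwards + phi_downwards) / 2
and the crimp length (mean valley-to-valley distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "OrientationImage",
    "ROI",
    "CrimpSegments",
    "CrimpMeasurement",
    "CrimpConfig",
    "CrimpDetectionError",
    "normalize_orientation",
    "mean_fiber_angle",
    "select_rois",
    "extract_orientation_profile",
    "detect_crimp",
    "crimp_angle",
    "crimp_length",
    "sample_crimp_summary",
]


class CrimpDetectionError(RuntimeError):
    """Raised when a profile does not contain a measurable crimp wave."""


@dataclass
class OrientationImage:
    """Slow-axis azimuth image (degrees, modulo 180) with an optional
    retardance channel; ``longitudinal_axis_angle`` is the image-frame
    direction of the ligament long axis (columns run along it when 0)."""

    azimuth: np.ndarray
    retardance: np.ndarray | None = None
    pixel_size: float = 1.0
    longitudinal_axis_angle: float = 0.0

    def __post_init__(self) -> None:
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        if self.azimuth.ndim != 2:
            raise ValueError("azimuth must be a 2-D image")
        if self.retardance is not None:
            self.retardance = np.asarray(self.retardance, dtype=float)
            if self.retardance.shape != self.azimuth.shape:
                raise ValueError("retardance shape differs from azimuth")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.azimuth.shape


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle (top-left row/col, height, width) with an
    in-plane flag; out-of-plane ROIs are excluded downstream."""

    row: int
    col: int
    height: int
    width: int
    in_plane: bool = True

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row, self.row + self.height),
            slice(self.col, self.col + self.width),
        )

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.row + self.height <= other.row
            or other.row + other.height <= self.row
            or self.col + self.width <= other.col
            or other.col + other.width <= self.col
        )


@dataclass
class CrimpSegments:
    """Limb decomposition of one ROI profile: mean ascending and
    descending limb angles (degrees) and valley positions (micrometres
    along the longitudinal axis, strictly increasing)."""

    phi_upwards: float
    phi_downwards: float
    valleys_um: np.ndarray
    limbs: list[tuple[int, int, int]]  # (start, stop, sign)


@dataclass
class CrimpMeasurement:
    """Per-sample crimp summary averaged over accepted ROIs."""

    theta: float
    crimp_length: float
    mean_fiber_angle: float
    n_rois: int
    per_roi: list[dict]
    excluded: bool = False


@dataclass(frozen=True)
class CrimpConfig:
    """Tunables of the crimp pipeline.  ROI geometry defaults to five
    50 x 500 pixel strips; ``edge_margin`` pixels at each limb end are
    excluded from limb-angle averaging so that smoothing ramps around
    zero crossings do not bias phi."""

    n_rois: int = 5
    roi_height: int = 50
    roi_width: int = 500
    smooth_window: int = 5
    min_run: int = 3
    edge_margin: int = 5
    low_retardance_threshold: float = 0.5
    max_low_fraction: float = 0.2


def _signed_deviation(image: OrientationImage) -> np.ndarray:
    """Azimuth minus longitudinal axis, wrapped to [-90, 90)."""
    dev = image.azimuth - image.longitudinal_axis_angle
    return (dev + 90.0) % 180.0 - 90.0


def normalize_orientation(image: OrientationImage) -> np.ndarray:
    """Fold azimuths into [0, 90] degrees relative to the longitudinal
    axis: 0 is parallel, 90 perpendicular; values beyond 90 reflect."""
    folded = np.abs(image.azimuth - image.longitudinal_axis_angle) % 180.0
    return np.where(folded > 90.0, 180.0 - folded, folded)


def mean_fiber_angle(
    image: OrientationImage, mask: np.ndarray | None = None
) -> float:
    """Arithmetic mean of normalized fiber angles over the mask."""
    normalized = normalize_orientation(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return float("nan")
        normalized = normalized[mask]
    return float(normalized.mean())


def select_rois(
    image: OrientationImage,
    n: int = 5,
    size: tuple[int, int] = (50, 500),
    low_retardance_threshold: float = 0.5,
    max_low_fraction: float = 0.2,
) -> list[ROI]:
    """Choose ``n`` non-overlapping ROIs maximizing mean retardance.

    Candidates lie on a coarse grid with stride equal to the ROI size
    and are ranked by mean retardance (row-major tie-break).  An ROI
    whose fraction of low-retardance pixels exceeds
    ``max_low_fraction`` is flagged ``in_plane=False``.  Without a
    retardance channel all candidates score equally and are assumed
    in-plane.  If the image holds fewer than ``n`` candidates, the
    available ones are returned with a warning.
    """
    height, width = size
    rows, cols = image.shape
    candidates = []
    for r in range(0, rows - height + 1, height):
        for c in range(0, cols - width + 1, width):
            if image.retardance is not None:
                patch = image.retardance[r : r + height, c : c + width]
                score = float(patch.mean())
                low_frac = float((patch < low_retardance_threshold).mean())
            else:
                score, low_frac = 1.0, 0.0
            candidates.append((-score, r, c, low_frac))
    candidates.sort()
    if len(candidates) < n:
        warnings.warn(
            f"image holds only {len(candidates)} candidate ROIs of size {size}; "
            f"requested {n}"
        )
    rois = [
        ROI(r, c, height, width, in_plane=low_frac <= max_low_fraction)
        for _, r, c, low_frac in candidates[:n]
    ]
    return rois


def extract_orientation_profile(
    image: OrientationImage, roi: ROI, smooth_window: int = 5
) -> np.ndarray:
    """Signed orientation profile along the longitudinal axis of an ROI.

    Per column, the signed deviation of azimuth from the longitudinal
    axis is averaged across the transverse (row) direction, then
    smoothed with a moving average.  Profile length equals ROI width.
    """
    rows, cols = image.shape
    if (
        roi.row < 0
        or roi.col < 0
        or roi.row + roi.height > rows
        or roi.col + roi.width > cols
    ):
        raise ValueError("ROI lies outside the image")
    dev = _signed_deviation(image)[roi.slices()]
    profile = dev.mean(axis=0)
    if smooth_window > 1:
        profile = uniform_filter1d(profile, size=smooth_window, mode="nearest")
    return profile


def _merge_short_runs(signs: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb sign runs shorter than ``min_run`` into their left
    neighbour (or right neighbour for a leading run)."""
    signs = signs.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(signs)
        if len(runs) <= 1:
            break
        lengths = [stop - start for start, stop, _ in runs]
        idx = int(np.argmin(lengths))
        if lengths[idx] < min_run:
            start, stop, _ = runs[idx]
            neighbour = runs[idx - 1][2] if idx > 0 else runs[idx + 1][2]
            signs[start:stop] = neighbour
            changed = True
    return signs


def _runs(signs: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            out.append((start, i, int(signs[start])))
            start = i
    return out


def detect_crimp(
    profile: np.ndarray,
    pixel_size: float,
    min_run: int = 3,
    edge_margin: int = 5,
) -> CrimpSegments:
    """Partition a signed orientation profile into crimp limbs.

    The profile is centred by subtracting the midrange of its 10th and
    90th percentiles — absorbing any constant fiber tilt without the
    duty-cycle bias a plain mean would pick up from a non-integer
    number of crimp periods — then sign runs shorter than ``min_run``
    are merged into neighbours, and the remaining alternating runs are
    the ascending (positive) and descending (negative) limbs.
    ``phi_upwards``/``phi_downwards`` are the means of |angle| over limb
    interiors (``edge_margin`` pixels trimmed at each end when the limb
    is long enough).  Valleys are descending-to-ascending zero
    crossings, localized by linear interpolation and reported in
    micrometres.  Raises :class:`CrimpDetectionError` when the profile
    has a single sign or fewer than two valleys.
    """
    profile = np.asarray(profile, dtype=float)
    lo_q, hi_q = np.quantile(profile, [0.1, 0.9])
    centred = profile - 0.5 * (lo_q + hi_q)
    signs = np.where(centred >= 0, 1, -1)
    if np.all(signs == signs[0]):
        raise CrimpDetectionError("profile has a single sign: no crimp wave")
    signs = _merge_short_runs(signs, min_run)
    runs = _runs(signs)
    if len(runs) < 2:
        raise CrimpDetectionError("profile has a single limb after run merging")

    up_vals, down_vals = [], []
    for start, stop, sign in runs:
        lo, hi = start, stop
        if hi - lo > 2 * edge_margin + 1:
            lo, hi = lo + edge_margin, hi - edge_margin
        vals = np.abs(centred[lo:hi])
        (up_vals if sign > 0 else down_vals).append(vals)
    phi_up = float(np.concatenate(up_vals).mean()) if up_vals else float("nan")
    phi_down = float(np.concatenate(down_vals).mean()) if down_vals else float("nan")

    valleys = []
    for (s0, e0, sign0), (s1, _, sign1) in zip(runs[:-1], runs[1:]):
        if sign0 < 0 and sign1 > 0:
            i = s1  # first sample of the ascending run
            y0, y1 = centred[i - 1], centred[i]
            frac = y0 / (y0 - y1) if y0 != y1 else 0.5
            valleys.append(((i - 1) + frac) * pixel_size)
    if len(valleys) < 2:
        raise CrimpDetectionError(
            f"only {len(valleys)} valley(s) found: need at least 2"
        )
    return CrimpSegments(
        phi_upwards=phi_up,
        phi_downwards=phi_down,
        valleys_um=np.asarray(valleys),
        limbs=runs,
    )


def crimp_angle(phi_up: float, phi_down: float) -> float:
    """Crimp angle theta = (phi_upwards + phi_downwards) / 2."""
    if phi_up < 0 or phi_down < 0:
        raise ValueError("limb angles must be non-negative")
    return 0.5 * (phi_up + phi_down)


def crimp_length(segments: CrimpSegments) -> float:
    """Mean valley-to-valley distance (micrometres); NaN below 2 valleys."""
    if segments.valleys_um.size < 2:
        return float("nan")
    return float(np.diff(segments.valleys_um).mean())


def sample_crimp_summary(
    image: OrientationImage, config: CrimpConfig = CrimpConfig()
) -> CrimpMeasurement:
    """Full per-sample crimp pipeline: ROI selection, profile
    extraction, crimp detection, and averaging over accepted ROIs.

    ROIs flagged out-of-plane or failing crimp detection are dropped;
    with zero accepted ROIs the sample is flagged ``excluded``.
    """
    rois = select_rois(
        image,
        n=config.n_rois,
        size=(config.roi_height, config.roi_width),
        low_retardance_threshold=config.low_retardance_threshold,
        max_low_fraction=config.max_low_fraction,
    )
    per_roi = []
    for roi in rois:
        if not roi.in_plane:
            continue
        profile = extract_orientation_profile(image, roi, config.smooth_window)
        try:
            seg = detect_crimp(
                profile,
                image.pixel_size,
                min_run=config.min_run,
                edge_margin=config.edge_margin,
            )
        except CrimpDetectionError:
            continue
        per_roi.append(
            {
                "roi": roi,
                "theta": crimp_angle(seg.phi_upwards, seg.phi_downwards),
                "crimp_length": crimp_length(seg),
                "phi_upwards": seg.phi_upwards,
                "phi_downwards": seg.phi_downwards,
            }
        )
    mfa = mean_fiber_angle(image)
    if not per_roi:
        return CrimpMeasurement(
            theta=float("nan"),
            crimp_length=float("nan"),
            mean_fiber_angle=mfa,
            n_rois=0,
            per_roi=[],
            excluded=True,
        )
    thetas = [r["theta"] for r in per_roi]
    lengths = [r["crimp_length"] for r in per_roi]
    return CrimpMeasurement(
        theta=float(np.mean(thetas)),
        crimp_length=float(np.nanmean(lengths)),
        mean_fiber_angle=mfa,
        n_rois=len(per_roi),
        per_roi=per_roi,
    )
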