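"""Choriocapillaris flow-void quantification.

The measurement chain, applied to a pair of en-face OCTA slabs (superficial
retinal plexus + choriocapillaris):

1.  binarize the superficial slab to a vessel mask (Otsu by default);
2.  dilate it (optionally) into a projection-artifact exclusion mask —
    superficial vessels cast spurious decorrelation onto the deeper slab;
3.  Gaussian-smooth the choriocapillaris image (sigma given in micrometres,
    20 um by default, converted via the scan's um/px scale);
4.  threshold at ``I_mean - eta * SD`` computed over the analyzable
    (non-artifact) pixels, population SD, eta = 1 by default;
5.  pixels strictly below the threshold and outside the artifact mask are
    flow voids; connected components (8-connectivity by default) give the
    void count and mean void size, and the void-pixel fraction of the
    analyzable area gives the area percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .angiogram import EnFaceAngiogram

__all__ = [
    "ThresholdParams",
    "BinaryMask",
    "FlowVoidResult",
    "DegenerateInputError",
    "binarize_superficial",
    "build_artifact_mask",
    "smooth",
    "compute_threshold",
    "segment_voids",
    "label_components",
    "summarize",
    "quantify",
    "qc_filter",
    "QC_FLAGS",
]


class DegenerateInputError(ValueError):
    """Raised when an input leaves the quantity undefined (e.g. no pixels)."""


@dataclass(frozen=True)
class ThresholdParams:
    """Parameters of the adaptive flow-void threshold ``I_mean - eta * SD``.

    eta
        Positive multiplier on the intensity SD.  Default 1, the value with
        the best reported repeatability for this choriocapillaris protocol.
    sigma_um
        SD of the speckle-reduction Gaussian, in micrometres (default 20;
        0 disables smoothing).
    strictly_below
        Void test is ``intensity < threshold`` when true (default); ties at
        the threshold are background.
    sd_mode
        "population" (divide by N, default) or "sample" (N - 1).
    stats_support
        Which pixels enter I_mean and SD: "analyzable" (outside the artifact
        mask, default) or "full" (whole image).
    """

    eta: float = 1.0
    sigma_um: float = 20.0
    strictly_below: bool = True
    sd_mode: Literal["population", "sample"] = "population"
    stats_support: Literal["analyzable", "full"] = "analyzable"

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.sigma_um < 0:
            raise ValueError(f"sigma_um must be >= 0, got {self.sigma_um}")
        if self.sd_mode not in ("population", "sample"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if self.stats_support not in ("analyzable", "full"):
            raise ValueError(f"unknown stats_support {self.stats_support!r}")


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid tagged with what it marks (vessel / artifact / void)."""

    values: np.ndarray
    kind: Literal["vessel", "artifact", "void"]
    warning: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FlowVoidResult:
    """Flow-void morphometry of one choriocapillaris scan.

    ``mean_size_px`` is NaN when no voids were detected.  The integer
    identity ``total_void_px = sum(component sizes)`` is exact;
    ``mean_size_px`` is its float quotient by ``count``.
    """

    area_pct: float
    mean_size_px: float
    count: int
    total_void_px: int
    label_map: np.ndarray
    threshold_value: float
    analyzable_px: int
    excluded_px: int
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_pct <= 100.0):
            raise ValueError(f"area_pct out of range: {self.area_pct}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


def binarize_superficial(
    superficial: EnFaceAngiogram,
    method: Literal["otsu", "mean_plus_k_sd"] = "otsu",
    k: float = 1.0,
) -> BinaryMask:
    """Threshold the superficial-plexus slab into a vessel mask.

    Pixels strictly above the threshold are vessels.  A constant image has no
    detectable vessels: the mask comes back empty with a warning note rather
    than raising.
    """
    img = superficial.intensities
    if np.ptp(img) == 0:
        return BinaryMask(
            values=np.zeros(img.shape, dtype=bool),
            kind="vessel",
            warning="constant superficial image: no vessels detectable",
        )
    if method == "otsu":
        thr = threshold_otsu(img)
    elif method == "mean_plus_k_sd":
        thr = img.mean() + k * img.std()
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(values=img > thr, kind="vessel")


def build_artifact_mask(
    vessel: BinaryMask, dilation_um: float = 0.0, um_per_px: float = 1.0
) -> BinaryMask:
    """Grow the vessel mask into the projection-artifact exclusion mask.

    The dilation radius is ``round(dilation_um / um_per_px)`` pixels of
    8-neighbourhood dilation; the default 0 um uses the vessel mask as-is.
    """
    if dilation_um < 0:
        raise ValueError(f"dilation_um must be >= 0, got {dilation_um}")
    if not (um_per_px > 0):
        raise ValueError(f"um_per_px must be positive, got {um_per_px}")
    n_iter = int(round(dilation_um / um_per_px))
    values = vessel.values
    if n_iter > 0 and values.any():
        values = ndimage.binary_dilation(
            values, structure=np.ones((3, 3), dtype=bool), iterations=n_iter
        )
    return BinaryMask(values=values.copy(), kind="artifact")


def smooth(cc: EnFaceAngiogram, params: ThresholdParams) -> EnFaceAngiogram:
    """Gaussian speckle smoothing; sigma converted from um to pixels.

    Uses reflect padding at the image border.  ``sigma_um = 0`` returns the
    input unchanged.
    """
    if params.sigma_um == 0:
        return cc
    sigma_px = params.sigma_um / cc.um_per_px
    smoothed = ndimage.gaussian_filter(cc.intensities, sigma=sigma_px, mode="reflect")
    return cc.with_intensities(smoothed)


def compute_threshold(
    smoothed: EnFaceAngiogram,
    artifact: BinaryMask | None,
    eta: float = 1.0,
    sd_mode: Literal["population", "sample"] = "population",
    stats_support: Literal["analyzable", "full"] = "analyzable",
) -> float:
    """Adaptive threshold ``I_mean - eta * SD`` over the analyzable pixels."""
    if not (eta > 0):
        raise ValueError(f"eta must be positive, got {eta}")
    img = smoothed.intensities
    if artifact is not None and stats_support == "analyzable":
        if artifact.shape != img.shape:
            raise ValueError("artifact mask dimensions do not match the image")
        vals = img[~artifact.values]
    else:
        vals = img.ravel()
    if vals.size < 2:
        raise DegenerateInputError(
            f"threshold needs >= 2 analyzable pixels, got {vals.size}"
        )
    ddof = 0 if sd_mode == "population" else 1
    return float(vals.mean() - eta * vals.std(ddof=ddof))


def segment_voids(
    smoothed: EnFaceAngiogram,
    threshold_value: float,
    artifact: BinaryMask | None = None,
    strictly_below: bool = True,
) -> BinaryMask:
    """Mark flow voids: below-threshold pixels outside the artifact mask."""
    if not np.isfinite(threshold_value):
        raise ValueError("threshold must be finite")
    img = smoothed.intensities
    if strictly_below:
        void = img < threshold_value
    else:
        void = img <= threshold_value
    if artifact is not None:
        if artifact.shape != img.shape:
            raise ValueError("artifact mask dimensions do not match the image")
        void &= ~artifact.values
    return BinaryMask(values=void, kind="void")


_STRUCTURE = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_components(
    void: BinaryMask | np.ndarray, connectivity: Literal[4, 8] = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component labelling of the void mask.

    Returns ``(label_map, sizes)`` with labels 1..K (0 = background) and
    ``sizes[k-1]`` the pixel count of component k.
    """
    if connectivity not in _STRUCTURE:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    values = void.values if isinstance(void, BinaryMask) else np.asarray(void, bool)
    label_map, n = ndimage.label(values, structure=_STRUCTURE[connectivity])
    sizes = np.bincount(label_map.ravel(), minlength=n + 1)[1:]
    return label_map, sizes


def summarize(
    label_map: np.ndarray,
    sizes: np.ndarray,
    analyzable_px: int,
    excluded_px: int,
    threshold_value: float,
    notes: Iterable[str] = (),
) -> FlowVoidResult:
    """Assemble the morphometry: area %, mean component size, count."""
    if analyzable_px <= 0:
        raise DegenerateInputError("analyzable_px must be positive")
    sizes = np.asarray(sizes, dtype=np.int64)
    count = int(sizes.size)
    total = int(sizes.sum())
    area_pct = 100.0 * total / analyzable_px
    mean_size = total / count if count > 0 else float("nan")
    return FlowVoidResult(
        area_pct=area_pct,
        mean_size_px=mean_size,
        count=count,
        total_void_px=total,
        label_map=label_map,
        threshold_value=float(threshold_value),
        analyzable_px=int(analyzable_px),
        excluded_px=int(excluded_px),
        notes=tuple(notes),
    )


def quantify(
    superficial: EnFaceAngiogram,
    cc: EnFaceAngiogram,
    params: ThresholdParams = ThresholdParams(),
    method: Literal["otsu", "mean_plus_k_sd"] = "otsu",
    k: float = 1.0,
    dilation_um: float = 0.0,
    connectivity: Literal[4, 8] = 8,
) -> FlowVoidResult:
    """Full pipeline: vessel mask -> artifact exclusion -> smooth ->
    adaptive threshold -> void components -> morphometry."""
    if superficial.shape != cc.shape:
        raise ValueError(
            f"image dimensions differ: superficial {superficial.shape}, "
            f"choriocapillaris {cc.shape}"
        )
    if abs(superficial.fov_mm - cc.fov_mm) > 1e-9:
        raise ValueError("superficial and choriocapillaris scans have different FOV")
    vessel = binarize_superficial(superficial, method=method, k=k)
    artifact = build_artifact_mask(vessel, dilation_um=dilation_um, um_per_px=cc.um_per_px)
    smoothed = smooth(cc, params)
    thr = compute_threshold(
        smoothed,
        artifact,
        eta=params.eta,
        sd_mode=params.sd_mode,
        stats_support=params.stats_support,
    )
    void = segment_voids(smoothed, thr, artifact, strictly_below=params.strictly_below)
    label_map, sizes = label_components(void, connectivity=connectivity)
    excluded = int(artifact.values.sum())
    analyzable = int(artifact.values.size - excluded)
    notes = []
    if vessel.warning:
        notes.append(vessel.warning)
    notes.append("components labelled on the artifact-excluded void mask")
    return summarize(label_map, sizes, analyzable, excluded, thr, notes=notes)


# --- scan quality-control filtering -----------------------------------------

QC_FLAGS = (
    "eye_disease",
    "missing",
    "poor_clarity",
    "local_weak_signal",
    "motion_artifact",
    "segmentation_failure",
)


def qc_filter(
    scan_records: Sequence[Mapping[str, object]],
) -> tuple[list[Mapping[str, object]], list[Mapping[str, object]], dict[str, int]]:
    """Apply manual quality-control flags to scan/participant records.

    Each record carries boolean flags from :data:`QC_FLAGS` (absent flags are
    treated as false; unknown flag-like keys are a schema error).  A record
    with any flag set is excluded once, attributed to the first matching
    reason in :data:`QC_FLAGS` order.  Returns ``(included, excluded,
    counts)`` where counts holds enrolled/analyzed totals and one entry per
    exclusion reason.
    """
    known = set(QC_FLAGS)
    included: list[Mapping[str, object]] = []
    excluded: list[Mapping[str, object]] = []
    counts: dict[str, int] = {flag: 0 for flag in QC_FLAGS}
    for rec in scan_records:
        flag_keys = {k for k, v in rec.items() if isinstance(v, (bool, np.bool_))}
        unknown = flag_keys - known
        if unknown:
            raise KeyError(f"unknown QC flag keys: {sorted(unknown)}")
        reason = next((f for f in QC_FLAGS if rec.get(f, False)), None)
        if reason is None:
            included.append(rec)
        else:
            excluded.append(rec)
            counts[reason] += 1
    counts["enrolled"] = len(scan_records)
    counts["analyzed"] = len(included)
    return included, excluded, counts
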