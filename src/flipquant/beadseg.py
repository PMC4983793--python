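"""Bead detection and shape filtering.

Agarose beads appear as bright, nearly circular objects on a dark
background. Each connected foreground object is measured and either
retained as a bead or rejected with a reason: non-spherical shapes are
likely contaminants, low-circularity but otherwise round-and-solid
shapes are merged bead clumps, and beads cut by the image border have
an incomplete rim. Clumps are rejected rather than split — the analysis
treats every bead as a single entity and simply excludes anything that
is not one.

The pipeline is: Gaussian smoothing, automatic (Otsu) or fixed
thresholding, hole filling, connected-component labelling, then
per-region shape scores. Thresholding runs on the smoothed image, but
all downstream intensity statistics are taken from the raw pixels so
the rim is not blurred away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .image import FluorImage

#: Rejection reasons a BeadRegion can carry.
REASONS = ("none", "too_small", "too_large", "non_spherical", "clump", "border")


@dataclass(frozen=True)
class SegParams:
    """Segmentation and shape-filter settings.

    Defaults were chosen for bright beads on a dark background: a
    digital disc measures circularity about 0.91 and solidity 0.91+
    regardless of radius, while elongated contaminants and merged bead
    pairs fall below the cuts (a 2:1 ellipse measures ~0.81 circularity
    but trips the aspect-ratio cut; a touching bead pair measures
    ~0.7 circularity).
    """

    smoothing_sigma: float = 2.0  # px
    threshold: float | None = None  # fixed intensity threshold; None = Otsu
    mask_smooth_sigma: float = 1.5  # px; 0 disables boundary smoothing
    min_radius: float = 5.0  # px, equivalent radius
    max_radius: float = 100.0
    min_circularity: float = 0.80  # 4*pi*area/perimeter^2
    min_solidity: float = 0.90
    max_aspect_ratio: float = 2.0  # major/minor axis; >= this is non-spherical
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_radius < self.max_radius:
            raise ValueError("need 0 < min_radius < max_radius")
        if not (0 <= self.min_circularity <= 1 and 0 <= self.min_solidity <= 1):
            raise ValueError("circularity/solidity thresholds must lie in [0, 1]")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass(frozen=True)
class BeadRegion:
    """One detected connected component with its shape scores."""

    label: int
    mask: np.ndarray = field(repr=False, compare=False)
    centroid: tuple[float, float]
    equivalent_radius: float  # sqrt(area / pi), px
    circularity: float
    solidity: float
    aspect_ratio: float
    retained: bool
    reason: str = "none"

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")
        if self.retained and self.reason != "none":
            raise ValueError("retained region cannot carry a rejection reason")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QCReport:
    """Bead-distribution quality report for one image.

    Mirrors the manual pre-check that the bead layer is a uniform
    monolayer: the flag is raised when too few beads survive filtering
    or when clumps dominate the field.
    """

    n_retained: int
    n_rejected: int
    area_fraction_covered: float
    rejections_by_reason: dict[str, int]
    monolayer_ok: bool
    flags: tuple[str, ...]


def _score_component(
    prop, shape: tuple[int, int], params: SegParams
) -> BeadRegion:
    area = prop.area
    perimeter = prop.perimeter
    circularity = 4 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    circularity = min(circularity, 1.05)  # discretisation can push past 1
    solidity = float(prop.solidity)
    minor = prop.axis_minor_length
    aspect = float(prop.axis_major_length / minor) if minor > 0 else np.inf
    radius = float(np.sqrt(area / np.pi))

    mask = np.zeros(shape, dtype=bool)
    minr, minc, maxr, maxc = prop.bbox
    mask[minr:maxr, minc:maxc] = prop.image

    touches_border = (
        minr == 0 or minc == 0 or maxr == shape[0] or maxc == shape[1]
    )

    reason = "none"
    if params.exclude_border and touches_border:
        reason = "border"
    elif radius < params.min_radius:
        reason = "too_small"
    elif radius > params.max_radius:
        reason = "too_large"
    elif (
        aspect >= params.max_aspect_ratio
        or solidity < params.min_solidity
    ):
        reason = "non_spherical"
    elif circularity < params.min_circularity:
        # round-ish and solid but ragged outline: merged beads
        reason = "clump"

    return BeadRegion(
        label=prop.label,
        mask=mask,
        centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
        equivalent_radius=radius,
        circularity=float(circularity),
        solidity=solidity,
        aspect_ratio=aspect,
        retained=reason == "none",
        reason=reason,
    )


def detect_beads(
    image: FluorImage, params: SegParams | None = None
) -> list[BeadRegion]:
    """Detect all foreground objects and score each as bead or reject.

    Returns every connected component, retained or not, ordered by
    centroid (row, then column) with labels renumbered in that order.
    A blank (constant) image yields an empty list; a fully saturated
    image yields an empty list with a warning.
    """
    params = params or SegParams()
    raw = image.pixels

    if image.is_saturated():
        warnings.warn("image is fully saturated; no beads detected", stacklevel=2)
        return []
    if np.ptp(raw) == 0:
        return []

    smoothed = (
        filters.gaussian(raw, sigma=params.smoothing_sigma, preserve_range=True)
        if params.smoothing_sigma > 0
        else raw
    )
    if params.threshold is not None:
        thr = params.threshold
    else:
        # lowest of the 3-class Otsu thresholds: separates background
        # from the dimmest foreground class, so a control bead's dark
        # rim (dimmer than the body, brighter than background) stays
        # inside the bead mask instead of being cut off
        try:
            thr = float(filters.threshold_multiotsu(smoothed, classes=3)[0])
        except ValueError:  # fewer than 3 distinct grey levels
            thr = float(filters.threshold_otsu(smoothed))
    # threshold the smoothed image for stability, but trim the mask to
    # raw pixels above threshold so smoothing cannot dilate the bead
    # boundary into the background (that halo would dilute the rim band)
    fg = (smoothed > thr) & (raw > thr)
    if not fg.any() or fg.all():
        return []
    fg = ndi.binary_fill_holes(fg)
    if params.mask_smooth_sigma > 0:
        # position-preserving boundary smoothing: the raw trim leaves a
        # ragged outline on low-contrast rims, which would wreck the
        # perimeter-based circularity score
        fg = filters.gaussian(fg.astype(float), sigma=params.mask_smooth_sigma) > 0.5
        fg = ndi.binary_fill_holes(fg)
        if not fg.any():
            return []

    labelled = measure.label(fg, connectivity=2)
    props = measure.regionprops(labelled)
    regions = [_score_component(p, raw.shape, params) for p in props]
    regions.sort(key=lambda r: r.centroid)
    return [
        BeadRegion(
            label=i,
            mask=r.mask,
            centroid=r.centroid,
            equivalent_radius=r.equivalent_radius,
            circularity=r.circularity,
            solidity=r.solidity,
            aspect_ratio=r.aspect_ratio,
            retained=r.retained,
            reason=r.reason,
        )
        for i, r in enumerate(regions, start=1)
    ]


def check_bead_distribution(
    regions: list[BeadRegion],
    image: FluorImage,
    min_retained: int = 3,
    max_clump_fraction: float = 0.5,
) -> QCReport:
    """Summarise detection results and flag suspect bead layers.

    The monolayer flag is lowered (``monolayer_ok`` False) when fewer
    than ``min_retained`` beads survive or when more than
    ``max_clump_fraction`` of all detected objects were rejected as
    clumps — both signs that the beads did not settle into the uniform
    single layer the assay expects.
    """
    retained = [r for r in regions if r.retained]
    rejected = [r for r in regions if not r.retained]
    by_reason: dict[str, int] = {}
    for r in rejected:
        by_reason[r.reason] = by_reason.get(r.reason, 0) + 1

    covered = (
        sum(r.area for r in regions) / image.pixels.size if regions else 0.0
    )

    flags: list[str] = []
    if len(retained) < min_retained:
        flags.append(f"too-few-beads ({len(retained)} < {min_retained})")
    if regions:
        clump_fraction = by_reason.get("clump", 0) / len(regions)
        if clump_fraction > max_clump_fraction:
            flags.append("clump-dominated")

    return QCReport(
        n_retained=len(retained),
        n_rejected=len(rejected),
        area_fraction_covered=float(covered),
        rejections_by_reason=by_reason,
        monolayer_ok=not flags,
        flags=tuple(flags),
    )
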