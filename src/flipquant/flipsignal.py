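"""Ring-versus-body quantification of FLIP signals.

A successful immunoprecipitation coats each agarose bead with captured
YFP-tagged protein, producing a bright ring at the bead perimeter. The
per-bead FLIP contribution is the mean intensity of that rim band minus
the mean intensity of the bead body inside it; the per-image signal is
the unweighted mean over retained beads, so it does not depend on how
many beads settled in the field. Subtracting the matched IgG-control
signal gives the corrected FLIP signal; control signals are typically
zero or negative (control beads are uniform or darker at the edge), so
the subtraction can raise the corrected value.

The legacy whole-image method — mean of all pixels in the test image
minus mean of all pixels in the control image — is kept for comparison;
it is deliberately sensitive to bead number and contaminants, which is
exactly the weakness the per-bead method removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .beadseg import BeadRegion
from .image import FluorImage


class DegenerateBeadError(ValueError):
    """Bead too small to hold a rim band, guard gap and non-empty body."""


class NoBeadsError(ValueError):
    """No usable bead in the image — distinct from a measured zero signal."""


@dataclass(frozen=True)
class RimParams:
    """Geometry of the rim band measured on each bead.

    The rim is the band of mask pixels within depth ``d`` of the bead
    boundary, with ``d = max(min_rim_px, rim_fraction * equivalent
    radius)``; the body is the mask eroded by ``d + guard_px``. The
    guard gap keeps partial-rim pixels out of the body estimate.
    """

    rim_fraction: float = 0.15  # of equivalent radius
    min_rim_px: float = 2.0
    guard_px: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.rim_fraction <= 0.5:
            raise ValueError("rim_fraction must lie in (0, 0.5]")
        if self.min_rim_px < 1 or self.guard_px < 0:
            raise ValueError("min_rim_px >= 1 and guard_px >= 0 required")

    def rim_depth(self, equivalent_radius: float) -> float:
        return max(self.min_rim_px, self.rim_fraction * equivalent_radius)


@dataclass(frozen=True)
class RingStats:
    """Per-bead rim and body means; ``difference`` is the bead's signal."""

    bead_label: int
    ring_mean: float
    body_mean: float
    difference: float
    ring_pixel_count: int
    body_pixel_count: int

    def __post_init__(self) -> None:
        if self.ring_pixel_count < 1 or self.body_pixel_count < 1:
            raise ValueError("ring and body must each contain >= 1 pixel")


@dataclass(frozen=True)
class FlipResult:
    """Image- or condition-level FLIP signal.

    ``raw_signal`` may be negative (dark-edged control beads).
    ``corrected_signal`` is present exactly when a control was
    subtracted. ``variability`` is the range (max - min) of replicate
    signals, the "var." reported for duplicate bead aliquots.
    """

    raw_signal: float
    n_beads: int
    control_signal: float | None = None
    corrected_signal: float | None = None
    replicate_values: tuple[float, ...] = field(default_factory=tuple)
    variability: float | None = None

    def __post_init__(self) -> None:
        if (self.control_signal is None) != (self.corrected_signal is None):
            raise ValueError("corrected_signal present iff control_signal present")


def ring_body_stats(
    image: FluorImage, bead: BeadRegion, params: RimParams | None = None
) -> RingStats:
    """Measure rim and body mean intensity for one retained bead.

    Pixels are assigned by Euclidean distance to the background: rim =
    mask pixels within the rim depth of the boundary, body = pixels
    deeper than rim depth + guard. Statistics use the raw image, never
    a smoothed copy. The difference is signed and never clipped.
    """
    params = params or RimParams()
    depth = ndi.distance_transform_edt(bead.mask)
    d = params.rim_depth(bead.equivalent_radius)
    ring = bead.mask & (depth <= d)
    body = depth > d + params.guard_px
    n_ring = int(ring.sum())
    n_body = int(body.sum())
    if n_ring < 1 or n_body < 1:
        raise DegenerateBeadError(
            f"bead {bead.label} (r={bead.equivalent_radius:.1f}px) too small "
            f"for rim depth {d:.1f}px + guard {params.guard_px}px"
        )
    ring_mean = float(image.pixels[ring].mean())
    body_mean = float(image.pixels[body].mean())
    return RingStats(
        bead_label=bead.label,
        ring_mean=ring_mean,
        body_mean=body_mean,
        difference=ring_mean - body_mean,
        ring_pixel_count=n_ring,
        body_pixel_count=n_body,
    )


def image_flip_signal(
    image: FluorImage,
    regions: list[BeadRegion],
    params: RimParams | None = None,
) -> FlipResult:
    """Aggregate per-bead differences into one image-level FLIP signal.

    The signal is the unweighted mean of the per-bead (rim - body)
    differences over retained beads, so duplicating a bead leaves it
    unchanged and large beads do not dominate. Raises
    :class:`NoBeadsError` when no retained, non-degenerate bead exists.
    """
    params = params or RimParams()
    diffs = []
    for bead in regions:
        if not bead.retained:
            continue
        try:
            diffs.append(ring_body_stats(image, bead, params).difference)
        except DegenerateBeadError:
            continue
    if not diffs:
        raise NoBeadsError("no retained, non-degenerate beads in image")
    return FlipResult(raw_signal=float(np.mean(diffs)), n_beads=len(diffs))


def control_subtract(test: FlipResult, control: FlipResult) -> FlipResult:
    """Subtract the IgG-control signal from the test signal.

    The corrected signal is ``test.raw - control.raw``; a negative
    control (dark-edged control beads) therefore increases the
    corrected value. Negative corrected signals are preserved here —
    zero-clipping is purely a reporting convention applied at the
    screening layer.
    """
    return replace(
        test,
        control_signal=control.raw_signal,
        corrected_signal=test.raw_signal - control.raw_signal,
    )


def replicate_merge(results: list[FlipResult]) -> FlipResult:
    """Merge replicate measurements of one condition.

    The merged signal is the mean of the replicate signals and the
    variability is their range (max - min), matching the "var." quoted
    for duplicate pictures of separate bead aliquots. Works on raw or
    corrected results; corrected results are merged on the corrected
    scale with the mean control carried along.
    """
    if not results:
        raise ValueError("replicate_merge needs at least one result")
    corrected = [r.corrected_signal is not None for r in results]
    if any(corrected) and not all(corrected):
        raise ValueError("cannot merge a mix of corrected and raw results")
    values = tuple(
        float(r.corrected_signal if r.corrected_signal is not None else r.raw_signal)
        for r in results
    )
    mean_signal = float(np.mean(values))
    n_beads = sum(r.n_beads for r in results)
    if all(corrected):
        mean_control = float(np.mean([r.control_signal for r in results]))
        return FlipResult(
            raw_signal=mean_signal + mean_control,
            n_beads=n_beads,
            control_signal=mean_control,
            corrected_signal=mean_signal,
            replicate_values=values,
            variability=float(max(values) - min(values)),
        )
    return FlipResult(
        raw_signal=mean_signal,
        n_beads=n_beads,
        replicate_values=values,
        variability=float(max(values) - min(values)),
    )


def global_mean_flip(test_image: FluorImage, control_image: FluorImage) -> float:
    """Legacy whole-image quantification.

    Returns (mean of all pixels in the test image) minus (mean of all
    pixels in the control image). Kept for comparison: it needs no
    segmentation but scales with bead count and is inflated by bright
    contaminants, the shortcomings the per-bead method was built to fix.
    """
    return float(test_image.pixels.mean() - control_image.pixels.mean())
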