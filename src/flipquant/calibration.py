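"""YFP standard-curve calibration and assay planning.

Lysate YFP content is read off a linear standard curve fitted to the
fluorescence of known amounts of recombinant YFP (typically a dilution
series from 0 to 500 ng) measured on the same plate as the samples.
From the ng/ul concentration, the planner checks the assay-format
rules: a large-volume reaction uses 700 ul of lysate and needs at
least 0.5 ng/ul of YFP (>= 350 ng total per IP); the miniaturised
format runs in 100-120 ul and needs at least 0.3 ng/ul. Exceeding the
minimum is recommended, particularly for weak antibodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateFitError(ValueError):
    """Standard-curve fit impossible (e.g. a single mass value)."""


class PlateMismatchError(ValueError):
    """Curve points from different plates/gain contexts mixed in one fit."""


#: (default volume ul, minimum concentration ng/ul, volume range) per format.
ASSAY_FORMATS: dict[str, dict] = {
    "large": {"default_volume": 700.0, "min_concentration": 0.5, "volume_range": (700.0, 700.0)},
    "mini": {"default_volume": 120.0, "min_concentration": 0.3, "volume_range": (100.0, 120.0)},
}


@dataclass(frozen=True)
class StandardCurve:
    """OLS line ``fluorescence = slope * mass_ng + intercept``."""

    points: tuple[tuple[float, float], ...]  # (mass ng, fluorescence)
    slope: float
    intercept: float
    r_squared: float
    mass_range: tuple[float, float]
    plate_id: str | None = None
    negative_slope: bool = False


@dataclass(frozen=True)
class LysateQuant:
    """YFP concentration of one lysate reading.

    ``extrapolated`` flags a fluorescence implying a mass outside the
    fitted range of the curve; ``floored`` flags a reading below the
    curve intercept whose implied (negative) mass was clamped to zero.
    """

    well_fluorescence: float
    mass_ng: float
    measured_volume_ul: float
    concentration_ng_per_ul: float
    extrapolated: bool = False
    floored: bool = False


@dataclass(frozen=True)
class AssayPlan:
    """Feasibility verdict for one assay format and lysate."""

    assay_format: str
    concentration_ng_per_ul: float
    volume_ul: float
    total_yfp_ng: float
    min_concentration_ng_per_ul: float
    feasible: bool
    verdict: str


def fit_standard_curve(
    points: list[tuple[float, float]] | np.ndarray,
    plate_ids: list[str] | None = None,
) -> StandardCurve:
    """Fit the linear standard curve by ordinary least squares.

    ``points`` are (mass ng, fluorescence) pairs, blank (mass 0) wells
    included as ordinary points. If ``plate_ids`` is given, all points
    must come from the same plate — a curve must share its gain context
    with the samples it will quantify.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateFitError("need >= 2 (mass, fluorescence) points")
    if not np.all(np.isfinite(pts)):
        raise DegenerateFitError("non-finite values in standard-curve points")
    masses, fluor = pts[:, 0], pts[:, 1]
    if np.unique(masses).size < 2:
        raise DegenerateFitError("all masses identical; cannot fit a line")
    plate_id = None
    if plate_ids is not None:
        unique = set(plate_ids)
        if len(unique) > 1:
            raise PlateMismatchError(
                f"curve points span plates {sorted(unique)}; fit one plate at a time"
            )
        plate_id = next(iter(unique))

    fit = stats.linregress(masses, fluor)
    negative = fit.slope <= 0
    if negative:
        import warnings

        warnings.warn(
            f"standard curve has non-positive slope ({fit.slope:.3g}); "
            "check fluorophore or plate orientation",
            stacklevel=2,
        )
    return StandardCurve(
        points=tuple(map(tuple, pts)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mass_range=(float(masses.min()), float(masses.max())),
        plate_id=plate_id,
        negative_slope=negative,
    )


def quantify_lysate(
    fluorescence: float,
    curve: StandardCurve,
    measured_volume_ul: float = 10.0,
) -> LysateQuant:
    """Invert the standard curve to ng YFP per ul of lysate.

    ``mass = (fluorescence - intercept) / slope``; concentration is
    mass over the measured volume (default 10 ul, the standard reading
    volume). Masses outside the fitted range are flagged as
    extrapolated; negative implied masses are floored at zero and
    flagged.
    """
    if curve.slope == 0:
        raise DegenerateFitError("curve slope is zero; cannot invert")
    if measured_volume_ul <= 0:
        raise ValueError("measured_volume_ul must be > 0")
    mass = (fluorescence - curve.intercept) / curve.slope
    floored = mass < 0
    extrapolated = not (curve.mass_range[0] <= mass <= curve.mass_range[1])
    if floored:
        mass = 0.0
    return LysateQuant(
        well_fluorescence=float(fluorescence),
        mass_ng=float(mass),
        measured_volume_ul=float(measured_volume_ul),
        concentration_ng_per_ul=float(mass / measured_volume_ul),
        extrapolated=extrapolated,
        floored=floored,
    )


def plan_assay(
    concentration_ng_per_ul: float,
    assay_format: str = "large",
    volume_ul: float | None = None,
) -> AssayPlan:
    """Check whether a lysate supports a FLIP at the given format.

    Total YFP is concentration times volume. The verdict compares the
    concentration with the format minimum (large: 0.5 ng/ul in 700 ul,
    i.e. >= 350 ng per IP; mini: 0.3 ng/ul in 100-120 ul) and, when the
    minimum is only just met, echoes the recommendation to use more.
    """
    if concentration_ng_per_ul < 0:
        raise ValueError("concentration must be >= 0")
    try:
        fmt = ASSAY_FORMATS[assay_format]
    except KeyError:
        raise ValueError(
            f"unknown assay format {assay_format!r}; expected one of {sorted(ASSAY_FORMATS)}"
        ) from None
    volume = fmt["default_volume"] if volume_ul is None else float(volume_ul)
    total = concentration_ng_per_ul * volume
    min_conc = fmt["min_concentration"]
    feasible = concentration_ng_per_ul >= min_conc
    if not feasible:
        verdict = (
            f"infeasible: {concentration_ng_per_ul:g} ng/ul is below the "
            f"{assay_format}-format minimum of {min_conc:g} ng/ul"
        )
    elif concentration_ng_per_ul == min_conc:
        verdict = (
            "minimum met; using more YFP-protein than the minimum is "
            "recommended, especially for weak-affinity antibodies"
        )
    else:
        verdict = "feasible"
    return AssayPlan(
        assay_format=assay_format,
        concentration_ng_per_ul=float(concentration_ng_per_ul),
        volume_ul=volume,
        total_yfp_ng=float(total),
        min_concentration_ng_per_ul=min_conc,
        feasible=feasible,
        verdict=verdict,
    )
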