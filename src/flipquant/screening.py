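"""Antibody-screening reports: IP-efficiency index, calls, concordance.

An antibody screen pairs each candidate's corrected FLIP signal with a
conventional immunoprecipitation/immunoblot (IP/IB) readout. The IP
efficiency index ("% tot. lysate") scales the immunoprecipitated band
and the input-lysate band to whole-reaction equivalents before taking
their ratio, so it is invariant to how much of each was loaded on the
gel and to overall gel exposure. FLIP calls are positive when the
corrected signal exceeds zero; for display, negative signals are
reported as zero. Signal tiers annotate the empirical separation seen
between true and false FLIP positives: most true positives score above
1.0 while false positives stay below 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TIER_LOW = 0.6
TIER_HIGH = 1.0


class UndefinedIndexError(ValueError):
    """% tot. lysate undefined (no detectable input band)."""


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (fewer than 3 pairs or zero variance)."""


@dataclass(frozen=True)
class BlotMeasurement:
    """Band intensities with the fraction of each reaction loaded.

    ``ip_fraction_loaded`` is the fraction of the whole IP reaction run
    on the gel; ``input_fraction_of_lysate`` is the fraction of the
    total lysate loaded in the input lane. Both are required — the
    loaded-fraction correction is explicit, never guessed.
    """

    ip_band_intensity: float
    input_band_intensity: float
    ip_fraction_loaded: float
    input_fraction_of_lysate: float

    def __post_init__(self) -> None:
        if self.ip_band_intensity < 0 or self.input_band_intensity < 0:
            raise ValueError("band intensities must be >= 0")
        for f in (self.ip_fraction_loaded, self.input_fraction_of_lysate):
            if not 0 < f <= 1:
                raise ValueError("loaded fractions must lie in (0, 1]")


@dataclass(frozen=True)
class ScreenRecord:
    """One antibody's screen outcome.

    ``flip_signal`` is the signed corrected FLIP value;
    ``flip_reported`` clips negatives to zero for display. ``tier`` is
    high (> 1.0), low (< 0.6) or intermediate. ``agreement`` is filled
    by :func:`classify` when an IP/IB call is present: concordant,
    flip_false_positive or flip_false_negative.
    """

    antibody_id: str
    target: str
    flip_signal: float
    percent_total_lysate: float | None = None
    ipib_call: str | None = None  # "positive" | "negative" | None
    flip_call: str = "negative"
    flip_reported: float = 0.0
    tier: str = "intermediate"
    agreement: str | None = None
    index_over_100: bool = False


def percent_total_lysate(m: BlotMeasurement) -> tuple[float, bool]:
    """IP efficiency as % of the total lysate's target protein captured.

    Both bands are first scaled to whole-reaction equivalents
    (intensity / fraction loaded); the index is 100 x their ratio.
    Returns the index and a flag set when it exceeds 100 % (possible
    with densitometry noise; reported, not clamped). Raises
    :class:`UndefinedIndexError` when the input band is zero.
    """
    if m.input_band_intensity == 0:
        raise UndefinedIndexError("input band intensity is zero; index undefined")
    whole_ip = m.ip_band_intensity / m.ip_fraction_loaded
    whole_input = m.input_band_intensity / m.input_fraction_of_lysate
    index = 100.0 * whole_ip / whole_input
    return float(index), index > 100.0


def classify(
    antibody_id: str,
    target: str,
    flip_signal: float,
    percent_index: float | None = None,
    ipib_call: str | None = None,
) -> ScreenRecord:
    """Build a fully-annotated screen record for one antibody.

    The FLIP call is positive iff the signed signal exceeds zero. When
    an IP/IB call is supplied the record is labelled concordant,
    flip_false_positive (FLIP positive, IP/IB negative) or
    flip_false_negative (FLIP negative, IP/IB positive).
    """
    if ipib_call not in (None, "positive", "negative"):
        raise ValueError(f"ipib_call must be positive/negative/None, got {ipib_call!r}")
    flip_call = "positive" if flip_signal > 0 else "negative"
    if flip_signal > TIER_HIGH:
        tier = "high"
    elif flip_signal < TIER_LOW:
        tier = "low"
    else:
        tier = "intermediate"
    agreement = None
    if ipib_call is not None:
        if flip_call == ipib_call:
            agreement = "concordant"
        elif flip_call == "positive":
            agreement = "flip_false_positive"
        else:
            agreement = "flip_false_negative"
    return ScreenRecord(
        antibody_id=antibody_id,
        target=target,
        flip_signal=float(flip_signal),
        percent_total_lysate=percent_index,
        ipib_call=ipib_call,
        flip_call=flip_call,
        flip_reported=max(float(flip_signal), 0.0),
        tier=tier,
        agreement=agreement,
        index_over_100=percent_index is not None and percent_index > 100.0,
    )


@dataclass(frozen=True)
class ConcordanceSummary:
    """2x2 agreement between FLIP and IP/IB calls over a screen."""

    tp: int  # FLIP positive, IP/IB positive
    tn: int  # FLIP negative, IP/IB negative
    fp: int  # FLIP positive, IP/IB negative
    fn: int  # FLIP negative, IP/IB positive

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def concordance_rate(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def fraction_by_class(self) -> dict[str, float]:
        n = self.total
        return {"tp": self.tp / n, "tn": self.tn / n, "fp": self.fp / n, "fn": self.fn / n}


def concordance(records: list[ScreenRecord]) -> ConcordanceSummary:
    """Tally FLIP-vs-IP/IB agreement over a set of screened antibodies.

    Every record must carry both calls. The concordance rate is
    (TP + TN) / total — the screen's success rate at predicting IP/IB
    behaviour.
    """
    if not records:
        raise ValueError("concordance needs at least one record")
    tp = tn = fp = fn = 0
    for r in records:
        if r.ipib_call not in ("positive", "negative"):
            raise ValueError(f"record {r.antibody_id} lacks an IP/IB call")
        if r.flip_call == "positive":
            if r.ipib_call == "positive":
                tp += 1
            else:
                fp += 1
        else:
            if r.ipib_call == "negative":
                tn += 1
            else:
                fn += 1
    return ConcordanceSummary(tp=tp, tn=tn, fp=fp, fn=fn)


def correlate(records: list[ScreenRecord]) -> tuple[float, int]:
    """Squared Pearson correlation of FLIP signal vs % tot. lysate.

    Records missing either value are dropped (their count is returned
    alongside R^2). Needs >= 3 complete pairs with variance in both
    variables.
    """
    pairs = [
        (r.flip_signal, r.percent_total_lysate)
        for r in records
        if r.percent_total_lysate is not None
    ]
    dropped = len(records) - len(pairs)
    if len(pairs) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 complete (FLIP, %tot.lysate) pairs, have {len(pairs)}"
        )
    x, y = np.asarray(pairs, dtype=float).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2), dropped


def screen_report(records: list[ScreenRecord]) -> dict:
    """Aggregate a screen into a summary dict (counts, rate, tiers).

    R^2 and the confusion summary are included when computable; the
    report never fails just because a screen is partial.
    """
    report: dict = {"n_antibodies": len(records)}
    with_calls = [r for r in records if r.ipib_call in ("positive", "negative")]
    if with_calls:
        summary = concordance(with_calls)
        report["confusion"] = {
            "tp": summary.tp,
            "tn": summary.tn,
            "fp": summary.fp,
            "fn": summary.fn,
        }
        report["concordance_rate"] = summary.concordance_rate
    try:
        r2, dropped = correlate(records)
        report["r_squared"] = r2
        report["n_dropped_from_correlation"] = dropped
    except UndefinedCorrelationError:
        pass
    report["tiers"] = {
        t: sum(1 for r in records if r.tier == t)
        for t in ("high", "intermediate", "low")
    }
    return report
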