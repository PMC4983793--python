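"""End-to-end orchestration: manifest in, quantified conditions out.

For each condition the pipeline detects beads in every picture, runs
the monolayer QC check, measures per-bead rim/body statistics, merges
replicate pictures (mean signal, range as variability), subtracts the
matched IgG control, and writes per-bead and per-condition tables.
Outputs carry the configuration hash and package version so a result
can always be traced to the exact settings that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .beadseg import check_bead_distribution, detect_beads
from .flipsignal import (
    FlipResult,
    NoBeadsError,
    control_subtract,
    image_flip_signal,
    replicate_merge,
    ring_body_stats,
)
from .io import Config, ManifestRow, read_image, read_manifest

log = logging.getLogger("flipquant")


@dataclass(frozen=True)
class ConditionResult:
    """Quantified outcome for one condition."""

    condition: str
    result: FlipResult
    control_available: bool
    n_test_images: int
    n_control_images: int
    warnings: tuple[str, ...] = ()


def _quantify_images(
    rows: list[ManifestRow], config: Config, bead_rows: list[dict]
) -> tuple[list[FlipResult], list[str]]:
    """Quantify each picture of one condition/role group."""
    seg = config.segmentation.to_params()
    rim = config.rim.to_params()
    results: list[FlipResult] = []
    warnings: list[str] = []
    for row in sorted(rows, key=lambda r: r.replicate):
        image = read_image(row.path)
        regions = detect_beads(image, seg)
        qc = check_bead_distribution(regions, image)
        log.info(
            "%s (%s rep %d): %d retained, %d rejected %s",
            row.condition,
            row.role,
            row.replicate,
            qc.n_retained,
            qc.n_rejected,
            dict(qc.rejections_by_reason),
        )
        if not qc.monolayer_ok:
            warnings.append(f"{row.path.name}: QC flags {', '.join(qc.flags)}")
        for bead in regions:
            entry = {
                "condition": row.condition,
                "role": row.role,
                "replicate": row.replicate,
                "image": str(row.path),
                "bead_label": bead.label,
                "centroid_row": bead.centroid[0],
                "centroid_col": bead.centroid[1],
                "equivalent_radius": bead.equivalent_radius,
                "circularity": bead.circularity,
                "solidity": bead.solidity,
                "retained": bead.retained,
                "reason": bead.reason,
                "ring_mean": None,
                "body_mean": None,
                "difference": None,
            }
            if bead.retained:
                try:
                    stats = ring_body_stats(image, bead, rim)
                    entry.update(
                        ring_mean=stats.ring_mean,
                        body_mean=stats.body_mean,
                        difference=stats.difference,
                    )
                except Exception:  # degenerate bead; recorded but unusable
                    entry["reason"] = "degenerate"
            bead_rows.append(entry)
        try:
            results.append(image_flip_signal(image, regions, rim))
        except NoBeadsError:
            warnings.append(f"{row.path.name}: no usable beads")
    return results, warnings


def run_pipeline(
    manifest_path: str | Path,
    config: Config | None = None,
    out_dir: str | Path | None = None,
) -> list[ConditionResult]:
    """Run the full analysis for every condition in a manifest.

    Conditions lacking a control are reported raw-only with a warning,
    never silently zero-subtracted. When ``out_dir`` is given, writes
    ``beads.csv`` (every detected object) and ``conditions.csv`` /
    ``conditions.json`` (per-condition FLIP results with provenance).
    """
    config = config or Config()
    rows = read_manifest(manifest_path)
    bead_rows: list[dict] = []
    outcomes: list[ConditionResult] = []

    by_condition: dict[str, list[ManifestRow]] = {}
    for row in rows:
        by_condition.setdefault(row.condition, []).append(row)

    for condition in sorted(by_condition):
        group = by_condition[condition]
        test_rows = [r for r in group if r.role == "test"]
        control_rows = [r for r in group if r.role == "control"]
        test_results, warn = _quantify_images(test_rows, config, bead_rows)
        control_results, cwarn = _quantify_images(control_rows, config, bead_rows)
        warnings = warn + cwarn
        if not test_results:
            raise NoBeadsError(f"condition {condition!r}: no usable test image")
        merged_test = replicate_merge(test_results)
        if control_results:
            merged_control = replicate_merge(control_results)
            final = control_subtract(merged_test, merged_control)
            # keep replicate bookkeeping from the test side
            final = FlipResult(
                raw_signal=final.raw_signal,
                n_beads=final.n_beads,
                control_signal=final.control_signal,
                corrected_signal=final.corrected_signal,
                replicate_values=merged_test.replicate_values,
                variability=merged_test.variability,
            )
            control_available = True
        else:
            final = merged_test
            control_available = False
            warnings.append(f"condition {condition!r}: no control; raw signal only")
            log.warning("condition %s has no IgG control; reporting raw signal", condition)
        outcomes.append(
            ConditionResult(
                condition=condition,
                result=final,
                control_available=control_available,
                n_test_images=len(test_rows),
                n_control_images=len(control_rows),
                warnings=tuple(warnings),
            )
        )

    if out_dir is not None:
        _write_outputs(outcomes, bead_rows, config, Path(out_dir))
    return outcomes


def _write_outputs(
    outcomes: list[ConditionResult],
    bead_rows: list[dict],
    config: Config,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.digest(), "version": __version__}

    beads = pd.DataFrame(bead_rows)
    for key, value in provenance.items():
        beads[key] = value
    beads.to_csv(out_dir / "beads.csv", index=False)

    rows = []
    for o in outcomes:
        rows.append(
            {
                "condition": o.condition,
                "raw_signal": o.result.raw_signal,
                "control_signal": o.result.control_signal,
                "corrected_signal": o.result.corrected_signal,
                "n_beads": o.result.n_beads,
                "variability": o.result.variability,
                "control_available": o.control_available,
                "n_test_images": o.n_test_images,
                "n_control_images": o.n_control_images,
                "warnings": "; ".join(o.warnings),
                **provenance,
            }
        )
    conditions = pd.DataFrame(rows)
    conditions.to_csv(out_dir / "conditions.csv", index=False)
    (out_dir / "conditions.json").write_text(
        json.dumps({"provenance": provenance, "conditions": rows}, indent=2, default=str)
    )
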