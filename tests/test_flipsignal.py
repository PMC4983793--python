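"""Ring/body quantification: per-pixel oracle, aggregation, controls."""

import numpy as np
import pytest

from flipquant import (
    BeadSpec,
    FlipResult,
    FluorImage,
    RimParams,
    SceneSpec,
    control_subtract,
    detect_beads,
    global_mean_flip,
    image_flip_signal,
    render_scene,
    replicate_merge,
    ring_body_stats,
)
from flipquant.flipsignal import DegenerateBeadError, NoBeadsError

from conftest import distance_masks, ringed_bead


def one_retained(image):
    regions = [r for r in detect_beads(image) if r.retained]
    assert len(regions) == 1
    return regions[0]


class TestRingBodyStats:
    def test_matches_per_pixel_brute_force_exactly(self, single_bead_scene):
        """Measured means equal those of the distance-mask oracle."""
        _, image, _ = single_bead_scene
        stats = ring_body_stats(image, one_retained(image))
        rim, body = distance_masks(image.shape, (64, 64), 20.0, 3.0)
        assert stats.ring_mean == image.pixels[rim].mean() == 1000.0
        assert stats.body_mean == image.pixels[body].mean() == 200.0
        assert stats.difference == 800.0
        assert stats.difference == stats.ring_mean - stats.body_mean

    @pytest.mark.parametrize("rim_fraction", [0.1, 0.15, 0.3])
    def test_uniform_bead_gives_zero_for_any_params(self, rim_fraction):
        spec = SceneSpec(
            image_shape=(96, 96),
            background_intensity=10.0,
            beads=(BeadSpec((48, 48), 20, body_intensity=500.0),),
        )
        image, _ = render_scene(spec)
        stats = ring_body_stats(
            image, one_retained(image), RimParams(rim_fraction=rim_fraction)
        )
        assert stats.difference == 0.0

    def test_dark_edged_control_bead_is_negative(self):
        spec = SceneSpec(
            image_shape=(96, 96),
            background_intensity=10.0,
            beads=(BeadSpec((48, 48), 20, body_intensity=300, rim_intensity=100, rim_thickness=3),),
        )
        image, _ = render_scene(spec)
        stats = ring_body_stats(image, one_retained(image))
        assert stats.difference == -200.0

    def test_ring_and_body_pixels_disjoint_and_nonempty(self, single_bead_scene):
        _, image, _ = single_bead_scene
        bead = one_retained(image)
        stats = ring_body_stats(image, bead)
        assert stats.ring_pixel_count >= 1 and stats.body_pixel_count >= 1
        assert stats.ring_pixel_count + stats.body_pixel_count <= bead.area

    def test_bead_too_small_for_rim_raises_named_error(self, single_bead_scene):
        _, image, _ = single_bead_scene
        bead = one_retained(image)
        with pytest.raises(DegenerateBeadError, match=str(bead.label)):
            ring_body_stats(image, bead, RimParams(rim_fraction=0.5, min_rim_px=19, guard_px=5))


class TestImageSignal:
    def test_mean_of_per_bead_differences(self):
        """One ringed (800) + one uniform (0) bead average to 400."""
        beads = (ringed_bead((60, 60)), BeadSpec((60, 160), 20, body_intensity=500.0))
        spec = SceneSpec(image_shape=(224, 224), background_intensity=10.0, beads=beads)
        image, _ = render_scene(spec)
        result = image_flip_signal(image, detect_beads(image))
        assert result.raw_signal == 400.0
        assert result.n_beads == 2

    def test_bead_count_invariance(self):
        """Duplicating identical beads leaves the signal unchanged."""
        few = tuple(ringed_bead((60, 60 + 60 * i)) for i in range(2))
        many = tuple(
            ringed_bead((60 + 120 * j, 60 + 60 * i)) for j in range(3) for i in range(4)
        )
        signals = []
        for beads in (few, many):
            spec = SceneSpec(image_shape=(360, 300), background_intensity=10.0, beads=beads)
            image, _ = render_scene(spec)
            signals.append(image_flip_signal(image, detect_beads(image)).raw_signal)
        assert abs(signals[0] - signals[1]) < 1e-9

    def test_blank_image_raises_no_beads(self):
        image = FluorImage(np.full((64, 64), 10.0))
        with pytest.raises(NoBeadsError):
            image_flip_signal(image, detect_beads(image))

    def test_signal_monotone_in_rim_intensity(self):
        signals = []
        for rim in (400.0, 700.0, 1000.0, 1300.0):
            spec = SceneSpec(
                image_shape=(128, 128),
                background_intensity=10.0,
                beads=(ringed_bead((64, 64), rim_intensity=rim),),
            )
            image, _ = render_scene(spec)
            signals.append(image_flip_signal(image, detect_beads(image)).raw_signal)
        assert all(b > a for a, b in zip(signals, signals[1:]))

    def test_dilution_series_linearity(self):
        """Signal vs rim intensity (YFP-load surrogate) is linear, R^2 >= 0.95."""
        loads = np.array([100.0, 200.0, 400.0, 800.0, 1600.0])
        signals = []
        for load in loads:
            spec = SceneSpec(
                image_shape=(128, 128),
                background_intensity=10.0,
                beads=(ringed_bead((64, 64), body_intensity=50.0, rim_intensity=50.0 + load),),
            )
            image, _ = render_scene(spec)
            signals.append(image_flip_signal(image, detect_beads(image)).raw_signal)
        r = np.corrcoef(loads, signals)[0, 1]
        assert r**2 >= 0.95


class TestControlSubtract:
    def test_negative_control_raises_corrected_signal(self):
        corrected = control_subtract(
            FlipResult(raw_signal=800.0, n_beads=5),
            FlipResult(raw_signal=-50.0, n_beads=5),
        )
        assert corrected.corrected_signal == 850.0
        assert corrected.control_signal == -50.0

    def test_identical_test_and_control_give_zero(self):
        r = FlipResult(raw_signal=1.5, n_beads=3)
        assert control_subtract(r, r).corrected_signal == 0.0

    def test_negative_corrected_preserved_not_clipped(self):
        corrected = control_subtract(
            FlipResult(raw_signal=0.3, n_beads=3),
            FlipResult(raw_signal=0.5, n_beads=3),
        )
        assert corrected.corrected_signal == pytest.approx(-0.2)

    def test_absent_control_is_explicit_state(self):
        raw = FlipResult(raw_signal=800.0, n_beads=5)
        assert raw.control_signal is None and raw.corrected_signal is None
        with pytest.raises(ValueError):
            FlipResult(raw_signal=1.0, n_beads=1, corrected_signal=1.0)


class TestReplicateMerge:
    def test_mean_and_range_of_duplicates(self):
        merged = replicate_merge(
            [FlipResult(raw_signal=790.0, n_beads=4), FlipResult(raw_signal=810.0, n_beads=6)]
        )
        assert merged.raw_signal == 800.0
        assert merged.variability == 20.0
        assert merged.replicate_values == (790.0, 810.0)
        assert merged.n_beads == 10

    def test_single_replicate_has_zero_variability(self):
        merged = replicate_merge([FlipResult(raw_signal=800.0, n_beads=4)])
        assert merged.raw_signal == 800.0 and merged.variability == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            replicate_merge([])

    def test_two_noisy_renders_merge_close_to_truth(self):
        """Duplicate noisy pictures of one condition recover the 800 truth."""
        results = []
        for seed in (101, 202):
            spec = SceneSpec(
                image_shape=(224, 224),
                background_intensity=10.0,
                beads=tuple(ringed_bead((60 + 100 * i, 60 + 100 * j)) for i in range(2) for j in range(2)),
                gaussian_sigma=50.0,
                seed=seed,
            )
            image, _ = render_scene(spec)
            results.append(image_flip_signal(image, detect_beads(image)))
        merged = replicate_merge(results)
        assert abs(merged.raw_signal - 800.0) / 800.0 < 0.02


class TestLegacyGlobalMean:
    def test_constant_images(self):
        assert global_mean_flip(
            FluorImage(np.full((32, 32), 60.0)), FluorImage(np.full((32, 32), 10.0))
        ) == 50.0

    def test_half_bright_image(self):
        px = np.zeros((32, 32))
        px[:16] = 100.0
        assert global_mean_flip(FluorImage(px), FluorImage(np.zeros((32, 32)))) == 50.0

    def test_legacy_method_depends_on_bead_count_per_bead_does_not(self):
        """The whole-image mean rises with bead count; the per-bead signal
        stays put — the advantage of per-bead quantification."""
        control = FluorImage(np.full((300, 300), 10.0))
        legacy, per_bead = [], []
        for n_rows in (1, 3):
            beads = tuple(
                ringed_bead((60 + 90 * j, 60 + 60 * i)) for j in range(n_rows) for i in range(4)
            )
            spec = SceneSpec(image_shape=(300, 300), background_intensity=10.0, beads=beads)
            image, _ = render_scene(spec)
            legacy.append(global_mean_flip(image, control))
            per_bead.append(image_flip_signal(image, detect_beads(image)).raw_signal)
        assert legacy[1] > legacy[0] * 1.5
        assert abs(per_bead[0] - per_bead[1]) < 1e-9
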