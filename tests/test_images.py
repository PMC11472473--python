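"""Image QC, blank-anchored cutoff, pixel counting, and replicate stats."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfida.errors import AssayInvalidError, DataError, ParameterError
from sfida.images import (
    BlankCutoff,
    QcParams,
    TirfmImage,
    determine_cutoff,
    pixel_count,
    qc_image,
    replicate_stats,
    well_readout,
)
from sfida.simulate import gen_blank_image, gen_corrupted_image, gen_spot_image

from conftest import reseed


def oracle_cutoff(pixels: np.ndarray, target: float, max_int: int = 16383) -> int:
    """Exhaustive scan over every integer candidate: the smallest c with
    fraction(pixels > c) <= target. Independent of the bincount route."""
    sorted_px = np.sort(pixels.ravel())
    n = sorted_px.size
    for c in range(max_int + 1):
        above = n - np.searchsorted(sorted_px, c, side="right")
        if above <= target * n:
            return c
    raise AssertionError("unreachable: fraction above max intensity is 0")


class TestDetermineCutoff:
    def test_constant_blank(self):
        im = TirfmImage(np.full((50, 50), 100, dtype=np.uint16))
        cut = determine_cutoff([im])
        assert cut.cutoff == 100
        assert cut.positive_fraction_at_cutoff == 0.0

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(60):
            kind = rng.integers(0, 3)
            n = int(rng.integers(500, 3000))
            if kind == 0:
                px = rng.integers(0, 16384, n)
            elif kind == 1:
                px = np.clip(np.rint(rng.normal(500, 200, n)), 0, 16383)
            else:  # background plus a bright contaminating tail
                px = np.clip(np.rint(rng.normal(300, 30, n)), 0, 16383)
                hot = rng.integers(0, n, max(1, n // 50))
                px[hot] = rng.integers(2000, 16384, len(hot))
            px = px.astype(np.uint16).reshape(1, -1)
            target = float(rng.choice([1e-5, 1e-4, 1e-3, 0.01, 0.05]))
            cut = determine_cutoff([TirfmImage(px)], target_fraction=target)
            assert cut.cutoff == oracle_cutoff(px, target)

    def test_fraction_above_never_exceeds_target(self, small_params):
        blanks = [gen_blank_image(reseed(small_params, s), i)
                  for s in range(3) for i in range(5)]
        cut = determine_cutoff(blanks)
        pooled = np.concatenate([b.pixels.ravel() for b in blanks])
        frac = np.count_nonzero(pooled > cut.cutoff) / pooled.size
        assert frac <= cut.target_fraction
        assert frac == cut.positive_fraction_at_cutoff

    @given(seed=st.integers(0, 500),
           t1=st.sampled_from([1e-5, 1e-4, 1e-3, 1e-2]),
           t2=st.sampled_from([1e-5, 1e-4, 1e-3, 1e-2]))
    @settings(max_examples=40, deadline=None)
    def test_cutoff_monotone_in_target_fraction(self, seed, t1, t2):
        px = np.random.default_rng(seed).integers(0, 5000, (40, 40)).astype(np.uint16)
        im = TirfmImage(px)
        lo, hi = min(t1, t2), max(t1, t2)
        # a stricter (smaller) target fraction never lowers the cutoff
        assert determine_cutoff([im], lo).cutoff >= determine_cutoff([im], hi).cutoff

    def test_no_accepted_blanks_is_assay_invalid(self, small_params):
        corrupted = [gen_corrupted_image(small_params, "artifact", i) for i in range(3)]
        with pytest.raises(AssayInvalidError):
            determine_cutoff(corrupted, qc_params=QcParams())
        with pytest.raises(AssayInvalidError):
            determine_cutoff([])

    def test_estimator_api(self, small_params):
        from sklearn.base import clone

        blanks = [gen_blank_image(small_params, i) for i in range(4)]
        est = BlankCutoff(target_fraction=1e-4)
        assert clone(est).get_params()["target_fraction"] == 1e-4
        est.fit(blanks)
        counts = est.transform(blanks)
        assert counts.shape == (4,)
        assert (counts <= 1e-4 * small_params.n_pixels + 5).all()


class TestPixelCount:
    def test_strict_inequality_and_bounds(self):
        zero = TirfmImage(np.zeros((10, 10), dtype=np.uint16))
        assert pixel_count(zero, 0) == 0
        px = np.zeros((64, 64), dtype=np.uint16)
        flat = px.ravel()
        flat[np.random.default_rng(1).choice(px.size, 37, replace=False)] = 5000
        im = TirfmImage(flat.reshape(64, 64))
        assert pixel_count(im, 1000) == 37
        assert pixel_count(im, 16383) == 0
        with pytest.raises(ParameterError):
            pixel_count(im, 20000)
        with pytest.raises(ParameterError):
            pixel_count(im, -1)

    @given(seed=st.integers(0, 1000), cutoff=st.integers(0, 16383))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance_and_additivity(self, seed, cutoff):
        r = np.random.default_rng(seed)
        px = r.integers(0, 16384, (20, 30)).astype(np.uint16)
        whole = pixel_count(TirfmImage(px), cutoff)
        shuffled = r.permutation(px.ravel()).reshape(30, 20)
        assert pixel_count(TirfmImage(shuffled), cutoff) == whole
        top, bottom = px[:10], px[10:]
        assert pixel_count(TirfmImage(top), cutoff) + pixel_count(TirfmImage(bottom), cutoff) == whole


class TestQc:
    def test_clean_blank_accepted(self, small_params):
        v = qc_image(gen_blank_image(small_params, 1))
        assert v.accepted and not v.artifact_flag and not v.defocus_flag

    def test_artifact_flagged(self, small_params):
        # oracle: the constructed saturated fraction >= 0.005 > the 0.001 gate
        im = gen_corrupted_image(small_params, "artifact", 1)
        sat = np.count_nonzero(im.pixels >= im.max_intensity) / im.pixels.size
        assert sat >= 0.005
        assert qc_image(im).artifact_flag

    def test_defocus_flagged(self, small_params):
        infocus, _ = gen_spot_image(small_params, 50, 3)
        defocused = gen_corrupted_image(small_params, "defocus", 3)
        v_in, v_de = qc_image(infocus), qc_image(defocused)
        assert v_de.focus_score < v_in.focus_score
        assert v_de.defocus_flag and not v_in.defocus_flag

    def test_corruption_detection_rate(self, small_params):
        """Both corruption modes must be caught at the default thresholds
        (>=95% over 200 corrupted images)."""
        flagged = 0
        for i in range(100):
            p = reseed(small_params, 9000 + i)
            flagged += not qc_image(gen_corrupted_image(p, "artifact", i)).accepted
            flagged += not qc_image(gen_corrupted_image(p, "defocus", i)).accepted
        assert flagged >= 190

    def test_empty_image_rejected(self):
        with pytest.raises(DataError):
            TirfmImage(np.zeros((0, 0), dtype=np.uint16))


class TestWellReadout:
    def _flat_images(self, n_images, bright_per_image):
        out = []
        for i in range(n_images):
            px = np.zeros((50, 50), dtype=np.uint16)
            px.ravel()[:bright_per_image] = 5000
            out.append(TirfmImage(px, well_id="A01", position_index=i + 1))
        return out

    def test_additivity_over_accepted_images(self):
        w = well_readout(self._flat_images(25, 4), cutoff=1000)
        assert w.images_accepted == 25
        assert w.raw_pixel_count == 100
        assert w.pixel_count == 100

    def test_rescaling_after_exclusions(self):
        images = self._flat_images(20, 4)
        for i in range(5):  # saturate 1% of pixels -> artifact exclusion
            px = np.zeros((50, 50), dtype=np.uint16)
            px.ravel()[: px.size // 100] = 16383
            images.append(TirfmImage(px, well_id="A01"))
        w = well_readout(images, cutoff=1000)
        assert (w.images_total, w.images_accepted) == (25, 20)
        assert w.raw_pixel_count == 80
        assert w.pixel_count == pytest.approx(100.0)  # 80 * 25/20
        # identity: rescaled readout equals mean-per-image x nominal images
        assert w.pixel_count == pytest.approx(w.raw_pixel_count / w.images_accepted * 25)

    def test_majority_exclusion_invalidates_well(self, small_params):
        images = [gen_corrupted_image(reseed(small_params, i), "artifact", i) for i in range(4)]
        images += [gen_blank_image(small_params, i) for i in range(2)]
        w = well_readout(images, cutoff=1000)
        assert not w.valid and w.exclusion_reason == "accepted_fraction_below_minimum"
        all_bad = well_readout(images[:4], cutoff=1000)
        assert not all_bad.valid and np.isnan(all_bad.pixel_count)
        assert all_bad.exclusion_reason == "no_accepted_images"

    def test_empty_well_rejected(self):
        with pytest.raises(DataError):
            well_readout([], cutoff=100)


class TestReplicateStats:
    def test_hand_computed_sample_sd(self):
        s = replicate_stats([90, 100, 110, 100], "S1", "standard")
        assert s.mean == 100.0
        assert s.sd == pytest.approx(8.16496580927726)  # sqrt(200/3), n-1
        assert s.cv_percent == pytest.approx(8.16496580927726)
        assert s.cv_pass is True

    def test_identical_replicates_cv_zero(self):
        s = replicate_stats([42.0] * 4, "S1", "fecal")
        assert s.cv_percent == 0.0 and s.cv_pass is True

    def test_kind_specific_gates(self):
        # CV of exactly 24%: passes the 25% fecal gate, fails the 20% standard gate
        x = 24.0 / np.sqrt(4.0 / 3.0)
        reps = [100 - x, 100 + x, 100 - x, 100 + x]
        fecal = replicate_stats(reps, "F", "fecal")
        standard = replicate_stats(reps, "S", "standard")
        assert fecal.cv_percent == pytest.approx(24.0)
        assert fecal.cv_pass is True
        assert standard.cv_pass is False

    def test_gate_is_strict_below(self):
        x = 20.0 / np.sqrt(4.0 / 3.0)
        s = replicate_stats([100 - x, 100 + x, 100 - x, 100 + x], "S", "standard")
        assert s.cv_percent == pytest.approx(20.0)
        assert s.cv_pass is False  # "below 20%" accepted; exactly 20% is not

    def test_unreliable_and_undefined_cases(self):
        single = replicate_stats([100.0], "S", "fecal")
        assert not single.reliable and single.cv_pass is None
        zero_mean = replicate_stats([0.0, 0.0, 0.0], "S", "fecal")
        assert not zero_mean.cv_defined and np.isnan(zero_mean.cv_percent)


def test_blank_wells_end_to_end_bound(small_params):
    """Mean blank-well pixel count stays within the cutoff target times the
    pixels per well, up to Poisson slack."""
    wells = [[gen_blank_image(reseed(small_params, 100 + w), i) for i in range(5)]
             for w in range(8)]
    blanks = [im for stack in wells for im in stack]
    cut = determine_cutoff(blanks)
    counts = [well_readout(stack, cut).pixel_count for stack in wells]
    per_well_pixels = 5 * small_params.n_pixels
    n = len(wells)
    assert np.mean(counts) <= cut.target_fraction * per_well_pixels * (1 + 5 / np.sqrt(n))
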