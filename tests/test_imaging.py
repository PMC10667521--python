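"""Spot colocalization rules, pixel-wise Pearson r, FRAP processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condmix.imaging import (DEFAULT_SPOT_RADIUS_PX, FRAPTraces, NucleusSet,
                             SpotField, colocalized_fraction, frap_process,
                             nuclear_proximal_split, pearson_colocalization,
                             pixel_shift_control)
from condmix.synth import gen_frap_traces


def brute_force_fraction(ref, other, thresh):
    hits = 0
    for p in ref:
        if any(np.hypot(*(p - q)) < thresh for q in other):
            hits += 1
    return hits / len(ref)


class TestColocalizedFraction:
    def test_identical_fields_fully_colocalized(self, rng):
        pts = rng.random((30, 2)) * 100
        f = SpotField(pts)
        assert colocalized_fraction(f, SpotField(pts.copy())) == 1.0

    def test_far_fields_zero(self):
        a = SpotField([[0, 0], [10, 10]])
        b = SpotField([[50, 50]])
        assert colocalized_fraction(a, b) == 0.0

    def test_threshold_arithmetic_at_default_radius(self):
        # 2r = 2.778 px: 2.5 px is colocalized, 2.8 px is not
        ref = SpotField([[0.0, 0.0]])
        assert colocalized_fraction(ref, SpotField([[2.5, 0.0]])) == 1.0
        assert colocalized_fraction(ref, SpotField([[2.8, 0.0]])) == 0.0

    def test_exactly_2r_is_not_colocalized(self):
        r = DEFAULT_SPOT_RADIUS_PX
        ref = SpotField([[0.0, 0.0]], spot_radius=r)
        assert colocalized_fraction(ref, SpotField([[2 * r, 0.0]])) == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            colocalized_fraction(SpotField(np.empty((0, 2))),
                                 SpotField([[1, 1]]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            ref = SpotField(rng.random((60, 2)) * 40)
            oth = SpotField(rng.random((80, 2)) * 40)
            expect = brute_force_fraction(ref.centers, oth.centers,
                                          2 * ref.spot_radius)
            assert colocalized_fraction(ref, oth) == expect


class TestPixelShift:
    def test_zero_shift_equals_unshifted(self, rng):
        ref = SpotField(rng.random((40, 2)) * 50)
        oth = SpotField(rng.random((40, 2)) * 50)
        assert pixel_shift_control(ref, oth, shift=0.0) == \
            colocalized_fraction(ref, oth)

    def test_shift_breaks_perfect_coincidence(self, rng):
        pts = rng.random((50, 2)) * 200
        ref, oth = SpotField(pts), SpotField(pts.copy())
        assert pixel_shift_control(ref, oth) < 1.0

    def test_matches_brute_force_after_shift(self, rng):
        ref = SpotField(rng.random((50, 2)) * 30)
        oth = SpotField(rng.random((50, 2)) * 30)
        s = 2 * ref.spot_radius
        expect = brute_force_fraction(ref.centers + s, oth.centers, s)
        assert pixel_shift_control(ref, oth) == expect


class TestNuclearProximity:
    def test_spot_at_centroid_is_proximal(self):
        nuclei = NucleusSet([[10, 10]], [20.0])
        prox, dist = nuclear_proximal_split(SpotField([[10, 10]]), nuclei)
        assert list(prox) == [0] and len(dist) == 0

    def test_area_pi_gives_unit_radius(self):
        assert NucleusSet([[0, 0]], [np.pi]).radii[0] == pytest.approx(1.0)

    def test_exactly_r_plus_R_is_distal(self):
        r = DEFAULT_SPOT_RADIUS_PX
        nuclei = NucleusSet([[0, 0]], [np.pi * 4.0])  # R = 2
        spots = SpotField([[r + 2.0, 0.0]], spot_radius=r)
        prox, dist = nuclear_proximal_split(spots, nuclei)
        assert len(prox) == 0 and list(dist) == [0]

    def test_matches_brute_force_split(self, rng):
        nuclei = NucleusSet(rng.random((5, 2)) * 60,
                            rng.random(5) * 40 + 5)
        spots = SpotField(rng.random((80, 2)) * 60)
        prox, dist = nuclear_proximal_split(spots, nuclei)
        R = nuclei.radii
        for i, p in enumerate(spots.centers):
            d = np.hypot(*(nuclei.centroids - p).T)
            expect = np.any(d < spots.spot_radius + R)
            assert (i in prox) == expect


class TestPearson:
    def test_identity_and_inversion(self, rng):
        img = rng.random((16, 16))
        assert pearson_colocalization(img, img) == pytest.approx(1.0)
        assert pearson_colocalization(img, -img + 3) == pytest.approx(-1.0)

    def test_four_pixel_hand_computation(self):
        c1 = np.array([[0, 1], [2, 3]], float)
        c2 = np.array([[1, 0], [3, 2]], float)
        # cov = 3, var1 = var2 = 5 -> r = 0.6
        assert pearson_colocalization(c1, c2) == pytest.approx(0.6)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_colocalization(np.ones((4, 4)), np.random.rand(4, 4))

    def test_mask_restricts_pixels(self, rng):
        c1 = rng.random((8, 8))
        c2 = c1.copy()
        c2[:4] = rng.random((4, 8))  # decorrelate the top half
        mask = np.zeros((8, 8), bool)
        mask[4:] = True
        assert pearson_colocalization(c1, c2, mask=mask) == pytest.approx(1.0)

    @given(st.floats(0.1, 50), st.floats(-10, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_gain_invariance(self, gain, offset):
        rng = np.random.default_rng(7)
        c1 = rng.random((12, 12))
        c2 = rng.random((12, 12))
        base = pearson_colocalization(c1, c2)
        assert pearson_colocalization(c1 * gain + offset, c2) == \
            pytest.approx(base, abs=1e-9)


class TestFRAP:
    def test_qc_excludes_six_percent_drift(self):
        traces, _ = gen_frap_traces(plateau=0.2, noise_sd=0.0, n_acq=3)
        t = traces.unbleached.shape[1]
        traces.unbleached[1] = traces.unbleached[1] * np.linspace(1, 1.06, t)
        res = frap_process(traces)
        assert 1 not in res.passed_qc
        assert set(res.passed_qc) == {0, 2}

    def test_all_failing_qc_raises(self):
        traces, _ = gen_frap_traces(plateau=0.2, noise_sd=0.0, n_acq=2)
        t = traces.unbleached.shape[1]
        traces.unbleached *= np.linspace(1, 1.1, t)
        with pytest.raises(ValueError, match="QC"):
            frap_process(traces)

    def test_background_identical_trace_goes_to_zero(self):
        time = np.arange(10.0)
        b = np.ones((2, 10)) * 0.3
        traces = FRAPTraces(time=time, bleached=b, unbleached=np.ones((2, 10)),
                            background=b.copy(), pre_bleach_index=2)
        res = frap_process(traces)
        assert np.allclose(res.normalized, 0.0)
        assert res.max_recovery == 0.0

    def test_monotone_recovery_max_is_final_value(self):
        traces, _ = gen_frap_traces(plateau=0.3, tau=50.0, noise_sd=0.0,
                                    n_acq=3, n_post=30)
        res = frap_process(traces)
        post = res.normalized[traces.pre_bleach_index:]
        assert res.max_recovery == pytest.approx(post[-1])

    def test_identical_acquisitions_have_zero_sem(self):
        traces, _ = gen_frap_traces(plateau=0.2, noise_sd=0.0, n_acq=3)
        res = frap_process(traces)
        assert np.allclose(res.sem, 0.0, atol=1e-12)
        assert res.max_recovery_sem == pytest.approx(0.0, abs=1e-12)

    def test_acquisition_order_invariance(self):
        traces, _ = gen_frap_traces(plateau=0.25, noise_sd=0.01, n_acq=3, seed=4)
        res1 = frap_process(traces)
        perm = FRAPTraces(time=traces.time, bleached=traces.bleached[::-1],
                          unbleached=traces.unbleached[::-1],
                          background=traces.background[::-1],
                          pre_bleach_index=traces.pre_bleach_index)
        res2 = frap_process(perm)
        assert np.allclose(res1.normalized, res2.normalized)
        assert res1.max_recovery == pytest.approx(res2.max_recovery)
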