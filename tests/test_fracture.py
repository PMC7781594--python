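import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from sarcoquant.core import Micrograph
from sarcoquant.fracture import (
    ZDiskSegment,
    fit_segment_line,
    fracture_area,
    score_image,
    segment_zdisks,
)
from sarcoquant.synthetic import gen_em_micrograph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_msr(coords, n_angles=20000):
    """Oracle: minimum mean squared orthogonal distance over all lines,
    by dense search over line angles (optimal offset passes through the
    centroid for any fixed direction)."""
    c = coords - coords.mean(axis=0)
    best = np.inf
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        normal = np.array([-np.sin(theta), np.cos(theta)])
        msr = np.mean((c @ normal) ** 2)
        best = min(best, msr)
    return best


def weighted_average_oracle(msrs, angles, lengths, theta_ref):
    """Oracle: spreadsheet-style recomputation of the disorder score."""
    msrs, angles, lengths = map(np.asarray, (msrs, angles, lengths))
    two = np.radians(2.0 * angles)
    ref = np.degrees(0.5 * np.arctan2((lengths * np.sin(two)).sum(),
                                      (lengths * np.cos(two)).sum()))
    d = (angles - ref + 90.0) % 180.0 - 90.0
    w = 1.0 + np.abs(d) / theta_ref
    return float((lengths * msrs * w).sum() / lengths.sum())


def seg_from_coords(coords):
    return fit_segment_line(ZDiskSegment(coords_nm=np.asarray(coords, dtype=float)))


# ---------------------------------------------------------------------------
# fit_segment_line
# ---------------------------------------------------------------------------

class TestFitSegmentLine:
    def test_collinear_diagonal(self):
        t = np.linspace(0, 10, 25)
        seg = seg_from_coords(np.column_stack([t, t]))
        np.testing.assert_allclose(seg.residuals_nm, 0.0, atol=1e-9)
        assert seg.angle_deg == pytest.approx(45.0)
        assert abs(np.mean(seg.residuals_nm)) < 1e-9

    def test_square_msr_matches_brute_force(self):
        coords = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0], [10.0, 10.0]])
        seg = seg_from_coords(coords)
        oracle = brute_force_msr(coords)
        assert oracle == pytest.approx(25.0, rel=1e-6)
        assert seg.mean_squared_residual_nm2 == pytest.approx(oracle, rel=1e-6)

    def test_sinusoid_msr_is_half_amplitude_squared(self):
        y = np.linspace(0, 4000, 4000)
        x = 20.0 * np.sin(2 * np.pi * y / 500.0)  # 8 full periods
        seg = seg_from_coords(np.column_stack([x, y]))
        assert seg.mean_squared_residual_nm2 == pytest.approx(200.0, rel=0.05)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            seg_from_coords([[1.0, 1.0], [1.0, 1.0]])

    def test_random_segments_match_brute_force(self, rng):
        for _ in range(5):
            coords = rng.normal(size=(30, 2)) * [5.0, 100.0]
            seg = seg_from_coords(coords)
            assert seg.mean_squared_residual_nm2 == pytest.approx(
                brute_force_msr(coords), rel=1e-4
            )


# ---------------------------------------------------------------------------
# fracture_area
# ---------------------------------------------------------------------------

class TestFractureArea:
    def test_straight_parallel_lines_score_zero(self):
        segs = []
        for x0 in (0.0, 500.0, 1000.0):
            y = np.linspace(0, 1000, 50)
            segs.append(seg_from_coords(np.column_stack([np.full_like(y, x0), y])))
        assert fracture_area(segs).fracture_area_nm2 == pytest.approx(0.0, abs=1e-12)

    def test_straight_crossed_lines_score_zero(self):
        t = np.linspace(0, 1000, 50)
        a = seg_from_coords(np.column_stack([np.zeros_like(t), t]))
        b = seg_from_coords(np.column_stack([0.3 * t, t]))
        assert fracture_area([a, b]).fracture_area_nm2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # equal lengths, MSRs {100, 400}, dtheta {0, 45}, theta_ref 45
        # -> (100*1 + 400*2) / 2 = 450
        class Stub:
            def __init__(self, msr, angle, length):
                self._msr = msr
                self.angle_deg = angle
                self.length_nm = length
                self.segment_id = 0
                self.residuals_nm = np.array([0.0])

            @property
            def fitted(self):
                return True

            @property
            def mean_squared_residual_nm2(self):
                return self._msr

        # reference angle must be 0 for the stated deviations: use lengths
        # heavily favouring the first segment? No -- the spec example fixes
        # dtheta directly, so make angles {0, 45} with the reference pinned
        # by a zero-MSR, long third segment at angle 0.
        anchor = Stub(0.0, 0.0, 1e9)
        segs = [Stub(100.0, 0.0, 1.0), Stub(400.0, 45.0, 1.0), anchor]
        res = fracture_area(segs, theta_ref_deg=45.0)
        without_anchor = (1.0 * 100.0 * 1.0 + 1.0 * 400.0 * 2.0) / 2.0
        total = sum(
            s.length_nm * c for s, c in zip(segs, [r[4] for r in res.per_segment])
        )
        # strip the anchor's (zero) contribution and its length weight
        score_without_anchor = (total - 0.0) / 2.0
        assert score_without_anchor == pytest.approx(without_anchor)

    def test_oracle_equivalence_on_random_segments(self, rng):
        segs, msrs, angles, lengths = [], [], [], []
        for _ in range(8):
            theta = rng.uniform(-80, 80)
            length = rng.uniform(400, 1200)
            t = np.linspace(-length / 2, length / 2, 60)
            d = np.radians(theta)
            base = np.column_stack([t * np.cos(d), t * np.sin(d)])
            noise = rng.normal(0, rng.uniform(1, 15), size=(60, 1))
            normal = np.array([-np.sin(d), np.cos(d)])
            seg = seg_from_coords(base + noise * normal)
            segs.append(seg)
            msrs.append(seg.mean_squared_residual_nm2)
            angles.append(seg.angle_deg)
            lengths.append(seg.length_nm)
        got = fracture_area(segs, theta_ref_deg=45.0).fracture_area_nm2
        want = weighted_average_oracle(msrs, angles, lengths, 45.0)
        assert got == pytest.approx(want, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no Z-disks"):
            fracture_area([])

    def test_unfitted_rejected(self):
        seg = ZDiskSegment(coords_nm=np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="not fitted"):
            fracture_area([seg])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentZdisks:
    def test_recovers_all_zdisks_within_one_pixel(self, clean_scene):
        img, gt = clean_scene
        segs = segment_zdisks(img)
        assert len(segs) == len(gt.zdisk_paths)
        nmpp = img.nm_per_px
        for seg in segs:
            x_mean = seg.coords_nm[:, 0].mean()
            path = gt.zdisk_paths[int(np.argmin(np.abs(gt.zdisk_x_nm - x_mean)))]
            x_true = np.interp(seg.coords_nm[:, 1], path[:, 1], path[:, 0])
            assert np.max(np.abs(seg.coords_nm[:, 0] - x_true)) <= 1.0 * nmpp

    def test_blank_image_yields_empty_list(self):
        img = Micrograph(np.full((64, 64), 0.5), nm_per_px=4.0)
        with pytest.warns(UserWarning):
            assert segment_zdisks(img) == []

    def test_min_length_filter(self, noisy_scene):
        img, gt = noisy_scene
        # a gate longer than the image height removes everything
        with pytest.warns(UserWarning):
            assert segment_zdisks(img, min_length_nm=10000.0) == []


# ---------------------------------------------------------------------------
# score_image properties
# ---------------------------------------------------------------------------

class TestScoreImage:
    def test_zero_law_below_discretisation_floor(self, noisy_scene):
        img, _ = noisy_scene
        res = score_image(img)
        assert res.fracture_area_nm2 < 0.5 * img.nm_per_px**2

    def test_monotone_in_waviness(self):
        scores = []
        for amp in (10.0, 20.0, 40.0):
            img, _ = gen_em_micrograph(
                sl_um=3.3, n_sarcomeres=3, nm_per_px=8.0, height_px=200,
                waviness_amplitude_nm=amp, waviness_model="random",
                noise_fraction=0.03, seed=2,
            )
            scores.append(score_image(img).fracture_area_nm2)
        assert scores[0] < scores[1] < scores[2]

    def test_monotone_in_angular_jitter(self):
        scores = []
        for jit in (0.0, 3.0, 8.0):
            img, _ = gen_em_micrograph(
                sl_um=3.3, n_sarcomeres=3, nm_per_px=8.0, height_px=200,
                waviness_amplitude_nm=15.0, waviness_model="random",
                angle_jitter_deg=jit, noise_fraction=0.03, seed=3,
            )
            scores.append(score_image(img).fracture_area_nm2)
        assert scores[0] < scores[1] < scores[2]

    def test_rotation_invariance(self):
        img, _ = gen_em_micrograph(
            sl_um=3.3, n_sarcomeres=3, nm_per_px=8.0, height_px=360,
            waviness_amplitude_nm=25.0, waviness_model="random",
            noise_fraction=0.02, seed=4,
        )
        base = score_image(img).fracture_area_nm2
        rotated = sk_rotate(img.pixels, 30.0, resize=True, cval=float(np.median(img.pixels)))
        rot = score_image(Micrograph(rotated, img.nm_per_px)).fracture_area_nm2
        assert rot == pytest.approx(base, rel=0.10)

    def test_calibration_covariance(self):
        # the same scene sampled at 4 and (block-averaged) 8 nm/px must give
        # the same nm^2 score
        from skimage.transform import downscale_local_mean

        img, _ = gen_em_micrograph(
            sl_um=3.3, n_sarcomeres=3, nm_per_px=4.0, height_px=400,
            waviness_amplitude_nm=25.0, waviness_model="random",
            noise_fraction=0.02, seed=5,
        )
        fine = score_image(img).fracture_area_nm2
        coarse_px = downscale_local_mean(img.pixels, (2, 2))
        coarse = score_image(Micrograph(coarse_px, 8.0)).fracture_area_nm2
        assert coarse == pytest.approx(fine, rel=0.05)

    def test_genotype_ordering(self):
        # matched scenes parameterised as increasing disorder must rank
        # Wt < Het < Hom
        params = dict(sl_um=3.3, n_sarcomeres=3, nm_per_px=8.0, height_px=200,
                      waviness_model="random", noise_fraction=0.03, seed=6)
        wt, _ = gen_em_micrograph(waviness_amplitude_nm=5.0, angle_jitter_deg=0.5, **params)
        het, _ = gen_em_micrograph(waviness_amplitude_nm=20.0, angle_jitter_deg=2.0, **params)
        hom, _ = gen_em_micrograph(waviness_amplitude_nm=45.0, angle_jitter_deg=6.0, **params)
        s = [score_image(i).fracture_area_nm2 for i in (wt, het, hom)]
        assert s[0] < s[1] < s[2]

    def test_exclusion_recorded(self, noisy_scene):
        img, _ = noisy_scene
        res = score_image(img, exclude_ids=[0])
        assert res.provenance["excluded_ids"] == [0]
        assert res.n_segments == score_image(img).n_segments - 1
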