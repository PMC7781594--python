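import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sarcoquant.core import Micrograph
from sarcoquant.labels import (
    ParticleSet,
    apply_iband_roi,
    detect_particles,
    epitope_distances,
    fit_two_gaussians,
    if_intensity_ratio,
    particles_per_sarcomere,
    percent_ratio,
    thick_filament_lengths,
)
from sarcoquant.synthetic import gen_em_micrograph, gen_if_channels, gen_particle_field
from sarcoquant.synthetic.images import _render_discs


def render_field(truth_rows, shape=(300, 300), nm_per_px=2.0, noise=0.0, seed=0):
    """Plain background + discs at the given (x_nm, y_nm, d_nm) rows."""
    img = np.full(shape, 0.85)
    _render_discs(img, np.asarray(truth_rows, dtype=float), nm_per_px)
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, shape)
    return Micrograph(img, nm_per_px, modality="IEM")


def match_detections(detected, truth, tol_nm=10.0):
    """Greedy matching of detections to truth positions within a tolerance."""
    hits = 0
    used = np.zeros(len(truth), dtype=bool)
    for _, det in detected.iterrows():
        d = np.hypot(truth[:, 0] - det.x_nm, truth[:, 1] - det.y_nm)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_nm:
            used[j] = True
            hits += 1
    return hits


class TestDetectParticles:
    def test_recall_precision_on_clean_field(self, rng):
        truth = np.column_stack([
            rng.uniform(30, 570, 50),
            rng.uniform(30, 570, 50),
            rng.uniform(9.0, 14.0, 50),
        ])
        # enforce 30 nm minimum spacing so blobs are resolvable
        keep = []
        for i, (x, y, d) in enumerate(truth):
            if all(np.hypot(x - truth[j, 0], y - truth[j, 1]) > 30 for j in keep):
                keep.append(i)
        truth = truth[keep]
        img = render_field(truth, shape=(300, 300), nm_per_px=2.0, noise=0.02)
        det = detect_particles(img).particles
        hits = match_detections(det, truth)
        recall = hits / len(truth)
        precision = hits / max(len(det), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_all_below_size_gate_yields_empty(self, rng):
        truth = np.column_stack([
            rng.uniform(50, 550, 20), rng.uniform(50, 550, 20), np.full(20, 6.0)
        ])
        img = render_field(truth, nm_per_px=2.0)
        assert len(detect_particles(img, min_diameter_nm=8.0)) == 0

    def test_separated_pair_gives_two_detections(self):
        d = 12.0
        truth = [(200.0, 200.0, d), (200.0 + 1.5 * d, 200.0, d)]
        img = render_field(truth, nm_per_px=2.0)
        det = detect_particles(img)
        assert len(det) == 2

    def test_intensity_scale_invariance(self, rng):
        truth = np.column_stack([
            rng.uniform(50, 550, 10), rng.uniform(50, 550, 10), np.full(10, 12.0)
        ])
        img = render_field(truth, nm_per_px=2.0, noise=0.02)
        a = detect_particles(img).particles
        scaled = Micrograph(img.pixels * 7.3, img.nm_per_px, modality="IEM")
        b = detect_particles(scaled).particles
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_wrong_modality(self):
        img = Micrograph(np.ones((10, 10)), 2.0, modality="EM")
        with pytest.raises(ValueError):
            detect_particles(img)


class TestIbandRoi:
    def pset(self, rows):
        return ParticleSet(pd.DataFrame(rows, columns=["x_nm", "y_nm", "diameter_nm"]))

    def test_on_zdisk_center_retained(self):
        out = apply_iband_roi(self.pset([(1000.0, 50.0, 10.0)]), [1000.0],
                              sl_um=3.3, aband_length_nm=1600.0)
        assert out.particles["included"].all()

    def test_mid_aband_excluded(self):
        # M-band position: SL/2 = 1650 nm from the Z-disk
        out = apply_iband_roi(self.pset([(2650.0, 50.0, 10.0)]), [1000.0],
                              sl_um=3.3, aband_length_nm=1600.0)
        assert not out.particles["included"].any()

    def test_idempotent(self, clean_scene):
        _, gt = clean_scene
        _, truth = gen_particle_field(gt, "N2A", mean_per_half_sarcomere=10,
                                      background_per_um2=2.0, seed=4)
        pset = ParticleSet(truth[["x_nm", "y_nm", "diameter_nm"]].copy())
        once = apply_iband_roi(pset, list(gt.zdisk_x_nm), gt.sl_um)
        twice = apply_iband_roi(once, list(gt.zdisk_x_nm), gt.sl_um)
        pd.testing.assert_frame_equal(once.particles, twice.particles)

    def test_background_exclusion_matches_geometry(self, clean_scene):
        # binomial oracle: uniform background labels are excluded in
        # proportion to the area outside the ROI stripes
        img, gt = clean_scene
        excluded_fracs = []
        for seed in range(12):
            _, truth = gen_particle_field(gt, "T12", mean_per_half_sarcomere=0.0,
                                          background_per_um2=6.0, seed=seed)
            pset = ParticleSet(truth[["x_nm", "y_nm", "diameter_nm"]].copy())
            out = apply_iband_roi(pset, list(gt.zdisk_x_nm), gt.sl_um,
                                  aband_length_nm=gt.aband_length_nm)
            excluded_fracs.append(1.0 - out.particles["included"].mean())
        width_nm = img.pixels.shape[1] * img.nm_per_px
        half = (gt.sl_um * 1000 - gt.aband_length_nm) / 2 + 20.0
        roi = 0.0
        for zx in gt.zdisk_x_nm:
            roi += min(zx + half, width_nm) - max(zx - half, 0.0)
        expected = 1.0 - roi / width_nm
        fracs = np.array(excluded_fracs)
        sem = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) <= 3 * sem + 0.01

    def test_missing_geometry_rejected(self):
        with pytest.raises(ValueError):
            apply_iband_roi(self.pset([(0.0, 0.0, 10.0)]), [], sl_um=3.3)


class TestEpitopeDistances:
    def pset(self, rows):
        return ParticleSet(pd.DataFrame(rows, columns=["x_nm", "y_nm", "diameter_nm"]))

    def test_nearest_zdisk_selected(self):
        res = epitope_distances(self.pset([(1100.0, 0.0, 10.0)]), [1000.0, 4300.0])
        assert res.distances_nm[0] == pytest.approx(100.0)

    def test_on_center_distance_zero(self):
        res = epitope_distances(self.pset([(1000.0, 5.0, 10.0)]),
                                [np.column_stack([np.full(10, 1000.0), np.arange(10.0)])])
        assert res.distances_nm[0] == pytest.approx(0.0)

    def test_mixture_recovery(self, rng):
        near = rng.normal(50.0, 20.0, 200)
        far = rng.normal(700.0, 20.0, 200)
        d = np.abs(np.concatenate([near, far]))
        fit = fit_two_gaussians(d)
        assert fit["means"][0] == pytest.approx(50.0, abs=25.0)
        assert fit["means"][1] == pytest.approx(700.0, abs=25.0)
        assert fit["weights"][0] == pytest.approx(0.5, abs=0.1)


class TestCounts:
    def test_printed_group_ratio(self):
        assert percent_ratio(34.42, 93.60) == pytest.approx(36.8, abs=0.05)

    def test_empty_counts(self):
        pset = ParticleSet(pd.DataFrame(columns=["x_nm", "y_nm", "diameter_nm"]))
        res = particles_per_sarcomere(pset, [(0.0, 100.0), (100.0, 200.0)])
        assert list(res["counts"]) == [0, 0]

    def test_overlapping_boundaries_rejected(self):
        pset = ParticleSet(pd.DataFrame(columns=["x_nm", "y_nm", "diameter_nm"]))
        with pytest.raises(ValueError):
            particles_per_sarcomere(pset, [(0.0, 150.0), (100.0, 200.0)])

    def test_poisson_rate_recovered(self, clean_scene):
        _, gt = clean_scene
        zx = gt.zdisk_x_nm
        bounds = list(zip(zx[:-1], zx[1:]))
        means = []
        for seed in range(20):
            _, truth = gen_particle_field(gt, "N2A", mean_per_half_sarcomere=17.21,
                                          seed=seed)
            pset = ParticleSet(truth[["x_nm", "y_nm", "diameter_nm"]].copy())
            means.append(particles_per_sarcomere(pset, bounds)["mean"])
        means = np.array(means)
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 34.42) <= 2 * sem + 0.5

    def test_poisson_chi2_not_rejected(self, clean_scene):
        # counts over many seeds follow the generating Poisson law
        _, gt = clean_scene
        zx = gt.zdisk_x_nm
        bounds = list(zip(zx[:-1], zx[1:]))
        counts = []
        for seed in range(100):
            _, truth = gen_particle_field(gt, "N2A", mean_per_half_sarcomere=5.0,
                                          seed=seed)
            x = truth["x_nm"].to_numpy()
            counts.extend(int(np.sum((x >= a) & (x < b))) for a, b in bounds)
        counts = np.array(counts)
        lam = counts.mean()
        edges = [-0.5, 4.5, 6.5, 8.5, 10.5, 12.5, 14.5, np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        cdf = stats.poisson.cdf(np.array(edges[1:]), lam)
        cdf_lo = stats.poisson.cdf(np.array(edges[:-1]), lam)
        exp = (cdf - cdf_lo) * len(counts)
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        # dof = bins - 1 - 1 estimated parameter
        assert chi2 < stats.chi2.ppf(0.99, len(obs) - 2)


class TestThickFilaments:
    def test_straddling_pair_length(self):
        labels = [(-800.0 + 2000.0, 100.0), (800.0 + 2000.0, 100.0)]
        res = thick_filament_lengths(labels, [2000.0], sl_um=3.3)
        assert res.lengths_nm[0] == pytest.approx(1600.0)

    def test_transverse_gate_blocks_pairing(self):
        labels = [(1200.0, 100.0), (2800.0, 180.0)]  # 80 nm transverse offset
        res = thick_filament_lengths(labels, [2000.0], sl_um=3.3,
                                     transverse_gate_nm=20.0)
        assert len(res.lengths_nm) == 0

    def test_one_sided_labels_warn(self):
        with pytest.warns(UserWarning):
            res = thick_filament_lengths([(1200.0, 0.0), (1300.0, 50.0)],
                                         [2000.0], sl_um=3.3)
        assert len(res.lengths_nm) == 0

    def test_length_distribution_recovery(self, rng):
        # contraction-like scene: true A-band lengths 900-1600 nm
        true_lengths = rng.uniform(900.0, 1600.0, 60)
        labels, mlines = [], []
        for i, L in enumerate(true_lengths):
            m = 3000.0 * (i + 1)
            y = rng.uniform(0, 500.0)
            labels += [(m - L / 2, y), (m + L / 2, y)]
            mlines.append(m)
        res = thick_filament_lengths(labels, mlines, sl_um=2.9)
        assert res.lengths_nm.mean() == pytest.approx(true_lengths.mean(), rel=0.05)

    def test_perpendicular_line_mode(self):
        labels = [(1200.0, 0.0), (1200.0, 400.0), (2800.0, 200.0), (2800.0, 600.0)]
        res = thick_filament_lengths(labels, [2000.0], sl_um=3.3,
                                     pairing_mode="perpendicular-line")
        assert list(res.lengths_nm) == [pytest.approx(1600.0)]


class TestIFRatio:
    def test_printed_group_ratio(self):
        assert percent_ratio(32.08, 55.95) == pytest.approx(57.3, abs=0.05)

    def test_zero_halotag_gives_zero_ratios(self, clean_scene):
        _, gt = clean_scene
        halo, actn2 = gen_if_channels(gt, halo_to_actn2_ratio=0.5, noise_fraction=0.0, seed=0)
        zero = Micrograph(np.zeros_like(halo.pixels), halo.nm_per_px, modality="IF")
        zx = gt.zdisk_x_nm
        bounds = list(zip(zx[:-1], zx[1:]))
        res = if_intensity_ratio(zero, actn2, bounds, background=0.0)
        assert np.allclose(res.per_sarcomere["ratio"], 0.0)

    def test_synthetic_ratio_recovered(self, clean_scene):
        _, gt = clean_scene
        halo, actn2 = gen_if_channels(gt, halo_to_actn2_ratio=0.5,
                                      background=0.05, noise_fraction=0.003, seed=2)
        zx = gt.zdisk_x_nm
        # interior sarcomeres only: border stripes are clipped by the image
        bounds = [(zx[1] - 1650.0, zx[1] + 1650.0), (zx[2] - 1650.0, zx[2] + 1650.0)]
        res = if_intensity_ratio(halo, actn2, bounds, background=0.05)
        assert res.group_mean == pytest.approx(0.50, abs=0.02)

    def test_mismatched_channels_rejected(self):
        a = Micrograph(np.ones((10, 10)), 4.0, modality="IF")
        b = Micrograph(np.ones((10, 12)), 4.0, modality="IF")
        with pytest.raises(ValueError):
            if_intensity_ratio(a, b, [(0.0, 40.0)])
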