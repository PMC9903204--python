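"""Thresholding, watershed separation, particle counting, areas, ATAC."""

import math

import numpy as np
import pytest
from skimage.draw import disk
from skimage.filters import threshold_isodata as sk_threshold_isodata
from skimage.measure import label as sk_label

from chromassay import nucleim, synthio
from chromassay.synthio import SynthConfig


def kapur_oracle(image):
    """Exhaustive search of the Kapur entropy objective over 256 bins."""
    img = np.asarray(image, dtype=float)
    counts, edges = np.histogram(img, bins=256, range=(img.min(), img.max()))
    centres = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    best_t, best_obj = None, -np.inf
    for t in range(256):
        pb = p[: t + 1]
        pf = p[t + 1 :]
        Pb, Pf = pb.sum(), pf.sum()
        if Pb <= 0 or Pf <= 0:
            continue
        hb = -sum(q / Pb * math.log(q / Pb) for q in pb if q > 0)
        hf = -sum(q / Pf * math.log(q / Pf) for q in pf if q > 0)
        if hb + hf > best_obj:
            best_obj, best_t = hb + hf, t
    return centres[best_t]


def disks_image(centres, radius, shape=(80, 80)):
    img = np.zeros(shape, dtype=bool)
    for c in centres:
        rr, cc = disk(c, radius, shape=shape)
        img[rr, cc] = True
    return img


class TestMaxEntropy:
    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(24, 24)).astype(float)
            got = nucleim.threshold_maxentropy(img)
            assert got.threshold_used == pytest.approx(kapur_oracle(img), abs=1e-12)

    def test_two_valued_image_separates_populations(self):
        img = np.where(np.arange(400).reshape(20, 20) % 3 == 0, 20.0, 220.0)
        mask = nucleim.threshold_maxentropy(img)
        assert np.array_equal(mask.mask, img == 220.0)

    def test_inverted_image_gives_complementary_foreground(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(float)
        t_fwd = nucleim.threshold_maxentropy(img).threshold_used
        t_inv = nucleim.threshold_maxentropy(255.0 - img).threshold_used
        # the mirrored histogram's optimum sits at the mirrored bin
        assert t_fwd + t_inv == pytest.approx(
            255.0, abs=2 * 255.0 / 256
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nucleim.threshold_maxentropy(np.full((10, 10), 7.0))

    def test_export_convention_black_white(self):
        img = np.where(np.eye(8, dtype=bool), 200.0, 10.0)
        out = nucleim.threshold_maxentropy(img).to_uint8()
        assert set(np.unique(out)) == {0, 255}


class TestIsodata:
    def test_two_delta_populations_split_midway(self):
        img = np.concatenate([np.full(500, 50.0), np.full(500, 150.0)]).reshape(20, 50)
        mask = nucleim.threshold_isodata(img)
        assert 50.0 < mask.threshold_used < 150.0
        assert np.array_equal(mask.mask, img > 100.0)

    def test_fixed_point_property(self, rng):
        img = np.concatenate(
            [rng.normal(60, 10, 2000), rng.normal(180, 15, 1500)]
        ).reshape(70, 50)
        t = nucleim.threshold_isodata(img).threshold_used
        m_lo = img[img <= t].mean()
        m_hi = img[img > t].mean()
        # fixed point of the intermeans iteration, to histogram-bin width
        binw = (img.max() - img.min()) / 256
        assert t == pytest.approx(0.5 * (m_lo + m_hi), abs=2 * binw)

    def test_agrees_with_skimage_reference(self, rng):
        img = np.concatenate(
            [rng.normal(50, 8, 3000), rng.normal(200, 12, 2000)]
        ).reshape(100, 50)
        ours = nucleim.threshold_isodata(img).threshold_used
        ref = sk_threshold_isodata(img, nbins=256)
        binw = (img.max() - img.min()) / 256
        assert ours == pytest.approx(ref, abs=3 * binw)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nucleim.threshold_isodata(np.zeros((5, 5)))


class TestWatershed:
    def test_disjoint_disks_kept_whole(self):
        m = disks_image([(20, 20), (60, 60)], 10)
        field = nucleim.watershed_split(
            nucleim.BinaryMask(m, 0.5, "manual")
        )
        assert field.n_objects == 2
        assert not field.separation_lines.any()
        assert field.objects["area_px"].sum() == m.sum()

    def test_overlapping_disks_split_by_one_pixel_line(self):
        m = disks_image([(40, 30), (40, 45)], 10)
        assert sk_label(m).max() == 1  # fused before splitting
        field = nucleim.watershed_split(nucleim.BinaryMask(m, 0.5, "manual"))
        assert field.n_objects == 2
        lines = field.separation_lines
        assert lines.any()
        # the cut is one pixel thick: no 2x2 block is all line
        blocks = lines[:-1, :-1] & lines[1:, :-1] & lines[:-1, 1:] & lines[1:, 1:]
        assert not blocks.any()
        # nothing beyond the line was removed
        assert field.objects["area_px"].sum() + lines.sum() == m.sum()

    def test_single_convex_disk_not_split(self):
        m = disks_image([(40, 40)], 18)
        field = nucleim.watershed_split(nucleim.BinaryMask(m, 0.5, "manual"))
        assert field.n_objects == 1
        assert not field.separation_lines.any()

    def test_empty_mask_gives_empty_labeling(self):
        field = nucleim.watershed_split(
            nucleim.BinaryMask(np.zeros((10, 10), bool), 0.5, "manual")
        )
        assert field.n_objects == 0


class TestCountParticles:
    def make_field(self, seed=0, n=20, overlap_pairs=0, noise=8.0):
        images, truth = synthio.make_nuclei_field(
            n, overlap_pairs=overlap_pairs, cfg=SynthConfig(seed=seed, noise_sd=noise)
        )
        mask = nucleim.threshold_isodata(images["dna"])
        return nucleim.watershed_split(mask), truth

    def test_disjoint_field_counted_exactly(self):
        field, truth = self.make_field(seed=4, noise=0.0)
        assert nucleim.count_particles(field, min_size=50).count == len(truth)

    def test_overlapping_field_recovered_after_watershed(self):
        field, truth = self.make_field(seed=8, overlap_pairs=3)
        assert nucleim.count_particles(field, min_size=50).count == len(truth)

    def test_min_size_above_all_areas_gives_zero(self):
        field, _ = self.make_field(seed=4, noise=0.0)
        assert nucleim.count_particles(field, min_size=1e9).count == 0

    def test_count_monotone_in_min_size(self):
        field, _ = self.make_field(seed=6)
        counts = [
            nucleim.count_particles(field, min_size=s).count
            for s in (0, 10, 100, 400, 700, 2000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_negative_min_size_rejected(self):
        field, _ = self.make_field(seed=4, noise=0.0)
        with pytest.raises(ValueError):
            nucleim.count_particles(field, min_size=-1)

    def test_pipeline_recovery_rate(self):
        # 50 seeded fields, n=20 with 3 overlapping pairs: counted n
        # within +-1 of truth in at least 95% of fields
        ok = 0
        for seed in range(50):
            images, truth = synthio.make_nuclei_field(
                20, overlap_pairs=3, cfg=SynthConfig(seed=seed, noise_sd=8.0)
            )
            mask = nucleim.threshold_isodata(images["dna"])
            count = nucleim.count_particles(
                nucleim.watershed_split(mask), min_size=50
            ).count
            ok += abs(count - 20) <= 1
        assert ok >= 48


class TestPolygonArea:
    def test_axis_aligned_rectangle(self):
        # vertices at pixel centres: a 10x20 px block inclusive of bounds
        verts = [(0, 0), (19, 0), (19, 9), (0, 9)]
        px2, um2 = nucleim.polygon_area(verts, pixel_size=0.5)
        assert px2 == 200
        assert um2 == pytest.approx(50.0)

    def test_agrees_with_shoelace_within_half_perimeter(self, rng):
        for _ in range(20):
            # random convex polygon from points on a circle
            angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
            r = rng.uniform(8, 25)
            cx, cy = rng.uniform(30, 50, 2)
            verts = [(cx + r * np.cos(a), cy + r * np.sin(a)) for a in angles]
            xs = np.array([v[0] for v in verts])
            ys = np.array([v[1] for v in verts])
            shoelace = 0.5 * abs(
                np.dot(xs, np.roll(ys, 1)) - np.dot(ys, np.roll(xs, 1))
            )
            perimeter = np.sum(np.hypot(np.diff(np.r_[xs, xs[0]]),
                                        np.diff(np.r_[ys, ys[0]])))
            px2, _ = nucleim.polygon_area(verts)
            assert abs(px2 - shoelace) <= perimeter / 2 + 1

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError, match="3 vertices"):
            nucleim.polygon_area([(0, 0), (5, 5)])

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError, match="self-intersect"):
            nucleim.polygon_area([(0, 0), (10, 10), (10, 0), (0, 10)])


class TestAtacFraction:
    def test_zero_atac_signal_gives_zero_fraction(self):
        images, _ = synthio.make_nuclei_field(
            8, atac_positive_fraction=0.0, cfg=SynthConfig(seed=1, noise_sd=0.0)
        )
        q = nucleim.atac_fraction(images["dna"], np.zeros_like(images["atac"]))
        assert q.accessible_fraction == 0.0

    def test_identical_channels_give_unit_fraction(self):
        images, _ = synthio.make_nuclei_field(
            8, atac_positive_fraction=1.0, cfg=SynthConfig(seed=1, noise_sd=0.0)
        )
        q = nucleim.atac_fraction(images["dna"], images["dna"])
        assert q.accessible_fraction == pytest.approx(1.0)
        assert np.allclose(q.per_nucleus["accessible_fraction"], 1.0)

    def test_half_positive_field_recovers_half(self):
        images, truth = synthio.make_nuclei_field(
            20, atac_positive_fraction=0.5, cfg=SynthConfig(seed=12, noise_sd=5.0)
        )
        q = nucleim.atac_fraction(images["dna"], images["atac"])
        assert q.per_nucleus["accessible_fraction"].mean() == pytest.approx(
            0.5, abs=0.1
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal shape"):
            nucleim.atac_fraction(np.ones((4, 4)), np.ones((5, 5)))
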