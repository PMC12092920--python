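"""Synthetic generator: masks, textures, reader panels, dataset assembly."""
import numpy as np
import pytest
from scipy import ndimage

from mammodiff.radiomics import RadiomicsConfig, region_quantities
from mammodiff.roi import largest_inscribed_square
from mammodiff.synthetic import (EASIEST_TEXTURE, HARDEST_TEXTURE, CaseSpec,
                                 GeneratorConfig, TextureParams,
                                 make_breast_mask, make_case, make_dataset,
                                 simulate_ratings)

SMALL = GeneratorConfig(image_height=320, image_width=256)


class TestBreastMask:
    def test_left_chest_wall(self):
        mask = make_breast_mask(512, 400, "L", seed=1)
        assert mask.pixels[:, 0].any()
        assert not mask.pixels[:, -1].any()

    def test_right_is_mirror_of_left(self):
        left = make_breast_mask(512, 400, "L", seed=1)
        right = make_breast_mask(512, 400, "R", seed=1)
        np.testing.assert_array_equal(right.pixels, left.pixels[:, ::-1])

    def test_deterministic(self):
        a = make_breast_mask(512, 400, "L", seed=1)
        b = make_breast_mask(512, 400, "L", seed=1)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_connected_hole_free_and_area_bounds(self):
        for seed in range(5):
            mask = make_breast_mask(400, 300, "L", seed=seed)
            frac = mask.area / mask.pixels.size
            assert 0.2 < frac < 0.8
            _, n = ndimage.label(mask.pixels)
            assert n == 1
            filled = ndimage.binary_fill_holes(mask.pixels)
            np.testing.assert_array_equal(filled, mask.pixels)

    def test_minimum_dimensions_enforced(self):
        with pytest.raises(ValueError):
            make_breast_mask(63, 400, "L", seed=0)


class TestTexture:
    def test_no_noise_sources_gives_constant_breast(self):
        from mammodiff.synthetic import make_texture

        mask = make_breast_mask(320, 256, "L", seed=3)
        par = TextureParams(field_sd=0.0, blob_count=0, range_jitter_sd=0.0,
                            range_markers=False)
        img = make_texture(mask, par, seed=5)
        fg = img.pixels[mask.pixels]
        assert fg.min() == fg.max()
        assert (img.pixels[~mask.pixels] == 0).all()

    def test_deterministic_and_8bit(self):
        from mammodiff.synthetic import make_texture

        mask = make_breast_mask(320, 256, "L", seed=3)
        a = make_texture(mask, HARDEST_TEXTURE, seed=9)
        b = make_texture(mask, HARDEST_TEXTURE, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.pixels.dtype == np.uint8

    def test_empty_mask_rejected(self):
        from mammodiff.images import BreastMask
        from mammodiff.synthetic import make_texture

        with pytest.raises(ValueError):
            make_texture(BreastMask(pixels=np.zeros((64, 64), dtype=bool)),
                         EASIEST_TEXTURE, seed=0)

    def test_hardest_class_raises_square_cluster_prominence(self):
        """Mean inscribed-square cluster prominence must exceed the easiest
        class by at least 2 pooled standard errors over 50 images/class."""
        cfg = RadiomicsConfig()
        vals = {"hardest": [], "easiest": []}
        for cls, par in (("hardest", HARDEST_TEXTURE), ("easiest", EASIEST_TEXTURE)):
            for s in range(50):
                mask = make_breast_mask(1600, 640, "L", seed=1000 + s)
                from mammodiff.synthetic import make_texture

                img = make_texture(mask, par, seed=2000 + s)
                sq = largest_inscribed_square(mask)
                q = region_quantities(img.pixels[sq.slices()], cfg)
                vals[cls].append(q["Cluster_prominence"])
        h = np.asarray(vals["hardest"])
        e = np.asarray(vals["easiest"])
        pooled_se = np.sqrt(h.var(ddof=1) / h.size + e.var(ddof=1) / e.size)
        assert h.mean() - e.mean() >= 2 * pooled_se


class TestMakeCase:
    SPEC = CaseSpec(case_id="c1", latent_difficulty=0.8,
                    difficulty_class="hardest", density_class="B", seed=42)

    def test_four_views_with_expected_labels(self):
        views = make_case(self.SPEC, SMALL)
        assert set(views) == {"LCC", "RCC", "LMLO", "RMLO"}
        for name, (img, mask) in views.items():
            assert img.laterality == name[0]
            assert img.view == name[1:]
            assert img.shape == mask.shape

    def test_right_views_have_right_chest_wall(self):
        views = make_case(self.SPEC, SMALL)
        _, rcc_mask = views["RCC"]
        assert rcc_mask.pixels[:, -1].any()
        assert not rcc_mask.pixels[:, 0].any()

    def test_deterministic(self):
        a = make_case(self.SPEC, SMALL)
        b = make_case(self.SPEC, SMALL)
        for name in a:
            np.testing.assert_array_equal(a[name][0].pixels, b[name][0].pixels)

    def test_high_density_brighter_than_low(self):
        spec_a = CaseSpec("c", 0.2, "easiest", "A", seed=7)
        spec_d = CaseSpec("c", 0.2, "easiest", "D", seed=7)
        img_a, mask = make_case(spec_a, SMALL)["LCC"]
        img_d, _ = make_case(spec_d, SMALL)["LCC"]
        assert img_d.pixels[mask.pixels].mean() > img_a.pixels[mask.pixels].mean()

    def test_different_seeds_differ(self):
        spec2 = CaseSpec("c2", 0.8, "hardest", "B", seed=43)
        a = make_case(self.SPEC, SMALL)["LCC"][0]
        b = make_case(spec2, SMALL)["LCC"][0]
        assert (a.pixels != b.pixels).any()


class TestSimulateRatings:
    def test_zero_difficulty_all_normal_calls(self):
        r = simulate_ratings([0.0] * 5, n_readers=20, seed=1)
        assert r.isin([1, 2]).all().all()

    def test_unit_difficulty_all_false_positives(self):
        r = simulate_ratings([1.0] * 5, n_readers=20, seed=1)
        assert r.isin([3, 4, 5]).all().all()

    def test_marginal_matches_latent_difficulty(self):
        # binomial expectation at d=0.3 with 5000 readers, tolerance 3 SD
        r = simulate_ratings([0.3], n_readers=5000, reader_bias_sd=0.0, seed=2)
        frac = (r >= 3).to_numpy().mean()
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_invalid_difficulty_rejected(self):
        with pytest.raises(ValueError):
            simulate_ratings([1.2], n_readers=3)

    def test_missingness_rate(self):
        r = simulate_ratings([0.5] * 50, n_readers=100, seed=3, missing_rate=0.2)
        assert r.isna().to_numpy().mean() == pytest.approx(0.2, abs=0.03)

    def test_deterministic(self):
        a = simulate_ratings([0.4, 0.6], n_readers=10, seed=5)
        b = simulate_ratings([0.4, 0.6], n_readers=10, seed=5)
        assert a.equals(b)


class TestMakeDataset:
    def test_four_images_per_case(self):
        ds = make_dataset(n_cases=8, n_readers=5, config=SMALL, seed=1)
        assert len(ds.images) == 8
        for views in ds.images.values():
            assert len(views) == 4

    def test_ratings_deterministic_across_runs(self):
        a = make_dataset(n_cases=12, n_readers=9, config=SMALL, seed=4,
                         generate_images=False)
        b = make_dataset(n_cases=12, n_readers=9, config=SMALL, seed=4,
                         generate_images=False)
        assert a.ratings.equals(b.ratings)
        assert a.truth.equals(b.truth)

    def test_hardest_class_latents_exceed_easiest(self):
        ds = make_dataset(n_cases=40, n_readers=10, config=SMALL, seed=2,
                          generate_images=False)
        t = ds.truth
        assert (t.loc[t.difficulty_class == "hardest", "latent_difficulty"].min()
                > t.loc[t.difficulty_class == "easiest", "latent_difficulty"].max())

    def test_empirical_difficulty_orders_classes(self):
        from mammodiff.difficulty import score_rating_matrix

        ds = make_dataset(n_cases=60, n_readers=137, config=SMALL, seed=3,
                          generate_images=False)
        scores = score_rating_matrix(ds.ratings)
        t = ds.truth
        hardest = scores[t.difficulty_class == "hardest"].mean()
        easiest = scores[t.difficulty_class == "easiest"].mean()
        assert hardest > easiest

    def test_minimum_case_count(self):
        with pytest.raises(ValueError):
            make_dataset(n_cases=7, n_readers=5, config=SMALL, seed=0)


class TestWriteDataset:
    def test_round_trip_layout(self, tmp_path):
        from mammodiff.preprocess import read_image
        from mammodiff.synthetic import write_dataset

        ds = make_dataset(n_cases=8, n_readers=4, config=SMALL, seed=6)
        out = write_dataset(ds, tmp_path / "ds")
        assert (out / "manifest.csv").is_file()
        assert (out / "ratings.csv").is_file()
        assert (out / "truth.csv").is_file()
        import pandas as pd

        manifest = pd.read_csv(out / "manifest.csv")
        assert len(manifest) == 32
        row = manifest.iloc[0]
        img = read_image(out / row["path"])
        case_img = ds.images[row["case_id"]][f"{row['laterality']}{row['view']}"][0]
        np.testing.assert_array_equal(img.pixels, case_img.pixels)
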