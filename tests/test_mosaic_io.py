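from __future__ import annotations

import numpy as np
import pytest

from thgq import (
    EnhanceParams,
    IntensityImage,
    MosaicLayout,
    ObjectClass,
    PhantomSpec,
    cut_into_tiles,
    generate_phantom,
    stitch_mosaic,
)
from thgq.datatypes import PhaseOrigin
from thgq.io import (
    load_config,
    read_image,
    render_overlay,
    save_config,
    write_image,
)
from thgq.objects import make_object


class TestStitch:
    def test_one_by_two_output_width(self):
        rng = np.random.default_rng(0)
        tiles = [IntensityImage(rng.random((100, 100))) for _ in range(2)]
        out = stitch_mosaic(tiles, MosaicLayout((1, 2), 0.20))
        assert out.pixels.shape == (100, 180)

    def test_single_tile_is_identity(self):
        rng = np.random.default_rng(1)
        t = IntensityImage(rng.random((120, 120)))
        out = stitch_mosaic([t], MosaicLayout((1, 1), 0.20))
        assert np.allclose(out.pixels, t.pixels)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_cut_and_restitch_round_trip(self, seed):
        spec = PhantomSpec(image_shape=(580, 580), n_cells=8, rng_seed=seed)
        img, _ = generate_phantom(spec)
        layout = MosaicLayout((2, 2), 0.20)
        tiles = cut_into_tiles(img, layout)
        stitched = stitch_mosaic(tiles, layout)
        assert stitched.pixels.shape == img.pixels.shape
        assert np.abs(stitched.pixels - img.pixels).max() <= 1e-6

    def test_tile_count_mismatch_rejected(self):
        t = IntensityImage(np.zeros((100, 100)) + 0.5)
        with pytest.raises(ValueError):
            stitch_mosaic([t], MosaicLayout((1, 2), 0.20))


class TestOverlay:
    def test_empty_object_set_is_grayscale_passthrough(self):
        rng = np.random.default_rng(2)
        img = IntensityImage(rng.random((80, 80)))
        rgb = render_overlay(img, [])
        assert rgb.shape == (80, 80, 3)
        assert np.array_equal(rgb[..., 0], rgb[..., 1])
        assert np.array_equal(rgb[..., 1], rgb[..., 2])

    def test_contours_lie_on_mask_boundary(self):
        from skimage.draw import disk
        from skimage.segmentation import find_boundaries

        img = IntensityImage(np.zeros((80, 80)) + 0.5)
        m = np.zeros((80, 80), dtype=bool)
        rr, cc = disk((40, 40), 15)
        m[rr, cc] = True
        obj = make_object(m, 0, PhaseOrigin.DARK_HOLE, ObjectClass.CELL_BODY)
        rgb = render_overlay(img, [obj])
        colored = np.any(rgb != rgb[0, 0], axis=-1) & \
            ~np.all(rgb == rgb[0, 0, 0], axis=-1)
        boundary = find_boundaries(m, mode="inner")
        painted = np.any(rgb != np.repeat((np.clip(img.pixels, 0, 1) * 255)
                                          .astype(np.uint8)[..., None], 3, 2),
                         axis=-1)
        assert np.array_equal(painted, boundary)

    def test_three_classes_get_three_distinct_colors(self):
        img = IntensityImage(np.zeros((100, 100)) + 0.5)
        objs = []
        for i, (cls, pos) in enumerate([
            (ObjectClass.CELL_BODY, (20, 20)),
            (ObjectClass.NUCLEUS, (50, 50)),
            (ObjectClass.NEUROPIL, (80, 80)),
        ]):
            m = np.zeros((100, 100), dtype=bool)
            m[pos[0] - 5 : pos[0] + 5, pos[1] - 5 : pos[1] + 5] = True
            objs.append(make_object(m, i, PhaseOrigin.BRIGHT, cls))
        rgb = render_overlay(img, objs)
        gray = np.repeat((0.5 * 255 * np.ones((100, 100)))
                         .astype(np.uint8)[..., None], 3, 2)
        colors = {tuple(c) for c in rgb[np.any(rgb != gray, axis=-1)]}
        assert len(colors) == 3


class TestImageIO:
    def test_tiff_round_trip_16bit(self, tmp_path):
        rng = np.random.default_rng(6)
        img = IntensityImage(rng.random((90, 90)))
        path = tmp_path / "x.tif"
        write_image(path, img)
        back = read_image(path)
        assert np.allclose(back.pixels, img.pixels, atol=1.0 / 65535 + 1e-9)


class TestConfig:
    def test_round_trip(self, tmp_path):
        p = EnhanceParams(truncate_low=1.0, truncate_high=98.0,
                          tile_grid=(4, 4), clip_limit=0.02)
        path = tmp_path / "cfg.yaml"
        save_config(path, {"preprocess": p})
        back = load_config(path, {"preprocess": EnhanceParams})
        assert back["preprocess"] == p

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("mystery:\n  a: 1\n")
        with pytest.raises(ValueError, match="unknown config sections"):
            load_config(path, {"preprocess": EnhanceParams})

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("preprocess:\n  no_such_knob: 3\n")
        with pytest.raises(ValueError, match="unknown keys"):
            load_config(path, {"preprocess": EnhanceParams})

    def test_nested_noise_model_round_trip(self, tmp_path):
        spec = PhantomSpec(n_cells=5, rng_seed=3)
        path = tmp_path / "cfg.yaml"
        save_config(path, {"phantom": spec})
        back = load_config(path, {"phantom": PhantomSpec})["phantom"]
        assert back == spec


class TestRunPipeline:
    def test_batch_with_corrupt_file_continues(self, tmp_path):
        from thgq import run_pipeline

        spec = PhantomSpec(image_shape=(300, 300), n_cells=3,
                           cell_radius_range=(20.0, 24.0), n_fibers=6,
                           n_granules=2, rng_seed=8)
        img, _ = generate_phantom(spec)
        good1 = tmp_path / "a.tif"
        good2 = tmp_path / "b.tif"
        bad = tmp_path / "c.tif"
        write_image(good1, img)
        write_image(good2, img)
        bad.write_bytes(b"not a tiff at all")
        out = tmp_path / "report"
        code = run_pipeline([good1, bad, good2], out, write_overlays=False)
        assert code == 1
        report = (out / "report.json").read_text()
        assert report.count('"image_id"') == 2
        assert (out / "errors.txt").exists()

    def test_identical_runs_produce_identical_bytes(self, tmp_path):
        from thgq import run_pipeline

        spec = PhantomSpec(image_shape=(300, 300), n_cells=3,
                           cell_radius_range=(20.0, 24.0), n_fibers=6,
                           n_granules=2, rng_seed=9)
        img, _ = generate_phantom(spec)
        outputs = []
        for run in ("r1", "r2"):
            out = tmp_path / run
            run_pipeline([img], out, write_overlays=False)
            outputs.append({f.name: f.read_bytes()
                            for f in sorted(out.iterdir())})
        assert outputs[0] == outputs[1]


class TestCli:
    def test_phantom_and_classify_commands(self, tmp_path):
        from click.testing import CliRunner

        from thgq.cli import main

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "phantom:\n"
            "  image_shape: [300, 300]\n"
            "  n_cells: 3\n"
            "  n_fibers: 6\n"
            "  n_granules: 2\n"
        )
        runner = CliRunner()
        res = runner.invoke(main, ["phantom", "--spec", str(cfg),
                                   "--out", str(tmp_path / "ph"),
                                   "--seed", "5"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "ph" / "thg.tif").exists()
        res = runner.invoke(main, ["classify", str(tmp_path / "ph" / "thg.tif")])
        assert res.exit_code == 0, res.output
        assert "cell_pos=" in res.output
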