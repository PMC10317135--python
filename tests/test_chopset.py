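"""Contour measure, acceptance filters, rim extraction, record packing."""

import warnings

import numpy as np
import pytest

from artscore.chopset import (
    FilterConfig,
    accept_chop,
    build_training_set,
    contour_measure,
    extract_rim_chops,
    read_record_file,
    write_record_file,
)
from artscore.synthgen import generate_well, scene_for_class
from artscore.tiling import is_border_window, smallest_overlap_grid


class TestContourMeasure:
    def test_uniform_chop_measures_zero(self):
        assert contour_measure(np.full((64, 64), 0.5)) == 0.0

    def test_filled_square_measures_its_perimeter(self):
        img = np.full((64, 64), 0.3)
        img[20:40, 20:40] = 0.8  # 20x20 step edge, perimeter 80
        assert contour_measure(img) == pytest.approx(80.0, rel=0.15)

    def test_invariant_to_joint_intensity_offset(self):
        rng = np.random.default_rng(0)
        img = rng.random((48, 48)) * 0.3 + 0.2
        level = img.mean()
        shifted = img + 0.17
        assert contour_measure(img, level) == pytest.approx(
            contour_measure(shifted, level + 0.17), abs=1e-6
        )

    def test_nonnegative_on_arbitrary_images(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            assert contour_measure(rng.random((32, 32))) >= 0.0


class TestAcceptChop:
    def setup_method(self):
        self.cfg = FilterConfig()
        self.flat = np.full((64, 64), 0.5)
        edgy = np.full((64, 64), 0.5)
        edgy[16:48, 16:48] = 0.1
        self.edgy = edgy

    def test_crystal_with_flat_uv_is_rejected(self):
        assert not accept_chop(self.edgy, self.flat, 23, self.cfg)

    def test_crystal_with_structure_in_both_is_accepted(self):
        assert accept_chop(self.edgy, self.edgy, 22, self.cfg)

    def test_crystal_without_uv_mate_raises(self):
        with pytest.raises(ValueError, match="UV"):
            accept_chop(self.edgy, None, 21, self.cfg)

    def test_crystal_without_uv_allowed_when_not_required(self):
        cfg = FilterConfig(require_uv=False)
        assert accept_chop(self.edgy, None, 21, cfg)

    def test_uniform_precipitate_chop_is_rejected(self):
        assert not accept_chop(self.flat, None, 12, self.cfg)

    def test_textured_other_chop_is_accepted(self):
        assert accept_chop(self.edgy, None, 33, self.cfg)

    def test_clear_chops_always_accepted(self):
        assert accept_chop(self.flat, None, 1, self.cfg)
        assert accept_chop(self.flat, None, 2, self.cfg)

    def test_acceptance_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        chops = [rng.random((64, 64)) for _ in range(20)]
        counts = []
        for t in (5.0, 40.0, 400.0):
            cfg = FilterConfig(t_texture=t)
            counts.append(sum(accept_chop(c, None, 13, cfg) for c in chops))
        assert counts[0] >= counts[1] >= counts[2]


class TestRimExtraction:
    def test_rim_chops_come_only_from_border_windows(self, clear_well):
        grid = smallest_overlap_grid(*clear_well.visible.shape, 128, 128)
        rims = extract_rim_chops(clear_well, grid, FilterConfig())
        assert rims, "clear well with a rim ring must yield rim chops"
        for _, window in rims:
            assert is_border_window(window, grid)

    def test_centered_small_droplet_yields_no_rim_chops(self, full13):
        from artscore.synthgen import SceneSpec

        # droplet much smaller than the center window: ring never
        # reaches the border bands
        spec = SceneSpec(
            image_height=384, image_width=384,
            droplet_radius=40.0, seed=8,
        )
        well = generate_well(spec, scheme=full13)
        grid = smallest_overlap_grid(384, 384, 128, 128)
        assert extract_rim_chops(well, grid, FilterConfig()) == []

    def test_non_clear_well_is_misuse(self, crystal_well):
        grid = smallest_overlap_grid(*crystal_well.visible.shape, 128, 128)
        with pytest.raises(ValueError, match="clear"):
            extract_rim_chops(crystal_well, grid, FilterConfig())


@pytest.mark.filterwarnings("ignore:no accepted chops")
class TestBuildTrainingSet:
    @pytest.fixture(scope="class")
    def wells(self, full13):
        out = []
        for score, n in [(23, 2), (13, 2), (32, 2), (1, 2)]:
            for k in range(n):
                spec = scene_for_class(
                    full13.by_score(score), 384, 384, seed=100 * score + k
                )
                out.append(generate_well(spec, scheme=full13))
        return out

    def test_every_record_passes_its_own_filter_again(self, wells, full13):
        ts = build_training_set(wells, full13, 64, FilterConfig(), seed=0)
        cfg = FilterConfig(require_uv=False)
        for r in ts.records:
            if r.is_rim:
                continue  # rim uses its own selection rule
            chop = r.chop.astype(float) / 255.0
            assert accept_chop(chop, None, r.score_no, cfg)

    def test_rim_records_come_only_from_clear_wells(self, wells, full13):
        ts = build_training_set(wells, full13, 64, FilterConfig(), seed=0)
        clear_ids = {
            f"well_{i:04d}" for i, w in enumerate(wells)
            if w.well_label.score_no == 1
        }
        rim_records = [r for r in ts.records if r.is_rim]
        assert rim_records
        assert all(r.well_id in clear_ids for r in rim_records)

    def test_deterministic_for_fixed_seed(self, wells, full13):
        a = build_training_set(wells, full13, 64, FilterConfig(), seed=3)
        b = build_training_set(wells, full13, 64, FilterConfig(), seed=3)
        assert len(a.records) == len(b.records)
        assert all(
            np.array_equal(x.chop, y.chop) and x.score_no == y.score_no
            for x, y in zip(a.records, b.records)
        )

    def test_raising_texture_threshold_only_shrinks_counts(self, wells, full13):
        sizes = []
        for t in (10.0, 40.0, 160.0):
            ts = build_training_set(
                wells, full13, 64, FilterConfig(t_texture=t), seed=0
            )
            counts = ts.counts(full13)
            sizes.append(counts["Precipitate"] + counts["Spherolites"])
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_missing_classes_are_reported_not_silent(self, wells, full13):
        with pytest.warns(UserWarning, match="no accepted chops"):
            build_training_set(wells[:2], full13, 64, FilterConfig(), seed=0)

    def test_record_file_round_trip(self, wells, full13, tmp_path):
        ts = build_training_set(
            wells, full13, 64, FilterConfig(), seed=0, out_dir=tmp_path
        )
        assert (tmp_path / "chops.csv").exists()
        ts2 = read_record_file(tmp_path / "chops.rec")
        assert ts2.chop_size == ts.chop_size
        assert len(ts2.records) == len(ts.records)
        for a, b in zip(ts.records, ts2.records):
            assert np.array_equal(a.chop, b.chop)
            assert (a.score_no, a.is_rim, a.well_id) == (b.score_no, b.is_rim, b.well_id)
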