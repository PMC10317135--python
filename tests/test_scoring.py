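"""Priority aggregation, the scoring sweep and evidence rendering."""

import numpy as np
import pytest

from artscore.scoring import (
    ChopScore,
    ConfusionChopClassifier,
    OracleChopClassifier,
    aggregate_well_score,
    render_annotations,
    score_well,
    select_top_chops,
)
from artscore.synthgen import generate_well, scene_for_class
from artscore.tiling import Window


def cs(scheme, score_no, prob, is_rim=False, x=0, y=0):
    return ChopScore(
        window=Window(x, y, 16, 16),
        class_def=scheme.by_score(score_no, is_rim=is_rim),
        probability=prob,
    )


def brute_force_aggregate(chop_scores, c):
    """Independent oracle: scan qualifying chops for the best table rank."""
    best = None
    for s in chop_scores:
        if s.probability < c:
            continue
        if best is None or s.class_def.priority_rank < best.priority_rank:
            best = s.class_def
    if best is None:
        return None
    return 1 if best.is_rim else best.score_no


class TestAggregate:
    def test_single_crystal_chop_beats_many_confident_clears(self, full13):
        scores = [cs(full13, 21, 0.90)] + [cs(full13, 1, 0.99) for _ in range(50)]
        assert aggregate_well_score(scores, full13, 0.85) == 21

    def test_all_below_threshold_is_unscored(self, full13):
        scores = [cs(full13, 23, 0.80), cs(full13, 13, 0.84)]
        assert aggregate_well_score(scores, full13, 0.85) is None

    def test_empty_list_is_unscored(self, full13):
        assert aggregate_well_score([], full13, 0.85) is None

    def test_rim_only_wells_are_reported_clear(self, full13):
        scores = [cs(full13, 1, 0.95, is_rim=True)]
        assert aggregate_well_score(scores, full13, 0.85) == 1

    def test_matches_brute_force_oracle_on_random_sets(self, full13):
        rng = np.random.default_rng(0)
        score_pool = [(23, False), (22, False), (21, False), (13, False),
                      (12, False), (11, False), (34, False), (33, False),
                      (32, False), (31, False), (1, False), (2, False), (1, True)]
        for _ in range(1000):
            n = int(rng.integers(0, 31))
            scores = []
            for _ in range(n):
                sc, rim = score_pool[int(rng.integers(13))]
                scores.append(cs(full13, sc, float(rng.random()), is_rim=rim))
            c = float(rng.uniform(0.3, 1.0))
            assert aggregate_well_score(scores, full13, c) == brute_force_aggregate(scores, c)

    def test_result_rank_never_rises_as_c_rises(self, full13):
        rng = np.random.default_rng(1)
        ranks = {c.score_no if not c.is_rim else "rim": c.priority_rank
                 for c in full13.classes}
        for _ in range(100):
            scores = [
                cs(full13, [23, 13, 34, 1][int(rng.integers(4))], float(rng.random()))
                for _ in range(10)
            ]
            prev_rank = -1
            for c in (0.5, 0.7, 0.9, 0.99):
                got = aggregate_well_score(scores, full13, c)
                rank = 99 if got is None else ranks[got]
                assert rank >= prev_rank
                prev_rank = rank


class TestScoreWell:
    @pytest.fixture(scope="class")
    def scored_crystal(self, merged5):
        spec = scene_for_class(merged5.by_name("crystal"), 384, 384, seed=21)
        well = generate_well(spec, scheme=merged5)
        ws = score_well(
            well.visible, well.uv,
            lambda im: well.droplet_mask.astype(float),
            OracleChopClassifier(spec, merged5),
            merged5, s=32, c=0.85, chop_size=96, well_id="w-crystal",
        )
        return well, ws

    def test_crystal_well_scores_crystal(self, scored_crystal):
        well, ws = scored_crystal
        assert ws.scored and ws.class_def.group == "crystal"

    def test_clear_well_scores_clear(self, merged5):
        spec = scene_for_class(merged5.by_name("clear"), 384, 384, seed=22)
        well = generate_well(spec, scheme=merged5)
        ws = score_well(
            well.visible, None,
            lambda im: well.droplet_mask.astype(float),
            OracleChopClassifier(spec, merged5),
            merged5, s=32, c=0.85, chop_size=96,
        )
        assert ws.score_no == 1

    def test_droplet_not_found_reports_unscored(self, merged5):
        spec = scene_for_class(merged5.by_name("clear"), 384, 384, seed=23)
        well = generate_well(spec, scheme=merged5)
        ws = score_well(
            well.visible, None,
            lambda im: np.zeros_like(im),
            OracleChopClassifier(spec, merged5),
            merged5, chop_size=96,
        )
        assert not ws.scored and "droplet" in ws.unscored_reason

    def test_deterministic(self, merged5, scored_crystal):
        well, first = scored_crystal
        spec = well.spec
        again = score_well(
            well.visible, well.uv,
            lambda im: well.droplet_mask.astype(float),
            OracleChopClassifier(spec, merged5),
            merged5, s=32, c=0.85, chop_size=96, well_id="w-crystal",
        )
        assert again.score_no == first.score_no
        assert [c.window for c in again.top_chops] == [c.window for c in first.top_chops]
        assert np.array_equal(again.annotated_image, first.annotated_image)

    def test_top_chops_sorted_and_capped(self, scored_crystal):
        _, ws = scored_crystal
        assert len(ws.top_chops) <= 5
        ranks = [c.class_def.priority_rank for c in ws.top_chops]
        assert ranks == sorted(ranks)

    def test_lowering_c_never_unscores_a_scored_well(self, merged5):
        for seed in range(10):
            cdef = merged5.classes[seed % 4]
            spec = scene_for_class(cdef, 384, 384, seed=300 + seed)
            well = generate_well(spec, scheme=merged5)
            args = (
                well.visible, well.uv,
                lambda im, w=well: w.droplet_mask.astype(float),
                OracleChopClassifier(spec, merged5, confidence=0.90),
                merged5,
            )
            high = score_well(*args, s=48, c=0.85, chop_size=96, render=False)
            low = score_well(*args, s=48, c=0.80, chop_size=96, render=False)
            if high.scored:
                assert low.scored

    def test_confusion_mock_emits_matrix_rows(self, merged5):
        spec = scene_for_class(merged5.by_name("clear"), 256, 256, seed=30)
        oracle = OracleChopClassifier(spec, merged5)
        confusion = np.full((5, 5), 0.05)
        np.fill_diagonal(confusion, 0.8)
        clf = ConfusionChopClassifier(oracle, confusion)
        probs = clf.predict_windows(
            np.zeros((1, 64, 64)), [Window(96, 96, 64, 64)]
        )
        assert probs[0].max() == pytest.approx(0.8)


class TestRender:
    def test_no_chops_changes_only_the_border(self, merged5):
        img = np.random.default_rng(0).random((100, 120))
        out = render_annotations(img, [], winner=merged5.by_name("clear"), border=6)
        inner = out[6:-6, 6:-6]
        expected = np.repeat((img * 255).round().astype(np.uint8)[:, :, None], 3, 2)
        assert np.array_equal(inner, expected[6:-6, 6:-6])

    def test_crystal_frames_are_red(self, merged5):
        img = np.zeros((100, 100))
        chop = ChopScore(Window(10, 10, 40, 40), merged5.by_name("crystal"), 0.9)
        out = render_annotations(img, [chop])
        assert tuple(out[10, 30]) == (255, 0, 0)

    def test_overlapping_frames_painted_in_probability_order(self, merged5):
        img = np.zeros((100, 100))
        low = ChopScore(Window(10, 10, 40, 40), merged5.by_name("precipitate"), 0.6)
        high = ChopScore(Window(30, 10, 40, 40), merged5.by_name("crystal"), 0.9)
        out = render_annotations(img, [high, low])
        # the high-probability crystal frame overlaps the precipitate one
        # at x in [30, 50); painted last, it must be on top
        assert tuple(out[10, 35]) == (255, 0, 0)

    def test_rim_frames_are_white(self, merged5):
        img = np.zeros((60, 60))
        chop = ChopScore(Window(0, 0, 30, 30), merged5.by_name("rim"), 0.9)
        out = render_annotations(img, [chop])
        assert tuple(out[0, 15]) == (255, 255, 255)


def test_select_top_chops_prefers_qualifying_by_rank_then_probability(full13):
    scores = [
        cs(full13, 1, 0.99), cs(full13, 23, 0.86), cs(full13, 13, 0.95),
        cs(full13, 23, 0.90), cs(full13, 34, 0.20),
    ]
    top = select_top_chops(scores, c=0.85, n=3)
    assert [(t.class_def.score_no, t.probability) for t in top] == [
        (23, 0.90), (23, 0.86), (13, 0.95)
    ]
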