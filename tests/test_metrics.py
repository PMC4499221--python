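"""Confusion analysis, similarity indices, arch morphometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_confusion, naive_mass_center
from archseg import metrics
from archseg.metrics import (
    ConfusionCounts,
    ToothMeasurement,
    confusion_counts,
    dice_from_jaccard,
    error_vs_reference,
    mass_center,
    pair_distances,
    similarity_report,
)
from conftest import make_disc


class TestConfusionCounts:
    def test_identical_masks(self):
        m = make_disc((20, 20), (10, 10), 5)
        c = confusion_counts(m, m)
        assert (c.fp, c.fn) == (0, 0) and c.tp == m.sum()

    def test_disjoint_masks_arithmetic(self):
        result = np.zeros((10, 10), dtype=bool)
        truth = np.zeros((10, 10), dtype=bool)
        result.flat[:10] = True
        truth.flat[50:62] = True
        c = confusion_counts(result, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 10, 12, 78)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(50)
        a, b = rng.random((16, 16)) > 0.5, rng.random((16, 16)) > 0.5
        c = confusion_counts(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == naive_confusion(a, b)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSimilarityReport:
    def test_perfect_overlap(self):
        rep = similarity_report(ConfusionCounts(tp=100, fp=0, fn=0, tn=900))
        assert rep.tpr == rep.tnr == rep.accuracy == rep.jaccard == rep.dice == 1.0
        assert rep.fpr == rep.fnr == 0.0

    def test_unit_counts_arithmetic(self):
        rep = similarity_report(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        assert rep.jaccard == pytest.approx(1 / 3)
        assert rep.dice == pytest.approx(1 / 2)
        assert rep.accuracy == pytest.approx(1 / 2)

    def test_degenerate_denominators_flagged_not_zeroed(self):
        with pytest.warns(UserWarning) as record:
            rep = similarity_report(ConfusionCounts(tp=0, fp=5, fn=0, tn=95))
        assert np.isnan(rep.tpr) and np.isnan(rep.fnr)
        assert any("TPR" in str(w.message) for w in record)

    def test_dice_from_printed_jaccard(self):
        assert dice_from_jaccard(0.9330) == pytest.approx(0.9653, abs=5e-5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tp=st.integers(1, 10_000),
    fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
    tn=st.integers(1, 100_000),
)
def test_dice_jaccard_identity_and_rate_complements(tp, fp, fn, tn):
    rep = similarity_report(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    assert rep.dice == pytest.approx(2 * rep.jaccard / (1 + rep.jaccard))
    assert rep.tpr + rep.fnr == pytest.approx(1.0)
    assert rep.tnr + rep.fpr == pytest.approx(1.0)


class TestMassCenter:
    def test_solid_square(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0:3, 0:3] = True
        assert mass_center(m) == (1.0, 1.0)

    def test_two_equal_discs_symmetry(self):
        m = make_disc((40, 60), (20, 20), 6) | make_disc((40, 60), (20, 30), 6)
        r, c = mass_center(m)
        assert c == pytest.approx(25.0, abs=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(51)
        m = rng.random((16, 16)) > 0.6
        assert mass_center(m) == pytest.approx(naive_mass_center(m))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mass_center(np.zeros((4, 4), dtype=bool))


def _tooth(side, index, center, shape=(120, 260)):
    return ToothMeasurement(side=side, index=index, mask=make_disc(shape, center, 6))


class TestPairDistances:
    def test_mirrored_masks_simple_distance(self):
        teeth = [_tooth("L", 1, (60, 50)), _tooth("R", 1, (60, 150))]
        rep = pair_distances(teeth, pixel_scale=0.1)
        assert rep.pair_distances_mm[1] == pytest.approx(10.0)

    def test_zero_separation_flagged(self):
        with pytest.warns(UserWarning, match="coincident"):
            rep = pair_distances([_tooth("L", 1, (60, 50)), _tooth("R", 1, (60, 50))], 0.1)
        assert rep.invalid_pairs == [1]

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pair_distances([_tooth("L", 1, (60, 50))], 0.1)

    def test_translation_invariance(self):
        t1 = [_tooth("L", 1, (40, 50)), _tooth("R", 1, (60, 150))]
        t2 = [_tooth("L", 1, (50, 70)), _tooth("R", 1, (70, 170))]
        a = pair_distances(t1, 0.2).pair_distances_mm[1]
        b = pair_distances(t2, 0.2).pair_distances_mm[1]
        assert a == pytest.approx(b)

    def test_truth_masks_round_trip_generator_geometry(self, default_truth):
        teeth = [
            ToothMeasurement(side=b.side, index=b.index, mask=b.mask) for b in default_truth.bodies
        ]
        rep = pair_distances(teeth, default_truth.pixel_scale)
        for b in default_truth.bodies:
            if b.side != "L":
                continue
            partner = next(x for x in default_truth.bodies if x.side == "R" and x.index == b.index)
            configured = np.linalg.norm(np.array(b.center) - partner.center) * default_truth.pixel_scale
            assert rep.pair_distances_mm[b.index] == pytest.approx(
                configured, abs=default_truth.pixel_scale
            )


class TestErrorVsReference:
    def test_reference_row_arithmetic(self):
        measured = metrics.ArchReport(pair_distances_mm={1: 32.14}, pixel_scale=0.1)
        rep = error_vs_reference(measured, {1: 32.68})
        assert rep.errors_mm[1] == pytest.approx(0.54)
        assert rep.errors_pct[1] == pytest.approx(1.65, abs=0.005)

    def test_exact_match_gives_zero_errors(self):
        measured = metrics.ArchReport(pair_distances_mm={1: 10.0, 2: 20.0}, pixel_scale=0.1)
        rep = error_vs_reference(measured, {1: 10.0, 2: 20.0})
        assert rep.mean_percent_error == 0.0

    def test_nonpositive_reference_rejected(self):
        measured = metrics.ArchReport(pair_distances_mm={1: 10.0}, pixel_scale=0.1)
        with pytest.raises(ValueError):
            error_vs_reference(measured, {1: 0.0})
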