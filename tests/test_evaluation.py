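import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import decade_enm as de
from decade_enm.raster import RasterStack


def brute_force_threshold(p, a):
    """Independent oracle: scan every candidate threshold."""
    best_tau, best_total = None, -np.inf
    for tau in sorted(np.unique(np.concatenate([p, a]))):
        sens = np.mean(p >= tau)
        spec = np.mean(a < tau)
        if sens + spec > best_total + 1e-12:
            best_total = sens + spec
            best_tau = tau
    return best_tau


def flat_stack(n_rows, n_cols):
    return RasterStack(
        data=np.zeros((1, n_rows, n_cols)), x_origin=0.0, y_origin=0.0, cell_size=1.0
    )


def binary_map(values):
    values = np.asarray(values, float)
    return RasterStack(
        data=values[None], x_origin=0.0, y_origin=0.0, cell_size=1.0
    )


class TestCheckerboard:
    def test_unit_blocks_alternate(self):
        part = de.checkerboard_partition(flat_stack(4, 4), 1)
        assert part.fold.sum() == 8
        assert np.all(part.fold[:-1, :] != part.fold[1:, :])
        assert np.all(part.fold[:, :-1] != part.fold[:, 1:])

    def test_single_block_degenerates_to_one_fold(self):
        part = de.checkerboard_partition(flat_stack(4, 4), 4)
        assert len(np.unique(part.fold)) == 1

    @pytest.mark.parametrize("block", [1, 2, 3, 5])
    def test_adjacent_blocks_always_differ(self, block):
        part = de.checkerboard_partition(flat_stack(16, 16), block)
        f = part.fold[::block, ::block]
        assert np.all(f[:-1, :] != f[1:, :])
        assert np.all(f[:, :-1] != f[:, 1:])

    def test_invalid_block_size(self):
        with pytest.raises(ValueError):
            de.checkerboard_partition(flat_stack(4, 4), 0)


class TestConfusion:
    def test_hand_enumerated_confusion_matrix(self):
        sens, spec, tss = de.confusion_stats(
            [0.9, 0.8, 0.4], [0.3, 0.2, 0.7], 0.5
        )
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(2 / 3)
        assert tss == pytest.approx(1 / 3)

    def test_perfect_separation_gives_tss_one(self):
        _, _, tss = de.confusion_stats([0.9, 0.8], [0.1, 0.2], 0.5)
        assert tss == pytest.approx(1.0)

    def test_threshold_above_everything(self):
        sens, spec, tss = de.confusion_stats([0.4, 0.5], [0.1, 0.2], 0.9)
        assert (sens, spec, tss) == (0.0, 1.0, 0.0)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            de.confusion_stats([], [0.1], 0.5)

    def test_tss_identity_on_random_scores(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.random(rng.integers(1, 30))
            a = rng.random(rng.integers(1, 30))
            tau = rng.random()
            sens, spec, tss = de.confusion_stats(p, a, tau)
            assert tss == pytest.approx(sens + spec - 1.0, abs=1e-12)
            assert -1.0 <= tss <= 1.0


class TestThresholdSelection:
    def test_separable_example(self):
        assert de.select_threshold([0.9, 0.8], [0.1, 0.2]) == pytest.approx(0.8)

    def test_identical_scores_degenerate(self):
        tau = de.select_threshold([0.5, 0.5], [0.5, 0.5])
        assert tau == 0.5
        _, _, tss = de.confusion_stats([0.5, 0.5], [0.5, 0.5], tau)
        assert tss == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            p = rng.choice(np.round(rng.random(10), 2), size=rng.integers(1, 15))
            a = rng.choice(np.round(rng.random(10), 2), size=rng.integers(1, 15))
            assert de.select_threshold(p, a) == pytest.approx(
                brute_force_threshold(p, a)
            )

    @given(
        p=st.lists(st.integers(0, 20).map(lambda v: v / 20), min_size=1, max_size=12),
        a=st.lists(st.integers(0, 20).map(lambda v: v / 20), min_size=1, max_size=12),
    )
    def test_brute_force_equivalence_property(self, p, a):
        p, a = np.array(p), np.array(a)
        assert de.select_threshold(p, a) == pytest.approx(brute_force_threshold(p, a))


class TestMaps:
    def test_binarize_extremes_and_idempotence(self, score_stack):
        suit = score_stack.with_data(
            np.abs(score_stack.data[:1]) / np.nanmax(np.abs(score_stack.data[0]))
        )
        b0 = de.binarize(suit, 0.0)
        assert np.all(b0.data[0][b0.valid] == 1)
        b_hi = de.binarize(suit, 1.0 + 1e-9)
        assert np.all(b_hi.data[0][b_hi.valid] == 0)
        b = de.binarize(suit, 0.4)
        again = de.binarize(b, 0.5)
        np.testing.assert_array_equal(
            b.data[0][b.valid], again.data[0][again.valid]
        )

    def test_ensemble_sum_examples_and_oracle(self):
        ones = binary_map(np.ones((4, 4)))
        assert np.all(de.ensemble_sum([ones, ones, ones]).data[0] == 3)

        rng = np.random.default_rng(2)
        maps = [binary_map((rng.random((5, 5)) > 0.5).astype(float)) for _ in range(3)]
        ens = de.ensemble_sum(maps)
        brute = sum(m.data[0] for m in maps)
        np.testing.assert_array_equal(ens.data[0], brute)
        assert set(np.unique(ens.data[0])) <= {0.0, 1.0, 2.0, 3.0}

    def test_ensemble_requires_three_aligned_maps(self):
        ones = binary_map(np.ones((4, 4)))
        with pytest.raises(ValueError):
            de.ensemble_sum([ones, ones])
        other = RasterStack(
            data=np.ones((1, 4, 4)), x_origin=1.0, y_origin=0.0, cell_size=1.0
        )
        with pytest.raises(ValueError):
            de.ensemble_sum([ones, ones, other])

    def test_area_proportion_counting(self):
        vals = np.zeros((2, 5))
        vals[0, :3] = 3
        vals[1, :2] = 1
        ens = binary_map(vals)
        assert de.area_proportion(ens, "conservative") == pytest.approx(0.3)
        assert de.area_proportion(ens, "nonconservative") == pytest.approx(0.5)
        zero = binary_map(np.zeros((2, 5)))
        assert de.area_proportion(zero, "conservative") == 0.0
        assert de.area_proportion(zero, "nonconservative") == 0.0

    def test_conservative_never_exceeds_nonconservative(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ens = binary_map(rng.integers(0, 4, size=(6, 6)).astype(float))
            assert de.area_proportion(ens, "conservative") <= de.area_proportion(
                ens, "nonconservative"
            )


class TestEvaluateModel:
    def make_inputs(self, truth, score_stack, n_pres=120, seed=0):
        rng = np.random.default_rng(seed)
        grid = truth.suitability
        rows, cols = np.nonzero(truth.presence_mask)
        pick = rng.choice(len(rows), n_pres, replace=False)
        x, y = grid.cell_center(rows[pick], cols[pick])
        pres_xy = np.column_stack([x, y])
        pres_env = de.extract_values(score_stack, pres_xy)
        envp = de.build_envelope(pres_env)
        pa_xy = de.sample_pseudo_absences(score_stack, envp, 50, seed=seed)
        pa_env = de.extract_values(score_stack, pa_xy)
        return pres_xy, pres_env, pa_xy, pa_env

    def test_separable_species_has_high_tss(self, truth, score_stack):
        pres_xy, pres_env, pa_xy, pa_env = self.make_inputs(truth, score_stack)
        part = de.checkerboard_partition(score_stack, 8)
        ev = de.evaluate_model(
            "RDF", pres_xy, pres_env, pa_xy, pa_env, part, score_stack,
            seed=1, window="w",
        )
        assert ev.tss > 0.8
        assert -1.0 <= ev.tss <= 1.0
        assert ev.tss == pytest.approx(ev.sensitivity + ev.specificity - 1.0)

    def test_shuffled_labels_give_near_zero_mean_tss(self, truth, score_stack):
        # permutation null: swap presence/contrast roles randomly
        pres_xy, pres_env, pa_xy, pa_env = self.make_inputs(
            truth, score_stack, n_pres=50
        )
        part = de.checkerboard_partition(score_stack, 8)
        rng = np.random.default_rng(21)
        all_xy = np.vstack([pres_xy, pa_xy])
        all_env = np.vstack([pres_env, pa_env])
        tss = []
        for rep in range(25):
            perm = rng.permutation(len(all_xy))
            ev = de.evaluate_model(
                "RDF",
                all_xy[perm[:50]], all_env[perm[:50]],
                all_xy[perm[50:]], all_env[perm[50:]],
                part, score_stack, seed=rep, window="null",
            )
            tss.append(ev.tss)
        assert abs(np.mean(tss)) < 0.1

    def test_single_class_fold_is_infeasible(self, truth, score_stack):
        pres_xy, pres_env, pa_xy, pa_env = self.make_inputs(truth, score_stack)
        # one block covering everything puts all data in a single fold
        part = de.checkerboard_partition(score_stack, max(score_stack.data.shape))
        with pytest.raises(ValueError, match="block_size"):
            de.evaluate_model(
                "RDF", pres_xy, pres_env, pa_xy, pa_env, part, score_stack
            )
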