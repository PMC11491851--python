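"""Cross-validation, condition crossings, sweeps, group statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import fast_config
from decabt.decoder import fit_islr, predict_islr
from decabt.evaluation import (
    _balanced_indices,
    bh_adjust,
    bootstrap_balance_test,
    cross_condition_decode,
    direction_split_accuracy,
    group_tests,
    loro_cv,
    paired_tests,
    search_roi_sweep,
)
from decabt.pipeline import decode_synthetic, label_dataset
from decabt.preprocess import FeatureMatrix, build_features
from decabt.synthetic_data import GroundTruth, gen_dataset, gen_rt_dataset, gen_voxel_timeseries


def toy_features(rng, n_runs=3, per_run=20, d=8, k=3, effect=2.0, condition="gaming"):
    """Feature matrix with class-coded means in the first k columns."""
    X, y, runs, dirs = [], [], [], []
    for r in range(n_runs):
        yr = (np.arange(per_run) % 2).astype(int)
        rng.shuffle(yr)
        Xr = rng.standard_normal((per_run, d))
        Xr[:, :k] += effect * (yr[:, None] - 0.5)
        X.append(Xr)
        y.append(yr)
        runs.append(np.full(per_run, r))
        dirs.append(rng.choice(["approach", "avoidance"], size=per_run))
    return FeatureMatrix(
        X=np.vstack(X),
        y=np.concatenate(y),
        run=np.concatenate(runs),
        direction=np.concatenate(dirs),
        condition=np.full(n_runs * per_run, condition),
        trial=np.arange(n_runs * per_run),
        voxel_ids=np.arange(d),
    )


class TestLoroCv:
    def test_balancing_exact_counts(self, rng):
        y = np.array([1] * 30 + [0] * 12)
        for _ in range(10):
            idx = _balanced_indices(y, rng)
            assert (y[idx] == 1).sum() == (y[idx] == 0).sum() == 12

    def test_balanced_classes_make_downsampling_noop(self, rng):
        fm = toy_features(rng)
        res = loro_cv(fm, n_resamples=3, seed=0, n_islr_iter=2)
        # with equal class counts every resample trains on the same rows,
        # so the per-resample fold accuracies are identical
        per = res.predictions.assign(c=lambda d: d.y_true == d.y_pred)
        spread = per.groupby(["run", "resample"])["c"].mean().groupby("run").std()
        assert np.allclose(spread.fillna(0.0), 0.0)

    def test_separable_data_decodes_accurately(self, default_session, default_cv):
        """Full pipeline on the default synthetic session recovers the
        planted state well above chance (standardized effect 1.0)."""
        assert default_cv.accuracy > 0.8

    def test_strong_signal_near_ceiling(self):
        from decabt.synthetic_data import SimConfig

        cfg = SimConfig(signal_effect=1.5, seed=21)
        res = decode_synthetic(cfg, n_resamples=2, seed=0)
        assert res.accuracy > 0.9

    def test_single_run_rejected(self, rng):
        fm = toy_features(rng, n_runs=1)
        with pytest.raises(ValueError, match="2 runs"):
            loro_cv(fm)


class TestConditionCrossings:
    def test_self_crossing_equals_loro(self, rng):
        fm = toy_features(rng)
        a = loro_cv(fm, n_resamples=2, seed=3, n_islr_iter=2)
        b = cross_condition_decode(fm, fm, n_resamples=2, seed=3, n_islr_iter=2)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_four_crossings_and_signal_asymmetry(self):
        """Only gaming labels track the planted neural state, so the gaming
        condition must decode better than the neutral->gaming crossing."""
        cfg = fast_config(seed=13)
        trials, truth, runs = gen_dataset(cfg)
        run_list = list(runs.values())
        gaming = label_dataset(trials, condition="gaming")
        fake = label_dataset(trials, condition="neutral")
        labeled = pd.concat([gaming, fake], ignore_index=True)
        fg = build_features(run_list, labeled, condition="gaming")
        fn = build_features(run_list, labeled, condition="neutral")
        results = {}
        for name, (tr, te) in {
            "gaming": (fg, fg),
            "gaming_to_neutral": (fg, fn),
            "neutral": (fn, fn),
            "neutral_to_gaming": (fn, fg),
        }.items():
            results[name] = cross_condition_decode(
                tr, te, n_resamples=2, seed=1, n_islr_iter=3
            ).accuracy
        assert len(results) == 4
        assert results["gaming"] > results["neutral_to_gaming"]

    def test_voxel_space_mismatch_rejected(self, rng):
        a = toy_features(rng, d=8)
        b = toy_features(rng, d=6)
        with pytest.raises(ValueError, match="voxel"):
            cross_condition_decode(a, b)


class TestDirectionSplit:
    def test_all_correct_both_directions(self, rng):
        fm = toy_features(rng, effect=8.0)
        res = loro_cv(fm, n_resamples=1, seed=0, n_islr_iter=1)
        split = direction_split_accuracy(res)
        assert split["approach"] == 1.0 and split["avoidance"] == 1.0

    def test_weighted_mean_identity(self, default_cv):
        split = direction_split_accuracy(default_cv)
        preds = default_cv.predictions
        weights = preds["direction"].value_counts(normalize=True)
        combined = sum(split[d] * weights[d] for d in ("approach", "avoidance"))
        assert combined == pytest.approx(default_cv.pooled_accuracy)

    def test_direction_specific_signal(self, rng):
        """Signal planted only in avoidance trials -> avoidance decodes better."""
        fm = toy_features(rng, per_run=30, effect=0.0)
        is_avoid = np.asarray(fm.direction) == "avoidance"
        fm.X[is_avoid, :3] += 3.0 * (fm.y[is_avoid, None] - 0.5)
        res = loro_cv(fm, n_resamples=2, seed=0, n_islr_iter=2)
        split = direction_split_accuracy(res)
        assert split["avoidance"] > split["approach"]


class TestSearchRoiSweep:
    @staticmethod
    def _gridded_dataset(seed, n_regions, signal_region):
        """Small session whose voxels tile a 2-D slab; the planted informative
        voxels are exactly the voxels of one parcel."""
        shape = (8, 6, 2)
        parcellation = (
            np.arange(n_regions).repeat(np.prod(shape) // n_regions) + 1
        ).reshape(shape)
        coords = np.argwhere(np.ones(shape, dtype=bool))
        informative = np.flatnonzero(parcellation.ravel() == signal_region)
        cfg = fast_config(
            n_voxels=int(np.prod(shape)),
            n_informative_voxels=informative.size,
            n_dead_voxels=0,
            n_noisy_voxels=0,
            signal_effect=1.5,
            seed=seed,
        )
        trials, truth, _ = gen_dataset(cfg)
        truth = GroundTruth(
            latent_state=truth.latent_state,
            informative_voxel_ids=informative,
            dead_voxel_ids=np.empty(0, dtype=int),
            noisy_voxel_ids=np.empty(0, dtype=int),
        )
        runs = []
        for r in range(cfg.n_runs_per_participant):
            run = gen_voxel_timeseries(cfg, trials, truth, 0, r)
            run.voxel_coords = coords
            runs.append(run)
        labeled = label_dataset(trials)
        return parcellation, runs, labeled

    def test_planted_region_attains_maximum(self):
        parcellation, runs, labeled = self._gridded_dataset(seed=5, n_regions=8, signal_region=3)
        table = search_roi_sweep(
            parcellation, [(runs, labeled)], n_resamples=2, n_islr_iter=3, seed=0
        )
        assert len(table) == 8
        best = table.loc[table["accuracy"].idxmax(), "region"]
        assert best == 3

    def test_single_region_equals_whole_mask(self):
        parcellation, runs, labeled = self._gridded_dataset(seed=6, n_regions=1, signal_region=1)
        table = search_roi_sweep(
            parcellation, [(runs, labeled)], n_resamples=2, n_islr_iter=3, seed=4
        )
        feats = build_features(runs, labeled)
        direct = loro_cv(feats, n_resamples=2, n_islr_iter=3, seed=4)
        assert len(table) == 1
        assert table["accuracy"].iloc[0] == pytest.approx(direct.accuracy * 100.0)


class TestGroupStats:
    @staticmethod
    def _acc_frame(values_by_cell, participants=5):
        rows = []
        for (roi, cond), vals in values_by_cell.items():
            for p, v in enumerate(vals):
                rows.append({"participant": p, "roi": roi, "condition": cond, "accuracy": v})
        return pd.DataFrame(rows)

    def test_chance_accuracies_give_null_stats(self):
        df = self._acc_frame({("insula", "gaming"): [0.5] * 5, ("vmPFC", "gaming"): [0.5] * 5})
        out = group_tests(df)
        assert (out["t_stat"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_bh_adjustment_matches_step_up_enumeration(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.2])
        # step-up by hand: p_(i) * n/i, cumulative minimum from the largest
        expected = [0.005, 0.025, 0.02 * 5 / 3, 0.05, 0.2]
        assert np.allclose(bh_adjust(p), expected)

    def test_roi_by_condition_family_size(self, rng):
        rois = ["vmPFC", "insula", "amygdala", "hippocampus", "VS", "mesolimbic", "cerebellum"]
        conds = ["gaming", "gaming_to_neutral", "neutral", "neutral_to_gaming"]
        cells = {
            (roi, cond): 0.5 + 0.05 * rng.standard_normal(6)
            for roi, cond in itertools.product(rois, conds)
        }
        out = group_tests(self._acc_frame(cells))
        assert len(out) == 28

    def test_paired_contrast(self, rng):
        cells = {
            ("insula", "gaming"): 0.62 + 0.02 * rng.standard_normal(8),
            ("insula", "neutral"): 0.50 + 0.02 * rng.standard_normal(8),
        }
        out = paired_tests(self._acc_frame(cells), [("gaming", "neutral")])
        assert out["p"].iloc[0] < 0.01
        assert out["mean_diff"].iloc[0] > 0.05

    def test_type_one_error_control(self):
        """Signal-free accuracies (binomial at chance, 21 participants x 112
        held-out trials) reject H0: mean = 0.5 at ~5% over 200 simulations."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            acc = rng.binomial(112, 0.5, size=21) / 112.0
            df = self._acc_frame({("roi", "gaming"): acc})
            out = group_tests(df)
            rejections += int(out["p"].iloc[0] < 0.05)
        assert 0.025 <= rejections / n_sims <= 0.075

    def test_accuracy_monotone_in_signal_effect(self):
        """Mean pipeline accuracy is non-decreasing over a 3-point signal grid."""
        means = []
        for effect in (0.0, 0.75, 1.5):
            accs = [
                decode_synthetic(
                    fast_config(signal_effect=effect, seed=100 + s),
                    n_resamples=2,
                    seed=s,
                    n_islr_iter=5,
                ).accuracy
                for s in range(20)
            ]
            means.append(np.mean(accs))
        assert means[0] <= means[1] <= means[2]


class TestBootstrapBalance:
    def test_identical_groups_null(self):
        a = np.full(6, 0.6)
        b = np.full(4, 0.6)
        res = bootstrap_balance_test(a, b, n_sub=4, n_boot=500, seed=0)
        assert res.p_value == 1.0

    def test_disjoint_supports_floor(self):
        a = np.linspace(10.0, 11.0, 6)
        b = np.linspace(0.0, 1.0, 4)
        res = bootstrap_balance_test(a, b, n_sub=3, n_boot=1000, seed=0)
        assert res.exact  # C(6,3) = 20 subsets enumerated
        assert res.p_value == pytest.approx(1.0 / 21.0)

    def test_matches_exhaustive_enumeration_oracle(self):
        """|a| = 4, n_sub = 2: independent enumeration of all 6 subsets."""
        a = np.array([0.3, 0.9, 0.6, 0.8])
        b = np.array([0.4, 0.5])
        res = bootstrap_balance_test(a, b, n_sub=2, n_boot=100, seed=1)
        stats = [
            a[list(c)].mean() - b.mean() for c in itertools.combinations(range(4), 2)
        ]
        observed = a.mean() - b.mean()
        count = sum(s <= 0 for s in stats) if observed > 0 else sum(s >= 0 for s in stats)
        assert res.exact
        assert res.p_value == pytest.approx((count + 1) / (len(stats) + 1))

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError, match="n_sub"):
            bootstrap_balance_test(np.ones(3), np.ones(2), n_sub=5)


class TestPermutedLabels:
    def test_permuted_labels_fall_to_chance_small(self):
        """Label permutation kills decodability (scaled-down, 5 seeds)."""
        accs = [
            decode_synthetic(
                fast_config(seed=300 + s), n_resamples=2, seed=s,
                permute_labels=True, n_islr_iter=5,
            ).accuracy
            for s in range(5)
        ]
        assert 0.4 <= np.mean(accs) <= 0.6
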