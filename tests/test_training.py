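"""Training protocol: augmentation bookkeeping, the cosine schedule, the
optimisation loop contract, cross-validation, and random search."""

import numpy as np
import pandas as pd
import pytest

from octostack import (AugmentConfig, SearchSpace, TrainConfig, augment_sample,
                       cross_validate, default_spec, expand_dataset, lr_at,
                       random_search, train, validate_sample)
from tests.conftest import dummy_samples


def fast_config(**kw):
    defaults = dict(batch_size=4, max_epochs=2, early_stop_patience=10, seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestAugmentation:
    def test_hflip_is_an_involution(self, rng):
        s = dummy_samples(1, shape=(8, 8))[0]
        cfg = AugmentConfig(hflip=True, gaussian_sigma=0.0,
                            contrast_range=(1.0, 1.0))
        twice = augment_sample(augment_sample(s, cfg, rng), cfg, rng)
        assert np.array_equal(twice.image, s.image)
        assert np.array_equal(twice.mask, s.mask)

    def test_zero_config_changes_only_the_flag(self, rng):
        s = dummy_samples(1)[0]
        cfg = AugmentConfig(hflip=False, gaussian_sigma=0.0,
                            contrast_range=(1.0, 1.0))
        out = augment_sample(s, cfg, rng)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)
        assert out.augmented and not s.augmented

    def test_flip_reverses_every_mask_column(self, rng):
        s = dummy_samples(1, shape=(8, 8))[0]
        cfg = AugmentConfig(hflip=True, gaussian_sigma=0.0,
                            contrast_range=(1.0, 1.0))
        out = augment_sample(s, cfg, rng)
        for j in range(8):
            assert np.array_equal(out.mask[:, j], s.mask[:, 7 - j])

    def test_noise_and_contrast_touch_image_not_mask(self, rng):
        s = dummy_samples(1)[0]
        cfg = AugmentConfig(hflip=False, gaussian_sigma=0.05,
                            contrast_range=(0.8, 1.2))
        out = augment_sample(s, cfg, rng)
        assert not np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)
        assert out.image.min() >= 0 and out.image.max() <= 1


class TestExpansion:
    def test_factor_two_doubles_122_to_244(self):
        samples = dummy_samples(122)
        out = expand_dataset(samples, AugmentConfig(expansion_factor=2), seed=0)
        assert len(out) == 244
        assert out[:122] == samples  # originals verbatim

    def test_factor_one_is_identity(self):
        samples = dummy_samples(5)
        assert expand_dataset(samples, AugmentConfig(expansion_factor=1),
                              seed=0) == samples

    @pytest.mark.parametrize("factor", [2, 3, 4])
    def test_output_size_scales_exactly(self, factor):
        out = expand_dataset(dummy_samples(7),
                             AugmentConfig(expansion_factor=factor), seed=0)
        assert len(out) == 7 * factor

    def test_augmented_copies_remain_valid(self):
        from octostack import make_label_scheme
        samples = dummy_samples(10, C=3)
        scheme = make_label_scheme(["background", "a", "b"])
        out = expand_dataset(samples, AugmentConfig(), seed=1)
        assert all(validate_sample(s, scheme) == [] for s in out)

    def test_seeded_reproducibility(self):
        samples = dummy_samples(6)
        a = expand_dataset(samples, AugmentConfig(), seed=3)
        b = expand_dataset(samples, AugmentConfig(), seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)


class TestSchedule:
    def test_endpoints_match_protocol(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(0.001)
        assert lr_at(cfg.max_epochs, cfg) == pytest.approx(1e-5)

    def test_cosine_midpoint(self):
        cfg = TrainConfig(max_epochs=10)
        assert lr_at(5, cfg) == pytest.approx((0.001 + 1e-5) / 2)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig()
        lrs = [lr_at(e, cfg) for e in range(cfg.max_epochs + 1)]
        assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))

    def test_warmup_prefix_rises_linearly(self):
        cfg = TrainConfig(schedule="cosine+warmup", warmup_epochs=5,
                          max_epochs=20)
        warm = [lr_at(e, cfg) for e in range(5)]
        assert all(b > a for a, b in zip(warm, warm[1:]))
        assert lr_at(cfg.max_epochs, cfg) == pytest.approx(1e-5)

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at(100, TrainConfig(max_epochs=75))


class TestTrainLoop:
    def test_one_epoch_logs_once_and_moves_weights(self, tiny_phantoms):
        samples, cfg = tiny_phantoms
        spec = default_spec(cfg.n_classes, n_stacks=1, encoder="tiny-slim")
        from octostack import build_stacked
        init = build_stacked(spec, seed=0).state_dict()
        model, log = train(spec, samples[:8], samples[8:],
                           fast_config(max_epochs=1))
        assert len(log) == 1
        assert {"epoch", "train_loss", "val_loss", "val_dice", "lr"} <= \
            set(log.columns)
        trained = model.state_dict()
        assert any(not np.array_equal(trained[k], init[k]) for k in init)

    def test_early_stopping_on_flat_validation(self, tiny_phantoms, monkeypatch):
        samples, cfg = tiny_phantoms
        monkeypatch.setattr("octostack.training._evaluate",
                            lambda *a, **k: (0.5, 0.5))
        spec = default_spec(cfg.n_classes, n_stacks=1, encoder="tiny-slim")
        _, log = train(spec, samples[:8], samples[8:],
                       fast_config(max_epochs=10, early_stop_patience=2))
        assert len(log) == 3  # best at epoch 0, two stalls, stop

    def test_seeded_runs_are_identical(self, tiny_phantoms):
        samples, cfg = tiny_phantoms
        spec = default_spec(cfg.n_classes, n_stacks=1, encoder="tiny-slim")
        _, log_a = train(spec, samples[:8], samples[8:], fast_config())
        _, log_b = train(spec, samples[:8], samples[8:], fast_config())
        pd.testing.assert_frame_equal(log_a, log_b)

    def test_joint_mode_updates_both_stacks(self, tiny_phantoms):
        """Both stacks train jointly; the refiner's zero-initialised head
        needs one warm-up step before its body receives gradients, so the
        audit runs two optimisation steps."""
        samples, cfg = tiny_phantoms
        spec = default_spec(cfg.n_classes, n_stacks=2, encoder="tiny-slim")
        from octostack import build_stacked
        init = build_stacked(spec, seed=0).state_dict()
        model, _ = train(spec, samples[:8], samples[8:10],
                         fast_config(max_epochs=1, early_stop_patience=1))
        trained = model.state_dict()
        for k in range(2):
            stack_names = [n for n, _ in model.encoders[k].named_parameters()]
            moved = sum(
                not np.array_equal(trained[f"encoders.{k}.{n}"],
                                   init[f"encoders.{k}.{n}"])
                for n in stack_names)
            assert moved > 0

    def test_sequential_mode_trains_stacks_in_phases(self, tiny_phantoms):
        samples, cfg = tiny_phantoms
        spec = default_spec(cfg.n_classes, n_stacks=2, encoder="tiny-slim")
        _, log = train(spec, samples[:4], samples[4:6],
                       fast_config(max_epochs=1, stack_mode="sequential"))
        assert list(log["phase"].unique()) == ["stack1", "stack2"]

    def test_empty_validation_rejected(self, tiny_phantoms):
        samples, cfg = tiny_phantoms
        with pytest.raises(ValueError):
            train(default_spec(cfg.n_classes, n_stacks=1), samples, [],
                  fast_config())


class TestCrossValidation:
    def test_two_fold_summary(self, tiny_phantoms):
        samples, cfg = tiny_phantoms
        spec = default_spec(cfg.n_classes, n_stacks=1, encoder="tiny-slim")
        summary, logs = cross_validate(samples, spec,
                                       fast_config(max_epochs=1), k=2)
        assert len(summary.fold_scores) == 2
        assert all(0.0 <= s <= 1.0 for s in summary.fold_scores)
        assert len(logs) == 2


class TestRandomSearch:
    def test_singleton_grids_yield_identical_draws(self):
        space = SearchSpace(grids={"batch_size": [32]}, budget=3, seed=0)
        trials = random_search(space, lambda cfg: 1.0)
        assert len(trials) == 3
        assert all(cfg == {"batch_size": 32} for _, cfg in trials)

    def test_draws_are_grid_members_and_ranked(self):
        space = SearchSpace(grids={"batch_size": [16, 32, 64],
                                   "lr_init": [0.01, 0.001]},
                            budget=8, seed=1)
        trials = random_search(space, lambda cfg: cfg["lr_init"])
        for score, cfg in trials:
            assert cfg["batch_size"] in (16, 32, 64)
            assert cfg["lr_init"] in (0.01, 0.001)
        scores = [s for s, _ in trials]
        assert scores == sorted(scores, reverse=True)

    def test_same_seed_same_sequence(self):
        space = SearchSpace(grids={"batch_size": [16, 32, 64]}, budget=5)
        a = random_search(space, lambda c: 0.0, seed=9)
        b = random_search(space, lambda c: 0.0, seed=9)
        assert [c for _, c in a] == [c for _, c in b]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(grids={"batch_size": []}, budget=1)
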