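"""Training regimes: data hygiene, reproducibility, merge contract."""

import numpy as np
import pytest

from slicefill.completion_net import (
    NetworkSpec,
    TrainConfig,
    TrainedModel,
    build_network,
    complete,
    train_full_supervision,
    train_ov2assion,
)
from slicefill.metrics import dice_per_structure
from slicefill.phantom import generate_cohort, generate_phantom
from slicefill.schedule import ScheduleError, build_schedule, foreground_extent, mask_annotations
from slicefill.volume_io import TUMOR

from conftest import small_phantom_config

TINY_SPEC = NetworkSpec(depth=2, base_channels=4)


def tiny_cfg(**kw):
    base = dict(epochs=3, batch_size=8, seed=0)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(small_phantom_config(seed=8))


@pytest.fixture(scope="module")
def micro_cohort():
    return generate_cohort(3, seed=3, base=small_phantom_config(), rater_targets=None)


class TestTrainOv2assion:
    def test_trains_only_on_manual_slices(self, phantom):
        vol, lm = phantom
        schedule = build_schedule(lm.n_slices, 5)
        sparse = mask_annotations(lm, schedule)
        seen = []
        model = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg(),
                                batch_hook=lambda e, keys: seen.extend(keys))
        seen_slices = {s for _, s in seen}
        assert seen_slices == set(schedule.manual_indices.tolist())
        assert set(model.trained_slice_keys) == {(0, int(s)) for s in schedule.manual_indices}

    def test_gap0_uses_every_slice(self, phantom):
        vol, lm = phantom
        sparse = mask_annotations(lm, build_schedule(lm.n_slices, 0))
        model = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg())
        assert len(model.trained_slice_keys) == lm.n_slices

    def test_too_few_manual_slices(self, phantom):
        vol, lm = phantom
        schedule = build_schedule(lm.n_slices, 1)
        manual = np.zeros(lm.n_slices, bool)
        manual[0] = True
        starved = type(schedule)(gap=1, n_slices=lm.n_slices, manual=manual)
        sparse = mask_annotations(lm, starved)
        with pytest.raises(ScheduleError, match="at least 2"):
            train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg())

    def test_loss_log_and_reproducibility(self, phantom):
        vol, lm = phantom
        sparse = mask_annotations(lm, build_schedule(lm.n_slices, 3))
        a = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg(epochs=5))
        b = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg(epochs=5))
        assert len(a.log) == 5
        assert all(np.isfinite(l) for _, l in a.log)
        assert a.log == b.log  # identical loss trajectory
        np.testing.assert_array_equal(a.predict_volume(vol).labels,
                                      b.predict_volume(vol).labels)

    def test_overfits_manual_slices(self, phantom):
        # deliberate overlearning: memorising the annotated sections of one
        # patient is the intended behaviour of the per-volume regime
        vol, lm = phantom
        schedule = build_schedule(lm.n_slices, 5, extent=foreground_extent(lm))
        sparse = mask_annotations(lm, schedule)
        model = train_ov2assion(vol, sparse, NetworkSpec(depth=3, base_channels=16),
                                TrainConfig(epochs=40, batch_size=16, seed=1))
        pred = model.predict_volume(vol)
        manual = schedule.manual_indices
        d = dice_per_structure(pred, lm, TUMOR, manual)
        assert d > 0.9


class TestTrainFullSupervision:
    def test_excluded_patient_never_sampled(self, micro_cohort):
        seen = []
        train_full_supervision(micro_cohort, 1, TINY_SPEC, tiny_cfg(),
                               batch_hook=lambda e, keys: seen.extend(keys))
        assert seen
        assert all(pid != 1 for pid, _ in seen)

    def test_log_length_and_finiteness(self, micro_cohort):
        model = train_full_supervision(micro_cohort, 2, TINY_SPEC, tiny_cfg(epochs=5))
        assert len(model.log) == 5
        assert all(np.isfinite(l) for _, l in model.log)

    def test_loss_decreases_over_training(self, micro_cohort):
        model = train_full_supervision(micro_cohort, 0, TINY_SPEC,
                                       tiny_cfg(epochs=12, seed=2))
        assert model.log[-1][1] < model.log[0][1]

    def test_unknown_patient(self, micro_cohort):
        with pytest.raises(ValueError, match="unknown patient"):
            train_full_supervision(micro_cohort, 99, TINY_SPEC, tiny_cfg())

    def test_fingerprints_differ_per_heldout(self, micro_cohort):
        fp = [train_full_supervision(micro_cohort, p, TINY_SPEC, tiny_cfg(epochs=1)).data_fingerprint
              for p in range(3)]
        assert len(set(fp)) == 3


class TestComplete:
    def test_manual_slices_bit_identical(self, phantom):
        vol, lm = phantom
        schedule = build_schedule(lm.n_slices, 4)
        sparse = mask_annotations(lm, schedule)
        model = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg())
        out = complete(model, vol, sparse)
        np.testing.assert_array_equal(out.labels[schedule.manual],
                                      lm.labels[schedule.manual])

    def test_gap0_returns_annotation_exactly(self, phantom):
        vol, lm = phantom
        sparse = mask_annotations(lm, build_schedule(lm.n_slices, 0))
        model = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg(epochs=1))
        out = complete(model, vol, sparse)
        np.testing.assert_array_equal(out.labels, lm.labels)


class TestCheckpoint:
    def test_save_load_identical_predictions(self, phantom, tmp_path):
        vol, lm = phantom
        sparse = mask_annotations(lm, build_schedule(lm.n_slices, 3))
        model = train_ov2assion(vol, sparse, TINY_SPEC, tiny_cfg())
        path = tmp_path / "model.npz"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(model.predict_volume(vol).labels,
                                      back.predict_volume(vol).labels)
        assert back.data_fingerprint == model.data_fingerprint

    def test_build_network_spec_round_trip(self):
        net = build_network(NetworkSpec(depth=2, base_channels=8), seed=5)
        assert net.depth == 2 and net.base_channels == 8
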