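import numpy as np
import pytest

import postshim as ps
from postshim.extraction import conv_same
from postshim.training import REFERENCE_SCHEDULE, TrainingSchedule, smoke_schedule


class TestSchedule:
    def test_reference_schedule_totals_40_million(self):
        assert REFERENCE_SCHEDULE.total_spectra == 40_000_000
        assert REFERENCE_SCHEDULE.phases[0][1:] == (64, 0.0010)
        assert REFERENCE_SCHEDULE.phases[1][1:] == (512, 0.0010)
        assert REFERENCE_SCHEDULE.phases[2][1:] == (512, 0.0005)

    def test_indivisible_phase_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainingSchedule(phases=((100, 64, 1e-3),))

    def test_smoke_preset_rounds_to_batch_multiple(self):
        s = smoke_schedule(50_000, 64)
        assert s.total_spectra % 64 == 0
        assert abs(s.total_spectra - 50_000) < 64


class TestLoss:
    def test_zero_at_perfect_solution(self, freq_step):
        rng = np.random.default_rng(0)
        s_trg = rng.uniform(0, 4, size=(3, 128))
        r_trg = np.zeros((3, 9))
        r_trg[:, 4] = 1.0  # unit impulses: distortion-free
        s_inp = s_trg.copy()
        bd = ps.loss(s_trg, s_inp, s_trg, r_trg, r_trg)
        assert bd.total == pytest.approx(0.0, abs=1e-15)

    def test_total_is_sum_of_terms(self):
        rng = np.random.default_rng(1)
        s_trg, s_inp, s_out = rng.normal(size=(3, 2, 64))
        r_trg, r_out = rng.normal(size=(2, 2, 7))
        bd = ps.loss(s_trg, s_inp, s_out, r_trg, r_out)
        assert bd.total == pytest.approx(bd.reconstruction + bd.distortion + bd.consistency)
        assert bd.reconstruction >= 0 and bd.distortion >= 0 and bd.consistency >= 0

    def test_duplicating_batch_members_leaves_loss_unchanged(self):
        rng = np.random.default_rng(2)
        s_trg, s_inp, s_out = rng.normal(size=(3, 4, 64))
        r_trg, r_out = rng.normal(size=(2, 4, 9))
        single = ps.loss(s_trg, s_inp, s_out, r_trg, r_out)
        double = ps.loss(
            np.tile(s_trg, (2, 1)), np.tile(s_inp, (2, 1)), np.tile(s_out, (2, 1)),
            np.tile(r_trg, (2, 1)), np.tile(r_out, (2, 1)),
        )
        assert double.total == pytest.approx(single.total, rel=1e-12)

    def test_hand_built_scalar_oracle(self):
        """K=1, 8-point spectra, 3-point response: every term written out
        element by element."""
        s_trg = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        s_out = np.array([0.0, 1.0, 1.5, 1.0, 0.5, 0.0, 0.0, 0.0])
        s_inp = np.array([0.5, 1.0, 2.0, 1.0, 0.0, 0.5, 0.0, 0.0])
        r_trg = np.array([0.0, 1.0, 0.0])  # unit impulse
        r_out = np.array([0.1, 0.8, 0.1])

        rec = np.mean((s_trg - s_out) ** 2)
        dist = np.mean((r_trg - r_out) ** 2)
        # centered same-length convolution of s_out with r_out, zero padded
        conv = np.zeros(8)
        for n in range(8):
            for j, rj in enumerate(r_out):
                m = n - (j - 1)
                if 0 <= m < 8:
                    conv[n] += rj * s_out[m]
        cons = np.mean((s_inp - conv) ** 2)

        bd = ps.loss(s_trg, s_inp, s_out, r_trg, r_out)
        assert bd.reconstruction == pytest.approx(rec, abs=1e-12)
        assert bd.distortion == pytest.approx(dist, abs=1e-12)
        assert bd.consistency == pytest.approx(cons, abs=1e-12)
        assert bd.total == pytest.approx(rec + dist + cons, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ps.loss(np.zeros((2, 8)), np.zeros((2, 8)), np.zeros((2, 9)),
                    np.zeros((2, 3)), np.zeros((2, 3)))

    def test_output_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        s_trg, s_inp = rng.normal(size=(2, 2, 32))
        r_trg = rng.normal(size=(2, 5))
        s_out = rng.normal(size=(2, 32))
        r_out = rng.normal(size=(2, 5))
        bd, dS, dR = ps.loss_and_grads(s_trg, s_inp, s_out, r_trg, r_out)
        eps = 1e-7
        for arr, grad in ((s_out, dS), (r_out, dR)):
            for fi in (0, arr.size // 2, arr.size - 1):
                orig = arr.flat[fi]
                arr.flat[fi] = orig + eps
                lp = ps.loss(s_trg, s_inp, s_out, r_trg, r_out).total
                arr.flat[fi] = orig - eps
                lm = ps.loss(s_trg, s_inp, s_out, r_trg, r_out).total
                arr.flat[fi] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(grad.flat[fi], abs=1e-6)


class TestTrainLoop:
    def _setup(self, small_library, n_points=256, channels=6):
        config = ps.SpectrumSamplingConfig(freq_step=small_library.freq_step, n_points=n_points)
        cfg = ps.ModelConfig(
            channels=channels, kernel=7, depth=4, aux_hidden=8,
            n_response=small_library.n_response, seed=0,
        )
        state = ps.init_state(cfg)
        return config, state

    def test_one_step_touches_every_layer(self, small_library):
        config, state = self._setup(small_library)
        before = {k: v.copy() for k, v in state.params.items()}
        schedule = TrainingSchedule(phases=((8, 8, 1e-3),))
        state, history = ps.train(state, small_library, config, schedule, seed=1)
        for k, v in state.params.items():
            assert not np.array_equal(before[k], v), f"{k} unchanged after a step"
        assert history["n_generated"] == 8

    def test_reproducible_loss_history(self, small_library):
        config, state_a = self._setup(small_library)
        _, state_b = self._setup(small_library)
        schedule = TrainingSchedule(phases=((24, 8, 1e-3),))
        _, hist_a = ps.train(state_a, small_library, config, schedule, seed=5)
        _, hist_b = ps.train(state_b, small_library, config, schedule, seed=5)
        assert hist_a["total"] == hist_b["total"]

    def test_online_learning_never_reuses_spectra(self, small_library):
        config, state = self._setup(small_library)
        schedule = TrainingSchedule(phases=((16, 8, 1e-3), (16, 4, 1e-3)))
        _, history = ps.train(state, small_library, config, schedule, seed=2)
        assert history["n_generated"] == schedule.total_spectra == 32
        assert len(history["total"]) == schedule.total_batches == 6

    def test_library_length_mismatch_rejected(self, small_library):
        config, _ = self._setup(small_library)
        cfg = ps.ModelConfig(channels=4, kernel=3, depth=1, n_response=9, seed=0)
        state = ps.init_state(cfg)
        with pytest.raises(ValueError, match="n_response"):
            ps.train(state, small_library, config, TrainingSchedule(phases=((8, 8, 1e-3),)), seed=0)


class TestEvaluate:
    def test_impulse_library_noise_off_gives_zero_baseline(self, freq_step):
        imp = np.zeros(63)
        imp[31] = 1.0
        lib = ps.ResponseLibrary(imp[None, :], freq_step)
        config = ps.SpectrumSamplingConfig(freq_step=freq_step, n_points=256, noise_max=0.0)
        cfg = ps.ModelConfig(channels=4, kernel=7, depth=4, aux_hidden=8, n_response=63, seed=0)
        state = ps.init_state(cfg)
        metrics = ps.evaluate(state, 8, lib, config, seed=3)
        assert metrics["baseline_mse"] == pytest.approx(0.0, abs=1e-20)

    def test_untrained_state_is_same_order_as_baseline(self, small_library):
        config = ps.SpectrumSamplingConfig(freq_step=small_library.freq_step, n_points=256)
        cfg = ps.ModelConfig(channels=6, kernel=7, depth=4, aux_hidden=8,
                             n_response=small_library.n_response, seed=0)
        state = ps.init_state(cfg)
        metrics = ps.evaluate(state, 16, small_library, config, seed=4)
        # a random network neither solves nor catastrophically amplifies
        assert 0.1 < metrics["mse_ratio"] < 100
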