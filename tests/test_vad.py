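import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausekit.audio_io import TARGET_RATE, AudioSignal
from pausekit.vad import (
    DENSITY_EPS,
    ENERGY_EPS,
    SUBBAND_EDGES_HZ,
    FrameDecision,
    GaussianMixture1D,
    SubbandEnergies,
    VadModel,
    classify_frame,
    compute_subband_energies,
    fit_default_model,
    frame_loglik_ratios,
    gmm_density,
    run_vad,
    subband_energies_batch,
)

from conftest import random_model, tone


# ---------------------------------------------------------------------------
# independent scalar oracles (plain python math, no shared code paths)

def oracle_energies(frame, sr):
    n = len(frame)
    w = np.hanning(n)
    spec = np.abs(np.fft.rfft(np.asarray(frame) * w)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / sr)
    E = []
    for lo, hi in zip(SUBBAND_EDGES_HZ[:-1], SUBBAND_EDGES_HZ[1:]):
        E.append(10 * math.log10(float(spec[(freqs >= lo) & (freqs < hi)].sum()) + 1e-12))
    tot = float(spec[(freqs >= 80.0) & (freqs < 4000.0)].sum())
    return E, 10 * math.log10(tot + 1e-12)


def oracle_density(weights, means, stds, e):
    return sum(
        w / (s * math.sqrt(2 * math.pi)) * math.exp(-((e - m) ** 2) / (2 * s * s))
        for w, m, s in zip(weights, means, stds)
    )


def oracle_decision(model, energies):
    """Term-by-term evaluation of the gate, ratios and thresholds."""
    if energies.E_t <= model.Tm:
        return 0
    L = []
    for i in range(6):
        p0 = max(oracle_density(model.silent[i].weights, model.silent[i].means, model.silent[i].stds, energies.E[i]), DENSITY_EPS)
        p1 = max(oracle_density(model.voiced[i].weights, model.voiced[i].means, model.voiced[i].stds, energies.E[i]), DENSITY_EPS)
        L.append(math.log2(p1 / p0))
    L_t = sum(k * l for k, l in zip(model.K, L))
    return int(any(l > model.T_tau for l in L) or L_t > model.T_a)


# ---------------------------------------------------------------------------

class TestSubbandEnergies:
    def test_all_zero_frame_hits_floor(self):
        e = compute_subband_energies(np.zeros(1323), TARGET_RATE)
        np.testing.assert_allclose(e.E, 10 * np.log10(ENERGY_EPS))
        assert e.E_t == pytest.approx(10 * np.log10(ENERGY_EPS))

    def test_pure_tone_dominates_its_band(self):
        frame = tone(1500.0, 0.03).samples
        e = compute_subband_energies(frame, TARGET_RATE)
        others = np.delete(e.E, 3)
        assert np.all(e.E[3] - others >= 20.0)  # 1-2 kHz band wins by >= 20 dB

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(-1, 1, 1323)
        e = compute_subband_energies(frame, TARGET_RATE)
        E_ref, Et_ref = oracle_energies(frame, TARGET_RATE)
        np.testing.assert_allclose(e.E, E_ref, atol=1e-9)
        assert e.E_t == pytest.approx(Et_ref, abs=1e-9)

    def test_amplitude_scaling_adds_20db(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(-0.05, 0.05, 1323)
        e1 = compute_subband_energies(frame, TARGET_RATE)
        e10 = compute_subband_energies(10 * frame, TARGET_RATE)
        np.testing.assert_allclose(e10.E - e1.E, 20.0, atol=0.01)

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(5)
        frames = rng.uniform(-1, 1, (7, 1323))
        E, Et = subband_energies_batch(frames, TARGET_RATE)
        for i in range(7):
            e = compute_subband_energies(frames[i], TARGET_RATE)
            np.testing.assert_allclose(E[i], e.E, rtol=1e-12)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="8000"):
            compute_subband_energies(np.zeros(100), 4000)


class TestGmmDensity:
    def test_single_gaussian_peak(self):
        mix = GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [2.0, 1.0])
        assert gmm_density(mix, -30.0) == pytest.approx(1 / (2.0 * math.sqrt(2 * math.pi)))

    def test_symmetry_around_mean(self):
        mix = GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [2.0, 1.0])
        for d in (0.5, 3.0, 7.7):
            assert gmm_density(mix, -30 + d) == pytest.approx(gmm_density(mix, -30 - d))

    def test_two_component_value_matches_hand_evaluation(self):
        mix = GaussianMixture1D([0.5, 0.5], [0.0, 10.0], [1.0, 1.0])
        expected = oracle_density([0.5, 0.5], [0.0, 10.0], [1.0, 1.0], 0.0)
        assert gmm_density(mix, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GaussianMixture1D([0.5, 0.6], [0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            GaussianMixture1D([0.5, 0.5], [0.0, 1.0], [1.0, 0.0])


class TestLogLikRatios:
    def _model(self, silent, voiced, K=None):
        K = np.full(6, 1 / 6) if K is None else np.asarray(K, float)
        return VadModel(silent=silent, voiced=voiced, K=K, Tm=-1000.0)

    def test_identical_mixtures_give_zero_ratios(self):
        mixes = [GaussianMixture1D([0.6, 0.4], [-40.0, -20.0], [3.0, 5.0]) for _ in range(6)]
        model = self._model(mixes, [GaussianMixture1D(m.weights, m.means, m.stds) for m in mixes])
        e = SubbandEnergies(np.full(6, -30.0), -25.0)
        L, L_t = frame_loglik_ratios(model, e)
        np.testing.assert_allclose(L, 0.0, atol=1e-12)
        assert L_t == pytest.approx(0.0, abs=1e-12)

    def test_doubled_density_gives_unit_ratio(self):
        # voiced density is exactly 2x silent at the evaluation point:
        # same shape, half the std -> 2x peak height at the shared mean
        silent = [GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [4.0, 1.0]) for _ in range(6)]
        voiced = [GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [2.0, 1.0]) for _ in range(6)]
        model = self._model(silent, voiced)
        e = SubbandEnergies(np.full(6, -30.0), -25.0)
        L, L_t = frame_loglik_ratios(model, e)
        np.testing.assert_allclose(L, 1.0, atol=1e-12)
        assert L_t == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_band_weights(self):
        rng = np.random.default_rng(6)
        model = random_model(rng)
        model.K = np.array([1.0, 0, 0, 0, 0, 0])
        e = SubbandEnergies(rng.uniform(-60, 0, 6), 0.0)
        L, L_t = frame_loglik_ratios(model, e)
        assert L_t == pytest.approx(L[0])

    def test_weighted_total_identity(self):
        rng = np.random.default_rng(7)
        model = random_model(rng)
        e = SubbandEnergies(rng.uniform(-60, 0, 6), 0.0)
        L, L_t = frame_loglik_ratios(model, e)
        assert L_t == pytest.approx(float(model.K @ L), abs=1e-9)


class TestClassifyFrame:
    def test_energy_gate_forces_silent(self):
        rng = np.random.default_rng(8)
        model = random_model(rng)
        model.Tm = 10.0
        e = SubbandEnergies(rng.uniform(-60, 0, 6), 5.0)  # E_t below gate
        d = classify_frame(model, e)
        assert d.label == 0
        np.testing.assert_array_equal(d.L, 0.0)

    def test_all_zero_ratios_below_thresholds(self):
        mixes = [GaussianMixture1D([0.6, 0.4], [-40.0, -20.0], [3.0, 5.0]) for _ in range(6)]
        model = VadModel(
            silent=mixes,
            voiced=[GaussianMixture1D(m.weights, m.means, m.stds) for m in mixes],
            K=np.full(6, 1 / 6), Tm=-1000.0, T_tau=0.5, T_a=0.5,
        )
        d = classify_frame(model, SubbandEnergies(np.full(6, -30.0), -25.0))
        assert d.label == 0

    def test_single_band_exceedance_suffices(self):
        # band 3 voiced density >> silent there; other bands neutral, L_t negative
        silent = [GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [4.0, 1.0]) for _ in range(6)]
        voiced = [GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [4.0, 1.0]) for _ in range(6)]
        voiced[2] = GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [1.0, 1.0])  # 4x peak: L_3 = 2
        K = np.array([0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
        silent[0] = GaussianMixture1D([1.0, 0.0], [-30.0, 0.0], [0.5, 1.0])  # L_1 = -3
        model = VadModel(silent=silent, voiced=voiced, K=K, Tm=-1000.0, T_tau=0.5, T_a=0.5)
        e = SubbandEnergies(np.full(6, -30.0), -25.0)
        L, L_t = frame_loglik_ratios(model, e)
        assert L[2] > model.T_tau and L_t < model.T_a
        assert classify_frame(model, e).label == 1

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            model = random_model(rng)
            e = SubbandEnergies(rng.uniform(-100, 20, 6), rng.uniform(-100, 20))
            assert classify_frame(model, e).label == oracle_decision(model, e)


class TestRunVad:
    def test_all_zero_signal_all_silent(self, small_vad_model):
        sig = AudioSignal(np.zeros(TARGET_RATE), TARGET_RATE)
        labels = run_vad(sig, small_vad_model)
        assert labels.size == 33
        assert not labels.any()

    def test_012s_gives_four_labels(self, small_vad_model):
        labels = run_vad(tone(200.0, 0.12), small_vad_model)
        assert labels.size == 4

    def test_tone_then_silence(self):
        # calibrate on the alternating tone/silence signal itself, then the
        # tone half must come out voiced and the silent half non-voiced
        cycle = np.r_[tone(500.0, 0.5, amplitude=0.5).samples, np.zeros(int(0.5 * TARGET_RATE))]
        calib = AudioSignal(np.tile(cycle, 12), TARGET_RATE)
        model = fit_default_model([calib])
        labels = run_vad(AudioSignal(cycle, TARGET_RATE), model)
        assert labels[:16].all()  # frame 16 straddles the boundary
        assert not labels[17:].any()

    def test_matches_per_frame_classification(self, small_corpus, small_vad_model):
        sig = small_corpus.signals[0]
        short = AudioSignal(sig.samples[: 2 * TARGET_RATE], TARGET_RATE)
        labels = run_vad(short, small_vad_model)
        from pausekit.audio_io import frame_audio

        for i, frame in enumerate(frame_audio(short, 0.03)):
            e = compute_subband_energies(frame, TARGET_RATE)
            assert labels[i] == classify_frame(small_vad_model, e).label

    def test_determinism(self, small_corpus, small_vad_model):
        sig = small_corpus.signals[1]
        a = run_vad(sig, small_vad_model)
        b = run_vad(sig, small_vad_model)
        np.testing.assert_array_equal(a, b)

    @given(dt_tau=st.floats(0.0, 3.0), dt_a=st.floats(0.0, 3.0))
    @settings(max_examples=20, deadline=None)
    def test_threshold_monotonicity(self, small_corpus, small_vad_model, dt_tau, dt_a):
        sig = AudioSignal(small_corpus.signals[2].samples[: 3 * TARGET_RATE], TARGET_RATE)
        base = run_vad(sig, small_vad_model).sum()
        raised = VadModel(
            silent=small_vad_model.silent,
            voiced=small_vad_model.voiced,
            K=small_vad_model.K,
            Tm=small_vad_model.Tm,
            T_tau=small_vad_model.T_tau + dt_tau,
            T_a=small_vad_model.T_a + dt_a,
        )
        assert run_vad(sig, raised).sum() <= base

    def test_gate_dominance(self, small_corpus, small_vad_model):
        sig = small_corpus.signals[0]
        gated = VadModel(
            silent=small_vad_model.silent,
            voiced=small_vad_model.voiced,
            K=small_vad_model.K,
            Tm=1e6,
            T_tau=small_vad_model.T_tau,
            T_a=small_vad_model.T_a,
        )
        assert not run_vad(sig, gated).any()


class TestFitDefaultModel:
    def test_silence_plus_tone_orders_means(self):
        sig = AudioSignal(
            np.r_[np.zeros(6 * TARGET_RATE) + 1e-6, tone(1500.0, 6.0, amplitude=0.5).samples],
            TARGET_RATE,
        )
        model = fit_default_model([sig])
        band = 3  # 1-2 kHz
        assert model.silent[band].means.max() < model.voiced[band].means.min()

    def test_two_cluster_fit_recovers_cluster_means(self):
        # alternate -60 dB and -10 dB amplitude noise bursts; fitted silent/voiced
        # means per band must straddle the two cluster means within 1 dB
        rng = np.random.default_rng(10)
        frames = []
        for i in range(400):
            amp = 0.001 if i % 2 == 0 else 0.3  # about -60 and -10 dB frames
            frames.append(rng.uniform(-amp, amp, 1323))
        sig = AudioSignal(np.concatenate(frames), TARGET_RATE)
        model = fit_default_model([sig])
        E, _ = subband_energies_batch(np.stack(frames), TARGET_RATE)
        for band in range(6):
            lo_mean = E[::2, band].mean()
            hi_mean = E[1::2, band].mean()
            assert abs(model.silent[band].means @ model.silent[band].weights - lo_mean) < 1.0
            assert abs(model.voiced[band].means @ model.voiced[band].weights - hi_mean) < 1.0

    def test_refit_determinism(self, small_corpus):
        m1 = fit_default_model(small_corpus.signals[:3])
        m2 = fit_default_model(small_corpus.signals[:3])
        assert m1.to_dict() == m2.to_dict()

    def test_constant_signal_rejected(self):
        sig = AudioSignal(np.full(12 * TARGET_RATE, 0.1), TARGET_RATE)
        with pytest.raises(ValueError, match="degenerate|constant"):
            fit_default_model([sig])

    def test_too_short_calibration_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            fit_default_model([tone(200.0, 2.0)])

    def test_json_roundtrip(self, small_vad_model, tmp_path):
        small_vad_model.save(tmp_path / "model.json")
        back = VadModel.load(tmp_path / "model.json")
        assert back.to_dict() == small_vad_model.to_dict()
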