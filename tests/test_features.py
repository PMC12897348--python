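"""Acoustic feature families against analytic and brute-force oracles."""

import numpy as np
import pytest

from tbscreen.features import (
    DICTIONARY_VERSION,
    FAMILIES,
    ROUTE_PHASE_PREFIXES,
    _run_lengths_many,
    aggregate_subject,
    bispectrum_matrix,
    envelope_peak_count,
    extract_features,
    feature_dictionary,
    feature_family_map,
    higuchi_fd,
    hos_features,
    katz_fd,
    nonlinear_features,
    perturbation_features,
    rosenstein_lyapunov,
    spectral_features,
    tf_features,
    time_features,
)
from tbscreen.cohort import CohortSpec, generate_cohort

RATE = 16000


class TestDictionary:
    def test_size_and_uniqueness(self):
        names = feature_dictionary()
        assert len(names) == 188
        assert len(set(names)) == 188
        assert DICTIONARY_VERSION == "1.0"

    def test_prefix_structure(self):
        names = feature_dictionary()
        prefixed = [n for n in names
                    if n.startswith(ROUTE_PHASE_PREFIXES)]
        perturb = [n for n in names if n.endswith(("jitter", "shimmer"))]
        assert len(prefixed) + len(perturb) == 188
        assert len(perturb) == 4

    def test_family_map_covers_dictionary(self):
        fam = feature_family_map()
        names = feature_dictionary()
        assert set(fam) == set(names)
        assert set(fam.values()) <= set(FAMILIES) | {"perturbation"}


class TestSpectral:
    def test_sine_oracle(self):
        """A unit sine at 450 Hz: centroid at 450, all power in the
        300-600 Hz octave, total power = amplitude^2 / 2."""
        t = np.arange(2 * RATE) / RATE
        x = np.sin(2 * np.pi * 450 * t)
        out = spectral_features(x, RATE)
        assert out["spectral_centroid"] == pytest.approx(450, abs=5)
        assert out["band_ratio_3"] > 0.99
        assert out["total_power"] == pytest.approx(0.5, rel=0.01)

    def test_ratios_sum_to_one(self, rng):
        x = rng.standard_normal(4 * RATE)
        out = spectral_features(x, RATE)
        total = sum(out[f"band_ratio_{i}"] for i in range(1, 7))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_entropy_ordering(self, rng):
        t = np.arange(RATE) / RATE
        sine = spectral_features(np.sin(2 * np.pi * 450 * t), RATE)
        noise = spectral_features(rng.standard_normal(RATE), RATE)
        assert sine["spectral_entropy"] < noise["spectral_entropy"]
        assert 0 <= sine["spectral_entropy"] <= 1
        assert 0 <= noise["spectral_entropy"] <= 1

    def test_short_signal_empty(self):
        assert spectral_features(np.ones(100), RATE) == {}


class TestBicoherence:
    """Quadratic-phase-coupling oracle for the bispectrum estimator."""

    @staticmethod
    def _triad(coupled, nfft=256, nseg=64, seed=1):
        rng = np.random.default_rng(seed)
        i1, i2 = 16, 24
        t = np.arange(nfft)
        segs = []
        for _ in range(nseg):
            p1, p2 = rng.uniform(0, 2 * np.pi, 2)
            p3 = p1 + p2 if coupled else rng.uniform(0, 2 * np.pi)
            x = (np.cos(2 * np.pi * i1 * t / nfft + p1)
                 + np.cos(2 * np.pi * i2 * t / nfft + p2)
                 + np.cos(2 * np.pi * (i1 + i2) * t / nfft + p3)
                 + 0.01 * rng.standard_normal(nfft))
            segs.append(x)
        return np.concatenate(segs)

    def test_coupled_triad_high(self):
        _, b2, n = bispectrum_matrix(self._triad(True), nfft=256, overlap=0.0)
        assert n == 64
        assert b2[16, 24] > 0.95

    def test_uncoupled_triad_low(self):
        _, b2, _ = bispectrum_matrix(self._triad(False), nfft=256,
                                     overlap=0.0)
        assert b2[16, 24] < 0.2

    def test_bicoherence_bounded(self, rng):
        _, b2, _ = bispectrum_matrix(rng.standard_normal(8192), nfft=256)
        assert np.all(b2 >= 0) and np.all(b2 <= 1 + 1e-9)

    def test_hos_features_keys(self, rng):
        out = hos_features(rng.standard_normal(8192), RATE)
        assert set(out) == {"bispec_mean", "bispec_max", "bispec_entropy",
                            "bicoherence_mean"}
        assert out["bispec_max"] >= out["bispec_mean"]

    def test_too_short_empty(self):
        assert hos_features(np.ones(100), RATE) == {}


class TestFractal:
    def test_higuchi_line_near_one(self):
        x = np.linspace(0, 1, 2000)
        assert higuchi_fd(x) == pytest.approx(1.0, abs=0.05)

    def test_higuchi_noise_near_two(self, rng):
        vals = [higuchi_fd(rng.standard_normal(2000)) for _ in range(5)]
        assert 1.7 < np.mean(vals) < 2.2

    def test_katz_line(self):
        x = np.linspace(0, 1, 500)
        assert katz_fd(x) == pytest.approx(1.0, abs=0.05)

    def test_ordering(self, rng):
        line = np.linspace(0, 1, 1000)
        noise = rng.standard_normal(1000)
        assert higuchi_fd(line) < higuchi_fd(noise)
        assert katz_fd(line) < katz_fd(noise)


class TestTimeFeatures:
    def test_zcr_oracle(self):
        # alternating signal crosses zero at every step
        x = np.tile([1.0, -1.0], 500)
        out = time_features(x, rate=1)
        assert out["zcr"] == pytest.approx(1.0, abs=1e-9)

    def test_short_empty(self):
        assert time_features(np.ones(5)) == {}


class TestTF:
    def test_relative_energies_sum_to_one(self, rng):
        out = tf_features(rng.standard_normal(4 * RATE), RATE)
        total = sum(out[f"dwt_relenergy_{b}"]
                    for b in ("a4", "d4", "d3", "d2", "d1"))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_subband_localization(self):
        """A 100 Hz tone lands in the approximation band (0-500 Hz at four
        levels of a 16 kHz signal); a 6 kHz tone lands in d1 (4-8 kHz)."""
        t = np.arange(2 * RATE) / RATE
        low = tf_features(np.sin(2 * np.pi * 100 * t), RATE)
        high = tf_features(np.sin(2 * np.pi * 6000 * t), RATE)
        assert low["dwt_relenergy_a4"] > 0.9
        assert high["dwt_relenergy_d1"] > 0.9

    def test_entropy_bounds(self, rng):
        out = tf_features(rng.standard_normal(2 * RATE), RATE)
        for b in ("a4", "d4", "d3", "d2", "d1"):
            assert 0 <= out[f"dwt_logent_{b}"] <= 1 + 1e-9

    def test_cqt_octave_summaries_present(self, rng):
        out = tf_features(rng.standard_normal(2 * RATE), RATE)
        for o in range(1, 6):
            assert f"cqt_oct{o}_mean" in out
        assert "cqt_sd" in out

    def test_short_empty(self):
        assert tf_features(np.ones(50), RATE) == {}


class TestNonlinear:
    def test_recurrence_rate_target(self, rng):
        """The recurrence radius realizes the requested 10% rate."""
        from tbscreen.features import _embed, _delay_from_autocorr
        x = rng.standard_normal(400)
        x = (x - x.mean()) / x.std()
        tau = _delay_from_autocorr(x)
        emb = _embed(x, 3, tau)
        d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=-1))
        off = ~np.eye(len(emb), dtype=bool)
        radius = np.quantile(d[off], 0.10)
        assert (d[off] <= radius).mean() == pytest.approx(0.10, abs=0.01)

    def test_sine_more_deterministic_than_noise(self, rng):
        t = np.arange(1000) / 100
        det_sine = nonlinear_features(np.sin(2 * np.pi * 1.3 * t))
        det_noise = nonlinear_features(rng.standard_normal(1000))
        assert det_sine["rqa_determinism"] > det_noise["rqa_determinism"]
        assert 0 <= det_noise["rqa_determinism"] <= 1 + 1e-9
        assert 0 <= det_noise["rqa_laminarity"] <= 1 + 1e-9

    def test_lyapunov_ordering(self, rng):
        t = np.arange(1000) / 100
        sine = nonlinear_features(np.sin(2 * np.pi * 1.3 * t))
        noise = nonlinear_features(rng.standard_normal(1000))
        assert noise["lyapunov"] > sine["lyapunov"]

    def test_degenerate_inputs(self):
        assert nonlinear_features(np.ones(500)) == {}
        assert nonlinear_features(np.ones(10)) == {}
        assert np.isnan(rosenstein_lyapunov(np.ones(10)))


class TestRunLengths:
    def test_brute_force_oracle(self, rng):
        def oracle(mask):
            out, run = [], 0
            for v in mask:
                if v:
                    run += 1
                elif run:
                    out.append(run)
                    run = 0
            if run:
                out.append(run)
            return out

        for _ in range(20):
            arrays = [rng.random(rng.integers(1, 30)) < 0.5
                      for _ in range(rng.integers(1, 5))]
            expected = sorted(sum((oracle(a) for a in arrays), []))
            got = sorted(_run_lengths_many([a for a in arrays]).tolist())
            assert got == expected


class TestPerturbation:
    @staticmethod
    def _bursts(times, amps, rate=8000):
        total = int((times[-1] + 1.0) * rate)
        x = np.zeros(total)
        for t0, a in zip(times, amps):
            n = int(0.4 * rate)
            s = int(t0 * rate)
            tt = np.arange(n) / rate
            env = np.sin(np.linspace(0, np.pi, n)) ** 2
            x[s:s + n] += a * env * np.sin(2 * np.pi * 500 * tt)
        return x

    def test_jitter_closed_form(self):
        """Peak periods 2.0 s and 2.2 s: local jitter = 0.2 / 2.1."""
        x = self._bursts([1.0, 3.0, 5.2], [1.0, 1.0, 1.0])
        out = perturbation_features(x, 8000)
        assert out["cycle_count"] == 3.0
        assert out["jitter"] == pytest.approx(0.2 / 2.1, abs=0.005)
        assert out["shimmer"] == pytest.approx(0.0, abs=0.01)

    def test_shimmer_closed_form(self):
        """Peak amplitudes (1, 0.9, 1): local shimmer =
        mean(|0.1|, |0.1|) / mean = 0.1 / (2.9/3)."""
        x = self._bursts([1.0, 3.0, 5.0], [1.0, 0.9, 1.0])
        out = perturbation_features(x, 8000)
        expected = 0.1 / (2.9 / 3)
        assert out["shimmer"] == pytest.approx(expected, rel=0.1)
        assert out["jitter"] == pytest.approx(0.0, abs=0.005)

    def test_too_few_cycles_empty(self):
        x = self._bursts([1.0, 3.0], [1.0, 1.0])
        assert perturbation_features(x, 8000) == {}

    def test_silence_empty(self):
        assert perturbation_features(np.zeros(8000), 8000) == {}

    def test_envelope_peak_count(self):
        x = self._bursts([1.0, 3.0, 5.0, 7.0], [1.0, 1.0, 1.0, 1.0])
        assert envelope_peak_count(x, 8000) == 4


class TestAggregation:
    def test_mean_within_group(self):
        vecs = {("nose", "inspiration"): [{"a": 1.0, "b": 2.0},
                                          {"a": 3.0}],
                ("mouth", "expiration"): [{"a": 10.0}]}
        out = aggregate_subject(vecs)
        assert out["nose_insp_a"] == pytest.approx(2.0)
        assert out["nose_insp_b"] == pytest.approx(2.0)
        assert out["mouth_exp_a"] == pytest.approx(10.0)
        assert "mouth_exp_b" not in out

    def test_extract_features_shape(self):
        subjects = generate_cohort(CohortSpec(
            class_sizes={"non": 1, "mild": 0, "moderate": 0, "severe": 1},
            seed=0))
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            table = extract_features(subjects)
        assert table.values.shape == (2, 188 + 5)
        # the synthetic protocol populates the overwhelming majority of
        # the dictionary; a fully-missing table would indicate breakage
        filled = 1.0 - table.values[table.acoustic_names].isna().mean().mean()
        assert filled > 0.9
        assert set(table.labels) == {"non", "severe"}
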