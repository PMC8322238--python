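"""Tonal feature extraction: chromagram, key strength, clarity, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from musictrf.tonal import (
    ChromaVector,
    CumulativeKeyStrength,
    KK_MAJOR,
    angular_similarity,
    chromagram,
    feature_descriptives,
    key_clarity,
    key_names,
    key_strength,
    keyspace_pca,
    profile_matrix,
    sparse_tonal_encode,
    tonal_stability,
)
from musictrf.synthetic import StimulusSpec, synth_audio

FS = 8000.0


def _sine(freq, dur=0.5, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestChromagram:
    def test_pure_a440_concentrates_on_pitch_class_a(self):
        ch = chromagram(_sine(440.0), FS)
        assert ch.energies[9] / ch.energies.sum() > 0.9
        assert not ch.is_silent

    def test_silence_is_all_zero_and_flagged(self):
        ch = chromagram(np.zeros(4000), FS)
        assert np.all(ch.energies == 0)
        assert ch.is_silent

    def test_c_major_triad_matches_dft_binning_oracle(self):
        x = _sine(261.63) + _sine(329.63) + _sine(392.0)  # C4 E4 G4
        ch = chromagram(x, FS)
        # independent oracle: explicit DFT magnitude folding per bin
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / FS)
        expected = np.zeros(12)
        for f, e in zip(freqs, spec):
            if 30.0 <= f <= 3000.0:
                pc = (int(round(12 * np.log2(f / 440.0))) + 9) % 12
                expected[pc] += e
        np.testing.assert_allclose(ch.energies, expected, rtol=1e-10)
        assert set(np.argsort(ch.energies)[-3:]) == {0, 4, 7}

    def test_window_too_short_raises_with_minimum(self):
        with pytest.raises(ValueError, match=r"minimum \d+"):
            chromagram(np.ones(100), FS, pitch_floor_hz=30.0)

    def test_sample_rate_below_ceiling_raises(self):
        with pytest.raises(ValueError, match="ceiling"):
            chromagram(np.ones(4000), 4000.0, pitch_ceiling_hz=3000.0)


class TestKeyStrength:
    @pytest.mark.parametrize("k", range(24))
    def test_ideal_profile_yields_unit_strength_at_own_key(self, k):
        v = key_strength(profile_matrix()[k])
        assert v[k] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(v) == k

    def test_matches_pointwise_pearson_oracle(self, rng):
        chroma = rng.random(12)
        v = key_strength(chroma)
        for k, prof in enumerate(profile_matrix()):
            r, _ = stats.pearsonr(chroma, prof)
            assert v[k] == pytest.approx(r, abs=1e-12)

    def test_flat_chroma_propagates_missing(self):
        assert np.all(np.isnan(key_strength(np.ones(12))))

    @pytest.mark.parametrize("shift", [1, 3, 7])
    def test_transposition_shifts_both_mode_blocks(self, rng, shift):
        chroma = rng.random(12)
        v = key_strength(chroma)
        v_shifted = key_strength(np.roll(chroma, shift))
        np.testing.assert_allclose(v_shifted[:12], np.roll(v[:12], shift), atol=1e-12)
        np.testing.assert_allclose(v_shifted[12:], np.roll(v[12:], shift), atol=1e-12)

    def test_bounded_by_one(self, rng):
        v = key_strength(rng.random(12))
        assert np.all(np.abs(v) <= 1 + 1e-12)


class TestKeyClarity:
    def test_picks_maximum_and_key_name(self):
        v = key_strength(KK_MAJOR)  # C-major ideal chromagram
        kc = key_clarity(v)
        assert kc.clarity == pytest.approx(1.0, abs=1e-12)
        assert kc.key_name == "C major"

    def test_tie_resolves_to_lowest_index(self):
        kc = key_clarity(np.full(24, 0.3))
        assert kc.key_index == 0 and kc.clarity == 0.3

    def test_matches_bruteforce_max(self, rng):
        v = rng.uniform(-1, 1, 24)
        assert key_clarity(v).clarity == pytest.approx(max(v))


class TestAngularSimilarity:
    def test_anchor_values_parallel_orthogonal_opposite(self):
        u = np.zeros(24)
        u[0] = 2.0
        w = np.zeros(24)
        w[1] = 5.0
        assert angular_similarity(u, 3 * u)[0] == 1.0
        assert angular_similarity(u, w)[0] == 0.5
        assert angular_similarity(u, -u)[0] == 0.0

    def test_distant_key_stability_near_zero_matches_formula(self):
        V = np.stack([key_strength(p) for p in profile_matrix()])
        c_major, fsharp_major = V[0], V[6]
        s, _ = angular_similarity(c_major, fsharp_major)
        # direct-formula oracle
        cos = c_major @ fsharp_major / (
            np.linalg.norm(c_major) * np.linalg.norm(fsharp_major)
        )
        expected = 1.0 - np.arccos(np.clip(cos, -1, 1)) / np.pi
        assert s == pytest.approx(expected, abs=1e-12)
        assert 0.0 < s < 0.2  # close to zero but not exactly

    @settings(deadline=None, max_examples=200)
    @given(
        u=arrays(np.float64, 24, elements=st.floats(-1, 1)),
        v=arrays(np.float64, 24, elements=st.floats(-1, 1)),
        scale=st.floats(0.01, 100.0),
    )
    def test_bounds_symmetry_scale_invariance(self, u, v, scale):
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            return
        s_uv, _ = angular_similarity(u, v)
        assert 0.0 <= s_uv <= 1.0
        assert s_uv == pytest.approx(angular_similarity(v, u)[0], abs=1e-12)
        assert s_uv == pytest.approx(angular_similarity(scale * u, v)[0], abs=1e-9)

    def test_self_similarity_is_one(self, rng):
        for _ in range(1000):
            u = rng.standard_normal(24)
            assert abs(angular_similarity(u, u)[0] - 1.0) < 1e-12

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            angular_similarity(np.zeros(24), np.ones(24))


class TestCumulativeMean:
    def test_first_update_is_identity(self, rng):
        x = rng.standard_normal(24)
        c = CumulativeKeyStrength().update(x)
        np.testing.assert_array_equal(c.mean_vector, x)
        assert c.n_frames == 1

    def test_matches_bruteforce_reaveraging_at_every_step(self, rng):
        vs = rng.standard_normal((50, 24))
        c = CumulativeKeyStrength()
        for j, v in enumerate(vs, start=1):
            c = c.update(v)
            np.testing.assert_allclose(c.mean_vector, vs[:j].mean(axis=0), atol=1e-12)

    def test_constant_stream_keeps_constant_mean(self):
        v = np.arange(24.0)
        c = CumulativeKeyStrength()
        for _ in range(10):
            c = c.update(v)
        np.testing.assert_allclose(c.mean_vector, v, atol=1e-12)

    def test_stability_requires_prior_context(self):
        with pytest.raises(ValueError):
            tonal_stability(np.ones(24), CumulativeKeyStrength())


class TestSparseEncoding:
    def test_static_chord_loop_is_fully_stable(self):
        spec = StimulusSpec((("C major", 6.0),), 120.0, "4/4")
        audio, grid, _ = synth_audio(spec, seed=0)
        series = sparse_tonal_encode(audio, spec.fs_audio, grid.onsets_s)
        assert series.tonal_stability[0] == 1.0
        assert np.all(series.tonal_stability > 0.95)

    def test_abrupt_modulation_drops_stability_sharply(self):
        spec = StimulusSpec((("C major", 4.0), ("F# major", 4.0)), 120.0, "4/4")
        audio, grid, _ = synth_audio(spec, seed=0)
        series = sparse_tonal_encode(audio, spec.fs_audio, grid.onsets_s)
        pre = series.tonal_stability[series.event_times_s < 3.9]
        at_mod = series.tonal_stability[np.searchsorted(series.event_times_s, 4.0)]
        assert np.all(pre > 0.9)
        assert at_mod < 0.5

    def test_transposition_preserves_key_clarity(self):
        spec_c = StimulusSpec((("C major", 5.0),), 120.0, "4/4")
        spec_cs = StimulusSpec((("C# major", 5.0),), 120.0, "4/4")
        a1, g1, _ = synth_audio(spec_c, seed=0)
        a2, g2, _ = synth_audio(spec_cs, seed=0)
        s1 = sparse_tonal_encode(a1, spec_c.fs_audio, g1.onsets_s)
        s2 = sparse_tonal_encode(a2, spec_cs.fs_audio, g2.onsets_s)
        np.testing.assert_allclose(s1.key_clarity, s2.key_clarity, atol=0.02)

    def test_errors_on_too_few_or_out_of_range_events(self):
        audio = np.random.default_rng(0).standard_normal(8000)
        with pytest.raises(ValueError, match="at least 2"):
            sparse_tonal_encode(audio, FS, np.array([0.1]))
        with pytest.raises(ValueError, match="beyond"):
            sparse_tonal_encode(audio, FS, np.array([0.1, 5.0]))


class TestKeySpacePCA:
    def test_variance_fractions_sorted_and_sum_to_one(self):
        res = keyspace_pca()
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_c_major_and_fsharp_major_oppose_geometrically(self):
        res = keyspace_pca()
        i_c = res.key_names.index("C major")
        i_fs = res.key_names.index("F# major")
        assert np.dot(res.coordinates_2d[i_c], res.coordinates_2d[i_fs]) < 0

    def test_major12_subset_has_12_rows(self):
        res = keyspace_pca("major12")
        assert res.coordinates_2d.shape == (12, 2)
        assert all("major" in n for n in res.key_names)


class TestDescriptives:
    def _series(self, clar, stab):
        n = len(clar)
        from musictrf.tonal import TonalEventSeries

        return TonalEventSeries(
            np.arange(n, dtype=float), np.asarray(clar), np.asarray(stab),
            np.zeros(n, dtype=int), "beat",
        )

    def test_constant_series_reports_missing_correlation(self):
        d = feature_descriptives(self._series([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]))
        assert d["clarity_sd"] == 0.0
        assert np.isnan(d["clarity_stability_r"])

    def test_anticorrelated_pairs_give_minus_one(self):
        d = feature_descriptives(self._series([0.1, 0.2, 0.3], [0.3, 0.2, 0.1]))
        assert d["clarity_stability_r"] == pytest.approx(-1.0)

    def test_sample_r_recovers_population_rho(self, rng):
        n, rho = 200, 0.5
        cov = [[1, rho], [rho, 1]]
        x = rng.multivariate_normal([0, 0], cov, size=n)
        d = feature_descriptives(self._series(x[:, 0], x[:, 1]))
        # Fisher-z CI of the sample estimate should cover rho
        z = np.arctanh(d["clarity_stability_r"])
        half = 1.96 / np.sqrt(n - 3)
        assert np.tanh(z - half) < rho < np.tanh(z + half)

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            feature_descriptives(self._series([0.1, 0.2], [0.1, 0.2]))
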