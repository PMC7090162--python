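"""ASI properties: symmetry, invariances, envelope fidelity, coupling."""

import numpy as np
import pytest

from neomaturity.synchrony import (
    AsiParams,
    activation_envelope,
    asi_all_pairs,
    asi_pair,
    mutual_information,
    quantize_equal_occupancy,
)
from neomaturity.eeg_io import extract_state_segments, preprocess
from neomaturity.synthetic_data import simulate_coupled_envelopes, simulate_eeg

FS = 256.0
PARAMS = AsiParams()


class TestEnvelope:
    def test_tracks_amplitude_modulation(self, rng):
        # 10 s on / 10 s off amplitude gate
        n = int(400 * FS)
        t = np.arange(n) / FS
        gate = (np.floor(t / 10) % 2 == 0).astype(float)
        x = (5.0 + 45.0 * gate) * rng.standard_normal(n)
        env = activation_envelope(x, FS)
        gate_lo = gate[:: int(FS / PARAMS.env_rate)][: env.size]
        r = np.corrcoef(env, gate_lo)[0, 1]
        assert r > 0.8

    def test_zero_signal_zero_envelope(self):
        env = activation_envelope(np.zeros(int(400 * FS)), FS)
        np.testing.assert_allclose(env, 0.0, atol=1e-9)

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(int(400 * FS)) * 30
        np.testing.assert_allclose(
            activation_envelope(x, FS), activation_envelope(-x, FS), atol=1e-9
        )

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            activation_envelope(rng.standard_normal(int(60 * FS)), FS)


class TestQuantization:
    def test_equal_occupancy(self, rng):
        env = rng.random(4000)
        levels = quantize_equal_occupancy(env, 4)
        counts = np.bincount(levels, minlength=4)
        assert counts.min() == counts.max() == 1000

    def test_monotone_transform_invariance(self, rng):
        env = rng.random(1000)
        np.testing.assert_array_equal(
            quantize_equal_occupancy(env, 4),
            quantize_equal_occupancy(np.exp(3 * env), 4),
        )


def test_mutual_information_of_identical_sequences_is_entropy(rng):
    a = rng.integers(0, 4, size=4000)
    mi = mutual_information(a, a, 4)
    # equal-occupancy-ish labels: entropy close to log2(4) = 2 bits
    assert mi == pytest.approx(2.0, abs=0.05)


class TestAsiPair:
    def _env_pair(self, rho, seed, minutes=10):
        rng = np.random.default_rng(seed)
        return simulate_coupled_envelopes(rho, minutes * 60, rate=4.0, rng=rng)

    def test_symmetry_exact(self):
        x, y = self._env_pair(0.5, 1)
        a_xy = asi_pair(x, y, PARAMS, np.random.default_rng(7))
        a_yx = asi_pair(y, x, PARAMS, np.random.default_rng(7))
        assert a_xy == a_yx

    def test_amplitude_invariance(self):
        x, y = self._env_pair(0.5, 2)
        a1 = asi_pair(x, y, PARAMS, np.random.default_rng(7))
        a2 = asi_pair(10.0 * x, y, PARAMS, np.random.default_rng(7))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_identity_beats_independence(self):
        wins = 0
        for seed in range(20):
            x, y = self._env_pair(0.0, seed)
            self_asi = asi_pair(x, x, PARAMS, np.random.default_rng(seed))
            cross = asi_pair(x, y, PARAMS, np.random.default_rng(seed))
            wins += self_asi > cross
        assert wins == 20

    def test_degenerate_envelope_flagged(self):
        x = np.ones(4800)
        y = np.random.default_rng(0).random(4800)
        assert np.isnan(asi_pair(x, y, PARAMS, np.random.default_rng(1)))

    def test_coupling_monotonicity(self):
        means = []
        for rho in (0.0, 0.4, 0.8):
            vals = [
                asi_pair(*self._env_pair(rho, 100 + t), PARAMS,
                         np.random.default_rng(200 + t))
                for t in range(15)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


@pytest.fixture(scope="module")
def asi_result(small_sim_config, small_cohort):
    _, _, truth = small_cohort
    info = {**truth["infants"]["sim002"], "infant_id": "sim002"}
    rec, ann, rt = simulate_eeg(info, "T2", small_sim_config)
    rec = preprocess(rec)
    segments = extract_state_segments(rec, ann, "QS", 300)
    return asi_all_pairs(rec, segments, PARAMS, seed=5), rt


class TestAsiAllPairs:

    def test_all_28_pairs_populated_and_symmetric(self, asi_result):
        res, _ = asi_result
        m = res.pair_matrix
        assert np.isnan(np.diag(m)).all()
        off = m[~np.eye(8, dtype=bool)]
        assert np.isfinite(off).all() and off.size == 56
        np.testing.assert_array_equal(m, m.T)

    def test_global_asi_is_mean_of_upper_triangle(self, asi_result):
        res, _ = asi_result
        upper = res.pair_matrix[np.triu_indices(8, k=1)]
        assert res.global_asi == pytest.approx(np.mean(upper))
        assert upper.size == 28

    def test_six_symmetric_pairs(self, asi_result):
        res, _ = asi_result
        assert set(res.symmetric_pairs) == {"Fp-C", "Fp-T", "Fp-O", "C-O", "T-O", "C-T"}
        assert all(np.isfinite(v) for v in res.symmetric_pairs.values())

    def test_homologous_coupling_raises_symmetric_asi(self, small_sim_config, small_cohort):
        """Homologous referential pairs (sharing the modulation driver)
        exceed the mean of non-homologous pairs."""
        from neomaturity.synthetic_data import HOMOLOGOUS_PAIRS
        from neomaturity.eeg_io import ANALYSIS_CHANNELS

        _, _, truth = small_cohort
        info = {**truth["infants"]["sim003"], "infant_id": "sim003"}
        rec, ann, _ = simulate_eeg(info, "T2", small_sim_config)
        rec = preprocess(rec)
        segments = extract_state_segments(rec, ann, "QS", 300)
        res = asi_all_pairs(rec, segments, PARAMS, seed=9)
        idx = {c: i for i, c in enumerate(ANALYSIS_CHANNELS)}
        homologous = [res.pair_matrix[idx[a], idx[b]] for a, b in HOMOLOGOUS_PAIRS]
        mask = np.zeros((8, 8), dtype=bool)
        for a, b in HOMOLOGOUS_PAIRS:
            mask[idx[a], idx[b]] = mask[idx[b], idx[a]] = True
        others = res.pair_matrix[~mask & ~np.eye(8, dtype=bool)]
        assert np.mean(homologous) > np.nanmean(others)

    def test_identical_channels_give_equal_pairs(self, rng):
        from neomaturity.eeg_io import ANALYSIS_CHANNELS, Recording, Segment, SegmentSet

        one = 30 * rng.standard_normal(int(400 * FS))
        data = np.tile(one, (8, 1))
        rec = Recording("x", "T1", 32.0, FS, list(ANALYSIS_CHANNELS), data)
        segs = SegmentSet([Segment(data, 0.0, 400.0)], "QS", FS,
                          channels=list(ANALYSIS_CHANNELS))
        res = asi_all_pairs(rec, segs, PARAMS, seed=1)
        upper = res.pair_matrix[np.triu_indices(8, k=1)]
        np.testing.assert_allclose(upper, upper[0])
        assert res.global_asi == pytest.approx(upper[0])
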