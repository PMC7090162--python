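"""Burst detection against simulator ground truth; IBI/MSC oracles."""

import numpy as np
import pytest

from neomaturity.continuity import (
    BurstMask,
    DetectionParams,
    detect_bursts,
    derivation_ibi,
    interburst_intervals,
    runs_of,
    suppression_curve,
)
from neomaturity.eeg_io import Derivation, extract_state_segments, make_bipolar, preprocess
from neomaturity.synthetic_data import SimulationConfig, simulate_cohort, simulate_eeg


def _naive_runs(mask, value):
    out, start = [], None
    for i, v in enumerate(mask):
        if v == value and start is None:
            start = i
        elif v != value and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def test_run_extraction_matches_naive_scan(rng):
    for _ in range(50):
        mask = rng.random(rng.integers(1, 200)) > 0.5
        assert runs_of(mask, True) == _naive_runs(mask, True)
        assert runs_of(mask, False) == _naive_runs(mask, False)


class TestInterburstIntervals:
    def test_percentile_linear_interpolation(self):
        # mask: bursts separated by suppressions of 2,4,6,8,10 frames at 1 s/frame
        pieces = [np.ones(3)]
        for d in (2, 4, 6, 8, 10):
            pieces += [np.zeros(d), np.ones(3)]
        mask = np.concatenate(pieces).astype(bool)
        ibis, ibi95 = interburst_intervals(mask, 1.0)
        assert sorted(ibis) == [2, 4, 6, 8, 10]
        assert ibi95 == pytest.approx(9.6)  # (k-1)/(n-1) order-statistic rule

    def test_single_ibi(self):
        mask = np.concatenate([np.ones(4), np.zeros(7), np.ones(4)]).astype(bool)
        ibis, ibi95 = interburst_intervals(mask, 1.0)
        assert ibis == [7.0] and ibi95 == 7.0

    def test_edge_truncated_runs_excluded(self):
        mask = np.concatenate([np.zeros(5), np.ones(3), np.zeros(4), np.ones(3),
                               np.zeros(6)]).astype(bool)
        ibis, _ = interburst_intervals(mask, 1.0)
        assert ibis == [4.0]

    def test_no_complete_ibi_reports_missing(self):
        ibis, ibi95 = interburst_intervals(np.ones(10, dtype=bool), 1.0)
        assert ibis == [] and np.isnan(ibi95)

    def test_ibi95_at_least_median(self, rng):
        for _ in range(20):
            mask = rng.random(500) > 0.4
            ibis, ibi95 = interburst_intervals(mask, 0.5)
            if ibis:
                assert ibi95 >= np.median(ibis) - 1e-12


class TestSuppressionCurve:
    def test_half_channels_suppressed(self):
        masks = np.zeros((8, 100), dtype=bool)
        masks[:4] = True
        bm = BurstMask(masks, np.ones(100, dtype=bool), 0.5)
        curve, msc = suppression_curve(bm)
        np.testing.assert_allclose(curve, 0.5)
        assert msc == 0.5

    def test_no_suppression(self):
        bm = BurstMask(np.ones((4, 50), dtype=bool), np.ones(50, dtype=bool), 0.5)
        assert suppression_curve(bm)[1] == 0.0

    def test_msc_complements_burst_fraction(self, rng):
        masks = rng.random((8, 300)) > 0.4
        bm = BurstMask(masks, masks.all(axis=0), 0.5)
        _, msc = suppression_curve(bm)
        assert msc + masks.mean() == pytest.approx(1.0)


class TestDetector:
    def test_constant_high_amplitude_has_no_suppression(self, rng):
        x = 50.0 * rng.standard_normal((2, 256 * 360))
        bm = detect_bursts(x, 256.0, DetectionParams())
        assert bm.consensus.all()

    def test_constant_low_amplitude_fully_suppressed(self, rng):
        x = 1.0 * rng.standard_normal((2, 256 * 360))
        bm = detect_bursts(x, 256.0, DetectionParams())
        assert not bm.consensus.any()

    def test_flat_input_warns_and_suppresses(self):
        with pytest.warns(UserWarning, match="flat"):
            bm = detect_bursts(np.zeros((1, 256 * 360)), 256.0)
        assert not bm.masks.any()


@pytest.fixture(scope="module")
def oracle_recording():
    """Deterministic 3-s bursts / 5-s suppressions, all channels together."""
    cfg = SimulationConfig(
        n_infants=1, seed=3, duration_s=900, qs_onset_s=60, qs_duration_s=600,
        duration_log_sd=0.0, sup_median_32=5.0, burst_median_32=3.0,
        sup_log_slope=0.0, burst_log_slope=0.0, frontal_burst_delay_s=0.0,
    )
    _, _, truth = simulate_cohort(cfg)
    info = {**truth["infants"]["sim001"], "infant_id": "sim001"}
    rec, ann, rt = simulate_eeg(info, "T1", cfg)
    rec = preprocess(rec)
    seg = extract_state_segments(rec, ann, "QS", 300).segments[0]
    return rec, seg, rt


class TestDetectorVsGroundTruth:
    def _detect(self, rec, seg):
        idx = [rec.channels.index(c) for c in rec.channels[:8]]
        return detect_bursts(seg.data[idx], rec.fs, DetectionParams())

    def test_eventwise_recall_and_precision(self, oracle_recording):
        rec, seg, rt = oracle_recording
        bm = self._detect(rec, seg)
        true_sups = [(ev["onset"] - seg.onset, ev["duration"])
                     for ev in rt["global_suppressions"]]
        det = [(s * bm.frame_s, (e - s) * bm.frame_s)
               for s, e in runs_of(bm.consensus, False)]

        def hits(a, b):
            return sum(
                1 for (o, d) in a
                if any(min(o + d, oo + dd) - max(o, oo) >= 0.5 * d for (oo, dd) in b)
            )

        assert hits(true_sups, det) / len(true_sups) >= 0.9
        assert hits(det, true_sups) / len(det) >= 0.9

    def test_suppression_durations_recovered(self, oracle_recording):
        rec, seg, _ = oracle_recording
        bm = self._detect(rec, seg)
        durations = [(e - s) * bm.frame_s for s, e in runs_of(bm.consensus, False)]
        inner = durations[1:-1]
        assert np.mean(inner) == pytest.approx(5.0, abs=0.5)

    def test_msc_recovers_programmed_duty_cycle(self, oracle_recording):
        rec, seg, _ = oracle_recording
        bm = self._detect(rec, seg)
        _, msc = suppression_curve(bm)
        assert msc == pytest.approx(5.0 / 8.0, abs=0.05)


class TestDerivationIbi:
    def test_identical_derivations_average_trivially(self, rng):
        sig = np.concatenate(
            [np.r_[50 * rng.standard_normal(256 * 3), 1.0 * rng.standard_normal(256 * 4)]
             for _ in range(50)]
        )
        derivs = [Derivation("C3", "O1", sig), Derivation("C4", "O2", sig),
                  Derivation("Fp1", "C3", sig), Derivation("Fp2", "C4", sig)]
        out = derivation_ibi(derivs, 256.0)
        assert out["ibi_mean_CO"] == pytest.approx(out["ibi_mean_FC"])
        assert 3.0 < out["ibi_mean_CO"] < 5.0

    def test_missing_derivation_makes_group_missing(self, rng):
        sig = 50 * rng.standard_normal(256 * 320)
        out = derivation_ibi([Derivation("C3", "O1", sig)], 256.0)
        assert np.isnan(out["ibi_mean_CO"]) and np.isnan(out["ibi_mean_FC"])

    def test_frontal_delay_lengthens_frontocentral_ibis(self, oracle_recording, small_sim_config, small_cohort):
        # anterior burst-onset delay -> FC mean IBI exceeds CO mean IBI
        _, _, truth = small_cohort
        diffs = []
        for iid in list(truth["infants"])[:2]:
            info = {**truth["infants"][iid], "infant_id": iid}
            rec, ann, _ = simulate_eeg(info, "T1", small_sim_config)
            rec = preprocess(rec)
            seg = extract_state_segments(rec, ann, "QS", 300).segments[0]
            rec_seg = type(rec)(iid, "T1", 32.0, rec.fs, list(rec.channels), seg.data)
            derivs = make_bipolar(rec_seg, (("C3", "O1"), ("C4", "O2"),
                                            ("Fp1", "C3"), ("Fp2", "C4")))
            out = derivation_ibi(derivs, rec.fs)
            diffs.append(out["ibi_mean_FC"] - out["ibi_mean_CO"])
        assert np.mean(diffs) > 0


def test_discontinuity_decreases_with_age(small_sim_config, small_cohort, run_config):
    """MSC and IBI95 fall from T1 to T2 on the simulated cohort."""
    from neomaturity.pipeline import compute_recording_metrics

    _, _, truth = small_cohort
    msc, ibi = {"T1": [], "T2": []}, {"T1": [], "T2": []}
    for iid, info in truth["infants"].items():
        for ses in ("T1", "T2"):
            rec, ann, _ = simulate_eeg({**info, "infant_id": iid}, ses, small_sim_config)
            m = compute_recording_metrics(rec, ann, run_config)["qs"]
            msc[ses].append(m["msc"])
            ibi[ses].append(m["ibi95"])
    assert np.mean(msc["T2"]) < np.mean(msc["T1"])
    assert np.mean(ibi["T2"]) < np.mean(ibi["T1"])
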