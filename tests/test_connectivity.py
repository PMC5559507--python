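import numpy as np
import pytest

from mspli import (
    ConnectivityMatrix,
    DEFAULT_BANDS,
    LabelVector,
    PhaseDifferenceSeries,
    ROIMap,
    band_phase,
    extract_ms_epochs,
    ms_pli,
    ms_pli_from_phases,
    pair_series,
    pli,
    roi_aggregate,
)

ALPHA2 = DEFAULT_BANDS[2]


class TestPli:
    def test_constant_positive_lag_gives_one(self):
        assert pli(np.full(1000, np.pi / 4)) == 1.0

    def test_sign_balanced_series_gives_zero(self):
        d = np.concatenate([np.full(500, 0.1), np.full(500, -0.1)])
        assert pli(d) == 0.0

    def test_three_to_one_split(self):
        # direct sign-count oracle: |(3000 - 1000)| / 4000 = 0.5
        d = np.concatenate([np.full(3000, 0.1), np.full(1000, -0.1)])
        assert pli(d) == pytest.approx(0.5, abs=1e-15)

    def test_zero_differences_contribute_nothing(self):
        d = np.concatenate([np.full(10, 0.2), np.zeros(10)])
        assert pli(d) == pytest.approx(0.5)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pli(np.array([]))

    def test_common_phase_offset_invariance(self, rng):
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert pli(a - b) == pytest.approx(pli((a + 0.7) - (b + 0.7)))

    def test_pair_swap_leaves_magnitude(self, rng):
        d = rng.uniform(-np.pi, np.pi, 500)
        assert pli(d) == pytest.approx(pli(-d))

    def test_null_mean_matches_sqrt_two_over_pi_L(self, rng):
        # E|mean of L iid signs| ~ sqrt(2/(pi L))
        L = 400
        vals = [
            pli(rng.uniform(-np.pi, np.pi, L)) for _ in range(1000)
        ]
        assert np.mean(vals) == pytest.approx(np.sqrt(2 / (np.pi * L)), rel=0.1)


def _phases_and_labels(n_samples, labels_arr, k=2, n_channels=3, seed=0):
    rng = np.random.default_rng(seed)
    from mspli import PhaseTensor, BandDefinition

    phase = rng.uniform(-np.pi, np.pi, (n_channels, n_samples))
    pt = PhaseTensor(
        phase=phase,
        band=ALPHA2,
        valid_mask=np.ones(n_samples, dtype=bool),
        rate=250.0,
    )
    return pt, LabelVector(labels=labels_arr, k=k)


class TestExtractMsEpochs:
    def test_sixteen_thousand_samples_give_four_epochs(self):
        labels = np.zeros(17000, dtype=int)
        labels[16000:] = 1
        pt, lv = _phases_and_labels(17000, labels)
        epochs = extract_ms_epochs(pt, lv, epoch_len=4000, n_epochs=4)
        assert len(epochs[0]) == 4
        assert all(idx.size == 4000 for idx in epochs[0])

    def test_short_class_yields_partial_epochs(self):
        labels = np.zeros(8000, dtype=int)
        labels[6000:] = 1
        pt, lv = _phases_and_labels(8000, labels)
        epochs = extract_ms_epochs(pt, lv, epoch_len=4000, n_epochs=4)
        assert len(epochs[0]) == 1  # floor(6000 / 4000)
        assert len(epochs[1]) == 0  # only 2000 samples

    def test_absent_class_yields_zero_epochs(self):
        labels = np.zeros(5000, dtype=int)
        pt, lv = _phases_and_labels(5000, labels, k=3)
        epochs = extract_ms_epochs(pt, lv, epoch_len=1000, n_epochs=4)
        assert epochs[1] == [] and epochs[2] == []

    def test_epochs_preserve_temporal_order(self):
        labels = np.tile(np.repeat([0, 1], 500), 10)
        pt, lv = _phases_and_labels(10000, labels)
        epochs = extract_ms_epochs(pt, lv, epoch_len=2000, n_epochs=2)
        idx = np.concatenate(epochs[0])
        assert np.all(np.diff(idx) > 0)
        assert np.all(labels[idx] == 0)

    def test_invalid_epoch_len_rejected(self):
        pt, lv = _phases_and_labels(100, np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            extract_ms_epochs(pt, lv, epoch_len=0)

    def test_misaligned_labels_rejected(self):
        pt, _ = _phases_and_labels(100, np.zeros(100, dtype=int))
        lv = LabelVector(labels=np.zeros(50, dtype=int), k=2)
        with pytest.raises(ValueError, match="aligned"):
            extract_ms_epochs(pt, lv)


class TestMsPli:
    def test_planted_constant_lag_gives_unit_pli(self, pure_lag_recording):
        rec, _ = pure_lag_recording
        labels = LabelVector(
            labels=np.random.default_rng(1).integers(0, 4, rec.n_samples), k=4
        )
        W = ms_pli(rec, labels, ALPHA2, epoch_len=1000)
        assert W.W[0, 1] == 1.0

    def test_independent_phases_give_small_pli(self):
        # null oracle: |mean of 4,000 iid signs| averaged over 16 epochs
        n = 16 * 4000
        pt, lv = _phases_and_labels(n, np.zeros(n, dtype=int), n_channels=3, seed=4)
        W = ms_pli_from_phases(pt, lv, ["a", "b", "c"], epoch_len=4000, n_epochs=16)
        assert np.all(W.W[np.triu_indices(3, 1)] < 0.05)

    def test_independent_narrowband_channels_give_small_pli(self):
        # narrowband phases are autocorrelated (~1/bandwidth), so the PLI
        # floor sits well above the iid-sign level but far below coupling
        from mspli.synthetic import SimConfig, CouplingSpec, generate_subject_eeg

        cfg = SimConfig(
            n_subjects=4, n_channels=4, duration=120.0, noise_sd=0.0,
            ms_amplitude=0.0,
            coupling_spec=(
                CouplingSpec((0, 1), "alpha2", np.pi / 4, 0.0),
                CouplingSpec((2, 3), "alpha2", np.pi / 4, 0.0),
            ),
            channel_labels=("a", "b", "c", "d"), seed=2,
        )
        rec, _ = generate_subject_eeg(cfg, 0, 26.0)
        labels = LabelVector(labels=np.zeros(rec.n_samples, dtype=int), k=1)
        W = ms_pli(rec, labels, ALPHA2, epoch_len=1000, n_epochs=16)
        assert W.W[0, 1] < 0.2

    def test_single_class_equals_plain_pli(self, pure_lag_recording):
        # oracle equivalence: one class covering everything = windowed PLI
        full, _ = pure_lag_recording
        from mspli import EEGRecording

        rec = EEGRecording(full.data[:2], full.rate, full.labels[:2])
        labels = LabelVector(labels=np.zeros(rec.n_samples, dtype=int), k=1)
        phases = band_phase(rec, ALPHA2)
        W = ms_pli_from_phases(phases, labels, rec.labels, epoch_len=1000, n_epochs=4)
        idx = np.flatnonzero(phases.valid_mask)[:4000]
        plain = np.zeros((rec.n_channels, rec.n_channels))
        for i in range(rec.n_channels):
            for j in range(rec.n_channels):
                if i != j:
                    chunks = [
                        pli(pair_series(phases, idx[e * 1000 : (e + 1) * 1000], i, j))
                        for e in range(4)
                    ]
                    plain[i, j] = np.mean(chunks)
        np.testing.assert_allclose(W.W, plain, atol=1e-12)

    def test_partial_microstate_coverage_still_bounded(self, pure_lag_recording):
        rec, _ = pure_lag_recording
        lab = np.zeros(rec.n_samples, dtype=int)
        lab[: rec.n_samples // 3] = 1
        labels = LabelVector(labels=lab, k=4)  # classes 2, 3 absent
        W = ms_pli(rec, labels, ALPHA2, epoch_len=1000)
        assert sum(W.coverage.values()) <= 8
        assert np.all((W.W >= 0) & (W.W <= 1))

    def test_no_epochs_raises_naming_shortfall(self, pure_lag_recording):
        rec, _ = pure_lag_recording
        labels = LabelVector(labels=np.zeros(rec.n_samples, dtype=int), k=1)
        with pytest.raises(ValueError, match="epoch"):
            ms_pli(rec, labels, ALPHA2, epoch_len=10 * rec.n_samples)

    def test_output_contract(self, pure_lag_recording):
        rec, _ = pure_lag_recording
        labels = LabelVector(labels=np.zeros(rec.n_samples, dtype=int), k=1)
        W = ms_pli(rec, labels, ALPHA2, epoch_len=1000)
        assert np.allclose(W.W, W.W.T)
        assert np.all(np.diag(W.W) == 0)
        assert np.all((W.W >= 0) & (W.W <= 1))


class TestRoiAggregate:
    def _matrix(self, W, nodes):
        return ConnectivityMatrix(W=np.asarray(W, float), nodes=nodes)

    def test_equal_cross_pairs(self):
        W = np.zeros((4, 4))
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            W[i, j] = W[j, i] = 0.4
        m = self._matrix(W, ["a1", "a2", "b1", "b2"])
        roi = ROIMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = roi_aggregate(m, roi)
        assert out.W[0, 1] == pytest.approx(0.4)

    def test_mean_of_unequal_cross_pairs(self):
        W = np.zeros((3, 3))
        W[0, 2] = W[2, 0] = 0.2
        W[1, 2] = W[2, 1] = 0.6
        m = self._matrix(W, ["a1", "a2", "b1"])
        roi = ROIMap({"a1": "A", "a2": "A", "b1": "B"})
        out = roi_aggregate(m, roi)
        assert out.W[0, 1] == pytest.approx(0.4)

    def test_within_roi_pairs_excluded(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.9  # within-ROI pair must not leak anywhere
        W[0, 2] = W[2, 0] = 0.1
        W[1, 2] = W[2, 1] = 0.3
        m = self._matrix(W, ["a1", "a2", "b1"])
        out = roi_aggregate(m, ROIMap({"a1": "A", "a2": "A", "b1": "B"}))
        assert out.W[0, 1] == pytest.approx(0.2)
        assert out.W[0, 0] == 0

    def test_unmapped_channel_ignored(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        m = self._matrix(W, ["a1", "b1", "junk"])
        out = roi_aggregate(m, ROIMap({"a1": "A", "b1": "B"}))
        assert out.n_nodes == 2

    def test_empty_roi_rejected(self):
        W = np.zeros((2, 2))
        m = self._matrix(W, ["a1", "b1"])
        with pytest.raises(ValueError, match="no channels"):
            roi_aggregate(m, ROIMap({"a1": "A", "x9": "B"}))
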