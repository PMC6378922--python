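import numpy as np
import pytest

import hystnet as hn
from hystnet.connectivity import (
    ConnectivityTensor,
    ddtf,
    dtf,
    partial_coherence,
    threshold_edges,
    transfer_function,
)
from hystnet.networks import BrainNode, Condition, Edge, GroundTruthNetwork


def _two_node_model(cross=0.0):
    A = np.array([[[0.5, 0.0], [cross, 0.5]]])
    return hn.MVARModel(A, np.eye(2), 128.0, channel_names=["a", "b"])


class TestTransferFunction:
    def test_zero_coefficients_give_identity(self):
        model = hn.MVARModel(np.zeros((1, 2, 2)), np.eye(2), 128.0)
        spec = transfer_function(model, [5.0, 20.0])
        for H in spec.H:
            assert np.allclose(H, np.eye(2))

    def test_ar1_low_frequency_gain(self):
        model = hn.MVARModel(np.array([[[0.5]]]), np.eye(1), 128.0)
        spec = transfer_function(model, [1e-6])
        assert np.abs(spec.H[0, 0, 0]) ** 2 == pytest.approx(4.0, rel=1e-4)

    def test_spectral_matrix_integrates_to_process_variance(self):
        # Parseval: var(x) = (2/fs) * integral of S over (0, fs/2)
        model = hn.MVARModel(np.array([[[0.7]]]), np.eye(1), 128.0)
        x = hn.simulate_mvar(model, 200_000, seed=0)
        freqs = np.linspace(0.01, 63.99, 2000)
        spec = transfer_function(model, freqs)
        integral = np.trapezoid(np.real(spec.S[:, 0, 0]), freqs) * 2.0 / 128.0
        assert integral == pytest.approx(np.var(x), rel=0.02)

    def test_frequencies_outside_nyquist_rejected(self):
        model = _two_node_model()
        with pytest.raises(ValueError, match="inside"):
            transfer_function(model, [70.0])

    def test_hermitian_psd_spectral_matrix(self):
        model = _two_node_model(cross=0.3)
        spec = transfer_function(model, np.arange(2.0, 33.0))
        for S in spec.S:
            assert np.allclose(S, S.conj().T)
            assert np.all(np.linalg.eigvalsh(S) > -1e-12)


class TestDtf:
    def test_identity_transfer_gives_self_inflow_only(self):
        H = np.eye(3)[None, :, :].astype(complex)
        g = dtf(H)
        assert np.allclose(g[0], np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        H = rng.standard_normal((5, 4, 4)) + 1j * rng.standard_normal((5, 4, 4))
        g = dtf(H)
        assert np.allclose(g.sum(axis=2), 1.0, atol=1e-12)

    def test_unidirectional_drive_has_zero_reverse_flow(self):
        spec = transfer_function(_two_node_model(cross=0.4), np.arange(2.0, 33.0))
        g = dtf(spec.H)
        # flow b<-a present, a<-b absent (H is lower triangular)
        assert np.all(g[:, 1, 0] > 0)
        assert np.all(g[:, 0, 1] < 1e-10)


class TestPartialCoherence:
    def test_diagonal_spectrum_has_zero_partial_coherence(self):
        S = np.stack([np.diag([2.0, 3.0]).astype(complex)] * 4)
        chi = partial_coherence(S)
        assert np.allclose(chi[:, 0, 1], 0.0)

    def test_exact_symmetry_and_range(self):
        spec = transfer_function(_two_node_model(cross=0.4), np.arange(2.0, 33.0))
        chi = partial_coherence(spec.S)
        assert np.allclose(chi, chi.transpose(0, 2, 1))
        assert np.all((chi >= 0) & (chi <= 1))

    def test_chain_indirect_link_suppressed(self):
        # 1 -> 2 -> 3: ordinary coherence(1,3) is large, partial is small
        A = np.zeros((1, 3, 3))
        A[0] = np.diag([0.5, 0.5, 0.5])
        A[0, 1, 0] = 0.5
        A[0, 2, 1] = 0.5
        model = hn.MVARModel(A, np.eye(3), 128.0)
        spec = transfer_function(model, np.arange(2.0, 33.0))
        chi = partial_coherence(spec.S)
        S = spec.S
        ordinary = np.abs(S[:, 0, 2]) ** 2 / (
            np.real(S[:, 0, 0]) * np.real(S[:, 2, 2])
        )
        assert chi[:, 0, 2].mean() < 0.1 * ordinary.mean()


class TestDdtf:
    def test_disconnected_nodes_have_no_cross_flow(self):
        tensor = ddtf(_two_node_model(cross=0.0))
        off = tensor.values[0, 1] , tensor.values[1, 0]
        assert np.all(off[0] < 1e-10) and np.all(off[1] < 1e-10)

    def test_single_edge_recovery_from_simulated_data(self):
        nodes = [BrainNode(n, 0) for n in "ABCD"]
        net = GroundTruthNetwork(nodes, [Edge("A", "C", 0.35)], Condition.L1)
        gen = hn.network_to_mvar(net)
        x = hn.simulate_source_eeg(gen, 120.0, seed=6)
        model = hn.fit_window(hn.ensemble_normalize(x), p=5)
        bm = ddtf(model).band_mean((7.0, 30.0))
        off = bm.copy()
        np.fill_diagonal(off, 0.0)
        assert np.unravel_index(np.argmax(off), off.shape) == (0, 2)
        assert bm[2, 0] < 0.1 * bm[0, 2]

    def test_bounded_by_full_frequency_dtf(self):
        tensor = ddtf(_two_node_model(cross=0.4))
        eta = np.sqrt(tensor.intermediates["ffdtf"])
        assert np.all(tensor.values <= eta + 1e-12)
        assert np.all(tensor.values <= 1.0)
        # zero whenever either factor is zero
        zero = (tensor.intermediates["ffdtf"] < 1e-30) | (
            tensor.intermediates["pcoh"] < 1e-30
        )
        assert np.all(tensor.values[zero] < 1e-12)

    def test_frequency_range_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ddtf(_two_node_model(), freq_range=(2.0, 80.0))

    def test_long_format_export_round_trip(self, tmp_path):
        tensor = ddtf(_two_node_model(cross=0.3))
        df = tensor.to_frame()
        assert set(df.columns) == {"window", "freq_hz", "from_node", "to_node", "ddtf"}
        assert len(df) == 2 * 2 * len(tensor.freqs)
        sel = df[(df.from_node == "a") & (df.to_node == "b")]
        assert np.allclose(sel["ddtf"].to_numpy(), tensor.values[0, 1, :, 0])


class TestThresholdEdges:
    def _tensor(self, values, names=None):
        k = values.shape[0]
        names = names or [f"n{i}" for i in range(k)]
        freqs = np.arange(values.shape[2], dtype=float) + 2.0
        return ConnectivityTensor(values, freqs, names)

    def test_all_equal_values_retain_nothing(self):
        v = np.full((3, 3, 2, 1), 0.5)
        out = threshold_edges(self._tensor(v))
        assert all(len(e) == 0 for e in out.values())

    def test_cutoff_is_97_5th_percentile_of_off_diagonal(self):
        # distinct off-diagonal values; retained set = strictly above
        # the off-diagonal 97.5th percentile (independent oracle)
        rng = np.random.default_rng(2)
        k = 33
        v = np.zeros((k, k, 1, 1))
        off_mask = ~np.eye(k, dtype=bool)
        v[off_mask, 0, 0] = rng.permutation(off_mask.sum()) + 1.0
        tensor = self._tensor(v)
        cut = np.percentile(v[off_mask, 0, 0], 97.5)
        kept = threshold_edges(tensor)[2.0]
        assert len(kept) == int(np.sum(v[off_mask, 0, 0] > cut))
        assert all(w > cut for _, _, w in kept)
        # ~2.5% of 1056 values
        assert len(kept) == 27

    def test_retained_fraction_near_2_5_percent(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(size=(20, 20, 5, 1))
        v[np.arange(20), np.arange(20)] = 0.0
        out = threshold_edges(self._tensor(v))
        fracs = [len(e) / (20 * 19) for e in out.values()]
        assert np.mean(fracs) == pytest.approx(0.025, abs=0.01)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(size=(4, 4, 3, 2))
        t = self._tensor(v)
        assert threshold_edges(t) == threshold_edges(t)
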