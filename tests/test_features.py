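import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tinnconn import features
from tinnconn.types import (
    AUDITORY_CHANNELS_12,
    DEFAULT_BANDS,
    ConnectivityMatrix,
    EstimationError,
    InputError,
)

from ._oracles import pcc_oracle, pli_oracle, plv_oracle, te_oracle
from .conftest import make_epoch, sine

ALPHA = DEFAULT_BANDS[2]


class TestAnalyticPhase:
    def test_sinusoid_phase_slope(self):
        fs, f = 1000.0, 10.0
        ep = make_epoch(sine(f, fs, 10), fs)
        phase = features.analytic_phase(ep).phase[0]
        slope = np.diff(np.unwrap(phase))[500:-500].mean() * fs
        assert slope == pytest.approx(2 * np.pi * f, rel=1e-3)

    def test_cos_sin_quarter_cycle_offset(self):
        fs, f = 1000.0, 10.0
        t = np.arange(10_000) / fs
        ep = make_epoch(np.vstack([np.cos(2 * np.pi * f * t),
                                   np.sin(2 * np.pi * f * t)]), fs)
        ph = features.analytic_phase(ep).phase
        diff = np.angle(np.exp(1j * (ph[0] - ph[1])))[500:-500]
        assert np.allclose(diff, np.pi / 2, atol=0.01)

    def test_range_contract_on_noise(self, rng):
        ep = make_epoch(rng.normal(size=(3, 2500)), 250.0)
        ph = features.analytic_phase(ep, ALPHA).phase
        assert ph.min() > -np.pi - 1e-12
        assert ph.max() <= np.pi + 1e-12

    def test_band_outside_nyquist(self, rng):
        from tinnconn.types import BandDefinition
        ep = make_epoch(rng.normal(size=(1, 1000)), 100.0)
        with pytest.raises(InputError):
            features.analytic_phase(ep, BandDefinition("hg", 52, 90))


class TestPLV:
    def test_constant_lag_is_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=1000)
        assert features.plv(phi, phi + np.pi / 4) == pytest.approx(1.0, abs=1e-12)

    def test_independent_phases_near_zero(self, rng):
        a = rng.uniform(-np.pi, np.pi, size=10_000)
        b = rng.uniform(-np.pi, np.pi, size=10_000)
        assert features.plv(a, b) < 0.05

    def test_two_sample_cancellation(self):
        # oracle: |(1 + e^{j·pi}) / 2| = 0
        assert features.plv(np.array([0.0, 0.0]),
                            np.array([0.0, -np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.uniform(-np.pi, np.pi, size=50)
        b = rng.uniform(-np.pi, np.pi, size=50)
        assert features.plv(a, b) == pytest.approx(features.plv(b, a), abs=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            features.plv(np.zeros(5), np.zeros(6))

    def test_matches_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 21)
            a = rng.uniform(-np.pi, np.pi, size=n)
            b = rng.uniform(-np.pi, np.pi, size=n)
            expected = plv_oracle(list(a), list(b))
            assert features.plv(a, b) == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestPLI:
    def test_constant_quarter_lag_is_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=1000)
        z1 = np.exp(1j * phi)
        z2 = np.exp(1j * (phi - np.pi / 2))
        assert features.pli(z1, z2) == pytest.approx(1.0, abs=1e-12)

    def test_zero_lag_is_zero(self, rng):
        z = np.exp(1j * rng.uniform(-np.pi, np.pi, size=1000))
        assert features.pli(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_lag_cancels(self):
        phi = np.zeros(100)
        lag = np.tile([np.pi / 4, -np.pi / 4], 50)
        assert features.pli(np.exp(1j * phi),
                            np.exp(1j * (phi + lag))) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 21)
            z1 = np.exp(1j * rng.uniform(-np.pi, np.pi, size=n))
            z2 = np.exp(1j * rng.uniform(-np.pi, np.pi, size=n))
            expected = pli_oracle(list(z1), list(z2))
            assert features.pli(z1, z2) == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestPCC:
    def test_positive_affine_copy(self, rng):
        x = rng.normal(size=1000)
        assert features.pcc(x, 2 * x + 3) == pytest.approx(1.0, abs=1e-9)

    def test_negation(self, rng):
        x = rng.normal(size=1000)
        assert features.pcc(x, -x) == pytest.approx(-1.0, abs=1e-9)

    def test_independent_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(features.pcc(x, y)) < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(EstimationError):
            features.pcc(np.ones(10), np.arange(10.0))

    def test_matches_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(3, 21)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            expected = pcc_oracle(list(x), list(y))
            assert features.pcc(x, y) == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestTransferEntropy:
    def test_binary_lag1_copy_is_one_bit(self, rng):
        # cyclic pattern with exactly uniform empirical joint counts
        xi = np.tile([0.0, 0.0, 1.0, 1.0], 2500)
        xi = np.append(xi, xi[0])
        xk = np.roll(xi[:-1], 1)
        xk = np.append(xk, xi[-2])  # xk[t+1] = xi[t] exactly
        assert features.transfer_entropy(xi, xk, bins=2) == pytest.approx(1.0, abs=1e-9)

    def test_independent_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert features.transfer_entropy(x, y, bins=4) < 0.02

    def test_identical_signals_symmetric(self, rng):
        x = rng.normal(size=500)
        assert features.transfer_entropy(x, x) == pytest.approx(
            features.transfer_entropy(x, x), abs=1e-14)

    def test_bins_too_few(self, rng):
        with pytest.raises(InputError):
            features.transfer_entropy(rng.normal(size=10), rng.normal(size=10), bins=1)

    def test_matches_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 21))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            expected = te_oracle(list(x), list(y), bins=3)
            got = features.transfer_entropy(x, y, bins=3)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_noisy_copy_monotone_in_noise(self):
        # TE of a lag-1 copy decreases as symbol noise increases
        levels = [0.0, 0.25, 0.5]
        means = []
        for p in levels:
            vals = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                xi = r.integers(0, 2, size=4000).astype(float)
                xk = np.roll(xi, 1)
                flip = r.random(4000) < p
                xk[flip] = 1 - xk[flip]
                vals.append(features.transfer_entropy(xi, xk, bins=2))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_joint_histogram_normalized(self, rng):
        d = features.joint_histogram(rng.normal(size=100), rng.normal(size=100))
        assert d.probabilities.sum() == pytest.approx(1.0)
        assert d.probabilities.min() >= 0


class TestConnectivityMatrix:
    def test_plv_contract_12ch(self, rng):
        ep = make_epoch(rng.normal(size=(12, 1000)), 250.0,
                        labels=AUDITORY_CHANNELS_12)
        m = features.connectivity_matrix(ep, "plv")
        assert m.values.shape == (12, 12)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_permutation_equivariance(self, rng):
        data = rng.normal(size=(4, 500))
        ep = make_epoch(data, 250.0)
        m = features.connectivity_matrix(ep, "pcc").values
        perm = [2, 0, 3, 1]
        ep_p = make_epoch(data[perm], 250.0,
                          labels=[f"ch{i}" for i in perm])
        m_p = features.connectivity_matrix(ep_p, "pcc").values
        assert np.allclose(m_p, m[np.ix_(perm, perm)], atol=1e-12)

    @pytest.mark.parametrize("measure", ["plv", "pli", "pcc", "te"])
    def test_three_channel_toy_matches_pairwise(self, rng, measure):
        ep = make_epoch(rng.normal(size=(3, 200)), 100.0)
        m = features.connectivity_matrix(ep, measure).values
        if measure == "plv":
            ph = features.analytic_phase(ep).phase
            for i in range(3):
                for k in range(3):
                    if i != k:
                        assert m[i, k] == pytest.approx(
                            features.plv(ph[i], ph[k]), rel=1e-9)
        elif measure == "pli":
            z = features.analytic_signal(ep)
            for i in range(3):
                for k in range(i + 1, 3):
                    assert m[i, k] == pytest.approx(
                        features.pli(z[i], z[k]), rel=1e-12)
        elif measure == "pcc":
            for i in range(3):
                for k in range(i + 1, 3):
                    assert m[i, k] == pytest.approx(
                        features.pcc(ep.data[i], ep.data[k]), rel=1e-12)
        else:
            for i in range(3):
                for k in range(3):
                    if i != k:
                        assert m[i, k] == pytest.approx(
                            features.transfer_entropy(ep.data[i], ep.data[k]),
                            rel=1e-12)

    def test_unknown_measure(self, rng):
        ep = make_epoch(rng.normal(size=(2, 100)), 100.0)
        with pytest.raises(InputError):
            features.connectivity_matrix(ep, "granger")

    def test_te_directed(self, rng):
        x = rng.normal(size=2000)
        y = np.roll(x, 1) + 0.1 * rng.normal(size=2000)
        ep = make_epoch(np.vstack([x, y]), 250.0)
        m = features.connectivity_matrix(ep, "te")
        assert m.directed
        assert m.values[0, 1] > m.values[1, 0]


class TestRhythmStats:
    def test_length_144(self, rng):
        ep = make_epoch(rng.normal(size=(12, 2500)), 250.0,
                        labels=AUDITORY_CHANNELS_12)
        fv = features.rhythm_stats(ep)
        assert len(fv) == 144

    def test_alpha_tone_band_isolation(self):
        fs = 1000.0
        ep = make_epoch(sine(10, fs, 10), fs)
        fv = features.rhythm_stats(ep)
        stds = {b.name: fv.values[2 * i + 1] for i, b in enumerate(DEFAULT_BANDS)}
        assert stds["alpha"] == pytest.approx(np.sqrt(0.5), rel=0.02)
        for name, val in stds.items():
            if name != "alpha":
                assert val < 0.05

    def test_zero_signal_zero_features(self):
        ep = make_epoch(np.zeros((2, 1000)), 250.0)
        assert np.allclose(features.rhythm_stats(ep).values, 0.0)

    def test_layout_name_recorded(self, rng):
        ep = make_epoch(rng.normal(size=(2, 500)), 250.0)
        assert features.rhythm_stats(ep).layout.startswith("rhythm:")


class TestPSDFeatures:
    def test_tone_power(self):
        fs = 1000.0
        ep = make_epoch(sine(10, fs, 10), fs)
        fv = features.psd_features(ep)
        powers = dict(zip([b.name for b in DEFAULT_BANDS], fv.values))
        assert powers["alpha"] == pytest.approx(0.5, rel=0.05)
        for name, val in powers.items():
            if name != "alpha":
                assert powers["alpha"] > 100 * val

    def test_white_noise_flat_spectrum(self, rng):
        fs = 1000.0
        ep = make_epoch(rng.normal(size=(1, 10_000)), fs)
        fv = features.psd_features(ep)
        density = {
            b.name: p / (b.high_hz - b.low_hz)
            for b, p in zip(DEFAULT_BANDS, fv.values)
        }
        ref = np.mean(list(density.values()))
        for val in density.values():
            assert val == pytest.approx(ref, rel=0.2)

    def test_length_72(self, rng):
        ep = make_epoch(rng.normal(size=(12, 2500)), 250.0,
                        labels=AUDITORY_CHANNELS_12)
        assert len(features.psd_features(ep)) == 72

    def test_bad_resolution(self, rng):
        ep = make_epoch(rng.normal(size=(1, 100)), 100.0)
        with pytest.raises(InputError):
            features.psd_features(ep, nperseg=500)


class TestFlatten:
    def test_undirected_length_66(self, rng):
        ep = make_epoch(rng.normal(size=(12, 500)), 250.0,
                        labels=AUDITORY_CHANNELS_12)
        m = features.connectivity_matrix(ep, "pcc")
        fv = features.flatten_connectivity(m)
        assert len(fv) == 66
        assert fv.layout == "conn:pcc:uppertri:v1"

    def test_directed_length_132(self, rng):
        ep = make_epoch(rng.normal(size=(12, 500)), 250.0,
                        labels=AUDITORY_CHANNELS_12)
        m = features.connectivity_matrix(ep, "te")
        assert len(features.flatten_connectivity(m)) == 132

    def test_round_trip_symmetric(self, rng):
        ep = make_epoch(rng.normal(size=(5, 400)), 250.0)
        m = features.connectivity_matrix(ep, "pcc")
        fv = features.flatten_connectivity(m)
        back = features.unflatten_connectivity(fv, m.channel_labels, "pcc")
        assert np.allclose(back.values, m.values, atol=1e-12)

    def test_round_trip_directed(self, rng):
        ep = make_epoch(rng.normal(size=(4, 400)), 250.0)
        m = features.connectivity_matrix(ep, "te")
        fv = features.flatten_connectivity(m)
        back = features.unflatten_connectivity(fv, m.channel_labels, "te")
        assert np.allclose(back.values, m.values, atol=1e-12)

    def test_row_major_order(self):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        vals /= vals.max()  # valid PLI-ish range
        m = ConnectivityMatrix(vals, "pli", False, ["a", "b", "c"])
        fv = features.flatten_connectivity(m)
        assert np.allclose(fv.values, [vals[0, 1], vals[0, 2], vals[1, 2]])
        assert fv.names == ["a-b", "a-c", "b-c"]


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       seed=st.integers(min_value=0, max_value=2 ** 16))
def test_plv_pli_amplitude_invariance(scale, seed):
    r = np.random.default_rng(seed)
    phi1 = r.uniform(-np.pi, np.pi, size=64)
    phi2 = r.uniform(-np.pi, np.pi, size=64)
    z1, z2 = np.exp(1j * phi1), np.exp(1j * phi2)
    assert features.plv(phi1, phi2) == pytest.approx(
        features.plv(phi1, phi2), abs=0)  # phases carry no amplitude
    assert features.pli(scale * z1, z2) == pytest.approx(
        features.pli(z1, z2), rel=1e-9)
    assert features.pli(z1, scale * z2) == pytest.approx(
        features.pli(z1, z2), rel=1e-9)


@settings(max_examples=50, deadline=None)
@given(a=st.floats(min_value=1e-3, max_value=1e3),
       b=st.floats(min_value=-100, max_value=100),
       seed=st.integers(min_value=0, max_value=2 ** 16))
def test_pcc_affine_invariance(a, b, seed):
    r = np.random.default_rng(seed)
    x = r.normal(size=128)
    y = r.normal(size=128)
    base = features.pcc(x, y)
    assert features.pcc(x, a * y + b) == pytest.approx(base, abs=1e-6)
    assert features.pcc(x, -y) == pytest.approx(-base, abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(min_value=0, max_value=2 ** 16),
       n=st.integers(min_value=4, max_value=20))
def test_estimators_match_oracles_property(seed, n):
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    y = r.normal(size=n)
    phi1 = r.uniform(-np.pi, np.pi, size=n)
    phi2 = r.uniform(-np.pi, np.pi, size=n)
    assert features.plv(phi1, phi2) == pytest.approx(
        plv_oracle(list(phi1), list(phi2)), rel=1e-12, abs=1e-12)
    assert features.pcc(x, y) == pytest.approx(
        pcc_oracle(list(x), list(y)), rel=1e-12, abs=1e-12)
    assert features.transfer_entropy(x, y, bins=2) == pytest.approx(
        te_oracle(list(x), list(y), bins=2), rel=1e-12, abs=1e-12)
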