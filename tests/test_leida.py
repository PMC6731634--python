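"""The LEiDA chain: filtering, phases, coherence, eigenvectors, clustering."""

import numpy as np
import pytest
from scipy import linalg, signal
from scipy.optimize import linear_sum_assignment

from pmstates import (
    EigenvectorSeries,
    PhaseRepresentation,
    RegionalTimeSeries,
    assign_to_centroids,
    bandpass_filter,
    cluster_states,
    compute_phases,
    generate_eigenvector_clusters,
    generate_markov_labels,
    leading_eigenvectors,
    leida_chain,
    occupancy_probabilities,
    permutation_paired_test,
    phase_coherence_tensor,
    select_k,
    switching_matrix,
)


def _tone(f_hz, T=600, tr=2.0, n_regions=1, phase=0.0):
    t = np.arange(T) * tr
    x = np.tile(np.cos(2 * np.pi * f_hz * t + phase), (n_regions, 1))
    return RegionalTimeSeries(x, tr_s=tr)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        out = bandpass_filter(_tone(0.05), 0.02, 0.1)
        mid = out.values[0, 100:500]
        assert abs(mid.max() - 1.0) < 0.05

    def test_slow_drift_strongly_attenuated(self):
        """Attenuation at 0.005 Hz matches the design's frequency response
        (zero-phase order-2 Butterworth applied forward-backward)."""
        out = bandpass_filter(_tone(0.005, T=2000), 0.02, 0.1)
        assert np.max(np.abs(out.values[0, 500:1500])) < 0.1
        sos = signal.butter(2, [0.02, 0.1], btype="bandpass", fs=0.5, output="sos")
        _, h = signal.sosfreqz(sos, worN=[0.005], fs=0.5)
        assert np.abs(h[0]) ** 2 < 0.1  # filtfilt applies the response twice

    def test_constant_signal_maps_to_zero(self):
        ts = RegionalTimeSeries(np.full((2, 100), 3.7), tr_s=2.0)
        out = bandpass_filter(ts)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_band_above_nyquist_reports_achievable_band(self):
        with pytest.raises(ValueError, match="achievable band"):
            bandpass_filter(_tone(0.05), 0.02, 0.3)


class TestPhases:
    def test_cosine_phase_advances_at_signal_frequency(self):
        ph = compute_phases(bandpass_filter(_tone(0.05)), trim=3)
        start, stop = ph.valid_range
        unwrapped = np.unwrap(ph.phases[0, start:stop])
        slope = np.polyfit(np.arange(stop - start) * 2.0, unwrapped, 1)[0]
        assert abs(slope - 2 * np.pi * 0.05) < 0.01

    def test_identical_regions_have_zero_phase_difference(self, sinusoid_ts):
        ts = RegionalTimeSeries(
            np.vstack([sinusoid_ts.values[0], sinusoid_ts.values[0]]), tr_s=2.0
        )
        ph = compute_phases(ts, trim=3)
        d = ph.valid_phases[0] - ph.valid_phases[1]
        assert np.max(np.abs(d)) < 1e-9

    def test_quadrature_pair_offset_is_half_pi(self, sinusoid_ts):
        ph = compute_phases(sinusoid_ts, trim=10)
        d = np.angle(np.exp(1j * (ph.valid_phases[0] - ph.valid_phases[1])))
        assert np.allclose(np.abs(d), np.pi / 2, atol=0.05)

    def test_too_short_for_trim_rejected(self):
        ts = RegionalTimeSeries(np.random.default_rng(0).normal(size=(2, 6)), tr_s=2.0)
        with pytest.raises(ValueError):
            compute_phases(ts, trim=3)


class TestCoherenceTensor:
    @pytest.mark.parametrize(
        "offset, expected", [(0.0, 1.0), (np.pi / 2, 0.0), (np.pi, -1.0)]
    )
    def test_phase_offsets_map_to_cosine(self, offset, expected):
        phases = np.vstack([np.full(20, 0.7), np.full(20, 0.7 + offset)])
        ph = PhaseRepresentation(
            phases=np.angle(np.exp(1j * phases)),
            amplitudes=np.ones_like(phases),
            tr_s=2.0,
            valid_range=(0, 20),
        )
        tensor = phase_coherence_tensor(ph)
        assert np.allclose(tensor.values[0, 1], expected, atol=1e-12)

    def test_slices_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(4)
        ph = PhaseRepresentation(
            phases=rng.uniform(-np.pi, np.pi, (6, 50)),
            amplitudes=np.ones((6, 50)),
            tr_s=2.0,
            valid_range=(3, 47),
        )
        t = phase_coherence_tensor(ph).values
        assert np.max(np.abs(t - np.transpose(t, (1, 0, 2)))) < 1e-12
        assert np.allclose(t[np.arange(6), np.arange(6)], 1.0)
        assert t.min() >= -1 - 1e-12 and t.max() <= 1 + 1e-12


class TestLeadingEigenvectors:
    def _tensor(self, slices):
        arr = np.stack(slices, axis=2)
        from pmstates import CoherenceTensor

        return CoherenceTensor(values=arr, t_index=np.arange(arr.shape[2]))

    def test_all_ones_slice(self):
        eigs = leading_eigenvectors(self._tensor([np.ones((5, 5))]))
        assert np.allclose(np.abs(eigs.vectors[0]), 1 / np.sqrt(5))

    def test_rank_one_slice_returns_generator(self):
        v = np.array([-3.0, 1.0, -2.0, 0.5])
        v /= np.linalg.norm(v)
        eigs = leading_eigenvectors(self._tensor([np.outer(v, v)]))
        got = eigs.vectors[0]
        assert np.allclose(np.abs(got), np.abs(v), atol=1e-10)

    def test_matches_dense_symmetric_eigensolver(self):
        """Oracle: scipy.linalg.eigh on each slice independently."""
        rng = np.random.default_rng(12)
        slices = []
        for _ in range(10):
            m = rng.normal(size=(8, 8))
            m = 0.5 * (m + m.T)
            slices.append(m)
        eigs = leading_eigenvectors(self._tensor(slices))
        for k, m in enumerate(slices):
            w, v = linalg.eigh(m)
            lead = v[:, np.argmax(np.abs(w))]
            assert (
                np.linalg.norm(eigs.vectors[k] - lead) < 1e-8
                or np.linalg.norm(eigs.vectors[k] + lead) < 1e-8
            )

    def test_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(3)
        ph = PhaseRepresentation(
            phases=rng.uniform(-np.pi, np.pi, (7, 60)),
            amplitudes=np.ones((7, 60)),
            tr_s=2.0,
            valid_range=(3, 57),
        )
        eigs = leading_eigenvectors(phase_coherence_tensor(ph))
        assert np.allclose(np.linalg.norm(eigs.vectors, axis=1), 1.0, atol=1e-9)
        neg = (eigs.vectors < 0).sum(axis=1)
        pos = (eigs.vectors > 0).sum(axis=1)
        lead = np.take_along_axis(
            eigs.vectors, np.argmax(np.abs(eigs.vectors), axis=1)[:, None], axis=1
        )[:, 0]
        assert np.all((neg > pos) | ((neg == pos) & (lead < 0)))

    def test_asymmetric_slice_rejected(self):
        bad = np.ones((3, 3))
        bad[0, 1] = 0.0
        with pytest.raises(ValueError, match="symmetric"):
            leading_eigenvectors(self._tensor([bad]))


class TestClustering:
    def test_planted_clusters_recovered(self):
        vectors, labels = generate_eigenvector_clusters(3, 12, 300, separation=10.0, seed=6)
        eigs = EigenvectorSeries(vectors=vectors)
        model, got = cluster_states(eigs, k=3, seed=0)
        conf = np.zeros((3, 3))
        np.add.at(conf, (labels, got[0]), 1)
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / conf.sum() >= 0.99
        assert model.probabilities.sum() == pytest.approx(1.0)

    def test_k1_centroid_is_mean(self):
        vectors, _ = generate_eigenvector_clusters(2, 8, 60, seed=1)
        model, _ = cluster_states(EigenvectorSeries(vectors=vectors), k=1, seed=0)
        assert np.allclose(model.centroids[0], vectors.mean(axis=0), atol=1e-9)

    def test_deterministic_for_fixed_seed(self):
        vectors, _ = generate_eigenvector_clusters(3, 10, 120, seed=2)
        eigs = EigenvectorSeries(vectors=vectors)
        _, l1 = cluster_states(eigs, k=3, seed=42)
        _, l2 = cluster_states(eigs, k=3, seed=42)
        assert np.array_equal(l1[0], l2[0])

    def test_k_larger_than_samples_rejected(self):
        vectors, _ = generate_eigenvector_clusters(2, 6, 10, seed=0)
        with pytest.raises(ValueError):
            cluster_states(EigenvectorSeries(vectors=vectors), k=11)

    def test_select_k_finds_planted_three(self):
        vectors, _ = generate_eigenvector_clusters(3, 12, 240, separation=10.0, seed=9)
        table, best = select_k(EigenvectorSeries(vectors=vectors), (2, 6), seed=0)
        assert best == 3
        assert [row["k"] for row in table] == [2, 3, 4, 5, 6]

    def test_select_k_single_candidate(self):
        vectors, _ = generate_eigenvector_clusters(2, 8, 60, seed=3)
        table, best = select_k(EigenvectorSeries(vectors=vectors), (2, 2), seed=0)
        assert len(table) == 1 and best == 2


class TestOccupancyAndSwitching:
    def test_counting(self):
        assert np.allclose(
            occupancy_probabilities([0, 0, 1, 2], 3), [0.5, 0.25, 0.25]
        )
        assert np.allclose(occupancy_probabilities([1, 1, 1], 3), [0, 1, 0])
        with pytest.raises(ValueError):
            occupancy_probabilities([], 3)

    def test_long_chain_matches_stationary_distribution(self):
        from pmstates import stationary_distribution

        tpm = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = generate_markov_labels(tpm, 100_000, seed=17)
        occ = occupancy_probabilities(labels, 2)
        assert np.max(np.abs(occ - stationary_distribution(tpm))) < 0.02

    def test_switching_counts(self):
        tm = switching_matrix([0, 1, 0, 1, 0], 3)
        assert np.allclose(tm.values[0], [0, 1, 0])
        assert np.allclose(tm.values[1], [1, 0, 0])
        assert not tm.visited[2] and np.all(np.isnan(tm.values[2]))

    def test_constant_sequence_gives_identity_row(self):
        tm = switching_matrix([2, 2, 2, 2], 3)
        assert np.allclose(tm.values[2], [0, 0, 1])

    def test_no_transitions_across_session_boundary(self):
        pooled = switching_matrix([[0, 0], [1, 1]], 2)
        assert pooled.values[0, 1] == 0 and pooled.values[1, 0] == 0

    def test_chain_recovers_generating_tpm(self):
        tpm = np.array([[0.85, 0.1, 0.05], [0.15, 0.7, 0.15], [0.1, 0.2, 0.7]])
        labels = generate_markov_labels(tpm, 100_000, seed=23)
        tm = switching_matrix(labels, 3)
        assert np.max(np.abs(tm.values - tpm)) <= 0.02


class TestAssignment:
    def test_centroid_vectors_map_to_indices(self):
        cents = np.eye(4)
        eigs = EigenvectorSeries(vectors=cents[[2, 0, 3, 1]])
        assert np.array_equal(assign_to_centroids(eigs, cents), [2, 0, 3, 1])

    def test_reassignment_consistent_with_training_labels(self):
        vectors, _ = generate_eigenvector_clusters(3, 10, 150, separation=8.0, seed=4)
        eigs = EigenvectorSeries(vectors=vectors)
        model, labels = cluster_states(eigs, k=3, seed=0)
        again = assign_to_centroids(eigs, model.centroids)
        assert np.array_equal(labels[0], again)

    def test_exact_tie_resolves_to_lowest_index(self):
        cents = np.array([[1.0, 0.0], [-1.0, 0.0]])
        eigs = EigenvectorSeries(vectors=np.array([[0.0, 1.0]]))
        assert assign_to_centroids(eigs, cents)[0] == 0

    def test_dimension_mismatch_rejected(self):
        eigs = EigenvectorSeries(vectors=np.ones((3, 5)))
        with pytest.raises(ValueError, match="dimension"):
            assign_to_centroids(eigs, np.ones((2, 4)))


class TestPermutationTest:
    def test_identical_conditions_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = permutation_paired_test(a, a.copy(), seed=0)
        assert res.p_value == 1.0

    def test_large_shift_detected_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        b = rng.normal(size=10)
        a = b + 5.0
        res = permutation_paired_test(a, b, n_perm=2048, seed=0)
        # oracle: exhaustive enumeration of all 2^10 sign flips
        d = a - b
        import itertools

        def tstat(x):
            sd = x.std(ddof=1)
            if sd == 0:
                return np.inf * np.sign(x.mean()) if x.mean() else 0.0
            return x.mean() / (sd / np.sqrt(x.size))

        t_obs = abs(tstat(d))
        count = sum(
            abs(tstat(np.array(s) * d)) >= t_obs - 1e-12
            for s in itertools.product((1, -1), repeat=10)
        )
        assert res.p_value == pytest.approx(count / 1024)
        assert res.p_value <= 0.05

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(size=8)
        p1 = permutation_paired_test(a, b, seed=3).p_value
        p2 = permutation_paired_test(b, a, seed=3).p_value
        assert p1 == p2

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            permutation_paired_test([1.0], [2.0])


class TestEndToEndRecovery:
    def test_planted_substate_sequence_recovered(self):
        """Block signals driven by a sticky Markov chain: the full chain
        (filter, phases, coherence, eigenvectors, k-means) must recover the
        planted substate sequence with >= 95% accuracy."""
        rng = np.random.default_rng(0)
        k, n_regions, T, tr, f = 3, 12, 1000, 2.0, 0.05
        tpm = np.full((k, k), 0.005)
        np.fill_diagonal(tpm, 0.99)
        labels = generate_markov_labels(tpm, T, seed=1)
        offsets = np.zeros((k, n_regions))
        for s, grp in enumerate(np.array_split(np.arange(n_regions), k)):
            offsets[s, grp] = np.pi
        t = np.arange(T) * tr
        x = np.cos(2 * np.pi * f * t[None, :] + offsets[labels].T)
        x += 0.05 * rng.standard_normal((n_regions, T))
        ts = RegionalTimeSeries(x, tr_s=tr)
        eigs = leida_chain(ts, band=(0.02, 0.1), trim=3)
        _, pred = cluster_states(eigs, k=k, seed=0)
        true_valid = labels[3 : T - 3]
        conf = np.zeros((k, k))
        np.add.at(conf, (true_valid, pred[0]), 1)
        r, c = linear_sum_assignment(-conf)
        accuracy = conf[r, c].sum() / conf.sum()
        assert accuracy >= 0.95
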