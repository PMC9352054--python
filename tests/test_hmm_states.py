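import numpy as np
import pytest

from cionaswim import hmm_states as hs


def sample_ghmm(model: hs.GHMMModel, T, seed):
    """Independent forward sampler used as the generating oracle."""
    rng = np.random.default_rng(seed)
    K, d = model.means.shape
    states = np.empty(T, dtype=int)
    X = np.empty((T, d))
    states[0] = rng.choice(K, p=model.startprob)
    for t in range(1, T):
        states[t] = rng.choice(K, p=model.transmat[states[t - 1]])
    for k in range(K):
        idx = states == k
        cov = model.covars[k] if model.covariance_type == "full" else np.diag(model.covars[k])
        X[idx] = rng.multivariate_normal(model.means[k], cov, size=idx.sum())
    return X, states


def two_state_model():
    return hs.GHMMModel(
        n_states=2,
        startprob=np.array([0.5, 0.5]),
        transmat=np.array([[0.95, 0.05], [0.05, 0.95]]),
        means=np.array([[-3.0] * 7, [3.0] * 7]),
        covars=np.stack([np.eye(7), np.eye(7)]),
        covariance_type="full",
        loglik_trace=[0.0],
        seed=0,
    )


class TestFit:
    def test_two_state_parameter_recovery(self):
        gen = two_state_model()
        X, _ = sample_ghmm(gen, 10_000, seed=0)
        model = hs.fit_ghmm([X], n_states=2, seed=0)
        perm = hs.align_states(gen, model)
        assert np.abs(model.means[perm] - gen.means).max() < 0.2
        P = model.transmat[np.ix_(perm, perm)]
        assert np.abs(np.diag(P) - 0.95).max() < 0.03

    def test_loglik_trace_non_decreasing(self):
        gen = two_state_model()
        X, _ = sample_ghmm(gen, 3000, seed=1)
        model = hs.fit_ghmm([X], n_states=2, seed=0)
        diffs = np.diff(model.loglik_trace)
        assert (diffs > -1e-2).all()  # EM monotone up to stopping tolerance

    def test_same_seed_identical_fit(self):
        gen = two_state_model()
        X, _ = sample_ghmm(gen, 2000, seed=2)
        m1 = hs.fit_ghmm([X], n_states=3, seed=5)
        m2 = hs.fit_ghmm([X], n_states=3, seed=5)
        np.testing.assert_array_equal(m1.transmat, m2.transmat)
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_nan_features_rejected(self):
        X = np.full((100, 7), np.nan)
        with pytest.raises(ValueError):
            hs.fit_ghmm([X])

    def test_split_at_gaps(self):
        X = np.ones((10, 2))
        X[4] = np.nan
        segs = hs.split_at_gaps(X)
        assert [len(s) for s in segs] == [4, 5]


class TestDecode:
    def test_well_separated_states_recovered(self):
        gen = two_state_model()
        X, truth = sample_ghmm(gen, 5000, seed=3)
        dec = hs.decode(X, gen).states
        agree = max(np.mean(dec == truth), np.mean(1 - dec == truth))
        assert agree >= 0.99

    def test_single_state_constant_path(self):
        model = hs.GHMMModel(
            n_states=1,
            startprob=np.array([1.0]),
            transmat=np.array([[1.0]]),
            means=np.zeros((1, 3)),
            covars=np.eye(3)[None],
            covariance_type="full",
            loglik_trace=[0.0],
            seed=0,
        )
        dec = hs.decode(np.random.default_rng(0).normal(size=(50, 3)), model)
        assert (dec.states == 0).all()

    def test_viterbi_beats_random_paths(self, rng):
        gen = two_state_model()
        X, _ = sample_ghmm(gen, 200, seed=4)
        viterbi = hs.decode(X, gen).states
        lp_v = hs.path_log_probability(gen, X, viterbi)
        for _ in range(1000):
            lp_r = hs.path_log_probability(gen, X, rng.integers(0, 2, size=200))
            assert lp_v >= lp_r

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            hs.decode(np.zeros((10, 3)), two_state_model())


class TestUsageAndTransitions:
    def _seq(self, states, rec_id="r", frames=None):
        states = np.asarray(states)
        if frames is None:
            frames = np.arange(len(states))
        return hs.StateSequence(rec_id, np.asarray(frames), states)

    def test_usage_shares_hand_counted(self):
        decoded = {"wt": [self._seq([0, 0, 1, 1]), self._seq([1, 1, 1, 1])]}
        usage, _ = hs.state_usage(decoded, n_states=2)
        assert usage.loc["wt", "state_0"] == pytest.approx(25.0)
        assert usage.loc["wt", "state_1"] == pytest.approx(75.0)

    def test_usage_fold_change_zero_for_identical(self):
        seqs = [self._seq([0, 1, 1, 2])]
        usage, fold = hs.state_usage({"wt": seqs, "drug": seqs}, 3, {"drug": "wt"})
        np.testing.assert_allclose(fold.loc["drug"].dropna(), 0.0, atol=1e-12)

    def test_transitions_hand_count(self):
        # alpha alpha beta beta in one recording
        m, uniform = hs.empirical_transitions([self._seq([0, 0, 1, 1])], n_states=2)
        assert m[0, 0] == pytest.approx(0.5)
        assert m[0, 1] == pytest.approx(0.5)
        assert m[1, 1] == pytest.approx(1.0)
        assert not uniform[0] and not uniform[1]

    def test_recording_boundary_contributes_no_transition(self):
        m1, _ = hs.empirical_transitions([self._seq([0, 0]), self._seq([1, 1])], 2)
        # cross pair (0 -> 1) must not be counted
        assert m1[0, 1] == 0.0

    def test_rows_sum_to_one(self, rng):
        seqs = [self._seq(rng.integers(0, 5, size=100)) for _ in range(3)]
        m, _ = hs.empirical_transitions(seqs, 5)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_gap_in_frame_index_skipped(self):
        # non-adjacent frames contribute nothing: both rows end up empty
        m, uniform = hs.empirical_transitions([self._seq([0, 1], frames=[0, 5])], 2)
        assert uniform.all()

    @pytest.mark.parametrize(
        "p,shown,labeled",
        [(0.0005, False, False), (0.005, True, False), (0.5, True, True)],
    )
    def test_transition_graph_thresholds(self, p, shown, labeled):
        m = np.array([[1.0 - p, p], [0.0, 1.0]])
        edges = hs.export_transition_graph(m)
        row = edges[(edges["from"] == "α") & (edges["to"] == "β")]
        assert (len(row) == 1) == shown
        if shown:
            assert bool(row.iloc[0]["labeled"]) == labeled


@pytest.fixture(scope="module")
def three_state_data():
    model = hs.GHMMModel(
        n_states=3,
        startprob=np.ones(3) / 3,
        transmat=np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]),
        means=np.array([[-4.0] * 2, [0.0] * 2, [4.0] * 2]),
        covars=np.stack([np.eye(2) * 0.5] * 3),
        covariance_type="full",
        loglik_trace=[0.0],
        seed=0,
    )
    # a sprinkling of outlier frames (0.4%) mimics real segmentation
    # glitches: over-capacity fits park extra states on them
    data = []
    for s in range(6):
        X, _ = sample_ghmm(model, 2000, seed=s)
        rng = np.random.default_rng(100 + s)
        idx = rng.choice(2000, 8, replace=False)
        X[idx] += rng.normal(scale=15.0, size=(8, 2))
        data.append(X)
    return data


class TestSelectionAndStability:
    def test_overfitted_model_has_rare_states(self, three_state_data):
        report = hs.selection_report(
            three_state_data, n_states_grid=(2, 3, 6), covariance_types=("full",), seed=0
        )
        row6 = report[report.n_states == 6].iloc[0]
        assert row6["n_rare_states"] >= 1

    def test_likelihood_non_decreasing_in_states(self, three_state_data):
        report = hs.selection_report(
            three_state_data, n_states_grid=(2, 3, 6), covariance_types=("full",), seed=0
        )
        ll = report.sort_values("n_states")["loglik"].to_numpy()
        assert ll[1] >= ll[0] - 1.0  # training likelihood grows with capacity

    def test_report_reproducible(self, three_state_data):
        r1 = hs.selection_report(three_state_data, (2, 3), ("full",), seed=1)
        r2 = hs.selection_report(three_state_data, (2, 3), ("full",), seed=1)
        assert r1["loglik"].tolist() == r2["loglik"].tolist()

    def test_stability_replicates_correlate(self, three_state_data):
        report = hs.stability_protocol(
            three_state_data, ["a", "a", "b", "b", "c", "c"], n_states=3
        )
        assert set(report["protocol"]) == {"full_data", "random_split", "balanced_split"}
        assert (report["mean_correlation"] >= 0.9).all()

    def test_too_small_to_split(self):
        with pytest.raises(ValueError):
            hs.stability_protocol([np.zeros((10, 2))], ["a"], n_states=2)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        model = two_state_model()
        hs.save_model(model, tmp_path / "m.json")
        back = hs.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.transmat, model.transmat)
        np.testing.assert_allclose(back.covars, model.covars)
        assert back.covariance_type == "full"
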