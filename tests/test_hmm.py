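"""Zero-inflated NB HMM: initialisation, EM, Viterbi, baseline anchoring."""

import numpy as np
import pytest

from polarcall.binning import BinnedCounts, make_fixed_bins
from polarcall.errors import AnalysisError
from polarcall.genome import GenomeLayout
from polarcall.hmm import (
    N_STATES,
    SOMY_OF_STATE,
    ZI,
    HMMModel,
    anchor_baseline,
    fit_em,
    init_model,
    modal_state,
    nb_logpmf,
    path_loglik,
    viterbi,
    StatePath,
)


def counts_from_values(values, width=1_000_000, masked=None):
    """Wrap a 1-D count vector as single-chromosome BinnedCounts."""
    values = np.asarray(values, dtype=float)
    layout = GenomeLayout(["c"], {"c": int(len(values) * width)})
    bins = make_fixed_bins(layout, width)
    raw = np.round(np.maximum(values, 0)).astype(np.int64)
    m = np.zeros(len(values), bool) if masked is None else np.asarray(masked, bool)
    return BinnedCounts(bins, raw, values, m, np.full(len(values), np.nan))


def simulate_from_model(mu, var, states, seed=0):
    """Draw NB counts for a given state sequence under the tied-emission model."""
    rng = np.random.default_rng(seed)
    out = np.zeros(len(states))
    for i, st in enumerate(states):
        s = SOMY_OF_STATE[st]
        if s < 0:
            continue
        scale = 0.1 if s == 0 else float(s)
        m, v = scale * mu, max(scale * var, 1.06 * scale * mu)
        r = m * m / (v - m)
        p = r / (r + m)
        out[i] = rng.negative_binomial(r, p)
    return out


class TestInitModel:
    def test_moment_recovery(self):
        rng = np.random.default_rng(0)
        m, v = 300.0, 600.0
        r = m * m / (v - m)
        x = rng.negative_binomial(r, r / (r + m), size=2500)
        model = init_model(counts_from_values(x), expected_baseline=3)
        assert model.mu == pytest.approx(100, rel=0.05)
        assert model.var == pytest.approx(200, rel=0.10)

    def test_baseline_scaling(self):
        rng = np.random.default_rng(0)
        r = 300.0**2 / 300.0
        x = rng.negative_binomial(r, r / (r + 300.0), size=2500)
        m3 = init_model(counts_from_values(x), expected_baseline=3)
        m1 = init_model(counts_from_values(x), expected_baseline=1)
        assert m1.mu == pytest.approx(3 * m3.mu, rel=1e-9)

    def test_all_zero_counts_error(self):
        with pytest.raises(AnalysisError):
            init_model(counts_from_values(np.zeros(200)))


class TestFitEM:
    def test_single_state_monotone_and_fast_convergence(self):
        x = simulate_from_model(100, 180, [4] * 400, seed=1)  # all 3-somy
        model = init_model(counts_from_values(x))
        fitted = fit_em(model, counts_from_values(x))
        trace = np.array(fitted.loglik_trace)
        assert len(trace) < 50
        assert np.all(np.diff(trace) >= -1e-8)

    def test_parameter_recovery_with_gain_block(self):
        states = [4] * 2000 + [5] * 200 + [4] * 300  # one 4-somy block
        x = simulate_from_model(100, 180, states, seed=2)
        counts = counts_from_values(x)
        fitted = fit_em(init_model(counts), counts)
        assert fitted.mu == pytest.approx(100, rel=0.10)

    def test_infinite_tol_returns_after_one_update(self):
        x = simulate_from_model(100, 180, [4] * 200, seed=3)
        counts = counts_from_values(x)
        fitted = fit_em(init_model(counts), counts, tol=np.inf)
        assert len(fitted.loglik_trace) <= 2
        assert np.allclose(fitted.transition.sum(axis=1), 1.0)

    def test_transitions_stay_row_stochastic(self):
        x = simulate_from_model(80, 150, [4] * 150 + [3] * 150, seed=4)
        counts = counts_from_values(x)
        fitted = fit_em(init_model(counts), counts)
        np.testing.assert_allclose(fitted.transition.sum(axis=1), 1.0, atol=1e-9)


def brute_force_viterbi(model, x):
    """Exhaustive argmax over all N_STATES**n paths (oracle, n <= 10)."""
    n = len(x)
    log_b = model.emission_logprob(np.asarray(x, float))
    log_a = np.log(np.maximum(model.transition, 1e-300))
    log_pi = np.log(np.maximum(model.initial, 1e-300))
    n_paths = N_STATES**n
    codes = np.arange(n_paths)
    paths = np.empty((n_paths, n), dtype=np.int8)
    for t in range(n - 1, -1, -1):
        paths[:, t] = codes % N_STATES
        codes //= N_STATES
    score = log_pi[paths[:, 0]] + log_b[0, paths[:, 0]]
    for t in range(1, n):
        score += log_a[paths[:, t - 1], paths[:, t]] + log_b[t, paths[:, t]]
    return paths[np.argmax(score)], float(np.max(score))


class TestViterbi:
    def _model(self, mu=100.0, var=180.0, sticky=0.9):
        transition = np.full((N_STATES, N_STATES), (1 - sticky) / (N_STATES - 1))
        np.fill_diagonal(transition, sticky)
        return HMMModel(mu, var, transition, np.full(N_STATES, 1 / N_STATES))

    def test_matches_exhaustive_enumeration(self):
        model = self._model()
        x = [290, 310, 420, 395, 300, 0, 95, 210]
        counts = counts_from_values(x)
        path = viterbi(model, counts)
        oracle_path, oracle_score = brute_force_viterbi(model, x)
        np.testing.assert_array_equal(path.states, oracle_path)
        assert path_loglik(model, counts, path) == pytest.approx(oracle_score)

    def test_constant_counts_give_constant_baseline_path(self):
        model = self._model(sticky=0.99)
        counts = counts_from_values(np.full(30, 300.0))
        path = viterbi(model, counts)
        assert np.all(path.states == 4)  # 3-somy

    def test_zero_bins_decode_zero_inflation_not_nullisomy(self):
        model = self._model()
        counts = counts_from_values([300, 300, 0, 0, 300])
        path = viterbi(model, counts)
        assert np.all(path.states[2:4] == ZI)

    def test_posteriors_normalise(self):
        model = self._model()
        counts = counts_from_values(
            simulate_from_model(100, 180, [4] * 50 + [5] * 20, seed=5)
        )
        path = viterbi(model, counts)
        np.testing.assert_allclose(path.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_beats_random_paths(self):
        model = self._model()
        counts = counts_from_values(
            simulate_from_model(100, 180, [4] * 40 + [3] * 20, seed=6)
        )
        path = viterbi(model, counts)
        best = path_loglik(model, counts, path)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            rand = StatePath(
                path.bin_index,
                rng.integers(0, N_STATES, len(path)).astype(np.int8),
                path.posterior,
            )
            assert path_loglik(model, counts, rand) <= best + 1e-9


class TestAnchorBaseline:
    def test_underscaled_fit_reanchors_to_3somy(self):
        # euploid data but the model starts with mu underestimated by 25%,
        # a local optimum that decodes the main cluster as 4-somy
        x = simulate_from_model(100, 180, [4] * 600, seed=7)
        counts = counts_from_values(x)
        good = init_model(counts)
        bad = HMMModel(
            good.mu * 0.75, good.var * 0.75, good.transition, good.initial
        )
        fitted = fit_em(bad, counts)
        anchored = anchor_baseline(fitted, counts)
        path = viterbi(anchored, counts)
        assert SOMY_OF_STATE[modal_state(path, counts)] == 3
        assert not anchored.baseline_flag

    def test_already_anchored_fit_is_noop(self):
        x = simulate_from_model(100, 180, [4] * 500, seed=8)
        counts = counts_from_values(x)
        fitted = fit_em(init_model(counts), counts)
        anchored = anchor_baseline(fitted, counts)
        assert anchored.mu == fitted.mu
        assert not anchored.baseline_flag

    def test_pathological_bimodal_sets_flag(self):
        # two blocks, 60% of bins near 80 and 40% near 160: a perfect
        # (2-somy, 4-somy) explanation exists but no 3-somy-modal one does
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.normal(80, 4, 360), rng.normal(160, 5, 240)]
        ).clip(min=1)
        counts = counts_from_values(x)
        fitted = fit_em(init_model(counts), counts)
        anchored = anchor_baseline(fitted, counts)
        assert anchored.baseline_flag

    def test_zero_inflation_modal_errors(self):
        x = np.concatenate([np.zeros(300), np.full(50, 300.0)])
        counts = counts_from_values(x)
        model = HMMModel(
            100.0,
            180.0,
            np.full((N_STATES, N_STATES), 1 / N_STATES),
            np.full(N_STATES, 1 / N_STATES),
            loglik_trace=[-1.0],
        )
        with pytest.raises(AnalysisError, match="zero-inflation"):
            anchor_baseline(model, counts)


def test_nb_logpmf_matches_scipy_on_integers():
    from scipy.stats import nbinom

    mean, var = 120.0, 260.0
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    x = np.arange(0, 400)
    np.testing.assert_allclose(
        nb_logpmf(x, mean, var), nbinom.logpmf(x, r, p), atol=1e-10
    )


def test_model_json_roundtrip(tmp_path):
    x = simulate_from_model(100, 180, [4] * 200, seed=10)
    counts = counts_from_values(x)
    fitted = fit_em(init_model(counts), counts)
    path = tmp_path / "model.json"
    fitted.to_json(str(path))
    import json

    loaded = HMMModel.from_dict(json.loads(path.read_text()))
    assert loaded.mu == pytest.approx(fitted.mu)
    np.testing.assert_allclose(loaded.transition, fitted.transition)
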