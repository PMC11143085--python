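"""Zero-inflated negative-binomial HMM over somy states 0–4.

The model has six hidden states: a zero-inflation state (point mass at zero
count, absorbing dropped-out bins typical of WGA single-cell libraries) and
somy states 0–4. Emissions are tied to a single per-chromatid unit mean mu
and unit variance var: an s-somy bin emits NB counts with mean s*mu and
variance s*var (s = 1..4), which is the mean-proportional-to-copy-number
assumption that lets the euploid baseline be anchored at 3-somy for pooled
polar bodies. The 0-somy state uses a small residual mean eps*mu to stay
identifiable against the zero-inflation point mass.

Fitting is Baum–Welch with exact updates for the initial/transition
probabilities and a generalized-EM (numerically maximised, accepted only on
improvement) update for the tied (mu, var) pair, so the log-likelihood trace
is non-decreasing. Chromosomes are treated as independent sequences; no
transition crosses a chromosome boundary. Decoding is Viterbi, with
forward–backward posteriors. If the modal decoded state is not 3-somy the
baseline is re-anchored by rescaling mu and refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .binning import BinnedCounts
from .errors import AnalysisError, InputError

STATE_NAMES = ("zero-inflation", "0-somy", "1-somy", "2-somy", "3-somy", "4-somy")
N_STATES = 6
ZI = 0  # index of the zero-inflation state
SOMY_OF_STATE = np.array([-1, 0, 1, 2, 3, 4])  # -1 marks zero-inflation

#: residual per-chromatid fraction assigned to the 0-somy NB mean,
#: distinguishing misalignment background from the zero-inflation point mass
EPSILON_NULLISOMY = 0.1

#: minimum variance/mean ratio for a valid over-dispersed NB
MIN_DISPERSION = 1.05


def nb_logpmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """Negative-binomial log pmf in (mean, variance) form.

    Parameterised via size r = mean^2/(var-mean), p = r/(r+mean); evaluated
    through gamma functions so non-integer (GC-corrected) counts are valid.
    """
    var = max(var, MIN_DISPERSION * mean)
    r = mean * mean / (var - mean)
    logp = np.log(r) - np.log(r + mean)
    log1mp = np.log(mean) - np.log(r + mean)
    x = np.asarray(x, dtype=float)
    return gammaln(x + r) - gammaln(r) - gammaln(x + 1.0) + r * logp + x * log1mp


@dataclass
class HMMModel:
    """Tied-emission zero-inflated NB HMM over {ZI, 0-somy..4-somy}."""

    mu: float
    var: float
    transition: np.ndarray
    initial: np.ndarray
    expected_baseline: int = 3
    loglik_trace: list = field(default_factory=list)
    baseline_flag: bool = False

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise InputError("unit mean must be positive")
        self.var = max(self.var, MIN_DISPERSION * self.mu)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (N_STATES, N_STATES):
            raise InputError("transition matrix must be 6x6")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("transition rows must sum to 1")

    def state_mean(self, state: int) -> float:
        s = SOMY_OF_STATE[state]
        if s < 0:
            return 0.0
        return max(s, EPSILON_NULLISOMY) * self.mu if s == 0 else s * self.mu

    def emission_logprob(self, x: np.ndarray) -> np.ndarray:
        """(n, 6) matrix of per-state emission log-probabilities."""
        x = np.asarray(x, dtype=float)
        out = np.full((len(x), N_STATES), -np.inf)
        out[:, ZI] = np.where(x == 0, 0.0, -np.inf)
        for state in range(1, N_STATES):
            s = SOMY_OF_STATE[state]
            scale = EPSILON_NULLISOMY if s == 0 else float(s)
            out[:, state] = nb_logpmf(x, scale * self.mu, scale * self.var)
        return out

    def to_dict(self) -> dict:
        return {
            "states": list(STATE_NAMES),
            "mu": self.mu,
            "var": self.var,
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "expected_baseline": self.expected_baseline,
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "baseline_flag": self.baseline_flag,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        return cls(
            mu=d["mu"],
            var=d["var"],
            transition=np.asarray(d["transition"]),
            initial=np.asarray(d["initial"]),
            expected_baseline=d["expected_baseline"],
            loglik_trace=list(d["loglik_trace"]),
            baseline_flag=d["baseline_flag"],
        )


@dataclass
class StatePath:
    """Viterbi state sequence and forward–backward posteriors.

    ``bin_index`` maps each decoded position back into the full bin set
    (only unmasked bins are decoded).
    """

    bin_index: np.ndarray
    states: np.ndarray
    posterior: np.ndarray

    def __len__(self) -> int:
        return len(self.states)


def _sequences(counts: BinnedCounts) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (bin indices, corrected counts) over unmasked bins."""
    out = []
    for chrom in counts.binset.layout.chromosomes:
        sl = counts.binset.chromosome_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        keep = ~counts.masked[idx] & np.isfinite(counts.corrected[idx])
        idx = idx[keep]
        if idx.size:
            out.append((idx, counts.corrected[idx]))
    if not out:
        raise AnalysisError("no unmasked bins to decode")
    return out


def init_model(counts: BinnedCounts, expected_baseline: int = 3) -> HMMModel:
    """Moment-based initialisation anchored at the expected baseline somy.

    The unit mean is the 10%-trimmed mean of positive corrected counts
    divided by the baseline; the unit variance is the moment variance of the
    same counts divided by the baseline (floored at 1.05*mu).
    """
    from scipy.stats import trim_mean

    if expected_baseline < 1:
        raise InputError("expected baseline must be >= 1")
    seqs = _sequences(counts)
    x = np.concatenate([v for _, v in seqs])
    if len(x) < 100:
        raise AnalysisError(f"need >= 100 unmasked bins to fit, got {len(x)}")
    pos = x[x > 0]
    if pos.size == 0:
        raise AnalysisError("all counts are zero; cannot initialise model")
    mu0 = float(trim_mean(pos, 0.1)) / expected_baseline
    var0 = float(np.var(pos, ddof=1)) / expected_baseline
    var0 = max(var0, MIN_DISPERSION * mu0)
    transition = np.full((N_STATES, N_STATES), 0.01 / (N_STATES - 1))
    np.fill_diagonal(transition, 0.99)
    initial = np.full(N_STATES, 1.0 / N_STATES)
    return HMMModel(mu0, var0, transition, initial, expected_baseline)


def _scaled_forward_backward(
    log_b: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward–backward with per-bin scaling.

    Returns (gamma, xi_sum, loglik). Emission rows are shifted by their max
    before exponentiation so the scaled recursions cannot underflow.
    """
    n = log_b.shape[0]
    c = log_b.max(axis=1)
    if not np.all(np.isfinite(c)):
        raise AnalysisError("non-finite emission likelihood (all states impossible)")
    b = np.exp(log_b - c[:, None])
    alpha = np.empty((n, N_STATES))
    norms = np.empty(n)
    a = initial * b[0]
    norms[0] = a.sum()
    alpha[0] = a / norms[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ transition) * b[t]
        s = a.sum()
        if s <= 0 or not np.isfinite(s):
            raise AnalysisError(f"forward recursion degenerate at bin {t}")
        norms[t] = s
        alpha[t] = a / s
    beta = np.empty((n, N_STATES))
    beta[-1] = 1.0
    xi_sum = np.zeros((N_STATES, N_STATES))
    for t in range(n - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (transition @ bb) / norms[t + 1]
        xi = (alpha[t][:, None] * transition) * bb[None, :]
        xi_sum += xi / xi.sum()
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(norms)) + np.sum(c))
    return gamma, xi_sum, loglik


def _expected_emission_loglik(
    x: np.ndarray, gamma: np.ndarray, mu: float, var: float
) -> float:
    """Expected complete-data emission log-likelihood for the tied NB pair."""
    q = 0.0
    for state in range(1, N_STATES):
        w = gamma[:, state]
        tot = w.sum()
        if tot < 1e-12:
            continue
        s = SOMY_OF_STATE[state]
        scale = EPSILON_NULLISOMY if s == 0 else float(s)
        q += float(w @ nb_logpmf(x, scale * mu, scale * var))
    return q


def _update_emissions(
    x: np.ndarray, gamma: np.ndarray, mu: float, var: float
) -> tuple[float, float]:
    """Generalized-EM update of (mu, var): numeric maximisation of the
    expected emission log-likelihood, accepted only if it improves it."""
    q0 = _expected_emission_loglik(x, gamma, mu, var)
    eta0 = np.log(max(var / mu - MIN_DISPERSION, 1e-6))

    def neg_q(theta: np.ndarray) -> float:
        m = float(np.exp(theta[0]))
        v = m * (MIN_DISPERSION + float(np.exp(theta[1])))
        return -_expected_emission_loglik(x, gamma, m, v)

    res = minimize(
        neg_q,
        np.array([np.log(mu), eta0]),
        method="Nelder-Mead",
        options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-6},
    )
    if np.isfinite(res.fun) and -res.fun > q0:
        mu_new = float(np.exp(res.x[0]))
        var_new = mu_new * (MIN_DISPERSION + float(np.exp(res.x[1])))
        return mu_new, var_new
    return mu, var


def fit_em(
    model: HMMModel,
    counts: BinnedCounts,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> HMMModel:
    """Baum–Welch fit; stops when the relative log-likelihood gain drops
    below ``tol`` (so ``tol=inf`` returns after one iteration) or at
    ``max_iter``. The returned trace is non-decreasing."""
    seqs = _sequences(counts)
    mu, var = model.mu, model.var
    transition = model.transition.copy()
    initial = model.initial.copy()
    trace: list[float] = []
    prev = -np.inf
    for it in range(max_iter):
        trial = replace(model, mu=mu, var=var, transition=transition, initial=initial,
                        loglik_trace=[])
        gammas, xi_total, loglik = [], np.zeros((N_STATES, N_STATES)), 0.0
        init_acc = np.zeros(N_STATES)
        for _, x in seqs:
            log_b = trial.emission_logprob(x)
            gamma, xi_sum, ll = _scaled_forward_backward(log_b, transition, initial)
            gammas.append(gamma)
            xi_total += xi_sum
            init_acc += gamma[0]
            loglik += ll
        if not np.isfinite(loglik):
            raise AnalysisError(f"non-finite likelihood at EM iteration {it}")
        trace.append(loglik)
        if prev > -np.inf:
            gain = loglik - prev
            if gain < tol * abs(prev) or gain < 1e-12:
                break
        prev = loglik
        # M-step: exact for initial/transition, generalized for emissions
        initial = init_acc / init_acc.sum()
        row = xi_total.sum(axis=1, keepdims=True)
        new_transition = np.where(row > 1e-12, xi_total / np.maximum(row, 1e-300), transition)
        new_transition /= new_transition.sum(axis=1, keepdims=True)
        transition = new_transition
        x_all = np.concatenate([x for _, x in seqs])
        g_all = np.concatenate(gammas, axis=0)
        mu, var = _update_emissions(x_all, g_all, mu, var)
    return HMMModel(
        mu,
        var,
        transition,
        initial,
        model.expected_baseline,
        loglik_trace=trace,
        baseline_flag=model.baseline_flag,
    )


def fit_with_restarts(
    counts: BinnedCounts,
    expected_baseline: int = 3,
    tol: float = 1e-4,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
) -> HMMModel:
    """Run EM from ``n_restarts`` jittered transition initialisations and
    keep the best-likelihood fit. Local optima are the origin of the
    baseline shifts seen in real samples; restarts reduce them."""
    base = init_model(counts, expected_baseline)
    rng = np.random.default_rng(seed)
    best: HMMModel | None = None
    for r in range(max(1, n_restarts)):
        trans = base.transition.copy()
        if r > 0:
            jitter = rng.uniform(0.5, 1.5, size=trans.shape)
            trans = trans * jitter
            trans /= trans.sum(axis=1, keepdims=True)
        trial = replace(base, transition=trans, loglik_trace=[])
        fitted = fit_em(trial, counts, tol=tol, max_iter=max_iter)
        if best is None or fitted.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fitted
    assert best is not None
    return best


def viterbi(model: HMMModel, counts: BinnedCounts) -> StatePath:
    """Maximum-a-posteriori state sequence, decoded per chromosome, with
    forward–backward posteriors."""
    seqs = _sequences(counts)
    log_a = np.log(np.maximum(model.transition, 1e-300))
    log_pi = np.log(np.maximum(model.initial, 1e-300))
    all_idx, all_states, all_post = [], [], []
    for idx, x in seqs:
        log_b = model.emission_logprob(x)
        n = len(x)
        delta = log_pi + log_b[0]
        back = np.zeros((n, N_STATES), dtype=np.int8)
        for t in range(1, n):
            cand = delta[:, None] + log_a
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(N_STATES)] + log_b[t]
        states = np.empty(n, dtype=np.int8)
        states[-1] = int(np.argmax(delta))
        for t in range(n - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        gamma, _, _ = _scaled_forward_backward(log_b, model.transition, model.initial)
        all_idx.append(idx)
        all_states.append(states)
        all_post.append(gamma)
    return StatePath(
        np.concatenate(all_idx),
        np.concatenate(all_states),
        np.concatenate(all_post, axis=0),
    )


def path_loglik(model: HMMModel, counts: BinnedCounts, path: StatePath) -> float:
    """Joint log-likelihood of a specific state path (for oracle checks)."""
    seqs = _sequences(counts)
    log_a = np.log(np.maximum(model.transition, 1e-300))
    log_pi = np.log(np.maximum(model.initial, 1e-300))
    total = 0.0
    offset = 0
    for _, x in seqs:
        n = len(x)
        states = path.states[offset : offset + n]
        log_b = model.emission_logprob(x)
        total += log_pi[states[0]] + log_b[0, states[0]]
        total += float(np.sum(log_a[states[:-1], states[1:]]))
        total += float(np.sum(log_b[np.arange(1, n), states[1:]]))
        offset += n
    return total


def modal_state(path: StatePath, counts: BinnedCounts) -> int:
    """Decoded state occupying the greatest total bp (bin-width weighted)."""
    widths = counts.binset.widths[path.bin_index].astype(float)
    bp = np.zeros(N_STATES)
    np.add.at(bp, path.states, widths)
    return int(np.argmax(bp))


def anchor_baseline(
    model: HMMModel,
    counts: BinnedCounts,
    max_retries: int = 3,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> HMMModel:
    """Re-anchor the fit so the modal decoded state is the expected 3-somy.

    If the modal state (by total bp) is some other somy m, the unit mean is
    rescaled by m/3 and the model refit, up to ``max_retries`` times. If no
    3-somy-modal fit is reached the best-likelihood fit is returned with
    ``baseline_flag`` set. A zero-inflation-modal decode means the sample is
    unanalysable.
    """
    target = model.expected_baseline
    current = model
    best = model
    for attempt in range(max_retries + 1):
        path = viterbi(current, counts)
        state = modal_state(path, counts)
        if state == ZI:
            raise AnalysisError("modal state is zero-inflation; sample unanalysable")
        if current.loglik_trace and (
            not best.loglik_trace
            or current.loglik_trace[-1] > best.loglik_trace[-1]
        ):
            best = current
        modal_somy = int(SOMY_OF_STATE[state])
        if modal_somy == target:
            return replace(current, baseline_flag=False)
        if attempt == max_retries:
            break
        scale = max(modal_somy, 1) / target
        rescaled = replace(
            current,
            mu=current.mu * scale,
            var=current.var * scale,
            loglik_trace=[],
        )
        current = fit_em(rescaled, counts, tol=tol, max_iter=max_iter)
    return replace(best, baseline_flag=True)
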