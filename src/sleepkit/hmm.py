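"""Four-state Gaussian-emission HMM sleep stager.

The stager decodes 30-s epoch feature vectors (relative band powers) into a
Wake/REM/Light/Deep hypnogram. It is unsupervised: parameters are initialized
from sleep-physiology priors — the night starts awake, so the initial
distribution puts all mass on Wake; the transition matrix encodes typical
stage dynamics (e.g. no direct Wake→Deep jump); each stage's emission mean is
0.7 in its own band and 0.1 elsewhere — then refined per recording by
Baum-Welch EM, and the hypnogram is the Viterbi path. Stage identity is
anchored only by the diagonal structure of the initial emission means: EM
keeps each cluster attached to the stage whose band it started on.

All recursions run in log space. Emissions are diagonal Gaussians (independent
bands) with a floor on the per-band standard deviation to prevent cluster
collapse on degenerate features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .features import BandPowerTransformer, BandSet, segment_epochs
from .stages import Hypnogram

__all__ = [
    "HMMParameters",
    "init_params",
    "GaussianHMMStager",
    "log_likelihood",
    "em_fit",
    "viterbi_decode",
    "score_sleep",
]

_N_STATES = 4
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HMMParameters:
    """HMM parameter bundle: π, Q and the Gaussian emission (μ, σ).

    ``emission_stds`` holds per-stage, per-band standard deviations
    (independent bands; no cross-band covariance).
    """

    initial_probs: np.ndarray  # (4,)
    transition: np.ndarray  # (4, 4) row-stochastic
    emission_means: np.ndarray  # (4, 4) stage x band
    emission_stds: np.ndarray  # (4, 4) stage x band, all > 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial_probs, dtype=float).ravel()
        q = np.asarray(self.transition, dtype=float)
        mu = np.asarray(self.emission_means, dtype=float)
        sd = np.asarray(self.emission_stds, dtype=float)
        if pi.shape != (_N_STATES,) or q.shape != (_N_STATES, _N_STATES):
            raise ValueError("initial_probs must be length 4, transition 4x4")
        if mu.shape != (_N_STATES, _N_STATES) or sd.shape != mu.shape:
            raise ValueError("emission means/stds must be 4x4 (stage x band)")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial_probs must be non-negative and sum to 1")
        if np.any(q < 0) or np.max(np.abs(q.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must be non-negative and sum to 1")
        if np.any(sd <= 0):
            raise ValueError("all emission stds must be positive")
        for name, arr in (("initial_probs", pi), ("transition", q),
                          ("emission_means", mu), ("emission_stds", sd)):
            object.__setattr__(self, name, arr)

    def to_json(self) -> str:
        """Bit-exact round-trippable JSON serialization (full float repr)."""
        return json.dumps(
            {
                "initial_probs": self.initial_probs.tolist(),
                "transition": self.transition.tolist(),
                "emission_means": self.emission_means.tolist(),
                "emission_stds": self.emission_stds.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "HMMParameters":
        d = json.loads(text)
        return cls(
            np.array(d["initial_probs"]),
            np.array(d["transition"]),
            np.array(d["emission_means"]),
            np.array(d["emission_stds"]),
        )


def init_params() -> HMMParameters:
    """Physiology-prior initialization π0, Q0, μ0, σ0.

    The night starts awake (π0 concentrates on Wake); Q0 forbids direct
    Wake→Deep and REM→Deep transitions; μ0 puts 0.7 in each stage's own band
    and 0.1 elsewhere; σ0 is unit per-band standard deviation.
    """
    pi0 = np.array([1.0, 0.0, 0.0, 0.0])
    q0 = np.array(
        [
            [0.75, 0.01, 0.24, 0.00],
            [0.05, 0.88, 0.07, 0.00],
            [0.18, 0.11, 0.55, 0.16],
            [0.02, 0.00, 0.14, 0.84],
        ]
    )
    mu0 = np.full((4, 4), 0.1) + np.diag(np.full(4, 0.6))
    sigma0 = np.ones((4, 4))
    return HMMParameters(pi0, q0, mu0, sigma0)


def _check_features(features) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.size == 0:
        raise ValueError("empty feature matrix")
    if x.shape[1] != _N_STATES:
        raise ValueError(
            f"feature matrix must have 4 band columns, got {x.shape[1]}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    return x


def _log_emission(x: np.ndarray, params: HMMParameters) -> np.ndarray:
    """Per-epoch, per-state diagonal-Gaussian log density, shape (T, 4)."""
    mu = params.emission_means[None, :, :]  # (1, state, band)
    sd = params.emission_stds[None, :, :]
    z = (x[:, None, :] - mu) / sd
    return np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * _LOG2PI, axis=2)


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


# -- numba kernels for the log-space recursions -----------------------------

@njit(cache=False)
def _forward_nb(log_b, log_pi, log_q):  # pragma: no cover - exercised via wrappers
    T, S = log_b.shape
    alpha = np.empty((T, S))
    for j in range(S):
        alpha[0, j] = log_pi[j] + log_b[0, j]
    for t in range(1, T):
        for j in range(S):
            m = -np.inf
            for i in range(S):
                v = alpha[t - 1, i] + log_q[i, j]
                if v > m:
                    m = v
            if m == -np.inf:
                alpha[t, j] = -np.inf
            else:
                s = 0.0
                for i in range(S):
                    s += np.exp(alpha[t - 1, i] + log_q[i, j] - m)
                alpha[t, j] = m + np.log(s) + log_b[t, j]
    m = -np.inf
    for j in range(S):
        if alpha[T - 1, j] > m:
            m = alpha[T - 1, j]
    ll = -np.inf
    if m > -np.inf:
        s = 0.0
        for j in range(S):
            s += np.exp(alpha[T - 1, j] - m)
        ll = m + np.log(s)
    return alpha, ll


@njit(cache=False)
def _backward_nb(log_b, log_q):  # pragma: no cover
    T, S = log_b.shape
    beta = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        for i in range(S):
            m = -np.inf
            for j in range(S):
                v = log_q[i, j] + log_b[t + 1, j] + beta[t + 1, j]
                if v > m:
                    m = v
            if m == -np.inf:
                beta[t, i] = -np.inf
            else:
                s = 0.0
                for j in range(S):
                    s += np.exp(log_q[i, j] + log_b[t + 1, j] + beta[t + 1, j] - m)
                beta[t, i] = m + np.log(s)
    return beta


@njit(cache=False)
def _xi_sum_nb(alpha, beta, log_b, log_q, ll):  # pragma: no cover
    T, S = log_b.shape
    out = np.zeros((S, S))
    for t in range(T - 1):
        for i in range(S):
            for j in range(S):
                out[i, j] += np.exp(
                    alpha[t, i] + log_q[i, j] + log_b[t + 1, j] + beta[t + 1, j] - ll
                )
    return out


@njit(cache=False)
def _viterbi_nb(log_b, log_pi, log_q):  # pragma: no cover
    T, S = log_b.shape
    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=np.int64)
    for j in range(S):
        delta[0, j] = log_pi[j] + log_b[0, j]
    for t in range(1, T):
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[t - 1, i] + log_q[i, j]
                if v > best:  # strict: ties keep the lower state index
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(S):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _forward(log_b: np.ndarray, params: HMMParameters) -> tuple[np.ndarray, float]:
    alpha, ll = _forward_nb(
        log_b, _safe_log(params.initial_probs), _safe_log(params.transition)
    )
    return alpha, float(ll)


def _backward(log_b: np.ndarray, params: HMMParameters) -> np.ndarray:
    return _backward_nb(log_b, _safe_log(params.transition))


def log_likelihood(features, params: HMMParameters) -> float:
    """Log marginal probability of the feature sequence under the HMM."""
    x = _check_features(features)
    _, ll = _forward(_log_emission(x, params), params)
    return ll


class GaussianHMMStager(BaseEstimator):
    """Unsupervised four-state HMM sleep stager (scikit-learn estimator).

    ``fit(X)`` runs Baum-Welch EM on one recording's epoch features (rows =
    epochs, columns = Wake/REM/Light/Deep relative band powers), starting from
    :func:`init_params` unless ``init`` overrides it. ``predict(X)`` returns
    the Viterbi stage path; ``score(X)`` the log-likelihood.

    Parameters
    ----------
    max_iter : int, default 100
        Maximum EM iterations (must be >= 1).
    tol : float, default 1e-6
        Stop when the absolute log-likelihood improvement falls below this.
    update_startprob : bool, default True
        Whether EM re-estimates π or holds it at its initial value.
    variance_floor : float, default 1e-4
        Lower bound applied to every emission standard deviation.
    init : HMMParameters, optional
        Starting parameters; defaults to :func:`init_params`.

    Attributes
    ----------
    startprob_, transmat_, means_, stds_ : fitted parameter arrays
    loglik_history_ : log-likelihood after each EM iteration (the first entry
        is the likelihood under the initial parameters)
    n_iter_ : number of EM iterations performed
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-6,
        update_startprob: bool = True,
        variance_floor: float = 1e-4,
        init: HMMParameters | None = None,
    ) -> None:
        self.max_iter = max_iter
        self.tol = tol
        self.update_startprob = update_startprob
        self.variance_floor = variance_floor
        self.init = init

    # -- EM ----------------------------------------------------------------
    def fit(self, X, y=None):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        x = _check_features(X)
        if x.shape[0] < 2:
            raise ValueError("EM fitting needs at least 2 epochs")
        params = self.init if self.init is not None else init_params()

        history: list[float] = []
        prev_ll = -np.inf
        for iteration in range(self.max_iter):
            params, ll = self._em_step(x, params)
            if history and ll < history[-1] - 1e-8 * (abs(history[-1]) + 1.0):
                raise RuntimeError(
                    "EM log-likelihood decreased — internal error "
                    f"({history[-1]:.6f} -> {ll:.6f})"
                )
            history.append(ll)
            if abs(ll - prev_ll) < self.tol:
                break
            prev_ll = ll

        self.startprob_ = params.initial_probs
        self.transmat_ = params.transition
        self.means_ = params.emission_means
        self.stds_ = params.emission_stds
        self.loglik_history_ = np.asarray(history)
        self.n_iter_ = len(history)
        return self

    def _em_step(self, x: np.ndarray, params: HMMParameters) -> tuple[HMMParameters, float]:
        """One Baum-Welch update; returns (new params, log-likelihood of the
        *input* params on x)."""
        T = x.shape[0]
        log_b = _log_emission(x, params)
        alpha, ll = _forward(log_b, params)
        beta = _backward(log_b, params)

        log_gamma = alpha + beta - ll
        gamma = np.exp(log_gamma)  # (T, 4)

        # xi[t,i,j] summed over t = expected transition counts
        xi_sum = _xi_sum_nb(alpha, beta, log_b, _safe_log(params.transition), ll)

        # M-step with zero-occupancy guards: states EM never visits keep
        # their previous parameters rather than dividing 0/0
        occ_trans = gamma[:-1].sum(axis=0)
        new_q = params.transition.copy()
        visited = occ_trans > 1e-12
        new_q[visited] = xi_sum[visited] / occ_trans[visited, None]
        new_q = np.clip(new_q, 0.0, None)
        new_q /= new_q.sum(axis=1, keepdims=True)

        occ = gamma.sum(axis=0)
        new_mu = params.emission_means.copy()
        new_sd = params.emission_stds.copy()
        visited = occ > 1e-12
        mu_num = gamma.T @ x  # (4 states, 4 bands)
        new_mu[visited] = mu_num[visited] / occ[visited, None]
        diff2 = (x[:, None, :] - new_mu[None, :, :]) ** 2
        var_num = np.einsum("ts,tsb->sb", gamma, diff2)
        new_sd[visited] = np.sqrt(var_num[visited] / occ[visited, None])
        new_sd = np.maximum(new_sd, self.variance_floor)

        new_pi = gamma[0] / gamma[0].sum() if self.update_startprob else params.initial_probs
        # renormalize against accumulated float error before re-validation
        new_pi = np.clip(new_pi, 0.0, None)
        new_pi = new_pi / new_pi.sum()
        return HMMParameters(new_pi, new_q, new_mu, new_sd), ll

    # -- decoding ----------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Viterbi stage indices for each epoch (ties -> lower stage index)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "transmat_")
        params = HMMParameters(self.startprob_, self.transmat_, self.means_, self.stds_)
        return _viterbi_path(_check_features(X), params)

    def score(self, X, y=None) -> float:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "transmat_")
        params = HMMParameters(self.startprob_, self.transmat_, self.means_, self.stds_)
        return log_likelihood(X, params)

    def params_(self) -> HMMParameters:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "transmat_")
        return HMMParameters(self.startprob_, self.transmat_, self.means_, self.stds_)


def _viterbi_path(x: np.ndarray, params: HMMParameters) -> np.ndarray:
    log_b = _log_emission(x, params)
    return _viterbi_nb(
        log_b, _safe_log(params.initial_probs), _safe_log(params.transition)
    )


# ---------------------------------------------------------------------------
# thin functional wrappers

def em_fit(features, params: HMMParameters, max_iter: int = 100, tol: float = 1e-6,
           update_startprob: bool = True) -> HMMParameters:
    """Baum-Welch refinement of ``params`` on one recording's features."""
    stager = GaussianHMMStager(
        max_iter=max_iter, tol=tol, update_startprob=update_startprob, init=params
    ).fit(features)
    return stager.params_()


def viterbi_decode(features, params: HMMParameters,
                   epoch_seconds: float = 30.0) -> Hypnogram:
    """Most probable joint stage path as a Hypnogram."""
    x = _check_features(features)
    return Hypnogram(_viterbi_path(x, params), epoch_seconds=epoch_seconds)


def score_sleep(
    eeg,
    sampling_rate_hz: float,
    epoch_seconds: float = 30.0,
    band_set: BandSet | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    update_startprob: bool = True,
) -> Hypnogram:
    """Full staging pipeline: epoching → band features → EM → Viterbi.

    Deterministic given the input signal: initialization is the fixed
    physiology prior and EM/Viterbi involve no randomness.
    """
    epochs = segment_epochs(eeg, sampling_rate_hz, epoch_seconds)
    feats = BandPowerTransformer(
        sampling_rate_hz=sampling_rate_hz, band_set=band_set
    ).fit(epochs).transform(epochs)
    if epochs.shape[0] == 1:
        # too short for EM: decode the single epoch under the prior parameters
        return viterbi_decode(feats, init_params(), epoch_seconds=epoch_seconds)
    stager = GaussianHMMStager(
        max_iter=max_iter, tol=tol, update_startprob=update_startprob
    ).fit(feats)
    return Hypnogram(stager.predict(feats), epoch_seconds=epoch_seconds)
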