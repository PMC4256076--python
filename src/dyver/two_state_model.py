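"""Temporal two-state (H/L) model of a variant's effect over time.

Each retained time point is assigned a hidden state: high-effect (H) or
low-effect (L).  State sequences follow a first-order Markov chain with a
fixed switching probability lambda -- the *penalty*; lambda = 0.5 makes all
sequences equiprobable (no penalty) while smaller values favour sequences
with fewer transitions.  The observed effects at a time point are i.i.d.
Gaussian with state-specific mean and standard deviation, shared across all
time points in the same state.  Fitting maximizes the joint likelihood
P(S) * P(D | S, theta) over sequences and parameters via Baum-Welch
followed by segmental Viterbi refinement; H is the state whose fitted mean
has the larger absolute value (means are unrestricted in sign, so effect
inversions are representable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _engine
from ._engine import SIGMA_FLOOR, VAR_FLOOR
from .effects import EffectObservations, suff_stats

__all__ = [
    "TwoStateModel",
    "FitResult",
    "sequence_log_prob",
    "emissions_log_prob",
    "fit_two_state",
    "label_states",
    "enumerate_ml_oracle",
]

_STATE_CODE = {"L": 0, "H": 1, 0: 0, 1: 1}


def _as_state_array(states) -> np.ndarray:
    if isinstance(states, str):
        states = list(states)
    try:
        return np.array([_STATE_CODE[s] for s in states], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown state symbol {exc.args[0]!r}") from None


@dataclass
class TwoStateModel:
    """A state sequence plus Gaussian emission parameters per state."""

    states: str  # time-ordered "L"/"H" characters
    mu_h: float
    sigma_h: float
    mu_l: float
    sigma_l: float
    lam: float = 0.5
    pi: float = 0.5

    def __post_init__(self) -> None:
        _engine._check_lambda(self.lam)
        self.sigma_h = max(float(self.sigma_h), SIGMA_FLOOR)
        self.sigma_l = max(float(self.sigma_l), SIGMA_FLOOR)

    @property
    def pattern(self) -> str:
        return self.states

    @property
    def n_times(self) -> int:
        return len(self.states)


@dataclass
class FitResult:
    model: TwoStateModel
    log_likelihood: float  # maximized joint log P(S) + log P(D | S, theta)
    n_iterations: int
    converged: bool
    marginal_log_likelihood: float = np.nan
    ll_history: np.ndarray | None = None


def sequence_log_prob(states, lam: float, pi: float = 0.5) -> float:
    """log probability of a state sequence under the Markov-chain prior."""
    _engine._check_lambda(lam)
    path = _as_state_array(states)
    if path.size == 0:
        raise ValueError("empty state sequence")
    return float(_engine.sequence_log_prior(path[None, :], lam, pi)[0])


def _d_sample(effects) -> list:
    if isinstance(effects, EffectObservations):
        return effects.D
    return [np.asarray(x, dtype=float) for x in effects]


def emissions_log_prob(effects, states, params) -> float:
    """log P(observed effects | state sequence, emission parameters).

    ``params`` may be a TwoStateModel or a ``(mu_h, sigma_h, mu_l,
    sigma_l)`` tuple.  Parameters are shared by all time points in the same
    state.  Empty time points contribute zero.
    """
    sample = _d_sample(effects)
    path = _as_state_array(states)
    if len(sample) != path.size:
        raise ValueError("one state per retained time point is required")
    if isinstance(params, TwoStateModel):
        mu_h, sg_h, mu_l, sg_l = (
            params.mu_h,
            params.sigma_h,
            params.mu_l,
            params.sigma_l,
        )
    else:
        mu_h, sg_h, mu_l, sg_l = params
    n, s1, s2 = suff_stats(sample)
    mu = np.where(path == 1, mu_h, mu_l)
    var = np.maximum(np.where(path == 1, sg_h, sg_l) ** 2, VAR_FLOOR)
    quad = s2 - 2.0 * mu * s1 + n * mu**2
    return float(np.sum(-0.5 * (n * (_engine.LOG_2PI + np.log(var)) + quad / var)))


def _result_from_fit(fit, idx, lam, pi) -> FitResult:
    path = fit["path"][idx]
    mu = fit["mu"][idx]
    sd = np.sqrt(fit["var"][idx])
    # provisional labels: state 1 = H
    states = "".join("H" if s else "L" for s in path)
    model = TwoStateModel(states, mu[1], sd[1], mu[0], sd[0], lam, pi)
    res = FitResult(
        model=model,
        log_likelihood=float(fit["joint_ll"][idx]),
        n_iterations=int(fit["n_iter"][idx]),
        converged=bool(fit["converged"][idx]),
        marginal_log_likelihood=float(fit["marginal_ll"][idx]),
    )
    return label_states(res)


def fit_two_state(
    effects,
    lam: float = 0.5,
    pi: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 500,
    restarts: int = 0,
    seed=None,
    track: bool = False,
) -> FitResult:
    """Maximum-likelihood two-state model of an observed-effect sample.

    The default single start uses the pooled standard deviation in both
    states with means offset symmetrically around the pooled mean (a
    low-effect-like configuration with distinct state averages).
    ``restarts`` adds that many random initializations and returns the best
    fit; this is a robustness check, not the default behaviour.
    """
    sample = _d_sample(effects)
    if len(sample) < 1:
        raise ValueError("at least one retained time point is required")
    n, s1, s2 = suff_stats(sample)
    reps = 1 + int(restarts)
    N = np.tile(n, (reps, 1))
    S1 = np.tile(s1, (reps, 1))
    S2 = np.tile(s2, (reps, 1))
    mu0, var0 = _engine.default_init(n[None, :], s1[None, :], s2[None, :])
    mu_init = np.tile(mu0, (reps, 1))
    var_init = np.tile(var0, (reps, 1))
    if restarts:
        rng = np.random.default_rng(seed)
        m = mu0.mean()
        sd = np.sqrt(var0[0, 0])
        mu_init[1:] = m + sd * rng.uniform(-2.0, 2.0, size=(restarts, 2))
        var_init[1:] = var0[0, 0] * rng.uniform(0.5, 1.5, size=(restarts, 2)) ** 2
    fit = _engine.fit_batch(
        N,
        S1,
        S2,
        lam=lam,
        pi=pi,
        tol=tol,
        max_iter=max_iter,
        init=(mu_init, var_init),
        track=track,
    )
    best = int(np.argmax(fit["joint_ll"]))
    res = _result_from_fit(fit, best, lam, pi)
    if track:
        res = replace(res, ll_history=fit["ll_history"][:, best])
    return res


def label_states(fit: FitResult) -> FitResult:
    """Assign H to the state with the larger |mean| (idempotent).

    Exact |mean| ties are broken by the larger sigma, then by keeping the
    current H label, so relabeling is deterministic and stable.
    """
    m = fit.model
    flip = False
    if abs(m.mu_l) > abs(m.mu_h):
        flip = True
    elif abs(m.mu_l) == abs(m.mu_h) and m.sigma_l > m.sigma_h:
        flip = True
    if not flip:
        return fit
    swapped = TwoStateModel(
        states="".join("H" if c == "L" else "L" for c in m.states),
        mu_h=m.mu_l,
        sigma_h=m.sigma_l,
        mu_l=m.mu_h,
        sigma_l=m.sigma_h,
        lam=m.lam,
        pi=m.pi,
    )
    return replace(fit, model=swapped)


def enumerate_ml_oracle(
    effects, lam: float = 0.5, pi: float = 0.5, max_times: int = 12
) -> FitResult:
    """Exact global maximum-likelihood fit by exhaustive sequence search.

    Evaluates all 2^T state sequences with per-sequence closed-form Gaussian
    MLEs.  Intended as an independent check of the EM fit at small T; refuses
    T > ``max_times``.
    """
    _engine._check_lambda(lam)
    sample = _d_sample(effects)
    T = len(sample)
    if T > max_times:
        raise ValueError(f"exhaustive search refused for T={T} > {max_times}")
    if T < 1:
        raise ValueError("at least one retained time point is required")
    n, s1, s2 = suff_stats(sample)
    codes = np.arange(2**T)[:, None] >> np.arange(T)[None, :]  # (P, T)
    paths = (codes & 1).astype(np.int8)

    def state_ll(mask):
        N = mask @ n
        S1 = mask @ s1
        S2 = mask @ s2
        occ = N > 0
        Nn = np.where(occ, N, 1.0)
        mu = S1 / Nn
        var = np.maximum(S2 / Nn - mu**2, VAR_FLOOR)
        quad = S2 - 2.0 * mu * S1 + N * mu**2
        ll = -0.5 * (N * (_engine.LOG_2PI + np.log(var)) + quad / var)
        return np.where(occ, ll, 0.0), mu, var

    ll1, mu1, var1 = state_ll(paths.astype(float))
    ll0, mu0, var0 = state_ll(1.0 - paths)
    total = _engine.sequence_log_prior(paths, lam, pi) + ll0 + ll1
    best = int(np.argmax(total))
    path = paths[best]
    states = "".join("H" if s else "L" for s in path)
    model = TwoStateModel(
        states,
        mu1[best],
        np.sqrt(var1[best]),
        mu0[best],
        np.sqrt(var0[best]),
        lam,
        pi,
    )
    return label_states(
        FitResult(
            model=model,
            log_likelihood=float(total[best]),
            n_iterations=1,
            converged=True,
        )
    )
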