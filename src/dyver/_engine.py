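"""Vectorized two-state Gaussian HMM core.

Everything here operates on per-time-point sufficient statistics
``(n_t, S1_t, S2_t)`` of a difference sample: the model assumes all
observations at time t are i.i.d. Gaussian given the hidden state s_t, so
the complete emission likelihood factors through these statistics and a
genome scan never has to materialize the quadratic number of strain pairs.

Fitting runs Baum-Welch (EM with the transition probability held fixed at
the penalty value) followed by a segmental Viterbi-refit polish, so the
reported log-likelihood is the jointly maximized ``log P(S) + log P(D|S,
theta)`` -- the quantity an exhaustive search over state sequences with
per-sequence closed-form Gaussian MLEs would return.
"""

from __future__ import annotations

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA_FLOOR = 1e-6
VAR_FLOOR = SIGMA_FLOOR**2


def emission_logprob(n, s1, s2, mu, var):
    """Log-probability of all observations at each time under each state.

    n, s1, s2: (M, T); mu, var: (M, 2)  ->  (M, T, 2)
    """
    mu_ = mu[:, None, :]
    var_ = var[:, None, :]
    quad = s2[..., None] - 2.0 * mu_ * s1[..., None] + n[..., None] * mu_**2
    return -0.5 * (n[..., None] * (LOG_2PI + np.log(var_)) + quad / var_)


def _check_lambda(lam: float) -> None:
    if not (0.0 < lam <= 0.5):
        raise ValueError(
            f"transition probability (penalty) must be in (0, 0.5], got {lam}"
        )


def forward_backward(logf, lam, pi=0.5):
    """Scaled forward-backward pass.

    Returns (marginal log-likelihood (M,), state posteriors gamma (M, T, 2)).
    """
    M, T, _ = logf.shape
    stay, switch = 1.0 - lam, lam
    mx = logf.max(axis=2)
    w = np.exp(logf - mx[..., None])  # (M, T, 2), max-normalized

    alpha = np.empty_like(w)
    ll = mx[:, 0].copy()
    a = pi * w[:, 0, :]
    c = a.sum(axis=1)
    a /= c[:, None]
    ll += np.log(c)
    alpha[:, 0] = a
    for t in range(1, T):
        pred = a * stay + a[:, ::-1] * switch
        a = pred * w[:, t, :]
        c = a.sum(axis=1)
        a = a / c[:, None]
        ll += np.log(c) + mx[:, t]
        alpha[:, t] = a

    beta = np.empty_like(w)
    b = np.full((M, 2), 0.5)
    beta[:, T - 1] = b
    for t in range(T - 2, -1, -1):
        u = w[:, t + 1, :] * b
        b = u * stay + u[:, ::-1] * switch
        b = b / b.sum(axis=1)[:, None]
        beta[:, t] = b

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return ll, gamma


def viterbi(logf, lam, pi=0.5):
    """Most probable state path; ties broken toward staying in state 0/no switch."""
    M, T, _ = logf.shape
    lstay, lswitch = np.log(1.0 - lam), np.log(lam)
    delta = np.log(pi) + logf[:, 0, :]
    back = np.empty((M, T, 2), dtype=np.int8)
    for t in range(1, T):
        stay = delta + lstay
        swi = delta[:, ::-1] + lswitch
        use_switch = swi > stay
        delta = np.where(use_switch, swi, stay) + logf[:, t, :]
        back[:, t, 0] = np.where(use_switch[:, 0], 1, 0)
        back[:, t, 1] = np.where(use_switch[:, 1], 0, 1)
    path = np.empty((M, T), dtype=np.int8)
    path[:, T - 1] = np.argmax(delta, axis=1)
    rows = np.arange(M)
    for t in range(T - 1, 0, -1):
        path[:, t - 1] = back[rows, t, path[:, t]]
    return path


def sequence_log_prior(path, lam, pi=0.5):
    """log P(S) of paths (M, T) under the fixed-transition Markov chain."""
    switches = np.abs(np.diff(path.astype(np.int64), axis=1)).sum(axis=1)
    T = path.shape[1]
    return np.log(pi) + switches * np.log(lam) + (T - 1 - switches) * np.log(1.0 - lam)


def _hard_mle(n, s1, s2, path, mu_old, var_old):
    """Closed-form Gaussian MLE per state given a hard state path."""
    ind = path.astype(float)  # membership of state 1
    mu = mu_old.copy()
    var = var_old.copy()
    for s, m in ((0, 1.0 - ind), (1, ind)):
        ns = (n * m).sum(axis=1)
        s1s = (s1 * m).sum(axis=1)
        s2s = (s2 * m).sum(axis=1)
        occ = ns > 0
        mu_s = np.where(occ, s1s / np.where(occ, ns, 1.0), mu[:, s])
        var_s = np.where(
            occ, s2s / np.where(occ, ns, 1.0) - mu_s**2, var[:, s]
        )
        mu[:, s] = mu_s
        var[:, s] = np.maximum(var_s, VAR_FLOOR)
    return mu, var


def default_init(n, s1, s2):
    """Deterministic start: pooled sigma in both states, means at the pooled
    mean offset by +/- half the pooled sigma (state 0 low, state 1 high)."""
    N = np.maximum(n.sum(axis=1), 1.0)
    m = s1.sum(axis=1) / N
    var_p = np.maximum(s2.sum(axis=1) / N - m**2, VAR_FLOOR)
    sd = np.sqrt(var_p)
    mu = np.stack([m - 0.5 * sd, m + 0.5 * sd], axis=1)
    var = np.stack([var_p, var_p], axis=1)
    return mu, var


def fit_batch(
    n,
    s1,
    s2,
    lam=0.5,
    pi=0.5,
    tol=1e-8,
    max_iter=500,
    init=None,
    polish=True,
    track=False,
):
    """Fit the two-state model to a batch of problems.

    n, s1, s2 : (M, T) per-time-point sufficient statistics.
    Returns a dict with per-problem arrays: ``joint_ll`` (maximized
    ``log P(S)P(D|S)``), ``marginal_ll`` (EM objective at convergence),
    ``mu``/``var`` (M, 2), ``path`` (M, T, states in {0, 1}), ``n_iter``,
    ``converged``, and optionally ``ll_history``.
    """
    _check_lambda(lam)
    n = np.atleast_2d(np.asarray(n, dtype=float))
    s1 = np.atleast_2d(np.asarray(s1, dtype=float))
    s2 = np.atleast_2d(np.asarray(s2, dtype=float))
    M, T = n.shape

    if init is None:
        mu, var = default_init(n, s1, s2)
    else:
        mu = np.array(init[0], dtype=float).reshape(M, 2)
        var = np.maximum(np.array(init[1], dtype=float).reshape(M, 2), VAR_FLOOR)

    ll_final = np.full(M, -np.inf)
    n_iter = np.zeros(M, dtype=int)
    converged = np.zeros(M, dtype=bool)
    history = [] if track else None

    active = np.arange(M)
    ll_prev = np.full(M, -np.inf)
    for it in range(max_iter):
        na, s1a, s2a = n[active], s1[active], s2[active]
        logf = emission_logprob(na, s1a, s2a, mu[active], var[active])
        ll, gamma = forward_backward(logf, lam, pi)
        if track:
            full_ll = ll_final.copy()
            full_ll[active] = ll
            history.append(full_ll)
        done = ll - ll_prev[active] < tol if it > 0 else np.zeros(len(active), bool)
        ll_final[active] = ll
        n_iter[active] = it + 1
        if done.any():
            converged[active[done]] = True
        keep = ~done
        if not keep.any():
            break
        # exact M-step (transitions fixed at the penalty value)
        ka = active[keep]
        g = gamma[keep]
        w_state = np.einsum("mts,mt->ms", g, n[ka])
        w_state = np.maximum(w_state, 1e-300)
        mu_new = np.einsum("mts,mt->ms", g, s1[ka]) / w_state
        quad = (
            s2[ka][..., None]
            - 2.0 * mu_new[:, None, :] * s1[ka][..., None]
            + n[ka][..., None] * mu_new[:, None, :] ** 2
        )
        var_new = np.maximum(np.einsum("mts,mts->ms", g, quad) / w_state, VAR_FLOOR)
        mu[ka] = mu_new
        var[ka] = var_new
        ll_prev[ka] = ll[keep]
        active = ka

    logf = emission_logprob(n, s1, s2, mu, var)
    ll_marg, _ = forward_backward(logf, lam, pi)
    path = viterbi(logf, lam, pi)

    if polish:
        # segmental refinement: alternate closed-form per-state MLE and
        # Viterbi decoding; monotone in the joint objective, finite
        # convergence to a fixed point.
        for _ in range(100):
            mu, var = _hard_mle(n, s1, s2, path, mu, var)
            logf = emission_logprob(n, s1, s2, mu, var)
            new_path = viterbi(logf, lam, pi)
            if np.array_equal(new_path, path):
                break
            path = new_path

    rows = np.arange(M)[:, None]
    emit = logf[rows, np.arange(T)[None, :], path].sum(axis=1)
    joint_ll = sequence_log_prior(path, lam, pi) + emit

    out = {
        "joint_ll": joint_ll,
        "marginal_ll": ll_marg,
        "mu": mu,
        "var": var,
        "path": path,
        "n_iter": n_iter,
        "converged": converged,
    }
    if track:
        out["ll_history"] = np.array(history)
    return out


def _pooled_gaussian_ll(N, S1, S2):
    """Maximized Gaussian log-likelihood of an aggregated sample (MLE sigma,
    floored); zero for empty samples.  All inputs elementwise arrays."""
    occ = N > 0
    Nn = np.where(occ, N, 1.0)
    mu = S1 / Nn
    var = np.maximum(S2 / Nn - mu**2, VAR_FLOOR)
    quad = S2 - 2.0 * mu * S1 + N * mu**2
    ll = -0.5 * (N * (LOG_2PI + np.log(var)) + quad / var)
    return np.where(occ, ll, 0.0)


def score_given_path(path, d_stats, b_stats):
    """Likelihood-ratio association score conditioned on a state sequence.

    With the temporal two-state model fixed, observations pool within each
    state; each hypothesis term re-maximizes only the Gaussian parameters,
    so every term is a closed-form MLE likelihood:

        score = sum_s [ ll(D_s) + ll(B_s) - ll(D_s u B_s) ]

    path: (M, T) states; d_stats/b_stats: (n, S1, S2) triples of (M, T)
    arrays.  Returns (M,) scores (exactly 0 when D and B coincide).
    """
    score = np.zeros(path.shape[0])
    for s in (0, 1):
        m = (path == s).astype(float)
        agg = []
        for stats in (d_stats, b_stats):
            agg.append(tuple((x * m).sum(axis=1) for x in stats))
        (nd, s1d, s2d), (nb, s1b, s2b) = agg
        score += (
            _pooled_gaussian_ll(nd, s1d, s2d)
            + _pooled_gaussian_ll(nb, s1b, s2b)
            - _pooled_gaussian_ll(nd + nb, s1d + s1b, s2d + s2b)
        )
    return score


# ---------------------------------------------------------------------------
# sufficient statistics of difference samples for a block of permutations


def rank_coefficients(members: np.ndarray) -> np.ndarray:
    """Signed pair-orientation coefficients for within-group differences.

    For a group of size g, the member with within-group rank r (ascending
    strain index, 1-based) appears with coefficient ``g + 1 - 2r`` in the
    sum of all unordered-pair differences x_i - x_j (i < j).
    ``members``: (n_strains, K) 0/1 -> (n_strains, K) float coefficients.
    """
    g = members.sum(axis=0)
    rank = np.cumsum(members, axis=0)
    return members * (g[None, :] + 1.0 - 2.0 * rank)


def pair_suffstats(Yp: np.ndarray, a_ind: np.ndarray):
    """Sufficient statistics of the D / background / pooled samples.

    Yp    : (P, n, T) expression of one gene under P strain-label
            permutations (complete data).
    a_ind : (n, K) 0/1 membership of the A allele group per variant; both
            groups must have >= 2 members.

    Variance stabilization is applied implicitly: within every (time
    point, allele group) cell the variance is equalized to the gene's
    average within-group variance (means, and hence effects, unchanged);
    the stabilized group statistics depend only on the group size, mean
    and raw standard deviation.  Returns three (count, S1, S2) triples of
    shape (P, K, T) for D, B and the pooled sample.
    """
    a_ind = np.asarray(a_ind, dtype=float)
    b_ind = 1.0 - a_ind
    nA = a_ind.sum(axis=0)
    nB = b_ind.sum(axis=0)
    if np.any(nA < 2) or np.any(nB < 2):
        raise ValueError("pair_suffstats requires >= 2 strains per allele group")
    Yp2 = Yp * Yp
    At, Bt = a_ind.T, b_ind.T
    S1A = np.matmul(At, Yp)  # (P, K, T)
    S1B = np.matmul(Bt, Yp)
    S2A = np.matmul(At, Yp2)
    S2B = np.matmul(Bt, Yp2)
    coefA = rank_coefficients(a_ind)
    coefB = rank_coefficients(b_ind)
    BrawA = np.matmul(coefA.T, Yp)
    BrawB = np.matmul(coefB.T, Yp)

    nA_ = nA[None, :, None]
    nB_ = nB[None, :, None]
    out_shape = S1A.shape

    varA = (S2A - S1A * (S1A / nA_)) / (nA_ - 1.0)
    varB = (S2B - S1B * (S1B / nB_)) / (nB_ - 1.0)
    # scale-preserving target: mean over the 2T (time, allele) cells
    vbar = 0.5 * (varA.mean(axis=2) + varB.mean(axis=2))[..., None]  # (P, K, 1)

    def stabilized(S1, var, S2, ng, braw):
        m = S1 / ng
        ok = var > 1e-24
        sd = np.sqrt(np.where(ok, var, 1.0))
        s2_stab = np.where(ok, ng * m * m + (ng - 1.0) * vbar, S2)
        bsum = np.where(ok, braw * np.sqrt(vbar) / sd, braw)
        return s2_stab, bsum

    S2A_st, bsumA = stabilized(S1A, varA, S2A, nA_, BrawA)
    S2B_st, bsumB = stabilized(S1B, varB, S2B, nB_, BrawB)

    d_n = np.broadcast_to((nA * nB)[None, :, None], out_shape)
    d_s1 = nB_ * S1A - nA_ * S1B
    d_s2 = nB_ * S2A_st + nA_ * S2B_st - 2.0 * S1A * S1B

    b_count = 0.5 * (nA * (nA - 1.0) + nB * (nB - 1.0))
    b_n = np.broadcast_to(b_count[None, :, None], out_shape)
    b_s1 = bsumA + bsumB
    b_s2 = (nA_ * S2A_st - S1A**2) + (nB_ * S2B_st - S1B**2)

    pooled = (d_n + b_n, d_s1 + b_s1, d_s2 + b_s2)
    return (d_n, d_s1, d_s2), (b_n, b_s1, b_s2), pooled
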