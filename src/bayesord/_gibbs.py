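"""JIT-compiled Gibbs sweep shared by all four model variants.

The non-conjugate conditionals (thresholds alpha_k and coefficients beta_j)
are updated by univariate slice sampling with stepping-out and shrinkage;
lambda, gamma and pi use their conjugate full conditionals.  Everything here
operates in place on plain float/int arrays so the hot loop compiles to
machine code; :mod:`bayesord.samplers` owns the user-facing API.

Model codes: 1 = Bayesian LASSO, 2 = spike-and-slab normal,
3 = spike-and-slab LASSO, 4 = indicator regression.  The linear predictor
``eta`` is maintained incrementally and always equals X @ beta (models 1-3)
or X @ (gamma * beta) (model 4).

RNG: numba's internal numpy-compatible generator, seeded once per chain via
:func:`seed_rng`; a fixed seed gives bit-identical output.
"""

import numpy as np
from numba import njit

_MAX_STEPOUT = 1000
_MAX_SHRINK = 1000


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def loglik(alpha, eta, yk, K):
    """Full cumulative-logit log-likelihood; yk is 0-based (0..K-1)."""
    ll = 0.0
    for i in range(eta.shape[0]):
        k = yk[i]
        up = _sigmoid(alpha[k] - eta[i]) if k < K - 1 else 1.0
        lo = _sigmoid(alpha[k - 1] - eta[i]) if k > 0 else 0.0
        pr = up - lo
        if pr <= 0.0:
            return -np.inf
        ll += np.log(pr)
    return ll


@njit(cache=True)
def _loglik_alpha(aval, k, alpha, eta, yk, K):
    """Log-likelihood terms that involve alpha[k], with alpha[k] = aval.

    Only observations in categories k and k+1 (0-based) touch this
    threshold, so the sum is restricted to them; constant terms cancel in
    the slice-sampling accept test.
    """
    ll = 0.0
    for i in range(eta.shape[0]):
        c = yk[i]
        if c == k:
            up = _sigmoid(aval - eta[i])
            lo = _sigmoid(alpha[c - 1] - eta[i]) if c > 0 else 0.0
        elif c == k + 1:
            up = _sigmoid(alpha[c] - eta[i]) if c < K - 1 else 1.0
            lo = _sigmoid(aval - eta[i])
        else:
            continue
        pr = up - lo
        if pr <= 0.0:
            return -np.inf
        ll += np.log(pr)
    return ll


@njit(cache=True)
def _loglik_shift(alpha, eta, xj, delta, yk, K):
    """Log-likelihood with eta replaced by eta + delta * xj."""
    ll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i] + delta * xj[i]
        k = yk[i]
        up = _sigmoid(alpha[k] - e) if k < K - 1 else 1.0
        lo = _sigmoid(alpha[k - 1] - e) if k > 0 else 0.0
        pr = up - lo
        if pr <= 0.0:
            return -np.inf
        ll += np.log(pr)
    return ll


@njit(cache=True, inline="always")
def _log_beta_prior(bval, g, model, lam, lam0, s20, s21):
    """Unnormalized log prior density of one coefficient given its indicator."""
    if model == 1 or model == 4:
        return -lam * abs(bval)
    if model == 2:
        s2 = s21 if g == 1 else s20
        return -0.5 * bval * bval / s2
    rate = lam if g == 1 else lam0
    return -rate * abs(bval)


@njit(cache=True)
def _slice_alpha(k, alpha, eta, yk, K, s2a, lo_bound, hi_bound, w):
    """One slice-sampling update of alpha[k] on (lo_bound, hi_bound).

    Returns (new value, length of the final bracket) — the bracket length
    feeds width adaptation.  The ordering constraint is enforced by the
    bounds, so a proposal violating it is impossible by construction.
    """
    x0 = alpha[k]
    f0 = _loglik_alpha(x0, k, alpha, eta, yk, K) - 0.5 * x0 * x0 / s2a
    logy = f0 + np.log(np.random.random())
    u = np.random.random()
    L = x0 - w * u
    R = L + w
    if L < lo_bound:
        L = lo_bound
    if R > hi_bound:
        R = hi_bound
    for _ in range(_MAX_STEPOUT):
        if L <= lo_bound:
            break
        if _loglik_alpha(L, k, alpha, eta, yk, K) - 0.5 * L * L / s2a <= logy:
            break
        L -= w
        if L < lo_bound:
            L = lo_bound
    for _ in range(_MAX_STEPOUT):
        if R >= hi_bound:
            break
        if _loglik_alpha(R, k, alpha, eta, yk, K) - 0.5 * R * R / s2a <= logy:
            break
        R += w
        if R > hi_bound:
            R = hi_bound
    x1 = x0
    for _ in range(_MAX_SHRINK):
        x1 = L + np.random.random() * (R - L)
        if _loglik_alpha(x1, k, alpha, eta, yk, K) - 0.5 * x1 * x1 / s2a > logy:
            return x1, R - L
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0, R - L


@njit(cache=True)
def _slice_beta(j, xj, bj, g, in_lik, alpha, eta, yk, K, model, lam, lam0, s20, s21, w):
    """One slice-sampling update of beta[j].

    ``in_lik`` says whether this coefficient enters the likelihood (always
    true for models 1-3; gamma_j == 1 for model 4).  When it does not, the
    conditional is the bare prior and the slice target degenerates to it.
    Returns (new value, final bracket length).
    """
    x0 = bj
    if in_lik:
        f0 = _loglik_shift(alpha, eta, xj, 0.0, yk, K)
    else:
        f0 = 0.0
    f0 += _log_beta_prior(x0, g, model, lam, lam0, s20, s21)
    logy = f0 + np.log(np.random.random())
    u = np.random.random()
    L = x0 - w * u
    R = L + w

    for _ in range(_MAX_STEPOUT):
        fl = _log_beta_prior(L, g, model, lam, lam0, s20, s21)
        if in_lik:
            fl += _loglik_shift(alpha, eta, xj, L - x0, yk, K)
        if fl <= logy:
            break
        L -= w
    for _ in range(_MAX_STEPOUT):
        fr = _log_beta_prior(R, g, model, lam, lam0, s20, s21)
        if in_lik:
            fr += _loglik_shift(alpha, eta, xj, R - x0, yk, K)
        if fr <= logy:
            break
        R += w
    x1 = x0
    for _ in range(_MAX_SHRINK):
        x1 = L + np.random.random() * (R - L)
        f1 = _log_beta_prior(x1, g, model, lam, lam0, s20, s21)
        if in_lik:
            f1 += _loglik_shift(alpha, eta, xj, x1 - x0, yk, K)
        if f1 > logy:
            return x1, R - L
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0, R - L


@njit(cache=True, inline="always")
def _draw_de(rate):
    """Draw from the double-exponential DE(0, 1/rate) by inverse CDF."""
    u = np.random.random()
    if u < 0.5:
        return np.log(2.0 * u) / rate
    return -np.log(2.0 * (1.0 - u)) / rate


@njit(cache=True)
def gibbs_sweep(
    X,
    yk,
    K,
    model,
    alpha,
    beta,
    gamma,
    pi,
    lam_arr,
    eta,
    a,
    b,
    s2a,
    s20,
    s21,
    lam0,
    pi_is_beta,
    c,
    d,
    w_alpha,
    w_beta,
    adapt,
):
    """One full Gibbs sweep, in place.

    Update order: alpha (slice, each k), beta (slice, each j; direct prior
    draw for model-4 coefficients currently excluded from the likelihood),
    gamma (conjugate Bernoulli, models 2-4), pi (conjugate Beta, Beta
    hyperprior only), lambda (conjugate Gamma, models 1/3/4).  During
    adaptation the slice widths track the observed bracket lengths; outside
    it they are frozen so the kernel is a fixed Markov transition leaving
    the joint posterior invariant.
    """
    n, p = X.shape
    K1 = K - 1
    lam = lam_arr[0]

    for k in range(K1):
        lo = alpha[k - 1] if k > 0 else -np.inf
        hi = alpha[k + 1] if k < K1 - 1 else np.inf
        newv, bracket = _slice_alpha(k, alpha, eta, yk, K, s2a, lo, hi, w_alpha[k])
        alpha[k] = newv
        if adapt:
            bw = bracket if bracket > 1e-3 else 1e-3
            w_alpha[k] = 0.9 * w_alpha[k] + 0.1 * bw

    for j in range(p):
        g = gamma[j] if model != 1 else 1
        in_lik = True
        if model == 4 and g == 0:
            in_lik = False
        if not in_lik:
            # flat likelihood in beta_j: conditional is the DE prior itself
            beta[j] = _draw_de(lam)
            continue
        old = beta[j]
        newb, bracket = _slice_beta(
            j, X[:, j], old, g, in_lik, alpha, eta, yk, K, model, lam, lam0, s20, s21, w_beta[j]
        )
        beta[j] = newb
        if newb != old:
            delta = newb - old
            for i in range(n):
                eta[i] += delta * X[i, j]
        if adapt:
            bw = bracket if bracket > 1e-3 else 1e-3
            w_beta[j] = 0.9 * w_beta[j] + 0.1 * bw

    if model != 1:
        for j in range(p):
            pij = pi[j]
            if pij < 1e-12:
                pij = 1e-12
            elif pij > 1.0 - 1e-12:
                pij = 1.0 - 1e-12
            log_odds = np.log(pij) - np.log(1.0 - pij)
            bj = beta[j]
            if model == 2:
                log_odds += (
                    -0.5 * np.log(s21)
                    - 0.5 * bj * bj / s21
                    + 0.5 * np.log(s20)
                    + 0.5 * bj * bj / s20
                )
            elif model == 3:
                log_odds += np.log(lam) - lam * abs(bj) - np.log(lam0) + lam0 * abs(bj)
            else:  # model 4: gamma_j enters the likelihood
                if gamma[j] == 1:
                    ll1 = loglik(alpha, eta, yk, K)
                    ll0 = _loglik_shift(alpha, eta, X[:, j], -bj, yk, K)
                else:
                    ll0 = loglik(alpha, eta, yk, K)
                    ll1 = _loglik_shift(alpha, eta, X[:, j], bj, yk, K)
                log_odds += ll1 - ll0
            p1 = _sigmoid(log_odds)
            newg = 1 if np.random.random() < p1 else 0
            if model == 4 and newg != gamma[j]:
                delta = bj if newg == 1 else -bj
                for i in range(n):
                    eta[i] += delta * X[i, j]
            gamma[j] = newg

        if pi_is_beta:
            for j in range(p):
                pi[j] = np.random.beta(c + gamma[j], d + 1 - gamma[j])

    if model != 2:
        if model == 3:
            m = 0
            S = 0.0
            for j in range(p):
                if gamma[j] == 1:
                    m += 1
                    S += abs(beta[j])
        else:
            m = p
            S = 0.0
            for j in range(p):
                S += abs(beta[j])
        lam = np.random.gamma(a + m, 1.0 / (b + S))
        lam_arr[0] = lam


@njit(cache=True)
def run_chain(
    X,
    yk,
    K,
    model,
    alpha0,
    beta0,
    gamma0,
    pi0,
    lam_init,
    a,
    b,
    s2a,
    s20,
    s21,
    lam0,
    pi_is_beta,
    c,
    d,
    n_burnin,
    n_adapt,
    thin,
    n_save,
    seed,
):
    """Run one chain; returns saved draws of (alpha, beta, gamma, pi, lambda).

    Warm-up order is adaptation then burn-in; both are discarded.  After
    warm-up every ``thin``-th sweep is saved until ``n_save`` draws are
    stored.
    """
    np.random.seed(seed)
    n, p = X.shape
    K1 = K - 1

    alpha = alpha0.copy()
    beta = beta0.copy()
    gamma = gamma0.copy()
    pi = pi0.copy()
    lam_arr = np.empty(1)
    lam_arr[0] = lam_init

    eta = np.zeros(n)
    for j in range(p):
        coef = beta[j]
        if model == 4:
            coef *= gamma[j]
        if coef != 0.0:
            for i in range(n):
                eta[i] += coef * X[i, j]

    w_alpha = np.full(K1, 1.0)
    w_beta = np.full(p, 1.0)

    alpha_out = np.empty((n_save, K1))
    beta_out = np.empty((n_save, p))
    gamma_out = np.zeros((n_save, p), dtype=np.int8)
    pi_out = np.empty((n_save, p if pi_is_beta else 0))
    lam_out = np.empty(n_save)

    total = n_adapt + n_burnin + thin * n_save
    saved = 0
    for it in range(total):
        adapt = it < n_adapt
        gibbs_sweep(
            X, yk, K, model, alpha, beta, gamma, pi, lam_arr, eta,
            a, b, s2a, s20, s21, lam0, pi_is_beta, c, d,
            w_alpha, w_beta, adapt,
        )
        post = it - (n_adapt + n_burnin)
        if post >= 0 and (post + 1) % thin == 0:
            for k in range(K1):
                alpha_out[saved, k] = alpha[k]
            for j in range(p):
                beta_out[saved, j] = beta[j]
                gamma_out[saved, j] = gamma[j]
            if pi_is_beta:
                for j in range(p):
                    pi_out[saved, j] = pi[j]
            lam_out[saved] = lam_arr[0]
            saved += 1
    return alpha_out, beta_out, gamma_out, pi_out, lam_out
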