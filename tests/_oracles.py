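"""Independent reference computations used by the tests.

Everything here is deliberately written along a different route than the
package: brute-force loops, numerical quadrature, exhaustive enumeration and
transition-matrix algebra, so that agreement is meaningful.
"""

import math
from math import comb

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from pairsel.model import ModelConfiguration
from pairsel.sampler import (BIRTH_COUPLE, BIRTH_SINGLETON, CHANGE_C_TO_I,
                             CHANGE_I_TO_C, DEATH_COUPLE, DEATH_SINGLETON,
                             MoveProposal, _log_prior_proposal_ratio,
                             move_probabilities)


def all_configurations(p: int, kmax: int):
    """Every reachable configuration for p pairs, dimension at most kmax."""
    configs = []
    for mask in range(3 ** p):
        couples, singles = [], []
        m = mask
        for j in range(p):
            state = m % 3
            m //= 3
            if state == 1:
                singles.append(j)
            elif state == 2:
                couples.append(j)
        if len(couples) + len(singles) <= kmax:
            configs.append(ModelConfiguration(tuple(couples), tuple(singles)))
    return configs


def gh_log_marginal_bernoulli(y, U, V, config, prior_var_a=1.0,
                              prior_var_b=1.0, intercept_var=100.0,
                              npts=None):
    """Bernoulli marginal likelihood of one configuration by Laplace-centered
    Gauss-Hermite tensor quadrature over (beta0, a..., b...)."""
    n = y.size
    k, kC = config.k, config.k_C
    X = np.column_stack(
        [np.ones(n)] + [U[:, j] for j in config.included]
        + [V[:, j] for j in config.couples])
    pv = np.array([intercept_var] + [prior_var_a] * k + [prior_var_b] * kC)
    d = X.shape[1]
    if npts is None:
        npts = {1: 40, 2: 30, 3: 20, 4: 14, 5: 12}[d]
    th = np.zeros(d)
    for _ in range(200):
        e = X @ th
        p = 1 / (1 + np.exp(-e))
        g = X.T @ (y - p) - th / pv
        H = X.T @ (X * (p * (1 - p))[:, None]) + np.diag(1 / pv)
        step = np.linalg.solve(H, g)
        th = th + step
        if np.abs(step).max() < 1e-12:
            break
    L = np.linalg.cholesky(np.linalg.inv(H))
    nodes, wts = hermegauss(npts)
    Z = np.stack([g.ravel() for g in np.meshgrid(*([nodes] * d), indexing="ij")])
    W = np.stack([w.ravel() for w in
                  np.meshgrid(*([wts] * d), indexing="ij")]).prod(axis=0)
    TH = th[:, None] + L @ Z
    E = X @ TH
    ll = y @ E - np.logaddexp(0, E).sum(axis=0)
    lp = (-0.5 * np.sum(TH ** 2 / pv[:, None], axis=0)
          - 0.5 * np.log(2 * np.pi * pv).sum())
    f = ll + lp + 0.5 * np.sum(Z ** 2, axis=0)
    fmax = f.max()
    return float(np.log((W * np.exp(f - fmax)).sum()) + fmax
                 + np.log(np.linalg.det(L)))


def config_prior_logweights(configs, p, kmax):
    """log prior mass of each configuration: uniform k, uniform given k."""
    return np.array([
        -math.log(kmax + 1) - math.log(comb(p, c.k) * 2 ** c.k)
        for c in configs])


def prior_move_stationary_k(p: int, kmax: int) -> np.ndarray:
    """Exact stationary k-marginal of the flat-likelihood move chain.

    Builds the (k_I, k_C) transition matrix from the package's own move
    probabilities and acceptance ratios (likelihood forced flat) and solves
    for the stationary distribution.  If the transdimensional bookkeeping is
    correct this must be uniform on {0..kmax}.
    """
    states = [(ki, kc) for ki in range(kmax + 1) for kc in range(kmax + 1 - ki)]
    index = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for (ki, kc) in states:
        i = index[(ki, kc)]
        cur = ModelConfiguration(tuple(range(ki, ki + kc)), tuple(range(ki)))
        probs = move_probabilities(ki, kc, kmax)
        stay = 1.0
        moves = []
        if probs.birth_singleton:
            moves.append((BIRTH_SINGLETON, probs.birth_singleton, (ki + 1, kc),
                          MoveProposal(BIRTH_SINGLETON, p - 1, ModelConfiguration(
                              cur.couples, cur.singletons + (p - 1,)))))
        if probs.birth_couple:
            moves.append((BIRTH_COUPLE, probs.birth_couple, (ki, kc + 1),
                          MoveProposal(BIRTH_COUPLE, p - 1, ModelConfiguration(
                              cur.couples + (p - 1,), cur.singletons))))
        if probs.death_singleton:
            t = cur.singletons[-1]
            moves.append((DEATH_SINGLETON, probs.death_singleton, (ki - 1, kc),
                          MoveProposal(DEATH_SINGLETON, t, ModelConfiguration(
                              cur.couples, cur.singletons[:-1]))))
        if probs.death_couple:
            t = cur.couples[-1]
            moves.append((DEATH_COUPLE, probs.death_couple, (ki, kc - 1),
                          MoveProposal(DEATH_COUPLE, t, ModelConfiguration(
                              cur.couples[:-1], cur.singletons))))
        if probs.change_singleton_to_couple:
            t = cur.singletons[0]
            moves.append((CHANGE_I_TO_C, probs.change_singleton_to_couple,
                          (ki - 1, kc + 1),
                          MoveProposal(CHANGE_I_TO_C, t, ModelConfiguration(
                              cur.couples + (t,), cur.singletons[1:]))))
        if probs.change_couple_to_singleton:
            t = cur.couples[-1]
            moves.append((CHANGE_C_TO_I, probs.change_couple_to_singleton,
                          (ki + 1, kc - 1),
                          MoveProposal(CHANGE_C_TO_I, t, ModelConfiguration(
                              cur.couples[:-1], cur.singletons + (t,)))))
        for _, pr, ns, proposal in moves:
            A = min(1.0, math.exp(
                _log_prior_proposal_ratio(cur, proposal, p, kmax)))
            T[i, index[ns]] += pr * A
            stay -= pr * A
        T[i, i] = stay
    w, vecs = np.linalg.eig(T.T)
    j = np.argmin(np.abs(w - 1))
    pi = np.real(vecs[:, j])
    pi = pi / pi.sum()
    kmarg = np.zeros(kmax + 1)
    for (ki, kc), i in index.items():
        kmarg[ki + kc] += pi[i]
    return kmarg


def ks_mixing_density(lam: np.ndarray, nterms: int = 60) -> np.ndarray:
    """The logistic scale-mixture mixing density.

    For lam >= 1 the alternating series
    p(lambda) = sum_{n>=1} (-1)^{n+1} n^2 exp(-n^2 lambda / 2)
    converges; for small lam the Jacobi-theta transformed series
    p(lambda) = sqrt(2 pi) lambda^{-3/2} sum_{k>=0}
                e^{-c_k/lambda} (2 c_k / lambda - 1), c_k = pi^2 (2k+1)^2 / 2
    is used instead (the direct series oscillates there).
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.zeros_like(lam)
    big = lam >= 1.0
    for n in range(1, nterms + 1):
        out[big] += (-1) ** (n + 1) * n * n * np.exp(-n * n * lam[big] / 2.0)
    small = ~big
    if small.any():
        lm = lam[small]
        acc = np.zeros_like(lm)
        for k in range(nterms):
            ck = math.pi ** 2 * (2 * k + 1) ** 2 / 2.0
            acc += np.exp(-ck / lm) * (2.0 * ck / lm - 1.0)
        out[small] = math.sqrt(2.0 * math.pi) * lm ** -1.5 * acc
    return out


def lambda_conditional_moment(r: float, power: float = 1.0) -> float:
    """E[lambda^power | r] under p(lambda|r) ~ lambda^{-1/2}
    exp(-r^2/(2 lambda)) p(lambda), by direct numerical integration."""
    from scipy.integrate import quad

    def integrand(lam, pw):
        return (lam ** pw * lam ** -0.5 * math.exp(-r * r / (2 * lam))
                * float(ks_mixing_density(lam)[0]))

    num = quad(integrand, 1e-9, 200, args=(power,), limit=400)[0]
    den = quad(integrand, 1e-9, 200, args=(0.0,), limit=400)[0]
    return num / den
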