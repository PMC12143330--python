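"""Tissue-specific and cross-animal haplotype switching, and the imprinting
screen.

Within an animal, a gene's per-tissue haplotype-1 read counts ``x_i`` out of
totals ``y_i`` are modeled as a K-component beta-binomial mixture

    L = prod_i sum_k pi_k * BB(x_i; y_i, alpha_k, phi),

with component allelic ratios ``alpha_k`` in (0,1), weights ``pi_k > 0``
summing to 1, and a shared overdispersion ``phi``.  K is selected by forward
likelihood-ratio testing: starting from K=1, K+1 is accepted while the
chi-squared LRT (2 extra degrees of freedom per component: one ratio, one
weight) is significant at 0.05.  A gene is "consistent" when the selected
model puts all components on one side of 0.5, and "switching" when components
sit on both sides with non-trivial weight.

Cross-animal comparison requires a shared haplotype labeling: haplotype 1 is
anchored to the reference allele of the most widely shared heterozygous SNV
of the gene, and animals not heterozygous at the anchor are oriented
transitively through the next shared sites.

The imprinting screen looks for genes that are completely monoallelic (zero
reads from one haplotype) in every ASE sample, consistently within each
animal (tier 1), and additionally for the same canonical haplotype across all
animals (tier 2) — the signature expected of genomic imprinting absent
parent-of-origin information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import chi2

from .betabinom import RHO_MAX, RHO_MIN

__all__ = [
    "MixtureFit",
    "fit_bb_mixture",
    "fit_bb_mixture_batch",
    "canonicalize_haplotypes",
    "call_tissue_switching",
    "call_cross_animal_switching",
    "imprinting_screen",
]

_ALPHA_LO, _ALPHA_HI = 1e-6, 1.0 - 1e-6


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """theta = [u_1..u_K (logit alpha), w_1..w_{K-1} (softmax logits), v (phi)]."""
    u = theta[:k]
    alphas = _ALPHA_LO + (_ALPHA_HI - _ALPHA_LO) * _sigmoid(u)
    if k > 1:
        w = np.concatenate((theta[k : 2 * k - 1], [0.0]))
        w = w - w.max()
        pi = np.exp(w)
        pi /= pi.sum()
    else:
        pi = np.array([1.0])
    v = theta[-1]
    phi = RHO_MIN + (RHO_MAX - RHO_MIN) * float(_sigmoid(np.array([v]))[0])
    return alphas, pi, phi


def _neg_loglik_grad(
    theta: np.ndarray, x: np.ndarray, y: np.ndarray, k: int, logbinom: np.ndarray
) -> tuple[float, np.ndarray]:
    """Observed-data negative log-likelihood and its analytic gradient.

    Because phi is shared, a_k + b_k = c = (1-phi)/phi for every component,
    so the normalizing gammaln term depends on the tissue only.  The binomial
    coefficient term is precomputed once per series.
    """
    alphas, pi, phi = _unpack(theta, k)
    c = (1.0 - phi) / phi
    a = alphas * c  # (K,)
    b = (1.0 - alphas) * c

    n = len(x)
    xi = x[:, None]
    yi = y[:, None]
    # one fused special-function call over [x+a | y-x+b | y+c] and [a | b | c]
    big = np.concatenate((xi + a, yi - xi + b, yi + c), axis=1)
    small = np.concatenate((a, b, [c]))
    g_big = gammaln(big)
    g_small = gammaln(small)
    l_ik = (
        logbinom
        + (g_big[:, :k] - g_small[:k])
        + (g_big[:, k : 2 * k] - g_small[k : 2 * k])
        - (g_big[:, 2 * k :] - g_small[2 * k])
    )
    with np.errstate(divide="ignore"):
        z = np.log(pi)[None, :] + l_ik
    lse = logsumexp(z, axis=1)
    loglik = float(lse.sum())
    r = np.exp(z - lse[:, None])  # responsibilities (N, K)

    d_big = digamma(big)
    d_small = digamma(small)
    d1 = d_big[:, :k] - d_small[:k]
    d2 = d_big[:, k : 2 * k] - d_small[k : 2 * k]
    d3 = d_big[:, 2 * k :] - d_small[2 * k]  # (N, 1)

    # alpha_k via u_k
    dl_dalpha = (r * c * (d1 - d2)).sum(axis=0)
    dalpha_du = (_ALPHA_HI - _ALPHA_LO) * (
        _sigmoid(theta[:k]) * (1.0 - _sigmoid(theta[:k]))
    )
    grad_u = dl_dalpha * dalpha_du

    # phi via v
    dl_dc = (r * (alphas[None, :] * d1 + (1.0 - alphas[None, :]) * d2 - d3)).sum()
    dc_dphi = -1.0 / phi**2
    s_v = float(_sigmoid(np.array([theta[-1]]))[0])
    dphi_dv = (RHO_MAX - RHO_MIN) * s_v * (1.0 - s_v)
    grad_v = dl_dc * dc_dphi * dphi_dv

    if k > 1:
        grad_w = (r - pi[None, :]).sum(axis=0)[: k - 1]
        grad = np.concatenate((grad_u, grad_w, [grad_v]))
    else:
        grad = np.concatenate((grad_u, [grad_v]))
    return -loglik, -grad


def _pack_start(alphas: np.ndarray, pi: np.ndarray, phi: float) -> np.ndarray:
    alphas = np.clip(alphas, 1e-4, 1 - 1e-4)
    u = np.log(alphas / (1.0 - alphas))
    s = np.clip((phi - RHO_MIN) / (RHO_MAX - RHO_MIN), 1e-9, 1 - 1e-9)
    v = math.log(s / (1.0 - s))
    if len(pi) > 1:
        w = np.log(np.clip(pi, 1e-6, None))
        w = w[:-1] - w[-1]
        return np.clip(np.concatenate((u, w, [v])), -14.0, 14.0)
    return np.clip(np.concatenate((u, [v])), -14.0, 14.0)


def _fit_k(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    n_starts: int,
    rng: np.random.Generator,
    warm: tuple[np.ndarray, np.ndarray, float] | None,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Best-of-multistart fit for fixed K; returns (loglik, alphas, pi, phi)."""
    ratios = np.clip(x / np.maximum(y, 1), 0.02, 0.98)
    starts: list[np.ndarray] = []
    # deterministic quantile starts at two phi scales
    qs = (np.arange(k) + 0.5) / k
    q_alphas = np.quantile(ratios, qs) if len(ratios) else np.full(k, 0.5)
    q_alphas = np.clip(q_alphas + 1e-3 * np.arange(k), 1e-3, 1 - 1e-3)
    for phi0 in (1e-3, 3e-2):
        starts.append(_pack_start(q_alphas, np.full(k, 1.0 / k), phi0))
    # warm start from the (K-1)-component fit: split its widest component
    if warm is not None:
        w_alphas, w_pi, w_phi = warm
        idx = int(np.argmax(w_pi))
        alphas0 = np.concatenate(
            (w_alphas, [np.clip(w_alphas[idx] + 0.1, 1e-3, 1 - 1e-3)])
        )
        pi0 = np.concatenate((w_pi * (1 - w_pi[idx] / 2 / w_pi.sum()), [w_pi[idx] / 2]))
        pi0 /= pi0.sum()
        starts.append(_pack_start(alphas0, pi0, w_phi))
    # random restarts (the single-component likelihood is well behaved; the
    # deterministic starts suffice there)
    if k > 1:
        for _ in range(n_starts):
            alphas0 = rng.uniform(0.05, 0.95, size=k)
            pi0 = rng.dirichlet(np.ones(k))
            phi0 = float(np.exp(rng.uniform(math.log(1e-4), math.log(0.1))))
            starts.append(_pack_start(alphas0, pi0, phi0))

    logbinom = (gammaln(y + 1) - gammaln(x + 1) - gammaln(y - x + 1))[:, None]
    best = None
    for theta0 in starts:
        res = minimize(
            _neg_loglik_grad,
            theta0,
            args=(x, y, k, logbinom),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-14.0, 14.0)] * len(theta0),
            options={"maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"mixture optimization failed on all starts (K={k})")
    alphas, pi, phi = _unpack(best.x, k)
    order = np.argsort(alphas)
    return -float(best.fun), alphas[order], pi[order], phi


@dataclass
class MixtureFit:
    """Selected beta-binomial mixture for one animal-gene series.

    Components are sorted by allelic ratio.  ``lrt_trail`` records each
    nested comparison as (K, K+1, statistic, df, p); ``loglik_by_k`` keeps the
    maximized log-likelihood of every candidate K (non-decreasing).
    """

    k: int
    alphas: np.ndarray
    weights: np.ndarray
    phi: float
    loglik: float
    lrt_trail: list[tuple[int, int, float, int, float]]
    loglik_by_k: dict[int, float]
    posterior: np.ndarray  # per-tissue component assignment (argmax responsibility)
    n_starts: int
    seed: int


def fit_bb_mixture(
    x: np.ndarray,
    y: np.ndarray,
    k_max: int = 3,
    n_starts: int = 10,
    seed: int = 0,
    lrt_alpha: float = 0.05,
) -> MixtureFit:
    """Fit the shared-phi beta-binomial mixture and select K by forward LRT.

    Accepts K+1 over K while the chi-squared test of twice the log-likelihood
    increase (df = 2 per added component) is significant at ``lrt_alpha``,
    stopping at the first non-significant increment or ``k_max``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need per-tissue series of length >= 2")
    if np.any((x < 0) | (x > y)):
        raise ValueError("require 0 <= x_i <= y_i")
    rng = np.random.default_rng(seed)

    loglik_by_k: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    trail: list[tuple[int, int, float, int, float]] = []

    ll, alphas, pi, phi = _fit_k(x, y, 1, n_starts, rng, warm=None)
    loglik_by_k[1] = ll
    fits[1] = (alphas, pi, phi)
    selected = 1
    for k in range(2, k_max + 1):
        ll_new, alphas, pi, phi = _fit_k(
            x, y, k, n_starts, rng, warm=fits[k - 1]
        )
        # nesting guarantee: the warm start makes K+1 at least as good
        ll_new = max(ll_new, loglik_by_k[k - 1])
        loglik_by_k[k] = ll_new
        fits[k] = (alphas, pi, phi)
        stat = max(0.0, 2.0 * (ll_new - loglik_by_k[k - 1]))
        p = float(chi2.sf(stat, df=2))
        trail.append((k - 1, k, stat, 2, p))
        if p < lrt_alpha:
            selected = k
        else:
            break

    alphas, pi, phi = fits[selected]
    # per-tissue posterior assignment under the selected model
    c = (1.0 - phi) / phi
    a = alphas * c
    b = (1.0 - alphas) * c
    xi, yi = x[:, None], y[:, None]
    l_ik = (
        gammaln(yi + 1) - gammaln(xi + 1) - gammaln(yi - xi + 1)
        + gammaln(xi + a) - gammaln(a)
        + gammaln(yi - xi + b) - gammaln(b)
        - gammaln(yi + c) + gammaln(c)
    )
    z = np.log(pi)[None, :] + l_ik
    posterior = np.argmax(z, axis=1)

    return MixtureFit(
        k=selected,
        alphas=alphas,
        weights=pi,
        phi=phi,
        loglik=loglik_by_k[selected],
        lrt_trail=trail,
        loglik_by_k=loglik_by_k,
        posterior=posterior,
        n_starts=n_starts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# batched fitting across many animal-gene series
# ---------------------------------------------------------------------------

def _batch_neg_loglik_grad(
    theta_flat: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    M: np.ndarray,
    logbinom: np.ndarray,
    k: int,
) -> tuple[float, np.ndarray]:
    """Stacked objective over P independent series (block-diagonal problem).

    The summed likelihood separates per series, so the joint optimum equals
    the per-series optima; stacking simply amortizes the optimizer overhead.
    Padded tissues are masked out of both value and gradient.
    """
    P, _ = X.shape
    d = 2 * k
    theta = theta_flat.reshape(P, d)
    u = theta[:, :k]
    su = _sigmoid(u)
    alphas = _ALPHA_LO + (_ALPHA_HI - _ALPHA_LO) * su
    if k > 1:
        w = np.concatenate((theta[:, k : 2 * k - 1], np.zeros((P, 1))), axis=1)
        w = w - w.max(axis=1, keepdims=True)
        pi = np.exp(w)
        pi /= pi.sum(axis=1, keepdims=True)
    else:
        pi = np.ones((P, 1))
    sv = _sigmoid(theta[:, -1])
    phi = RHO_MIN + (RHO_MAX - RHO_MIN) * sv
    c = (1.0 - phi) / phi  # (P,)
    a = alphas * c[:, None]
    b = (1.0 - alphas) * c[:, None]

    big1 = X[:, :, None] + a[:, None, :]
    big2 = (Y - X)[:, :, None] + b[:, None, :]
    big3 = Y + c[:, None]
    l = (
        logbinom[:, :, None]
        + (gammaln(big1) - gammaln(a)[:, None, :])
        + (gammaln(big2) - gammaln(b)[:, None, :])
        - (gammaln(big3) - gammaln(c)[:, None])[:, :, None]
    )
    with np.errstate(divide="ignore"):
        z = np.log(pi)[:, None, :] + l
    zmax = z.max(axis=2, keepdims=True)
    ez = np.exp(z - zmax)
    lse = zmax[:, :, 0] + np.log(ez.sum(axis=2))
    ll_p = (lse * M).sum(axis=1)
    r = ez / ez.sum(axis=2, keepdims=True) * M[:, :, None]

    d1 = digamma(big1) - digamma(a)[:, None, :]
    d2 = digamma(big2) - digamma(b)[:, None, :]
    d3 = digamma(big3) - digamma(c)[:, None]

    dl_dalpha = (r * (d1 - d2)).sum(axis=1) * c[:, None]
    grad_u = dl_dalpha * (_ALPHA_HI - _ALPHA_LO) * su * (1.0 - su)
    dl_dc = (
        r * (alphas[:, None, :] * d1 + (1.0 - alphas)[:, None, :] * d2 - d3[:, :, None])
    ).sum(axis=(1, 2))
    grad_v = dl_dc * (-1.0 / phi**2) * (RHO_MAX - RHO_MIN) * sv * (1.0 - sv)

    grad = np.empty((P, d))
    grad[:, :k] = grad_u
    if k > 1:
        grad[:, k : 2 * k - 1] = (r.sum(axis=1) - pi * M.sum(axis=1)[:, None])[:, : k - 1]
    grad[:, -1] = grad_v
    return -float(ll_p.sum()), -grad.ravel()


def _batch_loglik_per_pair(theta, X, Y, M, logbinom, k):
    """Per-series log-likelihood at a stacked parameter vector."""
    P = X.shape[0]
    th = theta.reshape(P, 2 * k)
    alphas = _ALPHA_LO + (_ALPHA_HI - _ALPHA_LO) * _sigmoid(th[:, :k])
    if k > 1:
        w = np.concatenate((th[:, k : 2 * k - 1], np.zeros((P, 1))), axis=1)
        w = w - w.max(axis=1, keepdims=True)
        pi = np.exp(w)
        pi /= pi.sum(axis=1, keepdims=True)
    else:
        pi = np.ones((P, 1))
    phi = RHO_MIN + (RHO_MAX - RHO_MIN) * _sigmoid(th[:, -1])
    c = (1.0 - phi) / phi
    a = alphas * c[:, None]
    b = (1.0 - alphas) * c[:, None]
    l = (
        logbinom[:, :, None]
        + (gammaln(X[:, :, None] + a[:, None, :]) - gammaln(a)[:, None, :])
        + (gammaln((Y - X)[:, :, None] + b[:, None, :]) - gammaln(b)[:, None, :])
        - (gammaln(Y + c[:, None]) - gammaln(c)[:, None])[:, :, None]
    )
    with np.errstate(divide="ignore"):
        z = np.log(pi)[:, None, :] + l
    zmax = z.max(axis=2, keepdims=True)
    lse = zmax[:, :, 0] + np.log(np.exp(z - zmax).sum(axis=2))
    return (lse * M).sum(axis=1)


def _batch_pack(alphas: np.ndarray, pi: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Vectorized start packing: (P,K), (P,K), (P,) -> (P, 2K)."""
    P, k = alphas.shape
    alphas = np.clip(alphas, 1e-4, 1 - 1e-4)
    u = np.log(alphas / (1.0 - alphas))
    s = np.clip((phi - RHO_MIN) / (RHO_MAX - RHO_MIN), 1e-9, 1 - 1e-9)
    v = np.log(s / (1.0 - s))
    out = np.empty((P, 2 * k))
    out[:, :k] = u
    if k > 1:
        w = np.log(np.clip(pi, 1e-6, None))
        out[:, k : 2 * k - 1] = w[:, :-1] - w[:, -1:]
    out[:, -1] = v
    return np.clip(out, -14.0, 14.0)


def _batch_fit_k(
    X, Y, M, logbinom, k, starts: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Best-per-series theta across the stacked multistart runs.

    Two phases: every start gets a short exploratory run (enough to settle
    into its basin), then the per-series best parameters are polished jointly
    to full convergence.  This is the short-run/long-run strategy standard
    for mixture multistarts, stacked.
    """
    P = X.shape[0]
    best_ll = np.full(P, -np.inf)
    best_theta = None
    for theta0 in starts:
        res = minimize(
            _batch_neg_loglik_grad,
            theta0.ravel(),
            args=(X, Y, M, logbinom, k),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-14.0, 14.0)] * theta0.size,
            options={"maxiter": 150, "maxfun": 400},
        )
        ll_p = _batch_loglik_per_pair(res.x, X, Y, M, logbinom, k)
        if best_theta is None:
            best_theta = res.x.reshape(P, 2 * k).copy()
            best_ll = ll_p
        else:
            better = ll_p > best_ll
            best_theta[better] = res.x.reshape(P, 2 * k)[better]
            best_ll = np.maximum(best_ll, ll_p)
    polish = minimize(
        _batch_neg_loglik_grad,
        best_theta.ravel(),
        args=(X, Y, M, logbinom, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-14.0, 14.0)] * best_theta.size,
        options={"maxiter": 3000, "maxfun": 6000},
    )
    ll_p = _batch_loglik_per_pair(polish.x, X, Y, M, logbinom, k)
    better = ll_p > best_ll
    best_theta[better] = polish.x.reshape(P, 2 * k)[better]
    best_ll = np.maximum(best_ll, ll_p)
    return best_ll, best_theta


def fit_bb_mixture_batch(
    xs: list[np.ndarray],
    ys: list[np.ndarray],
    k_max: int = 3,
    n_starts: int = 10,
    seed: int = 0,
    lrt_alpha: float = 0.05,
) -> list[MixtureFit]:
    """Fit the shared-phi mixture for many series at once.

    Same model, constraints, multistart policy, and forward-LRT selection as
    :func:`fit_bb_mixture`; series are stacked in fixed-size blocks into
    block-diagonal optimizations, which amortizes the optimizer overhead
    while keeping per-block convergence tight.  Deterministic for a fixed
    input set and seed.
    """
    block = 64
    if len(xs) > block:
        children = np.random.SeedSequence(seed).spawn(-(-len(xs) // block))
        fits: list[MixtureFit] = []
        for i in range(0, len(xs), block):
            child_seed = int(children[i // block].generate_state(1)[0] % (2**31 - 1))
            fits.extend(
                fit_bb_mixture_batch(
                    xs[i : i + block], ys[i : i + block], k_max, n_starts,
                    child_seed, lrt_alpha,
                )
            )
        return fits
    P = len(xs)
    if P == 0:
        return []
    rng = np.random.default_rng(seed)
    lens = np.array([len(x) for x in xs])
    if (lens < 2).any():
        raise ValueError("need per-tissue series of length >= 2")
    nmax = int(lens.max())
    X = np.zeros((P, nmax))
    Y = np.zeros((P, nmax))
    M = np.zeros((P, nmax))
    for p, (x, y) in enumerate(zip(xs, ys)):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any((x < 0) | (x > y)):
            raise ValueError("require 0 <= x_i <= y_i")
        X[p, : lens[p]] = x
        Y[p, : lens[p]] = y
        M[p, : lens[p]] = 1.0
    logbinom = gammaln(Y + 1) - gammaln(X + 1) - gammaln(Y - X + 1)
    ratios = np.where(M > 0, X / np.maximum(Y, 1.0), np.nan)
    ratios = np.clip(ratios, 0.02, 0.98)

    def det_starts(k: int, r: np.ndarray) -> list[np.ndarray]:
        p = r.shape[0]
        qs = (np.arange(k) + 0.5) / k
        q_alphas = np.nanquantile(r, qs, axis=1).T  # (p, K)
        q_alphas = np.clip(q_alphas + 1e-3 * np.arange(k), 1e-3, 1 - 1e-3)
        pi0 = np.full((p, k), 1.0 / k)
        return [
            _batch_pack(q_alphas, pi0, np.full(p, phi0)) for phi0 in (1e-3, 3e-2)
        ]

    def random_starts(k: int, p: int) -> list[np.ndarray]:
        out = []
        for _ in range(n_starts):
            alphas0 = rng.uniform(0.05, 0.95, size=(p, k))
            g = rng.gamma(1.0, size=(p, k))
            pi0 = g / g.sum(axis=1, keepdims=True)
            phi0 = np.exp(rng.uniform(math.log(1e-4), math.log(0.1), size=p))
            out.append(_batch_pack(alphas0, pi0, phi0))
        return out

    # K = 1
    ll1, theta1 = _batch_fit_k(X, Y, M, logbinom, 1, det_starts(1, ratios))
    loglik_by_k: dict[int, np.ndarray] = {1: ll1}
    theta_by_k: dict[int, np.ndarray] = {1: theta1}
    selected = np.ones(P, dtype=int)
    active = np.ones(P, dtype=bool)
    trail: list[list[tuple[int, int, float, int, float]]] = [[] for _ in range(P)]

    for k in range(2, k_max + 1):
        if not active.any():
            break
        idx_active = np.flatnonzero(active)
        Xa, Ya, Ma = X[idx_active], Y[idx_active], M[idx_active]
        logbinom_a = logbinom[idx_active]
        ratios_a = ratios[idx_active]
        # warm start: split the widest component of the (k-1)-fit
        prev = theta_by_k[k - 1]
        pa = len(idx_active)
        warm_alphas = np.empty((pa, k))
        warm_pi = np.empty((pa, k))
        warm_phi = np.empty(pa)
        for j, p in enumerate(idx_active):
            al, pi_prev, ph = _unpack(prev[p], k - 1)
            i0 = int(np.argmax(pi_prev))
            warm_alphas[j] = np.concatenate(
                (al, [np.clip(al[i0] + 0.1, 1e-3, 1 - 1e-3)])
            )
            newpi = np.concatenate(
                (pi_prev * (1 - pi_prev[i0] / 2 / pi_prev.sum()), [pi_prev[i0] / 2])
            )
            warm_pi[j] = newpi / newpi.sum()
            warm_phi[j] = ph
        starts = det_starts(k, ratios_a) + [_batch_pack(warm_alphas, warm_pi, warm_phi)]
        starts += random_starts(k, pa)
        ll_a, theta_a = _batch_fit_k(Xa, Ya, Ma, logbinom_a, k, starts)
        ll_a = np.maximum(ll_a, loglik_by_k[k - 1][idx_active])  # nesting guarantee
        ll_k = np.full(P, -np.inf)
        ll_k[idx_active] = ll_a
        theta_k = np.zeros((P, 2 * k))
        theta_k[idx_active] = theta_a
        loglik_by_k[k] = ll_k
        theta_by_k[k] = theta_k
        stat = np.maximum(0.0, 2.0 * (ll_a - loglik_by_k[k - 1][idx_active]))
        pvals = chi2.sf(stat, df=2)
        for j, p in enumerate(idx_active):
            trail[p].append((k - 1, k, float(stat[j]), 2, float(pvals[j])))
        accept = np.zeros(P, dtype=bool)
        accept[idx_active] = pvals < lrt_alpha
        selected[accept] = k
        active = accept

    fits: list[MixtureFit] = []
    for p in range(P):
        k = int(selected[p])
        alphas, pi, phi = _unpack(theta_by_k[k][p], k)
        order = np.argsort(alphas)
        alphas, pi = alphas[order], pi[order]
        n = int(lens[p])
        c = (1.0 - phi) / phi
        a = alphas * c
        b = (1.0 - alphas) * c
        xi = X[p, :n, None]
        yi = Y[p, :n, None]
        l_ik = (
            logbinom[p, :n, None]
            + gammaln(xi + a) - gammaln(a)
            + gammaln(yi - xi + b) - gammaln(b)
            - gammaln(yi + c) + gammaln(c)
        )
        with np.errstate(divide="ignore"):
            post = np.argmax(np.log(pi)[None, :] + l_ik, axis=1)
        fits.append(
            MixtureFit(
                k=k,
                alphas=alphas,
                weights=pi,
                phi=float(phi),
                loglik=float(loglik_by_k[k][p]),
                lrt_trail=trail[p],
                loglik_by_k={kk: float(ll[p]) for kk, ll in loglik_by_k.items()},
                posterior=post,
                n_starts=n_starts,
                seed=seed,
            )
        )
    return fits


# ---------------------------------------------------------------------------
# cross-animal haplotype canonicalization
# ---------------------------------------------------------------------------

def canonicalize_haplotypes(phase: pd.DataFrame) -> pd.DataFrame:
    """Deterministic shared haplotype labels per gene across animals.

    ``phase`` columns: ``gene_id``, ``animal``, ``snv_id``, ``pos``,
    ``alt_on_hap1``.  For each gene the anchor SNV is the lowest-position site
    heterozygous in the largest number of animals; canonical haplotype 1
    carries the reference allele at the anchor.  Animals not heterozygous at
    the anchor are oriented transitively through the next-ranked shared sites
    using the allele consensus of already-oriented animals.

    Returns one row per (gene_id, animal): ``flip`` — whether the animal's
    local haplotype labels must be swapped to match the canonical labels —
    and ``comparable``.  Genes with no shared heterozygous SNV across >= 2
    animals have ``comparable`` = False for all their animals.
    """
    rows = []
    for gene, grp in phase.groupby("gene_id", sort=True):
        animals = sorted(grp["animal"].unique())
        # rank sites: most shared first, then lowest position
        site_info = (
            grp.groupby(["snv_id", "pos"])["animal"]
            .nunique()
            .reset_index(name="n_het")
            .sort_values(["n_het", "pos"], ascending=[False, True])
        )
        ranked = list(site_info.itertuples(index=False))
        comparable = bool(ranked and ranked[0].n_het >= 2)
        if not comparable:
            for animal in animals:
                rows.append(
                    {"gene_id": gene, "animal": animal, "flip": False, "comparable": False}
                )
            continue
        # alt_on_hap1 lookup per (animal, snv)
        local = {
            (r.animal, r.snv_id): bool(r.alt_on_hap1)
            for r in grp.itertuples(index=False)
        }
        # canonical orientation per site: does canonical hap1 carry alt there?
        anchor = ranked[0].snv_id
        consensus: dict[str, bool] = {anchor: False}  # canonical hap1 = ref at anchor
        flip: dict[str, bool] = {}
        changed = True
        while changed:
            changed = False
            for animal in animals:
                if animal in flip:
                    continue
                for site in ranked:
                    snv = site.snv_id
                    if snv in consensus and (animal, snv) in local:
                        # flip iff the local hap1 allele disagrees with canon
                        flip[animal] = local[(animal, snv)] != consensus[snv]
                        changed = True
                        break
                else:
                    continue
                # propagate this animal's alleles into the consensus
                for site in ranked:
                    snv = site.snv_id
                    if snv in consensus or (animal, snv) not in local:
                        continue
                    canon_alt = local[(animal, snv)] != flip[animal]
                    consensus[snv] = canon_alt
        for animal in animals:
            rows.append(
                {
                    "gene_id": gene,
                    "animal": animal,
                    "flip": flip.get(animal, False),
                    "comparable": animal in flip,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "animal", "flip", "comparable"])


# ---------------------------------------------------------------------------
# switching calls
# ---------------------------------------------------------------------------

def call_tissue_switching(
    fits: pd.DataFrame,
    delta: float = 0.1,
) -> pd.DataFrame:
    """Classify fitted animal-gene mixtures as consistent or switching.

    ``fits`` needs columns ``animal``, ``gene_id``, ``k``, ``alphas`` (array),
    ``weights`` (array), ``n_tissues``.  Consistent: a single component, or
    all components on one side of 0.5.  Switching: components with weight at
    least 1/(2N) on both sides of the band (0.5 - delta, 0.5 + delta), so a
    single flipped tissue out of >= 6 can still form a component.
    """
    rows = []
    for rec in fits.itertuples(index=False):
        alphas = np.asarray(rec.alphas, dtype=float)
        weights = np.asarray(rec.weights, dtype=float)
        n = int(rec.n_tissues)
        min_w = 1.0 / (2 * n)
        heavy = weights >= min_w
        lo = (alphas < 0.5 - delta) & heavy
        hi = (alphas > 0.5 + delta) & heavy
        switching = bool(lo.any() and hi.any())
        consistent = bool(
            rec.k == 1 or (alphas > 0.5).all() or (alphas < 0.5).all()
        )
        rows.append(
            {
                "animal": rec.animal,
                "gene_id": rec.gene_id,
                "k": rec.k,
                "consistent": consistent,
                "switching": switching,
                "component_sides": "".join(
                    "+" if a > 0.5 else "-" for a in alphas
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["animal", "gene_id", "k", "consistent", "switching", "component_sides"],
    )


def call_cross_animal_switching(
    gene_results: pd.DataFrame,
    canonical: pd.DataFrame,
    min_animals_per_side: int = 2,
) -> pd.DataFrame:
    """Genes whose major haplotype differs between animals within a tissue.

    ``gene_results`` is the gene-level ASE table (needs ``animal``,
    ``tissue``, ``gene_id``, ``is_ase``, ``major_hap``); ``canonical`` comes
    from :func:`canonicalize_haplotypes`.  A gene x tissue is flagged when at
    least ``min_animals_per_side`` ASE animals favor canonical haplotype 1
    and at least as many favor canonical haplotype 2.  Non-comparable genes
    are excluded.
    """
    merged = gene_results.merge(canonical, on=["gene_id", "animal"], how="inner")
    merged = merged[merged["comparable"] & merged["is_ase"]].copy()
    flip = merged["flip"].astype(bool)
    merged["canonical_major_hap"] = np.where(
        flip, 3 - merged["major_hap"], merged["major_hap"]
    )
    rows = []
    for (gene, tissue), grp in merged.groupby(["gene_id", "tissue"], sort=True):
        per_animal = grp.groupby("animal")["canonical_major_hap"].first()
        n1 = int((per_animal == 1).sum())
        n2 = int((per_animal == 2).sum())
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "n_hap1_major": n1,
                "n_hap2_major": n2,
                "switching": n1 >= min_animals_per_side and n2 >= min_animals_per_side,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "n_hap1_major", "n_hap2_major", "switching"]
    )


# ---------------------------------------------------------------------------
# imprinting screen
# ---------------------------------------------------------------------------

def imprinting_screen(
    snv_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    canonical: pd.DataFrame,
    known_imprinted: set[str] | None = None,
    min_ase_snvs: int = 4,
) -> pd.DataFrame:
    """Screen for imprinting-like monoallelic expression.

    Eligible genes have at least ``min_ase_snvs`` distinct ASE SNVs (SNV-level
    test) and all SNVs phased into a single haplotype block in every animal
    considered.  Tier "within-animal-consistent": in every sample where the
    gene is ASE, expression is completely monoallelic and, within each animal,
    always from the same (local) haplotype.  Tier "all-sample-consistent":
    additionally the same canonical haplotype across all animals.

    Returns one row per candidate with the tier, ASE-SNV support, and the
    known-imprinted flag; a per-animal expressed-haplotype table is included
    in the ``per_animal_hap`` column (canonical labels, ``animal=hap`` pairs).
    """
    known = known_imprinted or set()
    ase_snvs = (
        snv_results[snv_results["is_ase"]]
        .dropna(subset=["gene_id"])
        .groupby("gene_id")["snv_id"]
        .nunique()
    )
    eligible_genes = set(ase_snvs[ase_snvs >= min_ase_snvs].index)

    canon_flip = {
        (r.gene_id, r.animal): (bool(r.flip), bool(r.comparable))
        for r in canonical.itertuples(index=False)
    }

    rows = []
    gr = gene_results.dropna(subset=["gene_id"])
    for gene, grp in gr.groupby("gene_id", sort=True):
        if gene not in eligible_genes:
            continue
        ase = grp[grp["is_ase"]]
        if ase.empty:
            continue
        if "single_block" in grp.columns and not grp["single_block"].all():
            continue
        tier1 = True
        per_animal_local: dict[str, int] = {}
        for animal, agrp in ase.groupby("animal"):
            mono = (agrp["x"] == 0) | (agrp["x"] == agrp["y"])
            if not mono.all():
                tier1 = False
                break
            haps = np.where(agrp["x"] == agrp["y"], 1, 2)
            if len(set(haps)) != 1:
                tier1 = False
                break
            per_animal_local[animal] = int(haps[0])
        if not tier1:
            continue
        # canonical expressed haplotype per animal
        per_animal_canon: dict[str, int | None] = {}
        for animal, local_hap in per_animal_local.items():
            flip, comparable = canon_flip.get((gene, animal), (False, False))
            per_animal_canon[animal] = (3 - local_hap if flip else local_hap) if comparable else None
        canon_vals = [h for h in per_animal_canon.values() if h is not None]
        tier2 = (
            len(canon_vals) == len(per_animal_canon)
            and len(set(canon_vals)) == 1
            and len(canon_vals) > 0
        )
        rows.append(
            {
                "gene_id": gene,
                "tier": "all-sample-consistent" if tier2 else "within-animal-consistent",
                "n_ase_snvs": int(ase_snvs[gene]),
                "n_animals": len(per_animal_local),
                "n_ase_samples": int(len(ase)),
                "known_imprinted": gene in known,
                "per_animal_hap": ";".join(
                    f"{a}={per_animal_canon[a] if per_animal_canon[a] else 'NA'}"
                    for a in sorted(per_animal_local)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "tier",
            "n_ase_snvs",
            "n_animals",
            "n_ase_samples",
            "known_imprinted",
            "per_animal_hap",
        ],
    )
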