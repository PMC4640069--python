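"""Dirichlet multinomial mixture (DMM) metacommunity typing.

Each sample's taxon counts are modelled as a multinomial whose
proportion vector is drawn from one of K component-specific Dirichlet
distributions; integrating the proportions out gives the
Dirichlet-multinomial, which captures the overdispersion of real
community profiles.  Mixtures are fitted by EM (quasi-Newton M-step on
log alpha), the number of metacommunities K is chosen by a Laplace
approximation to the model evidence, and samples are assigned to the
metacommunity with maximal posterior responsibility.

Evidence values are comparable across K only under one prior
configuration: an i.i.d. log-normal prior (mean 0, sd 10 on the log
scale) on every Dirichlet parameter and a uniform (Dirichlet(1)) prior
on the mixture weights.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp, polygamma

from .data_model import CountTable, to_relative
from .ordination import bray_curtis, pam_cluster

__all__ = [
    "DMMModel",
    "MetacommunityAssignment",
    "dm_loglik",
    "fit_dmm",
    "laplace_evidence",
    "select_k",
    "KSelection",
    "assign_metacommunity",
]

#: sd of the log-normal prior on each Dirichlet parameter (log scale)
PRIOR_LOG_SD = 10.0

_trigamma = lambda x: polygamma(1, x)  # noqa: E731


def dm_loglik(counts, alpha, *, log_coef: bool = False) -> np.ndarray:
    """Dirichlet-multinomial log pmf of count vectors under ``alpha``.

    ``counts`` may be a single vector or a (samples x taxa) matrix.  The
    multinomial coefficient is omitted unless ``log_coef=True``: it is
    constant in alpha, hence irrelevant for fitting and for comparing
    components, but needed for the pmf to normalise to one.
    """
    x = np.atleast_2d(np.asarray(counts, dtype=float))
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise ValueError("all Dirichlet parameters must be positive")
    if x.shape[-1] != a.shape[0]:
        raise ValueError("counts and alpha dimension mismatch")
    n = x.sum(axis=-1)
    big_a = a.sum()
    ll = gammaln(big_a) - gammaln(big_a + n)
    ll += (gammaln(x + a) - gammaln(a)).sum(axis=-1)
    if log_coef:
        ll += gammaln(n + 1) - gammaln(x + 1).sum(axis=-1)
    if np.ndim(counts) == 1:
        return float(ll[0])
    return ll


def _log_prior_beta(beta: np.ndarray) -> float:
    """i.i.d. normal log-density of log-alpha entries (mean 0, sd PRIOR_LOG_SD)."""
    s2 = PRIOR_LOG_SD**2
    return float(-0.5 * np.sum(beta**2) / s2
                 - beta.size * np.log(PRIOR_LOG_SD * np.sqrt(2 * np.pi)))


def _component_neg_obj(beta: np.ndarray, X: np.ndarray, w: np.ndarray, n: np.ndarray):
    """Negative penalized weighted DM log-likelihood and gradient in log-alpha."""
    alpha = np.exp(np.clip(beta, -30, 30))
    big_a = alpha.sum()
    ll = float(w @ (gammaln(big_a) - gammaln(big_a + n))
               + w @ (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1))
    ll += _log_prior_beta(beta)
    g = (w @ (digamma(X + alpha) - digamma(alpha))
         + w.sum() * digamma(big_a) - w @ digamma(big_a + n))
    grad = alpha * g - beta / PRIOR_LOG_SD**2
    return -ll, -grad


class _Component:
    """Workspace for one mixture component's M-step."""

    def __init__(self, beta0: np.ndarray):
        self.beta = beta0.copy()

    def maximize(self, X, w, n, maxiter: int) -> None:
        res = minimize(
            _component_neg_obj, self.beta, args=(X, w, n),
            method="L-BFGS-B", jac=True,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        # keep the previous point if the line search stalled below it
        old = _component_neg_obj(self.beta, X, w, n)[0]
        if res.fun <= old:
            self.beta = res.x


@dataclass
class DMMModel:
    """A fitted Dirichlet multinomial mixture."""

    K: int
    weights: np.ndarray  # (K,) mixture weights on the simplex
    alphas: np.ndarray  # (K, n_taxa) positive Dirichlet parameters
    responsibilities: np.ndarray  # (n_samples, K) posterior membership
    taxon_ids: list[str]
    sample_ids: list[str]
    log_evidence: float | None = None
    fit_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.alphas <= 0):
            raise ValueError("Dirichlet parameters must be positive")
        if self.responsibilities.size and not np.allclose(
            self.responsibilities.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("responsibility rows must sum to 1")

    @property
    def converged(self) -> bool:
        return bool(self.fit_log.get("converged", False))

    def hard_labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)

    def component_letters(self) -> list[str]:
        """Letters A, B, ... assigned to components by descending weight."""
        order = np.argsort(-self.weights, kind="stable")
        letters = [""] * self.K
        for rank, comp in enumerate(order):
            letters[comp] = string.ascii_uppercase[rank]
        return letters

    def to_json_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "alphas": self.alphas.tolist(),
            "taxon_ids": self.taxon_ids,
            "log_evidence": self.log_evidence,
            "seed": self.fit_log.get("seed"),
        }


def _mixture_terms(X, n, log_weights, alphas):
    """Per-sample per-component log joint; (n_samples, K)."""
    L = np.stack([dm_loglik(X, a) for a in alphas], axis=1)
    return L + log_weights[np.newaxis, :]


def _init_responsibilities(table, K, restart, rng):
    n = table.n_samples
    if restart == 0 and K > 1:
        # PAM on Bray-Curtis stabilises EM and mirrors the dual
        # (medoid/model-based) framing of the cluster-number analysis
        try:
            dist = bray_curtis(to_relative(table))
            labels = pam_cluster(dist, K, seed=int(rng.integers(2**31))).labels
            R = np.full((n, K), 0.05 / max(K - 1, 1))
            R[np.arange(n), labels] = 0.95
            return R / R.sum(axis=1, keepdims=True)
        except Exception:
            pass
    R = rng.dirichlet(np.full(K, 2.0), size=n)
    return R


def fit_dmm(
    table: CountTable,
    K: int,
    *,
    seed: int | None = None,
    n_restarts: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    mstep_maxiter: int = 30,
) -> DMMModel:
    """Fit a K-component Dirichlet multinomial mixture by EM.

    The E-step computes posterior responsibilities proportional to
    ``pi_k * DM(x_j | alpha_k)``; the M-step updates the weights in
    closed form and maximizes each component's responsibility-weighted
    DM log-likelihood (plus log-prior) over log alpha with L-BFGS.  The
    best of ``n_restarts`` initialisations by final penalized objective
    is returned.  The objective trace is recorded in ``fit_log`` and is
    non-decreasing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > table.n_samples:
        raise ValueError(f"K={K} exceeds number of samples {table.n_samples}")
    X = table.counts.T.astype(float)  # samples x taxa
    n = X.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("zero-depth sample; rarefy/filter first")
    props = X / n[:, np.newaxis]
    rng = np.random.default_rng(seed)

    best = None
    restart_objs = []
    for restart in range(max(1, n_restarts)):
        R = (np.ones((table.n_samples, 1))
             if K == 1 else _init_responsibilities(table, K, restart, rng))
        comps = []
        for k in range(K):
            w = R[:, k]
            p_bar = (w @ props) / w.sum()
            comps.append(_Component(np.log(np.maximum(p_bar, 1e-8) * 50.0)))
        weights = R.mean(axis=0)

        trace = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            for k in range(K):
                comps[k].maximize(X, R[:, k], n,
                                  maxiter=(100 if it == 0 else mstep_maxiter))
            weights = np.maximum(R.mean(axis=0), 1e-12)
            weights = weights / weights.sum()
            alphas = np.exp(np.array([c.beta for c in comps]))
            T = _mixture_terms(X, n, np.log(weights), alphas)
            obj = float(logsumexp(T, axis=1).sum()) + sum(
                _log_prior_beta(c.beta) for c in comps
            ) + float(gammaln(K))
            trace.append(obj)
            R = np.exp(T - logsumexp(T, axis=1, keepdims=True))
            if prev > -np.inf and (obj - prev) < tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = obj
        restart_objs.append(trace[-1])
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], weights, alphas, R, trace, converged)

    obj, weights, alphas, R, trace, converged = best
    if not converged:
        warnings.warn(f"DMM EM (K={K}) did not converge in {max_iter} iterations")
    return DMMModel(
        K=K,
        weights=weights,
        alphas=alphas,
        responsibilities=R,
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        fit_log={
            "iterations": len(trace),
            "converged": converged,
            "seed": seed,
            "objective_trace": trace,
            "restart_objectives": restart_objs,
        },
    )


def _component_neg_hessian(alpha, w, X, n):
    """Negative Hessian (in log-alpha) of the penalized weighted DM loglik.

    Analytic: H = -(diag(alpha^2 h + alpha g - 1/sd^2) + c * alpha alpha^T)
    where g/h are first/second derivative sums and c the shared
    total-concentration curvature term.
    """
    big_a = alpha.sum()
    g = (w @ (digamma(X + alpha) - digamma(alpha))
         + w.sum() * digamma(big_a) - w @ digamma(big_a + n))
    h = w @ (_trigamma(X + alpha) - _trigamma(alpha))
    c = float(w.sum() * _trigamma(big_a) - w @ _trigamma(big_a + n))
    H = -(np.diag(alpha**2 * h + alpha * g - 1.0 / PRIOR_LOG_SD**2)
          + c * np.outer(alpha, alpha))
    return H


def _robust_logdet(H: np.ndarray) -> tuple[float, bool]:
    """log|H| with escalating ridge regularization for non-PD blocks."""
    ridge_flag = False
    scale = float(np.mean(np.abs(np.diag(H)))) or 1.0
    ridge = 0.0
    for _ in range(12):
        sign, logdet = np.linalg.slogdet(H + ridge * np.eye(H.shape[0]))
        if sign > 0:
            return float(logdet), ridge_flag
        ridge_flag = True
        ridge = max(ridge * 10, 1e-8 * scale)
    eigs = np.maximum(np.linalg.eigvalsh(H), 1e-8 * scale)
    return float(np.sum(np.log(eigs))), True


def laplace_evidence(model: DMMModel, table: CountTable) -> float:
    """Laplace approximation to the log model evidence of a fitted DMM.

    log p(data) ~ log-posterior at the mode + (P/2) log 2*pi
    - 0.5 log|H|, with H the negative-log-posterior Hessian approximated
    block-diagonally: one analytic block per component over log alpha
    (responsibility-weighted) plus a finite-difference block for the
    K-1 free mixture weights.  Higher is better; values are comparable
    across K under the fixed prior configuration of this module.
    """
    if model.fit_log and not model.fit_log.get("converged", True):
        warnings.warn("evidence computed on a non-converged model")
    X = table.counts.T.astype(float)
    n = X.sum(axis=1)
    T = _mixture_terms(X, n, np.log(model.weights), model.alphas)
    ll = float(logsumexp(T, axis=1).sum())
    R = np.exp(T - logsumexp(T, axis=1, keepdims=True))

    betas = np.log(model.alphas)
    log_prior = sum(_log_prior_beta(b) for b in betas) + float(gammaln(model.K))

    logdet = 0.0
    flagged = False
    for k in range(model.K):
        H = _component_neg_hessian(model.alphas[k], R[:, k], X, n)
        ld, flag = _robust_logdet(H)
        logdet += ld
        flagged = flagged or flag

    K = model.K
    if K > 1:
        L = T - np.log(model.weights)[np.newaxis, :]  # per-component loglik

        def negll_weights(phi):
            pi = np.append(phi, 1.0 - phi.sum())
            if np.any(pi <= 0):
                return np.inf
            return -float(logsumexp(L + np.log(pi), axis=1).sum())

        phi0 = model.weights[:-1].copy()
        eps = 1e-5
        Hw = np.empty((K - 1, K - 1))
        f0 = negll_weights(phi0)
        for a in range(K - 1):
            for b in range(a, K - 1):
                ea = np.zeros(K - 1); ea[a] = eps
                eb = np.zeros(K - 1); eb[b] = eps
                Hw[a, b] = Hw[b, a] = (
                    negll_weights(phi0 + ea + eb) - negll_weights(phi0 + ea)
                    - negll_weights(phi0 + eb) + f0
                ) / eps**2
        ld, flag = _robust_logdet(Hw)
        logdet += ld
        flagged = flagged or flag

    P = K * model.alphas.shape[1] + (K - 1)
    ev = ll + log_prior + 0.5 * P * np.log(2 * np.pi) - 0.5 * logdet
    if flagged:
        warnings.warn("singular Hessian block ridge-regularized in evidence")
    return float(ev)


@dataclass
class KSelection:
    best_K: int
    models: list[DMMModel]
    evidence: dict[int, float]
    errors: dict[int, str] = field(default_factory=dict)

    @property
    def best_model(self) -> DMMModel:
        return next(m for m in self.models if m.K == self.best_K)


def select_k(
    table: CountTable,
    k_range=range(1, 8),
    *,
    seed: int | None = None,
    n_restarts: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> KSelection:
    """Fit DMMs over a range of K and pick the evidence-optimal one."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    rng = np.random.default_rng(seed)
    models, evidence, errors = [], {}, {}
    for K in k_range:
        sub_seed = int(rng.integers(2**31))
        try:
            m = fit_dmm(table, K, seed=sub_seed, n_restarts=n_restarts,
                        tol=tol, max_iter=max_iter)
            m.log_evidence = laplace_evidence(m, table)
            models.append(m)
            evidence[K] = m.log_evidence
        except Exception as exc:  # skip-and-flag
            errors[K] = str(exc)
    if not evidence:
        raise RuntimeError(f"all K failed: {errors}")
    best_K = max(evidence, key=evidence.get)
    return KSelection(best_K=best_K, models=models, evidence=evidence, errors=errors)


@dataclass
class MetacommunityAssignment:
    sample_ids: list[str]
    labels: list[str]  # letters, by descending mixture weight
    posteriors: np.ndarray  # (n_samples, K), columns in component order
    component_letters: list[str]

    def label_of(self, sample_id: str) -> str:
        return self.labels[self.sample_ids.index(sample_id)]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))


def assign_metacommunity(model: DMMModel, table: CountTable) -> MetacommunityAssignment:
    """Posterior metacommunity assignment of (possibly new) samples.

    Taxa are aligned to the model's taxon list; taxa the table lacks
    are treated as zero counts (with a warning).  Ties in the posterior
    are broken toward the lowest component index.
    """
    overlap = set(model.taxon_ids) & set(table.taxon_ids)
    if not overlap:
        raise ValueError("no overlapping taxa between model and table")
    missing = [t for t in model.taxon_ids if t not in set(table.taxon_ids)]
    if missing:
        warnings.warn(f"{len(missing)} model taxa absent from table; filled with zeros")
    row = {t: i for i, t in enumerate(table.taxon_ids)}
    X = np.zeros((table.n_samples, len(model.taxon_ids)))
    for i, t in enumerate(model.taxon_ids):
        if t in row:
            X[:, i] = table.counts[row[t], :]
    n = X.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("sample with no counts on the model's taxa")
    T = _mixture_terms(X, n, np.log(model.weights), model.alphas)
    post = np.exp(T - logsumexp(T, axis=1, keepdims=True))
    letters = model.component_letters()
    labels = [letters[j] for j in post.argmax(axis=1)]
    return MetacommunityAssignment(
        sample_ids=list(table.sample_ids),
        labels=labels,
        posteriors=post,
        component_letters=letters,
    )
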