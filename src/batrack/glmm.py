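"""Generalized linear mixed models with nested random intercepts, fitted by
Laplace approximation.

This is the same approximation lme4 uses for GLMMs (nAGQ = 1): random
effects are integrated out by a second-order expansion around their
conditional mode. Random effects are spherically reparameterised
(u = sigma * v, v ~ N(0, I)) so variance components may sit exactly at
zero; the inner problem maximises the penalized log-likelihood jointly over
fixed effects and spherical modes by damped Fisher-scoring Newton steps,
and the outer problem maximises the Laplace marginal likelihood over the
random-effect SDs (plus any family auxiliary parameter) with Nelder-Mead.

Families: Poisson (log link), negative binomial NB2 (log link, size k
estimated on the log scale), and Beta regression for continuous proportions
(complementary log-log link, precision phi estimated on the log scale).

Only nested (or crossed) random *intercepts* are supported — exactly the
structure of the block-design analyses here. Hessian blocks for the
indicator random-effect columns are assembled by group-sum cross-
tabulations, so a fit costs O(n) per inner iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["Family", "Poisson", "Gaussian", "NegativeBinomial", "BetaCloglog",
           "GLMMResult", "fit_glmm", "GLMMConvergenceError",
           "DegenerateDataError"]

_CLIP_ETA = 30.0


class GLMMConvergenceError(RuntimeError):
    """The optimizer failed to produce a finite maximum."""


class DegenerateDataError(ValueError):
    """The response carries no information for the requested family."""


class Family:
    """Interface: log-likelihood and its first/expected-second eta-derivatives."""

    name = "family"
    link = "log"
    n_aux = 0

    def loglik(self, y, eta, aux): ...
    def d1(self, y, eta, aux): ...
    def weight(self, y, eta, aux): ...  # expected -d2 (Fisher weights), > 0

    def init_aux(self, y) -> list[float]:
        return []


class Poisson(Family):
    name = "poisson"

    def loglik(self, y, eta, aux):
        eta = np.clip(eta, -_CLIP_ETA, _CLIP_ETA)
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)

    def d1(self, y, eta, aux):
        return y - np.exp(np.clip(eta, -_CLIP_ETA, _CLIP_ETA))

    def weight(self, y, eta, aux):
        return np.exp(np.clip(eta, -_CLIP_ETA, _CLIP_ETA))


class Gaussian(Family):
    """Identity link; aux[0] = log residual SD. Laplace is exact here, so
    this is a full-ML linear mixed model (used where the variance-component
    structure defeats the dedicated LMM routines)."""

    name = "gaussian"
    link = "identity"
    n_aux = 1

    def loglik(self, y, eta, aux):
        s2 = np.exp(2.0 * aux[0])
        return -0.5 * np.log(2.0 * np.pi * s2) - (y - eta) ** 2 / (2.0 * s2)

    def d1(self, y, eta, aux):
        return (y - eta) / np.exp(2.0 * aux[0])

    def weight(self, y, eta, aux):
        return np.full_like(np.asarray(y, dtype=float),
                            1.0 / np.exp(2.0 * aux[0]))

    def init_aux(self, y):
        sd = float(np.std(y))
        if sd <= 0:
            raise DegenerateDataError("response variance is zero")
        return [float(np.log(sd))]


class NegativeBinomial(Family):
    """NB2: var = mu + mu^2 / k; aux[0] = log k."""

    name = "negative_binomial"
    n_aux = 1

    def loglik(self, y, eta, aux):
        k = np.exp(aux[0])
        eta = np.clip(eta, -_CLIP_ETA, _CLIP_ETA)
        mu = np.exp(eta)
        return (special.gammaln(y + k) - special.gammaln(k)
                - special.gammaln(y + 1.0)
                + k * np.log(k / (k + mu)) + y * (eta - np.log(k + mu)))

    def d1(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -_CLIP_ETA, _CLIP_ETA))
        return y - (y + k) * mu / (k + mu)

    def weight(self, y, eta, aux):
        k = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -_CLIP_ETA, _CLIP_ETA))
        return k * mu / (k + mu)

    def init_aux(self, y):
        m, v = np.mean(y), np.var(y)
        k = m ** 2 / max(v - m, 1e-3)
        return [float(np.log(np.clip(k, 0.05, 100.0)))]


class BetaCloglog(Family):
    """Beta regression on (0, 1) with cloglog link; aux[0] = log precision."""

    name = "beta"
    link = "cloglog"
    n_aux = 1

    @staticmethod
    def _mu(eta):
        eta = np.clip(eta, -_CLIP_ETA, 3.0)
        mu = 1.0 - np.exp(-np.exp(eta))
        return np.clip(mu, 1e-10, 1.0 - 1e-10)

    def loglik(self, y, eta, aux):
        phi = np.exp(aux[0])
        mu = self._mu(eta)
        return (special.gammaln(phi) - special.gammaln(mu * phi)
                - special.gammaln((1.0 - mu) * phi)
                + (mu * phi - 1.0) * np.log(y)
                + ((1.0 - mu) * phi - 1.0) * np.log1p(-y))

    def _dmu_deta(self, eta):
        eta = np.clip(eta, -_CLIP_ETA, 3.0)
        return np.exp(eta - np.exp(eta))

    def d1(self, y, eta, aux):
        phi = np.exp(aux[0])
        mu = self._mu(eta)
        score_mu = phi * (np.log(y) - np.log1p(-y)
                          - special.digamma(mu * phi)
                          + special.digamma((1.0 - mu) * phi))
        return score_mu * self._dmu_deta(eta)

    def weight(self, y, eta, aux):
        phi = np.exp(aux[0])
        mu = self._mu(eta)
        info_mu = phi ** 2 * (special.polygamma(1, mu * phi)
                              + special.polygamma(1, (1.0 - mu) * phi))
        return info_mu * self._dmu_deta(eta) ** 2 + 1e-10

    def init_aux(self, y):
        m, v = np.mean(y), np.var(y)
        if v <= 0:
            raise DegenerateDataError(
                "response variance is zero; beta model precision is unbounded")
        phi = m * (1.0 - m) / v - 1.0
        return [float(np.log(np.clip(phi, 0.5, 500.0)))]


@dataclass
class GLMMResult:
    """A fitted GLMM: fixed effects, variance components, marginal loglik."""

    family: str
    link: str
    fe_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigmas: dict[str, float]       # random-intercept SDs (linear-predictor scale)
    aux: dict[str, float]
    loglik: float
    n: int
    k_params: int
    converged: bool
    n_inner_fail: int = 0
    fitted_eta: np.ndarray | None = None  # conditional on the random-effect modes

    def fixed_table(self) -> pd.DataFrame:
        z = self.beta / np.where(self.se > 0, self.se, np.nan)
        return pd.DataFrame({"term": self.fe_names, "estimate": self.beta,
                             "se": self.se, "z": z})

    def random_table(self) -> pd.DataFrame:
        var = {g: s ** 2 for g, s in self.sigmas.items()}
        total = sum(var.values())
        rows = [(g, v, np.sqrt(v), 100.0 * v / total if total > 0 else np.nan)
                for g, v in var.items()]
        return pd.DataFrame(rows, columns=["group", "variance", "sd",
                                           "pct_of_total"])


def _group_codes(labels) -> tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(int), len(uniq)


def fit_glmm(y, X, groups: dict[str, np.ndarray], family: Family,
             fe_names: list[str] | None = None,
             start_sigma: float = 0.3, max_outer: int = 400,
             tol: float = 1e-7) -> GLMMResult:
    """Fit a GLMM with random intercepts for each factor in ``groups``.

    ``X`` is the fixed-effects design (n, p) including the intercept column;
    ``groups`` maps factor name -> length-n label array. Raises
    :class:`GLMMConvergenceError` if the outer optimizer cannot find a
    finite optimum, and :class:`DegenerateDataError` for responses the
    family cannot fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(p)]
    gnames = list(groups)
    codes = {}
    sizes = {}
    for g in gnames:
        c, q = _group_codes(groups[g])
        codes[g], sizes[g] = c, q
    offsets = {}
    q_total = 0
    for g in gnames:
        offsets[g] = q_total
        q_total += sizes[g]

    aux0 = family.init_aux(y)
    n_aux = len(aux0)
    state = {"beta": np.zeros(p), "v": np.zeros(q_total), "fail": 0}
    # crude intercept start on the link scale
    if family.name in ("poisson", "negative_binomial"):
        state["beta"][0] = np.log(max(np.mean(y), 0.05))
    elif family.name == "gaussian":
        state["beta"][0] = float(np.mean(y))
    else:
        state["beta"][0] = np.log(-np.log1p(-np.clip(np.mean(y), 1e-4, 1 - 1e-4)))

    def eta_of(beta, v, sig):
        eta = X @ beta
        for g in gnames:
            eta = eta + sig[g] * v[offsets[g]: offsets[g] + sizes[g]][codes[g]]
        return eta

    def penalized(beta, v, sig, aux):
        return float(np.sum(family.loglik(y, eta_of(beta, v, sig), aux))
                     - 0.5 * np.dot(v, v))

    def inner(sig, aux):
        """Mode of the penalized loglik over (beta, v); returns mode + pieces."""
        beta = state["beta"].copy()
        v = state["v"].copy()
        obj = penalized(beta, v, sig, aux)
        for _ in range(60):
            eta = eta_of(beta, v, sig)
            d1 = family.d1(y, eta, aux)
            w = np.clip(family.weight(y, eta, aux), 1e-12, None)
            # gradient
            gb = X.T @ d1
            gv = np.empty(q_total)
            for g in gnames:
                gv[offsets[g]: offsets[g] + sizes[g]] = (
                    sig[g] * np.bincount(codes[g], weights=d1, minlength=sizes[g]))
            gv -= v
            grad = np.concatenate([gb, gv])
            # Hessian blocks via group sums
            H = np.zeros((p + q_total, p + q_total))
            Xw = X * w[:, None]
            H[:p, :p] = X.T @ Xw
            for g in gnames:
                og, qg = offsets[g], sizes[g]
                for j in range(p):
                    H[j, p + og: p + og + qg] = sig[g] * np.bincount(
                        codes[g], weights=Xw[:, j], minlength=qg)
                H[p + og: p + og + qg, :p] = H[:p, p + og: p + og + qg].T
                for h in gnames:
                    oh, qh = offsets[h], sizes[h]
                    if g == h:
                        np.fill_diagonal(
                            H[p + og: p + og + qg, p + og: p + og + qg],
                            sig[g] ** 2 * np.bincount(codes[g], weights=w,
                                                      minlength=qg))
                    else:
                        flat = codes[g] * qh + codes[h]
                        ct = np.bincount(flat, weights=w, minlength=qg * qh)
                        H[p + og: p + og + qg, p + oh: p + oh + qh] = (
                            sig[g] * sig[h] * ct.reshape(qg, qh))
            H[p:, p:] += np.eye(q_total)
            H[:p, :p] += 1e-10 * np.eye(p)
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, grad, rcond=None)[0]
            step = 1.0
            improved = False
            for _ls in range(25):
                nb = beta + step * delta[:p]
                nv = v + step * delta[p:]
                nobj = penalized(nb, nv, sig, aux)
                if np.isfinite(nobj) and nobj >= obj - 1e-12:
                    improved = nobj > obj + tol * (1.0 + abs(obj))
                    beta, v, obj = nb, nv, nobj
                    break
                step *= 0.5
            else:
                break
            if not improved:
                break
        state["beta"], state["v"] = beta.copy(), v.copy()
        # log-determinant of the v-block of the (Fisher) Hessian at the mode
        eta = eta_of(beta, v, sig)
        w = np.clip(family.weight(y, eta, aux), 1e-12, None)
        Hv = np.zeros((q_total, q_total))
        for g in gnames:
            og, qg = offsets[g], sizes[g]
            for h in gnames:
                oh, qh = offsets[h], sizes[h]
                if g == h:
                    np.fill_diagonal(Hv[og: og + qg, og: og + qg],
                                     sig[g] ** 2 * np.bincount(
                                         codes[g], weights=w, minlength=qg))
                else:
                    flat = codes[g] * qh + codes[h]
                    ct = np.bincount(flat, weights=w, minlength=qg * qh)
                    Hv[og: og + qg, oh: oh + qh] = sig[g] * sig[h] * ct.reshape(qg, qh)
        Hv += np.eye(q_total)
        sign, logdet = np.linalg.slogdet(Hv)
        if sign <= 0:
            return None
        ll = (float(np.sum(family.loglik(y, eta, aux)))
              - 0.5 * float(np.dot(v, v)) - 0.5 * logdet)
        return ll, beta, v

    def neg_marginal(theta):
        sig = {g: abs(theta[i]) for i, g in enumerate(gnames)}
        aux = list(theta[len(gnames):])
        res = inner(sig, aux)
        if res is None:
            state["fail"] += 1
            return 1e12
        return -res[0]

    theta0 = np.array([start_sigma] * len(gnames) + aux0)
    if len(theta0):
        sol = optimize.minimize(neg_marginal, theta0, method="Nelder-Mead",
                                options={"maxiter": max_outer, "xatol": 1e-4,
                                         "fatol": 1e-6})
        theta = sol.x
        converged = bool(sol.success) or sol.fun < 1e11
        if not np.isfinite(sol.fun) or sol.fun >= 1e11:
            raise GLMMConvergenceError(
                f"outer optimizer failed: {getattr(sol, 'message', '')}")
    else:
        theta = theta0
        converged = True

    sig = {g: abs(theta[i]) for i, g in enumerate(gnames)}
    aux = list(theta[len(gnames):])
    res = inner(sig, aux)
    if res is None:
        raise GLMMConvergenceError("final inner mode finding failed")
    ll, beta, v = res

    # fixed-effect covariance from the full Fisher information at the mode
    eta = eta_of(beta, v, sig)
    w = np.clip(family.weight(y, eta, aux), 1e-12, None)
    Xw = X * w[:, None]
    H = np.zeros((p + q_total, p + q_total))
    H[:p, :p] = X.T @ Xw
    for g in gnames:
        og, qg = offsets[g], sizes[g]
        blk = np.zeros((p, qg))
        for j in range(p):
            blk[j] = sig[g] * np.bincount(codes[g], weights=Xw[:, j], minlength=qg)
        H[:p, p + og: p + og + qg] = blk
        H[p + og: p + og + qg, :p] = blk.T
        for h in gnames:
            oh, qh = offsets[h], sizes[h]
            if g == h:
                np.fill_diagonal(H[p + og: p + og + qg, p + og: p + og + qg],
                                 sig[g] ** 2 * np.bincount(codes[g], weights=w,
                                                           minlength=qg))
            else:
                flat = codes[g] * qh + codes[h]
                ct = np.bincount(flat, weights=w, minlength=qg * qh)
                H[p + og: p + og + qg, p + oh: p + oh + qh] = (
                    sig[g] * sig[h] * ct.reshape(qg, qh))
    H[p:, p:] += np.eye(q_total)
    try:
        cov = np.linalg.inv(H)[:p, :p]
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    aux_names = {"negative_binomial": ["log_size"], "beta": ["log_precision"],
                 "gaussian": ["log_sd"]}
    auxd = dict(zip(aux_names.get(family.name, []), aux))
    k_params = p + len(gnames) + len(aux)
    return GLMMResult(family=family.name, link=family.link, fe_names=fe_names,
                      beta=beta, se=se, sigmas=sig, aux=auxd, loglik=ll,
                      n=n, k_params=k_params, converged=converged,
                      n_inner_fail=state["fail"], fitted_eta=eta)
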