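"""Longitudinal count models for differential phylotype abundance.

Each phylotype's read counts are modelled one at a time as a function of
study group with a subject-level random intercept and the log total reads
of the sample as offset, so the group coefficient beta1 is a difference in
mean log *relative* abundance.  Three families are fitted:

* PLME    — Poisson linear mixed effects;
* NBLME   — negative binomial (NB2, mean/size) linear mixed effects;
* ZINBLME — zero-inflated NB mixed effects, with a free zero-inflation
  probability pi (intercept-only on the logit scale) and the random
  intercept entering only the NB mean:

      f_ZID(y) = pi * I(y = 0) + (1 - pi) * f_NB(y).

The marginal likelihood integrates the Normal(0, sigma_b^2) random
intercept out by adaptive Gauss-Hermite quadrature (default 15 nodes,
recentred per subject at the conditional mode).  The family with the lowest
AIC is retained per phylotype and only that family's Wald p-value is
reported; p-values are BH-adjusted across phylotypes, and a phylotype is
called significant when q < 0.1 and |fold change| > 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gee import bh_fdr
from .tables import CountTable, prevalence_filter

__all__ = ["CountModelFit", "zinb_pmf", "fit_count_model", "select_best_model",
           "fold_change", "differential_abundance", "FAMILIES"]

FAMILIES = ("PLME", "NBLME", "ZINBLME")
_N_PARAMS = {"PLME": 3, "NBLME": 4, "ZINBLME": 5}
_COMPLEXITY = {"PLME": 0, "NBLME": 1, "ZINBLME": 2}


# ---------------------------------------------------------------------------
# probability kernels
# ---------------------------------------------------------------------------

def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 log pmf with mean ``mu`` and size ``theta``."""
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu), out=np.zeros_like(mu), where=y > 0))


def zinb_pmf(y, mu, theta: float, pi: float) -> np.ndarray | float:
    """Zero-inflated negative binomial probability mass.

    P(0) = pi + (1 - pi) f_NB(0); P(y > 0) = (1 - pi) f_NB(y), with the NB
    in mean/size (NB2) parameterisation.  ``pi = 0`` recovers the plain NB.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), y_arr.shape).copy()
    if np.any(mu_arr <= 0) or theta <= 0 or not 0 <= pi < 1:
        raise ValueError("require mu > 0, theta > 0, pi in [0, 1)")
    base = np.exp(_nb_logpmf(y_arr, mu_arr, theta))
    out = (1.0 - pi) * base
    out[y_arr == 0] += pi
    return out if np.ndim(y) else float(out[0])


# ---------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class _MarginalLoglik:
    """Marginal log-likelihood of one family on one phylotype's data.

    Observations are sorted by subject; per-subject conditional modes of the
    random intercept are cached and warm-started between calls so the
    adaptive recentring costs only a few damped Newton steps per evaluation.
    """

    def __init__(self, y, x, subject, offset, family: str, n_nodes: int = 15):
        order = np.argsort(subject, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.x = np.asarray(x, dtype=float)[order]
        self.offset = np.asarray(offset, dtype=float)[order]
        subj = np.asarray(subject)[order]
        _, self.subj_idx = np.unique(subj, return_inverse=True)
        self.n_subjects = self.subj_idx.max() + 1
        self.family = family
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        self.z = nodes
        self.logw = np.log(weights)
        self._bhat = np.zeros(self.n_subjects)

    # conditional (per-subject) log joint h_i(b) = sum_j log f(y_ij|b) + log phi(b)
    def _h(self, b_per_subject: np.ndarray, params: dict) -> np.ndarray:
        b = b_per_subject[self.subj_idx]
        eta = params["beta0"] + params["beta1"] * self.x + self.offset + b
        mu = np.exp(np.clip(eta, -500, 500))
        if self.family == "PLME":
            ll = self.y * eta - mu - special.gammaln(self.y + 1.0)
        else:
            ll = _nb_logpmf(self.y, mu, params["theta"])
            if self.family == "ZINBLME":
                pi = params["pi"]
                is0 = self.y == 0
                ll = np.where(is0,
                              np.logaddexp(np.log(pi), np.log1p(-pi) + ll),
                              np.log1p(-pi) + ll)
        per_subject = np.bincount(self.subj_idx, weights=ll,
                                  minlength=self.n_subjects)
        sigma = params["sigma_b"]
        prior = -0.5 * (b_per_subject / sigma) ** 2 - np.log(sigma) \
            - 0.5 * np.log(2.0 * np.pi)
        return per_subject + prior

    def _recenter(self, params: dict, eps: float = 1e-4, n_iter: int = 12
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Damped Newton search for the per-subject mode and curvature of h."""
        b = self._bhat.copy()
        for _ in range(n_iter):
            h0 = self._h(b, params)
            hp = self._h(b + eps, params)
            hm = self._h(b - eps, params)
            grad = (hp - hm) / (2.0 * eps)
            curv = (hp - 2.0 * h0 + hm) / eps**2
            curv = np.minimum(curv, -1e-8)  # keep steps downhill-safe
            step = np.clip(-grad / curv, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-8:
                break
        hp = self._h(b + eps, params)
        hm = self._h(b - eps, params)
        h0 = self._h(b, params)
        curv = np.minimum((hp - 2.0 * h0 + hm) / eps**2, -1e-8)
        self._bhat = b
        return b, 1.0 / np.sqrt(-curv)

    def _unpack(self, theta_vec: np.ndarray) -> dict:
        params = {"beta0": theta_vec[0], "beta1": theta_vec[1],
                  "sigma_b": float(np.exp(np.clip(theta_vec[2], -12, 6)))}
        if self.family in ("NBLME", "ZINBLME"):
            params["theta"] = float(np.exp(np.clip(theta_vec[3], -8, 12)))
        if self.family == "ZINBLME":
            params["pi"] = float(special.expit(np.clip(theta_vec[4], -30, 30)))
            params["pi"] = min(max(params["pi"], 1e-12), 1 - 1e-12)
        return params

    def __call__(self, theta_vec: np.ndarray) -> float:
        params = self._unpack(theta_vec)
        bhat, scale = self._recenter(params)
        # integral of exp(h) via GH nodes recentred at the mode
        node_h = np.empty((len(self.z), self.n_subjects))
        for k, zk in enumerate(self.z):
            node_h[k] = self._h(bhat + np.sqrt(2.0) * scale * zk, params)
        log_integrand = self.logw[:, None] + self.z[:, None] ** 2 + node_h
        log_li = np.log(np.sqrt(2.0) * scale) + special.logsumexp(log_integrand, axis=0)
        return float(np.sum(log_li))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class CountModelFit:
    """One fitted count mixed model for one phylotype."""

    family: str
    beta1: float
    ci_lower: float
    ci_upper: float
    se: float
    p_value: float
    sigma_b: float
    theta: float | None
    pi: float | None
    loglik: float
    aic: float
    converged: bool
    n_params: int
    message: str = ""

    @property
    def fold(self) -> float:
        return fold_change(self.beta1)


def _start_values(y, x, offset, family: str) -> np.ndarray:
    rate = max(y.sum() / np.exp(offset).sum(), 1e-8)
    beta0 = np.log(rate)
    in1, in0 = x > 0.5, x <= 0.5
    r1 = y[in1].sum() / max(np.exp(offset[in1]).sum(), 1e-12)
    r0 = y[in0].sum() / max(np.exp(offset[in0]).sum(), 1e-12)
    beta1 = np.log(max(r1, 1e-8)) - np.log(max(r0, 1e-8))
    start = [beta0, np.clip(beta1, -8, 8), np.log(0.7)]
    if family in ("NBLME", "ZINBLME"):
        start.append(np.log(1.0))
    if family == "ZINBLME":
        start.append(special.logit(0.1))
    return np.asarray(start)


def fit_count_model(y, group, subject, offset, family: str,
                    n_nodes: int = 15, n_restarts: int = 3,
                    seed: int = 0) -> CountModelFit:
    """Maximum-likelihood fit of one family to one phylotype's counts.

    ``offset`` is the log total reads per sample.  The optimiser is a
    bounded quasi-Newton (L-BFGS-B) run from a moment-based start plus
    jittered restarts; the fit is flagged unconverged (AIC = NaN) when no
    restart succeeds or the restart log-likelihoods disagree.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(group, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite (zero-total samples?)")
    if len(np.unique(np.asarray(subject))) < 2:
        raise ValueError("need at least 2 subjects")

    loglik = _MarginalLoglik(y, x, subject, offset, family, n_nodes)
    nll = lambda v: -loglik(v)
    start = _start_values(y, x, offset, family)
    rng = np.random.default_rng(seed)

    best, logliks = None, []
    for r in range(max(n_restarts, 1)):
        v0 = start if r == 0 else start + rng.normal(0.0, 0.3, size=start.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, v0, method="L-BFGS-B",
                                    options={"maxiter": 300, "ftol": 1e-10})
        if np.isfinite(res.fun):
            logliks.append(-res.fun)
            if best is None or res.fun < best.fun - 1e-12:
                best = res

    k = _N_PARAMS[family]
    if best is None:
        return CountModelFit(family, np.nan, np.nan, np.nan, np.nan, np.nan,
                             np.nan, None, None, np.nan, np.nan, False, k,
                             message="all restarts failed")
    logliks = sorted(logliks, reverse=True)
    agree = len(logliks) < 2 or (logliks[0] - logliks[1]) < 1e-3 * max(1, abs(logliks[0]))
    converged = bool(best.success) and agree

    params = loglik._unpack(best.x)
    ll = -best.fun
    se = _wald_se(nll, best.x, index=1)
    beta1 = params["beta1"]
    zcrit = stats.norm.ppf(0.975)
    if np.isfinite(se) and se > 0:
        ci = (beta1 - zcrit * se, beta1 + zcrit * se)
        p = 2.0 * stats.norm.sf(abs(beta1) / se)
    else:
        ci, p, converged = (np.nan, np.nan), np.nan, False
    return CountModelFit(
        family=family, beta1=float(beta1), ci_lower=float(ci[0]),
        ci_upper=float(ci[1]), se=float(se), p_value=float(p),
        sigma_b=params["sigma_b"], theta=params.get("theta"),
        pi=params.get("pi"), loglik=float(ll),
        aic=float(2 * k - 2 * ll) if converged else float("nan"),
        converged=converged, n_params=k,
        message="" if converged else "optimiser restarts disagree or failed")


def _wald_se(nll, x_opt: np.ndarray, index: int) -> float:
    """Standard error from the observed information (central differences)."""
    n = len(x_opt)
    h = 1e-4 * np.maximum(np.abs(x_opt), 1.0)
    hess = np.zeros((n, n))
    f0 = nll(x_opt)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                fpp = nll(x_opt + ei); fmm = nll(x_opt - ei)
                hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            else:
                fpp = nll(x_opt + ei + ej); fpm = nll(x_opt + ei - ej)
                fmp = nll(x_opt - ei + ej); fmm = nll(x_opt - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        var = cov[index, index]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def select_best_model(fits: dict[str, CountModelFit] | list[CountModelFit]
                      ) -> CountModelFit:
    """Retain the converged fit with minimal AIC.

    Exact ties prefer the simpler family (PLME over NBLME over ZINBLME).
    Raises if no fit converged.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    usable = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not usable:
        raise ValueError("no converged fit to select from")
    return min(usable, key=lambda f: (f.aic, _COMPLEXITY[f.family]))


def fold_change(beta: float) -> float:
    """Signed fold change: exp(beta) for beta >= 0, -exp(-beta) otherwise.

    Depleted taxa thus print negative folds (e.g. beta = -0.726 -> -2.1).
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(beta)) if beta >= 0 else float(-np.exp(-beta))


# ---------------------------------------------------------------------------
# per-phylotype screen
# ---------------------------------------------------------------------------

def differential_abundance(table: CountTable, min_prevalence: float = 0.25,
                           q_cut: float = 0.1, fc_cut: float = 1.5,
                           n_nodes: int = 15, n_restarts: int = 3,
                           seed: int = 0) -> pd.DataFrame:
    """Fit PLME/NBLME/ZINBLME to every prevalent phylotype and screen by FDR.

    Returns a DataFrame indexed by phylotype with the three AICs, the best
    family, its estimate, 95% CI, signed fold change, p and BH q-value, and
    a significance flag (q < ``q_cut`` and |fold| > ``fc_cut``).  A failing
    phylotype is flagged, never fatal.
    """
    taxa = prevalence_filter(table, min_prevalence)
    x = (table.metadata["group"] == "pregnant").astype(float).to_numpy()
    subject = table.metadata["subject_id"].to_numpy()
    offset = np.log(table.totals.to_numpy(dtype=float))

    rows = []
    for taxon in taxa:
        y = table.counts[taxon].to_numpy(dtype=float)
        fits = {}
        for family in FAMILIES:
            try:
                fits[family] = fit_count_model(y, x, subject, offset, family,
                                               n_nodes=n_nodes,
                                               n_restarts=n_restarts, seed=seed)
            except Exception as exc:  # noqa: BLE001 - per-phylotype isolation
                fits[family] = CountModelFit(family, np.nan, np.nan, np.nan,
                                             np.nan, np.nan, np.nan, None, None,
                                             np.nan, np.nan, False,
                                             _N_PARAMS[family], message=str(exc))
        row = {f"{fam}_aic": fits[fam].aic for fam in FAMILIES}
        try:
            best = select_best_model(fits)
            row.update(best_model=best.family, estimate=best.beta1,
                       ci_lower=best.ci_lower, ci_upper=best.ci_upper,
                       fold_change=best.fold, p_value=best.p_value,
                       converged=True, message="")
        except ValueError:
            row.update(best_model="none", estimate=np.nan, ci_lower=np.nan,
                       ci_upper=np.nan, fold_change=np.nan, p_value=np.nan,
                       converged=False,
                       message="; ".join(f.message for f in fits.values() if f.message))
        rows.append(pd.Series(row, name=taxon))

    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = bh_fdr(out.loc[ok, "p_value"].to_numpy()).q_values
    out["significant"] = (out["q_value"] < q_cut) & (out["fold_change"].abs() > fc_cut)
    return out
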