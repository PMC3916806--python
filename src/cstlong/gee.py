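"""Marginal (GEE) models for clustered responses and FDR utilities.

Within-subject correlation of longitudinal samples rules out ordinary
contingency-table tests for CST frequencies.  Instead, each CST is screened
one at a time: the binary indicator "sample belongs to this CST" is
regressed on group with a binomial GEE, exchangeable working correlation
and robust sandwich variance; the group coefficient is a log odds ratio and
its Wald test gives the p-value.  P-values across CSTs are
Benjamini-Hochberg adjusted and screened at q < 0.05.

The same machinery tests the association between a high Nugent score
(>= 7, the research threshold for bacterial vaginosis) and CST IV-B
membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["GEEResult", "FDRResult", "fit_binomial_gee", "cst_gee_screen",
           "nugent_association", "bh_fdr"]


@dataclass
class GEEResult:
    """One fitted GEE contrast: coefficient, robust SE, Wald test, odds ratio."""

    coefficient: float
    robust_se: float
    wald_z: float
    p_value: float
    odds_ratio: float | None
    n_clusters: int
    n_obs: int
    converged: bool
    fold: float | None = None
    message: str = ""

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _gee_result_from_fit(res, coef_index: int = 1, binomial: bool = False) -> GEEResult:
    coef = float(res.params[coef_index])
    se = float(res.bse[coef_index])
    z = coef / se if se > 0 else np.nan
    p = float(res.pvalues[coef_index])
    return GEEResult(
        coefficient=coef,
        robust_se=se,
        wald_z=float(z),
        p_value=p,
        odds_ratio=float(np.exp(coef)) if binomial else None,
        n_clusters=len(np.unique(res.model.groups)),
        n_obs=int(res.nobs),
        converged=bool(getattr(res, "converged", True)),
    )


def fit_binomial_gee(y, x, cluster) -> GEEResult:
    """Binomial GEE of a binary response on a single indicator covariate.

    Exchangeable working correlation within clusters; robust covariance.
    With one observation per cluster this reduces to ordinary logistic
    regression.  Separation or non-convergence yields a flagged result
    (``converged=False``) rather than a silent estimate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cluster = np.asarray(cluster)
    if y.shape != x.shape or y.shape != cluster.shape:
        raise ValueError("y, x and cluster must have equal length")
    if len(np.unique(cluster)) < 2:
        raise ValueError("need at least 2 clusters")
    if len(np.unique(y)) < 2:
        raise ValueError("response is constant")
    exog = sm.add_constant(x)
    # quasi-separation: a cell of the 2x2 table is empty
    tab = pd.crosstab(y, x)
    separated = tab.shape != (2, 2) or (tab.to_numpy() == 0).any()
    try:
        model = sm.GEE(y, exog, groups=cluster, family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit(maxiter=100)
        out = _gee_result_from_fit(res, coef_index=1, binomial=True)
    except Exception as exc:  # noqa: BLE001 - surfaced via the flag
        return GEEResult(np.nan, np.nan, np.nan, np.nan, None,
                         len(np.unique(cluster)), len(y), converged=False,
                         message=f"fit failed: {exc}")
    if separated:
        out.converged = False
        out.message = "separation: empty cell in response x group table"
    return out


@dataclass
class FDRResult:
    """Benjamini-Hochberg adjusted p-values with a significance threshold."""

    p_values: np.ndarray
    q_values: np.ndarray
    threshold: float
    significant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p_value": self.p_values, "q_value": self.q_values,
                             "significant": self.significant})


def bh_fdr(p_values, threshold: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRResult(p, p.copy(), threshold, np.zeros(0, dtype=bool))
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=threshold, method="fdr_bh")
    return FDRResult(p, q, threshold, q < threshold)


def cst_gee_screen(labels, groups, subjects, q_threshold: float = 0.05) -> pd.DataFrame:
    """One binomial GEE per CST (indicator vs. rest), BH-adjusted across CSTs.

    Returns a DataFrame indexed by CST with columns estimate, odds_ratio,
    robust_se, p_value, q_value, significant, converged — the layout of a
    CST-frequency association table.  Unconverged fits keep NaN p-values and
    are excluded from the BH adjustment.
    """
    labels = pd.Series(list(labels))
    groups = np.asarray(list(groups))
    subjects = np.asarray(list(subjects))
    csts = sorted(labels.unique())
    if len(csts) < 2:
        raise ValueError("need at least 2 CSTs for a screen")
    x = (groups == "pregnant").astype(float)

    rows = {}
    for cst in csts:
        y = (labels == cst).astype(float).to_numpy()
        try:
            rows[cst] = fit_binomial_gee(y, x, subjects)
        except ValueError as exc:
            rows[cst] = GEEResult(np.nan, np.nan, np.nan, np.nan, None,
                                  len(np.unique(subjects)), len(y),
                                  converged=False, message=str(exc))
    out = pd.DataFrame({
        "estimate": {c: r.coefficient for c, r in rows.items()},
        "odds_ratio": {c: r.odds_ratio for c, r in rows.items()},
        "robust_se": {c: r.robust_se for c, r in rows.items()},
        "p_value": {c: r.p_value for c, r in rows.items()},
        "converged": {c: r.converged for c, r in rows.items()},
        "message": {c: r.message for c, r in rows.items()},
    })
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        fdr = bh_fdr(out.loc[ok, "p_value"].to_numpy(), threshold=q_threshold)
        out.loc[ok, "q_value"] = fdr.q_values
    out["significant"] = out["q_value"] < q_threshold
    return out.sort_values("p_value")


def nugent_association(labels, nugent_scores, subjects,
                       high_cutoff: int = 7) -> GEEResult:
    """Association of high Nugent score (>= cutoff) with CST IV-B membership.

    Binomial GEE of the high-Nugent indicator on IV-B membership with
    subject clustering; a score of exactly ``high_cutoff`` counts as high.
    Degenerate inputs (no high-Nugent samples) yield a flagged result.
    """
    labels = pd.Series(list(labels))
    scores = np.asarray(list(nugent_scores), dtype=float)
    subjects = np.asarray(list(subjects))
    y = (scores >= high_cutoff).astype(float)
    x = (labels == "IV-B").astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        return GEEResult(np.nan, np.nan, np.nan, np.nan, None,
                         len(np.unique(subjects)), len(y), converged=False,
                         message="degenerate: high-Nugent indicator is constant")
    if x.sum() == 0:
        return GEEResult(np.nan, np.nan, np.nan, np.nan, None,
                         len(np.unique(subjects)), len(y), converged=False,
                         message="degenerate: no IV-B samples")
    return fit_binomial_gee(y, x, subjects)
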