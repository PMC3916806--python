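"""Community stability statistics and their group contrasts.

Two per-sample statistics quantify longitudinal behaviour:

* ``d_subject_mean`` — JS distance between each community state and the mean
  community state of its subject (elementwise mean relative abundance over
  the subject's samples).  Larger values mean a less stable community.
* ``d_cst4`` — JS distance between each community state and the pooled
  centroid of all samples assigned to CST IV-A or IV-B.  Larger values mean
  the community sits further from the anaerobe-dominated states.

Each statistic is compared between groups on the natural-log scale with a
Gaussian GEE (identity link, exchangeable within-subject correlation,
robust sandwich variance); the contrast is reported as a difference in mean
log distance together with its fold equivalent exp(|difference|).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .divergence import js_distance
from .tables import CountTable, to_relative_abundance
from .gee import GEEResult, _gee_result_from_fit

__all__ = ["subject_mean_state", "instability_distances", "cst4_centroid_distance",
           "stability_table", "stability_contrast"]

LOG_FLOOR = 1e-6  # distances identical to the reference are floored before log


def subject_mean_state(states: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Elementwise mean of a subject's community states (a valid state itself)."""
    arr = np.asarray(states, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise ValueError("no states supplied")
    mean = arr.mean(axis=0)
    return mean / mean.sum()


def _log_distance(d: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(d, LOG_FLOOR))


def instability_distances(table: CountTable, log_base: float = 2.0) -> pd.DataFrame:
    """Per-sample JS distance to the subject's own mean community state.

    Subjects with a single sample get distance 0 and are flagged in the
    ``single_sample`` column.
    """
    states = to_relative_abundance(table)
    meta = table.metadata
    rows = []
    for subject, idx in states.groupby(meta["subject_id"]).groups.items():
        sub = states.loc[idx]
        mean = subject_mean_state(sub)
        single = len(idx) < 2
        for sid in idx:
            d = 0.0 if single else js_distance(sub.loc[sid].to_numpy(), mean, log_base)
            rows.append((sid, subject, meta.loc[sid, "group"], d, single))
    out = pd.DataFrame(rows, columns=["sample_id", "subject_id", "group",
                                      "d_subject_mean", "single_sample"])
    out = out.set_index("sample_id").loc[table.sample_ids]
    out["log_d_subject_mean"] = _log_distance(out["d_subject_mean"].to_numpy())
    return out


def cst4_centroid_distance(table: CountTable, cst_labels: pd.Series,
                           log_base: float = 2.0) -> pd.DataFrame:
    """Per-sample JS distance to the pooled CST IV-A/IV-B centroid.

    The centroid is the elementwise mean state over all samples labelled
    IV-A or IV-B, both study groups pooled.  Raises if no such samples
    exist (supply a reference centroid by relabelling in that case).
    """
    states = to_relative_abundance(table)
    labels = pd.Series(cst_labels).reindex(states.index)
    iv_mask = labels.isin(["IV-A", "IV-B"])
    if not iv_mask.any():
        raise ValueError("no samples labelled IV-A or IV-B; supply a reference centroid")
    centroid = subject_mean_state(states.loc[iv_mask])
    d = np.array([js_distance(states.loc[sid].to_numpy(), centroid, log_base)
                  for sid in states.index])
    out = pd.DataFrame({
        "subject_id": table.metadata["subject_id"],
        "group": table.metadata["group"],
        "d_cst4": d,
    }, index=states.index)
    out["log_d_cst4"] = _log_distance(d)
    return out


def stability_table(table: CountTable, cst_labels: pd.Series,
                    log_base: float = 2.0) -> pd.DataFrame:
    """Both stability statistics (and their logs) in one per-sample table."""
    a = instability_distances(table, log_base)
    b = cst4_centroid_distance(table, cst_labels, log_base)
    return a.join(b[["d_cst4", "log_d_cst4"]])


def stability_contrast(stab: pd.DataFrame, column: str = "log_d_subject_mean") -> GEEResult:
    """Group contrast of a log-distance column via Gaussian GEE.

    Returns the pregnant-minus-non-pregnant difference in mean log distance
    with robust (sandwich) SE and Wald p; ``fold`` is exp(|difference|).
    """
    if column not in stab.columns:
        raise ValueError(f"no column {column!r} in stability table")
    y = stab[column].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("degenerate response: all log distances equal")
    x = (stab["group"] == "pregnant").astype(float).to_numpy()
    if len(np.unique(x)) < 2:
        raise ValueError("both groups must be present")
    exog = sm.add_constant(x)
    model = sm.GEE(y, exog, groups=stab["subject_id"].to_numpy(),
                   family=sm.families.Gaussian(),
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit()
    out = _gee_result_from_fit(res, coef_index=1)
    out.fold = float(np.exp(abs(out.coefficient)))
    return out
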