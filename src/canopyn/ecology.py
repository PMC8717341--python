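"""Plot-level ecology: survey table assembly, detection GLM, thresholds.

The central question is whether canopy nitrogen predicts where greater
gliders are found.  Detection (any glider seen on the plot's transect) is
modelled against mean plot foliar N (% DM, the mean of the five sampled
dominant trees) with a binomial GLM fitted by iteratively reweighted least
squares; empirical detection thresholds (the minimum meanN, mean habitat
likelihood and favorable-area fraction among detection plots) summarize
where detections did and did not occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GLMResult", "fit_logistic", "assemble_plot_table",
           "detection_thresholds"]

#: meanN bins used for detection-rate summaries, % DM
MEAN_N_BINS = ((-np.inf, 1.1), (1.1, 1.4), (1.4, np.inf))


@dataclass
class GLMResult:
    """Binomial GLM fit: coefficients, Wald inference, convergence state."""

    intercept: float
    slope: float
    se: tuple[float, float]
    conf_int: tuple[tuple[float, float], tuple[float, float]]  # 95% Wald
    p_values: tuple[float, float]
    converged: bool
    n_iter: int
    separation: bool = False
    log_likelihood: float = float("nan")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.slope])


def _logistic(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(detected, mean_n, tol: float = 1e-8, max_iter: int = 100
                 ) -> GLMResult:
    """Maximum-likelihood logistic regression of detection on mean plot N.

    Fisher scoring / iteratively reweighted least squares to relative
    tolerance ``tol``; standard errors from the inverse of the final
    weighted information matrix; 95% CI = estimate +/- 1.96 SE and two-sided
    Wald p-values.  Complete or quasi-complete separation is flagged
    (``separation=True``, ``converged=False``) with a warning rather than
    silently returning diverging estimates.
    """
    from scipy import stats

    y = np.asarray(detected, dtype=float)
    x = np.asarray(mean_n, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("detection outcomes must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both detection outcomes must be present")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(_logistic(eta), 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta) / (np.abs(beta) + 1e-8)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    mu = np.clip(_logistic(X @ beta), 1e-12, 1 - 1e-12)
    separation = bool(np.all((mu > 0.999) == (y == 1)) and
                      np.all((mu < 0.001) == (y == 0)) and
                      np.all((mu > 0.999) | (mu < 0.001)))
    if separation or np.max(np.abs(beta)) > 1e4:
        separation = True
        converged = False
        warnings.warn("complete separation: logistic estimates diverge; "
                      "coefficients are not interpretable", stacklevel=2)
    w = mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov))
    zscores = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zscores))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    ci = tuple((float(b - 1.96 * s), float(b + 1.96 * s))
               for b, s in zip(beta, se))
    return GLMResult(intercept=float(beta[0]), slope=float(beta[1]),
                     se=(float(se[0]), float(se[1])),
                     conf_int=(ci[0], ci[1]),
                     p_values=(float(pvals[0]), float(pvals[1])),
                     converged=converged, n_iter=it,
                     separation=separation, log_likelihood=ll)


def assemble_plot_table(trees: pd.DataFrame, detections: pd.DataFrame,
                        habitat_summaries: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Join the per-plot survey table.

    meanN (and mean digN) are arithmetic means over the plot's sampled
    trees; digN is missing when no sampled tree has a value.  Glider counts
    join by ``plot_id`` (unmatched ids raise), and habitat-map summaries
    (mean likelihood, favorable fraction, clumpiness) join when provided.
    """
    sampled = trees[trees["sampled"]] if "sampled" in trees.columns else trees
    per_plot = sampled.groupby("plot_id").agg(
        mean_n_pct_dm=("n_pct_dm", "mean"),
        mean_dign_pct_dm=("dign_pct_dm", lambda s: s.mean()),
        n_sampled_trees=("n_pct_dm", "size"),
    ).reset_index()
    if (per_plot["n_sampled_trees"] == 0).any():
        raise ValueError("every plot needs at least one sampled tree")

    det_cols = [c for c in ("glider_count", "detected", "count") if
                c in detections.columns]
    if not det_cols:
        raise ValueError("detections table needs a glider_count/detected column")
    det = detections[["plot_id"] + det_cols].copy()
    unmatched = set(det["plot_id"]) ^ set(per_plot["plot_id"])
    if unmatched:
        raise ValueError(f"plot ids not shared by trees and detections: "
                         f"{sorted(unmatched)}")
    table = per_plot.merge(det, on="plot_id", how="left")
    if "glider_count" in table.columns:
        table["detected"] = (table["glider_count"] >= 1).astype(int)
    elif "detected" in table.columns:
        table["detected"] = table["detected"].astype(int)
    if habitat_summaries is not None:
        table = table.merge(habitat_summaries, on="plot_id", how="left")
    if "elevation_band" in trees.columns:
        bands = trees.groupby("plot_id")["elevation_band"].first().reset_index()
        table = table.merge(bands, on="plot_id", how="left")
    return table


def detection_thresholds(table: pd.DataFrame) -> dict:
    """Empirical minima among plots with a glider detection.

    Returns the minimum measured meanN, mean likelihood and favorable-area
    fraction over detection plots, detection rates per elevation band and
    per meanN bin (< 1.1, 1.1-1.4, > 1.4 % DM).  Row order never matters.
    A table without detections yields missing minima with a warning.
    """
    t = table.copy()
    if "detected" not in t.columns:
        t["detected"] = (t["glider_count"] >= 1).astype(int)
    det = t[t["detected"] == 1]
    out: dict = {"n_detection_plots": int(len(det))}
    if det.empty:
        warnings.warn("no detection plots; threshold minima undefined",
                      stacklevel=2)
        for k in ("min_mean_n_pct_dm", "min_mean_likelihood",
                  "min_favorable_fraction_pct"):
            out[k] = float("nan")
    else:
        out["min_mean_n_pct_dm"] = float(det["mean_n_pct_dm"].min())
        out["min_mean_likelihood"] = (
            float(det["mean_likelihood"].min())
            if "mean_likelihood" in det.columns else float("nan"))
        out["min_favorable_fraction_pct"] = (
            float(det["favorable_fraction_pct"].min())
            if "favorable_fraction_pct" in det.columns else float("nan"))
    if "elevation_band" in t.columns:
        out["detection_rate_by_band"] = {
            str(band): float(grp["detected"].mean())
            for band, grp in t.groupby("elevation_band")}
    rates = {}
    for lo, hi in MEAN_N_BINS:
        sel = t[(t["mean_n_pct_dm"] >= lo) & (t["mean_n_pct_dm"] < hi)]
        label = f"[{lo:g}, {hi:g})"
        rates[label] = float(sel["detected"].mean()) if len(sel) else float("nan")
    out["detection_rate_by_mean_n_bin"] = rates
    return out
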