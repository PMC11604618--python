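"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Cochran's Q measures dispersion of the per-instrument Wald ratios around the
fixed-effect IVW estimate; the Egger intercept tests directional pleiotropy;
MR-PRESSO detects pleiotropic outlier instruments by comparing observed
residual sums of squares with a parametric simulation under the causal
model; leave-one-out re-estimates IVW with each instrument removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerResult,
    MREstimate,
    _as_frame,
    _wald_arrays,
    ivw,
)
from .exceptions import ArityError, DegenerateCorrectionError

__all__ = [
    "QResult",
    "PressoResult",
    "LOOResult",
    "PleiotropyVerdict",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
]


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic with chi-square p-value."""

    q: float
    df: int
    pvalue: float
    per_snp: np.ndarray | None = None  # per-instrument contributions; sums to q


class PleiotropyVerdict(NamedTuple):
    pvalue: float
    significant: bool


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    n_sim: int
    outlier_indices: list[int]
    outlier_rsids: list[str]
    outlier_pvalues: np.ndarray  # Bonferroni-adjusted, one per instrument
    distortion_p: float | None
    raw: MREstimate
    corrected: MREstimate | None


@dataclass
class LOOResult:
    """Leave-one-out IVW table (forest-plot-ready) plus the full estimate."""

    table: pd.DataFrame  # rsid, beta, se, pvalue, ci_low, ci_high
    full: MREstimate


def cochran_q(h) -> QResult:
    """Q = Σ wⱼ(βⱼ − β_IVW)² over Wald ratios, wⱼ = 1/se_waldⱼ²; df = J − 1."""
    df = _as_frame(h)
    if len(df) < 2:
        raise ArityError("Cochran's Q requires >= 2 instruments")
    ratios, _, w = _wald_arrays(df)
    beta_fe = float(np.sum(w * ratios) / np.sum(w))
    contrib = w * (ratios - beta_fe) ** 2
    q = float(contrib.sum())
    dof = len(ratios) - 1
    return QResult(q=q, df=dof, pvalue=float(stats.chi2.sf(q, dof)), per_snp=contrib)


def egger_intercept_test(e: EggerResult, alpha: float = 0.05) -> PleiotropyVerdict:
    """Directional-pleiotropy verdict from the MR-Egger intercept."""
    return PleiotropyVerdict(
        pvalue=e.intercept_pvalue, significant=e.intercept_pvalue < alpha
    )


def _loo_beta(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the last axis.

    Works on 1-D arrays (one dataset) or 2-D arrays (n_sim, J).
    """
    swxy = (w * x * y).sum(axis=-1, keepdims=True)
    swxx = (w * x * x).sum(axis=-1, keepdims=True)
    return (swxy - w * x * y) / (swxx - w * x * x)


def mr_presso(
    h,
    *,
    n_sim: int = 1000,
    seed: int,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    Global test: for each instrument j the IVW slope β₋ⱼ is fit without it;
    the observed residual sum of squares RSSobs = Σⱼ wⱼ(beta_outⱼ −
    β₋ⱼ·beta_expⱼ)² with wⱼ = 1/se_outⱼ² is compared against ``n_sim``
    parametric simulations (beta_exp* ~ N(beta_exp, se_exp), beta_out* ~
    N(β₋ⱼ·beta_exp, se_out), the leave-one-out fit recomputed per
    simulation). The add-one rule (1 + #{RSSsim ≥ RSSobs})/(n_sim + 1) keeps
    p away from zero.

    Outlier test: each instrument's observed residual term against its own
    simulated distribution, Bonferroni-adjusted by J; instruments below
    ``outlier_alpha`` are outliers. The corrected estimate is IVW (random
    effects) on the non-outliers.

    Distortion test (experimental): the displacement between raw and
    outlier-corrected IVW is compared to the displacement obtained by
    removing random subsets of the same size.
    """
    frame = _as_frame(h)
    j = len(frame)
    if j < 4:
        raise ArityError("MR-PRESSO requires >= 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)

    x = frame["beta_exp"].to_numpy(float)
    y = frame["beta_out"].to_numpy(float)
    sx = frame["se_exp"].to_numpy(float)
    sy = frame["se_out"].to_numpy(float)
    w = 1.0 / sy**2

    beta_loo = _loo_beta(x, y, w)
    resid_obs = w * (y - beta_loo * x) ** 2
    rss_obs = float(resid_obs.sum())

    x_sim = rng.normal(x, sx, size=(n_sim, j))
    y_sim = rng.normal(beta_loo * x, sy, size=(n_sim, j))
    beta_loo_sim = _loo_beta(x_sim, y_sim, w)
    resid_sim = w * (y_sim - beta_loo_sim * x_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_raw = (1 + (resid_sim >= resid_obs).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outliers = np.flatnonzero(p_adj < outlier_alpha)

    raw = ivw(frame, mode="random") if j >= 2 else None
    rsids = (
        frame["rsid"].tolist() if "rsid" in frame.columns else [str(i) for i in range(j)]
    )

    corrected = None
    distortion_p = None
    if len(outliers) == j:
        raise DegenerateCorrectionError("every instrument flagged as an outlier")
    if len(outliers) > 0:
        keep = np.setdiff1d(np.arange(j), outliers)
        if len(keep) < 2:
            raise DegenerateCorrectionError(
                "fewer than 2 instruments remain after outlier removal"
            )
        corrected = ivw(frame.iloc[keep], mode="random")
        # distortion: displacement vs random removal of |outliers| instruments
        k = len(outliers)
        if corrected.beta != 0 and j - k >= 2:
            d_obs = abs(raw.beta - corrected.beta) / abs(corrected.beta)
            d_sim = np.empty(n_distortion)
            for b in range(n_distortion):
                drop = rng.choice(j, size=k, replace=False)
                kp = np.setdiff1d(np.arange(j), drop)
                beta_b = float(
                    np.sum(w[kp] * x[kp] * y[kp]) / np.sum(w[kp] * x[kp] ** 2)
                )
                d_sim[b] = abs(raw.beta - beta_b) / abs(corrected.beta)
            distortion_p = float(
                (1 + np.sum(d_sim >= d_obs)) / (n_distortion + 1)
            )

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_indices=[int(i) for i in outliers],
        outlier_rsids=[rsids[i] for i in outliers],
        outlier_pvalues=p_adj,
        distortion_p=distortion_p,
        raw=raw,
        corrected=corrected,
    )


def leave_one_out(h, mode: str = "random") -> LOOResult:
    """IVW re-estimated with each instrument excluded in turn.

    Returns one row per excluded rsid (beta, se, p, 95% CI on the OR scale)
    plus the all-instrument estimate for reference.
    """
    frame = _as_frame(h)
    j = len(frame)
    if j < 3:
        raise ArityError("leave-one-out requires >= 3 instruments")
    full = ivw(frame, mode=mode)
    rsids = (
        frame["rsid"].tolist() if "rsid" in frame.columns else [str(i) for i in range(j)]
    )
    rows = []
    for i in range(j):
        est = ivw(frame.drop(frame.index[i]), mode=mode)
        rows.append(
            {
                "rsid": rsids[i],
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or_value": est.or_value,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return LOOResult(table=pd.DataFrame(rows), full=full)
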