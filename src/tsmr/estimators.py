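"""Causal-effect estimators for two-sample MR on harmonized instrument sets.

Each estimator is an sklearn-style class (``fit`` on a harmonized table,
fitted attributes with trailing underscores, ``get_params``/``set_params``)
so they compose with sklearn tooling; the module-level functions
(:func:`ivw`, :func:`egger`, ...) are thin wrappers kept as the primary
scripting surface.

All causal effects are on the log-odds scale for a binary outcome and are
reported alongside the odds ratio ``exp(beta)`` with a 95% normal CI.

Estimators
----------
WaldRatio         single-instrument ratio beta_out / beta_exp
IVW               inverse-variance-weighted meta-analysis of Wald ratios;
                  fixed or multiplicative random-effects SE
EggerRegression   weighted regression with a free intercept; the intercept
                  tests directional horizontal pleiotropy
WeightedMedian    0.5-quantile of the weighted Wald-ratio distribution;
                  consistent when >= 50% of weight comes from valid
                  instruments; bootstrap SE
ModeEstimator     kernel-density mode of the Wald ratios (simple/weighted);
                  consistent when the largest instrument cluster is valid
MultivariableIVW  joint weighted regression on exposure and mediator betas
                  giving conditional (direct) effects
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ArityError,
    CollinearityError,
    DegenerateInstrumentError,
)

Z_975 = stats.norm.ppf(0.975)

__all__ = [
    "MREstimate",
    "EggerResult",
    "WaldRatio",
    "IVW",
    "EggerRegression",
    "WeightedMedian",
    "ModeEstimator",
    "MultivariableIVW",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "mvmr_ivw",
    "to_odds_ratio",
    "beta_from_odds_ratio",
]


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal effect with SE, p, OR and 95% CI."""

    method: str
    beta: float
    se: float
    pvalue: float
    or_value: float
    ci_low: float
    ci_high: float
    n_snp: int


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope estimate plus the pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% CI) from a log-odds effect: exp(beta), exp(beta ∓ 1.96·se)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        math.exp(beta),
        math.exp(beta - Z_975 * se),
        math.exp(beta + Z_975 * se),
    )


def beta_from_odds_ratio(or_value: float) -> float:
    """Log-odds effect implied by an odds ratio: ln(OR)."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return math.log(or_value)


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)))


def _t_p(beta: float, se: float, df: int) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(min(1.0, 2.0 * stats.t.sf(abs(beta) / se, df)))


def _make_estimate(
    method: str, beta: float, se: float, n_snp: int, pvalue: float | None = None
) -> MREstimate:
    if pvalue is None:
        pvalue = _normal_p(beta, se)
    or_value, ci_low, ci_high = to_odds_ratio(beta, se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pvalue=float(pvalue),
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        n_snp=int(n_snp),
    )


def _as_frame(h, need_mediator: bool = False) -> pd.DataFrame:
    """Retained instrument rows from a HarmonizedSet/InstrumentSet/DataFrame."""
    if hasattr(h, "data"):  # InstrumentSet
        h = h.data
    if hasattr(h, "retained"):  # HarmonizedSet
        df = h.retained
    else:
        df = h
    required = ["beta_exp", "se_exp", "beta_out", "se_out"]
    if need_mediator:
        required += ["beta_med", "se_med"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"harmonized table missing column(s) {missing}")
    return df


def _wald_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ratios, first-order Wald SEs, IVW weights 1/se_wald²)."""
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise DegenerateInstrumentError("instrument with beta_exp = 0")
    ratios = by / bx
    se_wald = sy / np.abs(bx)
    return ratios, se_wald, 1.0 / se_wald**2


class _BaseMR(BaseEstimator):
    """Shared fit machinery; subclasses implement ``_fit`` and ``_min_snp``."""

    method: str = "base"
    _min_snp: int = 1
    _needs_mediator: bool = False

    def fit(self, X, y=None):
        """Fit on a harmonized instrument table.

        X may be a :class:`~tsmr.gwas_io.HarmonizedSet`, an
        :class:`~tsmr.instruments.InstrumentSet`, or a DataFrame carrying
        ``beta_exp, se_exp, beta_out, se_out`` (``beta_med, se_med`` for
        multivariable estimators). ``y`` is ignored (outcome betas live in X).
        """
        df = _as_frame(X, need_mediator=self._needs_mediator)
        if len(df) < self._min_snp:
            raise ArityError(
                f"{self.method} requires >= {self._min_snp} instruments, "
                f"got {len(df)}"
            )
        self._fit(df)
        est = self.estimate_
        self.beta_ = est.beta
        self.se_ = est.se
        self.pvalue_ = est.pvalue
        self.or_ = est.or_value
        self.ci_ = (est.ci_low, est.ci_high)
        self.n_snp_ = est.n_snp
        return self

    def _fit(self, df: pd.DataFrame) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class WaldRatio(_BaseMR):
    """Single-instrument causal estimate beta_out / beta_exp.

    The SE is first-order (se_out / |beta_exp|), ignoring exposure-side
    variance, matching standard two-sample practice.
    """

    method = "wald"
    _min_snp = 1

    def _fit(self, df):
        if len(df) != 1:
            raise ArityError("Wald ratio is defined for exactly one instrument")
        ratios, se_wald, _ = _wald_arrays(df)
        self.estimate_ = _make_estimate("wald", ratios[0], se_wald[0], 1)


class IVW(_BaseMR):
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Equivalent to weighted regression of beta_out on beta_exp through the
    origin with weights 1/se_out². ``mode="fixed"`` uses se = sqrt(1/Σw);
    ``mode="random"`` (multiplicative random effects) scales that SE by
    max(1, sqrt(Q/(J−1))) where Q is Cochran's Q, and never deflates it.
    """

    method = "ivw"

    def __init__(self, mode: str = "random"):
        self.mode = mode

    @property
    def _min_snp(self):
        return 1 if self.mode == "fixed" else 2

    def _fit(self, df):
        if self.mode not in ("fixed", "random"):
            raise ValueError(f"unknown IVW mode '{self.mode}'")
        ratios, _, w = _wald_arrays(df)
        j = len(ratios)
        beta = float(np.sum(w * ratios) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        q = float(np.sum(w * (ratios - beta) ** 2))
        self.q_ = q
        scale = 1.0
        if self.mode == "random" and j >= 2:
            scale = max(1.0, math.sqrt(q / (j - 1)))
        self.se_scale_ = scale
        method = "ivw_fe" if self.mode == "fixed" else "ivw_re"
        self.estimate_ = _make_estimate(method, beta, se * scale, j)


class EggerRegression(_BaseMR):
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Instruments are first oriented so every beta_exp is non-negative (the
    outcome beta flips sign with it). A nonzero intercept indicates
    directional horizontal pleiotropy; the slope is the pleiotropy-corrected
    causal estimate under the InSIDE assumption. Coefficient SEs use the
    multiplicative scale floored at 1; p-values use Student-t with J−2 df.
    """

    method = "egger"
    _min_snp = 3

    def _fit(self, df):
        sign = np.sign(df["beta_exp"].to_numpy(float))
        sign[sign == 0] = 1.0
        x = df["beta_exp"].to_numpy(float) * sign
        y = df["beta_out"].to_numpy(float) * sign
        w = 1.0 / df["se_out"].to_numpy(float) ** 2
        j = len(x)
        design = sm.add_constant(x)
        res = sm.WLS(y, design, weights=w).fit()
        scale = max(1.0, float(res.scale))  # residual variance floored at 1
        se = np.sqrt(np.diag(res.normalized_cov_params) * scale)
        slope_p = _t_p(res.params[1], se[1], j - 2)
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(se[0])
        self.intercept_pvalue_ = _t_p(res.params[0], se[0], j - 2)
        self.estimate_ = _make_estimate(
            "egger", res.params[1], se[1], j, pvalue=slope_p
        )
        self.result_ = EggerResult(
            slope=self.estimate_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_pvalue=self.intercept_pvalue_,
        )


def _weighted_median_1d(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: value at cumulative weight 0.5, with
    cumulative weight taken as the running sum minus half the own weight."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights[order].sum()
    cum = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, cum, v))


def _bootstrap_betas(df: pd.DataFrame, n_boot: int, rng: np.random.Generator):
    """Parametric bootstrap draws of (beta_exp, beta_out), shape (n_boot, J)."""
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sx = df["se_exp"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    return bxs, bys, sy


class WeightedMedian(_BaseMR):
    """Weighted median of the Wald ratios (WME).

    The point estimate interpolates the ratio at cumulative weight 0.5 with
    weights 1/se_wald²; the SE is a parametric bootstrap (both exposure and
    outcome betas resampled from their stated normals). A seed is mandatory.
    """

    method = "weighted_median"
    _min_snp = 3

    def __init__(self, n_boot: int = 5000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def _fit(self, df):
        if self.random_state is None:
            raise ValueError("WeightedMedian requires an explicit random_state")
        ratios, se_wald, w = _wald_arrays(df)
        est = _weighted_median_1d(ratios, w)

        rng = np.random.default_rng(self.random_state)
        bxs, bys, sy = _bootstrap_betas(df, self.n_boot, rng)
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        rb = bys / bxs
        wb = bxs**2 / sy**2
        draws = np.empty(self.n_boot)
        for i in range(self.n_boot):
            draws[i] = _weighted_median_1d(rb[i], wb[i])
        se = float(draws.std(ddof=1))
        self.bootstrap_draws_ = draws
        self.estimate_ = _make_estimate("weighted_median", est, se, len(ratios))


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float, n_grid: int = 512
) -> tuple[float, float]:
    """Normal-kernel density mode of the ratios; returns (mode, bandwidth).

    Bandwidth h = phi · 0.9 · min(sd, MAD/0.6745) · J^(−1/5); the density is
    maximized on an ``n_grid``-point grid spanning the ratios ± 3h.
    """
    j = len(ratios)
    s = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    h = phi * 0.9 * min(s, mad) * j ** (-1 / 5)
    if h == 0 or not np.isfinite(h):
        return float(ratios[0]), 0.0
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    wn = weights / weights.sum()
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ wn
    return float(grid[np.argmax(dens)]), h


class ModeEstimator(_BaseMR):
    """Simple or weighted mode-based estimate (kernel-density argmax).

    Weights are uniform (``weighted=False``) or 1/se_wald²; ``phi`` scales
    the bandwidth. When every ratio coincides the bandwidth degenerates and
    that common ratio is returned with se 0. SE via parametric bootstrap.
    """

    _min_snp = 3

    def __init__(
        self,
        weighted: bool = True,
        phi: float = 1.0,
        n_boot: int = 5000,
        random_state: int | None = None,
    ):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    @property
    def method(self):
        return "weighted_mode" if self.weighted else "simple_mode"

    def _fit(self, df):
        if self.random_state is None:
            raise ValueError("ModeEstimator requires an explicit random_state")
        ratios, se_wald, w_inv = _wald_arrays(df)
        weights = w_inv if self.weighted else np.ones_like(ratios)
        est, h = _mode_point(ratios, weights, self.phi)
        self.bandwidth_ = h
        if h == 0.0:
            self.estimate_ = _make_estimate(self.method, est, 0.0, len(ratios))
            return
        rng = np.random.default_rng(self.random_state)
        bxs, bys, sy = _bootstrap_betas(df, self.n_boot, rng)
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        rb = bys / bxs
        wb = bxs**2 / sy**2 if self.weighted else np.ones_like(rb)
        draws = np.empty(self.n_boot)
        for i in range(self.n_boot):
            draws[i], _ = _mode_point(rb[i], wb[i], self.phi)
        se = float(draws.std(ddof=1))
        self.estimate_ = _make_estimate(self.method, est, se, len(ratios))


class MultivariableIVW(_BaseMR):
    """Multivariable IVW: conditional effects of exposure and mediator.

    Weighted least squares of beta_out on (beta_exp, beta_med) without
    intercept, weights 1/se_out². Fitted attributes carry the conditional
    exposure effect (``estimate_``) and the conditional mediator effect
    (``mediator_estimate_``).
    """

    method = "mvmr_ivw"
    _min_snp = 3
    _needs_mediator = True

    def __init__(self, cond_threshold: float = 1e8):
        self.cond_threshold = cond_threshold

    def _fit(self, df):
        x = df[["beta_exp", "beta_med"]].to_numpy(float)
        y = df["beta_out"].to_numpy(float)
        w = 1.0 / df["se_out"].to_numpy(float) ** 2
        j = len(y)
        xw = x * np.sqrt(w)[:, None]
        # zero-norm columns are degenerate-but-defined (pinv gives a zero
        # coefficient); the collinearity check covers the nonzero ones
        nonzero = np.linalg.norm(xw, axis=0) > 0
        if nonzero.sum() >= 2 and np.linalg.cond(xw[:, nonzero]) > self.cond_threshold:
            raise CollinearityError(
                "exposure and mediator instrument effects are collinear"
            )
        res = sm.WLS(y, x, weights=w).fit()
        scale = max(1.0, float(res.scale))
        se = np.sqrt(np.diag(res.normalized_cov_params) * scale)
        self.estimate_ = _make_estimate("mvmr_exposure", res.params[0], se[0], j)
        self.mediator_estimate_ = _make_estimate(
            "mvmr_mediator", res.params[1], se[1], j
        )


# ---------------------------------------------------------------------------
# thin functional wrappers


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> MREstimate:
    """Single-instrument Wald ratio estimate (first-order SE)."""
    df = pd.DataFrame(
        {
            "beta_exp": [beta_exp],
            "se_exp": [se_exp],
            "beta_out": [beta_out],
            "se_out": [se_out],
        }
    )
    return WaldRatio().fit(df).estimate_


def ivw(h, mode: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate (fixed or multiplicative random)."""
    return IVW(mode=mode).fit(h).estimate_


def egger(h) -> EggerResult:
    """MR-Egger slope and pleiotropy intercept."""
    return EggerRegression().fit(h).result_


def weighted_median(h, n_boot: int = 5000, *, seed: int) -> MREstimate:
    """Weighted median estimate with parametric-bootstrap SE."""
    return WeightedMedian(n_boot=n_boot, random_state=seed).fit(h).estimate_


def mode_estimate(
    h, weighted: bool = True, phi: float = 1.0, n_boot: int = 5000, *, seed: int
) -> MREstimate:
    """Simple/weighted mode estimate with parametric-bootstrap SE."""
    est = ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot, random_state=seed)
    return est.fit(h).estimate_


def mvmr_ivw(h) -> tuple[MREstimate, MREstimate]:
    """Conditional (exposure, mediator) effects from multivariable IVW."""
    fitted = MultivariableIVW().fit(h)
    return fitted.estimate_, fitted.mediator_estimate_
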