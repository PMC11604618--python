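"""Batch bidirectional screening with tiered significance and direction calls.

Each exposure is run against the outcome through the full estimator battery;
findings are tiered as Bonferroni-significant (IVW p below 0.05/n for the
exposure's group), suggestive (IVW p < 0.05) or null, with a consistency
flag requiring sign agreement of IVW, weighted median and MR-Egger. Pairs
failing the MR-PRESSO global test or the Egger intercept test at 0.05 are
downgraded to null with a reason code. Reverse MR (disease as exposure,
P < 5e-5 instruments) then classifies each surviving pair as forward-only or
bidirectional; only forward-only pairs are eligible for mediation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import PressoResult, QResult, cochran_q, mr_presso
from .estimators import (
    EggerResult,
    MREstimate,
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
)
from .exceptions import TsmrError
from .gwas_io import LDMatrix, SummaryStats
from .instruments import (
    InstrumentSet,
    SelectionConfig,
    reverse_config,
    select_instruments,
)

logger = logging.getLogger(__name__)

TIER_BONFERRONI = "bonferroni_significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"

DEFAULT_METHODS = (
    "ivw",
    "ivw_fe",
    "weighted_median",
    "egger",
    "simple_mode",
    "weighted_mode",
)


@dataclass
class ScreenResult:
    """One exposure→outcome screening row."""

    exposure_id: str
    outcome_id: str
    group: str = ""
    n_snp: int = 0
    estimates: dict = field(default_factory=dict)  # method -> MREstimate
    egger_result: EggerResult | None = None
    q_result: QResult | None = None
    presso_result: PressoResult | None = None
    tier: str = TIER_NULL
    consistency_flag: bool | None = None
    direction: str | None = None
    reason: str = ""
    counts: dict = field(default_factory=dict)

    @property
    def ivw(self) -> MREstimate | None:
        return self.estimates.get("ivw") or self.estimates.get("wald")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-group multiple-testing threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def run_battery(
    instruments: InstrumentSet,
    *,
    seed: int,
    n_boot: int = 1000,
    methods: tuple[str, ...] | None = None,
) -> tuple[dict, EggerResult | None]:
    """Run the estimator battery appropriate to the instrument count.

    A single instrument yields only the Wald ratio; two instruments yield
    IVW; three or more yield the full five-method table.
    """
    methods = tuple(methods or DEFAULT_METHODS)
    h = instruments.data
    j = h.n_snp
    estimates: dict[str, MREstimate] = {}
    egger_res: EggerResult | None = None
    if j == 1:
        row = h.retained.iloc[0]
        estimates["wald"] = wald_ratio(
            row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"]
        )
        return estimates, None
    if "ivw" in methods:
        estimates["ivw"] = ivw(h, mode="random")
    if "ivw_fe" in methods:
        estimates["ivw_fe"] = ivw(h, mode="fixed")
    if j >= 3:
        if "egger" in methods:
            egger_res = egger(h)
            estimates["egger"] = egger_res.slope
        if "weighted_median" in methods:
            estimates["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
        if "simple_mode" in methods:
            estimates["simple_mode"] = mode_estimate(
                h, weighted=False, n_boot=n_boot, seed=seed
            )
        if "weighted_mode" in methods:
            estimates["weighted_mode"] = mode_estimate(
                h, weighted=True, n_boot=n_boot, seed=seed
            )
    return estimates, egger_res


def classify(
    result: ScreenResult, group_threshold: float, alpha: float = 0.05
) -> ScreenResult:
    """Assign tier, consistency flag and downgrade reason in place.

    Tier requires IVW p < ``group_threshold`` (Bonferroni) or < ``alpha``
    (suggestive). Pairs failing the MR-PRESSO global test or the Egger
    intercept test at ``alpha`` are downgraded to null. Single-instrument
    pairs can reach at most the suggestive tier.
    """
    primary = result.ivw
    if primary is None:
        result.tier = TIER_NULL
        result.reason = result.reason or "no_estimate"
        return result

    if result.n_snp == 1:
        result.tier = TIER_SUGGESTIVE if primary.pvalue < alpha else TIER_NULL
        result.consistency_flag = None
        result.reason = "single_instrument"
        return result

    if result.presso_result is not None and result.presso_result.global_p < alpha:
        result.tier = TIER_NULL
        result.reason = "presso_global"
        return result
    if (
        result.egger_result is not None
        and result.egger_result.intercept_pvalue < alpha
    ):
        result.tier = TIER_NULL
        result.reason = "egger_intercept"
        return result

    if primary.pvalue < group_threshold:
        result.tier = TIER_BONFERRONI
    elif primary.pvalue < alpha:
        result.tier = TIER_SUGGESTIVE
    else:
        result.tier = TIER_NULL

    signs = [np.sign(primary.beta)]
    for key in ("weighted_median", "egger"):
        if key in result.estimates:
            signs.append(np.sign(result.estimates[key].beta))
    result.consistency_flag = bool(len(set(signs)) == 1)
    return result


def reverse_mr(
    outcome_as_exposure: SummaryStats,
    original_exposure: SummaryStats,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    *,
    seed: int,
    n_boot: int = 1000,
    methods: tuple[str, ...] | None = None,
) -> dict:
    """Reverse-direction MR: the disease becomes the exposure (P < 5e-5)."""
    cfg = reverse_config(config)
    instruments = select_instruments(outcome_as_exposure, original_exposure, ld, cfg)
    estimates, _ = run_battery(instruments, seed=seed, n_boot=n_boot, methods=methods)
    return estimates


def direction_filter(
    forward: ScreenResult, reverse_ivw: MREstimate | None, alpha: float = 0.05
) -> str:
    """Classify causal direction from the forward tier and reverse IVW p.

    forward_only (reverse p >= alpha) pairs qualify for mediation analysis;
    a significant reverse estimate marks the pair bidirectional.
    """
    if forward.tier == TIER_NULL:
        return "none"
    if reverse_ivw is None:
        return "forward_only"
    return "bidirectional" if reverse_ivw.pvalue < alpha else "forward_only"


def batch_screen(
    exposures,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    *,
    seed: int,
    alpha: float = 0.05,
    n_boot: int = 1000,
    methods: tuple[str, ...] | None = None,
    run_diagnostics: bool = True,
    presso_n_sim: int = 1000,
    group_n: dict | None = None,
) -> list[ScreenResult]:
    """Screen every exposure against the outcome; never raises per-exposure.

    Group Bonferroni thresholds default to alpha divided by the number of
    exposures sharing the group label; ``group_n`` supplies externally
    computed effective numbers per group instead. Results are ordered by
    exposure_id and per-exposure randomness is derived deterministically
    from ``seed``, so a rerun with the same inputs is identical.
    """
    config = config or SelectionConfig()
    exposures = sorted(exposures, key=lambda s: s.trait_id)
    if group_n is None:
        group_n = {}
        for exp in exposures:
            group_n[exp.group] = group_n.get(exp.group, 0) + 1

    results: list[ScreenResult] = []
    for i, exp in enumerate(exposures):
        res = ScreenResult(
            exposure_id=exp.trait_id, outcome_id=outcome.trait_id, group=exp.group
        )
        sub_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0]
            % 2**31
        )
        try:
            instruments = select_instruments(exp, outcome, ld, config)
        except TsmrError as exc:
            res.reason = f"skipped: {exc}"
            logger.info("exposure %s skipped: %s", exp.trait_id, exc)
            results.append(res)
            continue
        res.n_snp = instruments.n_snp
        res.counts = instruments.counts
        try:
            res.estimates, res.egger_result = run_battery(
                instruments, seed=sub_seed, n_boot=n_boot, methods=methods
            )
            if run_diagnostics and instruments.n_snp >= 2:
                res.q_result = cochran_q(instruments.data)
                if instruments.n_snp >= 4:
                    res.presso_result = mr_presso(
                        instruments.data, n_sim=presso_n_sim, seed=sub_seed
                    )
        except TsmrError as exc:
            res.reason = f"skipped: {exc}"
            results.append(res)
            continue
        threshold = bonferroni_threshold(alpha, max(1, group_n.get(exp.group, 1)))
        classify(res, threshold, alpha)
        results.append(res)
    return results


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """One row per exposure: primary IVW stats, diagnostics, tier, direction."""
    rows = []
    for r in results:
        primary = r.ivw
        rows.append(
            {
                "exposure_id": r.exposure_id,
                "outcome_id": r.outcome_id,
                "group": r.group,
                "n_snp": r.n_snp,
                "beta_ivw": primary.beta if primary else np.nan,
                "se_ivw": primary.se if primary else np.nan,
                "p_ivw": primary.pvalue if primary else np.nan,
                "or_ivw": primary.or_value if primary else np.nan,
                "ci_low": primary.ci_low if primary else np.nan,
                "ci_high": primary.ci_high if primary else np.nan,
                "q_p": r.q_result.pvalue if r.q_result else np.nan,
                "egger_intercept_p": (
                    r.egger_result.intercept_pvalue if r.egger_result else np.nan
                ),
                "presso_global_p": (
                    r.presso_result.global_p if r.presso_result else np.nan
                ),
                "tier": r.tier,
                "consistent": r.consistency_flag,
                "direction": r.direction,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def findings_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Forest-table rows (exposure, n_snp, method, OR, CI, P) for findings."""
    rows = []
    for r in results:
        if r.tier == TIER_NULL:
            continue
        for method, est in r.estimates.items():
            rows.append(
                {
                    "exposure_id": r.exposure_id,
                    "n_snp": r.n_snp,
                    "method": method,
                    "or_value": est.or_value,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pvalue": est.pvalue,
                    "tier": r.tier,
                }
            )
    return pd.DataFrame(rows)
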