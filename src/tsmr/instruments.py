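"""Genetic instrument selection: p-value thresholding, LD clumping, F filter.

Selection follows the conventional two-sample MR chain: keep SNPs below the
exposure-side significance threshold (default P < 1e-5), greedily clump to
approximate independence (r² < 0.001 within a 10,000 kb window), harmonize
against the outcome with palindromic variants excluded, then require an
instrument-strength F statistic (beta²/SE²) above 10 to guard against weak
instrument bias. Provenance counts are recorded after every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInstrumentError
from .gwas_io import HarmonizedSet, LDMatrix, SummaryStats, harmonize

logger = logging.getLogger(__name__)

#: Reverse-MR exposure threshold (disease as exposure uses a looser cutoff).
REVERSE_P_THRESHOLD = 5e-5


@dataclass
class SelectionConfig:
    """Instrument selection thresholds.

    p_threshold : exposure significance cutoff, strict inequality.
    clump_r2 : SNP pairs at or above this r² within the window are pruned.
    clump_kb : clumping window in kilobases.
    f_min : minimum instrument F statistic, strict inequality.
    palindrome_policy : "exclude" (default) or "eaf_infer".
    ld_fallback : behaviour when no LD matrix is supplied —
        "assume_independent" keeps all SNPs (warning) while "distance_only"
        prunes by window regardless of r².
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0
    palindrome_policy: str = "exclude"
    ld_fallback: str = "assume_independent"

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if not 0 < self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must lie in (0, 1]")
        if self.clump_kb <= 0 or self.f_min <= 0:
            raise ConfigurationError("clump_kb and f_min must be positive")
        if self.ld_fallback not in ("assume_independent", "distance_only"):
            raise ConfigurationError(f"unknown ld_fallback '{self.ld_fallback}'")


def reverse_config(config: SelectionConfig | None = None) -> SelectionConfig:
    """Selection config for reverse MR (outcome as exposure, P < 5e-5)."""
    base = config or SelectionConfig()
    return replace(base, p_threshold=REVERSE_P_THRESHOLD)


@dataclass
class InstrumentSet:
    """Harmonized set restricted to selected instruments, with provenance.

    ``counts`` records the surviving SNP count after each filter stage and is
    non-increasing along the chain.
    """

    data: HarmonizedSet
    counts: dict = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return self.data.n_snp

    @property
    def f_stat(self) -> pd.Series:
        return self.data.retained["f_stat"]


def f_statistic(beta, se):
    """Instrument strength F = beta² / se² (vectorized)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def clump(
    snps: SummaryStats | pd.DataFrame,
    ld: LDMatrix | None,
    config: SelectionConfig | None = None,
) -> list[str]:
    """Greedy LD clumping; returns retained rsids in retention order.

    SNPs are ordered by ascending p-value (ties broken by rsid); the best
    remaining SNP is retained and all others on the same chromosome within
    ``clump_kb`` kilobases whose r² with it is at or above ``clump_r2`` are
    removed. Cross-chromosome and out-of-window pairs are exempt regardless
    of any recorded r². The result does not depend on the input row order.
    """
    config = config or SelectionConfig()
    df = snps.table if isinstance(snps, SummaryStats) else snps
    if len(df) == 0:
        return []
    if ld is None:
        if config.ld_fallback == "assume_independent":
            logger.warning(
                "no LD matrix supplied: assuming all %d SNPs independent", len(df)
            )
            order = df.sort_values(["p_value", "rsid"], kind="mergesort")
            return list(order["rsid"])
        # distance_only falls through with r² treated as 1 within the window

    order = df.sort_values(["p_value", "rsid"], kind="mergesort")
    window_bp = config.clump_kb * 1000.0
    candidates = order[["rsid", "chromosome", "base_pair_location"]].to_dict("records")
    retained: list[str] = []
    while candidates:
        best = candidates.pop(0)
        retained.append(best["rsid"])
        survivors = []
        for cand in candidates:
            if cand["chromosome"] != best["chromosome"]:
                survivors.append(cand)
                continue
            if abs(cand["base_pair_location"] - best["base_pair_location"]) > window_bp:
                survivors.append(cand)
                continue
            if ld is None:  # distance_only fallback
                continue
            if cand["rsid"] not in ld or best["rsid"] not in ld:
                raise ConfigurationError(
                    f"LD matrix is missing the pair ({best['rsid']}, {cand['rsid']})"
                )
            if ld.lookup(best["rsid"], cand["rsid"]) >= config.clump_r2:
                continue
            survivors.append(cand)
        candidates = survivors
    return retained


def select_instruments(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
) -> InstrumentSet:
    """Full selection chain: p-threshold → clump → harmonize → F filter.

    The F filter runs after harmonization so that reported instrument counts
    match the analyzed set. Raises :class:`EmptyInstrumentError` carrying the
    stage name whenever a filter empties the candidate set.
    """
    config = config or SelectionConfig()
    counts: dict[str, int] = {}

    sig = exposure.table[exposure.table["p_value"] < config.p_threshold]
    counts["n_after_p"] = len(sig)
    if len(sig) == 0:
        raise EmptyInstrumentError("p_threshold")

    kept = clump(sig, ld, config)
    counts["n_after_clump"] = len(kept)
    if not kept:
        raise EmptyInstrumentError("clump")

    h = harmonize(
        exposure.subset(kept), outcome, palindrome_policy=config.palindrome_policy
    )
    counts["n_after_palindrome"] = h.n_snp
    if h.n_snp == 0:
        raise EmptyInstrumentError("harmonization")

    table = h.table.copy()
    retained = table["dropped_reason"] == "none"
    table["f_stat"] = np.nan
    table.loc[retained, "f_stat"] = f_statistic(
        table.loc[retained, "beta_exp"], table.loc[retained, "se_exp"]
    )
    weak = retained & ~(table["f_stat"] > config.f_min)
    table.loc[weak, "dropped_reason"] = "weak_instrument"
    h = HarmonizedSet(h.exposure_id, h.outcome_id, table, h.mediator_id)
    counts["n_after_f"] = h.n_snp
    if h.n_snp == 0:
        raise EmptyInstrumentError("f_filter")

    return InstrumentSet(data=h, counts=counts)
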