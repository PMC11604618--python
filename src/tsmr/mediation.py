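"""Two-step mediation MR with product-of-coefficients decomposition.

The total effect of the exposure on the outcome is split into an indirect
(mediated) path and a direct path::

    indirect = b1 * b2          b1: exposure → mediator
    direct   = total - indirect b2: mediator → outcome
    proportion mediated = indirect / total

Additivity direct + indirect = total holds exactly by construction. The
indirect-effect standard error uses the delta method,
sqrt(b1²·se2² + b2²·se1²). When the indirect and total effects disagree in
sign (inconsistent mediation) the proportion is negative and the result is
flagged rather than silently taking absolute values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate, _normal_p, ivw, mvmr_ivw
from .exceptions import EligibilityError
from .gwas_io import LDMatrix, SummaryStats, harmonize
from .instruments import SelectionConfig, select_instruments

__all__ = [
    "MediationResult",
    "decompose",
    "mediation_proportion",
    "two_step_mediation",
]


@dataclass
class MediationResult:
    """Effect decomposition for an exposure → mediator → outcome triple."""

    total: float
    b1: float
    se1: float
    b2: float
    se2: float
    indirect: float
    direct: float
    proportion: float  # NaN when total == 0 (undefined)
    se_indirect: float
    p_indirect: float
    sign_discordant: bool
    total_se: float = float("nan")
    exposure_id: str = ""
    mediator_id: str = ""
    outcome_id: str = ""
    b2_mode: str = "univariable"
    legs: dict = field(default_factory=dict)  # leg name -> MREstimate

    @property
    def proportion_pct(self) -> float:
        return self.proportion * 100.0


def mediation_proportion(indirect: float, total: float) -> float:
    """Proportion mediated, indirect / total; NaN when the total is zero."""
    if total == 0:
        return float("nan")
    return indirect / total


def decompose(
    total: float,
    b1: float,
    se1: float,
    b2: float,
    se2: float,
    total_se: float = float("nan"),
) -> MediationResult:
    """Product-of-coefficients decomposition of a total effect.

    indirect = b1·b2, direct = total − indirect (exact additivity), with a
    delta-method SE and two-sided normal p-value for the indirect effect.
    """
    for name, value in (("se1", se1), ("se2", se2)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    indirect = b1 * b2
    direct = total - indirect
    se_indirect = math.sqrt(b1**2 * se2**2 + b2**2 * se1**2)
    p_indirect = _normal_p(indirect, se_indirect)
    proportion = mediation_proportion(indirect, total)
    discordant = bool(
        indirect != 0 and total != 0 and np.sign(indirect) != np.sign(total)
    )
    return MediationResult(
        total=total,
        b1=b1,
        se1=se1,
        b2=b2,
        se2=se2,
        indirect=indirect,
        direct=direct,
        proportion=proportion,
        se_indirect=se_indirect,
        p_indirect=p_indirect,
        sign_discordant=discordant,
        total_se=total_se,
    )


def _check_direction(directions, leg: str) -> None:
    if directions is None:
        return
    status = directions.get(leg)
    if status is not None and status != "forward_only":
        raise EligibilityError(
            f"{leg} leg is '{status}', not forward_only; pair is ineligible "
            "for mediation"
        )


def two_step_mediation(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    b2_mode: str = "univariable",
    directions: dict | None = None,
) -> MediationResult:
    """Estimate and decompose the mediated pathway from summary statistics.

    Three IVW legs are fit: total (exposure→outcome, exposure instruments),
    b1 (exposure→mediator, exposure instruments) and b2 (mediator→outcome,
    mediator instruments). With ``b2_mode="mvmr"`` the b2 leg is the
    conditional mediator effect from multivariable IVW on the union of
    exposure and mediator instruments. ``directions`` optionally carries the
    direction-filter verdicts for the "exposure" and "mediator" legs; any
    value other than "forward_only" raises :class:`EligibilityError`.
    """
    if b2_mode not in ("univariable", "mvmr"):
        raise ValueError(f"unknown b2_mode '{b2_mode}'")
    _check_direction(directions, "exposure")
    _check_direction(directions, "mediator")
    config = config or SelectionConfig()

    exp_instruments = select_instruments(exposure, outcome, ld, config)
    total_est = ivw(exp_instruments.data, mode="random")

    b1_instruments = select_instruments(exposure, mediator, ld, config)
    b1_est = ivw(b1_instruments.data, mode="random")

    legs: dict[str, MREstimate] = {
        "total": total_est,
        "b1": b1_est,
    }
    if b2_mode == "univariable":
        b2_instruments = select_instruments(mediator, outcome, ld, config)
        b2_est = ivw(b2_instruments.data, mode="random")
        legs["b2"] = b2_est
    else:
        med_instruments = select_instruments(mediator, outcome, ld, config)
        union = set(exp_instruments.data.retained["rsid"]) | set(
            med_instruments.data.retained["rsid"]
        )
        h = harmonize(
            exposure.subset(union),
            outcome,
            palindrome_policy=config.palindrome_policy,
            mediator=mediator,
        )
        _, b2_est = mvmr_ivw(h)
        legs["b2"] = b2_est

    result = decompose(
        total=total_est.beta,
        b1=b1_est.beta,
        se1=b1_est.se,
        b2=b2_est.beta,
        se2=b2_est.se,
        total_se=total_est.se,
    )
    result.exposure_id = exposure.trait_id
    result.mediator_id = mediator.trait_id
    result.outcome_id = outcome.trait_id
    result.b2_mode = b2_mode
    result.legs = legs
    return result
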