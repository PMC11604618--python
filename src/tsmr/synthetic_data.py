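"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of real two-sample MR
inputs — a modest-n quantitative exposure GWAS (microbiome-abundance
scale), an intermediate mediator GWAS, and a large case/control outcome
GWAS with log-odds effects and correspondingly larger standard errors —
without touching individual-level data. Per SNP j:

* minor-allele frequency pⱼ ~ Uniform(maf_range)
* true instrument effect γⱼ from ``gamma_dist``
* exposure SE = 1/sqrt(2 pⱼ (1−pⱼ) n_exp); observed beta ~ N(γⱼ, se²)
* mediator beta ~ N(b1·γⱼ, se_med²)
* outcome beta ~ N((θ + b1·b2)·γⱼ + αⱼ, se_out²) with pleiotropy αⱼ

Outcome SEs use the binary-trait approximation
1/sqrt(2p(1−p)·N·phi·(1−phi)) with case fraction phi, so a disease GWAS of
realistic case imbalance yields realistically noisy log-odds estimates.
Optional mediator- and outcome-specific instrument blocks give those traits
their own genome-wide hits (needed for the b2 mediation leg and for reverse
MR); LD blocks, palindromic variants, allele flips and planted outliers
exercise clumping, harmonization and MR-PRESSO. All randomness flows from
the single config seed, so identical configs reproduce byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .gwas_io import LDMatrix, SummaryStats

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "simulate_study",
    "plant_outliers",
    "binary_trait_se",
]

_NONPALINDROMIC = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def binary_trait_se(n_case: int, n_control: int, maf) -> np.ndarray:
    """Approximate log-odds SE for a case/control GWAS.

    se ≈ 1 / sqrt(2 p (1−p) · N · phi (1−phi)) with N = n_case + n_control
    and case fraction phi; the standard large-sample approximation for a
    per-allele logistic effect.
    """
    n = n_case + n_control
    phi = n_case / n
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * phi * (1.0 - phi))


@dataclass
class SimulationConfig:
    """Generating parameters for a full exposure/mediator/outcome system.

    Sample sizes default to the study scale the package targets: a 5,959-
    participant quantitative exposure GWAS and a 1,748 case / 454,600
    control binary outcome GWAS. ``theta`` is the direct exposure→outcome
    log-odds effect; ``b1_true``/``b2_true`` the mediator-path effects, so
    the analytic total effect is theta + b1_true·b2_true.
    """

    n_snp: int = 20
    n_exp: int = 5959
    n_med: int = 5000
    n_case: int = 1748
    n_control: int = 454_600
    theta: float = 0.0
    b1_true: float = 0.0
    b2_true: float = 0.0
    # instrument-effect distribution: fixed list wins over (mean, sd)
    gamma_mean: float = 0.3
    gamma_sd: float = 0.05
    gamma_fixed: list | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    # pleiotropy: none | balanced | directional | inside_violating
    pleiotropy: str = "none"
    pleio_mu: float = 0.0
    pleio_tau: float = 0.0
    pleio_rho: float = 0.0
    n_outlier: int = 0
    outlier_displacement: float = 0.0
    palindromic_frac: float = 0.0
    flip_frac: float = 0.0
    ld_blocks: list = field(default_factory=list)  # [(extra_snps, r2), ...]
    # mediator-/outcome-specific instruments (their own genome-wide hits)
    n_snp_mediator: int = 0
    gamma_med_mean: float = 0.5
    gamma_med_sd: float = 0.05
    n_snp_outcome: int = 0
    gamma_out_mean: float = 0.25
    gamma_out_sd: float = 0.03
    theta_reverse: float = 0.0  # outcome → exposure effect (bidirectional systems)
    se_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("palindromic_frac", "flip_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if min(self.n_exp, self.n_med, self.n_case + self.n_control) < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if self.gamma_sd < 0 or self.pleio_tau < 0:
            raise ConfigurationError("spread parameters must be >= 0")
        if self.n_outlier > self.n_snp:
            raise ConfigurationError("n_outlier cannot exceed n_snp")
        if not 0 < self.maf_range[0] <= self.maf_range[1] < 1:
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.pleiotropy not in (
            "none", "balanced", "directional", "inside_violating",
        ):
            raise ConfigurationError(f"unknown pleiotropy model '{self.pleiotropy}'")


@dataclass
class GroundTruth:
    """Everything needed to recompute expected estimands analytically."""

    theta: float
    b1: float
    b2: float
    total: float  # theta + b1*b2, exactly
    rsids: list
    gamma: np.ndarray  # true exposure effects (0 for non-exposure SNPs)
    alpha: np.ndarray  # per-SNP pleiotropic outcome effects
    delta: np.ndarray  # true mediator-specific effects
    gamma_out: np.ndarray  # true outcome-specific effects
    outlier_rsids: list = field(default_factory=list)
    config: SimulationConfig | None = None

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        for key in ("gamma", "alpha", "delta", "gamma_out"):
            payload[key] = np.asarray(payload[key]).tolist()
        return json.dumps(payload, indent=2, default=str)


@dataclass
class SyntheticStudy:
    """Generated summary statistics plus their generating truth."""

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, ss in (
            ("exposure", self.exposure),
            ("mediator", self.mediator),
            ("outcome", self.outcome),
        ):
            ss.table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                            float_format="%.12g")
        self.ld.write(out / "ld.tsv")
        (out / "truth.json").write_text(self.truth.to_json() + "\n")


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    j = len(gamma)
    if cfg.pleiotropy == "none":
        return np.zeros(j)
    if cfg.pleiotropy == "balanced":
        return rng.normal(0.0, cfg.pleio_tau, j)
    if cfg.pleiotropy == "directional":
        return rng.normal(cfg.pleio_mu, cfg.pleio_tau, j)
    # inside_violating: pleiotropy correlated with instrument strength
    g_sd = cfg.gamma_sd if cfg.gamma_sd > 0 else 1.0
    z = rng.normal(0.0, 1.0, j)
    resid = float(np.sqrt(max(0.0, 1.0 - cfg.pleio_rho**2)))
    return (
        cfg.pleio_rho * cfg.pleio_tau / g_sd * (gamma - gamma.mean())
        + resid * cfg.pleio_tau * z
    )


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full exposure/mediator/outcome summary-statistic system."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_rep = int(sum(size for size, _ in cfg.ld_blocks))
    if len(cfg.ld_blocks) > cfg.n_snp:
        raise ConfigurationError("more LD blocks than index instruments")
    n_total = cfg.n_snp + n_rep + cfg.n_snp_mediator + cfg.n_snp_outcome

    # --- true effects -----------------------------------------------------
    if cfg.gamma_fixed is not None:
        if len(cfg.gamma_fixed) != cfg.n_snp:
            raise ConfigurationError("gamma_fixed length must equal n_snp")
        gamma_idx = np.asarray(cfg.gamma_fixed, dtype=float)
    else:
        gamma_idx = rng.normal(cfg.gamma_mean, cfg.gamma_sd, cfg.n_snp)
    alpha_idx = _draw_alpha(cfg, gamma_idx, rng)
    delta_med = rng.normal(cfg.gamma_med_mean, cfg.gamma_med_sd, cfg.n_snp_mediator)
    gamma_out = rng.normal(cfg.gamma_out_mean, cfg.gamma_out_sd, cfg.n_snp_outcome)

    total = cfg.theta + cfg.b1_true * cfg.b2_true

    # --- per-SNP bookkeeping ---------------------------------------------
    rsids = [f"rs{1000000 + i}" for i in range(n_total)]
    chrom = np.array([1 + (i % 22) for i in range(n_total)], dtype=object)
    pos = np.array(
        [1_000_000 + (i // 22) * 30_000_000 for i in range(n_total)], dtype=float
    )
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n_total)

    # true per-SNP effects on each trait
    mu_exp = np.zeros(n_total)
    mu_med = np.zeros(n_total)
    mu_out = np.zeros(n_total)
    gamma_full = np.zeros(n_total)
    alpha_full = np.zeros(n_total)
    delta_full = np.zeros(n_total)
    gamma_out_full = np.zeros(n_total)

    idx = np.arange(cfg.n_snp)
    gamma_full[idx] = gamma_idx
    alpha_full[idx] = alpha_idx
    mu_exp[idx] = gamma_idx
    mu_med[idx] = cfg.b1_true * gamma_idx
    mu_out[idx] = total * gamma_idx + alpha_idx

    # LD replicates: attenuated copies of index-SNP signals, co-located
    ld_pairs = []  # (replicate_index, index_index, r2)
    cursor = cfg.n_snp
    for b, (size, r2) in enumerate(cfg.ld_blocks):
        r = float(np.sqrt(r2))
        anchor = b  # block b hangs off index instrument b
        for s in range(int(size)):
            k = cursor
            cursor += 1
            chrom[k] = chrom[anchor]
            pos[k] = pos[anchor] + 50_000.0 * (s + 1)
            maf[k] = maf[anchor]
            mu_exp[k] = r * gamma_idx[anchor]
            mu_med[k] = cfg.b1_true * r * gamma_idx[anchor]
            mu_out[k] = total * r * gamma_idx[anchor] + r * alpha_idx[anchor]
            ld_pairs.append((k, anchor, r2))

    med_idx = np.arange(cursor, cursor + cfg.n_snp_mediator)
    delta_full[med_idx] = delta_med
    mu_med[med_idx] = delta_med
    mu_out[med_idx] = cfg.b2_true * delta_med
    cursor += cfg.n_snp_mediator

    out_idx = np.arange(cursor, cursor + cfg.n_snp_outcome)
    gamma_out_full[out_idx] = gamma_out
    mu_out[out_idx] = gamma_out
    mu_exp[out_idx] = cfg.theta_reverse * gamma_out

    # --- standard errors and observed betas -------------------------------
    se_exp = cfg.se_scale / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
    se_med = cfg.se_scale / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_med)
    se_out = cfg.se_scale * binary_trait_se(cfg.n_case, cfg.n_control, maf)

    beta_exp = rng.normal(mu_exp, se_exp)
    beta_med = rng.normal(mu_med, se_med)
    beta_out = rng.normal(mu_out, se_out)

    # --- alleles: palindromic fraction, then outcome-side flips ------------
    pal_mask = rng.random(n_total) < cfg.palindromic_frac
    allele_pick = rng.integers(0, 8, n_total)
    ea = np.empty(n_total, dtype=object)
    oa = np.empty(n_total, dtype=object)
    for i in range(n_total):
        pool = _PALINDROMIC if pal_mask[i] else _NONPALINDROMIC
        ea[i], oa[i] = pool[allele_pick[i] % len(pool)]

    def _frame(beta, se, n_samples) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": rsids,
                "chromosome": chrom,
                "base_pair_location": pos.astype(int),
                "effect_allele": ea,
                "other_allele": oa,
                "effect_allele_frequency": maf,
                "beta": beta,
                "standard_error": se,
                "p_value": _pvalues(beta, se),
                "n": n_samples,
            }
        )

    exp_tab = _frame(beta_exp, se_exp, cfg.n_exp)
    med_tab = _frame(beta_med, se_med, cfg.n_med)
    out_tab = _frame(beta_out, se_out, cfg.n_case + cfg.n_control)

    flip_mask = rng.random(n_total) < cfg.flip_frac
    if flip_mask.any():
        f = flip_mask
        out_tab.loc[f, ["effect_allele", "other_allele"]] = out_tab.loc[
            f, ["other_allele", "effect_allele"]
        ].to_numpy()
        out_tab.loc[f, "beta"] = -out_tab.loc[f, "beta"]
        out_tab.loc[f, "effect_allele_frequency"] = (
            1.0 - out_tab.loc[f, "effect_allele_frequency"]
        )

    # --- LD matrix ---------------------------------------------------------
    r2 = np.eye(n_total)
    for k, anchor, block_r2 in ld_pairs:
        r2[k, anchor] = r2[anchor, k] = block_r2
    # replicates of the same anchor correlate with each other too
    by_anchor: dict[int, list[tuple[int, float]]] = {}
    for k, anchor, block_r2 in ld_pairs:
        by_anchor.setdefault(anchor, []).append((k, block_r2))
    for members in by_anchor.values():
        for a_i, (ki, ri) in enumerate(members):
            for kj, rj in members[a_i + 1:]:
                r2[ki, kj] = r2[kj, ki] = min(ri, rj)
    ld = LDMatrix(rsids, r2)

    truth = GroundTruth(
        theta=cfg.theta,
        b1=cfg.b1_true,
        b2=cfg.b2_true,
        total=total,
        rsids=rsids,
        gamma=gamma_full,
        alpha=alpha_full,
        delta=delta_full,
        gamma_out=gamma_out_full,
        config=cfg,
    )
    study = SyntheticStudy(
        exposure=SummaryStats("synthetic_exposure", exp_tab, group="synthetic"),
        mediator=SummaryStats("synthetic_mediator", med_tab, group="synthetic"),
        outcome=SummaryStats("synthetic_outcome", out_tab, group="synthetic"),
        ld=ld,
        truth=truth,
    )
    if cfg.n_outlier > 0:
        study = plant_outliers(
            study, cfg.n_outlier, cfg.outlier_displacement, seed=cfg.seed + 1
        )
    return study


def plant_outliers(
    study: SyntheticStudy, k: int, displacement: float, *, seed: int
) -> SyntheticStudy:
    """Shift k instruments' outcome betas by ``displacement`` outcome-SEs.

    Outliers are drawn among the exposure index instruments; their rsids are
    recorded in the truth record. k = 0 returns the study unchanged.
    """
    cfg = study.truth.config
    n_idx = cfg.n_snp if cfg is not None else len(study.outcome.table)
    if k > n_idx:
        raise ConfigurationError("cannot plant more outliers than instruments")
    if k == 0:
        return study
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n_idx, size=k, replace=False))
    out_tab = study.outcome.table.copy()
    shift = displacement * out_tab.loc[chosen, "standard_error"]
    # sign of observed outcome beta preserved in direction of displacement
    out_tab.loc[chosen, "beta"] = out_tab.loc[chosen, "beta"] + shift
    out_tab["p_value"] = _pvalues(
        out_tab["beta"].to_numpy(), out_tab["standard_error"].to_numpy()
    )
    truth = dataclasses.replace(
        study.truth,
        outlier_rsids=[study.truth.rsids[i] for i in chosen],
    )
    outcome = SummaryStats(
        study.outcome.trait_id, out_tab, study.outcome.trait_name, study.outcome.group
    )
    return SyntheticStudy(study.exposure, study.mediator, outcome, study.ld, truth)
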