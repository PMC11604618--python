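"""Reading, validation, harmonization and writing of GWAS summary statistics.

Summary statistics are kept as pandas DataFrames with a canonical column
vocabulary following GWAS-SSF naming::

    rsid, chromosome, base_pair_location, effect_allele, other_allele,
    effect_allele_frequency, beta, standard_error, p_value, n

``beta`` is the additive per-effect-allele association: a log odds ratio for
binary traits, standardized units otherwise. Harmonization aligns outcome
(and optionally mediator) associations to the exposure's effect allele,
resolving strand complements and flagging palindromic (A/T, C/G) variants,
which are excluded by default because their strand cannot be resolved from
alleles alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError, EmptyOverlapError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "rsid",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
]

#: Columns that must be present after applying the user's column map.
REQUIRED_COLUMNS = [
    "rsid",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: eaf band inside which a palindromic SNP cannot be oriented by frequency.
EAF_AMBIGUOUS_BAND = (0.42, 0.58)


@dataclass
class SummaryStats:
    """One trait's GWAS summary associations, uniquely keyed by rsid."""

    trait_id: str
    table: pd.DataFrame
    trait_name: str = ""
    group: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        if len(self.table) == 0:
            raise EmptyInputError(f"trait '{self.trait_id}' has no valid records")
        if self.table["rsid"].duplicated().any():
            n_dup = int(self.table["rsid"].duplicated().sum())
            logger.warning(
                "trait %s: %d duplicated rsids, keeping first occurrence",
                self.trait_id,
                n_dup,
            )
            self.table = self.table.drop_duplicates("rsid", keep="first")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, rsids: Iterable[str]) -> "SummaryStats":
        keep = self.table[self.table["rsid"].isin(set(rsids))]
        return SummaryStats(self.trait_id, keep.copy(), self.trait_name, self.group)


@dataclass
class HarmonizedSet:
    """Exposure/outcome (optionally mediator) betas aligned to one effect allele.

    ``table`` keeps one row per input exposure rsid. Retained rows have
    ``dropped_reason == "none"``; every dropped row carries a reason
    (``palindromic``, ``allele_mismatch``, ``missing_in_outcome``,
    ``missing_in_mediator``).
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    mediator_id: str | None = None

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["dropped_reason"] == "none"]

    @property
    def n_snp(self) -> int:
        return int(len(self.retained))

    def restrict(self, rsids: Iterable[str]) -> "HarmonizedSet":
        keep = set(rsids)
        tab = self.table[self.table["rsid"].isin(keep)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_id, self.outcome_id, tab, self.mediator_id)


@dataclass
class LDMatrix:
    """Symmetric matrix of squared correlations (r²) keyed by rsid."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.rsids = list(self.rsids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("LD matrix shape does not match rsid count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ConfigurationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ConfigurationError("LD r² values must lie in [0, 1]")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ConfigurationError(
                f"LD matrix is missing the pair ({a}, {b})"
            ) from exc

    def write(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids)
        frame.to_csv(path, sep="\t", float_format="%.12g", index_label="rsid")

    @classmethod
    def read(cls, path: str | Path) -> "LDMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.columns), frame.to_numpy(dtype=float))


def _validate_rows(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-SNP invariants; return (clean, n_dropped)."""
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    df["rsid"] = df["rsid"].astype(str)
    for col in ("beta", "standard_error", "p_value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "effect_allele_frequency" in df.columns:
        df["effect_allele_frequency"] = pd.to_numeric(
            df["effect_allele_frequency"], errors="coerce"
        )
    else:
        df["effect_allele_frequency"] = np.nan
    if "n" in df.columns:
        df["n"] = pd.to_numeric(df["n"], errors="coerce")
    else:
        df["n"] = np.nan

    eaf = df["effect_allele_frequency"]
    ok = (
        df["beta"].notna()
        & (df["standard_error"] > 0)
        & (df["p_value"] > 0)
        & (df["p_value"] <= 1)
        & df["effect_allele"].isin(_COMPLEMENT)
        & df["other_allele"].isin(_COMPLEMENT)
        & (df["effect_allele"] != df["other_allele"])
        & (eaf.isna() | ((eaf >= 0) & (eaf <= 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("trait %s: dropped %d invalid rows", trait_id, n_dropped)
    return df[ok], n_dropped


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_name: str = "",
    group: str = "",
    sep: str | None = None,
) -> SummaryStats:
    """Read one trait's GWAS summary statistics from a delimited text file.

    Parameters
    ----------
    path : path to a TSV (default) or CSV table, one row per SNP.
    column_map : optional mapping from the file's column names to the
        canonical GWAS-SSF vocabulary, e.g. ``{"SNP": "rsid", "se":
        "standard_error"}``.
    sep : field delimiter; autodetected (tab/comma) when None.

    Rows failing the per-SNP invariants (se > 0, p in (0, 1], valid distinct
    A/C/G/T alleles, eaf in [0, 1] when present) are dropped and counted in
    ``SummaryStats.n_dropped``; alleles are upper-cased. Duplicate rsids keep
    the first occurrence.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    clean, n_dropped = _validate_rows(df, trait_id or path.stem)
    if len(clean) == 0:
        raise EmptyInputError(f"{path.name}: zero valid rows after validation")
    clean = clean[[c for c in CANONICAL_COLUMNS if c in clean.columns]]
    return SummaryStats(
        trait_id=trait_id or path.stem,
        table=clean.reset_index(drop=True),
        trait_name=trait_name,
        group=group,
        n_dropped=n_dropped,
    )


def is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC_PAIRS


def _match_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """Classify how trait-y alleles relate to trait-x alleles.

    Returns "same", "flip", or None when irreconcilable. Strand complements
    are resolved before comparison.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flip"
    cey, coy = _COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)
    if (cey, coy) == (ea_x, oa_x):
        return "same"
    if (cey, coy) == (oa_x, ea_x):
        return "flip"
    return None


def _align_one(
    row_x: Mapping, row_y: Mapping, palindrome_policy: str
) -> tuple[str | None, bool, str]:
    """Align one trait-y record to the exposure orientation of row_x.

    Returns (action, is_palindromic, reason) where action is "same"/"flip"
    or None when the row must be dropped with ``reason``.
    """
    ea_x, oa_x = row_x["effect_allele"], row_x["other_allele"]
    ea_y, oa_y = row_y["effect_allele"], row_y["other_allele"]
    pal = is_palindromic(ea_x, oa_x)
    if pal:
        if frozenset((ea_y, oa_y)) != frozenset((ea_x, oa_x)):
            return None, True, "allele_mismatch"
        if palindrome_policy == "exclude":
            return None, True, "palindromic"
        # eaf_infer: orient by allele frequency; ambiguous band or missing
        # frequency on either side cannot be resolved.
        lo, hi = EAF_AMBIGUOUS_BAND
        fx = row_x.get("effect_allele_frequency", np.nan)
        fy = row_y.get("effect_allele_frequency", np.nan)
        if pd.isna(fx) or pd.isna(fy) or lo <= fx <= hi or lo <= fy <= hi:
            return None, True, "palindromic"
        return ("same" if (fx < 0.5) == (fy < 0.5) else "flip"), True, "none"
    action = _match_alleles(ea_x, oa_x, ea_y, oa_y)
    if action is None:
        return None, False, "allele_mismatch"
    return action, False, "none"


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "exclude",
    mediator: SummaryStats | None = None,
) -> HarmonizedSet:
    """Align outcome (and optional mediator) betas to the exposure effect allele.

    For each exposure rsid found in the outcome: matching alleles keep the
    outcome beta as-is; swapped alleles (outcome effect allele equals the
    exposure other allele) negate the outcome beta, replace eaf by 1 − eaf
    and set ``allele_flipped``; strand complements are resolved first.
    Palindromic exposure SNPs are excluded under the default policy, or
    oriented by allele frequency under ``eaf_infer`` (dropped when either
    frequency falls in the ambiguous band around 0.5). Irreconcilable
    alleles are dropped with reason ``allele_mismatch``.
    """
    if palindrome_policy not in ("exclude", "eaf_infer"):
        raise ConfigurationError(f"unknown palindrome policy '{palindrome_policy}'")
    out_by_rsid = {r["rsid"]: r for r in outcome.table.to_dict("records")}
    med_by_rsid = (
        {r["rsid"]: r for r in mediator.table.to_dict("records")} if mediator else None
    )
    if not any(rs in out_by_rsid for rs in exposure.table["rsid"]):
        raise EmptyOverlapError(
            f"no shared rsids between exposure '{exposure.trait_id}' "
            f"and outcome '{outcome.trait_id}'"
        )

    rows = []
    for rec in exposure.table.to_dict("records"):
        row = {
            "rsid": rec["rsid"],
            "chromosome": rec.get("chromosome"),
            "base_pair_location": rec.get("base_pair_location"),
            "effect_allele": rec["effect_allele"],
            "other_allele": rec["other_allele"],
            "eaf_exp": rec.get("effect_allele_frequency", np.nan),
            "beta_exp": rec["beta"],
            "se_exp": rec["standard_error"],
            "p_exp": rec["p_value"],
            "beta_out": np.nan,
            "se_out": np.nan,
            "p_out": np.nan,
            "eaf_out": np.nan,
            "palindromic": is_palindromic(rec["effect_allele"], rec["other_allele"]),
            "allele_flipped": False,
            "dropped_reason": "none",
        }
        orow = out_by_rsid.get(rec["rsid"])
        if orow is None:
            row["dropped_reason"] = "missing_in_outcome"
            rows.append(row)
            continue
        action, pal, reason = _align_one(rec, orow, palindrome_policy)
        row["palindromic"] = pal
        if action is None:
            row["dropped_reason"] = reason
            rows.append(row)
            continue
        sign = -1.0 if action == "flip" else 1.0
        eaf_o = orow.get("effect_allele_frequency", np.nan)
        row["beta_out"] = sign * orow["beta"]
        row["se_out"] = orow["standard_error"]
        row["p_out"] = orow["p_value"]
        row["eaf_out"] = 1.0 - eaf_o if (action == "flip" and pd.notna(eaf_o)) else eaf_o
        row["allele_flipped"] = action == "flip"

        if med_by_rsid is not None:
            mrow = med_by_rsid.get(rec["rsid"])
            if mrow is None:
                row["dropped_reason"] = "missing_in_mediator"
                rows.append(row)
                continue
            m_action, _, m_reason = _align_one(rec, mrow, palindrome_policy)
            if m_action is None:
                row["dropped_reason"] = m_reason
                rows.append(row)
                continue
            m_sign = -1.0 if m_action == "flip" else 1.0
            row["beta_med"] = m_sign * mrow["beta"]
            row["se_med"] = mrow["standard_error"]
            row["p_med"] = mrow["p_value"]
        rows.append(row)

    table = pd.DataFrame(rows)
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        table=table,
        mediator_id=mediator.trait_id if mediator else None,
    )


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if dataclasses.is_dataclass(records) and not isinstance(records, type):
        records = [records]
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot serialize record of type {type(rec)!r}")
    return pd.DataFrame(rows)


def write_results(records, path: str | Path, format: str = "tsv") -> None:
    """Write a result collection (dataclasses, dicts or a DataFrame) to disk.

    Column order is deterministic and floats carry 12 significant digits so a
    round-trip read reproduces values.
    """
    frame = _records_to_frame(records)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        path.write_text(
            json.dumps(frame.to_dict("records"), indent=2, default=_default) + "\n"
        )
    else:
        raise ConfigurationError(f"unknown output format '{format}'")
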