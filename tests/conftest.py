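import numpy as np
import pandas as pd
import pytest

from tsmr.gwas_io import SummaryStats


@pytest.fixture
def harmonized_frame() -> pd.DataFrame:
    """Seeded 8-instrument harmonized table with a true slope of 0.25."""
    rng = np.random.default_rng(42)
    j = 8
    bx = rng.normal(0.3, 0.05, j)
    sx = rng.uniform(0.01, 0.03, j)
    by = 0.25 * bx + rng.normal(0.0, 0.02, j)
    sy = rng.uniform(0.02, 0.05, j)
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(j)],
            "beta_exp": bx,
            "se_exp": sx,
            "beta_out": by,
            "se_out": sy,
        }
    )


@pytest.fixture
def mvmr_frame() -> pd.DataFrame:
    """Seeded 10-instrument table with exposure and mediator columns."""
    rng = np.random.default_rng(7)
    j = 10
    bx = rng.normal(0.3, 0.08, j)
    bm = rng.normal(0.4, 0.1, j)
    by = 0.2 * bx + 0.1 * bm + rng.normal(0.0, 0.01, j)
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(j)],
            "beta_exp": bx,
            "se_exp": rng.uniform(0.01, 0.02, j),
            "beta_med": bm,
            "se_med": rng.uniform(0.01, 0.02, j),
            "beta_out": by,
            "se_out": rng.uniform(0.02, 0.04, j),
        }
    )


def make_stats(
    trait_id: str,
    rows: list[dict],
    group: str = "",
) -> SummaryStats:
    """Build a SummaryStats from shorthand row dicts with sensible defaults."""
    defaults = {
        "chromosome": 1,
        "base_pair_location": 1_000_000,
        "effect_allele": "A",
        "other_allele": "G",
        "effect_allele_frequency": 0.3,
        "beta": 0.1,
        "standard_error": 0.02,
        "p_value": 1e-6,
        "n": 1000,
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["rsid"] = f"rs{i + 1}"
        rec["base_pair_location"] = 1_000_000 + i * 50_000_000
        rec.update(row)
        full.append(rec)
    return SummaryStats(trait_id, pd.DataFrame(full), group=group)
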