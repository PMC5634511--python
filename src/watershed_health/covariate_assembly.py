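"""Child-level analysis table: recodes, climate z-scores, environment join.

Water-source and sanitation categories are dichotomized into improved /
unimproved following the WHO/JMP classification. Long-term monthly climate
means are linked to each cluster's survey month with a one-month lag and a
month-over-month change term, both standardized to z-scores over the
pooled analysis sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .schema import ENV_COLUMNS, ID_COLUMNS, MODEL_TERMS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_JMP_WATER",
    "DEFAULT_JMP_SANITATION",
    "recode_jmp",
    "standardize_climate",
    "build_table",
]

# WHO/JMP improved (1) vs unimproved (0) drinking-water source categories.
DEFAULT_JMP_WATER: dict[str, int] = {
    "piped into dwelling": 1,
    "piped to yard/plot": 1,
    "public tap/standpipe": 1,
    "tube well or borehole": 1,
    "protected well": 1,
    "protected spring": 1,
    "rainwater": 1,
    "bottled water": 1,
    "unprotected well": 0,
    "unprotected spring": 0,
    "tanker truck": 0,
    "cart with small tank": 0,
    "surface water": 0,
}

# WHO/JMP improved (1) vs unimproved (0) sanitation facility categories.
DEFAULT_JMP_SANITATION: dict[str, int] = {
    "flush to piped sewer system": 1,
    "flush to septic tank": 1,
    "flush to pit latrine": 1,
    "ventilated improved pit latrine": 1,
    "pit latrine with slab": 1,
    "composting toilet": 1,
    "flush to somewhere else": 0,
    "pit latrine without slab/open pit": 0,
    "bucket": 0,
    "hanging toilet/hanging latrine": 0,
    "no facility/bush/field": 0,
}


def recode_jmp(
    source_category: str,
    kind: str = "water",
    mapping: dict[str, int] | None = None,
) -> int:
    """Dichotomize a water or sanitation category into improved (1) or not (0).

    The shipped mapping follows the WHO/JMP definitions; pass ``mapping``
    to override (e.g., from a YAML config). Unknown categories raise with
    the list of valid ones.
    """
    if mapping is None:
        if kind == "water":
            mapping = DEFAULT_JMP_WATER
        elif kind == "sanitation":
            mapping = DEFAULT_JMP_SANITATION
        else:
            raise ValueError(f"kind must be 'water' or 'sanitation', got {kind!r}")
    key = source_category.strip().lower()
    if key not in mapping:
        raise KeyError(
            f"unknown {kind} category {source_category!r}; valid categories: {sorted(mapping)}"
        )
    return int(mapping[key])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance column")
    return (x - x.mean()) / sd


def standardize_climate(
    climatology: pd.DataFrame,
    survey_month: pd.Series,
) -> pd.DataFrame:
    """One-month-lag climate z-scores and standardized change terms.

    ``climatology`` is long format with columns (cluster_id, month, precip,
    temp), months 1-12 as long-term means; ``survey_month`` maps cluster_id
    to the interview month. For a survey in month m the lag value is the
    climatology of month m-1 (January wraps to December) and the change
    term is month m minus month m-1. Both are standardized to mean 0, SD 1
    over the pooled sample of clusters.
    """
    if survey_month.empty or len(survey_month) < 2:
        raise ValueError("need at least 2 clusters to standardize climate")
    wide_p = climatology.pivot(index="cluster_id", columns="month", values="precip")
    wide_t = climatology.pivot(index="cluster_id", columns="month", values="temp")
    if wide_p.isna().any().any() or set(wide_p.columns) != set(range(1, 13)):
        raise ValueError("climatology must cover months 1..12 for every cluster")

    m = survey_month.loc[wide_p.index].to_numpy(dtype=int)
    lag = np.where(m == 1, 12, m - 1)
    rows = np.arange(len(wide_p))
    p_now = wide_p.to_numpy()[rows, m - 1]
    p_lag = wide_p.to_numpy()[rows, lag - 1]
    t_now = wide_t.to_numpy()[rows, m - 1]
    t_lag = wide_t.to_numpy()[rows, lag - 1]

    return pd.DataFrame(
        {
            "precip_lag_z": _zscore(p_lag),
            "precip_change": _zscore(p_now - p_lag),
            "temp_lag_z": _zscore(t_lag),
            "temp_change": _zscore(t_now - t_lag),
        },
        index=wide_p.index,
    )


def build_table(survey: pd.DataFrame, cluster_environment: pd.DataFrame) -> pd.DataFrame:
    """Join cluster-level environment onto child rows and enforce integrity.

    Every child row must reference a household and cluster present in the
    survey, and every cluster must have environment values. Rows with any
    missing model covariate are dropped with a logged count (listwise
    deletion).
    """
    for col in ID_COLUMNS:
        if col not in survey.columns:
            raise ValueError(f"survey table is missing identifier column {col!r}")
    env = (
        cluster_environment.set_index("cluster_id")
        if "cluster_id" in cluster_environment.columns
        else cluster_environment
    )
    missing_env = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing_env:
        raise ValueError(f"cluster environment is missing columns: {missing_env}")
    orphans = set(survey["cluster_id"]) - set(env.index)
    if orphans:
        raise ValueError(f"clusters without environment values: {sorted(orphans)[:10]}")
    # one household must not span clusters
    hh_clusters = survey.groupby("household_id")["cluster_id"].nunique()
    if (hh_clusters > 1).any():
        bad = hh_clusters[hh_clusters > 1].index.tolist()[:10]
        raise ValueError(f"households referenced by multiple clusters: {bad}")

    table = survey.merge(
        env[list(ENV_COLUMNS)], left_on="cluster_id", right_index=True, how="left"
    )
    model_cols = ["diarrhea", *MODEL_TERMS]
    complete = table[model_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_table: dropped %d of %d rows with missing covariates", n_dropped, len(table))
    return table.loc[complete].reset_index(drop=True)
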