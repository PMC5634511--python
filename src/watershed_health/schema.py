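"""Column names shared across the pipeline.

The fixed-effect terms are listed in the order they enter the linear
predictor of the three-level logit: child age, household socioeconomics,
cluster climate (one-month lag levels and month-over-month changes), then
the two upstream watershed indices.
"""

OUTCOME = "diarrhea"

#: Fixed-effect terms of the main model, in canonical order.
MODEL_TERMS = (
    "age",
    "wealth_high",
    "edu_secondary",
    "improved_sanitation",
    "improved_water",
    "precip_lag_z",
    "precip_change",
    "temp_lag_z",
    "temp_change",
    "human_index",
    "tree_index",
)

#: Binary household-level policy variables (used for discrete marginal effects).
BINARY_POLICY_TERMS = (
    "wealth_high",
    "edu_secondary",
    "improved_sanitation",
    "improved_water",
)

#: Cluster-level environmental columns joined onto the child table.
ENV_COLUMNS = (
    "human_index",
    "tree_index",
    "precip_lag_z",
    "precip_change",
    "temp_lag_z",
    "temp_change",
)

ID_COLUMNS = ("child_id", "household_id", "cluster_id")
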