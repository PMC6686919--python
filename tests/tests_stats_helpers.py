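"""Shared helper: pathway-call matrices sampled straight from generator truth.

For Monte-Carlo statistics (type-I error, power) only the proteome sizes and
the planted pathway membership matter, so the matrix is built from
``sample_truth`` without synthesising any sequences.
"""

from __future__ import annotations

import pandas as pd

from reservescan.pathway_caller import PathwayCallMatrix
from reservescan.synthetic_cohort import (
    CohortConfig,
    DistributionSpec,
    Scenario,
    sample_truth,
)


def null_cohort_matrix(
    registry,
    seed: int,
    size_effect: int = 0,
    n: int = 400,
    decoy_mean: float = 3100.0,
    decoy_sd: float = 300.0,
) -> PathwayCallMatrix:
    """Two equal groups (with/without WS/DGAT); decoy counts normal
    (mean ``decoy_mean``, sd ``decoy_sd``); the positive group shifted by
    ``size_effect``."""
    config = CohortConfig(
        n_proteomes=n,
        scenario_table=(
            Scenario("With", {"ws_dgat": 1}, 0.5),
            Scenario("Without", {}, 0.5),
        ),
        decoy_count_sampler=DistributionSpec(
            "normal", {"mean": decoy_mean, "sd": decoy_sd}, minimum=1
        ),
        size_effect=size_effect,
        rng_seed=seed,
    )
    truths = sample_truth(config, registry)
    rows = [
        {
            "proteome_id": t.proteome_id,
            "proteome_size": t.protein_count,
            "we_tag": bool(t.planted_enzymes),
            "polyp_status": "absent",
        }
        for t in truths
    ]
    return PathwayCallMatrix(data=pd.DataFrame(rows), enzyme_ids=[], pathway_ids=["we_tag"])
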