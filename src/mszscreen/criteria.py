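"""Stage-resolved marker criteria and planted-signal recovery metrics.

A gene qualifies as a mesodermal-stem-zone marker when, against a detection
threshold ``delta``:

i.   it is not expressed in any region during gastrulation;
ii.  at the initiation of axial elongation it is expressed in the anterior
     primitive streak and nowhere else (anterior-midline expression may
     optionally be tolerated);
iii. it retains anterior-PS expression at every elongation timepoint.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from mszscreen.simulate import REGIONS, STAGES

_CALL_COLUMNS = [
    "gene_id",
    "c1_not_gastrulation",
    "c2_anteriorPS_only_at_initiation",
    "c3_retained_through_elongation",
    "is_marker",
]


def _stage_cube(stages: pd.DataFrame, candidates: Sequence[str]) -> pd.DataFrame:
    """Pivot the long stage table to (gene) x (stage, timepoint, region).

    Raises ``ValueError`` naming the first missing stage/region combination.
    """
    required = {"gene_id", "stage", "timepoint", "region", "value"}
    missing_cols = required - set(stages.columns)
    if missing_cols:
        raise ValueError(f"stage table is missing columns: {sorted(missing_cols)}")
    bad_stage = set(stages["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stage name(s): {sorted(bad_stage)}")
    bad_region = set(stages["region"]) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown region name(s): {sorted(bad_region)}")

    sub = stages[stages["gene_id"].isin(set(candidates))]
    absent = set(candidates) - set(sub["gene_id"])
    if absent:
        raise ValueError(
            f"candidate gene(s) absent from the stage table: {sorted(absent)[:5]}"
        )
    cube = sub.pivot_table(
        index="gene_id", columns=["stage", "timepoint", "region"],
        values="value", aggfunc="first",
    )
    # Every gene must cover every (stage, timepoint, region) seen in the table.
    expected = sorted(
        {(s, t) for s, t, _ in cube.columns}, key=lambda st: (STAGES.index(st[0]), st[1])
    )
    for stage in STAGES:
        if not any(s == stage for s, _ in expected):
            raise ValueError(f"stage table has no rows for stage {stage!r}")
    for s, t in expected:
        for r in REGIONS:
            if (s, t, r) not in cube.columns:
                raise ValueError(
                    f"missing stage/region combination: ({s}, timepoint {t}, {r})"
                )
    nan_mask = cube.isna()
    if nan_mask.to_numpy().any():
        g = cube.index[nan_mask.any(axis=1)][0]
        col = nan_mask.columns[nan_mask.loc[g]][0]
        raise ValueError(
            f"gene {g!r} is missing stage/region combination "
            f"({col[0]}, timepoint {col[1]}, {col[2]})"
        )
    if (cube.to_numpy() < 0).any():
        raise ValueError("stage expression contains negative values")
    return cube


def apply_marker_criteria(
    stages: pd.DataFrame,
    candidates: Sequence[str],
    delta: float = 1.0,
    allow_midline_at_initiation: bool = False,
) -> pd.DataFrame:
    """Evaluate the three marker criteria for each candidate gene.

    Returns one row per candidate (input order preserved) with the three
    per-criterion booleans and ``is_marker`` = their conjunction.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if not len(candidates):
        return pd.DataFrame(columns=_CALL_COLUMNS)
    cube = _stage_cube(stages, candidates).loc[list(dict.fromkeys(candidates))]
    on = cube >= delta

    gastrulation = on.loc[:, on.columns.get_level_values("stage") == "gastrulation"]
    c1 = ~gastrulation.any(axis=1)

    init = on.loc[:, on.columns.get_level_values("stage") == "initiation"]
    init = init.droplevel(["stage", "timepoint"], axis=1)
    off_regions = [r for r in REGIONS if r != "anterior_PS"]
    if allow_midline_at_initiation:
        off_regions = [r for r in off_regions if r != "anterior_midline"]
    c2 = init["anterior_PS"] & ~init[off_regions].any(axis=1)

    elong = on.loc[:, on.columns.get_level_values("stage") == "elongation"]
    elong_ps = elong.loc[:, elong.columns.get_level_values("region") == "anterior_PS"]
    c3 = elong_ps.all(axis=1)

    calls = pd.DataFrame(
        {
            "gene_id": cube.index,
            "c1_not_gastrulation": c1.to_numpy(),
            "c2_anteriorPS_only_at_initiation": c2.to_numpy(),
            "c3_retained_through_elongation": c3.to_numpy(),
        }
    )
    calls["is_marker"] = (
        calls["c1_not_gastrulation"]
        & calls["c2_anteriorPS_only_at_initiation"]
        & calls["c3_retained_through_elongation"]
    )
    return calls.reset_index(drop=True)


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Precision/recall of marker calls against the planted gene classes.

    Positives are called markers; true positives are planted ``msz_marker``
    genes.  The 0/0 case is defined as 0 for both precision and recall.
    Genes absent from ``calls`` (e.g. filtered out upstream) count as
    negative calls.
    """
    called = set(calls.loc[calls["is_marker"], "gene_id"])
    unknown = called - set(truth["gene_id"])
    if unknown:
        raise ValueError(f"called gene(s) absent from truth: {sorted(unknown)[:5]}")
    true_pos_genes = set(truth.loc[truth["gene_class"] == "msz_marker", "gene_id"])
    tp = len(called & true_pos_genes)
    fp = len(called - true_pos_genes)
    fn = len(true_pos_genes - called)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "n_true_positive": tp,
        "n_false_positive": fp,
        "n_false_negative": fn,
    }
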