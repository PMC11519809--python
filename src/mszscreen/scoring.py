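"""Paired red/white enrichment scoring, aggregate ranking and selection.

The scoring rule is applied per (method, replicate) pair of a labelled
"red" sample and its unlabelled "white" partner, on normalized abundances:

* score 2 — the white abundance is exactly zero and the red abundance is at
  least ``tau`` (a "significant" count in the red sample, nothing in white);
* score 1 — otherwise, the red abundance is at least ``fold_threshold``
  times the (positive) white abundance;
* score 0 — anything else.

The aggregate score is the sum over pairs (0..2 x n_pairs); genes are ranked
by aggregate score with deterministic tie-breaking.  Candidate selection
keeps consistently enriched genes, removes a discard list of known
nonspecific genes, and rescues low-ranking genes with extreme enrichment in
at least ``rescue_min_pairs`` pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds of the pair-scoring rule.

    ``tau`` is the minimum normalized abundance for a red count to be
    considered significant in the zero-in-white branch (units of the chosen
    normalization, CPM by default).  ``pseudocount`` is used only in the
    reported fold changes, never in score decisions.
    """

    fold_threshold: float = 5.0
    tau: float = 1.0
    pseudocount: float = 0.0
    normalization: str = "cpm"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError(
                f"fold_threshold must be > 1, got {self.fold_threshold}"
            )
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.normalization not in ("cpm", "none"):
            raise ValueError(
                f"normalization must be 'cpm' or 'none', got {self.normalization!r}"
            )


@dataclass(frozen=True)
class SelectionParams:
    """Candidate-selection rules (consistency, discard, rescue)."""

    consistency_rule: str = "all_pairs_positive"
    min_aggregate_score: int = 6
    discard: frozenset[str] = frozenset()
    rescue_min_pairs: int = 2
    rescue_fold: float = 25.0

    def __post_init__(self) -> None:
        if self.consistency_rule not in ("all_pairs_positive", "min_aggregate"):
            raise ValueError(
                "consistency_rule must be 'all_pairs_positive' or "
                f"'min_aggregate', got {self.consistency_rule!r}"
            )
        if self.rescue_min_pairs < 0:
            raise ValueError(
                f"rescue_min_pairs must be >= 0, got {self.rescue_min_pairs}"
            )

    def replace(self, **changes) -> "SelectionParams":
        return replace(self, **changes)


@dataclass
class PairScores:
    """Per-(gene, pair) scores and fold changes.

    ``fold_changes`` is red/(white+pseudocount), NaN where white is zero and
    the pseudocount is zero.  ``log_ratios`` is log(red+1) - log(white+1),
    always defined; its pair-average feeds the ranking tie-break.
    """

    scores: pd.DataFrame  # gene x pair, int in {0,1,2}
    fold_changes: pd.DataFrame  # gene x pair, float (NaN = undefined)
    log_ratios: pd.DataFrame  # gene x pair, float
    pairs: pd.DataFrame  # pair_id, method, replicate, red_sample, white_sample

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def normalize_counts(counts: pd.DataFrame, params: ScoringParams) -> pd.DataFrame:
    """Return per-sample normalized abundances (CPM or identity).

    An all-zero sample column is left all-zero and logged as a warning.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    if params.normalization == "none":
        return counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        for s in counts.columns[zero]:
            logger.warning("sample %s has zero total counts; left all-zero", s)
    safe = totals.where(~zero, 1.0)
    return counts.div(safe, axis=1) * 1e6


def score_gene_pair(red: float, white: float, params: ScoringParams) -> int:
    """Score a single red/white abundance pair; see module docstring.

    The zero-in-white test takes precedence: the fold rule is undefined at
    white = 0, and absence from the white sample is the stronger evidence.
    """
    if red < 0 or white < 0:
        raise ValueError(f"abundances must be >= 0, got red={red}, white={white}")
    if white == 0:
        return 2 if red >= params.tau else 0
    if red >= params.fold_threshold * white:
        return 1
    return 0


def make_pairs(samples: pd.DataFrame) -> pd.DataFrame:
    """Build the (method, replicate) red/white pair table from a sample sheet.

    Raises ``ValueError`` naming any sample that cannot be paired.
    """
    required = {"sample_id", "color", "method", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    bad_color = set(samples["color"]) - {"red", "white"}
    if bad_color:
        raise ValueError(f"unknown sample colors: {sorted(bad_color)}")
    rows = []
    for (method, rep), grp in samples.groupby(["method", "replicate"], sort=False):
        reds = grp.loc[grp["color"] == "red", "sample_id"].to_list()
        whites = grp.loc[grp["color"] == "white", "sample_id"].to_list()
        if len(reds) != 1 or len(whites) != 1:
            offender = (reds + whites or [f"{method}/rep{rep}"])[0]
            raise ValueError(
                f"sample {offender!r}: ({method}, replicate {rep}) must have "
                f"exactly one red and one white sample, got {len(reds)} red / "
                f"{len(whites)} white"
            )
        rows.append((f"{method}_rep{rep}", method, rep, reds[0], whites[0]))
    return pd.DataFrame(
        rows, columns=["pair_id", "method", "replicate", "red_sample", "white_sample"]
    )


def score_all_pairs(
    abundances: pd.DataFrame, samples: pd.DataFrame, params: ScoringParams
) -> PairScores:
    """Vectorized pair scoring of every gene in every red/white pair."""
    pairs = make_pairs(samples)
    unpaired = set(abundances.columns) - set(samples["sample_id"])
    if unpaired:
        raise ValueError(
            f"samples not present in the sample sheet: {sorted(unpaired)}"
        )
    if (abundances.to_numpy() < 0).any():
        raise ValueError("abundance matrix contains negative entries")

    red = abundances[pairs["red_sample"].to_list()].to_numpy(dtype=float)
    white = abundances[pairs["white_sample"].to_list()].to_numpy(dtype=float)

    white_zero = white == 0
    score2 = white_zero & (red >= params.tau)
    with np.errstate(invalid="ignore"):
        score1 = ~white_zero & (red >= params.fold_threshold * white)
    scores = np.where(score2, 2, np.where(score1, 1, 0)).astype(np.int64)

    eps = params.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = red / (white + eps)
    if eps == 0:
        fold = np.where(white_zero, np.nan, fold)
    log_ratio = np.log(red + 1.0) - np.log(white + 1.0)

    idx = abundances.index
    cols = pairs["pair_id"].to_list()
    return PairScores(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        fold_changes=pd.DataFrame(fold, index=idx, columns=cols),
        log_ratios=pd.DataFrame(log_ratio, index=idx, columns=cols),
        pairs=pairs,
    )


def aggregate_and_rank(pair_scores: PairScores) -> pd.DataFrame:
    """Aggregate pair scores per gene and rank deterministically.

    Rank 1 is best.  Ties on the aggregate score are broken by the number of
    score-2 pairs (descending), then the mean log ratio (descending), then
    the gene id (ascending), so identical inputs always yield the identical
    ranking.
    """
    s = pair_scores.scores
    out = pd.DataFrame(
        {
            "gene_id": s.index,
            "aggregate_score": s.sum(axis=1).to_numpy(),
            "n_score2": (s == 2).sum(axis=1).to_numpy(),
            "n_score1": (s == 1).sum(axis=1).to_numpy(),
            "mean_log_fold": pair_scores.log_ratios.mean(axis=1).to_numpy(),
        }
    )
    out = out.sort_values(
        ["aggregate_score", "n_score2", "mean_log_fold", "gene_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_candidates(
    ranking: pd.DataFrame, pair_scores: PairScores, params: SelectionParams
) -> list[str]:
    """Select candidate genes for the downstream localization screen.

    The base set holds genes scoring >= 1 in every pair (or, with the
    ``min_aggregate`` rule, aggregate >= ``min_aggregate_score``); rescued
    genes have at least ``rescue_min_pairs`` pairs at score 2 or fold >=
    ``rescue_fold`` and are appended after the base set in rank order.  The
    discard list of known-nonspecific genes is removed from both.
    """
    if params.rescue_min_pairs > pair_scores.n_pairs:
        raise ValueError(
            f"rescue_min_pairs={params.rescue_min_pairs} exceeds the "
            f"{pair_scores.n_pairs} available pairs"
        )
    scores = pair_scores.scores
    if params.consistency_rule == "all_pairs_positive":
        base_ok = (scores >= 1).all(axis=1)
    else:
        base_ok = scores.sum(axis=1) >= params.min_aggregate_score

    fold = pair_scores.fold_changes
    extreme = (scores == 2) | (fold >= params.rescue_fold)
    rescued_ok = extreme.sum(axis=1) >= params.rescue_min_pairs

    ordered = ranking["gene_id"].to_list()
    base = [g for g in ordered if base_ok.get(g, False) and g not in params.discard]
    base_set = set(base)
    rescued = [
        g
        for g in ordered
        if rescued_ok.get(g, False)
        and g not in base_set
        and g not in params.discard
    ]
    return base + rescued
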