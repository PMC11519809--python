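"""Pair scoring, aggregate ranking and candidate selection.

The vectorized implementation is checked against independent scalar oracles
that restate the rules literally, and against the invariants the rules imply
(bounds, monotonicity, scale invariance under CPM).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mszscreen import (
    ScoringParams,
    SelectionParams,
    aggregate_and_rank,
    make_pairs,
    normalize_counts,
    score_all_pairs,
    score_gene_pair,
    select_candidates,
)

PARAMS = ScoringParams()


def oracle_pair_score(red, white, fold_threshold=5.0, tau=1.0):
    """Literal restatement of the scoring rule, kept independent of the
    implementation under test."""
    if white == 0:
        return 2 if red >= tau else 0
    if red / white >= fold_threshold:
        return 1
    return 0


def small_sheet(n_methods=2, n_reps=3):
    rows = []
    for m in range(n_methods):
        for r in range(1, n_reps + 1):
            rows.append((f"m{m}_rep{r}_red", "red", f"m{m}", r))
            rows.append((f"m{m}_rep{r}_white", "white", f"m{m}", r))
    return pd.DataFrame(rows, columns=["sample_id", "color", "method", "replicate"])


def abundance_frame(values, sheet):
    genes = [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=sheet["sample_id"].to_list())


# ------------------------------------------------------------- the rule

@pytest.mark.parametrize(
    "red, white, expected",
    [
        (50.0, 5.0, 1),  # tenfold enrichment
        (20.0, 0.0, 2),  # significant red, silent white
        (0.5, 0.0, 0),  # red below the significance floor
        (4.0, 1.0, 0),  # fourfold misses the fivefold bar
        (5.0, 1.0, 1),  # exactly fivefold counts (closed threshold)
        (1.0, 0.0, 2),  # red exactly at tau counts as significant
        (0.0, 0.0, 0),
    ],
)
def test_pair_score_rule(red, white, expected):
    assert score_gene_pair(red, white, PARAMS) == expected


def test_negative_abundance_rejected():
    with pytest.raises(ValueError):
        score_gene_pair(-1.0, 0.0, PARAMS)


def test_vectorized_scoring_matches_scalar_oracle():
    """1000 random 20-gene x 6-pair matrices agree exactly with the oracle,
    including planted exact zeros and boundary folds."""
    rng = np.random.default_rng(2024)
    sheet = small_sheet()
    for _ in range(1000):
        vals = rng.gamma(1.0, 20.0, size=(20, 12))
        vals[rng.random(vals.shape) < 0.3] = 0.0
        a = abundance_frame(vals, sheet)
        ps = score_all_pairs(a, sheet, PARAMS)
        for gi, g in enumerate(a.index):
            for pi, prow in ps.pairs.iterrows():
                red = a.loc[g, prow["red_sample"]]
                white = a.loc[g, prow["white_sample"]]
                assert ps.scores.loc[g, prow["pair_id"]] == oracle_pair_score(
                    red, white
                ), (g, prow["pair_id"], red, white)


def test_scores_bounded_and_pair_count(noisy_data):
    counts, samples, *_ = noisy_data
    ps = score_all_pairs(normalize_counts(counts, PARAMS), samples, PARAMS)
    assert ps.n_pairs == 6
    assert ps.scores.isin([0, 1, 2]).all().all()
    agg = aggregate_and_rank(ps)
    assert agg["aggregate_score"].between(0, 2 * ps.n_pairs).all()
    assert sorted(agg["rank"]) == list(range(1, len(agg) + 1))


def test_gene_row_permutation_permutes_scores_identically():
    rng = np.random.default_rng(7)
    sheet = small_sheet()
    a = abundance_frame(rng.gamma(1.0, 20.0, size=(15, 12)), sheet)
    ps = score_all_pairs(a, sheet, PARAMS)
    perm = a.sample(frac=1.0, random_state=1)
    ps_perm = score_all_pairs(perm, sheet, PARAMS)
    assert ps_perm.scores.loc[a.index].equals(ps.scores)


@settings(max_examples=300, derandomize=True)
@given(
    red=st.floats(0, 1e4, allow_nan=False),
    white=st.floats(0, 1e4, allow_nan=False),
    bump=st.floats(0, 1e4, allow_nan=False),
)
def test_score_monotone_in_red_and_white(red, white, bump):
    """More red never lowers the score; more white never raises it."""
    s = score_gene_pair(red, white, PARAMS)
    assert score_gene_pair(red + bump, white, PARAMS) >= s
    assert score_gene_pair(red, white + bump, PARAMS) <= s


def test_white_to_zero_crossing_jumps_to_two_iff_red_significant():
    assert score_gene_pair(1.0, 0.0, PARAMS) == 2
    assert score_gene_pair(0.99, 0.0, PARAMS) == 0


def test_cpm_scale_invariance():
    """Rescaling any raw sample column leaves all CPM-mode scores unchanged."""
    rng = np.random.default_rng(11)
    sheet = small_sheet()
    raw = rng.integers(0, 200, size=(30, 12)).astype(float)
    a = abundance_frame(raw, sheet)
    scaled = a.copy()
    for j, c in enumerate(scaled.columns):
        scaled[c] *= [3.0, 0.5, 17.0, 1.0, 2.5, 9.0, 0.1, 4.0, 1.7, 8.0, 2.0, 5.0][j]
    s0 = score_all_pairs(normalize_counts(a, PARAMS), sheet, PARAMS).scores
    s1 = score_all_pairs(normalize_counts(scaled, PARAMS), sheet, PARAMS).scores
    assert s0.equals(s1)


# ------------------------------------------------------- normalization

def test_cpm_columns_sum_to_a_million():
    sheet = small_sheet(1, 1)
    a = abundance_frame(np.array([[10.0, 1.0], [30.0, 1.0], [60.0, 1.0]]), sheet)
    out = normalize_counts(a, PARAMS)
    assert np.allclose(out.iloc[:, 0], [1e5, 3e5, 6e5])
    assert np.allclose(out.sum(axis=0), 1e6)


def test_norm_none_is_identity_and_zero_column_warns(caplog):
    sheet = small_sheet(1, 1)
    a = abundance_frame(np.array([[5.0, 0.0], [7.0, 0.0]]), sheet)
    out = normalize_counts(a, ScoringParams(normalization="none"))
    assert out.equals(a.astype(float))
    with caplog.at_level("WARNING"):
        cpm = normalize_counts(a, PARAMS)
    assert "zero total counts" in caplog.text
    assert (cpm.iloc[:, 1] == 0).all()


# ------------------------------------------------------------ ranking

def test_aggregate_sums_and_tie_breaks():
    scores = pd.DataFrame(
        [[1, 1, 2, 0, 1, 2], [2, 2, 2, 2, 2, 2], [0, 0, 0, 0, 0, 0]],
        index=["mid", "top", "flat"],
        columns=[f"p{i}" for i in range(6)],
    )
    logr = pd.DataFrame(0.0, index=scores.index, columns=scores.columns)
    from mszscreen import PairScores

    pairs = pd.DataFrame(
        {"pair_id": scores.columns, "method": "m", "replicate": range(6),
         "red_sample": "r", "white_sample": "w"}
    )
    ps = PairScores(scores=scores, fold_changes=logr, log_ratios=logr, pairs=pairs)
    agg = aggregate_and_rank(ps).set_index("gene_id")
    assert agg.loc["mid", "aggregate_score"] == 7
    assert agg.loc["top", "aggregate_score"] == 12
    assert agg.loc["top", "rank"] == 1
    assert agg.loc["flat", "rank"] == 3


def test_rank_ties_break_deterministically_by_gene_id():
    scores = pd.DataFrame(
        [[1] * 6, [1] * 6], index=["zeta", "alpha"], columns=[f"p{i}" for i in range(6)]
    )
    logr = pd.DataFrame(0.0, index=scores.index, columns=scores.columns)
    from mszscreen import PairScores

    pairs = pd.DataFrame(
        {"pair_id": scores.columns, "method": "m", "replicate": range(6),
         "red_sample": "r", "white_sample": "w"}
    )
    agg = aggregate_and_rank(
        PairScores(scores=scores, fold_changes=logr, log_ratios=logr, pairs=pairs)
    )
    assert agg["gene_id"].to_list() == ["alpha", "zeta"]


# ---------------------------------------------------------- selection

def oracle_select(scores, folds, ranking_order, sel):
    """Exhaustive set-builder restating the selection rules literally."""
    base, rescued = [], []
    for g in ranking_order:
        row = scores.loc[g]
        if sel.consistency_rule == "all_pairs_positive":
            in_base = bool((row >= 1).all())
        else:
            in_base = row.sum() >= sel.min_aggregate_score
        n_extreme = 0
        for p in scores.columns:
            f = folds.loc[g, p]
            if scores.loc[g, p] == 2 or (not np.isnan(f) and f >= sel.rescue_fold):
                n_extreme += 1
        if g in sel.discard:
            continue
        if in_base:
            base.append(g)
        elif n_extreme >= sel.rescue_min_pairs:
            rescued.append(g)
    return base + rescued


def test_selection_matches_set_builder_oracle():
    rng = np.random.default_rng(3)
    sheet = small_sheet()
    for trial in range(20):
        vals = rng.gamma(1.0, 30.0, size=(50, 12))
        vals[rng.random(vals.shape) < 0.35] = 0.0
        a = abundance_frame(vals, sheet)
        ps = score_all_pairs(a, sheet, PARAMS)
        ranking = aggregate_and_rank(ps)
        discard = frozenset(rng.choice(a.index, size=5, replace=False))
        sel = SelectionParams(discard=discard)
        got = select_candidates(ranking, ps, sel)
        want = oracle_select(ps.scores, ps.fold_changes,
                             ranking["gene_id"].to_list(), sel)
        assert got == want, f"trial {trial}"


def test_all_positive_gene_selected_and_discard_beats_perfect_scores():
    sheet = small_sheet()
    a = abundance_frame(
        np.array([[60.0, 10.0] * 6, [60.0, 0.0] * 6, [1.0, 1.0] * 6]), sheet
    )
    ps = score_all_pairs(a, sheet, PARAMS)
    ranking = aggregate_and_rank(ps)
    assert select_candidates(ranking, ps, SelectionParams()) == ["g1", "g0"]
    sel = SelectionParams(discard=frozenset({"g1"}))
    assert select_candidates(ranking, ps, sel) == ["g0"]


def test_rescue_readmits_inconsistent_but_extreme_genes():
    """A gene failing one pair but with >= 2 extreme pairs is appended."""
    sheet = small_sheet()
    row = [200.0, 1.0, 200.0, 1.0, 1.0, 1.0] + [1.0] * 6  # folds 200,200 then flat
    a = abundance_frame(np.array([row]), sheet)
    ps = score_all_pairs(a, sheet, PARAMS)
    ranking = aggregate_and_rank(ps)
    assert select_candidates(ranking, ps, SelectionParams()) == ["g0"]
    strict = SelectionParams(rescue_min_pairs=3)
    assert select_candidates(ranking, ps, strict) == []


def test_min_aggregate_rule():
    sheet = small_sheet()
    a = abundance_frame(np.array([[60.0, 10.0] * 3 + [1.0, 1.0] * 3]), sheet)
    ps = score_all_pairs(a, sheet, PARAMS)
    ranking = aggregate_and_rank(ps)
    assert ps.scores.loc["g0"].sum() == 3
    loose = SelectionParams(consistency_rule="min_aggregate", min_aggregate_score=3,
                            rescue_min_pairs=6)
    tight = SelectionParams(consistency_rule="min_aggregate", min_aggregate_score=4,
                            rescue_min_pairs=6)
    assert select_candidates(ranking, ps, loose) == ["g0"]
    assert select_candidates(ranking, ps, tight) == []


# ------------------------------------------------------------- pairing

def test_unpaired_sample_is_named():
    sheet = small_sheet().drop(index=0)  # remove m0_rep1_red
    with pytest.raises(ValueError, match="m0_rep1_white"):
        make_pairs(sheet)


def test_planted_markers_outrank_housekeeping(noisefree_data):
    counts, samples, _, _, truth = noisefree_data
    ps = score_all_pairs(normalize_counts(counts, PARAMS), samples, PARAMS)
    agg = aggregate_and_rank(ps).set_index("gene_id")
    markers = truth.loc[truth["gene_class"] == "msz_marker", "gene_id"]
    housekeeping = truth.loc[truth["gene_class"] == "housekeeping", "gene_id"]
    assert (agg.loc[markers, "aggregate_score"] == 12).all()
    assert agg.loc[markers, "rank"].max() < agg.loc[housekeeping, "rank"].min()
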