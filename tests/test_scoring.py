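"""Combined score, rank scores, rank differences, filters and IC50 counts."""

import numpy as np
import pandas as pd
import pytest

from pepex import reference_data as ref
from pepex.scoring import (
    ScoreRecord,
    ScoringError,
    add_combined_columns,
    combined_ranking_value,
    combined_score,
    count_improved,
    cutoff_filter,
    mmgbsa_threshold,
    overall_rank,
    parse_ic50,
    rank_difference,
    rank_scores,
    threshold_filter,
)


def _rec(pep, i_sc, pep_sc, i_bsa, rms, mmgbsa=None):
    return ScoreRecord(pep, I_sc=i_sc, pep_sc=pep_sc, I_bsa=i_bsa, rmsALL_if=rms, mmgbsa=mmgbsa)


def _random_frame(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "peptide": [f"P{i}" for i in range(n)],
            "I_sc": rng.normal(-5, 2, n),
            "pep_sc": rng.normal(-3, 1, n),
            "I_bsa": rng.uniform(100, 350, n),
            "rmsALL_if": rng.normal(0, 0.15, n),
        }
    )


class TestCombinedScore:
    def test_printed_formula(self):
        assert combined_score(_rec("p", -3, -2, 100, 2)) == pytest.approx(300.0)
        assert combined_score(_rec("p", 1, 1, 1, 1)) == pytest.approx(1.0)

    def test_zero_rms_is_error(self):
        with pytest.raises(ScoringError, match="epsilon|floors"):
            combined_score(_rec("p", -3, -2, 100, 0.0))

    def test_ranking_matches_brute_force_sort(self):
        df = _random_frame(50, seed=0)
        vals = [combined_ranking_value(row) for _, row in df.iterrows()]
        brute = [
            abs(r["pep_sc"] * r["I_sc"]) * r["I_bsa"] / max(abs(r["rmsALL_if"]), 0.01)
            for _, r in df.iterrows()
        ]
        assert np.argsort(vals).tolist() == np.argsort(brute).tolist()


class TestRankScores:
    def test_two_point_lower_better(self):
        df = _random_frame(2, seed=1)
        df["I_sc"] = [-5.0, -1.0]
        assert rank_scores(df, "I_sc").tolist() == [0.0, 1.0]

    def test_ibsa_orientation_flipped(self):
        df = _random_frame(2, seed=1)
        df["I_bsa"] = [300.0, 100.0]
        assert rank_scores(df, "I_bsa").tolist() == [0.0, 1.0]

    def test_all_ties_midrank(self):
        df = _random_frame(4, seed=2)
        df["pep_sc"] = -2.0
        assert rank_scores(df, "pep_sc").tolist() == [0.5] * 4

    def test_invariant_under_monotone_transform(self):
        df = _random_frame(30, seed=3)
        shifted = df.copy()
        shifted["I_sc"] = np.exp(df["I_sc"] / 3.0)  # strictly increasing map
        assert np.allclose(rank_scores(df, "I_sc"), rank_scores(shifted, "I_sc"))

    def test_unknown_metric(self):
        with pytest.raises(ScoringError):
            rank_scores(_random_frame(3, 0), "dG")


class TestOverallRank:
    def test_dominant_record_scores_zero(self):
        df = _random_frame(5, seed=4)
        df.loc[0, ["I_sc", "pep_sc", "rmsALL_if"]] = [-99, -99, -99]
        df.loc[0, "I_bsa"] = 999
        ranks = overall_rank(df)
        assert ranks[0] == 0.0

    def test_worst_record_scores_one_normalized(self):
        df = _random_frame(5, seed=5)
        df.loc[2, ["I_sc", "pep_sc", "rmsALL_if"]] = [99, 99, 99]
        df.loc[2, "I_bsa"] = 0
        assert overall_rank(df)[2] == 1.0
        assert overall_rank(df, normalize=False)[2] == 4.0

    def test_permutation_invariance(self):
        df = _random_frame(20, seed=6)
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        r1 = dict(zip(df["peptide"], overall_rank(df)))
        r2 = dict(zip(shuffled["peptide"], overall_rank(shuffled)))
        assert all(np.isclose(r1[p], r2[p]) for p in r1)

    def test_missing_metric_is_error(self):
        with pytest.raises(ScoringError):
            overall_rank(_random_frame(5, 0).drop(columns="pep_sc"))


class TestRankDifference:
    def test_enriching_model_positive_mean(self):
        good = _random_frame(20, seed=7)
        good[["I_sc", "pep_sc"]] -= 10  # dominates the pool
        good["I_bsa"] += 200
        bad = _random_frame(20, seed=8)
        bad["peptide"] = [f"Q{i}" for i in range(20)]
        rd = rank_difference({"good": good, "bad": bad})
        means = rd.groupby("model")["rank_difference"].mean()
        assert means["good"] > 0 > means["bad"]

    def test_swapping_distributions_flips_sign(self):
        a, b = _random_frame(15, seed=9), _random_frame(15, seed=10)
        b["peptide"] = [f"Q{i}" for i in range(15)]
        rd1 = rank_difference({"A": a, "B": b}).groupby("model")["rank_difference"].mean()
        a2, b2 = a.copy(), b.copy()
        a2[["I_sc", "pep_sc", "I_bsa", "rmsALL_if"]] = b[
            ["I_sc", "pep_sc", "I_bsa", "rmsALL_if"]
        ].to_numpy()
        b2[["I_sc", "pep_sc", "I_bsa", "rmsALL_if"]] = a[
            ["I_sc", "pep_sc", "I_bsa", "rmsALL_if"]
        ].to_numpy()
        rd2 = rank_difference({"A": a2, "B": b2}).groupby("model")["rank_difference"].mean()
        assert np.sign(rd1["A"]) == -np.sign(rd2["A"]) or (rd1["A"] == rd2["A"] == 0)

    def test_size_weighted_mean_is_zero(self):
        tables = {f"m{i}": _random_frame(10 + 5 * i, seed=20 + i) for i in range(3)}
        for i, t in enumerate(tables.values()):
            t["peptide"] = [f"m{i}_{j}" for j in range(len(t))]
        rd = rank_difference(tables)
        assert abs(rd["rank_difference"].mean()) < 0.02

    def test_missing_from_pool_is_error(self):
        a = _random_frame(5, seed=0)
        pool = _random_frame(4, seed=0)
        with pytest.raises(ScoringError):
            rank_difference({"A": a}, pooled=pool)


class TestCutoffFilter:
    def test_all_three_strict_inequalities(self):
        df = pd.DataFrame(
            {
                "peptide": ["pass", "boundary", "fail"],
                "I_sc": [-7.0, -6.0, -7.0],
                "pep_sc": [-1.0, -1.0, -1.0],
                "I_bsa": [260.0, 260.0, 200.0],
                "rmsALL_if": [-0.3, -0.3, -0.3],
            }
        )
        kept = cutoff_filter(df)
        assert kept["peptide"].tolist() == ["pass"]

    def test_partition_and_idempotence(self):
        df = _random_frame(40, seed=11)
        kept = cutoff_filter(df)
        assert len(kept) + (len(df) - len(kept)) == len(df)
        assert cutoff_filter(kept).equals(kept.reset_index(drop=True))


class TestMmgbsaThreshold:
    def test_printed_control_statistics(self):
        assert mmgbsa_threshold(-43.0, 3.0) == pytest.approx(-40.0)

    def test_zero_sd(self):
        assert mmgbsa_threshold(-50.0, 0.0) == -50.0

    def test_never_below_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m, s = rng.normal(-45, 5), rng.uniform(0, 5)
            assert mmgbsa_threshold(m, s) >= m

    def test_negative_sd_rejected(self):
        with pytest.raises(ScoringError):
            mmgbsa_threshold(-40, -1)


class TestThresholdFilter:
    def test_published_nterm_candidates(self):
        table = ref.bcatenin_nterm_table().rename(columns={"flexpepdock_reu": "I_sc"})
        recs = [
            _rec(row["name"], row["I_sc"], -1, 200, -0.1, mmgbsa=row["mmgbsa"])
            for _, row in table.iterrows()
        ]
        kept, discarded = threshold_filter(recs, mmgbsa_threshold(-43.0, 3.0))
        assert sorted(discarded["peptide"]) == ["NAL-2", "NAL-3"]
        assert len(kept) == 8

    def test_none_discarded_and_partition(self):
        recs = [_rec(f"p{i}", -5, -2, 200, 0.1, mmgbsa=-45 - i) for i in range(5)]
        kept, discarded = threshold_filter(recs, -40.0)
        assert len(discarded) == 0 and len(kept) == 5


class TestIc50:
    def test_parse_open_bounds(self):
        assert parse_ic50(">3") == (">", 3.0)
        assert parse_ic50("<0.1") == ("<", 0.1)
        assert parse_ic50(0.15) == ("=", 0.15)

    def test_malformed_entry(self):
        with pytest.raises(ScoringError):
            parse_ic50("n.d.")

    def test_published_improvement_counts(self):
        assert count_improved(ref.tested_ic50s(), ref.PARENT_IC50_UM) == 6
        nemo = dict(zip(ref.nemo_table()["name"], ref.nemo_table()["ic50_um"]))
        assert count_improved(nemo, ref.PARENT_NBD_IC50_BOUND_UM) == 2

    def test_lower_bounds_never_improve(self):
        assert count_improved({"a": ">100", "b": 50, "c": ">100", "d": 75}, 100) == 2

    def test_empty_table(self):
        assert count_improved({}, 0.15) == 0


def test_combinatorial_diversity():
    d = ref.combinatorial_diversity()
    assert d == 29**4 == 707281
    assert len(ref.OBOC_BUILDING_BLOCKS) == 29


def test_add_combined_columns_round_trips_records():
    df = add_combined_columns(_random_frame(10, seed=12))
    assert {"combined_score", "combined_ranking_value"} <= set(df.columns)
    assert df["combined_ranking_value"].gt(0).all()
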