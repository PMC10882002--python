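"""Docking-score bookkeeping and every selection rule built on it.

Four interface metrics drive candidate selection: the interface energy I_sc
and the peptide score pep_sc (Rosetta Energy Units, lower is better), the
buried interface surface area I_bsa (A^2, higher is better), and the
interface RMSD rmsALL_if (A, lower is better).  Scores may be absolute or
expressed as extended-minus-parent differences (``is_delta``).  On top of
these sit: the combined binding score pep_sc*I_sc*I_bsa/rmsALL_if, per-metric
rank scores in [0, 1] with 0 the best, the overall rank (sum of the four),
the rank-difference enrichment statistic, the hard cutoff filter, the
mean+1*sigma MM/GBSA threshold, and IC50 improvement counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class ScoringError(ValueError):
    pass


#: ranking orientation per metric: +1 means lower values are better
METRIC_ORIENTATION = {"I_sc": 1, "pep_sc": 1, "rmsALL_if": 1, "I_bsa": -1}
METRICS = tuple(METRIC_ORIENTATION)

#: floor applied to |rmsALL_if| when forming the ranking-oriented combined score
RMS_EPSILON = 0.01


@dataclass(frozen=True)
class ScoreRecord:
    """One peptide's docking metrics, optionally with an MM/GBSA energy."""

    peptide: str
    I_sc: float
    pep_sc: float
    I_bsa: float
    rmsALL_if: float
    is_delta: bool = True
    mmgbsa: Optional[float] = None
    mmgbsa_sd: Optional[float] = None

    def __post_init__(self):
        for name in ("I_sc", "pep_sc", "I_bsa", "rmsALL_if"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ScoringError(f"{name} must be finite, got {v!r}")


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [
        {
            "peptide": r.peptide,
            "I_sc": r.I_sc,
            "pep_sc": r.pep_sc,
            "I_bsa": r.I_bsa,
            "rmsALL_if": r.rmsALL_if,
            "is_delta": r.is_delta,
            "mmgbsa": r.mmgbsa,
            "mmgbsa_sd": r.mmgbsa_sd,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def combined_score(rec) -> float:
    """Literal combined binding score pep_sc * I_sc * I_bsa / rmsALL_if."""
    rms = rec.rmsALL_if if hasattr(rec, "rmsALL_if") else rec["rmsALL_if"]
    if rms == 0:
        raise ScoringError(
            "rmsALL_if is zero; use combined_ranking_value, which floors |rms| at "
            f"{RMS_EPSILON} A"
        )
    get = (lambda k: getattr(rec, k)) if hasattr(rec, "I_sc") else (lambda k: rec[k])
    return get("pep_sc") * get("I_sc") * get("I_bsa") / rms


def combined_ranking_value(rec, eps: float = RMS_EPSILON) -> float:
    """Orientation-stable variant of the combined score; larger is better.

    With typical signs (both energies negative, I_bsa positive) the raw
    product's sign flips with the sign of rmsALL_if, so ranking uses
    |pep_sc * I_sc| * I_bsa / max(|rms|, eps): bigger contact area, lower
    energies and smaller interface displacement all increase it.
    """
    get = (lambda k: getattr(rec, k)) if hasattr(rec, "I_sc") else (lambda k: rec[k])
    rms = max(abs(get("rmsALL_if")), eps)
    return abs(get("pep_sc") * get("I_sc")) * get("I_bsa") / rms


def add_combined_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["combined_score"] = [
        combined_score(row) if row["rmsALL_if"] != 0 else np.nan
        for _, row in df.iterrows()
    ]
    df["combined_ranking_value"] = [
        combined_ranking_value(row) for _, row in df.iterrows()
    ]
    return df


def rank_scores(records, metric: str) -> np.ndarray:
    """Normalized rank of one metric: best -> 0, worst -> 1, midrank ties."""
    if metric not in METRIC_ORIENTATION:
        raise ScoringError(f"unknown metric {metric!r}")
    df = records_to_frame(records)
    if len(df) < 2:
        raise ScoringError("ranking needs at least two records")
    vals = df[metric].to_numpy(dtype=float) * METRIC_ORIENTATION[metric]
    ranks = rankdata(vals, method="average")
    return (ranks - 1.0) / (len(vals) - 1.0)


def overall_rank(records, metrics: Sequence[str] = METRICS, normalize: bool = True) -> np.ndarray:
    """Sum of the per-metric rank scores (optionally renormalized to [0, 1])."""
    df = records_to_frame(records)
    missing = [m for m in metrics if m not in df.columns or df[m].isna().any()]
    if missing:
        raise ScoringError(f"metrics missing from records: {missing}")
    total = np.zeros(len(df))
    for m in metrics:
        total += rank_scores(df, m)
    return total / len(metrics) if normalize else total


def rank_difference(model_tables: Mapping[str, object], pooled=None) -> pd.DataFrame:
    """Within-model overall rank minus pooled overall rank, per peptide.

    A model whose designs dominate the pooled top end gets positive rank
    differences: its internal ranks span [0, 1] uniformly while its pooled
    ranks crowd near 0.  ``pooled`` defaults to the union of all model tables;
    every peptide must appear in exactly one model table and in the pool.
    """
    frames = {tag: records_to_frame(t) for tag, t in model_tables.items()}
    if pooled is None:
        pooled_df = pd.concat(frames.values(), ignore_index=True)
    else:
        pooled_df = records_to_frame(pooled)
    pooled_df = pooled_df.reset_index(drop=True)
    pooled_rank = overall_rank(pooled_df)
    pooled_lookup = {}
    for i, pep in enumerate(pooled_df["peptide"]):
        pooled_lookup[pep] = pooled_rank[i]
    rows = []
    for tag, df in frames.items():
        within = overall_rank(df)
        for i, pep in enumerate(df["peptide"]):
            if pep not in pooled_lookup:
                raise ScoringError(f"peptide {pep!r} missing from the pooled table")
            rows.append(
                {
                    "peptide": pep,
                    "model": tag,
                    "model_rank": within[i],
                    "pooled_rank": pooled_lookup[pep],
                    "rank_difference": within[i] - pooled_lookup[pep],
                }
            )
    return pd.DataFrame(rows)


def cutoff_filter(
    records,
    rms_max: float = -0.2,
    i_sc_max: float = -6.0,
    i_bsa_min: float = 250.0,
) -> pd.DataFrame:
    """Keep delta-convention records passing all three strict inequalities.

    Defaults are the selection cutoffs used before MM/GBSA re-evaluation:
    rmsALL_if < -0.2 A, I_sc < -6 REU, I_bsa > 250 A^2.
    """
    df = records_to_frame(records)
    keep = (
        (df["rmsALL_if"] < rms_max)
        & (df["I_sc"] < i_sc_max)
        & (df["I_bsa"] > i_bsa_min)
    )
    return df.loc[keep].reset_index(drop=True)


def mmgbsa_threshold(control_mean: float, control_sd: float) -> float:
    """Mean + 1*sd of the positive-control MM/GBSA energies (kcal/mol).

    One standard deviation toward less favorable energy, for robustness of
    the selection; e.g. controls at -43 +/- 3 kcal/mol give -40.
    """
    if control_sd < 0:
        raise ScoringError("standard deviation must be non-negative")
    return control_mean + control_sd


def threshold_filter(records, threshold: float):
    """Split records into (kept, discarded) by MM/GBSA energy.

    Discarded records have an energy strictly greater (less favorable) than
    the threshold.
    """
    df = records_to_frame(records)
    if df["mmgbsa"].isna().any():
        raise ScoringError("every record needs an MM/GBSA energy")
    discard = df["mmgbsa"] > threshold
    return df.loc[~discard].reset_index(drop=True), df.loc[discard].reset_index(drop=True)


# ---------------------------------------------------------------------------
# IC50 bookkeeping


def parse_ic50(entry):
    """Parse an IC50 cell into an (operator, value) pair.

    Accepts numbers and open bounds such as ``">3"`` or ``"<0.1"``; open
    bounds are kept symbolic, never coerced to floats.
    """
    if isinstance(entry, (int, float)):
        if not math.isfinite(entry) or entry <= 0:
            raise ScoringError(f"IC50 must be a positive finite number, got {entry!r}")
        return ("=", float(entry))
    text = str(entry).strip().replace("≥", ">").replace("≤", "<")
    op = "="
    if text[:1] in (">", "<"):
        op, text = text[0], text[1:].strip()
    try:
        value = float(text)
    except ValueError as exc:
        raise ScoringError(f"malformed IC50 entry {entry!r}") from exc
    if value <= 0:
        raise ScoringError(f"IC50 bound must be positive, got {entry!r}")
    return (op, value)


def count_improved(tested: Mapping[str, object], parent_ic50: float) -> int:
    """Count peptides with IC50 strictly below the parent's.

    ``tested`` maps peptide name to an IC50 entry (number or open bound).
    A lower-bounded entry (">x") can never be confirmed as improved; an
    upper-bounded entry ("<x") counts only when its bound is at or below the
    parent value.
    """
    n = 0
    for entry in tested.values():
        op, value = parse_ic50(entry)
        if op == "=" and value < parent_ic50:
            n += 1
        elif op == "<" and value <= parent_ic50:
            n += 1
    return n


def selection_report(df: pd.DataFrame, filters_applied: Iterable[str]) -> dict:
    """Small JSON-serializable summary of a selection step."""
    return {
        "n_records": int(len(df)),
        "filters": list(filters_applied),
        "best_combined_ranking_value": (
            float(df["combined_ranking_value"].max())
            if "combined_ranking_value" in df and len(df)
            else None
        ),
    }
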