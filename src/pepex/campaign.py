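"""Iterative fine-tuning campaign: generate, score, relabel, refit, repeat.

Cycle 0 ("Pretrain") samples extensions conditioned on a classifier trained
on the general binder/non-binder corpus.  Each later cycle ("Fine-tune1",
"Fine-tune2", ...) relabels the accumulated scored designs — the top 10% by
combined binding score become positives, the rest negatives — refits the
posterior ensemble from scratch on that pool, and samples a fresh batch
excluding everything already seen.  The VAE weights stay frozen after
pretraining; the fine-tuning signal enters purely through q(c|z).
Enrichment across cycles is summarized by the rank-difference statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import LabeledSplit, PeptideRecord, assemble_labeled
from .latent import fit_posterior
from .mh import MhConfig, concatenate, generate_extensions
from .scoring import add_combined_columns, rank_difference

MODEL_TAGS = ("Pretrain", "Fine-tune1", "Fine-tune2", "Fine-tune3")

#: residues counted as hydrophobic by the polarity rule
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWYP")


class CampaignError(RuntimeError):
    pass


@dataclass
class CycleResult:
    tag: str
    extensions: list
    scores: pd.DataFrame  # includes combined columns and a label column
    seed: int


@dataclass
class CampaignState:
    """Ledger of a generation campaign; cycle provenance is append-only."""

    parent: str
    terminus: str
    cycles: list = field(default_factory=list)
    exclusion: set = field(default_factory=set)

    @property
    def model_tags(self) -> list:
        return [c.tag for c in self.cycles]

    def all_scores(self) -> pd.DataFrame:
        frames = []
        for c in self.cycles:
            df = c.scores.copy()
            df["model"] = c.tag
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def relabel_top_fraction(
    scored: pd.DataFrame, fraction: float = 0.10, by: str = "overall_rank"
) -> pd.DataFrame:
    """Label the top ``fraction`` of scored peptides as positive.

    Peptides are rank-ordered from best to worst by the summed per-metric
    rank scores (``by="overall_rank"``, the fine-tuning criterion) or by the
    combined binding score (``by="combined"``).  Exactly ceil(fraction * n)
    positives; ties at the boundary break by lexicographic peptide order so
    relabeling is rerun-stable.  Requires at least 10 records.
    """
    if len(scored) < 10:
        raise CampaignError("relabeling needs at least 10 scored records")
    df = add_combined_columns(scored) if "combined_ranking_value" not in scored else scored.copy()
    df = df.reset_index(drop=True)
    if by == "overall_rank":
        from .scoring import overall_rank

        df["_order"] = overall_rank(df)  # 0 = best
        ascending = True
    elif by == "combined":
        df["_order"] = -df["combined_ranking_value"]
        ascending = True
    else:
        raise CampaignError(f"unknown relabeling criterion {by!r}")
    n_pos = math.ceil(fraction * len(df))
    order = df.sort_values(["_order", "peptide"], ascending=[ascending, True]).index
    df["label"] = "negative"
    df.loc[order[:n_pos], "label"] = "positive"
    return df.drop(columns="_order")


def _labeled_split_from_frame(
    df: pd.DataFrame, seed: int, base_records: Sequence[PeptideRecord] = ()
) -> LabeledSplit:
    """Build the dynamic labeled dataset: relabeled designs plus, optionally,
    the original corpus records (the labeled pool is *updated with* each
    cycle's evaluation results, not replaced by them)."""
    pos = [
        PeptideRecord(row["extension"], label="positive", source="campaign")
        for _, row in df.iterrows()
        if row["label"] == "positive"
    ]
    neg = [
        PeptideRecord(row["extension"], label="negative", source="campaign")
        for _, row in df.iterrows()
        if row["label"] == "negative"
    ]
    for rec in base_records:
        (pos if rec.label == "positive" else neg).append(rec)
    if not pos or not neg:
        raise CampaignError("relabeled pool must contain both classes")
    return assemble_labeled(pos, neg, seed=seed)


def run_cycle(
    state: CampaignState,
    vae,
    prior,
    ensemble,
    oracle,
    lengths: Sequence[int],
    quota: int,
    tag: str,
    seed: int,
    mh_config: Optional[MhConfig] = None,
) -> CampaignState:
    """Sample novel extensions, score them, and append a labeled cycle.

    Every extension already seen in the campaign is excluded; all scored
    peptides (old and new) are then relabeled top-10%-positive so the next
    cycle's classifier sees the accumulated evidence.
    """
    cfg = mh_config or MhConfig(seed=seed, n_chains=48, thinning=3, burn_in=150)
    pairs = generate_extensions(
        vae,
        prior,
        ensemble,
        target_lengths=lengths,
        per_length_quota=quota,
        exclusion_set=state.exclusion,
        terminus=state.terminus,
        config=cfg,
    )
    if not pairs:
        raise CampaignError(f"cycle {tag}: no extensions generated")
    extensions = [ext for ext, _ in pairs]
    peptides = [concatenate(state.parent, ext, state.terminus) for ext in extensions]
    try:
        scores = oracle.score_table(peptides)
    except Exception as exc:  # oracle failure aborts the cycle with context
        raise CampaignError(f"cycle {tag}: oracle failed: {exc}") from exc
    scores["extension"] = extensions
    scores = add_combined_columns(scores)
    scores["label"] = "unlabeled"
    state.cycles.append(CycleResult(tag=tag, extensions=extensions, scores=scores, seed=seed))
    state.exclusion.update(extensions)
    return state


def augment_finetune3(
    state: CampaignState,
    n_extra: int = 600,
    mutate: bool = False,
    seed: int = 0,
    conserved_choices: str = "VAIL",
) -> pd.DataFrame:
    """Extra Pretrain peptides for the third fine-tune variant.

    Adds ``n_extra`` randomly chosen Pretrain-cycle designs; with ``mutate``
    the last two parent residues (positions 14-15 of a 15-residue parent)
    are substituted uniformly from the conserved hydrophobic set {V, A, I, L}
    per peptide.
    """
    pretrain = next((c for c in state.cycles if c.tag == "Pretrain"), None)
    if pretrain is None:
        raise CampaignError("no Pretrain cycle recorded")
    if n_extra == 0:
        return pretrain.scores.iloc[0:0].copy()
    if len(pretrain.scores) < n_extra:
        raise CampaignError(
            f"Pretrain pool has {len(pretrain.scores)} peptides, need {n_extra}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pretrain.scores), size=n_extra, replace=False)
    out = pretrain.scores.iloc[pick].copy().reset_index(drop=True)
    if mutate:
        parent = state.parent
        mutated = []
        for pep in out["peptide"]:
            core_start = pep.find(parent)
            sub = list(pep)
            for offset in (len(parent) - 2, len(parent) - 1):
                sub[core_start + offset] = conserved_choices[
                    int(rng.integers(len(conserved_choices)))
                ]
            mutated.append("".join(sub))
        out["peptide"] = mutated
    return out


def hydrophobic_fraction(extension: str) -> float:
    if not extension:
        return 0.0
    return sum(ch in HYDROPHOBIC_RESIDUES for ch in extension) / len(extension)


def select_candidates(
    records: pd.DataFrame,
    top_k: int = 10,
    hydrophobic_cutoff: float = 0.6,
) -> pd.DataFrame:
    """Final shortlist: rank by MM/GBSA, drop overly hydrophobic extensions.

    Extensions whose hydrophobic-residue fraction exceeds the cutoff are
    discarded (greasy extensions invite non-specific binding); survivors are
    sorted by MM/GBSA energy ascending and the best ``top_k`` returned with a
    human-readable rationale per decision.
    """
    df = records.copy()
    if "mmgbsa" not in df.columns or df["mmgbsa"].isna().any():
        raise CampaignError("candidate selection requires MM/GBSA energies")
    df["hydrophobic_fraction"] = [hydrophobic_fraction(e) for e in df["extension"]]
    df["rationale"] = [
        (
            f"discarded: hydrophobic fraction {hf:.2f} > {hydrophobic_cutoff}"
            if hf > hydrophobic_cutoff
            else f"retained: hydrophobic fraction {hf:.2f}, MM/GBSA {mm:.1f} kcal/mol"
        )
        for hf, mm in zip(df["hydrophobic_fraction"], df["mmgbsa"])
    ]
    kept = df[df["hydrophobic_fraction"] <= hydrophobic_cutoff]
    return kept.sort_values("mmgbsa").head(top_k).reset_index(drop=True)


def run_campaign(
    vae,
    prior,
    pretrain_split: LabeledSplit,
    oracle,
    parent: str,
    terminus: str = "N",
    lengths: Sequence[int] = (2, 3, 4, 5),
    quota: int = 20,
    n_cycles: int = 2,
    family: str = "svc",
    seed: int = 0,
    mh_config: Optional[MhConfig] = None,
    keep_corpus_labels: bool = False,
) -> CampaignState:
    """Full Pretrain + fine-tune campaign against a scoring oracle.

    Cycle 0 conditions on a posterior fitted to the general labeled corpus;
    each subsequent cycle refits the posterior from scratch on the
    relabeled, accumulated designs.  Returns the populated CampaignState.
    """
    state = CampaignState(parent=parent, terminus=terminus)
    encoder = vae.encode_strings
    ensemble = fit_posterior(pretrain_split, encoder, family=family, seed=seed)
    for cycle_idx in range(n_cycles):
        tag = MODEL_TAGS[cycle_idx] if cycle_idx < len(MODEL_TAGS) else f"Fine-tune{cycle_idx}"
        cycle_seed = seed + 1000 * cycle_idx
        cfg = mh_config
        if cfg is not None:
            cfg = MhConfig(
                proposal_sigma=cfg.proposal_sigma,
                burn_in=cfg.burn_in,
                thinning=cfg.thinning,
                max_iterations=cfg.max_iterations,
                seed=cycle_seed,
                n_chains=cfg.n_chains,
            )
        run_cycle(
            state, vae, prior, ensemble, oracle,
            lengths=lengths, quota=quota, tag=tag, seed=cycle_seed, mh_config=cfg,
        )
        if cycle_idx < n_cycles - 1:
            pooled = state.all_scores()
            labeled = relabel_top_fraction(pooled)
            base = (
                list(pretrain_split.train) + list(pretrain_split.test)
                if keep_corpus_labels
                else ()
            )
            split = _labeled_split_from_frame(labeled, seed=cycle_seed + 17, base_records=base)
            ensemble = fit_posterior(split, encoder, family=family, seed=cycle_seed + 17)
    return state


def enrichment_summary(state: CampaignState, oracle=None) -> pd.DataFrame:
    """Per-cycle mean rank difference and reward-residue fraction."""
    tables = {c.tag: c.scores for c in state.cycles}
    rd = rank_difference(tables)
    summary = rd.groupby("model")["rank_difference"].mean().rename("mean_rank_difference")
    rows = []
    for c in state.cycles:
        row = {"model": c.tag, "mean_rank_difference": float(summary[c.tag])}
        if oracle is not None:
            fracs = [oracle.reward_fraction(e) for e in c.extensions]
            row["reward_fraction"] = float(np.mean(fracs))
        rows.append(row)
    return pd.DataFrame(rows)
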