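"""Scoring-oracle contract plus a deterministic synthetic docking oracle.

Real campaigns obtain the four interface metrics and the MM/GBSA energy from
external docking and molecular-dynamics engines.  This module defines the
adapter contract those engines must satisfy and ships a synthetic oracle so
the full generate-score-relabel loop runs self-contained: scores are a pure,
seeded function of (peptide, parent) built from a documented composition
formula, with output ranges mimicking real delta-vs-parent score tables
(I_sc around -10..0 REU, I_bsa around 100..350 A^2, rmsALL_if around
-0.3..0.3 A, MM/GBSA around -55..-30 kcal/mol).
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

from .codec import split_base_extension
from .corpus import REWARD_RESIDUES
from .scoring import ScoreRecord


class ScoringOracle(Protocol):
    """Adapter contract: anything that maps an extended peptide to scores."""

    parent: str

    def score(self, peptide: str) -> ScoreRecord: ...


class SyntheticDockingOracle:
    """Pseudo-docking scores driven by reward-residue content.

    The structural part of every metric is an affine function of the fraction
    ``f`` of reward residues (default W/F/D/E) in the extension, so that more
    reward residues monotonically improve I_sc, pep_sc, I_bsa, rmsALL_if and
    the MM/GBSA energy.  Small per-sequence Gaussian noise is added, seeded by
    a stable hash of (peptide, parent, seed): the oracle is a pure function of
    its inputs.  Scores follow the delta-vs-parent convention.
    """

    def __init__(
        self,
        parent: str,
        seed: int = 0,
        reward_residues: str = REWARD_RESIDUES,
    ):
        if not parent:
            raise ValueError("parent peptide must be non-empty")
        self.parent = parent
        self.seed = int(seed)
        self.reward_residues = set(reward_residues)

    def _rng(self, peptide: str) -> np.random.Generator:
        key = f"{peptide}|{self.parent}|{self.seed}".encode()
        digest = hashlib.sha256(key).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "little"))

    def reward_fraction(self, extension: str) -> float:
        if not extension:
            return 0.0
        return sum(ch in self.reward_residues for ch in extension) / len(extension)

    def score(self, peptide: str) -> ScoreRecord:
        # raises if the parent is not a prefix or suffix of the peptide
        _, extension, _ = split_base_extension(peptide, self.parent)
        f = self.reward_fraction(extension)
        rng = self._rng(peptide)
        noise = rng.normal(size=5)
        i_sc = -2.0 - 7.0 * f + 0.10 * noise[0]
        pep_sc = -1.5 - 5.0 * f + 0.10 * noise[1]
        i_bsa = 125.0 + 190.0 * f + 5.0 * noise[2]
        rms = 0.22 - 0.45 * f + 0.02 * noise[3]
        mmgbsa = -31.0 - 20.0 * f + 0.50 * noise[4]
        return ScoreRecord(
            peptide=peptide,
            I_sc=float(i_sc),
            pep_sc=float(pep_sc),
            I_bsa=float(i_bsa),
            rmsALL_if=float(rms),
            is_delta=True,
            mmgbsa=float(mmgbsa),
            mmgbsa_sd=0.5,
        )

    def score_table(self, peptides: Iterable[str]) -> pd.DataFrame:
        from .scoring import records_to_frame

        return records_to_frame([self.score(p) for p in peptides])


def synth_oracle(peptide: str, parent: str, seed: int = 0) -> ScoreRecord:
    """Functional form of :class:`SyntheticDockingOracle` for one peptide."""
    return SyntheticDockingOracle(parent, seed=seed).score(peptide)


# CSV score-table dialect -----------------------------------------------------

SCORE_CSV_COLUMNS = [
    "peptide",
    "extension",
    "terminus",
    "I_sc",
    "pep_sc",
    "I_bsa",
    "rmsALL_if",
    "mmgbsa",
    "is_delta",
]


def read_score_csv(path) -> pd.DataFrame:
    """Read a score table; requires a header with at least the four metrics."""
    df = pd.read_csv(path)
    missing = {"peptide", "I_sc", "pep_sc", "I_bsa", "rmsALL_if"} - set(df.columns)
    if missing:
        raise ValueError(f"score CSV missing columns: {sorted(missing)}")
    return df


def write_score_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in SCORE_CSV_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, columns=cols, index=False)
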