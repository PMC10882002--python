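"""Dataset construction: labeling, slicing, splits, and synthetic fixtures.

Training data for the generative model come from peptide corpora of short
sequences (<= 50 residues).  Positives are experimentally supported
protein-protein-interaction binders (or, downstream of docking, the
top-scored designs); negatives are random database peptides.  This module
implements the corpus rules — random fragment slicing, length filtering, the
interface-energy positive filter, the stratified 80/20 split with four 80%
bootstrap resamples — together with a seeded synthetic corpus generator that
emulates those corpora so the whole pipeline runs without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import AMBIGUOUS_RESIDUES, AMINO_ACIDS

_VALID_CHARS = set(AMINO_ACIDS) | {"X"}


class CorpusError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide sequence with an optional class label and provenance tag."""

    sequence: str
    label: str = "unlabeled"
    source: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise CorpusError("peptide sequence must be non-empty")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise CorpusError(
                f"sequence contains characters outside the 20-letter alphabet: {sorted(bad)}"
            )
        if self.label not in ("positive", "negative", "unlabeled"):
            raise CorpusError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(raw: str) -> str:
    """Uppercase and map non-canonical residue codes (B,J,O,U,X,Z) to 'X'."""
    out = []
    for ch in raw.upper():
        if ch in AMINO_ACIDS:
            out.append(ch)
        elif ch in AMBIGUOUS_RESIDUES:
            out.append("X")
        elif ch in ("*", "-", " "):
            continue
        else:
            raise CorpusError(f"character {ch!r} is not a residue code")
    return "".join(out)


@dataclass(frozen=True)
class LabeledSplit:
    """Stratified 80/20 train/test split plus four 80%-of-train bootstraps."""

    train: tuple
    test: tuple
    bootstraps: tuple

    def __post_init__(self):
        if len(self.bootstraps) != 4:
            raise CorpusError("a labeled split carries exactly 4 bootstrap resamples")
        want = math.ceil(0.8 * len(self.train))
        train_set = {(r.sequence, r.label) for r in self.train}
        for b in self.bootstraps:
            if len(b) != want:
                raise CorpusError("each bootstrap must hold ceil(80% of train) records")
            for r in b:
                if (r.sequence, r.label) not in train_set:
                    raise CorpusError("bootstraps must be drawn from the training pool")


# ---------------------------------------------------------------------------
# corpus construction rules


def slice_fragments(
    records: Sequence[PeptideRecord],
    max_len: int = 50,
    n_fragments: int = 1000,
    seed: int = 0,
    min_len: int = 5,
) -> list:
    """Randomly slice peptides into ``n_fragments`` contiguous fragments.

    Each fragment takes a uniform random length in ``[min_len, max_len]``
    (clipped to the source sequence) and a uniform random start.  Used to
    turn long therapeutic-peptide entries into a pool of short candidates.
    """
    if not records:
        raise CorpusError("cannot slice an empty record list")
    if n_fragments <= 0:
        raise CorpusError("n_fragments must be positive")
    if max_len < 1:
        raise CorpusError("max_len must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_fragments):
        rec = records[int(rng.integers(len(records)))]
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, len(rec.sequence))
        start = int(rng.integers(0, len(rec.sequence) - length + 1))
        out.append(
            PeptideRecord(
                rec.sequence[start : start + length],
                label=rec.label,
                source=f"{rec.source}|slice",
            )
        )
    return out


def length_filter(
    records: Iterable[PeptideRecord], min_len: int = 17, max_len: int = 50
) -> list:
    """Keep records with ``min_len <= length <= max_len`` (inclusive bounds)."""
    if min_len > max_len:
        raise CorpusError("min_len must not exceed max_len")
    return [r for r in records if min_len <= len(r) <= max_len]


def filter_by_interface_energy(
    table: pd.DataFrame, cutoff_reu: float = -35.0
) -> list:
    """Label as positive the peptides whose interface energy is strictly below cutoff.

    ``table`` needs ``sequence`` and ``dG`` columns (Rosetta Energy Units);
    a missing or non-finite dG is an error.
    """
    if "dG" not in table.columns or "sequence" not in table.columns:
        raise CorpusError("table must have 'sequence' and 'dG' columns")
    dg = pd.to_numeric(table["dG"], errors="coerce")
    if dg.isna().any() or not np.isfinite(dg).all():
        raise CorpusError("every row must carry a finite dG value")
    kept = table.loc[dg < cutoff_reu]
    return [
        PeptideRecord(sanitize_sequence(s), label="positive", source="interface_filter")
        for s in kept["sequence"]
    ]


def assemble_labeled(
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    seed: int = 0,
    test_fraction: float = 0.2,
    bootstrap_fraction: float = 0.8,
    n_bootstraps: int = 4,
) -> LabeledSplit:
    """Stratified train/test split plus bootstrap resamples of the train pool.

    80% of positives and 80% of negatives form the training pool, the rest the
    test pool; four datasets of ceil(80% of train) records are then drawn from
    the training pool without replacement.
    """
    if not positives or not negatives:
        raise CorpusError("both positive and negative pools must be non-empty")
    rng = np.random.default_rng(seed)

    def relabel(recs, label):
        return [PeptideRecord(r.sequence, label=label, source=r.source) for r in recs]

    positives = relabel(positives, "positive")
    negatives = relabel(negatives, "negative")

    train, test = [], []
    for pool in (positives, negatives):
        idx = rng.permutation(len(pool))
        n_train = round((1.0 - test_fraction) * len(pool))
        train.extend(pool[i] for i in idx[:n_train])
        test.extend(pool[i] for i in idx[n_train:])
    n_boot = math.ceil(bootstrap_fraction * len(train))
    bootstraps = []
    for _ in range(n_bootstraps):
        pick = rng.choice(len(train), size=n_boot, replace=False)
        bootstraps.append(tuple(train[i] for i in pick))
    return LabeledSplit(train=tuple(train), test=tuple(test), bootstraps=tuple(bootstraps))


# ---------------------------------------------------------------------------
# synthetic fixtures

#: residues enriched in the synthetic positive class; chosen to mirror the
#: aromatic/acidic preference seen in strong interface binders
REWARD_RESIDUES = "WFDE"


def _bias_weights(composition_bias) -> np.ndarray:
    if composition_bias is None:
        weights = np.ones(20)
        for aa in REWARD_RESIDUES:
            weights[AMINO_ACIDS.index(aa)] = 5.0
    elif isinstance(composition_bias, dict):
        weights = np.ones(20)
        for aa, w in composition_bias.items():
            weights[AMINO_ACIDS.index(aa)] = w
    else:
        weights = np.asarray(composition_bias, dtype=float)
        if weights.shape != (20,):
            raise CorpusError("bias vector must have 20 entries")
    if (weights < 0).any() or weights.sum() <= 0:
        raise CorpusError("bias weights must be non-negative with positive sum")
    return weights / weights.sum()


def synth_corpus(
    n_pos: int,
    n_neg: int,
    length_range: tuple = (5, 12),
    composition_bias=None,
    seed: int = 0,
):
    """Generate a two-class synthetic peptide corpus.

    Positives are drawn with a residue-frequency bias (default: W/F/D/E at
    five-fold weight, emulating binder-like composition); negatives are
    uniform over the 20 letters.  Lengths are uniform over ``length_range``.
    Deterministic given ``seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise CorpusError("n_pos and n_neg must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise CorpusError("invalid length range")
    rng = np.random.default_rng(seed)
    p_pos = _bias_weights(composition_bias)
    p_neg = np.full(20, 0.05)
    letters = np.array(list(AMINO_ACIDS))

    def draw(n, probs, label):
        recs = []
        for _ in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(letters[rng.choice(20, size=length, p=probs)])
            recs.append(PeptideRecord(seq, label=label, source="synthetic"))
        return recs

    return draw(n_pos, p_pos, "positive"), draw(n_neg, p_neg, "negative")


# ---------------------------------------------------------------------------
# FASTA / plain-text IO


def read_fasta(path) -> list:
    return [
        PeptideRecord(sanitize_sequence(str(rec.seq)), source=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[PeptideRecord], path, wrap: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.source or f"pep{i}", description=r.label)
        for i, r in enumerate(records)
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_lines(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(PeptideRecord(sanitize_sequence(line), source="lines"))
    return out
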