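"""Published assay and simulation values used as worked-example inputs.

These are the printed MM/GBSA energies, IC50 measurements and library
combinatorics for the beta-catenin and NEMO peptide-extension studies.  They
are consumed as *inputs* by the selection logic (threshold filtering,
improvement counting) — nothing here is computed by this package.
"""

from __future__ import annotations

import pandas as pd

#: parent (base) peptide for beta-catenin extension design, 15 residues
PARENT_BCATENIN = "YPEDILDKHLQRVIL"
#: truncated parent with the C-terminal Ile-Leu removed, 13 residues
PARENT_BCATENIN_TRUNCATED = "YPEDILDKHLQRV"
#: parent NEMO-binding domain (NBD) peptide of IKK-beta
PARENT_NBD = "TALDWSWLQTE"

#: parent peptide IC50 against beta-catenin (uM)
PARENT_IC50_UM = 0.15
#: the NBD parent binds NEMO only weakly (IC50 >> 100 uM); comparisons use
#: this bound
PARENT_NBD_IC50_BOUND_UM = 100.0

#: positive-control MM/GBSA statistics (kcal/mol) used to set the selection
#: threshold at mean + 1 sd = -40
CONTROL_MMGBSA_MEAN = -43.0
CONTROL_MMGBSA_SD = 3.0

# N-terminally extended beta-catenin binders: top 10 by docking rank, with
# MM/GBSA energies and (where tested) competitive FP IC50s.  "ic50_um" is a
# number, an open bound string like ">3", or None when not tested.
_NAL_ROWS = [
    ("NAL-1", "RYSYPEDILDKHLQRVIL", -39.9, 6.0, -46.2, 8.5, None),
    ("NAL-2", "LYDYPEDILDKHLQRVIL", -38.5, 6.1, -33.9, 5.9, None),
    ("NAL-3", "WHSYPEDILDKHLQRVIL", -39.5, 6.4, -35.9, 3.0, None),
    ("NAL-4", "SQRPYPEDILDKHLQRVIL", -38.6, 5.9, -44.2, 8.2, 0.17),
    ("NAL-5", "IWWWYPEDILDKHLQRVIL", -39.3, 6.2, -46.8, 6.7, None),
    ("NAL-6", "SGKVSYPEDILDKHLQRVIL", -37.5, 5.2, -48.0, 8.9, 0.10),
    ("NAL-7", "RALRLYPEDILDKHLQRVIL", -38.2, 6.0, -43.6, 8.5, None),
    ("NAL-8", "VYFWQYPEDILDKHLQRVIL", -39.0, 6.5, -44.1, 5.4, None),
    ("NAL-9", "EGEKQYPEDILDKHLQRVIL", -38.2, 5.3, -46.1, 8.1, 0.084),
    ("NAL-10", "AGSQPYPEDILDKHLQRVIL", -37.9, 6.3, -42.2, 2.0, ">3"),
]

# C-terminally extended beta-catenin binders with the generating model tag.
_CAL_ROWS = [
    ("CAL-1", "Fine-tune3", "YPEDILDKHLQRVWCWDDNT", -52.9, 3.2, 0.078),
    ("CAL-2", "Fine-tune3", "YPEDILDKHLQRVWWFTDDHW", -52.9, 2.8, 0.010),
    ("CAL-3", "Fine-tune1", "YPEDILDKHLQRVEYYYFRWHH", -54.4, 3.2, 0.089),
    ("CAL-4", "Fine-tune2", "YPEDILDKHLQRVFVWCDDE", -55.3, 4.6, 0.070),
    ("CAL-6", "Fine-tune2", "YPEDILDKHLQRVILYYYIIG", -49.1, 4.7, 0.24),
    ("CAL-9", "Fine-tune3", "YPEDILDKHLQRVILYYFSIE", -49.2, 3.3, 0.30),
    ("CAL-10", "Fine-tune2", "YPEDILDKHLQRVILFFC", -47.2, 3.8, 0.20),
    ("CAL-7", "Fine-tune3", "YPEDILDKHLQRVILFHFFCL", -47.9, 4.5, None),
    ("CAL-7err", "human-error", "YPEDILDKHLQRVILFHFCIL", None, None, 1.4),
]

# N-terminally extended NEMO binders (all Fine-tune3).
_NBD_ROWS = [
    ("NBD+1", "IKKSSTALDWSWLQTE", -19.2, 1.5, ">100"),
    ("NBD+2", "WSHSSHTALDWSWLQTE", -17.9, 1.1, 50.0),
    ("NBD+4", "LNQQQSSTALDWSWLQTE", -14.9, 1.2, ">100"),
    ("NBD+12", "LKSDDSSTALDWSWLQTE", -16.3, 1.1, 75.0),
]


def bcatenin_nterm_table() -> pd.DataFrame:
    """Top-10 N-terminal extension candidates with MM/GBSA and IC50 columns."""
    return pd.DataFrame(
        _NAL_ROWS,
        columns=[
            "name",
            "peptide",
            "flexpepdock_reu",
            "flexpepdock_sd",
            "mmgbsa",
            "mmgbsa_sd",
            "ic50_um",
        ],
    )


def bcatenin_cterm_table() -> pd.DataFrame:
    """Tested C-terminal extension candidates with model provenance."""
    return pd.DataFrame(
        _CAL_ROWS,
        columns=["name", "model", "peptide", "mmgbsa", "mmgbsa_sd", "ic50_um"],
    )


def nemo_table() -> pd.DataFrame:
    """Tested N-terminally extended NEMO-binding peptides."""
    return pd.DataFrame(
        _NBD_ROWS, columns=["name", "peptide", "mmgbsa", "mmgbsa_sd", "ic50_um"]
    )


def tested_ic50s() -> dict:
    """Name -> IC50 entry for every experimentally tested beta-catenin design."""
    out = {}
    for df in (bcatenin_nterm_table(), bcatenin_cterm_table()):
        for _, row in df.iterrows():
            entry = row["ic50_um"]
            if isinstance(entry, str) or (entry is not None and pd.notna(entry)):
                out[row["name"]] = entry
    return out


# One-bead-one-compound (OBOC) library combinatorics: four randomized
# N-terminal positions, each built from 29 amino-acid building blocks
# (7 proteinogenic, 12 alpha-D, 10 nonproteinogenic).
OBOC_BUILDING_BLOCKS = (
    "Gly", "Ala", "Ser", "Ile", "Asp", "Gln", "His",
    "D-Ala", "D-Pro", "D-Val", "D-Thr", "D-Leu", "D-Asn", "D-Lys",
    "D-Glu", "D-Phe", "D-Arg", "D-Tyr", "D-Trp",
    "beta-Ala", "D-beta-homoAla", "Pip", "cis-Acp", "Isa", "Phg",
    "D-Nal", "Fpa", "Nle", "Orn",
)
OBOC_RANDOM_POSITIONS = 4


def combinatorial_diversity(
    n_building_blocks: int = len(OBOC_BUILDING_BLOCKS),
    n_positions: int = OBOC_RANDOM_POSITIONS,
) -> int:
    """Theoretical diversity of a split-and-pool library: blocks ** positions."""
    if n_building_blocks < 1 or n_positions < 0:
        raise ValueError("need at least one building block and n_positions >= 0")
    return int(n_building_blocks) ** int(n_positions)
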