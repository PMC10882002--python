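"""Selection logic on the published beta-catenin / NEMO assay tables.

Applies the mean + 1 sigma MM/GBSA threshold to the ten N-terminal
candidates, counts IC50 improvements over both parent peptides, and prints
the combinatorial diversity of the chemically screened library.
"""

from pepex import reference_data as ref
from pepex.scoring import ScoreRecord, count_improved, mmgbsa_threshold, threshold_filter

threshold = mmgbsa_threshold(ref.CONTROL_MMGBSA_MEAN, ref.CONTROL_MMGBSA_SD)
print(f"MM/GBSA selection threshold: {threshold:.1f} kcal/mol "
      f"(controls {ref.CONTROL_MMGBSA_MEAN} +/- {ref.CONTROL_MMGBSA_SD})")

records = [
    ScoreRecord(row["name"], I_sc=row["flexpepdock_reu"], pep_sc=-1.0,
                I_bsa=200.0, rmsALL_if=-0.1, mmgbsa=row["mmgbsa"])
    for _, row in ref.bcatenin_nterm_table().iterrows()
]
kept, discarded = threshold_filter(records, threshold)
print(f"N-terminal candidates kept: {len(kept)}, discarded: "
      f"{sorted(discarded['peptide'])} (binding too weak for follow-up)")

n_improved = count_improved(ref.tested_ic50s(), ref.PARENT_IC50_UM)
print(f"beta-catenin designs with IC50 below the {ref.PARENT_IC50_UM} uM parent: {n_improved}")

nemo = dict(zip(ref.nemo_table()["name"], ref.nemo_table()["ic50_um"]))
n_nemo = count_improved(nemo, ref.PARENT_NBD_IC50_BOUND_UM)
print(f"NEMO designs improving on the weakly binding NBD parent: {n_nemo} of {len(nemo)}")

diversity = ref.combinatorial_diversity()
print(f"OBOC library diversity: {len(ref.OBOC_BUILDING_BLOCKS)} building blocks at "
      f"{ref.OBOC_RANDOM_POSITIONS} positions = {diversity:,} unique members")
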